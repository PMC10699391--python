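CORRECT                                          | INCORRECT
+3.00                                            | BFHR                                            
+2.75                                            | NORM UPFH                                       
+2.50                                            | PHYS RANZ                                       
+2.25 MHR UNCOM                                  | DECEL                                           
+2.00                                            | BFHR NORM                                       
+1.75 -------------------------------------------| PHYS RANZ UPFH----------------------------------
+1.50                                            | MHR UNCOM                                       
+1.25                                            | BFHR DECEL NORM                                 
+1.00                                            | PHYS UPFH                                       
+0.75 UNCOM                                      | MHR RANZ                                        
+0.50 BFHR                                       | DECEL                                           
+0.25 NORM PHYS                                  | UPFH                                            
+0.00 ===========================================| RANZ UNCOM======================================
-0.25 MHR                                        | DECEL                                           
-0.50 BFHR NORM UPFH                             |                                                 
-0.75 PHYS RANZ                                  |                                                 
-1.00 DECEL UNCOM                                | MHR                                             
-1.25 NORM                                       | BFHR                                            
-1.50 PHYS RANZ UPFH                             |                                                 
-1.75 MHR                                        | UNCOM                                           
-2.00 BFHR DECEL NORM                            |                                                 
-2.25 PHYS UPFH                                  |                                                 
-2.50 MHR RANZ UNCOM                             |                                                 
-2.75 BFHR DECEL                                 |                                                 
-3.00 NORM PHYS UPFH                             |                                                 
candidate C0001  ability +0.22  pass +1.76  flags: NORM:strength, PHYS:strength, UNCOM:weakness
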