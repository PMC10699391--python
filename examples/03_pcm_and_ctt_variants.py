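"""The partial-credit and classical-test-theory map variants.

Shows (1) how a polytomous item's score categories split across the map for
a candidate who earned partial credit, and (2) the facility-axis variant
that needs no Rasch scaling, plus practitioner-level classification.
"""

import numpy as np

from gimkit import (
    classify_practitioner_level,
    facility_axis_position,
    facility_table,
    make_fsep_fixture,
    map_pcm_to_gim,
    pcm_category_probability,
)
from gimkit.pcm import PcmItem

# --- partial credit: a 3-point item, candidate scored 2 of 3 ---------------
item = PcmItem("CTG-trace", "DECEL", thresholds=np.array([-0.8, 0.3, 1.6]))
placement = map_pcm_to_gim(2, item)
for c in placement.categories:
    side = "left (attained)" if c in placement.left else "right (not attained)"
    print(f"category {c.category}: {side} at {c.y:+.1f} logits")
# Categories 1 and 2 were attained so they sit on the left at their own
# threshold difficulties; category 3 was not and sits on the right.

probs = pcm_category_probability(0.5, item.thresholds)
print("category probabilities at theta=+0.5:",
      np.round(probs, 3).tolist())

# --- CTT variant: facility axis and practitioner levels --------------------
_, responses, _ = make_fsep_fixture(seed=7, n_persons=500)
records = facility_table(responses)
easiest = max(records, key=lambda r: r.facility)
hardest = min(records, key=lambda r: r.facility)
print(f"easiest item {easiest.item_id}: facility {easiest.facility:.1f}% "
      f"-> axis position {facility_axis_position(easiest.facility):.1f}")
print(f"hardest item {hardest.item_id}: facility {hardest.facility:.1f}% "
      f"-> axis position {facility_axis_position(hardest.facility):.1f}")
# The facility axis is inverted (100 - facility) so harder items sit higher,
# matching the logit map's orientation.

for pct in (50, 60, 70, 80):
    print(f"score {pct}% -> practitioner level {classify_practitioner_level(pct)}")
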