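"""Build one candidate's Graphical Item Map and render it.

Uses the anchored fixture bank (difficulties known in advance, as in
operational use), estimates the candidate's ability from their raw score,
converts the 75% pass mark to a logit pass line through the test
characteristic curve, and prints the finished map.
"""

from pathlib import Path

from gimkit import (
    LayoutConfig,
    build_gim,
    estimate_persons,
    make_fsep_fixture,
    render_svg,
    render_text,
)

bank, responses, _ = make_fsep_fixture(seed=42)
abilities = estimate_persons(responses, bank.difficulties())
config = LayoutConfig(pass_standard="75%")

layout = build_gim("C0001", responses, bank, abilities, config)
print(render_text(layout, width=100))
# Left of the axis: items answered correctly; right: incorrectly.  Height is
# Rasch difficulty in logits (harder is higher).  "=" marks the candidate's
# ability, "-" the pass standard; incorrect items BELOW the pass line are the
# priority-revision zone.  Flags summarise per-cluster strengths/weaknesses.

counts = layout.quadrant_counts()
print("quadrant counts:", {q.value: n for q, n in counts.items()})

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
(out / "C0001_gim.svg").write_text(render_svg(layout))
print(f"SVG written to {out / 'C0001_gim.svg'}")
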