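"""Score FAFHES questionnaires and build the dyad table.

Generates a small item-level sample with the synthetic generator, scores the
62 Likert items into the three scale sums, and pairs patients with their
nearest relatives into the wide analysis table.
"""

import dyadmed as dm
from dyadmed import scoring
from dyadmed.dyads import build_dyads, wide_frame

# 20 dyads of 62-item responses at the study's score regime
cfg = dm.default_config(n_dyads=20, seed=1)
items = dm.simulate_items(cfg)
print(f"item table: {len(items)} respondents x {items.shape[1] - 3} items")

responses = [
    scoring.FafhesResponse(
        respondent_id=r["respondent_id"], dyad_id=r["dyad_id"], role=r["role"],
        items=tuple(int(r[f"item_{i:02d}"]) for i in range(1, 63)))
    for _, r in items.iterrows()
]
report = dm.validate_batch(responses)
print(f"validation: {report.n_flagged} flagged, {len(report.valid)} valid")

scored = scoring.scores_frame([dm.score_fafhes(r) for r in report.valid])
dyads = build_dyads(scored)
print(f"dyads built: {dyads.n} retained, {len(dyads.exclusions)} excluded")
print(wide_frame(dyads).head(3).round(1).to_string(index=False))
# Columns x1/x2 are patient/relative social support (range 20-120), m family
# health (23-138), y family functioning (19-114); one row per dyad.
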