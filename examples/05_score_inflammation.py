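"""Inflammation scoring, remission rules and abundance patterns.

Scores pseudobulked samples for enrichment of an inflammation gene
signature (0-10 scale, cutoff at the maximum reference-sample score),
applies the two-of-three remission rules, and classifies a few
longitudinal abundance outcomes into the six-pattern taxonomy.
"""

from gepatlas import AtlasConfig, generate_atlas
from gepatlas.preprocess import pseudobulk
from gepatlas.scoring import (
    classify_pattern,
    classify_remission_cd,
    classify_remission_uc,
    inflammation_score,
)

sig = tuple(f"G{i:04d}" for i in range(200, 220))
cfg = AtlasConfig(signature_genes=sig, signature_effect=2.0, seed=1)
adata, meta, _ = generate_atlas(cfg)

pb = pseudobulk(adata)
reference = meta.loc[~meta["inflamed"], "sample_id"].tolist()
scores = inflammation_score(pb, list(sig), healthy_ids=reference)
by_status = scores.scores.join(meta.set_index("sample_id")["inflamed"])
print(by_status.groupby("inflamed")["scaled"].mean().round(2))
print(f"cutoff (max reference score): {scores.cutoff:.2f}")
flagged = by_status[by_status["above_cutoff"]]
print(f"samples above cutoff: {len(flagged)}, "
      f"of which inflamed: {int(flagged['inflamed'].sum())}")

# remission: two-of-three over clinical / endoscopic / histological indices
print("CD, HBI=4 ulcers Nancy=1 ->",
      classify_remission_cd(hbi=4, ulcers_present=True, nancy=1))
print("UC, SSCAI=5 UCEIS=4 Nancy=2 ->",
      classify_remission_uc(sscai=5, uceis=4, nancy=2))

# longitudinal abundance patterns from upstream test outcomes
print("no baseline diff, falls in remission only ->",
      classify_pattern("none", "down", "none"))       # pattern 1
print("higher at baseline in remission, then falls ->",
      classify_pattern("higher_in_R", "down", "none"))  # pattern 3
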