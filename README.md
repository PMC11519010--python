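# gepatlas

Tools for the computational core of a longitudinal single-cell therapeutic
atlas: deriving **gene expression programmes** (GEPs) by consensus
non-negative matrix factorisation, finding **hubs** of covarying
programmes with a permutation test on a signed correlation network,
computing a composite **0–10 inflammation score**, classifying
**remission** and longitudinal **abundance patterns**, and **projecting**
GEP spectra onto bulk or spatial expression. It is written for analysts of
inflammatory-disease cohorts (IBD and related immune-mediated diseases)
who work with cells × genes count matrices and per-sample clinical
metadata, and it ships a synthetic-atlas generator with planted ground
truth so every stage can be validated without access to patient data.

## The models in brief

**GEPs.** A count matrix `X` (N cells × M genes) is factorised as
`X ≈ W H` with `W ≥ 0` (N × k usages) and `H ≥ 0` (k × M spectra).
Factorisation is repeated from many random initialisations; pooled,
L2-normalised spectra are cleaned of outlier components by
nearest-neighbour distance, clustered into k groups, and each group's
median becomes a consensus spectrum. Usages are refit by non-negative
least squares against the fixed consensus. k is selected by silhouette of
the pooled-spectra clustering with Frobenius error as tie-breaker. Gene
scores are joint least-squares coefficients of z-scored expression on all
usages.

**Hubs.** Per sample, a GEP's activity is summarised at usage quantiles
(0.25, 0.5, 0.75, 0.95, 0.99) over the cells of its own compartment. For
each GEP pair the statistic is the mean over quantiles of
`atanh(Pearson r)` across samples; its null comes from shuffling cells'
sample labels within compartments (10,000 permutations), with two-sided
p = `2·min(#above, #below)/n_perm` and BH correction at FDR 10%.
Significant edges form a signed weighted network whose communities —
the hubs — are found by a resolution-swept signed Leiden search
(resolutions 0.001–0.2, consensus threshold tau = 0.2) with iterative
splitting of hubs larger than three nodes when it improves signed
modularity. A hub is *inflammatory* if more than half its members are
significantly enriched in inflamed samples (mixed-model association with
a patient random intercept).

**Scoring.** The inflammation score is a single-sample rank-based
enrichment of a signature gene set in pseudobulk profiles, min–max scaled
to 0–10 across the cohort, with the maximum healthy-sample score as
cutoff. Remission is two-of-three over clinical/endoscopic/histological
indices (CD: HBI < 5, no ulcers, Nancy ≤ 1; UC: SSCAI ≤ 2, UCEIS ≤ 1,
Nancy ≤ 1), with biologic escalation forcing nonremission.

**Projection.** External samples are projected onto fixed spectra by
per-sample NNLS over shared genes: `w = argmin_{w≥0} ‖x − wH‖₂`.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from gepatlas import AtlasConfig, generate_atlas
from gepatlas.hubs import permutation_null, build_signed_network, detect_hubs

cfg = AtlasConfig(within_hub_usage_correlation=0.7, seed=1)
adata, meta, truth = generate_atlas(cfg)          # 3,200 cells, 40 samples
W = pd.DataFrame(truth.W_true, index=adata.obs_names, columns=truth.gep_ids)

edges = permutation_null(W, adata.obs, truth.gep_compartments,
                         n_perm=1000, seed=2)
part = detect_hubs(build_signed_network(edges), seed=3)
nodes = sorted(part.assignment)
print("significant edges:", int(edges["significant"].sum()), "of", len(edges))
print("hubs:", part.hubs())
print("ARI vs planted:", adjusted_rand_score(
    [truth.hub_assignment_true[n] for n in nodes],
    [part.assignment[n] for n in nodes]))
```

prints

```
significant edges: 28 of 66
hubs: {0: ['pEP01', 'pEP04', 'pMY01', 'pMY04'],
       1: ['pEP02', 'pEP05', 'pMY02', 'pMY05'],
       2: ['pEP03', 'pEP06', 'pMY03', 'pMY06']}
ARI vs planted: 1.0
```

The 28 network edges are the GEP pairs whose per-sample activities covary
beyond the stratified permutation null at FDR 10%; the three detected hubs
reproduce the planted hub assignment exactly (adjusted Rand index 1.0).
The scripts in `examples/` walk through each capability — simulation,
preprocessing, GEP discovery, hub detection, scoring, projection — each
printing the quantities it computes and what they mean.

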