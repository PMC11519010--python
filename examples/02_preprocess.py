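"""Quality control, TP10K log-normalisation and pseudobulking.

Filters cells by detected genes and mitochondrial fraction, drops rarely
detected genes, normalises each cell to 10,000 counts before log1p, and
sums counts per sample.
"""

from gepatlas import AtlasConfig, generate_atlas
from gepatlas.preprocess import (
    filter_cells,
    filter_genes,
    normalize_tp10k_log,
    pseudobulk,
)

adata, sample_meta, _ = generate_atlas(AtlasConfig(seed=1))

# the synthetic universe has 400 genes, so the detected-gene threshold is
# scaled down from the 500 used on genome-wide data
qc = filter_genes(filter_cells(adata, min_genes=50, max_mito=0.60), min_cells=3)
print(f"cells {adata.n_obs} -> {qc.n_obs}, genes {adata.n_vars} -> {qc.n_vars}")

X = normalize_tp10k_log(qc)
print(f"normalised entry range: [{X.min():.3f}, {X.max():.3f}]")

pb = pseudobulk(qc)
print(f"pseudobulk: {pb.shape[0]} samples x {pb.shape[1]} genes; "
      f"total counts conserved: {pb.to_numpy().sum() == qc.X.sum()}")
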