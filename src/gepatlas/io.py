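"""Reading and writing the pipeline's on-disk formats.

Counts travel as Matrix Market triplets with gene/barcode TSVs (10x
convention: genes x cells on disk); metadata and result tables as TSV;
planted ground truth as an HDF5 container of named arrays.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

from .synthetic import GroundTruth

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_ground_truth",
    "read_ground_truth",
]


def write_counts_mtx(adata: AnnData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(str(out / "matrix.mtx"), X.T.tocoo())  # genes x cells on disk
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(out / "cell_meta.tsv", sep="\t")


def read_counts_mtx(in_dir: str | Path) -> AnnData:
    ind = Path(in_dir)
    X = sio.mmread(str(ind / "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(ind / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(ind / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(ind / "cell_meta.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = AnnData(
        X=X,
        obs=obs.loc[barcodes],
        var=pd.DataFrame(index=pd.Index(genes, name=None)),
    )
    return adata


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("H_true", data=truth.H_true)
        f.create_dataset("W_true", data=truth.W_true)
        str_dt = h5py.string_dtype()
        f.create_dataset("gep_ids", data=np.array(truth.gep_ids, dtype=object),
                         dtype=str_dt)
        f.create_dataset(
            "gep_compartments",
            data=np.array([truth.gep_compartments[g] for g in truth.gep_ids],
                          dtype=object),
            dtype=str_dt,
        )
        f.create_dataset(
            "hub_assignment",
            data=np.array(
                [truth.hub_assignment_true.get(g, -1) for g in truth.gep_ids]
            ),
        )
        f.create_dataset(
            "inflamed_sample_ids",
            data=np.array(truth.inflamed_sample_ids, dtype=object),
            dtype=str_dt,
        )


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        gep_ids = [s.decode() for s in f["gep_ids"][:]]
        comps = [s.decode() for s in f["gep_compartments"][:]]
        hub = {g: int(h) for g, h in zip(gep_ids, f["hub_assignment"][:]) if h >= 0}
        return GroundTruth(
            H_true=f["H_true"][:],
            W_true=f["W_true"][:],
            gep_ids=gep_ids,
            gep_compartments=dict(zip(gep_ids, comps)),
            hub_assignment_true=hub,
            inflamed_sample_ids=[s.decode() for s in f["inflamed_sample_ids"][:]],
            remission_labels={},
        )
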