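"""Synthetic single-cell atlases with planted ground truth.

Every downstream stage of the pipeline (consensus factorisation, hub
discovery, inflammation scoring, projection) is exercised against data
generated here, where the gene-expression-programme (GEP) spectra, per-cell
usages, hub structure and inflammation effects are all known exactly.

The generative model, briefly:

* Each cell compartment carries ``k_true`` GEPs. A GEP's spectrum is a
  non-negative gene-weight vector with a dedicated block of signal genes on
  top of a flat baseline.
* Per sample and GEP, a latent log-activity is drawn from a Gaussian factor
  model: GEPs assigned to the same hub share a per-sample latent factor, so
  their sample-level mean usages correlate at a configurable level.
* Per cell, GEP usages are Gamma draws around the sample-level activity;
  gene counts are Dirichlet-multinomial around ``usage x spectra`` given a
  drawn library size, so total counts per cell equal the library size
  exactly while per-gene marginals are overdispersed (negative-binomial
  like). As ``noise_dispersion`` grows the Dirichlet collapses and the
  count model approaches a plain multinomial (Poisson limit).
* Inflamed samples shift the latent activity of designated GEPs upward and
  inflate the rates of designated signature genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "AtlasConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_bulk_from_geps",
]

#: Gamma shape for per-cell usage around the sample-level mean
_USAGE_SHAPE = 4.0
#: number of mitochondrial genes prefixed ``MT-`` placed at the start of var
_N_MITO = 5


@dataclass
class AtlasConfig:
    """Configuration of a planted-truth synthetic atlas.

    Defaults describe the standard study conditions used throughout the
    test-suite: 20 patients sampled twice (pre/post treatment), two
    compartments with six GEPs each organised into three hubs spanning the
    compartments, within-hub sample-level usage correlation 0.7, and half
    of all samples inflamed.
    """

    n_patients: int = 20
    samples_per_patient: int = 2
    cells_per_sample: int = 40  # per compartment
    n_genes: int = 400
    compartments: Sequence[str] = ("epithelial", "myeloid")
    k_true: int = 6  # GEPs per compartment
    hub_assignment_true: Mapping[str, int] | None = None  # gep_id -> hub id
    within_hub_usage_correlation: float = 0.7
    inflamed_fraction: float = 0.5
    inflammation_effect_geps: Sequence[str] = ()
    inflammation_effect_size: float = 1.0  # latent log-activity shift
    signature_genes: Sequence[str] = ()
    signature_effect: float = 2.0  # multiplicative rate bump in inflamed samples
    #: spread (log scale) of per-sample GEP activity around its global mean;
    #: 0 makes cells exchangeable across samples (the permutation-test null)
    sample_heterogeneity_sd: float = 0.6
    noise_dispersion: float = 1000.0  # Dirichlet concentration; np.inf -> multinomial
    mean_library_size: int = 2000
    remission_fraction: float = 0.5
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.n_patients * self.samples_per_patient

    @property
    def k_total(self) -> int:
        return self.k_true * len(self.compartments)

    def gep_ids(self) -> list[str]:
        """GEP identifiers ``p<COMPARTMENT-PREFIX><NN>``, e.g. ``pEP01``."""
        ids = []
        for comp in self.compartments:
            prefix = comp[:2].upper()
            ids.extend(f"p{prefix}{i + 1:02d}" for i in range(self.k_true))
        return ids

    def gep_compartments(self) -> dict[str, str]:
        out = {}
        for comp in self.compartments:
            prefix = comp[:2].upper()
            for i in range(self.k_true):
                out[f"p{prefix}{i + 1:02d}"] = comp
        return out

    def resolved_hub_assignment(self) -> dict[str, int]:
        """Explicit hub map, defaulting to three interleaved hubs."""
        if self.hub_assignment_true is not None:
            return dict(self.hub_assignment_true)
        ids = self.gep_ids()
        return {g: i % 3 for i, g in enumerate(ids)}

    def validate(self) -> None:
        if self.k_true < 2:
            raise ValueError("invalid config: k_true must be >= 2")
        if self.n_genes < 10 * self.k_true:
            raise ValueError("invalid config: n_genes must be >= 10 * k_true")
        if not 0 <= self.within_hub_usage_correlation < 1:
            raise ValueError(
                "invalid config: within_hub_usage_correlation must lie in [0, 1)"
            )
        if not 0 < self.inflamed_fraction < 1:
            raise ValueError("invalid config: inflamed_fraction must lie in (0, 1)")
        if not self.noise_dispersion > 0:
            raise ValueError("invalid config: noise_dispersion must be positive")
        if self.sample_heterogeneity_sd < 0:
            raise ValueError("invalid config: sample_heterogeneity_sd must be >= 0")
        ids = set(self.gep_ids())
        hub = self.resolved_hub_assignment()
        if set(hub) - ids:
            raise ValueError(
                "invalid config: hub_assignment_true names unknown GEPs "
                f"{sorted(set(hub) - ids)}"
            )
        unknown = set(self.inflammation_effect_geps) - ids
        if unknown:
            raise ValueError(
                f"invalid config: inflammation_effect_geps not in atlas: {sorted(unknown)}"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    H_true: np.ndarray  # k_total x n_genes, rows sum to 1
    W_true: np.ndarray  # cells x k_total (zero outside a cell's compartment)
    gep_ids: list[str]
    gep_compartments: dict[str, str]
    hub_assignment_true: dict[str, int]
    inflamed_sample_ids: list[str]
    remission_labels: dict[str, bool]  # patient_id -> in remission
    sample_mean_usage: pd.DataFrame = field(repr=False, default=None)


def _make_spectra(cfg: AtlasConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-structured spectra: flat baseline plus a disjoint signal block
    per GEP. Mito genes get extra baseline so every cell has a nonzero
    mitochondrial fraction."""
    k, g = cfg.k_total, cfg.n_genes
    H = np.full((k, g), 0.3)
    block = max(5, (g - _N_MITO) // (2 * k))
    for j in range(k):
        lo = _N_MITO + j * block
        hi = min(lo + block, g)
        H[j, lo:hi] += rng.uniform(5.0, 12.0, size=hi - lo)
    H[:, :_N_MITO] += 2.0
    return H / H.sum(axis=1, keepdims=True)


def _sample_metadata(cfg: AtlasConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    patients = [f"PT{p + 1:02d}" for p in range(cfg.n_patients)]
    sample_ids, patient_ids, timepoints = [], [], []
    for p in patients:
        for s in range(cfg.samples_per_patient):
            sample_ids.append(f"{p}_S{s + 1}")
            patient_ids.append(p)
            timepoints.append("pre" if s % 2 == 0 else "post")
    n_inflamed = int(round(cfg.inflamed_fraction * n))
    inflamed = np.zeros(n, dtype=bool)
    inflamed[rng.choice(n, size=n_inflamed, replace=False)] = True

    disease_by_patient = {
        p: rng.choice(["CD", "UC"]) for p in patients
    }
    remission_by_patient = {
        p: bool(rng.random() < cfg.remission_fraction) for p in patients
    }
    sex_by_patient = {p: rng.choice(["F", "M"]) for p in patients}
    age_by_patient = {p: int(rng.integers(18, 75)) for p in patients}
    dur_by_patient = {p: float(np.round(rng.gamma(2.0, 3.0), 1)) for p in patients}

    rows = []
    for i, (sid, pid, tp) in enumerate(zip(sample_ids, patient_ids, timepoints)):
        infl = bool(inflamed[i])
        # clinical indices drawn conditional on inflammation status
        hbi = int(rng.poisson(7 if infl else 2))
        sscai = int(rng.poisson(5 if infl else 1))
        uceis = int(rng.integers(3, 8) if infl else rng.integers(0, 2))
        nancy = int(rng.integers(2, 5) if infl else rng.integers(0, 2))
        rows.append(
            {
                "sample_id": sid,
                "patient_id": pid,
                "disease": disease_by_patient[pid],
                "site": rng.choice(["TI", "AC", "DC", "R"]),
                "inflamed": infl,
                "timepoint": tp,
                "age": age_by_patient[pid],
                "sex": sex_by_patient[pid],
                "disease_duration": dur_by_patient[pid],
                "HBI": hbi,
                "SSCAI": sscai,
                "UCEIS": uceis,
                "Nancy": nancy,
                "ulcers_present": bool(infl and rng.random() < 0.7),
                "treatment": tp,
                "remission": remission_by_patient[pid],
            }
        )
    return pd.DataFrame(rows)


def generate_atlas(
    config: AtlasConfig,
) -> tuple[AnnData, pd.DataFrame, GroundTruth]:
    """Generate a compartment-structured UMI-count atlas with planted truth.

    Returns
    -------
    adata
        cells x genes sparse counts; ``obs`` carries ``sample_id``,
        ``patient_id``, ``compartment``, ``mito_fraction`` and
        ``n_genes_detected``.
    sample_meta
        one row per sample with clinical covariates and inflammation labels.
    truth
        planted spectra, usages, hub map and effect labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    gep_ids = cfg.gep_ids()
    gep_comp = cfg.gep_compartments()
    hub = cfg.resolved_hub_assignment()
    hub_ids = sorted(set(hub.values()))

    H = _make_spectra(cfg, rng)
    meta = _sample_metadata(cfg, rng)
    n_samples = len(meta)
    inflamed = meta["inflamed"].to_numpy()

    # --- per-sample latent log-activity with hub-shared factors ---------
    rho = cfg.within_hub_usage_correlation
    hub_factor = rng.standard_normal((n_samples, len(hub_ids)))
    eps = rng.standard_normal((n_samples, cfg.k_total))
    hub_col = np.array([hub_ids.index(hub[g]) if g in hub else -1 for g in gep_ids])
    shared = np.where(
        hub_col[None, :] >= 0, hub_factor[:, np.clip(hub_col, 0, None)], 0.0
    )
    latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    effect_idx = [gep_ids.index(g) for g in cfg.inflammation_effect_geps]
    if effect_idx:
        latent[np.ix_(inflamed.nonzero()[0], effect_idx)] += cfg.inflammation_effect_size
    # per-sample mean usage scale; sd 0 collapses samples to a common mean
    sample_activity = np.exp(cfg.sample_heterogeneity_sd * latent)

    gene_names = [f"MT-G{i + 1}" for i in range(_N_MITO)] + [
        f"G{i + 1:04d}" for i in range(cfg.n_genes - _N_MITO)
    ]
    sig_idx = np.array(
        [gene_names.index(g) for g in cfg.signature_genes], dtype=int
    )

    n_cells = n_samples * cfg.cells_per_sample * len(cfg.compartments)
    counts = np.zeros((n_cells, cfg.n_genes), dtype=np.int64)
    W_true = np.zeros((n_cells, cfg.k_total))
    lib_sizes = np.zeros(n_cells, dtype=np.int64)
    cell_samples, cell_patients, cell_comps = [], [], []

    comp_slices = {
        comp: slice(ci * cfg.k_true, (ci + 1) * cfg.k_true)
        for ci, comp in enumerate(cfg.compartments)
    }

    row = 0
    for si in range(n_samples):
        sid = meta.loc[si, "sample_id"]
        pid = meta.loc[si, "patient_id"]
        for comp in cfg.compartments:
            ksl = comp_slices[comp]
            mean_usage = sample_activity[si, ksl]
            n_c = cfg.cells_per_sample
            w = rng.gamma(
                _USAGE_SHAPE, mean_usage / _USAGE_SHAPE, size=(n_c, cfg.k_true)
            )
            W_true[row : row + n_c, ksl] = w
            rates = w @ H[ksl]  # n_c x genes
            if sig_idx.size and inflamed[si]:
                rates[:, sig_idx] *= 1.0 + cfg.signature_effect
            probs = rates / rates.sum(axis=1, keepdims=True)
            lib = rng.poisson(cfg.mean_library_size, size=n_c)
            lib_sizes[row : row + n_c] = lib
            for c in range(n_c):
                p = probs[c]
                if np.isfinite(cfg.noise_dispersion):
                    p = rng.dirichlet(cfg.noise_dispersion * p)
                counts[row + c] = rng.multinomial(lib[c], p)
            cell_samples.extend([sid] * n_c)
            cell_patients.extend([pid] * n_c)
            cell_comps.extend([comp] * n_c)
            row += n_c

    totals = counts.sum(axis=1)
    mito = counts[:, :_N_MITO].sum(axis=1)
    obs = pd.DataFrame(
        {
            "sample_id": cell_samples,
            "patient_id": cell_patients,
            "compartment": cell_comps,
            "library_size": lib_sizes,
            "mito_fraction": np.divide(
                mito, totals, out=np.zeros_like(mito, dtype=float), where=totals > 0
            ),
            "n_genes_detected": (counts > 0).sum(axis=1),
        },
        index=[f"cell{i:06d}" for i in range(n_cells)],
    )
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )

    mean_usage_df = pd.DataFrame(
        sample_activity, index=meta["sample_id"], columns=gep_ids
    )
    truth = GroundTruth(
        H_true=H,
        W_true=W_true,
        gep_ids=gep_ids,
        gep_compartments=gep_comp,
        hub_assignment_true=hub,
        inflamed_sample_ids=meta.loc[meta["inflamed"], "sample_id"].tolist(),
        remission_labels=dict(
            meta.drop_duplicates("patient_id")[["patient_id", "remission"]].itertuples(
                index=False, name=None
            )
        ),
        sample_mean_usage=mean_usage_df,
    )
    return adata, meta, truth


def generate_bulk_from_geps(
    H_true: np.ndarray,
    n_samples: int,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bulk expression profiles as noisy non-negative mixtures of spectra.

    ``bulk = W_bulk_true @ H_true + noise`` with Gaussian noise truncated at
    zero; ``W_bulk_true`` (samples x k, Gamma-distributed) is returned so
    projection can be validated against it.
    """
    H_true = np.asarray(H_true, dtype=float)
    if (H_true < 0).any():
        raise ValueError("H_true must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    k = H_true.shape[0]
    W_bulk = rng.gamma(2.0, 1.0, size=(n_samples, k))
    bulk = W_bulk @ H_true
    if noise_sd > 0:
        bulk = np.clip(bulk + rng.normal(0.0, noise_sd, size=bulk.shape), 0.0, None)
    return bulk, W_bulk
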