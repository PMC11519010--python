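"""Inflammation scoring, remission classification and longitudinal
abundance patterns.

The inflammation score is a single-sample rank-based enrichment of an
inflammation gene signature in per-sample pseudobulk profiles, min-max
scaled to 0-10 across the scored cohort; the maximum score among healthy
samples serves as a heuristic inflamed/noninflamed cutoff. Remission is a
two-of-three rule over clinical, endoscopic and histological indices
(HBI / ulcers / Nancy for CD; SSCAI / UCEIS / Nancy for UC), with
escalation to another biologic forcing nonremission. Post-treatment
abundance changes are organised into six qualitative patterns from the
outcomes of baseline-difference and within-group change tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import rankdata

from .hubs import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "InflammationScores",
    "ssgsea_score",
    "inflammation_score",
    "classify_remission_cd",
    "classify_remission_uc",
    "classify_pattern",
    "abundance_change_test",
]


@dataclass
class InflammationScores:
    scores: pd.DataFrame  # sample_id index; raw, scaled, is_healthy, above_cutoff
    cutoff: float
    healthy_sample_ids: list[str]


def ssgsea_score(expr: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """Single-sample enrichment of a gene set in one expression profile.

    Genes are ranked by expression (ties averaged) and walked from the
    highest rank down; signature genes advance a weighted running sum
    (weight ``rank**alpha``), other genes advance a uniform one. The score
    is the sum of the running differences — the area between the two
    empirical CDFs — so it depends on the profile only through ranks.
    """
    n = expr.size
    ranks = rankdata(expr)  # 1 = lowest expression
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    w = ranks[order] ** alpha
    step_in = np.where(in_ordered, w, 0.0)
    denom_in = step_in.sum()
    if denom_in == 0:
        raise ValueError("signature genes absent from the expression profile")
    step_out = np.where(~in_ordered, 1.0, 0.0)
    cdf_in = np.cumsum(step_in) / denom_in
    cdf_out = np.cumsum(step_out) / max(n - int(in_set.sum()), 1)
    return float(np.sum(cdf_in - cdf_out))


def inflammation_score(
    pseudobulk: pd.DataFrame,
    signature: list[str],
    healthy_ids: list[str],
    alpha: float = 0.25,
) -> InflammationScores:
    """Score samples for signature enrichment and scale to 0-10.

    Scaling is cohort-relative (min score 0, max score 10 within the scored
    cohort), so scores are only comparable within one scored cohort. The
    cutoff is the maximum scaled score among the healthy samples.
    """
    if len(pseudobulk) < 2:
        raise ValueError("need at least 2 samples to scale scores")
    if not set(healthy_ids) & set(pseudobulk.index):
        raise ValueError("no healthy samples present in the cohort")
    sig = pd.unique(pd.Series(signature))
    in_set = pseudobulk.columns.isin(sig)
    if not in_set.any():
        raise ValueError("signature is disjoint from the measured genes")
    if in_set.sum() < len(sig):
        logger.warning(
            "%d signature genes not measured", len(sig) - int(in_set.sum())
        )
    X = pseudobulk.to_numpy(dtype=float)
    raw = np.array([ssgsea_score(X[i], in_set, alpha=alpha) for i in range(len(X))])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("all samples score identically; cannot scale to 0-10")
    scaled = 10.0 * (raw - lo) / (hi - lo)
    is_healthy = pseudobulk.index.isin(healthy_ids)
    cutoff = float(scaled[is_healthy].max())
    df = pd.DataFrame(
        {
            "raw": raw,
            "scaled": scaled,
            "is_healthy": is_healthy,
            "above_cutoff": scaled > cutoff,
        },
        index=pseudobulk.index,
    )
    return InflammationScores(
        scores=df, cutoff=cutoff, healthy_sample_ids=list(healthy_ids)
    )


def _two_of_three(criteria: tuple[bool, bool, bool], escalated: bool) -> bool:
    if escalated:
        return False
    return sum(criteria) >= 2


def _check_index(name: str, value: float) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"{name} is missing; remission unevaluable")
    if value < 0:
        raise ValueError(f"{name} must be non-negative")
    return value


def classify_remission_cd(
    hbi: float, ulcers_present: bool, nancy: float, escalated: bool = False
) -> bool:
    """CD remission: two of three of HBI < 5, no macroscopic ulcers,
    Nancy <= 1 at follow-up; escalation to another biologic forces
    nonremission."""
    hbi = _check_index("HBI", hbi)
    nancy = _check_index("Nancy", nancy)
    return _two_of_three((hbi < 5, not ulcers_present, nancy <= 1), escalated)


def classify_remission_uc(
    sscai: float, uceis: float, nancy: float, escalated: bool = False
) -> bool:
    """UC remission: two of three of SSCAI <= 2, UCEIS <= 1, Nancy <= 1."""
    sscai = _check_index("SSCAI", sscai)
    uceis = _check_index("UCEIS", uceis)
    nancy = _check_index("Nancy", nancy)
    return _two_of_three((sscai <= 2, uceis <= 1, nancy <= 1), escalated)


_BASELINE = {"higher_in_R", "higher_in_NR", "none"}
_CHANGE = {"up", "down", "none"}


def classify_pattern(
    baseline_diff: str, change_R: str, change_NR: str
) -> int | str:
    """Map test outcomes to one of six longitudinal abundance patterns.

    Inputs are categorical outcomes of upstream tests: the baseline
    remission-vs-nonremission difference and the significant direction of
    post-treatment change within each outcome group. Rules are evaluated in
    the order 3, 1, 4, 5, 6, 2 — baseline-difference patterns first, then
    concordant, then discordant — returning the first match, else
    ``"unclassified"``.
    """
    if baseline_diff not in _BASELINE:
        raise ValueError(f"invalid baseline_diff {baseline_diff!r}")
    if change_R not in _CHANGE or change_NR not in _CHANGE:
        raise ValueError("invalid change category")
    if baseline_diff == "higher_in_R" and change_R == "down":
        return 3
    if baseline_diff == "none" and change_R == "down" and change_NR == "none":
        return 1
    if change_R == "up" and change_NR == "up":
        return 4
    if change_R == "up" and change_NR == "none":
        return 5
    if baseline_diff == "none" and change_R == "none" and change_NR == "up":
        return 6
    if change_NR == "down" and change_R in ("none", "down"):
        return 2
    return "unclassified"


def abundance_change_test(
    cell_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    grouping: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-state differential abundance between two groups.

    ``cell_counts`` is samples x states (integer cell counts). Each state's
    per-sample proportion is modelled by a linear mixed model on the
    grouping indicator with a random intercept per patient (OLS fallback on
    convergence failure); directions are the sign of the group coefficient
    and significance is BH-controlled across states.
    """
    meta = sample_meta.set_index("sample_id").loc[cell_counts.index]
    groups = meta[grouping]
    levels = sorted(pd.unique(groups.dropna().astype(str)))
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    if (groups.value_counts() < 2).any():
        raise ValueError("need >= 2 samples per group")
    totals = cell_counts.sum(axis=1)
    props = cell_counts.div(totals, axis=0)

    rows = []
    for state in cell_counts.columns:
        df = pd.DataFrame(
            {
                "y": props[state],
                "grp": (groups.astype(str) == levels[1]).astype(int),
                "patient": meta["patient_id"],
            }
        )
        present = cell_counts[state].groupby(groups).sum()
        if (present == 0).any():
            rows.append({"state": state, "direction": 0, "p_value": np.nan,
                         "untestable": True})
            continue
        effect = p = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm("y ~ grp", df, groups=df["patient"]).fit(reml=False)
            if np.isfinite(res.pvalues.get("grp", np.nan)):
                effect, p = float(res.params["grp"]), float(res.pvalues["grp"])
        except Exception:
            pass
        if p is None:
            if df["y"].nunique() <= 1:  # constant proportions: no difference
                effect, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = smf.ols("y ~ grp", df).fit()
                effect, p = float(res.params["grp"]), float(res.pvalues["grp"])
        rows.append(
            {"state": state, "direction": int(np.sign(effect)), "p_value": p,
             "untestable": False}
        )
    out = pd.DataFrame(rows).set_index("state")
    testable = ~out["untestable"] & out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if testable.any():
        adj, _ = bh_adjust(out.loc[testable, "p_value"].to_numpy(), fdr=fdr)
        out.loc[testable, "p_adjusted"] = adj
    out["significant"] = (out["p_adjusted"] <= fdr).fillna(False)
    out.attrs["group_levels"] = levels  # direction +1 means higher in levels[1]
    return out
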