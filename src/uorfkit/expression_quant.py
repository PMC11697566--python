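"""Relative expression quantification: efficiency-corrected qPCR (Pfaffl),
dual-luciferase reporter normalization, and loading-control normalization.

All three normalizations share one convention: per-well (or per-reaction)
ratios are computed first, then every ratio is divided by the reference
group's mean ratio, so the reference group's mean is exactly 1 and all
values are dimensionless fold changes relative to control. When an
``experiment`` column is present, scaling is applied within each
independent experiment before pooling (the default); a single pooled
scaling is available via ``per_experiment=False``.

The Pfaffl ratio uses assay-specific amplification efficiencies E
(amplification factor per cycle, 1 < E <= 2.2, experimentally determined
upstream, e.g. by LinRegPCR — efficiency estimation is an input here):

    ratio = E_target ** dCq_target / E_ref ** dCq_ref,   dCq = Cq_control - Cq_treated

With E_target = E_ref = 2 this reduces to the classic Livak 2^-ddCq form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrAssay",
    "RatioResult",
    "pfaffl_ratio",
    "dlr_normalize",
    "loading_normalize",
    "ratio_normalize",
    "group_summary",
    "ttest_vs_reference",
    "anova_tukey",
]

logger = logging.getLogger(__name__)


@dataclass
class QpcrAssay:
    """One qPCR assay: name, per-cycle amplification efficiency E, and
    replicate Cq values keyed by sample/group label."""

    name: str
    efficiency: float
    cq: dict[str, list[float]]

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(f"{self.name}: efficiency must be in (1, 2.2]")
        for label, values in self.cq.items():
            if any(v <= 0 or not np.isfinite(v) for v in values):
                raise ValueError(f"{self.name}/{label}: Cq values must be positive and finite")

    def mean_cq(self, label: str) -> float:
        return float(np.mean(self.cq[label]))


@dataclass(frozen=True)
class RatioResult:
    """Per-group relative value (reference group mean == 1) with SD."""

    label: str
    value: float
    dispersion: float
    n: int


def pfaffl_ratio(
    e_target: float,
    cq_target_control,
    cq_target_treated,
    e_ref: float,
    cq_ref_control,
    cq_ref_treated,
) -> float:
    """Efficiency-corrected relative expression of target vs reference.

    Replicate Cq values (sequences) are averaged on the Cq scale before
    exponentiation.
    """
    for e in (e_target, e_ref):
        if e <= 1.0:
            raise ValueError(f"amplification efficiency must exceed 1, got {e}")
    cqs = [np.atleast_1d(np.asarray(c, dtype=float))
           for c in (cq_target_control, cq_target_treated, cq_ref_control, cq_ref_treated)]
    if any(not np.all(np.isfinite(c)) for c in cqs):
        raise ValueError("Cq values must be finite")
    d_target = cqs[0].mean() - cqs[1].mean()
    d_ref = cqs[2].mean() - cqs[3].mean()
    return float(e_target**d_target / e_ref**d_ref)


def ratio_normalize(
    rows: pd.DataFrame,
    numerator: str,
    denominator: str,
    reference_group: str,
    group_col: str = "group",
    experiment_col: str = "experiment",
    per_experiment: bool = True,
) -> pd.DataFrame:
    """Shared engine for DLR and loading-control normalization.

    Computes per-row numerator/denominator ratios and scales them so the
    reference group's mean is exactly 1 (within each experiment when an
    experiment column is present and ``per_experiment`` is set). Rows with
    missing values are dropped with a logged warning, never imputed.
    """
    df = rows.copy()
    required = [group_col, numerator, denominator]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns {missing_cols}")
    n_before = len(df)
    df = df.dropna(subset=[numerator, denominator])
    if len(df) < n_before:
        logger.warning("dropped %d rows with missing signals", n_before - len(df))
    if (df[denominator] <= 0).any():
        raise ValueError(f"{denominator} must be positive in every well")
    if reference_group not in set(df[group_col]):
        raise ValueError(f"reference group {reference_group!r} absent or empty")

    df["ratio"] = df[numerator] / df[denominator]

    def _scale(block: pd.DataFrame) -> pd.DataFrame:
        ref_mean = block.loc[block[group_col] == reference_group, "ratio"].mean()
        if not np.isfinite(ref_mean) or ref_mean <= 0:
            raise ValueError(f"reference group {reference_group!r} has no usable wells")
        block = block.copy()
        block["relative"] = block["ratio"] / ref_mean
        return block

    if per_experiment and experiment_col in df.columns:
        df = pd.concat(
            [_scale(block) for _, block in df.groupby(experiment_col, sort=False)],
            ignore_index=True,
        )
    else:
        df = _scale(df)
    return df


def dlr_normalize(
    rows: pd.DataFrame,
    reference_group: str,
    rluc_col: str = "rluc",
    fluc_col: str = "fluc",
    **kwargs,
) -> pd.DataFrame:
    """Dual-luciferase normalization: per-well Renilla/firefly ratios,
    scaled so the reference (e.g. wild-type control) group mean is 1."""
    return ratio_normalize(rows, rluc_col, fluc_col, reference_group, **kwargs)


def loading_normalize(
    rows: pd.DataFrame,
    reference_group: str,
    target_col: str = "target_signal",
    loading_col: str = "loading_signal",
    **kwargs,
) -> pd.DataFrame:
    """Western-blot style normalization of a target signal to a loading
    control (e.g. vinculin), scaled so the untreated group mean is 1."""
    return ratio_normalize(rows, target_col, loading_col, reference_group, **kwargs)


def group_summary(df: pd.DataFrame, group_col: str = "group") -> list[RatioResult]:
    """Mean +/- SD of the scaled relative values, one row per group."""
    out = []
    for label, block in df.groupby(group_col, sort=False):
        vals = block["relative"].to_numpy()
        out.append(RatioResult(str(label), float(vals.mean()),
                               float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, len(vals)))
    return out


# -- thin statistical reporting (stock routines, not bespoke math) -----


def ttest_vs_reference(df: pd.DataFrame, reference_group: str, group_col: str = "group",
                       paired: bool = False) -> pd.DataFrame:
    ref = df.loc[df[group_col] == reference_group, "relative"].to_numpy()
    rows = []
    for label, block in df.groupby(group_col, sort=False):
        if label == reference_group:
            continue
        vals = block["relative"].to_numpy()
        if paired:
            res = stats.ttest_rel(vals, ref)
        else:
            res = stats.ttest_ind(vals, ref)
        rows.append({"group": label, "t": res.statistic, "p": res.pvalue})
    return pd.DataFrame(rows)


def anova_tukey(df: pd.DataFrame, group_col: str = "group") -> dict:
    groups = [block["relative"].to_numpy() for _, block in df.groupby(group_col, sort=False)]
    labels = [str(label) for label, _ in df.groupby(group_col, sort=False)]
    f_res = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    pairs = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs[f"{labels[i]} vs {labels[j]}"] = float(tukey.pvalue[i, j])
    return {"anova_F": float(f_res.statistic), "anova_p": float(f_res.pvalue),
            "tukey_p": pairs}
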