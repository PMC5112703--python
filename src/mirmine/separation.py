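"""Phenotype-separation statistic d_Sep,norm for miR-mRNA associations.

For one association, each sample is a point in the (miR abundance, mRNA
abundance) plane.  The statistic is the Euclidean distance between the
high- and low-phenotype group centroids, normalised by the maximal possible
span

    d_Sep,max  = sqrt( (max[mRNA] - min[mRNA])^2 + (max[miR] - min[miR])^2 )
    d_Sep,norm = ||centroid_high - centroid_low|| / d_Sep,max

so d_Sep,norm lies in [0, 1].  Centroids are arithmetic means of the
labelled samples' log2 abundances (equivalently, geometric means on the
linear scale); the ranges in d_Sep,max are taken over *all* samples,
labelled or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panel import ExpressionMatrix

LABEL_VALUES = ("high", "low", "unknown")


@dataclass
class DSepResult:
    mir_id: str
    probe_id: str
    mu_mir_low: float
    mu_mir_high: float
    mu_mrna_low: float
    mu_mrna_high: float
    d_sep_max: float
    d_sep_norm: float
    rank_pct: float | None = None


def _check_labels(labels: pd.Series, samples: list[str]) -> pd.Series:
    labels = labels.reindex(samples).fillna("unknown")
    bad = set(labels.unique()) - set(LABEL_VALUES)
    if bad:
        raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("need at least one 'high' and one 'low' labelled sample")
    return labels


def d_sep_norm(
    mir_values: np.ndarray,
    mrna_values: np.ndarray,
    labels: pd.Series | list[str],
    mir_id: str = "",
    probe_id: str = "",
) -> DSepResult:
    """Phenotype separation of one miR-mRNA association.

    ``labels`` aligns positionally with the value vectors (or by index if a
    Series whose index matches is given).  Raises if either group is empty or
    both axes are constant (d_Sep,max = 0).
    """
    x = np.asarray(mir_values, dtype=float)
    y = np.asarray(mrna_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("mir_values and mrna_values must be equal-length vectors")
    lab = np.asarray(list(labels))
    if lab.shape != x.shape:
        raise ValueError("labels must align with the sample vectors")
    hi = lab == "high"
    lo = lab == "low"
    if not hi.any() or not lo.any():
        raise ValueError("need at least one sample per phenotype group")

    d_max = float(np.hypot(np.ptp(y), np.ptp(x)))
    if d_max == 0:
        raise ValueError("d_Sep,max is zero: both axes constant")
    mu_x_hi, mu_x_lo = float(x[hi].mean()), float(x[lo].mean())
    mu_y_hi, mu_y_lo = float(y[hi].mean()), float(y[lo].mean())
    d = float(np.hypot(mu_y_hi - mu_y_lo, mu_x_hi - mu_x_lo))
    return DSepResult(
        mir_id=mir_id, probe_id=probe_id,
        mu_mir_low=mu_x_lo, mu_mir_high=mu_x_hi,
        mu_mrna_low=mu_y_lo, mu_mrna_high=mu_y_hi,
        d_sep_max=d_max, d_sep_norm=d / d_max,
    )


def percentile_ranks(values) -> np.ndarray:
    """Mid-rank percentile of each value within the list, in [0, 100).

    rank_pct(v) = 100 * (#{u < v} + 0.5 * #{u == v}) / n, counting v itself
    among its ties, so distinct values map to (i + 0.5)/n * 100 and an
    all-tied list maps to 50 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    return (rankdata(v, method="average") - 0.5) / v.size * 100.0


def dsep_table(
    mir_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    labels: pd.Series,
) -> pd.DataFrame:
    """d_Sep,norm and its percentile rank for every retained miR x probe pair.

    The statistic factorises over per-feature group means and ranges, so the
    full pair table is assembled from per-feature statistics without looping
    over pairs.  Percentile ranks are computed across all pairs in the table
    (the associations that passed preprocessing).
    """
    if mir_m.sample_ids != mrna_m.sample_ids:
        raise ValueError("matrices must share an identical ordered sample list")
    lab = _check_labels(pd.Series(labels), mir_m.sample_ids)
    hi = (lab == "high").to_numpy()
    lo = (lab == "low").to_numpy()

    X, Y = mir_m.values, mrna_m.values
    dmu_x = X[:, hi].mean(axis=1) - X[:, lo].mean(axis=1)     # (n_mir,)
    dmu_y = Y[:, hi].mean(axis=1) - Y[:, lo].mean(axis=1)     # (n_probe,)
    range_x = np.ptp(X, axis=1)
    range_y = np.ptp(Y, axis=1)

    dist = np.hypot(dmu_x[:, None], dmu_y[None, :])
    dmax = np.hypot(range_x[:, None], range_y[None, :])
    if (dmax == 0).any():
        raise ValueError("d_Sep,max is zero for some pair (constant features)")
    dnorm = dist / dmax

    out = pd.DataFrame({
        "mir_id": np.repeat(mir_m.feature_ids, mrna_m.n_features),
        "probe_id": np.tile(mrna_m.feature_ids, mir_m.n_features),
        "d_sep_norm": dnorm.ravel(),
    })
    out["d_sep_rank_pct"] = percentile_ranks(out["d_sep_norm"].to_numpy())
    return out


def annotate_putative_with_dsep(
    putative: pd.DataFrame,
    dsep: pd.DataFrame,
) -> pd.DataFrame:
    """Fill the d_sep_norm / d_sep_rank_pct columns of a putative table."""
    merged = putative.drop(columns=["d_sep_norm", "d_sep_rank_pct"]).merge(
        dsep[["mir_id", "probe_id", "d_sep_norm", "d_sep_rank_pct"]],
        on=["mir_id", "probe_id"], how="left")
    return merged
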