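"""Expression-panel containers, IO, normalisation and feature filtering.

The unit of data throughout the package is a feature-by-sample matrix of
log2 abundances: miR read counts (log2, after normalisation) or microarray
probe intensities (log2, quantile-normalised).  Multiple probes per gene are
kept as distinct features; probe-to-gene collapsing happens only at the
database-matching stage.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FeatureKind = Literal["miR", "mRNA-probe"]

_VALID_KINDS = ("miR", "mRNA-probe")


@dataclass
class ExpressionMatrix:
    """Feature-by-sample abundance grid.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples, values are (log2) abundances.
    feature_kind : {"miR", "mRNA-probe"}
        What the rows measure.
    """

    data: pd.DataFrame
    feature_kind: FeatureKind

    def __post_init__(self) -> None:
        if self.feature_kind not in _VALID_KINDS:
            raise ValueError(f"feature_kind must be one of {_VALID_KINDS}, "
                             f"got {self.feature_kind!r}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.issubdtype(self.data.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: `feature_id` column followed by one column per sample."""
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass
class FilterReport:
    """Book-keeping for :func:`filter_features`.

    ``n_input == n_dropped_abundance + n_dropped_range + n_retained`` always
    holds; a feature failing both rules is charged to the abundance rule,
    which is applied first.
    """

    n_input: int
    n_dropped_abundance: int
    n_dropped_range: int
    n_retained: int
    thresholds_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.n_dropped_abundance + self.n_dropped_range + self.n_retained
        if total != self.n_input:
            raise ValueError("FilterReport counts do not reconcile: "
                             f"{self.n_input} != {total}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def read_expression(path: str | Path, feature_kind: FeatureKind) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = feature ids).

    Duplicate feature ids are disambiguated with ``.1``, ``.2`` ... suffixes
    (with a warning) rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"empty expression file: {path}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing/ragged values in {path}")
    if df.index.duplicated().any():
        warnings.warn(f"duplicate feature ids in {path}; suffix-disambiguating",
                      stacklevel=2)
        counts: dict[str, int] = {}
        new_index = []
        for fid in df.index:
            k = counts.get(fid, 0)
            new_index.append(fid if k == 0 else f"{fid}.{k}")
            counts[fid] = k + 1
        df.index = new_index
    return ExpressionMatrix(df, feature_kind)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common per-rank mean distribution.

    After normalisation each column holds the same multiset of values (the
    cross-sample means of the rank-ordered values) and the within-column
    ordering is preserved.  Ties are assigned by stable sort order.
    """
    if m.n_samples < 2:
        warnings.warn("quantile_normalize with a single sample is the identity",
                      stacklevel=2)
        return ExpressionMatrix(m.data.copy(), m.feature_kind)
    x = m.values
    order = np.argsort(x, axis=0, kind="stable")
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = rank_means
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, m.feature_kind)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply ``v -> log2(v + offset)`` elementwise."""
    shifted = m.values + offset
    if (shifted <= 0).any():
        raise ValueError("log2_transform: values + offset must be positive")
    df = pd.DataFrame(np.log2(shifted), index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, m.feature_kind)


def filter_features(
    m: ExpressionMatrix,
    abundance_percentile: float = 10.0,
    min_count_above: int | None = None,
    range_rule: Literal["value_percentile", "range_percentile", "fraction_of_total"] | None = None,
    range_percentile: float = 90.0,
    range_fraction: float = 0.10,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop low-abundance and low-dynamic-range features.

    Abundance rule: the ``abundance_percentile``-th percentile of *all* values
    in the matrix is computed (linear interpolation); a feature is retained
    only if at least ``min_count_above`` of its samples are strictly above it.
    The default count is ``floor(0.25 * n_samples)`` (14 for a 57-sample
    panel).

    Range rule (applied to abundance survivors; thresholds always computed on
    the pre-filter matrix):

    * miRs (default ``value_percentile``): per-feature range (max - min) must
      exceed the ``range_percentile``-th percentile of all abundance values.
      ``range_percentile`` mode compares against the same percentile of the
      per-feature ranges instead — provided because the value-based reading,
      though literal, is unusually aggressive.
    * mRNA probes (default ``fraction_of_total``): per-feature range must
      exceed ``range_fraction`` of the global (max - min) of the matrix.

    Returns the retained matrix and a :class:`FilterReport` recording every
    realised threshold.
    """
    if m.n_features == 0:
        raise ValueError("empty matrix")
    x = m.values
    n = m.n_samples
    if min_count_above is None:
        min_count_above = math.floor(0.25 * n)
    if range_rule is None:
        range_rule = "value_percentile" if m.feature_kind == "miR" else "fraction_of_total"

    abund_thr = float(np.percentile(x, abundance_percentile))
    count_above = (x > abund_thr).sum(axis=1)
    pass_abund = count_above >= min_count_above

    ranges = x.max(axis=1) - x.min(axis=1)
    if range_rule == "value_percentile":
        range_thr = float(np.percentile(x, range_percentile))
    elif range_rule == "range_percentile":
        range_thr = float(np.percentile(ranges, range_percentile))
    elif range_rule == "fraction_of_total":
        range_thr = float(range_fraction * (x.max() - x.min()))
    else:
        raise ValueError(f"unknown range_rule: {range_rule!r}")
    pass_range = ranges > range_thr

    retained = pass_abund & pass_range
    n_drop_abund = int((~pass_abund).sum())
    n_drop_range = int((pass_abund & ~pass_range).sum())
    report = FilterReport(
        n_input=m.n_features,
        n_dropped_abundance=n_drop_abund,
        n_dropped_range=n_drop_range,
        n_retained=int(retained.sum()),
        thresholds_used={
            "abundance_percentile": abundance_percentile,
            "abundance_threshold": abund_thr,
            "min_count_above": int(min_count_above),
            "range_rule": range_rule,
            "range_threshold": range_thr,
        },
    )
    logger.info("filter_features[%s]: abundance thr=%.4g (need >%d samples above), "
                "range rule=%s thr=%.4g; retained %d/%d",
                m.feature_kind, abund_thr, min_count_above - 1, range_rule,
                range_thr, report.n_retained, report.n_input)
    if report.n_retained == 0:
        raise ValueError(f"all features dropped by filtering; report: {report}")
    out = ExpressionMatrix(m.data.loc[retained], m.feature_kind)
    return out, report


def match_cohort_samples(
    mir_table: ExpressionMatrix | pd.DataFrame,
    mrna_table: ExpressionMatrix | pd.DataFrame,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Match two barcode-keyed cohort tables on their shared sample barcodes.

    Matching is by full-length barcode string equality, so two samples from
    one patient (distinct sample barcodes) are retained as distinct samples.
    Unpaired barcodes are logged and dropped.
    """
    mir_df = mir_table.data if isinstance(mir_table, ExpressionMatrix) else mir_table
    mrna_df = mrna_table.data if isinstance(mrna_table, ExpressionMatrix) else mrna_table
    shared = sorted(set(mir_df.columns) & set(mrna_df.columns))
    if not shared:
        raise ValueError("no shared sample barcodes between miR and mRNA tables")
    unpaired = (set(mir_df.columns) ^ set(mrna_df.columns))
    if unpaired:
        logger.info("match_cohort_samples: %d unpaired barcodes dropped", len(unpaired))
    mir_out = ExpressionMatrix(mir_df[shared].astype(float), "miR")
    mrna_out = ExpressionMatrix(mrna_df[shared].astype(float), "mRNA-probe")
    return mir_out, mrna_out
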