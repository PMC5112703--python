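"""Selection of strong negative associations and database-supported integration.

A pair is a candidate post-transcriptional repression event when it sits in
the joint tail of the association table: mutual information above the top
``mi_top_pct`` percentile AND Pearson correlation below the most-negative
``r_bottom_pct`` percentile (the bottom-right region of an MI-vs-r density
plot).  Candidates are then matched against the high-confidence prediction
sources and the strong-evidence validation table to give the putative
relationship list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .targets import IdMap, expand_to_mature, map_identifiers

logger = logging.getLogger(__name__)

PUTATIVE_COLUMNS = [
    "mir_id", "probe_id", "gene_symbol", "pearson_r", "mi_nats",
    "targetscan_support", "diana_support", "mirtarbase_validated",
    "d_sep_norm", "d_sep_rank_pct",
]


@dataclass
class SelectionThresholds:
    """Realised tail cutoffs of one selection run (data-dependent)."""

    mi_cutoff: float
    r_cutoff: float
    mi_top_pct: float = 10.0
    r_bottom_pct: float = 2.5


def select_strong_negative(
    assoc: pd.DataFrame,
    mi_top_pct: float = 10.0,
    r_bottom_pct: float = 2.5,
    mode: str = "and",
) -> tuple[SelectionThresholds, pd.DataFrame]:
    """Select the joint MI-high / r-most-negative tail of an association table.

    Cutoffs are linear-interpolated quantiles of the table itself; rows must
    satisfy ``mi > mi_cutoff`` and ``r < r_cutoff`` strictly (conjunction by
    default; ``mode="or"`` unions the tails instead).  A percentile of 100
    disables that criterion.  Degenerate inputs (all values equal) yield an
    empty selection with a warning.
    """
    if assoc.empty:
        raise ValueError("association table is empty")
    if mode not in ("and", "or"):
        raise ValueError("mode must be 'and' or 'or'")
    mi = assoc["mi_nats"].to_numpy(dtype=float)
    r = assoc["pearson_r"].to_numpy(dtype=float)

    mi_cutoff = (-np.inf if mi_top_pct >= 100.0
                 else float(np.quantile(mi, 1.0 - mi_top_pct / 100.0)))
    r_cutoff = (np.inf if r_bottom_pct >= 100.0
                else float(np.quantile(r, r_bottom_pct / 100.0)))
    in_mi = mi > mi_cutoff
    in_r = r < r_cutoff
    mask = (in_mi & in_r) if mode == "and" else (in_mi | in_r)
    if not mask.any():
        warnings.warn("selection is empty (degenerate association "
                      "distributions or extreme percentiles)", stacklevel=2)
    thresholds = SelectionThresholds(mi_cutoff=mi_cutoff, r_cutoff=r_cutoff,
                                     mi_top_pct=mi_top_pct,
                                     r_bottom_pct=r_bottom_pct)
    logger.info("select_strong_negative: mi > %.4g and r < %.4g -> %d/%d rows",
                mi_cutoff, r_cutoff, int(mask.sum()), len(assoc))
    return thresholds, assoc.loc[mask].reset_index(drop=True)


def build_putative_list(
    selected: pd.DataFrame,
    targetscan: pd.DataFrame,
    diana: pd.DataFrame,
    validated: pd.DataFrame,
    idmap: IdMap,
) -> pd.DataFrame:
    """Match tail-selected associations against filtered prediction sources.

    ``targetscan`` and ``diana`` must already be percentile-filtered;
    ``validated`` must already be reduced to strong evidence.  A selected
    (miR, probe) row is emitted once per supporting gene symbol iff the
    (miR-or-family, gene) pair appears in at least one prediction source;
    the validated flag marks pairs present in the strong-evidence table.
    """
    mapped = map_identifiers(selected, idmap)
    ts_pairs = expand_to_mature(targetscan, idmap) if len(targetscan) else set()
    di_pairs = expand_to_mature(diana, idmap) if len(diana) else set()
    val_pairs = (set(zip(validated["mir_id"], validated["gene_symbol"]))
                 if len(validated) else set())

    rows = []
    for rec in mapped.itertuples(index=False):
        if rec.unmapped or pd.isna(rec.gene_symbol):
            continue
        key = (rec.mir_id, rec.gene_symbol)
        ts = key in ts_pairs
        di = key in di_pairs
        if not (ts or di):
            continue
        rows.append({
            "mir_id": rec.mir_id,
            "probe_id": rec.probe_id,
            "gene_symbol": rec.gene_symbol,
            "pearson_r": rec.pearson_r,
            "mi_nats": rec.mi_nats,
            "targetscan_support": ts,
            "diana_support": di,
            "mirtarbase_validated": key in val_pairs,
            "d_sep_norm": np.nan,
            "d_sep_rank_pct": np.nan,
        })
    out = pd.DataFrame(rows, columns=PUTATIVE_COLUMNS)
    out = out.drop_duplicates(subset=["mir_id", "probe_id", "gene_symbol"])
    out = out.reset_index(drop=True)
    logger.info("build_putative_list: %d supported rows from %d selected "
                "associations", len(out), len(selected))
    return out
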