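"""Target-prediction and validation tables: parsing, percentile filtering, id maps.

Two sequence-based prediction sources are supported, distinguished by their
score semantics:

* ``targetscan`` — context+ style scores; more negative = stronger predicted
  repression, so the high-confidence tail is the most-negative percentile.
* ``diana`` — miTG style scores; larger = higher confidence, so the
  high-confidence tail is the largest percentile.

Validated interactions carry a free-text experimental method; the
strong-evidence subset is the exact method set
{Luciferase reporter assay, qRT-PCR, Western blot} (case-insensitive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("targetscan", "diana")
#: default high-confidence percentile per source
DEFAULT_PERCENTILES = {"targetscan": 15.0, "diana": 30.0}
STRONG_EVIDENCE_METHODS = frozenset(
    m.lower() for m in ("Luciferase reporter assay", "qRT-PCR", "Western blot")
)

PREDICTION_COLUMNS = ["mir_key", "gene_symbol", "score"]
VALIDATED_COLUMNS = ["mir_id", "gene_symbol", "method"]


@dataclass
class IdMap:
    """Identifier maps: probe -> gene symbol and miR family -> mature miR.

    Both maps may be one-to-many; unmapped keys are reported by the consumers,
    never silently dropped.
    """

    probe_to_gene: pd.DataFrame     # columns: probe_id, gene_symbol
    family_to_mir: pd.DataFrame     # columns: family, mir_id

    def __post_init__(self) -> None:
        for df, cols in ((self.probe_to_gene, ("probe_id", "gene_symbol")),
                         (self.family_to_mir, ("family", "mir_id"))):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"IdMap table missing columns {missing}")

    @classmethod
    def from_tsv(cls, probe_gene_path: str | Path,
                 family_mir_path: str | Path) -> "IdMap":
        return cls(
            probe_to_gene=pd.read_csv(probe_gene_path, sep="\t", dtype=str),
            family_to_mir=pd.read_csv(family_mir_path, sep="\t", dtype=str),
        )

    def mirs_for_family(self, family: str) -> list[str]:
        hit = self.family_to_mir.loc[self.family_to_mir["family"] == family,
                                     "mir_id"]
        return hit.tolist()

    def family_of_mir(self) -> pd.DataFrame:
        """Inverse family map: columns mir_id, family."""
        return self.family_to_mir[["mir_id", "family"]].drop_duplicates()


def _aggregate_best(records: pd.DataFrame, source: str) -> pd.DataFrame:
    """Collapse duplicate (mir_key, gene) rows to the best score per pair."""
    agg = "min" if source == "targetscan" else "max"
    return (records.groupby(["mir_key", "gene_symbol"], as_index=False)
            .agg(score=("score", agg)))


def load_predictions(path: str | Path, source: str) -> pd.DataFrame:
    """Read a prediction TSV (mir_key, gene_symbol, score) for one source.

    Duplicate (mir_key, gene_symbol) rows are aggregated to the pair's best
    score (most negative for targetscan, largest for diana).
    """
    if source not in SOURCES:
        raise ValueError(f"unknown prediction source {source!r}; "
                         f"expected one of {SOURCES}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing prediction columns {missing}")
    if df.empty:
        warnings.warn(f"empty prediction table: {path}", stacklevel=2)
        out = df[PREDICTION_COLUMNS].copy()
        out["source"] = source
        return out
    if not np.issubdtype(df["score"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric score column")
    out = _aggregate_best(df[PREDICTION_COLUMNS], source)
    out["source"] = source
    return out


def percentile_filter_predictions(
    records: pd.DataFrame,
    source: str,
    percentile: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Keep the high-confidence `percentile` % of one source's predictions.

    targetscan keeps scores strictly below the `percentile`-th percentile of
    the score distribution (most negative tail, default 15 %); diana keeps
    scores strictly above the ``100 - percentile``-th percentile (largest
    tail, default 30 %).  Percentiles use linear interpolation; the strict
    inequality mirrors the "< cutoff" / "> cutoff" form in which such
    thresholds are conventionally reported.

    Returns the filtered table and the realised cutoff score.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown prediction source {source!r}")
    if "source" in records.columns:
        present = set(records["source"].unique())
        if present - {source}:
            raise ValueError(f"mixed prediction sources {present} in one "
                             "percentile filter call")
    if percentile is None:
        percentile = DEFAULT_PERCENTILES[source]
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if records.empty:
        return records.copy(), float("nan")
    scores = records["score"].to_numpy(dtype=float)
    if source == "targetscan":
        cutoff = float(np.percentile(scores, percentile))
        kept = records.loc[scores < cutoff]
    else:
        cutoff = float(np.percentile(scores, 100.0 - percentile))
        kept = records.loc[scores > cutoff]
    logger.info("percentile_filter[%s]: cutoff=%.4g, kept %d/%d",
                source, cutoff, len(kept), len(records))
    return kept.reset_index(drop=True), cutoff


def filter_validated_strong(records: pd.DataFrame) -> pd.DataFrame:
    """Keep validated interactions whose method is strong experimental evidence.

    Matching is by exact method-name membership after trimming, case-
    insensitive: luciferase reporter assay, qRT-PCR or Western blot.
    """
    if records.empty:
        return records.copy()
    missing = [c for c in VALIDATED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"validated table missing columns {missing}")
    methods = records["method"].astype(str).str.strip().str.lower()
    return records.loc[methods.isin(STRONG_EVIDENCE_METHODS)].reset_index(drop=True)


def load_validated(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VALIDATED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing validated columns {missing}")
    return df


def map_identifiers(assoc: pd.DataFrame, idmap: IdMap) -> pd.DataFrame:
    """Annotate an association table with gene symbols and miR families.

    Probes mapping to several genes fan out into one row per gene; rows whose
    probe (or miR) has no mapping are retained with a null symbol and flagged
    ``unmapped`` rather than dropped.
    """
    required = {"mir_id", "probe_id"}
    if not required <= set(assoc.columns):
        raise ValueError(f"association table must have columns {required}")
    out = assoc.merge(idmap.probe_to_gene, on="probe_id", how="left")
    out = out.merge(idmap.family_of_mir(), on="mir_id", how="left")
    out["unmapped"] = out["gene_symbol"].isna()
    n_unmapped = int(out["unmapped"].sum())
    if n_unmapped:
        logger.info("map_identifiers: %d rows without a probe->gene mapping",
                    n_unmapped)
    return out


def expand_to_mature(predictions: pd.DataFrame, idmap: IdMap) -> set[tuple[str, str]]:
    """Resolve prediction keys to mature-miR level (mir_id, gene) pairs.

    A key found in the family map fans out to every member miR; any other key
    is treated as a mature miR id directly.
    """
    fam_members: dict[str, list[str]] = {}
    for fam, grp in idmap.family_to_mir.groupby("family"):
        fam_members[fam] = grp["mir_id"].tolist()
    pairs: set[tuple[str, str]] = set()
    for key, gene in zip(predictions["mir_key"], predictions["gene_symbol"]):
        for mir in fam_members.get(key, [key]):
            pairs.add((mir, gene))
    return pairs
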