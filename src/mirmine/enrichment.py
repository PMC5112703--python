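"""Per-miR enrichment of active associations and GO-substring target enrichment.

"Active associations" are putative relationships that passed both statistical
tails and database support; per miR, their enrichment among that miR's
predicted-and-measurable targets is summarised as a fold change against the
pooled background fraction, with a one-sided hypergeometric tail probability
as a significance companion.  The enrichment formula is a reconstruction
(fold = per-miR active fraction / pooled active fraction); both components
are reported so either can be ranked on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .targets import IdMap, expand_to_mature

logger = logging.getLogger(__name__)

DEFAULT_SUBSTRINGS = ("epith", "mesench", "pigment", "melan")


def hypergeom_tail(n_active: int, total: int, total_active: int,
                   n_drawn: int) -> float:
    """One-sided tail P(X >= n_active) for X ~ Hypergeom(total, total_active,
    n_drawn): the chance of at least this many active pairs among a miR's
    predictions if activity were spread at random over the pooled universe."""
    return float(hypergeom.sf(n_active - 1, total, total_active, n_drawn))


@dataclass(frozen=True)
class GoCategory:
    term_id: str
    name: str
    members: frozenset[str]


def load_go_table(path: str | Path) -> pd.DataFrame:
    """Read a ragged GO TSV: term_id, name, then one member gene per column."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GO line: {line[:80]!r}")
            rows.append({"term_id": fields[0], "name": fields[1],
                         "members": fields[2:]})
    return pd.DataFrame(rows, columns=["term_id", "name", "members"])


def select_go_categories(
    go: pd.DataFrame,
    substrings: tuple[str, ...] = DEFAULT_SUBSTRINGS,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GoCategory]:
    """Categories whose name contains a substring (case-insensitive) and whose
    member count lies within [min_size, max_size]."""
    subs = tuple(s.lower() for s in substrings)
    out = []
    for rec in go.itertuples(index=False):
        name = str(rec.name).lower()
        if not any(s in name for s in subs):
            continue
        members = frozenset(rec.members)
        if min_size <= len(members) <= max_size:
            out.append(GoCategory(rec.term_id, rec.name, members))
    return out


def mir_active_enrichment(
    putative: pd.DataFrame,
    predictions: pd.DataFrame,
    universe: pd.DataFrame,
    idmap: IdMap,
) -> pd.DataFrame:
    """Per-miR enrichment of active associations among predicted targets.

    ``predictions`` is one percentile-filtered source; ``universe`` is the
    identifier-mapped association table of every retained pair.  For each miR:
    n_predicted_in_universe counts the source's (miR, gene) predictions whose
    gene is represented among retained probes (and whose miR was screened);
    n_active counts those also present in the putative table.  The background
    fraction pools active and predicted counts over all miRs.  miRs with no
    predicted pair in the universe are omitted.
    """
    if universe.empty:
        raise ValueError("empty universe")
    uni_pairs = {(m, g) for m, g in zip(universe["mir_id"],
                                        universe["gene_symbol"])
                 if pd.notna(g)}
    pred_pairs = expand_to_mature(predictions, idmap) if len(predictions) else set()
    pred_in_uni = pred_pairs & uni_pairs
    active_pairs = (set(zip(putative["mir_id"], putative["gene_symbol"]))
                    if len(putative) else set())
    active_in_pred = pred_in_uni & active_pairs

    total_pred = len(pred_in_uni)
    total_active = len(active_in_pred)
    if total_pred == 0:
        return pd.DataFrame(columns=[
            "mir_id", "n_predicted_in_universe", "n_active",
            "observed_fraction", "background_fraction", "fold_enrichment",
            "p_hypergeometric"])
    background = total_active / total_pred

    per_mir_pred: dict[str, int] = {}
    per_mir_active: dict[str, int] = {}
    for mir, _ in pred_in_uni:
        per_mir_pred[mir] = per_mir_pred.get(mir, 0) + 1
    for mir, _ in active_in_pred:
        per_mir_active[mir] = per_mir_active.get(mir, 0) + 1

    rows = []
    for mir in sorted(per_mir_pred):
        n_pred = per_mir_pred[mir]
        n_act = per_mir_active.get(mir, 0)
        frac = n_act / n_pred
        fold = frac / background if background > 0 else float("nan")
        p = hypergeom_tail(n_act, total_pred, total_active, n_pred)
        rows.append({
            "mir_id": mir,
            "n_predicted_in_universe": n_pred,
            "n_active": n_act,
            "observed_fraction": frac,
            "background_fraction": background,
            "fold_enrichment": fold,
            "p_hypergeometric": p,
        })
    return pd.DataFrame(rows)


def go_target_enrichment(
    target_genes: set[str],
    categories: list[GoCategory],
    background_genes: set[str],
) -> tuple[float, float]:
    """Fraction of targets inside the union of category members, and its fold
    change against the same fraction over the background gene set."""
    if not target_genes:
        raise ValueError("empty target gene set")
    if not target_genes <= background_genes:
        raise ValueError("target genes must be a subset of the background")
    union: set[str] = set()
    for cat in categories:
        union |= cat.members
    fraction = len(target_genes & union) / len(target_genes)
    bg_fraction = (len(background_genes & union) / len(background_genes)
                   if background_genes else 0.0)
    fold = fraction / bg_fraction if bg_fraction > 0 else 0.0
    return fraction, fold
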