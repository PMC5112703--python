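"""Synthetic panel generator with planted miR->mRNA repression.

Emulates the statistical structure the screening pipeline assumes in a
~57-sample cell-line panel: a miR matrix in which a large fraction of miRs
have no reads at all, an mRNA probe matrix an order of magnitude wider,
a set of planted negative miR->mRNA relationships (linear and sigmoidal
repression in log2-log2 space), phenotype groups with shifted centroids for
a subset of planted pairs, and prediction/validation tables that cover the
planted pairs plus random decoys.

Planted regulator miRs are given per-sample spreads at the top of the
panel's dynamic range: a miR whose abundance barely varies across the panel
cannot exhibit an observable repression slope, and the downstream
dynamic-range filter is designed to discard exactly such features.
Background (non-regulator) miRs get smaller spreads and are therefore
largely removed by that filter, mirroring the aggressive retention seen on
real panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ExpressionMatrix
from .targets import IdMap

STRONG_METHODS = ("Luciferase reporter assay", "qRT-PCR", "Western blot")
_VALIDATION_METHODS = STRONG_METHODS + ("Microarray",)

# per-sample spread (log2 units) of planted-regulator vs background miRs
_TRUE_MIR_SD = (2.2, 3.2)
_BG_MIR_SD = (0.5, 2.0)
_MRNA_SD = (0.5, 1.5)
# score models: context+ (more negative = better), miTG (larger = better)
_TS_DECOY_SCORES = (-1.0, 0.0)
_TS_TRUE_SCORES = (-1.0, -0.9)
_DIANA_DECOY_SCORES = (0.0, 1.0)
_DIANA_TRUE_SCORES = (0.8, 1.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Scale defaults follow the planted-pair recovery study (57 samples,
    100 miRs of which ~35% are read-free, 1000 probes, 30 planted pairs);
    the real panel's full width (thousands of miRs, tens of thousands of
    probes) is reachable by raising ``n_mirs``/``n_mrnas``.
    """

    n_samples: int = 57
    n_mirs: int = 100
    n_mrnas: int = 1000
    frac_zero_mirs: float = 0.35
    n_true_pairs: int = 30
    slope_range: tuple[float, float] = (-1.5, -0.8)
    frac_nonlinear: float = 0.3
    noise_sd: float = 0.5
    group_effect: float = 2.0
    db_coverage: float = 0.9
    n_decoys: int = 5000
    rng_seed: int = 0
    # extensions beyond the core knobs
    n_labelled: int = 24
    frac_phenotype_linked: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mirs", "n_mrnas", "n_true_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frac_zero_mirs", "frac_nonlinear", "db_coverage",
                     "frac_phenotype_linked"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.slope_range
        if not (lo < 0 and hi < 0):
            raise ValueError("slope_range must be strictly negative")
        if self.n_true_pairs > self.n_mirs * self.n_mrnas:
            raise ValueError("n_true_pairs exceeds the number of possible pairs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_labelled > self.n_samples:
            raise ValueError("n_labelled exceeds n_samples")


@dataclass(frozen=True)
class GroundTruthPair:
    mir_id: str
    mrna_id: str
    mechanism: str           # "linear" | "sigmoidal"
    slope: float
    phenotype_linked: bool

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("planted repression slope must be negative")
        if self.mechanism not in ("linear", "sigmoidal"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(config.n_samples)]


def mir_ids(config: SimulationConfig) -> list[str]:
    return [f"sim-miR-{i + 1:04d}" for i in range(config.n_mirs)]


def probe_ids(config: SimulationConfig) -> list[str]:
    return [f"PROBE_{i + 1:05d}" for i in range(config.n_mrnas)]


def make_idmap(config: SimulationConfig) -> IdMap:
    """Deterministic identifier maps for a simulated study.

    Every 10th probe interrogates the same gene as its predecessor (multiple
    probes per gene); miRs whose index satisfies ``i % 17 == 1`` share a
    family with their predecessor (family-level prediction fan-out).
    """
    probes = probe_ids(config)
    gene_of = []
    for i in range(config.n_mrnas):
        j = i - 1 if (i % 10 == 9) else i
        gene_of.append(f"GENE{j + 1:05d}")
    probe_gene = pd.DataFrame({"probe_id": probes, "gene_symbol": gene_of})

    mirs = mir_ids(config)
    fam_rows = []
    for i, mid in enumerate(mirs):
        j = i - 1 if (i % 17 == 1 and i > 0) else i
        fam_rows.append({"family": f"simFAM-{j + 1:04d}", "mir_id": mid})
    family_mir = pd.DataFrame(fam_rows)
    return IdMap(probe_to_gene=probe_gene, family_to_mir=family_mir)


def phenotype_assignment(config: SimulationConfig) -> pd.Series:
    """Sample -> {high, low, unknown}; deterministic in the config seed.

    A fixed salt keeps this assignment identical between the expression
    generator (which applies the centroid shifts) and the annotation
    generator (which emits the labels).
    """
    rng = np.random.default_rng([config.rng_seed, 101])
    samples = sample_ids(config)
    labelled = rng.choice(config.n_samples, size=config.n_labelled, replace=False)
    labels = pd.Series("unknown", index=samples, name="phenotype")
    n_high = config.n_labelled // 2
    labels.iloc[labelled[:n_high]] = "high"
    labels.iloc[labelled[n_high:]] = "low"
    return labels


def _sigmoid_response(x: np.ndarray, slope: float, center: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Monotone-decreasing logistic repression a - b / (1 + exp(-s (x - x0)))."""
    b = abs(slope) * max(np.ptp(x), 1e-9) * 0.8
    s = 4.0 / max(np.std(x), 1e-9)
    x0 = float(np.median(x))
    return center + b / 2.0 - b / (1.0 + np.exp(-s * (x - x0)))


def generate_expression_panel(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[GroundTruthPair]]:
    """Simulate paired log2 miR/mRNA matrices with planted repression.

    Planted pairs use distinct miRs and distinct mRNA probes.  Phenotype-
    linked pairs have the miR centroid shifted by +/- group_effect/2 between
    the high- and low-invasiveness sample groups; the target mRNA inherits
    the opposite shift through the repression function.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, n_mir, n_mrna = config.n_samples, config.n_mirs, config.n_mrnas
    n_zero = round(config.frac_zero_mirs * n_mir)
    if config.n_true_pairs + n_zero > n_mir:
        raise ValueError("not enough non-zero miRs for the requested "
                         "n_true_pairs; lower frac_zero_mirs or n_true_pairs")

    perm = rng.permutation(n_mir)
    true_mir_idx = perm[:config.n_true_pairs]
    zero_idx = perm[config.n_true_pairs:config.n_true_pairs + n_zero]
    true_mrna_idx = rng.choice(n_mrna, size=config.n_true_pairs, replace=False)

    labels = phenotype_assignment(config)
    shift = np.where(labels.to_numpy() == "high", 0.5,
                     np.where(labels.to_numpy() == "low", -0.5, 0.0))

    mir_mu = rng.normal(6.0, 2.0, size=n_mir)
    mir_sd = rng.uniform(*_BG_MIR_SD, size=n_mir)
    mir_sd[true_mir_idx] = rng.uniform(*_TRUE_MIR_SD, size=config.n_true_pairs)
    X = mir_mu[:, None] + mir_sd[:, None] * rng.normal(size=(n_mir, n))

    slopes = rng.uniform(config.slope_range[0], config.slope_range[1],
                         size=config.n_true_pairs)
    nonlinear = rng.random(config.n_true_pairs) < config.frac_nonlinear
    pheno_linked = rng.random(config.n_true_pairs) < config.frac_phenotype_linked
    for j in np.flatnonzero(pheno_linked):
        X[true_mir_idx[j]] += config.group_effect * shift
    X[zero_idx] = 0.0

    mrna_mu = rng.normal(6.0, 2.0, size=n_mrna)
    mrna_sd = rng.uniform(*_MRNA_SD, size=n_mrna)
    Y = mrna_mu[:, None] + mrna_sd[:, None] * rng.normal(size=(n_mrna, n))
    mids = mir_ids(config)
    pids = probe_ids(config)
    truth: list[GroundTruthPair] = []
    for j in range(config.n_true_pairs):
        x = X[true_mir_idx[j]]
        center = mrna_mu[true_mrna_idx[j]]
        if nonlinear[j]:
            signal = _sigmoid_response(x, slopes[j], center, rng)
            mech = "sigmoidal"
        else:
            signal = center + slopes[j] * (x - x.mean())
            mech = "linear"
        Y[true_mrna_idx[j]] = signal + rng.normal(0.0, config.noise_sd, size=n)
        truth.append(GroundTruthPair(
            mir_id=mids[true_mir_idx[j]],
            mrna_id=pids[true_mrna_idx[j]],
            mechanism=mech,
            slope=float(slopes[j]),
            phenotype_linked=bool(pheno_linked[j]),
        ))

    samples = sample_ids(config)
    mir_m = ExpressionMatrix(pd.DataFrame(X, index=mids, columns=samples), "miR")
    mrna_m = ExpressionMatrix(pd.DataFrame(Y, index=pids, columns=samples),
                              "mRNA-probe")
    return mir_m, mrna_m, truth


def generate_prediction_db(
    truth: list[GroundTruthPair],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prediction tables (targetscan-like and diana-like) plus validations.

    Each planted pair enters each source with probability ``db_coverage``
    and draws its score inside that source's high-confidence region
    (context+ <= -0.9; miTG >= 0.8).  A single set of ``n_decoys`` random
    non-planted (miR, gene) pairs is scored in both sources from each
    source's full score distribution.  Targetscan-like records are keyed by
    miR family; diana-like records by mature miR id.

    Returns ``(predictions, validated)``: predictions has columns
    ``mir_key, gene_symbol, score, source``; validated has
    ``mir_id, gene_symbol, method`` for a random subset of planted pairs.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng([config.rng_seed, 202])
    idmap = make_idmap(config)
    gene_of_probe = dict(zip(idmap.probe_to_gene["probe_id"],
                             idmap.probe_to_gene["gene_symbol"]))
    family_of_mir = dict(zip(idmap.family_to_mir["mir_id"],
                             idmap.family_to_mir["family"]))

    truth_gene_pairs = {(p.mir_id, gene_of_probe[p.mrna_id]) for p in truth}
    rows = []
    for p in truth:
        gene = gene_of_probe[p.mrna_id]
        if rng.random() < config.db_coverage:
            rows.append({"mir_key": family_of_mir[p.mir_id], "gene_symbol": gene,
                         "score": rng.uniform(*_TS_TRUE_SCORES),
                         "source": "targetscan"})
        if rng.random() < config.db_coverage:
            rows.append({"mir_key": p.mir_id, "gene_symbol": gene,
                         "score": rng.uniform(*_DIANA_TRUE_SCORES),
                         "source": "diana"})

    all_mirs = mir_ids(config)
    genes = sorted(set(gene_of_probe.values()))
    decoys: set[tuple[str, str]] = set()
    max_attempts = 50 * config.n_decoys + 1000
    attempts = 0
    while len(decoys) < config.n_decoys and attempts < max_attempts:
        attempts += 1
        pair = (all_mirs[rng.integers(len(all_mirs))],
                genes[rng.integers(len(genes))])
        if pair in truth_gene_pairs or pair in decoys:
            continue
        decoys.add(pair)
    for mir, gene in sorted(decoys):
        rows.append({"mir_key": family_of_mir[mir], "gene_symbol": gene,
                     "score": rng.uniform(*_TS_DECOY_SCORES),
                     "source": "targetscan"})
        rows.append({"mir_key": mir, "gene_symbol": gene,
                     "score": rng.uniform(*_DIANA_DECOY_SCORES),
                     "source": "diana"})
    predictions = pd.DataFrame(rows,
                               columns=["mir_key", "gene_symbol", "score", "source"])

    val_rows = []
    for p in truth:
        if rng.random() < 0.5:
            val_rows.append({
                "mir_id": p.mir_id,
                "gene_symbol": gene_of_probe[p.mrna_id],
                "method": _VALIDATION_METHODS[rng.integers(len(_VALIDATION_METHODS))],
            })
    validated = pd.DataFrame(val_rows, columns=["mir_id", "gene_symbol", "method"])
    return predictions, validated


_GO_TEMPLATES = [
    # (name, target size) -- sizes straddle the 5..500 selection window
    ("epithelial to mesenchymal transition", 40),
    ("mesenchymal cell differentiation", 80),
    ("regulation of epithelial cell migration", 3),
    ("pigmentation", 25),
    ("melanocyte differentiation", 12),
    ("melanosome organization", 7),
    ("pigment granule transport", 501),
    ("ribosome biogenesis", 150),
    ("cell cycle checkpoint", 60),
    ("dna repair", 2),
]


def generate_annotations(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """GO-style annotation table and phenotype labels.

    The GO table (columns ``term_id, name, members``; members as a list)
    contains categories whose names carry the EMP/pigmentation substrings
    alongside unrelated ones, with member counts below 5, inside [5, 500]
    and above 500.  Labels assign ``n_labelled`` samples (default 24) to
    high/low invasiveness; the rest are unknown.
    """
    rng = np.random.default_rng([config.rng_seed, 303])
    idmap = make_idmap(config)
    genes = sorted(set(idmap.probe_to_gene["gene_symbol"]))
    rows = []
    for i, (name, size) in enumerate(_GO_TEMPLATES):
        k = min(size, len(genes))
        members = sorted(rng.choice(genes, size=k, replace=False))
        rows.append({"term_id": f"GO:{7000000 + i}", "name": name,
                     "members": list(members)})
    go = pd.DataFrame(rows, columns=["term_id", "name", "members"])
    return go, phenotype_assignment(config)


def generate_cohort(
    config: SimulationConfig,
    n_cohort_samples: int = 10,
    n_patients: int = 9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode-keyed miR and mRNA cohort tables with partial overlap.

    Emulates a tumour cohort where samples carry patient/sample barcodes:
    one patient contributes two samples, and each assay table covers only a
    subset of samples, so the barcode intersection is non-empty but smaller
    than either table.
    """
    if n_patients >= n_cohort_samples:
        n_patients = n_cohort_samples - 1
    rng = np.random.default_rng([config.rng_seed, 404])
    barcodes = []
    for i in range(n_patients):
        barcodes.append(f"SIM-{i + 1:02d}-{1000 + i}-01A")
    for i in range(n_cohort_samples - n_patients):
        # extra samples from the first patients (vial 06A)
        barcodes.append(f"SIM-{i + 1:02d}-{1000 + i}-06A")
    barcodes = sorted(barcodes)

    mir_cols = barcodes[:-1]           # drop the last barcode from the miR assay
    mrna_cols = barcodes[1:]           # drop the first from the mRNA assay
    mir_feats = [f"sim-miR-c{i + 1:03d}" for i in range(20)]
    mrna_feats = [f"COHORT_PROBE_{i + 1:03d}" for i in range(30)]
    mir = pd.DataFrame(rng.normal(6.0, 2.0, size=(len(mir_feats), len(mir_cols))),
                       index=mir_feats, columns=mir_cols)
    mrna = pd.DataFrame(rng.normal(8.0, 2.0, size=(len(mrna_feats), len(mrna_cols))),
                        index=mrna_feats, columns=mrna_cols)
    return mir, mrna


def write_go_table(go: pd.DataFrame, path: str | Path) -> None:
    """Write the GO table as ragged TSV: term_id, name, member, member, ..."""
    with open(path, "w") as fh:
        for _, row in go.iterrows():
            fh.write("\t".join([row["term_id"], row["name"], *row["members"]]) + "\n")


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate every pipeline input and write it under ``outdir`` as TSV.

    Returns a manifest of output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mir_m, mrna_m, truth = generate_expression_panel(config)
    predictions, validated = generate_prediction_db(truth, config)
    go, labels = generate_annotations(config)
    idmap = make_idmap(config)

    paths = {
        "mir_expression": outdir / "mir_expression.tsv",
        "mrna_expression": outdir / "mrna_expression.tsv",
        "targetscan": outdir / "targetscan_predictions.tsv",
        "diana": outdir / "diana_predictions.tsv",
        "validated": outdir / "validated_interactions.tsv",
        "go": outdir / "go_annotations.tsv",
        "labels": outdir / "phenotype_labels.tsv",
        "probe_gene_map": outdir / "probe_gene_map.tsv",
        "family_mir_map": outdir / "family_mir_map.tsv",
        "truth": outdir / "ground_truth_pairs.tsv",
    }
    mir_m.write_tsv(paths["mir_expression"])
    mrna_m.write_tsv(paths["mrna_expression"])
    for source in ("targetscan", "diana"):
        sub = predictions.loc[predictions["source"] == source,
                              ["mir_key", "gene_symbol", "score"]]
        sub.to_csv(paths[source], sep="\t", index=False)
    validated.to_csv(paths["validated"], sep="\t", index=False)
    write_go_table(go, paths["go"])
    labels.rename_axis("sample_id").to_frame().to_csv(paths["labels"], sep="\t")
    idmap.probe_to_gene.to_csv(paths["probe_gene_map"], sep="\t", index=False)
    idmap.family_to_mir.to_csv(paths["family_mir_map"], sep="\t", index=False)
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(paths["truth"], sep="\t",
                                                     index=False)
    return {k: str(v) for k, v in paths.items()}
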