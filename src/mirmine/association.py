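"""Pairwise association screening: Pearson correlation and KSG mutual information.

Mutual information between miR and mRNA abundance is estimated with the
Kraskov-Stoegbauer-Grassberger k-nearest-neighbour estimator, algorithm 2:

    I(X;Y) = psi(k) - 1/k - < psi(n_x) + psi(n_y) > + psi(N)

where for each point i the k nearest neighbours are found under the max-norm
in the joint (x, y) space, eps_x(i)/2 is the largest marginal x-distance to
any of those k neighbours (analogously eps_y), and n_x(i) counts the points
j != i with |x_j - x_i| <= eps_x(i)/2 (closed ball, self excluded).  The
psi-based correction makes the estimator approximately unbiased; near
independence it can legitimately return small negative values.

Expression matrices contain ties (e.g. zero counts), which break the
distinct-distance assumption of the estimator; a small seeded uniform jitter
(default amplitude 1e-8) is added to every variable before neighbour search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .panel import ExpressionMatrix

logger = logging.getLogger(__name__)

_PROGRESS_EVERY = 100_000


@dataclass
class MiEstimatorParams:
    """Knobs for the KSG estimator.

    k is the neighbour count (the JIDT/MATLAB toolchain the estimator
    convention follows defaults to 4); noise_amplitude is the tie-breaking
    jitter in abundance units; rng_seed seeds the jitter stream.
    """

    k: int = 4
    noise_amplitude: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _ksg_mi_block(x: np.ndarray, Y: np.ndarray, k: int) -> np.ndarray:
    """KSG algorithm-2 MI of one x-vector against each row of Y (nats).

    Brute-force O(N^2) neighbour search vectorised over the block; N is small
    in panel applications (tens of samples) so no spatial index is needed, and
    at N ~ 2000 a dense distance matrix is still cheap.
    """
    n = x.size
    dx = np.abs(x[:, None] - x[None, :])                     # (N, N)
    dY = np.abs(Y[:, :, None] - Y[:, None, :])               # (m, N, N)
    dj = np.maximum(dx[None, :, :], dY)
    m = Y.shape[0]
    diag = np.arange(n)
    dj[:, diag, diag] = np.inf

    # indices of the k nearest joint neighbours of each point
    idx = np.argpartition(dj, k - 1, axis=2)[:, :, :k]       # (m, N, k)
    dx_b = np.broadcast_to(dx, (m, n, n))
    eps_x = np.take_along_axis(dx_b, idx, axis=2).max(axis=2)  # eps_x/2, (m, N)
    eps_y = np.take_along_axis(dY, idx, axis=2).max(axis=2)

    n_x = (dx[None, :, :] <= eps_x[:, :, None]).sum(axis=2) - 1  # self excluded
    n_y = (dY <= eps_y[:, :, None]).sum(axis=2) - 1
    return (digamma(k) - 1.0 / k + digamma(n)
            - (digamma(n_x) + digamma(n_y)).mean(axis=1))


def ksg_mi(
    x: np.ndarray,
    y: np.ndarray,
    params: MiEstimatorParams | None = None,
) -> float:
    """Mutual information (nats) between two sample vectors, KSG algorithm 2.

    Jitter of amplitude ``params.noise_amplitude`` is drawn per variable
    (x first, then y) from ``default_rng(params.rng_seed)``.  The estimator
    itself is symmetric: on jitter-free input (``noise_amplitude=0``, e.g.
    pre-jittered data) ``ksg_mi(x, y) == ksg_mi(y, x)`` exactly.
    """
    if params is None:
        params = MiEstimatorParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n <= params.k:
        raise ValueError(f"need more than k={params.k} samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if params.noise_amplitude > 0:
        rng = np.random.default_rng(params.rng_seed)
        x = x + params.noise_amplitude * rng.uniform(size=n)
        y = y + params.noise_amplitude * rng.uniform(size=n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    return float(_ksg_mi_block(x, y[None, :], params.k)[0])


def pairwise_associations(
    mir_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    params: MiEstimatorParams | None = None,
    block_size: int = 128,
) -> pd.DataFrame:
    """Pearson r and KSG MI for every (miR, mRNA probe) pair.

    Jitter for the MI estimate is drawn once per feature row (all miRs first,
    then all probes) from a single stream seeded with ``params.rng_seed``, so
    results are deterministic for a fixed seed and invariant to block size.
    Constant features (Pearson undefined) are excluded with a warning.

    Returns a DataFrame with columns ``mir_id, probe_id, pearson_r, mi_nats``,
    one row per pair, miR-major order.
    """
    if params is None:
        params = MiEstimatorParams()
    if mir_m.sample_ids != mrna_m.sample_ids:
        raise ValueError("miR and mRNA matrices must share an identical "
                         "ordered sample list")
    n = mir_m.n_samples
    if n <= params.k:
        raise ValueError(f"need more than k={params.k} samples, got {n}")

    X = mir_m.values
    Y = mrna_m.values
    keep_x = np.ptp(X, axis=1) > 0
    keep_y = np.ptp(Y, axis=1) > 0
    if not keep_x.all() or not keep_y.all():
        logger.warning("excluding %d constant miRs and %d constant probes "
                       "from association screening",
                       int((~keep_x).sum()), int((~keep_y).sum()))
    X = X[keep_x]
    Y = Y[keep_y]
    mir_ids = np.asarray(mir_m.feature_ids)[keep_x]
    probe_ids = np.asarray(mrna_m.feature_ids)[keep_y]

    # Pearson via standardised matrix product
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    Yc /= np.linalg.norm(Yc, axis=1, keepdims=True)
    R = Xc @ Yc.T                                            # (n_mir, n_probe)

    rng = np.random.default_rng(params.rng_seed)
    if params.noise_amplitude > 0:
        Xn = X + params.noise_amplitude * rng.uniform(size=X.shape)
        Yn = Y + params.noise_amplitude * rng.uniform(size=Y.shape)
    else:
        Xn, Yn = X, Y

    MI = np.empty_like(R)
    done = 0
    total = R.size
    for i in range(Xn.shape[0]):
        for start in range(0, Yn.shape[0], block_size):
            block = Yn[start:start + block_size]
            MI[i, start:start + block.shape[0]] = _ksg_mi_block(
                Xn[i], block, params.k)
            done += block.shape[0]
            if done // _PROGRESS_EVERY != (done - block.shape[0]) // _PROGRESS_EVERY:
                logger.info("pairwise_associations: %d/%d pairs", done, total)

    out = pd.DataFrame({
        "mir_id": np.repeat(mir_ids, probe_ids.size),
        "probe_id": np.tile(probe_ids, mir_ids.size),
        "pearson_r": R.ravel(),
        "mi_nats": MI.ravel(),
    })
    return out
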