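import numpy as np
import pandas as pd
import pytest

from mirmine.panel import ExpressionMatrix


@pytest.fixture
def preprocessing_fixture() -> ExpressionMatrix:
    """20 miR features x 57 samples with hand-designed filtering outcomes.

    Feature groups (zeros make up ~30% of all values, so the global 10th
    percentile is 0 and 'above threshold' means '> 0'):

    * zero_1..3      — all zeros: fail the abundance rule.
    * low13_1..2     — 13 samples at 12, rest 0: 13 < 14 above threshold.
    * low14_1..2     — 14 samples at 12, rest 0: pass abundance, but the
                       range (12) is below the 90th-percentile-of-values
                       threshold (~14.6), so they fail the range rule.
    * wide_1..7      — spread over ~[1, 20]: pass both rules.
    * const_1..2     — constant 10: zero range.
    * narrow_1..2    — 10 +/- 0.5: range 1.
    * mid_1..2       — spread 5..9: range 4, below the range threshold.
    """
    n = 57
    rows: dict[str, np.ndarray] = {}
    for i in range(3):
        rows[f"zero_{i + 1}"] = np.zeros(n)
    for i in range(2):
        v = np.zeros(n)
        v[: 13] = 12.0
        rows[f"low13_{i + 1}"] = v
    for i in range(2):
        v = np.zeros(n)
        v[: 14] = 12.0
        rows[f"low14_{i + 1}"] = v
    for i in range(7):
        rows[f"wide_{i + 1}"] = np.linspace(1.0, 20.0, n) + 0.01 * i
    for i in range(2):
        rows[f"const_{i + 1}"] = np.full(n, 10.0)
    for i in range(2):
        rows[f"narrow_{i + 1}"] = 10.0 + 0.5 * np.cos(np.arange(n))
    for i in range(2):
        rows[f"mid_{i + 1}"] = np.linspace(5.0, 9.0, n)
    df = pd.DataFrame(rows).T
    df.columns = [f"CL{j + 1:02d}" for j in range(n)]
    return ExpressionMatrix(df, "miR")


EXPECTED_RETAINED = [f"wide_{i + 1}" for i in range(7)]


@pytest.fixture
def selection_fixture() -> pd.DataFrame:
    """40-row association table with exactly one row in both selection tails.

    mi runs 1..40, so the top-10% tail (mi > quantile(mi, 0.9) = 36.1) is
    {37, 38, 39, 40}.  r is -mi/100 except the row with mi = 38, which gets
    r = -0.90; the bottom-2.5% cutoff falls between the two most negative r
    values, so only that row is in the r tail — the joint selection is the
    single row with mi = 38.
    """
    mi = np.arange(1, 41, dtype=float)
    r = -mi / 100.0
    r[mi == 38] = -0.90
    return pd.DataFrame({
        "mir_id": [f"m{i}" for i in range(40)],
        "probe_id": [f"p{i}" for i in range(40)],
        "pearson_r": r,
        "mi_nats": mi,
    })
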