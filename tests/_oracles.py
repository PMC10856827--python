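"""Independent brute-force oracles used by the test suite only.

Deliberately written with explicit Python loops over sums of squares, so they
share no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import math


def icc_a1_bruteforce(matrix) -> dict:
    """ICC(A,1) from explicit two-way ANOVA sums of squares (pure Python)."""
    x = [[float(v) for v in row] for row in matrix]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = sum(
        (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * mse + (k / n) * (ms_cols - mse)
    icc = float("nan") if denom == 0 else (ms_rows - mse) / denom
    return {"icc": icc, "ms_rows": ms_rows, "ms_cols": ms_cols, "mse": mse}


def mdc_closed_form(mse: float) -> float:
    return 1.96 * math.sqrt(mse) * math.sqrt(2.0)
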