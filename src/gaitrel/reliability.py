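"""Test-retest reliability: comparison designs, ICC(A,1), SEM and MDC.

Three comparison types are analyzed per variable and surface, each built from
five measurement pairs:

* ``between_day`` - the first run of each day, processed with the first
  calibration, across day pairs (1,2), (2,3), (3,4), (4,5) and (5,2);
* ``within_day`` - the two analyzed runs of the same day under the same
  calibration, for each of the five days;
* ``calibration`` - the same run processed with the two different calibration
  trials, for each of the five days.

For every pair an n_subjects x 2 matrix feeds a two-way ANOVA, from which the
absolute-agreement single-measure intraclass correlation ICC(A,1) (the
two-way random-effects "case 2" form of McGraw and Wong) is computed as

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

the standard error of measurement as SEM = sqrt(MSE), and the minimal
detectable change as MDC = 1.96 * SEM * sqrt(2).  Per variable, surface and
comparison type the five per-pair ICCs are aggregated as median [min, max]
and labelled with the Koo-Li category (poor < 0.5 <= moderate < 0.75 <= good
< 0.9 <= excellent), conservatively downgraded when the minimum ICC falls in
a lower category than the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import features as _features

COMPARISON_TYPES = ("between_day", "within_day", "calibration")

#: MDC = MDC_FACTOR * SEM, exactly.
MDC_FACTOR = 1.96 * math.sqrt(2.0)

#: Koo-Li category cut-offs (lower inclusive bound -> label).
CATEGORY_CUTOFFS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


class DesignError(ValueError):
    """A comparison design cannot be built or applied."""


def day_pairs(n_days: int) -> list[tuple[int, int]]:
    """Day-to-day comparison pairs: consecutive days, closed by (last, 2).

    For the canonical 5-day design this is (1,2), (2,3), (3,4), (4,5), (5,2):
    the last day is compared to day 2 to equalize the number of comparisons
    underlying the median.  Generalization: consecutive pairs, plus the
    (n, 2) closure whenever n >= 3.
    """
    if n_days < 2:
        raise DesignError("need at least 2 days for a between-day design")
    pairs = [(d, d + 1) for d in range(1, n_days)]
    if n_days >= 3:
        pairs.append((n_days, 2))
    return pairs


@dataclass(frozen=True)
class ComparisonDesign:
    """Pairs of measurement selectors over the feature-table keys."""

    type: str
    surface: str | None
    pairs: tuple[tuple[dict, dict], ...]
    labels: tuple[str, ...]


def build_design(
    comparison_type: str,
    n_days: int = 5,
    surface: str | None = None,
    runs: tuple[int, int] = (1, 3),
    calibrations: tuple[int, int] = (1, 2),
) -> ComparisonDesign:
    """Build one comparison design (selectors are dicts over day/run/calibration)."""
    if comparison_type not in COMPARISON_TYPES:
        raise DesignError(f"unknown comparison type {comparison_type!r}")
    if n_days < 2 and comparison_type == "between_day":
        raise DesignError("between-day design needs n_days >= 2")
    first_run, second_run = runs[0], runs[-1]
    first_cal, second_cal = calibrations[0], calibrations[-1]
    pairs: list[tuple[dict, dict]] = []
    labels: list[str] = []
    if comparison_type == "between_day":
        for a, b in day_pairs(n_days):
            pairs.append(
                (
                    {"day": a, "run": first_run, "calibration": first_cal},
                    {"day": b, "run": first_run, "calibration": first_cal},
                )
            )
            labels.append(f"day{a}-day{b}")
    elif comparison_type == "within_day":
        for d in range(1, n_days + 1):
            pairs.append(
                (
                    {"day": d, "run": first_run, "calibration": first_cal},
                    {"day": d, "run": second_run, "calibration": first_cal},
                )
            )
            labels.append(f"day{d}")
    else:  # calibration
        for d in range(1, n_days + 1):
            pairs.append(
                (
                    {"day": d, "run": first_run, "calibration": first_cal},
                    {"day": d, "run": first_run, "calibration": second_cal},
                )
            )
            labels.append(f"day{d}")
    return ComparisonDesign(
        type=comparison_type, surface=surface, pairs=tuple(pairs), labels=tuple(labels)
    )


@dataclass
class IccResult:
    """ICC(A,1) with the mean squares of its underlying two-way ANOVA."""

    icc: float
    ms_rows: float
    ms_cols: float
    mse: float
    n: int
    k: int
    degenerate: bool = False  # zero total variance: ICC undefined


def icc_a1(matrix: np.ndarray) -> IccResult:
    """ICC(A,1) from a complete n_subjects x k_measurements matrix.

    Rows are subjects, columns are repeated measurements.  Negative estimates
    are returned as computed, never clipped.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x measurements)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 measurements, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("matrix must be complete (no missing cells)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * mse + (k / n) * (ms_cols - mse)
    if denom == 0.0:
        return IccResult(float("nan"), ms_rows, ms_cols, mse, n, k, degenerate=True)
    icc = (ms_rows - mse) / denom
    return IccResult(float(icc), float(ms_rows), float(ms_cols), float(mse), n, k)


def sem_mdc(mse: float) -> tuple[float, float]:
    """SEM = sqrt(MSE); MDC = 1.96 * SEM * sqrt(2)."""
    if mse < 0:
        raise ValueError(f"mse must be >= 0, got {mse}")
    sem = math.sqrt(mse)
    return sem, MDC_FACTOR * sem


def _base_category(icc: float) -> str:
    if np.isnan(icc):
        return "undefined"
    for cutoff, label in CATEGORY_CUTOFFS:
        if icc >= cutoff:
            return label
    return "poor"


def categorize(icc_median: float, icc_min: float | None = None) -> str:
    """Koo-Li category of the median ICC, conservatively downgraded by the minimum.

    If the minimum ICC falls in a lower category than the median, the lower
    category is reported as the single (conservative) label.
    """
    cat = _base_category(icc_median)
    if icc_min is not None and not np.isnan(icc_min):
        order = ["poor", "moderate", "good", "excellent"]
        low = _base_category(icc_min)
        if low in order and cat in order and order.index(low) < order.index(cat):
            cat = low
    return cat


@dataclass
class ReliabilityEstimate:
    """ICC/SEM/MDC summary for one variable x surface x comparison type."""

    variable: str
    surface: str
    comparison_type: str
    pair_labels: tuple[str, ...]
    icc: np.ndarray  # per pair
    ms_rows: np.ndarray
    ms_cols: np.ndarray
    mse: np.ndarray
    sem: np.ndarray
    mdc: np.ndarray
    pair_mean_abs_diff: np.ndarray
    pair_sd_abs_diff: np.ndarray
    mean_abs_diff: float  # pooled across pairs and participants
    sd_abs_diff: float
    icc_median: float
    icc_min: float
    icc_max: float
    mdc_median: float
    category: str
    n_subjects: tuple[int, ...] = ()
    excluded: list = field(default_factory=list)


def _pair_matrix(
    sub: pd.DataFrame, variable: str, sel_a: dict, sel_b: dict
) -> tuple[np.ndarray, list]:
    """Align the two selected measurements by participant; listwise-drop NaNs."""

    def _select(sel: dict) -> pd.Series:
        mask = (
            (sub["day"] == sel["day"])
            & (sub["run"] == sel["run"])
            & (sub["calibration"] == sel["calibration"])
        )
        chunk = sub.loc[mask, ["participant", variable]]
        if chunk["participant"].duplicated().any():
            raise DesignError(f"duplicate rows for selector {sel} (variable {variable})")
        return chunk.set_index("participant")[variable]

    a = _select(sel_a)
    b = _select(sel_b)
    participants = sorted(set(a.index) | set(b.index))
    mat = np.column_stack(
        [a.reindex(participants).to_numpy(), b.reindex(participants).to_numpy()]
    )
    complete = ~np.isnan(mat).any(axis=1)
    excluded = [p for p, ok in zip(participants, complete) if not ok]
    return mat[complete], excluded


def run_reliability(
    features: pd.DataFrame,
    n_days: int | None = None,
    surfaces: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
    runs: tuple[int, int] = (1, 3),
    calibrations: tuple[int, int] = (1, 2),
    comparison_types: Sequence[str] = COMPARISON_TYPES,
) -> list[ReliabilityEstimate]:
    """Compute all reliability estimates from a discrete-feature table.

    By default the nine joint-angle variables are analyzed for all three
    comparison types; running speed and stride frequency only for the
    between-day and within-day designs (a calibration cannot change the
    timing-gate speed or the detected cycle durations, so calibration
    reliability is not applicable to them).
    """
    if n_days is None:
        n_days = int(features["day"].max())
    if surfaces is None:
        surfaces = sorted(features["surface"].unique())
    estimates: list[ReliabilityEstimate] = []
    for comparison_type in comparison_types:
        if variables is None:
            angle_vars = [v for v in _features.ANGLE_VARIABLES if v in features.columns]
            var_list = list(angle_vars)
            if comparison_type != "calibration":
                var_list += [v for v in ("RS", "SF") if v in features.columns]
        else:
            var_list = list(variables)
        for surface in surfaces:
            design = build_design(
                comparison_type, n_days=n_days, surface=surface, runs=runs, calibrations=calibrations
            )
            sub = features[features["surface"] == surface]
            for variable in var_list:
                estimates.append(_estimate_one(sub, variable, design))
    return estimates


def _estimate_one(
    sub: pd.DataFrame, variable: str, design: ComparisonDesign
) -> ReliabilityEstimate:
    iccs, msr, msc, mses, sems, mdcs = [], [], [], [], [], []
    pair_means, pair_sds, ns = [], [], []
    all_abs_diffs: list[np.ndarray] = []
    excluded: list = []
    for (sel_a, sel_b), label in zip(design.pairs, design.labels):
        mat, excl = _pair_matrix(sub, variable, sel_a, sel_b)
        excluded.extend((label, p) for p in excl)
        if len(mat) < 2:
            raise DesignError(
                f"{variable} {design.type} {label}: fewer than 2 complete subjects"
            )
        res = icc_a1(mat)
        sem, mdc = sem_mdc(res.mse)
        abs_diff = np.abs(mat[:, 0] - mat[:, 1])
        iccs.append(res.icc)
        msr.append(res.ms_rows)
        msc.append(res.ms_cols)
        mses.append(res.mse)
        sems.append(sem)
        mdcs.append(mdc)
        pair_means.append(abs_diff.mean())
        pair_sds.append(abs_diff.std(ddof=1))
        ns.append(res.n)
        all_abs_diffs.append(abs_diff)
    icc_arr = np.asarray(iccs)
    pooled = np.concatenate(all_abs_diffs)
    mdc_arr = np.asarray(mdcs)
    icc_median = float(np.median(icc_arr))
    icc_min = float(np.min(icc_arr))
    icc_max = float(np.max(icc_arr))
    return ReliabilityEstimate(
        variable=variable,
        surface=design.surface if design.surface is not None else "",
        comparison_type=design.type,
        pair_labels=design.labels,
        icc=icc_arr,
        ms_rows=np.asarray(msr),
        ms_cols=np.asarray(msc),
        mse=np.asarray(mses),
        sem=np.asarray(sems),
        mdc=mdc_arr,
        pair_mean_abs_diff=np.asarray(pair_means),
        pair_sd_abs_diff=np.asarray(pair_sds),
        mean_abs_diff=float(pooled.mean()),
        sd_abs_diff=float(pooled.std(ddof=1)),
        icc_median=icc_median,
        icc_min=icc_min,
        icc_max=icc_max,
        mdc_median=float(np.median(mdc_arr)),
        category=categorize(icc_median, icc_min),
        n_subjects=tuple(ns),
        excluded=excluded,
    )


def estimates_to_frame(estimates: Iterable[ReliabilityEstimate]) -> pd.DataFrame:
    """Aggregate table: one row per variable x surface x comparison type."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "variable": e.variable,
                "surface": e.surface,
                "comparison_type": e.comparison_type,
                "icc_median": e.icc_median,
                "icc_min": e.icc_min,
                "icc_max": e.icc_max,
                "icc_formatted": f"{e.icc_median:.2f} [{e.icc_min:.2f}, {e.icc_max:.2f}]",
                "category": e.category,
                "mdc_median": e.mdc_median,
                "mean_abs_diff": e.mean_abs_diff,
                "sd_abs_diff": e.sd_abs_diff,
            }
        )
    return pd.DataFrame(rows)
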