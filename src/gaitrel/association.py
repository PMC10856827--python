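"""Between-day error sources: difference matrix and random-intercept mixed model.

For every discrete joint-angle variable, the absolute between-day difference
is assembled for each participant, day pair and surface alongside the
corresponding absolute differences in running speed and stride frequency,
giving (for the canonical 17 x 5 x 2 design) a 170-row matrix.  A linear
mixed model with a random intercept per runner cluster,

    y_cj = a + (a_j - a) + b_speed x_speed,cj + b_sf x_sf,cj
           + b_surface x_surface,cj + e_cj,

is then fitted by restricted maximum likelihood: fixed effects quantify how
between-day variation in speed (deg per m/s), stride frequency (deg per Hz)
and the surface (deg, woodchip minus asphalt) predict the between-day
joint-angle error; the marginal R-squared (Nakagawa-Schielzeth) reports the
share of variance explained by the fixed effects alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from . import features as _features
from .reliability import day_pairs

FIXED_EFFECTS = ("speed", "stride_frequency", "surface")
_Z975 = stats.norm.ppf(0.975)


def build_difference_matrix(
    features: pd.DataFrame,
    variable: str,
    n_days: int | None = None,
    surfaces: Sequence[str] | None = None,
    run: int = 1,
    calibration: int = 1,
) -> pd.DataFrame:
    """Absolute between-day differences of one variable, with speed/SF/surface.

    Uses the first analyzed run of each day under the first calibration.
    Columns: participant, day_a, day_b, surface, abs_diff_angle, abs_diff_speed,
    abs_diff_sf.  Symmetric in pair order by construction (|a-b| = |b-a|).
    """
    if n_days is None:
        n_days = int(features["day"].max())
    if surfaces is None:
        surfaces = sorted(features["surface"].unique())
    sel = features[(features["run"] == run) & (features["calibration"] == calibration)]
    needed = [variable, "RS", "SF"]
    rows = []
    for surface in surfaces:
        sub = sel[sel["surface"] == surface]
        by_day = {
            d: g.set_index("participant")[needed] for d, g in sub.groupby("day")
        }
        for a, b in day_pairs(n_days):
            if a not in by_day or b not in by_day:
                raise ValueError(f"missing day {a if a not in by_day else b} on {surface}")
            fa, fb = by_day[a], by_day[b]
            participants = sorted(set(fa.index) & set(fb.index))
            missing = sorted(set(fa.index) ^ set(fb.index))
            if missing:
                raise ValueError(
                    f"missing cells for participants {missing} in day pair ({a},{b}) on {surface}"
                )
            diff = (fa.loc[participants] - fb.loc[participants]).abs()
            for p in participants:
                rows.append(
                    {
                        "participant": p,
                        "day_a": a,
                        "day_b": b,
                        "surface": surface,
                        "abs_diff_angle": diff.loc[p, variable],
                        "abs_diff_speed": diff.loc[p, "RS"],
                        "abs_diff_sf": diff.loc[p, "SF"],
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class MixedModelResult:
    """Fixed effects, variance components and marginal R^2 of one fitted model."""

    variable: str
    params: dict[str, float]  # intercept + fixed-effect estimates
    conf_int: dict[str, tuple[float, float]]  # Wald 95% intervals
    pvalues: dict[str, float]  # normal-approximation Wald p-values
    random_intercept_var: float
    residual_var: float
    marginal_r2: float
    singular: bool  # random-intercept variance estimated at the boundary 0
    n_obs: int
    n_groups: int

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.conf_int[name]
        return lo <= value <= hi


def _surface_code(surface: pd.Series) -> tuple[np.ndarray, str]:
    levels = sorted(surface.unique())
    if len(levels) == 1:
        return np.zeros(len(surface)), levels[0]
    if len(levels) != 2:
        raise ValueError(f"expected two surface levels, got {levels}")
    # asphalt (stable) is the reference when present, so b_surface is
    # woodchip minus asphalt
    ref = "asphalt" if "asphalt" in levels else levels[0]
    other = [l for l in levels if l != ref][0]
    return (surface == other).to_numpy(dtype=float), other


def fit_mixed_model(dm: pd.DataFrame, variable: str = "") -> MixedModelResult:
    """Fit the random-intercept model to one variable's difference matrix (REML)."""
    groups = dm["participant"]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 runner clusters")
    surface_num, _ = _surface_code(dm["surface"])
    columns = {
        "intercept": np.ones(len(dm)),
        "speed": dm["abs_diff_speed"].to_numpy(dtype=float),
        "stride_frequency": dm["abs_diff_sf"].to_numpy(dtype=float),
        "surface": surface_num,
    }
    # constant predictors carry no information and make the normal equations
    # singular; they are excluded and reported as NaN coefficients
    used = ["intercept"] + [n for n in FIXED_EFFECTS if np.ptp(columns[n]) > 0]
    # unit-SD scaling of the predictors conditions the profiled likelihood
    # (SF differences live on a ~0.03 Hz scale); estimates are unscaled below
    scales = np.array(
        [1.0] + [float(np.std(columns[n])) or 1.0 for n in used[1:]]
    )
    X = np.column_stack([columns[n] / s for n, s in zip(used, scales)])
    y = dm["abs_diff_angle"].to_numpy(dtype=float)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
    if fit is None:
        raise RuntimeError(f"mixed model did not converge for {variable or 'variable'}")
    beta = np.asarray(fit.fe_params, dtype=float) / scales
    bse = np.asarray(fit.bse_fe, dtype=float) / scales
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    var_fixed = float(np.var(X @ np.asarray(fit.fe_params, dtype=float), ddof=1))
    total = var_fixed + re_var + resid_var
    marginal_r2 = 0.0 if total == 0 else var_fixed / total
    z = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    singular = re_var <= 1e-10 * max(total, 1.0)
    nan = float("nan")
    params = {n: nan for n in ("intercept",) + FIXED_EFFECTS}
    conf = {n: (nan, nan) for n in params}
    pdict = {n: nan for n in params}
    for n, b, s, p in zip(used, beta, bse, pvals):
        params[n] = float(b)
        conf[n] = (float(b - _Z975 * s), float(b + _Z975 * s))
        pdict[n] = float(p)
    return MixedModelResult(
        variable=variable,
        params=params,
        conf_int=conf,
        pvalues=pdict,
        random_intercept_var=re_var,
        residual_var=resid_var,
        marginal_r2=float(np.clip(marginal_r2, 0.0, 1.0)),
        singular=singular,
        n_obs=len(dm),
        n_groups=int(groups.nunique()),
    )


def fit_all_variables(
    features: pd.DataFrame,
    variables: Sequence[str] | None = None,
    n_days: int | None = None,
) -> dict[str, MixedModelResult]:
    """Build the difference matrix and fit the mixed model for every variable."""
    if variables is None:
        variables = [v for v in _features.ANGLE_VARIABLES if v in features.columns]
    results = {}
    for variable in variables:
        dm = build_difference_matrix(features, variable, n_days=n_days)
        results[variable] = fit_mixed_model(dm, variable=variable)
    return results


def significance_screen(
    results: Mapping[str, MixedModelResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Flag models with any fixed-effect p below ``alpha`` (intercept excluded)."""
    rows = []
    for variable, res in results.items():
        row = {"variable": variable, "marginal_r2": res.marginal_r2}
        for name in FIXED_EFFECTS:
            lo, hi = res.conf_int[name]
            row[f"b_{name}"] = res.params[name]
            row[f"b_{name}_low"] = lo
            row[f"b_{name}_high"] = hi
            row[f"p_{name}"] = res.pvalues[name]
        row["significant"] = bool(any(res.pvalues[n] < alpha for n in FIXED_EFFECTS))
        row["singular"] = res.singular
        rows.append(row)
    return pd.DataFrame(rows)
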