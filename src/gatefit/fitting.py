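"""Least-squares estimation of dose-response and AND-gate parameters.

Univariate titration slices are fitted to the four-parameter logistic and
full bivariate induction matrices to the leaky AND-gate surface, both by
bounded Levenberg-Marquardt with a deterministic multi-start protocol so
that repeated runs give identical fits. Derived quantities (EC10/EC90,
DRLR, the dual-induction enhancement 1/f1) and analytic iso-response
contours are computed from the fitted parameters.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np

from .models import (
    ANDGateParams,
    FourPLParams,
    ParameterError,
    drlr_analytic,
    ec_quantile,
    eval_and_gate,
    eval_four_pl,
    hill,
)

__all__ = [
    "InsufficientDataError",
    "UnidentifiableError",
    "ExpressionMatrix",
    "DoseResponseSeries",
    "FourPLFit",
    "GlobalFit",
    "ContourSet",
    "slice_matrix",
    "fit_four_pl",
    "fit_and_gate_global",
    "extract_contours",
    "drlr_numeric",
]

_MAX_ITER = 500
_N_BOUNDS = (0.05, 50.0)


class InsufficientDataError(ValueError):
    """Too few observations or concentration levels to attempt the fit."""


class UnidentifiableError(ValueError):
    """The design cannot identify a named parameter (e.g. a single level)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Normalized expression (RFU/OD) on an inducer-I x inducer-P grid.

    ``values`` has shape ``(len(i_levels), len(p_levels), n_replicates)``;
    missing replicates may be NaN. Levels are in uM and strictly increasing;
    zero is allowed (and required when basal quantities are to be estimated).
    """

    i_levels: np.ndarray
    p_levels: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_levels = np.asarray(self.i_levels, dtype=float)
        self.p_levels = np.asarray(self.p_levels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.shape[:2] != (self.i_levels.size, self.p_levels.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.i_levels.size} I levels x {self.p_levels.size} P levels"
            )
        for name, lv in (("i_levels", self.i_levels), ("p_levels", self.p_levels)):
            if lv.size < 2:
                raise ValueError(f"{name} needs at least 2 levels")
            if np.any(np.diff(lv) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if np.any(lv < 0):
                raise ValueError(f"{name} must be >= 0")
        finite = self.values[np.isfinite(self.values)]
        if finite.size == 0:
            raise ValueError("matrix contains no finite responses")
        if np.any(finite < 0):
            raise ValueError("responses must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def cell_means(self) -> np.ndarray:
        """Per-cell mean response over replicates (NaN-aware)."""
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=2)

    def observations(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to pooled (i, p, response) observation vectors."""
        ii, pp = np.meshgrid(self.i_levels, self.p_levels, indexing="ij")
        i_all = np.repeat(ii[:, :, None], self.n_replicates, axis=2).ravel()
        p_all = np.repeat(pp[:, :, None], self.n_replicates, axis=2).ravel()
        y_all = self.values.ravel()
        keep = np.isfinite(y_all)
        return i_all[keep], p_all[keep], y_all[keep]


@dataclass
class DoseResponseSeries:
    """One titration axis at a fixed co-inducer level.

    ``responses`` has shape ``(len(conc), n_replicates)``.
    """

    conc: np.ndarray
    responses: np.ndarray
    axis: str = "I"
    fixed_level: float | None = None

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.repeat(self.conc, self.responses.shape[1])
        y = self.responses.ravel()
        keep = np.isfinite(y)
        return c[keep], y[keep]


@dataclass
class FourPLFit:
    """A fitted four-parameter logistic with derived EC quantities."""

    params: FourPLParams | None
    se: Mapping[str, float]
    rss: float
    n_obs: int
    converged: bool
    ec10: float | None = None
    ec90: float | None = None
    drlr: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class GlobalFit:
    """A jointly fitted AND-gate surface over a full induction matrix."""

    params: ANDGateParams | None
    se: Mapping[str, float]
    rss: float
    n_obs: int
    converged: bool
    start_points_tried: int
    warnings: list[str] = field(default_factory=list)

    @property
    def enhancement(self) -> float | None:
        """Dual-induction enhancement 1/f1; inf for a strict AND gate."""
        if self.params is None:
            return None
        return self.params.enhancement


@dataclass
class ContourSet:
    """Iso-response polylines on the (I, P) plane, normalized scale."""

    levels: tuple[float, ...]
    curves: dict[float, np.ndarray]  # level -> (m, 2) array of (i_uM, p_uM)


# ---------------------------------------------------------------------------
# slicing


def slice_matrix(m: ExpressionMatrix, axis: str, fixed_level: float) -> DoseResponseSeries:
    """Extract one titration axis at a fixed level of the co-inducer.

    ``axis`` names the varying inducer: slicing ``axis="P"`` holds I fixed
    at ``fixed_level`` and returns the P titration.
    """
    axis = axis.upper()
    if axis not in ("I", "P"):
        raise ValueError("axis must be 'I' or 'P'")
    fixed_axis_levels = m.i_levels if axis == "P" else m.p_levels
    idx = np.flatnonzero(np.isclose(fixed_axis_levels, fixed_level, rtol=1e-9, atol=0.0))
    if idx.size == 0:
        raise LookupError(
            f"fixed level {fixed_level} uM not on the "
            f"{'I' if axis == 'P' else 'P'} grid; available: "
            f"{np.array2string(fixed_axis_levels, precision=4)}"
        )
    k = int(idx[0])
    if axis == "P":
        resp = m.values[k, :, :]
        conc = m.p_levels
    else:
        resp = m.values[:, k, :]
        conc = m.i_levels
    return DoseResponseSeries(conc=conc.copy(), responses=resp.copy(), axis=axis, fixed_level=fixed_level)


# ---------------------------------------------------------------------------
# 4PL fitting


def _geomedian(levels: np.ndarray) -> float:
    nz = levels[levels > 0]
    if nz.size == 0:
        return 1.0
    return float(np.exp(np.median(np.log(nz))))


def _fit_once_4pl(c, y, w, start: dict) -> lmfit.minimizer.MinimizerResult:
    p = lmfit.Parameters()
    ymag = max(1.0, float(np.max(np.abs(y))))
    p.add("y0", value=start["y0"], min=0.0)
    p.add("span", value=max(start["span"], 1e-6 * ymag), min=0.0)
    p.add("ec50", value=start["ec50"], min=1e-12)
    p.add("n", value=start["n"], min=_N_BOUNDS[0], max=_N_BOUNDS[1])

    def resid(pars):
        v = pars.valuesdict()
        model = v["y0"] + v["span"] * hill(c, v["ec50"], v["n"])
        r = model - y
        return r * w if w is not None else r

    return lmfit.minimize(resid, p, method="leastsq", max_nfev=_MAX_ITER * 5)


def fit_four_pl(
    series: DoseResponseSeries | tuple[np.ndarray, np.ndarray],
    weights: np.ndarray | None = None,
    inverse_y_weighting: bool = False,
) -> FourPLFit:
    """Fit a four-parameter logistic to a titration series.

    Replicates are pooled (each replicate is an observation). Starts are
    deterministic and data-driven: basal from the series minimum, span from
    the range, EC50 from the geometric median of nonzero concentrations,
    Hill coefficient from {0.5, 1, 2}. The best start by residual sum of
    squares wins; ties break toward the lower Hill coefficient. EC10, EC90
    and DRLR = EC90/EC10 are derived from the fitted parameters.

    Parameters
    ----------
    weights : array, optional
        Per-observation residual weights (after pooling/NaN removal).
    inverse_y_weighting : bool
        Use 1/y weights for variance-proportional noise instead.
    """
    if isinstance(series, DoseResponseSeries):
        c, y = series.pooled()
    else:
        c = np.asarray(series[0], dtype=float)
        y = np.asarray(series[1], dtype=float)
        keep = np.isfinite(y)
        c, y = c[keep], y[keep]
    if np.unique(c).size < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct concentrations, got {np.unique(c).size}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    w = None
    if inverse_y_weighting:
        w = 1.0 / np.maximum(y, 1e-12 * max(1.0, float(np.max(y))))
    if weights is not None:
        w = np.asarray(weights, dtype=float) if w is None else w * np.asarray(weights)

    span0 = float(np.max(y) - np.min(y))
    base = {
        "y0": max(float(np.min(y)), 0.0),
        "span": span0,
        "ec50": _geomedian(c),
        "n": 1.0,
    }
    starts = [dict(base, n=nn) for nn in (1.0, 0.5, 2.0)]

    best = None
    for s in starts:
        try:
            res = _fit_once_4pl(c, y, w, s)
        except Exception:
            continue
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        key = (rss, float(res.params["n"].value))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return FourPLFit(params=None, se={}, rss=np.inf, n_obs=y.size, converged=False,
                         warnings=["all starts failed"])
    res = best[1]
    v = res.params.valuesdict()
    rss = best[0][0]
    warns: list[str] = []

    ymag = max(1.0, float(np.max(np.abs(y))))
    flat = v["span"] <= 1e-8 * ymag
    at_n_bound = (
        abs(v["n"] - _N_BOUNDS[0]) < 1e-6 or abs(v["n"] - _N_BOUNDS[1]) < 1e-6
    )
    if flat:
        warns.append("no dynamic range: fitted span ~ 0; curve unidentifiable")
    if at_n_bound:
        warns.append(f"Hill coefficient at bound ({v['n']:.3g})")
    converged = bool(res.success) and not flat

    se = {}
    for name in ("y0", "span", "ec50", "n"):
        err = res.params[name].stderr
        se[name] = float(err) if err is not None else np.nan
    # ymax = y0 + span; propagate ignoring covariance if unavailable
    if res.covar is not None and res.var_names == ["y0", "span", "ec50", "n"]:
        cv = res.covar
        se["ymax"] = float(np.sqrt(max(cv[0, 0] + cv[1, 1] + 2 * cv[0, 1], 0.0)))
    else:
        se["ymax"] = float(np.hypot(se["y0"], se["span"]))

    if not converged:
        return FourPLFit(params=None, se=se, rss=rss, n_obs=y.size,
                         converged=False, warnings=warns)
    params = FourPLParams(y0=v["y0"], ymax=v["y0"] + v["span"], ec50=v["ec50"], n=v["n"])
    fit = FourPLFit(
        params=params,
        se=se,
        rss=rss,
        n_obs=y.size,
        converged=True,
        ec10=ec_quantile(params, 0.10),
        ec90=ec_quantile(params, 0.90),
        drlr=drlr_analytic(params),
        warnings=warns,
    )
    return fit


# ---------------------------------------------------------------------------
# global AND-gate fitting

_F1_STARTS = (0.01, 0.1, 0.5, 0.9)
_N_STARTS = (0.5, 1.0, 2.0)


def _fit_once_gate(i, p, y, start: dict, shared_n: bool) -> lmfit.minimizer.MinimizerResult:
    pars = lmfit.Parameters()
    pars.add("y0", value=start["y0"], min=0.0)
    pars.add("dy", value=max(start["dy"], 1e-9), min=0.0)
    pars.add("n", value=start["n"], min=_N_BOUNDS[0], max=_N_BOUNDS[1])
    pars.add("k1", value=start["k1"], min=1e-12)
    pars.add("k2", value=start["k2"], min=1e-12)
    pars.add("f1", value=start["f1"], min=0.0, max=1.0)
    if not shared_n:
        pars.add("n2", value=start["n"], min=_N_BOUNDS[0], max=_N_BOUNDS[1])

    def resid(q):
        v = q.valuesdict()
        n2 = v["n"] if shared_n else v["n2"]
        hi = hill(i, v["k1"], v["n"])
        hp = hill(p, v["k2"], n2)
        return v["y0"] + v["dy"] * hi * (v["f1"] + (1 - v["f1"]) * hp) - y

    return lmfit.minimize(resid, pars, method="leastsq", max_nfev=_MAX_ITER * 10)


def fit_and_gate_global(m: ExpressionMatrix, shared_n: bool = True) -> GlobalFit:
    """Jointly fit all AND-gate parameters to every cell of the matrix.

    Every replicate observation enters the least-squares objective. A
    deterministic multi-start grid over the leak fraction f1 in
    {0.01, 0.1, 0.5, 0.9} and Hill coefficient n in {0.5, 1, 2}, plus one
    data-driven f1 start from the corner responses, guards against local
    minima; the lowest-RSS start is returned (ties toward lower n).

    With ``shared_n=False`` a separate Hill coefficient is fitted per
    inducer axis (reported in ``se`` under ``n2``).
    """
    for name, lv in (("I", m.i_levels), ("P", m.p_levels)):
        if np.unique(lv).size == 1:
            par = "k1" if name == "I" else "k2"
            raise UnidentifiableError(
                f"single {name} level: parameter {par} is unidentifiable"
            )
        if np.unique(lv).size < 4:
            raise InsufficientDataError(
                f"need >= 4 {name} levels including 0, got {np.unique(lv).size}"
            )
    i, p, y = m.observations()
    if y.size <= 8:
        raise InsufficientDataError(f"need > 8 observations, got {y.size}")

    means = m.cell_means()
    y0_start = max(float(np.nanmin(means)), 0.0)
    dy_start = float(np.nanmax(means) - np.nanmin(means))
    k1_start = _geomedian(m.i_levels)
    k2_start = _geomedian(m.p_levels)
    # corner-based leak-fraction start: response at max I alone vs both inducers
    denom = means[-1, -1] - y0_start
    f1_data = (means[-1, 0] - y0_start) / denom if denom > 0 else 0.5
    f1_data = float(np.clip(f1_data, 0.01, 0.99))

    starts = [
        {"y0": y0_start, "dy": dy_start, "k1": k1_start, "k2": k2_start,
         "n": 1.0, "f1": f1_data}
    ]
    for f1s in _F1_STARTS:
        for ns in _N_STARTS:
            starts.append({"y0": y0_start, "dy": dy_start, "k1": k1_start,
                           "k2": k2_start, "n": ns, "f1": f1s})

    best = None
    tried = 0
    for s in starts:
        try:
            res = _fit_once_gate(i, p, y, s, shared_n)
        except Exception:
            continue
        tried += 1
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        key = (rss, float(res.params["n"].value))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return GlobalFit(params=None, se={}, rss=np.inf, n_obs=y.size,
                         converged=False, start_points_tried=tried,
                         warnings=["all starts failed"])
    res = best[1]
    v = res.params.valuesdict()
    warns: list[str] = []
    if v["f1"] >= 1.0 - 1e-3:
        warns.append(
            "f1 at upper bound: response is P-independent; "
            "k2 (and the P-axis Hill coefficient) are unidentifiable"
        )
    if v["dy"] <= 1e-8 * max(1.0, float(np.max(np.abs(y)))):
        warns.append("no dynamic range: fitted dy ~ 0")
    se = {}
    for name in res.params:
        err = res.params[name].stderr
        se[name] = float(err) if err is not None else np.nan
    params = ANDGateParams(
        y0=v["y0"], dy=v["dy"], n=v["n"], k1=v["k1"], k2=v["k2"], f1=v["f1"],
        n2=None if shared_n else v["n2"],
    )
    return GlobalFit(
        params=params,
        se=se,
        rss=best[0][0],
        n_obs=y.size,
        converged=bool(res.success),
        start_points_tried=tried,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# contours


def extract_contours(
    fit: GlobalFit | ANDGateParams,
    i_range: tuple[float, float] | None = None,
    p_range: tuple[float, float] | None = None,
    levels: Sequence[float] = (0.10, 0.50, 0.90),
    n_grid: int = 60,
) -> ContourSet:
    """Analytic iso-response contours of the fitted AND-gate surface.

    For each level q (normalized response, basal-subtracted fraction of dy)
    the P solving ``H(I)(f1 + (1-f1)H(P)) = q`` is computed at each log-
    spaced I grid point, and symmetrically I at each P grid point; grid
    points where the level is unreachable (or already exceeded at P = 0 by
    the f1 leak) are omitted. Points are returned ordered by increasing I.
    """
    params = fit.params if isinstance(fit, GlobalFit) else fit
    if params is None:
        raise ValueError("cannot extract contours from a non-converged fit")
    if i_range is None:
        i_range = (params.k1 * 1e-2, params.k1 * 1e2)
    if p_range is None:
        p_range = (params.k2 * 1e-2, params.k2 * 1e2)
    n1, n2 = params.n, (params.n if params.n2 is None else params.n2)
    f1 = params.f1
    i_grid = np.geomspace(i_range[0], i_range[1], n_grid)
    p_grid = np.geomspace(p_range[0], p_range[1], n_grid)

    curves: dict[float, np.ndarray] = {}
    for q in levels:
        if not 0.0 < q < 1.0:
            raise ValueError(f"contour levels must lie in (0, 1), got {q}")
        pts: list[tuple[float, float]] = []
        # P(I) branch
        for iv in i_grid:
            g = hill(iv, params.k1, n1)
            if g <= q:  # even saturating P cannot reach q at this I
                continue
            t = q / g
            if f1 >= 1.0:
                continue
            h = (t - f1) / (1.0 - f1)
            if h <= 0.0 or h >= 1.0:
                continue
            pts.append((float(iv), float(params.k2 * (h / (1 - h)) ** (1.0 / n2))))
        # I(P) branch
        for pv in p_grid:
            amp = f1 + (1.0 - f1) * hill(pv, params.k2, n2)
            g = q / amp
            if g >= 1.0:
                continue
            pts.append((float(params.k1 * (g / (1 - g)) ** (1.0 / n1)), float(pv)))
        if not pts:
            _warnings.warn(
                f"level {q} unreachable anywhere on the grid; empty contour",
                stacklevel=2,
            )
            curves[q] = np.empty((0, 2))
            continue
        arr = np.array(sorted(set(pts)))
        curves[q] = arr
    return ContourSet(levels=tuple(levels), curves=curves)


# ---------------------------------------------------------------------------
# numeric DRLR


def drlr_numeric(
    model_curve: Callable[[float], float],
    y0: float,
    ymax: float,
    bracket: tuple[float, float] = (1e-6, 1e6),
    max_expansions: int = 20,
) -> float:
    """EC90/EC10 by bisection on an arbitrary monotone dose-response curve.

    Serves non-logistic slices of the AND-gate surface; on an exact 4PL it
    agrees with the closed form 81**(1/n).
    """
    from scipy.optimize import brentq

    if not ymax > y0:
        raise ValueError("requires ymax > y0 (activating curve)")

    def f(x: float) -> float:
        return (model_curve(x) - y0) / (ymax - y0)

    probe = np.geomspace(bracket[0], bracket[1], 50)
    vals = np.array([f(x) for x in probe])
    if np.any(np.diff(vals) < -1e-9):
        raise ValueError("curve is not monotone nondecreasing on the search interval")

    def solve(q: float) -> float:
        lo, hi = bracket
        for _ in range(max_expansions):
            if f(lo) < q < f(hi):
                return brentq(lambda x: f(x) - q, lo, hi, xtol=1e-14, rtol=1e-13)
            lo, hi = lo / 10.0, hi * 10.0
        raise ValueError(f"could not bracket the EC{int(q * 100)} root")

    return solve(0.90) / solve(0.10)
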