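"""Model fitting, nested F-test model selection and parameter maps.

Per-curve fitting is bounded nonlinear least squares of the forward
intensity-autocorrelation model to a measured g2(tau) curve. The zero-lag
point is always excluded (uncorrelated acquisition noise dominates it) and
the curve tail is cut where the correlation amplitude drops below 10% of
its first-lag value; if fewer than 5 points survive, the first 5 nonzero
lags are used.

Model complexity is chosen per pixel by a forward chain of F tests over the
nested family (Siegert -> +offset -> +static scattering -> +mixed
dynamics); at each single-component level the field-correlation exponent
n in {0.5, 1, 2} is chosen by minimum residual sum of squares, and at the
mixed level the second-component exponent X in {0.5, 2} likewise.

Image-level fitting processes pixels in descending order of the tau_c
initializer and, after the first 30% of pixels, adaptively constrains the
beta upper bound and rho lower bound to mean +/- 2 SD over the most recent
30% of (converged) fits, which suppresses the characteristic artifacts of
low beta in slow pixels and low rho in fast pixels.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .correlation import G2Curve
from .models import (
    MIX_EXPONENTS,
    DLSIParams,
    ModelLevel,
    ModelSpec,
    Regime,
    classify_regime,
    regime_for_pure_n,
)

__all__ = [
    "FitWindow",
    "FitBounds",
    "FitResult",
    "ParameterMaps",
    "tau_c_initial",
    "fit_window",
    "fit_curve",
    "select_model",
    "fit_image",
    "rcbf_dlsi",
]

#: Hard lower bound on tau_c in seconds (optimizer needs a finite bracket).
TAU_C_MIN = 1e-8

#: Minimum number of fitted points when the 10% tail rule is too aggressive.
MIN_WINDOW_POINTS = 5


@dataclass(frozen=True)
class FitWindow:
    """Ordered lag indices included in the fit; never contains lag 0."""

    indices: np.ndarray
    short: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(idx) and idx[0] == 0:
            raise ValueError("fit window must exclude lag index 0")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the model parameters.

    Defaults follow the conventional fitting ranges: [0, 1] for beta, rho
    and d, [-1, 1] for C, and (0, max lag] for tau_c (``tau_c_upper=None``
    resolves to the curve's maximum lag).
    """

    beta_upper: float = 1.0
    rho_lower: float = 0.0
    tau_c_upper: float | None = None
    c_range: tuple[float, float] = (-1.0, 1.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one curve."""

    params: DLSIParams
    model: ModelSpec
    rss: float
    window: FitWindow
    tau_c_init: float
    regime: Regime
    converged: bool

    @property
    def n_points(self) -> int:
        return len(self.window)


def tau_c_initial(curve: G2Curve) -> tuple[float, bool]:
    """Initial tau_c estimate: lag where g2 crosses ``1 + (g2(0)-1)/e**2``.

    The crossing is linearly interpolated between samples. If the curve
    never reaches the threshold (or has no decay, g2(0) <= 1), the maximum
    lag is returned with ``found=False``.
    """
    if len(curve) < 2:
        raise ValueError("curve must have at least two lags")
    g = curve.values
    lags = curve.lags
    amp = g[0] - 1.0
    if amp <= 0:
        return float(lags[-1]), False
    threshold = 1.0 + amp / np.e**2
    below = np.nonzero(g < threshold)[0]
    below = below[below > 0]
    if len(below) == 0:
        return float(lags[-1]), False
    k = below[0]
    g_hi, g_lo = g[k - 1], g[k]
    if g_hi - g_lo <= 0:  # flat segment; no unique crossing to interpolate
        return float(lags[k]), True
    frac = float(np.clip((g_hi - threshold) / (g_hi - g_lo), 0.0, 1.0))
    return float(lags[k - 1] + frac * (lags[k] - lags[k - 1])), True


def fit_window(curve: G2Curve) -> FitWindow:
    """Select the lag indices used for fitting.

    Lag 0 is always excluded. The tail is cut at the first lag where the
    correlation amplitude ``g2 - 1`` drops below 10% of its value at the
    first nonzero lag; if fewer than ``MIN_WINDOW_POINTS`` survive, the
    first ``MIN_WINDOW_POINTS`` nonzero lags are used instead. Curves
    shorter than 6 lags return all nonzero lags flagged as short.
    """
    if len(curve) < 2:
        raise ValueError("curve must have at least two lags")
    n = len(curve)
    if n < MIN_WINDOW_POINTS + 1:
        return FitWindow(indices=np.arange(1, n), short=True)
    amp = curve.values[1] - 1.0
    rel = curve.values[1:] - 1.0
    below = np.nonzero(rel < 0.1 * amp)[0]
    cut = below[0] + 1 if len(below) else n  # absolute index of first tail point
    if cut - 1 < MIN_WINDOW_POINTS:
        return FitWindow(indices=np.arange(1, MIN_WINDOW_POINTS + 1))
    return FitWindow(indices=np.arange(1, cut))


# --- packed parameter vectors -------------------------------------------------
# SIEGERT:        [beta, tau_c]
# SIEGERT_OFFSET: [beta, tau_c, C]
# STATIC:         [beta, rho, tau_c, C]
# MIXED:          [beta, rho, tau_c, d, C]


def _model_values(tau: np.ndarray, level: ModelLevel, n_fixed: float, X: float,
                  x: np.ndarray) -> np.ndarray:
    if level == ModelLevel.MIXED:
        b, r, tc, d, c = x
        m = d * np.exp(-((tau / tc) ** X)) + (1.0 - d) * np.exp(-(tau / tc))
    else:
        if level == ModelLevel.SIEGERT:
            b, tc = x
            r, c = 1.0, 0.0
        elif level == ModelLevel.SIEGERT_OFFSET:
            b, tc, c = x
            r = 1.0
        else:
            b, r, tc, c = x
        m = np.exp(-((tau / tc) ** n_fixed))
    return 1.0 + b * r * r * m * m + 2.0 * b * (1.0 - r) * r * m + c


def _bounds_vectors(level: ModelLevel, bounds: FitBounds, tau_c_upper: float):
    bu = max(bounds.beta_upper, 1e-6)
    rl = min(bounds.rho_lower, 1.0 - 1e-9)
    cl, cu = bounds.c_range
    if level == ModelLevel.SIEGERT:
        return np.array([0.0, TAU_C_MIN]), np.array([bu, tau_c_upper])
    if level == ModelLevel.SIEGERT_OFFSET:
        return np.array([0.0, TAU_C_MIN, cl]), np.array([bu, tau_c_upper, cu])
    if level == ModelLevel.STATIC:
        return (np.array([0.0, rl, TAU_C_MIN, cl]),
                np.array([bu, 1.0, tau_c_upper, cu]))
    return (np.array([0.0, rl, TAU_C_MIN, 0.0, cl]),
            np.array([bu, 1.0, tau_c_upper, 1.0, cu]))


def _initial_vector(level: ModelLevel, beta0: float, tau0: float,
                    lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    if level == ModelLevel.SIEGERT:
        x0 = np.array([beta0, tau0])
    elif level == ModelLevel.SIEGERT_OFFSET:
        x0 = np.array([beta0, tau0, 0.0])
    elif level == ModelLevel.STATIC:
        x0 = np.array([beta0, 0.9, tau0, 0.0])
    else:
        x0 = np.array([beta0, 0.9, tau0, 0.5, 0.0])
    eps = 1e-12 + 1e-9 * (ub - lb)
    return np.clip(x0, lb + eps, ub - eps)


def _params_from_vector(level: ModelLevel, n_fixed: float, X: float,
                        x: np.ndarray) -> DLSIParams:
    if level == ModelLevel.MIXED:
        b, r, tc, d, c = x
        return DLSIParams(
            beta=float(np.clip(b, 0, 1)), rho=float(np.clip(r, 0, 1)),
            tau_c=float(max(tc, TAU_C_MIN)), d=float(np.clip(d, 0, 1)),
            X=float(X), C=float(np.clip(c, -1, 1)),
        )
    if level == ModelLevel.SIEGERT:
        b, tc = x
        r, c = 1.0, 0.0
    elif level == ModelLevel.SIEGERT_OFFSET:
        b, tc, c = x
        r = 1.0
    else:
        b, r, tc, c = x
    if n_fixed == 1.0:
        d, xx = 0.0, 0.5
    else:
        d, xx = 1.0, n_fixed
    return DLSIParams(
        beta=float(np.clip(b, 0, 1)), rho=float(np.clip(r, 0, 1)),
        tau_c=float(max(tc, TAU_C_MIN)), d=d, X=xx, C=float(np.clip(c, -1, 1)),
    )


def _regime_of(model: ModelSpec, params: DLSIParams) -> Regime:
    if model.level == ModelLevel.MIXED:
        return classify_regime(model.X, params.d)
    return regime_for_pure_n(model.n_fixed)


def fit_curve(
    curve: G2Curve,
    model: ModelSpec,
    bounds: FitBounds | None = None,
    window: FitWindow | None = None,
    tau_c_init: float | None = None,
    warm_start: np.ndarray | None = None,
) -> FitResult:
    """Fit one model to one curve by bounded nonlinear least squares.

    ``tau_c_init`` defaults to :func:`tau_c_initial`; ``window`` defaults to
    :func:`fit_window`. When ``warm_start`` (a packed parameter vector of the
    model's dimension) is given, both it and the default initialization are
    tried and the lower-RSS solution returned — used by :func:`select_model`
    to guarantee that nested models never fit worse than their restriction.
    """
    bounds = bounds or FitBounds()
    if window is None:
        window = fit_window(curve)
    tau = curve.lags[window.indices]
    y = curve.values[window.indices]
    found = True
    if tau_c_init is None:
        tau_c_init, found = tau_c_initial(curve)
    tau_c_upper = bounds.tau_c_upper if bounds.tau_c_upper else float(curve.lags[-1])
    lb, ub = _bounds_vectors(model.level, bounds, tau_c_upper)
    beta0 = min(max(curve.values[window.indices[0]] - 1.0, 1e-3), 1.0)
    tau0 = float(np.clip(tau_c_init, TAU_C_MIN * 10, tau_c_upper))
    x0 = _initial_vector(model.level, beta0, tau0, lb, ub)

    def residual(x):
        return _model_values(tau, model.level, model.n_fixed, model.X, x) - y

    def solve(x_init):
        scale = np.ones_like(x_init)
        scale[2 if model.level >= ModelLevel.STATIC else 1] = max(tau0, TAU_C_MIN * 10)
        return least_squares(
            residual, x_init, bounds=(lb, ub), method="trf",
            x_scale=scale, ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400,
        )

    res = solve(x0)
    if warm_start is not None:
        eps = 1e-12 + 1e-9 * (ub - lb)
        res2 = solve(np.clip(np.asarray(warm_start, dtype=float), lb + eps, ub - eps))
        if res2.cost < res.cost:
            res = res2
    params = _params_from_vector(model.level, model.n_fixed, model.X, res.x)
    degenerate = curve.values[window.indices[0]] - 1.0 <= 0 and params.beta < 1e-6
    return FitResult(
        params=params,
        model=model,
        rss=float(2.0 * res.cost),
        window=window,
        tau_c_init=tau_c_init,
        regime=_regime_of(model, params),
        converged=bool(res.success and found) and not degenerate,
    )


def _pack(result: FitResult) -> np.ndarray:
    p = result.params
    level = result.model.level
    if level == ModelLevel.SIEGERT:
        return np.array([p.beta, p.tau_c])
    if level == ModelLevel.SIEGERT_OFFSET:
        return np.array([p.beta, p.tau_c, p.C])
    if level == ModelLevel.STATIC:
        return np.array([p.beta, p.rho, p.tau_c, p.C])
    return np.array([p.beta, p.rho, p.tau_c, p.d, p.C])


def _embed(simple: FitResult, level: ModelLevel, X: float) -> np.ndarray:
    """Embed a simpler solution as a starting vector for the next level."""
    p = simple.params
    if level == ModelLevel.SIEGERT_OFFSET:
        return np.array([p.beta, p.tau_c, 0.0])
    if level == ModelLevel.STATIC:
        return np.array([p.beta, 1.0, p.tau_c, p.C])
    # mixed: exact embedding exists when the simple n matches the mixture ends
    n_simple = simple.model.n_fixed
    if n_simple == 1.0:
        d0 = 0.0
    elif n_simple == X:
        d0 = 1.0
    else:
        d0 = 0.5
    return np.array([p.beta, p.rho, p.tau_c, d0, p.C])


def f_test_pvalue(rss_simple: float, rss_complex: float, delta_p: int,
                  n_points: int, p_complex: int) -> float:
    """Upper-tail p-value of the nested-model F statistic.

    ``F = ((RSS_s - RSS_c)/delta_p) / (RSS_c/(n - p_c))`` with
    ``(delta_p, n - p_c)`` degrees of freedom. A perfect complex fit
    (RSS_c = 0) gives p = 0.
    """
    dof2 = n_points - p_complex
    if dof2 <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss_complex <= 0.0:
        return 0.0
    f_stat = ((rss_simple - rss_complex) / delta_p) / (rss_complex / dof2)
    if f_stat <= 0:
        return 1.0
    return float(f_dist.sf(f_stat, delta_p, dof2))


def select_model(
    curve: G2Curve,
    alpha: float = 0.05,
    bounds: FitBounds | None = None,
    window: FitWindow | None = None,
) -> tuple[FitResult, list[FitResult]]:
    """Choose model complexity by a forward chain of F tests.

    Fits the nested chain Siegert -> +offset -> +static -> +mixed, choosing
    the best field exponent (n, or X at the mixed level) by minimum RSS
    within each level. Each level is tested against the currently accepted
    model (with the parameter-count difference as the numerator degrees of
    freedom) and accepted when the F test is significant at ``alpha``, so
    the chain does not stop at the first non-significant step and the
    false-selection rate of the most complex model stays near ``alpha``.
    Levels with no residual degrees of freedom are skipped. Returns the
    accepted fit and the per-level record of best fits.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if window is None:
        window = fit_window(curve)
    n_pts = len(window)
    tau_c_init, _ = tau_c_initial(curve)

    def best_at_level(level: ModelLevel, current: FitResult | None) -> FitResult:
        candidates = []
        forms = MIX_EXPONENTS if level == ModelLevel.MIXED else (0.5, 1.0, 2.0)
        for form in forms:
            spec = (ModelSpec(level=level, X=form) if level == ModelLevel.MIXED
                    else ModelSpec(level=level, n_fixed=form))
            warm = _embed(current, level, spec.X) if current is not None else None
            candidates.append(
                fit_curve(curve, spec, bounds=bounds, window=window,
                          tau_c_init=tau_c_init, warm_start=warm)
            )
        return min(candidates, key=lambda r: r.rss)

    record: list[FitResult] = []
    current = best_at_level(ModelLevel.SIEGERT, None)
    record.append(current)
    for level in (ModelLevel.SIEGERT_OFFSET, ModelLevel.STATIC, ModelLevel.MIXED):
        p_complex = ModelSpec(level=level).free_parameter_count
        if n_pts <= p_complex:
            break
        candidate = best_at_level(level, current)
        record.append(candidate)
        p_val = f_test_pvalue(current.rss, candidate.rss, 1, n_pts, p_complex)
        if p_val <= alpha:
            current = candidate
        else:
            break
    return current, record


@dataclass
class ParameterMaps:
    """Per-pixel images of the fitted parameters and labels."""

    tau_c: np.ndarray
    rho: np.ndarray
    beta: np.ndarray
    C: np.ndarray
    d: np.ndarray
    regime: np.ndarray        # int codes from models.Regime
    model_level: np.ndarray   # int codes from models.ModelLevel, -1 invalid
    converged: np.ndarray
    rss: np.ndarray
    tau_c_init: np.ndarray

    @classmethod
    def empty(cls, h: int, w: int) -> "ParameterMaps":
        nan = lambda: np.full((h, w), np.nan)
        return cls(
            tau_c=nan(), rho=nan(), beta=nan(), C=nan(), d=nan(),
            regime=np.full((h, w), int(Regime.INVALID), dtype=int),
            model_level=np.full((h, w), -1, dtype=int),
            converged=np.zeros((h, w), dtype=bool),
            rss=nan(), tau_c_init=nan(),
        )

    def set_pixel(self, y: int, x: int, result: FitResult) -> None:
        p = result.params
        self.tau_c[y, x] = p.tau_c
        self.rho[y, x] = p.rho
        self.beta[y, x] = p.beta
        self.C[y, x] = p.C
        self.d[y, x] = p.d if result.model.level == ModelLevel.MIXED else (
            0.0 if result.model.n_fixed == 1.0 else 1.0)
        self.regime[y, x] = int(result.regime)
        self.model_level[y, x] = int(result.model.level)
        self.converged[y, x] = result.converged
        self.rss[y, x] = result.rss
        self.tau_c_init[y, x] = result.tau_c_init

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "tau_c": self.tau_c, "rho": self.rho, "beta": self.beta,
            "C": self.C, "d": self.d, "regime": self.regime,
            "model_level": self.model_level, "converged": self.converged,
            "rss": self.rss, "tau_c_init": self.tau_c_init,
        }


class _AdaptiveBounds:
    """Streaming mean/SD of recent (beta, rho) fits for adaptive constraints.

    Activates after 30% of pixels are fitted; the statistics window holds
    the most recent ceil(0.3 * n_pixels) converged fits and the bounds are
    recomputed for each next pixel as <beta> + 2 sd and <rho> - 2 sd.
    """

    def __init__(self, n_pixels: int):
        self.activation = int(np.ceil(0.3 * n_pixels))
        self.window: deque[tuple[float, float]] = deque(maxlen=self.activation)
        self.fitted = 0

    def record(self, result: FitResult) -> None:
        self.fitted += 1
        if result.converged:
            self.window.append((result.params.beta, result.params.rho))

    def current(self, base: FitBounds) -> FitBounds:
        if self.fitted < self.activation or len(self.window) < 2:
            return base
        arr = np.asarray(self.window)
        beta_up = float(np.clip(arr[:, 0].mean() + 2 * arr[:, 0].std(), 1e-3, 1.0))
        rho_low = float(np.clip(arr[:, 1].mean() - 2 * arr[:, 1].std(), 0.0, 1.0))
        return replace(base, beta_upper=beta_up, rho_lower=rho_low)


def _pixel_order(tau_init_flat: np.ndarray) -> np.ndarray:
    """Descending tau_c_init, ties broken by raster (row-major) order."""
    return np.lexsort((np.arange(len(tau_init_flat)), -tau_init_flat))


def fit_image(
    lags: np.ndarray,
    g2: np.ndarray,
    degenerate: np.ndarray | None = None,
    model: ModelSpec | str = "auto",
    alpha: float = 0.05,
    adaptive_bounds: bool = True,
    bounds: FitBounds | None = None,
    progress: bool = False,
) -> ParameterMaps:
    """Fit every pixel of an H x W x L g2 array and assemble parameter maps.

    ``model`` is either a fixed :class:`ModelSpec` or ``"auto"`` for F-test
    selection per pixel. Degenerate pixels keep sentinel values (NaN /
    invalid codes) at their positions. With ``adaptive_bounds=False`` the
    result equals independent per-pixel fits.
    """
    h, w, n_lags = g2.shape
    if degenerate is None:
        degenerate = ~np.isfinite(g2).all(axis=2)
    else:
        degenerate = degenerate | ~np.isfinite(g2).all(axis=2)
    maps = ParameterMaps.empty(h, w)
    base_bounds = bounds or FitBounds()

    flat = g2.reshape(h * w, n_lags)
    valid = np.nonzero(~degenerate.ravel())[0]
    if len(valid) == 0:
        return maps

    curves = {}
    tau_init = np.full(h * w, -np.inf)
    n_pairs = np.ones(n_lags, dtype=int)
    for j in valid:
        curve = G2Curve(lags=lags, values=flat[j], n_pairs=n_pairs)
        curves[j] = curve
        tau_init[j], _ = tau_c_initial(curve)

    order = _pixel_order(tau_init)
    order = order[~degenerate.ravel()[order]]
    adapt = _AdaptiveBounds(len(valid)) if adaptive_bounds else None

    for count, j in enumerate(order):
        y, x = divmod(j, w)
        eff_bounds = adapt.current(base_bounds) if adapt else base_bounds
        if model == "auto":
            result, _ = select_model(curves[j], alpha=alpha, bounds=eff_bounds)
        else:
            result = fit_curve(curves[j], model, bounds=eff_bounds)
        maps.set_pixel(y, x, result)
        if adapt:
            adapt.record(result)
        if progress and count % 100 == 0:
            import sys
            print(f"fit {count + 1}/{len(order)} pixels", file=sys.stderr)
    return maps


def rcbf_dlsi(tau_c_baseline, tau_c_test):
    """Relative blood flow from correlation times: tau_c_baseline / tau_c_test.

    Flow slowdowns lengthen tau_c, so a ratio below one indicates reduced
    flow in the test condition.
    """
    tb = np.asarray(tau_c_baseline, dtype=float)
    tt = np.asarray(tau_c_test, dtype=float)
    if np.any(tb <= 0) or np.any(tt <= 0):
        raise ValueError("correlation times must be > 0")
    out = tb / tt
    return out if out.ndim else float(out)
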