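"""Per-transcript weighted nonlinear regression and bootstrap CIs.

Each transcript's normalized labeled counts from both replicates are pooled
and fit to Y(t) = Y_eq * (1 - exp(-alpha (t - t_d))) by weighted least
squares with weights 1/Y.  Count variance grows with the mean, so 1/Y
weighting keeps late, plateau-level points from dominating the fit; weights
use the observed values, floored at ``weight_floor`` so zero counts stay
finite.  t_d is fixed from the config, alpha is constrained positive, and
alpha_rna = alpha - alpha_growth.

Confidence intervals are percentile bootstrap (2.5/97.5) over resamples of
the observation list, re-estimating alpha only with Y_eq frozen at the point
estimate: resamples that miss the late part of the curve cannot pin down
Y_eq, so the one-parameter refit is what keeps the bootstrap stable.
Iterations that still degenerate (fewer than two distinct times, no
positive signal, an optimizer error, or alpha pinned at a box bound) are
counted as failures and left out of the percentile pool.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .io import KineticEstimate, NormalizedSeries, RunConfig
from .kinetics import half_life

__all__ = ["FitObservations", "make_observations", "fit_transcript", "bootstrap_ci", "fit_all"]

_ALPHA_MIN = 1e-6


@dataclass
class FitObservations:
    """Pooled (t, y, weight) observations for one transcript's fit."""

    transcript_id: str
    t: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def make_observations(series: NormalizedSeries, cfg: RunConfig) -> FitObservations:
    """Collect included points from both replicates with 1/Y weights."""
    inc = series.included()
    y = inc["value"].to_numpy(float)
    t = inc["time_min"].to_numpy(float)
    w = 1.0 / np.maximum(y, cfg.weight_floor)
    return FitObservations(series.transcript_id, t, y, w)


def _curve(t: np.ndarray, alpha: float, t_d: float) -> np.ndarray:
    """Saturation term (1 - exp(-alpha (t - t_d))), zero before the delay."""
    dt = np.clip(t - t_d, 0.0, None)
    return -np.expm1(-alpha * dt)


def _wsse(obs: FitObservations, alpha: float, y_eq: float, t_d: float) -> float:
    r = obs.y - y_eq * _curve(obs.t, alpha, t_d)
    return float(np.sum(obs.w * r * r))


def _profile_y_eq(dt: np.ndarray, y: np.ndarray, w: np.ndarray, alpha) -> np.ndarray:
    """Optimal Y_eq given alpha: the objective is linear in Y_eq."""
    g = -np.expm1(-np.multiply.outer(np.atleast_1d(alpha), dt))
    denom = (g * g * w).sum(axis=-1)
    num = (g * w * y).sum(axis=-1)
    return np.clip(np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0), 0.0, None)


def _profiled_minimum(
    dt: np.ndarray, y: np.ndarray, w: np.ndarray, alpha_max: float
) -> tuple[float, float]:
    """Global search for alpha on the profiled 1-D objective.

    The (alpha, Y_eq) objective has a flat ridge toward alpha -> 0 with
    Y_eq -> inf for slow transcripts, where a joint Newton-type step can
    stall; profiling Y_eq out reduces the problem to one well-behaved
    dimension.  Coarse log-spaced scan, then bounded scalar refinement.
    """
    grid = np.exp(np.linspace(np.log(1e-5), np.log(alpha_max), 120))
    y_eq = _profile_y_eq(dt, y, w, grid)
    r = y[None, :] - y_eq[:, None] * -np.expm1(-np.outer(grid, dt))
    sse = (w * r * r).sum(axis=1)
    i = int(np.argmin(sse))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]

    def f(a):
        ye = float(_profile_y_eq(dt, y, w, a)[0])
        res = y - ye * -np.expm1(-a * dt)
        return float(np.sum(w * res * res))

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    alpha = float(res.x) if res.success and res.fun <= sse[i] else float(grid[i])
    return alpha, float(_profile_y_eq(dt, y, w, alpha)[0])


def fit_transcript(obs: FitObservations, cfg: RunConfig) -> KineticEstimate:
    """Weighted least-squares fit of (alpha, Y_eq) for one transcript.

    Returns a non-converged estimate (NaN parameters) when there are fewer
    than ``min_points`` usable observations, fewer than
    ``min_distinct_times`` distinct times past the delay, no positive
    signal, or the optimizer fails.
    """
    est = KineticEstimate(transcript_id=obs.transcript_id, n_points_used=len(obs))
    usable = obs.t > cfg.t_d
    if (
        len(obs) < cfg.min_points
        or len(np.unique(obs.t[usable])) < cfg.min_distinct_times
        or not (obs.y > 0).any()
    ):
        return est

    sw = np.sqrt(obs.w)
    dt = np.clip(obs.t - cfg.t_d, 0.0, None)
    alpha0, y_eq0 = _profiled_minimum(dt, obs.y, obs.w, cfg.alpha_max)

    def resid(p):
        alpha, y_eq = p
        return sw * (obs.y - y_eq * -np.expm1(-alpha * dt))

    def jac(p):
        alpha, y_eq = p
        e = np.exp(-alpha * dt)
        return np.column_stack((-sw * y_eq * dt * e, -sw * -np.expm1(-alpha * dt)))

    alpha, y_eq = alpha0, y_eq0
    try:
        # polish the profiled solution with bounded LS (analytic Jacobian)
        res = least_squares(
            resid,
            x0=[alpha0, max(y_eq0, 1e-9)],
            jac=jac,
            bounds=([_ALPHA_MIN, 1e-12], [cfg.alpha_max, np.inf]),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-10,
        )
        if (
            res.status > 0
            and np.isfinite(res.x).all()
            and np.sum(resid(res.x) ** 2) <= np.sum(resid([alpha0, max(y_eq0, 1e-9)]) ** 2)
        ):
            alpha, y_eq = map(float, res.x)
    except Exception:
        pass
    if y_eq <= 0 or not np.isfinite(alpha):
        return est
    est.alpha_total = alpha
    est.alpha_rna = alpha - cfg.alpha_growth
    est.y_eq = y_eq
    est.half_life = half_life(alpha, cfg.alpha_growth)
    est.converged = True
    return est


def _refit_alpha(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, y_eq: float, cfg: RunConfig
) -> float | None:
    """1-D weighted refit of alpha with Y_eq frozen; None on failure."""
    dt = np.clip(t - cfg.t_d, 0.0, None)
    if len(np.unique(t[t > cfg.t_d])) < cfg.min_distinct_times or not (y > 0).any():
        return None

    def f(alpha):
        r = y - y_eq * -np.expm1(-alpha * dt)
        return float(np.sum(w * r * r))

    try:
        res = minimize_scalar(
            f, bounds=(_ALPHA_MIN, cfg.alpha_max), method="bounded",
            options={"xatol": 1e-10},
        )
    except Exception:
        return None
    if not res.success:
        return None
    a = float(res.x)
    # an estimate pinned at a box bound is a non-identified resample
    if a <= 2 * _ALPHA_MIN or a >= cfg.alpha_max * (1 - 1e-6):
        return None
    return a


def bootstrap_ci(
    obs: FitObservations,
    fitted: KineticEstimate,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, int, bool]:
    """Percentile-bootstrap 95% CI on alpha_total, Y_eq frozen.

    Returns (ci_low, ci_high, n_failures, unreliable); ``unreliable`` is set
    when fewer than ``min_bootstrap_converged_frac`` of the iterations yield
    a usable alpha.
    """
    if not fitted.converged:
        raise ValueError(f"{obs.transcript_id}: cannot bootstrap a non-converged fit")
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    n = len(obs)
    alphas = []
    n_fail = 0
    if cfg.bootstrap_unit == "timepoint":
        times = np.unique(obs.t)
        groups = [np.flatnonzero(obs.t == t) for t in times]
    for _ in range(cfg.n_bootstrap):
        if cfg.bootstrap_unit == "timepoint":
            picks = rng.integers(0, len(groups), len(groups))
            idx = np.concatenate([groups[p] for p in picks])
        else:
            idx = rng.integers(0, n, n)
        a = _refit_alpha(obs.t[idx], obs.y[idx], obs.w[idx], fitted.y_eq, cfg)
        if a is None:
            n_fail += 1
        else:
            alphas.append(a)
    if not alphas:
        return float("nan"), float("nan"), n_fail, True
    lo, hi = np.percentile(alphas, [2.5, 97.5])
    unreliable = len(alphas) < cfg.min_bootstrap_converged_frac * cfg.n_bootstrap
    return float(lo), float(hi), n_fail, unreliable


def _transcript_rng(seed: int, transcript_id: str) -> np.random.Generator:
    """Independent stream per transcript, keyed by id: order-independent."""
    key = zlib.crc32(transcript_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def fit_all(
    series_list: list[NormalizedSeries], cfg: RunConfig, with_ci: bool = True
) -> list[KineticEstimate]:
    """Fit every transcript; deterministic given ``cfg.rng_seed``.

    Each transcript draws from its own RNG stream keyed by id, so results do
    not depend on the order transcripts are processed in.
    """
    out = []
    for series in series_list:
        obs = make_observations(series, cfg)
        est = fit_transcript(obs, cfg)
        if est.converged and with_ci:
            rng = _transcript_rng(cfg.rng_seed, series.transcript_id)
            est.ci_low, est.ci_high, est.n_bootstrap_failures, est.ci_unreliable = bootstrap_ci(
                obs, est, cfg, rng
            )
        out.append(est)
    return out
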