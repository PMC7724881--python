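"""Empirical false discovery rate estimation by EM on a censored mixture.

Significant p values (those below a threshold ``alpha``) are modelled as
a two-component mixture: false discoveries are uniform on (0, alpha),
true discoveries follow a Beta(a, b) distribution truncated to
(0, alpha).  The mixing weight ``pi0`` of the uniform component is the
empirical false discovery rate.

Reported p values are rarely exact.  A rounded report ("p = 0.01")
contributes the probability of the rounding interval (0.005, 0.015); a
truncated report ("p < 0.05") contributes the probability of (0, 0.05).
The EM algorithm below maximises this interval (censored) likelihood
jointly over (pi0, a, b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .records import CLASS_EXACT, CLASS_ROUNDED, CLASS_TRUNCATED, ReportedPValue

logger = logging.getLogger(__name__)

_AB_BOUNDS = (1e-3, 1e3)
_PI0_BOUNDS = (1e-6, 1.0 - 1e-6)


class DegenerateParameterError(ValueError):
    """Beta mass below alpha vanishes numerically for these shapes."""


class RecordExcluded(ValueError):
    """The report's likelihood interval is empty after intersection with (0, alpha]."""


class InsufficientDataError(ValueError):
    """Fewer usable records than the configured minimum per fit."""


@dataclass(frozen=True)
class MixtureParams:
    """Parameters (pi0, a, b) of the significant-p-value mixture.

    The fitted mixture has pi0 strictly inside (0, 1); the closed bounds
    here additionally admit the degenerate pure-uniform (pi0 = 1) and
    pure-Beta (pi0 = 0) cases used when simulating from a single
    component.  EM keeps its iterates inside the open interval.
    """

    pi0: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in [0, 1], got {self.pi0}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"Beta shapes must be positive, got a={self.a}, b={self.b}")


@dataclass
class EstimatorConfig:
    alpha: float = 0.05
    tol: float = 1e-6
    max_iter: int = 2000
    init: MixtureParams = field(default_factory=lambda: MixtureParams(0.5, 1.0, 20.0))
    n_multistart: int = 1
    min_count: int = 10
    mstep_maxiter: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    params: MixtureParams
    loglik: float
    n_iter: int
    converged: bool
    n_used: int
    message: str = ""
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def truncated_beta_prob(lower: float, upper: float, a: float, b: float, alpha: float) -> float:
    """P(lower < P <= upper) for Beta(a, b) truncated to (0, alpha).

    Returns [F(upper) - F(lower)] / F(alpha) with F the Beta(a, b) CDF.
    """
    if not (0.0 <= lower <= upper <= alpha):
        raise ValueError("need 0 <= lower <= upper <= alpha")
    if a <= 0 or b <= 0:
        raise ValueError("Beta shapes must be positive")
    fa = special.betainc(a, b, alpha)
    if not np.isfinite(fa) or fa <= 1e-300:
        raise DegenerateParameterError(
            f"Beta({a}, {b}) has no numeric mass below alpha={alpha}"
        )
    num = special.betainc(a, b, upper) - special.betainc(a, b, lower)
    return float(np.clip(num / fa, 0.0, 1.0))


Interval = Union[float, tuple[float, float]]


def report_interval(record: ReportedPValue, alpha: float) -> Interval:
    """Likelihood support of one report: a point, or a censoring interval.

    Truncated reports integrate over (0, threshold); rounded reports over
    the half-unit rounding interval intersected with (0, alpha]; exact
    reports are point observations.  Raises :class:`RecordExcluded` when
    the intersection is empty.
    """
    if record.cls == CLASS_TRUNCATED:
        upper = min(record.value, alpha)
        if upper <= 0:
            raise RecordExcluded(f"truncation threshold {record.value} not above 0")
        return (0.0, upper)
    if record.cls == CLASS_ROUNDED:
        if record.decimals is None:
            raise ValueError("rounded report without decimal count")
        half = 0.5 * 10.0 ** (-record.decimals)
        lo = max(record.value - half, 0.0)
        hi = min(record.value + half, alpha)
        if lo >= hi:
            raise RecordExcluded(
                f"rounding interval of {record.value} ({record.decimals} dp) "
                f"is empty within (0, {alpha}]"
            )
        return (lo, hi)
    # exact
    if not 0.0 < record.value <= alpha:
        raise RecordExcluded(f"exact value {record.value} outside (0, {alpha}]")
    return float(record.value)


def observation_likelihood(record: ReportedPValue, params: MixtureParams, alpha: float) -> float:
    """Mixture likelihood contribution of one report (density or probability)."""
    iv = report_interval(record, alpha)
    if isinstance(iv, tuple):
        lo, hi = iv
        unif = (hi - lo) / alpha
        tb = truncated_beta_prob(lo, hi, params.a, params.b, alpha)
    else:
        fa = special.betainc(params.a, params.b, alpha)
        if fa <= 1e-300:
            raise DegenerateParameterError("no Beta mass below alpha")
        unif = 1.0 / alpha
        tb = float(stats.beta.pdf(iv, params.a, params.b)) / fa
    val = params.pi0 * unif + (1.0 - params.pi0) * tb
    if val <= 0:
        raise ValueError("non-positive likelihood for a valid record")
    return float(val)


# -- internal compiled representation ---------------------------------------


@dataclass
class _Compiled:
    """Deduplicated point/interval observations with multiplicities.

    ``lp`` and ``l1p`` cache log(p) and log1p(-p) of the point values:
    the weighted Beta log-density sum is linear in their weighted sums,
    which makes every M-step objective evaluation O(#unique intervals).
    """

    points: np.ndarray      # exact values
    w_points: np.ndarray
    lo: np.ndarray          # interval lower bounds
    hi: np.ndarray
    w_int: np.ndarray
    alpha: float
    n_records: int

    def __post_init__(self) -> None:
        self.lp = np.log(self.points) if self.points.size else np.empty(0)
        self.l1p = np.log1p(-self.points) if self.points.size else np.empty(0)

    @property
    def u(self) -> np.ndarray:
        """Uniform-component likelihood per compiled row (constant in params)."""
        up = np.full(self.points.shape, 1.0 / self.alpha)
        ui = (self.hi - self.lo) / self.alpha
        return np.concatenate([up, ui])

    @property
    def w(self) -> np.ndarray:
        return np.concatenate([self.w_points, self.w_int])

    @property
    def uninformative(self) -> bool:
        """True when every observation spans essentially all of (0, alpha)."""
        if self.points.size:
            return False
        eps = 1e-12 * self.alpha
        return bool(np.all((self.lo <= eps) & (self.hi >= self.alpha - eps)))


def _compile(records: Iterable[ReportedPValue], alpha: float) -> tuple[_Compiled, int]:
    pts: list[float] = []
    ivs: list[tuple[float, float]] = []
    excluded = 0
    for r in records:
        try:
            iv = report_interval(r, alpha)
        except RecordExcluded:
            excluded += 1
            continue
        if isinstance(iv, tuple):
            ivs.append(iv)
        else:
            pts.append(iv)
    p_arr = np.asarray(pts, dtype=float)
    if p_arr.size:
        p_u, p_w = np.unique(p_arr, return_counts=True)
    else:
        p_u, p_w = np.empty(0), np.empty(0)
    if ivs:
        iv_arr = np.asarray(ivs, dtype=float)
        iv_u, iv_w = np.unique(iv_arr, axis=0, return_counts=True)
        lo, hi = iv_u[:, 0], iv_u[:, 1]
    else:
        lo = hi = np.empty(0)
        iv_w = np.empty(0)
    n = int(p_arr.size + len(ivs))
    return _Compiled(p_u, p_w.astype(float), lo, hi, iv_w.astype(float), alpha, n), excluded


def _comp_log_t(data: _Compiled, a: float, b: float) -> np.ndarray:
    """Log truncated-Beta likelihood per compiled row; -inf when degenerate."""
    fa = special.betainc(a, b, data.alpha)
    if not np.isfinite(fa) or fa <= 1e-300:
        return np.full(data.points.size + data.lo.size, -np.inf)
    log_norm = special.betaln(a, b) + np.log(fa)
    out_p = ((a - 1.0) * data.lp + (b - 1.0) * data.l1p - log_norm
             if data.points.size else np.empty(0))
    if data.lo.size:
        mass = special.betainc(a, b, data.hi) - special.betainc(a, b, data.lo)
        out_i = np.log(np.maximum(mass, 1e-300)) - np.log(fa)
    else:
        out_i = np.empty(0)
    return np.concatenate([out_p, out_i])


def _mstep_shapes(
    data: _Compiled, w_beta: np.ndarray, a: float, b: float, maxiter: int
) -> tuple[float, float]:
    """Update (a, b) by bounded derivative-free maximisation of the
    responsibility-weighted truncated-Beta interval log-likelihood.

    The point-observation part of the objective depends on the data only
    through the weighted sums of log(p) and log1p(-p), so each objective
    evaluation costs O(#unique intervals), not O(n).
    """
    if w_beta.sum() <= 0:
        return a, b
    np_pts = data.points.size
    wp = w_beta[:np_pts]
    wi = w_beta[np_pts:]
    s_lp = float(wp @ data.lp) if np_pts else 0.0
    s_l1p = float(wp @ data.l1p) if np_pts else 0.0
    w_pts_tot = float(wp.sum()) if np_pts else 0.0
    wi_pos = wi > 0
    w_int_tot = float(wi.sum()) if wi.size else 0.0

    def nll(theta: np.ndarray) -> float:
        aa, bb = np.exp(theta)
        fa = special.betainc(aa, bb, data.alpha)
        if not np.isfinite(fa) or fa <= 1e-300:
            return 1e300
        log_fa = np.log(fa)
        val = ((aa - 1.0) * s_lp + (bb - 1.0) * s_l1p
               - w_pts_tot * (special.betaln(aa, bb) + log_fa))
        if wi.size:
            mass = special.betainc(aa, bb, data.hi) - special.betainc(aa, bb, data.lo)
            if np.any(mass[wi_pos] <= 0):
                return 1e300
            val += float(wi @ (np.log(np.maximum(mass, 1e-300)))) - w_int_tot * log_fa
        if not np.isfinite(val):
            return 1e300
        return -float(val)

    x0 = np.log([a, b])
    f0 = nll(x0)
    bounds = [(np.log(_AB_BOUNDS[0]), np.log(_AB_BOUNDS[1]))] * 2
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-12},
    )
    if np.isfinite(res.fun) and res.fun < f0:
        aa, bb = np.exp(res.x)
        return float(aa), float(bb)
    return a, b


def _obs_loglik(data: _Compiled, pi0: float, a: float, b: float) -> float:
    t = np.exp(_comp_log_t(data, a, b))
    mix = pi0 * data.u + (1.0 - pi0) * t
    return float(np.sum(data.w * np.log(np.maximum(mix, 1e-300))))


def _joint_polish(
    data: _Compiled, pi0: float, a: float, b: float
) -> tuple[float, float, float]:
    """Direct ascent over (pi0, a, b); accepted only when it improves the
    observed log-likelihood.  The pi0-b ridge of this mixture makes plain
    EM steps tiny; an occasional joint move traverses it quickly while
    keeping the ascent monotone."""

    def nll(theta: np.ndarray) -> float:
        p = 1.0 / (1.0 + np.exp(-theta[0]))
        aa, bb = np.exp(theta[1:])
        if not (_AB_BOUNDS[0] <= aa <= _AB_BOUNDS[1] and _AB_BOUNDS[0] <= bb <= _AB_BOUNDS[1]):
            return 1e300
        return -_obs_loglik(data, p, aa, bb)

    x0 = np.array([np.log(pi0 / (1.0 - pi0)), np.log(a), np.log(b)])
    f0 = nll(x0)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 300, "xatol": 1e-6, "fatol": 1e-10})
    if np.isfinite(res.fun) and res.fun < f0:
        p = float(np.clip(1.0 / (1.0 + np.exp(-res.x[0])), *_PI0_BOUNDS))
        aa, bb = np.exp(res.x[1:])
        return p, float(aa), float(bb)
    return pi0, a, b


_POLISH_EVERY = 20


def _em_single(data: _Compiled, init: MixtureParams, cfg: EstimatorConfig) -> FitResult:
    pi0, a, b = init.pi0, init.a, init.b
    u = data.u
    w = data.w
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        t = np.exp(_comp_log_t(data, a, b))
        mix = pi0 * u + (1.0 - pi0) * t
        ll = float(np.sum(w * np.log(np.maximum(mix, 1e-300))))
        trace.append(ll)
        if n_iter > 1 and abs(ll - trace[-2]) < cfg.tol:
            converged = True
            break
        gamma = pi0 * u / np.maximum(mix, 1e-300)
        pi0 = float(np.clip(np.sum(w * gamma) / np.sum(w), *_PI0_BOUNDS))
        a, b = _mstep_shapes(data, w * (1.0 - gamma), a, b, cfg.mstep_maxiter)
        if n_iter % _POLISH_EVERY == 0:
            pi0, a, b = _joint_polish(data, pi0, a, b)
    return FitResult(
        params=MixtureParams(pi0, a, b),
        loglik=trace[-1],
        n_iter=n_iter,
        converged=converged,
        n_used=data.n_records,
        message="" if converged else "max iterations reached",
        loglik_trace=np.asarray(trace),
    )


#: Shape-parameter grid walked by multistart, in order.
MULTISTART_GRID = [(a, b) for a in (0.5, 1.0, 2.0) for b in (5.0, 20.0, 50.0)]


def em_fit(records: Sequence[ReportedPValue], config: Optional[EstimatorConfig] = None) -> FitResult:
    """Maximum-likelihood fit of (pi0, a, b) by EM on interval likelihoods.

    The E step computes each report's posterior probability of the
    uniform (false discovery) component from the two components' interval
    probabilities or densities; the M step sets pi0 to the weighted mean
    posterior and updates the Beta shapes numerically.  The observed-data
    log-likelihood is non-decreasing across iterations.
    """
    cfg = config or EstimatorConfig()
    data, excluded = _compile(records, cfg.alpha)
    if excluded:
        logger.info("em_fit: %d records excluded (empty likelihood interval)", excluded)
    if data.n_records < cfg.min_count:
        raise InsufficientDataError(
            f"{data.n_records} usable records < minimum {cfg.min_count}"
        )
    if data.uninformative:
        ll = 0.0  # every observation has likelihood 1 under both components
        return FitResult(
            params=cfg.init, loglik=ll, n_iter=0, converged=False,
            n_used=data.n_records,
            message="likelihood is flat: every report spans all of (0, alpha)",
        )
    inits = [cfg.init]
    if cfg.n_multistart > 1:
        for a, b in MULTISTART_GRID:
            if len(inits) >= cfg.n_multistart:
                break
            if (a, b) != (cfg.init.a, cfg.init.b):
                inits.append(MixtureParams(cfg.init.pi0, a, b))
    best: Optional[FitResult] = None
    for init in inits:
        fit = _em_single(data, init, cfg)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def estimate_journal_years(
    pvals: pd.DataFrame, config: Optional[EstimatorConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One mixture fit per journal-year; flag journals to drop.

    ``pvals`` needs columns journal, year, value, comparator, decimals
    (nullable), cls.  Returns ``(estimates, removals)``: every fitted
    journal-year (fdr = fitted pi0, n_pvalues, converged, loglik), and
    one row per journal excluded from downstream modelling because at
    least one of its years failed to converge or lacked data.
    """
    cfg = config or EstimatorConfig()
    rows = []
    removal: dict[str, str] = {}
    if len(pvals) == 0:
        empty = pd.DataFrame(columns=["journal", "year", "fdr", "n_pvalues", "converged", "loglik"])
        return empty, pd.DataFrame(columns=["journal", "reason"])
    for (journal, year), grp in pvals.groupby(["journal", "year"], sort=True):
        records = []
        for row in grp.itertuples(index=False):
            dec = getattr(row, "decimals", None)
            dec = None if dec is None or (isinstance(dec, float) and np.isnan(dec)) else int(dec)
            records.append(
                ReportedPValue(
                    value=float(row.value), comparator=row.comparator,
                    decimals=dec, cls=row.cls, journal=journal, year=int(year),
                )
            )
        try:
            fit = em_fit(records, cfg)
            rows.append({
                "journal": journal, "year": int(year),
                "fdr": fit.params.pi0 if fit.converged else np.nan,
                "n_pvalues": fit.n_used, "converged": fit.converged,
                "loglik": fit.loglik,
            })
            if not fit.converged:
                removal.setdefault(journal, f"year {year}: {fit.message}")
        except InsufficientDataError as exc:
            rows.append({
                "journal": journal, "year": int(year), "fdr": np.nan,
                "n_pvalues": len(records), "converged": False, "loglik": np.nan,
            })
            removal.setdefault(journal, f"year {year}: {exc}")
    estimates = pd.DataFrame(rows)
    removals = pd.DataFrame(
        [{"journal": j, "reason": r} for j, r in sorted(removal.items())],
        columns=["journal", "reason"],
    )
    return estimates, removals


def modeling_table(estimates: pd.DataFrame, removals: pd.DataFrame) -> pd.DataFrame:
    """Estimates restricted to journals with every year converged."""
    return estimates[~estimates["journal"].isin(set(removals["journal"]))].reset_index(drop=True)
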