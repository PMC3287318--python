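"""Time-dependent pure-birth (Yule) and birth-death model fitting.

The likelihood for a reconstructed chronogram under a time-dependent
pure-birth process with speciation rate λ(t) (t = time since the root),
conditioned on the root split, is

    log L = sum_i log λ(t_i)  -  ∫_0^T N(t) λ(t) dt  +  log((n-1)!)

where the sum runs over the n-2 non-root branching events, N(t) is the
reconstructed lineage count and T the root age.  The log((n-1)!)
labelled-histories constant is included so absolute values follow the
convention of the classic LTT-likelihood literature; AIC comparisons are
invariant to it.

For a constant rate this collapses to (n-2)·log λ - λ·X + log((n-1)!)
with X the total branch length, giving the closed-form MLE
λ̂ = (n-2)/X.  Piecewise and sea-level covariate models have analytic
per-epoch MLEs (events / lineage-time); breakpoints are profiled over an
exhaustive grid because the profile likelihood is piecewise-constant in
the breakpoint with jumps at branching ages.  The constant-rate
birth-death model uses the reconstructed-process likelihood conditioned
on the root split and survival of both root lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import (
    DegenerateTreeError,
    DomainError,
    InsufficientTipsError,
)
from .rates import (
    ConstantRate,
    CovariateStepRate,
    LogisticRate,
    PiecewiseRate,
    SeaLevelIntervals,
    _sigmoid,
    _softplus,
)
from .tree import Chronogram

__all__ = [
    "DiversificationResults",
    "YuleModel",
    "BirthDeathModel",
    "integrated_intensity",
    "yule_time_loglik",
    "fit_yule_constant",
    "fit_birth_death_constant",
    "fit_yule_piecewise",
    "fit_yule_logistic",
    "fit_yule_covariate",
    "aic",
    "lrt_clock",
    "LTTCurve",
    "ltt_curve",
    "ltt_envelope",
    "window_rates",
    "compare_models",
]


# ----------------------------------------------------------------------
# likelihood primitives
# ----------------------------------------------------------------------
def integrated_intensity(model, tree: Chronogram) -> float:
    """∫_0^T N(t) λ(t) dt, exact for every supported family.

    Families that are constant within age epochs are integrated by exact
    piecewise summation over the union of branching times and epoch
    boundaries; the logistic family uses its softplus primitive on each
    inter-event interval (N is constant there), which is also exact.
    """
    T = tree.root_age
    if isinstance(model, LogisticRate):
        ev_t = np.sort(T - tree.event_ages)  # ascending times since root
        knots = np.concatenate((ev_t, [T]))
        total = 0.0
        for i in range(len(knots) - 1):
            t0, t1 = knots[i], knots[i + 1]
            if t1 <= t0:
                continue
            N = i + 2  # after the (i+1)-th event
            total += N * model.integral(t0, t1)
        return total
    # constant-within-age-epoch families
    bounds = sorted(set(model.boundary_ages(T)), reverse=True)
    edges = [T] + [b for b in bounds if 0 < b < T] + [0.0]
    total = 0.0
    for i in range(len(edges) - 1):
        old, young = edges[i], edges[i + 1]
        lam = model.rate_in_age_epoch(old, young)
        lt = float(tree.lineage_time_below_age(old) - tree.lineage_time_below_age(young))
        total += lam * lt
    return total


def yule_time_loglik(model, tree: Chronogram) -> float:
    """Log-likelihood of a chronogram under a time-dependent pure-birth model.

    Conditions on the root split: the root event contributes no rate factor.
    Returns -inf if any non-root event falls where λ(t) = 0.
    """
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3 (at least one non-root event)")
    T = tree.root_age
    event_t = T - tree.nonroot_event_ages()
    lam = np.array([model.rate_at(t, T) for t in event_t], dtype=float)
    if np.any(lam <= 0):
        return -np.inf
    return (
        float(np.sum(np.log(lam)))
        - integrated_intensity(model, tree)
        + float(gammaln(tree.n))
    )


def aic(logL: float, k: int) -> float:
    """Akaike information criterion, -2 log L + 2 k."""
    if k < 0:
        raise DomainError("k must be >= 0")
    return -2.0 * logL + 2.0 * k


def lrt_clock(
    logL_clock: float, logL_nonclock: float, df: int = 1, tol: float = 1e-8
) -> tuple[float, float]:
    """Likelihood-ratio test of a clock against an unconstrained-rates model.

    Returns (LR, p) with LR = 2 (logL_nonclock - logL_clock) and p from the
    upper tail of a chi-square with ``df`` degrees of freedom.  A nonclock
    likelihood below the clock one (beyond tolerance) is a fitting artefact
    and triggers a warning; the statistic is then clamped at 0 for the test.
    """
    diff = logL_nonclock - logL_clock
    if diff < -tol:
        warnings.warn(
            "nonclock log-likelihood is below the clock one; "
            "LR clamped to 0 for the test",
            stacklevel=2,
        )
    lr = 2.0 * diff
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return lr, p


# ----------------------------------------------------------------------
# results container
# ----------------------------------------------------------------------
@dataclass
class DiversificationResults:
    """Fitted diversification model: estimates, uncertainty, fit statistics."""

    model: object
    model_name: str
    params: dict
    bse: dict
    llf: float
    k: int
    converged: bool = True
    n_evals: int = 0
    tree: Optional[Chronogram] = None

    @property
    def aic(self) -> float:
        return aic(self.llf, self.k)

    def summary(self) -> str:
        lines = [
            f"Diversification fit: {self.model_name}",
            f"  n tips: {self.tree.n if self.tree is not None else '?'}"
            f"   root age: "
            f"{self.tree.root_age:.4g} Myr" if self.tree is not None else "",
            f"  log L = {self.llf:.4f}   k = {self.k}   AIC = {self.aic:.4f}",
            f"  converged: {self.converged}",
            "  parameters:",
        ]
        for name, val in self.params.items():
            se = self.bse.get(name)
            se_s = f" +/- {se:.4g}" if se is not None else ""
            lines.append(f"    {name} = {val:.6g}{se_s}")
        return "\n".join(x for x in lines if x)

    def to_row(self) -> dict:
        est = "; ".join(
            f"{k}={v:.4g}"
            + (f"±{self.bse[k]:.3g}" if self.bse.get(k) is not None else "")
            for k, v in self.params.items()
        )
        return {
            "model": self.model_name,
            "estimates": est,
            "logL": self.llf,
            "k": self.k,
            "AIC": self.aic,
            "converged": self.converged,
        }


# ----------------------------------------------------------------------
# fitting: pure birth families
# ----------------------------------------------------------------------
def fit_yule_constant(tree: Chronogram) -> DiversificationResults:
    """Closed-form constant-rate Yule fit: λ̂ = (n-2)/X, X = total branch length."""
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3")
    X = tree.total_branch_length()
    if X <= 0:
        raise DegenerateTreeError("tree has zero total branch length")
    lam = (tree.n - 2) / X
    model = ConstantRate(lam)
    llf = yule_time_loglik(model, tree)
    se = lam / np.sqrt(tree.n - 2)
    return DiversificationResults(
        model=model,
        model_name="yule",
        params={"lambda": lam},
        bse={"lambda": se},
        llf=llf,
        k=1,
        tree=tree,
    )


def _epoch_stats(tree: Chronogram, edges_desc: Sequence[float]):
    """Per-epoch (events, lineage-time) for age edges descending root->0."""
    edges = np.asarray(edges_desc, dtype=float)
    E = tree.nonroot_events_below_age(edges)
    G = tree.lineage_time_below_age(edges)
    ev = E[:-1] - E[1:]
    lt = G[:-1] - G[1:]
    return ev.astype(float), np.asarray(lt, dtype=float)


def _breakpoint_candidates(tree: Chronogram, resolution: float) -> np.ndarray:
    ages = np.unique(tree.event_ages)
    mids = 0.5 * (ages[:-1] + ages[1:])
    grid = np.arange(resolution, tree.root_age, resolution)
    cand = np.unique(np.round(np.concatenate((mids, grid)), 9))
    return cand[(cand > 0) & (cand < tree.root_age)]


def _profile_loglik_terms(e, lt):
    """sum_j e_j log(e_j / lt_j) with 0 log 0 = 0; -inf where invalid."""
    e = np.asarray(e, dtype=float)
    lt = np.asarray(lt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(e > 0, e * (np.log(e) - np.log(lt)), 0.0)
    bad = (lt <= 0) & (e > 0)
    term = np.where(bad, -np.inf, term)
    return term


def fit_yule_piecewise(
    tree: Chronogram,
    n_epochs: int,
    grid_resolution: float = 0.1,
    fixed_breakpoints: Optional[Sequence[float]] = None,
    min_epoch_frac: float = 0.15,
) -> DiversificationResults:
    """Piecewise-constant Yule fit with profiled breakpoints.

    For fixed breakpoints the per-epoch MLE is analytic
    (events / lineage-time); free breakpoints are profiled by exhaustive
    search over the midpoints between consecutive distinct branching ages
    plus a uniform grid at ``grid_resolution`` Myr.  Epochs are indexed
    oldest-first; an event exactly at a breakpoint age belongs to the
    younger epoch.  Supports 1-3 epochs for free breakpoints, any number
    for fixed ones.

    The free-breakpoint search is trimmed: every epoch must contain at
    least ``min_epoch_frac`` of the non-root events (floored at 1 and
    capped so a partition always exists).  An unconstrained supremum over
    breakpoints is dominated by spurious spikes from near-empty edge
    epochs — the same pathology that motivates trimming in structural
    break tests — and the trimmed profile is what the AIC comparison
    assumes.  Set ``min_epoch_frac=0`` to recover the raw supremum.
    """
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3")
    m = int(n_epochs)
    if m < 1:
        raise DomainError("n_epochs must be >= 1")
    if m > tree.n - 2 + 1:
        raise DomainError(
            f"{m} epochs exceed the {tree.n - 2} available non-root events"
        )
    if m == 1:
        res = fit_yule_constant(tree)
        res.model_name = "yule"
        return res
    T = tree.root_age
    n_free_bp = 0

    if fixed_breakpoints is not None:
        bps = sorted((float(b) for b in fixed_breakpoints), reverse=True)
        if len(bps) != m - 1:
            raise DomainError("need n_epochs - 1 fixed breakpoints")
        edges = [T] + bps + [0.0]
        ev, lt = _epoch_stats(tree, edges)
        if np.any(lt <= 0):
            raise DomainError("an epoch has zero lineage-time")
        best_bps = bps
    else:
        n_free_bp = m - 1
        cand = _breakpoint_candidates(tree, grid_resolution)
        if len(cand) == 0:
            raise DomainError("no breakpoint candidates in (0, root_age)")
        E = np.asarray(tree.nonroot_events_below_age(cand), dtype=float)
        G = np.asarray(tree.lineage_time_below_age(cand), dtype=float)
        E_tot = float(tree.n - 2)
        G_tot = tree.total_branch_length()
        min_ev = max(1.0, np.floor(min_epoch_frac * E_tot))
        min_ev = min(min_ev, np.floor(E_tot / m))
        min_ev = max(min_ev, 0.0)
        if m == 2:
            e = np.stack([E_tot - E, E])  # (old, young) x candidates
            l = np.stack([G_tot - G, G])
            score = _profile_loglik_terms(e, l).sum(axis=0)
            score[np.any(l <= 0, axis=0) | np.any(e < min_ev, axis=0)] = -np.inf
            if not np.any(np.isfinite(score)):
                raise DomainError("no admissible breakpoint under the trimming rule")
            j = int(np.argmax(score))
            best_bps = [float(cand[j])]
        elif m == 3:
            # tau1 (older) x tau2 (younger) grids via broadcasting
            E1 = E[:, None]  # candidate as tau1
            E2 = E[None, :]
            G1 = G[:, None]
            G2 = G[None, :]
            e_old = E_tot - E1
            e_mid = E1 - E2
            e_young = E2 + np.zeros_like(E1)
            l_old = G_tot - G1
            l_mid = G1 - G2
            l_young = G2 + np.zeros_like(G1)
            score = (
                _profile_loglik_terms(e_old, l_old)
                + _profile_loglik_terms(e_mid, l_mid)
                + _profile_loglik_terms(e_young, l_young)
            )
            valid = (
                (cand[:, None] > cand[None, :])
                & (l_old > 0)
                & (l_mid > 0)
                & (l_young > 0)
                & (e_old >= min_ev)
                & (e_mid >= min_ev)
                & (e_young >= min_ev)
            )
            score = np.where(valid, score, -np.inf)
            if not np.any(np.isfinite(score)):
                raise DomainError("no admissible breakpoints under the trimming rule")
            j1, j2 = np.unravel_index(int(np.argmax(score)), score.shape)
            best_bps = [float(cand[j1]), float(cand[j2])]
        else:
            raise DomainError(
                "free-breakpoint search supports at most 3 epochs; "
                "pass fixed_breakpoints for more"
            )
        edges = [T] + best_bps + [0.0]
        ev, lt = _epoch_stats(tree, edges)

    rates = np.where(lt > 0, ev / np.where(lt > 0, lt, 1.0), 0.0)
    model = PiecewiseRate(tuple(rates), tuple(best_bps))
    llf = yule_time_loglik(model, tree)
    params: dict = {}
    bse: dict = {}
    for j, (r, e) in enumerate(zip(rates, ev), start=1):
        params[f"lambda_{j}"] = float(r)
        bse[f"lambda_{j}"] = float(r / np.sqrt(e)) if e > 0 else None
    for j, b in enumerate(best_bps, start=1):
        params[f"tau_{j}"] = float(b)
        bse[f"tau_{j}"] = None  # profile is piecewise-constant in tau
    k = m + n_free_bp if fixed_breakpoints is None else m
    return DiversificationResults(
        model=model,
        model_name=f"piecewise_{m}_epochs",
        params=params,
        bse=bse,
        llf=llf,
        k=k,
        tree=tree,
    )


def fit_yule_covariate(
    tree: Chronogram, intervals: SeaLevelIntervals
) -> DiversificationResults:
    """Two-rate Yule fit keyed to high/low sea-level stands.

    Events and lineage-time are pooled across all high-stand epochs and all
    low-stand epochs; both MLEs are analytic.  Ages older than the covariate
    record count as low-stand.
    """
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3")
    if len(intervals.intervals) == 0:
        warnings.warn(
            "empty sea-level interval table: covariate model degenerates "
            "to a constant rate",
            stacklevel=2,
        )
        const = fit_yule_constant(tree)
        model = CovariateStepRate(const.params["lambda"], const.params["lambda"], intervals)
        return DiversificationResults(
            model=model,
            model_name="sea_level",
            params={"lambda_high": const.params["lambda"], "lambda_low": const.params["lambda"]},
            bse={"lambda_high": None, "lambda_low": None},
            llf=const.llf,
            k=2,
            tree=tree,
        )
    T = tree.root_age
    bounds = [b for b in intervals.boundary_ages() if 0 < b < T]
    edges = [T] + sorted(set(bounds), reverse=True) + [0.0]
    ev, lt = _epoch_stats(tree, edges)
    high = np.array(
        [intervals.is_high(0.5 * (edges[i] + edges[i + 1])) for i in range(len(ev))]
    )
    e_hi, l_hi = float(ev[high].sum()), float(lt[high].sum())
    e_lo, l_lo = float(ev[~high].sum()), float(lt[~high].sum())
    lam_hi = e_hi / l_hi if l_hi > 0 else 0.0
    lam_lo = e_lo / l_lo if l_lo > 0 else 0.0
    model = CovariateStepRate(lam_hi, lam_lo, intervals)
    llf = yule_time_loglik(model, tree)
    return DiversificationResults(
        model=model,
        model_name="sea_level",
        params={"lambda_high": lam_hi, "lambda_low": lam_lo},
        bse={
            "lambda_high": lam_hi / np.sqrt(e_hi) if e_hi > 0 else None,
            "lambda_low": lam_lo / np.sqrt(e_lo) if e_lo > 0 else None,
        },
        llf=llf,
        k=2,
        tree=tree,
    )


def _logistic_negloglik_factory(tree: Chronogram):
    T = tree.root_age
    event_t = np.sort(T - tree.nonroot_event_ages())
    all_t = np.sort(T - tree.event_ages)
    knots = np.concatenate((all_t, [T]))
    Ns = np.arange(2, 2 + len(all_t))  # N on [knots[i], knots[i+1])
    lgn = float(gammaln(tree.n))

    dts = np.diff(knots)
    mids = 0.5 * (knots[:-1] + knots[1:])

    def negloglik(theta):
        a, b = theta
        x = a * event_t + b
        log_rates = -_softplus(-x)  # log sigmoid
        if abs(a) * float(knots[-1]) < 1e-6:
            # primitive difference cancels at tiny |a|; midpoint rule is
            # accurate to O((a Δt)^2) there
            integral = float(np.sum(Ns * _sigmoid(a * mids + b) * dts))
        else:
            sp = _softplus(a * knots + b)
            integral = float(np.sum(Ns * (sp[1:] - sp[:-1])) / a)
        return -(float(np.sum(log_rates)) - integral + lgn)

    return negloglik


def _numerical_hessian(f, x, step=1e-4):
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.zeros((n, n))
    h = step * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _bse_from_hessian(negloglik, x, names):
    try:
        H = _numerical_hessian(negloglik, x)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(d)
        return {nm: float(s) for nm, s in zip(names, se)}
    except np.linalg.LinAlgError:
        return {nm: None for nm in names}


def fit_yule_logistic(
    tree: Chronogram, n_starts: int = 5, seed: int = 0
) -> DiversificationResults:
    """Yule fit with λ(t) = sigmoid(a t + b), t since the root; numeric ML.

    Multi-start Nelder-Mead from fixed and seeded random starting points;
    standard errors from the observed information (numerical Hessian).
    """
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3")
    negll = _logistic_negloglik_factory(tree)
    rng = np.random.default_rng(seed)
    lam0 = (tree.n - 2) / tree.total_branch_length()
    b0 = float(np.log(lam0 / (1 - lam0))) if 0 < lam0 < 1 else 0.0
    starts = [(0.0, b0), (-0.05, b0), (0.05, b0), (0.0, 0.0), (-0.02, -1.5)]
    while len(starts) < n_starts:
        starts.append((float(rng.normal(0, 0.05)), float(rng.normal(b0, 1.0))))
    best = None
    evals = 0
    for x0 in starts[: max(n_starts, 5)]:
        r = optimize.minimize(negll, x0, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        evals += r.nfev
        if best is None or r.fun < best.fun:
            best = r
    a, b = best.x
    model = LogisticRate(float(a), float(b))
    llf = -float(best.fun)
    bse = _bse_from_hessian(negll, best.x, ["a", "b"])
    return DiversificationResults(
        model=model,
        model_name="logistic",
        params={"a": float(a), "b": float(b)},
        bse=bse,
        llf=llf,
        k=2,
        converged=bool(best.success),
        n_evals=evals,
        tree=tree,
    )


# ----------------------------------------------------------------------
# birth-death
# ----------------------------------------------------------------------
def _bd_negloglik_factory(tree: Chronogram):
    x = tree.branching_times()  # descending, x[0] = root age
    n = tree.n
    x_nonroot = x[1:]
    lgn = float(gammaln(n))

    def negloglik(theta):
        r, a = theta  # r = lambda - mu, a = mu / lambda
        if r <= 0 or not (0 <= a < 1):
            return np.inf
        rx = r * x
        # log(exp(r x) - a) = r x + log1p(-a exp(-r x))
        log_terms = rx + np.log1p(-a * np.exp(-rx))
        ll = (
            lgn
            + (n - 2) * np.log(r)
            + r * float(np.sum(x_nonroot))
            + n * np.log1p(-a)
            - 2.0 * float(np.sum(log_terms))
        )
        return -ll

    return negloglik


def fit_birth_death_constant(tree: Chronogram) -> DiversificationResults:
    """Constant-rate birth-death ML fit on a reconstructed chronogram.

    Uses the reconstructed-process likelihood conditioned on the root split
    and the survival of both root lineages, parameterised as
    (r, a) = (λ - μ, μ/λ) with μ constrained >= 0.  At a = 0 the
    likelihood equals the constant Yule one, so the models nest.
    """
    if tree.n < 3:
        raise InsufficientTipsError("need n >= 3")
    negll = _bd_negloglik_factory(tree)
    lam0 = (tree.n - 2) / tree.total_branch_length()
    starts = [(lam0, 1e-6), (0.5 * lam0, 0.5), (1.5 * lam0, 0.2), (lam0, 0.9)]
    best = None
    evals = 0
    converged = False
    for x0 in starts:
        r = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=[(1e-10, None), (0.0, 1.0 - 1e-10)],
        )
        evals += r.nfev
        if best is None or r.fun < best.fun:
            best = r
            converged = bool(r.success)
    r_hat, a_hat = best.x
    lam = r_hat / (1.0 - a_hat)
    mu = a_hat * lam
    model = ConstantRate(lam)  # reconstructed-process speciation rate
    llf = -float(best.fun)
    at_boundary = a_hat < 1e-8
    if at_boundary:
        bse = {"lambda": lam / np.sqrt(tree.n - 2), "mu": None}
    else:
        def negll_lm(theta):
            l, m = theta
            if l <= 0 or m < 0 or m >= l:
                return np.inf
            return negll((l - m, m / l))

        bse = _bse_from_hessian(negll_lm, np.array([lam, mu]), ["lambda", "mu"])
    return DiversificationResults(
        model=model,
        model_name="birth_death",
        params={"lambda": float(lam), "mu": float(mu)},
        bse=bse,
        llf=llf,
        k=2,
        converged=converged,
        n_evals=evals,
        tree=tree,
    )


# ----------------------------------------------------------------------
# statsmodels-style model façades
# ----------------------------------------------------------------------
class YuleModel:
    """Time-dependent pure-birth model bound to a chronogram.

    Parameters
    ----------
    tree : Chronogram
    rate_family : {"constant", "piecewise", "logistic", "covariate_step"}
    n_epochs : int, for the piecewise family
    intervals : SeaLevelIntervals, for the covariate family
    """

    def __init__(
        self,
        tree: Chronogram,
        rate_family: str = "constant",
        *,
        n_epochs: int = 2,
        intervals: Optional[SeaLevelIntervals] = None,
        grid_resolution: float = 0.1,
        fixed_breakpoints: Optional[Sequence[float]] = None,
    ):
        self.tree = tree
        self.rate_family = rate_family
        self.n_epochs = n_epochs
        self.intervals = intervals
        self.grid_resolution = grid_resolution
        self.fixed_breakpoints = fixed_breakpoints

    def loglike(self, model) -> float:
        """Log-likelihood of an explicit rate model on the bound tree."""
        return yule_time_loglik(model, self.tree)

    def fit(self, **kwargs) -> DiversificationResults:
        fam = self.rate_family
        if fam == "constant":
            return fit_yule_constant(self.tree)
        if fam == "piecewise":
            return fit_yule_piecewise(
                self.tree,
                self.n_epochs,
                grid_resolution=self.grid_resolution,
                fixed_breakpoints=self.fixed_breakpoints,
            )
        if fam == "logistic":
            return fit_yule_logistic(self.tree, **kwargs)
        if fam == "covariate_step":
            if self.intervals is None:
                raise DomainError("covariate_step family needs sea-level intervals")
            return fit_yule_covariate(self.tree, self.intervals)
        raise DomainError(f"unknown rate family {fam!r}")


class BirthDeathModel:
    """Constant-rate birth-death model bound to a chronogram."""

    def __init__(self, tree: Chronogram):
        self.tree = tree

    def loglike(self, lam: float, mu: float) -> float:
        if lam <= 0 or mu < 0 or mu >= lam:
            return -np.inf
        negll = _bd_negloglik_factory(self.tree)
        return -float(negll((lam - mu, mu / lam)))

    def fit(self) -> DiversificationResults:
        return fit_birth_death_constant(self.tree)


# ----------------------------------------------------------------------
# LTT analysis
# ----------------------------------------------------------------------
@dataclass
class LTTCurve:
    """Lineage-through-time step curve, optionally with a simulation envelope."""

    times: np.ndarray  # event times since root, ascending, starting at 0
    counts: np.ndarray  # lineage counts after each event, 2..n
    grid: Optional[np.ndarray] = None
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    reps: int = 0

    def count_at(self, t) -> np.ndarray:
        return 1 + np.searchsorted(self.times, np.asarray(t), side="right")

    def to_frame(self) -> pd.DataFrame:
        if self.grid is None:
            return pd.DataFrame({"time": self.times, "count": self.counts})
        obs = self.count_at(self.grid)
        return pd.DataFrame(
            {
                "time": self.grid,
                "count": obs,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def plot(self, ax=None, **kwargs):  # pragma: no cover - thin plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.times, self.counts, where="post", **kwargs)
        if self.grid is not None:
            ax.plot(self.grid, self.lower, "k--", lw=0.8)
            ax.plot(self.grid, self.upper, "k--", lw=0.8)
        ax.set_xlabel("time since root (Myr)")
        ax.set_ylabel("lineages")
        ax.set_yscale("log")
        return ax


def ltt_curve(tree: Chronogram) -> LTTCurve:
    """Observed LTT step curve: counts rise from 2 at the root to n."""
    if tree.n < 2:
        raise InsufficientTipsError("need n >= 2")
    ev_t = np.sort(tree.root_age - tree.event_ages)
    counts = np.arange(2, 2 + len(ev_t))
    return LTTCurve(times=ev_t, counts=counts)


def ltt_envelope(
    tree: Chronogram,
    fit: DiversificationResults,
    reps: int = 1000,
    seed: Optional[int] = None,
    grid_size: int = 101,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> LTTCurve:
    """Pointwise simulation envelope around the observed LTT curve.

    Simulates ``reps`` trees under the fitted rate model conditioned on the
    observed (n, root_age) and takes pointwise quantiles of the lineage
    count on a shared time grid.
    """
    from .simulate import simulate_conditioned_tree

    if reps < 100:
        raise DomainError("need reps >= 100 for a stable envelope")
    rng = np.random.default_rng(seed)
    T = tree.root_age
    grid = np.linspace(0.0, T, grid_size)
    counts = np.empty((reps, grid_size), dtype=int)
    for i in range(reps):
        sim = simulate_conditioned_tree(
            fit.model, tree.n, T, seed=int(rng.integers(2**31 - 1))
        )
        ev_t = np.sort(T - sim.event_ages)
        counts[i] = 1 + np.searchsorted(ev_t, grid, side="right")
    lo = np.quantile(counts, quantiles[0], axis=0)
    hi = np.quantile(counts, quantiles[1], axis=0)
    base = ltt_curve(tree)
    return LTTCurve(
        times=base.times,
        counts=base.counts,
        grid=grid,
        lower=lo,
        upper=hi,
        reps=reps,
    )


def window_rates(tree: Chronogram, width: float = 10.0) -> pd.DataFrame:
    """Per-window speciation-rate estimates, windows of ``width`` Myr by age.

    Windows are half-open toward the past with the youngest window touching
    the present; the rate in a window is (non-root events) / (lineage-time).
    Windows with zero lineage-time get a missing rate, never 0.
    """
    if width <= 0:
        raise DomainError("width must be positive")
    T = tree.root_age
    young_edges = np.arange(0.0, T, width)
    edges_desc = np.concatenate(([T], young_edges[::-1]))
    edges_desc = np.unique(edges_desc)[::-1]
    ev, lt = _epoch_stats(tree, edges_desc)
    rate = np.where(lt > 0, ev / np.where(lt > 0, lt, 1.0), np.nan)
    return pd.DataFrame(
        {
            "old_age": edges_desc[:-1],
            "young_age": edges_desc[1:],
            "events": ev.astype(int),
            "lineage_time": lt,
            "rate": rate,
        }
    )


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------
def compare_models(
    tree: Chronogram,
    intervals: Optional[SeaLevelIntervals] = None,
    seed: int = 0,
    grid_resolution: float = 0.1,
    include_birth_death: bool = True,
) -> tuple[pd.DataFrame, dict[str, DiversificationResults]]:
    """Fit the full model suite and tabulate logL / k / AIC.

    Returns the comparison table (best model flagged by minimum AIC, ties
    broken toward fewer parameters) and the fitted results keyed by name.
    """
    fits: dict[str, DiversificationResults] = {}
    fits["yule"] = fit_yule_constant(tree)
    candidates = []
    if include_birth_death:
        candidates.append(("birth_death", lambda: fit_birth_death_constant(tree)))
    if intervals is not None:
        candidates.append(("sea_level", lambda: fit_yule_covariate(tree, intervals)))
    candidates.append(("logistic", lambda: fit_yule_logistic(tree, seed=seed)))
    candidates.append(
        ("one_breakpoint",
         lambda: fit_yule_piecewise(tree, 2, grid_resolution=grid_resolution))
    )
    candidates.append(
        ("two_breakpoints",
         lambda: fit_yule_piecewise(tree, 3, grid_resolution=grid_resolution))
    )
    for name, fitter in candidates:
        try:
            fits[name] = fitter()
        except (DomainError, InsufficientTipsError) as exc:
            warnings.warn(f"{name} model skipped: {exc}", stacklevel=2)
    rows = []
    for name, res in fits.items():
        row = res.to_row()
        row["model"] = name
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table.sort_values(["AIC", "k"], kind="stable")
    table["best"] = False
    table.loc[order.index[0], "best"] = True
    return table, fits
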