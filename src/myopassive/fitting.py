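"""Nonlinear least-squares fitting of the passive constitutive laws.

The objective is the mean of squared stress residuals

    Ξ(θ) = (1/n) Σ_i [P_i − P(L_i; θ)]²        (kPa²)

minimised over the law parameters.  "Multiple fitting" of a group of
specimens means pooling every record of the group into one objective
with a single shared parameter set — the per-group average response.

The optimiser is deliberately simple and reproducible: uniform random
multistart inside a finite bound box, followed by Nelder-Mead polish of
the few best starts (with one simplex restart at the incumbent).  The
problems are 1-4 parameter smooth exponential fits for which this is
robust; results are bit-identical for a fixed seed.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
constructor params untouched, fitted attributes with a trailing
underscore) and compose with sklearn model selection.  Thin wrappers
(:func:`fit_fibre_law`, :func:`fit_bundle_ecm`,
:func:`fit_single_exponential`) accept measurement records and return a
:class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DomainError, FitError, NonIdentifiableError
from .laws import (
    BundleModel,
    ECMParams,
    FibreLawParams,
    TangLawParams,
    VolumeFractions,
    ZhangLawParams,
    bundle_uniaxial_stress,
    ecm_uniaxial_stress,
    fibre_stress,
    tang_stress,
    zhang_stress,
)

__all__ = [
    "FitResult",
    "FibreLawRegressor",
    "BundleECMRegressor",
    "SingleExponentialRegressor",
    "objective_xi",
    "fit_fibre_law",
    "fit_bundle_ecm",
    "fit_single_exponential",
    "FIBRE_LAWS",
]

# free parameters, in optimisation order, for each fibre law
FIBRE_LAWS = {
    "exponential": ("A", "L0"),
    "quadratic": ("P0", "L0"),
    "zhang": ("P0", "a", "A", "L0"),
}

_DEFAULT_BOUNDS = {
    "exponential": {"A": (1e-9, 1e3), "L0": (1.5, 3.5)},
    "quadratic": {"P0": (1e-9, 1e3), "L0": (1.5, 3.5)},
    "zhang": {"P0": (1e-9, 1e3), "a": (1e-9, 10.0),
              "A": (1e-9, 1e2), "L0": (1.5, 3.5)},
    "bundle": {"beta": (1e-9, 1e6), "L0b": (1.0, 3.0)},
}

_LAW_PARAM_CLS = {
    "exponential": FibreLawParams,
    "quadratic": TangLawParams,
    "zhang": ZhangLawParams,
}

_LAW_FN = {
    "exponential": fibre_stress,
    "quadratic": tang_stress,
    "zhang": zhang_stress,
}


@dataclass(frozen=True)
class FitResult:
    """Outcome of one pooled fit.

    xi is the mean-of-squared-residuals objective (kPa²); rss = xi · n_exp
    is the residual sum of squares; nu = n_exp − n_params the degrees of
    freedom.
    """

    law: str
    params: object
    xi: float
    rss: float
    n_exp: int
    n_params: int
    nu: int
    seed: int
    converged: bool
    at_bounds: bool = False

    def __post_init__(self):
        if self.nu < 1:
            raise FitError(f"degrees of freedom must be >= 1, got {self.nu}")


def predict_stress(L, law: str, params):
    """Nominal stress under any supported law (``bundle`` = total stress)."""
    if law == "bundle":
        return bundle_uniaxial_stress(L, params).total
    try:
        fn = _LAW_FN[law]
    except KeyError:
        raise DomainError(f"unknown law {law!r}")
    return fn(L, params)


def _records_to_arrays(records):
    L = np.array([r.sarcomere_length for r in records], dtype=float)
    P = np.array([r.nominal_stress for r in records], dtype=float)
    return L, P


def objective_xi(records, law: str, params) -> float:
    """Mean of squared residuals Ξ (kPa²) of a parameter set on records."""
    if len(records) == 0:
        raise DomainError("objective requires at least one record")
    L, P = _records_to_arrays(records)
    resid = P - predict_stress(L, law, params)
    return float(np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# multistart Nelder-Mead optimiser


def _multistart_minimize(fun, lower, upper, seed, n_starts, n_polish):
    """Minimise fun over a box: uniform multistart + Nelder-Mead polish.

    Deterministic for a fixed seed; ties between polished starts are
    broken by start order.  Returns (x, fun(x), converged).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    ndim = lower.size
    span = upper - lower

    def penalised(x):
        xc = np.clip(x, lower, upper)
        viol = np.sum(np.abs(x - xc) / span)
        base = fun(xc)
        if viol > 0:
            return base + (1e8 + base) * viol
        return base

    rng = np.random.default_rng(seed)
    starts = lower + span * rng.random((max(n_starts, 1), ndim))
    f0 = np.array([penalised(x) for x in starts])
    order = np.argsort(f0, kind="stable")

    best_x, best_f, converged = None, np.inf, False
    opts = dict(xatol=1e-10, fatol=1e-13, maxiter=4000 * ndim,
                maxfev=8000 * ndim)
    for idx in order[: max(n_polish, 1)]:
        x0 = starts[idx]
        res = minimize(penalised, x0, method="Nelder-Mead", options=opts)
        # one restart at the incumbent: re-seeds the simplex, which
        # rescues runs that stalled on badly scaled parameters
        res = minimize(penalised, res.x, method="Nelder-Mead", options=opts)
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lower, upper), float(res.fun)
            converged = bool(res.success)
    return best_x, best_f, converged


def _near_bounds(x, lower, upper, rel=1e-6):
    span = np.asarray(upper) - np.asarray(lower)
    return bool(np.any((x - lower) <= rel * span) or
                np.any((upper - x) <= rel * span))


def _resolve_bounds(law, free_names, user_bounds):
    table = dict(_DEFAULT_BOUNDS[law])
    if user_bounds:
        table.update(user_bounds)
    lower = np.array([table[n][0] for n in free_names], dtype=float)
    upper = np.array([table[n][1] for n in free_names], dtype=float)
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise DomainError("parameter bounds must be finite")
    if np.any(lower >= upper):
        raise DomainError("lower bounds must be below upper bounds")
    return lower, upper


def _validate_xy(X, y):
    L = np.asarray(X, dtype=float)
    if L.ndim == 2 and L.shape[1] == 1:
        L = L.ravel()
    if L.ndim != 1:
        raise DomainError("X must be 1-d sarcomere lengths (or a column)")
    P = np.asarray(y, dtype=float)
    if P.shape != L.shape:
        raise DomainError("X and y must have the same length")
    if np.any(L <= 0) or not np.all(np.isfinite(L)) or not np.all(np.isfinite(P)):
        raise DomainError("lengths must be positive and all values finite")
    return L, P


class FibreLawRegressor(RegressorMixin, BaseEstimator):
    """Pooled fit of one fibre passive law to (sarcomere length, stress) data.

    Parameters
    ----------
    law : "exponential", "quadratic" or "zhang".
    fixed : mapping of parameter name to frozen value (e.g. fix P0 for
        the Zhang law); the remaining parameters are fitted.
    bounds : per-parameter (low, high) overrides of the default box.
    n_starts, n_polish : multistart budget.
    random_state : seed of the start draws.

    Fitted attributes: ``params_`` (law parameter record), ``xi_``,
    ``rss_``, ``n_exp_``, ``n_params_``, ``nu_``, ``converged_``,
    ``at_bounds_``.
    """

    def __init__(self, law="exponential", fixed=None, bounds=None,
                 n_starts=64, n_polish=5, random_state=0):
        self.law = law
        self.fixed = fixed
        self.bounds = bounds
        self.n_starts = n_starts
        self.n_polish = n_polish
        self.random_state = random_state

    def fit(self, X, y):
        if self.law not in FIBRE_LAWS:
            raise DomainError(f"unknown fibre law {self.law!r}")
        L, P = _validate_xy(X, y)
        if L.size < 2 or np.ptp(L) == 0:
            raise FitError("degenerate data: need at least two distinct lengths")
        fixed = dict(self.fixed or {})
        names = FIBRE_LAWS[self.law]
        unknown = [k for k in fixed if k not in names]
        if unknown:
            raise DomainError(f"fixed parameters {unknown} not in law {self.law!r}")
        free = [n for n in names if n not in fixed]
        if not free:
            raise DomainError("no free parameters left to fit")
        if L.size - len(free) < 1:
            raise FitError("not enough points for the number of parameters")
        lower, upper = _resolve_bounds(self.law, free, self.bounds)
        cls = _LAW_PARAM_CLS[self.law]
        law_fn = _LAW_FN[self.law]

        def fun(x):
            params = cls(**{**fixed, **dict(zip(free, x))})
            resid = P - law_fn(L, params)
            return float(np.mean(resid ** 2))

        x, f, converged = _multistart_minimize(
            fun, lower, upper, self.random_state, self.n_starts, self.n_polish)
        self.params_ = cls(**{**fixed, **{n: float(v) for n, v in zip(free, x)}})
        self.free_names_ = tuple(free)
        self.xi_ = f
        self.n_exp_ = int(L.size)
        self.n_params_ = len(free)
        self.rss_ = f * self.n_exp_
        self.nu_ = self.n_exp_ - self.n_params_
        self.converged_ = converged
        self.at_bounds_ = _near_bounds(x, lower, upper)
        if self.at_bounds_:
            warnings.warn("fitted parameters lie at the bound box boundary",
                          RuntimeWarning, stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        L = np.asarray(X, dtype=float)
        if L.ndim == 2 and L.shape[1] == 1:
            L = L.ravel()
        return _LAW_FN[self.law](L, self.params_)

    def fit_result(self) -> FitResult:
        check_is_fitted(self, "params_")
        return FitResult(law=self.law, params=self.params_, xi=self.xi_,
                         rss=self.rss_, n_exp=self.n_exp_,
                         n_params=self.n_params_, nu=self.nu_,
                         seed=self.random_state, converged=self.converged_,
                         at_bounds=self.at_bounds_)


class BundleECMRegressor(RegressorMixin, BaseEstimator):
    """Fit the bundle composition with fibre parameters frozen.

    Only the ECM parameters (β, and optionally the bundle stress-free
    length L0b) are free; the fast/slow fibre laws and the volume
    fractions are inputs.  The bulk modulus k_v does not enter the
    uniaxial incompressible response and is carried through unchanged.
    """

    def __init__(self, fibre_fast=None, fibre_slow=None, fractions=None,
                 fit_L0b=True, L0b=1.6, k_v=0.0, bounds=None,
                 n_starts=64, n_polish=5, random_state=0):
        self.fibre_fast = fibre_fast
        self.fibre_slow = fibre_slow
        self.fractions = fractions
        self.fit_L0b = fit_L0b
        self.L0b = L0b
        self.k_v = k_v
        self.bounds = bounds
        self.n_starts = n_starts
        self.n_polish = n_polish
        self.random_state = random_state

    @staticmethod
    def _as_fibre_params(obj) -> FibreLawParams:
        if isinstance(obj, FitResult):
            obj = obj.params
        if isinstance(obj, FibreLawParams):
            return obj
        raise DomainError(
            "fibre parameters must be FibreLawParams or a FitResult holding them")

    def fit(self, X, y):
        fast = self._as_fibre_params(self.fibre_fast)
        slow = self._as_fibre_params(self.fibre_slow)
        fractions = self.fractions
        if not isinstance(fractions, VolumeFractions):
            raise DomainError("fractions must be a VolumeFractions instance")
        if fractions.alpha_c == 0:
            raise NonIdentifiableError(
                "alpha_c = 0: the ECM term does not enter the bundle stress "
                "and beta is not identifiable")
        L, P = _validate_xy(X, y)
        if L.size < 2 or np.ptp(L) == 0:
            raise FitError("degenerate data: need at least two distinct lengths")
        free = ["beta", "L0b"] if self.fit_L0b else ["beta"]
        if L.size - len(free) < 1:
            raise FitError("not enough points for the number of parameters")
        lower, upper = _resolve_bounds("bundle", free, self.bounds)

        fib = (fractions.alpha_f * fibre_stress(L, fast)
               + fractions.alpha_s * fibre_stress(L, slow))

        def fun(x):
            beta = x[0]
            l0b = x[1] if self.fit_L0b else self.L0b
            ecm = ECMParams(beta=beta, k_v=self.k_v, L0b=l0b)
            resid = P - (fib + fractions.alpha_c * ecm_uniaxial_stress(L, ecm))
            return float(np.mean(resid ** 2))

        x, f, converged = _multistart_minimize(
            fun, lower, upper, self.random_state, self.n_starts, self.n_polish)
        l0b = float(x[1]) if self.fit_L0b else float(self.L0b)
        self.ecm_params_ = ECMParams(beta=float(x[0]), k_v=self.k_v, L0b=l0b)
        self.model_ = BundleModel(fast=fast, slow=slow, ecm=self.ecm_params_,
                                  fractions=fractions)
        self.xi_ = f
        self.n_exp_ = int(L.size)
        self.n_params_ = len(free)
        self.rss_ = f * self.n_exp_
        self.nu_ = self.n_exp_ - self.n_params_
        self.converged_ = converged
        self.at_bounds_ = _near_bounds(x, lower, upper)
        if self.at_bounds_:
            warnings.warn("fitted parameters lie at the bound box boundary",
                          RuntimeWarning, stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        L = np.asarray(X, dtype=float)
        if L.ndim == 2 and L.shape[1] == 1:
            L = L.ravel()
        return bundle_uniaxial_stress(L, self.model_).total

    def fit_result(self) -> FitResult:
        check_is_fitted(self, "model_")
        return FitResult(law="bundle", params=self.model_, xi=self.xi_,
                         rss=self.rss_, n_exp=self.n_exp_,
                         n_params=self.n_params_, nu=self.nu_,
                         seed=self.random_state, converged=self.converged_,
                         at_bounds=self.at_bounds_)


class SingleExponentialRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of y(t) = y∞ + (y0 − y∞) exp(−k t).

    Used for two time-domain reductions: extraction of the relaxed
    stress plateau after a stretch step (``kind="decay_to_asymptote"``)
    and the tension-redevelopment rate constant k_tr after a quick
    release-restretch (``kind="rise_to_plateau"``).  The two kinds share
    the same model; ``kind`` only determines which orientation of the
    data triggers a warning.
    """

    def __init__(self, kind="decay_to_asymptote"):
        self.kind = kind

    def fit(self, X, y):
        if self.kind not in ("decay_to_asymptote", "rise_to_plateau"):
            raise DomainError(f"unknown kind {self.kind!r}")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        v = np.asarray(y, dtype=float)
        if t.size < 4:
            raise DomainError("need at least 4 samples")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if v.shape != t.shape:
            raise DomainError("times and values must have the same length")

        if np.ptp(v) == 0.0:
            self.asymptote_, self.amplitude_, self.rate_ = float(v[0]), 0.0, 0.0
            self.converged_ = True
            return self

        rising = v[-1] > v[0]
        if (self.kind == "decay_to_asymptote") == rising:
            warnings.warn(
                f"data orientation does not match kind={self.kind!r}; "
                "fitting anyway", RuntimeWarning, stacklevel=2)

        y_inf0 = float(v[-1])
        amp0 = float(v[0] - v[-1])
        # crude rate guess: time to cover 63% of the amplitude
        target = y_inf0 + amp0 / np.e
        crossed = np.nonzero((v - target) * np.sign(amp0) <= 0)[0]
        t63 = t[crossed[0]] if crossed.size else (t[-1] - t[0])
        k0 = 1.0 / max(t63 - t[0], (t[-1] - t[0]) / 100.0)

        def resid(p):
            y_inf, amp, k = p
            return y_inf + amp * np.exp(-k * t) - v

        res = least_squares(
            resid, x0=np.array([y_inf0, amp0, k0]),
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        y_inf, amp, k = res.x
        self.asymptote_ = float(y_inf)
        self.amplitude_ = float(amp)
        self.rate_ = float(k)
        self.converged_ = bool(res.success)
        return self

    def predict(self, X):
        check_is_fitted(self, "asymptote_")
        t = np.asarray(X, dtype=float)
        return self.asymptote_ + self.amplitude_ * np.exp(-self.rate_ * t)


# ---------------------------------------------------------------------------
# record-level wrappers


def _check_preparation(records, preparation):
    if preparation is None:
        return
    bad = {r.preparation for r in records} - {preparation}
    if bad:
        raise DomainError(
            f"expected only preparation={preparation!r} records, found {sorted(bad)}")


def fit_fibre_law(records, law="exponential", fixed=None, bounds=None,
                  seed=0, preparation="fibre", n_starts=64, n_polish=5) -> FitResult:
    """Pooled ("multiple") fit of a fibre law to measurement records.

    All records are concatenated into a single objective with one shared
    parameter set.  Pass ``preparation=None`` to fit mixed
    fibre+bundle groups (used by the fibres-vs-bundles comparison).
    """
    if len(records) == 0:
        raise DomainError("no records to fit")
    _check_preparation(records, preparation)
    L, P = _records_to_arrays(records)
    est = FibreLawRegressor(law=law, fixed=fixed, bounds=bounds,
                            n_starts=n_starts, n_polish=n_polish,
                            random_state=seed).fit(L, P)
    return est.fit_result()


def fit_bundle_ecm(records, fibre_fast, fibre_slow, fractions,
                   fit_L0b=True, L0b=1.6, bounds=None, seed=0,
                   n_starts=64, n_polish=5) -> FitResult:
    """Fit the ECM parameters of the bundle law with fibre laws frozen."""
    if len(records) == 0:
        raise DomainError("no records to fit")
    _check_preparation(records, "bundle")
    L, P = _records_to_arrays(records)
    est = BundleECMRegressor(fibre_fast=fibre_fast, fibre_slow=fibre_slow,
                             fractions=fractions, fit_L0b=fit_L0b, L0b=L0b,
                             bounds=bounds, n_starts=n_starts,
                             n_polish=n_polish, random_state=seed).fit(L, P)
    return est.fit_result()


def fit_single_exponential(times, values, kind="decay_to_asymptote"):
    """Fit y(t) = y∞ + (y0 − y∞) exp(−k t); return (amplitude, k, y∞)."""
    est = SingleExponentialRegressor(kind=kind).fit(times, values)
    return est.amplitude_, est.rate_, est.asymptote_
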