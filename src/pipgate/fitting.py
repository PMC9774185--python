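"""Parametric curve fits: Hill dose-response, GHK current-voltage, linear
rate-vs-concentration regression, and exponential dwell-time mixtures.

The fits are scikit-learn style estimators (``fit`` + fitted attributes with a
trailing underscore, ``get_params``/``set_params``), so they compose with
sklearn model-selection tooling; the module-level ``fit_*`` functions are thin
wrappers kept for scripting convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .constants import GAS_CONSTANT_J, FARADAY

__all__ = [
    "HillCurve",
    "GHKCurve",
    "ExponentialMixture",
    "MixtureFit",
    "LinFit",
    "hill_po",
    "fit_hill",
    "fit_ghk",
    "slope_conductance",
    "linear_rate_fit",
]


def hill_po(L, pmax: float, k05: float, n: float):
    """Hill open probability Po = Pmax / (1 + (K0.5/L)^n); Po(0) = 0 by limit."""
    L = np.asarray(L, dtype=float)
    out = np.zeros_like(L)
    pos = L > 0
    out[pos] = pmax / (1.0 + (k05 / L[pos]) ** n)
    return out


class HillCurve(BaseEstimator):
    """Nonlinear least-squares Hill fit of open probability vs concentration.

    Parameters
    ----------
    init : optional (pmax, k05, n) starting point; when omitted a small
        multi-start grid over K0.5 in {5, 20, 50} uM and n in {1, 2, 3} is
        scanned and the best sum of squares kept.
    bounds : ((lo,...), (hi,...)) box constraints; defaults keep Pmax in
        (0, 1], K0.5 > 0 and n > 0.

    Fitted attributes: ``pmax_``, ``k05_`` (uM), ``n_``, ``se_`` (array of
    standard errors from the Jacobian), ``cov_``, ``r_squared_``.
    """

    def __init__(self, init=None, bounds=None):
        self.init = init
        self.bounds = bounds

    def fit(self, L, po):
        L = np.asarray(L, dtype=float).ravel()
        po = np.asarray(po, dtype=float).ravel()
        if L.size != po.size:
            raise ValueError("L and po must have equal length")
        if len(np.unique(L)) < 4:
            raise ValueError("need >= 4 distinct concentrations")
        bounds = self.bounds or ((1e-6, 1e-6, 1e-3), (1.0, 1e6, 50.0))
        if self.init is not None:
            starts = [tuple(self.init)]
        else:
            pmax0 = min(max(po.max(), 0.05), 1.0)
            starts = [(pmax0, k, n) for k in (5.0, 20.0, 50.0) for n in (1.0, 2.0, 3.0)]
        best = None
        last_err = None
        for p0 in starts:
            try:
                popt, pcov = optimize.curve_fit(
                    hill_po, L, po, p0=np.clip(p0, bounds[0], bounds[1]),
                    bounds=bounds, maxfev=20000)
            except RuntimeError as err:  # pragma: no cover - rare
                last_err = err
                continue
            ssr = float(np.sum((po - hill_po(L, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise RuntimeError(f"Hill fit failed to converge from all starts: {last_err}")
        ssr, popt, pcov = best
        self.pmax_, self.k05_, self.n_ = map(float, popt)
        self.cov_ = pcov
        self.se_ = np.sqrt(np.diag(pcov))
        sst = float(np.sum((po - po.mean()) ** 2))
        self.r_squared_ = 1.0 - ssr / sst if sst > 0 else 1.0
        return self

    def predict(self, L):
        return hill_po(L, self.pmax_, self.k05_, self.n_)


def _ghk_flux(V, p_abs: float, ratio: float, c_in: float, c_out: float, T: float):
    """GHK current (pA) for one internal and one external monovalent cation.

    ``I = p_abs * (c_in * g(u) - ratio * c_out * g(-u))`` with
    ``g(u) = u / (1 - exp(-u))`` and ``u = F V / (R T)``.  ``p_abs`` is the
    absolute permeability scale of the internal ion in pA/mM (the GHK
    prefactor P*z^2*F^2/(R*T) folded into one constant); ``ratio`` is the
    external/internal permeability ratio.  V is membrane potential in mV
    (intracellular minus extracellular); inward current is negative.
    """
    V = np.asarray(V, dtype=float)
    u = V * 1e-3 * FARADAY / (GAS_CONSTANT_J * T)

    def g(x):
        x = np.asarray(x, dtype=float)
        out = np.ones_like(x)
        nz = np.abs(x) > 1e-9
        out[nz] = x[nz] / (-np.expm1(-x[nz]))
        return out

    return p_abs * (c_in * g(u) - ratio * c_out * g(-u))


class GHKCurve(BaseEstimator):
    """Least-squares fit of the GHK current equation to a single-channel I-V.

    The geometry is one permeant cation inside (concentration ``c_in``, mM)
    and one outside (``c_out``, mM), e.g. cytosolic Na+ vs pipette Li+.  The
    two free parameters are the absolute permeability scale of the internal
    ion (pA/mM) and the external/internal permeability ratio.  The reversal
    potential follows analytically:  Erev = (RT/F) ln(ratio * c_out / c_in).

    Fitted attributes: ``p_abs_``, ``perm_ratio_``, ``erev_`` (mV),
    ``erev_se_``, ``cov_``.
    """

    def __init__(self, c_in: float = 3.0, c_out: float = 140.0, temperature: float = 295.15):
        self.c_in = c_in
        self.c_out = c_out
        self.temperature = temperature

    def fit(self, V, I):
        V = np.asarray(V, dtype=float).ravel()
        I = np.asarray(I, dtype=float).ravel()
        if len(np.unique(V)) < 4:
            raise ValueError("need >= 4 distinct voltages")
        if np.all(I > 0) or np.all(I < 0):
            warnings.warn("currents do not bracket zero; reversal potential is extrapolated",
                          stacklevel=2)
        rt_f = GAS_CONSTANT_J * self.temperature / FARADAY * 1e3  # mV

        # fit in (p_abs, Erev); the permeability ratio follows from Erev
        def model(v, p_abs, erev):
            ratio = np.exp(erev / rt_f) * self.c_in / self.c_out
            return _ghk_flux(v, p_abs, ratio, self.c_in, self.c_out, self.temperature)

        scale = max(np.abs(I).max(), 1e-12) / max(np.abs(model(V, 1.0, 0.0)).max(), 1e-12)
        best = None
        for e0 in (-50.0, 0.0, 50.0, 100.0):
            try:
                popt, pcov = optimize.curve_fit(
                    model, V, I, p0=(scale, e0),
                    bounds=((1e-15, -500.0), (np.inf, 500.0)), maxfev=20000)
            except RuntimeError:  # pragma: no cover
                continue
            ssr = float(np.sum((I - model(V, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise RuntimeError("GHK fit failed to converge")
        _, popt, pcov = best
        self.p_abs_, self.erev_ = map(float, popt)
        self.perm_ratio_ = float(np.exp(self.erev_ / rt_f) * self.c_in / self.c_out)
        self.cov_ = pcov
        self.erev_se_ = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
        return self

    def predict(self, V):
        return _ghk_flux(V, self.p_abs_, self.perm_ratio_,
                         self.c_in, self.c_out, self.temperature)

    def slope_conductance(self, v_lo: float = -120.0, v_hi: float = -40.0,
                          with_se: bool = False):
        """Chord slope conductance (pS) of the fitted curve over [v_lo, v_hi].

        Least-squares line on a 1 mV grid; 1 pA/mV = 1000 pS.  With
        ``with_se`` the fit covariance is propagated numerically.
        """
        if v_lo >= v_hi:
            raise ValueError("v_lo must be < v_hi")
        rt_f = GAS_CONSTANT_J * self.temperature / FARADAY * 1e3

        def slope(p_abs, erev):
            ratio = np.exp(erev / rt_f) * self.c_in / self.c_out
            grid = np.arange(v_lo, v_hi + 0.5, 1.0)
            cur = _ghk_flux(grid, p_abs, ratio, self.c_in, self.c_out, self.temperature)
            return float(np.polyfit(grid, cur, 1)[0]) * 1e3  # pA/mV -> pS

        g = slope(self.p_abs_, self.erev_)
        if not with_se:
            return g
        # numeric gradient for the delta method
        eps = np.array([self.p_abs_ * 1e-6 + 1e-18, 1e-3])
        grad = np.array([
            (slope(self.p_abs_ + eps[0], self.erev_) - g) / eps[0],
            (slope(self.p_abs_, self.erev_ + eps[1]) - g) / eps[1],
        ])
        cov = np.where(np.isfinite(self.cov_), self.cov_, 0.0)
        se = float(np.sqrt(grad @ cov @ grad))
        return g, se


@dataclass(frozen=True)
class MixtureFit:
    """Exponential mixture fit: (weight, tau ms) components, taus ascending."""

    weights: np.ndarray
    taus: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool


class ExponentialMixture(BaseEstimator):
    """EM maximum-likelihood fit of a 1-3 component exponential mixture.

    Dwell-time densities of an aggregated Markov class are mixtures of
    exponentials with as many components as states in the class, so open-time
    distributions discriminate one open state from two.

    Convergence: log-likelihood gain < ``tol`` or ``max_iter`` iterations;
    ``n_init`` random restarts keep the best likelihood.  Fitted attributes:
    ``weights_``, ``taus_`` (ms, ascending), ``log_likelihood_``, ``n_iter_``,
    ``converged_``, ``result_`` (a :class:`MixtureFit`).
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-8,
                 n_init: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, durations, y=None):
        t = np.asarray(durations, dtype=float).ravel()
        if self.n_components not in (1, 2, 3):
            raise ValueError("n_components must be 1, 2 or 3")
        if t.size < 50:
            raise ValueError("need >= 50 durations")
        if np.any(t <= 0):
            raise ValueError("durations must be > 0")
        if np.ptp(t) == 0:
            raise ValueError("degenerate data: all durations equal")
        k = self.n_components
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init if k > 1 else 1):
            if k == 1:
                taus = np.array([t.mean()])
                w = np.ones(1)
            else:
                # spread starts over the quantile range
                q = rng.uniform(0.05, 0.95, size=k)
                taus = np.maximum(np.quantile(t, np.sort(q)), t.min() / 2)
                taus *= rng.uniform(0.5, 2.0, size=k)
                w = rng.dirichlet(np.ones(k))
            w, taus, ll, n_iter, conv = self._em(t, w, taus)
            if best is None or ll > best[2]:
                best = (w, taus, ll, n_iter, conv)
        w, taus, ll, n_iter, conv = best
        order = np.argsort(taus)
        self.weights_, self.taus_ = w[order], taus[order]
        self.log_likelihood_ = ll
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.result_ = MixtureFit(self.weights_, self.taus_, ll, n_iter, conv)
        return self

    def _em(self, t, w, taus):
        n = t.size
        ll_old = -np.inf
        conv = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E step: responsibilities under current mixture
            log_pdf = np.log(w)[:, None] - np.log(taus)[:, None] - t[None, :] / taus[:, None]
            m = log_pdf.max(axis=0)
            lse = m + np.log(np.exp(log_pdf - m).sum(axis=0))
            r = np.exp(log_pdf - lse)
            ll = float(lse.sum())
            # M step
            nk = r.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            w = nk / n
            taus = np.maximum((r @ t) / nk, 1e-12)
            if ll - ll_old < self.tol and ll >= ll_old:
                conv = True
                break
            ll_old = ll
        return w, taus, ll, it, conv

    def score(self, durations, y=None) -> float:
        t = np.asarray(durations, dtype=float).ravel()
        log_pdf = (np.log(self.weights_)[:, None] - np.log(self.taus_)[:, None]
                   - t[None, :] / self.taus_[:, None])
        m = log_pdf.max(axis=0)
        return float((m + np.log(np.exp(log_pdf - m).sum(axis=0))).sum())


@dataclass(frozen=True)
class LinFit:
    """Ordinary least-squares line with standard errors and slope p-value."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float
    r_squared: float


def linear_rate_fit(L_values, rate_values) -> LinFit:
    """OLS of a rate on ligand concentration with a two-sided slope t-test."""
    L = np.asarray(L_values, dtype=float)
    y = np.asarray(rate_values, dtype=float)
    if len(L) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(L) == 0:
        raise ValueError("singular design: all concentrations equal")
    res = stats.linregress(L, y)
    return LinFit(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), intercept_se=float(res.intercept_stderr),
        p_value=float(res.pvalue), r_squared=float(res.rvalue ** 2),
    )


# --- thin functional wrappers -------------------------------------------


def fit_hill(concentrations, po_values, init=None, bounds=None) -> HillCurve:
    return HillCurve(init=init, bounds=bounds).fit(concentrations, po_values)


def fit_ghk(voltages, currents, c_in: float = 3.0, c_out: float = 140.0,
            temperature: float = 295.15) -> GHKCurve:
    return GHKCurve(c_in=c_in, c_out=c_out, temperature=temperature).fit(voltages, currents)


def slope_conductance(fit: GHKCurve, v_lo: float = -120.0, v_hi: float = -40.0) -> float:
    return fit.slope_conductance(v_lo, v_hi)
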