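"""Nucleation kinetics: the cumulative-probability model and its fits.

In a DAmFRET experiment each cell's concentration ramps from 0 to its final
value ``c_T`` over the induction time ``T``, and nucleation is a Poisson
event with rate ``k * c(t)^n`` (``n`` the apparent reaction order).  The
fraction of cells that have nucleated by harvest is therefore

    P(c_T) = 1 - exp(-k_eff * integral_0^T c(t)^n dt)

which for the default linear ramp reduces to
``1 - exp(-k_eff * c_T^n * T / (n + 1))``.  ``n`` close to one is the
signature of a monomeric nucleus.

Self-poisoning -- stalled growth of nascent zippers at high monomer flux --
shows up as a multiphasic fraction-positive curve: the probability of
reaching the *high*-AmFRET state is the nucleation probability multiplied by
a logistic window that closes on ``[poisoning_c, escape_c]``.  The window's
logistic form is a convention of this package (flagged in fit reports); the
underlying observation is only that the curve plateaus and then rises again.

Fits maximize the binomial likelihood over per-bin counts; model selection
between the monophasic and poisoned forms uses a small-sample corrected
information criterion (AICc) with the number of informative bins as the
sample size and a selection threshold of Delta = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "NucleationParams",
    "BinnedCurve",
    "NucleationFit",
    "UnidentifiableCurveError",
    "cumulative_hazard",
    "predict_fraction",
    "poisoning_window",
    "fit_reaction_order",
    "detect_poisoning",
]

_EPS = 1e-9


class UnidentifiableCurveError(ValueError):
    """Raised when a fraction-positive curve carries no kinetic information."""


@dataclass(frozen=True)
class NucleationParams:
    """Rate law of stochastic nucleation.

    ``k`` is the rate constant (per hour per concentration-unit^n), ``n`` the
    apparent reaction order and ``pin_factor`` (>= 1) the multiplicative rate
    enhancement from a pre-existing conformational template.  The optional
    poisoning window ``[poisoning_c, escape_c]`` stalls growth of nucleated
    assemblies with sharpness ``poisoning_m`` and maximal probability
    ``poisoning_depth``.
    """

    k: float = 0.1
    n: float = 1.0
    pin_factor: float = 1.0
    poisoning_c: Optional[float] = None
    escape_c: Optional[float] = None
    poisoning_m: float = 4.0
    poisoning_depth: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.pin_factor < 1:
            raise ValueError("pin_factor must be >= 1")
        if (self.poisoning_c is None) != (self.escape_c is None):
            raise ValueError("poisoning_c and escape_c must be set together")
        if self.poisoning_c is not None and self.poisoning_c >= self.escape_c:
            raise ValueError("poisoning_c must be < escape_c")
        if not 0.0 <= self.poisoning_depth <= 1.0:
            raise ValueError("poisoning_depth must be within [0, 1]")


@dataclass
class BinnedCurve:
    """A fraction-positive curve with binomial counts per concentration bin."""

    conc: np.ndarray
    edges: np.ndarray
    n: np.ndarray
    k: np.ndarray
    fraction: np.ndarray
    n_out_of_range: int = 0

    @property
    def empty_bins(self) -> np.ndarray:
        return np.flatnonzero(self.n == 0)

    def informative(self) -> "BinnedCurve":
        """Restrict to bins with at least one event."""
        keep = self.n > 0
        return BinnedCurve(
            conc=self.conc[keep],
            edges=self.edges,
            n=self.n[keep],
            k=self.k[keep],
            fraction=self.fraction[keep],
            n_out_of_range=self.n_out_of_range,
        )

    def rescaled(self, s: float) -> "BinnedCurve":
        return BinnedCurve(
            conc=self.conc * s,
            edges=self.edges * s,
            n=self.n,
            k=self.k,
            fraction=self.fraction,
            n_out_of_range=self.n_out_of_range,
        )


@dataclass
class NucleationFit:
    """Result of kinetic fitting and monophasic/poisoned model selection."""

    k_hat: float
    n_hat: float
    n_ci: tuple[float, float]
    model: str  # "monophasic" | "poisoned" | "unidentifiable"
    information_criteria: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "k_hat": self.k_hat,
            "n_hat": self.n_hat,
            "n_ci": list(self.n_ci),
            "model": self.model,
            "information_criteria": self.information_criteria,
            "params": self.params,
            "notes": self.notes,
        }


def _ramp_integral(c_final: np.ndarray, T: float, n: float, ramp: str, ramp_rate: float):
    """integral_0^T c(t)^n dt for the supported concentration ramps."""
    c = np.asarray(c_final, dtype=float)
    if ramp == "linear":
        return c**n * T / (n + 1.0)
    if ramp == "exponential":
        # c(t) = c_T * exp(-r (T - t)): rises monotonically to c_T
        r = ramp_rate
        return c**n * (1.0 - np.exp(-r * n * T)) / (r * n)
    raise ValueError(f"unknown ramp {ramp!r}")


def cumulative_hazard(
    c_final,
    T: float,
    params: NucleationParams,
    ramp: str = "linear",
    ramp_rate: float = 0.3,
    expression=None,
):
    """Cumulative nucleation hazard by harvest for final concentration(s).

    ``expression`` may be any object with ``ramp``/``ramp_rate`` attributes
    (e.g. an ExpressionModel), overriding the explicit arguments.
    """
    if expression is not None:
        ramp = getattr(expression, "ramp", ramp)
        ramp_rate = getattr(expression, "ramp_rate", ramp_rate)
    k_eff = params.k * params.pin_factor
    return k_eff * _ramp_integral(c_final, T, params.n, ramp, ramp_rate)


def poisoning_window(c, params: NucleationParams) -> np.ndarray:
    """Probability that growth stalls at concentration ``c`` (0 outside the
    window; ``poisoning_depth`` deep inside ``[poisoning_c, escape_c]``)."""
    c = np.asarray(c, dtype=float)
    if params.poisoning_c is None or params.escape_c is None:
        return np.zeros_like(c)
    m = params.poisoning_m
    with np.errstate(divide="ignore", over="ignore"):
        open_side = 1.0 / (1.0 + (params.poisoning_c / np.maximum(c, 1e-300)) ** m)
        close_side = 1.0 / (1.0 + (c / params.escape_c) ** m)
    return params.poisoning_depth * open_side * close_side


def predict_fraction(
    c_T,
    T: float,
    params: NucleationParams,
    ramp: str = "linear",
    ramp_rate: float = 0.3,
) -> np.ndarray:
    """Expected fraction of cells in the high-AmFRET state at concentration c_T.

    Without poisoning this is the cumulative nucleation probability; with a
    poisoning window the nucleation probability is multiplied by the
    probability that growth did *not* stall.
    """
    p_nuc = 1.0 - np.exp(-cumulative_hazard(c_T, T, params, ramp, ramp_rate))
    return p_nuc * (1.0 - poisoning_window(c_T, params))


# --------------------------------------------------------------------------
# fitting


def _binom_nll(p: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _mono_nll(theta, curve: BinnedCurve, T: float) -> float:
    log_k, log_n = theta
    n_ord = np.exp(log_n)
    if not 1e-3 < n_ord < 1e3:
        return 1e12
    a = curve.conc**n_ord * T / (n_ord + 1.0)
    p = 1.0 - np.exp(-np.exp(log_k) * a)
    return _binom_nll(p, curve.k, curve.n)


def _k0_for_order(curve: BinnedCurve, T: float, n_ord: float) -> float:
    """Moment-match k from the bin whose fraction is nearest one half."""
    frac = np.clip(curve.k / np.maximum(curve.n, 1), 1e-4, 1.0 - 1e-4)
    i = int(np.argmin(np.abs(frac - 0.5)))
    a = curve.conc[i] ** n_ord * T / (n_ord + 1.0)
    return -np.log1p(-frac[i]) / a


def _check_identifiable(curve: BinnedCurve) -> BinnedCurve:
    cur = curve.informative()
    if len(cur.n) < 5:
        raise UnidentifiableCurveError("need >= 5 informative (non-empty) bins")
    frac = cur.k / cur.n
    interior = np.sum((frac > 0) & (frac < 1))
    if np.all(cur.k == 0) or np.all(cur.k == cur.n) or interior < 3:
        raise UnidentifiableCurveError(
            "curve is flat (all-0 or all-1) or has < 3 interior fractions"
        )
    return cur


def fit_reaction_order(
    curve: BinnedCurve, T: float, ci_level: float = 0.95
) -> NucleationFit:
    """Maximum-binomial-likelihood estimate of (k, n) for the monophasic model.

    Deterministic given the curve.  The confidence interval for ``n`` is a
    profile-likelihood interval at ``ci_level``.
    """
    cur = _check_identifiable(curve)

    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        theta0 = np.array([np.log(_k0_for_order(cur, T, n0)), np.log(n0)])
        res = minimize(
            _mono_nll,
            theta0,
            args=(cur, T),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    log_k_hat, log_n_hat = best.x
    nll_min = best.fun
    k_hat, n_hat = float(np.exp(log_k_hat)), float(np.exp(log_n_hat))

    # profile likelihood over log n
    thresh = chi2.ppf(ci_level, df=1) / 2.0

    def profile(log_n: float) -> float:
        res = minimize_scalar(
            lambda lk: _mono_nll((lk, log_n), cur, T),
            bounds=(log_k_hat - 12.0, log_k_hat + 12.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return res.fun - nll_min

    grid = log_n_hat + np.linspace(-1.5, 1.5, 61)
    prof = np.array([profile(g) for g in grid])
    below = prof <= thresh

    def _edge(side: str) -> float:
        idx = np.flatnonzero(below)
        if len(idx) == 0:
            return n_hat
        if side == "lo":
            i = idx[0]
            if i == 0:
                return float(np.exp(grid[0]))
            x0, x1, y0, y1 = grid[i - 1], grid[i], prof[i - 1], prof[i]
        else:
            i = idx[-1]
            if i == len(grid) - 1:
                return float(np.exp(grid[-1]))
            x0, x1, y0, y1 = grid[i], grid[i + 1], prof[i], prof[i + 1]
        # linear interpolation to the threshold crossing
        if y1 == y0:
            return float(np.exp(x1))
        t = (thresh - y0) / (y1 - y0)
        return float(np.exp(x0 + t * (x1 - x0)))

    ci = (_edge("lo"), _edge("hi"))
    pred = 1.0 - np.exp(-k_hat * cur.conc**n_hat * T / (n_hat + 1.0))
    return NucleationFit(
        k_hat=k_hat,
        n_hat=n_hat,
        n_ci=ci,
        model="monophasic",
        information_criteria={},
        params={"monophasic": {"k": k_hat, "n": n_hat, "nll": float(nll_min)}},
        curves={"monophasic": pred},
    )


def _poisoned_nll(theta, curve: BinnedCurve, T: float, m: float) -> float:
    log_k, log_n, log_pc, log_gap = theta
    n_ord = np.exp(log_n)
    if not 1e-3 < n_ord < 1e3:
        return 1e12
    pc = np.exp(np.clip(log_pc, -300.0, 300.0))
    ec = pc * (1.0 + np.exp(np.clip(log_gap, -30.0, 30.0)))
    par = NucleationParams(
        k=np.exp(log_k), n=n_ord, poisoning_c=pc, escape_c=ec, poisoning_m=m
    )
    p = predict_fraction(curve.conc, T, par)
    return _binom_nll(p, curve.k, curve.n)


def _aicc(nll: float, n_params: int, n_obs: int) -> float:
    aic = 2.0 * nll + 2.0 * n_params
    denom = n_obs - n_params - 1
    if denom <= 0:
        return np.inf
    return aic + 2.0 * n_params * (n_params + 1) / denom


def detect_poisoning(
    curve: BinnedCurve,
    T: float,
    poisoning_m: float = 4.0,
    delta: float = 2.0,
) -> NucleationFit:
    """Fit monophasic and poisoned-window models and select by AICc.

    Returns the monophasic fit augmented with both models' parameters and
    AICc scores; ``model`` is ``"poisoned"`` only when its AICc beats the
    monophasic score by more than ``delta``.  Flat curves yield an
    ``"unidentifiable"`` fit rather than an error.
    """
    try:
        mono = fit_reaction_order(curve, T)
    except UnidentifiableCurveError as err:
        return NucleationFit(
            k_hat=np.nan,
            n_hat=np.nan,
            n_ci=(np.nan, np.nan),
            model="unidentifiable",
            notes=str(err),
        )
    cur = curve.informative()
    n_obs = len(cur.n)
    nll_mono = mono.params["monophasic"]["nll"]

    # multi-start for the window position: anchor candidates on the empirical
    # dip (local max followed by lower values), plus quantile fallbacks
    frac = cur.k / cur.n
    candidates = []
    run_max = np.maximum.accumulate(frac)
    dip = np.flatnonzero(run_max - frac > 0.1)
    if len(dip):
        pc0 = cur.conc[max(dip[0] - 1, 0)]
        candidates.append((pc0, pc0 * 10.0))
        candidates.append((pc0, pc0 * 3.0))
    for q in (0.25, 0.5):
        pc0 = float(np.quantile(cur.conc, q))
        candidates.append((pc0, pc0 * 10.0))

    best = None
    lk0, ln0 = np.log(mono.k_hat), np.log(mono.n_hat)
    for pc0, ec0 in candidates:
        theta0 = np.array([lk0, ln0, np.log(pc0), np.log(ec0 / pc0 - 1.0 + 1e-9)])
        res = minimize(
            _poisoned_nll,
            theta0,
            args=(cur, T, poisoning_m),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    log_k, log_n, log_pc, log_gap = best.x
    pc = float(np.exp(np.clip(log_pc, -300.0, 300.0)))
    ec = pc * (1.0 + float(np.exp(np.clip(log_gap, -30.0, 30.0))))
    nll_poi = float(best.fun)

    ic = {
        "monophasic": _aicc(nll_mono, 2, n_obs),
        "poisoned": _aicc(nll_poi, 4, n_obs),
    }
    chosen = "poisoned" if ic["poisoned"] < ic["monophasic"] - delta else "monophasic"

    poi_params = NucleationParams(
        k=float(np.exp(log_k)),
        n=float(np.exp(log_n)),
        poisoning_c=pc,
        escape_c=ec,
        poisoning_m=poisoning_m,
    )
    fit = NucleationFit(
        k_hat=mono.k_hat,
        n_hat=mono.n_hat,
        n_ci=mono.n_ci,
        model=chosen,
        information_criteria=ic,
        params={
            "monophasic": mono.params["monophasic"],
            "poisoned": {
                "k": poi_params.k,
                "n": poi_params.n,
                "poisoning_c": pc,
                "escape_c": ec,
                "poisoning_m": poisoning_m,
                "nll": nll_poi,
            },
        },
        curves={
            "monophasic": mono.curves["monophasic"],
            "poisoned": predict_fraction(cur.conc, T, poi_params),
        },
        notes="poisoning window is a logistic convention, not a mechanistic form",
    )
    return fit
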