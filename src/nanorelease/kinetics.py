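"""Dissolution / drug-release kinetic models, fitting and mechanism calls.

Seven classical models of cumulative release are implemented on their
natural (untransformed) scale, together with the customary linearized
regressions, coefficient-of-determination ranking, and the
transport-mechanism classification rules based on the power-law exponent
``n`` (Korsmeyer-Peppas / Ritger-Peppas) and the Weibull shape factor
``b``.

Model forms (``t`` in minutes, ``C`` cumulative release as amount or
fraction):

==============  ================================================  ==========
name            C(t)                                              parameters
==============  ================================================  ==========
zero_order      ``C0 + K0*t``                                     C0, K0
first_order     ``Cd*(1 - exp(-K1*t))``                           Cd, K1
second_order    ``Cd - 1/(1/Cd + K2*t)``                          Cd, K2
higuchi         ``KH*sqrt(t)``                                    KH
hixson_crowell  ``Cd - (Cd**(1/3) - KHC*t)**3`` (clipped at Cd)   Cd, KHC
weibull         ``Cs*(1 - exp(-(t - T)**b / a))``                 Cs, T, a, b
power_law       ``K*t**n``                                        K, n
==============  ================================================  ==========

The second-order form integrates the rate law ``d(Cd-C)/dt = -K2*(Cd-C)^2``
so that release increases with time; the sign convention in which
``1/(Cd-C)`` *decreases* with time is available through
``printed_sign=True``.  The Weibull exponent groups the scale parameter
outside the power, ``(t-T)**b / a``; the alternative grouping
``((t-T)/a)**b`` is selected with ``scale_inside=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DomainError",
    "ParameterError",
    "FitError",
    "InputError",
    "ReleaseCurve",
    "KineticModelSpec",
    "FitResult",
    "MechanismCall",
    "MODELS",
    "predict",
    "r_squared",
    "fit_model",
    "fit_all",
    "classify_power_law",
    "classify_weibull",
    "read_release_csv",
    "write_release_csv",
]

# Exponent thresholds for the cylindrical-geometry power-law mechanism
# rules: n below N_FICKIAN is Fickian diffusion, n up to N_CASE_II is
# anomalous (diffusion + swelling), n == N_CASE_II is Case II
# relaxation-controlled transport, larger n is Super Case II.
N_FICKIAN = 0.5
N_CASE_II = 1.0
N_CASE_II_ATOL = 1e-9
# Weibull shape-factor thresholds: b <= B_FICKIAN is Fickian,
# B_FICKIAN < b <= B_COMBINED combined Fickian/swelling, larger b complex.
B_FICKIAN = 0.75
B_COMBINED = 1.0

# Fraction curves may slightly overshoot 1 with measurement noise.
FRACTION_OVERSHOOT = 1.05


class DomainError(ValueError):
    """A parameter or statistic lies outside its physical domain."""


class ParameterError(KeyError):
    """A model was called with an incomplete or unknown parameter set."""


class FitError(RuntimeError):
    """Least-squares optimisation failed to converge; carries diagnostics."""


class InputError(ValueError):
    """Input data violate a precondition (too few points, wrong kind...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseCurve:
    """A time-ordered cumulative release curve.

    Parameters
    ----------
    times :
        Sampling times in minutes, strictly increasing, at least 3 points.
    values :
        Cumulative release at each time, either an amount (e.g. ug/mL)
        or a fraction of the equilibrium amount, per ``value_kind``.
    value_kind :
        ``"amount"`` or ``"fraction"``.
    c_inf :
        Equilibrium amount C_inf; required to convert amounts to fractions.
    """

    times: np.ndarray
    values: np.ndarray
    value_kind: str = "amount"
    c_inf: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise InputError("times and values must be 1-D and equal length")
        if t.size < 3:
            raise InputError("a release curve needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(t < 0):
            raise InputError("times must be non-negative")
        if np.any(v < 0):
            raise InputError("release values must be non-negative")
        if self.value_kind not in ("amount", "fraction"):
            raise InputError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "fraction" and np.any(v > FRACTION_OVERSHOOT):
            raise InputError(
                f"fraction values must lie in [0, {FRACTION_OVERSHOOT}]"
            )
        if self.c_inf is not None and self.c_inf <= 0:
            raise InputError("c_inf must be positive")

    def as_fraction(self) -> "ReleaseCurve":
        """Return the curve on the fraction scale (C_t / C_inf)."""
        if self.value_kind == "fraction":
            return self
        if self.c_inf is None:
            raise InputError(
                "cannot convert amounts to fractions without c_inf"
            )
        return ReleaseCurve(
            self.times, self.values / self.c_inf, "fraction", None
        )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class KineticModelSpec:
    """Static description of one kinetic model."""

    name: str
    parameter_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    # prediction on the natural scale; signature (params, t, **flags)
    _predict: Callable[..., np.ndarray] = field(repr=False, compare=False)
    requires_fraction: bool = False

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)


@dataclass
class FitResult:
    """Parameter estimates for one model with goodness of fit.

    ``r_squared`` is the plain coefficient of determination on the
    fitted scale; ``adj_r_squared`` and ``aicc`` (small-sample corrected
    Akaike information criterion) additionally penalise parameter count,
    which matters when ranking models of different sizes on few points.
    """

    model: KineticModelSpec
    estimates: dict[str, float]
    r_squared: float  # NaN when undefined (degenerate data / failed fit)
    fit_scale: str  # "natural" or "linearized"
    residuals: np.ndarray
    converged: bool = True
    message: str = ""

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def n_obs(self) -> int:
        return int(self.residuals.size)

    @property
    def adj_r_squared(self) -> float:
        n, p = self.n_obs, self.model.n_parameters
        if n - p - 1 <= 0 or not np.isfinite(self.r_squared):
            return float("nan")
        return 1.0 - (1.0 - self.r_squared) * (n - 1) / (n - p - 1)

    @property
    def aicc(self) -> float:
        """AICc = n ln(SS/n) + 2p + 2p(p+1)/(n-p-1); +inf when p >= n-1."""
        n, p = self.n_obs, self.model.n_parameters
        if not self.converged or not np.isfinite(self.r_squared):
            return math.inf
        if n - p - 1 <= 0:
            return math.inf
        ss = float(np.sum(self.residuals**2))
        if ss <= 0.0:
            return -math.inf
        return n * math.log(ss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


@dataclass(frozen=True)
class MechanismCall:
    """A transport-mechanism label derived from n or b."""

    source: str  # "power_law_n" or "weibull_b"
    statistic_value: float
    label: str


# ---------------------------------------------------------------------------
# Model equations (natural scale)
# ---------------------------------------------------------------------------

def _zero_order(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    return p["C0"] + p["K0"] * t


def _first_order(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    return p["Cd"] * (1.0 - np.exp(-p["K1"] * t))


def _second_order(
    p: Mapping[str, float], t: np.ndarray, printed_sign: bool = False
) -> np.ndarray:
    sign = -1.0 if printed_sign else 1.0
    return p["Cd"] - 1.0 / (1.0 / p["Cd"] + sign * p["K2"] * t)


def _higuchi(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    return p["KH"] * np.sqrt(t)


def _hixson_crowell(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    root = np.clip(np.cbrt(p["Cd"]) - p["KHC"] * t, 0.0, None)
    return p["Cd"] - root**3


def _weibull(
    p: Mapping[str, float], t: np.ndarray, scale_inside: bool = False
) -> np.ndarray:
    if p["b"] < 0:
        raise DomainError("weibull shape b must be non-negative")
    dt = np.clip(t - p["T"], 0.0, None)
    if scale_inside:
        expo = (dt / p["a"]) ** p["b"]
    else:
        expo = dt ** p["b"] / p["a"]
    return p["Cs"] * (1.0 - np.exp(-expo))


def _power_law(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if p["n"] < 0:
        raise DomainError("release exponent n must be non-negative")
    return p["K"] * t ** p["n"]


_INF = math.inf

MODELS: dict[str, KineticModelSpec] = {
    "zero_order": KineticModelSpec(
        "zero_order", ("C0", "K0"),
        {"C0": (0.0, _INF), "K0": (0.0, _INF)}, _zero_order,
    ),
    "first_order": KineticModelSpec(
        "first_order", ("Cd", "K1"),
        {"Cd": (1e-12, _INF), "K1": (0.0, _INF)}, _first_order,
    ),
    "second_order": KineticModelSpec(
        "second_order", ("Cd", "K2"),
        {"Cd": (1e-12, _INF), "K2": (0.0, _INF)}, _second_order,
    ),
    "higuchi": KineticModelSpec(
        "higuchi", ("KH",), {"KH": (0.0, _INF)}, _higuchi,
    ),
    "hixson_crowell": KineticModelSpec(
        "hixson_crowell", ("Cd", "KHC"),
        {"Cd": (1e-12, _INF), "KHC": (0.0, _INF)}, _hixson_crowell,
    ),
    "weibull": KineticModelSpec(
        "weibull", ("Cs", "T", "a", "b"),
        {"Cs": (1e-12, _INF), "T": (0.0, _INF), "a": (1e-12, _INF),
         "b": (1e-6, 20.0)},
        _weibull, requires_fraction=True,
    ),
    "power_law": KineticModelSpec(
        "power_law", ("K", "n"),
        {"K": (0.0, _INF), "n": (0.0, 10.0)},
        _power_law, requires_fraction=True,
    ),
}


def _resolve_model(model: KineticModelSpec | str) -> KineticModelSpec:
    if isinstance(model, str):
        try:
            return MODELS[model]
        except KeyError:
            raise ParameterError(f"unknown model {model!r}") from None
    return model


def predict(
    model: KineticModelSpec | str,
    params: Mapping[str, float],
    times: Sequence[float] | np.ndarray,
    **flags,
) -> np.ndarray:
    """Evaluate a kinetic model at the given times.

    Parameters
    ----------
    model :
        Model spec or registry name.
    params :
        Complete parameter mapping for the model.
    times :
        Times in minutes, non-negative.
    **flags :
        ``printed_sign`` (second_order) or ``scale_inside`` (weibull).

    Raises
    ------
    ParameterError
        If a model parameter is missing.
    DomainError
        If times are negative or an exponent is negative.
    """
    spec = _resolve_model(model)
    missing = [k for k in spec.parameter_names if k not in params]
    if missing:
        raise ParameterError(
            f"{spec.name}: missing parameter(s) {missing}"
        )
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    return spec._predict({k: float(params[k]) for k in spec.parameter_names},
                         t, **flags)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Returns NaN when the observations are all identical (SS_tot = 0),
    in which case R^2 is undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InputError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Return (slope, intercept) of the least-squares line y = s*x + i."""
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def _anchor_cd(curve: ReleaseCurve) -> float:
    """Total-amount anchor used by the linearized first/second-order and
    Hixson-Crowell regressions (the classical fits assume the total is
    known).  Fractions anchor at 1; amounts at c_inf when given, else at
    a 5% margin above the largest observation."""
    if curve.value_kind == "fraction":
        return 1.0
    if curve.c_inf is not None:
        return float(curve.c_inf)
    return 1.05 * float(curve.values.max())


def _initial_guess(spec: KineticModelSpec, t: np.ndarray,
                   v: np.ndarray) -> dict:
    """Deterministic data-driven starting point for the nonlinear fit."""
    vmax = float(v.max()) if v.max() > 0 else 1.0
    if spec.name == "zero_order":
        s, i = _ols(t, v)
        return {"C0": max(i, 0.0), "K0": max(s, 0.0)}
    if spec.name == "higuchi":
        s, _ = _ols(np.sqrt(t), v)
        return {"KH": max(s, 1e-6)}
    if spec.name == "power_law":
        mask = (t > 0) & (v > 0)
        if mask.sum() >= 2:
            s, i = _ols(np.log(t[mask]), np.log(v[mask]))
            return {"K": float(np.exp(i)), "n": min(max(s, 0.0), 10.0)}
        return {"K": vmax, "n": 0.5}
    if spec.name in ("first_order", "second_order", "hixson_crowell"):
        cd = 1.05 * vmax
        remain = np.clip(cd - v, 1e-12, None)
        if spec.name == "first_order":
            s, _ = _ols(t, np.log(remain))
            return {"Cd": cd, "K1": max(-s, 1e-6)}
        if spec.name == "second_order":
            s, _ = _ols(t, 1.0 / remain)
            return {"Cd": cd, "K2": max(s, 1e-9)}
        s, _ = _ols(t, np.cbrt(cd) - np.cbrt(remain))
        return {"Cd": cd, "KHC": max(s, 1e-9)}
    if spec.name == "weibull":
        return {"Cs": vmax, "T": 0.0, "a": float(np.median(t)), "b": 1.0}
    raise ParameterError(f"unknown model {spec.name!r}")


def _fit_natural(
    spec: KineticModelSpec, t: np.ndarray, v: np.ndarray, flags: dict
) -> tuple[dict, np.ndarray, bool, str]:
    names = spec.parameter_names
    lo = np.array([spec.bounds[k][0] for k in names])
    hi = np.array([spec.bounds[k][1] for k in names])
    if spec.name == "weibull":
        # lag time cannot exceed the first observation
        hi = hi.copy()
        hi[names.index("T")] = float(t.min())

    def resid(x: np.ndarray) -> np.ndarray:
        return spec._predict(dict(zip(names, x)), t, **flags) - v

    starts = [_initial_guess(spec, t, v)]
    if spec.name == "weibull":
        base = starts[0]
        for b0 in (0.5, 2.0):
            starts.append({**base, "b": b0})
    best = None
    for guess in starts:
        x0 = np.clip(np.array([guess[k] for k in names]), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20_000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            return {}, np.full_like(v, np.nan), False, str(exc)
        if best is None or sol.cost < best.cost - 1e-18:
            best = sol
    estimates = dict(zip(names, map(float, best.x)))
    return estimates, resid(best.x), bool(best.success), best.message


def _fit_linearized(
    spec: KineticModelSpec, t: np.ndarray, v: np.ndarray, anchor: float
) -> tuple[dict, np.ndarray, np.ndarray, np.ndarray]:
    """Classical linearizing regression.

    Returns (estimates, observed-on-fitted-scale, predicted-on-fitted-scale,
    residuals).  The fitted scale is the transformed response where the
    model has a genuinely transformed response (first/second order,
    Hixson-Crowell, log-log power law) and the natural response otherwise.
    """
    name = spec.name
    if name == "zero_order":
        s, i = _ols(t, v)
        est = {"C0": i, "K0": s}
        pred = i + s * t
        return est, v, pred, v - pred
    if name == "higuchi":
        rt = np.sqrt(t)
        kh = float(np.sum(rt * v) / np.sum(t))  # through the origin
        pred = kh * rt
        return {"KH": kh}, v, pred, v - pred
    if name == "power_law":
        if np.any(t <= 0) or np.any(v <= 0):
            raise InputError("log-log regression needs positive t and values")
        y, x = np.log(v), np.log(t)
        s, i = _ols(x, y)
        pred = i + s * x
        return {"K": float(np.exp(i)), "n": s}, y, pred, y - pred
    if name in ("first_order", "second_order", "hixson_crowell"):
        cd = anchor
        remain = cd - v
        if np.any(remain <= 0):
            raise InputError(
                "linearized fit needs values strictly below the total"
            )
        if name == "first_order":
            y = np.log(remain)
            s, i = _ols(t, y)
            pred = i + s * t
            return {"Cd": float(np.exp(i)), "K1": -s}, y, pred, y - pred
        if name == "second_order":
            y = 1.0 / remain
            s, i = _ols(t, y)
            cd_hat = 1.0 / i if i > 0 else cd
            return {"Cd": cd_hat, "K2": s}, y, i + s * t, y - (i + s * t)
        y = np.cbrt(cd) - np.cbrt(remain)
        khc = float(np.sum(t * y) / np.sum(t * t))  # through the origin
        pred = khc * t
        return {"Cd": cd, "KHC": khc}, y, pred, y - pred
    raise InputError(f"no linearized form implemented for {name!r}")


def fit_model(
    curve: ReleaseCurve,
    model: KineticModelSpec | str,
    scale: str = "natural",
    **flags,
) -> FitResult:
    """Fit one kinetic model to a release curve by least squares.

    Parameters
    ----------
    curve :
        The observed cumulative release curve.  The power-law and Weibull
        models operate on the fraction scale; amount curves are converted
        through ``c_inf`` (an error is raised if it is missing).
    model :
        Model spec or registry name.
    scale :
        ``"natural"`` for nonlinear least squares on untransformed values,
        ``"linearized"`` for the classical linearizing regression.  R^2 is
        reported on the scale that was fitted.
    """
    spec = _resolve_model(model)
    if scale not in ("natural", "linearized"):
        raise InputError(f"unknown fit scale {scale!r}")
    t, v = curve.times, curve.values
    if spec.requires_fraction and curve.value_kind != "fraction":
        if curve.c_inf is None:
            raise InputError(
                f"{spec.name} operates on the fraction scale; provide "
                "c_inf to convert an amount curve"
            )
        v = v / curve.c_inf
    if len(curve) < spec.n_parameters + 1:
        raise InputError(
            f"{spec.name} needs at least {spec.n_parameters + 1} points"
        )
    degenerate = bool(np.all(v == v[0]))
    if scale == "linearized":
        if spec.name == "weibull":
            raise InputError("no linearized form implemented for 'weibull'")
        anchor = 1.0 if spec.requires_fraction else _anchor_cd(curve)
        est, obs_s, pred_s, res = _fit_linearized(spec, t, v, anchor)
        r2 = float("nan") if degenerate else r_squared(obs_s, pred_s)
        return FitResult(spec, est, r2, "linearized", res, True,
                         "degenerate data" if degenerate else "")
    est, res, ok, msg = _fit_natural(spec, t, v, flags)
    if not ok and not est:
        raise FitError(f"{spec.name}: {msg}")
    pred = v + res
    r2 = float("nan") if degenerate else r_squared(v, pred)
    return FitResult(spec, est, r2, "natural", res, ok,
                     "degenerate data" if degenerate else msg)


def _rank_key(fr: FitResult, rank_by: str) -> tuple:
    usable = fr.converged and np.isfinite(fr.r_squared)
    if rank_by == "aicc":
        score = fr.aicc if usable else math.inf
    elif rank_by == "r_squared":
        score = -fr.r_squared if usable else math.inf
    else:
        raise InputError(f"unknown ranking statistic {rank_by!r}")
    return (0 if usable else 1, score, fr.model.n_parameters, fr.model.name)


def fit_all(
    curve: ReleaseCurve,
    scale: str = "natural",
    models: Sequence[str] | None = None,
    rank_by: str = "aicc",
    **flags,
) -> list[FitResult]:
    """Fit every registered model and rank them, best first.

    The default ranking statistic is the small-sample corrected Akaike
    criterion (AICc): with four-parameter models competing against
    one- and two-parameter models on six-point curves, raw R^2 always
    prefers the most flexible model, so a parsimony-corrected statistic
    is needed for the best-supported model to be the data-generating
    one.  ``rank_by="r_squared"`` ranks by plain R^2 instead.

    Non-convergent fits (and models whose preconditions the curve cannot
    satisfy, e.g. power law on an amount curve without ``c_inf``) are
    retained with ``converged=False`` and ranked last.  Ties are broken
    by fewer parameters, then lexical model name, so the ordering is
    deterministic.
    """
    if len(curve) < 3:
        raise InputError("need at least 3 points")
    names = list(models) if models is not None else list(MODELS)
    results: list[FitResult] = []
    for name in names:
        spec = _resolve_model(name)
        kw = {}
        if spec.name == "second_order" and "printed_sign" in flags:
            kw["printed_sign"] = flags["printed_sign"]
        if spec.name == "weibull" and "scale_inside" in flags:
            kw["scale_inside"] = flags["scale_inside"]
        try:
            results.append(fit_model(curve, spec, scale=scale, **kw))
        except (InputError, FitError, DomainError) as exc:
            results.append(
                FitResult(spec, {}, float("nan"), scale,
                          np.full(len(curve), np.nan), False, str(exc))
            )
    results.sort(key=lambda fr: _rank_key(fr, rank_by))
    return results


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def classify_power_law(n: float) -> MechanismCall:
    """Transport mechanism from the release exponent n.

    n < 0.5 is Fickian diffusion; 0.5 <= n < 1 anomalous (diffusion and
    swelling); n == 1 Case II relaxation-controlled transport; n > 1
    Super Case II.  The boundary n = 0.5 belongs to the anomalous class
    (Fickian is *below* 0.5) and n = 1 is matched within 1e-9.
    """
    n = float(n)
    if n < 0:
        raise DomainError("release exponent n must be non-negative")
    if abs(n - N_CASE_II) <= N_CASE_II_ATOL:
        label = "case_II"
    elif n < N_FICKIAN:
        label = "fickian"
    elif n < N_CASE_II:
        label = "anomalous"
    else:
        label = "super_case_II"
    return MechanismCall("power_law_n", n, label)


def classify_weibull(b: float) -> MechanismCall:
    """Transport mechanism from the Weibull shape factor b.

    b <= 0.75 indicates Fickian diffusion; 0.75 < b <= 1 combined
    Fickian and swelling-controlled transport; b > 1 a complex
    mechanism.  The boundary b = 0.75 belongs to the Fickian class.
    """
    b = float(b)
    if b <= 0:
        raise DomainError("weibull shape b must be positive")
    if b <= B_FICKIAN:
        label = "fickian"
    elif b <= B_COMBINED:
        label = "combined"
    else:
        label = "complex"
    return MechanismCall("weibull_b", b, label)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_release_csv(path) -> ReleaseCurve:
    """Read a release curve from CSV with columns time_min, release.

    Optional metadata rows (key in the first column) may set
    ``value_kind`` and ``c_inf``; they are recognised by a non-numeric
    first field.
    """
    df = pd.read_csv(path, header=0, dtype=str)
    if df.shape[1] < 2:
        raise InputError("expected columns time_min, release")
    meta: dict[str, str] = {}
    rows = []
    for _, row in df.iterrows():
        key = str(row.iloc[0]).strip()
        try:
            rows.append((float(key), float(row.iloc[1])))
        except ValueError:
            meta[key] = str(row.iloc[1]).strip()
    if not rows:
        raise InputError("no numeric data rows found")
    rows.sort(key=lambda r: r[0])  # row order in the file is immaterial
    t, v = map(np.array, zip(*rows))
    kind = meta.get("value_kind", "amount")
    c_inf = float(meta["c_inf"]) if "c_inf" in meta else None
    return ReleaseCurve(t, v, kind, c_inf)


def write_release_csv(curve: ReleaseCurve, path) -> None:
    """Write a release curve to CSV (metadata rows appended)."""
    df = pd.DataFrame({"time_min": curve.times, "release": curve.values})
    extra = [("value_kind", curve.value_kind)]
    if curve.c_inf is not None:
        extra.append(("c_inf", curve.c_inf))
    df = pd.concat(
        [df, pd.DataFrame(extra, columns=["time_min", "release"])],
        ignore_index=True,
    )
    df.to_csv(path, index=False)
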