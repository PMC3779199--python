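"""Two-state thermal unfolding: forward model and apparent-T_m fitting.

Thermal denaturation followed by intrinsic fluorescence is modelled as a
two-state N <-> U equilibrium with a van't Hoff temperature dependence and
zero heat-capacity change:

    dG(T)  = dH_m * (1 - T / T_m)
    K(T)   = exp(-dG / (R T))
    f_U(T) = K / (1 + K)
    y(T)   = (y_N + p T) (1 - f_U) + (y_U + q T) f_U

where y_N + pT and y_U + qT are linear pre- and post-transition baselines,
T_m the mid-transition temperature and dH_m the unfolding enthalpy at T_m.
Unfolding of proteases under study is irreversible (the unfolded state is
consumed by aggregation/autolysis), so the fitted T_m is reported as an
*apparent* melting temperature throughout; no reversibility analysis is
attempted.

Internal unit is Kelvin; CSV I/O and reporting use degrees Celsius to
match how melting temperatures are tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GAS_CONSTANT",
    "MeltingCurve",
    "TwoStateFit",
    "FitConvergenceError",
    "fraction_unfolded",
    "two_state_signal",
    "init_guess_melting",
    "fit_melting",
    "read_melting_csv",
    "write_melting_csv",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

CELSIUS_OFFSET = 273.15


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; ``best`` carries the last iterate."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class MeltingCurve:
    """A thermal scan: strictly increasing temperature grid (K) and the
    fluorescence signal recorded at each read."""

    temperature_K: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_K.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if self.temperature_K.size < 20:
            raise ValueError("melting curve needs at least 20 points")
        if not np.all(np.diff(self.temperature_K) > 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_celsius(cls, temperature_C, signal, metadata=None) -> "MeltingCurve":
        return cls(np.asarray(temperature_C, float) + CELSIUS_OFFSET,
                   signal, metadata or {})

    @property
    def temperature_C(self) -> np.ndarray:
        return self.temperature_K - CELSIUS_OFFSET


@dataclass
class TwoStateFit:
    """Parameters of the two-state melting model.

    ``tm_K`` mid-transition temperature (K); ``dh_J_mol`` van't Hoff
    enthalpy at T_m (J/mol); ``y_native``/``y_unfolded`` baseline
    intercepts (signal units) with slopes ``slope_native``/
    ``slope_unfolded`` (signal units per K).  ``apparent`` is always True
    for fits of irreversible transitions.
    """

    tm_K: float
    dh_J_mol: float
    y_native: float
    y_unfolded: float
    slope_native: float = 0.0
    slope_unfolded: float = 0.0
    stderr: dict = field(default_factory=dict)
    apparent: bool = True
    converged: bool = True
    residual_norm: float = float("nan")
    edge_warning: bool = False

    @property
    def tm_C(self) -> float:
        return self.tm_K - CELSIUS_OFFSET


def fraction_unfolded(T, tm_K: float, dh_J_mol: float):
    """Equilibrium unfolded fraction f_U = K/(1+K) at temperature T (K),
    with K = exp(-dH_m (1 - T/T_m) / (R T)).  Vectorized over T."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or tm_K <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    dG = dh_J_mol * (1.0 - T / tm_K)
    # f = K/(1+K) = logistic(-dG/RT); expit avoids overflow at the tails
    out = expit(-dG / (GAS_CONSTANT * T))
    return out if out.ndim else float(out)


def two_state_signal(T, fit: TwoStateFit):
    """Observed signal at T (K): baseline-weighted mix of native and
    unfolded states."""
    T = np.asarray(T, dtype=float)
    fU = fraction_unfolded(T, fit.tm_K, fit.dh_J_mol)
    y = ((fit.y_native + fit.slope_native * T) * (1.0 - fU)
         + (fit.y_unfolded + fit.slope_unfolded * T) * fU)
    return y if y.ndim else float(y)


def _model_func(T, tm, dh, yn, yu, p, q):
    fU = expit(-dh * (1.0 - T / tm) / (GAS_CONSTANT * T))
    return (yn + p * T) * (1.0 - fU) + (yu + q * T) * fU


def init_guess_melting(curve: MeltingCurve) -> TwoStateFit:
    """Heuristic starting parameters.

    Baselines are fitted to the first and last 10% of points; the T_m
    guess is the temperature of steepest baseline-corrected signal change;
    dH_m defaults to 300 kJ/mol (a typical value for a ~25 kDa globular
    protein).  A curve with no resolvable transition is rejected.
    """
    T, y = curve.temperature_K, curve.signal
    n = T.size
    k = max(3, n // 10)
    pn = np.polyfit(T[:k], y[:k], 1)       # native baseline [slope, icpt]
    pu = np.polyfit(T[-k:], y[-k:], 1)     # unfolded baseline

    # transition amplitude = residual after removing the global linear trend
    trend = np.polyval(np.polyfit(T, y, 1), T)
    detrended = y - trend
    amplitude = detrended.max() - detrended.min()
    # point-to-point scatter as a noise scale
    noise = 1.4826 * np.median(np.abs(np.diff(detrended))) / np.sqrt(2)
    floor = 1e-7 * max(np.max(np.abs(y)), 1.0)   # numerically flat curve
    if amplitude <= floor or amplitude < 6.0 * noise:
        raise ValueError("no resolvable unfolding transition in curve "
                         f"(amplitude {amplitude:.3g}, noise {noise:.3g})")

    # steepest change of the baseline-corrected signal; a short moving
    # average keeps point noise from dominating the numerical derivative
    dydT = np.gradient(y, T)
    win = min(5, n)
    dydT = np.convolve(dydT, np.ones(win) / win, mode="same")
    base_slope = 0.5 * (pn[0] + pu[0])
    imax = int(np.argmax(np.abs(dydT - base_slope)))
    tm_guess = float(T[imax])
    edge = imax <= k or imax >= n - k - 1
    if edge:
        tm_guess = float(np.clip(tm_guess, T[k], T[-k - 1]))
        warnings.warn("transition near edge of scanned range; T_m guess clamped")
    return TwoStateFit(
        tm_K=tm_guess, dh_J_mol=300e3,
        y_native=float(pn[1]), y_unfolded=float(pu[1]),
        slope_native=float(pn[0]), slope_unfolded=float(pu[0]),
        edge_warning=edge,
    )


def fit_melting(curve: MeltingCurve, init: TwoStateFit | None = None) -> TwoStateFit:
    """Least-squares fit of all six two-state parameters.

    Returns a :class:`TwoStateFit` with per-parameter standard errors and
    the residual norm; raises :class:`FitConvergenceError` (carrying the
    best iterate) when the optimizer does not converge.  T_m outside the
    scanned range sets ``edge_warning``.
    """
    if init is None:
        init = init_guess_melting(curve)
    T, y = curve.temperature_K, curve.signal
    model = lmfit.Model(_model_func, independent_vars=["T"])
    params = model.make_params(
        tm=dict(value=init.tm_K, min=T[0] - 20.0, max=T[-1] + 20.0),
        dh=dict(value=init.dh_J_mol, min=1e3),
        yn=init.y_native, yu=init.y_unfolded,
        p=init.slope_native, q=init.slope_unfolded,
    )
    res = model.fit(y, params, T=T)
    stderr = {name: (par.stderr if par.stderr is not None else float("nan"))
              for name, par in res.params.items()}
    fit = TwoStateFit(
        tm_K=res.params["tm"].value, dh_J_mol=res.params["dh"].value,
        y_native=res.params["yn"].value, y_unfolded=res.params["yu"].value,
        slope_native=res.params["p"].value, slope_unfolded=res.params["q"].value,
        stderr=stderr, apparent=True, converged=bool(res.success),
        residual_norm=float(np.linalg.norm(res.residual)),
        edge_warning=not (T[0] <= res.params["tm"].value <= T[-1]),
    )
    if not res.success:
        raise FitConvergenceError("melting fit did not converge", best=fit)
    if fit.edge_warning:
        warnings.warn(
            f"fitted T_m {fit.tm_C:.1f} C lies outside the scanned range")
    return fit


# ---------------------------------------------------------------------------
# I/O — two-column CSV, temperatures in Celsius


def read_melting_csv(path) -> MeltingCurve:
    df = pd.read_csv(path, comment="#")
    if not {"temperature_C", "signal"} <= set(df.columns):
        raise ValueError("melting CSV needs columns temperature_C, signal")
    return MeltingCurve.from_celsius(df["temperature_C"].to_numpy(),
                                     df["signal"].to_numpy())


def write_melting_csv(curve: MeltingCurve, path) -> None:
    pd.DataFrame({"temperature_C": curve.temperature_C,
                  "signal": curve.signal}).to_csv(path, index=False)
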