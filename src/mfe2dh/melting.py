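"""Two-state thermal-melt fitting: T_m from 222 nm ellipticity curves.

The observable is modelled as a logistic transition between linear folded
and unfolded baselines,

    signal(T) = b_f(T) + [b_u(T) - b_f(T)] / (1 + exp(-s·(T - T_m))),

with b_f(T) = a_f + m_f·T and b_u(T) = a_u + m_u·T.  Only the midpoint T_m
is thermodynamically interpreted; no van 't Hoff enthalpy is extracted, so
the transition slope ``s`` (1/°C) is a shape parameter.  The fit is
invariant to affine rescaling of the signal axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TwoStateMeltModel",
    "TwoStateMeltResults",
    "MeltFit",
    "MeltFitError",
    "fit_two_state_melt",
    "delta_tm",
]


class MeltFitError(RuntimeError):
    """No usable two-state transition in the curve."""


def _two_state(T, t_m, slope, a_f, m_f, a_u, m_u):
    bf = a_f + m_f * T
    bu = a_u + m_u * T
    return bf + (bu - bf) / (1.0 + np.exp(-slope * (T - t_m)))


class TwoStateMeltModel:
    """Two-state unfolding model for one thermal-melt curve.

    Parameters
    ----------
    temperature, signal : array-like
        Ascending temperatures (°C) and the monitored signal (e.g. mdeg
        ellipticity at 222 nm).  At least 10 points spanning both baseline
        regimes are required.
    """

    def __init__(self, temperature, signal):
        self.temperature = np.asarray(temperature, dtype=float)
        self.signal = np.asarray(signal, dtype=float)
        if self.temperature.shape != self.signal.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and signal must be equal-length 1-D arrays")
        if self.temperature.size < 10:
            raise ValueError("need at least 10 points spanning both baselines")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly ascending")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temperature: str = "temperature_C", signal: str = "ellipticity"
    ) -> "TwoStateMeltModel":
        return cls(df[temperature].to_numpy(), df[signal].to_numpy())

    def _start_values(self):
        T, y = self.temperature, self.signal
        k = max(3, T.size // 5)
        mf, af = np.polyfit(T[:k], y[:k], 1)
        mu, au = np.polyfit(T[-k:], y[-k:], 1)
        dy = np.gradient(y, T)
        interior = slice(1, -1)
        tm0 = float(T[interior][np.argmax(np.abs(dy[interior]))])
        return tm0, 0.5, af, mf, au, mu

    def fit(self) -> "TwoStateMeltResults":
        """Least-squares fit; T_m is initialized at the steepest point of
        the numerical derivative and constrained to the scanned interval.

        Raises
        ------
        MeltFitError
            If the fit fails or the fitted transition amplitude is
            negligible against the signal range (flat / purely linear
            curve: no transition detectable).
        """
        T, y = self.temperature, self.signal
        p0 = self._start_values()
        lo = [T[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [T[-1], np.inf, np.inf, np.inf, np.inf, np.inf]
        try:
            popt, pcov = curve_fit(
                _two_state, T, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except RuntimeError as err:
            raise MeltFitError(f"two-state melt fit did not converge: {err}") from err
        t_m, slope, a_f, m_f, a_u, m_u = popt
        amplitude = abs((a_u + m_u * t_m) - (a_f + m_f * t_m))
        span = float(np.ptp(y))
        if span == 0 or amplitude < 0.05 * span:
            raise MeltFitError(
                "no transition detectable: fitted amplitude "
                f"{amplitude:.3g} is negligible against the signal range {span:.3g}"
            )
        t_range = T[-1] - T[0]
        if t_m - T[0] < 0.02 * t_range or T[-1] - t_m < 0.02 * t_range:
            warnings.warn(
                f"fitted T_m = {t_m:.1f} C sits at the edge of the scanned "
                f"interval [{T[0]:.0f}, {T[-1]:.0f}] C", stacklevel=2,
            )
        resid = y - _two_state(T, *popt)
        se = np.sqrt(np.diag(pcov))
        return TwoStateMeltResults(
            model=self,
            t_m=float(t_m),
            t_m_se=float(se[0]),
            transition_slope=float(slope),
            folded_baseline=(float(a_f), float(m_f)),
            unfolded_baseline=(float(a_u), float(m_u)),
            rss=float(resid @ resid),
            n_points=int(T.size),
        )


@dataclass
class TwoStateMeltResults:
    """Fitted melting midpoint with baselines and diagnostics."""

    model: TwoStateMeltModel
    t_m: float
    t_m_se: float
    transition_slope: float
    folded_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    rss: float
    n_points: int

    def predict(self, temperature) -> np.ndarray:
        T = np.asarray(temperature, dtype=float)
        return _two_state(
            T,
            self.t_m,
            self.transition_slope,
            *self.folded_baseline,
            *self.unfolded_baseline,
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-state melt fit",
                "==================",
                f"n points           {self.n_points:>10d}",
                f"T_m (C)            {self.t_m:>10.2f} +/- {self.t_m_se:.2g}",
                f"transition slope   {self.transition_slope:>10.3g} 1/C",
                f"folded baseline    {self.folded_baseline[0]:.3g} + {self.folded_baseline[1]:.3g}*T",
                f"unfolded baseline  {self.unfolded_baseline[0]:.3g} + {self.unfolded_baseline[1]:.3g}*T",
                f"RSS                {self.rss:>10.4g}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T = self.model.temperature
        grid = np.linspace(T[0], T[-1], 300)
        ax.plot(T, self.model.signal, "o", ms=3, label="observed")
        ax.plot(grid, self.predict(grid), "-", label="two-state fit")
        ax.axvline(self.t_m, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("ellipticity (mdeg)")
        ax.legend()
        return ax


#: convenience alias
MeltFit = TwoStateMeltResults


def fit_two_state_melt(curve) -> TwoStateMeltResults:
    """Fit from a DataFrame (``temperature_C``/``ellipticity``) or a
    two-column array-like of (temperature, signal)."""
    if isinstance(curve, pd.DataFrame):
        model = TwoStateMeltModel.from_dataframe(curve)
    else:
        arr = np.asarray(curve, dtype=float)
        model = TwoStateMeltModel(arr[:, 0], arr[:, 1])
    return model.fit()


def _tm_of(obj) -> float:
    return float(obj.t_m) if hasattr(obj, "t_m") else float(obj)


def delta_tm(variant, native) -> float:
    """Destabilization in °C: native T_m − variant T_m (positive means the
    variant melts earlier)."""
    return _tm_of(native) - _tm_of(variant)
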