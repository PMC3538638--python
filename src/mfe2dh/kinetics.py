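"""Michaelis–Menten kinetics: model fitting and catalytic constants.

The model object / results object split follows the statsmodels idiom:

>>> model = MichaelisMentenModel.from_dataframe(rates)      # doctest: +SKIP
>>> res = model.fit()                                       # doctest: +SKIP
>>> res.v_max, res.k_m, res.summary()                       # doctest: +SKIP

Rates are in µmol·min⁻¹·mg⁻¹, substrate in µM, turnover numbers in s⁻¹ and
catalytic efficiency k_cat/K_m on the s⁻¹·µM⁻¹ scale.  Note that published
turnover numbers are treated as data in this package: depending on the
active-site basis a laboratory assumed, k_cat may not be reconstructable
from V_max and the subunit mass (see :func:`vmax_to_kcat`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MichaelisMentenModel",
    "MichaelisMentenResults",
    "KineticsFit",
    "KineticsFitError",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "relative_efficiency",
    "vmax_to_kcat",
    "round_sig",
]


class KineticsFitError(RuntimeError):
    """Nonlinear fit failed; carries the initial values used."""

    def __init__(self, message: str, p0: tuple[float, float] | None = None):
        super().__init__(message)
        self.p0 = p0


def _mm(S, v_max, k_m):
    return v_max * S / (k_m + S)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


class MichaelisMentenModel:
    """Saturation kinetics v = V_max·S / (K_m + S) for one enzyme.

    Parameters
    ----------
    substrate, rate : array-like
        Substrate concentrations (µM) and observed rates.  At least 4
        points are required; ideally they bracket the half-saturation
        region.
    weights : array-like, optional
        Per-point weights for weighted least squares (1/σ). The default is
        an unweighted fit.
    """

    def __init__(self, substrate, rate, weights=None):
        self.substrate = np.asarray(substrate, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.substrate.shape != self.rate.shape or self.substrate.ndim != 1:
            raise ValueError("substrate and rate must be equal-length 1-D arrays")
        if self.substrate.size < 4:
            raise ValueError("need at least 4 (substrate, rate) points")
        if np.any(self.substrate <= 0):
            raise ValueError("substrate concentrations must be positive")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, substrate: str = "substrate_uM", rate: str = "rate", weights=None
    ) -> "MichaelisMentenModel":
        return cls(df[substrate].to_numpy(), df[rate].to_numpy(), weights=weights)

    def _start_values(self) -> tuple[float, float]:
        v0 = float(self.rate.max())
        if v0 <= 0:
            raise KineticsFitError("all observed rates are <= 0; nothing to fit")
        half = v0 / 2.0
        k0 = float(self.substrate[np.argmin(np.abs(self.rate - half))])
        return v0, max(k0, 1e-6)

    def fit(self) -> "MichaelisMentenResults":
        """Nonlinear least squares; asymptotic standard errors from the
        covariance of the optimum."""
        p0 = self._start_values()
        sigma = None if self.weights is None else 1.0 / self.weights
        try:
            popt, pcov, infodict, mesg, ier = curve_fit(
                _mm,
                self.substrate,
                self.rate,
                p0=p0,
                sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                full_output=True,
                maxfev=10000,
            )
        except RuntimeError as err:
            raise KineticsFitError(
                f"Michaelis–Menten fit did not converge from p0={p0}: {err}", p0=p0
            ) from err
        resid = self.rate - _mm(self.substrate, *popt)
        se = np.sqrt(np.diag(pcov))
        return MichaelisMentenResults(
            model=self,
            v_max=float(popt[0]),
            k_m=float(popt[1]),
            v_max_se=float(se[0]),
            k_m_se=float(se[1]),
            rss=float(resid @ resid),
            n_points=int(self.substrate.size),
            cov=pcov,
        )


@dataclass
class MichaelisMentenResults:
    """Fitted kinetic parameters with uncertainties and catalytic constants."""

    model: MichaelisMentenModel
    v_max: float
    k_m: float
    v_max_se: float
    k_m_se: float
    rss: float
    n_points: int
    cov: np.ndarray
    k_cat: float | None = None

    def with_kcat(self, k_cat: float) -> "MichaelisMentenResults":
        """Attach a turnover number (s⁻¹), e.g. a published value; needed
        before :attr:`efficiency` is available."""
        if k_cat < 0:
            raise ValueError("k_cat must be >= 0")
        self.k_cat = float(k_cat)
        return self

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency k_cat/K_m (s⁻¹·µM⁻¹ scale)."""
        if self.k_cat is None:
            raise ValueError("no k_cat attached; call with_kcat() first")
        return catalytic_efficiency(self.k_cat, self.k_m)

    def predict(self, substrate) -> np.ndarray:
        return _mm(np.asarray(substrate, dtype=float), self.v_max, self.k_m)

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            "====================",
            f"n points            {self.n_points:>10d}",
            f"V_max (umol/min/mg) {self.v_max:>10.4g} +/- {self.v_max_se:.2g}",
            f"K_m (uM)            {self.k_m:>10.4g} +/- {self.k_m_se:.2g}",
            f"RSS                 {self.rss:>10.4g}",
        ]
        if self.k_cat is not None:
            lines.append(f"k_cat (1/s)         {self.k_cat:>10.4g}")
            lines.append(f"k_cat/K_m (1/s/uM)  {self.efficiency:>10.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data plus fitted saturation curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        S = self.model.substrate
        grid = np.linspace(0, S.max() * 1.05, 200)
        ax.plot(S, self.model.rate, "o", label="observed")
        ax.plot(grid, _mm(grid, self.v_max, self.k_m), "-", label="fit")
        ax.set_xlabel("substrate (µM)")
        ax.set_ylabel("rate (µmol·min⁻¹·mg⁻¹)")
        ax.legend()
        return ax


#: convenience alias for the fit-results container
KineticsFit = MichaelisMentenResults


def fit_michaelis_menten(data, weights=None) -> MichaelisMentenResults:
    """Fit from a DataFrame (columns ``substrate_uM``/``rate``) or a
    two-column array-like of (substrate, rate)."""
    if isinstance(data, pd.DataFrame):
        model = MichaelisMentenModel.from_dataframe(data, weights=weights)
    else:
        arr = np.asarray(data, dtype=float)
        model = MichaelisMentenModel(arr[:, 0], arr[:, 1], weights=weights)
    return model.fit()


def catalytic_efficiency(k_cat: float, k_m: float) -> float:
    """k_cat/K_m on the printed scale (s⁻¹ / µM). Zero turnover → 0."""
    if k_m <= 0:
        raise ValueError("K_m must be positive")
    if k_cat == 0:
        return 0.0
    return k_cat / k_m


def _efficiency_of(obj) -> float:
    return float(obj.efficiency) if hasattr(obj, "efficiency") else float(obj)


def relative_efficiency(variant, native) -> int:
    """Variant efficiency as a whole percent of the native enzyme.

    Accepts fitted results (with ``.efficiency``) or plain numbers.
    """
    nat = _efficiency_of(native)
    if nat <= 0:
        raise ValueError("native efficiency must be positive")
    return int(round(100.0 * _efficiency_of(variant) / nat))


def vmax_to_kcat(v_max: float, molar_mass: float, sites_per_unit: int = 1) -> float:
    """Convert a specific activity to a turnover number.

    k_cat [s⁻¹] = V_max [µmol·min⁻¹·mg⁻¹] × M [g·mol⁻¹] / (6.0·10⁴ × sites):
    1 mg of enzyme holds 10⁻³/M mol of subunits, and minutes convert to
    seconds.  Beware that published k_cat values often assume an active-site
    or oligomer basis that this arithmetic cannot recover; use those as data
    rather than re-deriving them.
    """
    if v_max <= 0 or molar_mass <= 0 or sites_per_unit <= 0:
        raise ValueError("v_max, molar_mass and sites_per_unit must be positive")
    return v_max * molar_mass / (6.0e4 * sites_per_unit)
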