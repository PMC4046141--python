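"""Thermal-stability analysis of melt curves followed by circular dichroism.

Thermal denaturation of these enzymes is irreversible, which rules out an
equilibrium thermodynamic treatment (no ΔH, no van't Hoff analysis).  What
can be compared across variants measured under identical conditions is the
transition midpoint of a Boltzmann sigmoid fitted to the ellipticity-vs-
temperature trace — the apparent Tm:

    y(T) = bf + (bu - bf) / (1 + exp((Tm - T)/s))

with folded/unfolded baselines bf, bu (constants) and slope parameter s (°C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import FitError, _linearized_covariance

#: Mean molecular mass per residue (g/mol) used to normalize ellipticity.
MEAN_RESIDUE_MASS = 109.1

__all__ = [
    "MeltCurve",
    "MeltFitResults",
    "MeltCurveModel",
    "mre_convert",
    "boltzmann_signal",
    "fit_melt",
    "classify_stability",
    "MEAN_RESIDUE_MASS",
]


def mre_convert(ellipticity_mdeg, concentration_mg_ml: float,
                path_length_cm: float,
                mean_residue_mass: float = MEAN_RESIDUE_MASS):
    """Mean residue ellipticity (deg cm² dmol⁻¹) from raw ellipticity (mdeg).

    [Θ] = θ·MRW / (10·c·l) with c in mg/mL and l in cm.
    """
    if concentration_mg_ml <= 0 or path_length_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    theta = np.asarray(ellipticity_mdeg, dtype=float)
    out = theta * mean_residue_mass / (10.0 * concentration_mg_ml * path_length_cm)
    return float(out) if out.ndim == 0 else out


def boltzmann_signal(T, Tm: float, slope: float,
                     baseline_folded: float, baseline_unfolded: float):
    """Boltzmann sigmoid between two constant baselines.

    Monotone in T; at T = Tm the signal is midway between the baselines.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    T = np.asarray(T, dtype=float)
    out = baseline_folded + (baseline_unfolded - baseline_folded) / (
        1.0 + np.exp((Tm - T) / slope))
    return float(out) if out.ndim == 0 else out


@dataclass
class MeltCurve:
    """One thermal denaturation trace (signal vs temperature)."""

    temperatures: np.ndarray  # °C, strictly increasing
    signal: np.ndarray  # ellipticity (mdeg) or mean residue ellipticity
    variant: str = ""
    concentration_mg_ml: float | None = None
    path_length_cm: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape or self.temperatures.ndim != 1:
            raise ValueError("temperatures and signal must be 1-D, equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.temperatures) < 8:
            raise ValueError("need >= 8 points spanning both baselines")

    def __len__(self) -> int:
        return len(self.temperatures)

    def to_mre(self) -> "MeltCurve":
        """Convert an ellipticity trace to mean residue ellipticity."""
        if self.concentration_mg_ml is None or self.path_length_cm is None:
            raise ValueError("concentration and path length required for MRE")
        return MeltCurve(
            temperatures=self.temperatures,
            signal=mre_convert(self.signal, self.concentration_mg_ml,
                               self.path_length_cm),
            variant=self.variant,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str | None = None
                       ) -> "MeltCurve":
        sub = df if variant is None else df[df["variant"] == variant]
        if sub.empty:
            raise ValueError(f"no rows for variant {variant!r}")
        sub = sub.sort_values("temperature_C")
        return cls(temperatures=sub["temperature_C"].to_numpy(),
                   signal=sub["signal"].to_numpy(),
                   variant=variant or str(sub["variant"].iloc[0]))


@dataclass
class MeltFitResults:
    """Boltzmann fit of one melt curve; Tm_app reported to 0.1 °C."""

    model: object
    tm: float  # °C
    slope: float  # °C
    baseline_folded: float
    baseline_unfolded: float
    bse: dict[str, float]
    resid: np.ndarray
    n_obs: int

    @property
    def tm_app(self) -> float:
        """Apparent Tm rounded to the reporting precision (0.1 °C)."""
        return round(self.tm, 1)

    @property
    def params(self) -> dict[str, float]:
        return {"Tm": self.tm, "slope": self.slope,
                "baseline_folded": self.baseline_folded,
                "baseline_unfolded": self.baseline_unfolded}

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.resid))

    def predict(self, T) -> np.ndarray:
        return boltzmann_signal(T, self.tm, self.slope,
                                self.baseline_folded, self.baseline_unfolded)

    def summary(self) -> str:
        curve = self.model.curve
        lines = [
            "Boltzmann melt fit" + (f"  [{curve.variant}]" if curve.variant else ""),
            f"  n = {self.n_obs} points, ||resid|| = {self.residual_norm:.4g}",
            f"  Tm_app = {self.tm_app:.1f} +/- {self.bse['Tm']:#.2g} C",
            f"  slope  = {self.slope:#.3g} +/- {self.bse['slope']:#.2g} C",
            f"  baselines: folded {self.baseline_folded:#.4g}, "
            f"unfolded {self.baseline_unfolded:#.4g}",
        ]
        return "\n".join(lines)


class MeltCurveModel:
    """Single Boltzmann sigmoid with constant baselines.

    Initial guesses: baselines from the means of the first and last 10% of
    points, Tm from the half-range crossing, slope 2 °C.  A curve whose
    signal range is indistinguishable from noise, or whose fitted midpoint
    falls outside the scanned temperature range, is rejected.
    """

    param_names = ("Tm", "slope", "baseline_folded", "baseline_unfolded")

    def __init__(self, curve: MeltCurve, sloped_baselines: bool = False):
        if sloped_baselines:
            raise NotImplementedError(
                "sloped baselines are not implemented; constant baselines only")
        rng = float(np.ptp(curve.signal))
        if rng == 0:
            raise ValueError("flat curve: no unfolding transition to fit")
        self.curve = curve

    def _initial_guess(self) -> np.ndarray:
        T, y = self.curve.temperatures, self.curve.signal
        k = max(1, len(T) // 10)
        bf0, bu0 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
        half = (bf0 + bu0) / 2.0
        # first crossing of the half-range level
        crossings = np.nonzero(np.diff(np.sign(y - half)))[0]
        tm0 = float(T[crossings[0]]) if len(crossings) else float(np.median(T))
        return np.array([tm0, 2.0, bf0, bu0])

    def fit(self) -> MeltFitResults:
        T, y = self.curve.temperatures, self.curve.signal
        x0 = self._initial_guess()

        def unpack(x):
            tm, log_slope, bf, bu = x
            return tm, np.exp(log_slope), bf, bu

        def resid(x):
            tm, slope, bf, bu = unpack(x)
            return boltzmann_signal(T, tm, slope, bf, bu) - y

        x0[1] = np.log(x0[1])  # slope fitted in log space to stay positive
        sol = least_squares(resid, x0, method="lm", xtol=1e-10,
                            ftol=1e-15, gtol=1e-15, max_nfev=2000)
        if not sol.success:
            raise FitError(f"melt fit did not converge: {sol.message}")
        tm, slope, bf, bu = unpack(sol.x)
        if not (T[0] <= tm <= T[-1]):
            raise FitError(
                f"fitted midpoint {tm:.1f} C outside the scanned range "
                f"[{T[0]:.1f}, {T[-1]:.1f}] C — transition not captured")
        cov = _linearized_covariance(sol.jac, sol.fun, 4)
        se = np.sqrt(np.diag(cov))
        se[1] *= slope  # delta method for the log-fitted slope
        return MeltFitResults(
            model=self, tm=float(tm), slope=float(slope),
            baseline_folded=float(bf), baseline_unfolded=float(bu),
            bse=dict(zip(self.param_names, map(float, se))),
            resid=sol.fun, n_obs=len(y),
        )


def fit_melt(curve: MeltCurve) -> MeltFitResults:
    """Fit a single Boltzmann sigmoid to a melt curve."""
    return MeltCurveModel(curve).fit()


def classify_stability(tm_values: dict[str, float], reference: str,
                       delta_threshold: float = 5.0) -> pd.DataFrame:
    """Group variants by apparent-Tm shift from a reference enzyme.

    |ΔTm| ≤ threshold → reference-like; ΔTm > threshold → stabilized;
    ΔTm < −threshold → destabilized.
    """
    if reference not in tm_values:
        raise ValueError(f"reference {reference!r} missing from tm_values")
    ref_tm = tm_values[reference]
    rows = []
    for variant, tm in tm_values.items():
        delta = tm - ref_tm
        if abs(delta) <= delta_threshold:
            group = "reference-like"
        elif delta > delta_threshold:
            group = "stabilized"
        else:
            group = "destabilized"
        rows.append({"variant": variant, "tm_app_C": tm,
                     "delta_tm_C": delta, "group": group})
    return pd.DataFrame(rows, columns=["variant", "tm_app_C", "delta_tm_C", "group"])
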