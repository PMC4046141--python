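"""Steady-state kinetic models with and without substrate inhibition.

Initial velocities of aldehyde oxidation follow Michaelis–Menten kinetics,

    v/E = kcat·S / (Km + S),

except for 3-aminopropionaldehyde, where non-productive binding of the
aldehyde to the enzyme–NADH complex inhibits at high substrate:

    v/E = kcat·S / (Km + S·(1 + S/K_IS))        (total substrate inhibition)

Units follow the field's convention for these enzymes: kcat in s⁻¹
(velocities are expressed per enzyme concentration), Km and K_IS in µM, and
catalytic efficiency kcat/Km in mM⁻¹ s⁻¹.

Models follow the Model/Results idiom: build a model from a
:class:`KineticDataset`, call :meth:`fit`, and read estimates, standard
errors and diagnostics off the returned :class:`KineticsResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticDataset",
    "KineticsResults",
    "MichaelisMentenModel",
    "SubstrateInhibitionModel",
    "ActivityGrouping",
    "FitError",
    "mm_velocity",
    "si_velocity",
    "fit_mm",
    "fit_si",
    "catalytic_efficiency",
    "classify_badh_groups",
]

#: µM → mM conversion lives here and only here.
_UM_PER_MM = 1000.0

#: Default threshold (mM⁻¹ s⁻¹) separating BADH-active from AMADH-only
#: enzymes: midpoint of the empirical efficiency gap (1.1 … 15) between the
#: two observed groups.
BADH_EFFICIENCY_THRESHOLD = 5.0


class FitError(RuntimeError):
    """Nonlinear regression failed; carries solver diagnostics."""


def _check_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not (np.all(np.asarray(val) > 0)):
            raise ValueError(f"{name} must be positive, got {val}")


def mm_velocity(kcat: float, Km: float, S) -> np.ndarray | float:
    """Michaelis–Menten initial velocity per enzyme, v/E = kcat·S/(Km+S)."""
    _check_positive(kcat=kcat, Km=Km, S=S)
    S = np.asarray(S, dtype=float)
    out = kcat * S / (Km + S)
    return float(out) if out.ndim == 0 else out


def si_velocity(kcat: float, Km: float, K_IS: float, S) -> np.ndarray | float:
    """Total-substrate-inhibition velocity, v/E = kcat·S/(Km + S(1 + S/K_IS)).

    ``K_IS = inf`` recovers Michaelis–Menten exactly.  The velocity peaks at
    S = sqrt(Km·K_IS).
    """
    if not math.isinf(K_IS):
        _check_positive(K_IS=K_IS)
    _check_positive(kcat=kcat, Km=Km, S=S)
    S = np.asarray(S, dtype=float)
    inhib = np.zeros_like(S) if math.isinf(K_IS) else S / K_IS
    out = kcat * S / (Km + S * (1.0 + inhib))
    return float(out) if out.ndim == 0 else out


def catalytic_efficiency(kcat: float, Km: float) -> float:
    """kcat/Km in mM⁻¹ s⁻¹ from kcat in s⁻¹ and Km in µM."""
    _check_positive(kcat=kcat, Km=Km)
    return kcat / Km * _UM_PER_MM


@dataclass
class KineticDataset:
    """One saturation curve: substrate concentrations (µM) and v/E (s⁻¹)."""

    conc: np.ndarray  # µM
    rates: np.ndarray  # s⁻¹ (initial velocity / enzyme concentration)
    variant: str = ""
    substrate: str = ""

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.conc.shape != self.rates.shape or self.conc.ndim != 1:
            raise ValueError("conc and rates must be 1-D arrays of equal length")
        if np.any(self.conc <= 0):
            raise ValueError("substrate concentrations must be positive")

    def __len__(self) -> int:
        return len(self.conc)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str | None = None,
                       substrate: str | None = None) -> "KineticDataset":
        """Build from a tidy frame with columns
        (variant, substrate, concentration_uM, rate_per_s)."""
        sub = df
        if variant is not None:
            sub = sub[sub["variant"] == variant]
        if substrate is not None:
            sub = sub[sub["substrate"] == substrate]
        if sub.empty:
            raise ValueError(f"no rows for variant={variant!r}, substrate={substrate!r}")
        return cls(conc=sub["concentration_uM"].to_numpy(),
                   rates=sub["rate_per_s"].to_numpy(),
                   variant=variant or str(sub["variant"].iloc[0]),
                   substrate=substrate or str(sub["substrate"].iloc[0]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant": self.variant, "substrate": self.substrate,
            "concentration_uM": self.conc, "rate_per_s": self.rates,
        })


@dataclass
class KineticsResults:
    """Estimates, standard errors and diagnostics of a kinetic fit.

    Standard errors come from the linearized covariance at the optimum (the
    usual Gauss–Newton approximation); with replicate batches they would
    differ from between-batch standard deviations.
    """

    model: object
    params: dict[str, float]
    bse: dict[str, float]
    cov: np.ndarray
    resid: np.ndarray
    n_obs: int
    kis_unreliable: bool = False
    message: str = ""

    @property
    def kcat(self) -> float:
        return self.params["kcat"]

    @property
    def Km(self) -> float:
        return self.params["Km"]

    @property
    def K_IS(self) -> float:
        return self.params.get("K_IS", math.inf)

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km in mM⁻¹ s⁻¹."""
        return catalytic_efficiency(self.kcat, self.Km)

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid ** 2))

    def predict(self, S) -> np.ndarray:
        return si_velocity(self.kcat, self.Km, self.K_IS, S)

    def summary(self) -> str:
        ds = self.model.data
        lines = [
            f"Kinetic fit: {type(self.model).__name__}"
            + (f"  [{ds.variant} / {ds.substrate}]" if ds.variant or ds.substrate else ""),
            f"  n = {self.n_obs} points, SSR = {self.ssr:.4g}",
        ]
        units = {"kcat": "s^-1", "Km": "uM", "K_IS": "uM"}
        for name, value in self.params.items():
            lines.append(f"  {name:>5} = {value:#.4g} +/- {self.bse[name]:#.3g} {units[name]}")
        lines.append(f"  kcat/Km = {self.efficiency:#.4g} mM^-1 s^-1")
        if self.kis_unreliable:
            lines.append("  warning: K_IS not reliably identified "
                         "(no data beyond the velocity maximum)")
        return "\n".join(lines)


class _KineticModelBase:
    """Shared nonlinear least-squares machinery.

    Positivity of all parameters is enforced by fitting in log space with a
    damped least-squares solver; convergence when the relative parameter
    change falls below 1e-8, at most 500 iterations.
    """

    param_names: tuple[str, ...] = ()
    min_points: int = 4

    def __init__(self, data: KineticDataset):
        if len(data) < self.min_points:
            raise ValueError(
                f"{type(self).__name__} needs >= {self.min_points} points, "
                f"got {len(data)}"
            )
        if np.ptp(data.rates) == 0:
            raise ValueError("degenerate data: all rates identical")
        self.data = data

    # subclasses define the rate law on natural-scale parameters
    def _velocity(self, params: np.ndarray, S: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _initial_guess(self) -> np.ndarray:
        raise NotImplementedError

    def fit(self) -> KineticsResults:
        S, y = self.data.conc, self.data.rates
        theta0 = np.log(self._initial_guess())

        def resid(theta: np.ndarray) -> np.ndarray:
            return self._velocity(np.exp(theta), S) - y

        sol = least_squares(resid, theta0, method="lm", xtol=1e-8,
                            ftol=1e-15, gtol=1e-15, max_nfev=500 * len(theta0))
        if not sol.success:
            raise FitError(f"kinetic fit did not converge: {sol.message}")
        params = np.exp(sol.x)
        cov_log = _linearized_covariance(sol.jac, sol.fun, len(theta0))
        # delta method: Var(p) = p^2 Var(log p)
        se = params * np.sqrt(np.diag(cov_log))
        result = KineticsResults(
            model=self,
            params=dict(zip(self.param_names, map(float, params))),
            bse=dict(zip(self.param_names, map(float, se))),
            cov=cov_log * np.outer(params, params),
            resid=sol.fun,
            n_obs=len(y),
            message=sol.message,
        )
        self._post_fit(result)
        return result

    def _post_fit(self, result: KineticsResults) -> None:
        pass


def _linearized_covariance(jac: np.ndarray, resid: np.ndarray, n_params: int
                           ) -> np.ndarray:
    dof = max(len(resid) - n_params, 1)
    s2 = float(np.sum(resid ** 2)) / dof
    jtj = jac.T @ jac
    try:
        return s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return s2 * np.linalg.pinv(jtj)


class MichaelisMentenModel(_KineticModelBase):
    """Hyperbolic saturation kinetics, parameters (kcat, Km)."""

    param_names = ("kcat", "Km")
    min_points = 4

    def _velocity(self, params: np.ndarray, S: np.ndarray) -> np.ndarray:
        kcat, Km = params
        return kcat * S / (Km + S)

    def _initial_guess(self) -> np.ndarray:
        S, y = self.data.conc, self.data.rates
        kcat0 = float(np.max(y))
        Km0 = _half_saturation(S, y, kcat0)
        return np.array([kcat0, Km0])


class SubstrateInhibitionModel(_KineticModelBase):
    """Total substrate inhibition, parameters (kcat, Km, K_IS).

    The fitted K_IS is flagged unreliable when the assayed range does not
    reach the velocity maximum at sqrt(Km·K_IS) — inhibition then barely
    expresses itself in the data and the constant is not identified.
    """

    param_names = ("kcat", "Km", "K_IS")
    min_points = 5

    def _velocity(self, params: np.ndarray, S: np.ndarray) -> np.ndarray:
        kcat, Km, K_IS = params
        return kcat * S / (Km + S * (1.0 + S / K_IS))

    def _initial_guess(self) -> np.ndarray:
        S, y = self.data.conc, self.data.rates
        kcat0 = float(np.max(y))
        Km0 = _half_saturation(S, y, kcat0)
        return np.array([kcat0, Km0, 10.0 * float(np.max(S))])

    def _post_fit(self, result: KineticsResults) -> None:
        s_opt = math.sqrt(result.Km * result.K_IS)
        result.kis_unreliable = float(np.max(self.data.conc)) < s_opt


def _half_saturation(S: np.ndarray, y: np.ndarray, ymax: float) -> float:
    """Interpolated substrate concentration where the rate crosses ymax/2."""
    order = np.argsort(S)
    S, y = S[order], y[order]
    half = ymax / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return float(S[0])
    i = above[0]
    f = (half - y[i - 1]) / (y[i] - y[i - 1])
    return float(S[i - 1] + f * (S[i] - S[i - 1]))


def fit_mm(dataset: KineticDataset) -> KineticsResults:
    """Fit the Michaelis–Menten model to a saturation curve."""
    return MichaelisMentenModel(dataset).fit()


def fit_si(dataset: KineticDataset, total_inhibition: bool = True
           ) -> KineticsResults:
    """Fit the total-substrate-inhibition rate law to a saturation curve."""
    if not total_inhibition:
        raise NotImplementedError("only total substrate inhibition is modelled")
    return SubstrateInhibitionModel(dataset).fit()


@dataclass
class ActivityGrouping:
    """Two-group split of variants by catalytic efficiency with BAL."""

    efficiencies: dict[str, float]
    threshold: float
    groups: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.groups = {
            variant: ("BADH-active" if eff >= self.threshold else "AMADH-only")
            for variant, eff in self.efficiencies.items()
        }

    @property
    def badh_active(self) -> set[str]:
        return {v for v, g in self.groups.items() if g == "BADH-active"}

    @property
    def amadh_only(self) -> set[str]:
        return {v for v, g in self.groups.items() if g == "AMADH-only"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variant": v, "efficiency_mM_s": e, "group": self.groups[v]}
             for v, e in self.efficiencies.items()],
            columns=["variant", "efficiency_mM_s", "group"],
        )


def classify_badh_groups(efficiencies: dict[str, float],
                         threshold: float = BADH_EFFICIENCY_THRESHOLD
                         ) -> ActivityGrouping:
    """Split variants into BADH-active vs AMADH-only by their catalytic
    efficiency with betaine aldehyde (≥ threshold → BADH-active)."""
    if not efficiencies:
        raise ValueError("at least one variant required")
    return ActivityGrouping(efficiencies=dict(efficiencies), threshold=threshold)
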