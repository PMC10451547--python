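"""Nernstian mapping between chemistry and measured potential.

Two cells are modelled:

* the **generation cell** (37 degC), where the platinum electrode
  potential tracks the logarithm of the peroxyl-radical concentration,
  E(t) = e_ref + (RT/F) ln([RO2*]/c_ref); and
* the **mediator cell** (25 degC), a K3[Fe(CN)6]/K4[Fe(CN)6] couple
  whose potential shift on sample addition encodes the residual
  antioxidant concentration: the antioxidant reduces ferri- to
  ferrocyanide, moving the Ox/Red ratio from C_Ox/C_Red to alpha, and

      C_AO = n * (C_Ox - alpha C_Red) / (1 + alpha),
      alpha = (C_Ox/C_Red) * 10^((E2 - E1) F / (2.303 R T)),

  with n >= 1 the dilution of the sample into the cell.

``exp_delta_e`` builds the normalized Exp(dE) series used by the
area-based capacity statistics: exp((E(t) - E_baseline)/E_s), equal to
1 at baseline and < 1 while radicals are suppressed.  With
E_s = RT/F the series is exactly a radical-concentration ratio; the
default E_s = 1 V matches the magnitude convention of area tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import FARADAY, R_GAS, T_GENERATION, T_MEDIATOR, nernst_slope
from .exceptions import DomainError, InputError, MediatorCapacityError
from .kinetics import Trajectory
from .trace import PotentialTrace

__all__ = [
    "ElectrodeModel",
    "FerroFerriCell",
    "ResidualConcentrationResult",
    "NormalizedSeries",
    "potential_from_radicals",
    "exp_delta_e",
    "alpha_from_potentials",
    "residual_concentration",
    "expected_potential_shift",
]

#: floor applied inside the log to keep traces finite at t = 0
RADICAL_FLOOR = 1e-15  # M


@dataclass(frozen=True)
class ElectrodeModel:
    """Log-radical monitoring electrode.

    ``nernst_slope`` is in volts per natural-log unit (default RT/F at
    37 degC); ``exp_scale`` is the E_s used inside Exp(dE).
    """

    e_ref: float = 0.2
    nernst_slope: float = nernst_slope(T_GENERATION)
    c_ref: float = 1e-6
    exp_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.nernst_slope <= 0 or self.c_ref <= 0 or self.exp_scale <= 0:
            raise InputError("nernst_slope, c_ref, exp_scale must be > 0")


@dataclass(frozen=True)
class FerroFerriCell:
    """Ferri/ferrocyanide mediator cell (defaults per the 1 mM / 0.01 mM assay)."""

    c_ox: float = 1e-3
    c_red: float = 1e-5
    dilution_n: float = 1.0
    temperature: float = T_MEDIATOR

    def __post_init__(self) -> None:
        if self.c_ox <= 0 or self.c_red <= 0:
            raise InputError("c_ox and c_red must be > 0")
        if self.dilution_n < 1:
            raise InputError("dilution_n must be >= 1")

    @property
    def slope_decade(self) -> float:
        """2.303 RT/F, V per decade."""
        return nernst_slope(self.temperature, natural=False)


@dataclass(frozen=True)
class ResidualConcentrationResult:
    alpha: float
    c_ao: float  # M-eq (referred to the undiluted sample)
    e1: float
    e2: float
    negative_flagged: bool = False


@dataclass
class NormalizedSeries:
    """Dimensionless Exp(dE) series on the trace's native grid."""

    t: np.ndarray
    values: np.ndarray
    t_add: float


def potential_from_radicals(
    traj: Trajectory, electrode: ElectrodeModel | None = None
) -> PotentialTrace:
    """Render E(t) from a simulated trajectory via the Nernstian log law."""
    electrode = electrode or ElectrodeModel()
    if traj.t.size == 0:
        raise InputError("empty trajectory")
    x = np.maximum(traj.radical, RADICAL_FLOOR)
    e = electrode.e_ref + electrode.nernst_slope * np.log(x / electrode.c_ref)
    return PotentialTrace(
        t=traj.t.copy(), e=e, t_add=traj.t_add, meta={"electrode": electrode}
    )


def exp_delta_e(
    trace: PotentialTrace,
    t_add: float | None = None,
    electrode: ElectrodeModel | None = None,
    baseline_window: float = 30.0,
) -> NormalizedSeries:
    """exp(dE(t)/E_s) with dE relative to the pre-addition baseline."""
    electrode = electrode or ElectrodeModel()
    t_add = trace.t_add if t_add is None else float(t_add)
    if not (trace.t[0] <= t_add < trace.t[-1]):
        raise DomainError(f"t_add={t_add} s outside the trace")
    mask = (trace.t >= t_add - baseline_window) & (trace.t <= t_add)
    if not mask.any():
        raise DomainError("no pre-addition baseline window before t_add")
    baseline = float(trace.e[mask].mean())
    values = np.exp((trace.e - baseline) / electrode.exp_scale)
    return NormalizedSeries(t=trace.t.copy(), values=values, t_add=t_add)


def alpha_from_potentials(e1: float, e2: float, cell: FerroFerriCell) -> float:
    """Post-addition Ox/Red ratio from the two cell potentials."""
    return (cell.c_ox / cell.c_red) * 10.0 ** ((e2 - e1) / cell.slope_decade)


def residual_concentration(
    e1: float, e2: float, cell: FerroFerriCell
) -> ResidualConcentrationResult:
    """Antioxidant concentration (M-eq, undiluted sample) from the potential drop.

    ``e2 > e1`` implies an apparent negative concentration; the value is
    clamped to 0 and flagged.
    """
    alpha = alpha_from_potentials(e1, e2, cell)
    c_cell = (cell.c_ox - alpha * cell.c_red) / (1.0 + alpha)
    c_ao = cell.dilution_n * c_cell
    flagged = False
    if c_ao < 0:
        warnings.warn(
            f"E2={e2:.4f} V above E1={e1:.4f} V: apparent negative concentration "
            f"{c_ao:.3e} M clamped to 0",
            stacklevel=2,
        )
        c_ao, flagged = 0.0, True
    return ResidualConcentrationResult(
        alpha=alpha, c_ao=c_ao, e1=e1, e2=e2, negative_flagged=flagged
    )


def concentration_noise_sd(c_ao, cell: FerroFerriCell, sigma_e: float) -> np.ndarray:
    """Delta-method SD of the recovered concentration under potential noise.

    Both cell readings (E1, E2) carry independent Gaussian noise of SD
    ``sigma_e`` (V), so the potential difference has SD sqrt(2)*sigma_e.
    Propagation through alpha and the concentration formula gives

        sd(C_AO) = n (C_Ox + C_Red) alpha / (1 + alpha)^2 * (F/RT) * sqrt(2) sigma_e

    with alpha evaluated at the true concentration.
    """
    c_ao = np.asarray(c_ao, dtype=float)
    x = np.clip(c_ao, 0.0, None) / cell.dilution_n
    alpha = (cell.c_ox - x) / (cell.c_red + x)
    k = FARADAY / (R_GAS * cell.temperature)
    out = (
        cell.dilution_n
        * (cell.c_ox + cell.c_red)
        * alpha
        / (1.0 + alpha) ** 2
        * k
        * math.sqrt(2.0)
        * sigma_e
    )
    return float(out) if out.ndim == 0 else out


def expected_potential_shift(c_added: float, cell: FerroFerriCell) -> float:
    """Forward model: potential shift dE = E2 - E1 for a known spike.

    ``c_added`` is the antioxidant concentration in the undiluted
    sample (M-eq); in the cell it arrives diluted n-fold and converts
    ferri- to ferrocyanide stoichiometrically:
    Ox -> Ox - x, Red -> Red + x with x = c_added / n.
    """
    if c_added < 0:
        raise DomainError("c_added must be >= 0")
    x = c_added / cell.dilution_n
    if x >= cell.c_ox:
        raise MediatorCapacityError(
            f"spike {c_added:.3e} M-eq (cell {x:.3e} M) exhausts the "
            f"{cell.c_ox:.3e} M ferricyanide mediator"
        )
    alpha_prime = (cell.c_ox - x) / (cell.c_red + x)
    return cell.slope_decade * math.log10(alpha_prime / (cell.c_ox / cell.c_red))
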