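"""Forward kinetics of peroxyl-radical generation and inhibition.

The chemistry is the classical azo-initiator scheme: a thermally
unstable initiator I (AAPH) decomposes first-order into a pair of
radicals which, after O2 addition, act as peroxyl radicals RO2*:

    I   -> 2 RO2*               rate  Wi(t) = 2 ki [I]
    RO2* + RO2*  -> products    lumped constant 2k2
    RO2* + InH_j -> RO2- + ...  constant kinh_j, stoichiometry q_j

``simulate`` integrates the full stiff ODE system or, optionally, a
quasi-steady-state (QSSA) reduction in which the radical concentration
is replaced at every step by the algebraic balance of generation,
recombination and scavenging.  Running integrals of generated,
recombined and scavenged radicals are carried as extra states so that
mass balance can be checked to solver accuracy.

All quantities are SI: seconds, molar, M s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, InputError, IntegrationError, QSSAValidityError

__all__ = [
    "RateParameters",
    "AntioxidantSpec",
    "Trajectory",
    "initiation_rate",
    "steady_state_radical",
    "simulate",
]


@dataclass(frozen=True)
class RateParameters:
    """Kinetic constants and initiator load.

    Parameters
    ----------
    ki : float
        First-order initiator decomposition constant, s^-1.  The default
        1e-6 s^-1 is the standard magnitude for AAPH at 37 degC and, at
        0.1 M initiator, yields Wi = 2e-7 M s^-1.
    two_k2 : float
        Lumped radical recombination/disproportionation constant 2*k2,
        M^-1 s^-1.
    initiator_c0 : float
        Initial initiator concentration, M.
    temperature : float
        Reaction temperature, K (bookkeeping; no Arrhenius scaling).
    efficiency : float
        Radical cage-escape efficiency multiplying the generation rate.
    """

    ki: float = 1e-6
    two_k2: float = 5.0e4
    initiator_c0: float = 0.1
    temperature: float = 310.15
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ki > 0 and self.two_k2 > 0 and self.initiator_c0 >= 0):
            raise InputError("ki, two_k2 must be > 0 and initiator_c0 >= 0")
        if not (273.0 <= self.temperature <= 373.0):
            raise InputError(
                f"temperature {self.temperature} K outside [273, 373] K"
            )
        if not (0 < self.efficiency <= 1):
            raise InputError("efficiency must be in (0, 1]")

    @property
    def wi0(self) -> float:
        """Initiation rate at t = 0, M s^-1."""
        return self.efficiency * 2.0 * self.ki * self.initiator_c0


@dataclass(frozen=True)
class AntioxidantSpec:
    """One inhibitor species.

    ``q`` is the stoichiometric factor: radicals scavenged per inhibitor
    molecule (default 2, classical two-radical scavenging).  Species
    whose mediator-cell chemistry is incompatible with the residual
    concentration assay (e.g. thiadiazines) carry
    ``mediator_compatible=False``.
    """

    name: str
    c0: float
    kinh: float
    q: float = 2.0
    mediator_compatible: bool = True

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise InputError(f"{self.name}: c0 must be >= 0")
        if self.kinh <= 0:
            raise InputError(f"{self.name}: kinh must be > 0")
        if self.q <= 0:
            raise InputError(f"{self.name}: q must be > 0")


def initiation_rate(params: RateParameters, t):
    """Radical initiation rate Wi(t) = 2 ki [I]0 exp(-ki t), M s^-1.

    The commonly used constant-Wi approximation is the t = 0 value;
    over a <= 2 h run at ki ~ 1e-6 s^-1 the initiator depletes by < 1%.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("initiation_rate: t must be >= 0")
    out = params.wi0 * np.exp(-params.ki * t)
    return float(out) if out.ndim == 0 else out


def steady_state_radical(wi: float, two_k2: float, inhibitor_load: float = 0.0) -> float:
    """Quasi-steady radical concentration, M.

    Unique non-negative root of ``two_k2 x^2 + L x - wi = 0`` where
    ``L`` is the total pseudo-first-order scavenging load (s^-1), i.e.
    the sum of kinh_j * c_j (times q_j if stoichiometric radical
    consumption is modelled).  Reduces to sqrt(wi/two_k2) at L = 0 and
    to wi/L when scavenging dominates recombination.
    """
    if wi < 0 or two_k2 <= 0 or inhibitor_load < 0:
        raise DomainError("steady_state_radical: require wi >= 0, two_k2 > 0, L >= 0")
    if wi == 0.0:
        return 0.0
    L = inhibitor_load
    # root written in cancellation-free form (stable for L^2 >> 4 two_k2 wi)
    return 2.0 * wi / (L + math.sqrt(L * L + 4.0 * two_k2 * wi))


@dataclass
class Trajectory:
    """Concentration time courses from the simulator.

    ``cum_generated``, ``cum_recombined`` and ``cum_scavenged`` are
    running integrals (M of radicals) carried by the solver, so
    ``cum_generated - cum_recombined - cum_scavenged - radical`` is a
    direct mass-balance residual.
    """

    t: np.ndarray
    initiator: np.ndarray
    radical: np.ndarray
    inhibitors: dict[str, np.ndarray]
    cum_generated: np.ndarray
    cum_recombined: np.ndarray
    cum_scavenged: np.ndarray
    t_add: float = 0.0
    meta: dict = field(default_factory=dict)

    def mass_balance_residual(self) -> np.ndarray:
        return self.cum_generated - self.cum_recombined - self.cum_scavenged - self.radical

    def max_mass_balance_error(self) -> float:
        """max |residual| / max(cum_generated), dimensionless."""
        denom = max(float(self.cum_generated.max()), 1e-300)
        return float(np.abs(self.mass_balance_residual()).max() / denom)

    def inhibitor_at(self, name: str, t) -> np.ndarray | float:
        out = np.interp(np.asarray(t, dtype=float), self.t, self.inhibitors[name])
        return float(out) if out.ndim == 0 else out

    def to_dataframe(self):
        import pandas as pd

        data = {"t_s": self.t, "I_M": self.initiator, "RO2_M": self.radical}
        for name, c in self.inhibitors.items():
            data[name] = c
        return pd.DataFrame(data)


def _validate_grid(t_grid: np.ndarray) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise InputError("t_grid must be 1-D with at least two points")
    if t_grid[0] != 0.0:
        raise InputError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise InputError("t_grid must be strictly increasing")
    return t_grid


def simulate(
    params: RateParameters,
    antioxidants: list[AntioxidantSpec],
    t_grid,
    mode: str = "full",
    t_add: float = 0.0,
    stoich_in_radical_ode: bool = True,
    ferrocyanide_side_reaction: bool = False,
    side_reaction_k: float = 1e3,
    ferrocyanide_c: float = 1e-5,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the initiation/recombination/inhibition scheme.

    Parameters
    ----------
    t_grid : array
        Strictly increasing output grid starting at 0, s.
    mode : {"full", "qssa"}
        ``full`` integrates the stiff radical ODE; ``qssa`` replaces the
        radical by its algebraic steady state at each step (valid only
        when the radical relaxation time is much shorter than the grid
        spacing; checked, see :class:`QSSAValidityError`).
    t_add : float
        Time at which the antioxidants are introduced; before it they
        are present in the bookkeeping but chemically inert.
    stoich_in_radical_ode : bool
        If True (default) each inhibition event removes q_j radicals
        from the pool (fast secondary scavenging); if False only the
        primary radical is consumed and q enters capacity accounting
        only.
    ferrocyanide_side_reaction : bool
        Enable the RO2* + ferrocyanide side reaction (default off — at
        assay concentrations its contribution is negligible); when on,
        the pseudo-first-order loss ``side_reaction_k * ferrocyanide_c``
        is added to the radical sink and booked under scavenged.
    """
    t_grid = _validate_grid(t_grid)
    if mode not in ("full", "qssa"):
        raise InputError(f"unknown mode {mode!r}")
    if not 0.0 <= t_add <= t_grid[-1]:
        raise InputError("t_add must lie within the time grid")
    names = [a.name for a in antioxidants]
    if len(set(names)) != len(names):
        raise InputError("antioxidant names must be unique")

    kinh = np.array([a.kinh for a in antioxidants])
    q = np.array([a.q for a in antioxidants])
    c0 = np.array([a.c0 for a in antioxidants])
    s = q if stoich_in_radical_ode else np.ones_like(q)
    k_side = side_reaction_k * ferrocyanide_c if ferrocyanide_side_reaction else 0.0
    m = len(antioxidants)
    wi0, ki, two_k2 = params.wi0, params.ki, params.two_k2

    if mode == "qssa":
        return _simulate_qssa(
            params, names, kinh, q, c0, s, k_side, t_grid, t_add, rtol, atol
        )

    # state: [I, x, c_1..c_m, cumG, cumR, cumS]
    def rhs(t, y, active):
        I, x = y[0], max(y[1], 0.0)
        c = np.maximum(y[2 : 2 + m], 0.0)
        gen = params.efficiency * 2.0 * ki * I
        rec = two_k2 * x * x
        scav_j = active * kinh * x * c
        scav = float(np.dot(s, scav_j)) + k_side * x
        dy = np.empty_like(y)
        dy[0] = -ki * I
        dy[1] = gen - rec - scav
        dy[2 : 2 + m] = -scav_j
        dy[2 + m] = gen
        dy[3 + m] = rec
        dy[4 + m] = scav
        return dy

    y0 = np.concatenate(([params.initiator_c0, 0.0], c0, [0.0, 0.0, 0.0]))
    segments = []
    if t_add > 0.0:
        segments.append((0.0, t_add, 0.0))
    segments.append((t_add, t_grid[-1], 1.0))

    ys = []
    ts = []
    y_start = y0
    for (ta, tb, active) in segments:
        if tb <= ta:
            continue
        mask = (t_grid >= ta) & (t_grid <= tb)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (ta, tb),
            y_start,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            args=(active,),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"stiff solver failed on [{ta}, {tb}] s: {sol.message}"
            )
        if t_eval.size:
            # avoid duplicating the segment-boundary point
            start = 1 if (ts and t_eval[0] == ts[-1][-1]) else 0
            ts.append(t_eval[start:])
            ys.append(sol.y[:, start:])
        y_start = sol.y[:, -1] if sol.t[-1] == tb else _end_state(rhs, ta, tb, y_start, active, rtol, atol)

    t_out = np.concatenate(ts)
    y_out = np.concatenate(ys, axis=1)
    if t_out.size != t_grid.size:  # pragma: no cover - defensive
        raise IntegrationError("output grid mismatch after piecewise integration")

    inhibs = {names[j]: np.maximum(y_out[2 + j], 0.0) for j in range(m)}
    return Trajectory(
        t=t_out,
        initiator=y_out[0],
        radical=np.maximum(y_out[1], 0.0),
        inhibitors=inhibs,
        cum_generated=y_out[2 + m],
        cum_recombined=y_out[3 + m],
        cum_scavenged=y_out[4 + m],
        t_add=t_add,
        meta={"mode": "full", "wi0": wi0},
    )


def _end_state(rhs, ta, tb, y_start, active, rtol, atol):  # pragma: no cover
    sol = solve_ivp(rhs, (ta, tb), y_start, method="LSODA", args=(active,), rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"stiff solver failed on [{ta}, {tb}] s: {sol.message}")
    return sol.y[:, -1]


def _simulate_qssa(params, names, kinh, q, c0, s, k_side, t_grid, t_add, rtol, atol):
    """QSSA reduction: radical replaced by its algebraic steady state."""
    m = len(names)
    ki, two_k2 = params.ki, params.two_k2

    def x_ss(t, c, active):
        wi = params.wi0 * math.exp(-ki * t)
        load = active * float(np.dot(s, kinh * np.maximum(c, 0.0))) + k_side
        return steady_state_radical(wi, two_k2, load)

    # validity: radical relaxation must be fast on the post-addition grid
    post = t_grid[t_grid >= t_add]
    dt_min = float(np.diff(post).min()) if post.size >= 2 else float(np.diff(t_grid).min())
    x0 = x_ss(t_add, c0, 1.0)
    relax_rate = 2.0 * two_k2 * x0 + float(np.dot(s, kinh * c0)) + k_side
    if relax_rate * dt_min < 10.0:
        raise QSSAValidityError(
            f"QSSA invalid: radical relaxation rate {relax_rate:.3g} s^-1 times grid "
            f"spacing {dt_min:.3g} s is {relax_rate * dt_min:.3g} < 10; use mode='full' "
            "or a coarser grid"
        )

    # state: [I, c_1..c_m, cumG, cumR, cumS]
    def rhs(t, y, active):
        I = y[0]
        c = np.maximum(y[1 : 1 + m], 0.0)
        x = x_ss(t, c, active)
        gen = params.efficiency * 2.0 * ki * I
        rec = two_k2 * x * x
        scav_j = active * kinh * x * c
        dy = np.empty_like(y)
        dy[0] = -ki * I
        dy[1 : 1 + m] = -scav_j
        dy[1 + m] = gen
        dy[2 + m] = rec
        dy[3 + m] = float(np.dot(s, scav_j)) + k_side * x
        return dy

    y0 = np.concatenate(([params.initiator_c0], c0, [0.0, 0.0, 0.0]))
    ys, ts = [], []
    y_start = y0
    segments = ([(0.0, t_add, 0.0)] if t_add > 0 else []) + [(t_add, t_grid[-1], 1.0)]
    for (ta, tb, active) in segments:
        if tb <= ta:
            continue
        mask = (t_grid >= ta) & (t_grid <= tb)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs, (ta, tb), y_start, method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            args=(active,), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"QSSA solver failed on [{ta}, {tb}] s: {sol.message}")
        if t_eval.size:
            start = 1 if (ts and t_eval[0] == ts[-1][-1]) else 0
            ts.append(t_eval[start:])
            ys.append(sol.y[:, start:])
        if sol.t[-1] == tb:
            y_start = sol.y[:, -1]
        else:  # t_add between grid points: re-integrate to the boundary
            sol_end = solve_ivp(
                rhs, (ta, tb), y_start, method="LSODA", args=(active,),
                rtol=rtol, atol=atol,
            )
            if not sol_end.success:
                raise IntegrationError(
                    f"QSSA solver failed on [{ta}, {tb}] s: {sol_end.message}"
                )
            y_start = sol_end.y[:, -1]

    t_out = np.concatenate(ts)
    y_out = np.concatenate(ys, axis=1)
    c_out = np.maximum(y_out[1 : 1 + m], 0.0)
    radical = np.array(
        [
            x_ss(t_out[i], c_out[:, i], 1.0 if t_out[i] >= t_add else 0.0)
            for i in range(t_out.size)
        ]
    )
    inhibs = {names[j]: c_out[j] for j in range(m)}
    return Trajectory(
        t=t_out,
        initiator=y_out[0],
        radical=radical,
        inhibitors=inhibs,
        cum_generated=y_out[1 + m],
        cum_recombined=y_out[2 + m],
        cum_scavenged=y_out[3 + m],
        t_add=t_add,
        meta={"mode": "qssa", "wi0": params.wi0},
    )
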