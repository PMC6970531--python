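"""Steady-state transcription flux through a multi-step initiation scheme.

The promoter cycles through a linear pathway

    R+P ⇄ RP1 ⇄ RP2 ⇄ RPo → RP_ITC

driven by a free-energy landscape: well energies for the four states and
transition-state energies for the three reversible steps plus the final
irreversible promoter-escape step.  Energies are in units of thermal energy
kBT (dimensionless); rates follow the transition-state form
k = A·exp(−(G‡ − G_well)) with a single prefactor A, so absolute times are
not interpretable — only ratios and fold changes are.  Formation of RP_ITC
regenerates free promoter, the minimal closure admitting a steady state; the
steady-state flux J = k_cat · occupancy(RPo) is the transcription output.

Perturbation operators express how a secondary-channel regulator (TraR) or
the deletion of σ70 region 1.1 reshape the landscape; neither touches the
initial binding step.  The same TraR perturbation inhibits a promoter with
fast RPo formation and an unstable RPo while activating one limited by a
high RP2→RPo barrier — differential regulation from a shared mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, LandscapeError

__all__ = [
    "EnergyLandscape",
    "RateScheme",
    "PerturbationSpec",
    "FluxResult",
    "rates_from_landscape",
    "steady_state_flux",
    "ode_steady_state",
    "apply_perturbation",
    "sigma11_deletion_scenario",
    "traR_scenario",
    "boltzmann_occupancies",
    "DEFAULT_STATES",
]

DEFAULT_STATES = ("R+P", "RP1", "RP2", "RPo")


@dataclass(frozen=True)
class EnergyLandscape:
    """Free-energy diagram for the initiation pathway (kBT units)."""

    state_G: tuple[float, ...]
    barrier_G: tuple[float, ...]
    final_barrier_G: float
    state_names: tuple[str, ...] = DEFAULT_STATES
    label: str = ""

    def __post_init__(self) -> None:
        sg = tuple(float(g) for g in self.state_G)
        bg = tuple(float(g) for g in self.barrier_G)
        if len(bg) != len(sg) - 1:
            raise LandscapeError(
                f"{len(sg)} states need {len(sg) - 1} barriers, got {len(bg)}"
            )
        if len(self.state_names) != len(sg):
            raise LandscapeError("state_names length mismatch")
        for i, b in enumerate(bg):
            if b < max(sg[i], sg[i + 1]) - 1e-12:
                raise LandscapeError(
                    f"barrier {self.state_names[i]}⇄{self.state_names[i + 1]} "
                    f"({b:g} kBT) lies below a flanking well"
                )
        if self.final_barrier_G < sg[-1] - 1e-12:
            raise LandscapeError("final barrier lies below the RPo well")
        object.__setattr__(self, "state_G", sg)
        object.__setattr__(self, "barrier_G", bg)
        object.__setattr__(self, "final_barrier_G", float(self.final_barrier_G))

    @property
    def n_states(self) -> int:
        return len(self.state_G)


@dataclass(frozen=True)
class RateScheme:
    """Rate constants derived from a landscape (units of the prefactor A)."""

    k_fwd: tuple[float, ...]
    k_rev: tuple[float, ...]
    k_cat: float
    rnap_activity: float = 1.0
    state_names: tuple[str, ...] = DEFAULT_STATES

    @property
    def n_states(self) -> int:
        return len(self.k_fwd) + 1

    @property
    def K_B(self) -> float:
        """Equilibrium constant of the initial binding step."""
        return self.k_fwd[0] / self.k_rev[0]


@dataclass(frozen=True)
class PerturbationSpec:
    """Energy deltas applied to barriers and/or wells (negative = lowering)."""

    delta_barrier: Mapping[int, float] = field(default_factory=dict)
    delta_state: Mapping[int, float] = field(default_factory=dict)
    delta_final_barrier: float = 0.0
    label: str = ""


@dataclass(frozen=True)
class FluxResult:
    """Steady-state occupancies and transcription flux."""

    occupancies: np.ndarray  # per state, sums to 1
    flux_J: float  # k_cat × occupancy(RPo), units A·P_tot
    state_names: tuple[str, ...] = DEFAULT_STATES
    fold_change_vs_reference: float | None = None


# ---------------------------------------------------------------------------


def rates_from_landscape(
    landscape: EnergyLandscape, prefactor: float = 1.0, rnap_activity: float = 1.0
) -> RateScheme:
    """Transition-state mapping from energies to rate constants.

    k_fwd[i] = A exp(−(G‡_i − G_i)); k_rev[i] = A exp(−(G‡_i − G_{i+1}));
    k_cat = A exp(−(G‡_final − G_RPo)).  The first forward rate is further
    multiplied by ``rnap_activity`` (pseudo-first-order binding), so
    detailed balance k_fwd/k_rev = exp(G_i − G_{i+1}) holds per transition
    for the unscaled rates.
    """
    sg, bg = landscape.state_G, landscape.barrier_G
    k_fwd = [prefactor * np.exp(-(b - sg[i])) for i, b in enumerate(bg)]
    k_rev = [prefactor * np.exp(-(b - sg[i + 1])) for i, b in enumerate(bg)]
    k_fwd[0] *= rnap_activity
    k_cat = prefactor * np.exp(-(landscape.final_barrier_G - sg[-1]))
    return RateScheme(
        tuple(k_fwd), tuple(k_rev), float(k_cat), rnap_activity,
        landscape.state_names,
    )


def _rate_matrix(scheme: RateScheme) -> np.ndarray:
    """Master-equation generator M with dp/dt = M p (columns sum to 0)."""
    n = scheme.n_states
    M = np.zeros((n, n))
    for i, (kf, kr) in enumerate(zip(scheme.k_fwd, scheme.k_rev)):
        M[i, i] -= kf
        M[i + 1, i] += kf
        M[i + 1, i + 1] -= kr
        M[i, i + 1] += kr
    # irreversible escape from the last state regenerates free promoter
    M[n - 1, n - 1] -= scheme.k_cat
    M[0, n - 1] += scheme.k_cat
    return M


def steady_state_flux(scheme: RateScheme) -> FluxResult:
    """Exact steady state of the promoter cycle by linear solve.

    Solves M p = 0 with Σp = 1 (one balance row replaced by the
    normalization), then J = k_cat · p(RPo).
    """
    M = _rate_matrix(scheme)
    if not np.any(M):
        raise LandscapeError("degenerate scheme: all rates are zero")
    n = scheme.n_states
    A = M.copy()
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    p = np.linalg.solve(A, b)
    if (p < -1e-10).any():
        raise LandscapeError("steady-state solve produced negative occupancy")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return FluxResult(p, float(scheme.k_cat * p[-1]), scheme.state_names)


def ode_steady_state(
    scheme: RateScheme,
    t_end: float = 1e12,
    init: Sequence[float] | None = None,
    residual_tol: float = 1e-12,
) -> FluxResult:
    """Independent steady-state oracle by stiff integration of dp/dt = M p.

    Integrates from ``init`` (default: all mass in R+P), doubling the time
    horizon until max |dp/dt| < ``residual_tol`` or ``t_end`` is exceeded.
    """
    M = _rate_matrix(scheme)
    n = scheme.n_states
    p = np.zeros(n) if init is None else np.asarray(init, dtype=float)
    if init is None:
        p[0] = 1.0
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancies must sum to 1")
    rates = [r for r in (*scheme.k_fwd, *scheme.k_rev, scheme.k_cat) if r > 0]
    t = 10.0 / min(rates)
    while True:
        sol = solve_ivp(
            lambda _, y: M @ y, (0.0, t), p, method="BDF",
            rtol=1e-11, atol=1e-14, jac=lambda _, __: M,
        )
        p = sol.y[:, -1]
        resid = float(np.abs(M @ p).max())
        if resid < residual_tol:
            break
        if t >= t_end:
            raise ConvergenceError(
                f"no steady state within t={t:g} (residual {resid:g})"
            )
        t *= 4.0
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return FluxResult(p, float(scheme.k_cat * p[-1]), scheme.state_names)


def boltzmann_occupancies(landscape: EnergyLandscape) -> np.ndarray:
    """Equilibrium occupancies exp(−G_i)/Z — the k_cat → 0 limit."""
    w = np.exp(-np.array(landscape.state_G))
    return w / w.sum()


# ---------------------------------------------------------------------------
# Perturbations and scenarios


def apply_perturbation(
    landscape: EnergyLandscape, pert: PerturbationSpec
) -> EnergyLandscape:
    """New landscape with the energy deltas applied; the input is unchanged.

    Raises :class:`LandscapeError` (naming the transition) if a perturbed
    barrier would drop below a flanking well.
    """
    sg = list(landscape.state_G)
    bg = list(landscape.barrier_G)
    for i, d in pert.delta_state.items():
        sg[i] += d
    for i, d in pert.delta_barrier.items():
        bg[i] += d
    fb = landscape.final_barrier_G + pert.delta_final_barrier
    label = landscape.label
    if pert.label:
        label = f"{label}+{pert.label}" if label else pert.label
    return EnergyLandscape(
        tuple(sg), tuple(bg), fb, landscape.state_names, label
    )


#: Transition indices of the four-step scheme.
TR_BINDING, TR_RP1_RP2, TR_RP2_RPO = 0, 1, 2
ST_RP2, ST_RPO = 2, 3


def sigma11_deletion_scenario(
    landscape: EnergyLandscape,
    delta: float = -2.0,
    prefactor: float = 1.0,
    rnap_activity: float = 1.0,
) -> tuple[FluxResult, FluxResult]:
    """Model σ70 region-1.1 deletion as lowering the RP2⇄RPo barrier.

    Returns (basal, mutant) flux results; the mutant carries the fold change
    relative to basal.  ``delta`` must be negative (a lowered barrier).
    """
    if delta >= 0:
        raise ValueError("sigma 1.1 deletion lowers the barrier: delta must be < 0")
    pert = PerturbationSpec(
        delta_barrier={TR_RP2_RPO: delta}, label="delta_sigma70_1.1"
    )
    return _scenario(landscape, pert, prefactor, rnap_activity)


def traR_scenario(
    landscape: EnergyLandscape,
    d_barrier_12: float = -2.0,
    d_state_RP2: float = -2.0,
    d_barrier_2o: float = -2.0,
    f_dissoc: float = 1.0,
    prefactor: float = 1.0,
    rnap_activity: float = 1.0,
) -> tuple[FluxResult, FluxResult]:
    """Composite TraR perturbation of the landscape.

    TraR (i) lowers the RP1⇄RP2 barrier, (ii) lowers the RP2 well relative
    to RPo, and (iii) lowers the RP2⇄RPo barrier; it does not touch the
    initial binding step.  ``f_dissoc`` in (0, 1] optionally scales k_cat to
    express that bound TraR must dissociate before promoter escape
    (default 1: pure landscape perturbation).  Returns (basal, +TraR).
    """
    if any(d > 0 for d in (d_barrier_12, d_state_RP2, d_barrier_2o)):
        raise ValueError("TraR deltas are stabilizations: must be ≤ 0")
    if not 0 < f_dissoc <= 1:
        raise ValueError("f_dissoc must be in (0, 1]")
    pert = PerturbationSpec(
        delta_barrier={TR_RP1_RP2: d_barrier_12, TR_RP2_RPO: d_barrier_2o},
        delta_state={ST_RP2: d_state_RP2},
        label="TraR",
    )
    return _scenario(landscape, pert, prefactor, rnap_activity, k_cat_scale=f_dissoc)


def _scenario(
    landscape: EnergyLandscape,
    pert: PerturbationSpec,
    prefactor: float,
    rnap_activity: float,
    k_cat_scale: float = 1.0,
) -> tuple[FluxResult, FluxResult]:
    basal = steady_state_flux(
        rates_from_landscape(landscape, prefactor, rnap_activity)
    )
    scheme = rates_from_landscape(
        apply_perturbation(landscape, pert), prefactor, rnap_activity
    )
    if k_cat_scale != 1.0:
        scheme = replace(scheme, k_cat=scheme.k_cat * k_cat_scale)
    perturbed = steady_state_flux(scheme)
    fold = perturbed.flux_J / basal.flux_J if basal.flux_J > 0 else np.inf
    perturbed = replace(perturbed, fold_change_vs_reference=float(fold))
    return basal, perturbed
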