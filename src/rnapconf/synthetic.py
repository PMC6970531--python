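"""Synthetic test substrates with known ground truth.

Everything the analysis pipeline consumes can be generated here with the
answer attached: ideal and kinked Cα helices, two-domain coordinate models
with a known rigid rotation applied to one domain, Gaussian per-particle
eigenvalue ensembles with a known linear eigenvalue→rotation map, and the
preset promoter energy landscapes.  Every generator is deterministic given
its seed and returns a :class:`GroundTruth` record, so parameter recovery by
the geometry / heterogeneity / kinetics modules can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import AxisAngle, axis_angle_to_matrix
from .heterogeneity import (
    EXPECTED_TERCILE_MEAN,
    Z_TAIL_99,
    EigenvalueSeries,
)
from .kinetics import EnergyLandscape
from .structio import Atom, AtomModel

__all__ = [
    "GroundTruth",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_two_domain_model",
    "simulate_eigenvalues",
    "write_eigenvalue_table",
    "preset_landscapes",
    "HELIX_RADIUS",
]

#: Cα helix radius, Å (ideal α-helix).
HELIX_RADIUS = 2.3


@dataclass(frozen=True)
class GroundTruth:
    """What was put into a synthetic artifact, for recovery checks."""

    kind: str  # rotation | kink | eigen_map | landscape
    parameters: dict[str, Any] = field(default_factory=dict)


def _ca(chain: str, resnum: int, pos: np.ndarray) -> Atom:
    return Atom(
        chain_id=chain,
        residue_number=resnum,
        insertion_code="",
        residue_name="ALA",
        atom_name="CA",
        element="C",
        position=(float(pos[0]), float(pos[1]), float(pos[2])),
    )


def make_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = HELIX_RADIUS,
    chain: str = "A",
) -> AtomModel:
    """Cα-only ideal α-helix along +z (default 1.5 Å rise, 100° twist)."""
    if n_res < 6:
        raise ValueError("need at least 6 residues for a helix")
    atoms = []
    for i in range(n_res):
        phi = math.radians(twist * i)
        pos = np.array([radius * math.cos(phi), radius * math.sin(phi), rise * i])
        atoms.append(_ca(chain, i + 1, pos))
    return AtomModel(tuple(atoms), source_id="ideal_helix")


def make_kinked_helix(
    n_res: int,
    kink_pos: int,
    kink_angle: float,
    kink_axis: np.ndarray | None = None,
    rise: float = 1.5,
    twist: float = 100.0,
    chain: str = "A",
) -> tuple[AtomModel, GroundTruth]:
    """Ideal helix with its downstream half rotated about the kink residue.

    The rotation axis passes through the Cα of residue ``kink_pos``
    (1-based) and defaults to +x, perpendicular to the helix axis so the
    angle between the two helix-axis directions equals ``kink_angle``.
    """
    if not (6 <= kink_pos <= n_res - 6):
        raise ValueError("kink_pos must leave ≥6 residues on each side")
    axis = np.array([1.0, 0.0, 0.0]) if kink_axis is None else np.asarray(
        kink_axis, dtype=float
    )
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("kink axis must be non-zero")
    axis = axis / nrm
    straight = make_ideal_helix(n_res, rise=rise, twist=twist, chain=chain)
    R = axis_angle_to_matrix(axis, kink_angle)
    pivot = np.array(straight.atoms[kink_pos - 1].position)
    atoms = []
    for a in straight.atoms:
        if a.residue_number > kink_pos:
            pos = R @ (np.array(a.position) - pivot) + pivot
            atoms.append(_ca(chain, a.residue_number, pos))
        else:
            atoms.append(a)
    truth = GroundTruth(
        "kink",
        {
            "kink_angle_deg": float(kink_angle),
            "kink_residue": kink_pos,
            "kink_axis": axis,
        },
    )
    return AtomModel(tuple(atoms), source_id="kinked_helix"), truth


def make_two_domain_model(
    core_n: int,
    domain_n: int,
    rotation: AxisAngle,
    noise_sd: float = 0.0,
    seed: int = 0,
    spread: float = 10.0,
    domain_offset: float = 35.0,
) -> tuple[AtomModel, AtomModel, GroundTruth]:
    """Reference and moved two-domain Cα models with a known domain rotation.

    Chain A is a rigid ``core_n``-point cluster at the origin; chain B a
    ``domain_n``-point cluster offset along +x.  In the moved copy, chain B
    is rotated by ``rotation`` about a pivot at the domain centroid (plus
    any screw translation along the axis); optional isotropic Gaussian noise
    of ``noise_sd`` Å is added to every atom of the moved copy.
    """
    if core_n < 10 or domain_n < 10:
        raise ValueError("core_n and domain_n must each be ≥ 10")
    u = np.asarray(rotation.axis, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("rotation axis must be non-zero")
    u = u / nrm
    rng = np.random.default_rng(seed)
    core = rng.normal(scale=spread, size=(core_n, 3))
    domain = rng.normal(scale=spread, size=(domain_n, 3)) + np.array(
        [domain_offset, 0.0, 0.0]
    )
    pivot = (
        domain.mean(axis=0)
        if rotation.pivot_point is None
        else np.asarray(rotation.pivot_point, dtype=float)
    )
    R = axis_angle_to_matrix(u, rotation.angle_deg)
    moved_domain = (domain - pivot) @ R.T + pivot + rotation.screw_translation * u
    if noise_sd > 0:
        noise_core = rng.normal(scale=noise_sd, size=core.shape)
        noise_dom = rng.normal(scale=noise_sd, size=moved_domain.shape)
    else:
        noise_core = np.zeros_like(core)
        noise_dom = np.zeros_like(moved_domain)

    def build(core_xyz, dom_xyz, tag):
        atoms = [_ca("A", i + 1, core_xyz[i]) for i in range(core_n)]
        atoms += [_ca("B", i + 1, dom_xyz[i]) for i in range(domain_n)]
        return AtomModel(tuple(atoms), source_id=tag)

    reference = build(core, domain, "two_domain_ref")
    moved = build(core + noise_core, moved_domain + noise_dom, "two_domain_moved")
    truth = GroundTruth(
        "rotation",
        {
            "angle_deg": float(rotation.angle_deg),
            "axis": u,
            "pivot": pivot,
            "screw_translation": float(rotation.screw_translation),
            "noise_sd": float(noise_sd),
            "seed": seed,
        },
    )
    return reference, moved, truth


def simulate_eigenvalues(
    n: int,
    mu: float = 0.0,
    sigma: float = 1.0,
    degrees_per_unit: float = 1.0,
    seed: int = 0,
) -> tuple[EigenvalueSeries, GroundTruth]:
    """Gaussian per-particle eigenvalue ensemble with a known rotation map.

    The ground truth records the linear eigenvalue→angle calibration and the
    population values it implies: the tercile rotation
    theta_bin = dpu · 2·E[Z|top third]·σ and the 98% range
    theta_98 = dpu · 2·z(0.99)·σ.
    """
    if n < 100:
        raise ValueError("need at least 100 particles")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    values = mu + sigma * rng.standard_normal(n)
    series = EigenvalueSeries(values, component_index=1, source=f"sim(seed={seed})")
    truth = GroundTruth(
        "eigen_map",
        {
            "mu": float(mu),
            "sigma": float(sigma),
            "degrees_per_unit": float(degrees_per_unit),
            "seed": seed,
            "theta_bin_deg": degrees_per_unit * 2 * EXPECTED_TERCILE_MEAN * sigma,
            "theta_98_deg": degrees_per_unit * 2 * Z_TAIL_99 * sigma,
        },
    )
    return series, truth


def write_eigenvalue_table(path, *columns: np.ndarray, header: str = "") -> None:
    """Write one column per component as a whitespace-delimited text table."""
    data = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    np.savetxt(path, data, header=header, comments="# ")


# ---------------------------------------------------------------------------
# Preset promoter landscapes

def preset_landscapes() -> dict[str, EnergyLandscape]:
    """Hypothetical inhibited and activated promoter landscapes (kBT).

    Package-chosen energies realizing the qualitative promoter classes:

    ``inhibited_hypothetical``
        RPo forms fast (low barriers throughout) but the RPo well is shallow
        — RPo stays in equilibrium with earlier intermediates, and the slow
        escape step samples that equilibrium.
    ``activated_hypothetical``
        RPo formation is limited by a high RP2→RPo barrier; the RPo well is
        very deep, so complexes that reach RPo escape forward rather than
        dissociate.
    """
    return {
        "inhibited_hypothetical": EnergyLandscape(
            state_G=(0.0, -1.0, -2.0, -3.0),
            barrier_G=(2.5, 1.5, 1.0),
            final_barrier_G=7.0,
            label="inhibited_hypothetical",
        ),
        "activated_hypothetical": EnergyLandscape(
            state_G=(0.0, -0.5, -1.0, -8.0),
            barrier_G=(2.5, 1.5, 6.0),
            final_barrier_G=-3.0,
            label="activated_hypothetical",
        ),
    }
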