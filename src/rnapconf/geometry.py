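"""Rigid-body geometry between conformational states of a macromolecule.

Implements least-squares superposition (Kabsch SVD, with an independent
quaternion-method route for cross-checking), Cα pairing between models,
RMSD, two-stage core-then-domain rotation measurement with screw-axis
decomposition, helix kink angles, minimum distances, and buried interface
area (Shrake–Rupley solvent accessibility).

Conventions: angles in degrees in returned results, rotation matrices act on
column vectors, coordinates in Å.  The domain-rotation protocol superposes
model B onto model A using the core selection, then fits the residual rigid
transform carrying the domain of A onto the (core-aligned) domain of B and
decomposes it into an axis, an angle in [0, 180]°, a screw translation along
the axis, and a pivot point on the axis nearest the domain centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as bst

from .errors import (
    InsufficientAtomsError,
    NotARotationError,
    SelectionError,
)
from .structio import Atom, AtomModel, Selection, apply_selection

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "SuperpositionResult",
    "KinkResult",
    "pair_common_atoms",
    "superpose",
    "superpose_quaternion",
    "rmsd_between",
    "domain_rotation",
    "axis_angle_decompose",
    "axis_angle_to_matrix",
    "kink_angle",
    "min_distance",
    "interface_area",
    "VDW_RADII",
]

#: Angle (degrees) below which a rotation axis is numerically unreliable.
SMALL_ANGLE_DEG = 0.1


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise NotARotationError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise NotARotationError("rotation is not orthonormal to 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise NotARotationError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class AxisAngle:
    """Axis-angle (screw) decomposition of a rigid motion."""

    axis: np.ndarray  # unit 3-vector
    angle_deg: float  # in [0, 180]
    screw_translation: float = 0.0  # Å along axis
    pivot_point: np.ndarray | None = None  # point on the axis, Å
    axis_reliable: bool = True


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    pairing_report: tuple = ()


@dataclass(frozen=True)
class KinkResult:
    angle_deg: float
    upstream_axis: np.ndarray
    downstream_axis: np.ndarray
    kink_residue: tuple  # (chain_id, residue_number)
    n_upstream: int = 0
    n_downstream: int = 0


# ---------------------------------------------------------------------------
# Pairing and superposition


def pair_common_atoms(
    model_a: AtomModel,
    model_b: AtomModel,
    sel: Selection | None = None,
    atom_name: str = "CA",
):
    """Pair atoms sharing (chain, residue number, insertion code, atom name).

    Returns ``(coords_a, coords_b, n, unmatched)`` where the coordinate
    arrays are equal-length (N, 3), ordered as in model A, and ``unmatched``
    lists residue ids present in only one model within the selection.
    """
    if model_a.is_empty or model_b.is_empty:
        raise InsufficientAtomsError("both models must be non-empty")

    def index(model: AtomModel) -> dict[tuple, Atom]:
        out = {}
        for a in model.atoms:
            if atom_name and a.atom_name != atom_name:
                continue
            if sel is not None and not sel.with_atom_name(None).matches(a):
                continue
            out.setdefault((a.chain_id, a.residue_number, a.insertion_code), a)
        return out

    ia, ib = index(model_a), index(model_b)
    common = [k for k in ia if k in ib]
    unmatched = sorted(set(ia) ^ set(ib))
    if len(common) < 3:
        raise InsufficientAtomsError(
            f"only {len(common)} paired atoms; at least 3 required"
        )
    ca = np.array([ia[k].position for k in common], dtype=float)
    cb = np.array([ib[k].position for k in common], dtype=float)
    return ca, cb, len(common), unmatched


def superpose(
    coords_a: np.ndarray, coords_b: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal rigid superposition of ``coords_b`` onto ``coords_a``.

    Closed-form least squares via SVD of the weighted covariance (Kabsch),
    with a reflection guard so a proper rotation is always returned.  RMSD is
    computed after applying the transform to ``coords_b``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = A.shape[0]
    if n < 3:
        raise InsufficientAtomsError("superposition requires at least 3 points")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("coordinates contain non-finite values")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ca = (w[:, None] * A).sum(axis=0)
    cb = (w[:, None] * B).sum(axis=0)
    A0, B0 = A - ca, B - cb
    H = (w[:, None] * B0).T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    transform = RigidTransform(R, t)
    moved = transform.apply(B)
    rmsd = float(np.sqrt((w * ((moved - A) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(transform, rmsd, n)


def superpose_quaternion(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> SuperpositionResult:
    """Independent superposition route via Horn's quaternion eigen-method.

    Builds the 4x4 key matrix from the covariance of the centered clouds and
    takes the rotation from the eigenvector of its largest eigenvalue.  Used
    as a cross-check of :func:`superpose`; shares no code with it beyond the
    containers.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if A.shape[0] < 3:
        raise InsufficientAtomsError("superposition requires at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    M = B0.T @ A0  # rotate B onto A
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, np.argmax(evals)]  # (w, x, y, z)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = ca - R @ cb
    transform = RigidTransform(R, t)
    moved = transform.apply(B)
    rmsd = float(np.sqrt(((moved - A) ** 2).sum() / A.shape[0]))
    return SuperpositionResult(transform, rmsd, A.shape[0])


def rmsd_between(
    model_a: AtomModel,
    model_b: AtomModel,
    include: Selection | None = None,
    exclude: Selection | None = None,
    atom_name: str = "CA",
) -> tuple[float, int]:
    """Superposed Cα RMSD between two models over common residues.

    ``include`` restricts the pairing; ``exclude`` removes residues from it
    (e.g. excluding a mobile insertion before superposing the rest).
    """
    if exclude is not None:
        def keep(a: Atom) -> bool:
            return not exclude.with_atom_name(None).matches(a)

        model_a = AtomModel(tuple(x for x in model_a.atoms if keep(x)), model_a.source_id)
        model_b = AtomModel(tuple(x for x in model_b.atoms if keep(x)), model_b.source_id)
    ca, cb, n, _ = pair_common_atoms(model_a, model_b, include, atom_name)
    res = superpose(ca, cb)
    return res.rmsd, n


# ---------------------------------------------------------------------------
# Axis-angle decomposition


def axis_angle_to_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in degrees."""
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    u = u / norm
    th = math.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def axis_angle_decompose(rotation: np.ndarray) -> AxisAngle:
    """Angle/axis of a validated rotation matrix.

    angle = arccos((tr R − 1)/2); the axis comes from the antisymmetric part
    away from the branch points, from the symmetric part (R + I eigenvector)
    near 180°, and is flagged unreliable below ``SMALL_ANGLE_DEG``.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or (
        abs(np.linalg.det(R) - 1.0) > 1e-8
    ):
        raise NotARotationError("input is not a proper rotation matrix")
    tr = float(np.trace(R))
    cos_th = max(-1.0, min(1.0, (tr - 1.0) / 2.0))
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_norm = float(np.linalg.norm(v))  # = 2 sin(theta)
    # atan2 keeps full precision at both branch points, where acos of the
    # trace alone loses ~sqrt(eps)
    angle = math.degrees(math.atan2(sin_norm / 2.0, cos_th))
    if angle < SMALL_ANGLE_DEG:
        axis = v / sin_norm if sin_norm > 0 else np.array([0.0, 0.0, 1.0])
        return AxisAngle(axis, angle, axis_reliable=False)
    if sin_norm < 1e-7:
        # Essentially 180°: the antisymmetric part vanishes; the columns of
        # R + I are parallel to the axis.
        B = R + np.eye(3)
        j = int(np.argmax(np.diag(B)))
        axis = B[:, j] / np.linalg.norm(B[:, j])
        if sin_norm > 0 and np.dot(axis, v) < 0:
            axis = -axis
        return AxisAngle(axis, angle)
    return AxisAngle(v / sin_norm, angle)


def _screw_decompose(transform: RigidTransform, near_point: np.ndarray) -> AxisAngle:
    """Full screw decomposition with pivot nearest ``near_point``."""
    aa = axis_angle_decompose(transform.rotation)
    u = aa.axis
    t = transform.translation
    screw = float(np.dot(t, u))
    if not aa.axis_reliable:
        return AxisAngle(u, aa.angle_deg, screw, np.asarray(near_point, float), False)
    # Pivot c solves (I − R) c = t − (t·u) u in the plane perpendicular to u.
    A = np.eye(3) - transform.rotation
    b = t - screw * u
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    # Project c to the axis point nearest the domain centroid.
    c = c + np.dot(near_point - c, u) * u
    return AxisAngle(u, aa.angle_deg, screw, c, True)


def domain_rotation(
    model_a: AtomModel,
    model_b: AtomModel,
    core_sel: Selection,
    domain_sel: Selection,
    atom_name: str = "CA",
) -> AxisAngle:
    """Rotation of a domain between two conformational states.

    Two-stage protocol: superpose B onto A over the core selection, then fit
    the residual rigid transform carrying the domain of A onto the core-
    aligned domain of B and decompose it into a screw axis.  The pivot is the
    axis point nearest the domain centroid (of model A).
    """
    core_a, core_b, _, _ = pair_common_atoms(model_a, model_b, core_sel, atom_name)
    core_fit = superpose(core_a, core_b)
    dom_a, dom_b, n_dom, _ = pair_common_atoms(model_a, model_b, domain_sel, atom_name)
    dom_b_aligned = core_fit.transform.apply(dom_b)
    dom_fit = superpose(dom_b_aligned, dom_a)  # carries A-domain onto aligned B-domain
    centroid = dom_a.mean(axis=0)
    return _screw_decompose(dom_fit.transform, centroid)


# ---------------------------------------------------------------------------
# Helix kink


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Axis of a run of Cα coordinates, oriented N→C.

    Local-axis construction: at each interior residue the bisector of the
    vectors to its neighbours points at the helix axis, and cross products
    of successive bisectors give the local axis direction (exact for an
    ideal helix, so the estimate carries no partial-turn bias; a plain
    principal-component axis is tilted by fractions of a turn).  The mean
    local axis is returned, sign-fixed along the chain direction.
    """
    P = np.asarray(coords, dtype=float)
    bis = []
    for i in range(1, len(P) - 1):
        h = (P[i - 1] - P[i]) + (P[i + 1] - P[i])
        n = np.linalg.norm(h)
        if n > 0:
            bis.append(h / n)
    axes = []
    for a, b in zip(bis[:-1], bis[1:]):
        c = np.cross(a, b)
        n = np.linalg.norm(c)
        if n > 0:
            axes.append(c / n)
    if not axes:
        raise InsufficientAtomsError("degenerate flank geometry for axis fit")
    axis = np.mean(axes, axis=0)
    axis = axis / np.linalg.norm(axis)
    if np.dot(axis, P[-1] - P[0]) < 0:
        axis = -axis
    return axis


def kink_angle(
    model: AtomModel,
    helix_sel: Selection,
    kink_residue: int | tuple[str, int],
    flank: int = 12,
) -> KinkResult:
    """Kink angle of a helix at a given residue.

    Fits a principal axis to the Cα of up to ``flank`` residues on each side
    of the kink residue (the kink residue itself belongs to neither flank)
    and returns the angle between the two axes — ~0° for a straight helix.
    Requires at least 6 Cα per flank.
    """
    helix = apply_selection(model, helix_sel.with_atom_name("CA"))
    cas = sorted(
        helix.atoms, key=lambda a: (a.chain_id, a.residue_number, a.insertion_code)
    )
    if isinstance(kink_residue, tuple):
        chain_id, resnum = kink_residue
        cas = [a for a in cas if a.chain_id == chain_id]
    else:
        resnum = kink_residue
        chains = {a.chain_id for a in cas}
        if len(chains) > 1:
            raise SelectionError(
                "helix selection spans multiple chains; pass (chain, residue)"
            )
    idx = [i for i, a in enumerate(cas) if a.residue_number == resnum]
    if not idx:
        raise SelectionError(f"kink residue {resnum} not found in helix selection")
    k = idx[0]
    up = cas[max(0, k - flank): k]
    down = cas[k + 1: k + 1 + flank]
    if len(up) < 6 or len(down) < 6:
        raise InsufficientAtomsError(
            f"need ≥6 Cα per flank, got {len(up)} upstream / {len(down)} downstream"
        )
    ax_up = _helix_axis(np.array([a.position for a in up]))
    ax_down = _helix_axis(np.array([a.position for a in down]))
    cos_th = max(-1.0, min(1.0, float(np.dot(ax_up, ax_down))))
    angle = math.degrees(math.acos(cos_th))
    return KinkResult(
        angle, ax_up, ax_down, (cas[k].chain_id, resnum), len(up), len(down)
    )


# ---------------------------------------------------------------------------
# Distances and interfaces


def min_distance(
    model: AtomModel, sel_a: Selection, sel_b: Selection
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum Euclidean distance over all cross pairs, with the atom pair."""
    sub_a = apply_selection(model, sel_a)
    sub_b = apply_selection(model, sel_b)
    if sub_a.is_empty or sub_b.is_empty:
        raise SelectionError("both selections must match at least one atom")
    D = cdist(sub_a.coords(), sub_b.coords())
    i, j = np.unravel_index(np.argmin(D), D.shape)
    return float(D[i, j]), (sub_a.atoms[i], sub_b.atoms[j])


#: Bondi van der Waals radii (Å) by element symbol; 1.80 Å fallback.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "FE": 1.40, "MN": 1.40, "CA": 2.31,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63,
}
DEFAULT_VDW_RADIUS = 1.80


def _to_atom_array(model: AtomModel) -> "bst.AtomArray":
    n = len(model)
    arr = bst.AtomArray(n)
    arr.coord = model.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in model.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in model.atoms])
    arr.res_name = np.array([a.residue_name for a in model.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in model.atoms], dtype="U6")
    arr.element = np.array([a.element for a in model.atoms], dtype="U2")
    arr.hetero = np.array([a.hetero for a in model.atoms])
    return arr


def _sasa(model: AtomModel, probe: float, n_points: int, radii: np.ndarray) -> float:
    arr = _to_atom_array(model)
    per_atom = bst.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    return float(np.nansum(per_atom))


def interface_area(
    model: AtomModel,
    sel_a: Selection,
    sel_b: Selection,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> float:
    """Buried interface area between two disjoint selections, Å².

    One-sided convention: [SASA(A) + SASA(B) − SASA(A∪B)] / 2, evaluated by
    Shrake–Rupley sampling (default 960 points/atom) with the package's vdW
    radii table.  Values are method-dependent at the ±10% level across
    implementations.
    """
    table = VDW_RADII if radii is None else radii
    sub_a = apply_selection(model, sel_a)
    sub_b = apply_selection(model, sel_b)
    if sub_a.is_empty or sub_b.is_empty:
        raise SelectionError("both selections must match at least one atom")
    both_keys = {id(a) for a in sub_a.atoms} & {id(a) for a in sub_b.atoms}
    if both_keys:
        raise SelectionError("interface selections must be disjoint")

    def rad(sub: AtomModel) -> np.ndarray:
        return np.array(
            [table.get(a.element, DEFAULT_VDW_RADIUS) for a in sub.atoms], dtype=float
        )

    union = AtomModel(sub_a.atoms + sub_b.atoms, source_id=model.source_id)
    sa = _sasa(sub_a, probe, n_points, rad(sub_a))
    sb = _sasa(sub_b, probe, n_points, rad(sub_b))
    sab = _sasa(union, probe, n_points, rad(union))
    return max(0.0, (sa + sb - sab) / 2.0)
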