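"""Coordinate model I/O, residue-range selections, and RNAP domain definitions.

Atomic models are read through gemmi (PDB v3.3 and mmCIF/PDBx) into a small
immutable :class:`Atom` / :class:`AtomModel` container that every geometric
operation in the package consumes.  Residue numbering is author numbering,
1-based, with ranges inclusive on both ends.

The built-in domain table houses the residue-range definitions of the mobile
modules of *E. coli* RNA polymerase used throughout the analyses: the clamp
(β' N-terminal region + σ70 region 2), the β'shelf, the lineage-specific
insertions Si1 (β lobe) and Si3 (trigger-loop insertion), the bridge helix,
and the βlobe-Si1 super-module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    ConfigurationError,
    EmptyModelError,
    SelectionRangeError,
    SelectionSyntaxError,
    StructureParseError,
)

__all__ = [
    "Atom",
    "AtomModel",
    "Selection",
    "DomainDefinitions",
    "read_structure",
    "write_pdb",
    "write_mmcif",
    "parse_selection",
    "apply_selection",
    "builtin_domains",
    "BUILTIN_DOMAIN_RANGES",
]


@dataclass(frozen=True)
class Atom:
    """One atom site with author-numbered residue identity."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""
    hetero: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class AtomModel:
    """Ordered collection of atoms from one coordinate model."""

    atoms: tuple[Atom, ...]
    source_id: str = ""
    model_number: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def is_empty(self) -> bool:
        return len(self.atoms) == 0

    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinate array in Å."""
        if self.is_empty:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass(frozen=True)
class Selection:
    """Named residue ranges per chain, optionally restricted to one atom name.

    ``terms`` maps a chain id to inclusive ``(start, end)`` residue ranges.
    Construction normalizes: ranges sorted and merged, overlaps unioned.
    """

    terms: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    atom_name: str | None = None

    def __post_init__(self) -> None:
        norm = []
        for chain, ranges in self.terms:
            for start, end in ranges:
                if start > end:
                    raise SelectionRangeError(
                        f"range {start}-{end} on chain {chain!r} has start > end"
                    )
            norm.append((chain, _merge_ranges(ranges)))
        object.__setattr__(self, "terms", tuple(norm))

    def matches(self, atom: Atom) -> bool:
        if self.atom_name is not None and atom.atom_name != self.atom_name:
            return False
        for chain, ranges in self.terms:
            if atom.chain_id != chain:
                continue
            for start, end in ranges:
                if start <= atom.residue_number <= end:
                    return True
        return False

    def with_atom_name(self, name: str | None) -> "Selection":
        return replace(self, atom_name=name)

    def union(self, other: "Selection") -> "Selection":
        """Union of residue ranges; atom-name filters must agree."""
        if self.atom_name != other.atom_name:
            raise SelectionSyntaxError("cannot union selections with different atom filters")
        merged: dict[str, list[tuple[int, int]]] = {}
        for chain, ranges in self.terms + other.terms:
            merged.setdefault(chain, []).extend(ranges)
        return Selection(
            tuple((c, tuple(r)) for c, r in merged.items()), atom_name=self.atom_name
        )

    def to_expression(self) -> str:
        parts = []
        for chain, ranges in self.terms:
            body = ",".join(
                f"{s}" if s == e else f"{s}-{e}" for s, e in ranges
            )
            parts.append(f"{chain}:{body}")
        expr = "; ".join(parts)
        if self.atom_name:
            expr += f" @{self.atom_name}"
        return expr


def _merge_ranges(ranges: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    items = sorted(ranges)
    out: list[tuple[int, int]] = []
    for start, end in items:
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return tuple(out)


_TERM_RE = re.compile(r"^\s*([A-Za-z0-9]+)\s*:\s*([0-9,\-\s]+)$")


def parse_selection(text: str) -> Selection:
    """Parse ``"C:787-931,1135-1150,1216-1317; D:1-342 @CA"`` style expressions.

    Grammar: semicolon-separated chain terms ``CHAIN:RANGE(,RANGE)*`` with
    ``RANGE = N | N-M`` (inclusive), plus an optional trailing ``@NAME``
    atom-name filter applying to the whole selection.
    """
    work = text.strip()
    atom_name = None
    m = re.search(r"@\s*([A-Za-z0-9']+)\s*$", work)
    if m:
        atom_name = m.group(1)
        work = work[: m.start()].strip()
    if not work:
        raise SelectionSyntaxError(f"empty selection expression: {text!r}")
    terms: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    for chunk in work.split(";"):
        if not chunk.strip():
            continue
        tm = _TERM_RE.match(chunk)
        if not tm:
            raise SelectionSyntaxError(f"malformed selection term: {chunk.strip()!r}")
        chain = tm.group(1)
        ranges: list[tuple[int, int]] = []
        for rtext in tm.group(2).split(","):
            rtext = rtext.strip()
            if not rtext:
                raise SelectionSyntaxError(f"empty range in term {chunk.strip()!r}")
            rm = re.fullmatch(r"(\d+)(?:\s*-\s*(\d+))?", rtext)
            if not rm:
                raise SelectionSyntaxError(f"bad range token {rtext!r}")
            start = int(rm.group(1))
            end = int(rm.group(2)) if rm.group(2) else start
            ranges.append((start, end))
        terms.append((chain, tuple(ranges)))
    return Selection(tuple(terms), atom_name=atom_name)


def apply_selection(model: AtomModel, sel: Selection) -> AtomModel:
    """Sub-model of atoms matching the selection; input order preserved.

    An empty result is legal — check ``result.is_empty``.
    """
    atoms = tuple(a for a in model.atoms if sel.matches(a))
    return AtomModel(atoms, source_id=model.source_id, model_number=model.model_number)


# ---------------------------------------------------------------------------
# Reading / writing through gemmi


def _resolve_altlocs(atoms: list[Atom]) -> tuple[Atom, ...]:
    # Highest occupancy wins; ties go to first occurrence.
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        j = best.get(key)
        if j is None or a.occupancy > atoms[j].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return tuple(atoms[i] for i in keep)


def read_structure(
    path: str | Path, format: str = "auto", model_number: int | None = None
) -> AtomModel:
    """Read a PDB or mmCIF file into an :class:`AtomModel`.

    Returns the first model unless ``model_number`` is given.  Hetero atoms
    (metals, nucleic acids, ligands) are retained.  Alternate locations are
    resolved to the highest-occupancy conformer (ties: first occurrence).
    """
    path = Path(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = None
    if model_number is None:
        model = st[0]
    else:
        for m in st:
            if m.num == model_number:
                model = m
                break
        if model is None:
            raise EmptyModelError(f"{path}: no model numbered {model_number}")
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            for at in res:
                alt = at.altloc if at.altloc not in ("\0", "\x00") else ""
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=icode,
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name.upper(),
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        alt_loc=alt,
                        hetero=(res.het_flag == "H"),
                    )
                )
    if not atoms:
        raise EmptyModelError(f"{path}: model contains no atoms")
    return AtomModel(_resolve_altlocs(atoms), source_id=path.name, model_number=model.num)


def _to_gemmi(model: AtomModel, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model(str(model.model_number))
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
        rkey = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        res = residues.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            ch.add_residue(res)
            residues[rkey] = res
            # re-fetch reference owned by the chain
            res = ch[len(ch) - 1]
            residues[rkey] = res
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        if a.alt_loc:
            at.altloc = a.alt_loc
        res.add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: AtomModel, path: str | Path) -> None:
    """Write the model back to PDB for inspection."""
    _to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: AtomModel, path: str | Path) -> None:
    """Write the model as mmCIF/PDBx."""
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Domain definitions

#: Residue-range definitions of the mobile RNAP modules, keyed by domain name.
#: Each entry: (subunit, ranges, provenance note).  ``clamp`` spans three
#: subunits and is stored as a list of such entries.
BUILTIN_DOMAIN_RANGES: dict[str, list[tuple[str, tuple[tuple[int, int], ...], str]]] = {
    "clamp": [
        ("beta", ((1319, 1342),), "β clamp strands"),
        ("beta_prime", ((1, 342), (1318, 1344)), "β' clamp core"),
        ("sigma70", ((92, 137), (353, 449)), "σ70 region 2 moves with the clamp"),
    ],
    "shelf": [
        (
            "beta_prime",
            ((787, 931), (1135, 1150), (1216, 1317)),
            "β'shelf module (includes the β'jaw)",
        )
    ],
    "si3": [
        (
            "beta_prime",
            ((948, 1126),),
            "lineage-specific insertion in the trigger loop (SBHMa+SBHMb)",
        )
    ],
    "si1": [
        ("beta", ((225, 343),), "lineage-specific insertion in the β lobe")
    ],
    "bridge_helix": [
        (
            "beta_prime",
            ((770, 805),),
            "window bracketing the kink residue β'L788; width is a package "
            "choice and overridable",
        )
    ],
    "beta_lobe_si1": [
        (
            "beta",
            ((151, 453),),
            "β lobe including Si1; lobe boundaries are a package default "
            "(not from a printed definition) and overridable",
        )
    ],
}

#: Residue at which the bridge helix kinks.
BRIDGE_HELIX_KINK_RESIDUE = 788


@dataclass(frozen=True)
class DomainDefinitions:
    """Named map of RNAP domain selections with provenance notes."""

    domains: Mapping[str, Selection]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Selection:
        return self.domains[name]

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    def names(self) -> list[str]:
        return list(self.domains)

    def to_config_text(self) -> str:
        """Plain-text config: one domain per line, name, expression, note."""
        lines = []
        for name, sel in self.domains.items():
            note = self.provenance.get(name, "")
            lines.append(f"{name}\t{sel.to_expression()}\t{note}")
        return "\n".join(lines) + "\n"


REQUIRED_SUBUNITS = ("beta", "beta_prime", "sigma70")


def builtin_domains(chain_map: Mapping[str, str]) -> DomainDefinitions:
    """Translate the built-in domain table to concrete chain ids.

    ``chain_map`` names the chain id of each subunit, e.g.
    ``{"beta": "C", "beta_prime": "D", "sigma70": "F"}``.  β, β' and σ70 are
    required; α and ω may be supplied but no built-in domain uses them.
    """
    missing = [s for s in REQUIRED_SUBUNITS if s not in chain_map]
    if missing:
        raise ConfigurationError(
            f"chain_map is missing required subunit(s): {', '.join(missing)}"
        )
    domains: dict[str, Selection] = {}
    provenance: dict[str, str] = {}
    for name, entries in BUILTIN_DOMAIN_RANGES.items():
        terms = []
        notes = []
        for subunit, ranges, note in entries:
            terms.append((chain_map[subunit], ranges))
            notes.append(note)
        domains[name] = Selection(tuple(terms))
        provenance[name] = "; ".join(notes)
    return DomainDefinitions(domains, provenance)


def complement_atoms(model: AtomModel, sel: Selection) -> AtomModel:
    """Atoms of the model NOT matched by the selection (order preserved)."""
    atoms = tuple(a for a in model.atoms if not sel.matches(a))
    return AtomModel(atoms, source_id=model.source_id, model_number=model.model_number)
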