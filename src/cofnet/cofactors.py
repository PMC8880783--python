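"""Redox-cofactor detection, coordination shells and metal stoichiometry.

Cofactors are recognized from hetero residues by their chemical-component
codes (SF4 -> [4Fe-4S], FES -> [2Fe-2S], ...).  The bimetallic NiFe catalytic
center is assembled by pairing each Ni atom with its nearest free Fe atom
within a cutoff, mirroring how the site appears in deposited hydrogenase
models (separate NI / FE / FCO components rather than one residue).

Stoichiometry converts a cofactor inventory into elemental Fe and Ni totals;
for the electron-bifurcating NiFe-hydrogenase heteropentamer the expected
composition (8 x [4Fe-4S] + 4 x [2Fe-2S] + 1 NiFe) gives Fe:Ni = 41:1, the
quantity that ICP-MS measurements of the purified enzyme are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import AmbiguousComponentError, DegenerateCofactorError
from .structure_io import Atom, Structure

# Atoms of the fused tricyclic isoalloxazine system of FMN/FAD (the
# redox-active moiety flavin distances are measured to), and of the
# nicotinamide ring of NAD.  Names follow the chemical-component dictionary.
ISOALLOXAZINE_ATOMS = (
    "N1", "C2", "O2", "N3", "C4", "O4", "C4A", "N5", "C5A", "C6", "C7",
    "C7M", "C8", "C8M", "C9", "C9A", "N10", "C10",
    # spelling variants seen in older entries
    "C4X", "C5X", "C9X", "C10X",
)
NICOTINAMIDE_ATOMS = ("N1N", "C2N", "C3N", "C4N", "C5N", "C6N")


@dataclass(frozen=True)
class CofactorType:
    """A recognizable cofactor species and its elemental content."""

    code: str                      # e.g. "FES4"
    display: str                   # e.g. "[4Fe-4S]"
    component_codes: tuple[str, ...]
    fe_count: int = 0
    ni_count: int = 0
    ring_atom_names: tuple[str, ...] = ()


FES4 = CofactorType("FES4", "[4Fe-4S]", ("SF4",), fe_count=4)
FES2 = CofactorType("FES2", "[2Fe-2S]", ("FES", "FS2"), fe_count=2)
FES3 = CofactorType("FES3", "[3Fe-4S]", ("F3S",), fe_count=3)
FMN = CofactorType("FMN", "FMN", ("FMN",), ring_atom_names=ISOALLOXAZINE_ATOMS)
FAD = CofactorType("FAD", "FAD", ("FAD",), ring_atom_names=ISOALLOXAZINE_ATOMS)
NAD = CofactorType("NAD", "NAD", ("NAD", "NAI"), ring_atom_names=NICOTINAMIDE_ATOMS)
NIFE = CofactorType("NIFE", "NiFe center", (), fe_count=1, ni_count=1)
CUSTOM = CofactorType("CUSTOM", "custom", ())

DEFAULT_DICTIONARY: tuple[CofactorType, ...] = (FES4, FES2, FES3, FMN, FAD, NAD)
FES_CODES = ("FES4", "FES3", "FES2")

# Diatomic/carbonyl-cyanide components that belong to the NiFe site.
_NIFE_LIGAND_CODES = {"FCO", "CMO", "CYN", "CO", "CN"}

_METAL_ELEMENTS = {"FE", "NI", "MO", "ZN", "CU", "MN", "CO", "W"}


class UnpairedNickelWarning(UserWarning):
    """A Ni atom had no free Fe within the pairing cutoff."""


@dataclass
class Cofactor:
    """A detected redox center."""

    label: str
    type: CofactorType
    chain_id: str
    residue_numbers: tuple[int, ...]
    atoms: list[Atom]
    metal_atoms: list[Atom] = field(default_factory=list)
    ring_atoms: list[Atom] = field(default_factory=list)

    def center_atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        """Atoms defining the geometric center: the ring for flavins and
        nicotinamide, all (non-H) member atoms otherwise."""
        base = self.ring_atoms if self.ring_atoms else self.atoms
        if include_hydrogens:
            return list(base)
        return [a for a in base if not a.is_hydrogen]

    def distance_atoms(self, include_hydrogens: bool = False) -> list[Atom]:
        """Atoms participating in edge-to-edge (side-to-side) distances."""
        if include_hydrogens:
            return list(self.atoms)
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def center(self) -> np.ndarray:
        atoms = self.center_atoms()
        if not atoms:
            raise DegenerateCofactorError(f"cofactor {self.label!r} has no atoms")
        return np.mean([a.position for a in atoms], axis=0)

    def __repr__(self):
        return f"Cofactor({self.label!r}, {self.type.code}, {len(self.atoms)} atoms)"


def _match_type(residue_name: str, dictionary) -> CofactorType | None:
    hits = [t for t in dictionary if residue_name.upper() in t.component_codes]
    if len(hits) > 1:
        raise AmbiguousComponentError(
            f"residue name {residue_name!r} matches cofactor types "
            f"{[t.code for t in hits]}; fix the dictionary")
    return hits[0] if hits else None


def detect_cofactors(structure: Structure,
                     dictionary=DEFAULT_DICTIONARY,
                     nife_pair_cutoff: float = 3.5,
                     label_map: dict | None = None,
                     model_index: int | None = None) -> list[Cofactor]:
    """Detect cofactors among the hetero residues of one model.

    ``label_map`` maps ``"<chain>:<residue_number>"`` to a user label (the
    A1...A5 / B1...B5 / C1 / S1 / NiFe naming of the hydrogenase); otherwise
    labels are auto-generated as ``<chain><ordinal>``.  Each Ni atom is paired
    with its nearest Fe atom not already assigned to an FeS cluster; a NiFe
    cofactor is emitted when the pair is within ``nife_pair_cutoff`` Å,
    otherwise the Ni is reported as CUSTOM with a warning.
    """
    sub = structure.model(model_index)
    cofactors: list[Cofactor] = []
    assigned_fe_ids: set[int] = set()
    ni_atoms: list[tuple] = []            # (residue key, atoms)
    free_fe: list[tuple] = []             # residues with Fe not matched to a type
    ligand_residues: list[tuple] = []

    for key, atoms in sub.residues():
        _, chain_id, resnum, _, resname = key
        if not atoms[0].is_hetero:
            continue
        ctype = _match_type(resname, dictionary)
        if ctype is not None:
            metals = [a for a in atoms if a.element.upper() in _METAL_ELEMENTS]
            ring_names = set(ctype.ring_atom_names)
            ring = [a for a in atoms if a.atom_name.upper() in ring_names]
            cofactors.append(Cofactor(
                label="", type=ctype, chain_id=chain_id,
                residue_numbers=(resnum,), atoms=list(atoms),
                metal_atoms=metals, ring_atoms=ring))
            assigned_fe_ids.update(id(a) for a in metals if a.element.upper() == "FE")
            continue
        if resname.upper() in _NIFE_LIGAND_CODES:
            ligand_residues.append((key, atoms))
            continue
        elems = {a.element.upper() for a in atoms}
        if "NI" in elems:
            ni_atoms.append((key, atoms))
        elif "FE" in elems:
            free_fe.append((key, atoms))

    fe_pool = [a for _, atoms in free_fe for a in atoms if a.element.upper() == "FE"
               and id(a) not in assigned_fe_ids]
    # also consider ligand-residue iron (e.g. the Fe of an FCO component)
    fe_pool += [a for _, atoms in ligand_residues for a in atoms
                if a.element.upper() == "FE" and id(a) not in assigned_fe_ids]

    used_fe: set[int] = set()
    for key, atoms in ni_atoms:
        _, chain_id, resnum, _, _ = key
        ni = next(a for a in atoms if a.element.upper() == "NI")
        candidates = [(float(np.linalg.norm(ni.position - fe.position)), i, fe)
                      for i, fe in enumerate(fe_pool) if id(fe) not in used_fe]
        candidates.sort(key=lambda c: (c[0], c[1]))
        if candidates and candidates[0][0] <= nife_pair_cutoff:
            dist, _, fe = candidates[0]
            used_fe.add(id(fe))
            member = list(atoms) + [fe]
            resnums = {resnum, fe.residue_number}
            # pull in diatomic-ligand atoms close to either metal
            for _, lat in ligand_residues:
                for a in lat:
                    if id(a) in used_fe or a is fe:
                        continue
                    d = min(np.linalg.norm(a.position - ni.position),
                            np.linalg.norm(a.position - fe.position))
                    if d <= nife_pair_cutoff and a not in member:
                        member.append(a)
                        resnums.add(a.residue_number)
            cofactors.append(Cofactor(
                label="", type=NIFE, chain_id=chain_id,
                residue_numbers=tuple(sorted(resnums)), atoms=member,
                metal_atoms=[ni, fe]))
        else:
            warnings.warn(
                f"Ni atom in chain {chain_id} residue {resnum} has no free Fe "
                f"within {nife_pair_cutoff} Å; reporting as CUSTOM",
                UnpairedNickelWarning, stacklevel=2)
            cofactors.append(Cofactor(
                label="", type=CUSTOM, chain_id=chain_id,
                residue_numbers=(resnum,), atoms=list(atoms), metal_atoms=[ni]))

    # deterministic labels: chain + per-chain ordinal, unless a map is given
    counters: dict[str, int] = {}
    for c in cofactors:
        counters[c.chain_id] = counters.get(c.chain_id, 0) + 1
        auto = f"{c.chain_id}{counters[c.chain_id]}"
        mapped = None
        if label_map:
            for rn in c.residue_numbers:
                mapped = label_map.get(f"{c.chain_id}:{rn}")
                if mapped:
                    break
        c.label = mapped or auto
    return cofactors


@dataclass
class ShellEntry:
    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    distance: float


@dataclass
class CoordinationShell:
    """Protein side-chain donor atoms around a cofactor's metal atoms."""

    label: str
    entries: list[ShellEntry]
    note: str = ""

    def residue_names(self) -> list[str]:
        return [e.residue_name for e in self.entries]


def coordination_shell(structure: Structure, cofactor: Cofactor,
                       cutoff: float = 3.0,
                       model_index: int | None = None) -> CoordinationShell:
    """Side-chain S/N/O atoms within ``cutoff`` Å of any metal atom.

    Each donor atom is listed once with its minimal distance, sorted
    ascending.  Cofactors without metal atoms (FMN, NAD) yield an empty shell
    with an informational note.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not cofactor.metal_atoms:
        return CoordinationShell(cofactor.label, [],
                                 note=f"{cofactor.type.display} has no metal atoms")
    sub = structure.model(model_index)
    metal_pos = np.array([a.position for a in cofactor.metal_atoms])
    entries = []
    for a in sub.atoms:
        if a.is_hetero or a.element.upper() not in ("S", "N", "O"):
            continue
        if a.atom_name.upper() in ("N", "O", "OXT"):   # backbone donors excluded
            continue
        d = float(np.min(np.linalg.norm(metal_pos - a.position, axis=1)))
        if d <= cutoff:
            entries.append(ShellEntry(a.chain_id, a.residue_name,
                                      a.residue_number, a.atom_name, d))
    entries.sort(key=lambda e: e.distance)
    return CoordinationShell(cofactor.label, entries)


@dataclass
class Inventory:
    """Counts per cofactor type plus elemental totals."""

    counts: dict
    fe_total: int
    ni_total: int

    @property
    def fe_ni_ratio(self) -> Fraction | None:
        """Fe:Ni as an exact rational, or None when no Ni is present."""
        if self.ni_total == 0:
            return None
        return Fraction(self.fe_total, self.ni_total)

    def to_dict(self) -> dict:
        ratio = self.fe_ni_ratio
        return {
            "counts": dict(self.counts),
            "fe_total": self.fe_total,
            "ni_total": self.ni_total,
            "fe_ni_ratio": None if ratio is None else float(ratio),
        }


_TYPE_BY_CODE = {t.code: t for t in (FES4, FES2, FES3, FMN, FAD, NAD, NIFE, CUSTOM)}


def stoichiometry(counts: dict, dictionary=None) -> Inventory:
    """Elemental Fe/Ni totals for a cofactor-type count table.

    ``counts`` maps type codes (``"FES4"``, ``"NIFE"``, ...) to non-negative
    integers.  The expected hydrogenase composition
    ``{"FES4": 8, "FES2": 4, "NIFE": 1}`` gives 41 Fe and 1 Ni.
    """
    lookup = dict(_TYPE_BY_CODE)
    if dictionary:
        lookup.update({t.code: t for t in dictionary})
    fe = ni = 0
    for code, n in counts.items():
        if n < 0 or int(n) != n:
            raise ValueError(f"count for {code} must be a non-negative integer")
        t = lookup.get(code)
        if t is None:
            raise KeyError(f"unknown cofactor type code {code!r}")
        fe += int(n) * t.fe_count
        ni += int(n) * t.ni_count
    return Inventory(counts=dict(counts), fe_total=fe, ni_total=ni)


def inventory_of(cofactors: list[Cofactor]) -> Inventory:
    """Count detected cofactors by type and compute stoichiometry."""
    counts: dict[str, int] = {}
    for c in cofactors:
        counts[c.type.code] = counts.get(c.type.code, 0) + 1
    return stoichiometry(counts)
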