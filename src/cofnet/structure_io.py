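"""Reading, writing and selecting atoms of atomic models (PDB / mmCIF).

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Atom` records plus free-form metadata.  Parsing and writing are
delegated to gemmi; this module converts to and from the flat record list that
the rest of the package consumes, applies the altloc convention (keep the
highest-occupancy alternative, ties broken toward altloc 'A') and infers
elements from atom names when the element column is blank.

Selections use a tiny boolean grammar (EBNF in the README)::

    chain B and resnum 113-536
    hetero and resname SF4 FES
    not (element FE or name SG)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    FormatCapacityError,
    FormatError,
    SelectionSyntaxError,
    StructureParseError,
)

# Fallback for legacy files with a blank element column: leading characters of
# the atom name that denote common metals/ligand atoms in FeS/NiFe chemistry.
_ELEMENT_FALLBACK = {
    "FE": "FE", "NI": "NI", "ZN": "ZN", "MO": "MO", "MG": "MG", "MN": "MN",
    "CU": "CU", "SF": "S", "SG": "S", "SD": "S", "S": "S", "C": "C",
    "N": "N", "O": "O", "P": "P", "H": "H",
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    """One atom record, coordinates in Å."""

    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    insertion_code: str = ""
    altloc: str = ""
    model_index: int = 1
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def residue_key(self):
        """Unique (model, chain, residue) triple this atom belongs to."""
        return (self.model_index, self.chain_id, self.residue_number,
                self.insertion_code, self.residue_name)


@dataclass
class Structure:
    """An ordered collection of atoms from one coordinate file."""

    atoms: list[Atom] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def models(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.model_index, None)
        return list(seen)

    def model(self, model_index: int | None = None) -> "Structure":
        """Atoms of one model (default: the first model present)."""
        if model_index is None:
            model_index = self.models[0] if self.atoms else 1
        return Structure(
            atoms=[a for a in self.atoms if a.model_index == model_index],
            metadata=dict(self.metadata),
        )

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self):
        """Iterate residues as (key, [atoms]) preserving source order."""
        order: list = []
        groups: dict = {}
        for a in self.atoms:
            k = a.residue_key()
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(a)
        for k in order:
            yield k, groups[k]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with every position mapped to ``R @ x + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(atoms=new_atoms, metadata=dict(self.metadata))

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------

class _Node:
    def matches(self, atom: Atom) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError


class _And(_Node):
    def __init__(self, parts):
        self.parts = parts

    def matches(self, atom):
        return all(p.matches(atom) for p in self.parts)


class _Or(_Node):
    def __init__(self, parts):
        self.parts = parts

    def matches(self, atom):
        return any(p.matches(atom) for p in self.parts)


class _Not(_Node):
    def __init__(self, inner):
        self.inner = inner

    def matches(self, atom):
        return not self.inner.matches(atom)


class _Pred(_Node):
    def __init__(self, fn):
        self.fn = fn

    def matches(self, atom):
        return self.fn(atom)


_KEYWORDS = {"and", "or", "not", "(", ")", "chain", "resname", "resnum",
             "name", "element", "hetero", "protein", "all", "none"}


def _tokenize(text: str):
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(text) and not text[j].isspace() and text[j] not in "()":
            j += 1
        tokens.append((text[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for the selection grammar."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, message):
        position = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.text)
        raise SelectionSyntaxError(f"{message} (at position {position} in {self.text!r})", position)

    def parse(self) -> _Node:
        if not self.tokens:
            self.fail("empty selection expression")
        node = self.parse_or()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        parts = [self.parse_and()]
        while self.peek() == "or":
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else _Or(parts)

    def parse_and(self):
        parts = [self.parse_term()]
        while self.peek() == "and":
            self.take()
            parts.append(self.parse_term())
        return parts[0] if len(parts) == 1 else _And(parts)

    def parse_term(self):
        tok = self.peek()
        if tok is None:
            self.fail("expected a term")
        if tok == "not":
            self.take()
            return _Not(self.parse_term())
        if tok == "(":
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.take()
            return node
        return self.parse_primary()

    def _values(self):
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take()[0])
        if not vals:
            self.fail("keyword needs at least one value")
        return vals

    def parse_primary(self):
        tok, _ = self.take()
        if tok == "chain":
            wanted = set(self._values())
            return _Pred(lambda a: a.chain_id in wanted)
        if tok == "resname":
            wanted = {v.upper() for v in self._values()}
            return _Pred(lambda a: a.residue_name.upper() in wanted)
        if tok == "name":
            wanted = {v.upper() for v in self._values()}
            return _Pred(lambda a: a.atom_name.upper() in wanted)
        if tok == "element":
            wanted = {v.upper() for v in self._values()}
            return _Pred(lambda a: a.element.upper() in wanted)
        if tok == "resnum":
            ranges = []
            for v in self._values():
                try:
                    if "-" in v[1:]:
                        lo, hi = v.split("-", 1) if not v.startswith("-") else (v, v)
                        ranges.append((int(lo), int(hi)))
                    else:
                        ranges.append((int(v), int(v)))
                except ValueError:
                    self.fail(f"bad residue-number range {v!r}")
            return _Pred(lambda a: any(lo <= a.residue_number <= hi for lo, hi in ranges))
        if tok == "hetero":
            return _Pred(lambda a: a.is_hetero)
        if tok == "protein":
            return _Pred(lambda a: not a.is_hetero)
        if tok == "all":
            return _Pred(lambda a: True)
        if tok == "none":
            return _Pred(lambda a: False)
        self.pos -= 1
        self.fail(f"unknown keyword {tok!r}")


class Selection:
    """A parsed, reusable atom predicate.  Applying it twice is idempotent."""

    def __init__(self, expression: str):
        self.expression = expression
        self._root = _Parser(expression).parse()

    def matches(self, atom: Atom) -> bool:
        return self._root.matches(atom)

    def __repr__(self):
        return f"Selection({self.expression!r})"


def select(structure: Structure, expression: str | Selection,
           model_index: int | None = None) -> list[Atom]:
    """Atoms satisfying ``expression``, in source order.

    By default all models are searched; pass ``model_index`` to restrict.
    """
    sel = expression if isinstance(expression, Selection) else Selection(expression)
    atoms = structure.atoms
    if model_index is not None:
        atoms = [a for a in atoms if a.model_index == model_index]
    return [a for a in atoms if sel.matches(a)]


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip().upper()
    for prefix in (name[:2], name[:1]):
        if prefix in _ELEMENT_FALLBACK:
            return _ELEMENT_FALLBACK[prefix]
    stripped = name.lstrip("0123456789")
    return stripped[:1] if stripped else "X"


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom name; ties prefer altloc 'A'."""
    best: dict = {}
    order: list = []
    for a in atoms:
        key = (a.model_index, a.chain_id, a.residue_number, a.insertion_code,
               a.residue_name, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, a.altloc == "A", -ord(a.altloc or "~")) > \
               (b.occupancy, b.altloc == "A", -ord(b.altloc or "~")):
                best[key] = a
    return [best[k] for k in order]


def _guess_format(path: str) -> str:
    lower = path.lower()
    for ext in (".cif", ".mmcif", ".cif.gz"):
        if lower.endswith(ext):
            return "mmcif"
    for ext in (".pdb", ".ent", ".pdb.gz", ".ent.gz"):
        if lower.endswith(ext):
            return "pdb"
    # peek at content: mmCIF files start with data_ blocks
    try:
        with open(path, "r", errors="ignore") as fh:
            head = fh.read(4096)
    except OSError:
        return "pdb"
    return "mmcif" if "data_" in head.split("\n")[0] or "_atom_site." in head else "pdb"


def read_structure(path: str | os.PathLike, format: str = "auto",
                   keep_altlocs: bool = False) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    All models and all ATOM/HETATM records are captured; elements are inferred
    from atom names when the element column is blank.  Alternative locations
    are collapsed to one atom per name unless ``keep_altlocs`` is set.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = _guess_format(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(path)
        elif format == "mmcif":
            doc = gemmi.cif.read(path)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise FormatError(f"unknown format {format!r}: expected pdb, mmcif or auto")
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with context
        raise StructureParseError(f"failed to parse {path} as {format}: {exc}") from exc

    atoms: list[Atom] = []
    for i_model, model in enumerate(st, start=1):
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for at in residue:
                    element = at.element.name.upper() if at.element and \
                        at.element.name.upper() != "X" else ""
                    if not element:
                        element = _infer_element(at.name)
                    atoms.append(Atom(
                        element=element,
                        atom_name=at.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0) if at.occ is not None else 1.0,
                        altloc=(at.altloc or "").strip(),
                        model_index=i_model,
                        is_hetero=het,
                    ))
    if not keep_altlocs:
        atoms = _dedupe_altlocs(atoms)
    meta = {"source_path": path, "format": format, "title": st.name}
    return Structure(atoms=atoms, metadata=meta)


def _to_gemmi(structure: Structure, format: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(structure.metadata.get("title", "cofnet"))
    for model_index in (structure.models or [1]):
        model = gemmi.Model(model_index)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict = {}
        for a in structure.atoms:
            if a.model_index != model_index:
                continue
            if format == "pdb" and len(a.chain_id) > 2:
                raise FormatCapacityError(
                    f"chain id {a.chain_id!r} does not fit PDB fixed columns; write mmCIF instead")
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
            rkey = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            if rkey not in residues:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chains[a.chain_id].add_residue(res)
                residues[rkey] = chains[a.chain_id][-1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element.capitalize())
            at.pos = gemmi.Position(*a.position)
            at.occ = a.occupancy
            at.altloc = a.altloc or "\0"
            residues[rkey].add_atom(at)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | os.PathLike,
                    format: str = "auto") -> None:
    """Write a :class:`Structure` as PDB or mmCIF.

    The emitted file re-parses to an equal structure (coordinates at the
    format's precision: 3 decimals for PDB).
    """
    path = os.fspath(path)
    if format == "auto":
        format = _guess_format(path) if "." in os.path.basename(path) else "pdb"
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r}: expected pdb or mmcif")
    st = _to_gemmi(structure, format)
    if format == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)
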