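"""Conformational-state comparison: superposition, domain rotations, gating.

States of the same complex (e.g. the flavin-free apo, "bifurcation-ready" BR
and "post-bifurcation" PB conformations of the bifurcating hydrogenase) are
compared in three ways:

* least-squares (Kabsch) superposition over paired atoms;
* rigid-body rotation of a mobile domain after superposing on a fixed core,
  reported as an angle/axis (the HydC C-terminal domain swings ~24 degrees
  between the BR and PB states);
* per-cofactor-pair edge-distance deltas with a flag marking pairs that cross
  the electron-transfer threshold tau in exactly one state (distance gating).

Atom pairing is by (chain, residue number, atom name) identity: states are
models of the same molecule, so no sequence alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cofactors import Cofactor
from .errors import DegenerateGeometryError, PairingError
from .network import DEFAULT_TAU, edge_distance
from .structure_io import Selection, Structure, select


@dataclass
class Superposition:
    """Optimal rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def transform(self, structure: Structure) -> Structure:
        return structure.transformed(self.rotation, self.translation)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares proper rotation + translation (SVD; det +1 enforced).

    Raises :class:`DegenerateGeometryError` for < 3 pairs or collinear input.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape:
        raise PairingError(f"coordinate sets differ in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 atom pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    scale = float(S[0]) if S[0] > 0 else 1.0
    if S[1] / scale < 1e-8:
        raise DegenerateGeometryError("atom positions are collinear; rotation is underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _paired_coords(mobile: Structure, reference: Structure,
                   selection, mobile_selection=None):
    sel_ref = selection if isinstance(selection, Selection) else Selection(selection)
    sel_mob = mobile_selection or sel_ref
    if not isinstance(sel_mob, Selection):
        sel_mob = Selection(sel_mob)
    ref_atoms = {(a.chain_id, a.residue_number, a.insertion_code, a.atom_name): a
                 for a in select(reference, sel_ref)}
    mob_atoms = {(a.chain_id, a.residue_number, a.insertion_code, a.atom_name): a
                 for a in select(mobile, sel_mob)}
    common = [k for k in ref_atoms if k in mob_atoms]
    if not common or len(common) != len(ref_atoms) or len(common) != len(mob_atoms):
        raise PairingError(
            f"atom pairing mismatch: {len(mob_atoms)} mobile vs {len(ref_atoms)} "
            f"reference atoms, {len(common)} shared identities")
    common.sort()
    P = np.array([mob_atoms[k].position for k in common])
    Q = np.array([ref_atoms[k].position for k in common])
    return P, Q


def superpose(mobile: Structure, reference: Structure,
              selection="all", mobile_selection=None) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` over a selection.

    Atoms are paired by (chain, residue number, insertion code, atom name);
    a mismatch in the paired sets raises :class:`PairingError`.
    """
    P, Q = _paired_coords(mobile, reference, selection, mobile_selection)
    return kabsch(P, Q)


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, in [0, 180]) and unit axis of a proper rotation."""
    tr = float(np.trace(R))
    angle = float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
    # axis from the antisymmetric part; near 180 degrees fall back to eigenvector
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(w)
    if norm > 1e-8:
        axis = w / norm
    else:
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


@dataclass
class DomainMotion:
    """Rigid-body motion of a domain between two states of a complex."""

    angle: float                     # degrees, [0, 180]
    axis: np.ndarray                 # unit 3-vector (line of the screw axis)
    translation_along_axis: float    # Å, >= 0 by axis-sign convention
    core_rmsd: float
    domain_rmsd_before: float

    def to_dict(self) -> dict:
        return {"angle_deg": round(self.angle, 3),
                "axis": [round(float(x), 6) for x in self.axis],
                "translation_along_axis": round(self.translation_along_axis, 3),
                "core_rmsd": round(self.core_rmsd, 4)}


def domain_rotation(state_a: Structure, state_b: Structure,
                    core, domain) -> DomainMotion:
    """Rotation of ``domain`` between two states after superposing on ``core``.

    State B is first superposed onto state A over the core selection; the
    residual rigid transform of the domain selection is then extracted and its
    angle computed from the rotation-matrix trace.  The reported axis denotes
    the rotation line with its sign chosen so the translation component along
    it is non-negative.
    """
    sup_core = superpose(state_b, state_a, core)
    b_aligned = sup_core.transform(state_b)
    P, Q = _paired_coords(b_aligned, state_a, domain)
    before = float(np.sqrt(((P - Q) ** 2).sum() / len(P)))
    sup_dom = kabsch(P, Q)
    angle, axis = rotation_angle_axis(sup_dom.rotation)
    t_axis = float(np.dot(axis, sup_dom.translation))
    if t_axis < 0:
        axis, t_axis = -axis, -t_axis
    return DomainMotion(angle=angle, axis=axis, translation_along_axis=t_axis,
                        core_rmsd=sup_core.rmsd, domain_rmsd_before=before)


@dataclass
class ComparisonRow:
    label_a: str
    label_b: str
    distance_state_a: float
    distance_state_b: float
    crossed_threshold: bool

    @property
    def delta(self) -> float:
        return self.distance_state_b - self.distance_state_a


@dataclass
class StateComparison:
    """Per-pair edge distances in two states with threshold-crossing flags."""

    state_a: str
    state_b: str
    tau: float
    rows: list[ComparisonRow]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "pair": f"{r.label_a}-{r.label_b}",
            f"d_{self.state_a}": round(r.distance_state_a, 1),
            f"d_{self.state_b}": round(r.distance_state_b, 1),
            "delta": round(r.delta, 1),
            "crossed_threshold": r.crossed_threshold,
        } for r in self.rows])


def compare_states(cofactors_a: list[Cofactor], cofactors_b: list[Cofactor],
                   pairs, tau: float = DEFAULT_TAU,
                   state_names: tuple[str, str] = ("A", "B")) -> StateComparison:
    """Edge distances of selected label pairs in two states.

    ``crossed_threshold`` is true iff the pair is within tau in exactly one
    state — the signature of a conformational gate.  Swapping the states
    negates every delta.
    """
    by_label_a = {c.label: c for c in cofactors_a}
    by_label_b = {c.label: c for c in cofactors_b}
    rows = []
    for la, lb in pairs:
        for label in (la, lb):
            if label not in by_label_a:
                raise KeyError(f"label {label!r} missing from state {state_names[0]!r}")
            if label not in by_label_b:
                raise KeyError(f"label {label!r} missing from state {state_names[1]!r}")
        da, _ = edge_distance(by_label_a[la], by_label_a[lb])
        db, _ = edge_distance(by_label_b[la], by_label_b[lb])
        rows.append(ComparisonRow(la, lb, da, db,
                                  crossed_threshold=(da <= tau) != (db <= tau)))
    return StateComparison(state_a=state_names[0], state_b=state_names[1],
                           tau=tau, rows=rows)
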