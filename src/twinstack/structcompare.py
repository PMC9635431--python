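"""Structure reading, Kabsch superposition and NCS/twin-axis comparison.

The twinned CD9 crystal carries a non-crystallographic twofold that
relates the chains of the asymmetric unit and co-aligns with the twin
axis a*+b* — the geometric reason a twin interface can form at all.
This module reads PDB/mmCIF coordinates (through gemmi), superposes
chains by single-pass least squares (Kabsch, proper rotation enforced),
decomposes the rotation to axis/angle, and measures the angle between
an NCS axis and a stated lattice direction.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cellgeom import Basis, UnitCell

__all__ = [
    "ChainModel",
    "SuperpositionResult",
    "read_structure",
    "kabsch_superpose",
    "ncs_vs_twin_axis",
]

SELECTIONS = ("ca", "backbone", "heavy")
_BACKBONE = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class ChainModel:
    """Atoms of one chain in file order."""

    chain_id: str
    residue_numbers: np.ndarray  # (n,)
    atom_names: tuple
    elements: tuple
    positions: np.ndarray  # (n, 3) Cartesian A
    occupancies: np.ndarray
    b_factors: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_names)


def _chain_from_gemmi(chain) -> ChainModel:
    resnums, names, elements, pos, occ, b = [], [], [], [], [], []
    for res in chain:
        # keep one atom per name: highest occupancy, ties by altloc letter
        best: dict[str, object] = {}
        for atom in res:
            cur = best.get(atom.name)
            if cur is None or (atom.occ, -ord(atom.altloc or "~")) > (
                cur.occ, -ord(cur.altloc or "~")
            ):
                best[atom.name] = atom
        for name in best:
            atom = best[name]
            resnums.append(res.seqid.num)
            names.append(atom.name)
            elements.append(atom.element.name)
            pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
            occ.append(atom.occ)
            b.append(atom.b_iso)
    positions = np.asarray(pos, float)
    if positions.size and not np.isfinite(positions).all():
        raise ValueError(f"chain {chain.name}: non-finite atom coordinates")
    return ChainModel(
        chain_id=chain.name,
        residue_numbers=np.asarray(resnums, int),
        atom_names=tuple(names),
        elements=tuple(elements),
        positions=positions,
        occupancies=np.asarray(occ, float),
        b_factors=np.asarray(b, float),
    )


def read_structure(path) -> tuple[dict[str, ChainModel], UnitCell | None]:
    """Read a PDB or mmCIF file from local disk.

    Returns chains keyed by id (first model) and the unit cell from the
    file's cell record, or None when the record is absent or degenerate
    (the structure still loads).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains = {ch.name: _chain_from_gemmi(ch) for ch in st[0]}
    cell = None
    c = st.cell
    if c and c.volume > 1.0 and not (c.a == 1 and c.b == 1 and c.c == 1):
        cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return chains, cell


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body superposition: x_fixed ~ rotation @ x_moving + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    axis: np.ndarray  # unit rotation axis
    angle: float  # degrees
    selection: str
    warnings: tuple = ()


def _select_pairs(moving: ChainModel, fixed: ChainModel, selection: str):
    if selection not in SELECTIONS:
        raise ValueError(f"selection must be one of {SELECTIONS}")

    def keep(name: str, element: str) -> bool:
        if selection == "ca":
            return name == "CA"
        if selection == "backbone":
            return name in _BACKBONE
        return element != "H"

    def index(ch: ChainModel):
        return {
            (int(r), n): i
            for i, (r, n, e) in enumerate(
                zip(ch.residue_numbers, ch.atom_names, ch.elements)
            )
            if keep(n, e)
        }

    mi, fi = index(moving), index(fixed)
    common = sorted(set(mi) & set(fi))
    return (
        moving.positions[[mi[k] for k in common]],
        fixed.positions[[fi[k] for k in common]],
    )


def kabsch_superpose(
    moving: ChainModel, fixed: ChainModel, selection: str = "ca"
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Atoms are paired by (residue number, atom name) within the selection
    (default alpha-carbons); a proper rotation (det +1) is enforced, with
    no outlier rejection — flexible loops stay in unless the selection
    excludes them.
    """
    P, Q = _select_pairs(moving, fixed, selection)
    if len(P) < 3:
        raise ValueError(
            f"superposition needs >= 3 paired atoms, got {len(P)} "
            f"(selection {selection!r})"
        )
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    axis = rotvec / np.linalg.norm(rotvec) if np.linalg.norm(rotvec) > 0 else np.array([0.0, 0.0, 1.0])
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_atoms=len(P),
        axis=axis,
        angle=angle,
        selection=selection,
    )


def ncs_vs_twin_axis(result: SuperpositionResult, basis: Basis, axis_spec) -> float:
    """Angle (degrees) between an NCS rotation axis and a lattice direction.

    ``axis_spec`` is ``(kind, indices)`` with kind 'direct' or
    'reciprocal' — e.g. ('reciprocal', (1, 1, 0)) for the a*+b* twin
    axis.  Sign-agnostic (minimum over +/- axis).  A warning is attached
    via the warnings module when the superposition is not close to a
    twofold (angle further than 15 degrees from 180).
    """
    kind, indices = axis_spec
    idx = np.asarray(indices, float)
    v = basis.direct @ idx if kind == "direct" else basis.reciprocal @ idx
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("lattice axis has zero length")
    if abs(result.angle - 180.0) > 15.0:
        _warnings.warn(
            f"superposition rotation is {result.angle:.1f} deg, not close to a "
            "twofold; axis comparison may be meaningless",
            stacklevel=2,
        )
    cosang = min(1.0, abs(float(result.axis @ (v / n))))
    return float(np.degrees(np.arccos(cosang)))
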