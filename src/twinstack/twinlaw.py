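"""Twin-law construction, coincidence sublattices and overlap prediction.

A non-merohedral twin law is a rotation relating the lattices of two
domains.  Its action on reflection indices, Q = B^-1 R B (B the
reciprocal basis, R the Cartesian rotation), is in general irrational;
for a genuine twin it is close to a rational matrix.  Clearing the
denominators of the rationalized Q and reducing exposes the
*coincidence sublattice* — the set of reflections on which the two twin
lattices overlap exactly — whose index in the full lattice is the twin
(coincidence) index.  For the CD9 EC2 crystal the twofold about
(1,1,0)* gives index 4 with the congruence l = 0 (mod 4): only every
fourth reciprocal-space layer carries exactly superimposed spots.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .cellgeom import Basis, UnitCell, build_basis, enumerate_hkl

__all__ = [
    "TwinOperation",
    "CoincidenceResult",
    "SupercellSpec",
    "OverlapReport",
    "make_twin_op",
    "search_twin_laws",
    "coincidence_sublattice",
    "idealize_cell",
    "supercell_transform",
    "predict_overlap",
    "rotation_about",
    "rationalize_matrix",
]


class IrrationalTwinError(ValueError):
    """Raised when a sublattice operation is asked of a twin law whose
    index action could not be rationalized."""


def rotation_about(axis_cart: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about a Cartesian axis (Rodrigues)."""
    v = np.asarray(axis_cart, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("rotation axis has zero length")
    k = v / n
    t = math.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def _rationalize_entry(x: float, max_den: int, tol: float) -> Fraction | None:
    """Smallest-denominator fraction within ``tol`` of ``x``, or None.

    Taking the *smallest* admissible denominator (rather than the best
    approximation under the bound) is what lets a pseudo-symmetric twin
    misfit of a few 1e-2 snap to the intended low-denominator matrix
    instead of a spurious high-denominator one.
    """
    for den in range(1, max_den + 1):
        num = round(x * den)
        if abs(x - num / den) <= tol:
            return Fraction(num, den)
    return None


def rationalize_matrix(M: np.ndarray, max_den: int = 24, tol: float = 0.05):
    """Rationalize a matrix entrywise; returns a 3x3 list of Fractions or
    None if any entry has no admissible fraction."""
    out = []
    for row in np.asarray(M, dtype=float):
        frow = []
        for x in row:
            f = _rationalize_entry(float(x), max_den, tol)
            if f is None:
                return None
            frow.append(f)
        out.append(frow)
    return out


def _frac_matrix_to_float(Q) -> np.ndarray:
    return np.array([[float(x) for x in row] for row in Q])


@dataclass(frozen=True)
class TwinOperation:
    """A candidate twin law.

    ``Q_num`` is the floating-point conjugation of the rotation into the
    reflection-index frame; ``Q_rat`` its rationalization (None if no
    rational matrix exists within the configured tolerance — such an
    operation is refused by sublattice algebra).  ``misfit`` is the
    largest |Q_num - Q_rat| entry, a measure of how pseudo-symmetric the
    cell is under the law.  ``obliquity`` is the classical angular
    misfit between the twin axis and the nearest low-index lattice
    direction of the complementary kind.
    """

    basis: Basis = field(repr=False)
    axis_kind: str
    axis: tuple[int, int, int]
    angle: float
    R_cart: np.ndarray = field(repr=False)
    Q_num: np.ndarray = field(repr=False)
    Q_rat: tuple | None
    misfit: float
    obliquity: float
    nearest_complement: tuple[int, int, int]

    @property
    def rational(self) -> bool:
        return self.Q_rat is not None

    def q_rat_array(self) -> np.ndarray:
        if self.Q_rat is None:
            raise IrrationalTwinError(
                f"twin law about {self.axis_kind} {self.axis} has no rational "
                "index action within tolerance; raise max_den/tol or idealize"
            )
        return _frac_matrix_to_float(self.Q_rat)

    def apply_rational(self, hkl) -> tuple[Fraction, Fraction, Fraction]:
        """Exact rational image of an integer reflection under the law."""
        Q = self.Q_rat
        if Q is None:
            raise IrrationalTwinError("irrational twin law")
        h = tuple(int(v) for v in hkl)
        return tuple(sum(Q[i][j] * h[j] for j in range(3)) for i in range(3))


def _axis_cart(basis: Basis, axis_kind: str, indices) -> np.ndarray:
    idx = np.asarray(indices, dtype=float)
    if axis_kind == "direct":
        return basis.direct @ idx
    if axis_kind == "reciprocal":
        return basis.reciprocal @ idx
    raise ValueError(f"axis_kind must be 'direct' or 'reciprocal', got {axis_kind!r}")


def _complement_directions(max_index: int):
    seen = set()
    for uvw in itertools.product(range(-max_index, max_index + 1), repeat=3):
        if uvw == (0, 0, 0):
            continue
        g = math.gcd(math.gcd(abs(uvw[0]), abs(uvw[1])), abs(uvw[2]))
        red = tuple(v // g for v in uvw)
        if red in seen or tuple(-v for v in red) in seen:
            continue
        seen.add(red)
        yield red


def _obliquity(basis: Basis, axis_kind: str, axis_cart: np.ndarray,
               search_bound: int = 4) -> tuple[float, tuple[int, int, int]]:
    """Angle between the twin axis and the nearest low-index direction of
    the complementary kind (direct axis <-> reciprocal row and vice versa)."""
    other = "reciprocal" if axis_kind == "direct" else "direct"
    n = axis_cart / np.linalg.norm(axis_cart)
    best = (180.0, (0, 0, 0))
    for idx in _complement_directions(search_bound):
        v = _axis_cart(basis, other, idx)
        cosang = min(1.0, abs(float(v @ n)) / np.linalg.norm(v))
        ang = math.degrees(math.acos(cosang))
        if ang < best[0]:
            best = (ang, idx)
    return best


def make_twin_op(
    basis: Basis,
    axis_kind: str,
    axis_indices,
    angle: float,
    max_den: int = 24,
    rat_tol: float = 0.05,
    obliquity_search_bound: int = 4,
) -> TwinOperation:
    """Build the twin operation about a direct [uvw] or reciprocal (hkl)* axis.

    ``angle`` in degrees, in (0, 360].  The index action Q is the
    conjugation of the Cartesian rotation into the hkl frame and is
    rationalized by smallest-denominator rounding (bound ``max_den``,
    absolute tolerance ``rat_tol``); failure leaves ``Q_rat`` as None.
    """
    axis_indices = tuple(int(v) for v in axis_indices)
    if axis_indices == (0, 0, 0):
        raise ValueError("twin axis indices must not all be zero")
    if not 0.0 < angle <= 360.0:
        raise ValueError("twin rotation angle must lie in (0, 360] degrees")
    v = _axis_cart(basis, axis_kind, axis_indices)
    if np.linalg.norm(v) == 0:
        raise ValueError("twin axis has zero Cartesian length")
    R = rotation_about(v, angle)
    B = basis.reciprocal
    Q_num = np.linalg.inv(B) @ R @ B
    Q_rat = rationalize_matrix(Q_num, max_den=max_den, tol=rat_tol)
    misfit = (
        float(np.abs(Q_num - _frac_matrix_to_float(Q_rat)).max())
        if Q_rat is not None
        else math.inf
    )
    obl, nearest = _obliquity(basis, axis_kind, v, obliquity_search_bound)
    return TwinOperation(
        basis=basis,
        axis_kind=axis_kind,
        axis=axis_indices,
        angle=float(angle),
        R_cart=R,
        Q_num=Q_num,
        Q_rat=tuple(tuple(row) for row in Q_rat) if Q_rat is not None else None,
        misfit=misfit,
        obliquity=obl,
        nearest_complement=nearest,
    )


def search_twin_laws(
    basis: Basis,
    max_index: int = 2,
    angles=(180.0,),
    obliquity_max: float = 5.0,
    **op_kwargs,
) -> list[TwinOperation]:
    """Enumerate candidate twin laws about low-index axes of both kinds.

    All direct [uvw] and reciprocal (hkl)* axes with |indices| <=
    ``max_index`` (gcd-reduced, +/-v identified) are tried for each angle;
    operations with obliquity <= ``obliquity_max`` are returned,
    deduplicated by their Cartesian rotation and sorted by obliquity.
    """
    if max_index < 1:
        raise ValueError("max_index must be >= 1")
    allowed = {60.0, 90.0, 120.0, 180.0}
    if not set(float(a) for a in angles) <= allowed:
        raise ValueError(f"angles must be a subset of {sorted(allowed)}")
    ops: list[TwinOperation] = []
    seen_R: list[np.ndarray] = []
    for kind in ("direct", "reciprocal"):
        for idx in _complement_directions(max_index):
            if max(abs(v) for v in idx) > max_index:
                continue
            for angle in angles:
                op = make_twin_op(basis, kind, idx, float(angle), **op_kwargs)
                if op.obliquity > obliquity_max:
                    continue
                if any(np.abs(op.R_cart - S).max() < 1e-8 for S in seen_R):
                    continue
                seen_R.append(op.R_cart)
                ops.append(op)
    ops.sort(key=lambda o: (o.obliquity, o.axis_kind, o.axis))
    return ops


# ---------------------------------------------------------------------------
# integer lattice algebra


def _hnf_columns(M: np.ndarray) -> np.ndarray:
    """Column-style Hermite normal form of an integer matrix of full row
    rank 3: returns a lower-triangular 3x3 basis with positive diagonal
    and reduced off-diagonal entries, generating the column lattice."""
    A = [[int(x) for x in row] for row in np.asarray(M)]
    rows, cols = len(A), len(A[0])
    # work with Python ints for exactness
    col = 0
    for r in range(rows):
        # find pivot: eliminate across columns col..end in row r via gcd steps
        while True:
            nz = [j for j in range(col + 1, cols) if A[r][j] != 0]
            if A[r][col] == 0:
                pick = next((j for j in range(col, cols) if A[r][j] != 0), None)
                if pick is None:
                    raise ValueError("matrix does not have full row rank")
                for i in range(rows):
                    A[i][col], A[i][pick] = A[i][pick], A[i][col]
                continue
            if not nz:
                break
            j = nz[0]
            q = A[r][j] // A[r][col]
            for i in range(rows):
                A[i][j] -= q * A[i][col]
            if A[r][j] != 0:
                for i in range(rows):
                    A[i][col], A[i][j] = A[i][j], A[i][col]
        if A[r][col] < 0:
            for i in range(rows):
                A[i][col] = -A[i][col]
        col += 1
    H = [[A[i][j] for j in range(3)] for i in range(3)]
    # reduce entries left of each pivot
    for r in range(3):
        for j in range(r):
            if H[r][r] != 0:
                q = H[r][j] // H[r][r]
                for i in range(3):
                    H[i][j] -= q * H[i][r]
    return np.array(H, dtype=np.int64)


@dataclass(frozen=True)
class CoincidenceResult:
    """Exact-coincidence sublattice of a rational twin law."""

    sublattice_basis: np.ndarray  # integer columns generating the sublattice
    index: int
    layer_rule: str | None

    def contains(self, op: TwinOperation, hkl) -> bool:
        return all(f.denominator == 1 for f in op.apply_rational(hkl))


def coincidence_sublattice(op: TwinOperation) -> CoincidenceResult:
    """Sublattice {h integer : Q h integer} for a rational twin law.

    Computed exactly: the dual of the sum lattice Z^3 + Q^T Z^3, obtained
    by integer Hermite reduction after clearing denominators.  The index
    equals |det| of the reduced basis; when the sublattice is exactly
    {h : l = 0 (mod n)} (or the analogous rule on h or k) the congruence
    is reported as ``layer_rule``.
    """
    if op.Q_rat is None:
        raise IrrationalTwinError(
            "coincidence sublattice requires a rational twin-law action"
        )
    Q = op.Q_rat
    d = 1
    for row in Q:
        for x in row:
            d = d * x.denominator // math.gcd(d, x.denominator)
    # L = Z^3 ∩ Q^-1 Z^3 ;  L* = Z^3 + Q^T Z^3 = (1/d) * colspace([d I | d Q^T])
    dQt = np.array([[int(Q[j][i] * d) for j in range(3)] for i in range(3)], dtype=object)
    stack = np.hstack([d * np.eye(3, dtype=np.int64), np.asarray(dQt, dtype=np.int64)])
    H = _hnf_columns(stack)  # L* = (1/d) H Z^3
    # L = dual(L*) = d * H^-T Z^3 (integer by construction)
    Hinv = np.linalg.inv(H.astype(float))
    Bsub = d * Hinv.T
    Bsub_int = np.rint(Bsub).astype(np.int64)
    if np.abs(Bsub - Bsub_int).max() > 1e-9:
        raise RuntimeError("coincidence basis failed to be integral")
    Bsub_int = _hnf_columns(Bsub_int)
    index = int(round(abs(np.linalg.det(Bsub_int.astype(float)))))
    layer_rule = _layer_rule(op, Bsub_int, index)
    return CoincidenceResult(sublattice_basis=Bsub_int, index=index, layer_rule=layer_rule)


def _members(op: TwinOperation, hkl) -> bool:
    return all(f.denominator == 1 for f in op.apply_rational(hkl))


def _layer_rule(op: TwinOperation, Bsub: np.ndarray, index: int) -> str | None:
    if index == 1:
        return "all reflections coincide"
    names = "hkl"
    for axis in (2, 1, 0):  # prefer the l-rule the stacking literature quotes
        others = [i for i in range(3) if i != axis]
        e = [np.eye(3, dtype=int)[i] for i in range(3)]
        if all(_members(op, e[i]) for i in others) and _members(op, index * e[axis]):
            # sublattice {h : index | h_axis} has the right index and contains
            # the generators we just checked, hence equals the coincidence lattice
            return f"{names[axis]} ≡ 0 (mod {index})"
    return None


@dataclass(frozen=True)
class SupercellSpec:
    M: np.ndarray
    supercell: UnitCell
    volume_ratio: int


def supercell_transform(cell: UnitCell, M) -> SupercellSpec:
    """Supercell built by an integer matrix acting row-wise on (a, b, c).

    Row i of M gives supercell vector i as an integer combination of the
    parent cell vectors; the volume ratio is |det M|.
    """
    M = np.asarray(M, dtype=int)
    det = int(round(np.linalg.det(M.astype(float))))
    if det == 0:
        raise ValueError("supercell transformation matrix is singular")
    G = cell.metric_tensor()
    Gs = M @ G @ M.T
    return SupercellSpec(M=M, supercell=UnitCell.from_metric(Gs), volume_ratio=abs(det))


def supercell_indexes_both_lattices(op: TwinOperation, M) -> bool:
    """True when reflections of both twin lattices take integer indices on
    the supercell reciprocal lattice, i.e. M and M.Q are integer matrices."""
    M = np.asarray(M, dtype=int)
    if op.Q_rat is None:
        raise IrrationalTwinError("irrational twin law")
    for i in range(3):
        for j in range(3):
            s = sum(Fraction(int(M[i][k])) * op.Q_rat[k][j] for k in range(3))
            if s.denominator != 1:
                return False
    return True


def idealize_cell(op: TwinOperation) -> tuple[UnitCell, Basis, TwinOperation]:
    """Project the cell onto the nearest cell for which the twin law is exact.

    The reciprocal metric is averaged over the two-element group {I, Q}
    generated by the rationalized index action — the least-squares
    symmetrization under the law.  Returns the idealized cell, its basis
    and the twin operation rebuilt on it (whose numeric action now equals
    the rational one to machine precision).
    """
    Qf = op.q_rat_array()
    B = op.basis.reciprocal
    Gstar = B.T @ B
    Gstar_id = (Gstar + Qf.T @ Gstar @ Qf) / 2.0
    G_id = np.linalg.inv(Gstar_id)
    cell_id = UnitCell.from_metric(G_id)
    basis_id = build_basis(cell_id)
    op_id = make_twin_op(basis_id, op.axis_kind, op.axis, op.angle)
    if op_id.Q_rat is None or np.abs(op_id.Q_num - op_id.q_rat_array()).max() > 1e-6:
        raise RuntimeError("idealization failed to make the twin law exact")
    return cell_id, basis_id, op_id


@dataclass(frozen=True)
class OverlapReport:
    """Per-reflection twin-spot separations and overlap classification."""

    records: pd.DataFrame = field(repr=False)
    overlap_fraction: float
    tolerance: float
    group_stats: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def predict_overlap(
    basis: Basis,
    op: TwinOperation,
    dmin: float,
    tolerance: float = 0.002,
) -> OverlapReport:
    """Predicted spot separations between the two twin lattices.

    For every reflection of lattice 1 to ``dmin`` the separation is the
    Cartesian distance (1/Angstrom) to the nearest lattice-2 node; a
    reflection is *overlapping* when that distance is below ``tolerance``
    (default 0.002 1/A, about one detector spot width).  Separations of
    exact-coincidence reflections are established in rational arithmetic
    and reported as exactly zero.  Statistics are grouped by l modulo the
    coincidence index when the law is rational.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    hkl = enumerate_hkl(basis, dmin)
    B = basis.reciprocal
    Qn = op.Q_num
    # nearest lattice-2 node: lattice 2 = B Q Z^3; candidate h' near Q^-1 h
    target = np.linalg.solve(Qn, hkl.T).T
    base = np.rint(target).astype(np.int64)
    offsets = np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    sep = np.full(len(hkl), np.inf)
    for off in offsets:
        h2 = base + off
        diff = (hkl - h2 @ Qn.T) @ B.T
        sep = np.minimum(sep, np.linalg.norm(diff, axis=1))
    index = None
    if op.Q_rat is not None:
        index = coincidence_sublattice(op).index
        if op.misfit < 1e-9:
            # the law is exact on this cell: establish coincidences in integer
            # arithmetic (N h = 0 mod d) and report their separation as 0
            d = 1
            for row in op.Q_rat:
                for x in row:
                    d = d * x.denominator // math.gcd(d, x.denominator)
            N = np.array([[int(x * d) for x in row] for row in op.Q_rat], dtype=np.int64)
            exact = ((hkl @ N.T) % d == 0).all(axis=1)
            sep = np.where(exact, 0.0, sep)
    df = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "separation": sep,
            "overlapping": sep < tolerance,
        }
    )
    if index is not None and index > 1:
        df["l_mod"] = np.mod(df["l"], index)
        group_stats = (
            df.groupby("l_mod")["separation"].agg(["count", "mean", "max"]).reset_index()
        )
    else:
        group_stats = pd.DataFrame(
            {"l_mod": [0], "count": [len(df)], "mean": [df["separation"].mean()],
             "max": [df["separation"].max()]}
        )
    return OverlapReport(
        records=df,
        overlap_fraction=float(df["overlapping"].mean()),
        tolerance=tolerance,
        group_stats=group_stats,
    )
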