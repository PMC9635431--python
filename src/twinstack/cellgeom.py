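"""Triclinic unit-cell algebra.

Direct and reciprocal bases, metric tensors, d-spacings and reflection
enumeration for a P1 cell.  Conventions:

* reciprocal basis WITHOUT the 2*pi factor, so d = 1/|q|;
* cell orientation: **a** along Cartesian x, **b** in the xy plane;
* angles are degrees at every interface, radians only internally.

All twin-law and stacking-disorder geometry in the package flows through
the :class:`Basis` matrices built here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "UnitCell",
    "Basis",
    "build_basis",
    "d_spacing",
    "enumerate_hkl",
    "friedel_canonical",
    "parse_cell_config",
    "CD9_CELL",
]


class DegenerateCellError(ValueError):
    """Cell parameters that do not define a positive-definite metric."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic cell: axis lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise DegenerateCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError(
                    f"cell angle {name}={ang} must lie in (0, 180) degrees"
                )
        if self._volume_argument() <= 0:
            raise DegenerateCellError(
                "cell angles give a non-positive-definite metric "
                f"(volume argument {self._volume_argument():.3e} <= 0)"
            )

    def _volume_argument(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 + 2.0 * ca * cb * cg - ca * ca - cb * cb - cg * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom (closed-form triclinic expression)."""
        return self.a * self.b * self.c * math.sqrt(self._volume_argument())

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric G with G_ij = a_i . a_j."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @classmethod
    def from_metric(cls, G: np.ndarray) -> "UnitCell":
        """Rebuild cell parameters from a direct metric tensor."""
        G = np.asarray(G, dtype=float)
        a, b, c = np.sqrt(np.diag(G))
        alpha = math.degrees(math.acos(G[1, 2] / (b * c)))
        beta = math.degrees(math.acos(G[0, 2] / (a * c)))
        gamma = math.degrees(math.acos(G[0, 1] / (a * b)))
        return cls(a, b, c, alpha, beta, gamma)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


#: The CD9 EC2 crystal cell (P1, four molecules per asymmetric unit).
CD9_CELL = UnitCell(39.986, 39.998, 63.643, 80.39, 76.29, 68.15)


@dataclass(frozen=True)
class Basis:
    """Direct and reciprocal basis matrices for a cell.

    ``direct`` columns are the Cartesian cell vectors a, b, c (Angstrom);
    ``reciprocal`` columns are a*, b*, c* (1/Angstrom), the inverse
    transpose of ``direct`` (crystallographic convention, no 2*pi).
    """

    cell: UnitCell
    direct: np.ndarray = field(repr=False)
    reciprocal: np.ndarray = field(repr=False)

    @property
    def volume(self) -> float:
        return abs(float(np.linalg.det(self.direct)))

    def frac_to_cart(self, x) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.direct.T

    def cart_to_frac(self, r) -> np.ndarray:
        return np.asarray(r, dtype=float) @ np.linalg.inv(self.direct).T

    def hkl_to_cart(self, hkl) -> np.ndarray:
        """Scattering vector(s) q in Cartesian 1/Angstrom for (possibly
        fractional) reflection coordinates."""
        return np.asarray(hkl, dtype=float) @ self.reciprocal.T


def build_basis(cell: UnitCell) -> Basis:
    """Build mutually consistent direct/reciprocal bases for ``cell``.

    Orientation: a along x, b in the xy plane, c completing a right-handed
    set.  Raises :class:`DegenerateCellError` for an invalid cell.
    """
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise DegenerateCellError("degenerate cell: c vector has no z component")
    direct = np.column_stack(
        [
            [a, 0.0, 0.0],
            [b * math.cos(ga), b * math.sin(ga), 0.0],
            [cx, cy, math.sqrt(cz_sq)],
        ]
    )
    reciprocal = np.linalg.inv(direct).T
    return Basis(cell=cell, direct=direct, reciprocal=reciprocal)


def d_spacing(basis: Basis, hkl) -> float | np.ndarray:
    """Resolution d = 1/|q| in Angstrom for one or many integer triples."""
    h = np.asarray(hkl, dtype=float)
    if h.ndim == 1:
        if not h.any():
            raise ValueError("d-spacing undefined for (0,0,0)")
        return 1.0 / float(np.linalg.norm(basis.reciprocal @ h))
    if (~h.any(axis=1)).any():
        raise ValueError("d-spacing undefined for (0,0,0)")
    return 1.0 / np.linalg.norm(h @ basis.reciprocal.T, axis=1)


def friedel_canonical(hkl) -> tuple[int, int, int]:
    """Canonical member of a Friedel pair: l > 0, then k > 0, then h > 0."""
    h, k, l = (int(v) for v in hkl)
    if (l < 0) or (l == 0 and k < 0) or (l == 0 and k == 0 and h < 0):
        return (-h, -k, -l)
    return (h, k, l)


def _index_box(basis: Basis, dmin: float) -> tuple[int, int, int]:
    # |h_i| = |q . a_i| <= |a_i|/dmin
    lengths = np.linalg.norm(basis.direct, axis=0)
    return tuple(int(math.floor(L / dmin)) for L in lengths)


def enumerate_hkl(basis: Basis, dmin: float, friedel_unique: bool = False) -> np.ndarray:
    """All reflections with d >= dmin, excluding (0,0,0).

    When ``friedel_unique`` is set, exactly one member of each Friedel pair
    is kept (the canonical one).  Returns an (n, 3) int array sorted
    lexicographically.
    """
    if not dmin > 0:
        raise ValueError("dmin must be positive")
    hmax, kmax, lmax = _index_box(basis, dmin)
    hs = np.arange(-hmax, hmax + 1)
    ks = np.arange(-kmax, kmax + 1)
    ls = np.arange(-lmax, lmax + 1)
    H, K, L = np.meshgrid(hs, ks, ls, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    hkl = hkl[hkl.any(axis=1)]
    q = hkl @ basis.reciprocal.T
    keep = np.linalg.norm(q, axis=1) <= 1.0 / dmin
    hkl = hkl[keep]
    if friedel_unique:
        l, k, h = hkl[:, 2], hkl[:, 1], hkl[:, 0]
        pos = (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h > 0))
        hkl = hkl[pos]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def parse_cell_config(path) -> UnitCell:
    """Read cell parameters from a plain ``key = value`` config file.

    Recognized keys: a, b, c, alpha, beta, gamma (case-insensitive;
    ``#`` starts a comment).
    """
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip().lower()] = float(val)
    missing = {"a", "b", "c", "alpha", "beta", "gamma"} - set(values)
    if missing:
        raise ValueError(f"{path}: missing cell parameters: {sorted(missing)}")
    return UnitCell(
        values["a"], values["b"], values["c"],
        values["alpha"], values["beta"], values["gamma"],
    )
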