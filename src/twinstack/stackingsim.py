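"""Bragg + diffuse intensity from Markov stacking of twin-related layers.

The crystal is modelled as blocks of ``n_layers`` layers stacked along a
growth direction.  Each layer is one of two states drawn from a
two-state Markov chain; state 2 is state 1 transformed by a stated
rotation (normally the twin twofold), and each state carries its own
stacking translation to the next layer.  Within a block the layer
amplitudes add coherently,

    A(q) = sum_j F_{s_j}(q) exp(2 pi i q . d_j),   d_j = sum_{i<j} t_{s_i},

and blocks add incoherently — a finite coherent block standing in for
the X-ray coherence length.  The ensemble intensity splits into a Bragg
part |<A>|^2 and a diffuse part Var(A); when the per-layer phase
difference q.(t_1 - t_2) is an integer *and* the two states scatter
identically, every stacking sequence gives the same amplitude and the
diffuse part vanishes identically — this is the mechanism behind the
"ordered slices at l = 4n" of the twinned CD9 crystal, while all other
slices carry streaks along the stacking-conjugate direction a*+b*.

Two evaluation routes are provided: Monte-Carlo summation over sampled
stacking sequences (:func:`pattern_mc`) and the exact stationary-chain
expectation via transfer matrices (:func:`ht_intensity`, a
Hendricks-Teller-type computation with finite-block weights), plus the
classical damped infinite-stack closed form
(:func:`ht_intensity_infinite`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cellgeom import Basis, UnitCell

__all__ = [
    "LayerModel",
    "LayerState",
    "StackingModel",
    "RodGrid",
    "DiffusePattern",
    "section_grid",
    "plane_grid",
    "sample_sequences",
    "layer_form_factor",
    "pattern_mc",
    "ht_intensity",
    "ht_intensity_infinite",
    "extract_section",
    "streak_anisotropy",
    "write_ccp4_map",
    "read_ccp4_map",
]


@dataclass(frozen=True)
class LayerModel:
    """Toy layer content: Gaussian pseudo-atoms in cell-fractional coords.

    Each pseudo-atom contributes ``weight * exp(-width |q|^2) *
    exp(2 pi i q.r)``; widths are isotropic Gaussian form widths in A^2.

    A layer may carry a finite in-plane lattice: the motif repeated
    ``in_plane_cells`` times along each of two ``in_plane_vectors``
    (cell-fractional).  The amplitude then acquires two Dirichlet-kernel
    factors that confine the scattering towards the reciprocal rods of
    the layer lattice — the in-plane sharpness of real diffraction spots
    and streaks.  With the default of 1 cell the layer is a bare motif.
    """

    positions: np.ndarray  # (n, 3) fractional
    weights: np.ndarray  # (n,)
    widths: np.ndarray  # (n,) in A^2
    tag: str = "layer"
    in_plane_cells: int = 1
    in_plane_vectors: np.ndarray | None = None  # (2, 3) fractional

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.atleast_2d(np.asarray(self.positions, float)))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        object.__setattr__(self, "widths", np.asarray(self.widths, float))
        if self.in_plane_vectors is not None:
            object.__setattr__(
                self, "in_plane_vectors", np.asarray(self.in_plane_vectors, float)
            )
        if not (self.weights > 0).all():
            raise ValueError("pseudo-atom weights must be positive")
        if not (self.widths >= 0).all():
            raise ValueError("pseudo-atom widths must be non-negative")
        if self.in_plane_cells > 1 and self.in_plane_vectors is None:
            raise ValueError("in_plane_cells > 1 requires in_plane_vectors")


@dataclass(frozen=True)
class LayerState:
    """One stacking state: layer content, an optional index-space transform
    applied before form-factor evaluation (state 2 = rotated state 1 uses
    the twin law's inverse index action), and the fractional translation
    to the next layer."""

    layer: LayerModel
    stacking_vector: np.ndarray  # (3,) fractional
    hkl_transform: np.ndarray | None = None  # (3,3); F(q) = F_layer(T q)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stacking_vector", np.asarray(self.stacking_vector, float))
        if self.hkl_transform is not None:
            object.__setattr__(self, "hkl_transform", np.asarray(self.hkl_transform, float))


@dataclass(frozen=True)
class StackingModel:
    """Two-state Markov stacking model driving the diffraction simulator."""

    basis: Basis
    states: tuple[LayerState, LayerState]
    transition: np.ndarray  # (2,2) row-stochastic
    n_layers: int = 64
    block_count: int = 512

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, float)
        object.__setattr__(self, "transition", P)
        if P.shape != (2, 2) or (P < 0).any() or (P > 1).any():
            raise ValueError("transition must be a 2x2 matrix of probabilities")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution of the two-state chain."""
        a, b = self.transition[0, 1], self.transition[1, 0]
        if a + b == 0:  # two absorbing states: symmetric convention
            return np.array([0.5, 0.5])
        return np.array([b / (a + b), a / (a + b)])


def sample_sequences(model: StackingModel, seed) -> np.ndarray:
    """Draw ``block_count`` state sequences of length ``n_layers`` from the
    Markov chain started in its stationary distribution.  Reproducible:
    a pure function of (model, seed)."""
    rng = np.random.default_rng(seed)
    B, N = model.block_count, model.n_layers
    P = model.transition
    seqs = np.empty((B, N), dtype=np.int8)
    seqs[:, 0] = rng.random(B) < model.stationary[1]
    u = rng.random((B, N - 1)) if N > 1 else None
    for j in range(1, N):
        prev = seqs[:, j - 1]
        # switch with the off-diagonal probability of the current row
        p_switch = np.where(prev == 0, P[0, 1], P[1, 0])
        seqs[:, j] = np.where(u[:, j - 1] < p_switch, 1 - prev, prev)
    return seqs


def layer_form_factor(layer: LayerModel, basis: Basis, hfrac, hkl_transform=None) -> np.ndarray:
    """Complex layer amplitude at (possibly fractional) reflection coords.

    With a transform T the amplitude is evaluated at T.h — used to express
    a rotated layer as the parent layer at the rotated argument, so that
    twin-related layers satisfy F2(q) = F1(R^-1 q) exactly.
    """
    h = np.atleast_2d(np.asarray(hfrac, float))
    if hkl_transform is not None:
        h = h @ np.asarray(hkl_transform, float).T
    q = h @ basis.reciprocal.T
    q2 = np.einsum("ij,ij->i", q, q)
    phase = np.exp(2j * np.pi * (h @ layer.positions.T))  # q.r = h.x
    damp = np.exp(-np.outer(q2, layer.widths))
    F = (phase * damp * layer.weights).sum(axis=1)
    if layer.in_plane_cells > 1:
        n = layer.in_plane_cells
        for v in layer.in_plane_vectors:
            x = h @ v
            z = np.exp(2j * np.pi * x)
            num = 1.0 - z**n
            den = 1.0 - z
            near = np.abs(den) < 1e-12
            kernel = np.where(near, n + 0j, np.divide(num, np.where(near, 1, den)))
            F = F * kernel / n  # normalized so rod values match the bare motif
    return F


def _state_form_factors(model: StackingModel, hfrac) -> np.ndarray:
    return np.stack(
        [
            layer_form_factor(s.layer, model.basis, hfrac, s.hkl_transform)
            for s in model.states
        ]
    )


# ---------------------------------------------------------------------------
# reciprocal-space grids


@dataclass(frozen=True)
class RodGrid:
    """Samples along disorder rods in reciprocal space.

    The grid is a stack of sections; each section is a family of rods
    (lines along the streak direction through Bragg columns) sampled
    uniformly with ``samples_per_period`` points per reciprocal-lattice
    repeat.  ``hfrac`` holds all sample coordinates, shape
    (n_sections, n_rods, n_samples) flattened in C order.
    """

    hfrac: np.ndarray  # (G, 3)
    shape: tuple[int, int, int]
    section_labels: tuple  # length n_sections
    rod_labels: tuple  # length n_rods
    xi: np.ndarray  # (G,) coordinate along the rod (lattice units)
    node_mask: np.ndarray  # (G,) True at integer lattice-1 nodes
    direction: tuple[int, int, int]

    def reshape(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values).reshape(self.shape)


def section_grid(
    sections,
    rod_origins,
    direction,
    n_periods: int = 4,
    samples_per_period: int = 8,
    section_axis: int = 2,
) -> RodGrid:
    """Build a rod grid for one or more reciprocal-space sections.

    ``sections``: values of the fixed index (e.g. l for hk-sections);
    ``rod_origins``: integer (3,) starting reflections per rod, given for
    the first section (the ``section_axis`` component is overwritten);
    ``direction``: integer streak direction in hkl space.
    """
    sections = tuple(sections)
    rod_origins = [tuple(int(v) for v in o) for o in rod_origins]
    direction = tuple(int(v) for v in direction)
    ns = int(samples_per_period)
    xi_line = np.arange(n_periods * ns) / ns
    pts = []
    for sec in sections:
        for origin in rod_origins:
            o = list(origin)
            o[section_axis] = sec
            pts.append(np.asarray(o, float) + np.outer(xi_line, direction))
    hfrac = np.vstack(pts)
    n_rods = len(rod_origins)
    xi = np.tile(xi_line, len(sections) * n_rods)
    node = np.isclose(xi % 1.0, 0.0)
    return RodGrid(
        hfrac=hfrac,
        shape=(len(sections), n_rods, len(xi_line)),
        section_labels=sections,
        rod_labels=tuple(rod_origins),
        xi=xi,
        node_mask=node,
        direction=direction,
    )


def plane_grid(
    origin,
    e_par,
    e_perp,
    n_par: int = 3,
    samples_par: int = 8,
    n_perp: int = 3,
    samples_perp: int = 8,
    section_label=0,
) -> RodGrid:
    """A continuous 2D sampling of one reciprocal-space section.

    Points are origin + u*e_par + v*e_perp with u the streak-parallel
    coordinate (``samples_par`` per lattice repeat) and v the
    perpendicular in-plane coordinate; used to image streak elongation
    the way a detector section shows it.
    """
    e_par = np.asarray(e_par, float)
    e_perp = np.asarray(e_perp, float)
    us = np.arange(n_par * samples_par) / samples_par
    vs = np.arange(n_perp * samples_perp) / samples_perp
    pts = (
        np.asarray(origin, float)[None, None, :]
        + vs[:, None, None] * e_perp[None, None, :]
        + us[None, :, None] * e_par[None, None, :]
    )
    hfrac = pts.reshape(-1, 3)
    xi = np.tile(us, len(vs))
    vv = np.repeat(vs, len(us))
    node = np.isclose(xi % 1.0, 0.0) & np.isclose(vv % 1.0, 0.0)
    return RodGrid(
        hfrac=hfrac,
        shape=(1, len(vs), len(us)),
        section_labels=(section_label,),
        rod_labels=tuple(float(v) for v in vs),
        xi=xi,
        node_mask=node,
        direction=tuple(int(round(x)) for x in e_par),
    )


@dataclass(frozen=True)
class DiffusePattern:
    """Intensity on a rod grid, split into Bragg (|<A>|^2) and diffuse
    (Var A) parts; ``total = bragg + diffuse``.  Units are per coherent
    block of ``n_layers`` layers so Monte-Carlo and transfer-matrix
    results are directly comparable."""

    grid: RodGrid
    total: np.ndarray
    bragg: np.ndarray
    diffuse: np.ndarray
    se: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        for name in ("total", "bragg", "diffuse"):
            v = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, v)

    def section(self, label, component: str = "total") -> np.ndarray:
        return extract_section(self, label, component)


def pattern_mc(model: StackingModel, grid: RodGrid, seed) -> DiffusePattern:
    """Monte-Carlo pattern: coherent sum within each sampled block,
    incoherent average over blocks."""
    seqs = sample_sequences(model, seed)
    B, N = seqs.shape
    F = _state_form_factors(model, grid.hfrac)  # (2, G)
    tvec = np.stack([s.stacking_vector for s in model.states])  # (2,3)
    steps = tvec[seqs]  # (B, N, 3)
    d = np.concatenate(
        [np.zeros((B, 1, 3)), np.cumsum(steps[:, :-1, :], axis=1)], axis=1
    )  # (B, N, 3)
    G = grid.hfrac.shape[0]
    A = np.zeros((B, G), dtype=complex)
    for j in range(N):
        phase = np.exp(2j * np.pi * (d[:, j, :] @ grid.hfrac.T))  # (B, G)
        A += F[seqs[:, j]] * phase
    I = np.abs(A) ** 2
    total = I.mean(axis=0)
    Abar = A.mean(axis=0)
    bragg = np.abs(Abar) ** 2
    diffuse = np.mean(np.abs(A - Abar) ** 2, axis=0)
    se = I.std(axis=0, ddof=1) / np.sqrt(B)
    return DiffusePattern(grid=grid, total=total, bragg=bragg, diffuse=diffuse,
                          se=se, method="mc")


def _transfer_matrices(model: StackingModel, hfrac) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-point transfer matrix T[g, s, s'] = exp(2 pi i q.t_s) P_ss'
    and the state form factors."""
    F = _state_form_factors(model, hfrac)
    tvec = np.stack([s.stacking_vector for s in model.states])
    z = np.exp(2j * np.pi * (np.atleast_2d(hfrac) @ tvec.T))  # (G, 2)
    T = z[:, :, None] * model.transition[None, :, :]
    return T, F


def ht_intensity(model: StackingModel, grid: RodGrid, n_layers: int | None = None) -> DiffusePattern:
    """Exact expectation of the Monte-Carlo intensity by transfer matrices.

    For a stationary two-state chain the block-averaged intensity is

        E|A|^2 = N sum_s pi_s |F_s|^2
                 + 2 Re sum_{m=1}^{N-1} (N-m) (pi o F*)^T T^m F,

    with T_ss' = P_ss' exp(2 pi i q.t_s); the mean amplitude
    <A> = sum_j pi^T T^j F gives the Bragg part |<A>|^2 and the diffuse
    part is the difference.  This is the finite-block Hendricks-Teller
    computation matching :func:`pattern_mc` exactly in expectation.
    """
    N = int(n_layers or model.n_layers)
    T, F = _transfer_matrices(model, grid.hfrac)
    pi = model.stationary
    u = (pi[None, :] * np.conj(F.T))  # (G, 2)
    total = N * (pi[None, :] * np.abs(F.T) ** 2).sum(axis=1)
    M = T.copy()
    w = np.broadcast_to(pi[None, :].astype(complex), u.shape).copy()  # pi^T T^j
    Abar = (w * F.T).sum(axis=1).astype(complex)  # j = 0 term
    cross = np.zeros(total.shape, dtype=complex)
    for m in range(1, N):
        cross += (N - m) * np.einsum("gs,gst,tg->g", u, M, F)
        Abar += np.einsum("gs,gst,tg->g", np.broadcast_to(pi[None, :], u.shape), M, F)
        if m < N - 1:
            M = np.einsum("gij,gjk->gik", M, T)
    total = total + 2.0 * np.real(cross)
    bragg = np.abs(Abar) ** 2
    diffuse = np.maximum(total - bragg, 0.0)
    return DiffusePattern(grid=grid, total=total, bragg=bragg, diffuse=diffuse,
                          method="ht")


def ht_intensity_infinite(
    model: StackingModel, grid: RodGrid, damping: float | None = None
) -> DiffusePattern:
    """Damped infinite-stack Hendricks-Teller closed form, per layer:

        I/N = sum_s pi_s |F_s|^2 + 2 Re (pi o F*)^T Td (I - Td)^-1 F,

    with Td = rho T, rho = exp(-1/L_damp) (L_damp defaults to the model's
    n_layers).  The damping regularizes the resolvent at Bragg nodes and
    mimics finite-size broadening; without it (rho = 1) the resolvent is
    singular at Bragg nodes and the computation is refused.
    """
    L = damping if damping is not None else float(model.n_layers)
    if L == np.inf:
        rho = 1.0
    else:
        if not L > 0:
            raise ValueError("damping length must be positive")
        rho = float(np.exp(-1.0 / L))
    T, F = _transfer_matrices(model, grid.hfrac)
    Td = rho * T
    eigmax = np.abs(np.linalg.eigvals(Td)).max()
    if eigmax >= 1.0 - 1e-12:
        raise ValueError(
            "transfer matrix has spectral radius >= 1 at some grid point; "
            "enable damping (finite L_damp) to evaluate the infinite stack"
        )
    pi = model.stationary
    u = pi[None, :] * np.conj(F.T)
    base = (pi[None, :] * np.abs(F.T) ** 2).sum(axis=1)
    eye = np.eye(2)[None, :, :]
    Rv = np.linalg.solve(eye - Td, Td)  # (I-Td)^-1 Td, per grid point
    cross = np.einsum("gs,gst,tg->g", u, Rv, F)
    per_layer = base + 2.0 * np.real(cross)
    # the damped closed form smears the Bragg delta into the profile, so no
    # Bragg/diffuse split is attempted here: total carries everything
    return DiffusePattern(grid=grid, total=per_layer, bragg=np.zeros_like(per_layer),
                          diffuse=per_layer, method="ht-inf")


def extract_section(pattern: DiffusePattern, section_label, component: str = "total") -> np.ndarray:
    """The (rods x samples) image of one section of the pattern."""
    grid = pattern.grid
    if section_label not in grid.section_labels:
        raise ValueError(
            f"section {section_label!r} not in pattern (has {grid.section_labels})"
        )
    i = grid.section_labels.index(section_label)
    data = grid.reshape(getattr(pattern, component))
    return data[i]


def _corr_length(img: np.ndarray, axis: int, max_lag: int) -> float:
    x = img - img.mean()
    denom = (x * x).sum()
    if denom == 0:
        return 0.0
    L = 1.0
    for k in range(1, max_lag + 1):
        a = np.take(x, range(0, x.shape[axis] - k), axis=axis)
        b = np.take(x, range(k, x.shape[axis]), axis=axis)
        r = (a * b).sum() / denom
        if r <= 0:
            break
        L += 2.0 * r
    return L


def streak_anisotropy(pattern: DiffusePattern, section_label, component: str = "diffuse") -> float:
    """Ratio of streak-parallel to streak-perpendicular correlation length
    of a section's diffuse intensity (> 1 means elongation along the rod
    direction, i.e. visible streaks)."""
    img = extract_section(pattern, section_label, component)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("section too small for anisotropy analysis")
    L_par = _corr_length(img, axis=1, max_lag=img.shape[1] - 1)
    L_perp = _corr_length(img, axis=0, max_lag=img.shape[0] - 1)
    if L_perp == 0:
        return np.inf
    return L_par / L_perp


# ---------------------------------------------------------------------------
# CCP4/MRC map export


def write_ccp4_map(pattern: DiffusePattern, path, cell: UnitCell | None = None,
                   component: str = "total") -> None:
    """Write the 3D pattern as a CCP4/MRC mode-2 map (via gemmi).

    The three map axes are (section, rod, along-rod-sample); the header
    cell records the provided cell (defaults to the model cell the
    pattern's basis came from).
    """
    import gemmi

    data = pattern.grid.reshape(getattr(pattern, component)).astype(np.float32)
    if data.ndim != 3:
        raise ValueError("pattern grid is not a full 3D grid")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data))
    if cell is not None:
        m.grid.unit_cell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    else:
        m.grid.unit_cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_ccp4_map(path) -> tuple[np.ndarray, UnitCell]:
    """Read a CCP4/MRC map back as (array, cell)."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse CCP4 map {path}: {exc}") from exc
    arr = np.array(m.grid, copy=True)
    c = m.grid.unit_cell
    return arr, UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
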