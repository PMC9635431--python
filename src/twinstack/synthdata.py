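"""Synthetic inputs: twinned intensity datasets, stacking fixtures and
NCS-related structures.

Everything the downstream modules consume can be generated here with a
known ground truth, so the whole pipeline is testable without any
deposited data.  Every generator is a pure function of its spec and
seed.

True single-domain intensities are drawn log-normal (median 100,
sigma_log 1.0) to mimic the heavy right tail of real macromolecular
intensity distributions.  Composite (twinned) observations are formed
according to the exact-coincidence rule of the twin law — reflections
with l = 0 (mod 4) for the CD9 geometry — or a separation-threshold
rule, with I_obs = sum_k f_k I_k plus optional Gaussian or Poisson
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cellgeom import CD9_CELL, Basis, UnitCell, build_basis, enumerate_hkl, friedel_canonical
from .detwin import TwinnedObservation
from .stackingsim import LayerModel, LayerState, StackingModel
from .twinlaw import TwinOperation, idealize_cell, make_twin_op, predict_overlap

__all__ = [
    "SynthSpec",
    "TwinnedDataset",
    "make_twinned_dataset",
    "make_stacking_fixture",
    "make_ncs_structure",
    "STACKING_PRESETS",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic twinned observation set."""

    seed: int
    cell: UnitCell = CD9_CELL
    twin_axis_kind: str = "reciprocal"
    twin_axis: tuple[int, int, int] = (1, 1, 0)
    twin_angle: float = 180.0
    fractions: tuple[float, ...] = (0.7, 0.3)
    dmin: float = 3.0
    noise: tuple = ("none",)  # ("none") | ("gaussian", sigma) | ("poisson", mean_counts)
    overlap_rule: tuple = ("coincidence",)  # or ("threshold", tol_inv_angstrom)
    idealize: bool = True
    intensity_median: float = 100.0
    intensity_sigma_log: float = 1.0
    multiplicity: int = 1  # repeated measurements per reflection (Friedel-alternating)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        if not self.dmin > 0:
            raise ValueError("dmin must be positive")


@dataclass(frozen=True)
class TwinnedDataset:
    """Observations plus the ground truth that generated them."""

    observations: list = field(repr=False)
    fractions: tuple[float, ...]
    true_intensities: dict = field(repr=False)  # friedel-canonical hkl -> I
    composite_mask: np.ndarray = field(repr=False)
    hkl: np.ndarray = field(repr=False)
    op: TwinOperation = field(repr=False)
    basis: Basis = field(repr=False)
    spec: SynthSpec = field(repr=False)
    warnings: tuple = ()

    def reference(self, hkl, domain) -> float:
        return self.true_intensities[friedel_canonical(hkl)]


def _coincident_mask(op: TwinOperation, hkl: np.ndarray) -> np.ndarray:
    d = 1
    for row in op.Q_rat:
        for x in row:
            d = d * x.denominator // math.gcd(d, x.denominator)
    N = np.array([[int(x * d) for x in row] for row in op.Q_rat], dtype=np.int64)
    return ((hkl @ N.T) % d == 0).all(axis=1)


def make_twinned_dataset(spec: SynthSpec) -> TwinnedDataset:
    """Generate a twinned observation set with known ground truth.

    Reflections of domain 1 are enumerated to ``dmin``; those that
    coincide with a domain-2 reflection under the twin law (per the
    overlap rule) become two-component composites with
    I = f1 J(h) + f2 J(Q h); the rest are singles of domain 1, and the
    corresponding non-coincident domain-2 reflections are emitted as
    domain-2 singles.  J is a single intensity table (both domains are
    the same structure).
    """
    rng = np.random.default_rng(spec.seed)
    basis = build_basis(spec.cell)
    op = make_twin_op(basis, spec.twin_axis_kind, spec.twin_axis, spec.twin_angle)
    if spec.idealize:
        _, basis, op = idealize_cell(op)
    hkl = enumerate_hkl(basis, spec.dmin, friedel_unique=True)

    rule = spec.overlap_rule
    if rule[0] == "coincidence":
        comp_mask = _coincident_mask(op, hkl)
    elif rule[0] == "threshold":
        rep = predict_overlap(basis, op, spec.dmin, tolerance=float(rule[1]))
        rec = rep.records.set_index(["h", "k", "l"])["overlapping"]
        comp_mask = np.array(
            [bool(rec.get(tuple(h), False)) for h in hkl]
        )
    else:
        raise ValueError(f"unknown overlap rule {rule!r}")

    # intensity table over every index we will reference
    needed = {friedel_canonical(h) for h in hkl}
    Qr = op.Q_rat
    partners = {}
    for h, is_comp in zip(hkl, comp_mask):
        if is_comp:
            img = op.apply_rational(h)
            partner = tuple(int(f) for f in img)
            partners[tuple(h)] = partner
            needed.add(friedel_canonical(partner))
    keys = sorted(needed)
    mu = math.log(spec.intensity_median)
    vals = np.exp(rng.normal(mu, spec.intensity_sigma_log, size=len(keys)))
    J = dict(zip(keys, vals))

    f = np.asarray(spec.fractions, float)
    obs: list[TwinnedObservation] = []
    ideal: list[float] = []
    for h, is_comp in zip(hkl, comp_mask):
        th = tuple(int(v) for v in h)
        if is_comp:
            partner = partners[th]
            I = f[0] * J[friedel_canonical(th)] + f[1] * J[friedel_canonical(partner)]
            comps = [(th, 1), (partner, 2)]
        else:
            I = f[0] * J[friedel_canonical(th)]
            comps = [(th, 1)]
        obs.append(TwinnedObservation(components=tuple(comps), intensity=I, sigma=1.0))
        ideal.append(I)
        if not is_comp and f[1] > 0:
            # the matching non-overlapped domain-2 single
            I2 = f[1] * J[friedel_canonical(th)]
            obs.append(TwinnedObservation(components=((th, 2),), intensity=I2, sigma=1.0))
            ideal.append(I2)

    if spec.multiplicity > 1:
        # repeated measurements, alternating Friedel mates, each drawing its
        # own noise below (Laue -1 makes them merging-equivalent)
        repeated, rep_ideal = [], []
        for o, I in zip(obs, ideal):
            for m in range(spec.multiplicity):
                comps = o.components if m % 2 == 0 else tuple(
                    (tuple(-v for v in hkl), d) for hkl, d in o.components
                )
                repeated.append(replace(o, components=comps))
                rep_ideal.append(I)
        obs, ideal = repeated, rep_ideal

    ideal_arr = np.asarray(ideal)
    noise = spec.noise
    if noise[0] == "none":
        intensities = ideal_arr
        sigmas = np.maximum(0.01 * np.abs(intensities), 1e-6)
    elif noise[0] == "gaussian":
        s = float(noise[1])
        intensities = ideal_arr + rng.normal(0.0, s, size=ideal_arr.shape)
        sigmas = np.full_like(ideal_arr, s)
    elif noise[0] == "poisson":
        mean_counts = float(noise[1])
        gain = mean_counts / ideal_arr.mean()
        lam = np.maximum(ideal_arr * gain, 0.0)
        counts = rng.poisson(lam)
        intensities = counts / gain
        # standard uncertainties from the expected counts (the true Poisson
        # sd), not the observed ones: observed-count sigmas correlate with
        # the noise and bias any weighted fit
        sigmas = np.sqrt(np.maximum(lam, 1.0)) / gain
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    obs = [
        replace(o, intensity=float(I), sigma=float(s))
        for o, I, s in zip(obs, intensities, sigmas)
    ]
    warnings = ()
    if not comp_mask.any():
        warnings = ("overlap rule produced zero composite observations; "
                    "twin-fraction estimation downstream may be ill-posed",)
    return TwinnedDataset(
        observations=obs,
        fractions=tuple(f),
        true_intensities=J,
        composite_mask=comp_mask,
        hkl=hkl,
        op=op,
        basis=basis,
        spec=spec,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# stacking fixtures

STACKING_PRESETS = ("twin-stacking", "c-layer-rotation")


def _symmetric_motif(S: np.ndarray, rng, n_pairs: int = 2, in_plane: bool = False,
                     width_scale: float = 1.0):
    """Pseudo-atom motif exactly invariant under the direct-space twofold S
    (atom set closed under x -> S x), plus one atom on the axis fixed
    point at the origin.

    With ``in_plane`` the atoms are confined to the twin-interface plane
    spanned by c and a - b (coordinates d*(1,-1,0) + g*(0,0,1), for which
    S x = -x): the layer form factor then depends only on the rod indices
    (h - k, l), i.e. it is constant along each disorder rod up to the
    Gaussian width factor — the regime in which the transfer-matrix sum
    rule is an exact identity.
    """
    positions = [np.zeros(3)]
    weights = [2.0]
    widths = [2.0 * width_scale]
    for _ in range(n_pairs):
        if in_plane:
            d, g = rng.uniform(-0.4, 0.4, size=2)
            x = np.array([d, -d, g])
        else:
            x = rng.uniform(-0.4, 0.4, size=3)
        w = rng.uniform(0.5, 2.0)
        b = rng.uniform(1.0, 4.0) * width_scale
        positions += [x, S @ x]
        weights += [w, w]
        widths += [b, b]
    return np.array(positions), np.array(weights), np.array(widths)


def _asymmetric_motif(rng, n_atoms: int = 4):
    positions = rng.uniform(-0.45, 0.45, size=(n_atoms, 3))
    weights = rng.uniform(0.5, 2.0, size=n_atoms)
    widths = rng.uniform(1.0, 4.0, size=n_atoms)
    return positions, weights, widths


def make_stacking_fixture(preset: str, overrides: dict | None = None, seed: int = 0) -> StackingModel:
    """Seeded stacking model for one of the two disorder mechanisms.

    ``twin-stacking``: layers related by the twofold about (1,1,0)*,
    stacking step a for domain 1 and R a = b - c/4 for domain 2 (the
    growth directions of the two twin domains); layer content is
    R-symmetric, mirroring the NCS-symmetric interface layer, so the
    disorder is purely in the stacking step and slices l = 4n are exactly
    ordered.  Markov switch probability ``alpha`` (default 0.2).

    ``c-layer-rotation``: a single domain stacking along c in which a
    layer is occasionally replaced by its copy rotated by the same
    twofold (inclusion probability ``beta``, default 0.1, uncorrelated);
    the rotated content differs, disrupting periodicity along c* only.
    """
    if preset not in STACKING_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {STACKING_PRESETS}")
    ov = dict(overrides or {})
    rng = np.random.default_rng(seed)
    basis = build_basis(ov.pop("cell", CD9_CELL))
    op = make_twin_op(basis, "reciprocal", (1, 1, 0), 180.0)
    _, basis_id, op_id = idealize_cell(op)
    Q = op_id.q_rat_array()
    S = Q.T  # direct-space fractional action of the twofold
    n_layers = int(ov.pop("n_layers", 64))
    block_count = int(ov.pop("block_count", 512))

    cells = int(ov.pop("cells", 1))
    if preset == "twin-stacking":
        alpha = float(ov.pop("alpha", 0.2))
        pos, w, b = _symmetric_motif(
            S, rng,
            in_plane=bool(ov.pop("in_plane", False)),
            width_scale=float(ov.pop("width_scale", 1.0)),
        )
        # interface-layer lattice: spanned by c and a - b
        layer = LayerModel(pos, w, b, tag="twin-interface-layer",
                           in_plane_cells=cells,
                           in_plane_vectors=[[0, 0, 1], [1, -1, 0]])
        t1 = np.array([1.0, 0.0, 0.0])
        t2 = S @ t1  # = (0, 1, -1/4) exactly on the idealized cell
        states = (
            LayerState(layer, stacking_vector=t1),
            LayerState(layer, stacking_vector=t2, hkl_transform=Q),
        )
        P = np.array([[1 - alpha, alpha], [alpha, 1 - alpha]])
    else:
        beta = float(ov.pop("beta", 0.1))
        pos, w, b = _asymmetric_motif(rng)
        # ab-layer lattice: spanned by a and b
        layer = LayerModel(pos, w, b, tag="ab-layer",
                           in_plane_cells=cells,
                           in_plane_vectors=[[1, 0, 0], [0, 1, 0]])
        t = np.array([0.0, 0.0, 1.0])
        states = (
            LayerState(layer, stacking_vector=t),
            LayerState(layer, stacking_vector=t, hkl_transform=Q),
        )
        P = np.array([[1 - beta, beta], [1 - beta, beta]])
    if ov:
        raise ValueError(f"unknown overrides: {sorted(ov)}")
    return StackingModel(
        basis=basis_id, states=states, transition=P,
        n_layers=n_layers, block_count=block_count,
    )


# ---------------------------------------------------------------------------
# synthetic NCS structure (stand-in for a deposited model; purely synthetic)


def make_ncs_structure(
    seed: int = 0,
    n_residues: int = 60,
    jitter: float = 0.28,
    cell: UnitCell = CD9_CELL,
    axis: tuple[int, int, int] = (1, 1, 0),
):
    """Synthetic two-chain structure whose chains are related by a twofold
    NCS rotation about the reciprocal direction ``axis`` plus Gaussian
    coordinate jitter (A).  Returns a gemmi.Structure with CA-only chains
    A and B; used as a desk-scale stand-in for a deposited model when
    testing superposition and axis co-alignment.
    """
    import gemmi

    from .twinlaw import rotation_about

    rng = np.random.default_rng(seed)
    basis = build_basis(cell)
    v = basis.reciprocal @ np.asarray(axis, float)
    R = rotation_about(v, 180.0)
    # a compact random walk as a fake CA trace
    steps = rng.normal(0, 1.0, size=(n_residues, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    xyz_a = np.cumsum(steps, axis=0)
    xyz_a -= xyz_a.mean(axis=0)
    xyz_b = xyz_a @ R.T + np.array([5.0, -3.0, 8.0]) + rng.normal(0, jitter, xyz_a.shape)

    st = gemmi.Structure()
    st.name = "synthetic NCS pair"
    st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    for cid, xyz in (("A", xyz_a), ("B", xyz_b)):
        chain = gemmi.Chain(cid)
        for i, p in enumerate(xyz, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*p)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st
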