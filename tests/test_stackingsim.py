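"""Stacking-disorder simulator: Markov sampling, form factors, MC vs
transfer-matrix agreement, the ordered/streaked dichotomy and map I/O."""

import numpy as np
import pytest

from twinstack.stackingsim import (
    DiffusePattern,
    plane_grid,
    LayerModel,
    LayerState,
    StackingModel,
    extract_section,
    ht_intensity,
    ht_intensity_infinite,
    layer_form_factor,
    pattern_mc,
    read_ccp4_map,
    sample_sequences,
    section_grid,
    streak_anisotropy,
    write_ccp4_map,
)
from twinstack.synthdata import make_stacking_fixture


@pytest.fixture(scope="module")
def small_twin_model():
    return make_stacking_fixture("twin-stacking", {"n_layers": 32, "block_count": 128}, seed=1)


@pytest.fixture(scope="module")
def twin_grid():
    return section_grid([0, 2, 4], [(1, 1, 0), (2, 0, 0)], (1, 1, 0),
                        n_periods=2, samples_per_period=8)


class TestSequences:
    def test_alpha_zero_constant(self):
        m = make_stacking_fixture("twin-stacking", {"alpha": 0.0, "n_layers": 20,
                                                    "block_count": 16}, seed=1)
        seqs = sample_sequences(m, seed=3)
        assert (np.diff(seqs, axis=1) == 0).all()

    def test_alpha_one_alternates(self):
        m = make_stacking_fixture("twin-stacking", {"alpha": 1.0, "n_layers": 20,
                                                    "block_count": 16}, seed=1)
        seqs = sample_sequences(m, seed=3)
        assert (np.abs(np.diff(seqs, axis=1)) == 1).all()

    def test_switch_frequency_matches_alpha(self):
        alpha = 0.3
        m = make_stacking_fixture("twin-stacking",
                                  {"alpha": alpha, "n_layers": 101, "block_count": 100},
                                  seed=1)
        seqs = sample_sequences(m, seed=5)
        switches = (np.diff(seqs, axis=1) != 0).mean()
        n = seqs.shape[0] * (seqs.shape[1] - 1)
        assert abs(switches - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n)

    def test_reproducible(self, small_twin_model):
        a = sample_sequences(small_twin_model, seed=11)
        b = sample_sequences(small_twin_model, seed=11)
        assert (a == b).all()


class TestFormFactor:
    def test_single_atom_at_origin_real_positive(self, cd9_basis):
        layer = LayerModel([[0, 0, 0]], [2.0], [1.5])
        F = layer_form_factor(layer, cd9_basis, [[1, 2, 3], [0.5, 0.5, 2.0]])
        assert (np.abs(F.imag) < 1e-12).all()
        assert (F.real > 0).all()

    def test_shift_theorem(self, cd9_basis):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 1, (4, 3))
        layer = LayerModel(pos, np.ones(4), np.full(4, 2.0))
        t = np.array([0.1, -0.3, 0.25])
        shifted = LayerModel(pos + t, np.ones(4), np.full(4, 2.0))
        h = rng.uniform(-3, 3, (10, 3))
        F0 = layer_form_factor(layer, cd9_basis, h)
        F1 = layer_form_factor(shifted, cd9_basis, h)
        assert np.allclose(F1, F0 * np.exp(2j * np.pi * (h @ t)), atol=1e-12)
        assert np.allclose(np.abs(F1), np.abs(F0), atol=1e-12)

    def test_twin_states_equal_on_axis_fixed_points(self, idealized):
        # points q with R q = q (the twin-axis rows (h, h, 0)) see identical
        # form factors from the two states, whatever the layer content
        _, basis, op = idealized
        rng = np.random.default_rng(1)
        layer = LayerModel(rng.uniform(-0.5, 0.5, (5, 3)), np.ones(5), np.ones(5))
        Q = op.q_rat_array()
        h = np.array([[1, 1, 0], [2, 2, 0], [-3, -3, 0]], float)
        F1 = layer_form_factor(layer, basis, h)
        F2 = layer_form_factor(layer, basis, h, hkl_transform=Q)
        assert np.allclose(F1, F2, atol=1e-10)


class TestIntensity:
    def test_single_state_bragg_node_n_squared(self):
        m = make_stacking_fixture("twin-stacking", {"alpha": 0.0, "n_layers": 16,
                                                    "block_count": 8}, seed=1)
        grid = section_grid([4], [(1, 1, 0)], (1, 1, 0), 1, 1)  # one Bragg node
        ht = ht_intensity(m, grid)
        F = layer_form_factor(m.states[0].layer, m.basis, grid.hfrac)
        assert ht.total[0] == pytest.approx(16**2 * abs(F[0]) ** 2, rel=1e-10)
        mc = pattern_mc(m, grid, seed=2)
        assert mc.total[0] == pytest.approx(ht.total[0], rel=1e-10)

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.5])
    def test_mc_agrees_with_transfer_matrix(self, alpha):
        m = make_stacking_fixture(
            "twin-stacking", {"alpha": alpha, "n_layers": 32, "block_count": 256}, seed=1)
        grid = section_grid([1, 2], [(1, 1, 0)], (1, 1, 0), 2, 8)
        ht = ht_intensity(m, grid)
        mc = pattern_mc(m, grid, seed=7)
        scale = ht.total.max()
        ok = np.abs(mc.total - ht.total) <= 3 * mc.se + 1e-9 * scale
        assert ok.all()

    def test_ordered_slices_have_no_diffuse(self, small_twin_model, twin_grid):
        ht = ht_intensity(small_twin_model, twin_grid)
        mc = pattern_mc(small_twin_model, twin_grid, seed=7)
        for pat in (ht, mc):
            d0 = extract_section(pat, 0, "diffuse")
            d4 = extract_section(pat, 4, "diffuse")
            peak2 = extract_section(pat, 2, "diffuse").max()
            assert peak2 > 0
            assert max(d0.max(), d4.max()) <= 1e-10 * peak2

    def test_identical_states_reduce_to_ordered_lattice(self, idealized):
        # F1 = F2 and equal stacking vectors: diffuse identically zero and the
        # profile is the ordered interference function |F|^2 |sum z^j|^2
        _, basis, op = idealized
        rng = np.random.default_rng(3)
        layer = LayerModel(rng.uniform(-0.5, 0.5, (3, 3)), np.ones(3), np.ones(3))
        st = LayerState(layer, stacking_vector=np.array([1.0, 0.0, 0.0]))
        m = StackingModel(basis=basis, states=(st, st),
                          transition=np.array([[0.7, 0.3], [0.3, 0.7]]),
                          n_layers=12, block_count=8)
        grid = section_grid([1], [(1, 1, 0)], (1, 1, 0), 1, 16)
        ht = ht_intensity(m, grid)
        assert ht.diffuse.max() <= 1e-10 * ht.total.max()
        F = layer_form_factor(layer, basis, grid.hfrac)
        j = np.arange(12)
        interf = np.abs(np.exp(2j * np.pi * np.outer(grid.xi, j)).sum(axis=1)) ** 2
        assert np.allclose(ht.total, np.abs(F) ** 2 * interf, rtol=1e-8)

    def test_alpha_to_zero_limit_incoherent_domain_sum(self, idealized):
        # damped infinite-stack intensity tends to the pi-weighted sum of the
        # two ordered single-domain patterns (closed-form oracle)
        _, basis, op = idealized
        m = make_stacking_fixture("twin-stacking", {"alpha": 1e-9, "n_layers": 24},
                                  seed=4)
        grid = section_grid([1], [(1, 1, 0)], (1, 1, 0), 1, 13)
        got = ht_intensity_infinite(m, grid).total
        rho = np.exp(-1.0 / 24)
        expect = np.zeros(len(grid.hfrac))
        pi = m.stationary
        for s, w in zip(m.states, pi):
            F = layer_form_factor(s.layer, basis, grid.hfrac, s.hkl_transform)
            z = rho * np.exp(2j * np.pi * (grid.hfrac @ s.stacking_vector))
            expect += w * np.abs(F) ** 2 * (1 + 2 * np.real(z / (1 - z)))
        assert np.allclose(got, expect, rtol=1e-5)

    def test_sum_rule_conservation(self):
        # integral of I/N over one stacking-phase period equals the mean
        # incoherent single-layer power (exact when F is rod-constant)
        m = make_stacking_fixture(
            "twin-stacking",
            {"n_layers": 32, "in_plane": True, "width_scale": 1e-3}, seed=2)
        grid = section_grid([2], [(1, 1, 0)], (1, 1, 0), 1, 256)
        pi = m.stationary
        F = np.stack([
            layer_form_factor(s.layer, m.basis, grid.hfrac, s.hkl_transform)
            for s in m.states
        ])
        rhs = (pi[:, None] * np.abs(F) ** 2).sum(axis=0).mean()
        lhs_finite = ht_intensity(m, grid).total.mean() / m.n_layers
        lhs_damped = ht_intensity_infinite(m, grid).total.mean()
        assert abs(lhs_finite - rhs) / rhs < 1e-3
        assert abs(lhs_damped - rhs) / rhs < 1e-3

    def test_undamped_resolvent_refused_at_nodes(self, small_twin_model, twin_grid):
        with pytest.raises(ValueError, match="damping"):
            ht_intensity_infinite(small_twin_model, twin_grid, damping=np.inf)

    def test_diffuse_grows_with_alpha_on_streaked_sections(self):
        # measured away from BOTH domains' Bragg positions (integer and, on
        # l = 2, half-integer xi), the streak tails grow with the switch rate
        grid = section_grid([2], [(1, 1, 0)], (1, 1, 0), 2, 8)
        off_peak = ~np.isclose((2 * grid.xi) % 1.0, 0.0)
        powers = []
        for alpha in (0.02, 0.05, 0.1):
            m = make_stacking_fixture("twin-stacking",
                                      {"alpha": alpha, "n_layers": 32}, seed=2)
            powers.append(ht_intensity(m, grid).diffuse[off_peak].mean())
        assert powers[0] < powers[1] < powers[2]

    def test_friedel_symmetry_of_intensity(self, small_twin_model):
        g_plus = section_grid([2], [(1, 1, 0)], (1, 1, 0), 1, 8)
        minus_origin = [(-1 - 1, -1 - 1, 0)]  # -(origin + direction) start
        ht_p = ht_intensity(small_twin_model, g_plus)
        # evaluate at the negated coordinates directly
        import dataclasses
        g_minus = dataclasses.replace(g_plus, hfrac=-g_plus.hfrac)
        ht_m = ht_intensity(small_twin_model, g_minus)
        assert np.allclose(ht_p.total, ht_m.total, rtol=1e-10)


class TestSections:
    def test_constant_pattern_constant_section(self, twin_grid):
        const = np.full(twin_grid.hfrac.shape[0], 3.5)
        pat = DiffusePattern(grid=twin_grid, total=const, bragg=const * 0, diffuse=const)
        img = extract_section(pat, 2)
        assert img.shape == (2, 16)
        assert (img == 3.5).all()

    def test_out_of_range_section_rejected(self, small_twin_model, twin_grid):
        pat = ht_intensity(small_twin_model, twin_grid)
        with pytest.raises(ValueError, match="section"):
            extract_section(pat, 3)

    def test_twin_preset_streaks_along_a_star_plus_b_star(self):
        # continuous hk2 image (finite 4x4-cell layers): diffuse correlation
        # is longer along (1,1,0) than across it
        m = make_stacking_fixture("twin-stacking",
                                  {"n_layers": 32, "block_count": 64, "cells": 4},
                                  seed=1)
        grid = plane_grid(origin=(1, 1, 2), e_par=(1, 1, 0), e_perp=(1, -1, 0),
                          n_par=2, samples_par=8, n_perp=2, samples_perp=8,
                          section_label=2)
        pat = ht_intensity(m, grid)
        assert streak_anisotropy(pat, 2) > 1.0

    def test_c_rotation_streaks_along_c_star(self):
        m = make_stacking_fixture("c-layer-rotation",
                                  {"n_layers": 32, "block_count": 64, "cells": 4},
                                  seed=3)
        grid = plane_grid(origin=(1, 0, 0), e_par=(0, 0, 1), e_perp=(1, 0, 0),
                          n_par=2, samples_par=8, n_perp=2, samples_perp=8,
                          section_label=0)
        pat = ht_intensity(m, grid)
        assert streak_anisotropy(pat, 0) > 1.0

    def test_c_rotation_ordered_at_beta_zero(self):
        m = make_stacking_fixture("c-layer-rotation",
                                  {"beta": 0.0, "n_layers": 32, "block_count": 8}, seed=3)
        grid = section_grid([0], [(1, 0, 0)], (0, 0, 1), 2, 8, section_axis=1)
        assert ht_intensity(m, grid).diffuse.max() <= 1e-10 * ht_intensity(m, grid).total.max()


class TestCcp4:
    def _pattern(self, seed=9):
        rng = np.random.default_rng(seed)
        grid = section_grid([0, 1, 2], [(1, 1, 0), (2, 0, 0)], (1, 1, 0), 1, 4)
        vals = rng.gamma(2.0, 10.0, size=grid.hfrac.shape[0])
        return DiffusePattern(grid=grid, total=vals, bragg=vals * 0, diffuse=vals)

    def test_round_trip(self, tmp_path, idealized):
        cell, _, _ = idealized
        pat = self._pattern()
        path = tmp_path / "pattern.ccp4"
        write_ccp4_map(pat, path, cell=cell)
        arr, got_cell = read_ccp4_map(path)
        assert arr.shape == pat.grid.shape
        assert np.allclose(arr, pat.grid.reshape(pat.total).astype(np.float32))
        assert got_cell.as_tuple() == pytest.approx(cell.as_tuple(), abs=1e-3)

    def test_header_conformance(self, tmp_path, idealized):
        # independent check of the binary header against the format layout:
        # words 1-3 columns/rows/sections, word 4 mode (2 = 32-bit float),
        # words 8-10 cell axes, 'MAP ' magic at word 53
        import struct

        cell, _, _ = idealized
        pat = self._pattern()
        path = tmp_path / "pattern.ccp4"
        write_ccp4_map(pat, path, cell=cell)
        raw = path.read_bytes()
        nc, nr, ns, mode = struct.unpack("<4i", raw[0:16])
        assert mode == 2
        assert sorted((nc, nr, ns)) == sorted(pat.grid.shape)
        a, b, c = struct.unpack("<3f", raw[40:52])
        assert (a, b, c) == pytest.approx((cell.a, cell.b, cell.c), abs=1e-3)
        assert raw[208:212] == b"MAP "
        mapc, mapr, maps_ = struct.unpack("<3i", raw[64:76])
        assert sorted((mapc, mapr, maps_)) == [1, 2, 3]

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.ccp4"
        bad.write_bytes(b"this is not a map file")
        with pytest.raises(ValueError):
            read_ccp4_map(bad)
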