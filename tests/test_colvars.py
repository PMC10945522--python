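"""Collective variables: values, invariances, exact gradients."""

import numpy as np
import pytest

from chromion import colvars, geometry
from chromion.fixtures import synthetic_nucleosome_core
from chromion.topology import assemble_nucleosome


def fd_gradient(value_fn, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp = x.copy(); xp[i, d] += h
            xm = x.copy(); xm[i, d] -= h
            g[i, d] = (value_fn(xp) - value_fn(xm)) / (2 * h)
    return g


@pytest.fixture(scope="module")
def wrapped_assembly():
    core = synthetic_nucleosome_core(n_bp=28)
    return assemble_nucleosome(core, linker_bp_each_side=4,
                               linker_sequence="ATCG")


class TestEndToEnd:
    def test_straight_duplex_length(self):
        frames = geometry.straight_frames(147)
        core = synthetic_nucleosome_core(n_bp=147)
        core.frames = frames
        asm = assemble_nucleosome(core)
        v, _ = colvars.end_to_end(asm.topology.positions, asm)
        assert v == pytest.approx(146 * 3.4, abs=0.5)

    def test_translation_invariance_and_gradient(self, wrapped_assembly):
        asm = wrapped_assembly
        x = asm.topology.positions
        v0, g = colvars.end_to_end(x, asm)
        v1, _ = colvars.end_to_end(x + 13.7, asm)
        assert v1 == pytest.approx(v0, rel=1e-12)
        num = fd_gradient(lambda xx: colvars.end_to_end(xx, asm)[0], x)
        assert np.abs(num - g).max() / np.abs(g).max() < 1e-5


class TestUnwrappedBasePairs:
    def test_native_pose_counts_zero(self, wrapped_assembly):
        asm = wrapped_assembly
        assert colvars.unwrapped_bp(asm.topology.positions, asm) == 0

    def test_displaced_terminal_bp_counted_from_both_ends(self, wrapped_assembly):
        asm = wrapped_assembly
        x = asm.topology.positions.copy()
        for bp in asm.wrapped_bp[:5] + asm.wrapped_bp[-5:]:
            for i in asm.bp_bead_indices[bp]:
                x[i] += 80.0
        assert colvars.unwrapped_bp(x, asm) == 10

    def test_agreement_with_bruteforce_scan(self, wrapped_assembly):
        asm = wrapped_assembly
        rng = np.random.default_rng(4)
        x = asm.topology.positions + rng.normal(0, 8.0,
                                                asm.topology.positions.shape)
        threshold = 15.0
        core = np.asarray(asm.histone_core_beads, int)
        detached = []
        for bp in asm.wrapped_bp:
            dmin = min(np.linalg.norm(x[i] - x[c]) for i in asm.bp_bead_indices[bp]
                       for c in core)
            detached.append(dmin > threshold)
        left = 0
        while left < len(detached) and detached[left]:
            left += 1
        right = 0
        while right < len(detached) - left and detached[-1 - right]:
            right += 1
        assert colvars.unwrapped_bp(x, asm, threshold=threshold) == left + right


class TestNucleosomeGeometry:
    def test_planar_ring_normal(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        ring = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        _, w = colvars.nucleosome_geometry(ring, bead_indices=range(40))
        assert abs(w @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_equivariance(self, wrapped_assembly):
        asm = wrapped_assembly
        x = asm.topology.positions
        R = geometry.rotation_matrix([1.0, 2.0, 0.5], 1.1)
        _, w0 = colvars.nucleosome_geometry(x, asm)
        _, w1 = colvars.nucleosome_geometry(
            x @ R.T, bead_indices=asm.wrapped_dna_beads(), orient=R @ w0)
        assert np.abs(np.abs(w1 @ (R @ w0)) - 1.0) < 1e-9

    def test_axis_stable_under_noise(self, wrapped_assembly):
        asm = wrapped_assembly
        x = asm.topology.positions
        _, w0 = colvars.nucleosome_geometry(x, asm)
        rng = np.random.default_rng(0)
        _, w1 = colvars.nucleosome_geometry(x + rng.normal(0, 1.0, x.shape), asm)
        angle = np.degrees(np.arccos(np.clip(abs(w0 @ w1), 0, 1)))
        assert angle <= 1.0

    def test_collinear_beads_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            colvars.nucleosome_geometry(line, bead_indices=range(10))


class TestPairCV:
    def test_stacked_and_perpendicular_angles(self):
        t = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        ring = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1) * 30
        stacked = np.vstack([ring, ring + [0, 0, 30.0]])
        groups = list(range(30)), list(range(30, 60))
        r, theta = colvars.pair_cv(stacked, beads1=groups[0], beads2=groups[1])
        assert theta == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(30.0)
        perp = ring @ geometry.rotation_matrix([1, 0, 0], np.pi / 2).T + [0, 60, 0]
        both = np.vstack([ring, perp])
        _, theta90 = colvars.pair_cv(both, beads1=groups[0], beads2=groups[1])
        assert theta90 == pytest.approx(90.0, abs=1e-9)

    def test_global_rotation_invariance(self, toy_dinucleosome):
        top, _, extras = toy_dinucleosome
        a1, a2 = extras["assembly1"], extras["assembly2"]
        x = top.positions
        r0, t0 = colvars.pair_cv(x, a1, a2)
        R = geometry.rotation_matrix([0.3, -1.0, 0.7], 2.0)
        r1, t1 = colvars.pair_cv(x @ R.T, a1, a2)
        assert r1 == pytest.approx(r0, rel=1e-10)
        # arccos is ill-conditioned near theta=0: micro-degree agreement
        assert t1 == pytest.approx(t0, abs=1e-4)

    def test_r_and_theta_gradients_match_finite_difference(self, toy_dinucleosome):
        top, _, extras = toy_dinucleosome
        a1, a2 = extras["assembly1"], extras["assembly2"]
        rng = np.random.default_rng(1)
        x = top.positions + rng.normal(0, 0.3, top.positions.shape)
        r, th, gr, gt = colvars.pair_cv(x, a1, a2, gradients=True)
        num_r = fd_gradient(lambda xx: colvars.pair_cv(xx, a1, a2)[0], x)
        num_t = fd_gradient(lambda xx: colvars.pair_cv(xx, a1, a2)[1], x)
        assert np.abs(num_r - gr).max() / np.abs(gr).max() < 1e-5
        assert np.abs(num_t - gt).max() / np.abs(gt).max() < 1e-4


class TestTwoStartSimilarity:
    def make_stack(self, n=6, rise=60.0, lateral=55.0):
        centers = []
        for i in range(n):
            centers.append([(i % 2) * lateral, 0.0, i * rise / 2.0])
        return np.array(centers)

    def test_reference_scores_unity(self):
        centers = self.make_stack()
        ref = colvars.twostart_reference(centers)
        groups = [[i] for i in range(len(centers))]
        q = colvars.twostart_similarity(centers, groups, ref)
        assert q == pytest.approx(1.0)

    def test_extended_chain_scores_near_zero(self):
        centers = self.make_stack()
        ref = colvars.twostart_reference(centers)
        groups = [[i] for i in range(len(centers))]
        extended = np.outer(np.arange(len(centers)), [400.0, 0, 0])
        q = colvars.twostart_similarity(extended, groups, ref, width=10.0)
        assert q < 1e-6

    def test_monotone_decrease_under_uniform_scaling(self):
        centers = self.make_stack()
        ref = colvars.twostart_reference(centers)
        groups = [[i] for i in range(len(centers))]
        qs = [colvars.twostart_similarity(centers * s, groups, ref, width=10.0)
              for s in (1.0, 1.2, 1.5, 2.0)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_gradient_matches_finite_difference(self):
        centers = self.make_stack()
        ref = colvars.twostart_reference(centers)
        groups = [[i] for i in range(len(centers))]
        x = centers * 1.13
        q, g = colvars.twostart_similarity(x, groups, ref, width=10.0,
                                           gradients=True)
        num = fd_gradient(lambda xx: colvars.twostart_similarity(
            xx, groups, ref, width=10.0), x)
        assert np.abs(num - g).max() / np.abs(g).max() < 1e-5

    def test_too_few_nucleosomes_rejected(self):
        with pytest.raises(ValueError):
            colvars.twostart_similarity(np.zeros((1, 3)), [[0]], {})
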