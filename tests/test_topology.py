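"""Topology construction: bead counts, charges, bonded terms, assemblies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromion import geometry
from chromion.fixtures import helix_ca_coords, synthetic_nucleosome_core
from chromion.topology import (CGTopology, ProteinStructure, assemble_nucleosome,
                               base_pair_centers, coarse_grain_dna,
                               coarse_grain_protein, complement,
                               define_rigid_groups, generate_bdna)

dna_sequences = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestProtein:
    def test_tripeptide_charges_and_bonded_terms(self):
        struct = ProteinStructure("A", ["LYS", "GLY", "ASP"], helix_ca_coords(3))
        top = coarse_grain_protein(struct)
        assert list(top.charges) == [1.0, 0.0, -1.0]
        assert len(top.bonds) == 2
        assert len(top.angles) == 1

    def test_histidine_is_neutral(self):
        struct = ProteinStructure("A", ["HIS", "HIS"], helix_ca_coords(2))
        assert coarse_grain_protein(struct).total_charge == 0.0

    def test_flexible_tail_has_no_native_contacts_or_angles(self):
        n = 30
        residues = ["ALA"] * n
        struct = ProteinStructure("A", residues, helix_ca_coords(n))
        top = coarse_grain_protein(struct, flexible_ranges=[(1, 10)])
        # beads 0..9 are the flexible tail
        assert all(i > 9 and j > 9 for i, j, _ in top.native_contacts)
        assert all(min(t[:3]) > 7 for t in top.angles)
        assert len(top.bonds) == n - 1  # connectivity everywhere

    def test_native_contacts_match_bruteforce_scan(self):
        coords = helix_ca_coords(10)
        struct = ProteinStructure("A", ["ALA"] * 10, coords)
        top = coarse_grain_protein(struct, contact_cutoff=6.5, contact_scale=1.5)
        expected = {(i, j) for i in range(10) for j in range(i + 4, 10)
                    if np.linalg.norm(coords[j] - coords[i]) <= 9.75}
        assert {(i, j) for i, j, _ in top.native_contacts} == expected

    def test_missing_ca_error_names_residue(self):
        coords = helix_ca_coords(3)
        coords[1] = np.nan
        struct = ProteinStructure("A", ["ALA", "GLY", "VAL"], coords)
        with pytest.raises(ValueError, match="residue 2"):
            coarse_grain_protein(struct)

    def test_overlapping_flexible_ranges_rejected(self):
        struct = ProteinStructure("A", ["ALA"] * 10, helix_ca_coords(10))
        with pytest.raises(ValueError, match="overlap"):
            coarse_grain_protein(struct, flexible_ranges=[(1, 5), (4, 8)])


class TestDNA:
    @pytest.mark.parametrize("n_bp, beads, phosphates", [
        (147, 2 * (3 * 147 - 1), 2 * 147 - 2),
        (20, 2 * 59, 38),
        (2, 2 * 5, 2),
    ])
    def test_duplex_bead_and_phosphate_counts(self, n_bp, beads, phosphates):
        top = coarse_grain_dna("A" * n_bp)
        assert top.n_beads == beads
        assert sum(s == "P" for s in top.species) == phosphates
        assert top.total_charge == -phosphates

    def test_single_nucleotide_has_no_phosphate(self):
        top = coarse_grain_dna("A", duplex=False)
        assert top.n_beads == 2
        assert sorted(top.species) == ["DA", "S"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seq=dna_sequences)
    def test_counting_formulas_hold_for_any_sequence(self, seq):
        n = len(seq)
        single = coarse_grain_dna(seq, duplex=False)
        assert single.n_beads == 3 * n - 1
        duplex = coarse_grain_dna(seq)
        assert duplex.n_beads == 2 * (3 * n - 1)
        assert duplex.total_charge == -(2 * n - 2)
        duplex.validate()

    def test_invalid_nucleotide_error_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            coarse_grain_dna("ACXG")

    def test_rebuild_is_bit_identical(self):
        a = coarse_grain_dna("ATCGATCG")
        b = coarse_grain_dna("ATCGATCG")
        assert np.array_equal(a.positions, b.positions)
        assert a.bonds == b.bonds and a.to_json() == b.to_json()

    def test_complement(self):
        assert complement("AACGT") == "ACGTT"


class TestBDNAGeometry:
    def test_contour_rise(self):
        top = coarse_grain_dna("A" * 147)
        centers = base_pair_centers(top)
        assert np.linalg.norm(centers[-1] - centers[0]) == pytest.approx(
            146 * 3.4, abs=0.5)

    def test_determinism(self):
        w1, c1 = generate_bdna("ATCGATCGAT")
        w2, c2 = generate_bdna("ATCGATCGAT")
        for key in ("sugar", "base", "phosphate"):
            assert np.array_equal(w1[key], w2[key])
            assert np.array_equal(c1[key], c2[key])

    def test_ten_bp_twist_closes_full_turn(self):
        # 10 bp at 36 deg/bp compose to a 360 deg rotation of the frame
        frames = geometry.straight_frames(11)
        assert frames.twist[10] - frames.twist[0] == pytest.approx(2 * np.pi)
        axis = frames.e3[0]
        R = geometry.rotation_matrix(axis, frames.twist[10] - frames.twist[0])
        assert np.allclose(R, np.eye(3), atol=1e-12)


class TestNucleosomeAssembly:
    def test_linker_extends_repeat_length(self):
        core = synthetic_nucleosome_core(n_bp=28)
        asm = assemble_nucleosome(core, linker_bp_each_side=10,
                                  linker_sequence="ATCGATCGAT")
        assert asm.n_bp == 48  # 28 wrapped + 10 per side
        assert len(asm.wrapped_bp) == 28
        # 147-bp core with 10-bp linkers reaches the 167-bp repeat length
        frames147 = geometry.superhelix_frames(147)
        core147 = type(core)(proteins=[], dna_sequence="A" * 147, frames=frames147)
        asm167 = assemble_nucleosome(core147, linker_bp_each_side=10,
                                     linker_sequence="A" * 10)
        assert asm167.n_bp == 167

    def test_zero_linker_matches_core_only_count(self):
        core = synthetic_nucleosome_core(n_bp=28)
        asm0 = assemble_nucleosome(core, linker_bp_each_side=0)
        ref = coarse_grain_dna(core.dna_sequence).n_beads
        n_protein = sum(len(p.residues) for p in core.proteins)
        assert asm0.topology.n_beads == ref + n_protein

    def test_linker_junction_is_bonded_continuously(self):
        core = synthetic_nucleosome_core(n_bp=28)
        asm = assemble_nucleosome(core, linker_bp_each_side=5,
                                  linker_sequence="ATCGA")
        # bonds touching linker base pairs (including the junction bonds into
        # the wrap) stay at physical bonding distance: the tangential
        # extension leaves no gap at the former terminal P-S junction
        top = asm.topology
        x = top.positions
        wrapped_beads = set(asm.wrapped_dna_beads())
        linker_beads = {i for bp in range(asm.n_bp)
                        for i in asm.bp_bead_indices[bp]
                        if bp not in asm.wrapped_bp}
        junction = [np.linalg.norm(x[i] - x[j]) for i, j, _ in top.bonds
                    if i in linker_beads or j in linker_beads]
        assert junction and max(junction) < 7.0
        assert wrapped_beads  # sanity: the wrap is non-empty

    def test_core_without_dna_rejected(self):
        core = synthetic_nucleosome_core(n_bp=28)
        core.dna_sequence = ""
        with pytest.raises(ValueError, match="DNA"):
            assemble_nucleosome(core)

    def test_rigid_group_membership(self):
        core = synthetic_nucleosome_core(n_bp=28)
        asm = assemble_nucleosome(core)
        only_core = set(define_rigid_groups(asm, inner_layer_bp=0))
        assert only_core == set(asm.histone_core_beads)
        inner = define_rigid_groups(asm, inner_layer_bp=10)
        half = 10 // 2
        expect_bp = range(asm.dyad_bp - half, asm.dyad_bp - half + 10)
        expected = set(asm.histone_core_beads) | {
            i for bp in expect_bp for i in asm.bp_bead_indices[bp]}
        assert set(inner) == expected

    def test_inner_layer_exceeding_wrap_rejected(self):
        core = synthetic_nucleosome_core(n_bp=28)
        asm = assemble_nucleosome(core)
        with pytest.raises(ValueError, match="exceeds"):
            define_rigid_groups(asm, inner_layer_bp=29)


class TestSerialization:
    def test_json_roundtrip_preserves_everything(self):
        core = synthetic_nucleosome_core(n_bp=10)
        asm = assemble_nucleosome(core)
        define_rigid_groups(asm, inner_layer_bp=4)
        top = asm.topology
        back = CGTopology.from_json(top.to_json())
        assert back.species == top.species
        assert np.allclose(back.positions, top.positions)
        assert back.bonds == [tuple(b) for b in top.bonds]
        assert back.rigid_groups == top.rigid_groups

    def test_charge_bookkeeping_enforced(self):
        top = coarse_grain_dna("ATCG")
        top.charges[0] = 5.0
        with pytest.raises(ValueError, match="charge bookkeeping"):
            top.validate()
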