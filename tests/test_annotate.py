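"""Turn annotation: hydrogen bonds, span detectors, T-runs, 8→3 mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnkit import annotate as ann
from turnkit.annotate import (
    BackboneChain,
    TurnConfig,
    annotate_turns,
    assign_ss8,
    detect_alpha_pi_turns,
    detect_beta_turns,
    detect_gamma_turns,
    map_ss8_to_ss3,
    trun_labels,
)
from turnkit.geometry import DegenerateGeometryError, hbond_energy
from turnkit.simulate import (
    DihedralSpec,
    build_backbone,
    make_helix_chain,
    make_turn_peptide,
)


class TestHbondEnergy:
    def test_far_apart_atoms_give_vanishing_energy(self):
        n = np.array([0.0, 0, 0])
        h = np.array([1.0, 0, 0])
        o = np.array([1e6, 0, 0])
        c = np.array([1e6 + 1.2, 0, 0])
        assert abs(hbond_energy(n, h, o, c)) < 1e-3

    def test_equal_distances_cancel_exactly(self):
        # regular tetrahedron: d(ON)=d(CH)=d(OH)=d(CN), terms cancel
        a = 2.0
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([a, 0.0, 0.0])
        o = np.array([a / 2, a * np.sqrt(3) / 2, 0.0])
        c = np.array([a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2 / 3)])
        assert hbond_energy(n, h, o, c) == pytest.approx(0.0, abs=1e-12)

    def test_helical_i_to_i4_geometry_is_bonded(self):
        chain = make_helix_chain(12)
        e = ann.backbone_hbond_energy(chain, 3, 7)
        assert e is not None and e < -0.5

    def test_coincident_atoms_raise(self):
        p = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            hbond_energy(p, p + 0.1, p + 0.2, p + 3.0)

    def test_first_residue_has_no_donor(self):
        chain = make_helix_chain(8)
        assert ann.backbone_hbond_energy(chain, 4, 0) is None


class TestBetaTurnDetector:
    def test_planted_beta_turn_recovered_exactly(self, beta_peptide):
        chain, labels = beta_peptide
        assert detect_beta_turns(chain) == [(4, 8)]

    def test_ideal_helix_yields_no_beta_spans(self):
        for length in (6, 10, 20, 30):
            assert detect_beta_turns(make_helix_chain(length)) == []

    def test_strict_seven_angstrom_boundary(self):
        # straight-line CA placements bracketing the threshold
        def chain_with_gap(d):
            res = []
            xs = [0.0, d / 3, 2 * d / 3, d]
            for i, x in enumerate(xs):
                res.append(ann.Residue(str(i + 1), "A",
                                       CA=np.array([x, 0.0, 0.0])))
            return BackboneChain("A", res, ss8="----")

        assert detect_beta_turns(chain_with_gap(6.999)) == [(0, 4)]
        assert detect_beta_turns(chain_with_gap(7.0)) == []  # strict '<'

    def test_short_chain_returns_empty(self):
        chain = BackboneChain("A", [ann.Residue("1", "A", CA=np.zeros(3))],
                              ss8="-")
        assert detect_beta_turns(chain) == []


class TestGammaTurnDetector:
    def test_planted_gamma_turn_recovered_exactly(self, gamma_peptide):
        chain, labels = gamma_peptide
        assert detect_gamma_turns(chain) == [(3, 6)]

    def test_extended_strand_has_no_gamma_spans(self):
        phi = np.full(10, -75.0)
        psi = np.full(10, 145.0)
        chain = build_backbone(DihedralSpec(phi=phi, psi=psi))
        assert detect_gamma_turns(chain) == []

    def test_two_residue_chain_empty(self):
        res = [ann.Residue(str(i), "A", CA=np.array([3.8 * i, 0.0, 0.0]))
               for i in range(2)]
        assert detect_gamma_turns(BackboneChain("A", res)) == []


class TestAlphaPiDetector:
    def test_ideal_helices_are_excluded(self):
        for length in range(6, 31):
            assert detect_alpha_pi_turns(make_helix_chain(length)) == []

    def test_isolated_alpha_turn_without_helix_assignment_is_reported(self):
        # helical 5-window between extended flanks: i->i+4 bond present;
        # with no helix assignment in ss8 the span must be reported
        phi = np.full(13, -75.0)
        psi = np.full(13, 145.0)
        phi[4:9] = -57.0
        psi[4:9] = -47.0
        chain = build_backbone(DihedralSpec(phi=phi, psi=psi))
        coil = BackboneChain(chain.chain_id, chain.residues, "-" * 13)
        spans = detect_alpha_pi_turns(coil)
        assert any(a <= 4 and b >= 8 for a, b in spans)

    def test_helix_window_with_own_assignment_is_excluded(self):
        # same geometry, helix states computed: the H run excludes the
        # wrapped spans (only the off-helix endpoint span may remain)
        phi = np.full(13, -75.0)
        psi = np.full(13, 145.0)
        phi[4:9] = -57.0
        psi[4:9] = -47.0
        chain = build_backbone(DihedralSpec(phi=phi, psi=psi))
        spans = detect_alpha_pi_turns(chain)
        assert all(not (4 <= a and b <= 9) for a, b in spans)

    def test_chain_of_length_four_empty(self):
        res = [ann.Residue(str(i), "A", CA=np.array([3.8 * i, 0.0, 0.0]))
               for i in range(4)]
        assert detect_alpha_pi_turns(BackboneChain("A", res, ss8="----")) == []


class TestTRunLabels:
    @pytest.mark.parametrize("ss8,expected", [
        ("CCTTTCC", "0011100"),
        ("CTTCTTC", "0000000"),
        ("TTTT", "1111"),
        ("TTT", "111"),
        ("", ""),
    ])
    def test_t_run_rule(self, ss8, expected):
        ss8 = ss8.replace("C", "-")
        got = "".join(map(str, trun_labels(ss8)))
        assert got == expected

    def test_invalid_symbol_is_named(self):
        with pytest.raises(ann.InvalidSecondaryStructureError, match="Z"):
            trun_labels("TTZTT")

    @given(st.lists(st.sampled_from("HGIEBS-"), min_size=1, max_size=30),
           st.lists(st.booleans(), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_depends_only_on_t_positions(self, fillers, t_mask):
        n = min(len(fillers), len(t_mask))
        s1 = "".join("T" if t_mask[i] else fillers[i] for i in range(n))
        s2 = "".join("T" if t_mask[i] else fillers[n - 1 - i] for i in range(n))
        assert np.array_equal(trun_labels(s1), trun_labels(s2))


class TestSS8Mapping:
    def test_quoted_mapping(self):
        assert map_ss8_to_ss3("HGIEBTS-") == "HHHECCCC"

    def test_empty_and_identity_cases(self):
        assert map_ss8_to_ss3("") == ""
        assert map_ss8_to_ss3("EEEE") == "EEEE"

    def test_invalid_character_raises(self):
        with pytest.raises(ann.InvalidSecondaryStructureError):
            map_ss8_to_ss3("HHXHH")


class TestAssignSS8:
    def test_ideal_helix_interior_is_H(self):
        ss8 = assign_ss8(make_helix_chain(20))
        assert set(ss8[2:-2]) == {"H"}

    def test_extended_strand_has_no_helix_states(self):
        chain = build_backbone(DihedralSpec(phi=np.full(10, -75.0),
                                            psi=np.full(10, 145.0)))
        assert not (set(assign_ss8(chain)) & set("HGI"))

    def test_too_short_chain_is_all_coil(self):
        res = [ann.Residue(str(i), "A", CA=np.array([3.8 * i, 0.0, 0.0]))
               for i in range(2)]
        assert assign_ss8(BackboneChain("A", res)) == "--"


class TestAnnotateTurns:
    def test_union_of_detectors_and_t_runs(self):
        # synthetic ss8 carries a T-run far from the planted beta span
        chain, planted = make_turn_peptide("beta_I", 6)
        ss8 = list(assign_ss8(chain))
        ss8[-4:-1] = "TTT"
        chain2 = BackboneChain(chain.chain_id, chain.residues, "".join(ss8))
        result = annotate_turns(chain2)
        expect = planted.labels.copy()
        expect[-4:-1] = 1
        assert np.array_equal(result.labels, expect)
        assert len(result.segments) == 2
        assert result.segments[1].types == {"trun"}

    def test_union_property_against_bruteforce(self):
        chain, _ = make_turn_peptide("beta_II", 5)
        cfg = TurnConfig()
        ss8 = assign_ss8(chain)
        chain = BackboneChain(chain.chain_id, chain.residues, ss8)
        labels = annotate_turns(chain, cfg).labels
        brute = np.zeros(len(chain), dtype=np.uint8)
        for a, b in (detect_beta_turns(chain, cfg)
                     + detect_gamma_turns(chain, cfg)
                     + detect_alpha_pi_turns(chain, cfg)):
            brute[a:b] = 1
        brute |= trun_labels(ss8, cfg.t_run_min)
        assert np.array_equal(labels, brute)

    def test_all_helix_chain_has_no_turns(self):
        chain = make_helix_chain(25)
        ss8 = assign_ss8(chain).replace("T", "-")  # no T states
        chain = BackboneChain(chain.chain_id, chain.residues, ss8)
        assert annotate_turns(chain).labels.sum() == 0

    def test_overlapping_spans_merge_into_one_segment(self):
        labels = np.array([0, 1, 1, 1, 1, 0], dtype=np.uint8)
        types = [set(), {"beta"}, {"beta", "gamma"}, {"gamma"}, {"beta"}, set()]
        segs = ann.segments_from_labels(labels, types)
        assert len(segs) == 1
        assert segs[0].types == {"beta", "gamma"}

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            BackboneChain("A", [])
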