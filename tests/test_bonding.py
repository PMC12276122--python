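import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsolv.bonding import (TABLE_ENVELOPES, BCPRecord, EnvelopeWarning,
                               NBOInteraction, classify_bcp,
                               detect_hbonds_geometric, e2, rank_by_density,
                               strongest_interaction)
from microsolv.conformer_io import ValidationError
from microsolv.synthetic import build_reference_geometries


class TestClassifyBCP:
    def test_monohydrate_worked_example(self):
        # the doubly-donating monohydrate motif: rho = 0.0188 au,
        # laplacian = 0.0738 au at both O-H...O critical points
        rec = BCPRecord(donor_atom="O18", hydrogen="H19", acceptor_atom="O1",
                        rho=0.0188, laplacian=0.0738)
        with warnings.catch_warnings():
            warnings.simplefilter("error", EnvelopeWarning)
            cls = classify_bcp(rec)
        assert cls.label == "OH_O"
        assert cls.non_covalent
        assert cls.in_envelope

    def test_ch_o_row_inside_envelope(self):
        cls = classify_bcp(BCPRecord(donor_atom="C4", hydrogen="H5",
                                     acceptor_atom="O6", rho=0.0050,
                                     laplacian=0.0210))
        assert cls.label == "CH_O" and cls.in_envelope

    @pytest.mark.parametrize("label", sorted(TABLE_ENVELOPES))
    def test_envelope_midpoints_classify_to_own_label(self, label):
        (rlo, rhi), (llo, lhi) = TABLE_ENVELOPES[label]
        don, hyd, acc = {
            "OH_O": ("O1", "H2", "O3"), "CH_O": ("C1", "H2", "O3"),
            "OH_PI": ("O1", "H2", "ring"), "O_C": ("O1", None, "C3"),
        }[label]
        rec = BCPRecord(donor_atom=don, hydrogen=hyd, acceptor_atom=acc,
                        rho=(rlo + rhi) / 2, laplacian=(llo + lhi) / 2)
        with warnings.catch_warnings():
            warnings.simplefilter("error", EnvelopeWarning)
            cls = classify_bcp(rec)
        assert cls.label == label and cls.in_envelope

    def test_negative_laplacian_not_noncovalent(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EnvelopeWarning)
            cls = classify_bcp(BCPRecord(donor_atom="O1", hydrogen="H2",
                                         acceptor_atom="O3", rho=0.3,
                                         laplacian=-0.5))
        assert not cls.non_covalent

    def test_out_of_envelope_warns_not_errors(self):
        rec = BCPRecord(donor_atom="O1", hydrogen="H2", acceptor_atom="O3",
                        rho=0.5, laplacian=0.06)
        with pytest.warns(EnvelopeWarning):
            cls = classify_bcp(rec)
        assert cls.label == "OH_O" and not cls.in_envelope

    def test_unknown_context_is_other(self):
        cls = classify_bcp(BCPRecord(donor_atom="N1", hydrogen="H2",
                                     acceptor_atom="O3", rho=0.01,
                                     laplacian=0.03))
        assert cls.label == "other"

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValidationError):
            classify_bcp(BCPRecord(donor_atom="O1", hydrogen="H2",
                                   acceptor_atom="O3", rho=0.0,
                                   laplacian=0.05))

    def test_classification_is_order_independent(self, rng):
        recs = [BCPRecord(donor_atom="O1", hydrogen="H2", acceptor_atom="O3",
                          rho=float(r), laplacian=0.06)
                for r in rng.uniform(0.012, 0.05, size=8)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EnvelopeWarning)
            labels = [classify_bcp(r).label for r in recs]
            shuffled = [classify_bcp(recs[i]).label
                        for i in rng.permutation(8)]
        assert set(labels) == set(shuffled) == {"OH_O"}


class TestRankByDensity:
    def test_equal_density_preserves_order(self):
        a = BCPRecord("O1", "O3", 0.0188, 0.0738, hydrogen="H2")
        b = BCPRecord("O4", "O6", 0.0188, 0.0738, hydrogen="H5")
        ranked = rank_by_density([a, b])
        assert ranked == [a, b]
        assert ranked[0].rho == ranked[1].rho  # same strength

    def test_empty_list_gives_empty(self):
        assert rank_by_density([]) == []

    def test_shuffled_matches_sort_oracle(self, rng):
        rhos = rng.permutation(np.linspace(0.005, 0.05, 12))
        recs = [BCPRecord("O1", "O3", float(r), 0.06, hydrogen="H2")
                for r in rhos]
        ranked = rank_by_density(recs)
        assert [r.rho for r in ranked] == sorted(rhos, reverse=True)


@pytest.fixture(scope="module")
def geoms():
    return build_reference_geometries()


class TestGeometricDetector:

    def test_monomer_has_no_contacts(self, geoms):
        el, xyz = geoms["water_monomer"]
        assert detect_hbonds_geometric(el, xyz) == []

    def test_linear_dimer_has_one_oh_o(self, geoms):
        el, xyz = geoms["water_dimer"]
        contacts = detect_hbonds_geometric(el, xyz)
        assert [c.kind for c in contacts] == ["OH_O"]
        assert contacts[0].distance == pytest.approx(2.98 - 0.9572, abs=1e-6)

    def test_monohydrate_motif_has_two_equal_oh_o(self, geoms):
        el, xyz = geoms["pba_monohydrate"]
        contacts = detect_hbonds_geometric(el, xyz)
        assert [c.kind for c in contacts] == ["OH_O", "OH_O"]
        assert contacts[0].distance == pytest.approx(contacts[1].distance,
                                                     abs=1e-9)

    def test_cubic_cage_contact_count(self, geoms):
        el, xyz = geoms["water_cube"]
        contacts = detect_hbonds_geometric(el, xyz)
        assert len(contacts) == 12
        assert all(c.kind == "OH_O" for c in contacts)

    def test_rigid_motion_invariance(self, geoms, rng):
        from scipy.spatial.transform import Rotation
        el, xyz = geoms["pba_monohydrate"]
        rot = Rotation.random(random_state=11).as_matrix()
        moved = xyz @ rot.T + np.array([3.0, -1.0, 2.0])
        ref = {(c.kind, c.donor, c.hydrogen, str(c.acceptor))
               for c in detect_hbonds_geometric(el, xyz)}
        got = {(c.kind, c.donor, c.hydrogen, str(c.acceptor))
               for c in detect_hbonds_geometric(el, moved)}
        assert ref == got

    def test_oh_pi_contact_detected(self, geoms):
        # a water above the ring centroid donating downward
        el, xyz = geoms["pba"]
        centroid = np.zeros(3)
        ow = centroid + np.array([0.0, 0.0, 3.2])
        h1 = ow + 0.9572 * np.array([0.0, 0.0, -1.0])
        h2 = ow + 0.9572 * np.array([np.sin(np.radians(75.5)), 0.0,
                                     np.cos(np.radians(75.5))])
        el2 = list(el) + ["O", "H", "H"]
        xyz2 = np.vstack([xyz, ow, h1, h2])
        kinds = [c.kind for c in detect_hbonds_geometric(el2, xyz2)]
        assert "OH_PI" in kinds

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            detect_hbonds_geometric(["O", "H"], [[0, 0, 0], [0.2, 0, 0]])


class TestE2:
    def test_zero_fock_element_gives_zero(self):
        assert e2(2.0, 0.0, -0.5, 0.1) == 0.0

    def test_hand_arithmetic_example(self):
        # q F^2 / gap = 2 * 0.0025 / 0.5 = 0.01 hartree
        assert e2(2.0, 0.05, -0.25, 0.25) == pytest.approx(6.27509474,
                                                           abs=1e-8)

    def test_doubling_f_quadruples(self):
        base = e2(2.0, 0.03, -0.5, 0.2)
        assert e2(2.0, 0.06, -0.5, 0.2) == pytest.approx(4 * base, rel=1e-12)

    def test_wrong_ordering_rejected(self):
        with pytest.raises(ValidationError):
            e2(2.0, 0.05, 0.3, -0.2)

    @settings(max_examples=200, derandomize=True)
    @given(q=st.floats(0.1, 2.0), f=st.floats(0.001, 0.2),
           gap=st.floats(0.05, 2.0), s=st.floats(0.1, 10.0))
    def test_homogeneity_in_q_and_gap(self, q, f, gap, s):
        base = e2(q, f, -gap / 2, gap / 2)
        assert e2(s * q, f, -gap / 2, gap / 2) == pytest.approx(
            s * base, rel=1e-9)
        assert e2(q, f, -s * gap / 2, s * gap / 2) == pytest.approx(
            base / s, rel=1e-9)


class TestStrongestInteraction:
    def _it(self, e2_kcal):
        # build an entry whose E(2) evaluates to the requested value
        gap = 0.5
        f = np.sqrt(e2_kcal / 627.509474 * gap / 2.0)
        return NBOInteraction("LP(2)O1", "BD*(1)O18-H19", 2.0, f, -gap / 2,
                              gap / 2)

    def test_single_entry_is_itself(self):
        it = self._it(7.27)
        assert strongest_interaction([it]) is it

    def test_printed_pair_prefers_larger(self):
        weak, strong = self._it(7.27), self._it(16.66)
        assert strongest_interaction([weak, strong]) is strong
        assert strong.e2 == pytest.approx(16.66, abs=1e-9)

    def test_matches_brute_force_max(self, rng):
        its = [self._it(v) for v in rng.uniform(0.1, 30.0, size=15)]
        best = strongest_interaction(its)
        assert best.e2 == max(i.e2 for i in its)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            strongest_interaction([])
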