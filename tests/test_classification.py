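"""Family assignment, anchor location, conftor measure and conformation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abcconform.classification import (
    ConftorMeasurement,
    AnchorResult,
    assign_family,
    classify_conformation_conftor,
    classify_conformation_rmsd,
    compute_conftor,
    locate_anchors,
    pair_nbds,
)
from abcconform.errors import AbcConformError, ReferenceLibraryError
from abcconform.references import NbdReference
from abcconform.structure_io import ResidueLabel, extract_ca
from abcconform.synthetic import (
    MockSpec,
    make_ideal_helix,
    make_mock_transporter,
    make_reference_nbd,
)

from conftest import coordinate_set


def _nbd_sets(structure, truth):
    ca = extract_ca(structure)
    sets = []
    for cid, lo, hi in truth.nbd_ranges:
        keep = [
            i
            for i, lab in enumerate(ca.labels)
            if lab.chain_id == cid and lo <= lab.residue_number <= hi
        ]
        sets.append(ca.subset(keep))
    return sets


class TestAssignFamily:
    def test_reference_assigns_to_itself_with_tm_one(self, small_library):
        ref = small_library.classes["Pgp-like"].structure
        fam = assign_family(ref, small_library)
        assert fam.class_name == "Pgp-like"
        assert fam.best_tm == pytest.approx(1.0, abs=1e-6)
        assert fam.runner_up_tm < fam.best_tm

    def test_noisy_copy_recovers_class(self, small_library):
        st, truth = make_mock_transporter(
            MockSpec(planted_class="ABCG2-like", noise_sigma=0.5, seed=21)
        )
        fam = assign_family(st, small_library)
        assert fam.class_name == "ABCG2-like"
        assert fam.best_tm > 0.6

    def test_extended_chain_unclassified(self, small_library):
        n = len(small_library.classes["Pgp-like"].ca("structure"))
        chain = make_ideal_helix(n)  # extended helical chain of equal length
        fam = assign_family(chain, small_library)
        assert fam.class_name is None
        assert fam.best_tm <= 0.6

    def test_hint_structure_disagreement_flagged(self, small_library):
        st, _ = make_mock_transporter(
            MockSpec(planted_class="MacB-like", noise_sigma=0.3, seed=22)
        )
        fam = assign_family(st, small_library, class_hint="Pgp-like")
        assert fam.class_name == "MacB-like"
        assert "hint_structure_disagreement" in fam.flags

    def test_empty_library_rejected(self, small_library):
        with pytest.raises((ReferenceLibraryError, Exception)):
            assign_family(
                small_library.classes["Pgp-like"].structure,
                type(small_library)(
                    classes={}, nbd_reference=small_library.nbd_reference
                ),
            )

    def test_class_recovery_rate_under_noise(self, full_library):
        """Noise-perturbed class templates are re-assigned to their source
        class in >= 95% of seeded trials (sigma <= 1.0 A), TMD-only mode."""
        r = np.random.default_rng(1234)
        names = full_library.class_names()
        n_trials = 100
        hits = 0
        for trial in range(n_trials):
            name = names[trial % len(names)]
            tmd = full_library.classes[name].tmd
            sigma = r.uniform(0.2, 1.0)
            noisy = tmd.coords + r.normal(0, sigma, tmd.coords.shape)
            R = Rotation.random(random_state=r).as_matrix()
            noisy = noisy @ R.T + r.uniform(-20, 20, 3)
            fam = assign_family(
                coordinate_set(noisy, "Q"), full_library, mode="tmd_only"
            )
            if fam.class_name == name:
                hits += 1
        assert hits >= 95


class TestLocateAnchors:
    def test_reference_finds_its_own_anchors(self, small_library):
        nbd = small_library.nbd_reference
        res = locate_anchors(nbd.ca, nbd)
        assert res.walker_a_k == nbd.walker_a_k
        assert res.signature_g == nbd.signature_g
        assert res.tm == pytest.approx(1.0, abs=1e-6)

    def test_offset_numbering_tracked(self, small_library):
        nbd = small_library.nbd_reference
        shifted_labels = [
            ResidueLabel(lab.chain_id, lab.residue_number + 100)
            for lab in nbd.ca.labels
        ]
        query = type(nbd.ca)(shifted_labels, nbd.ca.coords.copy())
        res = locate_anchors(query, nbd)
        assert res.walker_a_k.residue_number == nbd.walker_a_k.residue_number + 100
        assert res.signature_g.residue_number == nbd.signature_g.residue_number + 100

    def test_deleted_anchor_residue_uses_neighbor_and_flags(self, small_library):
        nbd = small_library.nbd_reference
        keep = [i for i, lab in enumerate(nbd.ca.labels) if lab != nbd.walker_a_k]
        query = nbd.ca.subset(keep)
        res = locate_anchors(query, nbd)
        assert res.walker_a_k is not None
        assert abs(
            res.walker_a_k.residue_number - nbd.walker_a_k.residue_number
        ) <= 2
        assert any("walker_a_anchor_neighbor" == f for f in res.flags)

    def test_unrelated_fold_flags_low_quality(self, small_library):
        helix = make_ideal_helix(90)
        res = locate_anchors(helix, small_library.nbd_reference)
        assert "low_anchor_quality" in res.flags


class TestConftor:
    def test_planted_symmetric_distances_recovered_exactly(self, small_library):
        st, truth = make_mock_transporter(
            MockSpec(planted_state="closed", planted_distances=(10.0, 10.0), seed=31)
        )
        a, b = _nbd_sets(st, truth)
        ra = locate_anchors(a, small_library.nbd_reference)
        rb = locate_anchors(b, small_library.nbd_reference)
        m = compute_conftor(a, b, ra, rb)
        assert m.distance_ab == pytest.approx(10.0, abs=1e-6)
        assert m.distance_ba == pytest.approx(10.0, abs=1e-6)

    def test_planted_asymmetric_distances_recovered(self, small_library):
        st, truth = make_mock_transporter(
            MockSpec(planted_state="open", planted_distances=(12.0, 30.0), seed=32)
        )
        a, b = _nbd_sets(st, truth)
        ra = locate_anchors(a, small_library.nbd_reference)
        rb = locate_anchors(b, small_library.nbd_reference)
        m = compute_conftor(a, b, ra, rb)
        got = sorted([m.distance_ab, m.distance_ba])
        assert got[0] == pytest.approx(12.0, abs=1e-6)
        assert got[1] == pytest.approx(30.0, abs=1e-6)

    def test_missing_anchor_marks_incomplete(self, small_library):
        st, truth = make_mock_transporter(MockSpec(seed=33))
        a, b = _nbd_sets(st, truth)
        ra = locate_anchors(a, small_library.nbd_reference)
        rb = AnchorResult(None, None, 0.0, ["walker_a_anchor_not_found"])
        m = compute_conftor(a, b, ra, rb)
        assert not m.complete
        assert "incomplete_measurement" in m.flags
        assert classify_conformation_conftor(m).state == "unassigned"


class TestConformationRules:
    @pytest.mark.parametrize(
        "distances,state,boundary",
        [
            ((10.0, 11.0), "closed", False),
            ((20.0, 22.0), "open", False),
            ((13.0, 15.0), "open", True),  # both-below rule: one side open
            ((14.0, 10.0), "open", True),  # exactly at cutoff counts open
            ((13.9, 13.9), "closed", True),
            ((16.5, 17.0), "open", False),
        ],
    )
    def test_conftor_rule_table(self, distances, state, boundary):
        m = ConftorMeasurement(
            distance_ab=distances[0],
            distance_ba=distances[1],
            anchors={},
        )
        call = classify_conformation_conftor(m)
        assert call.state == state
        assert ("boundary_case" in call.flags) is boundary

    def test_conftor_rule_monotone_in_distances(self):
        # increasing either distance never converts open -> closed
        base = ConftorMeasurement(distance_ab=9.0, distance_ba=9.0, anchors={})
        assert classify_conformation_conftor(base).state == "closed"
        for bump in (2.0, 5.0, 10.0, 40.0):
            grown = ConftorMeasurement(
                distance_ab=9.0 + bump, distance_ba=9.0, anchors={}
            )
            if classify_conformation_conftor(grown).state == "closed":
                smaller = ConftorMeasurement(
                    distance_ab=9.0 + bump - 1.0, distance_ba=9.0, anchors={}
                )
                assert classify_conformation_conftor(smaller).state == "closed"

    def test_rmsd_rule_inward_reference_labels_open(self, small_library):
        ref = small_library.classes["Pgp-like"]
        call, rmsd_in, rmsd_out = classify_conformation_rmsd(
            ref.inward_ref, ref.inward_ref, ref.outward_ref
        )
        assert call.state == "open"
        assert rmsd_in == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_rule_noisy_outward_labels_closed(self, small_library):
        ref = small_library.classes["Pgp-like"]
        r = np.random.default_rng(8)
        st = ref.outward_ref.copy()
        for _, res in st:
            res.atoms["CA"] = res.atoms["CA"] + r.normal(0, 0.3, 3)
        call, rmsd_in, rmsd_out = classify_conformation_rmsd(
            st, ref.inward_ref, ref.outward_ref
        )
        assert call.state == "closed"
        assert rmsd_out < rmsd_in

    def test_rmsd_tie_left_unassigned(self, small_library):
        ref = small_library.classes["Pgp-like"]
        call, *_ = classify_conformation_rmsd(
            ref.inward_ref, ref.inward_ref, ref.inward_ref
        )
        assert call.state == "unassigned"
        assert "rmsd_tie" in call.flags


class TestPairNbds:
    def _cs_at(self, center, n=10, seed=0):
        r = np.random.default_rng(seed)
        return coordinate_set(r.normal(size=(n, 3)) * 3 + np.asarray(center))

    def test_two_nbds_single_pair(self):
        nbds = [("a", self._cs_at([0, 0, 0])), ("b", self._cs_at([20, 0, 0]))]
        pairs, leftover, flags = pair_nbds(nbds)
        assert pairs == [(0, 1)]
        assert leftover == [] and flags == []

    def test_four_nbds_recover_planted_couples(self):
        nbds = [
            ("a1", self._cs_at([0, 0, 0], seed=1)),
            ("b1", self._cs_at([100, 0, 0], seed=2)),
            ("a2", self._cs_at([12, 0, 0], seed=3)),
            ("b2", self._cs_at([112, 0, 0], seed=4)),
        ]
        pairs, leftover, flags = pair_nbds(nbds)
        assert sorted(tuple(sorted(p)) for p in pairs) == [(0, 2), (1, 3)]
        assert "multi_unit" in flags

    def test_three_nbds_leftover_flagged(self):
        nbds = [
            ("a", self._cs_at([0, 0, 0], seed=1)),
            ("b", self._cs_at([10, 0, 0], seed=2)),
            ("c", self._cs_at([200, 0, 0], seed=3)),
        ]
        pairs, leftover, flags = pair_nbds(nbds)
        assert pairs == [(0, 1)]
        assert leftover == [2]
        assert "unpaired_nbd" in flags

    def test_fewer_than_two_rejected(self):
        with pytest.raises(AbcConformError):
            pair_nbds([("a", self._cs_at([0, 0, 0]))])
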