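"""Domain-hit parsing, filtering, categorization and unit calling."""

import pytest

from abcconform.domain_annotation import (
    PfamHit,
    call_functional_unit,
    categorize_hits,
    filter_hits,
    load_default_catalog,
    map_hit_to_structure,
    parse_domtblout,
    render_domtblout,
)
from abcconform.errors import AbcConformError, DomtbloutFormatError
from abcconform.synthetic import HitSpec, MockSpec, make_mock_domtblout, make_mock_transporter


def make_hit(**kw) -> PfamHit:
    defaults = dict(
        target_name="seq1",
        profile_name="ABC_tran",
        profile_accession="PF00005.30",
        profile_length=200,
        full_seq_evalue=1e-30,
        domain_ievalue=1e-30,
        hmm_from=1,
        hmm_to=200,
        ali_from=1,
        ali_to=200,
    )
    defaults.update(kw)
    return PfamHit(**defaults)


class TestParseDomtblout:
    def test_comment_lines_ignored(self):
        text = make_mock_domtblout(
            [
                HitSpec("e1_A", "ABC_tran", "PF00005", 1, 200),
                HitSpec("e1_A", "ABC_membrane", "PF00664", 210, 480),
            ]
        )
        hits = parse_domtblout(text)
        assert len(hits) == 2
        assert hits[0].target_name == "e1_A"

    def test_comments_only_gives_empty_list(self):
        assert parse_domtblout("# a comment\n\n# another\n") == []

    def test_crafted_row_fields_round_trip(self):
        # values chosen field by field; parsed numbers must match exactly
        spec = HitSpec(
            "chainX",
            "ABC_tran",
            "PF00005.30",
            ali_from=12,
            ali_to=260,
            ievalue=1e-30,
            profile_length=260,
            coverage=246 / 260,
        )
        (hit,) = parse_domtblout(make_mock_domtblout([spec]))
        assert hit.domain_ievalue == pytest.approx(1e-30)
        assert (hit.hmm_from, hit.hmm_to) == (1, 246)
        assert hit.profile_length == 260
        assert (hit.ali_from, hit.ali_to) == (12, 260)

    def test_wrong_column_count_cites_line(self):
        with pytest.raises(DomtbloutFormatError) as err:
            parse_domtblout("# header\nonly three columns\n")
        assert err.value.line_number == 2

    def test_render_parse_identity_on_modeled_fields(self):
        hits = [
            make_hit(target_name="a_A", domain_ievalue=3.2e-7, hmm_from=5,
                     hmm_to=190, ali_from=40, ali_to=230, target_length=300),
            make_hit(target_name="b_B", profile_name="ABC_membrane",
                     profile_accession="PF00664.25", profile_length=270,
                     hmm_from=1, hmm_to=270, ali_from=1, ali_to=280,
                     target_length=280),
        ]
        back = parse_domtblout(render_domtblout(hits))
        for orig, parsed in zip(hits, back):
            for name in (
                "target_name", "profile_name", "profile_accession",
                "profile_length", "hmm_from", "hmm_to", "ali_from", "ali_to",
                "target_length",
            ):
                assert getattr(parsed, name) == getattr(orig, name)
            assert parsed.domain_ievalue == pytest.approx(orig.domain_ievalue, rel=1e-2)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ievalue,coverage,kept",
        [
            (0.01, 1.00, False),  # fails the 0.001 E-value ceiling
            (1e-40, 0.85, False),  # fails the 90% profile-coverage floor
            (1e-5, 0.95, True),
            (0.001, 0.90, True),  # both thresholds inclusive
        ],
    )
    def test_thresholds(self, ievalue, coverage, kept):
        hit = make_hit(
            domain_ievalue=ievalue,
            hmm_from=1,
            hmm_to=int(round(coverage * 200)),
        )
        assert bool(filter_hits([hit])) is kept

    def test_idempotent_and_order_preserving(self):
        hits = [
            make_hit(target_name=f"s{i}", domain_ievalue=ev)
            for i, ev in enumerate([1e-10, 0.5, 1e-4, 0.01, 1e-20])
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert [h.target_name for h in once] == ["s0", "s2", "s4"]


class TestCategorize:
    def test_known_profiles_get_category_and_hint(self):
        catalog = load_default_catalog()
        hits = [
            make_hit(profile_name="ABC_membrane", profile_accession="PF00664.25"),
            make_hit(profile_name="ABC2_membrane", profile_accession="PF01061.27"),
            make_hit(profile_name="ABC_tran", profile_accession="PF00005.30"),
        ]
        annotated, uncataloged = categorize_hits(hits, catalog)
        assert not uncataloged
        assert annotated[0].category == "TMD"
        assert annotated[0].class_hint == "Pgp-like"
        assert annotated[1].class_hint == "ABCG2-like"
        assert annotated[2].category == "NBD"
        assert annotated[2].class_hint is None

    def test_unknown_accession_collected_not_dropped(self):
        catalog = load_default_catalog()
        hits = [make_hit(profile_name="Mystery", profile_accession="PF99999")]
        annotated, uncataloged = categorize_hits(hits, catalog)
        assert annotated == []
        assert len(uncataloged) == 1

    def test_name_fallback_for_unknown_accession(self):
        catalog = load_default_catalog()
        hits = [make_hit(profile_name="ABC_tran", profile_accession="LOCAL001")]
        annotated, _ = categorize_hits(hits, catalog)
        assert annotated[0].category == "NBD"


class TestUnitCall:
    def _hits(self, n_nbd, n_tmd, chain="A"):
        hits = []
        for i in range(n_nbd):
            hits.append(
                make_hit(
                    target_name=f"e_{chain}{i}",
                    category="NBD",
                    ali_from=1 + 300 * i,
                    ali_to=250 + 300 * i,
                )
            )
        for i in range(n_tmd):
            hits.append(
                make_hit(
                    target_name=f"e_{chain}{i}t",
                    profile_name="ABC_membrane",
                    category="TMD",
                    ali_from=1 + 300 * i,
                    ali_to=280 + 300 * i,
                )
            )
        return hits

    @pytest.mark.parametrize(
        "n_nbd,n_tmd,verdict",
        [
            (1, 1, "not_functional"),  # half of a functional unit
            (2, 1, "functional"),
            (2, 2, "functional"),  # homodimer of half transporters
            (2, 0, "needs_review"),  # possible novel TM fold
            (0, 2, "not_functional"),
            (4, 2, "functional"),
        ],
    )
    def test_truth_table(self, n_nbd, n_tmd, verdict):
        call = call_functional_unit("e", self._hits(n_nbd, n_tmd))
        assert call.verdict == verdict
        assert call.n_nbd == n_nbd
        assert call.n_tmd == n_tmd

    def test_verdict_invariant_under_chain_permutation(self):
        hits = self._hits(2, 1)
        fwd = call_functional_unit("e", hits)
        rev = call_functional_unit("e", list(reversed(hits)))
        assert fwd.verdict == rev.verdict == "functional"

    def test_overlapping_same_category_hits_collapse(self):
        # two NBD-category profiles on the same physical domain: one domain,
        # not two, so the unit stays incomplete
        a = make_hit(target_name="e_A", category="NBD", ali_from=10, ali_to=250)
        b = make_hit(
            target_name="e_A",
            profile_name="ABC_tran_like",
            category="NBD",
            ali_from=20,
            ali_to=260,
            domain_ievalue=1e-5,
        )
        call = call_functional_unit("e", [a, b])
        assert call.n_nbd == 1
        assert call.verdict == "not_functional"


class TestMapHitToStructure:
    def test_full_resolution_span(self):
        st, truth = make_mock_transporter(MockSpec(seed=2))
        chain, lo, hi = truth.nbd_ranges[0]
        hit = make_hit(ali_from=lo, ali_to=lo + 10)
        mapped = map_hit_to_structure(hit, st, chain)
        assert len(mapped.labels) == 11
        assert mapped.gap_count == 0
        assert not mapped.low_coverage

    def test_unresolved_positions_counted_as_gaps(self):
        st, truth = make_mock_transporter(MockSpec(seed=2))
        chain = truth.nbd_ranges[0][0]
        # delete residues 12-14 to fake missing density
        st.chains[chain] = [
            r for r in st.chains[chain] if not (12 <= (r.label_seq or 0) <= 14)
        ]
        hit = make_hit(ali_from=10, ali_to=20)
        mapped = map_hit_to_structure(hit, st, chain)
        assert len(mapped.labels) == 8
        assert mapped.gap_count == 3

    def test_absent_chain_raises(self):
        st, _ = make_mock_transporter(MockSpec(seed=2))
        with pytest.raises(AbcConformError):
            map_hit_to_structure(make_hit(), st, "Z")


def test_default_catalog_has_29_profiles_with_categories():
    catalog = load_default_catalog()
    assert len(catalog) == 29
    entry = catalog.lookup("PF00664")
    assert entry.category == "TMD" and entry.class_hint == "Pgp-like"
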