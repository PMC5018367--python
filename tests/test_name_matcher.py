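"""Matching cascade: normalization, salt/acid heuristics, fuzzy search, curation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chemannot as ca
from chemannot.name_matcher import NGramIndex, match_one


def brute_force_levenshtein(a: str, b: str) -> int:
    """Independent DP edit distance (the oracle; no library calls)."""
    prev = list(range(len(b) + 1))
    for i, ca_ in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca_ != cb))
            )
        prev = cur
    return prev[-1]


def brute_force_match(query, space, threshold=0.85):
    """Full-scan approximate matcher with the same scoring and tie-break."""
    norm = ca.normalize_name(query)
    best = None
    for syn, ids in space.synonym_to_ids.items():
        d = brute_force_levenshtein(norm, syn)
        sim = 1.0 if norm == syn else 1.0 - d / max(len(norm), len(syn))
        for cid in ids:
            key = (-sim, -len(space.records[cid].synonyms), cid, syn)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < threshold:
        return None, None
    return best[2], -best[0]


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Aspirin ", "aspirin"),
            ("Salicylic   Acid", "salicylic acid"),
            ("2,4-D", "2,4-d"),
            ("", ""),
            ("Nº 5\t x", "nº 5 x".replace("º", "o")),
        ],
    )
    def test_examples(self, raw, expected):
        assert ca.normalize_name(raw) == expected

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, s):
        once = ca.normalize_name(s)
        assert ca.normalize_name(once) == once


class TestExactAndStructural:
    def test_exact_hit(self, tiny_space):
        r = ca.exact_match("Aspirin", tiny_space)
        assert (r.match_type, r.matched_ids, r.score) == (
            "exact",
            ["CID000000001"],
            1.0,
        )

    def test_miss_is_unmatched(self, tiny_space):
        r = ca.exact_match("zzzz-not-a-chemical", tiny_space)
        assert r.match_type == "unmatched" and r.matched_ids == []

    def test_shared_synonym_is_ambiguous(self, tiny_space):
        r = ca.exact_match("mercaptopurine", tiny_space)
        assert r.match_type == "ambiguous"
        assert r.matched_ids == ["CID000000002", "CID000000003"]

    def test_inchikey_lookup(self, tiny_space):
        r = ca.match_structural("BSYNRYMUTXBXSQ-UHFFFAOYSA-N", tiny_space)
        assert (r.match_type, r.matched_ids) == ("structural", ["CID000000001"])

    def test_smiles_lookup_trims_whitespace(self, tiny_space):
        r = ca.match_structural("CC(=O)Oc1ccccc1C(=O)O ", tiny_space)
        assert r.match_type == "structural"

    def test_absent_key_unmatched(self, tiny_space):
        r = ca.match_structural("AAAAAAAAAAAAAA-BBBBBBBBBB-C", tiny_space)
        assert r.match_type == "unmatched"


class TestSaltAcid:
    def test_salicylate_converts_to_salicylic_acid(self):
        assert "salicylic acid" in ca.salt_acid_variants("salicylate")

    def test_counterion_strip_composes_with_suffix_rule(self):
        assert "salicylic acid" in ca.salt_acid_variants("sodium salicylate")

    def test_rules_are_involutive_on_the_example_pair(self):
        assert "salicylate" in ca.salt_acid_variants("salicylic acid")

    def test_ite_ous_acid_pair(self):
        assert "nitrous acid" in ca.salt_acid_variants("nitrite")
        assert "nitrite" in ca.salt_acid_variants("nitrous acid")

    def test_no_rule_applies(self):
        assert ca.salt_acid_variants("aspirin") == []

    def test_original_never_returned(self):
        for name in ("salicylate", "sodium salicylate", "tartrate"):
            assert name not in ca.salt_acid_variants(name)

    def test_trailing_counterion_stripped(self):
        assert "metformin" in ca.salt_acid_variants("metformin hydrochloride")


class TestApproximate:
    def test_single_deletion_scores_above_threshold(self, tiny_space):
        # "asprin" vs "aspirin": one edit over 7 chars -> 1 - 1/7
        r = ca.approximate_match("asprin", tiny_space)
        assert r.match_type == "approximate"
        assert r.matched_ids == ["CID000000001"]
        assert r.score == pytest.approx(1 - 1 / 7)

    def test_identity_scores_one(self, tiny_space):
        r = ca.approximate_match("purinethol", tiny_space)
        assert r.score == 1.0

    def test_dissimilar_query_unmatched(self, fixture_space):
        r = ca.approximate_match("qqqqqq", fixture_space)
        assert r.match_type == "unmatched"

    def test_empty_query_unmatched(self, fixture_space):
        assert ca.approximate_match("", fixture_space).match_type == "unmatched"

    def test_candidate_list_has_top_k_entries(self, fixture_space):
        config = ca.MatcherConfig(top_k=5)
        gold = ca.generate_gold_standard(fixture_space, 5, 0.3, seed=2)
        for query, _cid in gold.pairs:
            r = ca.approximate_match(query, fixture_space, config)
            assert len(r.candidate_list) == 5
            scores = [s for _c, _s2, s in r.candidate_list]
            assert scores == sorted(scores, reverse=True)

    def test_agrees_with_brute_force_oracle(self, fixture_space):
        gold = ca.generate_gold_standard(fixture_space, 100, 0.4, seed=13)
        for query, _cid in gold.pairs:
            r = ca.approximate_match(query, fixture_space)
            expect_id, expect_sim = brute_force_match(query, fixture_space)
            if expect_id is None:
                assert r.match_type == "unmatched"
            else:
                assert r.matched_ids == [expect_id]
                assert r.score == pytest.approx(expect_sim, abs=1e-12)

    def test_raising_threshold_never_adds_matches(self, fixture_space):
        gold = ca.generate_gold_standard(fixture_space, 60, 0.5, seed=17)
        queries = [q for q, _ in gold.pairs]
        counts = []
        for thr in (0.7, 0.85, 0.95):
            config = ca.MatcherConfig(approx_threshold=thr)
            counts.append(
                sum(
                    ca.approximate_match(q, fixture_space, config).match_type
                    == "approximate"
                    for q in queries
                )
            )
        assert counts == sorted(counts, reverse=True)


class TestCascade:
    def test_stage_order_on_demo_queries(self, demo_space):
        results = ca.match_all(["aspirin", "salicylate", "asprin"], demo_space)
        assert [r.match_type for r in results] == ["exact", "salt_acid", "approximate"]

    def test_empty_query_list(self, demo_space):
        assert ca.match_all([], demo_space) == []

    def test_ambiguous_synonym_flagged(self, tiny_space):
        (r,) = ca.match_all(["mercaptopurine"], tiny_space)
        assert r.match_type == "ambiguous" and len(r.matched_ids) == 2

    def test_duplicate_queries_each_get_result(self, demo_space):
        results = ca.match_all(["aspirin", "aspirin"], demo_space)
        assert len(results) == 2 and results[0].matched_ids == results[1].matched_ids

    def test_preferred_names_all_match_exactly(self, fixture_space):
        queries = [
            fixture_space.records[cid].preferred_name
            for cid in sorted(fixture_space.records)
        ]
        results = ca.match_all(queries, fixture_space)
        assert all(r.match_type == "exact" for r in results)

    def test_inchikey_routes_to_structural(self, fixture_space):
        cid = sorted(fixture_space.records)[0]
        key = sorted(fixture_space.records[cid].inchikeys)[0]
        (r,) = ca.match_all([key], fixture_space)
        assert (r.match_type, r.matched_ids) == ("structural", [cid])

    def test_disabled_stages_are_skipped(self, demo_space):
        config = ca.MatcherConfig(enable_salt_acid=False, enable_approximate=False)
        results = ca.match_all(["salicylate", "asprin"], demo_space, config)
        assert all(r.match_type == "unmatched" for r in results)


class TestCurationRoundTrip:
    def test_export_import_identity_without_edits(self, demo_space, tmp_path):
        results = ca.match_all(["aspirin", "asprin", "nosuchthing"], demo_space)
        p = str(tmp_path / "matches.tsv")
        ca.export_match_table(results, p)
        back = ca.import_curated_table(p, demo_space)
        for orig, re_read in zip(results, back):
            assert orig.matched_ids == re_read.matched_ids
            assert orig.match_type == re_read.match_type
            assert orig.score == pytest.approx(re_read.score, abs=1e-6)
            assert not re_read.curated

    def test_curating_ambiguous_to_one_id(self, tiny_space, tmp_path):
        results = ca.match_all(["mercaptopurine"], tiny_space)
        p = str(tmp_path / "matches.tsv")
        ca.export_match_table(results, p)
        text = open(p).read().splitlines()
        text[1] += "CID000000002"  # fill the empty curated_id column
        open(p, "w").write("\n".join(text) + "\n")
        (r,) = ca.import_curated_table(p, tiny_space)
        assert r.matched_ids == ["CID000000002"]
        assert r.curated and r.match_type == "exact"

    def test_dash_clears_to_unmatched(self, demo_space, tmp_path):
        results = ca.match_all(["aspirin"], demo_space)
        p = str(tmp_path / "matches.tsv")
        ca.export_match_table(results, p)
        lines = open(p).read().splitlines()
        lines[1] += "-"
        open(p, "w").write("\n".join(lines) + "\n")
        (r,) = ca.import_curated_table(p, demo_space)
        assert r.match_type == "unmatched" and r.matched_ids == [] and r.curated

    def test_unknown_curated_id_rejected(self, demo_space, tmp_path):
        results = ca.match_all(["aspirin"], demo_space)
        p = str(tmp_path / "matches.tsv")
        ca.export_match_table(results, p)
        lines = open(p).read().splitlines()
        lines[1] += "CID999999999"
        open(p, "w").write("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="CID999999999"):
            ca.import_curated_table(p, demo_space)


class TestEvaluation:
    def test_all_correct(self, demo_space):
        gold = ca.GoldStandard(pairs=[("aspirin", "CID000002244")])
        ev = ca.evaluate_matching(ca.match_all(["aspirin"], demo_space), gold)
        assert (ev.sensitivity, ev.precision) == (1.0, 1.0)

    def test_half_correct(self, demo_space):
        gold = ca.GoldStandard(
            pairs=[("aspirin", "CID000002244"), ("ibuprofen", "CID000002244")]
        )
        ev = ca.evaluate_matching(
            ca.match_all(["aspirin", "ibuprofen"], demo_space), gold
        )
        assert ev.sensitivity == 0.5 and ev.precision == 0.5

    def test_all_unmatched_precision_not_applicable(self, demo_space):
        gold = ca.GoldStandard(pairs=[("qqqq", "CID000002244")])
        ev = ca.evaluate_matching(ca.match_all(["qqqqqqqq"], demo_space), gold)
        assert ev.sensitivity == 0.0 and ev.n_matched == 0
        assert math.isnan(ev.precision)

    def test_length_mismatch_rejected(self, demo_space):
        gold = ca.GoldStandard(pairs=[("a", "x"), ("b", "y")])
        with pytest.raises(ValueError):
            ca.evaluate_matching(ca.match_all(["aspirin"], demo_space), gold)


class TestQueryFile:
    def test_comments_blank_lines_and_labels(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("# header\naspirin\n\nmylabel\tibuprofen\n", encoding="utf-8")
        assert ca.read_query_file(str(p)) == [
            ("aspirin", "aspirin"),
            ("mylabel", "ibuprofen"),
        ]
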