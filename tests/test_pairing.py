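"""Sequence-side unit and property tests: reverse complement, seed matching,
supplementary/compensatory site search, k-mer profiles, classification."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ripseek import (
    InputError,
    MatureMiRNA,
    SiteSearchParams,
    classify_gene_pairing,
    expression_by_pairing_type,
    find_compensatory_sites,
    find_seed_matches,
    find_supplementary_sites,
    kmer_offset_enrichment,
    pairing_type_relative_frequency,
    reverse_complement,
)
from ripseek.pairing import pairing_mismatches

from _oracles import naive_exact_occurrences, naive_rc, naive_two_block_sites, site_tuples
from conftest import random_rna

rna = st.text(alphabet="ACGU", max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("AAAA", "UUUU"), ("", ""), ("ACGU", "ACGU"), ("GGC", "GCC")]
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(rna)
    @settings(deadline=None)
    def test_involution_and_biopython_agreement(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert reverse_complement(seq) == str(Seq(seq).reverse_complement_rna())

    def test_invalid_character_names_position(self):
        with pytest.raises(InputError, match="position 2"):
            reverse_complement("ACTU")


class TestMatureMiRNA:
    def test_segments(self, let7):
        assert let7.seed == "GAGGUA"
        assert let7.three_prime_segment == "GGUUGUAU"

    def test_too_short_rejected(self):
        with pytest.raises(InputError, match="at least 20"):
            MatureMiRNA("short", "ACGUACGUACGU")

    def test_interval_order_enforced(self):
        with pytest.raises(InputError):
            MatureMiRNA("x", "ACGU" * 6, seed_interval=(2, 12), three_prime_interval=(11, 18))


class TestPairingMismatches:
    def test_perfect_pairing(self):
        # GAGGUA (read 3'->5': AUGGAG) pairs UACCUC
        assert pairing_mismatches("UACCUC", "GAGGUA") == 0

    def test_gu_wobble_flag(self):
        # miRNA G over target U: mismatch by default, pair when allowed
        assert pairing_mismatches("U", "G") == 1
        assert pairing_mismatches("U", "G", allow_gu=True) == 0


class TestSeedMatches:
    def test_utr_equal_to_motif(self, let7):
        motif = reverse_complement(let7.segment((2, 8)))
        sites = find_seed_matches(motif, let7)
        assert [(s.start, s.end) for s in sites] == [(0, 7)]

    def test_no_occurrence(self, let7):
        assert find_seed_matches("A" * 40, let7) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_scan(self, let7, seed):
        rng = np.random.default_rng(100 + seed)
        # AU-rich background makes chance hits of the AU-rich motif likely
        utr = "".join(rng.choice(list("AUUACG"), size=2000))
        motif = naive_rc("GAGGUAG")
        got = [(s.start, s.end) for s in find_seed_matches(utr, let7)]
        assert got == naive_exact_occurrences(utr, motif)


class TestSupplementaryCompensatory:
    """The worked let-7 example: seed 1-6 'UGAGGU' -> match ACCUCA, 3' 11-18
    'GGUUGUAU' -> match AUACAACC, nominal spacer 4."""

    UTR = "GGGAUACAACCCGCAACCUCAGGG"

    def test_worked_supplementary_example(self, let7, offset_params):
        sites = find_supplementary_sites(self.UTR, let7, offset_params, "g")
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end) == (3, 21)
        assert (s.seed_mismatches, s.three_prime_mismatches, s.spacer_length) == (0, 0, 4)

    def test_too_many_three_prime_mismatches(self, let7, offset_params):
        utr = self.UTR[:4] + "GGGG" + self.UTR[8:]  # 4 substitutions in the 3' block
        assert find_supplementary_sites(utr, let7, offset_params) == []

    def test_three_mismatches_still_allowed(self, let7, offset_params):
        utr = self.UTR[:4] + "GGG" + self.UTR[7:]
        sites = find_supplementary_sites(utr, let7, offset_params)
        assert [s.three_prime_mismatches for s in sites] == [3]

    def test_spacer_beyond_wobble(self, let7, offset_params):
        utr = self.UTR[:11] + "CC" + self.UTR[11:]  # spacer 4 -> 6
        assert find_supplementary_sites(utr, let7, offset_params) == []

    def test_spacer_within_wobble(self, let7, offset_params):
        utr = self.UTR[:11] + "C" + self.UTR[11:]  # spacer 5
        sites = find_supplementary_sites(utr, let7, offset_params)
        assert [s.spacer_length for s in sites] == [5]

    def test_compensatory_one_seed_mismatch(self, let7, offset_params):
        utr = self.UTR.replace("ACCUCA", "ACGUCA")
        sites = find_compensatory_sites(utr, let7, offset_params, "g")
        assert len(sites) == 1
        assert sites[0].seed_mismatches == 1
        # and the perfect-seed search no longer fires
        assert find_supplementary_sites(utr, let7, offset_params) == []

    def test_perfect_seed_not_compensatory(self, let7, offset_params):
        assert find_compensatory_sites(self.UTR, let7, offset_params) == []

    def test_two_seed_mismatches_rejected(self, let7, offset_params):
        utr = self.UTR.replace("ACCUCA", "AGGUCA")
        assert find_compensatory_sites(utr, let7, offset_params) == []

    def test_short_utr_yields_empty_list(self, let7, offset_params):
        assert find_supplementary_sites("ACCUCA", let7, offset_params) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_instances(self, seed):
        """Site lists equal naive all-positions enumeration on random inputs."""
        rng = np.random.default_rng(2000 + seed)
        params = SiteSearchParams(seed_interval=(1, 6), three_prime_interval=(11, 18))
        for _ in range(40):
            mirna = MatureMiRNA(
                "m", random_rna(rng, 22), seed_interval=(1, 6), three_prime_interval=(11, 18)
            )
            # bias the UTR toward the site content so matches actually occur
            site = naive_rc(mirna.sequence[10:18]) + random_rna(rng, 4) + naive_rc(mirna.sequence[0:6])
            utr = random_rna(rng, 120) + site + random_rna(rng, 120)
            for required_mm, finder in [(0, find_supplementary_sites), (1, find_compensatory_sites)]:
                expected = naive_two_block_sites(
                    utr, mirna.sequence, (1, 6), (11, 18), required_mm, 3, 1
                )
                assert site_tuples(finder(utr, mirna, params)) == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_supplementary_compensatory_disjoint(self, let7, offset_params, seed):
        rng = np.random.default_rng(3000 + seed)
        utr = random_rna(rng, 300)
        supp = {(s.start, s.end) for s in find_supplementary_sites(utr, let7, offset_params)}
        comp = {(s.start, s.end) for s in find_compensatory_sites(utr, let7, offset_params)}
        assert not (supp & comp)


class TestKmerOffsetEnrichment:
    def test_targets_equal_background_all_ones(self, let7):
        rng = np.random.default_rng(7)
        utrs = {f"g{i}": random_rna(rng, 200) for i in range(30)}
        profile = kmer_offset_enrichment(utrs, utrs, let7)
        assert len(profile) == len(let7) - 6 + 1
        defined = profile["ratio"].dropna()
        assert (defined == 1.0).all()

    def test_zero_background_offset_is_nan(self, let7):
        # G-only UTRs contain no match for any let-7 6-mer complement
        targets = {"t": "G" * 50}
        background = {"t": "G" * 50, "b": "G" * 50}
        profile = kmer_offset_enrichment(targets, background, let7)
        assert profile["ratio"].isna().all()

    def test_planted_seed_peak(self, let7_offset_seed):
        rng = np.random.default_rng(11)
        motif = reverse_complement(let7_offset_seed.sequence[0:6])
        background = {f"b{i}": random_rna(rng, 300) for i in range(200)}
        targets = {f"t{i}": random_rna(rng, 150) + motif + random_rna(rng, 150) for i in range(100)}
        all_utrs = {**background, **targets}
        profile = kmer_offset_enrichment(targets, all_utrs, let7_offset_seed).set_index("offset")
        assert profile.loc[1, "ratio"] > 1.5

    def test_target_not_in_background_rejected(self, let7):
        with pytest.raises(InputError, match="absent from background"):
            kmer_offset_enrichment({"t": "ACGU" * 10}, {"b": "ACGU" * 10}, let7)


class TestClassification:
    def test_precedence_supplementary_over_canonical(self, let7, offset_params):
        site = (
            reverse_complement(let7.sequence[10:18]) + "AAAA" + reverse_complement(let7.sequence[0:6])
        )
        utr = "GGG" + site + "GGG" + reverse_complement(let7.sequence[0:6]) + "GG"
        assert classify_gene_pairing(utr, let7, offset_params) == "supplementary"

    def test_no_sites_is_none(self, let7, offset_params):
        assert classify_gene_pairing("G" * 60, let7, offset_params) == "none"

    def test_canonical_only(self, let7, offset_params):
        utr = "GGG" + reverse_complement(let7.sequence[0:6]) + "GGG"
        assert classify_gene_pairing(utr, let7, offset_params) == "canonical_seed"


class TestPairingTypeFrequency:
    def test_targets_equal_background(self):
        labels = {"a": "supplementary", "b": "canonical_seed", "c": "none"}
        ratios = pairing_type_relative_frequency(["a", "b", "c"], ["a", "b", "c"], labels)
        assert ratios["supplementary"] == 1.0
        assert ratios["canonical_seed"] == 1.0

    def test_type_absent_from_targets(self):
        labels = {"a": "supplementary", "b": "canonical_seed"}
        ratios = pairing_type_relative_frequency(["b"], ["a", "b"], labels)
        assert ratios["supplementary"] == 0.0

    def test_type_absent_from_background_is_nan(self):
        labels = {"a": "none", "b": "none"}
        ratios = pairing_type_relative_frequency(["a"], ["a", "b"], labels)
        assert np.isnan(ratios["compensatory"])


class TestExpressionByPairingType:
    def _measures(self, values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(values))],
                "repression": values,
                "enrichment": values,
                "score": values,
            }
        )

    def test_identical_classes_p_one(self):
        measures = self._measures([1.0, 2.0, 4.0, 8.0])
        genes = list(measures["gene_id"])
        summary, tests = expression_by_pairing_type(
            measures, {}, classes={"a": genes, "b": genes}
        )
        assert tests.loc[0, "p_value"] == pytest.approx(1.0)
        a, b = summary.set_index("class").loc["a"], summary.set_index("class").loc["b"]
        assert a["median"] == b["median"] and a["q1"] == b["q1"]

    def test_quartiles_match_independent_order_statistics(self):
        rng = np.random.default_rng(5)
        values = 2.0 ** rng.normal(0, 1, 101)
        measures = self._measures(values)
        summary, _ = expression_by_pairing_type(
            measures, {}, classes={"a": list(measures["gene_id"])}
        )
        logs = sorted(np.log2(values))
        # with n=101, quartiles fall exactly on order statistics 25, 50, 75
        row = summary.set_index("class").loc["a"]
        assert row["q1"] == pytest.approx(logs[25])
        assert row["median"] == pytest.approx(logs[50])
        assert row["q3"] == pytest.approx(logs[75])

    def test_degenerate_class_flagged_not_tested(self):
        measures = self._measures([1.0, 2.0, 4.0])
        summary, tests = expression_by_pairing_type(
            measures, {}, classes={"a": ["g0"], "b": ["g1", "g2"]}
        )
        assert bool(summary.set_index("class").loc["a", "degenerate"])
        assert not tests.loc[0, "computed"]
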