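"""Variant calling, enrichment rates, classes, carryover, CAI, coverage."""

import math
from collections import Counter

import numpy as np
import pytest

from bridgedms.bridge_core import BridgedTemplate, Rejection
from bridgedms.fastq_io import ClusterKey
from bridgedms.sim_dms import default_anchor_specs, _template_reads
from bridgedms.variant_quant import (
    CAIReference,
    CountTable,
    EnrichmentRecord,
    cai,
    call_variant,
    class_summary,
    classify,
    enrichment_rate,
    estimate_carryover,
    library_coverage,
    stop_fraction,
    tally,
)

SPECS = default_anchor_specs()
KEY = ClusterKey("FC", 1, 1, 1, 1)


def template_for(codons):
    """Build a bridged template carrying the given five codons."""
    from bridgedms.sim_dms import (
        FWD_FLANK_5, FWD_FLANK_3, REV_FLANK_5, REV_LINKER, REV_FLANK_3,
    )
    c = list(codons)
    seg1 = FWD_FLANK_5 + c[0] + c[1] + FWD_FLANK_3
    seg2 = REV_FLANK_5 + c[2] + REV_LINKER + c[3] + c[4] + REV_FLANK_3
    return BridgedTemplate(key=KEY, segments=(seg1, seg2), segment_quals=((), ()))


class TestCallVariant:
    def test_wild_type_codons_give_tqwlh(self):
        call = call_variant(template_for(("ACC", "CAG", "TGG", "CTG", "CAC")), SPECS)
        assert call.aa_string == "TQWLH"

    def test_tag_translates_to_stop(self):
        call = call_variant(template_for(("ACC", "TAG", "TGG", "CTG", "CAC")), SPECS)
        assert call.aa_string == "T*WLH"

    def test_n_in_codon_rejected(self):
        result = call_variant(template_for(("ACN", "CAG", "TGG", "CTG", "CAC")), SPECS)
        assert isinstance(result, Rejection)

    def test_wrong_segment_length_raises(self):
        bad = BridgedTemplate(key=KEY, segments=("ACGT", "ACGT"),
                              segment_quals=((), ()))
        with pytest.raises(ValueError):
            call_variant(bad, SPECS)


class TestTally:
    def test_identical_calls_counted(self):
        t = tally({"naive": ["AAAAA"] * 3})
        assert t.counts["naive"]["AAAAA"] == 3
        assert t.totals["naive"] == 3

    def test_empty_input(self):
        t = tally({})
        assert t.populations == []

    def test_matches_brute_force_on_random_calls(self, rng):
        calls = ["".join(rng.choice(list("ACDEF"), 5)) for _ in range(10_000)]
        t = tally({"p": calls})
        assert t.counts["p"] == Counter(calls)
        assert t.totals["p"] == 10_000

    def test_frame_round_trip(self, rng):
        calls = {"naive": ["AA", "AB", "AA"], "PS1": ["AB"]}
        t = tally(calls)
        t2 = CountTable.from_frame(t.to_frame())
        assert t2.counts == t.counts


class TestEnrichmentRate:
    def test_hand_arithmetic(self):
        t = tally({"naive": ["A"] * 50 + ["B"] * 50, "PS4": ["A"] * 90 + ["B"] * 10})
        recs = {r.aa_string: r for r in enrichment_rate(t, "naive", "PS4", min_naive=1)}
        assert recs["A"].rate == pytest.approx(1.8)
        assert recs["B"].rate == pytest.approx(0.2)

    def test_below_min_naive_has_no_rate(self):
        t = tally({"naive": ["A"] * 10 + ["B"] * 90, "PS4": ["A"] * 50 + ["B"] * 50})
        recs = {r.aa_string: r for r in enrichment_rate(t, "naive", "PS4", min_naive=15)}
        assert not recs["A"].passes_threshold
        assert recs["A"].rate is None
        assert recs["B"].passes_threshold

    def test_absent_in_sorted_population_is_zero(self):
        t = tally({"naive": ["A"] * 20 + ["B"] * 20, "PS4": ["B"] * 40})
        recs = {r.aa_string: r for r in enrichment_rate(t, "naive", "PS4")}
        assert recs["A"].rate == 0.0

    def test_zero_total_errors(self):
        t = CountTable(populations=["naive", "PS4"],
                       counts={"naive": Counter(A=5), "PS4": Counter()})
        with pytest.raises(ValueError):
            enrichment_rate(t, "naive", "PS4")

    def test_population_enrichment_is_conserved(self, rng):
        # naive-frequency-weighted mean rate over a closed population is 1
        variants = [f"V{i}" for i in range(30)]
        naive = rng.integers(50, 200, size=30)
        ps = rng.integers(1, 500, size=30)
        t = CountTable(
            populations=["naive", "PS1"],
            counts={"naive": Counter(dict(zip(variants, map(int, naive)))),
                    "PS1": Counter(dict(zip(variants, map(int, ps))))},
        )
        recs = enrichment_rate(t, "naive", "PS1", min_naive=1)
        total_naive = naive.sum()
        weighted = sum(r.rate * t.counts["naive"][r.aa_string] / total_naive
                       for r in recs)
        assert weighted == pytest.approx(1.0)


GROUPS = ((0, 1), (2, 3, 4))


class TestClassify:
    @pytest.mark.parametrize(
        "aa, expected",
        [
            ("TQWLH", "wild_type"),
            ("SLNIG", "distal_multi"),
            ("TSWLH", "single"),
            ("TQYLG", "proximal_double"),
            ("TQYIG", "proximal_triple"),
            ("SSWLH", "proximal_double"),
            ("T*WLH", "stop"),
        ],
    )
    def test_examples(self, aa, expected):
        assert classify(aa, "TQWLH", GROUPS) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify("TQW", "TQWLH", GROUPS)

    def test_invariant_under_permutation_within_group(self, rng):
        # which positions within a group differ must not change the class
        for _ in range(50):
            aa = "".join(rng.choice(list("ACDEFGHIK"), 5))
            base = classify(aa, "TQWLH", GROUPS)
            perm = aa[1] + aa[0] + aa[2:]  # swap within group 0
            wt_perm = "QT" + "WLH"
            assert classify(perm, wt_perm, GROUPS) == base


class TestClassSummary:
    def _records(self):
        rows = [("SLNIG", 791, "distal_multi"), ("TSWLH", 336, "single"),
                ("TQYLG", 148, "proximal_double")]
        return [
            EnrichmentRecord(aa, 100, 100, rate, klass, True)
            for aa, rate, klass in rows
        ]

    def test_fold_ratios_to_one_decimal(self):
        summary = class_summary(self._records())
        assert summary["fold_vs_distal"]["single"] == 2.4
        assert summary["fold_vs_distal"]["proximal_double"] == 5.3

    def test_empty_class_absent(self):
        summary = class_summary(self._records())
        assert "proximal_triple" not in summary["fold_vs_distal"]
        assert "proximal_triple" not in summary["max_rate"]


class TestStopCarryover:
    def test_stop_fraction_cases(self):
        rounds = {
            "all": ["T*WLH"] * 5,
            "none": ["TQWLH"] * 5,
            "mixed": ["T*WLH"] * 27 + ["TQWLH"] * 173,
        }
        assert stop_fraction(rounds) == [1.0, 0.0, 0.135]

    def test_empty_round_errors(self):
        with pytest.raises(ValueError):
            stop_fraction({"naive": []})

    def test_lambda_arithmetic(self):
        est = estimate_carryover([0.135, 0.0405])
        assert est.lambdas == (pytest.approx(0.3),)
        assert estimate_carryover([0.1, 0.1]).lambdas == (1.0,)

    def test_zero_then_positive_is_flagged(self):
        est = estimate_carryover([0.0, 0.1])
        assert est.lambdas == (None,)
        assert est.flagged == (True,)

    def test_single_round_errors(self):
        with pytest.raises(ValueError):
            estimate_carryover([0.1])


class TestCAI:
    def test_all_optimal_codons_give_one(self):
        ref = CAIReference.yeast_highly_expressed()
        optimal = [c for c, w in ref.w.items() if w == 1.0]
        assert cai("".join(optimal), ref) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        ref = CAIReference(w={"GCT": 1.0, "GCC": 0.25, "TGG": 1.0})
        assert cai("GCTGCC", ref) == pytest.approx(0.5)

    def test_stop_codons_skipped(self):
        ref = CAIReference(w={"GCT": 1.0, "GCC": 0.25})
        assert cai("GCCTAG", ref) == pytest.approx(0.25)

    def test_unknown_codon_errors(self):
        ref = CAIReference(w={"GCT": 1.0})
        with pytest.raises(ValueError):
            cai("GCTAAA", ref)

    def test_matches_brute_force_product(self, rng):
        ref = CAIReference.yeast_highly_expressed()
        codons = list(rng.choice(list(ref.w), size=30))
        expected = math.prod(ref.w[c] for c in codons) ** (1 / 30)
        assert cai(codons, ref) == pytest.approx(expected)

    def test_from_frequencies_normalizes_families(self):
        ref = CAIReference.from_frequencies({"GCT": 40.0, "GCC": 10.0, "TGG": 7.0})
        assert ref.w["GCT"] == 1.0
        assert ref.w["GCC"] == pytest.approx(0.25)
        assert ref.w["TGG"] == 1.0


class TestLibraryCoverage:
    def test_observed_study_scale(self):
        assert library_coverage(1_700_000, 5) == pytest.approx(41.63, abs=0.01)

    def test_full_and_empty(self):
        assert library_coverage(21**5, 5) == 100.0
        assert library_coverage(0, 5) == 0.0

    def test_overfull_errors(self):
        with pytest.raises(ValueError):
            library_coverage(21**5 + 1, 5)


def test_rank_order_tracks_true_fitness(rng):
    """Estimated rates rank-match true fitness up to multinomial noise."""
    from scipy.stats import spearmanr
    from bridgedms.sim_dms import SimConfig, generate_library, simulate_rounds

    cfg = SimConfig(seed=11, library_size=120, reads_per_round=200_000,
                    fitness_log_sigma=1.2)
    pool = generate_library(cfg, rng)
    series = simulate_rounds(pool, cfg, rng)
    functional = pool.weights > 0
    naive = series.counts[0]
    ps1 = series.counts[1]
    ok = functional & (naive >= 15)
    rates = (ps1[ok] / ps1.sum()) / (naive[ok] / naive.sum())
    rho = spearmanr(rates, pool.weights[ok]).statistic
    assert rho > 0.95
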