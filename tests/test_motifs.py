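"""Motif scanning, classification, scoring, controls and KS comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnabubble import (
    AnchoredSequence,
    DEFAULT_MOTIFS,
    MotifDefinition,
    NucleotideSequence,
    OpeningProfile,
    SiteOccurrence,
    classify_sites,
    compare_distributions,
    compile_iupac,
    find_sites,
    run_signature_analysis,
    sample_random_sites,
    score_site,
    select_nonoverlapping,
    shuffle_motif,
)
from dnabubble.motifs import expand_iupac
from dnabubble.simulate import FixtureSpec, Planting, generate_collection

from conftest import random_seq

TATA = DEFAULT_MOTIFS[0]
INR = DEFAULT_MOTIFS[1]


def _anchored(bases: str, tss: int, id: str = "s") -> AnchoredSequence:
    return AnchoredSequence(NucleotideSequence(id, bases), tss)


def _flat_profile(seq_id: str, n: int, k: int, values=None) -> OpeningProfile:
    vals = np.linspace(0.01, 0.99, n - k + 1) if values is None else np.asarray(values)
    return OpeningProfile(seq_id, k, vals, "test")


class TestIupac:
    def test_tatawa_expansion(self):
        pat = compile_iupac("TATAWA")
        assert pat.fullmatch("TATAAA") and pat.fullmatch("TATATA")
        assert not pat.fullmatch("TATGAA")
        assert sorted(expand_iupac("TATAWA")) == ["TATAAA", "TATATA"]

    def test_inr_example(self):
        assert compile_iupac("YYANWYY").fullmatch("CCATTCC")

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="'X'"):
            compile_iupac("TAXA")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6))
    def test_matcher_agrees_with_expansion(self, consensus):
        pat = compile_iupac(consensus)
        expansion = set(expand_iupac(consensus))
        for cand in itertools.product("ACGT", repeat=len(consensus)):
            s = "".join(cand)
            assert bool(pat.fullmatch(s)) == (s in expansion)


class TestFindSites:
    def test_planted_position_found(self, rng):
        bases = "C" * 40 + "TATAAA" + "C" * 40
        aseq = _anchored(bases, 60)
        starts = [s.start for s in find_sites(aseq, TATA)]
        assert starts == [41]

    def test_no_gc_never_matches_gc_box(self):
        aseq = _anchored("AT" * 50, 50)
        assert find_sites(aseq, DEFAULT_MOTIFS[4]) == []

    def test_overlapping_matches_reported(self):
        aseq = _anchored("TATATATA", 5)
        starts = [s.start for s in find_sites(aseq, TATA)]
        assert starts == [1, 3]


class TestClassify:
    def _sites_at(self, aseq, rel_starts, motif):
        return [
            SiteOccurrence(aseq.id, aseq.to_absolute(r), motif.length, r)
            for r in rel_starts
        ]

    def test_three_way_partition_examples(self):
        # TATA window [-33, -23]; spans below are [rel_start, rel_start+5]
        aseq = _anchored("A" * 200, 150)
        sites = self._sites_at(aseq, [-33, -60, -40], TATA)
        labels = [s.label for s in classify_sites(sites, TATA, aseq, buffer=10)]
        assert labels == ["functional", "non-functional", "buffered"]

    def test_full_span_rule(self):
        # start -25: span [-25, -20] pokes past hi=-23 -> not functional
        aseq = _anchored("A" * 200, 150)
        (lab,) = classify_sites(self._sites_at(aseq, [-25], TATA), TATA, aseq)
        assert lab.label == "buffered"

    def test_partition_is_total_on_random_sites(self, rng):
        aseq = _anchored("".join(rng.choice(list("ACGT"), 400)), 300)
        sites = find_sites(aseq, INR)
        labeled = classify_sites(sites, INR, aseq)
        assert all(
            s.label in ("functional", "buffered", "non-functional") for s in labeled
        )
        assert len(labeled) == len(sites)

    def test_buffer_width_controls_exclusion(self):
        aseq = _anchored("A" * 200, 150)
        far = self._sites_at(aseq, [-45], TATA)  # span [-45, -40], window lo -33
        with_buffer = classify_sites(far, TATA, aseq, buffer=10)[0]
        without = classify_sites(far, TATA, aseq, buffer=0)[0]
        assert with_buffer.label == "buffered"
        assert without.label == "non-functional"


class TestNonoverlapping:
    @pytest.mark.parametrize(
        "starts, length, kept",
        [
            ([1, 3], 6, [1]),
            ([1, 10], 6, [1, 10]),
            ([1, 4, 8, 20], 5, [1, 8, 20]),
        ],
    )
    def test_greedy_selection(self, starts, length, kept):
        sites = [SiteOccurrence("s", st, length, st) for st in starts]
        assert [s.start for s in select_nonoverlapping(sites)] == kept

    def test_separate_sequences_do_not_interact(self):
        sites = [
            SiteOccurrence("a", 1, 6, 1),
            SiteOccurrence("b", 3, 6, 3),
        ]
        assert len(select_nonoverlapping(sites)) == 2


class TestScoreSite:
    def test_k_below_length_averages_contained_windows(self):
        prof = _flat_profile("s", 20, 4)
        site = SiteOccurrence("s", 5, 6, 5)
        # windows contained in the site: starts 5, 6, 7
        want = prof.values[4:7].mean()
        assert score_site(prof, site) == pytest.approx(want)

    def test_k_equal_length_single_window(self):
        prof = _flat_profile("s", 20, 6)
        site = SiteOccurrence("s", 5, 6, 5)
        assert score_site(prof, site) == pytest.approx(prof.at(5))

    def test_k_above_length_averages_containing_windows(self):
        prof = _flat_profile("s", 20, 7)
        site = SiteOccurrence("s", 5, 5, 5)
        # windows containing the site: starts 3, 4, 5
        want = prof.values[2:5].mean()
        assert score_site(prof, site) == pytest.approx(want)

    def test_boundary_clipping_drops_site(self):
        prof = _flat_profile("s", 10, 7)
        assert score_site(prof, SiteOccurrence("s", 1, 5, 1)) is None

    def test_deterministic_given_fixed_profile(self):
        prof = _flat_profile("s", 30, 4)
        site = SiteOccurrence("s", 10, 6, 10)
        assert score_site(prof, site) == score_site(prof, site)


class TestControls:
    def test_random_sites_count_length_and_determinism(self, rng):
        aseq = _anchored("ACGT" * 50, 100)
        fsite = SiteOccurrence(aseq.id, 80, 6, -20, label="functional")
        sites = sample_random_sites(aseq, fsite, rng=np.random.default_rng(7))
        again = sample_random_sites(aseq, fsite, rng=np.random.default_rng(7))
        assert len(sites) == 10
        assert all(s.length == 6 for s in sites)
        assert all(1 <= s.start <= aseq.sequence.n - 5 for s in sites)
        assert [s.start for s in sites] == [s.start for s in again]

    def test_shuffle_preserves_multiset_and_differs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            out = shuffle_motif(INR, rng=rng)
            assert sorted(out) == sorted(INR.consensus)
            assert out != INR.consensus

    def test_gc_box_has_seven_arrangements(self):
        gc = DEFAULT_MOTIFS[4]
        perms = {"".join(p) for p in itertools.permutations(gc.consensus)}
        assert len(perms) == 7

    def test_homopolymer_shuffle_rejected(self):
        mono = MotifDefinition("mono", "AAAA", (-5, 5))
        with pytest.raises(ValueError, match="one distinct arrangement"):
            shuffle_motif(mono, rng=np.random.default_rng(0))


class TestCompareDistributions:
    def test_identical_samples_give_zero(self):
        res = compare_distributions([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == 0.0

    def test_fully_separated_samples_give_one(self):
        res = compare_distributions([0.1, 0.2], [0.5, 0.6, 0.7])
        assert res.statistic == 1.0

    def test_hand_computed_ecdf_supremum(self):
        a, b = [0.1, 0.2, 0.3], [0.2, 0.4]
        # ECDF_a at pooled points 0.1,0.2,0.3,0.4 = 1/3,2/3,1,1; ECDF_b = 0,1/2,1/2,1
        res = compare_distributions(a, b)
        assert res.statistic == pytest.approx(1 / 2)

    def test_matches_brute_force_supremum_on_random_pairs(self, rng):
        for _ in range(50):
            a = rng.random(int(rng.integers(1, 51)))
            b = rng.random(int(rng.integers(1, 51)))
            res = compare_distributions(a, b)
            pooled = np.concatenate([a, b])
            sup = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in pooled
            )
            assert res.statistic == pytest.approx(sup, abs=1e-14)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [0.1])

    def test_ecdf_direction_summary(self):
        res = compare_distributions([0.9, 0.8], [0.1, 0.2], "hi", "lo")
        assert res.a_ecdf_below  # higher scores -> ECDF lies below


@pytest.fixture(scope="module")
def planted_report():
    spec = FixtureSpec(
        n_sequences=40,
        length=300,
        tss_index=201,
        gc_fraction=0.5,
        plantings=(Planting("TATAAA", -30, 1.0),),
        seed=11,
    )
    collection, manifest = generate_collection(spec)
    report = run_signature_analysis(
        collection, motifs=[TATA], k=4, rng=5, coord_range=(-100, 50)
    )
    return report, manifest, collection


class TestSignatureAnalysis:

    def test_every_sequence_classified_as_containing(self, planted_report):
        report, _, collection = planted_report
        entry = report["motifs"]["TATA box"]
        assert entry["n_containing"] == len(collection)
        assert entry["n_lacking"] == 0

    def test_counts_partition(self, planted_report):
        report, _, _ = planted_report
        counts = report["motifs"]["TATA box"]["site_counts"]
        sets = report["motifs"]["TATA box"]["score_sets"]
        total_labeled = (
            counts["functional"] + counts["non-functional"] + counts["buffered"]
        )
        assert total_labeled == sum(
            len(sets[lab]) for lab in ("functional", "non-functional", "buffered")
        )
        assert counts["functional"] >= 40  # at least the planted sites

    def test_at_rich_functional_sites_score_above_random(self, planted_report):
        report, _, _ = planted_report
        comp = report["motifs"]["TATA box"]["comparisons"]["functional_vs_random"]
        assert comp["first_ecdf_below"]  # functional ECDF below = higher scores
        assert comp["pvalue"] < 0.01

    def test_report_is_seed_deterministic(self):
        spec = FixtureSpec(
            n_sequences=10, length=200, tss_index=150,
            plantings=(Planting("TATAAA", -30, 1.0),), seed=2,
        )
        collection, _ = generate_collection(spec)
        r1 = run_signature_analysis(collection, motifs=[TATA], k=3, rng=9,
                                    coord_range=(-50, 20))
        r2 = run_signature_analysis(collection, motifs=[TATA], k=3, rng=9,
                                    coord_range=(-50, 20))
        c1 = r1["motifs"]["TATA box"]["comparisons"]
        c2 = r2["motifs"]["TATA box"]["comparisons"]
        assert c1.keys() == c2.keys()
        for key in c1:
            assert c1[key]["ks_statistic"] == c2[key]["ks_statistic"]
            assert c1[key]["pvalue"] == c2[key]["pvalue"]

    def test_zero_functional_sites_skips_comparisons(self, rng):
        # GC-free sequences cannot contain a GC box anywhere
        collection = [
            AnchoredSequence(NucleotideSequence(f"s{i}", "AT" * 100), 150)
            for i in range(3)
        ]
        report = run_signature_analysis(
            collection, motifs=[DEFAULT_MOTIFS[4]], k=4, rng=0,
            coord_range=(-100, 20),
        )
        entry = report["motifs"]["GC box"]
        assert entry["site_counts"]["functional"] == 0
        assert "functional_vs_random" in entry["skipped"]
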