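"""Statistics: random-occurrence model, Tajima's D, SFS, fits, Dxy, codons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarehap import (
    Frame,
    QuadraticFit,
    SimConfig,
    accession_occurrence,
    classify_locus,
    classify_snps,
    codon_effect,
    dxy,
    expected_neutral_sfs,
    fixation_probability,
    frequency_excess,
    identify_haplotypes,
    polarize_snps,
    quadratic_fit,
    random_occurrence,
    rare_allele_extent,
    simulate_neutral_locus,
    simulate_structured_locus,
    tajima_d,
    ts_tv,
)
from rarehap.haplotypes import SnpRecord

from conftest import make_locus, random_small_locus


# ---------------------------------------------------------------------------
# random occurrence model
# ---------------------------------------------------------------------------

class TestRandomOccurrence:
    def test_study_f1_gives_printed_expectations(self):
        # 179 of 939 loci with exactly one rare-allele type -> F1 = 0.1906
        model = random_occurrence({1: 179, 2: 26, 3: 10, 4: 4, 5: 1}, 939)
        assert model.f1 == pytest.approx(0.1906, abs=5e-5)
        assert round(100 * model.expectations[2], 2) == 3.63
        assert round(100 * model.expectations[3], 2) == 0.69
        assert round(100 * model.expectations[4], 2) == 0.13
        assert round(100 * model.expectations[5], 2) == 0.03

    def test_simple_f1(self):
        model = random_occurrence({1: 50}, 100)
        assert model.expectations[2] == pytest.approx(0.25)

    def test_chi2_matches_hand_pooling(self):
        obs = {1: 179, 2: 26, 3: 10, 4: 4, 5: 1}
        n = 939
        model = random_occurrence(obs, n)
        f1 = 179 / 939
        exp = [n * f1 ** i for i in range(1, 6)]
        # expected counts: 179, 34.1, 6.5, 1.2, 0.2 -> cells 4 and 5
        # (expected < 5) pool into cell 3
        pooled_exp = [exp[0], exp[1], exp[2] + exp[3] + exp[4]]
        pooled_obs = [179, 26, 10 + 4 + 1]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(pooled_obs, pooled_exp))
        assert model.chi2 == pytest.approx(chi2)
        assert model.dof == 2
        assert model.expectations[2] > model.expectations[3] \
            > model.expectations[4] > model.expectations[5]

    def test_f1_zero_is_undefined(self):
        with pytest.raises(ValueError):
            random_occurrence({2: 5}, 100)


class TestAccessionOccurrence:
    def test_membership_probability(self):
        # 939 loci x 96 accessions with 759 rare memberships -> p = 0.8 %
        p_hat = 759 / 939 / 96
        assert round(100 * p_hat, 1) == 0.8

    def test_degenerate_no_rare_alleles(self):
        cfg = SimConfig(theta_per_site=0.0, outgroup_divergence=0.0, seed=0)
        loci = [simulate_structured_locus(cfg, i, rare=False)[0]
                for i in range(3)]
        cls = [classify_locus(l.locus_id, identify_haplotypes(l))
               for l in loci]
        occ = accession_occurrence(cls, loci[0].accession_ids)
        assert occ["histogram"] == {0: 96}
        assert occ["outliers"] == []

    def test_uniform_placement_is_calibrated(self):
        """Random implant placement should not trigger outlier flags often."""
        flagged = 0
        reps = 30
        for rep in range(reps):
            cfg = SimConfig(theta_per_site=0.0, outgroup_divergence=0.0,
                            rare_spec=((5, 7),), rare_locus_fraction=1.0,
                            seed=100 + rep)
            cls = []
            acc_ids = None
            for i in range(12):
                locus, _ = simulate_structured_locus(cfg, i, rare=True)
                acc_ids = locus.accession_ids
                cls.append(classify_locus(locus.locus_id,
                                          identify_haplotypes(locus)))
            occ = accession_occurrence(cls, acc_ids)
            flagged += bool(occ["outliers"])
        assert flagged <= reps * 0.25


# ---------------------------------------------------------------------------
# Tajima's D against an independent textbook implementation
# ---------------------------------------------------------------------------

def tajima_oracle(sequences):
    """Direct re-derivation: explicit pairwise loops, textbook constants."""
    n = len(sequences)
    cols = [
        j for j in range(len(sequences[0]))
        if all(s[j] in "ACGT" for s in sequences)
    ]
    S = sum(1 for j in cols if len({s[j] for s in sequences}) > 1)
    diffs = [
        sum(a[j] != b[j] for j in cols)
        for a, b in itertools.combinations(sequences, 2)
    ]
    pi = sum(diffs) / len(diffs)
    if S == 0 or n < 4:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimaD:
    def test_monomorphic_is_na(self):
        locus = make_locus({c: "ACGT" for c in "abcd"})
        assert tajima_d(locus).D is None

    def test_single_singleton_matches_hand_calculation(self):
        locus = make_locus({"a": "AAAA", "b": "AAAA", "c": "AAAA",
                            "d": "AAAT"})
        res = tajima_d(locus)
        assert res.S == 1
        assert res.pi == pytest.approx(0.5)  # 3 of 6 pairs differ
        oracle = tajima_oracle(["AAAA", "AAAA", "AAAA", "AAAT"])
        assert res.D == pytest.approx(oracle, abs=1e-12)

    def test_matches_oracle_on_random_alignments(self, rng):
        checked = 0
        for _ in range(100):
            locus = random_small_locus(rng, with_outgroup=False)
            res = tajima_d(locus)
            oracle = tajima_oracle([s for _, s in locus.accessions])
            if oracle is None:
                assert res.D is None
            else:
                assert res.D == pytest.approx(oracle, abs=1e-9)
                checked += 1
        assert checked >= 50

    def test_sites_with_missing_data_excluded(self):
        locus = make_locus({"a": "AANA", "b": "AA-A", "c": "AACA",
                            "d": "AACT"})
        res = tajima_d(locus)
        assert res.S == 1  # only the last column is complete and variable

    def test_neutral_simulations_center_near_zero(self):
        cfg = SimConfig(seed=42)
        ds = []
        for i in range(500):
            locus, _ = simulate_neutral_locus(cfg, locus_index=i)
            d = tajima_d(locus).D
            if d is not None:
                ds.append(d)
        assert abs(np.mean(ds)) < 0.15


# ---------------------------------------------------------------------------
# neutral SFS, excess, quadratic fits, fixation probability
# ---------------------------------------------------------------------------

class TestExpectedNeutralSfs:
    def test_n4_closed_form(self):
        # P(i=1) = 1 / (1 + 1/2 + 1/3) = 6/11
        props = expected_neutral_sfs(4, n_bins=4)
        assert props[0] == 0.0  # i/n = 0.25 falls in the second bin
        assert props[1] == pytest.approx(6 / 11)

    @pytest.mark.parametrize("n", [2, 3, 10, 96, 500])
    def test_sums_to_one(self, n):
        assert expected_neutral_sfs(n).sum() == pytest.approx(1.0)

    def test_low_frequency_bin_by_direct_summation(self):
        a96 = sum(1 / j for j in range(1, 96))
        direct = sum((1 / i) / a96 for i in range(1, 96) if i / 96 < 0.1)
        assert expected_neutral_sfs(96, 10)[0] == pytest.approx(direct)


class TestFrequencyExcess:
    def test_arithmetic(self):
        assert frequency_excess(0.2, 0.1) == pytest.approx(1.0)
        assert frequency_excess(0.194, 0.019) == pytest.approx(9.21, abs=0.01)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    @settings(derandomize=True, max_examples=30)
    def test_identity_when_equal(self, x):
        assert frequency_excess(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            frequency_excess(0.1, 0.0)


class TestQuadraticFit:
    def test_printed_extrapolations(self):
        g = QuadraticFit(c0=1315.0, c1=-4535.6, c2=4230.7, r=1.0)
        r = QuadraticFit(c0=1012.8, c1=-3221.7, c2=2695.4, r=1.0)
        assert g.y_at_1 == pytest.approx(1010.1)
        assert r.y_at_1 == pytest.approx(486.5)
        assert round(round(g.y_at_1, 1)) == 1010
        assert round(round(r.y_at_1, 1)) == 486
        share = g.y_at_1 / (g.y_at_1 + r.y_at_1)
        assert round(100 * share, 1) == 67.5

    def test_exact_quadratic_recovered(self):
        x = np.linspace(0.05, 0.95, 10)
        y = 2.0 - 3.5 * x + 1.25 * x ** 2
        fit = quadratic_fit(x, y)
        assert fit.c0 == pytest.approx(2.0, abs=1e-9)
        assert fit.c1 == pytest.approx(-3.5, abs=1e-9)
        assert fit.c2 == pytest.approx(1.25, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.y_at_1 == pytest.approx(fit.c0 + fit.c1 + fit.c2)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            quadratic_fit([0.1, 0.5], [1, 2])


class TestFixationProbability:
    @pytest.mark.parametrize("high,low,expected", [
        (882, 1378, 64.0),
        (418, 5296, 7.9),
        (7, 7, 100.0),
    ])
    def test_printed_values(self, high, low, expected):
        assert fixation_probability(high, low) == expected

    def test_zero_low_rejected(self):
        with pytest.raises(ValueError):
            fixation_probability(10, 0)


# ---------------------------------------------------------------------------
# Dxy
# ---------------------------------------------------------------------------

class TestDxy:
    def test_identical_to_outgroup_is_zero(self):
        locus = make_locus({"a": "ACGT" * 25}, outgroup="ACGT" * 25)
        assert dxy(["a"], locus).dxy == 0.0

    def test_hand_counted_divergence(self):
        seq = "A" * 100
        out = "G" * 5 + "A" * 95
        locus = make_locus({"a": seq}, outgroup=out)
        res = dxy(["a"], locus)
        assert res.dxy == pytest.approx(0.05)
        assert res.n_sites == 100

    def test_invariant_to_order_and_missing_columns(self):
        locus1 = make_locus({"a": "ACGTAC", "b": "ACGTAT"},
                            outgroup="ACGAAC")
        locus2 = make_locus({"b": "ACGTAT", "a": "ACGTAC"},
                            outgroup="ACGAAC")
        padded = make_locus({"a": "ACGTACNN", "b": "ACGTATNN"},
                            outgroup="ACGAACGG")
        v1 = dxy(["a", "b"], locus1).dxy
        assert v1 == dxy(["a", "b"], locus2).dxy
        assert v1 == dxy(["a", "b"], padded).dxy

    def test_rare_haplotype_diverges_more(self):
        wins = trials = 0
        for rep in range(100):
            cfg = SimConfig(rare_spec=((5, 10),), seed=2000 + rep)
            locus, ledger = simulate_structured_locus(cfg, 0, rare=True)
            rare = ledger.haplotypes[0].members
            major = [a for a in locus.accession_ids if a not in rare]
            d_rare = dxy(rare, locus).dxy
            d_major = dxy(major, locus).dxy
            trials += 1
            wins += d_rare > d_major
        assert wins >= 0.95 * trials


# ---------------------------------------------------------------------------
# codon effects and Ts/Tv
# ---------------------------------------------------------------------------

def _coding_snp(column, focus, other, locus_id="L"):
    return SnpRecord(locus_id=locus_id, column=column, category="dSNP",
                     minor_count=1, n_called=4, focus_allele=focus,
                     other_allele=other)


class TestCodonEffect:
    # reference: GGA TCT ATG -> Gly Ser Met
    REF = "GGATCTATG"

    def _locus(self):
        seqs = {c: self.REF for c in "abcd"}
        return make_locus(seqs, frames=[Frame(0, 9, 0, "+")])

    def test_third_position_synonymous(self):
        # GGA -> GGG, both glycine
        res = codon_effect(_coding_snp(2, "G", "A"), self._locus())
        assert res == ("synonymous", 3)

    def test_third_position_nonsynonymous(self):
        # ATG -> ATA: Met -> Ile
        res = codon_effect(_coding_snp(8, "A", "G"), self._locus())
        assert res == ("nonsynonymous", 3)

    def test_first_position_nonsynonymous(self):
        # TCT -> GCT: Ser -> Ala
        res = codon_effect(_coding_snp(3, "G", "T"), self._locus())
        assert res == ("nonsynonymous", 1)

    def test_outside_frame_uncalled(self):
        locus = make_locus({c: self.REF for c in "abcd"},
                           frames=[Frame(0, 6, 0, "+")])
        assert codon_effect(_coding_snp(8, "A", "G"), locus) is None

    def test_gapped_reference_codon_uncalled(self):
        seqs = {c: "GG-TCTATG" for c in "abcd"}
        locus = make_locus(seqs, frames=[Frame(0, 9, 0, "+")])
        assert codon_effect(_coding_snp(1, "C", "G"), locus) is None

    def test_toy_gene_matches_hand_annotation(self):
        # 9 codons; hand-annotated effects for 6 planted substitutions
        ref = "ATGGCTTCTAAAGGGTTTCCCGAGTAA"
        locus = make_locus({c: ref for c in "abcd"},
                           frames=[Frame(0, 27, 0, "+")])
        expected = {
            2: ("nonsynonymous", 3),   # ATG->ATA Met->Ile
            5: ("synonymous", 3),      # GCT->GCA Ala
            6: ("nonsynonymous", 1),   # TCT->ACT Ser->Thr
            11: ("synonymous", 3),     # AAA->AAG Lys
            13: ("nonsynonymous", 2),  # GGG->GAG Gly->Glu
            20: ("synonymous", 3),     # CCC->CCA Pro
        }
        alt = {2: "A", 5: "A", 6: "A", 11: "G", 13: "A", 20: "A"}
        for col, want in expected.items():
            got = codon_effect(_coding_snp(col, alt[col], ref[col]), locus)
            assert got == want, f"column {col}"

    def test_reverse_strand(self):
        # locus is the reverse complement of ATG GGA: gene on '-'
        ref = "TCCCAT"
        locus = make_locus({c: ref for c in "abcd"},
                           frames=[Frame(0, 6, 0, "-")])
        # column 0 is codon 2 position 3 (GGA wobble): A<->G synonymous
        res = codon_effect(_coding_snp(0, "C", "T"), locus)
        assert res == ("synonymous", 3)


class TestTsTv:
    def test_balanced_set(self):
        snps = [_coding_snp(0, *pair) for pair in
                [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]]
        assert ts_tv(snps) == 1.0

    def test_printed_precision(self):
        snps = [_coding_snp(0, "A", "G")] * 1102 \
            + [_coding_snp(0, "A", "C")] * 1000
        assert ts_tv(snps) == 1.102

    def test_no_transversions_undefined(self):
        assert ts_tv([_coding_snp(0, "A", "G")]) is None


# ---------------------------------------------------------------------------
# rare allele extent
# ---------------------------------------------------------------------------

class TestRareAlleleExtent:
    def _extended(self, core=(2000, 2500), pattern_left=0, pattern_right=0,
                  L=5000, n=12, rare=("a00", "a01")):
        rows = {f"a{i:02d}": ["A"] * L for i in range(n)}
        lo, hi = core
        for j in range(lo, hi, 50):  # the core carries the fixed pattern
            for aid in rare:
                rows[aid][j] = "C"
        for j in range(lo - pattern_left, lo, 60):
            for aid in rare:
                rows[aid][j] = "C"
        for j in range(hi, hi + pattern_right, 60):
            for aid in rare:
                rows[aid][j] = "C"
        locus = make_locus({k: "".join(v) for k, v in rows.items()})
        groups = identify_haplotypes(locus)
        hap = next(g for g in groups if g.klass != "major")
        return locus, hap

    def test_no_flank_pattern_gives_core_extent(self):
        locus, hap = self._extended()
        res = rare_allele_extent(locus, hap, core=(2000, 2500))
        assert res == {"left_bp": 0, "right_bp": 0, "total_bp": 500,
                       "truncated": False}

    def test_pattern_extends_about_800bp(self):
        locus, hap = self._extended(pattern_right=800)
        res = rare_allele_extent(locus, hap, core=(2000, 2500))
        assert res["left_bp"] == 0
        assert 500 <= res["right_bp"] <= 1000  # within one window of 800
        assert res["total_bp"] == 500 + res["right_bp"]

    def test_short_flank_flagged_truncated(self):
        locus, hap = self._extended(core=(200, 700), pattern_left=200)
        res = rare_allele_extent(locus, hap, core=(200, 700))
        assert res["truncated"]

    def test_mean_recovered_extent_tracks_generator(self, rng):
        planted, recovered = [], []
        for rep in range(10):
            ext = int(rng.integers(500, 2500))
            ext -= ext % 500  # window granularity
            locus, hap = self._extended(pattern_right=ext)
            res = rare_allele_extent(locus, hap, core=(2000, 2500))
            planted.append(ext)
            recovered.append(res["right_bp"])
        assert np.mean(recovered) == pytest.approx(np.mean(planted),
                                                   rel=0.10)
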