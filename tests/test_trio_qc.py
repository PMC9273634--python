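import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftdnm.errors import InsufficientDataError, ValidationError
from cleftdnm.models import GenotypeCall
from cleftdnm.trio_qc import (
    QCThresholds,
    apply_qc,
    het_hom_ratio,
    hwe_exact_p,
    infer_sex,
    kinship,
    mendelian_consistent,
    missingness,
    x_inbreeding_f,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-fraction enumeration over all genotype configurations with the
    observed allele counts; p = sum of probabilities <= observed."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0

    def weight(h):
        hom_a = (na - h) // 2
        hom_b = (nb - h) // 2
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_a) * math.factorial(h) * math.factorial(hom_b),
        )

    rare = min(na, nb)
    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def transmission_oracle(f: GenotypeCall, m: GenotypeCall, c: GenotypeCall) -> bool:
    child = tuple(sorted((c.allele_a, c.allele_b)))
    return any(
        tuple(sorted((fa, ma))) == child
        for fa in (f.allele_a, f.allele_b)
        for ma in (m.allele_a, m.allele_b)
    )


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


class TestMissingness:
    def test_zero_missing(self):
        assert missingness([GenotypeCall(0, 0)] * 10) == 0.0

    def test_boundary_is_retained_under_strict_rule(self):
        calls = [GenotypeCall(0, 0)] * 9 + [GenotypeCall(None, None)]
        frac = missingness(calls)
        assert frac == 0.1
        assert not frac > QCThresholds().max_missingness  # strict > 10%

    def test_fifteen_percent_fails(self):
        calls = [GenotypeCall(0, 1)] * 17 + [GenotypeCall(None, None)] * 3
        frac = missingness(calls)
        assert frac == 0.15
        assert frac > QCThresholds().max_missingness

    def test_zero_sites_is_error(self):
        with pytest.raises(InsufficientDataError):
            missingness([])


# ---------------------------------------------------------------------------
# X inbreeding / sex inference
# ---------------------------------------------------------------------------


class TestXInbreedingF:
    def test_all_homozygous_gives_f_one(self):
        f = x_inbreeding_f([0, 2] * 5, [0.5] * 10)
        assert f == pytest.approx(1.0)
        assert infer_sex(f) == "male"

    def test_expected_het_count_gives_f_zero(self):
        f = x_inbreeding_f([1] * 5 + [0] * 5, [0.5] * 10)
        assert f == pytest.approx(0.0)
        assert infer_sex(f) == "female"

    def test_derived_formula_example(self):
        # 10 sites p=0.2, 7 hom: E_hom = 10*(1-2*0.2*0.8) = 6.8 -> F = 0.2/3.2
        codes = [0] * 7 + [1] * 3
        f = x_inbreeding_f(codes, [0.2] * 10)
        assert f == pytest.approx((7 - 6.8) / (10 - 6.8))
        assert f == pytest.approx(0.0625)
        assert infer_sex(f) == "female"

    def test_monomorphic_sites_error(self):
        with pytest.raises(InsufficientDataError):
            x_inbreeding_f([0, 0], [0.0, 1.0])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------


class TestHweExact:
    def test_spec_example_2_0_2(self):
        # enumeration over n_het in {0,2,4}, multiplicities 6/48/16 -> p = 6/70
        assert hwe_exact_p(2, 0, 2) == pytest.approx(6 / 70, abs=1e-12)

    def test_spec_example_0_4_0(self):
        expected = hwe_enumeration_oracle(0, 4, 0)
        assert hwe_exact_p(0, 4, 0) == pytest.approx(expected, abs=1e-12)
        # configurations with probability <= P(n_het=4)=16/70 are {0: 6/70, 4: 16/70}
        assert expected == pytest.approx(22 / 70)

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(5, 0, 0) == 1.0

    def test_negative_counts_error(self):
        with pytest.raises(ValidationError):
            hwe_exact_p(-1, 2, 3)

    @given(
        st.integers(0, 18),
        st.integers(0, 18),
        st.integers(0, 18),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle_and_symmetry(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        p = hwe_exact_p(n_aa, n_ab, n_bb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12)
        # allele-relabeling invariance
        assert p == pytest.approx(hwe_exact_p(n_bb, n_ab, n_aa), abs=1e-12)

    def test_larger_totals_match_oracle(self):
        for counts in [(10, 20, 20), (25, 0, 25), (1, 48, 1), (30, 10, 10)]:
            assert hwe_exact_p(*counts) == pytest.approx(
                hwe_enumeration_oracle(*counts), abs=1e-12
            )


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------


class TestMendelian:
    def test_denovo_config_inconsistent(self):
        assert not mendelian_consistent(
            GenotypeCall(0, 0), GenotypeCall(0, 0), GenotypeCall(0, 1)
        )

    def test_opposite_homozygotes_consistent(self):
        assert mendelian_consistent(GenotypeCall(0, 0), GenotypeCall(1, 1), GenotypeCall(0, 1))

    def test_all_27_configurations_match_transmission_oracle(self):
        genos = [GenotypeCall(0, 0), GenotypeCall(0, 1), GenotypeCall(1, 1)]
        for f, m, c in itertools.product(genos, repeat=3):
            assert mendelian_consistent(f, m, c) == transmission_oracle(f, m, c)

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValidationError):
            mendelian_consistent(GenotypeCall(None, None), GenotypeCall(0, 0), GenotypeCall(0, 0))


# ---------------------------------------------------------------------------
# het/hom ratio
# ---------------------------------------------------------------------------


class TestHetHom:
    def test_example(self):
        assert het_hom_ratio([1, 1, 2]) == 2.0

    def test_all_hom_alt(self):
        assert het_hom_ratio([2, 2]) == 0.0

    def test_no_hom_alt_flagged_extreme_not_crash(self):
        assert het_hom_ratio([1, 1, 0]) == math.inf

    def test_clean_cohort_has_no_4sd_outlier(self):
        # oracle: recompute mean/SD externally on simulated HWE samples
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.5, size=800)
        ratios = np.array(
            [het_hom_ratio(rng.binomial(2, p).astype(np.int8)) for _ in range(100)]
        )
        z = np.abs(ratios - ratios.mean()) / ratios.std(ddof=1)
        assert (z <= 4).all()


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


class TestKinship:
    def test_self_kinship_is_half(self):
        rng = np.random.default_rng(5)
        codes = rng.binomial(2, rng.uniform(0.1, 0.5, size=500)).astype(np.int8)
        assert kinship(codes, codes) == pytest.approx(0.5)

    def test_parent_offspring_window(self):
        # oracle: direct simulation under the transmission model
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.5, size=1000)
        parent = rng.binomial(2, p)
        other = rng.binomial(2, p)
        child = (rng.random(1000) < parent / 2).astype(int) + (
            rng.random(1000) < other / 2
        ).astype(int)
        assert 0.15 <= kinship(parent, child) <= 0.35

    def test_unrelated_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.5, size=1000)
        a = rng.binomial(2, p)
        b = rng.binomial(2, p)
        assert -0.1 <= kinship(a, b) <= 0.1

    def test_insufficient_overlap_errors(self):
        with pytest.raises(InsufficientDataError):
            kinship([1] * 10, [1] * 10)


# ---------------------------------------------------------------------------
# apply_qc
# ---------------------------------------------------------------------------


class TestApplyQC:
    def test_planted_failures_excluded_with_correct_reasons(self, small_cohort, small_qc):
        truth = small_cohort.truth.qc_failures
        excluded = {t for t, r in small_qc.results.items() if not r.passed}
        assert excluded == set(truth)
        for trio_id, failure_class in truth.items():
            assert small_qc.results[trio_id].reason_categories == {failure_class}

    def test_all_clean_cohort_fully_retained(self):
        from cleftdnm.synthetic_cohort import CohortSpec, generate_cohort

        cohort = generate_cohort(
            CohortSpec(
                n_trios=8,
                qc_failures={},
                decoys={},
                n_background_autosomal=300,
                n_background_x=300,
                seed=9,
            )
        )
        outcome = apply_qc(cohort.pedigrees, cohort.trios)
        assert len(outcome.retained) == 8
        assert all(r.passed for r in outcome.results.values())

    def test_one_failing_member_excludes_whole_trio(self, small_cohort, small_qc):
        # the missingness failure was planted in the child; the trio as a whole is gone
        trio_id = next(t for t, c in small_cohort.truth.qc_failures.items() if c == "missingness")
        assert trio_id not in small_qc.retained
        reasons = small_qc.results[trio_id].reasons
        child = next(p.child_id for p in small_cohort.pedigrees if p.trio_id == trio_id)
        assert reasons == [f"missingness:{child}"]

    def test_idempotent_with_original_stats(self, small_cohort, small_qc):
        retained_peds = [p for p in small_cohort.pedigrees if p.trio_id in set(small_qc.retained)]
        rerun = apply_qc(
            retained_peds,
            {p.trio_id: small_cohort.trios[p.trio_id] for p in retained_peds},
            stats=small_qc.stats,
        )
        assert set(rerun.retained) == set(small_qc.retained)

    def test_exclusion_monotone_in_thresholds(self, small_cohort, small_qc):
        tighter = QCThresholds(max_missingness=0.05, mendelian_sd=2.0, hethom_sd=3.0)
        outcome = apply_qc(small_cohort.pedigrees, small_cohort.trios, tighter)
        assert set(outcome.retained) <= set(small_qc.retained)

    def test_needs_at_least_two_trios(self, small_cohort):
        ped = small_cohort.pedigrees[:1]
        with pytest.raises(InsufficientDataError):
            apply_qc(ped, {ped[0].trio_id: small_cohort.trios[ped[0].trio_id]})
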