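import itertools
import math

import numpy as np
import pytest
from scipy import stats

from denscan.data import Group, ReferenceGroup
from denscan.scoring import (
    bh_adjust,
    binomial_score,
    combined_score,
    evaluate_predictions,
    score_all,
    score_specimen,
    wilcoxon_exact_p,
    wilcoxon_score,
)

from conftest import reference_ids


def enumerate_binomial_midp(n_pos, k):
    """Oracle: full 2^k enumeration of the fair-coin sign space with
    half-weight on outcomes equal to the observed positive count."""
    total = 0.0
    for combo in range(k + 1):
        weight = math.comb(k, combo)
        if combo > n_pos:
            total += weight
        elif combo == n_pos:
            total += 0.5 * weight
    return total / 2**k


def brute_force_signflip(distances):
    """Oracle: exact one-sided signed-rank p by explicit sign enumeration."""
    d = np.asarray(distances, dtype=float)
    r = stats.rankdata(np.abs(d))
    nz = np.nonzero(d)[0]
    if nz.size == 0:
        return 0.5
    w_obs = r[nz][d[nz] > 0].sum()
    count = total = 0
    for signs in itertools.product([1, -1], repeat=nz.size):
        w = sum(r[i] for i, s in zip(nz, signs) if s > 0)
        count += w >= w_obs - 1e-12
        total += 1
    return count / total


class TestBinomialScore:
    def test_sixteen_of_eighteen_matches_closed_form(self):
        d = [0.1] * 16 + [-0.1] * 2
        p, score = binomial_score(d)
        assert p == pytest.approx(95.5 / 2**18)
        assert score == pytest.approx(3.44, abs=0.005)

    def test_center_count_gives_half(self):
        p, score = binomial_score([0.1] * 9 + [-0.1] * 9)
        assert p == pytest.approx(0.5)
        assert score == pytest.approx(math.log10(2), abs=1e-12)

    def test_no_matches_scores_near_zero(self):
        p, score = binomial_score([-0.2] * 5)
        assert p > 0.95
        assert score < 0.02

    def test_zero_distance_counts_against_the_match(self):
        # an exact zero sits on the reference median: not a success
        p_zero, _ = binomial_score([0.1, 0.0, 0.1])
        p_neg, _ = binomial_score([0.1, -0.1, 0.1])
        assert p_zero == p_neg

    def test_midp_equals_full_enumeration(self):
        for k in range(1, 13):
            for n_pos in range(k + 1):
                d = [1.0] * n_pos + [-1.0] * (k - n_pos)
                p, _ = binomial_score(d)
                assert p == pytest.approx(enumerate_binomial_midp(n_pos, k), abs=1e-14)

    def test_variants_are_ordered(self):
        d = [0.1] * 16 + [-0.1] * 2
        p_mid = binomial_score(d, "midp")[0]
        p_exact = binomial_score(d, "exact")[0]
        assert p_mid < p_exact  # mid-p removes half the observed mass
        with pytest.raises(ValueError):
            binomial_score(d, "bogus")

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            binomial_score([])


class TestWilcoxonScore:
    def test_perfectly_symmetric_pair_is_half(self):
        p, score = wilcoxon_score([0.3, -0.3])
        assert p == pytest.approx(0.5)
        assert score == pytest.approx(math.log10(2), abs=1e-12)

    def test_all_positive_ties(self):
        d = [0.5] * 5
        assert wilcoxon_exact_p(d) == pytest.approx(1 / 32)
        p_asym, _ = wilcoxon_score(d)
        assert p_asym < 0.05

    def test_all_negative_is_above_half(self):
        p, score = wilcoxon_score([-0.4, -0.2, -0.6])
        assert p > 0.5
        assert score < math.log10(2)

    def test_all_zero_degenerate_convention(self):
        assert wilcoxon_score([0.0, 0.0])[0] == pytest.approx(0.5)
        assert wilcoxon_exact_p([0.0, 0.0]) == pytest.approx(0.5)

    def test_asymptotic_matches_scipy_pratt(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = rng.integers(3, 16)
            d = np.round(rng.normal(size=k), 1)
            if np.all(d == 0):
                continue
            expected = stats.wilcoxon(
                d,
                zero_method="pratt",
                alternative="greater",
                correction=False,
                method="approx",
            ).pvalue
            assert wilcoxon_score(d)[0] == pytest.approx(expected, rel=1e-10)

    def test_exact_enumerator_matches_independent_bruteforce(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            k = rng.integers(2, 10)
            d = np.round(rng.normal(size=k), 1)
            assert wilcoxon_exact_p(d) == pytest.approx(
                brute_force_signflip(d), abs=1e-14
            )

    def test_exact_and_asymptotic_rank_concordant(self):
        # tie-free vectors: the two null approximations must order specimens
        # identically even where the p-values differ
        rng = np.random.default_rng(7)
        for k in range(3, 11):
            vecs = [rng.normal(size=k) for _ in range(12)]
            exact = [wilcoxon_exact_p(v) for v in vecs]
            asym = [wilcoxon_score(v)[0] for v in vecs]
            assert stats.spearmanr(exact, asym).statistic > 0.99


class TestCombinedAndBH:
    @pytest.mark.parametrize("sb,sw,expected", [(3, 4, 5), (0, 0, 0), (2.5, 0, 2.5)])
    def test_euclidean_combination(self, sb, sw, expected):
        assert combined_score(sb, sw) == pytest.approx(expected)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            combined_score(-0.1, 1.0)

    def test_bh_step_up_hand_calculation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_singleton_and_constant(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.4, 0.4, 0.4]) == pytest.approx([0.4, 0.4, 0.4])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_bh_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestEvaluatePredictions:
    def test_specimen_at_reference_median_has_zero_distances(self, study):
        from denscan.data import MeasurementMatrix
        from denscan.scoring import reference_cdf

        matrix, records, profile = study
        refs = reference_ids(records)
        # craft a specimen sitting exactly at the median of each cleaned
        # AMH reference distribution (single-reference predictions only)
        amh_only = [
            p
            for p in profile
            if p.reference_group is ReferenceGroup.AMH
            and sum(q.measurement_id == p.measurement_id for q in profile) == 1
        ]
        assert amh_only
        row = np.full(len(matrix.measurement_ids), np.nan)
        for p in amh_only:
            cdf = reference_cdf(matrix, p.measurement_id, refs[ReferenceGroup.AMH])
            med = float(np.interp(0.5, cdf.quantiles, cdf.support))
            row[matrix.col_index(p.measurement_id)] = med
        aug = MeasurementMatrix(
            matrix.specimen_ids + ["MEDIAN"],
            list(matrix.measurement_ids),
            np.vstack([matrix.values, row]),
            dict(matrix.measurement_classes),
        )
        comps = evaluate_predictions("MEDIAN", profile, aug, refs)
        assert len(comps) == len(amh_only)
        for c in comps:
            assert c.distance == pytest.approx(0.0, abs=1e-9)

    def test_distances_bounded_and_quantiles_interior(self, study):
        matrix, records, profile = study
        refs = reference_ids(records)
        comps = evaluate_predictions("TST01", profile, matrix, refs)
        assert 0 < len(comps) <= len(profile)
        for c in comps:
            assert -1 < c.distance < 1
            assert 0 < c.quantile < 1

    def test_all_profile_measurements_missing_gives_empty(self, study):
        matrix, records, profile = study
        refs = reference_ids(records)
        hollow = matrix.copy()
        i = hollow.row_index("TST02")
        for p in profile:
            hollow.values[i, hollow.col_index(p.measurement_id)] = np.nan
        assert evaluate_predictions("TST02", profile, hollow, refs) == []
        assert score_specimen("TST02", profile, hollow, refs) is None

    def test_leave_one_out_reference_scores_below_planted(self, planted_study):
        matrix, records, profile = planted_study
        scores = score_all(profile, matrix, records)
        planted = scores["PLANTED"].combined
        ref_scores = [
            scores[r.specimen_id].combined
            for r in records
            if r.group in (Group.AMH, Group.NEANDERTHAL)
            and r.specimen_id in scores
        ]
        assert np.median(ref_scores) < planted

    def test_combined_identity_holds_exactly(self, study):
        matrix, records, profile = study
        refs = reference_ids(records)
        sc = score_specimen("TST03", profile, matrix, refs)
        assert sc.combined**2 == pytest.approx(
            sc.binomial_score**2 + sc.wilcoxon_score**2, rel=1e-12
        )
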