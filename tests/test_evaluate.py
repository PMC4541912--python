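import itertools
import statistics
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fingervein as fv
from fingervein.errors import ContractError


def brute_force_far_frr(authentic, imposter, n_thresholds):
    """Pure-python per-threshold sweep oracle (FAR = % imposter < t, FRR = % authentic >= t)."""
    lo = min(min(authentic), min(imposter))
    hi = max(max(authentic), max(imposter))
    grid = [float(t) for t in np.linspace(lo, hi, n_thresholds)]
    far = [100.0 * sum(s < t for s in imposter) / len(imposter) for t in grid]
    frr = [100.0 * sum(s >= t for s in authentic) / len(authentic) for t in grid]
    return grid, far, frr


def brute_force_eer(authentic, imposter, n_thresholds):
    grid, far, frr = brute_force_far_frr(authentic, imposter, n_thresholds)
    diffs = [abs(a - b) for a, b in zip(far, frr)]
    i = diffs.index(min(diffs))
    eer = 0.5 * (far[i] + frr[i])
    for a, b in ((i, i + 1), (i - 1, i)):
        if 0 <= a and b < n_thresholds and (far[a] - frr[a]) * (far[b] - frr[b]) < 0:
            da, db = far[a] - frr[a], far[b] - frr[b]
            alpha = da / (da - db)
            far_x = far[a] + alpha * (far[b] - far[a])
            frr_x = frr[a] + alpha * (frr[b] - frr[a])
            if abs(far_x - frr_x) < diffs[i]:
                eer = 0.5 * (far_x + frr_x)
            break
    return eer


def manifest_from_labels(labels):
    return fv.DatasetManifest([(None, lab) for lab in labels])


def balanced_labels(n_classes, n_per_class):
    """One class per person, images distinguished by trial."""
    labels = []
    for p in range(n_classes):
        for t in range(n_per_class):
            labels.append(fv.SampleLabel(p, "L", "index", t))
    return labels


class TestPairCounts:
    @pytest.mark.parametrize(
        "M,N,A,I",
        [
            (120, 10, 5_400, 714_000),
            (20, 60, 35_400, 684_000),
            (2, 600, 359_400, 360_000),
            (3, 400, 239_400, 480_000),
            (198, 10, 8_910, 1_950_300),
            (636, 6, 9_540, 7_269_480),
        ],
    )
    def test_closed_form_counts(self, M, N, A, I):
        pc = fv.pair_counts(M, N)
        assert (pc.authentic, pc.imposter) == (A, I)

    def test_degenerate_cases(self):
        assert fv.pair_counts(1, 7).imposter == 0
        assert fv.pair_counts(9, 1).authentic == 0

    @pytest.mark.parametrize(
        "M,N,E,A,I",
        [
            (120, 10, 3, 100_800, 17_136_000),
            (120, 10, 5, 151_200, 35_985_600),
            (1, 10, 3, 840, 0),
        ],
    )
    def test_enrollment_counts(self, M, N, E, A, I):
        pc = fv.enrollment_pair_counts(M, N, E)
        assert (pc.authentic, pc.imposter) == (A, I)

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            fv.pair_counts(0, 5)
        with pytest.raises(ContractError):
            fv.enrollment_pair_counts(5, 4, 4)

    @pytest.mark.parametrize("M,N", list(itertools.product(range(1, 7), range(1, 7))))
    def test_counts_agree_with_exhaustive_enumeration(self, M, N):
        labels = balanced_labels(M, N)
        design = fv.DESIGNS["by_person"]
        pairs = list(fv.enumerate_pairs(manifest_from_labels(labels), design))
        n_auth = sum(1 for *_, is_auth in pairs if is_auth)
        n_imp = len(pairs) - n_auth
        pc = fv.pair_counts(M, N)
        assert (n_auth, n_imp) == (pc.authentic, pc.imposter)

    @pytest.mark.parametrize(
        "M,N,E",
        [(m, n, e) for m in (1, 2, 4) for n in (2, 4, 6) for e in range(1, 3) if e < n],
    )
    def test_enrollment_counts_agree_with_enumeration(self, M, N, E):
        subsets = len(list(itertools.combinations(range(N), E)))
        assert fv.enrollment_pair_counts(M, N, E).authentic == subsets * (N - E) * M
        assert fv.enrollment_pair_counts(M, N, E).imposter == subsets * N * (M - 1) * M


class TestEnumeratePairs:
    def test_two_classes_two_images(self):
        labels = balanced_labels(2, 2)
        pairs = list(fv.enumerate_pairs(manifest_from_labels(labels), fv.DESIGNS["by_person"]))
        assert sum(p[2] for p in pairs) == 2
        assert sum(not p[2] for p in pairs) == 4

    def test_single_class_has_no_imposters(self):
        labels = balanced_labels(1, 4)
        pairs = list(fv.enumerate_pairs(manifest_from_labels(labels), fv.DESIGNS["by_person"]))
        assert all(is_auth for *_, is_auth in pairs)

    def test_unbalanced_manifest_warns(self):
        labels = balanced_labels(2, 2) + [fv.SampleLabel(0, "L", "index", 9)]
        with pytest.warns(UserWarning, match="unbalanced"):
            list(fv.enumerate_pairs(manifest_from_labels(labels), fv.DESIGNS["by_person"]))

    def test_empty_manifest_rejected(self):
        with pytest.raises(ContractError):
            list(fv.enumerate_pairs(fv.DatasetManifest([]), fv.DESIGNS["by_person"]))


class TestFarFrrCurve:
    def test_perfectly_separable(self):
        r = fv.far_frr_curve([0.1] * 5, [0.9] * 5)
        assert r.eer == pytest.approx(0.0)

    def test_indistinguishable(self):
        scores = [0.2, 0.4, 0.5, 0.7]
        r = fv.far_frr_curve(scores, scores)
        assert r.eer == pytest.approx(50.0)

    def test_fully_interleaved_scores_are_chance_level(self):
        # FAR and FRR are both 50% for any threshold in (0.2, 0.3]
        r = fv.far_frr_curve([0.1, 0.3], [0.2, 0.4], n_thresholds=101)
        assert r.eer == pytest.approx(brute_force_eer([0.1, 0.3], [0.2, 0.4], 101))
        assert r.eer == pytest.approx(50.0)

    def test_curve_monotonicity(self, rng):
        r = fv.far_frr_curve(rng.uniform(0, 0.5, 50), rng.uniform(0.2, 1.0, 80))
        assert np.all(np.diff(r.far) >= 0)
        assert np.all(np.diff(r.frr) <= 0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        g = np.random.default_rng(seed)
        auth = list(g.uniform(0, 0.6, size=g.integers(2, 200)))
        imp = list(g.uniform(0.2, 1.0, size=g.integers(2, 200)))
        r = fv.far_frr_curve(auth, imp, n_thresholds=201)
        grid, far_o, frr_o = brute_force_far_frr(auth, imp, 201)
        np.testing.assert_allclose(r.far, far_o, atol=1e-9)
        np.testing.assert_allclose(r.frr, frr_o, atol=1e-9)
        assert r.eer == pytest.approx(brute_force_eer(auth, imp, 201), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_eer_invariant_under_increasing_transform(self, seed):
        g = np.random.default_rng(seed)
        auth = g.uniform(0, 0.6, size=120)
        imp = g.uniform(0.2, 1.0, size=150)
        base = fv.far_frr_curve(auth, imp).eer
        squashed = fv.far_frr_curve(np.tanh(2 * auth), np.tanh(2 * imp)).eer
        assert squashed == pytest.approx(base, abs=0.25)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ContractError):
            fv.far_frr_curve([], [0.5])


class TestDPrime:
    def test_identical_distributions_zero(self, rng):
        x = rng.normal(0.4, 0.05, 100)
        assert fv.d_prime(x, x).d_prime == pytest.approx(0.0)

    def test_closed_form_value(self):
        # mu_A=0.2, mu_I=0.5, sigma=0.1 each -> (0.5-0.2)/0.1 = 3
        auth = [0.1, 0.3]  # mean .2, pop std .1
        imp = [0.4, 0.6]  # mean .5, pop std .1
        assert fv.d_prime(auth, imp).d_prime == pytest.approx(3.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_statistics_module_oracle(self, seed):
        g = np.random.default_rng(seed)
        auth = list(g.uniform(0, 0.5, 60))
        imp = list(g.uniform(0.3, 1.0, 80))
        s = fv.d_prime(auth, imp)
        mu_a, mu_i = statistics.fmean(auth), statistics.fmean(imp)
        sd_a, sd_i = statistics.pstdev(auth), statistics.pstdev(imp)
        expected = (mu_i - mu_a) / ((sd_a**2 + sd_i**2) / 2) ** 0.5
        assert s.d_prime == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, rng):
        auth = rng.uniform(0, 0.4, 50)
        imp = rng.uniform(0.3, 1.0, 50)
        d1 = fv.d_prime(auth, imp).d_prime
        d2 = fv.d_prime(auth * 7.5, imp * 7.5).d_prime
        assert d2 == pytest.approx(d1)

    def test_degenerate_distributions(self):
        assert fv.d_prime([0.5, 0.5], [0.5, 0.5]).d_prime == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isinf(fv.d_prime([0.1, 0.1], [0.9, 0.9]).d_prime)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ContractError):
            fv.d_prime([0.1], [0.2, 0.3])


class TestRunExperiment:
    def test_identical_images_per_class_give_zero_eer(self, rng):
        bits = rng.integers(0, 2, size=(4, 6912), dtype=bool)
        labels = balanced_labels(4, 3)
        stacked = np.repeat(bits, 3, axis=0)  # 3 identical trials per class
        r = fv.evaluate_design(labels, stacked, fv.DESIGNS["by_person"])
        assert r.rates.eer == pytest.approx(0.0)

    def test_scores_split_matches_pair_counts(self, coded_good_db):
        labels, _, bits, D = coded_good_db
        r = fv.evaluate_design(labels, bits, fv.DESIGNS["by_finger_hand_person"], distance_matrix=D)
        pc = fv.pair_counts(M=60, N=10)
        assert (r.n_authentic, r.n_imposter) == (pc.authentic, pc.imposter)

    def test_histogram_percentages_sum_to_100(self, rng):
        scores = fv.ScoreSet(rng.uniform(0, 0.4, 200), rng.uniform(0.3, 1.0, 300))
        _, auth_pct, imp_pct = scores.histogram(50)
        assert auth_pct.sum() == pytest.approx(100.0)
        assert imp_pct.sum() == pytest.approx(100.0)

    def test_fusion_experiment_counts(self, coded_good_db):
        labels, _, bits, D = coded_good_db
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fv.run_fusion_experiment(labels, bits, 3, "product", distance_matrix=D)
        # 60 classes x 7 enrolled-image authentic decisions; 60 x 590 imposter
        assert r.n_authentic == 60 * 7
        assert r.n_imposter == 60 * 590
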