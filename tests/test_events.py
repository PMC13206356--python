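"""Event labeling, lag-aware detection metrics and group statistics."""

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import matthews_corrcoef

from thermograph.events import (
    EventSeries,
    diff_alignment,
    dilate_events,
    group_compare,
    label_low_ssim_events,
    lag_aware_detection,
    mcc,
    node_energy_group_diff,
    permutation_test,
    spike_binarize,
    subject_variability,
)


def brute_force_auroc(score, labels):
    """Pairwise-comparison AUROC oracle (ties count half)."""
    pos = score[labels == 1]
    neg = score[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEventLabeling:
    def test_quantile_count_distinct_values(self, rng):
        ssim = rng.permutation(np.linspace(0, 1, 100))
        e = label_low_ssim_events(ssim, 0.05)
        assert e.n_events == 5

    def test_quantile_count_171_transitions(self, rng):
        ssim = rng.permutation(np.linspace(0.1, 0.9, 171))
        assert label_low_ssim_events(ssim, 0.10).n_events == 17

    def test_constant_series_degenerate(self):
        e = label_low_ssim_events(np.full(50, 0.7), 0.05)
        assert e.n_events == 0 and e.degenerate

    def test_nan_entries_never_positive(self, rng):
        ssim = rng.random(60)
        ssim[0] = np.nan
        e = label_low_ssim_events(ssim, 0.10)
        assert e.labels[0] == 0


class TestDilation:
    def test_single_positive_dilates_clipped(self):
        e = EventSeries(labels=np.eye(1, 15, 10).ravel())
        d = dilate_events(e, 2)
        assert set(np.flatnonzero(d.labels)) == {8, 9, 10, 11, 12}

    def test_zero_tolerance_identity(self, rng):
        labels = (rng.random(30) < 0.2).astype(int)
        assert np.array_equal(dilate_events(EventSeries(labels=labels), 0).labels,
                              labels)

    def test_all_positive_absorbing(self):
        ones = np.ones(10, dtype=int)
        assert np.array_equal(dilate_events(EventSeries(labels=ones), 3).labels, ones)


class TestLagAwareDetection:
    def test_perfect_score(self):
        labels = EventSeries(labels=[0, 0, 1, 0, 1, 0])
        auroc, ap = lag_aware_detection(np.array(labels.labels, dtype=float), labels, 0)
        assert auroc == 1.0 and ap == 1.0

    def test_constant_score_chance_level(self):
        labels = EventSeries(labels=[0, 1, 0, 1, 0, 0])
        auroc, _ = lag_aware_detection(np.full(6, 3.3), labels, 0)
        assert auroc == pytest.approx(0.5)

    def test_near_miss_rescued_by_tolerance(self):
        # event-centric mode: a spike one index from the only event is a
        # full detection under +-2 credit, but not at zero tolerance
        score = np.zeros(10)
        score[4] = 5.0
        labels = EventSeries(labels=np.eye(1, 10, 5).ravel())
        with_tol, ap = lag_aware_detection(score, labels, 2, mode="event_max")
        without, _ = lag_aware_detection(score, labels, 0, mode="event_max")
        assert with_tol == 1.0 and ap == 1.0
        assert without < 1.0
        # dilation mode credits the spike but keeps zero-score positives
        dilated, _ = lag_aware_detection(score, labels, 2)
        assert without < dilated < with_tol

    def test_dilate_mode_unbiased_under_null(self, rng):
        # structureless scores: expected AUROC 0.5 in dilation mode, while
        # the event-max variant is optimistic (max of 2L+1 draws)
        labels = EventSeries(labels=np.eye(1, 45, 22).ravel())
        dil, ev = [], []
        for _ in range(300):
            score = rng.standard_normal(45)
            dil.append(lag_aware_detection(score, labels, 2)[0])
            ev.append(lag_aware_detection(score, labels, 2, mode="event_max")[0])
        assert abs(np.mean(dil) - 0.5) < 0.05
        assert np.mean(ev) > 0.6

    def test_degenerate_labels_undefined(self):
        auroc, ap = lag_aware_detection(np.arange(5.0), EventSeries(labels=np.zeros(5)), 0)
        assert np.isnan(auroc) and np.isnan(ap)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            score = rng.standard_normal(n)
            score[rng.random(n) < 0.2] = 0.0  # force ties
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                continue
            auroc, _ = lag_aware_detection(score, EventSeries(labels=labels), 0)
            assert auroc == pytest.approx(brute_force_auroc(score, labels))


class TestSpikesAndMCC:
    def test_matched_spike_count(self, rng):
        score = rng.permutation(np.linspace(0.01, 1, 100))
        spikes = spike_binarize(score, 0.05)
        assert np.nansum(spikes) == 5

    def test_score_equal_labels_gives_mcc_one(self):
        labels = np.array([0, 0, 1, 0, 0, 1, 0, 0, 0, 0], dtype=float)
        spikes = spike_binarize(labels, 0.2)
        assert mcc(spikes, labels) == pytest.approx(1.0)

    def test_all_nan_score_rejected(self):
        with pytest.raises(ValueError):
            spike_binarize(np.full(5, np.nan), 0.1)

    def test_mcc_perfect_and_inverted(self):
        a = np.array([0, 1, 1, 0, 1])
        assert mcc(a, a) == pytest.approx(1.0)
        assert mcc(a, 1 - a) == pytest.approx(-1.0)

    def test_mcc_frozen_confusion_example(self):
        # TP=3, TN=90, FP=2, FN=5: 260/sqrt(5*8*92*95)
        a = np.r_[np.ones(3), np.zeros(90), np.ones(2), np.zeros(5)]
        b = np.r_[np.ones(3), np.zeros(90), np.zeros(2), np.ones(5)]
        assert mcc(a, b) == pytest.approx(0.4397315594696299, abs=1e-10)
        assert mcc(a, b) == pytest.approx(matthews_corrcoef(b, a))

    def test_mcc_zero_when_factor_vanishes(self):
        assert mcc(np.zeros(6), np.array([0, 1, 0, 1, 0, 0])) == 0.0

    def test_mcc_symmetric_and_relabel_invariant(self, rng):
        a = (rng.random(40) < 0.3).astype(float)
        b = (rng.random(40) < 0.3).astype(float)
        assert mcc(a, b) == pytest.approx(mcc(b, a))
        assert mcc(1 - a, 1 - b) == pytest.approx(mcc(a, b))


class TestPermutationTest:
    def test_identical_vectors_minimal_p(self, rng):
        a = np.r_[np.ones(5), np.zeros(45)]
        p = permutation_test(a, a, n_perm=999, seed=rng)
        assert p < 0.02  # only coincidentally-equal shuffles can match MCC=1

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones(4), np.ones(4), n_perm=50)

    def test_null_p_values_super_uniform(self, rng):
        # under independence, P(p <= x) <= x (conservative add-one estimator)
        pvals = []
        for _ in range(200):
            a = (rng.random(40) < 0.15).astype(float)
            b = rng.permutation(a)
            pvals.append(permutation_test(a, b, n_perm=99, seed=rng))
        pvals = np.array(pvals)
        for x in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / 200)

    def test_seeded_reproducibility(self):
        a = np.r_[np.ones(4), np.zeros(30)]
        b = np.roll(a, 3)
        assert permutation_test(a, b, 199, seed=7) == permutation_test(a, b, 199, seed=7)


class TestAlignmentAndGroups:
    def test_diff_alignment_self_and_negation(self, rng):
        s = np.cumsum(rng.standard_normal(30))
        assert diff_alignment(s, s) == pytest.approx(1.0)
        assert diff_alignment(s, -s) == pytest.approx(-1.0)

    def test_truncated_vs_full_entropy_anti_alignment(self, rng):
        # spectra whose leading-mode mass share fluctuates over time: when
        # mass moves into the top modes, the plain truncated entropy rises
        # while full-spectrum dispersion falls, so the differenced series
        # anti-align
        from thermograph.thermo import entropy_from_probabilities

        n = 40
        sce, vne = [], []
        for conc in rng.uniform(0.2, 0.8, 20):
            # top 5 modes carry `conc` of the spectral mass (trace n)
            top = np.full(5, conc * n / 5)
            tail = np.full(n - 5, (1 - conc) * n / (n - 5))
            eigs = np.r_[top, tail]
            sce.append(entropy_from_probabilities(np.sort(eigs)[::-1][:5] / n))
            vne.append(entropy_from_probabilities(eigs / n))
        rho = diff_alignment(np.array(vne), np.array(sce))
        assert rho < 0

    def test_subject_variability(self):
        class Traj:
            U = np.array([1.0, 3.0])
            S = np.array([2.0, 2.0])

        std_u, std_s = subject_variability(Traj())
        assert std_u == pytest.approx(np.sqrt(2))
        assert std_s == 0.0

    def test_variability_order_invariant(self, rng):
        class Traj:
            U = rng.random(20)
            S = rng.random(20)

        t = Traj()
        ref = subject_variability(t)
        perm = rng.permutation(20)
        t.U, t.S = t.U[perm], t.S[perm]
        assert subject_variability(t) == pytest.approx(ref)

    def test_group_compare_identical_and_disjoint(self, rng):
        a = rng.standard_normal(30)
        ks, _, kl = group_compare(a, a.copy())
        assert ks == 0.0 and kl == pytest.approx(0.0, abs=1e-6)
        ks, p, _ = group_compare(np.arange(10.0), np.arange(100.0, 110.0))
        assert ks == 1.0 and p < 1e-4

    def test_group_compare_shifted_normals_bracket(self, rng):
        # bracket established by a 5000-rep Monte-Carlo of ks_2samp at the
        # same sample sizes: observed range [0.171, 0.761]
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 35)
        ks, p, kl = group_compare(a, b)
        assert 0.15 <= ks <= 0.8
        assert kl > 0

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], [4, 5, 6, 7, 8])


class TestNodeEnergyGroupDiff:
    def test_identical_groups_zero_diff(self, rng):
        a = rng.random((6, 10))
        table = node_energy_group_diff(a, a.copy())
        assert np.allclose(table["diff"], 0.0)

    def test_planted_shift_ranks_first(self, rng):
        base = rng.random((8, 12))
        shifted = base.copy()
        shifted[:, 7] += 5.0
        table = node_energy_group_diff(shifted, base)
        assert table.iloc[0]["index"] == 7 and table.iloc[0]["rank"] == 1

    def test_label_join_schema(self, rng):
        import pandas as pd

        labels = pd.DataFrame({
            "index": [0, 1], "label": ["Right_V2", "Right_PEF"],
            "function": ["visual", "attention"],
        })
        table = node_energy_group_diff(rng.random((5, 3)), rng.random((5, 3)),
                                       labels=labels)
        assert {"index", "diff", "abs_diff", "rank", "label", "function"} \
            <= set(table.columns)
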