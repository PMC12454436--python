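"""Phase splitting, cluster permutation statistics and pattern similarity."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fingerdec as fd
from fingerdec import decoder as dec
from fingerdec.data import EpochSet
from fingerdec.phase import (
    PhaseSplit, _clusters_1d, cluster_permutation_f, f_oneway_two_groups,
    latent_contrast, pattern_similarity, split_phases,
)
from fingerdec.simulate import ConfigurationError


def _labeled_epochs(n, blocks):
    data = np.random.default_rng(0).standard_normal((n, 2, 10))
    return EpochSet(data=data, times=np.arange(10) / 10.0 - 0.5, sfreq=10.0,
                    labels=np.array(["LI"] * n), block=np.asarray(blocks))


class TestSplitPhases:
    def test_default_split_counts(self):
        table = fd.generate_trial_table(fd.SRTTConfig())
        x = _labeled_epochs(1440, table["block"].to_numpy())
        a, b = split_phases(x)
        assert a.n_trials == 360 and b.n_trials == 360
        assert set(a.block) == {1, 2, 3} and set(b.block) == {10, 11, 12}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            PhaseSplit(frozenset({1, 2}), frozenset({2, 3})).validate()

    def test_custom_single_block_split(self):
        table = fd.generate_trial_table(fd.SRTTConfig())
        x = _labeled_epochs(1440, table["block"].to_numpy())
        a, b = split_phases(x, PhaseSplit(frozenset({1}), frozenset({12})))
        assert a.n_trials == 120 and b.n_trials == 120

    def test_empty_phase_rejected(self):
        x = _labeled_epochs(10, [1] * 10)
        with pytest.raises(ConfigurationError):
            split_phases(x, PhaseSplit(frozenset({1}), frozenset({12})))


class TestFStatistic:
    def test_matches_scipy_anova_everywhere(self, rng):
        a = rng.standard_normal((9, 3, 12))
        b = 0.3 + rng.standard_normal((7, 3, 12))
        F = f_oneway_two_groups(a, b)
        for c in range(3):
            for t in range(12):
                ref = stats.f_oneway(a[:, c, t], b[:, c, t]).statistic
                assert abs(F[c, t] - ref) < 1e-10

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            f_oneway_two_groups(np.zeros((1, 2, 3)), np.zeros((5, 2, 3)))

    def test_cluster_extraction(self):
        F = np.array([0.0, 3.0, 4.0, 1.0, 5.0, 5.0, 5.0, 0.0])
        cl = _clusters_1d(F, 2.0)
        assert cl == [(1, 3, 7.0), (4, 7, 15.0)]


class TestClusterPermutation:
    def test_identical_groups_never_significant(self, rng):
        x = rng.standard_normal((8, 2, 15))
        F, thr, clusters, ps = cluster_permutation_f(x, x.copy(),
                                                     n_permutations=200, seed=0)
        for comp_ps in ps:
            assert (comp_ps >= 0.05).all() if comp_ps.size else True

    def test_exhaustive_p_matches_bruteforce_oracle(self, rng):
        # 6+6 trials, 2 components, 10 time points; mean offset in
        # component 1, times 4-6.  Oracle: enumerate all 924 assignments
        # with an independent implementation written here.
        a = rng.standard_normal((6, 2, 10))
        b = rng.standard_normal((6, 2, 10))
        b[:, 1, 4:7] += 2.5
        F_obs, thr, clusters, ps = cluster_permutation_f(a, b,
                                                         n_permutations=None)
        pooled = np.concatenate([a, b], axis=0)
        n = 12

        def max_mass(Frow):
            best, cur = 0.0, 0.0
            for v in Frow:
                cur = cur + v if v > thr else 0.0
                best = max(best, cur)
            return best

        for comp in range(2):
            null = []
            for g1 in combinations(range(n), 6):
                g2 = [i for i in range(n) if i not in g1]
                x1, x2 = pooled[list(g1), comp, :], pooled[g2, comp, :]
                n1, n2 = 6, 6
                m1, m2 = x1.mean(0), x2.mean(0)
                gm = (m1 + m2) / 2
                ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
                ssw = ((x1 - m1) ** 2).sum(0) + ((x2 - m2) ** 2).sum(0)
                null.append(max_mass(ssb / (ssw / (n1 + n2 - 2))))
            null = np.array(null)
            for (i, j, mass), p_mod in zip(clusters[comp], ps[comp]):
                # tolerate float-path differences in ties with the observed mass
                p_oracle = (null >= mass - 1e-9 * max(mass, 1.0)).mean()
                assert abs(p_mod - p_oracle) < 1e-12
        # the injected effect is detected in component 1, not component 0
        assert any(p < 0.05 for p in ps[1])
        assert all(p >= 0.05 for p in ps[0]) or len(ps[0]) == 0

    def test_random_permutation_p_close_to_exhaustive(self, rng):
        a = rng.standard_normal((6, 1, 10))
        b = rng.standard_normal((6, 1, 10))
        b[:, 0, 3:6] += 1.5
        _, _, cl_ex, ps_ex = cluster_permutation_f(a, b, n_permutations=None)
        _, _, cl_r, ps_r = cluster_permutation_f(a, b, n_permutations=2000,
                                                 seed=3)
        assert cl_ex == cl_r
        for pe, pr in zip(ps_ex[0], ps_r[0]):
            assert abs(pe - pr) < 0.03

    def test_cross_check_against_mne_clusters(self, rng):
        # independent route: mne's cluster permutation on the same data
        from mne.stats import permutation_cluster_test
        a = rng.standard_normal((10, 1, 20))
        b = rng.standard_normal((10, 1, 20))
        b[:, 0, 8:14] += 1.2
        F, thr, clusters, ps = cluster_permutation_f(a, b, n_permutations=500,
                                                     seed=1)
        _, mne_clusters, mne_ps, _ = permutation_cluster_test(
            [a[:, 0, :], b[:, 0, :]], threshold=thr, n_permutations=500,
            tail=1, stat_fun=None, seed=1, verbose="error", out_type="indices")
        ours = {(i, j) for i, j, _ in clusters[0]}
        theirs = {(int(idx[0].min()), int(idx[0].max()) + 1)
                  for idx in mne_clusters}
        assert ours == theirs
        sig_ours = {(i, j) for (i, j, _), p in zip(clusters[0], ps[0])
                    if p < 0.05}
        sig_theirs = {c for c, p in zip(sorted(theirs), np.atleast_1d(mne_ps))
                      if p < 0.05}
        assert sig_ours == sig_theirs


class TestPatternSimilarity:
    def test_basic_values(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        assert pattern_similarity(a, a) == pytest.approx(1.0)
        assert pattern_similarity(a, b) == pytest.approx(0.0)
        assert pattern_similarity(a, -a) == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            pattern_similarity(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            pattern_similarity(np.zeros(3), np.ones(3))

    def test_raw_variant(self):
        a = np.array([2.0, 0.0])
        assert pattern_similarity(a, a, normalized=False) == pytest.approx(4.0)

    @given(scale_a=st.floats(0.01, 100), scale_b=st.floats(0.01, 100),
           seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance_and_bounds(self, scale_a, scale_b, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(8), r.standard_normal(8)
        s = pattern_similarity(a, b)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert pattern_similarity(scale_a * a, scale_b * b) == pytest.approx(s)


class TestLatentContrast:
    def _model(self, n=6, k=2, t=20):
        hp = dec.LFCNNHyperparams(n_channels=n, n_times=t, k=k, p=3,
                                  pool_factor=4, n_classes=2, seed=0)
        return dec.build_model(hp)

    def _epochs(self, data):
        n, _, t = data.shape
        return EpochSet(data=data, times=np.arange(t) / 20.0 - 0.5, sfreq=20.0,
                        labels=np.array(["LI"] * n),
                        block=np.ones(n, dtype=int))

    def test_exact_null_no_significant_clusters(self, rng):
        m = self._model()
        x = self._epochs(rng.standard_normal((10, 6, 20)))
        res = latent_contrast(m, x, x, n_permutations=200, seed=0)
        assert res.n_significant_components == 0

    def test_detects_injected_difference_and_attaches_similarity(self, rng):
        m = self._model()
        m.W = np.abs(m.W)       # ensure a common offset survives projection
        base = rng.standard_normal((14, 6, 20))
        shifted = rng.standard_normal((14, 6, 20))
        shifted[:, :, 8:14] += 2.0
        a, b = self._epochs(base), self._epochs(shifted)
        res = latent_contrast(m, a, b, n_permutations=300, seed=1)
        assert res.n_significant_components >= 1
        assert res.similarities.size >= 1
        assert (np.abs(res.similarities) <= 1.0 + 1e-12).all()
        tab = res.cluster_table()
        assert {"component", "start_s", "end_s", "mass", "p"} <= set(tab.columns)
        assert (tab["mass"] > 0).all()

    def test_too_few_trials(self, rng):
        m = self._model()
        with pytest.raises(ValueError):
            latent_contrast(m, self._epochs(rng.standard_normal((1, 6, 20))),
                            self._epochs(rng.standard_normal((5, 6, 20))))
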