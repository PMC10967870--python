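import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from eegstim import stats as est


def brute_force_paired_cluster_p(a, b, cluster_alpha=0.05):
    """Independent oracle: exhaustive sign-flip null for the paired
    1-D cluster test, written with plain loops."""
    diffs = a - b
    n, nb = diffs.shape
    thr = sps.t.ppf(1 - cluster_alpha / 2, n - 1)

    def tstat(d):
        return d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))

    def clusters(t):
        out = []
        for sign in (1, -1):
            lab, k = ndimage.label(sign * t > thr)
            for i in range(1, k + 1):
                idx = np.flatnonzero(lab == i)
                out.append((idx, t[idx].sum()))
        return out

    obs = clusters(tstat(diffs))
    null = []
    for signs in itertools.product((1, -1), repeat=n):
        t = tstat(diffs * np.array(signs)[:, None])
        null.append(max((abs(m) for _, m in clusters(t)), default=0.0))
    null = np.array(null)
    return [(idx, mass, float((null >= abs(mass)).mean())) for idx, mass in obs]


class TestClusterPermutation:
    def test_paired_p_values_match_exhaustive_enumeration(self, rng):
        a = rng.normal(size=(4, 6))
        b = rng.normal(size=(4, 6))
        b[:, 2:4] -= 2.0  # force at least one supra-threshold cluster
        oracle = brute_force_paired_cluster_p(a, b)
        res = est.cluster_permutation(a, b, dimension="time", paired=True,
                                      n_perm=2000, seed=0)
        assert res.exact
        assert len(res.clusters) == len(oracle)
        got = sorted((tuple(c.members), round(c.mass, 10), c.p)
                     for c in res.clusters)
        want = sorted((tuple(idx.tolist()), round(mass, 10), p)
                      for idx, mass, p in oracle)
        for (gm, gmass, gp), (wm, wmass, wp) in zip(got, want):
            assert gm == wm
            assert gmass == pytest.approx(wmass)
            assert gp == wp  # exact equality of exhaustive p values

    def test_identical_conditions_give_no_clusters(self, rng):
        a = rng.normal(size=(5, 30))
        res = est.cluster_permutation(a, a.copy(), paired=True, n_perm=100,
                                      seed=0)
        assert res.clusters == []

    def test_affine_invariance_of_p_values(self, rng):
        a = rng.normal(size=(8, 40))
        b = rng.normal(size=(8, 40)) + 0.9
        r1 = est.cluster_permutation(a, b, paired=False, n_perm=300, seed=5)
        r2 = est.cluster_permutation(3.0 * a + 10, 3.0 * b + 10, paired=False,
                                     n_perm=300, seed=5)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
        assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]

    def test_seeded_runs_reproducible(self, rng):
        a = rng.normal(size=(10, 25))
        b = rng.normal(size=(10, 25)) + 0.7
        r1 = est.cluster_permutation(a, b, paired=False, n_perm=400, seed=9)
        r2 = est.cluster_permutation(a, b, paired=False, n_perm=400, seed=9)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_time_frequency_clustering_4_connectivity(self, rng):
        a = rng.normal(size=(10, 8, 12))
        b = rng.normal(size=(10, 8, 12))
        b[:, 2:4, 3:6] -= 3.0
        res = est.cluster_permutation(a, b, dimension="time-frequency",
                                      paired=True, n_perm=200, seed=2)
        big = max(res.clusters, key=lambda c: abs(c.mass))
        members = set(big.members)
        assert {(2, 3), (3, 5)} <= members
        assert big.p <= 0.05

    def test_paired_unequal_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="equal"):
            est.cluster_permutation(rng.normal(size=(4, 5)),
                                    rng.normal(size=(3, 5)), paired=True)


class TestTopoCompare:
    def test_injected_channel_effect_found(self, rng):
        labels = ("C3", "C1", "Cz", "C2", "C4")
        adj = {"C3": {"C1"}, "C1": {"C3", "Cz"}, "Cz": {"C1", "C2"},
               "C2": {"Cz", "C4"}, "C4": {"C2"}}
        a = rng.normal(size=(10, 5))
        b = rng.normal(size=(10, 5))
        b[:, :2] -= 2.5  # attenuate C3/C1 in group B
        res = est.topo_compare(pd.DataFrame(a, columns=labels),
                               pd.DataFrame(b, columns=labels),
                               adjacency=adj, n_perm=500, seed=1)
        sig = res.significant
        assert sig
        assert set(sig[0].members) & {"C3", "C1"}

    def test_identical_groups_nothing_significant(self, rng):
        labels = ("C3", "C4")
        a = rng.normal(size=(6, 2))
        res = est.topo_compare(a, a.copy(), labels=labels,
                               adjacency={"C3": {"C4"}, "C4": {"C3"}},
                               n_perm=200, seed=0)
        assert not res.significant

    def test_single_channel_montage_forms_own_cluster(self, rng):
        a = rng.normal(size=(8, 1))
        b = rng.normal(size=(8, 1)) + 4.0
        res = est.topo_compare(a, b, labels=("Cz",), adjacency={"Cz": set()},
                               n_perm=300, seed=0)
        assert res.clusters[0].members == ["Cz"]
        assert res.clusters[0].p <= 0.05

    def test_montage_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(4, 2)), columns=["C3", "C4"])
        b = pd.DataFrame(rng.normal(size=(4, 2)), columns=["C3", "Cz"])
        with pytest.raises(ValueError, match="montage"):
            est.topo_compare(a, b)


class TestParametricBattery:
    @staticmethod
    def _table(rng, n_subj=6, effect=0.0):
        rows = []
        for g in ("control", "stroke"):
            for s in range(n_subj):
                for k, scheme in enumerate(("FVS-1", "FVS-2", "NMES-1")):
                    rows.append({"group": g, "subject": s, "scheme": scheme,
                                 "value": rng.normal()
                                 + (effect * k if g == "control" else 0.0)})
        return pd.DataFrame(rows)

    def test_battery_produces_all_analyses(self, rng):
        out = est.parametric_battery(self._table(rng, effect=1.0))
        assert {"mixed_anova", "rm_anova", "rm_posthoc", "paired_t",
                "independent_t"} <= set(out["analysis"])
        assert out["p"].between(0, 1).all()

    def test_independent_t_matches_closed_form(self):
        # textbook 3+3 dataset: t = (2-5)/sqrt(s2p*(2/3)) = -3.6742
        x = np.array([1.0, 2.0, 3.0])[:, None]
        y = np.array([4.0, 5.0, 6.0])[:, None]
        t = est._independent_t(x, y)[0]
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert est.cohens_d(x.ravel(), y.ravel()) == pytest.approx(-3.0)

    def test_bonferroni_multiplication_rule(self):
        assert est.bonferroni(0.001, 28) == pytest.approx(0.028)
        assert est.bonferroni(0.5, 28) == 1.0

    def test_unbalanced_cells_rejected(self, rng):
        tab = self._table(rng)
        tab = tab[~((tab.subject == 0) & (tab.scheme == "NMES-1")
                    & (tab.group == "control"))]
        with pytest.raises(ValueError, match="unbalanced"):
            est.parametric_battery(tab)

    def test_null_anova_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(120):
            out = est.parametric_battery(self._table(rng))
            row = out[(out.analysis == "mixed_anova")
                      & (out.comparison == "Interaction")]
            pvals.append(float(row["p"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestNonparametric:
    def test_mann_whitney_exact_extreme_configuration(self):
        r = est.mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert r["U"] == 0.0
        assert r["p"] == pytest.approx(0.05)  # 1 / C(6,3)

    def test_wilcoxon_identical_pairs(self):
        with pytest.warns(UserWarning, match="identical"):
            r = est.wilcoxon_signed_rank([1, 2, 3, 4], [1, 2, 3, 4])
        assert r["p"] == 1.0

    def test_rank_biserial_antisymmetric(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=12) + 1.0
        assert est.rank_biserial(x, y) == pytest.approx(-est.rank_biserial(y, x))

    def test_battery_table(self, rng):
        plan = [("a vs b", "mann-whitney", rng.normal(size=8),
                 rng.normal(size=9)),
                ("pre vs post", "wilcoxon", rng.normal(size=7),
                 rng.normal(size=7))]
        out = est.nonparametric_battery(plan)
        assert list(out["comparison"]) == ["a vs b", "pre vs post"]
        assert out["p"].between(0, 1).all()


class TestNormalityCheck:
    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(11)
        rejected = sum(not est.normality_check(rng.normal(size=50))[0]
                       for _ in range(200))
        # binomial 95% band around 0.05 with n=200
        assert 2 <= rejected <= 19

    def test_uniform_sample_detected(self):
        rng = np.random.default_rng(12)
        rejected = sum(not est.normality_check(rng.uniform(size=200))[0]
                       for _ in range(50))
        assert rejected > 40

    def test_constant_sample_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            ok, p = est.normality_check([3.0, 3.0, 3.0, 3.0])
        assert not ok and p == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            est.normality_check([1.0, 2.0, 3.0])
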