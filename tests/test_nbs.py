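"""Network-based statistic: components, permutation engine, exchangeability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from fctopo.fc import FCMatrix
from fctopo.nbs import (
    Component,
    EdgeStats,
    edgewise_stats,
    macroarea_summary,
    nbs_permutation,
    supra_components,
)


def _edge_stats_from_p(p_edges, n):
    """Build an EdgeStats with given raw p for listed edges, p=1 elsewhere."""
    p = np.ones((n, n))
    t = np.zeros((n, n))
    for (i, j), pv in p_edges.items():
        p[i, j] = p[j, i] = pv
        t[i, j] = t[j, i] = stats.norm.isf(pv)
    return EdgeStats(t=t, p=p, direction="women_lt_men",
                     region_labels=[f"R{k}" for k in range(n)])


class TestSupraComponents:
    def test_toy_graph_two_components(self):
        es = _edge_stats_from_p({(1, 2): 1e-4, (2, 3): 1e-4, (5, 6): 1e-4}, 8)
        comps = supra_components(es, 0.005)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == (1, 2, 3)
        assert comps[1].nodes == (5, 6)

    def test_no_suprathreshold_edges_gives_empty_list(self):
        es = _edge_stats_from_p({}, 6)
        assert supra_components(es, 0.005) == []

    def test_complete_suprathreshold_graph_single_component(self):
        n = 6
        edges = {(i, j): 1e-5 for i in range(n) for j in range(i + 1, n)}
        comps = supra_components(_edge_stats_from_p(edges, n), 0.005)
        assert len(comps) == 1
        assert comps[0].extent == n * (n - 1) // 2

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        mask = np.triu(rng.random((n, n)) < 0.08, k=1)
        edges = {tuple(e): 1e-4 for e in np.argwhere(mask)}
        comps = supra_components(_edge_stats_from_p(edges, n), 0.005)
        adj = csr_matrix(mask + mask.T)
        n_comp, labels = connected_components(adj, directed=False)
        # scipy counts singletons too; compare only non-singleton components
        sizes = pd.Series(labels).value_counts()
        nontrivial = sorted(
            (sizes[sizes > 1]).index,
            key=lambda lab: -np.sum(labels == lab),
        )
        assert len(comps) == len(nontrivial)
        for comp in comps:
            labs = {labels[i] for i in comp.nodes}
            assert len(labs) == 1  # our component is one scipy component


class TestEdgewiseStats:
    def test_direction_reversal_complements_p(self, small_fc_stack):
        fcs, sess = small_fc_stack
        cov = sess[["sex", "age", "education", "handedness", "apoe4"]]
        a = edgewise_stats(fcs, cov, sess["subject_id"], sess["sex"],
                           direction="women_lt_men")
        b = edgewise_stats(fcs, cov, sess["subject_id"], sess["sex"],
                           direction="women_gt_men")
        iu = np.triu_indices(a.p.shape[0], 1)
        np.testing.assert_allclose(a.p[iu] + b.p[iu], 1.0, atol=1e-12)
        np.testing.assert_allclose(a.t[iu], -b.t[iu], atol=1e-12)

    def test_vectorized_adjustment_tracks_per_edge_mixed_model(self, small_fc_stack):
        fcs, sess = small_fc_stack
        cov = sess[["sex", "age", "education", "handedness", "apoe4"]]
        fast = edgewise_stats(fcs, cov, sess["subject_id"], sess["sex"],
                              method="ols")
        exact = edgewise_stats(fcs, cov, sess["subject_id"], sess["sex"],
                               method="lme")
        iu = np.triu_indices(fast.t.shape[0], 1)
        r = np.corrcoef(fast.t[iu], exact.t[iu])[0, 1]
        assert r > 0.95

    def test_implanted_deficit_gives_positive_median_t(self):
        import fctopo
        from fctopo.fc import ROITimeSeries, compute_fc

        cfg = fctopo.SimConfig(n_men=20, n_women=20, n_regions=10,
                               n_timepoints=100, sex_effect_scale=0.7,
                               reversal_regions=(), seed=99)
        c = fctopo.generate_cohort(cfg)
        ts = fctopo.generate_cohort_timeseries(c, cfg)
        sids = list(ts)
        fcs = [compute_fc(ROITimeSeries(ts[s], c.region_labels, s)) for s in sids]
        sess = c.sessions.set_index("session_id").loc[sids].reset_index()
        es = edgewise_stats(fcs, sess[["sex", "age", "education", "handedness",
                                       "apoe4"]],
                            sess["subject_id"], sess["sex"],
                            direction="women_lt_men")
        iu = np.triu_indices(10, 1)
        assert np.median(es.t[iu]) > 0


class TestPermutationEngine:
    def test_same_seed_reproduces_fwe_p(self, small_fc_stack):
        fcs, sess = small_fc_stack
        cov = sess[["sex", "age", "education", "handedness", "apoe4"]]
        kwargs = dict(n_perm=150, threshold=0.05, seed=42)
        a = nbs_permutation(fcs, cov, sess["subject_id"].to_numpy(),
                            sess["sex"].to_numpy(), **kwargs)
        b = nbs_permutation(fcs, cov, sess["subject_id"].to_numpy(),
                            sess["sex"].to_numpy(), **kwargs)
        assert [c.fwe_p for c in a.components] == [c.fwe_p for c in b.components]
        np.testing.assert_array_equal(a.null_max, b.null_max)

    def test_fwe_p_never_zero_and_monotone(self, small_fc_stack):
        fcs, sess = small_fc_stack
        cov = sess[["sex", "age", "education", "handedness", "apoe4"]]
        res = nbs_permutation(fcs, cov, sess["subject_id"].to_numpy(),
                              sess["sex"].to_numpy(), n_perm=150,
                              threshold=0.1, seed=7)
        extents = [c.extent for c in res.components]
        ps = [c.fwe_p for c in res.components]
        assert all(p > 0 for p in ps)
        for (e1, p1), (e2, p2) in zip(zip(extents, ps), zip(extents[1:], ps[1:])):
            assert e1 >= e2 and p1 <= p2

    def test_small_cohorts_enumerate_all_permutations(self):
        rng = np.random.default_rng(1)
        n = 5
        subj = np.arange(8).astype(str)
        sex = np.array(["M"] * 4 + ["F"] * 4)
        fcs = []
        for s in range(8):
            z = rng.standard_normal((n, n)) * 0.3
            z = np.triu(z, 1) + np.triu(z, 1).T
            fcs.append(FCMatrix(z=z, region_labels=[f"R{i}" for i in range(n)]))
        cov = pd.DataFrame({"sex": sex, "age": rng.normal(72, 4, 8),
                            "education": rng.normal(16, 2, 8),
                            "handedness": ["R"] * 8, "apoe4": [0, 1] * 4})
        with pytest.warns(UserWarning, match="enumerating"):
            res = nbs_permutation(fcs, cov, subj, sex, n_perm=100,
                                  threshold=0.05, seed=0,
                                  nuisance=("age", "education"))
        from math import comb

        assert res.n_permutations == comb(8, 4)

    def test_subject_level_permutation_controls_clustered_null(self):
        """Session-level shuffling underestimates the null spread when
        subjects contribute correlated repeated sessions; subject-level
        shuffling reproduces it."""
        rng = np.random.default_rng(3)
        n_subj, n_edges = 40, 30
        subj = np.repeat(np.arange(n_subj), 2)  # two sessions each
        true_sd = []
        for _ in range(300):
            u = rng.normal(0, 1.0, n_subj)[subj]
            y = u + rng.normal(0, 0.3, (len(subj)))
            sexs = np.repeat(np.arange(n_subj) < n_subj // 2, 2)
            t = stats.ttest_ind(y[sexs], y[~sexs])[0]
            true_sd.append(t)
        true_sd = np.std(true_sd)

        u = rng.normal(0, 1.0, n_subj)[subj]
        y = u + rng.normal(0, 0.3, len(subj))
        sess_t, subj_t = [], []
        for _ in range(300):
            perm_sess = rng.permutation(len(subj)) < len(subj) // 2
            sess_t.append(stats.ttest_ind(y[perm_sess], y[~perm_sess])[0])
            perm_subj = (rng.permutation(n_subj) < n_subj // 2)[subj]
            subj_t.append(stats.ttest_ind(y[perm_subj], y[~perm_subj])[0])
        assert np.std(sess_t) < 0.8 * true_sd      # broken exchangeability
        assert abs(np.std(subj_t) - true_sd) < 0.35 * true_sd


class TestMacroareaSummary:
    def _component(self, edges):
        return Component(nodes=tuple(sorted({n for e in edges for n in e})),
                         edges=[tuple(sorted(e)) for e in edges],
                         extent=len(edges))

    def test_within_area_component_single_diagonal_cell(self):
        comp = self._component([(0, 1), (1, 2), (0, 2)])
        areas = pd.Series({"A": "prefrontal", "B": "prefrontal", "C": "prefrontal"})
        counts = macroarea_summary(comp, areas, ["A", "B", "C"])
        assert counts.loc["prefrontal", "prefrontal"] == 3
        assert counts.to_numpy().sum() == 3

    def test_cross_area_counts_match_hand_enumeration(self):
        comp = self._component([(0, 1), (0, 2), (2, 3)])
        areas = pd.Series({"A": "temporal", "B": "temporal",
                           "C": "occipital", "D": "occipital"})
        counts = macroarea_summary(comp, areas, ["A", "B", "C", "D"])
        assert counts.loc["temporal", "temporal"] == 1    # (0,1)
        assert counts.loc["temporal", "occipital"] == 1   # (0,2)
        assert counts.loc["occipital", "temporal"] == 1   # mirror
        assert counts.loc["occipital", "occipital"] == 1  # (2,3)

    def test_total_equals_extent(self):
        rng = np.random.default_rng(5)
        labels = [f"R{i}" for i in range(10)]
        areas = pd.Series(rng.choice(["temporal", "parietal", "occipital"], 10),
                          index=labels)
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)
                 if rng.random() < 0.3]
        comp = self._component(edges)
        counts = macroarea_summary(comp, areas, labels)
        upper = np.triu(counts.to_numpy())
        assert upper.sum() == comp.extent
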