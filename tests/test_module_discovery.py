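"""Spearman panels, flat-cluster module extraction, leave-one-out stability,
per-patient module scores, and infiltration correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import stats

from chemomodules import module_discovery as md
from chemomodules import synthetic_data as sd

from conftest import average_linkage_flat_oracle


def _adata(x, genes, patients=None, cell_type="cancer"):
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    obs = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P0"] * n,
            "cell_type": cell_type,
        },
        index=[f"c{i}" for i in range(n)],
    )
    return AnnData(X=x, obs=obs, var=pd.DataFrame(index=list(genes)))


class TestSpearmanPanel:
    def test_duplicated_gene_column_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 50)
        adata = _adata(np.column_stack([v, v, rng.normal(0, 1, 50)]), ["a", "b", "c"])
        corr = md.spearman_panel(adata, ["a", "b", "c"])
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 5.0, 40)
        adata = _adata(np.column_stack([v, np.exp(v)]), ["x", "fx"])
        corr = md.spearman_panel(adata, ["x", "fx"])
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_five_cell_toy_matches_rank_then_pearson(self):
        x = np.array(
            [[1.0, 2.0], [3.0, 1.0], [2.0, 5.0], [5.0, 4.0], [4.0, 3.0]]
        )
        adata = _adata(x, ["a", "b"])
        corr = md.spearman_panel(adata, ["a", "b"])
        ra, rb = stats.rankdata(x[:, 0]), stats.rankdata(x[:, 1])
        expected = stats.pearsonr(ra, rb).statistic
        assert corr.r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_missing_panel_gene_reported(self):
        adata = _adata(np.ones((5, 1)), ["a"])
        with pytest.raises(KeyError, match="MISSING"):
            md.spearman_panel(adata, ["a", "MISSING"])

    def test_zero_variance_gene_flagged_with_zero_correlations(self):
        rng = np.random.default_rng(2)
        x = np.column_stack([np.full(30, 2.0), rng.normal(0, 1, (30, 2)).T.reshape(30, 2)])
        adata = _adata(x, ["flat", "u", "v"])
        corr = md.spearman_panel(adata, ["flat", "u", "v"])
        assert corr.zero_variance == ["flat"]
        assert corr.r[0, 1] == 0.0 and corr.r[0, 2] == 0.0
        assert corr.r[0, 0] == 1.0

    def test_population_filter_applied(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (40, 2))
        # perfectly correlated only in cancer cells
        x[:20, 1] = x[:20, 0]
        adata = _adata(x, ["a", "b"], cell_type="other")
        adata.obs.loc[adata.obs_names[:20], "cell_type"] = "cancer"
        corr = md.spearman_panel(adata, ["a", "b"], population=("cell_type", "cancer"))
        assert corr.r[0, 1] == pytest.approx(1.0)


def _corr_from_blocks(blocks, off=0.0, n=None):
    """Correlation matrix with given diagonal blocks of within-value."""
    sizes = [s for s, _ in blocks]
    n = n or sum(sizes)
    r = np.full((n, n), off)
    start = 0
    for size, val in blocks:
        r[start : start + size, start : start + size] = val
        start += size
    np.fill_diagonal(r, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return md.CorrelationMatrix(genes=genes, r=r)


class TestExtractModules:
    def test_ideal_blocks_recovered(self):
        corr = _corr_from_blocks([(3, 1.0), (4, 1.0)])
        mods = md.extract_modules(corr, linkage_distance=1.65)
        assert len(mods.modules) == 2
        recovered = sorted(tuple(sorted(m)) for m in mods.modules.values())
        assert recovered == [("g0", "g1", "g2"), ("g3", "g4", "g5", "g6")]

    def test_null_correlation_no_modules(self):
        corr = _corr_from_blocks([(8, 0.0)])
        mods = md.extract_modules(corr, linkage_distance=1.65)
        assert mods.modules == {}
        assert mods.unassigned == set(corr.genes)

    def test_gene_order_invariance(self, planted_adata):
        panel = list(planted_adata.var_names)
        corr = md.spearman_panel(planted_adata, panel)
        mods = md.extract_modules(corr, 1.65)
        rng = np.random.default_rng(7)
        shuffled = [panel[i] for i in rng.permutation(len(panel))]
        corr2 = md.spearman_panel(planted_adata, shuffled)
        mods2 = md.extract_modules(corr2, 1.65)
        a = sorted(tuple(sorted(m)) for m in mods.modules.values())
        b = sorted(tuple(sorted(m)) for m in mods2.modules.values())
        assert a == b

    def test_mean_r_criterion_enforced_post_hoc(self, planted_adata):
        corr = md.spearman_panel(planted_adata, list(planted_adata.var_names))
        mods = md.extract_modules(corr, 1.65, min_mean_r=0.15)
        pos = {g: i for i, g in enumerate(corr.genes)}
        for genes in mods.modules.values():
            assert len(genes) >= 2
            idx = [pos[g] for g in genes]
            iu = np.triu_indices(len(idx), k=1)
            assert corr.r[np.ix_(idx, idx)][iu].mean() > 0.15

    def test_raising_min_mean_r_never_adds_modules(self, planted_adata):
        corr = md.spearman_panel(planted_adata, list(planted_adata.var_names))
        counts = [
            len(md.extract_modules(corr, 1.65, min_mean_r=t).modules)
            for t in (0.05, 0.15, 0.4, 0.7)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_flat_clustering_matches_lance_williams_oracle(self):
        """For small panels the scipy linkage path must agree with a
        brute-force average-linkage agglomeration."""
        rng = np.random.default_rng(11)
        for trial in range(5):
            n = int(rng.integers(5, 13))
            # random correlation-like symmetric matrix
            a = rng.uniform(-0.5, 1.0, (n, n))
            r = (a + a.T) / 2
            np.fill_diagonal(r, 1.0)
            corr = md.CorrelationMatrix(genes=[f"g{i}" for i in range(n)], r=r)
            cut = float(rng.uniform(0.5, 3.0))
            mods = md.extract_modules(corr, cut, min_mean_r=-2.0)
            # package partition: modules plus singletons from `unassigned`
            part = {}
            for m, genes in mods.modules.items():
                for g in genes:
                    part[g] = m
            for g in mods.unassigned:
                part[g] = f"single_{g}"
            oracle = average_linkage_flat_oracle(r, cut)
            # compare partitions up to relabeling via pair agreement
            for i, j in itertools.combinations(range(n), 2):
                gi, gj = f"g{i}", f"g{j}"
                assert (part[gi] == part[gj]) == (oracle[i] == oracle[j])

    def test_planted_modules_recovered(self, planted_adata):
        corr = md.spearman_panel(planted_adata, list(planted_adata.var_names))
        mods = md.extract_modules(corr, 1.65)
        assert {tuple(sorted(m)) for m in mods.modules.values()} == {
            tuple(genes) for genes in planted_adata.uns["true_modules"].values()
        }


class TestLeaveOneOut:
    def _patient_invariant_adata(self):
        spec = sd.ModulePlantSpec(
            module_assignments=sd.make_module_assignments(3, 4, 6),
            loading=0.9,
            n_cells_per_patient=80,
            n_patients=6,
            seed=4,
        )
        return sd.generate_modular_expression(spec)

    def test_patient_invariant_structure_full_stability(self):
        adata = self._patient_invariant_adata()
        panel = list(adata.var_names)
        freq = md.leave_one_out_stability(
            adata, panel, None, linkage_distance=1.65
        )
        truth = adata.uns["true_modules"]
        for m, genes in truth.items():
            for a, b in itertools.combinations(genes, 2):
                assert freq.loc[a, b] == 1.0
        for ma, mb in itertools.combinations(sorted(truth), 2):
            for a, b in itertools.product(truth[ma], truth[mb]):
                assert freq.loc[a, b] == 0.0

    def test_frequencies_bounded_and_symmetric(self):
        adata = self._patient_invariant_adata()
        panel = list(adata.var_names)
        freq = md.leave_one_out_stability(adata, panel, None).to_numpy()
        assert freq.min() >= 0.0 and freq.max() <= 1.0
        np.testing.assert_allclose(freq, freq.T)
        np.testing.assert_allclose(np.diag(freq), 1.0)

    def test_single_patient_driven_module_drops_when_held_out(self):
        """A module whose correlation exists only in one patient's cells
        co-clusters in (n-1)/n of the leave-one-out iterations."""
        n_patients = 6
        spec = sd.ModulePlantSpec(
            module_assignments=sd.make_module_assignments(2, 4, 4),
            loading=0.95,
            n_cells_per_patient=150,
            n_patients=n_patients,
            seed=5,
            module_activity={"M2": {"P00"}},  # M2 active only in patient P00
        )
        adata = sd.generate_modular_expression(spec)
        panel = list(adata.var_names)
        freq = md.leave_one_out_stability(adata, panel, None)
        truth = adata.uns["true_modules"]
        for a, b in itertools.combinations(truth["M1"], 2):
            assert freq.loc[a, b] == 1.0
        expected = (n_patients - 1) / n_patients
        for a, b in itertools.combinations(truth["M2"], 2):
            assert freq.loc[a, b] <= expected + 1e-12


class TestModuleScores:
    def test_all_zero_expression_nothing_flagged(self):
        adata = _adata(
            np.zeros((30, 4)),
            ["a", "b", "c", "d"],
            patients=np.repeat(["P0", "P1", "P2"], 10),
        )
        mods = md.ModuleSet(
            modules={"M1": {"a", "b"}}, linkage_distance=1.65, min_mean_r=0.15
        )
        scores, flags = md.score_modules_per_patient(
            adata, mods, expression_threshold=0.01
        )
        assert (scores["M1"] == 0).all()
        assert not flags["M1"].any()

    def test_single_gene_module_reduces_to_per_patient_mean(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, (40, 3))
        patients = np.repeat(["P0", "P1"], 20)
        adata = _adata(x, ["a", "b", "c"], patients=patients)
        mods = md.ModuleSet(
            modules={"M1": {"b"}}, linkage_distance=1.65, min_mean_r=0.15
        )
        scores, _ = md.score_modules_per_patient(
            adata, mods, expression_threshold=0.0
        )
        assert scores.loc["P0", "M1"] == pytest.approx(x[:20, 1].mean())
        assert scores.loc["P1", "M1"] == pytest.approx(x[20:, 1].mean())

    def test_planted_carrier_patients_flagged(self):
        """18 of 21 patients carry the module factor; exactly those 18 exceed
        the planted threshold."""
        carriers = {f"P{i:02d}" for i in range(18)}
        spec = sd.ModulePlantSpec(
            module_assignments=sd.make_module_assignments(1, 6, 10),
            loading=0.95,
            n_cells_per_patient=150,
            n_patients=21,
            seed=8,
            module_activity={"M1": carriers},
        )
        adata = sd.generate_modular_expression(spec)
        mods = md.ModuleSet(
            modules={"M1": set(adata.uns["true_modules"]["M1"])},
            linkage_distance=1.65,
            min_mean_r=0.15,
        )
        scores, flags = md.score_modules_per_patient(adata, mods)
        flagged = set(flags.index[flags["M1"]])
        assert flagged == carriers
        assert flags["M1"].sum() == 18

    def test_patient_without_population_cells_gets_missing_score(self):
        x = np.ones((20, 2))
        patients = ["P0"] * 10 + ["P1"] * 10
        adata = _adata(x, ["a", "b"], patients=patients)
        adata.obs["cell_type"] = ["cancer"] * 10 + ["immune"] * 10
        mods = md.ModuleSet(
            modules={"M1": {"a", "b"}}, linkage_distance=1.65, min_mean_r=0.15
        )
        scores, flags = md.score_modules_per_patient(
            adata, mods, population=("cell_type", "cancer"),
            expression_threshold=0.5,
        )
        assert np.isnan(scores.loc["P1", "M1"])
        assert not flags.loc["P1", "M1"]


class TestInfiltration:
    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(9)
        n = 300
        adata = _adata(
            np.zeros((n, 1)),
            ["g"],
            patients=rng.choice(["P0", "P1", "P2"], n),
        )
        adata.obs["cell_type"] = rng.choice(["T", "NK", "B", "cancer"], n)
        infil = md.infiltration_from_labels(adata, ["T", "NK", "B"])
        np.testing.assert_allclose(infil.sum(axis=1), 100.0, atol=0.01)

    def test_monotone_relation_gives_r_one(self):
        scores = pd.DataFrame({"M1": np.arange(10.0)}, index=[f"P{i}" for i in range(10)])
        infil = pd.DataFrame(
            {"T": np.arange(10.0) ** 2}, index=[f"P{i}" for i in range(10)]
        )
        out = md.correlate_modules_with_infiltration(scores, infil)
        assert out.loc[0, "spearman_r"] == pytest.approx(1.0)

    def test_reversed_ranks_of_21_patients_r_minus_one(self):
        idx = [f"P{i:02d}" for i in range(21)]
        scores = pd.DataFrame({"M1": np.arange(1.0, 22.0)}, index=idx)
        infil = pd.DataFrame({"T": np.arange(21.0, 0.0, -1.0)}, index=idx)
        out = md.correlate_modules_with_infiltration(scores, infil)
        assert out.loc[0, "spearman_r"] == pytest.approx(-1.0)

    def test_small_n_p_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0, 1, 7)
        r_obs, p = md.spearman_with_p(x, y)
        # independent oracle: enumerate all rank permutations with scipy
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits, total = 0, 0
        for perm in itertools.permutations(range(7)):
            r = stats.pearsonr(rx, ry[list(perm)]).statistic
            total += 1
            hits += abs(r) >= abs(r_obs) - 1e-12
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_column_reported_missing(self):
        idx = [f"P{i}" for i in range(10)]
        scores = pd.DataFrame({"M1": np.ones(10)}, index=idx)
        infil = pd.DataFrame({"T": np.arange(10.0)}, index=idx)
        out = md.correlate_modules_with_infiltration(scores, infil)
        assert np.isnan(out.loc[0, "spearman_r"])
        assert np.isnan(out.loc[0, "p_value"])
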