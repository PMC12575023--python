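"""MicroME extraction and phenotype/dose association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from micronet.core import DoseDesign, PhenotypeTable, ValidationError
from micronet.micromes import (
    associate,
    cluster_differential_otus,
    extract_micromes,
    identify_biomarkers,
    mantel_test,
    module_eigenvector,
    phenotype_modules,
)


def _factor_matrix(n_samples=30, loading=0.8, n_per_factor=20, n_factors=2,
                   seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_factors))
    cols = {}
    truth = {}
    for f in range(n_factors):
        for i in range(n_per_factor):
            name = f"f{f}_o{i}"
            cols[name] = loading * z[:, f] + np.sqrt(
                1 - loading**2
            ) * rng.standard_normal(n_samples)
            truth[name] = f
    index = [f"s{i}" for i in range(n_samples)]
    return pd.DataFrame(cols, index=index), truth, z


class TestClustering:
    def test_two_planted_factors_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        matrix, truth, _ = _factor_matrix(seed=3)
        assign = cluster_differential_otus(matrix, 2)
        ari = adjusted_rand_score(
            [truth[o] for o in matrix.columns],
            [assign[o] for o in matrix.columns],
        )
        assert ari >= 0.9

    def test_identical_profiles_single_module(self):
        base = np.arange(10.0)
        m = pd.DataFrame({"a": base, "b": base, "c": base},
                         index=[f"s{i}" for i in range(10)])
        assign = cluster_differential_otus(m, 1)
        assert set(assign.values()) == {0}

    def test_deterministic(self):
        matrix, _, _ = _factor_matrix(seed=5)
        assert cluster_differential_otus(matrix, 2) == \
            cluster_differential_otus(matrix, 2)

    def test_more_modules_than_otus_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}, index=["s1", "s2"])
        with pytest.raises(ValidationError):
            cluster_differential_otus(m, 3)


class TestEigenvector:
    def test_single_otu_module_is_zscore(self):
        x = pd.Series([1.0, 4.0, 2.0, 8.0], index=list("abcd"))
        me = module_eigenvector(x.to_frame("o1"))
        z = (x - x.mean()) / x.std(ddof=0)
        np.testing.assert_allclose(me.eigenvector, z, atol=1e-12)
        assert me.variance_explained == pytest.approx(1.0)

    def test_rank_one_module_exact_recovery(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(25)
        m = pd.DataFrame({f"o{i}": (i + 1.0) * z for i in range(5)},
                         index=[f"s{i}" for i in range(25)])
        me = module_eigenvector(m)
        assert abs(np.corrcoef(me.eigenvector, z)[0, 1]) == pytest.approx(1.0)
        assert me.variance_explained == pytest.approx(1.0)

    def test_noisy_factor_recovered(self):
        """Loading 0.8 factors are recovered with |r| > 0.9 over 10 seeds."""
        for seed in range(10):
            m, _, z = _factor_matrix(n_factors=1, seed=seed)
            me = module_eigenvector(m)
            assert abs(np.corrcoef(me.eigenvector, z[:, 0])[0, 1]) > 0.9

    def test_invariant_to_order_and_scale(self):
        m, _, _ = _factor_matrix(n_factors=1, n_per_factor=6, seed=2)
        me1 = module_eigenvector(m)
        shuffled = m[list(m.columns[::-1])] * [3.0, 1.0, 0.2, 5.0, 1.0, 2.0]
        me2 = module_eigenvector(shuffled)
        np.testing.assert_allclose(
            np.abs(me1.eigenvector), np.abs(me2.eigenvector), atol=1e-8
        )

    def test_sign_oriented_by_mean_kme(self):
        m, _, _ = _factor_matrix(n_factors=1, seed=4)
        me = module_eigenvector(m)
        assert np.mean([r for r, _ in me.kme.values()]) >= 0

    def test_zero_variance_member_dropped_with_warning(self):
        m, _, _ = _factor_matrix(n_factors=1, n_per_factor=3, seed=1)
        m["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            me = module_eigenvector(m)
        assert "flat" not in me.members


class TestPhenotypeModules:
    @staticmethod
    def _pheno(values: pd.DataFrame, categories):
        units = tuple(values.index)
        return PhenotypeTable(units, values, categories,
                              {u: "CK" for u in units})

    def test_perfectly_correlated_pair_one_module(self):
        x = np.arange(12.0)
        values = pd.DataFrame({"a": x, "b": 2 * x + 1},
                              index=[f"u{i}" for i in range(12)])
        out = phenotype_modules(
            self._pheno(values, {"a": "growth", "b": "growth"}), 1
        )
        assert out.module_of == {"a": "growth1", "b": "growth1"}

    def test_orthogonal_blocks_recovered(self):
        rng = np.random.default_rng(0)
        z1, z2 = rng.standard_normal((2, 30))
        values = pd.DataFrame(
            {
                "g1": z1 + 0.1 * rng.standard_normal(30),
                "g2": -z1 + 0.1 * rng.standard_normal(30),
                "e1": z2 + 0.1 * rng.standard_normal(30),
                "e2": z2 + 0.1 * rng.standard_normal(30),
            },
            index=[f"u{i}" for i in range(30)],
        )
        cats = {"g1": "growth", "g2": "growth",
                "e1": "hepatopancreas_enzyme", "e2": "hepatopancreas_enzyme"}
        out = phenotype_modules(self._pheno(values, cats), 2)
        assert out.module_of["g1"] == out.module_of["g2"]
        assert out.module_of["e1"] == out.module_of["e2"]
        assert out.module_of["g1"] != out.module_of["e1"]
        assert out.module_of["g1"].startswith("growth")

    def test_single_variable_module_is_zscore(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        values = pd.DataFrame({"a": x, "b": rng.standard_normal(10)},
                              index=[f"u{i}" for i in range(10)])
        out = phenotype_modules(
            self._pheno(values, {"a": "growth", "b": "hemolymph"}), 2
        )
        col = out.module_of["a"]
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(
            np.abs(out.eigenvectors[col]), np.abs(z), atol=1e-10
        )


class TestAssociation:
    @staticmethod
    def _setup(seed=0):
        m, _, z = _factor_matrix(n_factors=1, seed=seed)
        mes = extract_micromes(m, {o: 0 for o in m.columns})
        values = pd.DataFrame(
            {"a": mes["MicroME1"].eigenvector.to_numpy(),
             "b": np.random.default_rng(seed + 1).standard_normal(len(m))},
            index=m.index,
        )
        pheno = phenotype_modules(
            PhenotypeTable(tuple(m.index), values,
                           {"a": "growth", "b": "hemolymph"},
                           {u: "CK" for u in m.index}),
            2,
        )
        return mes, pheno

    def test_identical_profile_gives_unit_r_and_p_floor(self):
        mes, pheno = self._setup()
        res = associate(mes, pheno, n_perm=199, seed=0)
        r_row = res.spearman_r.loc["MicroME1"].abs()
        assert r_row.max() == pytest.approx(1.0)
        assert res.mantel["MicroME1"][1] == pytest.approx(1 / 200)

    def test_spearman_matches_brute_force_ranks_on_toy(self):
        profile = pd.Series([3.0, 1.0, 4.0, 1.5, 5.0],
                            index=[f"u{i}" for i in range(5)])
        other = pd.Series([2.0, 1.0, 3.0, 2.5, 4.0], index=profile.index)
        r, _ = stats.spearmanr(profile, other)
        ra = profile.rank().to_numpy()
        rb = other.rank().to_numpy()
        brute = float(np.corrcoef(ra, rb)[0, 1])
        assert r == pytest.approx(brute, abs=1e-12)

    def test_independent_profiles_have_uniform_p(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            a, b = rng.standard_normal((2, 15))
            ps.append(stats.spearmanr(a, b)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_dose_association_flagged(self):
        """A dose-linked planted module correlates with dose at r > 0.4."""
        from micronet.differential import transform_log_relative
        from micronet.simulate import simulate_otu_table

        table, truth = simulate_otu_table(seed=3, dose_linked_modules=1)
        m = transform_log_relative(table)
        members = [o for o, mm in truth.module_assignment.items() if mm == 0]
        mes = extract_micromes(m[members], {o: 0 for o in members})
        dose = pd.Series(
            [float(table.group_of[s][1:]) * 500 for s in table.sample_ids],
            index=list(table.sample_ids),
        )
        r, p = stats.spearmanr(
            mes["MicroME1"].eigenvector.to_numpy(), dose.to_numpy()
        )
        assert abs(r) > 0.4
        assert p < 0.05

    def test_mismatched_units_rejected(self):
        mes, pheno = self._setup()
        bad = pd.Series(
            np.arange(5.0), index=[f"x{i}" for i in range(5)]
        )
        with pytest.raises(ValidationError):
            associate(mes, pheno, dose=bad)


class TestMantel:
    def test_identical_matrices_hit_floor(self):
        x = np.random.default_rng(0).standard_normal((12, 2))
        d = squareform(pdist(x))
        r, p = mantel_test(d, d, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 10, 3))
        d1, d2 = squareform(pdist(x)), squareform(pdist(y))
        r_ours, _ = mantel_test(d1, d2, n_perm=99, seed=0)
        r_oracle, _, _ = skbio_mantel(SkbioDM(d1), SkbioDM(d2),
                                      method="spearman", permutations=0)
        assert r_ours == pytest.approx(float(r_oracle), rel=1e-10)


class TestBiomarkers:
    @staticmethod
    def _microme_with_groups(seed=0):
        rng = np.random.default_rng(seed)
        group_idx = np.repeat(np.arange(5), 6)
        z = group_idx / 2.0 + 0.3 * rng.standard_normal(30)  # dose-ramped
        cols = {
            "driver": 0.95 * z + 0.1 * rng.standard_normal(30),
            "weak": 0.2 * z + rng.standard_normal(30),
        }
        index = [f"s{i}" for i in range(30)]
        m = pd.DataFrame(cols, index=index)
        me = module_eigenvector(m)
        group_of = {s: f"G{g}" for s, g in zip(index, group_idx)}
        return me, m, group_of

    def test_planted_driver_selected_weak_excluded(self):
        me, m, group_of = self._microme_with_groups()
        out = identify_biomarkers(me, m, group_of, alpha=0.05, kme_r_min=0.4)
        names = [rec["otu"] for rec in out]
        assert "driver" in names
        assert "weak" not in names

    def test_relaxed_thresholds_select_all_members(self):
        me, m, group_of = self._microme_with_groups()
        out = identify_biomarkers(me, m, group_of, alpha=1.0, kme_r_min=-1.0)
        assert {rec["otu"] for rec in out} == set(me.members)

    def test_selection_is_deterministic(self):
        me, m, group_of = self._microme_with_groups()
        a = identify_biomarkers(me, m, group_of)
        b = identify_biomarkers(me, m, group_of)
        assert a == b
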