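import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from estuarch.commstats import (
    DistanceMatrix,
    bray_curtis,
    env_correlations,
    euclidean_distance,
    mantel,
    partial_mantel,
    pcoa,
    permanova,
)
from estuarch.errors import DesignError, UndefinedCorrelationError
from estuarch.tables import FeatureTable, SampleMetadata


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return DistanceMatrix(squareform(pdist(points)), ids)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        tab = FeatureTable(
            pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]],
                         index=["a", "b", "c"], columns=["x", "y", "z"])
        )
        d = bray_curtis(tab)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_formula_example(self):
        tab = FeatureTable(
            pd.DataFrame([[2, 0, 1], [1, 1, 0]], index=["a", "b"],
                         columns=["x", "y", "z"])
        )
        assert bray_curtis(tab).values[0, 1] == pytest.approx(0.6)

    def test_all_zero_sample_rejected(self):
        tab = FeatureTable(pd.DataFrame([[1, 1], [0, 0]], index=["a", "bad"]))
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(tab)


class TestPcoa:
    def test_line_configuration_one_axis(self):
        d = _dm(np.array([[0.0], [1.0], [2.0], [5.0]]))
        coords, eig, prop = pcoa(d, 2)
        assert prop[0] == pytest.approx(1.0)
        # recovered first axis matches original spacing up to sign/shift
        x = coords["PC1"].to_numpy()
        got = squareform(pdist(x[:, None]))
        assert np.allclose(got, d.values, atol=1e-10)

    def test_planar_reconstruction(self):
        rng = np.random.default_rng(3)
        d = _dm(rng.normal(size=(12, 2)))
        coords, eig, _ = pcoa(d, 2)
        got = squareform(pdist(coords.to_numpy()))
        assert np.abs(got - d.values).max() < 1e-8

    def test_regular_simplex_equal_eigenvalues(self):
        n = 5
        vals = np.ones((n, n)) - np.eye(n)
        d = DistanceMatrix(vals, [f"s{i}" for i in range(n)])
        _, eig, _ = pcoa(d)
        pos = eig[eig > 1e-12]
        assert np.allclose(pos, pos[0])

    def test_eigenvalue_trace_identity(self):
        rng = np.random.default_rng(4)
        tab = FeatureTable(
            pd.DataFrame(rng.integers(0, 50, size=(10, 30)),
                         index=[f"s{i}" for i in range(10)])
        )
        d = bray_curtis(tab)
        _, eig, _ = pcoa(d)
        a = -0.5 * d.values**2
        j = np.eye(10) - np.ones((10, 10)) / 10
        g = j @ a @ j
        assert abs(eig.sum() - np.trace(g)) < 1e-9

    def test_n_axes_validation(self):
        d = _dm(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            pcoa(d, 4)


def _two_group_pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Classical group-sum pseudo-F oracle for a one-factor design."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ssa = sst - ssw
    return (ssa / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_matches_group_sum_oracle(self):
        rng = np.random.default_rng(5)
        d = _dm(rng.normal(size=(12, 4)))
        labels = np.array(["A"] * 6 + ["B"] * 6)
        meta = pd.DataFrame({"grp": labels}, index=d.sample_ids)
        res = permanova(d, meta, ["grp"], n_perm=99, seed=0)
        f_oracle = _two_group_pseudo_f(d.values, labels)
        assert res["grp"]["F"] == pytest.approx(f_oracle, abs=1e-9)

    def test_exhaustive_p_matches_enumeration(self):
        rng = np.random.default_rng(6)
        d = _dm(rng.normal(size=(6, 3)))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        meta = pd.DataFrame({"grp": labels}, index=d.sample_ids)
        res = permanova(d, meta, ["grp"], all_perms=True)
        # brute force: every relabeling via permutation of samples
        f_obs = _two_group_pseudo_f(d.values, labels)
        count = 0
        total = 0
        for pm in itertools.permutations(range(6)):
            dp = d.values[np.ix_(pm, pm)]
            count += _two_group_pseudo_f(dp, labels) >= f_obs - 1e-12
            total += 1
        assert res["grp"]["p"] == pytest.approx(count / total)

    def test_perfect_separation_is_degenerate(self):
        vals = np.ones((4, 4)) - np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.0
        vals[2, 3] = vals[3, 2] = 0.0
        d = DistanceMatrix(vals, list("abcd"))
        meta = pd.DataFrame({"grp": ["x", "x", "y", "y"]}, index=list("abcd"))
        res = permanova(d, meta, ["grp"], n_perm=19, seed=0)
        assert res["grp"]["R2"] == pytest.approx(1.0)
        assert np.isinf(res["grp"]["F"]) or res["grp"]["F"] > 1e12

    def test_total_ss_invariant_to_term_order(self, design_metadata):
        rng = np.random.default_rng(7)
        d = _dm(rng.normal(size=(6, 3)), ids=[f"s{i}" for i in range(1, 7)])
        r1 = permanova(d, design_metadata, ["estuary", "season"], n_perm=19, seed=0)
        r2 = permanova(d, design_metadata, ["season", "estuary"], n_perm=19, seed=0)
        assert r1.table.loc["Total", "SumOfSqs"] == pytest.approx(
            r2.table.loc["Total", "SumOfSqs"]
        )
        assert r1.table["R2"].iloc[:-1].sum() == pytest.approx(1.0)

    def test_aliased_design_raises(self):
        rng = np.random.default_rng(8)
        d = _dm(rng.normal(size=(4, 2)))
        meta = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]},
            index=d.sample_ids,
        )
        with pytest.raises(DesignError):
            permanova(d, meta, ["a", "b"], n_perm=9, seed=0)

    def test_add_one_rule_lower_bound(self):
        rng = np.random.default_rng(9)
        d = _dm(rng.normal(size=(8, 2)))
        meta = pd.DataFrame({"grp": ["A"] * 4 + ["B"] * 4}, index=d.sample_ids)
        res = permanova(d, meta, ["grp"], n_perm=99, seed=1)
        assert res["grp"]["p"] >= 1 / 100

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(10)
        d = _dm(rng.normal(size=(14, 5)))
        labels = ["A"] * 5 + ["B"] * 5 + ["C"] * 4
        meta = pd.DataFrame({"grp": labels}, index=d.sample_ids)
        ours = permanova(d, meta, ["grp"], n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids),
            meta, column="grp", permutations=99,
        )
        assert ours["grp"]["F"] == pytest.approx(theirs["test statistic"], abs=1e-9)


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _dm(np.random.default_rng(11).normal(size=(8, 3)))
        assert mantel(d, d, n_perm=99, seed=0).rho == pytest.approx(1.0)

    def test_rank_invariance_under_affine_transform(self):
        pts = np.random.default_rng(12).normal(size=(8, 3))
        d1 = _dm(pts)
        d2 = DistanceMatrix(d1.values * 3.7 + 0.0, d1.sample_ids)
        assert mantel(d1, d2, n_perm=99, seed=0).rho == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration(self):
        rng = np.random.default_rng(13)
        d1 = _dm(rng.normal(size=(5, 2)))
        d2 = _dm(rng.normal(size=(5, 2)), ids=d1.sample_ids)
        res = mantel(d1, d2, all_perms=True)
        # independent brute force with scipy primitives
        from scipy.stats import rankdata
        v1 = rankdata(squareform(d1.values, checks=False))
        count = total = 0
        for pm in itertools.permutations(range(5)):
            m = d2.values[np.ix_(pm, pm)]
            v2 = rankdata(squareform(m, checks=False))
            count += np.corrcoef(v1, v2)[0, 1] >= res.rho - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_constant_matrix_rejected(self):
        vals = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(vals, list("abcd"))
        with pytest.raises(UndefinedCorrelationError):
            mantel(d, d, n_perm=9, seed=0)


class TestPartialMantel:
    @staticmethod
    def _latent_fixture(n=25, seed=14):
        """D1 and D2 share the latent gradient D3 plus independent
        pair-level noise, so D1 is independent of D2 given D3."""
        rng = np.random.default_rng(seed)
        driver = rng.normal(size=(n, 1))
        d3 = squareform(pdist(driver))
        def noisy(seed_offset):
            noise = rng.normal(0, 0.2, size=(n, n))
            noise = np.abs(noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            vals = d3 + noise
            np.fill_diagonal(vals, 0.0)
            return DistanceMatrix(vals, [f"s{i}" for i in range(n)])
        return noisy(1), noisy(2), DistanceMatrix(d3, [f"s{i}" for i in range(n)])

    def test_conditioning_on_shared_driver_kills_correlation(self):
        d1, d2, d3 = self._latent_fixture()
        plain = mantel(d1, d2, n_perm=99, seed=0)
        partial = partial_mantel(d1, d2, d3, n_perm=99, seed=0)
        assert plain.rho > 0.5
        assert abs(partial.rho) < 0.1

    def test_irrelevant_control_changes_little(self):
        d1, d2, _ = self._latent_fixture()
        rng = np.random.default_rng(15)
        d3 = _dm(rng.normal(size=(25, 2)), ids=d1.sample_ids)
        plain = mantel(d1, d2, n_perm=99, seed=0)
        partial = partial_mantel(d1, d2, d3, n_perm=99, seed=0)
        assert abs(partial.rho - plain.rho) < 0.15

    def test_identical_triple_is_undefined(self):
        d = _dm(np.random.default_rng(16).normal(size=(6, 2)))
        with pytest.raises(UndefinedCorrelationError):
            partial_mantel(d, d, d, n_perm=9, seed=0)


class TestEnvCorrelations:
    def test_monotone_and_antimonotone(self):
        idx = [f"s{i}" for i in range(6)]
        ab = pd.DataFrame({"taxon": [1, 2, 3, 4, 5, 6]}, index=idx, dtype=float)
        env = pd.DataFrame(
            {"up": np.exp([1, 2, 3, 4, 5, 6]), "down": [6, 5, 4, 3, 2, 1]},
            index=idx, dtype=float,
        )
        out = env_correlations(ab, env).set_index("covariate")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_scipy_hand_ranking(self):
        from scipy.stats import spearmanr
        idx = [f"s{i}" for i in range(6)]
        ab = pd.DataFrame({"t": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]}, index=idx)
        env = pd.DataFrame({"e": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]}, index=idx)
        out = env_correlations(ab, env)
        rho, p = spearmanr(ab["t"], env["e"])
        assert out.loc[0, "rho"] == pytest.approx(rho)
        assert out.loc[0, "p"] == pytest.approx(p)

    def test_missing_values_pairwise_dropped_and_constant_is_nan(self):
        idx = [f"s{i}" for i in range(6)]
        ab = pd.DataFrame({"t": [1, 2, 3, 4, 5, 6]}, index=idx, dtype=float)
        env = pd.DataFrame(
            {"gap": [1.0, np.nan, 3.0, 4.0, np.nan, 6.0], "flat": [2.0] * 6},
            index=idx,
        )
        out = env_correlations(ab, env).set_index("covariate")
        assert out.loc["gap", "n"] == 4
        assert np.isnan(out.loc["flat", "rho"])


class TestEuclideanEnv:
    def test_standardized_distance_symmetry(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0], "b": [10.0, 20.0, 40.0]},
            index=["x", "y", "z"],
        )
        d = euclidean_distance(df)
        assert d.values[0, 1] == pytest.approx(d.values[1, 0])
        assert d.values[0, 0] == 0.0
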