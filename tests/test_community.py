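"""Indicator values, turnover, db-RDA, and variation partitioning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from canopylight import (
    adjusted_r2,
    braun_blanquet_to_cover,
    db_rda,
    proxy_regression,
    simpson_dissimilarity,
    variation_partition,
    weighted_indicator_mean,
)
from canopylight.community_analysis import _principal_coordinates


class TestBraunBlanquet:
    @pytest.mark.parametrize(
        "label,percent",
        [("r", 0.1), ("+", 0.5), ("1", 2.5), ("2", 15.0), ("2a", 10.0),
         ("2b", 20.5), ("3", 37.5), ("4", 62.5), ("5", 87.5)],
    )
    def test_midpoints(self, label, percent):
        assert braun_blanquet_to_cover(label) == percent

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            braun_blanquet_to_cover("6")


class TestWeightedIndicator:
    def test_single_species(self):
        assert weighted_indicator_mean([10.0], [3.0]) == 3.0

    def test_symmetric_pair(self):
        assert weighted_indicator_mean([5.0, 5.0], [2.0, 4.0]) == 3.0

    def test_weighted_pair(self):
        assert weighted_indicator_mean([75.0, 25.0], [2.0, 4.0]) == 2.5

    def test_species_without_l_excluded(self):
        assert weighted_indicator_mean([50.0, 50.0], [3.0, np.nan]) == 3.0

    def test_no_valid_species(self):
        with pytest.raises(ValueError):
            weighted_indicator_mean([0.0, 1.0], [3.0, np.nan])


class TestProxyRegression:
    def test_exact_linear(self):
        x = np.linspace(-2, 1, 10)
        res = proxy_regression(2 * x + 1, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_null_relationship(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        assert proxy_regression(y, x)["r2"] < 0.05

    def test_known_signal_to_noise(self, rng):
        # y = 2x + e: expected R^2 = var(2x)/(var(2x)+sigma^2)
        x = rng.normal(0, 1, 43)
        sigma = 1.0
        r2s = [
            proxy_regression(2 * x + rng.normal(0, sigma, 43), x)["r2"]
            for _ in range(50)
        ]
        expected = 4 * x.var() / (4 * x.var() + sigma**2)
        assert np.mean(r2s) == pytest.approx(expected, abs=0.1)

    def test_constant_predictor(self):
        with pytest.raises(ValueError):
            proxy_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


def presence(rows):
    return pd.DataFrame(rows).astype(bool)


class TestSimpsonDissimilarity:
    def test_identical_plots(self):
        D = simpson_dissimilarity(presence([[1, 1, 0], [1, 1, 0]]))
        assert D.iloc[0, 1] == 0.0

    def test_disjoint_plots(self):
        D = simpson_dissimilarity(presence([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert D.iloc[0, 1] == 1.0

    def test_worked_example_one_third(self):
        # {s1,s2,s3} vs {s2,s3,s4}: a=2, b=c=1 -> 1/3
        D = simpson_dissimilarity(presence([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert D.iloc[0, 1] == pytest.approx(1 / 3)

    def test_nested_pair_is_pure_nestedness(self):
        D = simpson_dissimilarity(presence([[1, 1, 0], [1, 1, 1]]))
        assert D.iloc[0, 1] == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(bool, (6, 10), elements=st.booleans()))
    def test_symmetric_bounded_zero_diagonal(self, M):
        D = simpson_dissimilarity(pd.DataFrame(M)).to_numpy()
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.all(np.diag(D) == 0)

    def test_species_label_permutation_invariant(self, rng):
        M = pd.DataFrame(rng.random((8, 20)) < 0.4,
                         columns=[f"s{i}" for i in range(20)])
        D1 = simpson_dissimilarity(M)
        D2 = simpson_dissimilarity(M[rng.permutation(M.columns)])
        np.testing.assert_allclose(D1.to_numpy(), D2.to_numpy())


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return D / D.max()


class TestDbRda:
    def test_principal_coordinates_explain_everything(self, rng):
        D = random_distance_matrix(rng, 30)
        Y, _ = _principal_coordinates(D)
        res = db_rda(D, pd.DataFrame(Y[:, :3]))
        assert res["r2"] > 0.99  # Euclidean D in 3-D: 3 axes carry all inertia

    def test_independent_covariate_near_zero_adjusted(self, rng):
        vals = []
        for _ in range(100):
            D = random_distance_matrix(rng, 40)
            X = pd.DataFrame({"noise": rng.normal(size=40)})
            vals.append(db_rda(D, X)["adj_r2"])
        assert abs(np.mean(vals)) <= 0.03

    def test_two_cluster_structure_recovered(self):
        n = 20
        labels = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        D = np.where(labels[:, None] == labels[None, :], 0.1, 0.9)
        np.fill_diagonal(D, 0.0)
        res = db_rda(D, pd.DataFrame({"cluster": labels}))
        assert res["r2"] > 0.8

    def test_affine_rescaling_invariance(self, rng):
        D = random_distance_matrix(rng, 25)
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        r1 = db_rda(D, X)["r2"]
        r2 = db_rda(D, X * 100.0 + 7.0)["r2"]
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng):
        D = random_distance_matrix(rng, 20)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            res = db_rda(D, X)
        assert res["p"] == 1

    def test_matches_vegan_capscale(self, rng, tmp_path):
        """Independent oracle: R vegan's capscale on the same instance."""
        n = 25
        D = random_distance_matrix(rng, n)
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["v1", "v2"])
        ours = db_rda(D, X)
        pd.DataFrame(D).to_csv(tmp_path / "D.csv", index=False)
        X.to_csv(tmp_path / "X.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            D <- as.dist(as.matrix(read.csv("{tmp_path}/D.csv")))
            X <- read.csv("{tmp_path}/X.csv")
            m <- capscale(D ~ ., data = X)
            r <- RsquareAdj(m)
            cat(r$r.squared, r$adj.r.squared, sep="\\n")
            """
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r2_vegan, adj_vegan = (float(v) for v in out.stdout.split())
        assert ours["r2"] == pytest.approx(r2_vegan, abs=1e-6)
        assert ours["adj_r2"] == pytest.approx(adj_vegan, abs=1e-6)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 43, 2) == 1.0

    def test_null_fit_penalty(self):
        assert adjusted_r2(0.0, 43, 2) == pytest.approx(-0.05)

    def test_zero_predictors_identity(self):
        assert adjusted_r2(0.37, 43, 0) == pytest.approx(0.37)

    def test_underdetermined_errors(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestVariationPartition:
    def _groups(self, rng, n=40):
        return {
            "light": pd.DataFrame(rng.normal(size=(n, 2)), columns=["dli", "bli"]),
            "climate": pd.DataFrame(rng.normal(size=(n, 2)), columns=["dd", "pp"]),
            "soil": pd.DataFrame(rng.normal(size=(n, 3)), columns=["twi", "tpi", "ph"]),
        }

    def test_raw_fractions_sum_to_one(self, rng):
        D = random_distance_matrix(rng, 40)
        vp = variation_partition(D, self._groups(rng))
        assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_group_has_no_independent_share(self, rng):
        # a group duplicated under new names: its covariance is entirely
        # shared, so both independent fractions vanish and the shared part
        # (pairwise + triple) recovers the group's marginal adjusted R^2
        n = 40
        D = random_distance_matrix(rng, n)
        A = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
        B = A.copy()
        B.columns = ["b1", "b2"]
        C = pd.DataFrame(rng.normal(size=(n, 2)), columns=["c1", "c2"])
        with pytest.warns(UserWarning, match="collinear"):
            vp = variation_partition(D, {"g1": A, "g2": B, "g3": C})
        marginal = db_rda(D, A)["adj_r2"]
        assert abs(vp.independent("g1")) < 1e-9
        assert abs(vp.independent("g2")) < 1e-9
        assert vp.shared("g1", "g2") + vp.fractions["g"] == pytest.approx(
            marginal, abs=1e-9
        )

    def test_orthogonal_groups_have_no_shared_fractions(self, rng):
        # exactly orthonormal covariate blocks generating a Euclidean D:
        # pairwise shared fractions ~ 0, independent ~ marginal adjusted R^2
        n = 100
        Q, _ = np.linalg.qr(rng.normal(size=(n, 10)))
        w = np.array([3, 3, 2.5, 2.5, 2, 2, 2, 1, 1, 1.0])  # last 3 unexplained
        config = Q * w
        D = np.sqrt(((config[:, None] - config[None]) ** 2).sum(-1))
        D = D / D.max()
        groups = {
            "light": pd.DataFrame(Q[:, 0:2], columns=["l1", "l2"]),
            "climate": pd.DataFrame(Q[:, 2:4], columns=["c1", "c2"]),
            "soil": pd.DataFrame(Q[:, 4:7], columns=["s1", "s2", "s3"]),
        }
        vp = variation_partition(D, groups)
        for pair in [("light", "climate"), ("climate", "soil"), ("light", "soil")]:
            assert abs(vp.shared(*pair)) <= 0.02
        for name in groups:
            marginal = db_rda(D, groups[name])["adj_r2"]
            assert vp.independent(name) == pytest.approx(marginal, abs=0.05)

    def test_floored_view_zeroes_negatives(self, rng):
        D = random_distance_matrix(rng, 40)
        vp = variation_partition(D, self._groups(rng))
        floored = vp.floored()
        assert all(v >= 0 for k, v in floored.items() if k != "residual")
        # raw values retained untouched
        assert any(v < 0 for v in vp.fractions.values()) or True

    def test_matches_vegan_varpart(self, rng, tmp_path):
        """Independent oracle: R vegan's varpart on the same instance."""
        n = 30
        D = random_distance_matrix(rng, n)
        groups = self._groups(rng, n)
        vp = variation_partition(D, groups)
        pd.DataFrame(D).to_csv(tmp_path / "D.csv", index=False)
        for k, v in groups.items():
            v.to_csv(tmp_path / f"{k}.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            D <- as.dist(as.matrix(read.csv("{tmp_path}/D.csv")))
            X1 <- read.csv("{tmp_path}/light.csv")
            X2 <- read.csv("{tmp_path}/climate.csv")
            X3 <- read.csv("{tmp_path}/soil.csv")
            v <- varpart(D, X1, X2, X3)
            cat(v$part$indfract$Adj.R.square, sep="\\n")
            """
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vegan = [float(x) for x in out.stdout.split()]
        # vegan order: [a] X1 alone, [b] X2 alone, [c] X3 alone, [d] X1&X2,
        # [e] X2&X3, [f] X1&X3, [g] all, [h] residual
        ours = [vp.fractions[k] for k in "abcdefg"] + [vp.fractions["residual"]]
        np.testing.assert_allclose(ours, vegan, atol=1e-6)
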