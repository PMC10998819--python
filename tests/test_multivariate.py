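import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import _oracles as oracles
from amfdyn.io import DesignError, TableFormatError
from amfdyn.multivariate import (
    DistanceMatrix,
    distance_matrix,
    mantel,
    nmds,
    pairwise_permanova,
    permanova,
    rda,
)


def comp_frame(rows, prefix="s"):
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(rows.shape[0])])


def meta_frame(ids, **columns):
    return pd.DataFrame(columns, index=ids)


class TestDistanceMatrix:
    def test_bray_curtis_examples(self):
        comp = comp_frame([[1, 0], [0, 1], [1, 0], [0.2, 0.8], [0.4, 0.6]])
        dm = distance_matrix(comp, "bray-curtis")
        assert dm.values[0, 1] == pytest.approx(1.0)  # disjoint compositions
        assert dm.values[0, 2] == pytest.approx(0.0)  # identical rows
        assert dm.values[3, 4] == pytest.approx(0.2)  # (|0.2-0.4|+|0.8-0.6|)/2
        assert dm.values.max() <= 1.0

    def test_bray_curtis_rejects_negative(self):
        with pytest.raises(TableFormatError):
            distance_matrix(comp_frame([[1, -0.1], [0.5, 0.5]]), "bray-curtis")

    def test_euclidean_standardizes_columns(self):
        data = comp_frame([[0, 0], [1, 100], [2, 200]])
        dm = distance_matrix(data, "euclidean")
        # both columns carry identical standardized information
        assert dm.values[0, 2] == pytest.approx(2 * dm.values[0, 1], rel=1e-9)

    def test_euclidean_rejects_constant_column(self):
        with pytest.raises(TableFormatError, match="zero-variance"):
            distance_matrix(comp_frame([[1, 5], [2, 5]]), "euclidean")


class TestPermanova:
    def random_case(self, seed, n=8, groups=2):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 5))
        comp = comp_frame(x / x.sum(1, keepdims=True))
        labels = [f"g{i % groups}" for i in range(n)]
        meta = meta_frame(comp.index, g=labels)
        return distance_matrix(comp, "bray-curtis"), meta, labels

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("groups", [2, 3])
    def test_pseudo_f_matches_naive_oracle(self, seed, groups):
        dm, meta, labels = self.random_case(seed, groups=groups)
        res = permanova(dm, meta, ["g"], n_perm=9, seed=0)[0]
        assert res.statistic == pytest.approx(
            oracles.permanova_oneway_F(dm.values, labels), abs=1e-10
        )

    def test_exhaustive_p_on_separated_pairs(self):
        comp = comp_frame([[1, 0], [0.99, 0.01], [0, 1], [0.01, 0.99]])
        dm = distance_matrix(comp, "bray-curtis")
        meta = meta_frame(comp.index, g=["x", "x", "y", "y"])
        res = permanova(dm, meta, ["g"], exhaustive=True)[0]
        assert res.p == pytest.approx(2 / 6, abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_exhaustive_p_matches_bruteforce(self, seed):
        dm, meta, labels = self.random_case(seed, n=6)
        res = permanova(dm, meta, ["g"], exhaustive=True)[0]
        assert res.p == pytest.approx(
            oracles.permanova_exhaustive_p(dm.values, labels), abs=1e-12
        )

    def test_duplicating_every_sample_leaves_f_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.random((8, 5))
        x = x / x.sum(1, keepdims=True)
        labels = [f"g{i % 2}" for i in range(8)]
        comp1 = comp_frame(x)
        comp2 = comp_frame(np.vstack([x, x]))
        r1 = permanova(distance_matrix(comp1, "bray-curtis"),
                       meta_frame(comp1.index, g=labels),
                       ["g"], n_perm=9, seed=0)[0]
        r2 = permanova(distance_matrix(comp2, "bray-curtis"),
                       meta_frame(comp2.index, g=labels * 2),
                       ["g"], n_perm=9, seed=0)[0]
        # explained-variance share is duplication-invariant; the pseudo-F
        # rescales exactly by the residual degrees of freedom
        assert r2.r2 == pytest.approx(r1.r2, rel=1e-9)
        assert r2.statistic == pytest.approx(r1.statistic * (16 - 2) / (8 - 2), rel=1e-9)

    def test_bit_reproducible_given_seed(self):
        dm, meta, _ = self.random_case(6, n=8)
        a = permanova(dm, meta, ["g"], n_perm=199, seed=42)[0]
        b = permanova(dm, meta, ["g"], n_perm=199, seed=42)[0]
        assert (a.statistic, a.p) == (b.statistic, b.p)

    def test_sequential_terms_sum_to_total(self, paper_dataset):
        from amfdyn.preprocess import relative_abundance

        comp = relative_abundance(paper_dataset.counts)
        dm = distance_matrix(comp, "bray-curtis")
        res = permanova(dm, paper_dataset.metadata,
                        ["site", "compartment", "month"], n_perm=49, seed=0)
        r2 = sum(r.r2 for r in res)
        assert 0 < r2 < 1
        assert all(r.p <= 1 and r.p > 0 for r in res)

    def test_confounded_term_rejected(self):
        dm, meta, _ = self.random_case(7)
        meta["g2"] = meta["g"]
        with pytest.raises(DesignError, match="confounded"):
            permanova(dm, meta, ["g", "g2"], n_perm=9, seed=0)

    def test_matches_skbio_single_factor(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        dm, meta, labels = self.random_case(8, n=10, groups=2)
        ours = permanova(dm, meta, ["g"], n_perm=9, seed=0)[0].statistic
        theirs = sk_permanova(SkDM(dm.values, ids=dm.ids), labels, permutations=9)
        assert ours == pytest.approx(theirs["test statistic"], rel=1e-6)


class TestPairwisePermanova:
    def test_identical_levels_have_high_p(self):
        rng = np.random.default_rng(9)
        x = rng.dirichlet(np.ones(5) * 50, 18)
        comp = comp_frame(x)
        meta = meta_frame(comp.index, month=[f"m{i % 3}" for i in range(18)])
        dm = distance_matrix(comp, "bray-curtis")
        out = pairwise_permanova(dm, meta, "month", n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
        assert (out["p_adjusted"] > 0.05).all()

    def test_adjust_none_keeps_raw_p(self):
        rng = np.random.default_rng(10)
        comp = comp_frame(rng.dirichlet(np.ones(4), 12))
        meta = meta_frame(comp.index, month=[f"m{i % 3}" for i in range(12)])
        dm = distance_matrix(comp, "bray-curtis")
        out = pairwise_permanova(dm, meta, "month", n_perm=49, seed=1, adjust="none")
        assert (out["p_adjusted"] == out["p"]).all()

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(11)
        comp = comp_frame(rng.dirichlet(np.ones(4), 12))
        meta = meta_frame(comp.index, month=[f"m{i % 3}" for i in range(12)])
        dm = distance_matrix(comp, "bray-curtis")
        out = pairwise_permanova(dm, meta, "month", n_perm=49, seed=1)
        assert np.allclose(out["p_adjusted"], np.minimum(1.0, out["p"] * 3))


class TestMantel:
    def euclid(self, seed, n=5, cols=3):
        rng = np.random.default_rng(seed)
        return distance_matrix(comp_frame(rng.random((n, cols))), "euclidean")

    def test_identity_gives_r_one(self):
        d1 = self.euclid(0)
        res = mantel(d1, d1, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_spearman_invariant_to_monotone_transform(self):
        d1 = self.euclid(1)
        d2 = DistanceMatrix(d1.ids, np.sqrt(d1.values), "euclidean")
        assert mantel(d1, d2, n_perm=9, seed=0).statistic == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_exhaustive_mode_equals_bruteforce_at_n5(self, seed):
        d1 = self.euclid(seed)
        d2 = self.euclid(seed + 100)
        res = mantel(d1, d2, exhaustive=True)
        r_ref, p_ref = oracles.mantel_exhaustive(d1.values, d2.values)
        assert res.statistic == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-15)
        assert res.n_permutations == 120

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        d1 = self.euclid(5, n=12)
        d2 = self.euclid(6, n=12)
        r_sk = sk_mantel(SkDM(d1.values, ids=d1.ids), SkDM(d2.values, ids=d2.ids),
                         method="spearman", permutations=0)[0]
        assert mantel(d1, d2, n_perm=9, seed=0).statistic == pytest.approx(r_sk, abs=1e-12)

    def test_mismatched_ids_rejected(self):
        d1 = self.euclid(7)
        d2 = DistanceMatrix([f"x{i}" for i in range(5)], d1.values, "euclidean")
        with pytest.raises(DesignError):
            mantel(d1, d2)

    def test_reproducible_given_seed(self):
        d1, d2 = self.euclid(8, n=10), self.euclid(9, n=10)
        assert mantel(d1, d2, n_perm=199, seed=3).p == mantel(d1, d2, n_perm=199, seed=3).p


class TestRda:
    def linear_case(self):
        ph = np.linspace(4, 6, 12)
        y = np.zeros((12, 3))
        y[:, 0] = 0.1 + 0.02 * ph
        y[:, 1] = 0.5 - 0.02 * ph
        y[:, 2] = 0.4
        comp = comp_frame(y)
        env = pd.DataFrame({"pH": ph}, index=comp.index)
        return comp, env

    def test_noiseless_single_predictor_matches_regression_oracle(self):
        comp, env = self.linear_case()
        res = rda(comp, env, n_perm=999, seed=1)
        r2 = oracles.regression_r2(comp.to_numpy(), env["pH"].to_numpy())
        assert res.axis_proportions[0] == pytest.approx(r2, abs=1e-9)
        assert res.model.p <= 0.01

    def test_orthogonal_environment_explains_nothing(self):
        rng = np.random.default_rng(12)
        comp = comp_frame(rng.dirichlet(np.ones(6) * 20, 24))
        env = pd.DataFrame({"noise": rng.normal(size=24)}, index=comp.index)
        res = rda(comp, env, n_perm=199, seed=2)
        assert res.constrained_proportion < 0.15
        assert res.model.p > 0.05

    def test_variance_proportions_sum_to_one(self, paper_dataset):
        from amfdyn.preprocess import relative_abundance

        comp = relative_abundance(paper_dataset.counts)
        env = paper_dataset.metadata[["pH", "TC", "TN", "CN", "TP"]].astype(float)
        res = rda(comp, env, n_perm=49, seed=0)
        total = res.axis_proportions.sum() + res.unconstrained_proportions.sum()
        assert total == pytest.approx(1.0, abs=1e-9)
        assert res.first_two_axes <= res.constrained_proportion + 1e-12

    def test_strong_correlation_flags_at_half(self):
        rng = np.random.default_rng(13)
        n = 30
        ph = np.sort(rng.normal(5, 0.5, n))
        y = rng.dirichlet(np.ones(5) * 30, n)
        y[:, 0] = np.linspace(0.05, 0.4, n)  # monotone in sorted pH
        y = y / y.sum(1, keepdims=True)
        comp = comp_frame(y)
        env = pd.DataFrame({"pH": ph}, index=comp.index)
        res = rda(comp, env, n_perm=199, seed=3)
        tab = res.otu_env_correlations.set_index("otu_id")
        assert bool(tab.loc[comp.columns[0], "strong"])
        assert tab.loc[comp.columns[0], "spearman_r"] > 0.9

    def test_collinear_environment_rejected(self):
        comp, env = self.linear_case()
        env2 = env.assign(pH2=env["pH"] * 2 + 1e-12)
        with pytest.raises(DesignError, match="collinear"):
            rda(comp, env2, n_perm=9, seed=0)

    def test_matches_vegan_axis_proportions(self, tmp_path):
        """Independent cross-check of the whole eigen-decomposition
        against vegan's rda on a modest random fixture."""
        rng = np.random.default_rng(14)
        n = 16
        y = rng.dirichlet(np.ones(6) * 8, n)
        env = pd.DataFrame(
            {"pH": rng.normal(5, 0.4, n), "TP": rng.normal(60, 12, n)},
        )
        comp = comp_frame(y)
        env.index = comp.index
        res = rda(comp, env, n_perm=9, seed=0)
        yp, xp = tmp_path / "y.csv", tmp_path / "x.csv"
        comp.to_csv(yp, index=False)
        env.to_csv(xp, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- read.csv("{yp}"); X <- as.data.frame(scale(read.csv("{xp}")))
            m <- rda(Y ~ pH + TP, data=X)
            cat(m$CCA$eig / m$tot.chi, sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(res.axis_proportions, ref, atol=1e-8)


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            "euclidean",
        )
        res = nmds(dm, restarts=5, seed=0)
        assert res.stress < 0.01

    def test_recovers_true_planar_configuration(self):
        # enough points that the rank constraints pin the configuration
        rng = np.random.default_rng(15)
        true = rng.random((40, 2))
        dm = distance_matrix(comp_frame(true), "euclidean")
        res = nmds(dm, restarts=10, seed=1, tol=1e-9, max_iter=1000)
        assert res.stress < 0.01
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(true, res.coordinates.to_numpy())
        assert disparity < 0.01

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(16)
        dm = distance_matrix(comp_frame(rng.random((12, 4))), "euclidean")
        s1 = nmds(dm, restarts=1, seed=2).stress
        s20 = nmds(dm, restarts=20, seed=2).stress
        assert s20 <= s1 + 1e-12

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "euclidean")
        with pytest.raises(DesignError):
            nmds(dm)
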