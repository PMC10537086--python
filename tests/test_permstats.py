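import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from engraft.datasets import DistanceMatrix
from engraft.permstats import (
    kruskal_wallis,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
)


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(np.atleast_2d(points).reshape(len(ids), -1))), "aitchison")


def meta_of(ids, **columns) -> pd.DataFrame:
    df = pd.DataFrame({"sample_id": ids, **columns})
    return df.set_index("sample_id", drop=False)


class TestPcoa:
    def test_points_on_a_line_recovered_on_axis_one(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        res = pcoa(euclidean_dm(x[:, None]))
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.diff(axis1)
        expected = np.diff(x - x.mean())
        assert np.allclose(np.abs(gaps), np.abs(expected), atol=1e-8)
        assert res.eigenvalues[1:] == pytest.approx(0.0, abs=1e-8)

    def test_zero_matrix_all_eigenvalues_zero(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "bray_curtis")
        res = pcoa(d)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_isometry(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        res = pcoa(euclidean_dm(pts), k=2)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, squareform(pdist(pts)), atol=1e-8)

    def test_negative_eigenvalues_reported_but_dropped(self):
        # Bray-Curtis-like non-Euclidean matrix
        v = np.array([[0, .9, .1, .5], [.9, 0, .8, .1],
                      [.1, .8, 0, .6], [.5, .1, .6, 0]])
        d = DistanceMatrix(list("abcd"), v, "bray_curtis")
        res = pcoa(d)
        assert res.eigenvalues.min() < -1e-6
        assert res.coordinates.shape[1] == (res.eigenvalues > 1e-9).sum()

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k="):
            pcoa(euclidean_dm(np.arange(3.0)[:, None]), k=3)


class TestPermanova:
    def test_univariate_euclidean_equals_classical_anova_f(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.5, 1, 7),
                            rng.normal(0.5, 1, 9)])
        groups = np.repeat(["a", "b", "c"], [8, 7, 9])
        d = euclidean_dm(y[:, None])
        meta = meta_of(d.sample_ids, g=groups)
        res = permanova(d, meta, ["g"], n_perm=9, seed=0)
        f_classic = stats.f_oneway(y[groups == "a"], y[groups == "b"], y[groups == "c"]).statistic
        assert res.table.loc["g", "F"] == pytest.approx(f_classic, abs=1e-10)

    def test_exact_enumeration_matches_brute_force_oracle(self):
        """n=6, one 2-level factor: p from enumerating all 720 label orders.

        The oracle computes pseudo-F from the classical within-group
        pairwise-distance formula, an independent route from the
        Gower-trace implementation.
        """
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.2
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        d = euclidean_dm(pts)
        dv = d.values

        def oracle_f(lab):
            n = len(lab)
            ss_total = (dv[np.triu_indices(n, 1)] ** 2).sum() / n
            ss_within = 0.0
            for lev in np.unique(lab):
                idx = np.flatnonzero(lab == lev)
                sub = dv[np.ix_(idx, idx)]
                ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
            ss_a = ss_total - ss_within
            return (ss_a / 1) / (ss_within / (n - 2))

        f_obs = oracle_f(labels)
        count = sum(oracle_f(labels[list(perm)]) >= f_obs - 1e-12
                    for perm in itertools.permutations(range(6)))
        p_oracle = count / 720

        res = permanova(d, meta_of(d.sample_ids, g=labels), ["g"], n_perm="exact")
        assert res.table.loc["g", "F"] == pytest.approx(f_obs, abs=1e-10)
        assert res.p_value("g") == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_skbio_one_way(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 4))
        labels = np.repeat(["a", "b", "c"], 4)
        d = euclidean_dm(pts)
        res = permanova(d, meta_of(d.sample_ids, g=labels), ["g"], n_perm=9, seed=0)
        theirs = skbio_permanova(SkbioDM(d.values, ids=d.sample_ids),
                                 grouping=list(labels), permutations=9)
        assert res.table.loc["g", "F"] == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_mirrored_groups_have_negligible_effect(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        both = np.vstack([pts, pts])  # group b duplicates group a exactly
        labels = np.repeat(["a", "b"], 8)
        d = euclidean_dm(both)
        res = permanova(d, meta_of(d.sample_ids, g=labels), ["g"], n_perm=199, seed=1)
        assert res.r_squared("g") < 0.01
        assert res.p_value("g") > 0.5

    def test_sequential_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(20, 5))
        meta = meta_of([f"s{i}" for i in range(20)],
                       g=rng.choice(["a", "b"], 20),
                       h=rng.choice(["u", "v", "w"], 20),
                       age=rng.uniform(1, 10, 20))
        d = euclidean_dm(pts)
        res = permanova(d, meta, ["g", "h", "age"], mode="sequential", n_perm=9)
        r2 = res.table.drop(index="Total")["R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_marginal_mode_adjusts_for_other_terms(self):
        # a term fully explained by another has ~zero marginal SS
        ids = [f"s{i}" for i in range(12)]
        g = np.repeat(["a", "b"], 6)
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3)) + (g == "b")[:, None] * 2.0
        meta = meta_of(ids, g=g, g2=g.copy())
        with pytest.raises(ValueError, match="aliased"):
            permanova(euclidean_dm(pts), meta, ["g", "g2"], n_perm=9)

    def test_constant_term_is_an_error_naming_it(self):
        d = euclidean_dm(np.arange(4.0)[:, None])
        meta = meta_of(d.sample_ids, g=["a"] * 4)
        with pytest.raises(ValueError, match="'g'"):
            permanova(d, meta, ["g"], n_perm=9)

    def test_marginal_mode_matches_vegan_adonis2(self, tmp_path):
        """Multi-term marginal SS/F/R2 agree with vegan's adonis2(by='margin')."""
        import subprocess
        rng = np.random.default_rng(12)
        n = 18
        pts = rng.normal(size=(n, 4))
        g = rng.choice(["a", "b"], n)
        h = rng.choice(["u", "v", "w"], n)
        age = rng.uniform(1, 10, n)
        pts += (g == "b")[:, None] * 0.8
        d = euclidean_dm(pts)
        meta = meta_of(d.sample_ids, g=g, h=h, age=age)
        res = permanova(d, meta, ["g", "h", "age"], n_perm=9, seed=0)

        pd.DataFrame(d.values, index=d.sample_ids, columns=d.sample_ids).to_csv(tmp_path / "d.csv")
        meta[["g", "h", "age"]].to_csv(tmp_path / "m.csv")
        script = (
            'suppressMessages(library(vegan))\n'
            'd <- as.dist(as.matrix(read.csv("d.csv", row.names=1)))\n'
            'm <- read.csv("m.csv", row.names=1)\n'
            'res <- adonis2(d ~ g + h + age, data=m, by="margin", permutations=9)\n'
            'write.csv(as.data.frame(res), "out.csv")\n'
        )
        (tmp_path / "t.R").write_text(script)
        proc = subprocess.run(["Rscript", "t.R"], cwd=tmp_path,
                              capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        vegan = pd.read_csv(tmp_path / "out.csv", index_col=0)
        for term in ("g", "h", "age"):
            assert res.table.loc[term, "SS"] == pytest.approx(vegan.loc[term, "SumOfSqs"], rel=1e-9)
            assert res.table.loc[term, "F"] == pytest.approx(vegan.loc[term, "F"], rel=1e-9)
            assert res.r_squared(term) == pytest.approx(vegan.loc[term, "R2"], rel=1e-9)

    def test_seed_determinism_and_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        labels = rng.choice(["a", "b"], 10)
        d = euclidean_dm(pts)
        meta = meta_of(d.sample_ids, g=labels)
        r1 = permanova(d, meta, ["g"], n_perm=99, seed=42)
        r2 = permanova(d, meta, ["g"], n_perm=99, seed=42)
        assert r1.p_value("g") == r2.p_value("g")
        order = list(reversed(d.sample_ids))
        r3 = permanova(d.submatrix(order), meta.loc[order], ["g"], n_perm=99, seed=42)
        assert r3.p_value("g") == r1.p_value("g")
        assert r3.table.loc["g", "F"] == pytest.approx(r1.table.loc["g", "F"], abs=1e-10)


class TestPairwisePermanova:
    def _three_groups(self, shift=0.0, n=6, seed=8):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3 * n, 3))
        pts[:n] += shift
        labels = np.repeat(["a", "b", "c"], n)
        d = euclidean_dm(pts)
        return d, meta_of(d.sample_ids, g=labels)

    def test_identical_groups_all_non_significant(self):
        d, meta = self._three_groups(shift=0.0)
        out = pairwise_permanova(d, meta, "g", n_perm=199, seed=0)
        assert len(out) == 3
        assert (out["p_adjusted"] > 0.05).all()

    def test_one_separated_group_flags_its_two_pairs(self):
        d, meta = self._three_groups(shift=4.0, n=8)
        out = pairwise_permanova(d, meta, "g", n_perm=199, seed=0)
        sig = out[out["p_adjusted"] < 0.05]
        assert set(map(tuple, sig[["level_a", "level_b"]].values)) == {("a", "b"), ("a", "c")}

    def test_adjust_none_returns_raw(self):
        d, meta = self._three_groups(shift=1.0)
        out = pairwise_permanova(d, meta, "g", n_perm=99, seed=0, adjust="none")
        assert (out["p_adjusted"] == out["p"]).all()

    def test_tiny_level_skipped_with_warning(self, caplog):
        import logging
        d, meta = self._three_groups()
        meta = meta.copy()
        meta.loc[meta.index[:5], "g"] = ["a"] * 5
        meta.loc[meta.index[5], "g"] = "solo"
        meta.loc[meta.index[6:], "g"] = ["b"] * 12
        with caplog.at_level(logging.WARNING, logger="engraft"):
            out = pairwise_permanova(d, meta, "g", n_perm=49, seed=0)
        assert "solo" not in set(out["level_a"]) | set(out["level_b"])
        assert "skipping" in caplog.text


class TestPermdisp:
    def test_zero_dispersion_group_vs_dispersed(self):
        rng = np.random.default_rng(9)
        tight = np.tile(rng.normal(size=(1, 3)), (8, 1))
        loose = rng.normal(scale=3.0, size=(8, 3))
        d = euclidean_dm(np.vstack([tight, loose]))
        meta = meta_of(d.sample_ids, g=np.repeat(["t", "l"], 8))
        res = permdisp(d, meta, "g", n_perm=199, seed=0)
        assert res.group_means["t"] == pytest.approx(0.0, abs=1e-9)
        assert res.p_value < 0.05

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b"], 6)
        d = euclidean_dm(pts)
        r1 = permdisp(d, meta_of(d.sample_ids, g=labels), "g", n_perm=49, seed=3)
        swapped = np.where(labels == "a", "b", "a")
        r2 = permdisp(d, meta_of(d.sample_ids, g=swapped), "g", n_perm=49, seed=3)
        assert r1.f_statistic == pytest.approx(r2.f_statistic, abs=1e-10)

    def test_group_of_one_errors(self):
        d = euclidean_dm(np.arange(5.0)[:, None])
        meta = meta_of(d.sample_ids, g=["a", "a", "a", "a", "solo"])
        with pytest.raises(ValueError, match="size 1"):
            permdisp(d, meta, "g")

    def test_agrees_with_skbio_centroid_f(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permdisp as skbio_permdisp
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(14, 4))
        pts[7:] *= 2.5
        labels = np.repeat(["a", "b"], 7)
        d = euclidean_dm(pts)
        res = permdisp(d, meta_of(d.sample_ids, g=labels), "g", n_perm=9, seed=0)
        theirs = skbio_permdisp(SkbioDM(d.values, ids=d.sample_ids),
                                grouping=list(labels), permutations=9, test="centroid")
        assert res.f_statistic == pytest.approx(theirs["test statistic"], rel=1e-6)


class TestKruskalWallis:
    def test_hand_ranked_closed_form(self):
        # groups {1,2} and {3,4}: ranks 1..4, H = 12/(4*5) * sum n_i (Rbar - 2.5)^2
        h, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        expected_h = 12 / (4 * 5) * (2 * (1.5 - 2.5) ** 2 + 2 * (3.5 - 2.5) ** 2)
        assert h == pytest.approx(expected_h, abs=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(expected_h, 1)), abs=1e-12)

    def test_invariant_to_within_group_order(self):
        h1, _ = kruskal_wallis([3, 1, 4, 1, 5, 9], ["a", "a", "a", "b", "b", "b"])
        h2, _ = kruskal_wallis([4, 3, 1, 9, 1, 5], ["a", "a", "a", "b", "b", "b"])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        h, p = kruskal_wallis([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert (h, p) == (0.0, 1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([1, 2], ["a", "a"])
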