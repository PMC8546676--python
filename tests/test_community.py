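"""Community profiling: rank aggregation, rare-taxon lumping, Bray-Curtis,
PCoA and PERMANOVA, each checked against brute-force or scikit-bio
oracles on small instances."""

import numpy as np
import pandas as pd
import pytest

from perihg.community import (
    DistanceMatrix,
    bray_curtis,
    lump_rare,
    pcoa,
    permanova,
    relative_abundance,
)
from conftest import make_asv_table


class TestRelativeAbundance:
    def test_single_sample_fractions(self):
        table = make_asv_table(
            {"s1": {"a1": 30, "a2": 70}},
            {"a1": ("Bacteria", "PhyA"), "a2": ("Bacteria", "PhyB")},
            {"s1": "wetland"},
        )
        fr = relative_abundance(table, "phylum")
        assert fr.loc["s1", "PhyA"] == pytest.approx(0.3)
        assert fr.loc["s1", "PhyB"] == pytest.approx(0.7)

    def test_unassigned_rank_pools_to_unclassified(self):
        table = make_asv_table(
            {"s1": {"a1": 50, "a2": 50}},
            {"a1": ("Bacteria", "PhyA"), "a2": ("Bacteria",)},
            {"s1": "x"},
        )
        fr = relative_abundance(table, "phylum")
        assert fr.loc["s1", "unclassified"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, rng):
        counts = {f"s{i}": {f"a{j}": int(rng.integers(1, 50)) for j in range(6)}
                  for i in range(4)}
        lineages = {f"a{j}": ("Bacteria", f"P{j % 3}") for j in range(6)}
        table = make_asv_table(counts, lineages, {f"s{i}": "x" for i in range(4)})
        fr = relative_abundance(table, "phylum")
        assert np.allclose(fr.sum(axis=1), 1.0)

    def test_zero_total_sample_is_an_error(self):
        table = make_asv_table(
            {"s1": {"a1": 0}, "s2": {"a1": 5}},
            {"a1": ("Bacteria", "P")},
            {"s1": "x", "s2": "x"},
        )
        with pytest.raises(ValueError, match="s1"):
            relative_abundance(table, "phylum")


class TestLumpRare:
    def test_threshold_is_strict(self):
        fr = pd.DataFrame(
            {"A": [0.019, 0.019], "B": [0.020, 0.020], "C": [0.961, 0.961]}
        )
        out = lump_rare(fr, 0.02)
        assert "others" in out.columns and "A" not in out.columns
        assert "B" in out.columns  # exactly 2% kept
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_all_rare_collapses_to_single_column(self):
        fr = pd.DataFrame({c: [0.01] for c in "abcdefghij"} | {"k": [0.9]})
        out = lump_rare(fr, 0.95)
        assert list(out.columns) == ["others"]
        assert out["others"].iloc[0] == pytest.approx(1.0)

    def test_mean_based_vs_per_sample(self):
        # rare on average but abundant in one sample
        fr = pd.DataFrame({"A": [0.001, 0.035], "B": [0.999, 0.965]})
        assert "A" not in lump_rare(fr, 0.02).columns
        assert "A" in lump_rare(fr, 0.02, per_sample=True).columns


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        fr = pd.DataFrame(
            [[10, 0, 5], [5, 5, 5], [10, 0, 5], [0, 7, 0]],
            index=["u", "v", "u2", "w"],
            dtype=float,
        )
        dm = bray_curtis(fr)
        idx = {label: i for i, label in enumerate(dm.labels)}
        assert dm.values[idx["u"], idx["u2"]] == pytest.approx(0.0)
        assert dm.values[idx["u"], idx["v"]] == pytest.approx(1 - 20 / 30)
        # u=(10,0,5) vs w=(0,7,0) share nothing
        assert dm.values[idx["u"], idx["w"]] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.uniform(0, 1, size=(8, 12))
        fr = pd.DataFrame(x, index=[f"s{i}" for i in range(8)])
        dm = bray_curtis(fr)
        for i in range(8):
            for j in range(8):
                expected = 1 - 2 * np.minimum(x[i], x[j]).sum() / (x[i] + x[j]).sum()
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)
        assert dm.values.max() <= 1.0 and dm.values.min() >= 0.0

    def test_two_zero_rows_error(self):
        fr = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"), dtype=float)
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(fr)


class TestPcoa:
    def test_two_points_on_one_axis(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        assert sorted(coords[:, 0]) == pytest.approx([-0.3, 0.3])
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(9, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(9)], d))
        coords = res.coordinates.to_numpy()
        recovered = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recovered, d, atol=1e-9)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)
        assert res.explained_fraction.sum() <= 1 + 1e-12

    def test_identical_samples_are_coincident(self):
        dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0  # no positive variance axes

    def test_matches_skbio_on_bray_curtis(self, rng):
        import skbio

        x = rng.uniform(0, 1, size=(7, 10))
        fr = pd.DataFrame(x, index=[f"s{i}" for i in range(7)])
        dm = bray_curtis(fr)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.labels)
        )
        n = ours.coordinates.shape[1]
        ref = theirs.samples.to_numpy()[:, :n]
        got = ours.coordinates.to_numpy()
        for k in range(n):  # eigenvectors defined up to sign
            assert np.allclose(np.abs(got[:, k]), np.abs(ref[:, k]), atol=1e-8)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestPermanova:
    def sep_matrix(self, n_per=4, k=3):
        n = n_per * k
        d = np.ones((n, n))
        labels = [f"s{i}" for i in range(n)]
        groups = {}
        for g in range(k):
            for i in range(g * n_per, (g + 1) * n_per):
                groups[labels[i]] = f"g{g}"
                for j in range(g * n_per, (g + 1) * n_per):
                    d[i, j] = 0.0
        return DistanceMatrix(labels, d), groups

    def test_perfect_separation_reaches_minimum_p(self):
        dm, groups = self.sep_matrix()
        res = permanova(dm, groups, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)
        assert 0 <= res.r2 <= 1

    def test_seeded_result_is_bit_reproducible(self):
        dm, groups = self.sep_matrix()
        a = permanova(dm, groups, n_perm=199, seed=42)
        b = permanova(dm, groups, n_perm=199, seed=42)
        assert (a.pseudo_F, a.p) == (b.pseudo_F, b.p)

    def test_invariant_to_group_renaming(self):
        dm, groups = self.sep_matrix()
        renamed = {s: g.replace("g", "site_") for s, g in groups.items()}
        a = permanova(dm, groups, n_perm=99, seed=5)
        b = permanova(dm, renamed, n_perm=99, seed=5)
        assert a.pseudo_F == b.pseudo_F and a.p == b.p

    def test_single_group_is_an_error(self):
        dm, groups = self.sep_matrix()
        with pytest.raises(ValueError):
            permanova(dm, {s: "one" for s in groups}, n_perm=9, seed=0)

    def test_pseudo_f_matches_skbio(self, rng):
        import skbio

        x = rng.uniform(0, 1, size=(12, 8))
        fr = pd.DataFrame(x, index=[f"s{i}" for i in range(12)])
        dm = bray_curtis(fr)
        groups = {f"s{i}": f"g{i % 3}" for i in range(12)}
        ours = permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.labels),
            grouping=[groups[s] for s in dm.labels],
            permutations=0,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_pseudo_f_matches_brute_force_oracle(self, rng):
        # oracle: explicit among/within partition from pairwise loops
        x = rng.uniform(0, 1, size=(9, 5))
        fr = pd.DataFrame(x, index=[f"s{i}" for i in range(9)])
        dm = bray_curtis(fr)
        groups = {f"s{i}": f"g{i % 3}" for i in range(9)}
        res = permanova(dm, groups, n_perm=9, seed=0)
        n, a = 9, 3
        ss_t = sum(
            dm.values[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_w = 0.0
        for g in {"g0", "g1", "g2"}:
            members = [i for i in range(n) if groups[f"s{i}"] == g]
            ss_w += sum(
                dm.values[i, j] ** 2
                for i in members
                for j in members
                if i < j
            ) / len(members)
        f_expected = ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))
        assert res.pseudo_F == pytest.approx(f_expected, rel=1e-12)
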