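import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from microdnds.stats import (
    cophenetic_distances,
    cv_summary,
    pairwise_pathway_correlation,
    phylo_distance_regression,
    taylor_regression,
)

from conftest import make_matrix


class TestTaylorRegression:
    def test_constructed_slope_two(self):
        # variance = mean^2 exactly -> slope 2, t_vs_2 = 0; build rows with
        # sd == mean: values mean*(1-c), mean, mean*(1+c) have sd = c*mean*sqrt(...)
        means = np.array([0.05, 0.1, 0.2, 0.4])
        rows = []
        for m in means:
            rows.append([m - m, m, m + m])  # sd over (0, m, 2m) = m, mean = m
        matrix = make_matrix(np.array(rows).T)
        fit = taylor_regression(matrix)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.t_vs_2 == pytest.approx(0.0, abs=1e-6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(-2, 0.5, (6, 5))
        m1 = make_matrix(values)
        m2 = make_matrix(values, pathways=[f"Z{j}" for j in range(5)])
        f1, f2 = taylor_regression(m1), taylor_regression(m2)
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.slope_se == pytest.approx(f2.slope_se)

    def test_five_point_normal_equations_oracle(self):
        # frozen from closed-form OLS on log10 means/variances
        means = np.array([0.05, 0.08, 0.12, 0.2, 0.3])
        variances = np.array([0.003, 0.007, 0.012, 0.05, 0.1])
        rows = []
        for m, v in zip(means, variances):
            # skewed positive 4-point set (m-e, m-e, m-e, m+3e): mean m,
            # unbiased variance 4e^2 = v
            e = np.sqrt(v) / 2
            rows.append([m - e, m - e, m - e, m + 3 * e])
        matrix = make_matrix(np.array(rows).T)
        fit = taylor_regression(matrix)
        assert fit.slope == pytest.approx(2.001160583708425, rel=1e-9)
        assert fit.intercept == pytest.approx(0.03737106494083209, rel=1e-6)
        assert fit.slope_se == pytest.approx(0.12851494328028337, rel=1e-9)
        assert fit.t_vs_2 == pytest.approx(0.009030729647477934, rel=1e-6)
        assert fit.n_pathways == 5

    def test_scale_invariance_of_slope(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(-2, 0.4, (8, 6))
        f1 = taylor_regression(make_matrix(values))
        f2 = taylor_regression(make_matrix(values * 3.7))
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)
        assert f1.intercept != pytest.approx(f2.intercept)

    def test_zero_variance_pathway_excluded(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(-2, 0.4, (5, 4))
        values[:, 0] = 0.1  # constant column: variance 0
        fit = taylor_regression(make_matrix(values))
        assert fit.n_pathways == 3

    def test_too_few_pathways_errors(self):
        with pytest.raises(ValueError):
            taylor_regression(make_matrix(np.random.default_rng(0).uniform(0.1, 0.2, (4, 2))))


class TestCvSummary:
    def test_sd_equal_mean_gives_cv_one(self):
        rows = []
        for m in (0.05, 0.1, 0.2):
            rows.append([0.0, m, 2 * m])  # sd = m exactly (ddof=1)
        cv = cv_summary(make_matrix(np.array(rows).T), seed=0)
        assert cv["median_cv"] == pytest.approx(1.0)
        assert np.allclose(cv["per_pathway"], 1.0)

    def test_constant_rows_cv_zero(self):
        cv = cv_summary(make_matrix(np.full((4, 3), 0.2)), seed=0)
        assert cv["median_cv"] == 0.0


class TestPairwiseCorrelation:
    def test_identical_vectors_r_one(self):
        row = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        matrix = make_matrix(np.vstack([row, row]))
        corr = pairwise_pathway_correlation(matrix, min_shared_pathways=5)
        assert corr["r"].iloc[0] == pytest.approx(1.0)

    def test_multiplicative_scaling_r_one_in_log(self):
        row = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        matrix = make_matrix(np.vstack([row, 3.0 * row]))
        corr = pairwise_pathway_correlation(matrix, min_shared_pathways=5)
        assert corr["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_covariance_oracle(self):
        u = np.array([0.1, 0.2, 0.05, 0.3])
        v = np.array([0.12, 0.25, 0.04, 0.5])
        matrix = make_matrix(np.vstack([u, v]))
        corr = pairwise_pathway_correlation(matrix, min_shared_pathways=4)
        # frozen from independent covariance-formula computation on log10 values
        assert corr["r"].iloc[0] == pytest.approx(0.9963150437372643, rel=1e-9)

    def test_overlap_threshold_drops_pair(self):
        values = np.array([[0.1, 0.2, np.nan, np.nan], [0.1, 0.2, 0.3, 0.4]])
        corr = pairwise_pathway_correlation(make_matrix(values), min_shared_pathways=3)
        assert corr.empty

    def test_zero_variance_pair_dropped(self):
        values = np.array([[0.1, 0.1, 0.1, 0.1, 0.1], [0.1, 0.2, 0.3, 0.4, 0.5]])
        corr = pairwise_pathway_correlation(make_matrix(values), min_shared_pathways=5)
        assert corr.empty

    def test_spearman_flag(self):
        rng = np.random.default_rng(4)
        matrix = make_matrix(rng.lognormal(-2, 0.4, (3, 8)))
        corr = pairwise_pathway_correlation(matrix, min_shared_pathways=5, method="spearman")
        assert len(corr) == 3
        assert corr["r"].between(-1, 1).all()


def star_distances(labels, d):
    n = len(labels)
    arr = np.full((n, n), d, dtype=float)
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=labels, columns=labels)


class TestPhyloDistanceRegression:
    def make_corr(self, pairs_r):
        return pd.DataFrame(
            [(a, b, r) for (a, b), r in pairs_r.items()],
            columns=["species_a", "species_b", "r"],
        )

    def test_constant_correlations_beta_zero(self):
        labels = ["A", "B", "C", "D"]
        rng = np.random.default_rng(0)
        arr = rng.uniform(0.1, 1.0, (4, 4))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0)
        dist = pd.DataFrame(arr, index=labels, columns=labels)
        corr = self.make_corr({(a, b): 0.5 for a, b in itertools.combinations(labels, 2)})
        fit = phylo_distance_regression(corr, dist, n_mantel=99, seed=0)
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_two_pairs_exact_line(self):
        labels = ["A", "B", "C"]
        arr = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        dist = pd.DataFrame(arr, index=labels, columns=labels)
        corr = self.make_corr({("A", "B"): 0.8, ("A", "C"): 0.4})
        fit = phylo_distance_regression(corr, dist, n_mantel=19, seed=0)
        assert fit.beta == pytest.approx((0.4 - 0.8) / (2.0 - 1.0))

    def test_constant_distances_error(self):
        labels = ["A", "B", "C"]
        corr = self.make_corr({(a, b): 0.5 for a, b in itertools.combinations(labels, 2)})
        with pytest.raises(ValueError, match="slope undefined"):
            phylo_distance_regression(corr, star_distances(labels, 1.0), n_mantel=9, seed=0)

    def test_exact_mantel_matches_enumeration_on_5_species(self):
        labels = [f"S{i}" for i in range(5)]
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 1, 5)
        arr = np.abs(pos[:, None] - pos[None, :])
        dist = pd.DataFrame(arr, index=labels, columns=labels)
        corr = self.make_corr(
            {
                (labels[i], labels[j]): float(np.exp(-2 * arr[i, j]) + 0.05 * rng.normal())
                for i, j in itertools.combinations(range(5), 2)
            }
        )
        fit = phylo_distance_regression(corr, dist, exact=True)
        assert fit.n_mantel == 120

        # independent enumeration oracle over all 5! label permutations
        ia = [labels.index(a) for a in corr["species_a"]]
        ib = [labels.index(b) for b in corr["species_b"]]
        c = corr["r"].to_numpy()

        def slope(d):
            dm, cm = d.mean(), c.mean()
            return np.sum((d - dm) * (c - cm)) / np.sum((d - dm) ** 2)

        obs = slope(arr[ia, ib])
        count = 0
        for perm in itertools.permutations(range(5)):
            perm = np.array(perm)
            if abs(slope(arr[perm[ia], perm[ib]])) >= abs(obs) - 1e-12:
                count += 1
        assert fit.p_mantel == pytest.approx(count / 120)
        assert fit.beta == pytest.approx(obs)

    def test_asymmetric_distances_rejected(self):
        labels = ["A", "B", "C"]
        arr = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 3.0], [2.0, 3.0, 0.0]])
        dist = pd.DataFrame(arr, index=labels, columns=labels)
        corr = self.make_corr({("A", "B"): 0.5, ("A", "C"): 0.4, ("B", "C"): 0.3})
        with pytest.raises(ValueError, match="symmetric"):
            phylo_distance_regression(corr, dist, n_mantel=9)

    def test_missing_species_rejected(self):
        labels = ["A", "B"]
        arr = np.array([[0.0, 1.0], [1.0, 0.0]])
        dist = pd.DataFrame(arr, index=labels, columns=labels)
        corr = self.make_corr({("A", "B"): 0.5, ("A", "Z"): 0.4})
        with pytest.raises(ValueError, match="Z"):
            phylo_distance_regression(corr, dist, n_mantel=9)


class TestCopheneticDistances:
    def test_three_tip_path_sums(self):
        dist = cophenetic_distances("((A:1,B:1):1,C:2);")
        assert dist.loc["A", "B"] == pytest.approx(2.0)
        assert dist.loc["A", "C"] == pytest.approx(4.0)
        assert dist.loc["B", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(dist.to_numpy()), 0.0)

    def test_star_tree_all_distances_2h(self):
        h = 1.5
        newick = "(" + ",".join(f"T{i}:{h}" for i in range(5)) + ");"
        dist = cophenetic_distances(newick)
        off_diag = dist.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.allclose(off_diag, 2 * h)

    def test_random_tree_matches_path_walk_oracle(self):
        rng = np.random.default_rng(17)
        import dendropy

        # random 8-tip tree via sequential joins with known branch lengths
        labels = [f"T{i}" for i in range(8)]
        ns = dendropy.TaxonNamespace(labels)
        nodes = []
        parents = {}
        lengths = {}
        for lbl in labels:
            node = dendropy.Node()
            node.taxon = ns.get_taxon(lbl)
            nodes.append(node)
        next_id = 0
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            a, b = nodes[i], nodes[j]
            parent = dendropy.Node()
            parent.label = f"I{next_id}"
            next_id += 1
            for child in (a, b):
                parent.add_child(child)
                child.edge.length = float(np.round(rng.uniform(0.1, 2.0), 3))
                key = child.taxon.label if child.taxon else child.label
                parents[key] = parent.label if parent else None
                lengths[key] = child.edge.length
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
        dist = cophenetic_distances(tree.as_string(schema="newick"))

        # oracle: walk root paths and sum branch lengths past the LCA
        def path_to_root(label):
            path = []
            cur = label
            while cur in parents:
                path.append(cur)
                cur = parents[cur]
            path.append(cur)
            return path

        for a in labels:
            for b in labels:
                if a == b:
                    continue
                pa, pb = path_to_root(a), path_to_root(b)
                shared = set(pa) & set(pb)
                d = sum(lengths[x] for x in pa if x not in shared) + sum(
                    lengths[x] for x in pb if x not in shared
                )
                assert dist.loc[a, b] == pytest.approx(d, rel=1e-9)

    def test_four_point_condition_on_additive_tree(self):
        dist = cophenetic_distances("((A:1,B:2):0.5,(C:1.5,D:0.7):0.8);")
        d = dist.loc
        sums = sorted(
            [
                d["A", "B"] + d["C", "D"],
                d["A", "C"] + d["B", "D"],
                d["A", "D"] + d["B", "C"],
            ]
        )
        assert sums[1] == pytest.approx(sums[2])

    def test_missing_branch_length_errors(self):
        with pytest.raises(ValueError, match="branch length"):
            cophenetic_distances("((A:1,B):1,C:2);")

    def test_duplicate_tips_error(self):
        with pytest.raises(ValueError, match="unique"):
            cophenetic_distances("((A:1,A:1):1,C:2);")
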