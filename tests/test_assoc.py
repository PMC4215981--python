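"""Filtering, imputation, PCA, UPGMA, kinship, the MLM scan and q-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pedqtl import assoc, sim
from pedqtl.core import ConfigError, GenotypeMatrix

from conftest import toy_matrix


class TestFilterMarkers:
    def test_low_maf_and_duplicates_removed(self):
        # 12 accessions x 10 markers: m1-m3 below MAF 0.1, m5 == m4 byte-identical
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(12, 10)).astype(np.int8)
        calls[:, 0] = 0
        calls[:, 1] = 0
        calls[:, 1][0] = 1  # MAF 1/12
        calls[:, 2] = 1
        calls[:, 2][3] = 0  # MAF 1/12
        for j in range(3, 10):  # make the rest clearly common
            calls[:6, j] = 0
            calls[6:, j] = 1
        calls[:, 4] = calls[:, 3]
        calls[0, 5] = 1  # distinguish m6 onward
        calls[1, 6] = 1
        calls[2, 7] = 1
        calls[3, 8] = 1
        calls[4, 9] = 1
        g = GenotypeMatrix([f"a{i}" for i in range(12)], [f"m{j+1}" for j in range(10)], calls)
        out = assoc.filter_markers(g, maf_min=0.1)
        # independent enumeration oracle
        expect = []
        seen = set()
        for j, m in enumerate(g.marker_ids):
            col = calls[:, j]
            f = col.mean()
            if min(f, 1 - f) < 0.1:
                continue
            sig = col.tobytes()
            if sig in seen:
                continue
            seen.add(sig)
            expect.append(m)
        assert out.marker_ids == expect
        assert len(expect) == 6

    def test_first_in_map_order_retained(self):
        g = toy_matrix(["01", "10", "01"])
        gmap = sim.GeneticMap(
            pd.DataFrame(
                {
                    "marker_id": ["m2", "m1"],
                    "linkage_group": ["LG1", "LG1"],
                    "position_cm": [1.0, 2.0],
                    "map_source": ["s", "s"],
                }
            )
        )
        # m1 and m2 are complementary, not identical; both kept, map order applied
        out = assoc.filter_markers(g, maf_min=0.1, gmap=gmap)
        assert out.marker_ids == ["m2", "m1"]


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        g = toy_matrix(["0101", "1010", "0011"])
        out = assoc.knn_impute(g, k=2, min_freq=0.5)
        np.testing.assert_array_equal(out.calls, g.calls)

    def test_hand_computed_neighbour_average(self):
        # distances from a1: a2 = 0, a4 = 1/3, a3 = 1; donors' calls at m4
        # are (0, 1, 0) -> mean 1/3 -> rounds to 0
        g = toy_matrix(["110N", "1100", "0011", "1000"])
        out = assoc.knn_impute(g, k=3, min_freq=0.5)
        assert out.calls[0, 3] == 0

    def test_half_rounds_up(self):
        g = toy_matrix(["11N", "110", "111", "000"])
        out = assoc.knn_impute(g, k=2, min_freq=0.5)
        # nearest two donors disagree (0 and 1) -> average 0.5 -> code 1
        assert out.calls[0, 2] == 1

    def test_low_data_accession_dropped(self):
        g = toy_matrix(["1NNN1NNNN1", "1111111111", "0000000000", "1010101010"])
        with pytest.warns(UserWarning, match="dropping"):
            out = assoc.knn_impute(g, k=2, min_freq=0.8)
        assert "a1" not in out.accession_ids

    def test_k_not_smaller_than_panel_rejected(self):
        g = toy_matrix(["01", "10"])
        with pytest.raises(ConfigError):
            assoc.knn_impute(g, k=2, min_freq=0.0)


class TestPca:
    def test_duplicated_accessions_share_coordinates(self):
        g = toy_matrix(["0101", "0101", "1010", "1100"])
        coords, _ = assoc.pca(g, n_components=2)
        np.testing.assert_allclose(coords.loc["a1"], coords.loc["a2"], atol=1e-10)

    def test_two_marker_eigenvalues_match_closed_form(self):
        # corr(m1, m2) = r -> eigenvalues (1 +- r), proportions (1 +- r)/2
        g = toy_matrix(["00", "10", "11"])
        x1, x2 = g.calls[:, 0].astype(float), g.calls[:, 1].astype(float)
        r = np.corrcoef(x1, x2)[0, 1]
        _, props = assoc.pca(g, n_components=2)
        np.testing.assert_allclose(props, [(1 + r) / 2, (1 - r) / 2], atol=1e-10)

    def test_proportions_invariant_to_allele_code_flips(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        g = GenotypeMatrix([f"a{i}" for i in range(12)], [f"m{j}" for j in range(30)], calls)
        flipped = calls.copy()
        flipped[:, ::2] = 1 - flipped[:, ::2]
        g2 = GenotypeMatrix(g.accession_ids, g.marker_ids, flipped)
        _, p1 = assoc.pca(g, 5)
        _, p2 = assoc.pca(g2, 5)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_missing_calls_rejected(self):
        with pytest.raises(ConfigError):
            assoc.pca(toy_matrix(["0N", "10"]))


class TestUpgma:
    @staticmethod
    def _dist(ids, values):
        return pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=ids)

    def test_identical_accessions_joined_first_at_zero(self):
        g = toy_matrix(["0101", "0101", "1010"])
        tree = assoc.upgma(assoc.distance_matrix(g))
        first = min(
            (c for c in tree.children if len(c.members) == 2),
            key=lambda n: n.height,
        )
        assert first.members == ["a1", "a2"] and first.height == 0.0

    def test_four_taxon_ultrametric_merge_order_and_heights(self):
        d = self._dist(
            list("ABCD"),
            [[0, 2, 10, 10], [2, 0, 10, 10], [10, 10, 0, 4], [10, 10, 4, 0]],
        )
        tree = assoc.upgma(d)
        assert tree.height == 5.0
        left, right = tree.children  # sorted by smallest member id
        assert left.members == ["A", "B"] and left.height == 1.0
        assert right.members == ["C", "D"] and right.height == 2.0

    def test_equal_distances_tie_break_lexicographic(self):
        d = self._dist(list("CBA"), np.ones((3, 3)) - np.eye(3))
        tree = assoc.upgma(d)
        two = next(c for c in tree.children if len(c.members) == 2)
        assert two.members == ["A", "B"]

    def test_focal_parents_in_smallest_clusters(self, study_panel):
        """Pedigree relatives cluster next to the focal line in the dendrogram."""
        g = assoc.knn_impute(assoc.filter_markers(study_panel.genotypes, 0.1))
        tree = assoc.upgma(assoc.distance_matrix(g))

        def containing(node, leaf, acc):
            if leaf in node.members:
                acc.append(node.members)
                for c in node.children:
                    containing(c, leaf, acc)
            return acc

        clusters = sorted(containing(tree, "focal", []), key=len)
        small = {m for c in clusters if len(c) <= 8 for m in c}
        mother, father = study_panel.pedigree.parents("focal")
        assert {mother, father} & small


class TestKinship:
    def test_identical_lines_have_unit_kinship(self):
        g = toy_matrix(["0101", "0101", "1010"])
        K = assoc.kinship(g)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_fully_discordant_pair_rescaled_to_zero(self):
        g = toy_matrix(["0101", "1010", "0111"])
        K = assoc.kinship(g)
        assert K.values[0, 1] == pytest.approx(0.0)

    def test_five_line_matrix_matches_brute_force(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        calls[rng.random((5, 40)) < 0.1] = -1
        g = GenotypeMatrix([f"a{i}" for i in range(5)], [f"m{j}" for j in range(40)], calls)
        K = assoc.kinship(g)
        sim_ = np.eye(5)
        for i in range(5):
            for j in range(5):
                ok = (calls[i] != -1) & (calls[j] != -1)
                sim_[i, j] = (calls[i][ok] == calls[j][ok]).mean()
        m = sim_[~np.eye(5, dtype=bool)].min()
        expect = (sim_ - m) / (1 - m)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(K.values, expect, atol=1e-12)


class TestMlmScan:
    def _toy(self, n=10, m=6, seed=0):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        g = GenotypeMatrix([f"a{i}" for i in range(n)], [f"x{j}" for j in range(m)], calls)
        kernel = pd.Series(rng.integers(0, 2, n), index=g.accession_ids)
        y = pd.Series(
            64 + 1.5 * calls[:, 0] + 2.0 * kernel.to_numpy() + rng.normal(0, 1, n),
            index=g.accession_ids,
        )
        return g, kernel, y

    def test_identity_kinship_reduces_to_ols_ancova(self):
        g, kernel, y = self._toy()
        K = assoc.KinshipMatrix(list(g.accession_ids), np.eye(10))
        scan = assoc.mlm_scan(g, y, K, covariates=kernel, delta=np.inf)
        X = sm.add_constant(
            pd.DataFrame({"kernel": kernel, "x0": g.calls[:, 0]}, index=g.accession_ids)
        )
        ols = sm.OLS(y, X).fit()
        assert scan.loc[0, "p_value"] == pytest.approx(float(ols.pvalues["x0"]), rel=1e-8)
        assert scan.loc[0, "effect"] == pytest.approx(float(ols.params["x0"]), rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_matches_fine_grid_search(self, seed):
        """1-D grid of the restricted likelihood (1e-4 resolution on the
        heritability ratio) agrees with the optimiser on a 6-line toy."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 3))
        K = A @ A.T
        K = K / np.mean(np.diag(K)) * 0.7 + 0.3 * np.eye(6)
        y = np.linalg.cholesky(K) @ rng.normal(size=6) + rng.normal(0, 0.5, 6)
        X = np.ones((6, 1))

        def neg2_rll(delta):  # independent matrix-form restricted likelihood
            V = K + delta * np.eye(6)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ beta
            sigma2 = float(r @ Vi @ r) / (6 - 1)
            _, ld_v = np.linalg.slogdet(V)
            _, ld_x = np.linalg.slogdet(X.T @ Vi @ X)
            return (6 - 1) * np.log(sigma2) + ld_v + ld_x

        hs = np.arange(1e-4, 1.0, 1e-4)
        deltas = (1 - hs) / hs
        grid_vals = np.array([neg2_rll(d) for d in deltas])
        best = grid_vals.min()
        delta_hat, _, _ = assoc.reml_variance_ratio(y, X, K)
        assert neg2_rll(delta_hat) <= best + 1e-3

    def test_confounded_marker_skipped_with_reason(self):
        g, kernel, y = self._toy()
        calls = g.calls.copy()
        calls[:, 1] = kernel.to_numpy()
        g = GenotypeMatrix(g.accession_ids, g.marker_ids, calls)
        K = assoc.KinshipMatrix(list(g.accession_ids), np.eye(10))
        scan = assoc.mlm_scan(g, y, K, covariates=kernel, delta=np.inf)
        assert scan.loc[1, "note"] == "confounded with covariates"
        assert np.isnan(scan.loc[1, "p_value"])

    def test_kernel_covariate_absorbs_kernel_linked_signal(self):
        """A marker associated only through the kernel locus loses
        significance once kernel type enters the model."""
        rng = np.random.default_rng(8)
        n = 65
        kernel = (rng.random(n) < 0.3).astype(np.int8)
        linked = kernel.copy()
        flip = rng.choice(n, size=6, replace=False)
        linked[flip] = 1 - linked[flip]
        others = rng.integers(0, 2, size=(n, 100)).astype(np.int8)
        calls = np.column_stack([linked, others])
        ids = [f"a{i}" for i in range(n)]
        g = GenotypeMatrix(ids, [f"x{j}" for j in range(101)], calls)
        y = pd.Series(64 + 3.0 * kernel + rng.normal(0, 1, n), index=ids)
        kt = pd.Series(kernel, index=ids)
        K = assoc.kinship(g)
        p_no = assoc.mlm_scan(g, y, K).set_index("marker_id")["p_value"]["x0"]
        p_yes = assoc.mlm_scan(g, y, K, covariates=kt).set_index("marker_id")["p_value"]["x0"]
        assert p_no < 1e-6
        assert p_yes > 1e-3 * 1  # signal collapses once kernel is modelled
        assert p_yes > p_no * 100

    def test_refit_per_marker_agrees_with_p3d_on_easy_data(self):
        """Per-marker variance re-estimation shifts p-values by at most an
        order of magnitude and preserves the top association."""
        g, kernel, y = self._toy(n=30, m=40, seed=3)
        K = assoc.kinship(g)
        fast = assoc.mlm_scan(g, y, K, covariates=kernel)
        slow = assoc.mlm_scan(g, y, K, covariates=kernel, refit_per_marker=True)
        assert fast["p_value"].idxmin() == slow["p_value"].idxmin()
        ratio = np.log10(fast["p_value"] / slow["p_value"]).abs()
        assert (ratio <= 1.0).all()


class TestStoreyQvalues:
    def test_single_p_with_fixed_pi0_is_itself(self):
        q, pi0 = assoc.storey_qvalues(np.array([0.05]), pi0=1.0)
        assert q[0] == pytest.approx(0.05)

    def test_four_value_worked_example(self):
        q, _ = assoc.storey_qvalues(np.array([0.01, 0.02, 0.8, 0.9]), pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.9, 0.9])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_threshold_minimisation(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 11))
        p = np.round(rng.random(m), 3)
        q, _ = assoc.storey_qvalues(p, pi0=1.0)
        for i in range(m):
            candidates = [
                min(1.0, 1.0 * m * t / (p <= t).sum()) for t in p if t >= p[i]
            ]
            assert q[i] == pytest.approx(min(candidates))

    def test_q_order_preserving_and_threshold_counts_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        q, pi0 = assoc.storey_qvalues(p)
        assert 0 < pi0 <= 1
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        counts = [(q <= a).sum() for a in np.linspace(0, 1, 21)]
        assert (np.diff(counts) >= 0).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ConfigError):
            assoc.storey_qvalues(np.array([0.5, 1.5]))
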