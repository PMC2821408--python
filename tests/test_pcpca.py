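import numpy as np
import pytest
from scipy import linalg

from placentome import (
    PromoterTFBSMatrix,
    SimulationConfig,
    default_promoter_ratios,
    project_promoters,
    promoter_composition,
    read_tfbs_matrix,
    run_pcpca,
    select_ratio_axes,
    simulate_promoters,
    tfbs_contrast,
    tfbs_ratio_correlation,
    write_tfbs_matrix,
)
from placentome.pcpca import RATIO_VARIABLE, PCPCAResult


def toy_matrix(seed=0, n_promoters=30, n_motifs=6, focal_beta=None):
    cfg = SimulationConfig(
        seed=seed,
        n_motifs=n_motifs,
        focal_motifs={"V$FKHD": focal_beta} if focal_beta else {},
    )
    rng = np.random.default_rng(seed)
    ratios = rng.uniform(-3, 3, n_promoters)
    return simulate_promoters(cfg, ratios)


class TestMatrixIO:
    def test_round_trip_canonical(self, tmp_path):
        matrix = toy_matrix(seed=1)
        path = tmp_path / "tfbs.tsv"
        write_tfbs_matrix(matrix, path)
        back = read_tfbs_matrix(path)
        assert back.promoter_ids == matrix.promoter_ids
        assert back.motif_ids == matrix.motif_ids
        np.testing.assert_array_equal(back.counts, matrix.counts)
        np.testing.assert_allclose(back.log2_ratios, matrix.log2_ratios, atol=5e-7)
        assert back.groups == matrix.groups

    def test_round_trip_transposed(self, tmp_path):
        matrix = toy_matrix(seed=2)
        path = tmp_path / "tfbs_t.tsv"
        write_tfbs_matrix(matrix, path, transposed=True)
        back = read_tfbs_matrix(path)
        np.testing.assert_array_equal(back.counts, matrix.counts)
        assert back.motif_ids == matrix.motif_ids

    def test_study_shaped_matrix(self, tmp_path):
        """60 promoters x 152 motif families plus the ratio variable."""
        cfg = SimulationConfig(seed=3)
        matrix = simulate_promoters(cfg, default_promoter_ratios(cfg))
        assert matrix.counts.shape == (60, 152)
        path = tmp_path / "tfbs.tsv"
        write_tfbs_matrix(matrix, path, transposed=True)
        assert read_tfbs_matrix(path).counts.shape == (60, 152)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "promoter_id\tgene_symbol\tlog2_induction_ratio\tV$A\tV$B\n"
            "p1\tg1\t1.0\t2\t-1\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_tfbs_matrix(path)

    def test_missing_ratio_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("promoter_id\tgene_symbol\tV$A\np1\tg1\t2\n")
        with pytest.raises(ValueError, match="log2_induction_ratio"):
            read_tfbs_matrix(path)

    def test_group_derived_from_ratio_sign(self, tmp_path):
        path = tmp_path / "nogroup.tsv"
        path.write_text(
            "promoter_id\tgene_symbol\tlog2_induction_ratio\tV$A\n"
            "p1\tg1\t1.5\t2\np2\tg2\t-0.5\t1\n"
        )
        assert read_tfbs_matrix(path).groups == ["induced", "repressed"]


class TestRunPCPCA:
    def test_two_perfectly_correlated_variables(self):
        counts = np.array([[1, 2], [2, 4], [3, 6], [4, 8]])
        matrix = PromoterTFBSMatrix(
            ["p1", "p2", "p3", "p4"], ["g"] * 4, np.zeros(4),
            ["unlabeled"] * 4, ["V$A", "V$B"], counts,
        )
        with pytest.warns(UserWarning, match="constant"):
            result = run_pcpca(matrix, ratio_as_variable=False)
        np.testing.assert_allclose(result.eigenvalues, [2.0, 0.0], atol=1e-12)

    def test_trace_identity(self):
        result = run_pcpca(toy_matrix(seed=4))
        assert result.eigenvalues.sum() == pytest.approx(len(result.variable_names))

    def test_matches_independent_svd_solver(self):
        matrix = toy_matrix(seed=5, n_promoters=40, n_motifs=12)
        result = run_pcpca(matrix)
        X = np.column_stack([matrix.counts.astype(float), matrix.log2_ratios])
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        s = linalg.svdvals(Z)
        oracle = np.zeros(Z.shape[1])
        oracle[: len(s)] = s**2 / (Z.shape[0] - 1)
        np.testing.assert_allclose(result.eigenvalues, np.sort(oracle)[::-1], atol=1e-8)

    def test_reconstructs_correlation_matrix(self):
        matrix = toy_matrix(seed=6, n_promoters=50, n_motifs=8)
        result = run_pcpca(matrix)
        recon = (result.loadings * result.eigenvalues) @ result.loadings.T
        X = np.column_stack([matrix.counts.astype(float), matrix.log2_ratios])
        np.testing.assert_allclose(recon, np.corrcoef(X, rowvar=False), atol=1e-6)

    def test_scores_uncorrelated_with_eigenvalue_variance(self):
        matrix = toy_matrix(seed=7, n_promoters=60, n_motifs=5)
        result = run_pcpca(matrix)
        for j in range(result.n_axes):
            assert result.scores[:, j].var(ddof=1) == pytest.approx(
                result.eigenvalues[j], abs=1e-8
            )
        cov = np.cov(result.scores, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)

    def test_ratio_loading_positive_on_top_axis(self):
        result = run_pcpca(toy_matrix(seed=8, focal_beta=0.5))
        top = result.ratio_axis_ranking()[0]
        assert result.ratio_loadings()[top] > 0

    def test_zero_variance_variable_dropped_with_warning(self):
        counts = np.array([[1, 5, 0], [2, 5, 1], [3, 5, 4], [1, 5, 2]])
        matrix = PromoterTFBSMatrix(
            [f"p{i}" for i in range(4)], ["g"] * 4, np.array([1.0, -1.0, 0.5, -0.5]),
            ["induced", "repressed", "induced", "repressed"],
            ["V$A", "V$FLAT", "V$B"], counts,
        )
        with pytest.warns(UserWarning, match="V\\$FLAT"):
            result = run_pcpca(matrix)
        assert "V$FLAT" in result.dropped_variables
        assert "V$FLAT" not in result.variable_names

    def test_too_few_promoters_rejected(self):
        matrix = PromoterTFBSMatrix(
            ["p1", "p2"], ["g"] * 2, np.array([1.0, -1.0]),
            ["induced", "repressed"], ["V$A"], np.array([[1], [2]]),
        )
        with pytest.raises(ValueError, match="3 promoters"):
            run_pcpca(matrix)

    def test_supplementary_ratio_mode(self):
        matrix = toy_matrix(seed=9, focal_beta=0.5)
        active = run_pcpca(matrix, ratio_as_variable=True)
        supp = run_pcpca(matrix, ratio_as_variable=False)
        assert supp.ratio_variable is None
        assert supp.ratio_correlations is not None
        # both modes rank a ratio-linked axis first
        assert abs(supp.ratio_loadings()[supp.ratio_axis_ranking()[0]]) > 0.3
        assert abs(active.ratio_loadings()[active.ratio_axis_ranking()[0]]) > 0.3


class TestAxisSelection:
    def _result_with_ratio_loadings(self, weights):
        n = len(weights)
        loadings = np.vstack([np.eye(n - 1, n), np.array(weights)])
        return PCPCAResult(
            eigenvalues=np.linspace(n, 1, n),
            loadings=loadings,
            scores=np.zeros((3, n)),
            variable_names=[f"V${i}" for i in range(n - 1)] + [RATIO_VARIABLE],
            dropped_variables=[],
            promoter_ids=["p1", "p2", "p3"],
            groups=["induced", "repressed", "unlabeled"],
        )

    def test_forced_ranking(self):
        result = self._result_with_ratio_loadings([0.9, 0.1, 0.05])
        assert select_ratio_axes(result, k=2) == [0, 1]

    def test_k_one_matches_argmax_oracle(self):
        weights = [0.2, -0.8, 0.3]
        result = self._result_with_ratio_loadings(weights)
        oracle = int(np.argmax(np.abs(weights)))
        assert select_ratio_axes(result, k=1) == [oracle]

    def test_k_out_of_range_rejected(self):
        result = self._result_with_ratio_loadings([0.9, 0.1, 0.05])
        with pytest.raises(ValueError):
            select_ratio_axes(result, k=4)


class TestProjection:
    def test_coordinates_equal_score_columns(self):
        matrix = toy_matrix(seed=10)
        result = run_pcpca(matrix)
        frame = project_promoters(result, (0, 2))
        np.testing.assert_array_equal(frame["axis_1"].to_numpy(), result.scores[:, 0])
        np.testing.assert_array_equal(frame["axis_3"].to_numpy(), result.scores[:, 2])
        assert list(frame["group"]) == matrix.groups

    def test_promoter_permutation_permutes_coordinates(self):
        matrix = toy_matrix(seed=11)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_promoters)
        permuted = PromoterTFBSMatrix(
            [matrix.promoter_ids[i] for i in perm],
            [matrix.gene_symbols[i] for i in perm],
            matrix.log2_ratios[perm],
            [matrix.groups[i] for i in perm],
            matrix.motif_ids,
            matrix.counts[perm],
        )
        a = run_pcpca(matrix)
        b = run_pcpca(permuted)
        fa = project_promoters(a, (0, 1)).set_index("promoter_id").sort_index()
        fb = project_promoters(b, (0, 1)).set_index("promoter_id").sort_index()
        np.testing.assert_allclose(
            fa[["axis_1", "axis_2"]].to_numpy(),
            fb[["axis_1", "axis_2"]].to_numpy(),
            atol=1e-9,
        )

    def test_groups_dichotomize_along_ratio_axis(self):
        """Induced promoters score higher than repressed along the leading
        ratio axis (rank-sum dichotomy; with 153 variables over 60 promoters
        the noise bulk precludes strict linear separability)."""
        from scipy.stats import mannwhitneyu

        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, focal_motifs={"V$FKHD": 0.5})
            matrix = simulate_promoters(cfg, default_promoter_ratios(cfg))
            result = run_pcpca(matrix)
            top = select_ratio_axes(result, k=1)[0]
            frame = project_promoters(result, (top, (top + 1) % result.n_axes))
            coord = frame[f"axis_{top + 1}"].to_numpy()
            grp = np.array(matrix.groups)
            _, p = mannwhitneyu(
                coord[grp == "induced"], coord[grp == "repressed"],
                alternative="greater",
            )
            hits += p < 0.05
        assert hits >= 9


class TestTFBSContrast:
    def _two_group_matrix(self, a_counts, b_counts, motif="V$A"):
        counts = np.array(a_counts + b_counts).reshape(-1, 1)
        n_a, n_b = len(a_counts), len(b_counts)
        return PromoterTFBSMatrix(
            [f"p{i}" for i in range(n_a + n_b)],
            ["g"] * (n_a + n_b),
            np.array([1.0] * n_a + [-1.0] * n_b),
            ["induced"] * n_a + ["repressed"] * n_b,
            [motif],
            counts,
        ), [f"p{i}" for i in range(n_a)], [f"p{i}" for i in range(n_a, n_a + n_b)]

    def test_hand_computed_pooled_t(self):
        matrix, a, b = self._two_group_matrix([1, 2, 3], [4, 5, 6])
        result = tfbs_contrast(matrix, a, b)
        assert result.t[0] == pytest.approx(-3.674, abs=5e-4)
        assert result.df == 4

    def test_equal_groups_give_zero_t(self):
        matrix, a, b = self._two_group_matrix([1, 2, 3], [1, 2, 3])
        result = tfbs_contrast(matrix, a, b)
        assert result.t[0] == pytest.approx(0.0, abs=1e-12)
        assert result.p_raw[0] == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self):
        matrix = toy_matrix(seed=12, focal_beta=0.5)
        induced = [p for p, g in zip(matrix.promoter_ids, matrix.groups) if g == "induced"]
        repressed = [p for p, g in zip(matrix.promoter_ids, matrix.groups) if g == "repressed"]
        fwd = tfbs_contrast(matrix, induced, repressed)
        rev = tfbs_contrast(matrix, repressed, induced)
        mask = fwd.testable
        np.testing.assert_allclose(fwd.t[mask], -rev.t[mask], atol=1e-10)
        np.testing.assert_allclose(fwd.p_raw[mask], rev.p_raw[mask], atol=1e-12)

    def test_small_group_rejected(self):
        matrix, a, b = self._two_group_matrix([1, 2, 3], [4])
        with pytest.raises(ValueError, match="at least 2"):
            tfbs_contrast(matrix, a, b)

    def test_constant_motif_untestable(self):
        matrix, a, b = self._two_group_matrix([5, 5, 5], [5, 5, 5])
        result = tfbs_contrast(matrix, a, b)
        assert not result.testable[0]
        assert np.isnan(result.p_bonferroni[0])

    def test_bonferroni_scales_raw_p(self):
        matrix = toy_matrix(seed=13, n_motifs=10, focal_beta=0.5)
        induced = [p for p, g in zip(matrix.promoter_ids, matrix.groups) if g == "induced"]
        repressed = [p for p, g in zip(matrix.promoter_ids, matrix.groups) if g == "repressed"]
        result = tfbs_contrast(matrix, induced, repressed)
        mask = result.testable
        np.testing.assert_allclose(
            result.p_bonferroni[mask],
            np.minimum(result.p_raw[mask] * result.n_tested, 1.0),
        )


class TestRatioCorrelation:
    def test_linear_counts_give_r_one(self):
        ratios = np.array([0.0, 1.0, 2.0, 3.0])
        counts = np.array([[0], [2], [4], [6]])
        matrix = PromoterTFBSMatrix(
            ["p1", "p2", "p3", "p4"], ["g"] * 4, ratios,
            ["unlabeled"] + ["induced"] * 3, ["V$A"], counts,
        )
        r, p = tfbs_ratio_correlation(matrix, "V$A")
        assert r == pytest.approx(1.0)

    def test_matches_textbook_quotient(self):
        rng = np.random.default_rng(14)
        ratios = rng.uniform(-2, 2, 10)
        counts = rng.poisson(3, size=(10, 1))
        if counts.std() == 0:
            counts[0, 0] += 1
        matrix = PromoterTFBSMatrix(
            [f"p{i}" for i in range(10)], ["g"] * 10, ratios,
            ["unlabeled"] * 10, ["V$A"], counts,
        )
        r, _ = tfbs_ratio_correlation(matrix, "V$A")
        x, y = counts[:, 0].astype(float), ratios
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        matrix = PromoterTFBSMatrix(
            ["p1", "p2", "p3"], ["g"] * 3, np.array([1.0, 2.0, 3.0]),
            ["induced"] * 3, ["V$A"], np.array([[2], [2], [2]]),
        )
        with pytest.raises(ValueError, match="zero count variance"):
            tfbs_ratio_correlation(matrix, "V$A")

    def test_unknown_motif_rejected(self):
        matrix = toy_matrix(seed=15)
        with pytest.raises(KeyError):
            tfbs_ratio_correlation(matrix, "V$GHOST")


class TestPromoterComposition:
    def test_hand_counted_examples(self):
        frame = promoter_composition(
            [("gcgc", "GCGC"), ("atat", "ATAT"), ("acgt", "ACGT")]
        ).set_index("promoter_id")
        assert frame.loc["gcgc", "gc_fraction"] == 1.0
        # one CG dinucleotide, L=4, C=G=2: o/e = 1*4/(2*2)
        assert frame.loc["gcgc", "cpg_obs_exp"] == pytest.approx(1.0)
        assert frame.loc["atat", "gc_fraction"] == 0.0
        assert frame.loc["acgt", "gc_fraction"] == 0.5
        assert frame.loc["acgt", "cpg_obs_exp"] == pytest.approx(4.0)

    def test_n_bases_excluded_from_denominators(self):
        frame = promoter_composition([("p", "ACGTNN")])
        assert frame["gc_fraction"].iloc[0] == pytest.approx(0.5)
        assert frame["cpg_obs_exp"].iloc[0] == pytest.approx(4.0)

    def test_fasta_path_input(self, tmp_path):
        fasta = tmp_path / "promoters.fasta"
        fasta.write_text(">p1\nACGT\n>p2\nGGGG\n")
        frame = promoter_composition(fasta)
        assert list(frame["promoter_id"]) == ["p1", "p2"]
        assert np.isnan(frame["cpg_obs_exp"].iloc[1])  # no C bases

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            promoter_composition([("p", "")])

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            promoter_composition([("p", "ACGU")])
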