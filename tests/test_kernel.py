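"""Standardization, kernel construction, and the gene-wise kernel scan."""

import numpy as np
import pytest

from methvc.kernel import (
    KernelError,
    build_all_kernels,
    build_kernel,
    kernel_scan,
    load_kernels,
    save_kernels,
    standardize_sites,
    write_grm_pairs,
    write_kernel_tsv,
)
from methvc.methylation import MethylationMatrix, build_gene_index, inverse_normalize


def matrix_of(values):
    values = np.asarray(values, float)
    return MethylationMatrix(
        [f"cg{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
        values,
        transformed=True,
    )


def brute_force_correlation(Z):
    """Independent oracle: pairwise correlation of standardized site vectors."""
    n = Z.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(Z[i, s] * Z[j, s] for s in range(Z.shape[1]))
            di = sum(Z[i, s] ** 2 for s in range(Z.shape[1]))
            dj = sum(Z[j, s] ** 2 for s in range(Z.shape[1]))
            K[i, j] = num / np.sqrt(di * dj)
    return K


class TestStandardize:
    def test_hand_example(self):
        # sites (1,2,3) and (4,6,8) over 3 samples; sample-sd convention
        m = matrix_of([[1, 2, 3], [4, 6, 8]])
        Z, kept, dropped = standardize_sites(m, ["cg0", "cg1"])
        assert kept == ["cg0", "cg1"] and not dropped
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(Z[:, 1], [-1.0, 0.0, 1.0])
        assert Z[0, 0] == -1.0

    def test_columns_mean_zero_unit_variance(self):
        rng = np.random.default_rng(0)
        m = matrix_of(rng.standard_normal((10, 25)))
        Z, kept, _ = standardize_sites(m, m.site_ids)
        assert len(kept) == 10
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_standardized_input_is_fixed_point(self):
        rng = np.random.default_rng(1)
        m = matrix_of(rng.standard_normal((3, 12)))
        Z1, *_ = standardize_sites(m, m.site_ids)
        m2 = matrix_of(Z1.T)
        Z2, *_ = standardize_sites(m2, m2.site_ids)
        np.testing.assert_allclose(Z2, Z1, atol=1e-12)

    def test_constant_site_dropped(self):
        m = matrix_of([[1, 1, 1, 1], [0.2, 0.4, 0.1, 0.8]])
        Z, kept, dropped = standardize_sites(m, m.site_ids)
        assert kept == ["cg1"]
        assert dropped[0][0] == "cg0"

    def test_excess_missingness_dropped(self):
        row = [0.1, np.nan, np.nan, 0.4, 0.5]
        m = matrix_of([row, [0.1, 0.2, 0.3, 0.4, 0.5]])
        _, kept, dropped = standardize_sites(m, m.site_ids, max_missing=0.2)
        assert kept == ["cg1"] and dropped[0][1].startswith("missingness")


class TestBuildKernel:
    def test_single_sample(self):
        k = build_kernel(np.array([[0.5, -0.2]]), "g", ["S0"])
        np.testing.assert_array_equal(k.K, [[1.0]])

    def test_identical_and_opposite_vectors(self):
        z = np.array([1.0, -1.0, 0.5])
        K_same = build_kernel(np.vstack([z, z]), "g", ["a", "b"]).K
        assert K_same[0, 1] == pytest.approx(1.0, abs=1e-12)
        K_opp = build_kernel(np.vstack([z, -z]), "g", ["a", "b"]).K
        assert K_opp[0, 1] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_correlation(self, seed):
        rng = np.random.default_rng(seed)
        n, s = rng.integers(4, 12), rng.integers(5, 20)
        m = matrix_of(rng.standard_normal((s, n)))
        Z, kept, _ = standardize_sites(m, m.site_ids)
        K = build_kernel(Z, "g", m.sample_ids).K
        assert np.abs(K - brute_force_correlation(Z)).max() < 1e-10

    def test_unit_diagonal_symmetry_psd(self, small_dataset):
        for kern in small_dataset.kernels:
            assert np.abs(np.diag(kern.K) - 1.0).max() <= 1e-10
            assert np.abs(kern.K - kern.K.T).max() <= 1e-12
            assert np.linalg.eigvalsh(kern.K).min() >= -1e-8
            assert np.abs(kern.K).max() <= 1.0 + 1e-12

    def test_site_column_order_invariance(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((6, 9))
        K1 = build_kernel(Z, "g", [f"S{i}" for i in range(6)]).K
        K2 = build_kernel(Z[:, rng.permutation(9)], "g", [f"S{i}" for i in range(6)]).K
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_zero_diagonal_names_sample(self):
        Z = np.array([[0.0, 0.0], [1.0, -1.0]])
        with pytest.raises(KernelError, match="S0"):
            build_kernel(Z, "g", ["S0", "S1"])

    def test_iid_noise_off_diagonals_concentrate(self):
        rng = np.random.default_rng(11)
        m = matrix_of(rng.standard_normal((250, 50)))
        Z, *_ = standardize_sites(m, m.site_ids)
        K = build_kernel(Z, "g", m.sample_ids).K
        off = K[~np.eye(50, dtype=bool)]
        assert np.abs(off).max() < 0.5


class TestKernelScan:
    def test_emits_one_kernel_per_eligible_gene(self, small_dataset):
        m = inverse_normalize(small_dataset.methylation)
        skipped = []
        kernels = list(kernel_scan(m, small_dataset.index, skipped=skipped))
        # independent recount of eligible genes with >= 5 usable sites
        expected = 0
        for gene in small_dataset.index.gene_ids:
            sites = small_dataset.index.sites_for(gene)
            usable = sum(
                np.nanstd(m.values[m.site_ids.index(s)]) > 0 for s in sites
            )
            expected += usable >= 5
        assert len(kernels) == expected
        assert [k.gene_id for k in kernels] == sorted(k.gene_id for k in kernels)

    def test_gene_dropping_below_threshold_lands_in_skip_report(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((10, 8))
        vals[6:] = 0.7  # constant rows cg6..cg9
        m = matrix_of(vals)
        import pandas as pd

        ann = pd.DataFrame(
            [(f"cg{i}", "G_OK", "1", i) for i in range(5)]
            + [(f"cg{i}", "G_BAD", "1", i) for i in range(3, 10)],
            columns=["site_id", "gene_id", "chromosome", "position"],
        )
        index = build_gene_index(ann, min_sites=5)
        skipped = []
        kernels = list(kernel_scan(m, index, skipped=skipped))
        assert [k.gene_id for k in kernels] == ["G_OK"]
        assert skipped and skipped[0][0] == "G_BAD"

    def test_container_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "kernels.npz"
        save_kernels(small_dataset.kernels, path)
        back = load_kernels(path)
        assert [k.gene_id for k in back] == [k.gene_id for k in small_dataset.kernels]
        np.testing.assert_array_equal(back[0].K, small_dataset.kernels[0].K)
        assert back[0].n_sites == small_dataset.kernels[0].n_sites

    def test_tsv_exports(self, tmp_path, small_dataset):
        import pandas as pd

        kern = small_dataset.kernels[0]
        write_kernel_tsv(kern, tmp_path / "k.tsv")
        square = pd.read_csv(tmp_path / "k.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(square.to_numpy(), kern.K, atol=1e-9)
        write_grm_pairs(kern, tmp_path / "k.grm.tsv")
        pairs = pd.read_csv(tmp_path / "k.grm.tsv", sep="\t")
        n = len(kern.sample_ids)
        assert len(pairs) == n * (n + 1) // 2
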