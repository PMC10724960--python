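import numpy as np
import pytest

from cssmo import (
    ExpressionDataset,
    PreprocessConfig,
    load_expression_matrix,
    load_selection_report,
    normalize_expression,
    write_expression_matrix,
    write_selection_report,
)
from cssmo.errors import ConfigError, FormatError, ValidationError


def write_csv(path, text):
    path.write_text(text)
    return path


class TestLoading:
    def test_basic_csv(self, tmp_path):
        p = write_csv(
            tmp_path / "d.csv",
            "id,g1,g2,g3,g4,class\ns1,1,2,3,4,A\ns2,5,6,7,8,A\ns3,9,10,11,12,B\n",
        )
        ds = load_expression_matrix(p, PreprocessConfig(normalization="none"))
        assert ds.n_samples == 3 and ds.n_genes == 4 and ds.n_classes == 2
        assert ds.class_names == ("A", "B")
        assert list(ds.labels) == [0, 0, 1]
        assert ds.matrix[2, 3] == 12.0

    def test_transposed_orientation_matches(self, tmp_path):
        plain = write_csv(
            tmp_path / "a.csv",
            "id,g1,g2,class\ns1,1,2,A\ns2,3,4,B\n",
        )
        transposed = write_csv(
            tmp_path / "b.csv",
            "id,s1,s2\ng1,1,3\ng2,2,4\nclass,A,B\n",
        )
        cfg = PreprocessConfig(normalization="none")
        cfg_t = PreprocessConfig(normalization="none", orientation="genes_by_samples")
        a = load_expression_matrix(plain, cfg)
        b = load_expression_matrix(transposed, cfg_t)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.labels.tolist() == b.labels.tolist()
        assert a.gene_ids == b.gene_ids

    def test_tab_delimiter_sniffed(self, tmp_path):
        p = write_csv(tmp_path / "d.tsv", "id\tg1\tclass\ns1\t1\tA\ns2\t2\tB\n")
        ds = load_expression_matrix(p, PreprocessConfig(normalization="none"))
        assert ds.n_genes == 1

    def test_na_cell_rejected_with_context(self, tmp_path):
        p = write_csv(
            tmp_path / "d.csv", "id,g1,g2,class\ns1,1,NA,A\ns2,2,3,B\n"
        )
        with pytest.raises(FormatError, match="g2"):
            load_expression_matrix(p, PreprocessConfig(normalization="none"))

    def test_missing_label_column(self, tmp_path):
        p = write_csv(tmp_path / "d.csv", "id,g1,g2,class\ns1,1,2,A\ns2,2,3,B\n")
        with pytest.raises(FormatError, match="label"):
            load_expression_matrix(
                p, PreprocessConfig(normalization="none", label_column="outcome")
            )

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = write_csv(tmp_path / "d.csv", "id,g1,class\ns1,1,A\ns1,2,B\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_expression_matrix(p, PreprocessConfig(normalization="none"))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            load_expression_matrix(tmp_path / "nope.csv")


class TestNormalization:
    def _one_gene(self, values, labels=(0, 0, 1)):
        n = len(values)
        return ExpressionDataset(
            matrix=np.array(values, dtype=float).reshape(n, 1),
            labels=np.array(labels[:n]),
            gene_ids=("g",),
            sample_ids=tuple(f"s{i}" for i in range(n)),
            class_names=("a", "b"),
        )

    def test_minmax_linear_map(self):
        ds = normalize_expression(self._one_gene([2, 4, 6]), "minmax_per_gene")
        assert np.allclose(ds.matrix[:, 0], [0, 0.5, 1])

    def test_minmax_constant_gene(self):
        ds = normalize_expression(self._one_gene([5, 5, 5]), "minmax_per_gene")
        assert np.all(ds.matrix == 0)

    def test_minmax_idempotent(self):
        ds = self._one_gene([2, 4, 6])
        once = normalize_expression(ds, "minmax_per_gene")
        twice = normalize_expression(once, "minmax_per_gene")
        assert np.array_equal(once.matrix, twice.matrix)

    def test_zscore_two_points(self):
        # sample sd (n-1): sd of (1,3) is sqrt(2), mean 2 -> (-1,1)/sqrt(2)*sqrt(2)
        ds = normalize_expression(self._one_gene([1, 3], (0, 1)), "zscore_per_gene")
        expected = (np.array([1.0, 3.0]) - 2.0) / np.std([1, 3], ddof=1)
        assert np.allclose(ds.matrix[:, 0], expected)
        assert np.allclose(ds.matrix[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_unknown_method(self, tiny_dataset):
        with pytest.raises(ConfigError):
            normalize_expression(tiny_dataset, "rank")

    def test_labels_and_ids_unchanged(self, tiny_dataset):
        out = normalize_expression(tiny_dataset, "zscore_per_gene")
        assert out.gene_ids == tiny_dataset.gene_ids
        assert np.array_equal(out.labels, tiny_dataset.labels)


class TestRoundTrips:
    def test_write_load_bit_identical(self, tmp_path, tiny_dataset):
        p = tmp_path / "out.csv"
        write_expression_matrix(tiny_dataset, p)
        back = load_expression_matrix(p, PreprocessConfig(normalization="none"))
        assert np.array_equal(back.matrix, tiny_dataset.matrix)
        assert back.gene_ids == tiny_dataset.gene_ids
        assert back.sample_ids == tiny_dataset.sample_ids
        assert np.array_equal(back.labels, tiny_dataset.labels)

    def test_selection_report_round_trip(self, tmp_path, recovery_benchmark, small_config):
        from cssmo import run_cssmo

        dataset, _, pool, fitness_fn = recovery_benchmark
        result = run_cssmo(dataset, pool, fitness_fn, small_config)
        p = tmp_path / "report.json"
        write_selection_report(result, p)
        back = load_selection_report(p)
        assert back.to_json() == result.to_json()
        assert back.selected_genes == result.selected_genes

    def test_empty_mask_report_rejected(self, tmp_path, recovery_benchmark, small_config):
        from cssmo import run_cssmo

        dataset, _, pool, fitness_fn = recovery_benchmark
        result = run_cssmo(dataset, pool, fitness_fn, small_config)
        object.__setattr__(result, "best_mask", np.zeros_like(result.best_mask))
        with pytest.raises(ValidationError):
            write_selection_report(result, tmp_path / "r.json")


class TestDatasetInvariants:
    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            ExpressionDataset(
                matrix=np.ones((2, 2)),
                labels=np.array([0, 0]),
                gene_ids=("g1", "g2"),
                sample_ids=("s1", "s2"),
                class_names=("a", "b"),
            )

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            ExpressionDataset(
                matrix=np.array([[1.0, np.nan], [0.0, 1.0]]),
                labels=np.array([0, 1]),
                gene_ids=("g1", "g2"),
                sample_ids=("s1", "s2"),
                class_names=("a", "b"),
            )
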