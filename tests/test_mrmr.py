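import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cssmo import (
    ExpressionDataset,
    discretize_expression,
    mrmr_select,
    mutual_information,
)
from cssmo.errors import ConfigError
from cssmo.mrmr import DiscretizedMatrix, relevance_vector


def brute_force_mi(x, y):
    """Independent plug-in MI oracle: direct sum over observed cells."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for a in np.unique(x):
        for b in np.unique(y):
            pxy = np.sum((x == a) & (y == b)) / n
            if pxy == 0:
                continue
            px = np.sum(x == a) / n
            py = np.sum(y == b) / n
            total += pxy * np.log(pxy / (px * py))
    return total


def dataset_from_matrix(values):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    labels = np.zeros(n, dtype=int)
    labels[n // 2 :] = 1
    return ExpressionDataset(
        matrix=values,
        labels=labels,
        gene_ids=tuple(f"g{i}" for i in range(g)),
        sample_ids=tuple(f"s{i}" for i in range(n)),
        class_names=("a", "b"),
    )


class TestDiscretize:
    def test_quantile_equal_occupancy(self):
        ds = dataset_from_matrix(np.array([[1, 2, 3, 4, 5, 6]]).T)
        disc = discretize_expression(ds, n_bins=3, strategy="quantile")
        assert disc.codes[:, 0].tolist() == [0, 0, 1, 1, 2, 2]

    def test_constant_gene_code_zero(self):
        ds = dataset_from_matrix(np.array([[7.0, 7, 7, 7]]).T)
        disc = discretize_expression(ds, n_bins=3)
        assert np.all(disc.codes == 0)

    def test_width_midpoint_split(self):
        ds = dataset_from_matrix(np.array([[0, 0.4, 0.6, 1.0]]).T)
        disc = discretize_expression(ds, n_bins=2, strategy="width")
        assert disc.codes[:, 0].tolist() == [0, 0, 1, 1]

    def test_bad_bins(self):
        ds = dataset_from_matrix(np.array([[1.0, 2]]).T)
        with pytest.raises(ConfigError):
            discretize_expression(ds, n_bins=1)


class TestMutualInformation:
    def test_identity_is_entropy(self):
        x = np.array([0, 0, 1, 1, 2, 2])
        assert mutual_information(x, x) == pytest.approx(np.log(3), abs=1e-12)

    def test_constant_zero(self):
        assert mutual_information(np.zeros(10, dtype=int),
                                  np.arange(10) % 2) == 0.0

    def test_printed_table_against_oracle(self):
        # joint counts [[5,1],[1,5]], n=12
        x = np.array([0] * 6 + [1] * 6)
        y = np.array([0] * 5 + [1] + [0] + [1] * 5)
        expected = brute_force_mi(x, y)
        # independent closed-form evaluation of the same table
        closed = 2 * (5 / 12) * np.log((5 / 12) / 0.25) + \
                 2 * (1 / 12) * np.log((1 / 12) / 0.25)
        assert expected == pytest.approx(closed, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_nonnegativity_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        x = rng.integers(0, 4, size=n)
        y = rng.integers(0, 3, size=n)
        mi = mutual_information(x, y)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        hx = brute_force_mi(x, x)
        hy = brute_force_mi(y, y)
        assert mi <= min(hx, hy) + 1e-12

    def test_independent_variables_small_mi(self):
        rng = np.random.default_rng(123)
        x = rng.integers(0, 3, size=10_000)
        y = rng.integers(0, 3, size=10_000)
        assert mutual_information(x, y) < 0.02


def oracle_mrmr(codes, labels, k, scheme="MID"):
    """Exhaustive per-step scoring oracle, recomputed from scratch each step."""
    n_genes = codes.shape[1]
    relevance = [brute_force_mi(codes[:, j], labels) for j in range(n_genes)]
    selected = [int(np.argmax(relevance))]
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in range(n_genes):
            if j in selected:
                continue
            red = np.mean([brute_force_mi(codes[:, j], codes[:, s]) for s in selected])
            if scheme == "MID":
                score = relevance[j] - red
            else:
                score = relevance[j] / max(red, 1e-12)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


class TestMrmrSelect:
    def _toy(self, seed=0):
        """8 genes: 2 informative (noisy label copies), 2 exact duplicates of
        them, 4 noise. The label noise keeps candidate scores well separated
        so the greedy/oracle comparison is not decided by float dust."""
        rng = np.random.default_rng(seed)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        g0 = labels + rng.normal(0, 0.3, n)
        g1 = (1.0 - labels) + rng.normal(0, 0.3, n)
        noise = rng.normal(0, 1, size=(n, 4))
        matrix = np.column_stack([g0, g1, g0, g1, noise])
        return dataset_from_matrix(matrix), labels

    def test_k1_picks_max_relevance(self):
        ds, labels = self._toy()
        disc = discretize_expression(ds, n_bins=3)
        pool = mrmr_select(disc, labels, k=1)
        rel = relevance_vector(disc, labels)
        assert pool.selected_idx[0] == int(np.argmax(rel))

    def test_matches_exhaustive_oracle(self):
        ds, labels = self._toy(seed=3)
        disc = discretize_expression(ds, n_bins=3)
        pool = mrmr_select(disc, labels, k=4)
        expected = oracle_mrmr(disc.codes, labels, k=4)
        assert list(pool.selected_idx) == expected

    def test_duplicate_never_beats_uncorrelated_equal_relevance(self):
        # gene 2 is an exact duplicate of gene 0 (already selected); its
        # redundancy penalty equals its self-entropy, so gene 1 (equally
        # informative, independent noise pattern) must be picked first
        ds, labels = self._toy()
        disc = discretize_expression(ds, n_bins=3)
        pool = mrmr_select(disc, labels, k=2)
        assert pool.selected_idx[0] in (0, 1)
        assert pool.selected_idx[1] not in (2, 3)

    def test_k_equal_n_genes_is_permutation(self):
        ds, labels = self._toy(seed=7)
        disc = discretize_expression(ds, n_bins=3)
        pool = mrmr_select(disc, labels, k=8)
        assert sorted(pool.selected_idx) == list(range(8))

    def test_miq_scheme_runs(self):
        ds, labels = self._toy(seed=5)
        disc = discretize_expression(ds, n_bins=3)
        pool = mrmr_select(disc, labels, k=4, scheme="MIQ")
        assert pool.scheme == "MIQ"
        assert list(pool.selected_idx) == oracle_mrmr(
            disc.codes, labels, k=4, scheme="MIQ"
        )

    def test_k_out_of_range(self):
        ds, labels = self._toy()
        disc = discretize_expression(ds, n_bins=3)
        with pytest.raises(ConfigError):
            mrmr_select(disc, labels, k=0)
        with pytest.raises(ConfigError):
            mrmr_select(disc, labels, k=9)
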