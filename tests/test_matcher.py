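"""Cardinality-constrained least squares via forward-backward greedy search."""

import itertools

import numpy as np
import pandas as pd
import pytest

import trsnmatch as tm
from trsnmatch.library import LibraryMatrix
from trsnmatch.targets import TRSN

import scipy.sparse as sp


def make_lib(A: np.ndarray) -> LibraryMatrix:
    """Wrap a dense array as a LibraryMatrix with generic metadata."""
    n, m = A.shape
    genes = pd.Index([f"g{i:03d}" for i in range(n)])
    columns = pd.DataFrame({
        "network_id": [f"CN{j:03d}" for j in range(m)],
        "condition": [f"c{j}" for j in range(m)],
        "cell_line": "CL1",
        "tf": [f"TF{j}" for j in range(m)],
        "direction": "up",
    })
    return LibraryMatrix(genes=genes, columns=columns, A=sp.csc_matrix(A))


def best_subset_rss(A: np.ndarray, b: np.ndarray, s: int) -> float:
    """Exhaustive best-subset oracle: min RSS over all supports of size <= s."""
    best = float(b @ b)
    for k in range(1, s + 1):
        for subset in itertools.combinations(range(A.shape[1]), k):
            x, *_ = np.linalg.lstsq(A[:, subset], b, rcond=None)
            r = b - A[:, subset] @ x
            best = min(best, float(r @ r))
    return best


class TestParseQuery:
    def test_two_column_parse(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("TP53\t1.2\nEGR1\t-0.4\n")
        q = tm.parse_query(p)
        assert q.entries == {"TP53": 1.2, "EGR1": -0.4}

    def test_header_autodetected(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("Symbol\tLogFC\nTP53\t1.2\n")
        assert tm.parse_query(p).entries == {"TP53": 1.2}

    def test_three_columns_rejected(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("TP53\t1.2\textra\n")
        with pytest.raises(ValueError, match="two"):
            tm.parse_query(p)

    def test_duplicate_symbols_listed(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("TP53\t1.2\nTP53\t0.3\n")
        with pytest.raises(ValueError, match="TP53"):
            tm.parse_query(p)

    def test_non_numeric_value_names_line(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("TP53\t1.2\nEGR1\tNA\n")
        with pytest.raises(ValueError, match=":2"):
            tm.parse_query(p)


class TestAlignQuery:
    def test_exact_cover_is_identity(self, tiny_library):
        q = tm.QueryProfile({g: float(i) for i, g in enumerate(tiny_library.genes, 1)})
        b, matched, dropped = tm.align_query(q, tiny_library)
        assert matched == len(tiny_library.genes) and dropped == 0
        assert b == pytest.approx(np.arange(1, len(b) + 1, dtype=float))

    def test_missing_gene_filled_with_zero(self, tiny_library):
        g0 = tiny_library.genes[0]
        q = tm.QueryProfile({g: 1.0 for g in tiny_library.genes if g != g0})
        b, *_ = tm.align_query(q, tiny_library)
        assert b[0] == 0.0

    def test_unknown_genes_counted_dropped(self, tiny_library):
        entries = {tiny_library.genes[0]: 1.0}
        entries.update({f"FAKE{i}": 0.5 for i in range(5)})
        _, matched, dropped = tm.align_query(tm.QueryProfile(entries), tiny_library)
        assert matched == 1 and dropped == 5

    def test_zero_overlap_rejected(self, tiny_library):
        with pytest.raises(ValueError, match="no gene overlap"):
            tm.align_query(tm.QueryProfile({"FAKE": 1.0}), tiny_library)


class TestFobaSelect:
    def test_exact_single_column_representation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 8))
        lib = make_lib(A)
        b = A[:, 3].copy()
        res = tm.foba_select(lib, b)
        assert res.support == [3]
        assert res.coefficients == pytest.approx([1.0])
        assert res.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_columns_closed_form(self):
        # orthogonal design: selected = s largest (a_j.b)^2/||a_j||^2,
        # coefficients a_j.b/||a_j||^2, exact to 1e-10
        n, m, s = 16, 8, 3
        Q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(n, m)))
        scales = np.arange(1.0, m + 1)
        A = Q * scales
        x_true = np.zeros(m)
        x_true[[1, 4, 6]] = [2.0, -1.5, 1.0]
        b = A @ x_true
        res = tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=s))
        proj = (A.T @ b) ** 2 / (scales ** 2)
        expect_support = sorted(np.argsort(-proj)[:s])
        assert res.support == expect_support
        expect_coef = (A.T @ b / scales ** 2)[expect_support]
        assert res.coefficients == pytest.approx(expect_coef, abs=1e-10)

    def test_orthogonal_b_gives_empty_selection(self):
        A = np.eye(6)[:, :3]
        b = np.zeros(6)
        b[4] = 1.0          # orthogonal to every column
        res = tm.foba_select(make_lib(A), b)
        assert res.support == [] and len(res.selected) == 0

    def test_all_zero_b_empty_selection(self):
        A = np.random.default_rng(2).normal(size=(10, 4))
        res = tm.foba_select(make_lib(A), np.zeros(10))
        assert res.support == []
        assert res.residual_norm == 0.0

    def test_non_finite_rejected(self):
        A = np.ones((4, 2))
        with pytest.raises(ValueError, match="non-finite"):
            tm.foba_select(make_lib(A), np.array([1.0, np.nan, 0.0, 0.0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_cardinality_never_exceeded(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 30), rng.integers(2, 25)
        A = rng.normal(size=(n, m))
        b = rng.normal(size=n)
        s = int(rng.integers(1, 11))
        res = tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=s))
        assert len(res.support) <= s
        assert len(res.selected) <= s

    def test_rss_matches_exhaustive_best_subset(self):
        """FoBa final RSS within 1e-9 of best subset in >=95% of trials."""
        hits = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n, m, s = 24, 10, 3
            A = rng.normal(size=(n, m))
            x_true = np.zeros(m)
            x_true[rng.choice(m, 2, replace=False)] = rng.normal(size=2)
            b = A @ x_true + rng.normal(0, 0.1, n)
            res = tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=s))
            if res.residual_norm ** 2 <= best_subset_rss(A, b, s) + 1e-9:
                hits += 1
        assert hits >= 0.95 * trials

    def test_planted_support_recovery(self):
        """Support of size 3 recovered exactly in >=95% of noisy trials."""
        hits = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(1000 + seed)
            n, m = 120, 30
            A = rng.normal(size=(n, m))
            support = sorted(rng.choice(m, 3, replace=False))
            x_true = np.zeros(m)
            x_true[support] = rng.choice([-1, 1], 3) * rng.uniform(0.8, 1.5, 3)
            b = A @ x_true + rng.normal(0, 0.05, n)
            cfg = tm.SparsityConfig(s=10, min_gain=1.0)   # stop above noise floor
            res = tm.foba_select(make_lib(A), b, cfg)
            if res.support == support:
                hits += 1
        assert hits >= 0.95 * trials

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 6))
        b = A @ np.array([1.0, 0, 0, -2.0, 0, 0]) + rng.normal(0, 0.02, 20)
        r1 = tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=3))
        r2 = tm.foba_select(make_lib(A), 3.0 * b, tm.SparsityConfig(s=3))
        assert r2.support == r1.support
        assert r2.coefficients == pytest.approx(3.0 * r1.coefficients)

    def test_rss_monotone_under_growing_sparsity(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(25, 12))
        b = rng.normal(size=25)
        lib = make_lib(A)
        rss = [tm.foba_select(lib, b, tm.SparsityConfig(s=s)).residual_norm
               for s in (1, 2, 4, 8)]
        assert all(a >= b_ - 1e-12 for a, b_ in zip(rss, rss[1:]))

    def test_standardize_flag_returns_original_scale_coefficients(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(30, 5)) * np.array([1, 10, 0.1, 5, 2.0])
        b = A[:, 1] * 0.7
        res = tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=2),
                             standardize=True)
        assert 1 in res.support
        j = res.support.index(1)
        assert res.coefficients[j] == pytest.approx(0.7)


class TestMatchingScores:
    def _result_with_coef(self, coef):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(15, 3))
        b = coef * A[:, 0]
        return tm.foba_select(make_lib(A), b, tm.SparsityConfig(s=1))

    def test_same_direction_profile_scores_negative(self):
        res = tm.matching_scores(self._result_with_coef(1.0), "paper")
        assert res.selected["matching_score"].iloc[0] == pytest.approx(-1.0)

    def test_counter_direction_scores_positive(self):
        res = tm.matching_scores(self._result_with_coef(-0.8), "paper")
        assert res.selected["matching_score"].iloc[0] == pytest.approx(0.8)

    def test_raw_convention_is_identity(self):
        res = tm.matching_scores(self._result_with_coef(-0.8), "raw")
        assert (res.selected["matching_score"]
                == res.selected["coefficient"]).all()

    def test_report_ordered_by_descending_magnitude(self, tiny_library):
        q, _ = tm.gen_query(tiny_library, ["CN00020", "CN00031"], [2.0, -0.5],
                            noise_sd=0.02, seed=9)
        res = tm.match_profile(tiny_library, q)
        mags = res.selected["matching_score"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)


def test_write_match_table_format(tmp_path, tiny_library):
    q, _ = tm.gen_query(tiny_library, ["CN00020"], [1.0], seed=3)
    res = tm.match_profile(tiny_library, q)
    out = tmp_path / "match.tsv"
    tm.write_match_table(res, out)
    text = out.read_text().splitlines()
    assert text[0].startswith("# residual_norm")
    header = text[3].split("\t")
    assert header[:2] == ["rank", "network_id"]
    assert "matching_score" in header
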