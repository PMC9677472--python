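"""Sparse matching of a differential-expression profile against the library.

Given the library matrix A and a query vector b of log2 fold changes, the
matcher solves the cardinality-constrained least-squares problem

    min ||A x - b||^2   subject to   card(x) <= s,

with an adaptive forward-backward greedy (FoBa) search: forward steps add
the column whose inclusion (with a full refit over the enlarged support)
most reduces the residual sum of squares; after every forward step, any
selected column whose removal would raise the RSS by less than
backward_factor times the latest forward gain is pruned. The search stops
when the support reaches s or the best forward gain falls below min_gain.
Final coefficients are the least-squares refit restricted to the support.

The reported matching score follows the library's sign convention: a query
that replicates a TRSN's own regulatory direction gets a NEGATIVE score
(score = -x_j), so negative scores flag same-direction matches (putative
causes) and positive scores counter-directional ones (putative
counteracting treatments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import LibraryMatrix


@dataclass(frozen=True)
class SparsityConfig:
    """FoBa controls: max support size s, forward floor, backward threshold."""

    s: int = 10
    min_gain: float = 1e-8
    backward_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.min_gain < 0:
            raise ValueError("min_gain must be non-negative")
        if not 0 < self.backward_factor < 1:
            raise ValueError("backward_factor must lie in (0, 1)")


@dataclass
class QueryProfile:
    """A user differential-expression profile: gene symbol -> log2FC."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.entries.values()))):
            raise ValueError("query log2FC values must be finite")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MatchResult:
    """Selected TRSNs with coefficients/scores plus fit diagnostics."""

    selected: pd.DataFrame          # network_id, coefficient, matching_score, ...
    residual_norm: float
    n_matched_genes: int
    n_dropped_genes: int
    support: list[int] = field(default_factory=list)   # column indices into A
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))


def parse_query(path: str | Path) -> QueryProfile:
    """Parse a two-column (Symbol, LogFC) TSV or CSV.

    A header row is detected when the first row's second field is not a
    number. More than two columns, duplicate symbols, or non-numeric LogFC
    values are errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    entries: dict[str, float] = {}
    dups: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != 2:
                raise ValueError(
                    f"{path.name}:{lineno}: query must contain exactly two "
                    f"columns (Symbol, LogFC); got {len(fields)}"
                )
            sym, val = fields[0].strip(), fields[1].strip()
            try:
                fc = float(val)
            except ValueError:
                if lineno == 1 and not entries:
                    continue  # header row
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric LogFC {val!r}"
                ) from None
            if sym in entries:
                dups.append(sym)
            entries[sym] = fc
    if dups:
        raise ValueError(f"duplicate symbols in query: {sorted(set(dups))}")
    return QueryProfile(entries=entries)


def align_query(query: QueryProfile, lib: LibraryMatrix) -> tuple[np.ndarray, int, int]:
    """Order the query as the library's gene rows.

    Returns (b, n_matched, n_dropped): b_i is the query's log2FC for gene i
    or 0 when the gene is absent from the query; query genes missing from
    the library are dropped (counted, not an error — unless nothing
    overlaps at all).
    """
    gene_pos = {g: i for i, g in enumerate(lib.genes)}
    b = np.zeros(len(lib.genes))
    n_matched = 0
    for sym, fc in query.entries.items():
        i = gene_pos.get(sym)
        if i is None:
            continue
        b[i] = fc
        n_matched += 1
    if n_matched == 0:
        raise ValueError("no gene overlap between query and library")
    return b, n_matched, len(query.entries) - n_matched


def _refit_rss(A: np.ndarray, b: np.ndarray, support: list[int]) -> tuple[np.ndarray, float]:
    """Least squares restricted to `support`; returns (coefficients, RSS)."""
    if not support:
        return np.zeros(0), float(b @ b)
    x, *_ = np.linalg.lstsq(A[:, support], b, rcond=None)
    r = b - A[:, support] @ x
    return x, float(r @ r)


def foba_select(
    lib: LibraryMatrix,
    b: np.ndarray,
    cfg: SparsityConfig = SparsityConfig(),
    *,
    standardize: bool = False,
    n_matched_genes: int = 0,
    n_dropped_genes: int = 0,
) -> MatchResult:
    """Adaptive forward-backward greedy solve of min ||Ax-b||^2, card(x)<=s.

    Columns are used at their raw log2FC scale by default so coefficients
    (and scores) are on the scale the library stores; `standardize`
    unit-normalizes columns before fitting and maps coefficients back.
    Forward ties break toward the lowest column index.
    """
    if not np.isfinite(b).all():
        raise ValueError("query vector contains non-finite values")
    A = lib.A.toarray().astype(float, copy=False)
    if not np.isfinite(A).all():
        raise ValueError("library matrix contains non-finite values")
    col_norms = np.linalg.norm(A, axis=0)
    if np.all(col_norms == 0):
        raise ValueError("library has no nonzero column")
    scale = np.ones(A.shape[1])
    if standardize:
        scale = np.where(col_norms > 0, col_norms, 1.0)
        A = A / scale

    support: list[int] = []
    rss = float(b @ b)
    # Orthonormal basis Q of A[:, support], grown one column per forward step;
    # the exact refit gain of adding column j is (r.q_j)^2 with q_j the
    # unit-normalized component of a_j orthogonal to span(Q).
    while len(support) < cfg.s:
        x_cur, rss = _refit_rss(A, b, support)
        r = b - (A[:, support] @ x_cur if support else 0.0)
        if support:
            Q, _ = np.linalg.qr(A[:, support])
            A_perp = A - Q @ (Q.T @ A)
        else:
            A_perp = A
        norms = np.linalg.norm(A_perp, axis=0)
        usable = norms > 1e-10 * np.maximum(col_norms, 1.0)
        usable[support] = False
        if not usable.any():
            break
        gains = np.zeros(A.shape[1])
        gains[usable] = (A_perp[:, usable].T @ r) ** 2 / norms[usable] ** 2
        j = int(np.argmax(gains))          # argmax takes the lowest index on ties
        forward_gain = float(gains[j])
        if forward_gain < cfg.min_gain:
            break
        support.append(j)
        _, rss = _refit_rss(A, b, support)

        # backward pruning: drop columns whose removal barely raises the RSS
        while len(support) > 1:
            increases = []
            for k in support:
                sub = [c for c in support if c != k]
                _, rss_without = _refit_rss(A, b, sub)
                increases.append(rss_without - rss)
            k_min = int(np.argmin(increases))
            if increases[k_min] < cfg.backward_factor * forward_gain:
                support.pop(k_min)
                _, rss = _refit_rss(A, b, support)
            else:
                break

    support = sorted(support)
    x, rss = _refit_rss(A, b, support)
    x = x / scale[support] if len(support) else x
    residual_norm = float(np.sqrt(rss))
    meta = lib.columns.iloc[support].reset_index(drop=True)
    selected = meta.assign(coefficient=x)
    order = np.argsort(-np.abs(x), kind="stable")
    selected = selected.iloc[order].reset_index(drop=True)
    return MatchResult(
        selected=selected,
        residual_norm=residual_norm,
        n_matched_genes=n_matched_genes,
        n_dropped_genes=n_dropped_genes,
        support=support,
        coefficients=x,
    )


def matching_scores(result: MatchResult, convention: str = "paper") -> MatchResult:
    """Attach signed matching scores, ordered by descending magnitude.

    'paper' convention: score = -coefficient, so a profile moving WITH a
    TRSN's regulatory direction scores negative and a counter-directional
    profile positive. 'raw' reports the coefficient unchanged.
    """
    if convention not in ("paper", "raw"):
        raise ValueError(f"unknown sign convention {convention!r}")
    sel = result.selected.copy()
    sign = -1.0 if convention == "paper" else 1.0
    sel["matching_score"] = sign * sel["coefficient"]
    sel = sel.iloc[np.argsort(-sel["matching_score"].abs(), kind="stable")]
    result.selected = sel.reset_index(drop=True)
    return result


def match_profile(
    lib: LibraryMatrix,
    query: QueryProfile,
    cfg: SparsityConfig = SparsityConfig(),
    *,
    convention: str = "paper",
    standardize: bool = False,
) -> MatchResult:
    """End-to-end: align the query, run FoBa, attach matching scores."""
    b, n_matched, n_dropped = align_query(query, lib)
    result = foba_select(lib, b, cfg, standardize=standardize,
                         n_matched_genes=n_matched, n_dropped_genes=n_dropped)
    return matching_scores(result, convention)


def write_match_table(result: MatchResult, path: str | Path) -> None:
    """Write the ranked match table as TSV with a '#' diagnostic header."""
    with Path(path).open("w") as fh:
        fh.write(f"# residual_norm\t{result.residual_norm:.6g}\n")
        fh.write(f"# n_matched_genes\t{result.n_matched_genes}\n")
        fh.write(f"# n_dropped_genes\t{result.n_dropped_genes}\n")
        out = result.selected.copy()
        out.insert(0, "rank", range(1, len(out) + 1))
        out.to_csv(fh, sep="\t", index=False)
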