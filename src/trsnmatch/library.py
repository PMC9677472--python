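"""TRSN library: up/down pair merging, sparse matrix assembly, persistence.

The library matrix A is genes x TRSN-columns; A[i, j] is gene i's log2 fold
change under column j's condition when gene i belongs to that TRSN, else 0.
Before assembly, the up- and down-regulated TRSNs of the same
(condition, cell line, TF) triple are merged into a single column whose
member set is their union, so each condition-specific TF contributes one
column even when it regulates genes in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .targets import TRSN

FORMAT_VERSION = 1


def assign_network_ids(trsns: Sequence[TRSN], prefix: str = "CN") -> list[TRSN]:
    """Give every TRSN lacking an id a running '<prefix><n>' id, in order."""
    out: list[TRSN] = []
    counter = 1
    taken = {t.network_id for t in trsns if t.network_id}
    for t in trsns:
        if t.network_id:
            out.append(t)
            continue
        while f"{prefix}{counter:04d}" in taken:
            counter += 1
        out.append(replace(t, network_id=f"{prefix}{counter:04d}"))
        counter += 1
    return out


def pair_and_merge(trsns: Sequence[TRSN]) -> list[TRSN]:
    """Merge each exact up/down pair on (condition, cell line, TF) into one column.

    A triple with exactly one 'up' and one 'down' TRSN becomes a single
    'merged' TRSN whose member map is the union (the ids joined by '+');
    every other TRSN passes through unchanged. A gene found in both halves
    of a pair is contradictory membership and raises.
    """
    ids = [t.network_id for t in trsns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate network_ids")
    by_key: dict[tuple, list[TRSN]] = {}
    for t in trsns:
        by_key.setdefault(t.key, []).append(t)
    out: list[TRSN] = []
    for t in trsns:
        group = by_key[t.key]
        dirs = sorted(g.direction for g in group)
        if dirs == ["down", "up"]:
            up = next(g for g in group if g.direction == "up")
            down = next(g for g in group if g.direction == "down")
            if t is down:
                continue  # emitted with its partner
            overlap = set(up.members) & set(down.members)
            if overlap:
                raise ValueError(
                    f"contradictory membership in pair {up.network_id}/"
                    f"{down.network_id}: {sorted(overlap)[:5]}"
                )
            out.append(TRSN(
                tf=t.tf, condition_id=t.condition_id, cell_line=t.cell_line,
                direction="merged", members={**up.members, **down.members},
                network_id=f"{up.network_id}+{down.network_id}",
            ))
        else:
            out.append(t)
    return out


@dataclass
class LibraryMatrix:
    """Sparse gene x TRSN matrix with row/column metadata."""

    genes: pd.Index                    # row labels, unique
    columns: pd.DataFrame              # network_id, condition, cell_line, tf, direction
    A: sp.csc_matrix                   # genes x columns

    def __post_init__(self) -> None:
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene row labels")
        if self.columns["network_id"].duplicated().any():
            raise ValueError("duplicate column ids")
        assert self.A.shape == (len(self.genes), len(self.columns))

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def column_ids(self) -> list[str]:
        return self.columns["network_id"].tolist()

    def browse(self, by: str, key: str) -> pd.DataFrame:
        """Columns whose metadata facet (or membership, for 'gene') matches key."""
        facets = {"condition": "condition", "cell_line": "cell_line", "tf": "tf"}
        if by in facets:
            return self.columns[self.columns[facets[by]] == key].copy()
        if by == "gene":
            if key not in self.genes:
                return self.columns.iloc[0:0].copy()
            hit_cols = self.A[self.genes.get_loc(key), :].nonzero()[1]
            return self.columns.iloc[np.sort(hit_cols)].copy()
        raise ValueError(f"unknown facet {by!r}; use condition/cell_line/tf/gene")


def assemble_matrix(columns: Iterable[TRSN], *, uppercase_genes: bool = False) -> LibraryMatrix:
    """Build the library matrix from TRSN columns.

    Rows are the union of member genes in lexicographic order; columns are
    ordered by network_id; both orderings are deterministic so the same
    inputs always give the same matrix.
    """
    cols = sorted(columns, key=lambda t: t.network_id)
    if not cols:
        raise ValueError("empty column collection")

    def norm(g: str) -> str:
        return g.upper() if uppercase_genes else g

    genes = pd.Index(sorted({norm(g) for t in cols for g in t.members}))
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows_idx, cols_idx, vals = [], [], []
    for j, t in enumerate(cols):
        for g, fc in t.members.items():
            rows_idx.append(gene_pos[norm(g)])
            cols_idx.append(j)
            vals.append(fc)
    A = sp.csc_matrix(
        (vals, (rows_idx, cols_idx)), shape=(len(genes), len(cols)), dtype=float
    )
    meta = pd.DataFrame({
        "network_id": [t.network_id for t in cols],
        "condition": [t.condition_id for t in cols],
        "cell_line": [t.cell_line for t in cols],
        "tf": [t.tf for t in cols],
        "direction": [t.direction for t in cols],
    })
    return LibraryMatrix(genes=genes, columns=meta, A=A)


def save_library(lib: LibraryMatrix, path: str | Path) -> None:
    """Write a library directory: matrix.mtx + rows.tsv + columns.tsv + meta.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(lib.A))
    pd.Series(lib.genes, name="gene").to_csv(path / "rows.tsv", sep="\t", index=False)
    lib.columns.to_csv(path / "columns.tsv", sep="\t", index=False)
    with (path / "meta.yaml").open("w") as fh:
        yaml.safe_dump({
            "format_version": FORMAT_VERSION,
            "n_genes": int(lib.shape[0]),
            "n_columns": int(lib.shape[1]),
            "nnz": int(lib.A.nnz),
        }, fh)


def load_library(path: str | Path) -> LibraryMatrix:
    """Load a library directory written by :func:`save_library`.

    Checks the format version and that matrix dimensions agree with the
    row/column tables; mismatches raise with a message.
    """
    path = Path(path)
    try:
        with (path / "meta.yaml").open() as fh:
            meta = yaml.safe_load(fh)
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported library format version {meta.get('format_version')!r}"
            )
        A = sp.csc_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
        genes = pd.Index(pd.read_csv(path / "rows.tsv", sep="\t")["gene"])
        columns = pd.read_csv(path / "columns.tsv", sep="\t")
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot load library at {path}: {exc}") from exc
    if A.shape != (len(genes), len(columns)) or A.shape[0] != meta["n_genes"]:
        raise ValueError(
            f"corrupted library at {path}: matrix shape {A.shape} does not match "
            f"metadata ({len(genes)} genes, {len(columns)} columns)"
        )
    return LibraryMatrix(genes=genes, columns=columns, A=A)
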