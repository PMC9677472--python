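"""Synthetic inputs with planted regulatory structure.

Every pipeline stage can be exercised without real downloads: the
generators here emit gene annotations, TF-binding peak sets, two-group
expression matrices, TRSN libraries and query profiles whose ground truth
(planted targets, planted sparse support) is known, so recovery can be
asserted. Expression noise is Gaussian on the log2 scale, the assumption
the moderated-t machinery makes; background peaks are kept at least twice
the regulatory-potential window away from every TSS so planted structure
is unambiguous. All generators are pure functions of their arguments and
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffexpr import CONTROL, TREATED, ExpressionMatrix
from .intervals import GenomicInterval, PeakSet
from .library import LibraryMatrix
from .matcher import QueryProfile
from .targets import DEFAULT_WINDOW, TRSN


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs for the planted-structure generators.

    Defaults are sized for a small but realistic two-group microarray-style
    screen: 3 replicates per arm, planted |log2FC| of 1.5 against a noise
    SD of 0.2 log2 units, peaks jittered 5 kb around their target TSS
    within a 100 kb regulatory window.
    """

    n_genes: int = 300
    n_chroms: int = 2
    chrom_len: int = 50_000_000
    n_conditions: int = 2
    n_tfs: int = 2
    replicates: int = 3
    effect_size: float = 1.5
    noise_sd: float = 0.2
    peak_jitter: float = 5_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_chroms", "chrom_len", "n_conditions",
                     "n_tfs", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.peak_jitter < 0:
            raise ValueError("noise_sd and peak_jitter must be >= 0")


def gen_annotation(spec: SimulationSpec) -> pd.DataFrame:
    """Place n_genes TSSs on n_chroms chromosomes, >=1 kb apart, random strands.

    Genes are named G0001..G{n}. Raises when a chromosome cannot host its
    share of genes at 1 kb spacing.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chroms)
    min_gap = 1_000
    rows = []
    for ci, idx in enumerate(per_chrom, start=1):
        k = len(idx)
        if k == 0:
            continue
        if k * min_gap >= spec.chrom_len:
            raise ValueError(
                f"chromosome of {spec.chrom_len} bp cannot host {k} TSSs "
                f">= {min_gap} bp apart"
            )
        # draw sorted positions then push apart to enforce the gap
        slack = spec.chrom_len - k * min_gap
        offsets = np.sort(rng.integers(0, slack, size=k))
        tss = offsets + min_gap * np.arange(k)
        strands = rng.choice(["+", "-"], size=k)
        for g, t, s in zip(idx, tss, strands):
            rows.append((f"G{g + 1:04d}", f"chr{ci}", int(t), s))
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])
    return ann.set_index("gene").sort_index()


def gen_condition(
    spec: SimulationSpec,
    tf: str,
    planted_targets: list[str],
    direction_map: dict[str, str],
    annotation: pd.DataFrame,
    *,
    condition_id: str = "cond1",
    cell_line: str = "CL1",
    n_background_peaks: int = 20,
    window: int = DEFAULT_WINDOW,
    seed: int | None = None,
) -> tuple[PeakSet, ExpressionMatrix]:
    """One condition with a recoverable planted TRSN.

    A peak is planted near each target's TSS (Gaussian jitter, clipped to
    the window); background peaks sit >= 2x window from every TSS.
    Expression is baseline + planted +/-effect_size shifts (targets per
    `direction_map`, the TF itself up-shifted) + N(0, noise_sd) noise in
    all samples.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    missing = set(planted_targets) - set(annotation.index)
    if missing:
        raise ValueError(f"planted targets not in annotation: {sorted(missing)}")

    half_width = 150
    intervals = []
    for g in planted_targets:
        row = annotation.loc[g]
        offset = rng.normal(0.0, spec.peak_jitter)
        offset = float(np.clip(offset, -window + half_width + 1, window - half_width - 1))
        center = int(max(half_width, min(row["tss"] + offset,
                                         spec.chrom_len - half_width - 1)))
        intervals.append(GenomicInterval(row["chrom"], center - half_width,
                                         center + half_width))
    # background peaks in TSS deserts (>= 2x window from every TSS)
    by_chrom = {c: np.sort(g["tss"].to_numpy())
                for c, g in annotation.groupby("chrom")}
    placed = 0
    attempts = 0
    chroms = sorted(by_chrom)
    while placed < n_background_peaks and attempts < 50 * n_background_peaks:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(half_width, spec.chrom_len - half_width))
        tss = by_chrom[chrom]
        if np.abs(tss - pos).min() >= 2 * window:
            intervals.append(GenomicInterval(chrom, pos - half_width, pos + half_width))
            placed += 1
    peaks = PeakSet(cell_line=cell_line, tf=tf, condition_id=condition_id,
                    intervals=intervals)

    genes = annotation.index
    n = spec.replicates
    baseline = rng.normal(7.0, 1.0, size=len(genes))
    shift = pd.Series(0.0, index=genes)
    for g in planted_targets:
        sgn = 1.0 if direction_map.get(g, "up") == "up" else -1.0
        shift[g] = sgn * spec.effect_size
    if tf in shift.index:
        shift[tf] = spec.effect_size
    cols = {}
    for i in range(n):
        cols[f"ctl{i + 1}"] = baseline + rng.normal(0, spec.noise_sd, len(genes))
    for i in range(n):
        cols[f"trt{i + 1}"] = (baseline + shift.to_numpy()
                               + rng.normal(0, spec.noise_sd, len(genes)))
    values = pd.DataFrame(cols, index=genes)
    group = pd.Series([CONTROL] * n + [TREATED] * n, index=values.columns)
    return peaks, ExpressionMatrix(values=values, group=group)


def gen_library(
    n_genes: int,
    n_trsns: int,
    n_pairs: int,
    members_per_trsn: int,
    seed: int = 0,
) -> list[TRSN]:
    """n_trsns single-direction TRSNs, 2*n_pairs of which form up/down pairs.

    Paired TRSNs share a (condition, cell line, TF) key and have disjoint
    member sets; member log2FCs are drawn sign-consistent with direction
    (|log2FC| ~ 0.5 + Exp(1), the DEG-filter floor plus an exponential tail).
    """
    if 2 * n_pairs > n_trsns:
        raise ValueError(f"2*n_pairs={2 * n_pairs} exceeds n_trsns={n_trsns}")
    if members_per_trsn > n_genes:
        raise ValueError("members_per_trsn exceeds n_genes")
    if n_pairs > 0 and 2 * members_per_trsn > n_genes:
        raise ValueError(
            "paired TRSNs need disjoint member sets: 2*members_per_trsn "
            f"= {2 * members_per_trsn} exceeds n_genes = {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    out: list[TRSN] = []

    def draw_members(direction: str, exclude: set[str] = frozenset()) -> dict[str, float]:
        pool = genes[~np.isin(genes, list(exclude))] if exclude else genes
        chosen = rng.choice(pool, size=members_per_trsn, replace=False)
        mags = 0.5 + rng.exponential(1.0, size=members_per_trsn)
        sgn = 1.0 if direction == "up" else -1.0
        return {g: sgn * m for g, m in zip(chosen, mags)}

    nid = 0
    for p in range(n_pairs):
        key = dict(condition_id=f"cond{p + 1:04d}", cell_line="CL1",
                   tf=f"TF{p + 1:03d}")
        up_members = draw_members("up")
        nid += 1
        out.append(TRSN(direction="up", members=up_members,
                        network_id=f"CN{nid:05d}", **key))
        nid += 1
        out.append(TRSN(direction="down",
                        members=draw_members("down", set(up_members)),
                        network_id=f"CN{nid:05d}", **key))
    for q in range(n_trsns - 2 * n_pairs):
        nid += 1
        direction = "up" if q % 2 == 0 else "down"
        out.append(TRSN(
            tf=f"TF{n_pairs + q + 1:03d}",
            condition_id=f"cond{n_pairs + q + 1:04d}",
            cell_line="CL1", direction=direction,
            members=draw_members(direction), network_id=f"CN{nid:05d}",
        ))
    return out


def gen_query(
    lib: LibraryMatrix,
    support: list[str],
    coefficients: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[QueryProfile, dict[str, float]]:
    """Query b = A x* + noise for a planted support of library columns.

    Returns the profile (over all library genes) plus the ground-truth
    column_id -> coefficient map for assertions.
    """
    rng = np.random.default_rng(seed)
    ids = lib.column_ids()
    x = np.zeros(lib.shape[1])
    truth: dict[str, float] = {}
    for cid, coef in zip(support, coefficients, strict=True):
        if cid not in ids:
            raise ValueError(f"unknown library column {cid}")
        x[ids.index(cid)] = coef
        truth[cid] = coef
    b = lib.A @ x + rng.normal(0.0, noise_sd, size=lib.shape[0])
    entries = dict(zip(lib.genes, map(float, b)))
    return QueryProfile(entries=entries), truth


def write_condition_dir(
    out_dir: str | Path,
    spec: SimulationSpec,
    tf: str,
    peaks: PeakSet,
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    planted_targets: list[str],
    direction_map: dict[str, str],
) -> None:
    """Write BED + expression TSV + sample sheet + annotation + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .intervals import write_bed
    write_bed(peaks, out / f"{tf}_peaks.bed")
    expr.values.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame({"sample": expr.values.columns,
                  "group": expr.group.values}).to_csv(
        out / "samples.tsv", sep="\t", index=False)
    annotation.reset_index().to_csv(out / "annotation.tsv", sep="\t", index=False)
    with (out / "ground_truth.yaml").open("w") as fh:
        yaml.safe_dump({
            "tf": tf,
            "planted_targets": list(planted_targets),
            "directions": dict(direction_map),
            "effect_size": spec.effect_size,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        }, fh)
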