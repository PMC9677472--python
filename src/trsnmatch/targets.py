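"""Peak-to-gene target linking: regulatory potential + rank integration.

Binding and expression are integrated in the style of binding-and-expression
target analysis: each gene receives a regulatory potential (RP) summing an
exponential decay over peak centers within a window of its TSS,

    rp(g) = sum over peaks with |center - tss| <= window of
            exp(-(0.5 + decay * |center - tss| / window)),

with defaults window=100000 bp and decay=4, so a peak sitting on the TSS
contributes e^-0.5 ~ 0.607 and a peak at the window edge e^-4.5 ~ 0.011.
Candidate targets (genes with rp > 0 that pass the DEG filter in the
requested direction) are then ranked by RP and by differential-expression
significance, combined by rank product, and capped at 200 genes per
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DEGCriteria, select_degs
from .intervals import PeakSet

DEFAULT_WINDOW = 100_000
DEFAULT_DECAY = 4.0
DEFAULT_CAP = 200


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Load a gene annotation as a DataFrame indexed by gene symbol.

    Accepts a 4-column TSV (gene, chrom, tss, strand) with or without a
    header, or BED6 (chrom, start, end, name, score, strand; TSS = start for
    + genes, end-1 for - genes). Duplicate symbols keep the most 5' TSS.
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    if first.shape[1] >= 6:
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "gene", "score", "strand"],
                          usecols=range(6))
        tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
        ann = pd.DataFrame({"gene": bed["gene"], "chrom": bed["chrom"],
                            "tss": tss, "strand": bed["strand"]})
    else:
        header = 0 if str(first.iloc[0, 2]).lstrip("-").isdigit() is False else None
        ann = pd.read_csv(path, sep="\t", header=header,
                          names=["gene", "chrom", "tss", "strand"])
    return dedupe_annotation(ann)


def dedupe_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """One TSS per symbol: for duplicates keep the most 5'-upstream TSS."""
    ann = ann.copy()
    upstream = np.where(ann["strand"] == "+", ann["tss"], -ann["tss"])
    ann["_key"] = upstream
    ann = ann.sort_values(["gene", "_key"]).drop_duplicates("gene", keep="first")
    return ann.drop(columns="_key").set_index("gene").sort_index()


def regulatory_potential(
    peaks: PeakSet,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    decay: float = DEFAULT_DECAY,
) -> pd.Series:
    """Decay-weighted sum of peak centers near each TSS.

    `annotation` is indexed by gene with columns chrom, tss. Peak position
    is the interval midpoint. Empty peaks give rp = 0 for every gene;
    an empty annotation is an error.
    """
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    if window <= 0:
        raise ValueError("window must be positive")
    rp = pd.Series(0.0, index=annotation.index, name="rp")
    if len(peaks) == 0:
        return rp
    centers: dict[str, np.ndarray] = {}
    for chrom, group in pd.DataFrame(
        [(iv.chrom, iv.midpoint) for iv in peaks], columns=["chrom", "center"]
    ).groupby("chrom"):
        centers[chrom] = np.sort(group["center"].to_numpy())
    for gene, row in annotation.iterrows():
        cs = centers.get(row["chrom"])
        if cs is None:
            continue
        lo = np.searchsorted(cs, row["tss"] - window, side="left")
        hi = np.searchsorted(cs, row["tss"] + window, side="right")
        if hi > lo:
            delta = np.abs(cs[lo:hi] - row["tss"]) / window
            rp[gene] = np.exp(-(0.5 + decay * delta)).sum()
    return rp


def rank_integrate(
    rp: pd.Series,
    de: pd.DataFrame,
    direction: str,
    criteria: DEGCriteria = DEGCriteria(),
) -> pd.DataFrame:
    """Rank-product integration of binding and differential expression.

    Candidates are genes with rp > 0 that pass the DEG filter in
    `direction` ('up' or 'down'). rp_rank is by descending rp; de_rank by
    ascending adjusted p then descending |log2fc|; combined score is the
    product of rank fractions (rp_rank/N)*(de_rank/N), smaller = better.
    Ties anywhere break lexicographically by gene symbol.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    degs = select_degs(de, criteria)
    degs = degs[degs["direction"] == direction]
    cand = degs.index.intersection(rp.index[rp > 0])
    if len(cand) == 0:
        return pd.DataFrame(
            columns=["rp", "log2fc", "p_adj", "rp_rank", "de_rank", "combined"]
        )
    tbl = pd.DataFrame({
        "rp": rp.loc[cand],
        "log2fc": degs.loc[cand, "log2fc"],
        "p_adj": degs.loc[cand, "p_adj"],
    })
    n = len(tbl)
    rp_order = _tiebreak(tbl, ["rp"], [False])
    tbl["rp_rank"] = pd.Series(range(1, n + 1), index=rp_order)
    de_order = _tiebreak(tbl, ["p_adj", "abs_fc"], [True, False],
                         extra={"abs_fc": tbl["log2fc"].abs()})
    tbl["de_rank"] = pd.Series(range(1, n + 1), index=de_order)
    tbl["combined"] = (tbl["rp_rank"] / n) * (tbl["de_rank"] / n)
    return tbl.loc[_tiebreak(tbl, ["combined"], [True])]


def _tiebreak(tbl: pd.DataFrame, cols: list[str], ascending: list[bool],
              extra: dict[str, pd.Series] | None = None) -> pd.Index:
    """Sort by cols (with optional computed columns) breaking ties by symbol."""
    work = tbl.copy()
    if extra:
        for name, series in extra.items():
            work[name] = series
    work["_sym"] = work.index
    ordered = work.sort_values(cols + ["_sym"], ascending=ascending + [True],
                               kind="stable")
    return ordered.index


@dataclass
class TRSN:
    """One TF's direction-specific regulated gene set under one condition."""

    tf: str
    condition_id: str
    cell_line: str
    direction: str                     # 'up', 'down', or 'merged'
    members: dict[str, float] = field(default_factory=dict)  # gene -> log2fc
    network_id: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "merged"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.direction == "up" and any(v <= 0 for v in self.members.values()):
            raise ValueError("up-regulated TRSN contains non-positive log2fc")
        if self.direction == "down" and any(v >= 0 for v in self.members.values()):
            raise ValueError("down-regulated TRSN contains non-negative log2fc")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.condition_id, self.cell_line, self.tf)

    def __len__(self) -> int:
        return len(self.members)


def build_trsn(
    tf: str,
    condition_id: str,
    cell_line: str,
    direction: str,
    candidates: pd.DataFrame,
    de: pd.DataFrame,
    cap: int = DEFAULT_CAP,
    criteria: DEGCriteria = DEGCriteria(),
) -> TRSN:
    """Assemble a TRSN from ranked candidates, capped at `cap` genes.

    The TF itself must be differentially expressed under this condition
    (any direction); otherwise no TRSN is built for it.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    degs = select_degs(de, criteria)
    if tf not in degs.index:
        raise ValueError(f"TF not differentially expressed: {tf}")
    top = candidates.head(cap)
    members = dict(zip(top.index, top["log2fc"].astype(float)))
    return TRSN(tf=tf, condition_id=condition_id, cell_line=cell_line,
                direction=direction, members=members)


def build_condition_trsns(
    tf: str,
    condition_id: str,
    cell_line: str,
    peaks: PeakSet,
    annotation: pd.DataFrame,
    de: pd.DataFrame,
    *,
    window: int = DEFAULT_WINDOW,
    decay: float = DEFAULT_DECAY,
    cap: int = DEFAULT_CAP,
    criteria: DEGCriteria = DEGCriteria(),
    prefilter_top_degs: bool = False,
) -> list[TRSN]:
    """Build the up- and down-regulated TRSNs for one TF x condition.

    Returns zero, one or two TRSNs (a direction with no candidates yields
    none). With `prefilter_top_degs` the `cap` most significant DEGs per
    direction are taken before rank integration instead of capping the
    integrated ranking afterwards.
    """
    rp = regulatory_potential(peaks, annotation, window=window, decay=decay)
    out: list[TRSN] = []
    for direction in ("up", "down"):
        de_in = de
        if prefilter_top_degs:
            degs = select_degs(de, criteria)
            degs = degs[degs["direction"] == direction]
            keep = degs.sort_values(["p_adj", "log2fc"],
                                    key=lambda s: s.abs() if s.name == "log2fc" else s,
                                    ascending=[True, False]).head(cap).index
            de_in = de.loc[de.index.isin(keep) | (de.index == tf)]
        cand = rank_integrate(rp, de_in, direction, criteria)
        if len(cand) == 0:
            continue
        out.append(build_trsn(tf, condition_id, cell_line, direction,
                              cand, de, cap=cap, criteria=criteria))
    return out
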