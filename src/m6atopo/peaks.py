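"""Reading, filtering, intersecting, merging and annotating m6A peak intervals.

Peaks come from MeRIP-seq peak calling (ENCODE narrowPeak) or as pre-filtered
BED6.  Confident peaks are those with more than two-fold IP/input enrichment
and FDR < 0.05 that reproduce across two replicates with at least 50 % overlap
(fraction of the query peak, the ``bedtools intersect -f`` convention); the
reproducible peaks of both replicates are then merged into one non-overlapping
set per condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneRegions

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "fold_enrichment", "fdr", "sample_id"]

#: peak-annotation priority, highest first (Intergenic is the fallback)
ANNOTATION_PRIORITY = ["fiveUTRs", "Promoters", "threeUTRs", "Exons", "Introns"]


@dataclass
class PeakSet:
    """A collection of peak intervals with per-peak enrichment metadata.

    ``df`` has columns chrom, start, end, fold_enrichment, fdr, sample_id and
    uses 0-based half-open coordinates.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "PeakSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        return PeakSet(df, list(self.provenance))


@dataclass
class AnnotatedPeak:
    chrom: str
    start: int
    end: int
    region: str
    gene_id: str | None


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                         zip(PEAK_COLUMNS, [str, int, int, float, float, str])})


def read_peaks(path: str, sample_id: str | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (10 columns) or BED (3-6 columns) peak file.

    narrowPeak: column 7 (signalValue) is the IP/input fold enrichment and
    column 9 (qValue) is -log10(FDR), so fdr = 10**(-q).  BED input is treated
    as already filtered: fold_enrichment = +inf, fdr = 0.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return PeakSet(_empty_df(), [sample_id])
    ncol = raw.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: expected at least 3 tab-separated columns, got {ncol}")
    for col in (1, 2):
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: non-numeric coordinate at line {bad + 1}")
    df = pd.DataFrame({
        "chrom": raw[0].astype(str),
        "start": raw[1].astype(int),
        "end": raw[2].astype(int),
    })
    if ncol >= 10:  # narrowPeak
        for col in (6, 8):
            if not pd.api.types.is_numeric_dtype(raw[col]):
                bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()].index[0]
                raise ValueError(f"{path}: non-numeric score at line {bad + 1}")
        df["fold_enrichment"] = raw[6].astype(float)
        df["fdr"] = np.power(10.0, -raw[8].astype(float))
    else:  # plain BED: pre-filtered peaks
        df["fold_enrichment"] = math.inf
        df["fdr"] = 0.0
    df["sample_id"] = sample_id
    bad = df["start"] >= df["end"]
    if bad.any():
        logger.warning("%s: rejected %d records with start >= end", path, int(bad.sum()))
        df = df[~bad]
    return PeakSet(df.reset_index(drop=True), [sample_id]).sorted()


def write_bed(ps: PeakSet, path: str) -> None:
    """Write peaks as BED6 (name '.', score 0, strand '.')."""
    df = ps.sorted().df
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": ".", "score": 0, "strand": ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_peaks(ps: PeakSet, min_fold: float = 2.0, max_fdr: float = 0.05) -> PeakSet:
    """Keep peaks with fold_enrichment > min_fold and fdr < max_fdr (both strict)."""
    keep = (ps.df["fold_enrichment"] > min_fold) & (ps.df["fdr"] < max_fdr)
    logger.info("filter_peaks: %d/%d kept (fold>%g, fdr<%g)", int(keep.sum()), len(ps),
                min_fold, max_fdr)
    return PeakSet(ps.df[keep].reset_index(drop=True), list(ps.provenance))


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping or book-ended intervals per chromosome."""
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge_peaks(ps: PeakSet) -> PeakSet:
    """Union of intervals: overlapping or book-ended peaks coalesced, sorted.

    Enrichment metadata does not survive merging; merged peaks carry the
    BED-style sentinel values (fold = +inf, fdr = 0).
    """
    merged = _merge_intervals(ps.df)
    merged["fold_enrichment"] = math.inf
    merged["fdr"] = 0.0
    merged["sample_id"] = "+".join(ps.provenance) if ps.provenance else "merged"
    return PeakSet(merged, list(ps.provenance))


def _coverage_overlap(starts: np.ndarray, ends: np.ndarray,
                      cov_starts: np.ndarray, cov_ends: np.ndarray) -> np.ndarray:
    """Bases of each query [start,end) covered by a merged (disjoint, sorted)
    interval set, vectorised over queries."""
    if len(cov_starts) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=int)
    cum = np.concatenate([[0], np.cumsum(cov_ends - cov_starts)])

    def covered_before(pos: np.ndarray) -> np.ndarray:
        # total covered bases in (-inf, pos)
        i = np.searchsorted(cov_starts, pos, side="right")
        full = cum[np.maximum(i - 1, 0)]
        partial = np.clip(pos - cov_starts[np.maximum(i - 1, 0)], 0,
                          (cov_ends - cov_starts)[np.maximum(i - 1, 0)])
        return np.where(i > 0, full + partial, 0)

    return covered_before(ends) - covered_before(starts)


def reproducible_peaks(a: PeakSet, b: PeakSet, min_frac: float = 0.5) -> PeakSet:
    """Peaks supported by both replicates, merged.

    A peak of one replicate is retained when the union of the other
    replicate's peaks covers at least ``min_frac`` of its own length
    (``bedtools intersect -f`` measured against the query peak).  The check is
    applied symmetrically and the union of retained peaks is merged.
    """
    kept = []
    for query, subject in ((a, b), (b, a)):
        qdf = query.sorted().df
        cov = _merge_intervals(subject.df)
        for chrom, grp in qdf.groupby("chrom", sort=False):
            c = cov[cov["chrom"] == chrom]
            ov = _coverage_overlap(grp["start"].to_numpy(), grp["end"].to_numpy(),
                                   c["start"].to_numpy(), c["end"].to_numpy())
            lengths = (grp["end"] - grp["start"]).to_numpy()
            kept.append(grp[ov >= min_frac * lengths])
    union = pd.concat(kept, ignore_index=True) if kept else _empty_df()
    n_in = len(a) + len(b)
    result = merge_peaks(PeakSet(union, sorted(set(a.provenance + b.provenance))))
    logger.info("reproducible_peaks: %d peaks in -> %d retained -> %d merged (min_frac=%g)",
                n_in, len(union), len(result), min_frac)
    return result


def combine_replicates(peaksets: list[PeakSet], min_frac: float = 0.5) -> PeakSet:
    """Reduce replicate peak sets to one confident set.

    Two replicates follow the reproducibility rule directly; more than two are
    reduced by sequential pairwise intersection in input order.
    """
    if not peaksets:
        raise ValueError("no peak sets given")
    if len(peaksets) == 1:
        return merge_peaks(peaksets[0])
    if len(peaksets) > 2:
        logger.warning("combine_replicates: %d replicates reduced by sequential "
                       "pairwise intersection", len(peaksets))
    out = peaksets[0]
    for nxt in peaksets[1:]:
        out = reproducible_peaks(out, nxt, min_frac=min_frac)
    return out


# ------------------------------------------------------------------ annotation

def _region_trees(regions: list[GeneRegions]) -> dict[str, dict[str, IntervalTree]]:
    """category -> chrom -> IntervalTree of (start, end, gene_id)."""
    cat_attr = {"fiveUTRs": "fiveUTR", "Promoters": "promoter", "threeUTRs": "threeUTR",
                "Exons": "exons", "Introns": "intron", "CDS": "CDS"}
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in cat_attr}
    for gr in regions:
        for cat, attr in cat_attr.items():
            for s, e in getattr(gr, attr):
                if s < e:
                    trees[cat].setdefault(gr.chrom, IntervalTree()).addi(s, e, gr.gene_id)
    return trees


def annotate_peaks(ps: PeakSet, regions: list[GeneRegions]) -> list[AnnotatedPeak]:
    """Assign each peak the highest-priority overlapping category.

    Priority: fiveUTRs > Promoters > threeUTRs > Exons > Introns; peaks
    overlapping nothing are Intergenic.  Any overlap (>= 1 bp) counts; gene
    ties are broken by the smallest gene_id.
    """
    trees = _region_trees(regions)
    out: list[AnnotatedPeak] = []
    for row in ps.sorted().df.itertuples(index=False):
        assigned = ("Intergenic", None)
        for cat in ANNOTATION_PRIORITY:
            tree = trees[cat].get(row.chrom)
            hits = tree.overlap(row.start, row.end) if tree is not None else ()
            if hits:
                gene = min(h.data for h in hits)
                assigned = (cat, gene)
                break
        out.append(AnnotatedPeak(row.chrom, int(row.start), int(row.end), *assigned))
    counts = pd.Series([p.region for p in out]).value_counts().to_dict()
    logger.info("annotate_peaks: %s", counts)
    return out


def region_frequency(annotated: list[AnnotatedPeak],
                     regions: list[GeneRegions] | None = None
                     ) -> tuple[dict[str, float], dict[str, int]]:
    """Frequency of peaks over the mRNA categories {fiveUTRs, CDS, threeUTRs}.

    Exon-assigned peaks count as CDS when they overlap a coding interval
    (given ``regions``) and are dropped otherwise; proportions are over the
    three categories and sum to 1.  Returns (proportions, raw counts).
    """
    if not annotated:
        raise ValueError("region_frequency: empty peak list")
    cds_trees = _region_trees(regions)["CDS"] if regions is not None else None
    counts = {"fiveUTRs": 0, "CDS": 0, "threeUTRs": 0}
    for p in annotated:
        if p.region in ("fiveUTRs", "threeUTRs"):
            counts[p.region] += 1
        elif p.region == "Exons":
            if cds_trees is None:
                counts["CDS"] += 1
            else:
                tree = cds_trees.get(p.chrom)
                if tree is not None and tree.overlap(p.start, p.end):
                    counts["CDS"] += 1
    total = sum(counts.values())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return props, counts


def annotated_to_frame(annotated: list[AnnotatedPeak]) -> pd.DataFrame:
    return pd.DataFrame([{"chrom": p.chrom, "start": p.start, "end": p.end,
                          "region": p.region, "gene_id": p.gene_id if p.gene_id else "."}
                         for p in annotated])


# ------------------------------------------------------------- signal averaging

def read_bedgraph(path: str) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={0: str})
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def region_mean_signal(intervals: list[tuple[str, int, int]], signal: pd.DataFrame) -> float:
    """Per-base mean of a bedGraph-style track over a set of genomic intervals.

    Bases without a signal record are excluded from the denominator; if no
    base of the intervals is covered the result is NaN (undefined, distinct
    from 0).
    """
    total = 0.0
    n = 0
    sig = signal.sort_values(["chrom", "start"])
    by_chrom = {c: g for c, g in sig.groupby("chrom", sort=False)}
    for chrom, qs, qe in intervals:
        g = by_chrom.get(chrom)
        if g is None:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = g["value"].to_numpy()
        lo = np.clip(starts, qs, qe)
        hi = np.clip(ends, qs, qe)
        lens = np.maximum(hi - lo, 0)
        total += float(np.dot(lens, vals))
        n += int(lens.sum())
    return total / n if n else float("nan")
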