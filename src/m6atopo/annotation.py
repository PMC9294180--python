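"""Gene models, representative-transcript selection and metatranscript coordinates.

A metatranscript concatenates the spliced 5'UTR, CDS and 3'UTR of one
representative transcript per gene and rescales each region to a fixed number
of windows (10 / 20 / 20, giving 50 windows per gene).  All genomic intervals
are 0-based half-open (BED convention); GTF records are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

#: windows per metatranscript region, 5' to 3'
REGION_WINDOWS = (("fiveUTR", 10), ("CDS", 20), ("threeUTR", 20))
N_WINDOWS = sum(w for _, w in REGION_WINDOWS)

#: default length filters: regions shorter than these are discarded
MIN_5UTR = 50
MIN_3UTR = 100
MIN_CDS = 100

#: promoter half-width around the TSS, in bp
PROMOTER_FLANK = 3000

#: spliced nucleotides kept on each side of the stop codon
STOP_FLANK = 100

Interval = tuple[int, int]


@dataclass
class MetaCoordinate:
    """Position of one base in metatranscript space."""

    region: str  # fiveUTR | CDS | threeUTR
    fraction: float  # in [0, 1) within the region
    window_index: int  # 1..50 global window


@dataclass
class TranscriptModel:
    """One transcript with exon/CDS structure and spliced region lengths.

    ``exons`` and ``cds`` are sorted by genomic start and pairwise
    non-overlapping; every CDS interval lies inside an exon.  Region lengths
    are spliced (exonic) lengths, not genomic spans.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    cds_complete: bool = True

    # spliced coordinates of the CDS within the transcript, filled in __post_init__
    len5utr: int = field(init=False)
    lencds: int = field(init=False)
    len3utr: int = field(init=False)

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for a, b in self.exons + self.cds:
            if a >= b:
                raise ValueError(f"{self.transcript_id}: empty interval [{a},{b})")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if not self.cds:
            raise ValueError(f"{self.transcript_id}: no CDS (non-coding transcripts are not modelled)")
        s_positions = [self.genomic_to_spliced(a) for a, _ in self.cds]
        s_ends = [self.genomic_to_spliced(b - 1) for _, b in self.cds]
        lo = min(x for x in s_positions + s_ends if x is not None)
        hi = max(x for x in s_positions + s_ends if x is not None)
        if any(x is None for x in s_positions + s_ends):
            raise ValueError(f"{self.transcript_id}: CDS outside exons")
        self.len5utr = lo
        self.lencds = hi + 1 - lo
        self.len3utr = self.spliced_length - (hi + 1)
        if self.lencds != sum(b - a for a, b in self.cds):
            raise ValueError(f"{self.transcript_id}: CDS not contiguous in spliced coordinates")

    # ------------------------------------------------------------------ splicing
    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def _exons_5to3(self) -> list[Interval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def genomic_to_spliced(self, pos: int) -> int | None:
        """Spliced (transcript) coordinate of a genomic base, or None if intronic."""
        offset = 0
        for a, b in self._exons_5to3():
            if a <= pos < b:
                return offset + (pos - a if self.strand == "+" else b - 1 - pos)
            offset += b - a
        return None

    def spliced_to_genomic(self, s: int) -> int:
        if not 0 <= s < self.spliced_length:
            raise IndexError(f"spliced position {s} outside [0,{self.spliced_length})")
        offset = 0
        for a, b in self._exons_5to3():
            if s < offset + (b - a):
                d = s - offset
                return a + d if self.strand == "+" else b - 1 - d
            offset += b - a
        raise AssertionError("unreachable")

    def spliced_to_genomic_intervals(self, s0: int, s1: int) -> list[Interval]:
        """Genomic intervals covering spliced range [s0, s1), sorted by start."""
        s0 = max(s0, 0)
        s1 = min(s1, self.spliced_length)
        out: list[Interval] = []
        offset = 0
        for a, b in self._exons_5to3():
            n = b - a
            lo, hi = max(s0, offset), min(s1, offset + n)
            if lo < hi:
                if self.strand == "+":
                    out.append((a + lo - offset, a + hi - offset))
                else:
                    out.append((b - (hi - offset), b - (lo - offset)))
            offset += n
        return sorted(out)

    def genomic_interval_to_spliced(self, start: int, end: int) -> list[Interval]:
        """Spliced intervals covered by genomic [start, end), merged and sorted."""
        out: list[Interval] = []
        offset = 0
        for a, b in self._exons_5to3():
            lo, hi = max(start, a), min(end, b)
            if lo < hi:
                if self.strand == "+":
                    out.append((offset + lo - a, offset + hi - a))
                else:
                    out.append((offset + b - hi, offset + b - lo))
            offset += b - a
        return sorted(out)

    # ------------------------------------------------------------------ windows
    def window_sizes(self) -> list[int]:
        """Spliced base count of each of the 50 windows (remainder to the 5' end)."""
        sizes: list[int] = []
        for region, w in REGION_WINDOWS:
            length = {"fiveUTR": self.len5utr, "CDS": self.lencds, "threeUTR": self.len3utr}[region]
            base, rem = divmod(length, w)
            sizes.extend(base + 1 if i < rem else base for i in range(w))
        return sizes

    def window_bounds(self) -> list[int]:
        """Cumulative spliced boundaries of the 50 windows (length 51)."""
        bounds = [0]
        for s in self.window_sizes():
            bounds.append(bounds[-1] + s)
        return bounds


def genomic_to_meta(t: TranscriptModel, pos: int) -> MetaCoordinate | None:
    """Map a genomic position into (region, fraction, window) metatranscript space.

    Returns None for intronic or intergenic positions.
    """
    s = t.genomic_to_spliced(pos)
    if s is None:
        return None
    if s < t.len5utr:
        region, r, length = "fiveUTR", s, t.len5utr
    elif s < t.len5utr + t.lencds:
        region, r, length = "CDS", s - t.len5utr, t.lencds
    else:
        region, r, length = "threeUTR", s - t.len5utr - t.lencds, t.len3utr
    bounds = t.window_bounds()
    # window containing spliced base s: largest i with bounds[i] <= s
    win = 0
    for i in range(N_WINDOWS):
        if bounds[i] <= s < bounds[i + 1]:
            win = i + 1
            break
    return MetaCoordinate(region=region, fraction=r / length, window_index=win)


@dataclass
class GeneRegions:
    """Genomic intervals of one gene's functional regions (all 0-based half-open)."""

    gene_id: str
    chrom: str
    fiveUTR: list[Interval]
    CDS: list[Interval]
    threeUTR: list[Interval]
    promoter: list[Interval]
    intron: list[Interval]
    stop_flank: list[Interval]
    exons: list[Interval]


def gene_regions(t: TranscriptModel, promoter_flank: int = PROMOTER_FLANK,
                 stop_flank: int = STOP_FLANK) -> GeneRegions:
    """Derive UTR/CDS/promoter/intron and stop-codon-flank intervals for one transcript.

    The stop flank covers up to ``stop_flank`` spliced nucleotides on each side
    of the stop codon (the CDS/3'UTR junction), crossing it; the promoter is
    TSS +/- ``promoter_flank`` bp.
    """
    cds_lo = t.len5utr
    cds_hi = t.len5utr + t.lencds
    five = t.spliced_to_genomic_intervals(0, cds_lo)
    three = t.spliced_to_genomic_intervals(cds_hi, t.spliced_length)
    flank = t.spliced_to_genomic_intervals(max(cds_lo, cds_hi - stop_flank),
                                           min(t.spliced_length, cds_hi + stop_flank))
    tss = t.exons[0][0] if t.strand == "+" else t.exons[-1][1] - 1
    promoter = [(max(0, tss - promoter_flank), tss + promoter_flank + 1)]
    introns = [(b1, a2) for (_, b1), (a2, _) in zip(t.exons, t.exons[1:]) if a2 > b1]
    return GeneRegions(gene_id=t.gene_id, chrom=t.chrom, fiveUTR=five, CDS=list(t.cds),
                       threeUTR=three, promoter=promoter, intron=introns,
                       stop_flank=flank, exons=list(t.exons))


# ---------------------------------------------------------------------- GTF I/O

def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    Only transcripts with at least one CDS record are returned (the topology
    analysis concerns protein-coding genes).  Transcripts whose ``cds_end_NF``
    / ``cds_start_NF`` tags mark an incomplete CDS are kept but flagged, and
    the CDS length is not required to be a multiple of 3 for them.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=False,
                            merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    models: list[TranscriptModel] = []
    for tr in db.features_of_type("transcript"):
        exons = [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
        if not cds:
            continue
        if not exons:
            logger.warning("transcript %s has CDS but no exons; skipped", tr.id)
            continue
        tags = tr.attributes.get("tag", [])
        complete = not any(tag in ("cds_end_NF", "cds_start_NF", "mRNA_end_NF", "mRNA_start_NF")
                           for tag in tags)
        m = TranscriptModel(
            gene_id=tr.attributes["gene_id"][0],
            transcript_id=tr.attributes["transcript_id"][0],
            chrom=tr.seqid, strand=tr.strand,
            exons=exons, cds=cds, cds_complete=complete,
        )
        if m.cds_complete and m.lencds % 3 != 0:
            logger.warning("transcript %s: complete CDS length %d not a multiple of 3",
                           m.transcript_id, m.lencds)
        models.append(m)
    logger.info("read_gtf: %d coding transcripts from %s", len(models), path)
    return models


def transcript_counts(models: list[TranscriptModel]) -> dict[str, int]:
    """Number of annotated transcripts per gene (before representative selection)."""
    counts: dict[str, int] = {}
    for m in models:
        counts[m.gene_id] = counts.get(m.gene_id, 0) + 1
    return counts


def select_longest_transcript(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One representative transcript per gene: maximal spliced length, ties by
    lexicographically smallest transcript_id."""
    if not models:
        raise ValueError("empty transcript set")
    chosen: dict[str, TranscriptModel] = {}
    for m in models:
        cur = chosen.get(m.gene_id)
        if (cur is None
                or m.spliced_length > cur.spliced_length
                or (m.spliced_length == cur.spliced_length
                    and m.transcript_id < cur.transcript_id)):
            chosen[m.gene_id] = m
    return chosen


def filter_transcripts(chosen: dict[str, TranscriptModel], min5: int = MIN_5UTR,
                       min3: int = MIN_3UTR, mincds: int = MIN_CDS) -> dict[str, TranscriptModel]:
    """Drop genes whose representative transcript has a 5'UTR, 3'UTR or CDS
    shorter than the thresholds (strict <, so boundary lengths pass)."""
    kept = {g: t for g, t in chosen.items()
            if t.len5utr >= min5 and t.len3utr >= min3 and t.lencds >= mincds}
    logger.info("filter_transcripts: %d/%d genes retained (min5=%d min3=%d mincds=%d)",
                len(kept), len(chosen), min5, min3, mincds)
    if not kept:
        logger.warning("filter_transcripts: no genes retained")
    return kept
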