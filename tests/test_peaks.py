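"""Peak I/O, filtering, interval arithmetic and annotation."""

import math

import numpy as np
import pandas as pd
import pytest

from m6atopo import peaks as pk
from m6atopo.annotation import TranscriptModel, gene_regions


def make_peakset(intervals, chrom="chr1", fold=5.0, fdr=0.01, sample="s1"):
    df = pd.DataFrame([{"chrom": chrom, "start": s, "end": e,
                        "fold_enrichment": fold, "fdr": fdr, "sample_id": sample}
                       for s, e in intervals])
    if df.empty:
        df = pk._empty_df()
    return pk.PeakSet(df, [sample])


def brute_force_coverage(intervals, size):
    """Per-base boolean coverage, the oracle for all interval operations."""
    cov = np.zeros(size, dtype=bool)
    for s, e in intervals:
        cov[s:e] = True
    return cov


def runs_of(cov):
    """Covered intervals of a boolean per-base array."""
    out, start = [], None
    for i, c in enumerate(cov):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(cov)))
    return out


class TestReadPeaks:
    def test_narrowpeak_fields(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpk1\t500\t.\t3.5\t4.0\t2.0\t-1\n")
        ps = pk.read_peaks(p)
        row = ps.df.iloc[0]
        assert row.fold_enrichment == 3.5
        assert row.fdr == pytest.approx(0.01)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.narrowPeak"
        p.write_text("")
        assert len(pk.read_peaks(p)) == 0

    def test_bed6_is_prefiltered(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t10\tx\t0\t+\nchr1\t20\t30\tx\t0\t+\nchr2\t5\t9\tx\t0\t-\n")
        ps = pk.read_peaks(p, sample_id="s")
        assert len(ps) == 3
        assert ps.provenance == ["s"]
        assert (ps.df.fold_enrichment == math.inf).all()
        assert (ps.df.fdr == 0).all()

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t50\t40\tx\t0\t+\nchr1\t0\t10\tx\t0\t+\n")
        assert len(pk.read_peaks(p)) == 1

    def test_bed_write_read_roundtrip(self, tmp_path):
        ps = make_peakset([(5, 50), (100, 130)])
        out = tmp_path / "out.bed"
        pk.write_bed(ps, out)
        back = pk.read_peaks(out)
        assert list(zip(back.df.start, back.df.end)) == [(5, 50), (100, 130)]

    def test_non_numeric_coordinate_errors(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\tzzz\t40\n")
        with pytest.raises(ValueError, match="line"):
            pk.read_peaks(p)


class TestFilterPeaks:
    def test_strict_boundaries(self):
        ps = make_peakset([(0, 10)], fold=2.0, fdr=0.01)
        assert len(pk.filter_peaks(ps)) == 0  # fold must exceed 2
        ps = make_peakset([(0, 10)], fold=2.1, fdr=0.05)
        assert len(pk.filter_peaks(ps)) == 0  # fdr must be below 0.05

    def test_per_peak_rule(self):
        df = pd.DataFrame({"chrom": "chr1", "start": [0, 20, 40], "end": [10, 30, 50],
                           "fold_enrichment": [2.5, 1.9, 3.0], "fdr": [0.01, 0.001, 0.2],
                           "sample_id": "s"})
        out = pk.filter_peaks(pk.PeakSet(df, ["s"]))
        assert list(out.df.start) == [0]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"chrom": "chr1",
                           "start": np.arange(0, 1000, 10), "end": np.arange(5, 1005, 10),
                           "fold_enrichment": rng.uniform(0, 5, 100),
                           "fdr": rng.uniform(0, 0.2, 100), "sample_id": "s"})
        ps = pk.PeakSet(df, ["s"])
        base = len(pk.filter_peaks(ps, 2.0, 0.05))
        assert len(pk.filter_peaks(ps, 3.0, 0.05)) <= base
        assert len(pk.filter_peaks(ps, 2.0, 0.01)) <= base


class TestMerge:
    def test_overlap_and_bookended(self):
        assert list(pk.merge_peaks(make_peakset([(0, 10), (5, 20)])).df.end) == [20]
        assert list(pk.merge_peaks(make_peakset([(0, 10), (10, 20)])).df.end) == [20]

    def test_idempotent_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 100)
            starts = rng.integers(0, 9900, n)
            ends = starts + rng.integers(1, 100, n)
            ps = make_peakset(list(zip(starts, ends)))
            merged = pk.merge_peaks(ps)
            got = list(zip(merged.df.start, merged.df.end))
            assert got == runs_of(brute_force_coverage(zip(starts, ends), 10000))
            again = pk.merge_peaks(merged)
            assert list(zip(again.df.start, again.df.end)) == got


class TestReproduciblePeaks:
    def test_half_overlap_retained(self):
        a, b = make_peakset([(100, 200)]), make_peakset([(150, 300)], sample="s2")
        out = pk.reproducible_peaks(a, b)
        # a's peak: 50/100 = 0.5 >= 0.5 retained; b's: 50/150 < 0.5 dropped
        assert list(zip(out.df.start, out.df.end)) == [(100, 200)]

    def test_below_half_dropped(self):
        a, b = make_peakset([(100, 200)]), make_peakset([(160, 300)], sample="s2")
        out = pk.reproducible_peaks(a, b)
        # a's peak has 40% overlap -> dropped; b's peak has 140/140... of its
        # own length? overlap 40/140 < 0.5 -> dropped too
        assert len(out) == 0

    def test_identical_sets_give_merged_input(self):
        ivs = [(0, 50), (40, 100), (200, 250)]
        a, b = make_peakset(ivs), make_peakset(ivs, sample="s2")
        out = pk.reproducible_peaks(a, b)
        expect = pk.merge_peaks(make_peakset(ivs))
        assert list(zip(out.df.start, out.df.end)) == \
               list(zip(expect.df.start, expect.df.end))

    def test_minfrac_zero_identical_inputs_equals_merge(self):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 1000, 30)
        ivs = list(zip(starts, starts + rng.integers(1, 50, 30)))
        a, b = make_peakset(ivs), make_peakset(ivs, sample="s2")
        out = pk.reproducible_peaks(a, b, min_frac=0.0)
        expect = pk.merge_peaks(make_peakset(ivs))
        assert list(zip(out.df.start, out.df.end)) == \
               list(zip(expect.df.start, expect.df.end))

    def test_matches_per_base_oracle(self):
        """-f semantics: a peak survives iff the other replicate's union covers
        >= min_frac of its bases; result is the merged union of survivors."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            def rand_ivs():
                n = rng.integers(1, 40)
                s = rng.integers(0, 4900, n)
                return list(zip(s, s + rng.integers(1, 200, n)))
            ia, ib = rand_ivs(), rand_ivs()
            cov_a = brute_force_coverage(ia, 5200)
            cov_b = brute_force_coverage(ib, 5200)
            kept = [iv for iv in ia if cov_b[iv[0]:iv[1]].sum() >= 0.5 * (iv[1] - iv[0])]
            kept += [iv for iv in ib if cov_a[iv[0]:iv[1]].sum() >= 0.5 * (iv[1] - iv[0])]
            expect = runs_of(brute_force_coverage(kept, 5200))
            out = pk.reproducible_peaks(make_peakset(ia), make_peakset(ib, sample="s2"))
            assert list(zip(out.df.start, out.df.end)) == expect


class TestAnnotate:
    @pytest.fixture
    def regions(self):
        # gene A: + strand, two exons, CDS split across them
        t1 = TranscriptModel(gene_id="A", transcript_id="tA", chrom="chr1", strand="+",
                             exons=[(1000, 1300), (1400, 1700)], cds=[(1100, 1300), (1400, 1550)])
        t2 = TranscriptModel(gene_id="B", transcript_id="tB", chrom="chr1", strand="+",
                             exons=[(4000, 4900)], cds=[(4100, 4700)])
        return [gene_regions(t1, promoter_flank=100), gene_regions(t2, promoter_flank=100)]

    def test_priority_five_utr_over_promoter(self, regions):
        # within gene A's promoter (TSS 1000 +/- 100) and gene A's 5'UTR
        out = pk.annotate_peaks(make_peakset([(1050, 1090)]), regions)
        assert out[0].region == "fiveUTRs" and out[0].gene_id == "A"

    def test_promoter_before_exon(self, regions):
        # upstream of gene B's TSS, in its promoter only
        out = pk.annotate_peaks(make_peakset([(3910, 3990)]), regions)
        assert out[0].region == "Promoters" and out[0].gene_id == "B"

    def test_intron_only(self, regions):
        out = pk.annotate_peaks(make_peakset([(1310, 1390)]), regions)
        assert out[0].region == "Introns" and out[0].gene_id == "A"

    def test_intergenic_fallback(self, regions):
        out = pk.annotate_peaks(make_peakset([(20000, 20100)]), regions)
        assert out[0].region == "Intergenic" and out[0].gene_id is None

    def test_region_frequency_normalisation(self, regions):
        annotated = [pk.AnnotatedPeak("chr1", 0, 1, "fiveUTRs", "A")] * 2 + \
                    [pk.AnnotatedPeak("chr1", 1100, 1200, "Exons", "A")] * 5 + \
                    [pk.AnnotatedPeak("chr1", 0, 1, "threeUTRs", "A")] * 3
        props, counts = pk.region_frequency(annotated, regions)
        assert counts == {"fiveUTRs": 2, "CDS": 5, "threeUTRs": 3}
        assert props == {"fiveUTRs": 0.2, "CDS": 0.5, "threeUTRs": 0.3}
        with pytest.raises(ValueError):
            pk.region_frequency([])


class TestRegionMeanSignal:
    def test_constant_signal(self):
        sig = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "value": [2.5]})
        assert pk.region_mean_signal([("chr1", 100, 200)], sig) == 2.5

    def test_half_and_half(self):
        sig = pd.DataFrame({"chrom": "chr1", "start": [0, 50], "end": [50, 100],
                            "value": [0.0, 1.0]})
        assert pk.region_mean_signal([("chr1", 0, 100)], sig) == 0.5

    def test_uncovered_is_nan_not_zero(self):
        sig = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "value": [1.0]})
        assert math.isnan(pk.region_mean_signal([("chr1", 500, 600)], sig))

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            # disjoint signal records with gaps
            edges = np.sort(rng.choice(np.arange(1, 999), size=20, replace=False))
            segs = list(zip(np.concatenate([[0], edges]), np.concatenate([edges, [1000]])))
            keep = rng.random(len(segs)) < 0.7
            vals = rng.normal(size=len(segs))
            sig = pd.DataFrame([{"chrom": "chr1", "start": s, "end": e, "value": v}
                                for (s, e), k, v in zip(segs, keep, vals) if k])
            base_val = np.full(1000, np.nan)
            for r in sig.itertuples():
                base_val[r.start:r.end] = r.value
            qs = rng.integers(0, 900, 3)
            intervals = [("chr1", int(q), int(q + rng.integers(10, 100))) for q in qs]
            sel = np.concatenate([base_val[s:e] for _, s, e in intervals])
            expect = np.nanmean(sel) if np.isfinite(sel).any() else np.nan
            got = pk.region_mean_signal(intervals, sig)
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)
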