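"""End-to-end orchestration: peak files + annotation -> topology -> transitions.

These helpers chain the per-module operations in the order the analysis
defines: read and filter peaks per replicate, keep reproducible peaks, merge,
build the window matrix over the filtered longest-transcript models, cluster
into the five topology groups, and (for two stages) cross-tabulate
transitions.  ``run_all`` drives the whole pipeline from a synthetic-data
config and writes every result table as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotation, peaks, quantify, stats, synthetic, topology, transition

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def load_filtered_transcripts(gtf_path, min5: int = annotation.MIN_5UTR,
                              min3: int = annotation.MIN_3UTR,
                              mincds: int = annotation.MIN_CDS):
    """GTF -> filtered map gene_id -> representative (longest) transcript."""
    models = annotation.read_gtf(gtf_path)
    chosen = annotation.select_longest_transcript(models)
    return annotation.filter_transcripts(chosen, min5=min5, min3=min3, mincds=mincds)


def confident_peaks(peak_files, min_fold: float = 2.0, max_fdr: float = 0.05,
                    min_frac: float = 0.5) -> peaks.PeakSet:
    """Replicate peak files -> filtered, reproducible, merged peak set."""
    sets = [peaks.filter_peaks(peaks.read_peaks(p), min_fold=min_fold, max_fdr=max_fdr)
            for p in peak_files]
    return peaks.combine_replicates(sets, min_frac=min_frac)


def classify_stage(gtf_path=None, peak_files=None, seed: int = topology.DEFAULT_SEED,
                   transcripts=None, **peak_kwargs) -> topology.TopologyAssignment:
    """Classify one stage from a GTF (or pre-loaded transcripts) and replicate
    peak files."""
    if transcripts is None:
        transcripts = load_filtered_transcripts(gtf_path)
    merged = confident_peaks(peak_files, **peak_kwargs)
    return topology.classify(merged, transcripts, seed=seed)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_all(cfg: synthetic.SyntheticConfig, outdir, seed: int | None = None) -> dict:
    """Simulate a two-stage dataset and run the full analysis on it.

    Writes, under ``outdir``: the dataset (data/), per-stage topology
    assignments and centroids, the 5x5 transition counts and ratios, overlap
    ratios, transition gene sets, per-stage TPM and m6A levels, differential
    expression between stages, and tau over the tissue panel.  Deterministic
    for a fixed config and seed.  Returns the key in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.seed = seed
    ds = synthetic.generate(cfg, outdir / "data")
    transcripts = load_filtered_transcripts(ds.gtf_path)
    _write(pd.DataFrame(
        [{"gene_id": g, "len5utr": t.len5utr, "lencds": t.lencds,
          "len3utr": t.len3utr} for g, t in sorted(transcripts.items())]),
        outdir / "filtered_genes.tsv", index=False)

    assignments = {}
    matrices = {}
    for stage in synthetic.STAGES:
        merged = confident_peaks(ds.peak_paths[stage])
        m = topology.build_window_matrix(merged, transcripts)
        matrices[stage] = m
        raw_assign = topology.classify(merged, transcripts, seed=cfg.seed)
        assignments[stage] = raw_assign
        out = pd.DataFrame({"group": raw_assign.groups})
        if raw_assign.distances is not None:
            out["distance"] = raw_assign.distances
        _write(out, outdir / f"assignment_{stage}.tsv")
        _write(raw_assign.centroids, outdir / f"centroids_{stage}.tsv")
        _write(m.to_frame(), outdir / f"window_matrix_{stage}.tsv")

    tab = transition.cross_tab(assignments["fetal"], assignments["adult"])
    _write(tab.counts, outdir / "transition_counts.tsv")
    _write(transition.transition_ratio(tab), outdir / "transition_ratio.tsv")
    _write(transition.overlap_ratios(tab), outdir / "overlap_ratios.tsv")
    _write(tab.long_format(), outdir / "transitions_long.tsv", index=False)
    tsets = transition.transition_sets(tab)
    for name, genes in tsets.as_dict().items():
        with open(outdir / f"geneset_{name}.txt", "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")

    # quantification: per-stage TPM, m6A level; DE between stages (input rep1)
    tpm_tables = {}
    for stage in synthetic.STAGES:
        ct = quantify.read_count_table(ds.counts_path[stage], ds.samples_path[stage])
        t = quantify.tpm(ct)
        tpm_tables[stage] = (ct, t)
        _write(t, outdir / f"tpm_{stage}.tsv")
        level = quantify.m6a_level(t[ct.samples_with_role("IP")],
                                   t[ct.samples_with_role("input")])
        _write(level, outdir / f"m6a_level_{stage}.tsv")
    ct_f, _ = tpm_tables["fetal"]
    ct_a, _ = tpm_tables["adult"]
    de = quantify.differential_between(ct_f.counts["input_rep1"], ct_a.counts["input_rep1"])
    de = quantify.differential_genes(de)
    _write(de, outdir / "differential_expression.tsv", index=False)

    tissue = pd.read_csv(ds.tissue_path, sep="\t", index_col=0)
    tau_scores = stats.tau(tissue)
    _write(tau_scores.to_frame(), outdir / "tau.tsv")

    return {"dataset": ds, "transcripts": transcripts, "assignments": assignments,
            "window_matrices": matrices, "transition_table": tab,
            "transition_sets": tsets, "tau": tau_scores, "de": de}
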