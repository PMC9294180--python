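"""Seed-reproducible synthetic MeRIP-seq dataset with planted ground truth.

Generates, under one output directory, everything the pipeline consumes:

- a GTF of protein-coding gene models (single-exon by default, optional
  multi-exon) whose 5'UTR / CDS / 3'UTR lengths mostly respect the
  50 / 100 / 100 nt length filters, with a configurable violating fraction;
- per-stage, per-replicate narrowPeak files in which each gene's peaks sit in
  the genic region dictated by its planted topology class (5MG: 5'UTR; CMG:
  CDS excluding the last 100 nt; SMG: centred near the stop codon; 3MG:
  3'UTR excluding the first 100 nt; NMG: none), with replicate boundary
  jitter and optional sub-threshold decoy peaks;
- IP / input count tables per stage with negative-binomial noise and a
  planted negative correlation between m6A level and expression;
- a multi-tissue expression panel with known tissue-specific genes;
- a truth table of all planted per-gene labels and parameters.

Stage-2 classes follow a planted 5x5 row-stochastic transition matrix applied
to the stage-1 classes, so transition statistics have a known target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .topology import GROUPS

logger = logging.getLogger(__name__)

STAGES = ("fetal", "adult")


def default_transition_matrix() -> np.ndarray:
    """Planted fetal -> adult transitions: each group mostly keeps its label
    (diagonal 0.6), except fetal 5MGs, half of which lose their 5'UTR m6A and
    become adult NMGs."""
    m = np.full((5, 5), 0.1)
    np.fill_diagonal(m, 0.6)
    i5, inmg = GROUPS.index("5MG"), GROUPS.index("NMG")
    m[i5] = 0.1
    m[i5, inmg] = 0.5
    m[i5, i5] = 0.2
    return m


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard simulated study."""

    n_genes: int = 2000
    class_probs: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)  # NMG, 5MG, 3MG, CMG, SMG
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    utr5_range: tuple = (150, 400)       # nt, spliced
    cds_range: tuple = (300, 1500)       # nt, spliced, rounded to a codon multiple
    utr3_range: tuple = (250, 800)       # nt, spliced
    peak_length: tuple = (100, 200)      # nt
    region_coverage: tuple = (0.5, 0.9)  # planted peak coverage of the target region
    n_replicates: int = 2
    jitter_sd: float = 10.0              # replicate boundary jitter, nt (0 = clean)
    expr_lognormal: tuple = (4.0, 1.5)   # mean, sd of log2 expression
    m6a_effect: float = 4.0              # IP/input enrichment of methylated genes
    m6a_effect_sd: float = 0.6           # sd of log2 per-gene effect
    m6a_expr_rho: float = -0.5           # target corr(log2 m6A level, log2 expression)
    nb_dispersion: float = 0.02
    depth_factor: float = 10.0           # counts per (expression x kb)
    n_tissues: int = 12
    tissue_specific_frac_nmg: float = 0.5
    tissue_specific_frac_other: float = 0.15
    filter_violation_frac: float = 0.05
    decoy_frac: float = 0.05
    multi_exon: bool = False
    seed: int = 42

    def validate(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (5, 5) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition_matrix must be 5x5 row-stochastic")
        for name, (lo, hi) in (("utr5_range", self.utr5_range),
                               ("cds_range", self.cds_range),
                               ("utr3_range", self.utr3_range),
                               ("peak_length", self.peak_length)):
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: {(lo, hi)}")
        if self.peak_length[0] > self.utr5_range[0]:
            raise ValueError("peak_length minimum exceeds the smallest 5'UTR "
                             "(5MG peak placement infeasible)")
        if self.cds_range[0] < 100 + self.peak_length[0]:
            raise ValueError("cds_range minimum too small for CMG peak placement")
        if self.utr3_range[0] < 100 + self.peak_length[0]:
            raise ValueError("utr3_range minimum too small for 3MG peak placement")


@dataclass
class SyntheticDataset:
    outdir: Path
    gtf_path: Path
    peak_paths: dict          # stage -> [replicate narrowPeak paths]
    counts_path: dict         # stage -> counts TSV
    samples_path: dict        # stage -> sample sheet TSV
    tissue_path: Path
    truth_path: Path
    truth: pd.DataFrame
    models: dict              # gene_id -> TranscriptModel
    config: SyntheticConfig


# --------------------------------------------------------------------- helpers

def _sample_gene_model(rng: np.random.Generator, cfg: SyntheticConfig, gene_id: str,
                       chrom: str, start: int, violate: bool) -> TranscriptModel:
    l5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
    lcds = 3 * int(rng.integers(cfg.cds_range[0] // 3, cfg.cds_range[1] // 3 + 1))
    l3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
    if violate:  # shrink one region below its filter threshold
        which = rng.integers(0, 3)
        if which == 0:
            l5 = int(rng.integers(5, 50))
        elif which == 1:
            lcds = 3 * int(rng.integers(10, 33))
        else:
            l3 = int(rng.integers(10, 100))
    total = l5 + lcds + l3
    strand = "+" if rng.random() < 0.5 else "-"
    if cfg.multi_exon and total > 400:
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
        seg_lens = np.diff(np.concatenate([[0], cuts, [total]]))
        introns = rng.integers(60, 500, size=n_exons - 1)
    else:
        seg_lens = np.array([total])
        introns = np.array([], dtype=int)
    # lay out exons genomically; spliced order is 5'->3', so on '-' the first
    # spliced segment sits at the genomically highest position
    exons = []
    pos = start
    genomic_segs = seg_lens if strand == "+" else seg_lens[::-1]
    for i, L in enumerate(genomic_segs):
        exons.append((pos, pos + int(L)))
        pos += int(L) + (int(introns[i]) if i < len(introns) else 0)
    return TranscriptModel(gene_id=gene_id, transcript_id=gene_id.replace("G", "T", 1),
                           chrom=chrom, strand=strand, exons=exons,
                           cds=_cds_from_spliced(exons, strand, l5, lcds))


def _cds_from_spliced(exons, strand, l5, lcds):
    probe = TranscriptModel(gene_id="_", transcript_id="_", chrom="_", strand=strand,
                            exons=exons, cds=[tuple(exons[0])])
    return probe.spliced_to_genomic_intervals(l5, l5 + lcds)


def _planted_peak_intervals(rng: np.random.Generator, cfg: SyntheticConfig,
                            t: TranscriptModel, group: str) -> list[tuple[int, int]]:
    """Spliced intervals of the true peaks for one gene and topology class."""
    if group == "NMG":
        return []
    l5, lcds, l3 = t.len5utr, t.lencds, t.len3utr
    total = t.spliced_length
    stop = l5 + lcds
    plo, phi = cfg.peak_length
    out = []
    if group == "SMG":
        pl = int(rng.integers(plo, phi + 1))
        center = stop + int(rng.integers(-60, 61))
        s0 = max(0, center - pl // 2)
        out.append((s0, min(total, s0 + pl)))
        return out
    if group == "5MG":
        lo, hi = 0, l5
    elif group == "CMG":
        lo, hi = l5, max(l5, stop - 100)
    elif group == "3MG":
        lo, hi = min(stop + 100, total), total
    else:
        raise ValueError(group)
    region = hi - lo
    if region < 20:
        return []
    # methylation of a region is planted as a target coverage fraction: peaks
    # are laid down until the region is covered to that density
    target = rng.uniform(*cfg.region_coverage)
    covered = np.zeros(region, dtype=bool)
    for _ in range(40):
        if covered.mean() >= target:
            break
        pl = min(int(rng.integers(plo, phi + 1)), region)
        s0 = lo + int(rng.integers(0, region - pl + 1))
        out.append((s0, s0 + pl))
        covered[s0 - lo:s0 - lo + pl] = True
    return out


def _jitter(rng: np.random.Generator, s0: int, s1: int, sd: float, total: int
            ) -> tuple[int, int]:
    """Jitter both boundaries, clamped so replicates keep >=50% overlap."""
    if sd <= 0:
        return s0, s1
    max_shift = max(1, (s1 - s0) // 5)
    d0 = int(np.clip(round(rng.normal(0, sd)), -max_shift, max_shift))
    d1 = int(np.clip(round(rng.normal(0, sd)), -max_shift, max_shift))
    a = max(0, s0 + d0)
    b = min(total, max(a + 30, s1 + d1))
    return a, b


def _write_gtf(path: Path, models: list[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##description: synthetic annotation\n")
        for t in models:
            attr = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            g0, g1 = t.span
            fh.write(f"{t.chrom}\tsynth\tgene\t{g0 + 1}\t{g1}\t.\t{t.strand}\t.\t"
                     f'gene_id "{t.gene_id}";\n')
            fh.write(f"{t.chrom}\tsynth\ttranscript\t{g0 + 1}\t{g1}\t.\t{t.strand}\t.\t{attr}\n")
            for a, b in t.exons:
                fh.write(f"{t.chrom}\tsynth\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attr}\n")
            for a, b in t.cds:
                fh.write(f"{t.chrom}\tsynth\tCDS\t{a + 1}\t{b}\t.\t{t.strand}\t0\t{attr}\n")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean `mean` and variance mean + dispersion*mean^2."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# -------------------------------------------------------------------- generate

def generate(cfg: SyntheticConfig, outdir: str) -> SyntheticDataset:
    """Write the full synthetic dataset under ``outdir``; deterministic per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n = cfg.n_genes
    chroms = [f"chr{i}" for i in range(1, 6)]
    cursors = {c: 10_000 for c in chroms}
    gap = 7000  # keeps promoters clear of neighbouring gene bodies

    stage1 = rng.choice(5, size=n, p=np.asarray(cfg.class_probs))
    tm = np.asarray(cfg.transition_matrix, dtype=float)
    stage2 = np.array([rng.choice(5, p=tm[c]) for c in stage1])
    violate = rng.random(n) < cfg.filter_violation_frac

    # planted expression / m6A-effect with target correlation; measurement
    # noise attenuates the realized correlation, so the latent correlation is
    # inflated by an analytic estimate of that attenuation
    mu_e, sd_e = cfg.expr_lognormal
    med_count = (2.0 ** mu_e) * (np.mean(cfg.cds_range) / 1000.0) * cfg.depth_factor
    cv2 = 1.0 / max(med_count, 1.0) + cfg.nb_dispersion
    noise_log2 = math.sqrt(2.0 * cv2 / cfg.n_replicates) / math.log(2)
    att = cfg.m6a_effect_sd / math.sqrt(cfg.m6a_effect_sd ** 2 + noise_log2 ** 2)
    rho_latent = float(np.clip(cfg.m6a_expr_rho / att, -0.99, 0.99))
    z_e = rng.standard_normal(n)
    z_m = rho_latent * z_e + math.sqrt(1 - rho_latent ** 2) * rng.standard_normal(n)
    log2_expr = mu_e + sd_e * z_e
    log2_effect = math.log2(cfg.m6a_effect) + cfg.m6a_effect_sd * z_m

    models: dict[str, TranscriptModel] = {}
    rows = []
    for i in range(n):
        gene = f"G{i:05d}"
        chrom = chroms[i % len(chroms)]
        t = _sample_gene_model(rng, cfg, gene, chrom, cursors[chrom], bool(violate[i]))
        cursors[chrom] = t.span[1] + gap
        models[gene] = t
        passes = (t.len5utr >= 50 and t.len3utr >= 100 and t.lencds >= 100)
        rows.append({"gene_id": gene, "stage1_class": GROUPS[stage1[i]],
                     "stage2_class": GROUPS[stage2[i]],
                     "len5utr": t.len5utr, "lencds": t.lencds, "len3utr": t.len3utr,
                     "passes_filter": passes,
                     "log2_expr": round(float(log2_expr[i]), 6),
                     "log2_effect": round(float(log2_effect[i]), 6)})
    truth = pd.DataFrame(rows)
    model_list = list(models.values())
    gtf_path = outdir / "annotation.gtf"
    _write_gtf(gtf_path, model_list)

    # ---------------------------------------------------------------- peaks
    peak_paths: dict[str, list[Path]] = {}
    decoy = rng.random(n) < cfg.decoy_frac
    for stage, classes in zip(STAGES, (stage1, stage2)):
        true_spliced = {}
        for i, gene in enumerate(models):
            t = models[gene]
            ivals = _planted_peak_intervals(rng, cfg, t, GROUPS[classes[i]])
            if decoy[i]:
                pl = min(int(rng.integers(*cfg.peak_length)), t.spliced_length - 1)
                s0 = int(rng.integers(0, t.spliced_length - pl))
                ivals.append((s0, s0 + pl, "decoy"))
            true_spliced[gene] = ivals
        paths = []
        for rep in range(1, cfg.n_replicates + 1):
            path = outdir / f"peaks_{stage}_rep{rep}.narrowPeak"
            lines = []
            for gene, ivals in true_spliced.items():
                t = models[gene]
                for k, item in enumerate(ivals):
                    is_decoy = len(item) == 3
                    s0, s1 = item[0], item[1]
                    j0, j1 = _jitter(rng, s0, s1, cfg.jitter_sd, t.spliced_length)
                    if is_decoy:
                        signal = rng.uniform(0.5, 1.9)
                        mlogq = rng.uniform(0.2, 1.0)   # fdr in [0.1, 0.63]
                    else:
                        signal = rng.uniform(4.0, 10.0)
                        mlogq = rng.uniform(4.0, 8.0)
                    mlogp = mlogq + rng.uniform(1.0, 3.0)
                    for a, b in t.spliced_to_genomic_intervals(j0, j1):
                        lines.append((t.chrom, a, b,
                                      f"{gene}_p{k}", int(min(1000, signal * 100)), ".",
                                      f"{signal:.3f}", f"{mlogp:.3f}", f"{mlogq:.3f}", -1))
            lines.sort(key=lambda r: (r[0], r[1], r[2]))
            with open(path, "w") as fh:
                for r in lines:
                    fh.write("\t".join(str(x) for x in r) + "\n")
            paths.append(path)
        peak_paths[stage] = paths

    # ---------------------------------------------------------------- counts
    lengths = np.array([models[g].spliced_length for g in models])
    base_mean = (2.0 ** log2_expr) * (lengths / 1000.0) * cfg.depth_factor
    counts_path, samples_path = {}, {}
    for stage, classes in zip(STAGES, (stage1, stage2)):
        effect = np.where(classes == GROUPS.index("NMG"), 1.0, 2.0 ** log2_effect)
        cols = {}
        for rep in range(1, cfg.n_replicates + 1):
            cols[f"input_rep{rep}"] = _nb_counts(rng, base_mean, cfg.nb_dispersion)
            cols[f"IP_rep{rep}"] = _nb_counts(rng, base_mean * effect, cfg.nb_dispersion)
        df = pd.DataFrame(cols, index=pd.Index(list(models), name="gene_id"))
        df.insert(0, "length", lengths)
        cpath = outdir / f"counts_{stage}.tsv"
        df.to_csv(cpath, sep="\t")
        spath = outdir / f"samples_{stage}.tsv"
        sheet = pd.DataFrame({"sample": list(cols),
                              "role": ["input" if c.startswith("input") else "IP"
                                       for c in cols],
                              "condition": stage})
        sheet.to_csv(spath, sep="\t", index=False)
        counts_path[stage] = cpath
        samples_path[stage] = spath

    # ----------------------------------------------------------- tissue panel
    p_specific = np.where(stage1 == GROUPS.index("NMG"),
                          cfg.tissue_specific_frac_nmg, cfg.tissue_specific_frac_other)
    specific = rng.random(n) < p_specific
    home = rng.integers(0, cfg.n_tissues, size=n)
    base = 2.0 ** log2_expr
    panel = np.empty((n, cfg.n_tissues))
    for j in range(cfg.n_tissues):
        noise = 2.0 ** rng.normal(0, 0.3, size=n)
        level = np.where(specific & (home != j), base * 0.02, base)
        panel[:, j] = level * noise
    tissue = pd.DataFrame(np.round(panel, 4),
                          index=pd.Index(list(models), name="gene_id"),
                          columns=[f"tissue{j + 1}" for j in range(cfg.n_tissues)])
    tissue_path = outdir / "tissue_tpm.tsv"
    tissue.to_csv(tissue_path, sep="\t")

    truth["tissue_specific"] = specific
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    logger.info("generate: %d genes (%d filter-violating), stages %s, seed %d",
                n, int(violate.sum()), STAGES, cfg.seed)
    return SyntheticDataset(outdir=outdir, gtf_path=gtf_path, peak_paths=peak_paths,
                            counts_path=counts_path, samples_path=samples_path,
                            tissue_path=tissue_path, truth_path=truth_path,
                            truth=truth, models=models, config=cfg)


def truth_report(ds: SyntheticDataset) -> pd.DataFrame:
    """Planted labels plus realized (measured) quantities, one row per gene.

    Also attaches, as DataFrame attrs, the realized m6A-level/expression
    correlation per stage computed from the written count tables (log2 scale,
    methylated genes only), which verifies empirically that the planted
    correlation survived count noise.
    """
    from . import quantify
    from .stats import pearson_correlation

    out = ds.truth.copy()
    realized = {}
    for stage in STAGES:
        ct = quantify.read_count_table(ds.counts_path[stage], ds.samples_path[stage])
        t = quantify.tpm(ct)
        level = quantify.m6a_level(t[ct.samples_with_role("IP")],
                                   t[ct.samples_with_role("input")])
        expr = t[ct.samples_with_role("input")].mean(axis=1)
        out[f"m6a_level_{stage}"] = level["level"].reindex(out["gene_id"]).to_numpy()
        out[f"expr_{stage}"] = expr.reindex(out["gene_id"]).to_numpy()
        meth = out[f"{'stage1' if stage == STAGES[0] else 'stage2'}_class"] != "NMG"
        lv = out.loc[meth, f"m6a_level_{stage}"].to_numpy()
        ex = out.loc[meth, f"expr_{stage}"].to_numpy()
        ok = np.isfinite(lv) & (lv > 0) & (ex > 0)
        res = pearson_correlation(np.log2(lv[ok]), np.log2(ex[ok]))
        realized[stage] = res.statistic
    out.attrs["realized_m6a_expr_corr"] = realized
    return out
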