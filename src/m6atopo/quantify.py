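"""Count normalisation and m6A-level quantification.

Expression is TPM of the input (RNA-seq) library; the m6A level of a gene is
IP TPM divided by input TPM.  Between-stage comparisons use TMM (trimmed mean
of M-values) scaling factors.  Differential expression / methylation between
two conditions uses an exact two-Poisson rate-ratio test (the conditional
binomial test) with the thresholds p < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Genes x samples integer counts with per-gene feature lengths and roles.

    ``counts``: DataFrame indexed by gene_id, columns = sample ids.
    ``lengths``: Series (nt) indexed by gene_id.
    ``roles``: sample -> 'IP' | 'input'.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            raise ValueError("non-positive feature length")
        missing = set(self.counts.columns) - set(self.roles)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == role]


def read_count_table(counts_path: str, samples_path: str) -> CountTable:
    """Read a TSV count table (first column gene_id, then one column per sample,
    plus a ``length`` column) and a sidecar sample sheet (sample, role)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError(f"{counts_path}: missing 'length' column")
    lengths = df.pop("length")
    sheet = pd.read_csv(samples_path, sep="\t")
    roles = dict(zip(sheet["sample"], sheet["role"]))
    return CountTable(counts=df.astype(int), lengths=lengths.astype(int), roles=roles)


def tpm(ct: CountTable) -> pd.DataFrame:
    """Transcripts per million:  counts*1e6 / (length * sum_j counts_j/length_j).

    Each column sums to 1e6.
    """
    counts = ct.counts.to_numpy(dtype=float)
    lengths = ct.lengths.reindex(ct.counts.index).to_numpy(dtype=float)
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        bad = [s for s, z in zip(ct.counts.columns, colsum == 0) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    rate = counts / lengths[:, None]
    vals = rate * 1e6 / rate.sum(axis=0)
    return pd.DataFrame(vals, index=ct.counts.index, columns=ct.counts.columns)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float = 0.30,
              trim_a: float = 0.05) -> float:
    """TMM scaling factor of `obs` against `ref` (one column each).

    Doubly-trimmed weighted mean of M-values with inverse-binomial-variance
    weights, as in the published trimmed-mean-of-M-values method.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # binomial inverse-variance weights in fraction form: proportional to the
    # count-based form at equal library sizes, and exactly invariant to
    # scaling a sample's counts by a constant
    w = (1 - p_obs) / p_obs + (1 - p_ref) / p_ref
    n = len(m)
    if n == 0:
        return 1.0
    # rank-based double trim, mirroring the reference implementation
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() < 10:
        logger.warning("tmm: <10 genes survive trimming; using untrimmed mean")
        keep2 = np.ones_like(keep2)
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(ct: CountTable, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    Factors are effective relative sizes: dividing each sample's counts by its
    factor makes samples comparable, and a pure library-size scaling of one
    sample moves only that sample's factor, by exactly the scaling constant
    (up to the geometric-mean rescale).  The reference sample, when not given,
    is the one whose upper-quartile count fraction is closest to the mean
    upper-quartile fraction.
    """
    counts = ct.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("all-zero sample")
    if ref_sample is None:
        uq = np.array([np.quantile(c, 0.75) for c in counts.T]) / libsize
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(ct.counts.columns).index(ref_sample)
    ref = counts[:, ref_idx]
    # effective factor = composition factor (computed on count fractions, so
    # it is exactly invariant to library-size scaling) x library-size ratio;
    # a pure scaling of one sample therefore moves only that sample's factor,
    # by exactly the scaling constant
    factors = np.array([_tmm_pair(counts[:, j], ref, trim_m, trim_a)
                        for j in range(counts.shape[1])])
    factors = factors * libsize / libsize[ref_idx]
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=ct.counts.columns, name="tmm_factor")


def tmm_scaled(ct: CountTable) -> pd.DataFrame:
    """Counts divided by their TMM effective-size factor, on a counts-per-
    million-like scale (anchored at the geometric-mean library size)."""
    factors = tmm_factors(ct)
    libsize = ct.counts.sum(axis=0)
    anchor = np.exp(np.mean(np.log(libsize)))
    return ct.counts / (factors * anchor) * 1e6


def m6a_level(ip: pd.DataFrame | pd.Series, inp: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """m6A level = normalised IP / normalised input, per gene.

    Multi-sample inputs are averaged per gene first.  Genes with zero input
    are flagged ``input_too_low`` (level NaN) and must be excluded from
    correlation analyses.
    """
    ip_v = ip.mean(axis=1) if isinstance(ip, pd.DataFrame) else ip
    in_v = inp.mean(axis=1) if isinstance(inp, pd.DataFrame) else inp
    if set(ip_v.index) != set(in_v.index):
        diff = set(ip_v.index) ^ set(in_v.index)
        raise ValueError(f"mismatched gene universes; {len(diff)} genes differ: "
                         f"{sorted(diff)[:5]}...")
    in_v = in_v.reindex(ip_v.index)
    ok = in_v > 0
    level = pd.Series(np.where(ok, ip_v / in_v.where(ok, 1.0), np.nan), index=ip_v.index)
    return pd.DataFrame({"level": level,
                         "flag": np.where(ok, "ok", "input_too_low")})


def rate_ratio_test(counts_a: int, counts_b: int, scale_a: float = 1.0,
                    scale_b: float = 1.0) -> tuple[float, float]:
    """Exact two-Poisson rate-ratio test (conditional binomial).

    Returns (log2fc, pvalue).  log2fc uses a 0.5 pseudocount; the p-value is
    the exact binomial test of counts_a given n = counts_a + counts_b with
    success probability scale_a/(scale_a+scale_b), two-sided by doubling the
    smaller tail, capped at 1.
    """
    if counts_a < 0 or counts_b < 0:
        raise ValueError("negative counts")
    if scale_a <= 0 or scale_b <= 0:
        raise ValueError("scales must be positive")
    log2fc = float(np.log2(((counts_a + 0.5) / scale_a) / ((counts_b + 0.5) / scale_b)))
    n = counts_a + counts_b
    if n == 0:
        return 0.0, 1.0
    p0 = scale_a / (scale_a + scale_b)
    lower = sps.binom.cdf(counts_a, n, p0)
    upper = sps.binom.sf(counts_a - 1, n, p0)
    return log2fc, float(min(1.0, 2.0 * min(lower, upper)))


def differential_genes(results: pd.DataFrame, alpha: float = 0.05,
                       min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Flag significant genes: pvalue < alpha AND |log2fc| > min_abs_log2fc
    (both strict).  ``results`` needs columns gene_id, log2fc, pvalue."""
    out = results.copy()
    out["significant"] = (out["pvalue"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    logger.info("differential_genes: %d/%d significant (p<%g, |log2FC|>%g)",
                int(out["significant"].sum()), len(out), alpha, min_abs_log2fc)
    return out


def differential_between(ct_a: pd.Series, ct_b: pd.Series,
                         scale_a: float | None = None,
                         scale_b: float | None = None) -> pd.DataFrame:
    """Per-gene rate-ratio tests between two count columns (same gene index).

    Scales default to library sizes.  Vectorised over genes.
    """
    a = ct_a.to_numpy(dtype=int)
    b = ct_b.reindex(ct_a.index).to_numpy(dtype=int)
    sa = float(scale_a if scale_a is not None else a.sum())
    sb = float(scale_b if scale_b is not None else b.sum())
    log2fc = np.log2(((a + 0.5) / sa) / ((b + 0.5) / sb))
    n = a + b
    p0 = sa / (sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = sps.binom.cdf(a, n, p0)
        upper = sps.binom.sf(a - 1, n, p0)
    pval = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    pval = np.where(n == 0, 1.0, pval)
    log2fc = np.where(n == 0, 0.0, log2fc)
    return pd.DataFrame({"gene_id": ct_a.index, "log2fc": log2fc, "pvalue": pval})
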