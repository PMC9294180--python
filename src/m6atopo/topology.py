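"""Metatranscript window matrix and five-group m6A topology classification.

Each retained gene's spliced 5'UTR / CDS / 3'UTR is divided into 10 / 20 / 20
equal windows and every window records the fraction of its bases covered by a
merged m6A peak.  K-means (k = 5, Euclidean) on the genes x 50 matrix yields
the five topology groups, which are then named from their centroid shapes:

- NMG: no or little m6A anywhere (smallest centroid mean)
- 5MG: m6A concentrated in the 5'UTR (windows 1-10)
- CMG: m6A in the CDS body (windows 11-27)
- SMG: m6A around the stop codon (windows 28-32)
- 3MG: m6A in the 3'UTR body (windows 33-50)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .annotation import N_WINDOWS, TranscriptModel
from .peaks import PeakSet

logger = logging.getLogger(__name__)

GROUPS = ["NMG", "5MG", "3MG", "CMG", "SMG"]

#: window-index bands (0-based, half-open) used to name the non-NMG centroids
LABEL_BANDS = {
    "5MG": (0, 10),    # 5'UTR
    "CMG": (10, 27),   # CDS body
    "SMG": (27, 32),   # stop-codon flank in window space
    "3MG": (32, 50),   # 3'UTR body
}

DEFAULT_SEED = 42


@dataclass
class WindowMatrix:
    """Genes x 50 per-window m6A peak coverage fractions (values in [0, 1])."""

    genes: list[str]
    values: np.ndarray  # shape (n_genes, 50)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), N_WINDOWS):
            raise ValueError(f"expected shape ({len(self.genes)}, {N_WINDOWS})")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{i}" for i in range(1, N_WINDOWS + 1)]
        return pd.DataFrame(self.values, index=pd.Index(self.genes, name="gene_id"),
                            columns=cols)


@dataclass
class TopologyAssignment:
    """gene -> topology group, with the centroids that defined the groups."""

    groups: pd.Series            # index gene_id, values in GROUPS
    centroids: pd.DataFrame      # index group label, columns w1..w50
    seed: int
    inertia: float
    distances: pd.Series | None = None  # distance to own centroid

    def genes_in(self, group: str) -> set[str]:
        return set(self.groups.index[self.groups == group])

    def sizes(self) -> pd.Series:
        return self.groups.value_counts().reindex(GROUPS, fill_value=0)


class LabelingError(RuntimeError):
    """Centroids could not be mapped one-to-one onto the five groups.

    Usually indicates a degenerate clustering; retry with a different seed or
    inspect the within-cluster variance diagnostic over k.
    """


def build_window_matrix(peaks: PeakSet, transcripts: dict[str, TranscriptModel]) -> WindowMatrix:
    """Per-gene, per-window peak coverage over the metatranscript.

    ``peaks`` must be merged (non-overlapping); coverage of a window is the
    fraction of its spliced bases covered by at least one peak.
    """
    genes = sorted(transcripts)
    values = np.zeros((len(genes), N_WINDOWS))
    pdf = peaks.sorted().df
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in pdf.groupby("chrom", sort=False)}
    for gi, gene in enumerate(genes):
        t = transcripts[gene]
        if t.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[t.chrom]
        span_s, span_e = t.span
        # candidate peaks overlapping the transcript span
        i0 = np.searchsorted(ends, span_s, side="right")
        i1 = np.searchsorted(starts, span_e, side="left")
        if i0 >= i1:
            continue
        bounds = np.array(t.window_bounds())
        sizes = np.diff(bounds)
        cov = np.zeros(N_WINDOWS)
        for ps, pe in zip(starts[i0:i1], ends[i0:i1]):
            for s0, s1 in t.genomic_interval_to_spliced(int(ps), int(pe)):
                # distribute spliced interval [s0,s1) over windows
                w0 = np.searchsorted(bounds, s0, side="right") - 1
                w1 = np.searchsorted(bounds, s1, side="left")
                for w in range(max(w0, 0), min(w1, N_WINDOWS)):
                    lo = max(s0, bounds[w])
                    hi = min(s1, bounds[w + 1])
                    if hi > lo:
                        cov[w] += hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(sizes > 0, cov / np.maximum(sizes, 1), 0.0)
        values[gi] = np.clip(frac, 0.0, 1.0)
    return WindowMatrix(genes=genes, values=values)


def kmeans_cluster(m: WindowMatrix, k: int = 5, seed: int = DEFAULT_SEED,
                   n_init: int = 10, max_iter: int = 300, tol: float = 1e-4
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean k-means on the window matrix; best of ``n_init`` runs.

    Returns (labels, centroids, inertia).  Deterministic given ``seed``.
    """
    distinct = np.unique(m.values, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(f"only {distinct.shape[0]} distinct rows for k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                max_iter=max_iter, tol=tol)
    labels = km.fit_predict(m.values)
    return labels, km.cluster_centers_, float(km.inertia_)


def label_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Name the 5 clusters from their centroid shapes.

    NMG is the centroid with the smallest overall mean (required to be below
    half the second-smallest mean); each remaining centroid takes the label of
    the window band holding its largest mean.  The mapping must be bijective.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (5, N_WINDOWS):
        raise ValueError("expected 5 x 50 centroids")
    means = centroids.mean(axis=1)
    order = np.argsort(means, kind="mergesort")
    if means[order[0]] >= 0.5 * means[order[1]]:
        raise LabelingError(
            f"ambiguous NMG centroid: smallest mean {means[order[0]]:.4f} is not "
            f"< 50% of second smallest {means[order[1]]:.4f}; try another seed or "
            "inspect the k diagnostic")
    labels = {int(order[0]): "NMG"}
    for ci in order[1:]:
        band_means = {g: centroids[ci, lo:hi].mean() for g, (lo, hi) in LABEL_BANDS.items()}
        best = max(sorted(band_means), key=lambda g: band_means[g])
        if best in labels.values():
            raise LabelingError(
                f"two centroids map to {best}; clustering is degenerate, try another "
                "seed or inspect the k diagnostic")
        labels[int(ci)] = best
    return labels


def classify(peaks: PeakSet, transcripts: dict[str, TranscriptModel],
             seed: int = DEFAULT_SEED, n_init: int = 10) -> TopologyAssignment:
    """Full topology classification: window matrix -> k-means -> group labels.

    If more than 99 % of genes have no peak coverage at all, k-means would be
    degenerate and every gene is reported as NMG directly.
    """
    m = build_window_matrix(peaks, transcripts)
    zero_rows = (m.values.sum(axis=1) == 0)
    cols = [f"w{i}" for i in range(1, N_WINDOWS + 1)]
    if zero_rows.mean() > 0.99:
        logger.warning("classify: >99%% of genes peak-free; assigning all to NMG")
        groups = pd.Series("NMG", index=pd.Index(m.genes, name="gene_id"))
        centroids = pd.DataFrame(np.zeros((5, N_WINDOWS)), index=GROUPS, columns=cols)
        return TopologyAssignment(groups=groups, centroids=centroids, seed=seed,
                                  inertia=0.0)
    raw, cents, inertia = kmeans_cluster(m, k=5, seed=seed, n_init=n_init)
    mapping = label_clusters(cents)
    groups = pd.Series([mapping[int(c)] for c in raw],
                       index=pd.Index(m.genes, name="gene_id"))
    cent_df = pd.DataFrame(cents, columns=cols)
    cent_df.index = pd.Index([mapping[i] for i in range(5)], name="group")
    cent_df = cent_df.loc[GROUPS]
    dist = np.linalg.norm(m.values - cents[raw], axis=1)
    distances = pd.Series(dist, index=groups.index, name="distance")
    logger.info("classify: sizes %s inertia %.3f seed %d",
                groups.value_counts().to_dict(), inertia, seed)
    return TopologyAssignment(groups=groups, centroids=cent_df, seed=seed,
                              inertia=inertia, distances=distances)


def k_diagnostic(m: WindowMatrix, ks=range(2, 9), seed: int = DEFAULT_SEED) -> pd.Series:
    """Within-cluster sum of squares for a range of k (classification always
    uses k = 5; this is a diagnostic only)."""
    out = {}
    for k in ks:
        try:
            _, _, inertia = kmeans_cluster(m, k=k, seed=seed)
            out[k] = inertia
        except ValueError:
            out[k] = float("nan")
    return pd.Series(out, name="within_cluster_ss")


def metagene_profile(assignment: TopologyAssignment, m: WindowMatrix) -> pd.DataFrame:
    """Mean per-window density per group (group x 50), for metagene plots."""
    df = m.to_frame()
    return df.groupby(assignment.groups.reindex(df.index)).mean().reindex(GROUPS)


def plot_metagene(profile: pd.DataFrame, path: str) -> None:
    """Line plot of per-group metagene densities with region boundaries."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(1, N_WINDOWS + 1)
    for group in profile.index:
        ax.plot(xs, profile.loc[group].to_numpy(), label=str(group))
    for boundary in (10.5, 30.5):
        ax.axvline(boundary, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("metatranscript window (5'UTR | CDS | 3'UTR)")
    ax.set_ylabel("mean m6A peak density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
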