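import numpy as np
import pytest

from m6atopo import pipeline, synthetic
from m6atopo.annotation import TranscriptModel


@pytest.fixture
def toy_plus():
    """Single-exon + strand transcript: exon [0,300), CDS [100,250)."""
    return TranscriptModel(gene_id="G1", transcript_id="T1", chrom="chr1",
                           strand="+", exons=[(0, 300)], cds=[(100, 250)])


@pytest.fixture
def toy_minus():
    """Same structure on the - strand (5'UTR at the genomic high end)."""
    return TranscriptModel(gene_id="G1", transcript_id="T1", chrom="chr1",
                           strand="-", exons=[(0, 300)], cds=[(100, 250)])


def random_transcript(rng: np.random.Generator, multi_exon: bool = True) -> TranscriptModel:
    """Random valid transcript for property tests."""
    l5 = int(rng.integers(50, 300))
    lcds = 3 * int(rng.integers(34, 400))
    l3 = int(rng.integers(100, 500))
    total = l5 + lcds + l3
    strand = "+" if rng.random() < 0.5 else "-"
    if multi_exon and rng.random() < 0.7:
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
        seg = np.diff(np.concatenate([[0], cuts, [total]]))
        introns = rng.integers(30, 300, size=n_exons - 1)
    else:
        seg = np.array([total])
        introns = np.array([], dtype=int)
    exons = []
    pos = int(rng.integers(0, 1000))
    genomic_segs = seg if strand == "+" else seg[::-1]
    for i, L in enumerate(genomic_segs):
        exons.append((pos, pos + int(L)))
        pos += int(L) + (int(introns[i]) if i < len(introns) else 0)
    probe = TranscriptModel(gene_id="G", transcript_id="T", chrom="chr1",
                            strand=strand, exons=exons, cds=[tuple(exons[0])])
    cds = probe.spliced_to_genomic_intervals(l5, l5 + lcds)
    return TranscriptModel(gene_id="G", transcript_id="T", chrom="chr1",
                           strand=strand, exons=exons, cds=cds)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 400-gene two-stage synthetic dataset shared across tests."""
    cfg = synthetic.SyntheticConfig(n_genes=400, seed=11)
    return synthetic.generate(cfg, tmp_path_factory.mktemp("smallds"))


@pytest.fixture(scope="session")
def small_transcripts(small_dataset):
    return pipeline.load_filtered_transcripts(small_dataset.gtf_path)
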