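import numpy as np
import pytest

from lincpipe.intervals import GenomicInterval, TranscriptModel
from lincpipe.pipeline import PipelineInputs, PipelineParams, run_pipeline
from lincpipe.simulate import SimulationConfig, simulate_bundle


def make_transcript(
    tid, chrom, strand, exon_coords, gene_id=None, biotype="unknown"
):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel(tid, gene_id or f"G_{tid}", chrom, strand, exons, biotype)


def random_transcript(rng, tid, chrom=None, max_pos=100_000):
    """A random valid transcript: 1-4 exons, random strand and placement."""
    chrom = chrom or f"chr{rng.integers(1, 3)}"
    strand = ["+", "-", "."][rng.integers(0, 3)]
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, max_pos))
    coords = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        coords.append((pos, pos + length))
        pos += length + int(rng.integers(30, 2_500))
    return make_transcript(tid, chrom, strand, coords)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study bundle (shared; treat as read-only)."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    """End-to-end pipeline report for the default bundle."""
    return run_pipeline(
        PipelineInputs.from_bundle(default_bundle), PipelineParams(seed=1)
    )
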