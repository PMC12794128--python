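import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protannot import GenomicInterval, PipelineConfig, run_pipeline
from protannot.pseudotranscript import Locus, PseudoTranscript, build_pseudotranscript
from protannot.synthetic import SyntheticSpec, write_synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_pt(seq: str, pt_id: str = "pt1", seqid: str = "c", strand: str = "+") -> PseudoTranscript:
    """A single-block pseudo-transcript whose genome is the sequence itself."""
    genome_seq = seq
    locus = Locus(seqid=seqid, strand=strand, members=[],
                  merged_blocks=[GenomicInterval(seqid, 1, len(seq), strand)])
    return build_pseudotranscript(locus, {seqid: genome_seq}, pt_id=pt_id)


def random_locus_pt(rng: np.random.Generator) -> tuple[PseudoTranscript, dict[str, str]]:
    """A pseudo-transcript over random disjoint blocks of a random contig."""
    n_blocks = int(rng.integers(1, 6))
    contig_len = int(rng.integers(200, 2000))
    strand = "+" if rng.random() < 0.5 else "-"
    starts = np.sort(rng.choice(np.arange(1, contig_len - 30), size=n_blocks, replace=False))
    blocks = []
    prev_end = 0
    for s in starts:
        s = max(int(s), prev_end + 2)
        if s > contig_len - 2:
            break
        e = int(min(contig_len, s + rng.integers(1, 60)))
        blocks.append(GenomicInterval("c", s, e, strand))
        prev_end = e
    if not blocks:
        blocks = [GenomicInterval("c", 1, 30, strand)]
    contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=contig_len)])
    genome = {"c": contig}
    locus = Locus(seqid="c", strand=strand, members=[], merged_blocks=blocks)
    return build_pseudotranscript(locus, genome, pt_id="rand"), genome


@pytest.fixture(scope="session")
def standard_sim(tmp_path_factory):
    """The standard 50-gene, 500 kb fixture (divergence 0, exact alignments)."""
    spec = SyntheticSpec(seed=123)
    prefix = tmp_path_factory.mktemp("sim") / "sim"
    paths = write_synthetic(spec, prefix)
    return spec, paths


@pytest.fixture(scope="session")
def standard_run(standard_sim, tmp_path_factory):
    """Annotation of the standard fixture with default parameters."""
    _, paths = standard_sim
    out = tmp_path_factory.mktemp("ann") / "ann"
    result = run_pipeline(paths["genome"], paths["alignments"], out, PipelineConfig())
    return paths, result
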