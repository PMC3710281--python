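import pytest

import fragbias as fb


@pytest.fixture(scope="session")
def transcriptome():
    """Small toy transcriptome shared across tests."""
    return fb.make_transcriptome(n_transcripts=10, len_mean=1000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def rnaseiii_library(transcriptome):
    """Strongly motif-biased library (lambda = 50)."""
    cfg = fb.FragSimConfig(mode="rnaseiii", bias_strength=50.0,
                           n_fragments=8000, seed=21)
    fastq, mapped, frags = fb.simulate_library(transcriptome, cfg)
    return cfg, fastq, mapped, frags


@pytest.fixture(scope="session")
def heat_library(transcriptome):
    """Unbiased (thermal fragmentation) library."""
    cfg = fb.FragSimConfig(mode="heat", n_fragments=8000, seed=22)
    fastq, mapped, frags = fb.simulate_library(transcriptome, cfg)
    return cfg, fastq, mapped, frags


def library_enrichment(mapped, transcriptome, seed, n_replicates=20, n_logo=10000):
    """Observed-vs-control enrichment tables for both read ends."""
    out = {}
    for end_type, read_len in (("5p", 50), ("3p", 35)):
        reads = [r for r in mapped if r.end_type == end_type]
        sample = fb.subsample_reads(reads, n=n_logo, seed=seed)
        profile = fb.profile_reads(sample)
        cfg = fb.ControlConfig(read_len=read_len, n_replicates=n_replicates, seed=seed)
        envelope = fb.control_entropy_envelope(sample, transcriptome, cfg)
        out[end_type] = fb.enrichment(profile, envelope)
    return out
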