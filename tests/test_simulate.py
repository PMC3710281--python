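"""Simulator: transcriptome generation, fragmentation models, end
selection, and read emission, checked against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import fragbias as fb
from fragbias.simulate import MIN_FRAG_LEN


def _count_dinucleotide_starts(seq, motif):
    """Brute-force count of positions where motif begins."""
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + 2] == motif)


class TestMakeTranscriptome:
    def test_deterministic_under_fixed_seed(self):
        a = fb.make_transcriptome(5, 1000, 0.5, seed=1)
        b = fb.make_transcriptome(5, 1000, 0.5, seed=1)
        assert a == b

    def test_pure_gc_composition(self):
        for t in fb.make_transcriptome(3, 500, gc=1.0, seed=2):
            assert set(t.spliced_seq) <= {"G", "C"}

    def test_gc_fraction_within_binomial_noise(self):
        ts = fb.make_transcriptome(200, 1000, gc=0.4, seed=7)
        pooled = "".join(t.spliced_seq for t in ts)
        n = len(pooled)
        gc_frac = sum(b in "GC" for b in pooled) / n
        sd = np.sqrt(0.4 * 0.6 / n)
        assert abs(gc_frac - 0.4) < 3 * sd

    def test_exon_structure_consistent(self):
        for t in fb.make_transcriptome(20, 800, 0.5, seed=3):
            assert len(t.exons) >= 1
            assert sum(e - s for s, e in t.exons) == t.length

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            fb.make_transcriptome(0, 1000, 0.5, seed=1)
        with pytest.raises(ValueError):
            fb.make_transcriptome(5, 100, 0.5, seed=1)


@pytest.fixture(scope="module")
def long_transcript():
    return fb.make_transcriptome(1, 100_000, 0.5, seed=9, max_exons=1)[0]


@pytest.fixture(scope="module")
def heat_fragments(transcriptome):
    cfg = fb.FragSimConfig(mode="heat", seed=31)
    return fb.fragment_heat(transcriptome[3], cfg, n=10_000)


class TestFragmentHeat:
    def test_breakpoints_uniform(self, long_transcript):
        """Start positions are uniform over eligible bonds (chi-square)."""
        cfg = fb.FragSimConfig(mode="heat", seed=3)
        frags = fb.fragment_heat(long_transcript, cfg, n=10_000)
        starts = np.array([f.start for f in frags])
        hi = long_transcript.length - MIN_FRAG_LEN + 1
        counts, _ = np.histogram(starts, bins=100, range=(0, hi))
        assert stats.chisquare(counts).pvalue > 0.001

    def test_lengths_centered_on_target(self, long_transcript):
        cfg = fb.FragSimConfig(mode="heat", target_len=200, len_sd=25.0, seed=4)
        lens = np.array([f.length for f in fb.fragment_heat(long_transcript, cfg, n=5000)])
        assert abs(lens.mean() - 200) < 2
        assert lens.min() >= MIN_FRAG_LEN

    def test_motif_fraction_matches_background(self, long_transcript):
        """Heat mode ignores the motif dial: AA-start fraction equals the
        transcript's dinucleotide background."""
        cfg = fb.FragSimConfig(mode="heat", seed=5)
        frags = fb.fragment_heat(long_transcript, cfg, n=10_000)
        frac = np.mean([f.seq[:2] == "AA" for f in frags])
        seq = long_transcript.spliced_seq
        background = _count_dinucleotide_starts(seq, "AA") / (len(seq) - 1)
        sd = np.sqrt(background * (1 - background) / len(frags))
        assert abs(frac - background) < 4 * sd

    def test_short_transcript_gives_empty_list(self):
        t = fb.TranscriptModel("short", "chr1", "+", ((0, 40),), "ACGT" * 10)
        assert fb.fragment_heat(t, fb.FragSimConfig(seed=1)) == []

    def test_seq_matches_coordinates(self, transcriptome):
        cfg = fb.FragSimConfig(mode="heat", seed=6)
        t = transcriptome[0]
        for f in fb.fragment_heat(t, cfg, n=200):
            assert f.seq == t.spliced_seq[f.start : f.end]


class TestFragmentRnaseiii:
    def test_lambda_one_reduces_to_heat(self, transcriptome):
        """At lambda = 1 the weighted sampler is the uniform sampler."""
        t = transcriptome[0]
        cfg1 = fb.FragSimConfig(mode="rnaseiii", bias_strength=1.0, seed=5)
        cfg2 = fb.FragSimConfig(mode="heat", seed=5)
        assert fb.fragment_rnaseiii(t, cfg1, n=2000) == fb.fragment_heat(t, cfg2, n=2000)

    def test_lambda_one_distribution_matches_heat(self):
        """Different seeds: length and start distributions agree (KS)."""
        t = fb.make_transcriptome(1, 50_000, 0.5, seed=13, max_exons=1)[0]
        f_bias = fb.fragment_rnaseiii(t, fb.FragSimConfig(mode="rnaseiii", seed=5), n=10_000)
        f_heat = fb.fragment_heat(t, fb.FragSimConfig(mode="heat", seed=6), n=10_000)
        for attr in ("start", "length"):
            a = [getattr(f, attr) for f in f_bias]
            b = [getattr(f, attr) for f in f_heat]
            assert stats.ks_2samp(a, b).pvalue > 0.001

    def test_strong_bias_enriches_motif_starts(self, transcriptome):
        t = transcriptome[1]
        frac = {}
        for lam in (1.0, 50.0):
            cfg = fb.FragSimConfig(mode="rnaseiii", bias_strength=lam, seed=8)
            frags = fb.fragment_rnaseiii(t, cfg, n=10_000)
            frac[lam] = np.mean([f.seq[:2] == "AA" for f in frags])
        assert frac[50.0] >= 3 * frac[1.0]

    def test_motif_fraction_monotone_in_lambda(self, transcriptome):
        t = transcriptome[2]
        fracs = []
        for lam in (1.0, 5.0, 20.0, 50.0):
            cfg = fb.FragSimConfig(mode="rnaseiii", bias_strength=lam, seed=12)
            frags = fb.fragment_rnaseiii(t, cfg, n=8000)
            fracs.append(np.mean([f.seq[:2] == "AA" for f in frags]))
        assert all(b >= a - 0.01 for a, b in zip(fracs, fracs[1:]))

    def test_no_motif_sites_behaves_like_uniform(self):
        """A transcript without the motifs gives the unbiased sampler."""
        seq = "CT" * 500  # contains neither AA nor CC
        t = fb.TranscriptModel("flat", "chr1", "+", ((0, 1000),), seq)
        cfg50 = fb.FragSimConfig(mode="rnaseiii", bias_strength=50.0, seed=4)
        cfg_heat = fb.FragSimConfig(mode="heat", seed=4)
        assert fb.fragment_rnaseiii(t, cfg50, n=1000) == fb.fragment_heat(t, cfg_heat, n=1000)

    def test_rejects_lambda_below_one(self):
        with pytest.raises(ValueError):
            fb.FragSimConfig(mode="rnaseiii", bias_strength=0.5)


class TestEndSelection:
    def test_all_weights_one_is_identity(self, heat_fragments):
        cfg = fb.FragSimConfig(
            mode="t4pnk_after_heat", seed=1,
            end5_weights={b: 1.0 for b in "ACGT"},
            end3_weights={b: 1.0 for b in "ACGT"},
        )
        assert fb.apply_end_selection(heat_fragments, cfg) == list(heat_fragments)

    def test_zero_weights_force_terminal_base(self, heat_fragments):
        cfg = fb.FragSimConfig(
            mode="t4pnk_after_heat", seed=2,
            end5_weights={b: 1.0 for b in "ACGT"},
            end3_weights={"A": 1.0, "T": 1.0, "G": 0.0, "C": 0.0},
        )
        survivors = fb.apply_end_selection(heat_fragments, cfg)
        assert survivors and all(f.seq[-1] in "AT" for f in survivors)

    def test_surviving_fraction_matches_bayes_posterior(self, heat_fragments):
        """Surviving A/T-terminal fraction equals the exact acceptance-
        probability posterior computed from input terminal counts."""
        w3 = {"A": 1.0, "T": 1.0, "G": 0.25, "C": 0.25}
        cfg = fb.FragSimConfig(
            mode="t4pnk_after_heat", seed=3,
            end5_weights={b: 1.0 for b in "ACGT"}, end3_weights=w3,
        )
        n_at = sum(f.seq[-1] in "AT" for f in heat_fragments)
        n_gc = len(heat_fragments) - n_at
        expected = n_at / (n_at + 0.25 * n_gc)  # Bayes posterior of A/T | kept
        survivors = fb.apply_end_selection(heat_fragments, cfg)
        observed = np.mean([f.seq[-1] in "AT" for f in survivors])
        sd = np.sqrt(expected * (1 - expected) / len(survivors))
        assert abs(observed - expected) < 3 * sd

    def test_sequences_never_altered(self, heat_fragments):
        cfg = fb.FragSimConfig(mode="t4pnk_after_heat", seed=4)
        survivors = fb.apply_end_selection(heat_fragments, cfg)
        pool = set(heat_fragments)
        assert all(f in pool for f in survivors)

    def test_fragmentation_modes_select_nothing(self, heat_fragments):
        for mode in ("heat", "rnaseiii"):
            cfg = fb.FragSimConfig(mode=mode, seed=5)
            assert fb.apply_end_selection(heat_fragments, cfg) == list(heat_fragments)

    def test_optik_shrinks_bias_toward_uniform(self, heat_fragments):
        """OptiKinase mode keeps more fragments than plain end repair."""
        kept = {}
        for mode in ("t4pnk_after_heat", "optik_then_t4pnk"):
            cfg = fb.FragSimConfig(mode=mode, seed=6)
            kept[mode] = len(fb.apply_end_selection(heat_fragments, cfg))
        assert kept["optik_then_t4pnk"] > kept["t4pnk_after_heat"]

    def test_empty_input(self):
        assert fb.apply_end_selection([], fb.FragSimConfig(seed=1)) == []


class TestFragmentsToReads:
    def test_direct_construction(self):
        seq = "ACGT" * 50
        frag = fb.Fragment("tx", 100, 300, seq)
        cfg = fb.FragSimConfig(seed=1)
        fastq, mapped = fb.fragments_to_reads([frag], cfg)
        r5 = next(r for r in mapped if r.end_type == "5p")
        r3 = next(r for r in mapped if r.end_type == "3p")
        assert r5.seq == seq[:50]
        assert (r5.start, r5.end, r5.strand) == (100, 150, "+")
        assert r3.seq == fb.revcomp(seq[-35:])
        assert (r3.start, r3.end, r3.strand) == (265, 300, "-")

    def test_lowq_read_count_is_binomial(self, transcriptome):
        """Reads failing the quality rule arrive at the configured rate."""
        cfg = fb.FragSimConfig(mode="heat", lowq_fraction=0.1, seed=2)
        frags = fb.fragment_heat(transcriptome[4], cfg, n=1000)
        _, mapped = fb.fragments_to_reads(frags, cfg)
        n = len(frags)
        sd = np.sqrt(n * 0.1 * 0.9)
        for end_type in ("5p", "3p"):
            reads = [r for r in mapped if r.end_type == end_type]
            _, dropped = fb.filter_by_quality(reads, fb.QcPolicy())
            assert abs(len(dropped) - 0.1 * n) < 3 * sd

    def test_short_fragments_skipped(self):
        frag = fb.Fragment("tx", 0, 40, "A" * 40)
        fastq, mapped = fb.fragments_to_reads([frag], fb.FragSimConfig(seed=1))
        assert fastq == [] and mapped == []

    def test_roundtrip_through_io(self, tmp_path, heat_library):
        _, fastq, mapped, _ = heat_library
        fb.write_fastq(fastq[:100], tmp_path / "r.fastq")
        assert fb.read_fastq(tmp_path / "r.fastq") == fastq[:100]
        fb.write_mapped_table(mapped[:100], tmp_path / "m.tsv")
        assert fb.read_mapped_table(tmp_path / "m.tsv") == mapped[:100]


def test_library_simulation_deterministic(transcriptome):
    cfg = fb.FragSimConfig(mode="rnaseiii", bias_strength=20.0, n_fragments=2000, seed=77)
    a = fb.simulate_library(transcriptome, cfg)
    b = fb.simulate_library(transcriptome, cfg)
    assert a == b
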