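"""End-to-end runs: simulate libraries, QC, pile-ups, profiles, controls,
signatures — with a manifest recording seeds and output checksums.

The pipeline is linear and desk-scale, driven by a single flat YAML config
with per-stage sections. Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from ._util import log
from .control import ControlConfig, control_entropy_envelope, predict_cdna_windows
from .io import write_fastq, write_mapped_table
from .pileup import group_pileups, ratio_curve, redundancy
from .profiles import profile_reads, subsample_reads
from .qc import QcPolicy, filter_by_quality, filter_contaminants, qc_report
from .signature import DEFAULT_FLOOR, cutter_signature, enrichment
from .simulate import (
    FragSimConfig,
    make_transcriptome,
    simulate_library,
    write_config,
    write_transcripts,
    write_truth_table,
)

DEMO_CONFIG = {
    "seed": 1,
    "transcriptome": {"n_transcripts": 20, "len_mean": 1000, "gc": 0.5},
    "libraries": [
        {"name": "ctl_rnaseiii", "mode": "rnaseiii", "bias_strength": 50.0,
         "n_fragments": 20000},
        {"name": "heat_t4pnk", "mode": "t4pnk_after_heat", "n_fragments": 20000},
        {"name": "heat_optik", "mode": "optik_then_t4pnk", "n_fragments": 20000},
    ],
    "qc": {"lowq_fraction": 0.02},
    "pileup": {"k_max": 10},
    "control": {"n_replicates": 50},
    "signature": {"floor": DEFAULT_FLOOR, "n_logo": 10000},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "libraries" not in config:
        raise ValueError(f"{path}: not a pipeline config (needs a 'libraries' section)")
    return config


def write_demo_config(path) -> dict:
    with open(path, "w") as fh:
        yaml.safe_dump(DEMO_CONFIG, fh, sort_keys=False)
    return DEMO_CONFIG


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the linear pipeline described by ``config``.

    Stages per library: simulate -> qc -> pileup -> bias profiles (5'/3')
    -> control envelopes -> cutter signature. Returns the run manifest
    (also written to ``outdir/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    tcfg = config.get("transcriptome", {})
    ccfg = config.get("control", {})
    scfg = config.get("signature", {})
    k_max = int(config.get("pileup", {}).get("k_max", 10))
    lowq = float(config.get("qc", {}).get("lowq_fraction", 0.0))
    n_logo = int(scfg.get("n_logo", 10000))

    transcripts = make_transcriptome(
        n_transcripts=int(tcfg.get("n_transcripts", 20)),
        len_mean=int(tcfg.get("len_mean", 1000)),
        gc=float(tcfg.get("gc", 0.5)),
        seed=seed,
    )
    write_transcripts(transcripts, outdir / "transcripts.tsv", outdir / "transcripts.fa")

    manifest: dict = {
        "fragbias_version": __version__,
        "seed": seed,
        "config": config,
        "libraries": {},
        "outputs": {},
    }

    for i, lib in enumerate(config["libraries"]):
        name = lib["name"]
        log.info("pipeline: simulating library %s (%s)", name, lib["mode"])
        sim = FragSimConfig(
            mode=lib["mode"],
            bias_strength=float(lib.get("bias_strength", 1.0)),
            n_fragments=int(lib.get("n_fragments", 10000)),
            target_len=int(lib.get("target_len", 200)),
            lowq_fraction=lowq,
            seed=seed * 1000 + i,
        )
        fastq, mapped, frags = simulate_library(transcripts, sim)
        libdir = outdir / name
        libdir.mkdir(exist_ok=True)
        write_fastq(fastq, libdir / "reads.fastq")
        write_mapped_table(mapped, libdir / "mapped.tsv")
        write_truth_table(frags, libdir / "truth.tsv")
        write_config(sim, libdir / "sim_config.txt")

        # QC
        policy = QcPolicy(seed=sim.seed)
        kept_q, _ = filter_by_quality(mapped, policy)
        kept, _ = filter_contaminants(kept_q, [], policy)
        report = qc_report(len(mapped), len(kept_q), len(kept))
        (libdir / "qc.json").write_text(json.dumps(report, indent=2))

        # Pile-ups
        table = group_pileups(kept)
        curve = ratio_curve(table, k_max=k_max)
        curve.to_frame().to_csv(libdir / "pileup_curve.tsv", sep="\t", index=False)

        lib_summary = {
            "mode": lib["mode"],
            "qc": report,
            "redundancy": redundancy(table),
            "ratio_k2": float(curve.ratio[1]) if k_max >= 2 else None,
        }

        # Profiles, controls, signature per end
        enr = {}
        for end_type, read_len in (("5p", 50), ("3p", 35)):
            end_reads = [r for r in kept if r.end_type == end_type]
            sample = subsample_reads(end_reads, n=n_logo, seed=sim.seed)
            profile = profile_reads(sample)
            profile.to_frame().to_csv(libdir / f"profile_{end_type}.tsv", sep="\t")
            cc = ControlConfig(
                window_len=int(ccfg.get("window_len", 200)),
                read_len=read_len,
                n_replicates=int(ccfg.get("n_replicates", 50)),
                seed=sim.seed,
            )
            windows = predict_cdna_windows(sample, transcripts, cc)
            envelope = control_entropy_envelope(sample, transcripts, cc, windows=windows)
            envelope.to_frame().to_csv(libdir / f"control_{end_type}.tsv", sep="\t")
            enr[end_type] = enrichment(profile, envelope)
            enr[end_type].to_csv(libdir / f"enrichment_{end_type}.tsv", sep="\t")

        sig = cutter_signature(enr["5p"], enr["3p"], floor=float(scfg.get("floor", DEFAULT_FLOOR)))
        sig_payload = sig.to_dict() | {"n_reads_5p": len(sample), "library": name}
        (libdir / "signature.json").write_text(json.dumps(sig_payload, indent=2))
        lib_summary["signature"] = sig.to_dict()
        manifest["libraries"][name] = lib_summary

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
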