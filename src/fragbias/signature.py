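"""Observed-versus-control enrichment and the enzyme cutter-signature
summary.

Enrichment compares an observed positional profile with its resampling-null
envelope: per-base frequency z-scores, a per-position entropy z-score, and
the *information excess* (control mean entropy minus observed entropy, in
bits — positive where the library is more biased than its composition
null). The cutter signature reads the dominant bases at the first two
positions of the 5'-read and 3'-read enrichment tables; the 3' dinucleotide
is reverse-complemented so the signature is reported in fragment sense
(5'-XX ... YY-3'). Positions whose information excess does not clear a
configurable floor are reported as N.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._util import BASES, revcomp
from .control import ControlEnvelope
from .profiles import PositionProfile

#: default minimum information excess (bits) for a signature base call
DEFAULT_FLOOR = 0.15


@dataclasses.dataclass
class CutterSignature:
    """Dinucleotide cutter signature with per-position confidence (bits)."""

    motif5: str
    motif3_rc: str
    confidence5: list[float]
    confidence3: list[float]
    floor: float

    @property
    def detected(self) -> bool:
        return self.motif5 != "NN" or self.motif3_rc != "NN"

    def to_dict(self) -> dict:
        return {
            "motif5": self.motif5,
            "motif3_rc": self.motif3_rc,
            "confidence5_bits": [round(c, 4) for c in self.confidence5],
            "confidence3_bits": [round(c, 4) for c in self.confidence3],
            "floor_bits": self.floor,
        }


def enrichment(observed: PositionProfile, control: ControlEnvelope) -> pd.DataFrame:
    """Per-position comparison of an observed profile with its control.

    Columns: observed and control-mean base frequencies, per-base z-scores
    ((obs - mean) / sd, NaN where the control sd is 0), observed and control
    entropy, the entropy z-score, and the information excess
    (control H mean - observed H). Window lengths must match.
    """
    if observed.window_len != control.read_len:
        raise ValueError(
            f"window mismatch: observed {observed.window_len}, control {control.read_len}"
        )
    out = pd.DataFrame(index=observed.freqs.index.copy())
    for b in BASES:
        obs = observed.freqs[b].to_numpy()
        mean = control.freq_mean[b].to_numpy()
        sd = control.freq_sd[b].to_numpy()
        out[f"obs_P_{b}"] = obs
        out[f"ctl_P_{b}"] = mean
        out[f"z_{b}"] = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    out["obs_H"] = observed.entropy
    out["ctl_H_mean"] = control.entropy_mean
    out["ctl_H_sd"] = control.entropy_sd
    sd = control.entropy_sd
    out["z_H"] = np.where(
        sd > 0, (observed.entropy - control.entropy_mean) / np.where(sd > 0, sd, 1.0), np.nan
    )
    out["info_excess"] = control.entropy_mean - observed.entropy
    return out


def _call_end(table: pd.DataFrame, floor: float, n_positions: int = 2) -> tuple[str, list[float]]:
    bases = []
    confidence = []
    for pos in range(n_positions):
        row = table.iloc[pos]
        excess = float(row["info_excess"])
        confidence.append(excess)
        if excess > floor:
            obs = {b: row[f"obs_P_{b}"] for b in BASES}
            bases.append(max(obs, key=obs.get))
        else:
            bases.append("N")
    return "".join(bases), confidence


def cutter_signature(
    profile5: pd.DataFrame,
    profile3: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
) -> CutterSignature:
    """Call the fragment-end cutter signature from 5' and 3' enrichment
    tables.

    ``motif5`` is the dominant base at 5'-read positions 1-2. The 3' table
    must be computed in sequenced read orientation (read position 1 = the
    fragment's 3'-terminal base); its positions 1-2 dinucleotide is
    reverse-complemented into ``motif3_rc`` so both motifs read in fragment
    sense: 5'-motif5 ... motif3_rc-3'. Positions below the information-
    excess floor are N.
    """
    motif5, conf5 = _call_end(profile5, floor)
    motif3_read, conf3 = _call_end(profile3, floor)
    return CutterSignature(
        motif5=motif5,
        motif3_rc=revcomp(motif3_read),
        confidence5=conf5,
        confidence3=conf3,
        floor=floor,
    )
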