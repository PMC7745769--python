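"""Infinium type I color-channel logic, β-values and intensities.

A type I probe pair is read in one declared color channel, fixed by the
nucleotide incorporated during single-base extension (A/T are labeled in
one dye, C/G in the other).  When a probe hybridizes off-target, the
template base preceding the off-target CpG position may differ from the
intended one; extension then incorporates a differently labeled nucleotide
and the off-target signal lands in the *out-of-band* (OOB) channel — the
channel the probe is not declared to use.  Predicting whether such a
channel switch occurs tells you where to look for off-target signal.

β-values are computed as ``M / (M + U + 100)`` from methylated (M) and
unmethylated (U) intensities; the same formula is applied to in-band and
OOB intensities.  The +100 offset regularizes low-intensity probes and
keeps β in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .manifest import ProbeRecord
from .mapping import MatchResult
from .seq_model import complement

__all__ = [
    "BETA_OFFSET",
    "ChannelPrediction",
    "IntensitySet",
    "BetaMatrix",
    "channel_of_base",
    "predict_oob_switch",
    "beta_values",
    "total_intensity",
    "read_intensity_matrix",
    "write_intensity_matrix",
]

#: Regularizing offset in the β denominator; fixed, not configurable, so
#: outputs stay comparable across datasets.
BETA_OFFSET = 100.0

# Dye chemistry convention: extension with A or T is read in the Red
# channel, C or G in the Green channel.  Only the discordance between
# declared and off-target channel matters downstream, and that is invariant
# to a global Red/Grn swap.
_BASE_CHANNEL = {"A": "Red", "T": "Red", "C": "Grn", "G": "Grn"}


class NotApplicableError(TypeError):
    """Raised for operations that exist only for type I probes."""


@dataclass(frozen=True)
class ChannelPrediction:
    probe_id: str
    declared_channel: str
    offtarget_extension_base: Optional[str]
    offtarget_channel: Optional[str]
    oob_switch: Optional[bool]
    status: str = "ok"  # ok | undefined_boundary | ambiguous_base


@dataclass
class IntensitySet:
    """Paired M/U intensity matrices (probes x samples) for one band."""

    M: pd.DataFrame
    U: pd.DataFrame
    band: str  # IN_BAND | OOB

    def __post_init__(self) -> None:
        if self.band not in ("IN_BAND", "OOB"):
            raise ValueError(f"band must be IN_BAND or OOB, got {self.band!r}")
        if not (self.M.index.equals(self.U.index) and self.M.columns.equals(self.U.columns)):
            raise ValueError("M and U must share probe and sample ordering")
        for name, df in (("M", self.M), ("U", self.U)):
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative intensities in {name}")


@dataclass
class BetaMatrix:
    beta: pd.DataFrame
    band: str


def channel_of_base(extension_base: str) -> str:
    """Color channel in which a single-base extension with this nucleotide
    is read. A/T -> Red, C/G -> Grn."""
    try:
        return _BASE_CHANNEL[extension_base]
    except KeyError:
        raise ValueError(f"invalid extension base {extension_base!r}") from None


def predict_oob_switch(
    record: ProbeRecord, strand: str, match: MatchResult
) -> ChannelPrediction:
    """Predict whether off-target hybridization switches the color channel.

    The probe's 3' end aligns at ``match.strand_end_pos``; the template
    base for extension is the strand base immediately past it, and the
    incorporated (extension) base is its complement.  At the strand
    boundary no extension context exists and the prediction is undefined.
    A Y context (template C or T, hence extension G or A) spans both
    channels and is reported as ambiguous.
    """
    if record.infinium_type != "I":
        raise NotApplicableError(
            f"{record.probe_id}: OOB channel predictions exist only for type I probes"
        )
    if match.strand_end_pos is None or match.inexact_width < 1:
        raise ValueError(f"{record.probe_id}: no match to derive extension context from")
    nxt = match.strand_end_pos + 1
    if nxt >= len(strand):
        return ChannelPrediction(
            record.probe_id, record.declared_channel, None, None, None,
            status="undefined_boundary",
        )
    template = strand[nxt]
    if template in ("Y", "R"):
        return ChannelPrediction(
            record.probe_id, record.declared_channel, None, None, None,
            status="ambiguous_base",
        )
    ext = complement(template)
    ch = channel_of_base(ext)
    return ChannelPrediction(
        probe_id=record.probe_id,
        declared_channel=record.declared_channel,
        offtarget_extension_base=ext,
        offtarget_channel=ch,
        oob_switch=(ch != record.declared_channel),
    )


def beta_values(intensities: IntensitySet) -> BetaMatrix:
    """Elementwise ``M / (M + U + 100)``; NaN intensities propagate."""
    m = intensities.M.to_numpy(dtype=float)
    u = intensities.U.to_numpy(dtype=float)
    beta = m / (m + u + BETA_OFFSET)
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=intensities.M.index, columns=intensities.M.columns),
        band=intensities.band,
    )


def total_intensity(intensities: IntensitySet) -> pd.DataFrame:
    """Elementwise total signal M + U."""
    return intensities.M + intensities.U


def read_intensity_matrix(path) -> pd.DataFrame:
    """TSV/CSV matrix with probe ids as rows and sample ids as columns."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def write_intensity_matrix(df: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=True, float_format="%.4f")
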