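"""Probe manifests and expansion into concrete hybridizing sequences.

Infinium type I assays use two beads per CpG (an unmethylated-allele and a
methylated-allele probe) read in a single declared color channel; type II
assays use one bead whose sequence carries a degenerate R (= A or G) base at
each CpG interrogated within the probe body, and read methylation as a
two-channel ratio.  For off-target scanning every concrete sequence that can
sit on the array matters, so a type I record expands to its U and M
sequences and a type II record with ``r`` R bases expands to all ``2**r``
resolutions.

Two on-disk dialects are supported: a simple one-header TSV (the canonical
fixture format, columns = :class:`ProbeRecord` fields) and the Illumina
manifest CSV with its ``[Heading]/[Assay]/[Controls]`` section structure.
File coordinates are 1-based; they are kept 1-based on the record (as in the
vendor annotation) and converted to 0-based only inside positional
computations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "ProbeRecord",
    "ProbeSequenceVariant",
    "ManifestError",
    "RejectedRow",
    "read_manifest",
    "write_manifest_tsv",
    "expand_probe_sequences",
    "expand_all",
    "variants_to_frame",
]

PROBE_LEN = 50

_SIMPLE_COLUMNS = [
    "probe_id",
    "infinium_type",
    "seq_A",
    "seq_B",
    "declared_channel",
    "chrom",
    "pos",
    "array",
]


class ManifestError(ValueError):
    """Unrecoverable manifest format problem (bad header, duplicate ids)."""


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    probe_id: str
    reason: str


@dataclass(frozen=True)
class ProbeRecord:
    """One manifest row, validated against the Infinium design invariants."""

    probe_id: str
    infinium_type: str  # "I" or "II"
    seq_A: str  # type I unmethylated / type II single sequence (may contain R)
    seq_B: Optional[str]  # type I methylated sequence
    declared_channel: str  # "Red", "Grn" or "Both"
    chrom: str = "NA"
    pos: int = 0
    array: str = "custom"

    def validate(self) -> Optional[str]:
        """Return a human-readable reason if the record violates an invariant."""
        if self.infinium_type not in ("I", "II"):
            return f"unknown Infinium type {self.infinium_type!r}"
        if len(self.seq_A) != PROBE_LEN:
            return f"seq_A length {len(self.seq_A)} != {PROBE_LEN}"
        if self.infinium_type == "I":
            if self.seq_B is None:
                return "missing methylated sequence"
            if len(self.seq_B) != PROBE_LEN:
                return f"seq_B length {len(self.seq_B)} != {PROBE_LEN}"
            if self.declared_channel not in ("Red", "Grn"):
                return f"type I channel must be Red/Grn, got {self.declared_channel!r}"
            for label, seq in (("seq_A", self.seq_A), ("seq_B", self.seq_B)):
                bad = set(seq) - set("ACGT")
                if bad:
                    return f"type I {label} has non-ACGT symbols {sorted(bad)}"
        else:
            if self.seq_B is not None:
                return "type II record must not carry a second sequence"
            if self.declared_channel != "Both":
                return f"type II channel must be Both, got {self.declared_channel!r}"
            bad = set(self.seq_A) - set("ACGTR")
            if bad:
                return f"type II sequence has symbols {sorted(bad)} outside ACGTR"
        return None

    @property
    def n_variants(self) -> int:
        if self.infinium_type == "I":
            return 2
        return 2 ** self.seq_A.count("R")


@dataclass(frozen=True)
class ProbeSequenceVariant:
    """A concrete 50-nt sequence a probe record can present on the array."""

    probe_id: str
    variant_index: int
    sequence: str
    allele: str  # "U", "M" for type I; "NA" for type II
    infinium_type: str


def read_manifest(
    path, dialect: Optional[str] = None
) -> Tuple[List[ProbeRecord], List[RejectedRow]]:
    """Read a manifest; returns (valid records, rejected rows).

    ``dialect`` is ``"simple_tsv"`` or ``"illumina_csv"``; when None it is
    sniffed (an Illumina file opens with a ``[Heading]`` or ``[Assay]``
    section marker).  Rows violating the design invariants go to the rejects
    list with a reason; structural problems raise :class:`ManifestError`.
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        dialect = "illumina_csv" if text.lstrip().startswith("[") else "simple_tsv"
    if dialect == "simple_tsv":
        rows = _parse_simple_tsv(text)
    elif dialect == "illumina_csv":
        rows = _parse_illumina_csv(text)
    else:
        raise ManifestError(f"unknown manifest dialect {dialect!r}")

    records: List[ProbeRecord] = []
    rejects: List[RejectedRow] = []
    seen = set()
    for row_number, rec in rows:
        if rec.probe_id in seen:
            raise ManifestError(f"duplicate probe_id {rec.probe_id!r} at row {row_number}")
        seen.add(rec.probe_id)
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            rejects.append(RejectedRow(row_number, rec.probe_id, reason))
    return records, rejects


def _parse_simple_tsv(text: str) -> Iterable[Tuple[int, ProbeRecord]]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None or list(reader.fieldnames) != _SIMPLE_COLUMNS:
        raise ManifestError(
            f"simple TSV header must be {_SIMPLE_COLUMNS}, got {reader.fieldnames}"
        )
    out = []
    for i, row in enumerate(reader, start=2):
        seq_b = row["seq_B"] or None
        if seq_b in ("", "NA", "."):
            seq_b = None
        out.append(
            (
                i,
                ProbeRecord(
                    probe_id=row["probe_id"],
                    infinium_type=row["infinium_type"],
                    seq_A=row["seq_A"].upper(),
                    seq_B=seq_b.upper() if seq_b else None,
                    declared_channel=row["declared_channel"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    array=row["array"],
                ),
            )
        )
    return out


def _parse_illumina_csv(text: str) -> Iterable[Tuple[int, ProbeRecord]]:
    """Parse the vendor CSV: sections in ``[...]`` brackets; probe rows live
    under ``[Assay]`` until the ``[Controls]`` section."""
    lines = text.splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.strip().strip('",').lower() == "[assay]"
        )
    except StopIteration:
        raise ManifestError("no [Assay] section in Illumina manifest") from None
    body = []
    for ln in lines[start + 1 :]:
        if ln.strip().strip('",').lower().startswith("[controls]"):
            break
        body.append(ln)
    if not body:
        raise ManifestError("[Assay] section is empty")
    df = pd.read_csv(io.StringIO("\n".join(body)), dtype=str, keep_default_na=False)
    required = {"IlmnID", "AlleleA_ProbeSeq", "Infinium_Design_Type", "Color_Channel"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"Illumina manifest missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=start + 3):
        dtype = "I" if row.Infinium_Design_Type == "I" else "II"
        seq_b = getattr(row, "AlleleB_ProbeSeq", "") or None
        channel = row.Color_Channel if dtype == "I" else "Both"
        out.append(
            (
                i,
                ProbeRecord(
                    probe_id=row.IlmnID,
                    infinium_type=dtype,
                    seq_A=row.AlleleA_ProbeSeq.upper(),
                    seq_B=seq_b.upper() if seq_b else None,
                    declared_channel=channel,
                    chrom=str(getattr(row, "CHR", "NA") or "NA"),
                    pos=int(getattr(row, "MAPINFO", 0) or 0),
                    array=str(getattr(row, "array", "custom") or "custom"),
                ),
            )
        )
    return out


def write_manifest_tsv(records: Sequence[ProbeRecord], path) -> None:
    """Write records in the simple TSV dialect (byte-exact round-trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SIMPLE_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.probe_id,
                    r.infinium_type,
                    r.seq_A,
                    r.seq_B or "",
                    r.declared_channel,
                    r.chrom,
                    r.pos,
                    r.array,
                ]
            )


def expand_probe_sequences(record: ProbeRecord) -> List[ProbeSequenceVariant]:
    """Expand one record into its concrete hybridizable sequences.

    Type I: two variants, allele U (seq_A) then M (seq_B).  Type II with
    ``r`` R bases: ``2**r`` variants; the leftmost R varies fastest, A
    before G, giving a reproducible variant_index.
    """
    reason = record.validate()
    if reason is not None:
        raise ManifestError(f"{record.probe_id}: {reason}")
    if record.infinium_type == "I":
        return [
            ProbeSequenceVariant(record.probe_id, 0, record.seq_A, "U", "I"),
            ProbeSequenceVariant(record.probe_id, 1, record.seq_B, "M", "I"),
        ]
    positions = [i for i, b in enumerate(record.seq_A) if b == "R"]
    variants = []
    seq = list(record.seq_A)
    # leftmost R varies fastest: enumerate the rightmost position in the
    # outer product slot so index parity follows the leftmost base.
    for idx, combo in enumerate(product("AG", repeat=len(positions))):
        for pos, base in zip(positions, reversed(combo)):
            seq[pos] = base
        variants.append(
            ProbeSequenceVariant(record.probe_id, idx, "".join(seq), "NA", "II")
        )
    return variants


def expand_all(records: Sequence[ProbeRecord]) -> List[ProbeSequenceVariant]:
    """Expand every record; deterministic (probe_id, variant_index) order."""
    variants: List[ProbeSequenceVariant] = []
    for rec in sorted(records, key=lambda r: r.probe_id):
        variants.extend(expand_probe_sequences(rec))
    return variants


def variants_to_frame(variants: Sequence[ProbeSequenceVariant]) -> pd.DataFrame:
    """Variant table as a DataFrame (TSV-writable)."""
    return pd.DataFrame(
        {
            "probe_id": [v.probe_id for v in variants],
            "variant_index": [v.variant_index for v in variants],
            "allele": [v.allele for v in variants],
            "infinium_type": [v.infinium_type for v in variants],
            "sequence": [v.sequence for v in variants],
        }
    )
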