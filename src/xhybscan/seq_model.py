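"""Target sequences and their in-silico bisulfite-converted strands.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T),
while 5-methyl-cytosine is protected.  On an array, only CpG cytosines are
potentially methylated, so an in-silico conversion of a target sequence has
three useful scenarios: the target is fully methylated (CpG C's stay C),
fully unmethylated (CpG C's become T), or of unknown/mixed state (CpG C's
become the IUPAC ambiguity code Y = C or T).  Non-CpG cytosines always
convert to T.

A double-stranded target yields four single strands after conversion:
the converted forward strand, the converted reverse strand (conversion of
the reverse complement of the target), and the complements of those two.
Probes can hybridize to any of the four, so the matching engine scans all
of them.  All four strands are emitted 5'->3' so a single left-to-right
substring scanner handles every case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MethylationAssumption",
    "TargetSequence",
    "ConvertedStrandSet",
    "STRAND_IDS",
    "build_repeat",
    "bisulfite_convert",
    "reverse_complement",
    "complement",
    "build_strand_set",
    "read_targets_fasta",
    "write_strand_set_fasta",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTYR", "TGCARY")

#: Fixed strand ordering used for deterministic provenance tie-breaks.
STRAND_IDS = ("FWD", "REV", "FWD_COMPLEMENT", "REV_COMPLEMENT")


class MethylationAssumption(str, Enum):
    """Assumed methylation state of every CpG in the target."""

    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"
    AMBIGUOUS = "AMBIGUOUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TargetSequence:
    """An unconverted DNA target (repeat concatemer or FASTA record)."""

    name: str
    bases: str
    source: str = "fasta"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("target sequence must be non-empty")
        bad = set(self.bases) - _DNA
        if bad:
            raise ValueError(
                f"target {self.name!r} contains non-ACGT symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ConvertedStrandSet:
    """The four bisulfite-converted strands of one target."""

    target_name: str
    assumption: MethylationAssumption
    strands: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.strands) != STRAND_IDS:
            raise ValueError(f"expected strands {STRAND_IDS}, got {tuple(self.strands)}")
        lengths = {len(s) for s in self.strands.values()}
        if len(lengths) != 1:
            raise ValueError("all four strands must have equal length")
        if self.assumption is not MethylationAssumption.AMBIGUOUS:
            for sid, seq in self.strands.items():
                if set(seq) & {"Y", "R"}:
                    raise ValueError(
                        f"degenerate bases in strand {sid} without AMBIGUOUS assumption"
                    )

    def __iter__(self):
        return iter(self.strands.items())


def build_repeat(unit: str, n_copies: int) -> TargetSequence:
    """Concatenate ``n_copies`` of ``unit`` into a linear target.

    A short fixed number of copies (e.g. 10 copies of GGGGCC = 60 bp) is
    enough for any 50-nt probe to match in full; carriers of a repeat
    expansion have far more copies, but extra copies add no new 50-mers.
    """
    unit = unit.upper()
    if not unit or set(unit) - _DNA:
        raise ValueError(f"repeat unit must be non-empty ACGT, got {unit!r}")
    if n_copies < 1:
        raise ValueError(f"n_copies must be >= 1, got {n_copies}")
    return TargetSequence(
        name=f"{unit}x{n_copies}", bases=unit * n_copies, source=f"repeat-unit×{n_copies}"
    )


def complement(seq: str) -> str:
    """Base-wise complement over {A,C,G,T,Y,R}; Y (C/T) <-> R (G/A)."""
    _check_alphabet(seq, "ACGTYR")
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,Y,R}, emitted 5'->3'."""
    return complement(seq)[::-1]


def bisulfite_convert(seq: str, assumption: MethylationAssumption) -> str:
    """In-silico bisulfite conversion of one strand.

    Every C not followed by G converts to T.  A C that begins a CpG becomes
    C (METHYLATED), T (UNMETHYLATED) or Y (AMBIGUOUS).  A terminal C (no
    following base) has no CpG partner on a linear sequence and converts to
    T.  Length is preserved.
    """
    _check_alphabet(seq, "ACGT")
    if assumption is MethylationAssumption.METHYLATED:
        cpg = "C"
    elif assumption is MethylationAssumption.UNMETHYLATED:
        cpg = "T"
    else:
        cpg = "Y"
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b != "C":
            out.append(b)
        elif i + 1 < n and seq[i + 1] == "G":
            out.append(cpg)
        else:
            out.append("T")
    return "".join(out)


def build_strand_set(
    target: TargetSequence, assumption: MethylationAssumption
) -> ConvertedStrandSet:
    """Convert both strands of ``target`` and add their complements.

    FWD converts the forward strand; REV converts the reverse complement of
    the target (each read 5'->3' before conversion, so CpG context is
    evaluated on the strand being converted).  FWD_COMPLEMENT and
    REV_COMPLEMENT are the reverse complements of FWD and REV, re-emitted
    5'->3' so all four strands share one scanning convention.
    """
    fwd = bisulfite_convert(target.bases, assumption)
    rev = bisulfite_convert(reverse_complement(target.bases), assumption)
    strands = {
        "FWD": fwd,
        "REV": rev,
        "FWD_COMPLEMENT": reverse_complement(fwd),
        "REV_COMPLEMENT": reverse_complement(rev),
    }
    return ConvertedStrandSet(target_name=target.name, assumption=assumption, strands=strands)


def read_targets_fasta(path) -> list[TargetSequence]:
    """Read arbitrary targets from FASTA; sequences are uppercased on ingest."""
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        targets.append(TargetSequence(name=rec.id, bases=str(rec.seq).upper(), source="fasta"))
    if not targets:
        raise ValueError(f"no FASTA records in {path}")
    return targets


def write_strand_set_fasta(strand_set: ConvertedStrandSet, handle_or_path) -> None:
    """Write the four converted strands as a 4-record FASTA."""
    records = [
        SeqRecord(
            Seq(seq),
            id=sid,
            description=f"{strand_set.target_name} {strand_set.assumption.value}",
        )
        for sid, seq in strand_set
    ]
    SeqIO.write(records, _as_handle(handle_or_path), "fasta")


def _as_handle(handle_or_path):
    if hasattr(handle_or_path, "write"):
        return handle_or_path
    return str(handle_or_path)


def _check_alphabet(seq: str, allowed: str) -> None:
    bad = set(seq) - set(allowed)
    if bad:
        raise ValueError(f"invalid symbols {sorted(bad)}; allowed alphabet is {allowed}")
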