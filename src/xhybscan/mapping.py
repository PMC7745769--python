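"""3'-anchored exact and single-edit probe-to-target matching.

Infinium probes prime a single-base extension at their 3' end, so
off-target hybridization is governed by how much of the probe's 3'
subsequence anneals to the off-target sequence.  For each probe sequence
the engine reports the maximal width ``w`` (in probe bases, 1..50) such
that the length-``w`` 3' suffix of the probe occurs in a converted target
strand — exactly, and allowing at most one edit (substitution or
single-base insertion/deletion).  Edits close to the 3' terminus prevent
extension, so an edit is only admitted strictly more than ``clearance``
bases (default 5) from the 3' end.

Conventions
-----------
* The 3'-terminal probe base has offset 1; "edit > 5 bp from the 3' end"
  therefore means edit offset >= 6.
* The ambiguity codes on a converted strand match degenerately (Y = C/T,
  R = A/G on complement strands); a probe base aligned to a degenerate
  strand base can never be repaired by the single edit.
* Indels must be internal to the aligned window: at least one matched probe
  base on the 5' side of the edit.  An edge indel is equivalent to a
  shorter exact match and never counts as the edit.
* Inexact width counts probe bases participating in the alignment, so
  insertion/deletion widths remain comparable to exact widths.

The per-(probe, strand) kernel is vectorized with numpy: every alignment of
the probe's 3' end against every strand position is scored in one sliding-
window comparison, and trailing-match runs give all suffix widths at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .manifest import ProbeSequenceVariant
from .seq_model import STRAND_IDS, ConvertedStrandSet, MethylationAssumption

__all__ = [
    "MatchOptions",
    "Edit",
    "MatchResult",
    "MatchTable",
    "FlagSet",
    "max_3prime_exact_width",
    "max_3prime_inexact_width",
    "match_variant",
    "map_probes",
    "flag_probes",
]

# base codes: A C G T Y R wildcard pad.  Y (C/T) appears on converted
# strands under the AMBIGUOUS assumption; their complement strands carry
# R (A/G).
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "Y": 4, "R": 5, "?": 6}
_PAD = 7
_DEGENERATE = (4, 5)

# MATCH[probe_code, strand_code]; probe rows use ACGT + wildcard.
_MATCH = np.zeros((8, 8), dtype=bool)
for _b in "ACGT":
    _MATCH[_CODE[_b], _CODE[_b]] = True
_MATCH[_CODE["C"], _CODE["Y"]] = True
_MATCH[_CODE["T"], _CODE["Y"]] = True
_MATCH[_CODE["A"], _CODE["R"]] = True
_MATCH[_CODE["G"], _CODE["R"]] = True
_MATCH[_CODE["?"], :6] = True  # wildcard matches any real strand base, not pad

_ASSUMPTION_ORDER = {
    MethylationAssumption.METHYLATED: 0,
    MethylationAssumption.UNMETHYLATED: 1,
    MethylationAssumption.AMBIGUOUS: 2,
}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid symbol {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class MatchOptions:
    """Scan parameters.

    ``three_prime_clearance`` is the number of 3'-terminal probe bases an
    edit must stay clear of (edit offset must exceed it).  ``max_edits=0``
    disables inexact matching; 1 allows the single edit.  Setting
    ``three_prime_clearance=0`` is the relaxed mode in which the edit may
    sit anywhere in the probe.
    """

    min_width: int = 1
    max_width: int = 50
    max_edits: int = 1
    three_prime_clearance: int = 5
    assumptions: Tuple[MethylationAssumption, ...] = (
        MethylationAssumption.METHYLATED,
        MethylationAssumption.UNMETHYLATED,
        MethylationAssumption.AMBIGUOUS,
    )

    def __post_init__(self) -> None:
        if not (1 <= self.min_width <= self.max_width <= 50):
            raise ValueError("require 1 <= min_width <= max_width <= 50")
        if self.max_edits not in (0, 1):
            raise ValueError("max_edits must be 0 or 1")
        if self.three_prime_clearance < 0:
            raise ValueError("clearance must be >= 0")


@dataclass(frozen=True)
class Edit:
    type: str  # substitution | insertion | deletion
    probe_offset_from_3prime: int


@dataclass(frozen=True)
class MatchResult:
    probe_id: str
    variant_index: int
    strand_id: str
    assumption: MethylationAssumption
    exact_width: int
    inexact_width: int
    edit: Optional[Edit] = None
    # 0-based strand position of the probe's 3'-aligned terminal base, for
    # the best inexact match; used by the channel module to find the
    # single-base-extension context.
    strand_end_pos: Optional[int] = None


@dataclass
class MatchTable:
    """Per-probe maxima over variants x strands x assumptions."""

    frame: pd.DataFrame  # indexed by probe_id

    COLUMNS = (
        "exact_width",
        "inexact_width",
        "strand",
        "assumption",
        "allele",
        "variant_index",
        "edit_type",
        "edit_offset",
        "strand_end_pos",
    )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=True, index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "MatchTable":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(frame=df)


@dataclass(frozen=True)
class FlagSet:
    threshold_bp: int
    flagged_probe_ids: frozenset

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.flagged_probe_ids


# ---------------------------------------------------------------------------
# kernels


def _alignment_runs(probe: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """Boolean alignment matrix reduced to per-alignment trailing runs.

    Row ``j`` aligns the probe's 3'-terminal base with strand position
    ``j``; entry ``k`` (0-based) is whether the probe base at 3'-offset
    ``k+1`` matches the strand.  Returns the matrix in 3'-first order,
    shape (len(strand), len(probe)).
    """
    n = len(probe)
    padded = np.concatenate([np.full(n - 1, _PAD, dtype=np.int8), strand])
    windows = sliding_window_view(padded, n)  # (L, n), last col = strand[j]
    B = _MATCH[probe[None, :], windows]
    return B[:, ::-1]  # column k = offset k+1 from the 3' end


def _trailing_runs(rev: np.ndarray) -> np.ndarray:
    """First-False index per row of a 3'-first boolean matrix."""
    n = rev.shape[1]
    allm = rev.all(axis=1)
    runs = np.where(allm, n, rev.argmin(axis=1))
    return runs


def max_3prime_exact_width(probe_seq: str, strand: str, max_width: int = 50) -> int:
    """Largest w such that the length-w 3' suffix of the probe occurs in
    the strand (Y matching C/T); 0 if even width 1 fails."""
    if not strand:
        raise ValueError("strand must be non-empty")
    rev = _alignment_runs(_encode(probe_seq), _encode(strand))
    w = int(_trailing_runs(rev).max(initial=0))
    return min(w, max_width)


def max_3prime_inexact_width(
    probe_seq: str, strand: str, options: MatchOptions = MatchOptions()
) -> Tuple[int, Optional[Edit]]:
    """Maximal 3' suffix width allowing at most one admissible edit.

    Returns ``(width, edit)``; ``edit`` is None when no edit extends the
    exact width (including when the best inexact alignment equals the
    exact one).
    """
    _, width, edit, _ = _scan(_encode(probe_seq), _encode(strand), options)
    return width, edit


def _scan(
    probe: np.ndarray, strand: np.ndarray, options: MatchOptions
) -> Tuple[int, int, Optional[Edit], Optional[int]]:
    """Full scan; returns (exact_width, inexact_width, edit, strand_end_pos)."""
    if strand.size == 0:
        raise ValueError("strand must be non-empty")
    n = len(probe)
    cap = min(options.max_width, n)
    clearance = options.three_prime_clearance

    rev = _alignment_runs(probe, strand)
    runs = _trailing_runs(rev)
    exact = min(int(runs.max(initial=0)), cap)
    j_exact = int(np.argmax(runs))
    best = (exact, None, j_exact if exact > 0 else None)
    if options.max_edits == 0 or exact >= cap:
        return (exact, *best)

    # --- substitution: extend through the first mismatch when admissible
    L = len(strand)
    j = np.arange(L)
    k0 = runs  # 0-based offset of first mismatch (= current run length)
    has_mm = k0 < n
    strand_pos = j - k0  # strand position under the mismatch
    on_strand = has_mm & (strand_pos >= 0)
    not_degen = np.zeros(L, dtype=bool)
    not_degen[on_strand] = ~np.isin(strand[strand_pos[on_strand]], _DEGENERATE)
    admissible = on_strand & not_degen & (k0 >= clearance)
    if admissible.any():
        rev2 = rev.copy()
        rows = np.where(admissible)[0]
        rev2[rows, k0[rows]] = True
        runs2 = _trailing_runs(rev2)
        runs2 = np.where(admissible, runs2, 0)
        w = int(runs2.max(initial=0))
        if min(w, cap) > best[0]:
            jj = int(np.argmax(runs2))
            best = (
                min(w, cap),
                Edit("substitution", int(k0[jj]) + 1),
                jj,
            )

    # --- indels, pruned: all bases 3'-ward of the edit must match exactly,
    # so the edit offset cannot exceed exact_width + 1.
    d_lo = clearance + 1
    for d in range(d_lo, min(exact + 1, n - 1) + 1):
        # deletion of the probe base at offset d: probe loses one base
        del_probe = np.delete(probe, n - d)
        rev_d = _alignment_runs(del_probe, strand)
        runs_d = _trailing_runs(rev_d)
        valid = runs_d >= d  # must extend past the deletion point
        if valid.any():
            w = int(np.where(valid, runs_d, 0).max()) + 1
            if min(w, cap) > best[0]:
                jj = int(np.argmax(np.where(valid, runs_d, 0)))
                best = (min(w, cap), Edit("deletion", d), jj)
    for d in range(d_lo, min(exact, n - 1) + 1):
        # insertion of one strand base between probe offsets d and d+1;
        # modelled as a wildcard probe base at offset d+1
        ins_probe = np.insert(probe, n - d, _CODE["?"])
        rev_i = _alignment_runs(ins_probe, strand)
        runs_i = _trailing_runs(rev_i)
        valid = runs_i >= d + 2  # wildcard plus >= 1 real probe base past it
        if valid.any():
            w = int(np.where(valid, runs_i, 0).max()) - 1
            if min(w, cap) > best[0]:
                jj = int(np.argmax(np.where(valid, runs_i, 0)))
                best = (min(w, cap), Edit("insertion", d), jj)
    # edit only reported when it strictly extends the exact width
    if best[0] <= exact:
        best = (exact, None, j_exact if exact > 0 else None)
    return (exact, *best)


def match_variant(
    variant: ProbeSequenceVariant,
    strand_id: str,
    strand: str,
    assumption: MethylationAssumption,
    options: MatchOptions = MatchOptions(),
) -> MatchResult:
    """Match one concrete probe sequence against one converted strand."""
    if set(variant.sequence) - set("ACGT"):
        raise ValueError(
            f"{variant.probe_id} variant {variant.variant_index} contains degenerate "
            "bases; expand the manifest record first"
        )
    probe = _encode(variant.sequence)
    strand_arr = _encode(strand)
    exact, width, edit, end_pos = _scan(probe, strand_arr, options)
    return MatchResult(
        probe_id=variant.probe_id,
        variant_index=variant.variant_index,
        strand_id=strand_id,
        assumption=assumption,
        exact_width=exact,
        inexact_width=width,
        edit=edit,
        strand_end_pos=end_pos,
    )


def map_probes(
    variants: Sequence[ProbeSequenceVariant],
    strand_sets: Sequence[ConvertedStrandSet],
    options: MatchOptions = MatchOptions(),
) -> MatchTable:
    """Aggregate per-probe maximal widths over variants, strands and
    methylation assumptions, recording argmax provenance.

    Ties are broken by the fixed ordering (strand FWD < REV < FWD_COMPLEMENT
    < REV_COMPLEMENT, assumption METHYLATED < UNMETHYLATED < AMBIGUOUS, then
    variant_index); the widths themselves are order-independent.
    """
    if not variants:
        raise ValueError("no probe variants to map")
    strand_sets = [s for s in strand_sets if s.assumption in options.assumptions]
    if not strand_sets:
        raise ValueError("no strand sets for the requested assumptions")

    variants = sorted(variants, key=lambda v: (v.probe_id, v.variant_index))
    allele = {(v.probe_id, v.variant_index): v.allele for v in variants}
    best: Dict[str, dict] = {}
    best_exact: Dict[str, int] = {}
    for sset in sorted(strand_sets, key=lambda s: _ASSUMPTION_ORDER[s.assumption]):
        for strand_id in STRAND_IDS:
            strand = sset.strands[strand_id]
            for v in variants:
                res = match_variant(v, strand_id, strand, sset.assumption, options)
                best_exact[v.probe_id] = max(
                    best_exact.get(v.probe_id, 0), res.exact_width
                )
                cur = best.get(v.probe_id)
                if cur is None or res.inexact_width > cur["inexact_width"]:
                    best[v.probe_id] = {
                        "inexact_width": res.inexact_width,
                        "strand": strand_id,
                        "assumption": sset.assumption.value,
                        "allele": allele[(v.probe_id, v.variant_index)],
                        "variant_index": v.variant_index,
                        "edit_type": res.edit.type if res.edit else "",
                        "edit_offset": res.edit.probe_offset_from_3prime if res.edit else -1,
                        "strand_end_pos": res.strand_end_pos if res.strand_end_pos is not None else -1,
                    }
    probe_ids = sorted(best)
    frame = pd.DataFrame(
        {
            "exact_width": [best_exact[p] for p in probe_ids],
            **{
                col: [best[p][col] for p in probe_ids]
                for col in (
                    "inexact_width",
                    "strand",
                    "assumption",
                    "allele",
                    "variant_index",
                    "edit_type",
                    "edit_offset",
                    "strand_end_pos",
                )
            },
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return MatchTable(frame=frame)


def flag_probes(table: MatchTable, threshold_bp: int = 14) -> FlagSet:
    """Flag probes whose maximal inexact width reaches the cutoff.

    The default 14 bp is a sensitivity/specificity compromise; the
    threshold is a parameter so cutoff sweeps are one loop away.
    """
    if not (1 <= threshold_bp <= 50):
        raise ValueError(f"threshold must be in [1, 50], got {threshold_bp}")
    flagged = frozenset(
        table.frame.index[table.frame["inexact_width"] >= threshold_bp]
    )
    return FlagSet(threshold_bp=threshold_bp, flagged_probe_ids=flagged)
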