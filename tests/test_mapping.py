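import numpy as np
import pytest
from _oracles import oracle_exact, oracle_inexact

from xhybscan.manifest import ProbeRecord, ProbeSequenceVariant, expand_all
from xhybscan.mapping import (
    MatchOptions,
    flag_probes,
    map_probes,
    match_variant,
    max_3prime_exact_width,
    max_3prime_inexact_width,
)
from xhybscan.seq_model import MethylationAssumption, build_repeat, build_strand_set

M, U, A = (
    MethylationAssumption.METHYLATED,
    MethylationAssumption.UNMETHYLATED,
    MethylationAssumption.AMBIGUOUS,
)

FWD_METH = build_strand_set(build_repeat("GGGGCC", 10), M).strands["FWD"]


def _probe_with_suffix(suffix: str, filler: str = "A") -> str:
    """50-nt probe ending in `suffix`, padded 5' with a non-matching base."""
    return filler * (50 - len(suffix)) + suffix


def _random_instance(rng, strand_alpha="ACGTY"):
    strand = "".join(rng.choice(list(strand_alpha), size=int(rng.integers(5, 100))))
    plen = int(rng.integers(1, 51))
    if rng.random() < 0.5:
        probe = "".join(rng.choice(list("ACGT"), size=plen))
    else:  # seed a strand chunk so long matches occur
        w = int(rng.integers(1, min(plen, len(strand)) + 1))
        s = int(rng.integers(0, len(strand) - w + 1))
        tail = "".join(
            str(rng.choice(["C", "T"])) if b == "Y" else
            str(rng.choice(["A", "G"])) if b == "R" else b
            for b in strand[s : s + w]
        )
        probe = "".join(rng.choice(list("ACGT"), size=plen - w)) + tail
        if rng.random() < 0.5 and plen > 8:
            i = int(rng.integers(0, plen))
            probe = probe[:i] + str(rng.choice(list("ACGT"))) + probe[i + 1 :]
    return probe, strand


class TestExactWidth:
    def test_constructed_18bp_match(self):
        # 18-base 3' suffix copied from the strand; 19th-from-3' base is A,
        # a symbol absent from the methylated forward strand
        probe = _probe_with_suffix(FWD_METH[:18], filler="A")
        assert "A" not in FWD_METH
        assert max_3prime_exact_width(probe, FWD_METH) == 18

    def test_no_match_is_zero(self):
        assert max_3prime_exact_width("A" * 50, "GGTTCC" * 10) == 0

    def test_empty_strand_raises(self):
        with pytest.raises(ValueError):
            max_3prime_exact_width("ACGT", "")

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(300):
            probe, strand = _random_instance(rng)
            assert max_3prime_exact_width(probe, strand) == oracle_exact(probe, strand)


class TestInexactWidth:
    def test_substitution_beyond_clearance_extends(self):
        # corrupt the base at offset 10 from the 3' end: exact collapses to
        # 9, one admissible substitution restores the full 18
        suffix = list(FWD_METH[:18])
        original = suffix[8]  # offset 10 = index 18 - 10
        suffix[8] = {"G": "A", "T": "A", "C": "A"}[original]
        probe = _probe_with_suffix("".join(suffix))
        assert max_3prime_exact_width(probe, FWD_METH) == 9
        width, edit = max_3prime_inexact_width(probe, FWD_METH)
        assert width == 18
        assert edit is not None and edit.type == "substitution"
        assert edit.probe_offset_from_3prime == 10

    def test_edit_within_clearance_disallowed(self):
        suffix = list(FWD_METH[:18])
        suffix[14] = "A"  # offset 4 from the 3' end
        probe = _probe_with_suffix("".join(suffix))
        exact = max_3prime_exact_width(probe, FWD_METH)
        width, edit = max_3prime_inexact_width(probe, FWD_METH)
        assert exact == 3
        assert width == exact and edit is None

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(300):
            probe, strand = _random_instance(rng)
            width, edit = max_3prime_inexact_width(probe, strand)
            assert width == oracle_inexact(probe, strand)
            if edit is not None:
                assert edit.probe_offset_from_3prime > 5

    def test_relaxed_mode_matches_bruteforce(self, rng):
        options = MatchOptions(three_prime_clearance=0)
        for _ in range(150):
            probe, strand = _random_instance(rng)
            width, _ = max_3prime_inexact_width(probe, strand, options)
            assert width == oracle_inexact(probe, strand, clearance=0)

    def test_monotonicity_in_clearance(self, rng):
        for _ in range(100):
            probe, strand = _random_instance(rng)
            widths = [
                max_3prime_inexact_width(
                    probe, strand, MatchOptions(three_prime_clearance=c)
                )[0]
                for c in (0, 5, 10)
            ]
            assert widths == sorted(widths, reverse=True)

    def test_inexact_at_least_exact(self, rng):
        for _ in range(100):
            probe, strand = _random_instance(rng)
            assert (
                max_3prime_inexact_width(probe, strand)[0]
                >= max_3prime_exact_width(probe, strand)
            )


class TestMapProbes:
    @staticmethod
    def _variant(pid, seq, idx=0, allele="NA"):
        return ProbeSequenceVariant(pid, idx, seq, allele, "II")

    def test_allele_provenance(self):
        strand_sets = [build_strand_set(build_repeat("GGGGCC", 10), M)]
        v_m = ProbeSequenceVariant("p1", 1, _probe_with_suffix(FWD_METH[:16]), "M", "I")
        v_u = ProbeSequenceVariant("p1", 0, _probe_with_suffix(FWD_METH[:6]), "U", "I")
        table = map_probes([v_u, v_m], strand_sets, MatchOptions(max_edits=0))
        row = table.frame.loc["p1"]
        assert row["exact_width"] == 16
        assert row["allele"] == "M"
        assert row["assumption"] == "METHYLATED"

    def test_ambiguous_dominates(self, rng):
        target = build_repeat("GGGGCC", 10)
        ssets = {a: build_strand_set(target, a) for a in (M, U, A)}
        for _ in range(50):
            probe, _ = _random_instance(rng, strand_alpha="ACGT")
            probe = probe.ljust(50, "A")[:50]
            v = self._variant("p", probe)
            per_assumption = {
                a: max(
                    match_variant(v, sid, strand, a).inexact_width
                    for sid, strand in ssets[a]
                )
                for a in (M, U, A)
            }
            assert per_assumption[A] >= max(per_assumption[M], per_assumption[U])

    def test_degenerate_variant_rejected(self):
        strand_sets = [build_strand_set(build_repeat("GGGGCC", 10), M)]
        v = self._variant("p", "R" + "A" * 49)
        with pytest.raises(ValueError, match="degenerate"):
            map_probes([v], strand_sets, MatchOptions())

    def test_empty_inputs_raise(self):
        strand_sets = [build_strand_set(build_repeat("GGGGCC", 10), M)]
        with pytest.raises(ValueError):
            map_probes([], strand_sets)
        v = self._variant("p", "A" * 50)
        with pytest.raises(ValueError):
            map_probes([v], [])


class TestFlagProbes:
    def test_threshold_selection(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"inexact_width": [18, 13, 14]},
            index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        )
        from xhybscan.mapping import MatchTable

        flags = flag_probes(MatchTable(frame=frame), 14)
        assert flags.flagged_probe_ids == frozenset({"p1", "p3"})
        assert flag_probes(MatchTable(frame=frame), 1).flagged_probe_ids == frozenset(
            {"p1", "p2", "p3"}
        )
        with pytest.raises(ValueError):
            flag_probes(MatchTable(frame=frame), 0)

    def test_flagged_set_shrinks_with_threshold(self, small_analysis):
        table = small_analysis.match_table
        sizes = [len(flag_probes(table, t).flagged_probe_ids) for t in range(1, 51)]
        assert sizes == sorted(sizes, reverse=True)
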