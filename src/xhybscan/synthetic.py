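"""Synthetic cohorts with known cross-hybridization ground truth.

The generator emulates the situation the toolkit is built to detect: a
cohort in which some samples carry a large tandem-repeat expansion
(carriers, >= 30 copies) and a handful of array probes cross-hybridize to
the bisulfite-converted repeat.  Injected probes receive off-target
intensity proportional to each sample's repeat copy number, routed to the
predicted color channel — in-band when the off-target extension base keeps
the declared channel, out-of-band (OOB) when it switches.  Background
probes are rejection-sampled so that none reaches the flagging cutoff, so
truth labels are exact.

Everything is driven by one integer seed; regenerating with the same
config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .channels import IntensitySet, channel_of_base, predict_oob_switch, write_intensity_matrix
from .manifest import ProbeRecord, expand_probe_sequences, write_manifest_tsv
from .mapping import MatchOptions, MatchTable, map_probes, match_variant
from .seq_model import (
    ConvertedStrandSet,
    MethylationAssumption,
    TargetSequence,
    build_repeat,
    build_strand_set,
    complement,
)

__all__ = ["InjectedSpec", "SyntheticConfig", "SyntheticDataset", "generate_manifest",
           "simulate_intensities", "generate_phenotype", "generate_dataset"]

_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass(frozen=True)
class InjectedSpec:
    """One injected cross-hybridizing probe."""

    match_width: int
    infinium_type: str = "I"
    edits: int = 0
    edit_offset: int = 10
    oob_switch: bool = False
    assumption: MethylationAssumption = MethylationAssumption.METHYLATED

    def __post_init__(self) -> None:
        if not 1 <= self.match_width <= 50:
            raise ValueError(f"match_width must be in [1,50], got {self.match_width}")
        if self.edits not in (0, 1):
            raise ValueError("edits must be 0 or 1")
        if self.oob_switch and self.infinium_type != "I":
            raise ValueError("oob_switch applies to type I probes only")


def _default_injected() -> Tuple[InjectedSpec, ...]:
    """30 injected probes spanning the interesting regimes.

    Widths straddle the 14 bp flagging cutoff (4 sub-threshold), cover
    exact and single-edit matches, both Infinium types, and both channel
    fates for type I.
    """
    inband_I = [InjectedSpec(w) for w in (14, 16, 18, 20, 22, 25, 30, 40)]
    oob_I = [InjectedSpec(w, oob_switch=True) for w in (14, 16, 18, 20, 24, 28, 35, 50)]
    type_II = [InjectedSpec(w, infinium_type="II") for w in (15, 17, 19, 21, 26, 32)]
    edited = [InjectedSpec(w, edits=1, edit_offset=10) for w in (16, 20, 24, 28)]
    sub = [InjectedSpec(w) for w in (9, 10, 11, 12)]
    return tuple(inband_I + oob_I + type_II + edited + sub)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized carrier cohort: 400 samples of which 10%
    carry the expansion (carrier copy numbers in the pathogenic range,
    200-1200 copies; non-carriers 2-10, below the 30-copy carrier
    threshold), 5000 background probes and 30 injected probes.  The
    off-target signal is ``gain * copy_number * weight(match_width)``
    fluorescence units with a logistic width weight centered at the 14 bp
    cutoff.
    """

    seed: int = 0
    n_samples: int = 400
    carrier_fraction: float = 0.1
    n_background_probes: int = 5000
    injected: Tuple[InjectedSpec, ...] = field(default_factory=_default_injected)
    repeat_unit: str = "GGGGCC"
    repeat_copies: int = 10
    carrier_copy_range: Tuple[int, int] = (200, 1200)
    noncarrier_copy_range: Tuple[int, int] = (2, 10)
    baseline_intensity_mean: float = 3000.0
    baseline_intensity_sd: float = 500.0
    noise_sd: float = 100.0
    oob_background_mean: float = 150.0
    oob_background_sd: float = 40.0
    offtarget_gain: float = 5.0
    weight_center_bp: float = 14.0
    weight_scale_bp: float = 2.0
    flag_threshold_bp: int = 14
    n_loci: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must be in (0,1)")
        if self.carrier_copy_range[0] < 30:
            raise ValueError("carrier copy numbers must be >= 30")
        if self.noncarrier_copy_range[1] >= 30:
            raise ValueError("non-carrier copy numbers must be < 30")
        if self.offtarget_gain < 0:
            raise ValueError("offtarget_gain must be >= 0")

    def width_weight(self, width_bp: float) -> float:
        """Logistic ramp encoding rising detectability with match length."""
        return float(1.0 / (1.0 + np.exp(-(width_bp - self.weight_center_bp) / self.weight_scale_bp)))


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    manifest: List[ProbeRecord]
    target: TargetSequence
    strand_sets: List[ConvertedStrandSet]
    inband: IntensitySet
    oob: IntensitySet
    phenotype: pd.DataFrame  # indexed by sample_id
    truth: Dict  # {"probes": {...}, "copy_numbers": {...}}


# ---------------------------------------------------------------------------
# manifest generation


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _background_record(rng: np.random.Generator, idx: int, chrom: str, pos: int) -> ProbeRecord:
    pid = f"bg{idx:06d}"
    if rng.random() < 0.3:  # roughly the 450k type I share
        seq_a = _random_seq(rng, 50)
        seq_b = list(seq_a)
        for j in rng.choice(50, size=3, replace=False):
            seq_b[j] = "C" if seq_a[j] == "T" else "T" if seq_a[j] == "C" else seq_a[j]
        return ProbeRecord(pid, "I", seq_a, "".join(seq_b),
                           str(rng.choice(["Red", "Grn"])), chrom, pos, "custom")
    seq = list(_random_seq(rng, 50))
    for j in rng.choice(49, size=int(rng.integers(0, 4)), replace=False):
        seq[j] = "R"
    return ProbeRecord(pid, "II", "".join(seq), None, "Both", chrom, pos, "custom")


def _max_inexact_width(record: ProbeRecord, strand_sets, options) -> int:
    width = 0
    for v in expand_probe_sequences(record):
        for sset in strand_sets:
            for sid, strand in sset:
                width = max(width, match_variant(v, sid, strand, sset.assumption, options).inexact_width)
    return width


def _resolve_degenerate(base: str, rng: np.random.Generator) -> str:
    if base == "Y":
        return str(rng.choice(["C", "T"]))
    if base == "R":
        return str(rng.choice(["A", "G"]))
    return base


def _build_injected_sequence(
    spec: InjectedSpec,
    strand_sets: List[ConvertedStrandSet],
    rng: np.random.Generator,
    options: MatchOptions,
    flag_threshold_bp: int,
) -> Tuple[str, str, int, int]:
    """Construct a 50-nt sequence realizing the configured match.

    For an exact injection (edits=0) ``match_width`` is the maximal exact
    width; the single-edit allowance typically stretches the inexact width
    a little past it, so sub-threshold injections are additionally
    rejection-sampled to keep the inexact width below the flag cutoff.
    For a single-edit injection ``match_width`` is the maximal inexact
    width and the exact width collapses to ``edit_offset - 1``.

    Returns (sequence, strand_id, realized_exact, realized_inexact),
    verified through the matching engine over all strands/assumptions.
    """
    sset = next(s for s in strand_sets if s.assumption == spec.assumption)
    w = spec.match_width
    for _ in range(2000):
        strand_id = str(rng.choice(["FWD", "REV", "FWD_COMPLEMENT", "REV_COMPLEMENT"]))
        strand = sset.strands[strand_id]
        L = len(strand)
        # leave the extension base on the strand: window must not touch the end
        end = int(rng.integers(w - 1, L - 1))
        tail = [_resolve_degenerate(b, rng) for b in strand[end - w + 1 : end + 1]]
        if spec.edits:
            i = w - spec.edit_offset  # 0-based index of the edited base in the tail
            if i < 1:
                raise ValueError(
                    f"edit_offset {spec.edit_offset} does not fit inside width {w}"
                )
            orig = strand[end - w + 1 + i]
            excluded = {"Y": "CT", "R": "AG"}.get(orig, orig)
            choices = [b for b in "ACGT" if b != tail[i] and b not in excluded]
            tail[i] = str(rng.choice(choices))
        prefix = _random_seq(rng, 50 - w)
        seq = prefix + "".join(tail)
        probe = _ProbeSeq(seq)
        results = [
            match_variant(probe, sid, strand_seq, s.assumption, options)
            for s in strand_sets
            for sid, strand_seq in s
        ]
        max_inexact = max(r.inexact_width for r in results)
        max_exact = max(r.exact_width for r in results)
        if spec.edits == 0:
            ok = max_exact == w and (
                w >= flag_threshold_bp or max_inexact < flag_threshold_bp
            )
        else:
            ok = max_inexact == w and max_exact == spec.edit_offset - 1
        if ok:
            return seq, strand_id, max_exact, max_inexact
    raise RuntimeError(f"could not construct injected probe for {spec}")


class _ProbeSeq:
    """Minimal variant-like shim for match_variant during construction."""

    probe_id = "candidate"
    variant_index = 0

    def __init__(self, sequence: str):
        self.sequence = sequence


def _best_provenance(record: ProbeRecord, strand_sets, options) -> Tuple:
    """Aggregated best match for one record with map_probes' tie-break:
    assumption order METHYLATED < UNMETHYLATED < AMBIGUOUS, strand order
    FWD < REV < FWD_COMPLEMENT < REV_COMPLEMENT, then variant order."""
    order = {a: i for i, a in enumerate(MethylationAssumption)}
    best = None
    for sset in sorted(strand_sets, key=lambda s: order[s.assumption]):
        for sid in ("FWD", "REV", "FWD_COMPLEMENT", "REV_COMPLEMENT"):
            strand = sset.strands[sid]
            for v in expand_probe_sequences(record):
                res = match_variant(v, sid, strand, sset.assumption, options)
                if best is None or res.inexact_width > best[0].inexact_width:
                    best = (res, strand)
    return best


def _injected_record(
    spec: InjectedSpec,
    idx: int,
    strand_sets: List[ConvertedStrandSet],
    rng: np.random.Generator,
    options: MatchOptions,
    chrom: str,
    pos: int,
    flag_threshold_bp: int,
) -> Tuple[ProbeRecord, Dict]:
    pid = f"inj{idx:03d}"
    for _ in range(100):
        seq, strand_id, exact_w, inexact_w = _build_injected_sequence(
            spec, strand_sets, rng, options, flag_threshold_bp=flag_threshold_bp
        )
        truth = {
            "label": "injected",
            "match_width": spec.match_width,
            "exact_width": exact_w,
            "inexact_width": inexact_w,
            "edits": spec.edits,
            "oob_switch": spec.oob_switch,
            "assumption": spec.assumption.value,
            "infinium_type": spec.infinium_type,
            "strand": strand_id,
        }
        if spec.infinium_type == "II":
            rec = ProbeRecord(pid, "II", seq, None, "Both", chrom, pos, "custom")
            if _max_inexact_width(rec, strand_sets, options) == inexact_w:
                return rec, truth
            continue
        # type I: the matched sequence is the methylated-allele probe; the
        # U allele gets a degraded tail so the M allele dominates the match.
        seq_u = list(seq)
        for j in rng.choice(np.arange(50 - spec.match_width + 2, 50), size=3, replace=False):
            seq_u[j] = str(rng.choice([b for b in "ACGT" if b != seq_u[j]]))
        rec = ProbeRecord(pid, "I", "".join(seq_u), seq, "Red", chrom, pos, "custom")
        if _max_inexact_width(rec, strand_sets, options) != inexact_w:
            continue
        # derive the off-target extension channel from the same provenance
        # the pipeline will use, then declare the channel to realize the
        # configured in-band / OOB fate
        res, strand = _best_provenance(rec, strand_sets, options)
        nxt = (res.strand_end_pos or 0) + 1
        if res.strand_end_pos is None or nxt >= len(strand) or strand[nxt] in ("Y", "R"):
            continue  # need a concrete extension context
        offtarget_channel = channel_of_base(complement(strand[nxt]))
        declared = (
            {"Red": "Grn", "Grn": "Red"}[offtarget_channel]
            if spec.oob_switch
            else offtarget_channel
        )
        rec = ProbeRecord(pid, "I", "".join(seq_u), seq, declared, chrom, pos, "custom")
        truth["strand"] = res.strand_id
        truth["offtarget_channel"] = offtarget_channel
        return rec, truth
    raise RuntimeError(f"could not realize injected probe {pid} for {spec}")


def generate_manifest(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[ProbeRecord], Dict[str, Dict], List[ConvertedStrandSet]]:
    """Generate manifest records plus exact truth labels.

    Background probes are rejection-sampled: any candidate whose maximal
    inexact width reaches the flag threshold is redrawn, so the background
    truly contains no flaggable probe.  Injected probes are built from the
    converted repeat strands and verified to reproduce their configured
    width through the matching engine.
    """
    rng = rng or np.random.default_rng(config.seed)
    target = build_repeat(config.repeat_unit, config.repeat_copies)
    strand_sets = [build_strand_set(target, a) for a in MethylationAssumption]
    options = MatchOptions()

    # probes live on clustered loci so regional checks have neighbors
    loci = [
        (str(rng.choice(_CHROMS)), int(rng.integers(1_000_000, 240_000_000)))
        for _ in range(config.n_loci)
    ]

    def sample_position() -> Tuple[str, int]:
        chrom, base = loci[int(rng.integers(len(loci)))]
        return chrom, base + int(rng.integers(0, 10_000))

    records: List[ProbeRecord] = []
    truth: Dict[str, Dict] = {}
    for i, spec in enumerate(config.injected):
        chrom, pos = sample_position()
        rec, t = _injected_record(
            spec, i, strand_sets, rng, options, chrom, pos, config.flag_threshold_bp
        )
        records.append(rec)
        truth[rec.probe_id] = t

    n_made = 0
    while n_made < config.n_background_probes:
        chrom, pos = sample_position()
        rec = _background_record(rng, n_made, chrom, pos)
        if _max_inexact_width(rec, strand_sets, options) >= config.flag_threshold_bp:
            continue  # rejection: background must stay below the cutoff
        records.append(rec)
        truth[rec.probe_id] = {"label": "background"}
        n_made += 1
    return records, truth, strand_sets


# ---------------------------------------------------------------------------
# phenotype and intensities


def generate_phenotype(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Sample-level carrier status, covariates and true copy numbers.

    Covariates are generated independent of status so any confounding in a
    test is injected deliberately.  Blood cell fractions follow a
    Dirichlet with granulocyte-dominated means; they sum to one, so models
    must drop one fraction (conventionally B cells).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_samples
    ids = [f"s{i:04d}" for i in range(n)]
    status = (rng.random(n) < config.carrier_fraction).astype(int)
    lo_c, hi_c = config.carrier_copy_range
    lo_n, hi_n = config.noncarrier_copy_range
    copies = np.where(
        status == 1,
        rng.integers(lo_c, hi_c + 1, size=n),
        rng.integers(lo_n, hi_n + 1, size=n),
    )
    cells = rng.dirichlet([4.0, 7.5, 4.0, 30.0, 2.5, 2.0], size=n)
    frame = pd.DataFrame(
        {
            "status": status,
            "sex": rng.choice(["M", "F"], size=n, p=[0.6, 0.4]),
            "batch": rng.choice(["b1", "b2", "b3", "b4"], size=n),
            "age": np.round(rng.normal(62, 10, size=n), 1),
            "smoking_score": np.round(rng.normal(0, 1, size=n), 3),
            "CD8T": cells[:, 0],
            "CD4T": cells[:, 1],
            "Mono": cells[:, 2],
            "Gran": cells[:, 3],
            "Bcell": cells[:, 4],
            "NK": cells[:, 5],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return frame, dict(zip(ids, (int(c) for c in copies)))


def simulate_intensities(
    manifest: Sequence[ProbeRecord],
    truth: Dict[str, Dict],
    phenotype: pd.DataFrame,
    copy_numbers: Dict[str, int],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[IntensitySet, IntensitySet]:
    """Draw in-band and OOB M/U intensities with the off-target mechanism.

    Baseline: per-probe methylation level from a bimodal (low/high) mix;
    per-(probe, sample) total intensity from a truncated normal.  Injected
    probes add ``gain * copy_number * weight(width)`` to the methylated
    component of the predicted band, for carriers and non-carriers alike —
    non-carriers simply contribute their sub-threshold copy numbers.  OOB
    rows exist only for type I probes; for type II they are absent.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = list(phenotype.index)
    n_s = len(samples)
    probe_ids = [r.probe_id for r in manifest]
    n_p = len(manifest)
    copies = np.array([copy_numbers[s] for s in samples], dtype=float)

    low = rng.beta(2, 10, size=n_p)
    high = rng.beta(10, 2, size=n_p)
    base_beta = np.where(rng.random(n_p) < 0.5, low, high)

    total = rng.normal(config.baseline_intensity_mean, config.baseline_intensity_sd, size=(n_p, n_s))
    total = np.clip(total, 200.0, None)
    M = base_beta[:, None] * total + rng.normal(0, config.noise_sd, size=(n_p, n_s))
    U = (1 - base_beta[:, None]) * total + rng.normal(0, config.noise_sd, size=(n_p, n_s))

    type1 = [i for i, r in enumerate(manifest) if r.infinium_type == "I"]
    oob_shape = (len(type1), n_s)
    oob_M = np.clip(rng.normal(config.oob_background_mean, config.oob_background_sd, oob_shape), 0, None)
    oob_U = np.clip(rng.normal(config.oob_background_mean, config.oob_background_sd, oob_shape), 0, None)
    oob_row = {i: k for k, i in enumerate(type1)}

    for i, rec in enumerate(manifest):
        t = truth[rec.probe_id]
        if t.get("label") != "injected":
            continue
        delta = config.offtarget_gain * copies * config.width_weight(t["match_width"])
        if t.get("oob_switch"):
            oob_M[oob_row[i]] += delta
        else:
            M[i] += delta

    M, U = np.clip(M, 0, None), np.clip(U, 0, None)
    idx = pd.Index(probe_ids, name="probe_id")
    inband = IntensitySet(
        M=pd.DataFrame(M, index=idx, columns=samples),
        U=pd.DataFrame(U, index=idx, columns=samples),
        band="IN_BAND",
    )
    t1_idx = pd.Index([probe_ids[i] for i in type1], name="probe_id")
    oob = IntensitySet(
        M=pd.DataFrame(oob_M, index=t1_idx, columns=samples),
        U=pd.DataFrame(oob_U, index=t1_idx, columns=samples),
        band="OOB",
    )
    return inband, oob


# ---------------------------------------------------------------------------
# end-to-end bundle


def generate_dataset(
    config: SyntheticConfig, outdir: Optional[Path] = None
) -> SyntheticDataset:
    """Generate the full bundle; optionally write all files to ``outdir``.

    Files: manifest.tsv, target.fasta, inband_M.tsv, inband_U.tsv,
    oob_M.tsv, oob_U.tsv, phenotype.tsv, truth.json.
    """
    rng = np.random.default_rng(config.seed)
    manifest, truth, strand_sets = generate_manifest(config, rng)
    phenotype, copy_numbers = generate_phenotype(config, rng)
    inband, oob = simulate_intensities(manifest, truth, phenotype, copy_numbers, config, rng)
    target = build_repeat(config.repeat_unit, config.repeat_copies)
    truth_bundle = {"probes": truth, "copy_numbers": copy_numbers}
    ds = SyntheticDataset(
        config=config,
        manifest=manifest,
        target=target,
        strand_sets=strand_sets,
        inband=inband,
        oob=oob,
        phenotype=phenotype,
        truth=truth_bundle,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_manifest_tsv(manifest, outdir / "manifest.tsv")
        with open(outdir / "target.fasta", "w") as fh:
            fh.write(f">{target.name}\n{target.bases}\n")
        write_intensity_matrix(inband.M, outdir / "inband_M.tsv")
        write_intensity_matrix(inband.U, outdir / "inband_U.tsv")
        write_intensity_matrix(oob.M, outdir / "oob_M.tsv")
        write_intensity_matrix(oob.U, outdir / "oob_U.tsv")
        phenotype.to_csv(outdir / "phenotype.tsv", sep="\t", index_label="sample_id")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_bundle, fh, indent=1, sort_keys=True)
    return ds
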