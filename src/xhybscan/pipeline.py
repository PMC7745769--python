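"""End-to-end workflow: map -> flag -> EWAS -> diagnose.

This is the library layer behind the command line: each stage is a plain
function over the domain objects, so the same path is exercised by tests,
the acceptance run and the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AssociationTable,
    EnrichmentResult,
    PhenotypeTable,
    RedFlagReport,
    bonferroni_threshold,
    correlation_check,
    enrichment_test,
    ewas,
    red_flag_report,
    regional_effect_check,
    shared_suffix_check,
)
from .channels import (
    ChannelPrediction,
    IntensitySet,
    beta_values,
    predict_oob_switch,
    total_intensity,
)
from .manifest import ProbeRecord, expand_all
from .mapping import (
    Edit,
    FlagSet,
    MatchOptions,
    MatchResult,
    MatchTable,
    flag_probes,
    map_probes,
)
from .seq_model import ConvertedStrandSet, MethylationAssumption
from .synthetic import SyntheticDataset

__all__ = ["AnalysisResult", "predictions_from_table", "analyze_dataset", "provenance_record"]

DEFAULT_COVARIATES = ("sex", "batch", "age", "smoking_score")


@dataclass
class AnalysisResult:
    match_table: MatchTable
    flags: FlagSet
    assoc_beta: AssociationTable
    assoc_oob: Optional[AssociationTable]
    assoc_intensity: AssociationTable
    significance_threshold: float
    significant_beta: Set[str]
    significant_oob: Set[str]
    significant_intensity: Set[str]
    channel_predictions: Dict[str, ChannelPrediction]
    enrichment: EnrichmentResult
    report: RedFlagReport


def predictions_from_table(
    records: Sequence[ProbeRecord],
    table: MatchTable,
    strand_sets: Sequence[ConvertedStrandSet],
) -> Dict[str, ChannelPrediction]:
    """Channel-switch predictions for type I probes from match provenance."""
    by_assumption = {s.assumption.value: s for s in strand_sets}
    preds: Dict[str, ChannelPrediction] = {}
    for rec in records:
        if rec.infinium_type != "I" or rec.probe_id not in table.frame.index:
            continue
        row = table.frame.loc[rec.probe_id]
        if row["inexact_width"] < 1 or row["strand_end_pos"] < 0:
            continue
        sset = by_assumption[row["assumption"]]
        strand = sset.strands[row["strand"]]
        match = MatchResult(
            probe_id=rec.probe_id,
            variant_index=int(row["variant_index"]),
            strand_id=row["strand"],
            assumption=sset.assumption,
            exact_width=int(row["exact_width"]),
            inexact_width=int(row["inexact_width"]),
            strand_end_pos=int(row["strand_end_pos"]),
        )
        preds[rec.probe_id] = predict_oob_switch(rec, strand, match)
    return preds


def analyze_dataset(
    ds: SyntheticDataset,
    threshold_bp: int = 14,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    options: MatchOptions = MatchOptions(),
    suffix_k: int = 10,
) -> AnalysisResult:
    """Run the full detection workflow on an in-memory dataset.

    Mirrors the intended study design: per-probe EWAS of in-band β-values
    on carrier status, the same for OOB β-values (type I probes) and total
    intensities, flagging of repeat-matching probes, enrichment of flagged
    probes among significant hits, and the five red-flag diagnostics.
    """
    variants = expand_all(ds.manifest)
    table = map_probes(variants, ds.strand_sets, options)
    flags = flag_probes(table, threshold_bp)

    pheno = PhenotypeTable(ds.phenotype)
    beta_in = beta_values(ds.inband)
    assoc_beta = ewas(beta_in.beta, pheno, covariates, response_kind="BETA")
    assoc_int = ewas(
        total_intensity(ds.inband), pheno, covariates, response_kind="TOTAL_INTENSITY"
    )
    assoc_oob = None
    if ds.oob is not None and len(ds.oob.M):
        assoc_oob = ewas(
            beta_values(ds.oob).beta, pheno, covariates, response_kind="OOB_BETA"
        )

    n_tested = int(assoc_beta.frame["p"].notna().sum())
    threshold = bonferroni_threshold(alpha, n_tested)
    sig_beta = assoc_beta.significant(threshold)
    sig_oob = assoc_oob.significant(threshold) if assoc_oob is not None else set()
    sig_int = assoc_int.significant(threshold)

    universe = set(assoc_beta.frame.index[assoc_beta.frame["p"].notna()])
    enrichment = enrichment_test(flags, sig_beta & universe, universe)

    preds = predictions_from_table(ds.manifest, table, ds.strand_sets)

    correlation = None
    if len(sig_beta) >= 2:
        carriers = (ds.phenotype["status"] == 1).to_numpy()
        if carriers.sum() >= 3:
            correlation = correlation_check(beta_in.beta, sig_beta, carriers)
    suffix = shared_suffix_check(variants, sig_beta, k=suffix_k) if sig_beta else None
    positions = {r.probe_id: (r.chrom, r.pos) for r in ds.manifest}
    regional = regional_effect_check(assoc_beta, positions, sig_beta) if sig_beta else None

    report = red_flag_report(
        significant=sig_beta,
        correlation=correlation,
        shared_suffix=suffix,
        regional=regional,
        enrichment=enrichment,
        intensity_assoc=assoc_int,
        oob_assoc=assoc_oob,
        significance_threshold=threshold,
    )
    return AnalysisResult(
        match_table=table,
        flags=flags,
        assoc_beta=assoc_beta,
        assoc_oob=assoc_oob,
        assoc_intensity=assoc_int,
        significance_threshold=threshold,
        significant_beta=sig_beta,
        significant_oob=sig_oob,
        significant_intensity=sig_int,
        channel_predictions=preds,
        enrichment=enrichment,
        report=report,
    )


def provenance_record(config: Dict, inputs: Sequence[Path] = ()) -> Dict:
    """Config echo + package version + input checksums, for reproducibility."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {"version": __version__, "config": config, "input_sha256": checksums}
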