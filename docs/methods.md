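# Methods

## Problem

Infinium methylation arrays (450k/EPIC) measure DNA methylation with 50-nt
probes that anneal to bisulfite-converted genomic DNA and report intensity
after a single-base extension at the probe's 3' end. A probe can also
anneal, partially, to a sequence it was never designed for. When that
off-target sequence varies with the phenotype under study — the canonical
case being a tandem-repeat expansion such as the C9orf72 GGGGCC repeat,
where carriers have hundreds to thousands of copies and non-carriers fewer
than thirty — the off-target hybridization load is phenotype-correlated and
produces spurious association signals at probes scattered across the
genome. Reference-genome-based cross-reactivity annotations cannot catch
this: the offending sequence (the expanded repeat) is not in the reference.

`xhybscan` implements the full diagnostic chain for this failure mode:
construct the converted target strands, measure how much of each probe's 3'
subsequence matches them, predict where the off-target signal lands
(in-band vs out-of-band color channel for type I probes), test intensities
and β-values for carrier association, and consolidate the evidence into a
red-flag report.

## Target strands

A target (repeat unit × copies, or a FASTA record) is bisulfite-converted
in silico on both strands: every non-CpG cytosine becomes T; a CpG cytosine
becomes C (fully methylated assumption), T (fully unmethylated) or the
IUPAC code Y (ambiguous — any mixture of per-CpG states). The converted
forward and reverse strands plus their complements give four strands; all
four are emitted 5'→3' so one left-to-right scanner covers every
hybridization geometry. Complementing a Y yields R (A/G), so the complement
strands of an ambiguous conversion carry R.

Two conventions worth noting:

* A terminal C (no following base) is treated as non-CpG and converted to
  T. The conversion rule is defined by the following base, and a linear
  n-copy concatemer simply loses the junction CpG of its last unit.
* Ten copies of a hexanucleotide unit (60 bp) suffice for any 50-nt probe
  to match in full; more copies add no new 50-mers.

## 3'-anchored matching

For each concrete probe sequence the engine reports the maximal width `w`
such that the length-`w` 3' suffix occurs in a converted strand:

* **exact** — substring occurrence, with Y matching C/T and R matching A/G;
* **inexact** — at most one edit (substitution, or a single-base insertion
  or deletion), with the edit strictly more than 5 bp from the 3' terminus
  (offset ≥ 6, counting the 3'-terminal base as offset 1). Variation close
  to the 3' end blocks the extension reaction, so such edits cannot rescue
  hybridization; the clearance is a parameter and setting it to 0 gives the
  relaxed every-position mode used for sensitivity analyses.

Additional conventions, chosen where the contract left room:

* An edit aligned to a degenerate strand base (Y/R) is never admitted —
  the degenerate base already matches two nucleotides for free.
* Indels must be internal to the aligned window (at least one matched
  probe base 5' of the edit). An edge indel is equivalent to a shorter
  exact match and is not counted as an edit.
* Inexact width is counted in probe bases, so indel alignments remain
  comparable to exact widths.
* Ties across strands/assumptions are broken by a fixed order (FWD, REV,
  FWD_COMPLEMENT, REV_COMPLEMENT; METHYLATED, UNMETHYLATED, AMBIGUOUS) for
  provenance only; the width itself is order-independent.

The implementation scores every probe-end-to-strand-position alignment in
one vectorized sliding-window comparison; trailing-run arithmetic yields
all suffix widths at once, a second pass extends through one admissible
substitution, and indel candidates are pruned by the observation that all
bases 3'-ward of an edit must match exactly (so the edit offset cannot
exceed the exact width + 1). The engine is validated against a brute-force
enumerator over all widths, windows and edits (tests and the acceptance
run; 1000 random instances).

Probes are flagged when their maximal inexact width over all variants,
strands and assumptions reaches a cutoff, default **14 bp**. The cutoff is
a parameter; flagged sets shrink monotonically as it grows, so cutoff
sweeps are cheap.

## Manifests and probe expansion

Type I records contribute their unmethylated and methylated bead sequences
(2 variants); a type II record with `r` degenerate R bases contributes all
`2^r` resolutions (up to 8 for the maximal `r = 3`), enumerated with the
leftmost R varying fastest, A before G, so variant indices are
reproducible. Both the vendor CSV dialect (`[Heading]/[Assay]/[Controls]`
sections, `AlleleA_ProbeSeq`/`AlleleB_ProbeSeq`/`Infinium_Design_Type`/
`Color_Channel` columns) and a simple one-header TSV are supported; rows
violating design invariants are collected into a rejects report rather than
silently dropped. Coordinates are 1-based in files.

## Color channels and β-values

Type I probes are read in one declared channel fixed by the extension
nucleotide: A/T are labeled in Red, C/G in Green. Since complementary
bases share a label, the channel of an extension is insensitive to which
strand it is read from, and only the *discordance* between declared and
off-target channel matters — the mapping constant could be globally swapped
without changing any prediction. When a probe hybridizes off-target, the
template base past its 3'-aligned end determines the incorporated
nucleotide; if its channel differs from the declared one, the off-target
signal lands in the out-of-band (OOB) channel. The predictor takes the
extension context from the match provenance; at a strand boundary it
reports `undefined_boundary`, and on a degenerate context (Y/R) it reports
`ambiguous_base` rather than guessing.

β-values are `M / (M + U + 100)` elementwise, the same formula for in-band
and OOB intensities. The offset 100 is fixed (not configurable) to keep
outputs comparable; it bounds β in [0, 1) and regularizes low-intensity
probes. OOB matrices exist only for type I probes and are absent — not
zero-filled — for type II.

## Association model

Per probe, ordinary least squares of the response (β, OOB β, or total
intensity M+U) on carrier status plus fixed covariates (sex, batch, age,
smoking score; optionally imputed cell fractions, one of which must be
dropped because they sum to one), with a two-sided t-test on the status
coefficient. Mixed-model alternatives that fit distal probes as random
effects are deliberately out of scope; the fixed-effects linear model is
the documented fallback and the detection logic does not depend on the
variance-component machinery. With a shared design matrix the fit is
vectorized across probes (one pseudoinverse solve); probes with missing
samples fall back to per-probe complete-case fits, and probes with zero
response variance or fewer than 3 samples per status group are reported NA
with a reason code. The vectorized path is cross-checked against
statsmodels OLS in the tests. Multiple testing is Bonferroni on the number
of probes actually tested.

Enrichment of flagged probes among significant hits is a 2×2 Fisher exact
test (scipy). The odds ratio is the conditional maximum-likelihood
estimate: the root of E[X | margins, ψ] = a under the noncentral
hypergeometric likelihood, solved with log-space weights and Brent's
method so tables with margins in the hundreds of thousands and
near-boundary counts remain numerically stable. (Generic root-finders with
loose absolute tolerances can be off by 10–15% on such tables when solving
in inverted-odds space; the in-package solver is validated against an
independent grid maximizer of the conditional likelihood and against
scipy's estimator.)

## Red-flag report

Five checks, consolidated into machine-readable JSON:

1. **Correlation** — pairwise Pearson correlation of β among significant
   probes, computed within carriers (where a shared copy-number driver is
   most visible); warns when mean off-diagonal |r| exceeds 0.3 (default).
2. **Shared 3' subsequences** — partition of significant probes by exact
   3' k-mer (default k = 10) over all alleles/variants; any non-singleton
   group warns.
3. **Regional effects** — a significant probe is `supported` if another
   probe within 100 kb has p < 0.01, `isolated` if neighbors exist but
   none pass, `no_neighbors` otherwise. Artefacts hit single CpGs; real
   regional signals have support.
4. **Intensity association** — probes whose total intensity associates
   with the phenotype (hybridization-load signature).
5. **OOB association** — probes significant in the OOB-β EWAS.

Missing inputs mark a check `not_run`; an empty significant set marks all
checks `not_run` with a reason.

## Synthetic cohorts

The generator emulates the study conditions end to end with exact ground
truth. Defaults (chosen once; all randomness flows from one seed):

* 400 samples, 10% expansion carriers — roughly the C9orf72 frequency in
  ALS cohorts. Carrier copy numbers uniform in 200–1200 (pathogenic
  range); non-carriers 2–10, below the 30-copy carrier threshold.
* 5000 background probes (≈30% type I, type II with 0–3 R bases),
  rejection-sampled so no background probe reaches the 14 bp flag cutoff —
  truth labels are therefore exact, and chance background matches stay
  well below the cutoff.
* 30 injected cross-hybridizing probes spanning the regimes of interest:
  8 type I in-band (exact widths 14–40), 8 type I with a channel switch
  (OOB fate, widths 14–50), 6 type II (widths 15–32), 4 single-edit
  matches (inexact widths 16–28 with the edit at offset 10, so the exact
  width collapses to 9 — the imperfect-match regime), and 4 sub-threshold
  probes (exact widths 9–12, verified to stay below the cutoff even with
  the one-edit allowance).
* Injected tails are copied from the converted strands and verified
  through the matching engine itself; because a single admissible edit
  generically stretches an exact width-w match to w+1 or slightly more,
  the configured width is the *exact* width for edit-free injections and
  the *inexact* width for single-edit injections, with the realized widths
  recorded in the truth labels.
* Declared channels of injected type I probes are set concordant or
  discordant with the off-target extension channel — derived from the same
  match provenance the pipeline will compute — to realize the configured
  in-band/OOB fate.
* Intensities: per-probe baseline β from a bimodal (low/high methylation)
  mixture; per-(probe, sample) total intensity truncated-normal
  (mean 3000, sd 500 fluorescence units); OOB background normal
  (mean 150, sd 40). Off-target signal δ = gain × copy_number ×
  weight(width) is added to the methylated component of the predicted
  band, with gain 5 units/copy and a logistic width weight centered at
  14 bp (scale 2 bp) encoding rising detectability with match length. The
  true functional form linking copy number to off-target signal is
  unknown; linear-in-copies is a modeling choice, not a claim.
* Covariates (sex, batch, age, smoking score, Dirichlet cell fractions)
  are generated independent of status, so any confounding in a test is
  injected deliberately.

What the generator does **not** emulate: bisulfite-conversion failure,
slide/plate batch effects on intensities, dye bias, signal saturation, or
probe-level SNP artefacts. Passing tests therefore demonstrate that the
detection chain recovers a known cross-hybridization mechanism under clean
conditions; they do not certify behavior under every real-data pathology,
and real analyses should still replicate flagged findings with a
sequencing-based assay.

## Numerical and scale choices

* The mapping kernel is exact (no heuristics); its cost is linear in
  strand length × probe length per alignment pass, with indel passes
  pruned by the exact width. Mapping 5030 probes × 4 strands × 3
  assumptions takes ~15 s on one core.
* The default test/acceptance cohort (400 × 5030, chosen to keep the full
  pipeline in tens of seconds) is the size at which all recovery
  statistics in the acceptance run are computed; the null-calibration run
  uses 12,000 independent probes × 200 samples.
* Degenerate inputs: empty strands, out-of-range thresholds and k-mer
  lengths, non-binary status, rank-deficient designs (with the collinear
  columns named) all raise immediately rather than propagating NaNs.

## Known limitations

* Genome-wide all-vs-all cross-reactivity against a reference assembly and
  thermodynamic duplex-stability modeling are out of scope.
* The OOB prediction assumes the single best match provenance; a probe
  matching several strands at the same width uses the fixed tie-break
  order, which can matter only when the tied contexts disagree on the
  extension base.
* Normalization (quantile, noob-style background correction, dye bias) is
  upstream of this package: it consumes already-normalized intensities.
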