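"""Per-probe association testing, enrichment and the red-flag diagnostics.

The association model is ordinary least squares per probe: response
(β-value, OOB β-value, or total intensity) on carrier status plus fixed
covariates (sex, batch, age, smoking score, optional cell fractions), with
a two-sided t-test on the status coefficient.  With a shared design matrix
across probes the fit is vectorized limma-style: one pseudoinverse solve
for all complete-case probes; probes with missing samples fall back to a
per-probe complete-case fit.

Enrichment of flagged probes among significant hits is a 2x2 Fisher exact
test; the reported odds ratio is the conditional maximum-likelihood
estimate (the root of the conditional score equation under the noncentral
hypergeometric likelihood), computed in log space so extreme tables are
handled stably.

The five red-flag checks screen an EWAS result for cross-hybridization
artefacts: (1) correlated residual methylation among significant probes,
(2) shared 3' subsequences, (3) isolated (region-free) association peaks,
(4) phenotype association of total signal intensity and (5) associations
in the type I out-of-band channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

from .manifest import ProbeSequenceVariant
from .mapping import FlagSet

__all__ = [
    "PhenotypeTable",
    "AssociationTable",
    "EnrichmentResult",
    "RedFlagReport",
    "ewas",
    "bonferroni_threshold",
    "format_threshold",
    "enrichment_test",
    "conditional_mle_or",
    "correlation_check",
    "shared_suffix_check",
    "regional_effect_check",
    "red_flag_report",
]


@dataclass
class PhenotypeTable:
    """Sample-level phenotype and covariates.

    ``frame`` is indexed by sample_id with a binary ``status`` column
    (1 = repeat-expansion carrier) plus covariate columns.  Categorical
    covariates (e.g. batch, sex) may be strings; they are dummy-coded at
    model-build time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValueError("duplicated sample ids in phenotype table")
        if "status" not in self.frame.columns:
            raise ValueError("phenotype table must carry a 'status' column")
        vals = set(pd.unique(self.frame["status"].dropna()))
        if not vals <= {0, 1}:
            raise ValueError(f"status must be binary 0/1, got values {sorted(vals)}")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class AssociationTable:
    """Per-probe OLS results for the status coefficient."""

    frame: pd.DataFrame  # index probe_id; effect, se, t, p, n, reason
    response_kind: str  # BETA | OOB_BETA | TOTAL_INTENSITY

    def significant(self, threshold: float) -> Set[str]:
        p = self.frame["p"]
        return set(self.frame.index[p.notna() & (p < threshold)])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path, response_kind: str = "BETA") -> "AssociationTable":
        return cls(pd.read_csv(path, sep="\t", index_col="probe_id"), response_kind)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[sig&flag, sig&unflag], [nonsig&flag, nonsig&unflag]]
    odds_ratio: float
    p_value: float
    status: str = "ok"  # ok | degenerate


def _build_design(
    phenotype: PhenotypeTable, covariates: Sequence[str]
) -> Tuple[np.ndarray, List[str], pd.Index]:
    """Dummy-coded design matrix [intercept, status, covariates...]."""
    df = phenotype.frame
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in phenotype table: {missing}")
    cols = [pd.Series(1.0, index=df.index, name="intercept"), df["status"].astype(float)]
    names = ["intercept", "status"]
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            for d in dummies.columns:
                cols.append(dummies[d])
                names.append(d)
        else:
            cols.append(col.astype(float))
            names.append(c)
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    return X, names, df.index


def _collinear_columns(X: np.ndarray, names: List[str]) -> List[str]:
    out = []
    for j in range(1, X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            out.append(names[j])
    return out


def _ols_block(Y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of Y on X; returns (beta_status, se, df)."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    coef = pinv @ Y  # (k, n_probes)
    resid = Y - X @ coef
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return coef[1], se, np.full(Y.shape[1], dof)


def ewas(
    response: pd.DataFrame,
    phenotype: PhenotypeTable,
    covariates: Sequence[str] = ("sex", "batch", "age", "smoking_score"),
    response_kind: str = "BETA",
) -> AssociationTable:
    """Per-probe OLS of response on carrier status with fixed covariates.

    ``response`` is probes x samples; samples are matched to the phenotype
    table by id.  Missing response values are dropped per probe
    (complete-case per test).  Probes with zero response variance, or with
    fewer than 3 samples in either status group after missingness
    filtering, are reported NA with a reason code.
    """
    common = response.columns.intersection(phenotype.frame.index)
    if len(common) < response.shape[1]:
        response = response[common]
    pheno = PhenotypeTable(phenotype.frame.loc[common])
    X, names, _ = _build_design(pheno, covariates)
    status = pheno.frame["status"].to_numpy()

    Y = response.to_numpy(dtype=float)
    n_probes = Y.shape[0]
    effect = np.full(n_probes, np.nan)
    se = np.full(n_probes, np.nan)
    tstat = np.full(n_probes, np.nan)
    pval = np.full(n_probes, np.nan)
    nused = np.zeros(n_probes, dtype=int)
    reason = np.array([""] * n_probes, dtype=object)

    complete = ~np.isnan(Y).any(axis=1)
    variance = np.nanvar(Y, axis=1)
    zerovar = variance == 0
    reason[zerovar] = "zero variance"

    run = complete & ~zerovar
    if run.any():
        b, s, dof = _ols_block(Y[run].T, X)
        t = np.divide(b, s, out=np.full_like(b, np.nan), where=s > 0)
        effect[run], se[run] = b, s
        tstat[run] = t
        pval[run] = 2 * stats.t.sf(np.abs(t), dof)
        nused[run] = X.shape[0]

    # per-probe complete-case fallback for probes with missing samples
    for i in np.where(~complete & ~zerovar)[0]:
        ok = ~np.isnan(Y[i])
        if np.var(Y[i, ok]) == 0:
            reason[i] = "zero variance"
            continue
        groups = status[ok]
        if (groups == 1).sum() < 3 or (groups == 0).sum() < 3:
            reason[i] = "insufficient samples per group"
            continue
        Xi = X[ok]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            reason[i] = "rank-deficient after missingness"
            continue
        b, s, dof = _ols_block(Y[i, ok][:, None], Xi)
        effect[i], se[i] = b[0], s[0]
        tstat[i] = b[0] / s[0] if s[0] > 0 else np.nan
        pval[i] = 2 * stats.t.sf(abs(tstat[i]), dof[0])
        nused[i] = int(ok.sum())

    frame = pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "t": tstat,
            "p": pval,
            "n": nused,
            "reason": reason,
        },
        index=response.index.rename("probe_id"),
    )
    return AssociationTable(frame=frame, response_kind=response_kind)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests (n = probes actually tested)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def format_threshold(threshold: float, sig_digits: int = 2) -> float:
    """Round to significant digits for reporting (1.07e-7 -> 1.1e-7)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    from math import floor, log10

    exp = floor(log10(threshold))
    return round(threshold, -exp + sig_digits - 1)


def conditional_mle_or(table: np.ndarray) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    Solves E[X | margins, psi] = a under the noncentral hypergeometric
    likelihood, with log-space weights so that extreme tables (huge
    margins, near-boundary counts) remain stable.  Returns inf/0 at the
    support boundary.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b
    m1 = a + c
    N = a + b + c + d
    m2 = N - m1
    lo, hi = max(0, n - m2), min(n, m1)
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1) - gammaln(k + 1) - gammaln(m1 - k + 1)
        + gammaln(m2 + 1) - gammaln(n - k + 1) - gammaln(m2 - n + k + 1)
    )

    def cond_mean_minus_a(log_psi: float) -> float:
        t = logw + k * log_psi
        t -= t.max()
        w = np.exp(t)
        return float((w * k).sum() / w.sum()) - a

    return float(np.exp(brentq(cond_mean_minus_a, -80.0, 80.0, xtol=1e-12, rtol=1e-14)))


def enrichment_test(
    flags: FlagSet, significant: Set[str], universe: Set[str]
) -> EnrichmentResult:
    """Fisher exact enrichment of flagged probes among significant probes."""
    if not universe:
        raise ValueError("empty probe universe")
    if not set(significant) <= set(universe):
        raise ValueError("significant set must be a subset of the universe")
    flagged = set(flags.flagged_probe_ids) & set(universe)
    a = len(flagged & significant)
    b = len(significant) - a
    c = len(flagged) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return EnrichmentResult(table, float("nan"), 1.0, status="degenerate")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(table, conditional_mle_or(table), p)


def correlation_check(
    beta: pd.DataFrame,
    significant: Iterable[str],
    sample_mask: Optional[Sequence[bool]] = None,
    warn_threshold: float = 0.3,
) -> Dict:
    """Pairwise Pearson correlations among significant probes.

    Computed within the masked samples (e.g. carriers only, where a shared
    copy-number driver shows up most clearly).  Mean off-diagonal |r|
    above ``warn_threshold`` yields a warn status.  Constant probes get NA
    correlations.
    """
    sig = [p for p in significant if p in beta.index]
    if len(sig) < 2:
        raise ValueError("need at least 2 significant probes")
    sub = beta.loc[sig]
    if sample_mask is not None:
        sub = sub.loc[:, np.asarray(sample_mask, dtype=bool)]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples in the mask")
    corr = sub.T.corr()  # pandas: NaN for constant rows
    vals = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(vals, np.nan)
    off = np.abs(vals)
    mean_abs_r = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return {
        "matrix": corr,
        "mean_abs_r": mean_abs_r,
        "status": "warn" if mean_abs_r > warn_threshold else "pass",
        "n_probes": len(sig),
        "n_samples": int(sub.shape[1]),
    }


def shared_suffix_check(
    variants: Sequence[ProbeSequenceVariant],
    significant: Iterable[str],
    k: int = 10,
) -> Dict:
    """Group significant probes sharing an identical 3' k-mer.

    A cluster of association hits whose probes end in the same subsequence
    is the signature of one off-target sequence captured by many probes.
    All alleles/variants of a probe contribute suffixes; singleton groups
    are suppressed.
    """
    if not 1 <= k <= 50:
        raise ValueError(f"k must be in [1, 50], got {k}")
    sig = set(significant)
    groups: Dict[str, Set[str]] = {}
    for v in variants:
        if v.probe_id in sig:
            groups.setdefault(v.sequence[-k:], set()).add(v.probe_id)
    shared = {suffix: sorted(ids) for suffix, ids in groups.items() if len(ids) > 1}
    n_in_shared = len(set().union(*shared.values())) if shared else 0
    return {
        "k": k,
        "groups": shared,
        "n_significant": len(sig),
        "n_in_shared_group": n_in_shared,
        "status": "warn" if shared else "pass",
    }


def regional_effect_check(
    assoc: AssociationTable,
    positions: Mapping[str, Tuple[str, int]],
    significant: Iterable[str],
    window_bp: int = 100_000,
    neighbor_p: float = 0.01,
) -> Dict[str, str]:
    """Classify each significant probe by neighborhood support.

    Genuine regional methylation signals extend to neighboring probes;
    cross-hybridization artefacts hit single CpGs.  A significant probe is
    ``supported`` if any other probe within ``window_bp`` has
    p < ``neighbor_p``, ``isolated`` if neighbors exist but none pass, and
    ``no_neighbors`` if none lie within the window.  Probes without a
    position get ``NA``.
    """
    out: Dict[str, str] = {}
    frame = assoc.frame
    pos_df = pd.DataFrame(
        {
            "chrom": {p: positions[p][0] for p in positions},
            "pos": {p: positions[p][1] for p in positions},
        }
    )
    for probe in significant:
        if probe not in positions:
            out[probe] = "NA"
            continue
        chrom, pos = positions[probe]
        near = pos_df[
            (pos_df["chrom"] == chrom)
            & ((pos_df["pos"] - pos).abs() <= window_bp)
            & (pos_df.index != probe)
        ]
        neighbors = near.index.intersection(frame.index)
        if len(neighbors) == 0:
            out[probe] = "no_neighbors"
            continue
        pvals = frame.loc[neighbors, "p"]
        out[probe] = "supported" if (pvals < neighbor_p).any() else "isolated"
    return out


@dataclass
class RedFlagReport:
    """Machine-readable consolidation of the five diagnostics."""

    checks: Dict[str, Dict]
    summary: str

    def to_json(self, path=None) -> str:
        payload = json.dumps({"checks": self.checks, "summary": self.summary}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def red_flag_report(
    *,
    significant: Set[str],
    correlation: Optional[Dict] = None,
    shared_suffix: Optional[Dict] = None,
    regional: Optional[Dict[str, str]] = None,
    enrichment: Optional[EnrichmentResult] = None,
    intensity_assoc: Optional[AssociationTable] = None,
    oob_assoc: Optional[AssociationTable] = None,
    significance_threshold: Optional[float] = None,
) -> RedFlagReport:
    """Consolidate the five red-flag checks into one report.

    Checks: (1) correlation structure among significant probes; (2) shared
    3' subsequences; (3) regional support; (4) overlap between β-significant
    and intensity-significant probes; (5) overlap with OOB-significant
    probes.  Missing inputs mark a check ``not_run`` rather than failing.
    """
    checks: Dict[str, Dict] = {}

    if not significant:
        for name in (
            "correlation",
            "shared_suffix",
            "regional_effects",
            "intensity_association",
            "oob_association",
        ):
            checks[name] = {"status": "not_run", "reason": "no significant probes"}
        return RedFlagReport(checks=checks, summary="no significant probes; nothing to check")

    if correlation is None:
        checks["correlation"] = {"status": "not_run", "reason": "missing input"}
    else:
        checks["correlation"] = {
            "status": correlation["status"],
            "mean_abs_r": correlation["mean_abs_r"],
            "n_probes": correlation["n_probes"],
        }

    if shared_suffix is None:
        checks["shared_suffix"] = {"status": "not_run", "reason": "missing input"}
    else:
        checks["shared_suffix"] = {
            "status": shared_suffix["status"],
            "k": shared_suffix["k"],
            "n_in_shared_group": shared_suffix["n_in_shared_group"],
            "groups": {s: ids for s, ids in shared_suffix["groups"].items()},
        }

    if regional is None:
        checks["regional_effects"] = {"status": "not_run", "reason": "missing input"}
    else:
        n_isolated = sum(1 for v in regional.values() if v in ("isolated", "no_neighbors"))
        checks["regional_effects"] = {
            "status": "warn" if n_isolated else "pass",
            "per_probe": dict(regional),
            "n_isolated": n_isolated,
        }

    for name, table in (
        ("intensity_association", intensity_assoc),
        ("oob_association", oob_assoc),
    ):
        if table is None or significance_threshold is None:
            checks[name] = {"status": "not_run", "reason": "missing input"}
            continue
        hits = table.significant(significance_threshold)
        overlap = sorted(hits & significant)
        checks[name] = {
            "status": "warn" if hits else "pass",
            "n_significant": len(hits),
            "overlap_with_beta_significant": overlap,
        }

    if enrichment is not None:
        checks["enrichment"] = {
            "status": "warn" if (enrichment.p_value < 0.05 and enrichment.odds_ratio > 1) else "pass",
            "odds_ratio": enrichment.odds_ratio,
            "p_value": enrichment.p_value,
            "table": enrichment.table.tolist(),
        }

    n_warn = sum(1 for c in checks.values() if c.get("status") == "warn")
    summary = f"{n_warn} of {len(checks)} checks raised warnings"
    return RedFlagReport(checks=checks, summary=summary)
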