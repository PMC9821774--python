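"""Differential expression: CPM, fold change, NB exact test, BH, gating.

The test is a self-contained classic exact negative-binomial test for
two small groups:

1. counts are scaled to a common effective library size (the geometric
   mean of the observed library sizes) and rounded to integer
   pseudo-counts;
2. a single common dispersion is estimated by maximizing the NB
   conditional likelihood (conditioning each group on its sum removes the
   mean) over all features, by bounded search on log10(phi) in [-4, 1];
3. for each feature, conditional on the total pseudo-count across both
   groups, the two group sums follow a conditional distribution whose
   NB success-probability cancels; the two-sided p-value sums the
   probabilities of all splits as or less likely than the observed one
   (minimum-likelihood method). At dispersion 0 the conditional law is
   binomial, so the test reduces to the exact binomial-split test.

Significance gates are class-specific: fold change >= 2 (|log2FC| >= 1)
with p < 0.05 for circRNAs and miRNAs, and with BH FDR < 0.05 for mRNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .design import StudyDesign
from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    EstimationError,
    InvalidDesignError,
)

#: Relative tolerance when deciding whether a split is "as or more extreme"
#: than the observed one; guards exact probability ties against float noise.
_TIE_RTOL = 1e-9


def normalize_cpm(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column rescaled to sum to 1e6."""
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample {zero.index[0]!r} has zero total counts and cannot be normalized"
        )
    return counts / colsums * 1e6


def _split_samples(matrix: ExpressionMatrix, design: StudyDesign) -> tuple[list[str], list[str]]:
    cond = design.condition_of(matrix.sample_ids)
    control = [s for s in matrix.sample_ids if cond[s] == design.control]
    treat = [s for s in matrix.sample_ids if cond[s] == design.treatment]
    if len(control) < 2 or len(treat) < 2:
        raise InvalidDesignError(
            f"need >= 2 samples per condition, got {len(control)} {design.control} "
            f"and {len(treat)} {design.treatment}"
        )
    return control, treat


def log2_fold_change(
    matrix: ExpressionMatrix, design: StudyDesign, pseudocount: float = 1.0
) -> pd.Series:
    """log2 of (mean treatment CPM + pseudocount) / (mean control CPM + pseudocount)."""
    control, treat = _split_samples(matrix, design)
    cpm = normalize_cpm(matrix)
    num = cpm[treat].mean(axis=1) + pseudocount
    den = cpm[control].mean(axis=1) + pseudocount
    return np.log2(num / den)


def pseudo_counts(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean library size, rounded to integers."""
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise DegenerateSampleError(
            f"sample {lib.index[lib == 0][0]!r} has zero total counts"
        )
    target = np.exp(np.mean(np.log(lib)))
    return (counts * (target / lib)).round().astype(np.int64)


def _conditional_loglik(r: float, groups: list[np.ndarray]) -> float:
    """NB conditional log-likelihood of size parameter r, summed over features.

    For i.i.d. NB(r, p) counts y_1..y_n with sum s, P(y | s) does not
    depend on p; terms constant in r are dropped.
    """
    ll = 0.0
    for y in groups:
        n = y.shape[1]
        s = y.sum(axis=1)
        ll += float(
            (
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                - gammaln(s + n * r)
                + gammaln(n * r)
            ).sum()
        )
    return ll


def estimate_common_dispersion(matrix: ExpressionMatrix, design: StudyDesign) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    Searches log10(dispersion) in [-4, 1]; features with all-zero counts
    are excluded. Returns the dispersion phi (Var = mu + phi mu^2).
    """
    control, treat = _split_samples(matrix, design)
    pc = pseudo_counts(matrix)
    keep = pc.sum(axis=1) > 0
    if not keep.any():
        raise EstimationError("no feature with nonzero counts")
    groups = [
        pc.loc[keep, control].to_numpy(dtype=float),
        pc.loc[keep, treat].to_numpy(dtype=float),
    ]
    res = minimize_scalar(
        lambda x: -_conditional_loglik(10.0 ** x, groups),
        bounds=(-1.0, 4.0),  # x = log10(r) = -log10(phi), phi in [1e-4, 10]
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0 ** (-res.x))


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, dispersion: float
) -> float:
    """Two-sided exact conditional NB test on two groups of pseudo-counts.

    Conditional on the total ``t`` over both groups, the group-A sum takes
    values 0..t with probabilities proportional to the product of the two
    group-sum NB pmfs (the success probability cancels). The p-value is
    the total probability of all splits whose probability does not exceed
    the observed split's. ``dispersion == 0`` gives the binomial-split
    (Poisson) special case.
    """
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise InvalidDesignError("both groups must be non-empty")
    sa = int(a.sum())
    t = sa + int(b.sum())
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if dispersion == 0:
        # Binomial(t, na/(na+nb)) log-pmf, written directly for stability.
        p = na / (na + nb)
        logp = (
            gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
            + s * np.log(p) + (t - s) * np.log1p(-p)
        )
    else:
        r = 1.0 / dispersion
        alpha, beta = na * r, nb * r
        logw = (
            gammaln(s + alpha) - gammaln(s + 1)
            + gammaln(t - s + beta) - gammaln(t - s + 1)
        )
        logp = logw - logsumexp(logw)
    keep = logp <= logp[sa] + _TIE_RTOL
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_significance(
    table: pd.DataFrame,
    rna_class: str,
    min_abs_log2fc: float = 1.0,
    p_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the class-specific significance gates to a DE table.

    circRNA/miRNA: |log2fc| >= min_abs_log2fc and p < p_alpha.
    mRNA: |log2fc| >= min_abs_log2fc and FDR < fdr_alpha.
    Direction is up/down when log2fc clears +/- min_abs_log2fc, else none.
    """
    if rna_class not in ("circRNA", "miRNA", "mRNA"):
        raise ConfigurationError(f"unknown rna_class {rna_class!r}")
    out = table.copy()
    lfc = out["log2fc"].to_numpy()
    fc_gate = np.abs(lfc) >= min_abs_log2fc
    if rna_class == "mRNA":
        prob_gate = out["fdr"].to_numpy() < fdr_alpha
    else:
        prob_gate = out["pvalue"].to_numpy() < p_alpha
    out["significant"] = fc_gate & prob_gate
    out["direction"] = np.where(
        lfc >= min_abs_log2fc, "up", np.where(lfc <= -min_abs_log2fc, "down", "none")
    )
    return out


def call_de(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    *,
    dispersion: float | None = None,
    pseudocount: float = 1.0,
    min_abs_log2fc: float = 1.0,
    p_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-feature DE call for one (class, tissue) matrix.

    Returns a table with columns feature_id, rna_class, tissue, log2fc,
    pvalue, fdr, significant, direction. BH adjustment is applied within
    this (tissue, class) stratum. ``dispersion=None`` estimates the common
    dispersion from the data.
    """
    control, treat = _split_samples(matrix, design)
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, design)
    lfc = log2_fold_change(matrix, design, pseudocount=pseudocount)
    pc = pseudo_counts(matrix)
    arr_a = pc[control].to_numpy()
    arr_b = pc[treat].to_numpy()
    pvals = np.array(
        [nb_exact_test(arr_a[i], arr_b[i], dispersion) for i in range(arr_a.shape[0])]
    )
    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "rna_class": matrix.rna_class,
            "tissue": matrix.tissue,
            "log2fc": lfc.to_numpy(),
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )
    table = classify_significance(
        table, matrix.rna_class,
        min_abs_log2fc=min_abs_log2fc, p_alpha=p_alpha, fdr_alpha=fdr_alpha,
    )
    table.attrs["dispersion"] = dispersion
    return table
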