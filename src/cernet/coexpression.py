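"""Correlation filtering of predicted pairs.

Step 1: miRNA-target pairs (target = circRNA or mRNA) are kept when both
members are differentially expressed and their Spearman rank correlation
across all samples of the tissue is strictly below the negative threshold
(default -0.7).

Step 2: circRNA-mRNA pairs that share at least one retained miRNA are
kept when their Pearson correlation (on log2(CPM+1)) is strictly above
the positive threshold (default 0.9).

Both conditions of a tissue are pooled when computing correlations by
default; a within-condition mode (Fisher-z average of per-condition
coefficients) is available.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .de import normalize_cpm
from .errors import UndefinedCorrelationError

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["id_a", "id_b", "pair_type", "method", "coefficient", "n_samples"]


def _validate_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return x, y


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x, y = _validate_vectors(x, y)
    return float(stats.spearmanr(x, y).statistic)


def pearson(x, y) -> float:
    """Pearson product-moment correlation."""
    x, y = _validate_vectors(x, y)
    return float(stats.pearsonr(x, y).statistic)


def _significant_ids(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.loc[de_table["significant"], "feature_id"])


def _correlate(method, xa: np.ndarray, xb: np.ndarray, conditions: np.ndarray | None) -> float:
    """Pooled correlation, or Fisher-z mean of per-condition correlations."""
    if conditions is None:
        return method(xa, xb)
    zs = []
    for cond in np.unique(conditions):
        m = conditions == cond
        r = np.clip(method(xa[m], xb[m]), -1 + 1e-12, 1 - 1e-12)
        zs.append(np.arctanh(r))
    return float(np.tanh(np.mean(zs)))


def filter_mirna_target_pairs(
    de_tables: dict[str, pd.DataFrame],
    interactions: pd.DataFrame,
    expr: dict[str, ExpressionMatrix],
    scc_threshold: float = -0.7,
    conditions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Retain miRNA-target interactions that are DE on both ends and
    negatively rank-correlated below ``scc_threshold`` (strict).

    Parameters
    ----------
    de_tables
        DE tables keyed by RNA class, for one tissue.
    interactions
        miRNA->target table (columns mirna_id, target_id, target_type).
    expr
        Expression matrices keyed by RNA class, same tissue; CPM is
        computed internally and samples are pooled across conditions
        unless ``conditions`` (one label per sample) is given.

    Returns a pair table; ``attrs['n_skipped']`` counts interaction rows
    that referenced unknown features, ``attrs['n_undefined']`` pairs with
    a constant expression vector, ``attrs['n_tested']`` pairs tested.
    """
    de_sig = {cls: _significant_ids(tab) for cls, tab in de_tables.items()}
    cpm = {cls: normalize_cpm(mat) for cls, mat in expr.items()}

    rows = []
    n_skipped = n_undefined = n_tested = 0
    for rec in interactions.itertuples(index=False):
        ttype = rec.target_type
        if ttype not in ("circRNA", "mRNA"):
            n_skipped += 1
            logger.warning("unknown target_type %r; row skipped", ttype)
            continue
        if rec.mirna_id not in cpm["miRNA"].index or rec.target_id not in cpm[ttype].index:
            n_skipped += 1
            logger.warning(
                "interaction %s -> %s references an unknown feature; skipped",
                rec.mirna_id, rec.target_id,
            )
            continue
        if rec.mirna_id not in de_sig.get("miRNA", set()):
            continue
        if rec.target_id not in de_sig.get(ttype, set()):
            continue
        x = cpm["miRNA"].loc[rec.mirna_id].to_numpy()
        y = cpm[ttype].loc[rec.target_id].to_numpy()
        n_tested += 1
        try:
            coef = _correlate(spearman, x, y, conditions)
        except UndefinedCorrelationError:
            n_undefined += 1
            logger.warning(
                "constant expression for pair (%s, %s); excluded",
                rec.mirna_id, rec.target_id,
            )
            continue
        if coef < scc_threshold:
            rows.append(
                {
                    "id_a": rec.mirna_id,
                    "id_b": rec.target_id,
                    "pair_type": "mirna_circ" if ttype == "circRNA" else "mirna_mrna",
                    "method": "spearman",
                    "coefficient": coef,
                    "n_samples": len(x),
                }
            )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out.attrs.update(n_skipped=n_skipped, n_undefined=n_undefined, n_tested=n_tested)
    return out


def filter_cerna_pairs(
    de_tables: dict[str, pd.DataFrame],
    retained_mirna_pairs: pd.DataFrame,
    expr: dict[str, ExpressionMatrix],
    pcc_threshold: float = 0.9,
    conditions: np.ndarray | None = None,
) -> pd.DataFrame:
    """circRNA-mRNA pairs sharing >= 1 retained miRNA, with Pearson
    correlation strictly above ``pcc_threshold``.

    Pearson is computed on log2(CPM + 1). Each kept pair records its
    common-miRNA set (sorted, semicolon-joined) in ``common_mirnas``.
    """
    circ_of: dict[str, set[str]] = {}
    mrna_of: dict[str, set[str]] = {}
    for rec in retained_mirna_pairs.itertuples(index=False):
        bucket = circ_of if rec.pair_type == "mirna_circ" else mrna_of
        bucket.setdefault(rec.id_a, set()).add(rec.id_b)

    common: dict[tuple[str, str], set[str]] = {}
    for mi in set(circ_of) & set(mrna_of):
        for circ, mrna in product(circ_of[mi], mrna_of[mi]):
            common.setdefault((circ, mrna), set()).add(mi)

    log_cpm = {
        cls: np.log2(normalize_cpm(expr[cls]) + 1.0) for cls in ("circRNA", "mRNA")
    }
    rows = []
    n_undefined = 0
    for (circ, mrna), mirnas in sorted(common.items()):
        x = log_cpm["circRNA"].loc[circ].to_numpy()
        y = log_cpm["mRNA"].loc[mrna].to_numpy()
        try:
            coef = _correlate(pearson, x, y, conditions)
        except UndefinedCorrelationError:
            n_undefined += 1
            logger.warning("constant expression for pair (%s, %s); excluded", circ, mrna)
            continue
        if coef > pcc_threshold:
            rows.append(
                {
                    "id_a": circ,
                    "id_b": mrna,
                    "pair_type": "circ_mrna",
                    "method": "pearson",
                    "coefficient": coef,
                    "n_samples": len(x),
                    "common_mirnas": ";".join(sorted(mirnas)),
                }
            )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS + ["common_mirnas"])
    out.attrs.update(n_tested=len(common), n_undefined=n_undefined)
    return out
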