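"""Immune signatures and the cyt-HERV annotation.

A cancer-associated provirus is annotated *cyt* (associated with a
cytotoxic T lymphocyte response) when an L1-penalized regression selects
it — positive coefficient at the cross-validated penalty — for at least
one T cell *phenotype* signature (criterion A) and at least one
*function* signature (cytolytic activity or IFN-gamma response,
criterion B), and it is not overexpressed by purified T or NK cells
(criterion C): cyt = A and B and not C.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lasso import LassoCVResult, lasso_cv
from .matrix import ExpressionMatrix

#: default signature -> criterion map; phenotype signatures feed criterion A,
#: function signatures feed criterion B.
DEFAULT_SIGNATURE_KINDS = {
    "CD4_T": "phenotype",
    "CD8_T": "phenotype",
    "CYT": "function",
    "IFNG": "function",
}

#: default signature -> GLM family map mirroring the use of gaussian models
#: for CYT / IFN-gamma scores and poisson models for cell-type abundance
#: (Xcell-type) scores.
DEFAULT_FAMILY_MAP = {
    "CD4_T": "poisson",
    "CD8_T": "poisson",
    "CYT": "gaussian",
    "IFNG": "gaussian",
}


# ----------------------------------------------------------------------
# signature scores
# ----------------------------------------------------------------------

def cyt_score(g1: Sequence[float], g2: Sequence[float]) -> np.ndarray:
    """Cytolytic activity score: per-sample geometric mean of a granzyme
    and perforin expression, sqrt(g1 * g2)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("gene expression vectors must have equal length")
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("expression must be nonnegative")
    return np.sqrt(g1 * g2)


def cyt_score_from_matrix(
    expr: ExpressionMatrix, genes: tuple[str, str] = ("GZMA", "PRF1")
) -> pd.Series:
    """CYT score for every sample of an expression matrix.

    The gene pair is configurable; GZMA+PRF1 is the default with
    GZMB+PRF1 the usual alternative.
    """
    for g in genes:
        if g not in expr.feature_ids:
            raise KeyError(f"gene {g!r} not present in the expression matrix")
    return pd.Series(
        cyt_score(expr.row(genes[0]), expr.row(genes[1])),
        index=expr.sample_ids,
        name="CYT",
    )


def ssgsea_score(
    expression: Sequence[float],
    gene_ids: Sequence[str],
    gene_set: Sequence[str],
    weight_exponent: float = 0.25,
) -> float:
    """Single-sample gene-set enrichment score (running-sum convention).

    Genes are ordered by decreasing expression (ties broken by input
    order, making the score deterministic); the score is the sum over
    positions of the difference between the weighted cumulative
    distribution of in-set genes (weights = rank magnitude to the
    ``weight_exponent`` power) and the uniform cumulative distribution of
    out-of-set genes.  A set covering every measured gene scores 0 by
    convention.
    """
    expression = np.asarray(expression, dtype=float)
    gene_ids = list(gene_ids)
    if expression.shape[0] != len(gene_ids):
        raise ValueError("expression and gene_ids must align")
    in_set = np.array([g in set(gene_set) for g in gene_ids])
    if not in_set.any():
        raise ValueError("gene set has empty intersection with measured genes")
    n = len(gene_ids)
    if in_set.all():
        return 0.0
    # stable descending sort: highest expression first, input order on ties
    order = np.argsort(-expression, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # highest expression -> rank n
    w = np.abs(ranks[order]) ** weight_exponent
    hit = in_set[order]
    p_in = np.cumsum(np.where(hit, w, 0.0))
    p_in /= p_in[-1]
    p_out = np.cumsum(~hit) / (n - in_set.sum())
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    log2cpm: ExpressionMatrix,
    gene_set: Sequence[str],
    weight_exponent: float = 0.25,
) -> pd.Series:
    """ssGSEA score of one gene set for every sample."""
    vals = [
        ssgsea_score(log2cpm.values[:, j], log2cpm.feature_ids, gene_set, weight_exponent)
        for j in range(log2cpm.n_samples)
    ]
    return pd.Series(vals, index=log2cpm.sample_ids, name="ssgsea")


# ----------------------------------------------------------------------
# penalized association
# ----------------------------------------------------------------------

def lasso_fit(
    X: pd.DataFrame,
    y: Sequence[float],
    family: str = "gaussian",
    n_folds: int = 10,
    seed: int = 0,
    signature_name: str = "",
    cancer_type: str = "",
) -> tuple[pd.DataFrame, LassoCVResult]:
    """Associate provirus expression with one signature in one cancer.

    Parameters
    ----------
    X
        Samples x proviruses log2(CPM+1) design (unstandardized).
    y
        Signature value per sample.
    family
        ``gaussian`` (CYT, IFN-gamma) or ``poisson`` (cell-type scores).

    Returns the per-provirus association table (columns herv_id,
    signature, cancer_type, coefficient, selected, lambda_used, family)
    and the underlying cross-validation result.  A provirus is
    *selected* iff its coefficient at the CV-optimal penalty is strictly
    positive.
    """
    fit = lasso_cv(X.to_numpy(dtype=float), np.asarray(y, dtype=float),
                   family=family, n_folds=n_folds, seed=seed)
    table = pd.DataFrame(
        {
            "herv_id": list(X.columns),
            "signature": signature_name,
            "cancer_type": cancer_type,
            "coefficient": fit.coef,
            "selected": fit.coef > 0,
            "lambda_used": fit.lambda_min,
            "family": family,
        }
    )
    return table, fit


def associate_signatures(
    log2cpm: ExpressionMatrix,
    metadata: pd.DataFrame,
    signatures: pd.DataFrame,
    signature_kinds: Mapping[str, str] | None = None,
    family_map: Mapping[str, str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the penalized association per cancer type and per signature.

    ``metadata`` needs columns sample_id, cancer_type, tissue_class; only
    tumor samples enter the models.  ``signatures`` is a long table with
    columns sample_id, signature, value.  Fold assignment derives from
    ``seed`` jointly with the cancer type and signature name so each
    model is independently reproducible.
    """
    signature_kinds = dict(signature_kinds or DEFAULT_SIGNATURE_KINDS)
    family_map = dict(family_map or DEFAULT_FAMILY_MAP)
    tumor = metadata[metadata["tissue_class"] == "tumor"]
    tables = []
    for c_idx, cancer in enumerate(sorted(tumor["cancer_type"].unique())):
        sample_ids = tumor.loc[tumor["cancer_type"] == cancer, "sample_id"].tolist()
        X = log2cpm.subset_samples(sample_ids).to_dataframe().T
        for s_idx, sig in enumerate(sorted(signature_kinds)):
            sv = signatures[signatures["signature"] == sig].set_index("sample_id")["value"]
            y = sv.reindex(sample_ids).to_numpy(dtype=float)
            if np.any(np.isnan(y)):
                raise ValueError(f"signature {sig!r} missing for some {cancer} samples")
            folds = min(n_folds, len(sample_ids))
            sub_seed = (seed * 1_000_003 + c_idx * 1009 + s_idx) % (2**31 - 1)
            table, _ = lasso_fit(
                X, y, family=family_map.get(sig, "gaussian"), n_folds=folds,
                seed=sub_seed, signature_name=sig, cancer_type=cancer,
            )
            table["kind"] = signature_kinds[sig]
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


# ----------------------------------------------------------------------
# criterion C and the final rule
# ----------------------------------------------------------------------

def pbmc_overexpression(
    sorted_log2cpm: ExpressionMatrix,
    cell_labels: Sequence[str],
    fc_threshold: float = 2.0,
) -> pd.Series:
    """Criterion C: overexpression in purified T or NK cells.

    For each provirus, compares the mean log2(CPM+1) in T cells (then NK
    cells) against the mean over all remaining sorted PBMC classes; C is
    true when either difference reaches log2(fc_threshold).  The
    boundary is inclusive.
    """
    labels = np.asarray([_canon_cell(c) for c in cell_labels])
    for needed in ("T", "NK"):
        if needed not in labels:
            raise ValueError(f"sorted-cell data lacks class {needed!r}")
    if not np.any(~np.isin(labels, ["T", "NK"])):
        raise ValueError("sorted-cell data lacks a non-T/NK PBMC class")
    log2_th = np.log2(fc_threshold)
    flags = np.zeros(sorted_log2cpm.n_features, dtype=bool)
    for cls in ("T", "NK"):
        own = sorted_log2cpm.values[:, labels == cls].mean(axis=1)
        rest = sorted_log2cpm.values[:, labels != cls].mean(axis=1)
        flags |= (own - rest) >= log2_th
    return pd.Series(flags, index=sorted_log2cpm.feature_ids, name="C")


def _canon_cell(label: str) -> str:
    label = str(label)
    if label in ("T", "sorted_T"):
        return "T"
    if label in ("NK", "sorted_NK"):
        return "NK"
    return "other"


def annotate_cyt(
    cah_ids: Sequence[str],
    associations: pd.DataFrame,
    c_flags: pd.Series,
) -> pd.DataFrame:
    """Apply the A and B not C rule to the cancer-associated proviruses.

    A provirus satisfies A when selected for >=1 phenotype signature in
    >=1 cancer, B likewise for function signatures; C comes from the
    purified-cell comparison.  Output is one row per CAH with boolean
    columns A, B, C, cyt; the result does not depend on the order of
    cancer types or signatures.
    """
    if "kind" not in associations.columns:
        associations = associations.assign(
            kind=associations["signature"].map(DEFAULT_SIGNATURE_KINDS)
        )
    sel = associations[associations["selected"]]
    a_ids = set(sel.loc[sel["kind"] == "phenotype", "herv_id"])
    b_ids = set(sel.loc[sel["kind"] == "function", "herv_id"])
    rows = []
    for herv in sorted(cah_ids):
        a = herv in a_ids
        b = herv in b_ids
        c = bool(c_flags.get(herv, False))
        rows.append({"herv_id": herv, "A": a, "B": b, "C": c, "cyt": a and b and not c})
    return pd.DataFrame(rows, columns=["herv_id", "A", "B", "C", "cyt"])
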