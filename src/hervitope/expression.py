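"""Normalization, negative-binomial differential expression and
cancer-associated HERV (CAH) annotation.

The differential test is a self-contained negative-binomial Wald test in
the DESeq tradition: median-of-ratios size factors, per-feature
method-of-moments dispersion (floored), a per-group log-link NB fit by
Newton iteration, a Wald test on the log2 fold change, Benjamini-Hochberg
correction across features, and an optional normal-prior shrinkage of the
fold changes.  It does not reproduce DESeq2's Cox-Reid dispersion
estimation or apeglm's heavy-tailed prior; externally computed tables in
the same schema can be supplied anywhere a differential result is
consumed.

The CAH rule mirrors the tumor-specificity filter of the discovery
pipeline: a provirus overexpressed at least ``fc_threshold``-fold in one
or more cancers, and never overexpressed in the matched peritumoral
tissue of any cancer, is cancer-associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

_LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization followed by log2(x + 1).

    Each sample is scaled so its column sums to 10^6 over all features,
    then transformed elementwise to log2(CPM + 1).
    """
    if counts.layer != "raw_counts":
        raise ValueError(f"expected raw_counts layer, got {counts.layer!r}")
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = ", ".join(counts.sample_ids[i] for i in zero)
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    cpm = counts.values / totals * 1e6
    return ExpressionMatrix(
        np.log2(cpm + 1.0), counts.feature_ids, counts.sample_ids, layer="log2cpm"
    )


def cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    if counts.layer != "raw_counts":
        raise ValueError(f"expected raw_counts layer, got {counts.layer!r}")
    totals = counts.values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("sample with zero total counts")
    return ExpressionMatrix(
        counts.values / totals * 1e6, counts.feature_ids, counts.sample_ids, layer="cpm"
    )


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NA passthrough.

    NaN entries are excluded from the ranking (and from the denominator)
    and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
# negative-binomial Wald test
# ----------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Ratios are taken to the geometric mean of each feature over samples,
    restricted to features expressed in every sample.  Falls back to
    library-size ratios when no feature is all-positive.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 1:
        logc = np.log(counts[positive])
        log_geomean = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_geomean, axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def _dispersion_mom(counts: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion, pooled within groups.

    Uses normalized counts; Var = mu + alpha * mu^2 solved for alpha and
    floored at ``DISPERSION_FLOOR``.
    """
    norm = counts / sf
    n_features = counts.shape[0]
    ss = np.zeros(n_features)
    dof = 0
    for g in np.unique(groups):
        cols = norm[:, groups == g]
        if cols.shape[1] >= 2:
            ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
            dof += cols.shape[1] - 1
    pooled_var = ss / max(dof, 1)
    base_mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - base_mean) / base_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _fit_group_log_mean(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the per-feature log mean for one group of samples.

    Model: K_ij ~ NB(mu_ij = s_j * exp(beta_i), alpha_i).  Newton-Raphson
    on beta with the expected (Fisher) information; returns (beta, info).
    """
    eps = 1e-8
    beta = np.log(np.maximum((counts / sf).mean(axis=1), eps))
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((counts - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, eps)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, -30.0, 30.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = sf[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def _shrink_lfc(lfc: np.ndarray, se: np.ndarray, min_prior_var: float = 0.0625) -> np.ndarray:
    """Normal-prior posterior-mode shrinkage of log2 fold changes.

    The zero-centred prior variance is a robust upper-tail estimate of
    the spread of the MLE fold changes (99th percentile of |log2FC|
    rescaled by the matching normal quantile) in excess of the typical
    sampling variance, so genuinely large effects are shrunk little
    while noise-dominated estimates are pulled strongly toward zero.
    Each estimate is multiplied by tau^2 / (tau^2 + se^2), which never
    flips a sign and never increases magnitude.
    """
    ok = np.isfinite(lfc) & np.isfinite(se)
    if ok.sum() < 3:
        tau2 = min_prior_var
    else:
        spread = float(np.quantile(np.abs(lfc[ok]), 0.99)) / 2.326
        tau2 = max(spread**2 - float(np.median(se[ok] ** 2)), min_prior_var)
    with np.errstate(invalid="ignore"):
        return lfc * tau2 / (tau2 + se**2)


def nb_differential(
    counts: ExpressionMatrix,
    group_labels,
    *,
    reference: str | None = None,
    shrink: bool = True,
    comparison: str = "",
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on raw counts.

    Parameters
    ----------
    counts
        Raw-count matrix (features x samples).
    group_labels
        One label per sample; exactly two distinct labels, each with at
        least two samples.
    reference
        The label treated as the denominator (e.g. peritumoral tissue).
        Positive log2 fold changes mean higher expression in the other
        group.  Defaults to the lexicographically smaller label.
    shrink
        Apply normal-prior shrinkage to the reported log2 fold change.
        P-values are always computed from the unshrunken Wald statistic.

    Returns
    -------
    DataFrame with columns herv_id, baseMean, log2FC, FC, stat, pvalue,
    padj, comparison.  All-zero features get NaN statistics and are
    excluded from the BH denominator.
    """
    if counts.layer != "raw_counts":
        raise ValueError("nb_differential requires raw counts")
    labels = np.asarray(group_labels)
    if labels.shape[0] != counts.n_samples:
        raise ValueError("one group label per sample required")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if reference is None:
        reference = uniq[0]
    if reference not in uniq:
        raise ValueError(f"reference {reference!r} not among groups {uniq}")
    other = uniq[1] if reference == uniq[0] else uniq[0]
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    K = counts.values
    sf = size_factors(K)
    norm = K / sf
    base_mean = norm.mean(axis=1)
    groups01 = (labels == other).astype(int)
    alpha = _dispersion_mom(K, sf, groups01)

    ref_cols = labels == reference
    oth_cols = labels == other
    beta_ref, info_ref = _fit_group_log_mean(K[:, ref_cols], sf[ref_cols], alpha)
    beta_oth, info_oth = _fit_group_log_mean(K[:, oth_cols], sf[oth_cols], alpha)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = (beta_oth - beta_ref) / _LN2
        se = np.sqrt(1.0 / info_oth + 1.0 / info_ref) / _LN2
        stat = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    all_zero = base_mean == 0
    lfc[all_zero] = np.nan
    se[all_zero] = np.nan
    stat = np.where(all_zero, np.nan, stat)
    pvalue = np.where(all_zero, np.nan, pvalue)

    lfc_out = _shrink_lfc(lfc, se) if shrink else lfc
    padj = bh_adjust(pvalue)

    return pd.DataFrame(
        {
            "herv_id": counts.feature_ids,
            "baseMean": base_mean,
            "log2FC": lfc_out,
            "FC": np.power(2.0, lfc_out),
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "comparison": comparison or f"{other}_vs_{reference}",
        }
    )


# ----------------------------------------------------------------------
# CAH annotation
# ----------------------------------------------------------------------

@dataclass
class CahSet:
    """Outcome of the cancer-associated HERV filter."""

    per_cancer: dict[str, set[str]] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)
    cah_ids: set[str] = field(default_factory=set)

    def __contains__(self, herv_id: str) -> bool:
        return herv_id in self.cah_ids


def annotate_cah(
    de_by_cancer: dict[str, pd.DataFrame],
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.05,
    require_significance: bool = True,
) -> CahSet:
    """Cancer-associated HERV annotation across tumor-vs-peritumoral tests.

    Exclusion comes first: any provirus overexpressed at least
    ``fc_threshold``-fold in peritumoral tissue (log2FC at or below the
    negative threshold) in *any* cancer is removed.  The remaining
    proviruses overexpressed at least ``fc_threshold``-fold in at least
    one tumor are cancer-associated.  With ``require_significance``,
    both rules additionally demand padj below ``padj_threshold``
    (pure fold-change mode otherwise).  The sign convention is fixed:
    positive log2FC means higher expression in the tumor.
    """
    if not de_by_cancer:
        raise ValueError("at least one tumor-vs-normal comparison is required")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    log2_th = np.log2(fc_threshold)

    per_cancer: dict[str, set[str]] = {}
    excluded: set[str] = set()
    for cancer in sorted(de_by_cancer):
        df = de_by_cancer[cancer]
        lfc = df["log2FC"].to_numpy(dtype=float)
        if require_significance:
            padj = df["padj"].to_numpy(dtype=float)
            sig = ~np.isnan(padj) & (padj < padj_threshold)
        else:
            sig = ~np.isnan(lfc)
        up = sig & (lfc >= log2_th)
        down = sig & (lfc <= -log2_th)
        ids = df["herv_id"].to_numpy()
        per_cancer[cancer] = set(ids[up])
        excluded |= set(ids[down])

    union_up = set().union(*per_cancer.values()) if per_cancer else set()
    return CahSet(per_cancer=per_cancer, excluded=excluded, cah_ids=union_up - excluded)
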