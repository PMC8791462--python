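"""Expression scores, survival stratification and methylation context.

The pi value combines statistical and biological significance for one
provirus in one tumor-vs-normal comparison: pi = log2FC * log10(1/p).
The cumulative epitope score sums pi over every provirus containing the
epitope sequence.  The survival analysis averages log2(CPM+1) over a
provirus set per patient, splits the cohort into terciles of that score
and compares overall survival between terciles with the log-rank
(Mantel-Cox) test.  The methylation context correlates a provirus'
expression with the mean beta value of the 10 probes nearest its locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .expression import bh_adjust
from .matrix import ExpressionMatrix

P_FLOOR = 1e-300


def pi_value(log2fc: float, p: float, p_floor: float | None = P_FLOOR) -> float:
    """pi = log2FC * log10(1/p); p is floored to avoid infinities."""
    if p_floor is None:
        if p <= 0:
            raise ValueError("p must be positive when flooring is disabled")
    else:
        p = max(p, p_floor)
    if p > 1:
        raise ValueError("p must not exceed 1")
    return float(log2fc * np.log10(1.0 / p))


def pi_values(de_table: pd.DataFrame, use_adjusted: bool = True) -> pd.Series:
    """Per-provirus pi values from a differential-expression table.

    ``use_adjusted`` selects the BH-adjusted p (the published tables
    report adjusted values); set False for raw p-values.
    """
    pcol = "padj" if use_adjusted else "pvalue"
    out = {}
    for row in de_table.itertuples(index=False):
        p = getattr(row, pcol)
        lfc = row.log2FC
        out[row.herv_id] = (
            np.nan if (pd.isna(p) or pd.isna(lfc)) else pi_value(lfc, float(p))
        )
    return pd.Series(out, name="pi")


def cumulative_epitope_score(
    peptide: str, containing_herv_pis: Mapping[str, float] | Sequence[float]
) -> float:
    """Sum of pi over all proviruses containing the peptide sequence."""
    vals = (
        list(containing_herv_pis.values())
        if isinstance(containing_herv_pis, Mapping)
        else list(containing_herv_pis)
    )
    if not vals:
        warnings.warn(f"peptide {peptide!r} contained in no provirus; score 0")
        return 0.0
    return float(np.sum(vals))


def cumulative_epitope_scores(
    presence: pd.DataFrame, pi: pd.Series
) -> pd.Series:
    """Cumulative score per peptide given a presence matrix and pi values.

    ``presence`` is the peptide x provirus boolean matrix from
    relocation; proviruses without a pi value contribute 0.
    """
    pi_full = pi.reindex(presence.columns).fillna(0.0)
    scores = presence.to_numpy(dtype=float) @ pi_full.to_numpy()
    return pd.Series(scores, index=presence.index, name="cumulative_score")


# ----------------------------------------------------------------------
# survival
# ----------------------------------------------------------------------

TERCILE_LABELS = ("low", "intermediate", "high")


def herv_set_score(log2cpm: ExpressionMatrix, herv_ids: Sequence[str]) -> pd.Series:
    """Per-sample mean log2(CPM+1) over a provirus set."""
    herv_ids = list(herv_ids)
    if not herv_ids:
        raise ValueError("empty provirus set")
    missing = [h for h in herv_ids if h not in log2cpm.feature_ids]
    if missing:
        raise KeyError(f"ids missing from the matrix: {missing[:5]}")
    sub = log2cpm.subset_features(herv_ids)
    return pd.Series(sub.values.mean(axis=0), index=log2cpm.sample_ids, name="set_score")


def tercile_groups(scores: pd.Series) -> pd.Series:
    """Split a cohort into score terciles (low / intermediate / high).

    Boundaries follow the empirical 1/3 and 2/3 quantiles; samples tied
    at a boundary are assigned in stable input order so group sizes
    differ by at most one.  A constant score collapses the cohort into a
    single group, with a warning.
    """
    scores = pd.Series(scores)
    n = len(scores)
    if n == 0:
        raise ValueError("empty cohort")
    if scores.nunique() == 1:
        warnings.warn("constant set score; all samples fall in one tercile group")
        return pd.Series(["low"] * n, index=scores.index, name="tercile")
    order = np.argsort(scores.to_numpy(), kind="stable")
    groups = np.empty(n, dtype=object)
    for label, chunk in zip(TERCILE_LABELS, np.array_split(order, 3)):
        groups[chunk] = label
    return pd.Series(groups, index=scores.index, name="tercile")


@dataclass
class LogrankResult:
    statistic: float
    pvalue: float
    df: int


def logrank_test(
    time: Sequence[float], event: Sequence[bool], group: Sequence
) -> LogrankResult:
    """K-group log-rank (Mantel-Cox) test; chi-square with k-1 df."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if len(set(group.tolist())) < 2:
        raise ValueError("at least two groups required")
    if not event.any():
        raise ValueError("no events observed")
    res = multivariate_logrank_test(time, group, event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        df=len(set(group.tolist())) - 1,
    )


def survival_by_set_score(
    log2cpm: ExpressionMatrix,
    herv_ids: Sequence[str],
    survival: pd.DataFrame,
) -> tuple[pd.DataFrame, LogrankResult]:
    """Tercile-stratified survival comparison for a provirus-set score.

    ``survival`` needs columns sample_id, time, event.  Returns the
    per-sample cohort table (set_score, tercile, time, event) and the
    log-rank result across terciles.
    """
    scores = herv_set_score(log2cpm, herv_ids)
    surv = survival.set_index("sample_id").loc[scores.index]
    cohort = pd.DataFrame(
        {
            "sample_id": scores.index,
            "set_score": scores.to_numpy(),
            "tercile": tercile_groups(scores).to_numpy(),
            "time": surv["time"].to_numpy(dtype=float),
            "event": surv["event"].to_numpy(dtype=bool),
        }
    )
    res = logrank_test(cohort["time"], cohort["event"], cohort["tercile"])
    return cohort, res


def kaplan_meier_curves(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival curves per tercile group, for plotting."""
    from lifelines import KaplanMeierFitter

    curves = {}
    for label, sub in cohort.groupby("tercile"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(label))
        curves[str(label)] = kmf.survival_function_
    return curves


# ----------------------------------------------------------------------
# methylation context
# ----------------------------------------------------------------------

@dataclass
class MethylationContext:
    herv_id: str
    probe_ids: list[str]
    mean_beta: pd.Series  # per-sample mean beta over the nearest probes
    rho: float
    pvalue: float


def nearest_probes(
    locus: tuple[str, int, int], probes: pd.DataFrame, k: int = 10
) -> pd.DataFrame:
    """The k probes nearest a locus midpoint on the same chromosome.

    ``probes`` needs columns probe_id, chrom, pos (plus beta columns).
    Distances are measured from the locus midpoint; ties resolve by
    probe position, then probe id.
    """
    chrom, start, end = locus
    on_chrom = probes[probes["chrom"] == chrom]
    if len(on_chrom) < k:
        raise ValueError(f"fewer than {k} probes on chromosome {chrom!r}")
    mid = (start + end) / 2.0
    dist = (on_chrom["pos"] - mid).abs()
    order = on_chrom.assign(_dist=dist).sort_values(
        ["_dist", "pos", "probe_id"], kind="stable"
    )
    return order.head(k).drop(columns="_dist")


def methylation_correlation(
    herv_id: str,
    locus: tuple[str, int, int],
    probes: pd.DataFrame,
    expression: pd.Series,
    k: int = 10,
    method: str = "spearman",
) -> MethylationContext:
    """Correlate provirus expression with nearby mean methylation.

    Selects the ``k`` nearest probes, averages their beta values per
    sample, and correlates (Spearman by default, Pearson by flag) that
    mean with the provirus' log2(CPM+1) across samples.  A negative
    correlation indicates demethylation-linked expression.
    """
    near = nearest_probes(locus, probes, k)
    sample_cols = [c for c in probes.columns if c not in ("probe_id", "chrom", "pos")]
    common = [s for s in expression.index if s in sample_cols]
    if len(common) < 3:
        raise ValueError("need >=3 samples shared between expression and probes")
    mean_beta = near[common].mean(axis=0)
    mean_beta.index = common
    if method == "spearman":
        rho, p = stats.spearmanr(mean_beta.to_numpy(), expression[common].to_numpy())
    elif method == "pearson":
        rho, p = stats.pearsonr(mean_beta.to_numpy(), expression[common].to_numpy())
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return MethylationContext(
        herv_id=herv_id,
        probe_ids=near["probe_id"].tolist(),
        mean_beta=mean_beta,
        rho=float(rho),
        pvalue=float(p),
    )


def methylation_screen(
    loci: pd.DataFrame,
    probes: pd.DataFrame,
    log2cpm: ExpressionMatrix,
    k: int = 10,
    method: str = "spearman",
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Methylation correlation across proviruses with BH correction.

    ``loci`` needs columns name, chrom, start, end (one row per
    provirus).  Output columns: herv_id, rho, pvalue, padj, label with
    label in {demethylation, methylation, none}.
    """
    rows = []
    for row in loci.itertuples(index=False):
        if row.name not in log2cpm.feature_ids:
            continue
        expr = pd.Series(log2cpm.row(row.name), index=log2cpm.sample_ids)
        ctx = methylation_correlation(
            row.name, (row.chrom, int(row.start), int(row.end)), probes, expr, k, method
        )
        rows.append({"herv_id": row.name, "rho": ctx.rho, "pvalue": ctx.pvalue})
    out = pd.DataFrame(rows, columns=["herv_id", "rho", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    sig = out["padj"] < padj_threshold
    out["label"] = np.select(
        [sig & (out["rho"] < 0), sig & (out["rho"] > 0)],
        ["demethylation", "methylation"],
        default="none",
    )
    return out
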