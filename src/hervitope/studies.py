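"""Validation studies: ground-truth recovery, statistical calibration
and the end-to-end screening funnel on synthetic cohorts.

These routines quantify how well the pipeline recovers planted structure
under the reference simulation conditions (200 proviruses, 100 tumor /
20 peritumoral samples, log2 effect +2, NB dispersion 0.1) and whether
the statistical tests hold their nominal error rates.  They are used by
the test suite and by the acceptance script; every quantity is computed
from scratch from a seeded simulation.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .epitopes import (
    AnchorHeuristicPredictor,
    homology_filter,
    kmers,
    predict_binding,
    proteome_exclusion,
    relocate_epitopes,
    six_frame_orfs,
)
from .expression import annotate_cah, nb_differential, normalize
from .immune import annotate_cyt, associate_signatures, pbmc_overexpression
from .lasso import _fit_one, lasso_path
from .scoring import logrank_test
from .sim import SimulationConfig, simulate_bundle, simulate_counts, simulate_signatures


def _tumor_normal_de(counts, metadata):
    m = metadata[metadata["tissue_class"].isin(["tumor", "peritumoral"])]
    de = {}
    for cancer in sorted(m["cancer_type"].unique()):
        sm = m[m["cancer_type"] == cancer]
        sub = counts.subset_samples(sm["sample_id"].tolist())
        labels = sm.set_index("sample_id").loc[sub.sample_ids, "tissue_class"]
        de[cancer] = nb_differential(sub, labels.to_numpy(), reference="peritumoral")
    return de


def cah_cyt_recovery(seeds: Sequence[int], config: SimulationConfig | None = None) -> dict:
    """Planted-structure recovery under the reference conditions.

    For each seed: simulate the cohort, run differential expression and
    the CAH filter (|log2FC| >= 1, padj < 0.05), then the penalized
    association restricted to the called CAHs plus the purified-cell
    exclusion, and score recall / false-positive rates against the
    planted truth.  False-positive denominators are the null proviruses
    (all proviruses minus the planted set).
    """
    base = config or SimulationConfig()
    cah_recalls, cah_fprs, cyt_recalls, cyt_fprs = [], [], [], []
    for seed in seeds:
        cfg = replace(base, rng_seed=int(seed))
        counts, metadata = simulate_counts(cfg)
        log2cpm = normalize(counts)
        bundle_truth_cah = {h for h, e in cfg.planted_cah_effects.items() if e != 0}
        truth_cyt = set(cfg.planted_cyt_ids) - set(cfg.planted_c_ids)

        de = _tumor_normal_de(counts, metadata)
        cah = annotate_cah(de, fc_threshold=2.0, padj_threshold=0.05)
        nulls_cah = set(cfg.herv_ids) - bundle_truth_cah
        cah_recalls.append(len(cah.cah_ids & bundle_truth_cah) / len(bundle_truth_cah))
        cah_fprs.append(len(cah.cah_ids & nulls_cah) / len(nulls_cah))

        signatures = simulate_signatures(
            log2cpm, metadata, cfg.planted_cyt_ids,
            cfg.signature_noise_sd, int(seed), cfg.noise_relative,
        )
        cah_ids = sorted(cah.cah_ids)
        if not cah_ids:
            cyt_recalls.append(0.0)
            cyt_fprs.append(0.0)
            continue
        assoc = associate_signatures(
            log2cpm.subset_features(cah_ids), metadata, signatures, seed=int(seed)
        )
        sorted_meta = metadata[metadata["tissue_class"].str.startswith("sorted")]
        c_flags = pbmc_overexpression(
            log2cpm.subset_samples(sorted_meta["sample_id"].tolist()),
            sorted_meta["tissue_class"].tolist(),
        )
        cyt_tbl = annotate_cyt(cah_ids, assoc, c_flags)
        called = set(cyt_tbl.loc[cyt_tbl["cyt"], "herv_id"])
        nulls_cyt = set(cfg.herv_ids) - truth_cyt
        cyt_recalls.append(len(called & truth_cyt) / len(truth_cyt))
        cyt_fprs.append(len(called & nulls_cyt) / len(nulls_cyt))
    return {
        "cah_recall": float(np.mean(cah_recalls)),
        "cah_fpr": float(np.mean(cah_fprs)),
        "cyt_recall": float(np.mean(cyt_recalls)),
        "cyt_fpr": float(np.mean(cyt_fprs)),
        "n_seeds": len(list(seeds)),
    }


def nb_wald_type1(n_reps: int = 200, seed: int = 0, n_hervs: int = 100,
                  n_tumor: int = 20, n_normal: int = 20) -> dict:
    """Pooled type-I error of the NB Wald test under the null."""
    hits = total = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_hervs=n_hervs, n_tumor=n_tumor, n_normal=n_normal,
            planted_cah_effects={}, planted_cyt_ids=(),
            rng_seed=(seed * 100_003 + r) % (2**31 - 1),
        )
        counts, metadata = simulate_counts(cfg)
        de = _tumor_normal_de(counts, metadata)
        p = next(iter(de.values()))["pvalue"].dropna().to_numpy()
        hits += int((p < 0.05).sum())
        total += p.size
    return {"type1": hits / total, "n_tests": total, "n_reps": n_reps}


def logrank_type1(n_reps: int = 200, seed: int = 0, n_per_group: int = 50) -> dict:
    """Type-I error of the two-group log-rank test under equal
    exponential hazards with uniform administrative censoring."""
    rng = np.random.default_rng([seed, 909])
    hits = 0
    for _ in range(n_reps):
        t = rng.exponential(1.0, size=2 * n_per_group)
        cens = rng.uniform(0, 2.0, size=2 * n_per_group)
        time = np.minimum(t, cens)
        event = t <= cens
        group = np.repeat(["a", "b"], n_per_group)
        res = logrank_test(time, event, group)
        hits += res.pvalue < 0.05
    return {"type1": hits / n_reps, "n_reps": n_reps}


def logrank_power(n_reps: int = 100, seed: int = 0, hazard_ratio: float = 3.0,
                  n_per_group: int = 40) -> dict:
    """Power of the log-rank test at a planted hazard ratio between the
    extreme groups, with roughly 50% censoring."""
    rng = np.random.default_rng([seed, 910])
    hits = 0
    for _ in range(n_reps):
        t = np.r_[
            rng.exponential(1.0, size=n_per_group),
            rng.exponential(1.0 / hazard_ratio, size=n_per_group),
        ]
        cens = rng.uniform(0, 2 * np.log(2.0), size=2 * n_per_group)
        time, event = np.minimum(t, cens), t <= cens
        res = logrank_test(time, event, np.repeat(["lo", "hi"], n_per_group))
        hits += res.pvalue < 0.05
    return {"power": hits / n_reps, "n_reps": n_reps}


def soft_threshold_error(seed: int = 0, n: int = 200, n_lambdas: int = 50) -> dict:
    """Max deviation of the single-predictor lasso from its closed form.

    With one standardized predictor the exact solution is the
    soft-threshold S(rho, lambda) of the inner product rho = x'y/n.
    """
    rng = np.random.default_rng([seed, 911])
    x = rng.normal(size=n)
    x -= x.mean()
    x /= np.sqrt((x**2).mean())
    z = rng.normal(size=n)
    z -= z.mean()
    z -= x * (x @ z) / (x @ x)
    rho = 0.9
    y = rho * x + 0.25 * z
    grid = np.geomspace(1.5, 1e-3, n_lambdas)
    _, coefs, _ = lasso_path(np.ascontiguousarray(x[:, None]), y, lambdas=grid)
    expected = np.maximum(rho - np.sort(grid)[::-1], 0.0)
    err = float(np.max(np.abs(coefs[0] - expected)))

    # lambda = 0 reduces to OLS on a full-rank design
    X = rng.normal(size=(40, 5))
    yy = X @ rng.normal(size=5) + rng.normal(size=40)
    beta = np.zeros(5)
    beta, b0 = _fit_one(np.ascontiguousarray(X), yy, 0.0, "gaussian", beta, 0.0,
                        max_iter=50000)
    ols = np.linalg.lstsq(np.column_stack([np.ones(40), X]), yy, rcond=None)[0]
    ols_err = float(np.max(np.abs(np.r_[b0, beta] - ols)))
    return {"soft_threshold_max_abs_error": err, "ols_max_abs_error": ols_err,
            "n_lambdas": n_lambdas}


def screening_funnel(seed: int = 0, config: SimulationConfig | None = None) -> dict:
    """End-to-end check that planted epitopes survive and decoys die at
    the predicted stage.

    Screens the ground-truth cyt proviruses plus the Env-decoy host,
    then verifies: (1) every planted strong-binding, non-self epitope is
    in the final candidate list with its ground-truth sharing count
    (relocation over all proviruses); (2) the Env-only peptide dies at
    the homology stage; (3) the weak binder dies at the rank stage;
    (4) the self-matching epitope dies at the proteome stage.
    """
    cfg = replace(config or SimulationConfig(), rng_seed=int(seed))
    bundle = simulate_bundle(cfg)
    truth = bundle.planted_epitopes.set_index("peptide")
    seqs = bundle.herv_sequences

    env_hosts = {
        h for h in truth.loc[truth["source"] == "HML2_Env", "herv_ids"]
        .str.split(";").explode() if h
    }
    screen_ids = sorted(set(bundle.config.planted_cyt_ids) | env_hosts)

    orfs = []
    for hid in screen_ids:
        orfs.extend(six_frame_orfs(seqs[hid], 10, herv_id=hid))
    retained = homology_filter(orfs, bundle.reference_proteins)
    peptides = sorted({p for o in retained for p in kmers(o.aa_seq, 9)})
    binding = predict_binding(peptides, "A*02:01", AnchorHeuristicPredictor(), 0.5)
    strong = binding.loc[binding["strong_binder"], "peptide"].tolist()
    kept, flagged = proteome_exclusion(strong, bundle.proteome)
    presence, sharing = relocate_epitopes(kept, seqs) if kept else (None, pd.Series(dtype=int))

    expected = truth[truth["strong"] & ~truth["in_proteome"]
                     & (truth["source"] != "HML2_Env")]
    recovered = sum(p in kept for p in expected.index)
    sharing_correct = sum(
        p in kept and sharing.loc[p] == len(row["herv_ids"].split(";"))
        for p, row in expected.iterrows()
    )
    env_pep = truth.index[truth["source"] == "HML2_Env"][0]
    weak_pep = truth.index[~truth["strong"]][0]
    self_pep = truth.index[truth["in_proteome"]][0]
    return {
        "n_expected": len(expected),
        "n_recovered": int(recovered),
        "n_sharing_correct": int(sharing_correct),
        "env_decoy_in_orf_kmers": env_pep in peptides,  # died at homology if False
        "weak_in_kmers": weak_pep in peptides,
        "weak_called_strong": weak_pep in strong,
        "self_called_strong": self_pep in strong,
        "self_flagged": self_pep in flagged,
    }
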