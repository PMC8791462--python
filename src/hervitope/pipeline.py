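"""End-to-end orchestration of the epitope-discovery pipeline.

Stage order: normalize -> differential expression (per cancer) ->
cancer-associated annotation -> cyt annotation (penalized association +
purified-cell exclusion) -> epitope screening (ORFs, homology, binding,
proteome exclusion) -> relocation / sharing -> expression scoring, with
optional survival stratification and methylation correlation.  Each
stage writes a provenance-tagged TSV into the output directory and
reports in/out record counts to the run manifest, which makes the
selection funnel auditable.  A failed stage aborts the run with the
stage named; outputs of completed stages are retained, and a resumed
run reuses them without recomputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as hio
from .epitopes import (
    AnchorHeuristicPredictor,
    RankTablePredictor,
    homology_filter,
    kmers,
    predict_binding,
    proteome_exclusion,
    relocate_epitopes,
    six_frame_orfs,
)
from .expression import annotate_cah, nb_differential, normalize
from .immune import (
    DEFAULT_FAMILY_MAP,
    DEFAULT_SIGNATURE_KINDS,
    annotate_cyt,
    associate_signatures,
    pbmc_overexpression,
)
from .matrix import ExpressionMatrix
from .scoring import cumulative_epitope_scores, methylation_screen, pi_values, survival_by_set_score


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and output location."""

    counts: str
    metadata: str
    signatures: str
    herv_sequences: str
    reference_proteins: str
    proteome: str
    outdir: str
    rank_table: str | None = None
    loci: str | None = None
    methylation: str | None = None
    survival: str | None = None
    fc_threshold: float = 2.0
    padj_threshold: float = 0.05
    require_significance: bool = True
    c_fc_threshold: float = 2.0
    identity_min: float = 90.0
    evalue_max: float = 0.05
    rank_cutoff: float = 0.5
    min_orf_len: int = 10
    k: int = 9
    allele: str = "A*02:01"
    keep_refs: tuple[str, ...] = ("Gag", "Pol")
    relocation_scope: str = "cahs"
    score_cancer: str | None = None
    n_folds: int = 10
    signature_kinds: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_KINDS))
    family_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relocation_scope not in ("cyt_hervs", "cahs", "all_hervs"):
            raise ValueError("relocation_scope must be cyt_hervs, cahs or all_hervs")
        if not 0 <= self.rank_cutoff:
            raise ValueError("rank_cutoff must be nonnegative")
        if self.k < 1 or self.min_orf_len < 1:
            raise ValueError("k and min_orf_len must be >= 1")
        if not 0 < self.padj_threshold <= 1:
            raise ValueError("padj_threshold must lie in (0, 1]")
        if self.fc_threshold <= 0 or self.c_fc_threshold <= 0:
            raise ValueError("fold-change thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "keep_refs" in data:
            data["keep_refs"] = tuple(data["keep_refs"])
        return cls(**data)


@dataclass
class PipelineResult:
    """Artifacts and funnel counts of one completed run."""

    outdir: Path
    manifest: dict
    cah_ids: list[str]
    cyt_ids: list[str]
    candidates: pd.DataFrame
    sharing: pd.Series
    scores: pd.DataFrame


def run_pipeline(config: PipelineConfig, resume: bool = False) -> PipelineResult:
    """Execute the full discovery pipeline from files on disk.

    With ``resume``, a stage whose primary output file already exists is
    loaded from disk instead of recomputed, so a run can restart after
    the last completed stage without drift.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only: where outputs land must not
    # change what they contain
    cfg_hash = hio.config_hash({k: v for k, v in asdict(config).items() if k != "outdir"})
    prov = dict(seed=config.seed, cfg_hash=cfg_hash)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "config": asdict(config),
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    # ---- load inputs ----
    stage = "load_inputs"
    try:
        counts = hio.read_counts(config.counts)
        metadata = hio.read_tsv(config.metadata)
        signatures = hio.read_tsv(config.signatures)
        sequences = hio.read_fasta(config.herv_sequences)
        ref_proteins = hio.read_fasta(config.reference_proteins)
        proteome = hio.read_fasta(config.proteome)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_hervs=counts.n_features, n_samples=counts.n_samples)

    # ---- normalize ----
    stage = "normalize"
    try:
        log2cpm = normalize(counts)
        hio.write_counts(log2cpm, outdir / "log2cpm.tsv", stage=stage, **prov)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_hervs=log2cpm.n_features)

    # ---- differential expression per cancer ----
    stage = "de"
    de_by_cancer: dict[str, pd.DataFrame] = {}
    try:
        tumor_meta = metadata[metadata["tissue_class"].isin(["tumor", "peritumoral"])]
        for cancer in sorted(tumor_meta["cancer_type"].unique()):
            path = outdir / f"de_{cancer}.tsv"
            if resume and path.exists():
                de_by_cancer[cancer] = hio.read_tsv(path)
                continue
            sub_meta = tumor_meta[tumor_meta["cancer_type"] == cancer]
            sub = counts.subset_samples(sub_meta["sample_id"].tolist())
            labels = sub_meta.set_index("sample_id").loc[sub.sample_ids, "tissue_class"]
            table = nb_differential(
                sub, labels.to_numpy(), reference="peritumoral",
                comparison=f"{cancer}_tumor_vs_peritumoral",
            )
            hio.write_tsv(table, path, stage=stage, **prov)
            de_by_cancer[cancer] = table
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_comparisons=len(de_by_cancer))

    # ---- CAH annotation ----
    stage = "annotate_cah"
    try:
        cah = annotate_cah(
            de_by_cancer,
            fc_threshold=config.fc_threshold,
            padj_threshold=config.padj_threshold,
            require_significance=config.require_significance,
        )
        cah_ids = sorted(cah.cah_ids)
        hio.write_tsv(pd.DataFrame({"herv_id": cah_ids}), outdir / "cah.tsv",
                      stage=stage, **prov)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_cah=len(cah_ids), n_excluded=len(cah.excluded))

    # ---- cyt annotation ----
    stage = "annotate_cyt"
    try:
        if not cah_ids:
            raise ValueError("no cancer-associated provirus survived the filter")
        cah_expr = log2cpm.subset_features(cah_ids)
        assoc_path = outdir / "associations.tsv"
        if resume and assoc_path.exists():
            associations = hio.read_tsv(assoc_path)
        else:
            associations = associate_signatures(
                cah_expr, metadata, signatures,
                signature_kinds=config.signature_kinds,
                family_map=config.family_map,
                n_folds=config.n_folds, seed=config.seed,
            )
            hio.write_tsv(associations, assoc_path, stage=stage, **prov)
        sorted_meta = metadata[metadata["tissue_class"].str.startswith("sorted")]
        sorted_expr = log2cpm.subset_samples(sorted_meta["sample_id"].tolist())
        c_flags = pbmc_overexpression(
            sorted_expr, sorted_meta["tissue_class"].tolist(), config.c_fc_threshold
        )
        cyt_table = annotate_cyt(cah_ids, associations, c_flags)
        hio.write_tsv(cyt_table, outdir / "cyt.tsv", stage=stage, **prov)
        cyt_ids = cyt_table.loc[cyt_table["cyt"], "herv_id"].tolist()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_cyt=len(cyt_ids), n_c_flagged=int(c_flags.sum()))

    # ---- epitope screening ----
    stage = "screen_epitopes"
    try:
        orfs = []
        for hid in cyt_ids:
            if hid in sequences:
                orfs.extend(six_frame_orfs(sequences[hid], config.min_orf_len, herv_id=hid))
        retained = homology_filter(
            orfs, ref_proteins,
            identity_min=config.identity_min,
            evalue_max=config.evalue_max,
            keep_refs=config.keep_refs,
        )
        peptides = sorted({p for orf in retained for p in kmers(orf.aa_seq, config.k)})
        if config.rank_table:
            predictor = RankTablePredictor.from_tsv(config.rank_table)
        else:
            predictor = AnchorHeuristicPredictor()
        binding = predict_binding(peptides, config.allele, predictor, config.rank_cutoff)
        strong = binding.loc[binding["strong_binder"], "peptide"].tolist()
        kept, flagged = proteome_exclusion(strong, proteome)
        candidates = binding[binding["peptide"].isin(kept)].reset_index(drop=True)
        hio.write_tsv(candidates, outdir / "candidates.tsv", stage=stage, **prov)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(
        stage,
        n_orfs=len(orfs),
        n_orfs_homologous=len(retained),
        n_peptides=len(peptides),
        n_strong_binders=len(strong),
        n_self_matching=len(flagged),
        n_candidates=len(candidates),
    )

    # ---- relocation / sharing ----
    stage = "relocate"
    try:
        scope = {
            "cyt_hervs": cyt_ids,
            "cahs": cah_ids,
            "all_hervs": list(sequences),
        }[config.relocation_scope]
        scope = [h for h in scope if h in sequences]
        cand_peptides = candidates["peptide"].tolist()
        if cand_peptides and scope:
            presence, sharing = relocate_epitopes(cand_peptides, sequences, scope)
        else:
            presence = pd.DataFrame(index=pd.Index(cand_peptides), columns=scope).fillna(False)
            sharing = pd.Series(0, index=cand_peptides, dtype=int, name="sharing_count")
        shared_tbl = sharing.rename_axis("peptide").reset_index()
        shared_tbl["source_herv_ids"] = [
            ";".join(sorted(presence.columns[presence.loc[p]])) for p in shared_tbl["peptide"]
        ]
        hio.write_tsv(shared_tbl, outdir / "sharing.tsv", stage=stage, **prov)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, scope=config.relocation_scope, n_in_scope=len(scope))

    # ---- expression scoring ----
    stage = "score"
    try:
        score_cancer = config.score_cancer or sorted(de_by_cancer)[0]
        pis = pi_values(de_by_cancer[score_cancer])
        if cand_peptides:
            presence_all, _ = relocate_epitopes(cand_peptides, sequences, list(sequences))
            scores = cumulative_epitope_scores(presence_all, pis).rename_axis(
                "peptide"
            ).reset_index()
        else:
            scores = pd.DataFrame(columns=["peptide", "cumulative_score"])
        scores["comparison"] = f"{score_cancer}_tumor_vs_peritumoral"
        hio.write_tsv(scores, outdir / "cumulative_scores.tsv", stage=stage, **prov)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    record(stage, n_scored=len(scores))

    # ---- optional survival ----
    if config.survival:
        stage = "survival"
        try:
            surv = hio.read_tsv(config.survival)
            containing = sorted(
                {h for p in presence.index for h in presence.columns[presence.loc[p]]}
            ) if len(presence) else []
            herv_set = containing or cyt_ids
            tumor_ids = metadata.loc[metadata["tissue_class"] == "tumor", "sample_id"]
            cohort_ids = [s for s in tumor_ids if s in set(surv["sample_id"])]
            expr = log2cpm.subset_samples(cohort_ids)
            cohort, logrank = survival_by_set_score(expr, herv_set, surv)
            hio.write_tsv(cohort, outdir / "survival_cohort.tsv", stage=stage, **prov)
            record(stage, n_patients=len(cohort), n_hervs_in_set=len(herv_set),
                   logrank_statistic=logrank.statistic, logrank_p=logrank.pvalue)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # ---- optional methylation ----
    if config.methylation and config.loci:
        stage = "methylation"
        try:
            probes = hio.read_tsv(config.methylation)
            loci = hio.read_bed(config.loci)
            loci_cyt = loci[loci["name"].isin(cyt_ids)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                meth = methylation_screen(loci_cyt, probes, log2cpm)
            hio.write_tsv(meth, outdir / "methylation_correlation.tsv", stage=stage, **prov)
            record(stage, n_tested=len(meth),
                   n_demethylation=int((meth["label"] == "demethylation").sum()),
                   n_methylation=int((meth["label"] == "methylation").sum()))
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)

    return PipelineResult(
        outdir=outdir,
        manifest=manifest,
        cah_ids=cah_ids,
        cyt_ids=cyt_ids,
        candidates=candidates,
        sharing=sharing,
        scores=scores,
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
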