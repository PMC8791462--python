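"""Synthetic inputs for the discovery pipeline.

Every input the pipeline consumes — raw HERV count matrices with tumor,
matched peritumoral and sorted-PBMC samples, immune signature scores,
provirus nucleotide sequences with embedded retroviral protein
fragments, reference proteins, a host proteome, methylation probes and
survival outcomes — can be generated here with the statistical structure
the analysis assumes, together with the ground-truth labels needed to
measure recovery.

Counts follow a negative-binomial model (Var = mu + alpha * mu^2, one
shared dispersion alpha per simulation) with per-sample library sizes
and per-provirus baselines shared between a tumor and its matched
peritumoral group; planted cancer-associated proviruses multiply their
tumor mean by 2^effect.  Signatures are linear combinations of the
log2(CPM+1) of the planted cyt proviruses plus Gaussian noise, clipped
at zero for the count-like (cell-type) signatures.  Sequences embed
reverse-translated reference-protein fragments (uniform synonymous codon
choice) at a random frame and strand inside random background DNA.
Survival times are exponential with a hazard proportional to a power of
the provirus-set score, with uniform administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .epitopes import revcomp
from .expression import normalize
from .matrix import ExpressionMatrix

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: synonymous codon choices per amino acid (standard code, no stops)
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _tables[1].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


def _default_planted() -> dict[str, float]:
    return {f"herv_{i:04d}": 2.0 for i in range(1, 11)}


def _default_cyt() -> tuple[str, ...]:
    return tuple(f"herv_{i:04d}" for i in range(1, 6))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference condition used throughout the test
    suite: 200 proviruses, one cancer type with 100 tumor and 20 matched
    peritumoral samples, 10 planted cancer-associated proviruses at a
    log2 effect of +2 of which the first 5 are the cyt ground truth,
    negative-binomial dispersion 0.1 and a mean of 10^5 provirus-mapped
    reads per sample.
    """

    n_hervs: int = 200
    n_tumor: int = 100
    n_normal: int = 20
    n_cancer_types: int = 1
    planted_cah_effects: dict[str, float] = field(default_factory=_default_planted)
    planted_cyt_ids: tuple[str, ...] = field(default_factory=_default_cyt)
    planted_c_ids: tuple[str, ...] = ()
    dispersion: float = 0.1
    library_size_mean: float = 1e5
    signature_noise_sd: float = 0.5
    noise_relative: bool = True
    n_sorted_per_class: int = 4
    survival_hazard_ratio_per_unit: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hervs", "n_tumor", "n_normal", "n_cancer_types", "n_sorted_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if not np.isfinite(self.library_size_mean) or self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive and finite")
        if self.signature_noise_sd < 0:
            raise ValueError("signature_noise_sd must be nonnegative")
        if not all(np.isfinite(v) for v in self.planted_cah_effects.values()):
            raise ValueError("planted effects must be finite")
        if not np.isfinite(self.survival_hazard_ratio_per_unit) or (
            self.survival_hazard_ratio_per_unit <= 0
        ):
            raise ValueError("survival_hazard_ratio_per_unit must be positive")
        ids = set(self.herv_ids)
        unknown = set(self.planted_cah_effects) - ids
        if unknown:
            raise ValueError(f"planted CAH ids outside the provirus set: {sorted(unknown)[:5]}")
        if not set(self.planted_cyt_ids) <= set(self.planted_cah_effects):
            raise ValueError("planted_cyt_ids must be a subset of planted_cah_effects")

    @property
    def herv_ids(self) -> list[str]:
        return [f"herv_{i:04d}" for i in range(1, self.n_hervs + 1)]


# ----------------------------------------------------------------------
# counts
# ----------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw: NB with Var = mu + alpha * mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * alpha)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Raw counts plus sample metadata for the configured cohort.

    Peritumoral samples share per-provirus baselines with their matched
    tumor group; planted effects act multiplicatively (2^effect) on
    tumor means only.  Sorted-PBMC samples (T, NK, other) are appended
    with normal-tissue baselines; proviruses listed in
    ``planted_c_ids`` are drawn 4-fold higher in the sorted T and NK
    classes, providing the exclusion-criterion ground truth.
    """
    rng = np.random.default_rng([config.rng_seed, 101])
    herv_ids = config.herv_ids
    n = config.n_hervs
    effects = np.zeros(n)
    for hid, eff in config.planted_cah_effects.items():
        effects[herv_ids.index(hid)] = eff
    c_mask = np.zeros(n, dtype=bool)
    for hid in config.planted_c_ids:
        c_mask[herv_ids.index(hid)] = True

    # per-provirus baseline abundance, lognormal over ~2 decades
    baseline = np.exp(rng.normal(0.0, 1.0, size=n))

    columns, sample_ids, meta_rows = [], [], []
    for c in range(1, config.n_cancer_types + 1):
        cancer = f"cancer_{c}"
        jitter = np.exp(rng.normal(0.0, 0.25, size=n))
        base_c = baseline * jitter
        props_t = base_c * np.power(2.0, effects)
        props_t = props_t / props_t.sum()
        props_n = base_c / base_c.sum()
        for klass, n_samp, props in (
            ("tumor", config.n_tumor, props_t),
            ("peritumoral", config.n_normal, props_n),
        ):
            for j in range(n_samp):
                lib = config.library_size_mean * np.exp(rng.normal(0.0, 0.2))
                counts = _nb_draw(rng, lib * props, config.dispersion)
                sid = f"{cancer}_{klass}_{j + 1:03d}"
                columns.append(counts)
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cancer_type": cancer, "tissue_class": klass})

    # sorted PBMC samples, shared across cancers
    props_sorted_base = baseline / baseline.sum()
    boost = np.where(c_mask, 4.0, 1.0)
    for klass in ("sorted_T", "sorted_NK", "sorted_other"):
        props = props_sorted_base * (boost if klass in ("sorted_T", "sorted_NK") else 1.0)
        props = props / props.sum()
        for j in range(config.n_sorted_per_class):
            lib = config.library_size_mean * np.exp(rng.normal(0.0, 0.2))
            counts = _nb_draw(rng, lib * props, config.dispersion)
            sid = f"pbmc_{klass}_{j + 1:03d}"
            columns.append(counts)
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "cancer_type": "none", "tissue_class": klass})

    values = np.column_stack(columns)
    matrix = ExpressionMatrix(values, herv_ids, sample_ids, layer="raw_counts")
    return matrix, pd.DataFrame(meta_rows)


# ----------------------------------------------------------------------
# signatures
# ----------------------------------------------------------------------

SIGNATURES = (
    ("CD4_T", "phenotype"),
    ("CD8_T", "phenotype"),
    ("CYT", "function"),
    ("IFNG", "function"),
)


def simulate_signatures(
    log2cpm: ExpressionMatrix,
    metadata: pd.DataFrame,
    planted_cyt_ids: Sequence[str],
    noise_sd: float,
    seed: int,
    relative: bool = True,
) -> pd.DataFrame:
    """Phenotype and function scores driven by the planted cyt proviruses.

    Each signature is the unit-weight sum of the planted proviruses'
    log2(CPM+1) plus independent Gaussian noise per signature; with
    ``relative`` the noise standard deviation is ``noise_sd`` times the
    across-sample standard deviation of the noise-free signal.
    Phenotype (cell-type-like) signatures are clipped at zero to mimic
    nonnegative abundance scores.  Output: long table with columns
    sample_id, signature, value, kind for every tumor sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    missing = [h for h in planted_cyt_ids if h not in log2cpm.feature_ids]
    if missing:
        raise ValueError(f"planted ids absent from counts: {missing}")
    rng = np.random.default_rng([seed, 202])
    tumor_ids = metadata.loc[metadata["tissue_class"] == "tumor", "sample_id"].tolist()
    sub = log2cpm.subset_samples(tumor_ids)
    idx = [sub.feature_ids.index(h) for h in planted_cyt_ids]
    signal = sub.values[idx, :].sum(axis=0)
    sd = noise_sd * (float(np.std(signal)) if relative else 1.0)
    rows = []
    for name, kind in SIGNATURES:
        noise = rng.normal(0.0, sd, size=signal.shape) if sd > 0 else 0.0
        value = signal + noise
        if kind == "phenotype":
            value = np.maximum(value, 0.0)
        for sid, v in zip(tumor_ids, np.atleast_1d(value)):
            rows.append({"sample_id": sid, "signature": name, "value": float(v), "kind": kind})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# reference proteins, sequences and epitopes
# ----------------------------------------------------------------------

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def make_reference_proteins(seed: int = 0) -> dict[str, str]:
    """Synthetic HML-2-style reference proteins (Gag, Pol, Env).

    Random amino-acid sequences standing in for curated retroviral
    reference proteins; the homology filter only needs stable, known
    sequences, not biologically real ones.
    """
    rng = np.random.default_rng([seed, 303])
    return {
        "HML2_Gag": random_protein(rng, 400),
        "HML2_Pol": random_protein(rng, 600),
        "HML2_Env": random_protein(rng, 300),
    }


def plant_anchor_epitope(protein: str, position: int) -> tuple[str, str]:
    """Rewrite a 9-mer window so it satisfies the A*02:01 anchor stub.

    Returns (modified_protein, epitope): position 2 becomes L and
    position 9 becomes V, making the window a strong binder under the
    anchor heuristic.
    """
    if position < 0 or position + 9 > len(protein):
        raise ValueError("window outside the protein")
    window = list(protein[position : position + 9])
    window[1] = "L"
    window[8] = "V"
    epitope = "".join(window)
    return protein[:position] + epitope + protein[position + 9 :], epitope


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue (no stop codons)."""
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in aa_seq)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_sequences(
    reference_proteins: Mapping[str, str],
    embeddings: Mapping[str, tuple[str, int, int]],
    herv_ids: Sequence[str],
    seq_len: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Provirus nucleotide sequences with embedded protein fragments.

    ``embeddings`` maps a provirus id to ``(ref_protein_id, aa_start,
    aa_end)``: that reference-protein fragment is reverse translated,
    bracketed by in-frame stop codons (so the resulting ORF is exactly
    the fragment, as in a degenerate proviral reading frame) and
    inserted at a random frame and strand inside random background DNA
    of total length ``seq_len``.  All other ids get pure background.
    Returns the sequences and a ground-truth table with columns herv_id,
    ref_protein_id, aa_start, aa_end, frame, strand, nt_offset (the
    forward-strand position of the coding segment).
    """
    rng = np.random.default_rng([seed, 404])
    for hid, (rid, a, b) in embeddings.items():
        if rid not in reference_proteins:
            raise ValueError(f"unknown reference protein {rid!r} for {hid}")
        if not (0 <= a < b <= len(reference_proteins[rid])):
            raise ValueError(f"fragment [{a}, {b}) outside {rid}")
    sequences: dict[str, str] = {}
    records = []
    for hid in herv_ids:
        if hid in embeddings:
            rid, a, b = embeddings[hid]
            fragment = reference_proteins[rid][a:b]
            core = reverse_translate(fragment, rng)
            insert = "TAA" + core + "TAG"
            strand = int(rng.choice([1, -1]))
            if strand == -1:
                insert = revcomp(insert)
            flank = seq_len - len(insert)
            if flank < 6:
                raise ValueError(f"seq_len too short for fragment of {len(fragment)} aa")
            ins_at = int(rng.integers(3, flank - 3))
            left = _random_dna(rng, ins_at)
            right = _random_dna(rng, flank - ins_at)
            seq = left + insert + right
            offset = ins_at + 3  # forward-strand start of the coding segment
            if strand == 1:
                frame = offset % 3 + 1
            else:
                frame = (len(seq) - offset - len(core)) % 3 + 1
            records.append(
                {
                    "herv_id": hid,
                    "ref_protein_id": rid,
                    "aa_start": a,
                    "aa_end": b,
                    "frame": strand * frame,
                    "strand": strand,
                    "nt_offset": offset,
                }
            )
            sequences[hid] = seq
        else:
            sequences[hid] = _random_dna(rng, seq_len)
    truth = pd.DataFrame(
        records,
        columns=["herv_id", "ref_protein_id", "aa_start", "aa_end", "frame", "strand", "nt_offset"],
    )
    return sequences, truth


def make_proteome(seed: int = 0, include_peptides: Sequence[str] = ()) -> dict[str, str]:
    """Synthetic host proteome; optionally embeds given peptides so the
    self-match exclusion has true positives to find."""
    rng = np.random.default_rng([seed, 505])
    proteome = {f"self_prot_{i:02d}": random_protein(rng, 350) for i in range(1, 21)}
    for i, pep in enumerate(include_peptides):
        key = f"self_prot_{(i % 20) + 1:02d}"
        body = proteome[key]
        pos = int(rng.integers(0, len(body) - len(pep)))
        proteome[key] = body[:pos] + pep + body[pos + len(pep) :]
    return proteome


# ----------------------------------------------------------------------
# methylation and survival
# ----------------------------------------------------------------------

def simulate_loci(herv_ids: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """BED-style loci: proviruses spread over three synthetic chromosomes."""
    rng = np.random.default_rng([seed, 606])
    rows = []
    for i, hid in enumerate(herv_ids):
        chrom = f"chr{i % 3 + 1}"
        start = int(10_000 + (i // 3) * 50_000 + rng.integers(0, 10_000))
        rows.append({"chrom": chrom, "start": start, "end": start + 5_000, "name": hid})
    return pd.DataFrame(rows)


def simulate_methylation(
    loci: pd.DataFrame,
    log2cpm: ExpressionMatrix,
    demethylated_ids: Sequence[str],
    seed: int = 0,
    probes_per_locus: int = 12,
    beta_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Probe beta values; near ``demethylated_ids`` loci, beta decreases
    with the provirus' expression across samples (plus noise); all other
    probes are independent Beta(2, 2) draws.
    """
    rng = np.random.default_rng([seed, 707])
    sample_ids = log2cpm.sample_ids
    rows = []
    probe_no = 0
    for row in loci.itertuples(index=False):
        mid = (row.start + row.end) // 2
        if row.name in demethylated_ids and row.name in log2cpm.feature_ids:
            expr = log2cpm.row(row.name)
            lo, hi = float(np.min(expr)), float(np.max(expr))
            scale = (expr - lo) / (hi - lo) if hi > lo else np.zeros_like(expr)
            base = 0.9 - 0.7 * scale  # high expression -> low methylation
        else:
            base = None
        for p in range(probes_per_locus):
            probe_no += 1
            pos = int(mid + (p - probes_per_locus // 2) * 200)
            if base is not None:
                beta = np.clip(base + rng.normal(0.0, beta_noise_sd, len(sample_ids)), 0, 1)
            else:
                beta = rng.beta(2.0, 2.0, size=len(sample_ids))
            rows.append([f"cg{probe_no:07d}", row.chrom, pos, *beta])
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", *sample_ids])


def simulate_survival(
    set_scores: pd.Series,
    hazard_ratio_per_unit: float = 0.6,
    seed: int = 0,
    median_days: float = 1000.0,
    censor_max_days: float = 2000.0,
) -> pd.DataFrame:
    """Exponential survival with hazard proportional to HR^score.

    The hazard for a sample with centred set score s is
    base_rate * hazard_ratio_per_unit**s, so an HR below one makes a
    high score protective; censoring is administrative, uniform on
    (0, censor_max_days].  Output columns: sample_id, time, event.
    """
    rng = np.random.default_rng([seed, 808])
    s = set_scores.to_numpy(dtype=float)
    s = s - s.mean()
    base_rate = np.log(2.0) / median_days
    rate = base_rate * np.power(hazard_ratio_per_unit, s)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, censor_max_days, size=len(s))
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return pd.DataFrame(
        {"sample_id": set_scores.index, "time": time, "event": event}
    )


# ----------------------------------------------------------------------
# the full bundle
# ----------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Every pipeline input for one simulated study, plus ground truth."""

    config: SimulationConfig
    counts: ExpressionMatrix
    metadata: pd.DataFrame
    phenotype_scores: pd.DataFrame
    herv_sequences: dict[str, str]
    sequence_truth: pd.DataFrame
    reference_proteins: dict[str, str]
    proteome: dict[str, str]
    planted_epitopes: pd.DataFrame  # peptide, herv_ids, strong, in_proteome
    loci: pd.DataFrame
    methylation: pd.DataFrame
    survival: pd.DataFrame
    gene_sets: dict[str, list[str]]

    @property
    def true_cah_ids(self) -> set[str]:
        return {h for h, e in self.config.planted_cah_effects.items() if e != 0.0}

    @property
    def true_cyt_ids(self) -> set[str]:
        return set(self.config.planted_cyt_ids) - set(self.config.planted_c_ids)


def simulate_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic study.

    Two epitopes are planted: a strong-binding Gag epitope embedded in
    the planted cyt proviruses plus two further cancer-associated
    proviruses, and a strong-binding Pol epitope embedded in a subset of
    the cyt proviruses.  A decoy strong-binding peptide lives only in an
    Env fragment (eliminated by the Gag/Pol homology rule), a weak
    binder sits inside the Gag fragment (eliminated by the rank filter),
    and one additional Gag epitope also occurs in the synthetic proteome
    (eliminated by the self-match rule).
    """
    config = config or SimulationConfig()
    seed = config.rng_seed
    counts, metadata = simulate_counts(config)
    log2cpm = normalize(counts)
    signatures = simulate_signatures(
        log2cpm, metadata, config.planted_cyt_ids,
        config.signature_noise_sd, seed, config.noise_relative,
    )

    proteins = make_reference_proteins(seed)
    gag, gag_epitope = plant_anchor_epitope(proteins["HML2_Gag"], 120)
    gag, self_epitope = plant_anchor_epitope(gag, 150)
    # force broken anchors at 130..138 so this window is a guaranteed weak binder
    gag = gag[:131] + "A" + gag[132:138] + "A" + gag[139:]
    weak_epitope = gag[130:139]
    pol, pol_epitope = plant_anchor_epitope(proteins["HML2_Pol"], 200)
    env, env_epitope = plant_anchor_epitope(proteins["HML2_Env"], 80)
    proteins = {"HML2_Gag": gag, "HML2_Pol": pol, "HML2_Env": env}

    planted = sorted(config.planted_cah_effects)
    cyt = list(config.planted_cyt_ids)
    extra_cah = [h for h in planted if h not in cyt]
    n_gag_cyt = max(1, (len(cyt) + 1) // 2)
    gag_hosts = cyt[:n_gag_cyt] + extra_cah[:2]
    pol_hosts = cyt[n_gag_cyt:] + extra_cah[2:5]
    env_host = [h for h in config.herv_ids if h not in planted][:1]

    embeddings: dict[str, tuple[str, int, int]] = {}
    for hid in gag_hosts:
        embeddings[hid] = ("HML2_Gag", 110, 170)  # covers both Gag epitopes
    for hid in pol_hosts:
        embeddings[hid] = ("HML2_Pol", 190, 250)
    for hid in env_host:
        embeddings[hid] = ("HML2_Env", 70, 130)

    sequences, truth = simulate_sequences(
        proteins, embeddings, config.herv_ids, seq_len=2000, seed=seed
    )
    proteome = make_proteome(seed, include_peptides=[self_epitope])

    def hosts_of(rid: str, pep: str, prot: str) -> list[str]:
        pa = prot.find(pep)
        return [
            h for h, (r, s, e) in embeddings.items()
            if r == rid and s <= pa and pa + len(pep) <= e
        ]

    planted_epitopes = pd.DataFrame(
        [
            {
                "peptide": gag_epitope,
                "source": "HML2_Gag",
                "herv_ids": ";".join(sorted(hosts_of("HML2_Gag", gag_epitope, gag))),
                "strong": True,
                "in_proteome": False,
            },
            {
                "peptide": self_epitope,
                "source": "HML2_Gag",
                "herv_ids": ";".join(sorted(hosts_of("HML2_Gag", self_epitope, gag))),
                "strong": True,
                "in_proteome": True,
            },
            {
                "peptide": pol_epitope,
                "source": "HML2_Pol",
                "herv_ids": ";".join(sorted(hosts_of("HML2_Pol", pol_epitope, pol))),
                "strong": True,
                "in_proteome": False,
            },
            {
                "peptide": weak_epitope,
                "source": "HML2_Gag",
                "herv_ids": ";".join(sorted(hosts_of("HML2_Gag", weak_epitope, gag))),
                "strong": False,
                "in_proteome": False,
            },
            {
                "peptide": env_epitope,
                "source": "HML2_Env",
                "herv_ids": ";".join(sorted(env_host)),
                "strong": True,
                "in_proteome": False,
            },
        ]
    )

    loci = simulate_loci(config.herv_ids, seed)
    methylation = simulate_methylation(
        loci.head(30), log2cpm, demethylated_ids=cyt, seed=seed
    )

    tumor_meta = metadata[metadata["tissue_class"] == "tumor"]
    tumor = log2cpm.subset_samples(tumor_meta["sample_id"].tolist())
    set_idx = [tumor.feature_ids.index(h) for h in cyt]
    set_scores = pd.Series(
        tumor.values[set_idx, :].mean(axis=0), index=tumor.sample_ids, name="set_score"
    )
    survival = simulate_survival(
        set_scores, config.survival_hazard_ratio_per_unit, seed
    )

    gene_sets = {"IFNG_RESPONSE": [f"ifng_gene_{i:02d}" for i in range(1, 11)]}

    return SyntheticBundle(
        config=config,
        counts=counts,
        metadata=metadata,
        phenotype_scores=signatures,
        herv_sequences=sequences,
        sequence_truth=truth,
        reference_proteins=proteins,
        proteome=proteome,
        planted_epitopes=planted_epitopes,
        loci=loci,
        methylation=methylation,
        survival=survival,
        gene_sets=gene_sets,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component to plain-text files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = bundle.config.rng_seed
    paths = {
        "counts": hio.write_counts(bundle.counts, outdir / "counts.tsv",
                                   stage="simulate", seed=seed),
        "metadata": hio.write_tsv(bundle.metadata, outdir / "metadata.tsv",
                                  stage="simulate", seed=seed),
        "signatures": hio.write_tsv(bundle.phenotype_scores, outdir / "signatures.tsv",
                                    stage="simulate", seed=seed),
        "sequences": hio.write_fasta(bundle.herv_sequences, outdir / "herv_sequences.fasta"),
        "reference_proteins": hio.write_fasta(
            bundle.reference_proteins, outdir / "reference_proteins.fasta"
        ),
        "proteome": hio.write_fasta(bundle.proteome, outdir / "proteome.fasta"),
        "loci": hio.write_bed(bundle.loci, outdir / "herv_loci.bed"),
        "methylation": hio.write_tsv(bundle.methylation, outdir / "methylation.tsv",
                                     stage="simulate", seed=seed),
        "survival": hio.write_tsv(bundle.survival, outdir / "survival.tsv",
                                  stage="simulate", seed=seed),
        "gene_sets": hio.write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt"),
        "planted_epitopes": hio.write_tsv(
            bundle.planted_epitopes, outdir / "planted_epitopes.tsv",
            stage="simulate", seed=seed,
        ),
        "sequence_truth": hio.write_tsv(
            bundle.sequence_truth, outdir / "sequence_truth.tsv",
            stage="simulate", seed=seed,
        ),
    }
    return paths
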