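"""Six-frame ORF detection, homology filtering and epitope screening.

The screening funnel translates each provirus in all six reading frames,
keeps stop-to-stop segments of at least ``min_len_aa`` amino acids (no
start codon required, matching the behaviour of sixpack-style ORF
scanners), retains only ORFs homologous to reference retroviral Gag/Pol
proteins (Smith-Waterman, BLOSUM62, affine gaps, Karlin-Altschul
e-values), enumerates 9-mer peptides, screens them for predicted strong
MHC-I binders, relocates each surviving peptide across a provirus set to
count how many distinct proviruses share it, and finally removes any
peptide whose exact sequence occurs in the host proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Karlin-Altschul parameters for gapped BLOSUM62 (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Standard-code translation; codons containing N become X."""
    aas = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


@dataclass
class Orf:
    """A stop-free translated segment in one of the six reading frames.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the
    *forward* strand; negative frames are read 5'->3' on the reverse
    complement.
    """

    herv_id: str
    frame: int
    aa_seq: str
    nt_start: int
    nt_end: int
    best_hit: "HomologyHit | None" = field(default=None, repr=False)

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


def six_frame_orfs(dna: str, min_len_aa: int = 10, herv_id: str = "") -> list[Orf]:
    """All stop-to-stop ORFs of >= ``min_len_aa`` amino acids in six frames.

    No start codon is required.  The translated segments never contain a
    stop symbol; N-containing codons translate to X and do not terminate
    a segment.
    """
    dna = dna.upper()
    if not dna:
        raise ValueError("empty sequence")
    if set(dna) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    length = len(dna)
    orfs: list[Orf] = []
    for strand, seq in ((1, dna), (-1, revcomp(dna))):
        for offset in range(3):
            protein = translate(seq[offset:])
            start = 0
            for segment in protein.split("*"):
                if len(segment) >= min_len_aa:
                    a, b = start, start + len(segment)
                    nt_a, nt_b = offset + 3 * a, offset + 3 * b
                    if strand == 1:
                        nt_start, nt_end = nt_a, nt_b
                    else:
                        nt_start, nt_end = length - nt_b, length - nt_a
                    orfs.append(
                        Orf(herv_id, strand * (offset + 1), segment, nt_start, nt_end)
                    )
                start += len(segment) + 1  # skip the stop
    return orfs


# ----------------------------------------------------------------------
# homology filtering
# ----------------------------------------------------------------------

@dataclass
class HomologyHit:
    """Best local alignment of an ORF against one reference protein."""

    ref_protein_id: str
    score: float
    percent_identity: float
    evalue: float
    bitscore: float
    alignment: tuple[str, str]


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # NCBI convention: a gap of length L costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def local_align(
    query_aa: str,
    ref_aa: str,
    ref_protein_id: str = "",
    search_space: int | None = None,
) -> HomologyHit:
    """Smith-Waterman alignment with BLOSUM62 and affine gaps (11/1).

    Percent identity is computed over all aligned columns, counting gap
    columns as mismatches.  The e-value uses the Karlin-Altschul formula
    E = K * m * n * exp(-lambda * S) with gapped BLOSUM62 constants;
    ``search_space`` overrides the m*n product when aligning against a
    database of several reference proteins.
    """
    if not query_aa or not ref_aa:
        raise ValueError("empty sequence")
    alignments = _ALIGNER.align(query_aa.upper(), ref_aa.upper())
    aln = alignments[0]
    q_row, r_row = str(aln[0]), str(aln[1])
    columns = len(q_row)
    matches = sum(1 for a, b in zip(q_row, r_row) if a == b and a != "-")
    pid = 100.0 * matches / columns if columns else 0.0
    score = float(aln.score)
    mn = search_space if search_space is not None else len(query_aa) * len(ref_aa)
    evalue = KA_K * mn * math.exp(-KA_LAMBDA * score)
    bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
    return HomologyHit(ref_protein_id, score, pid, evalue, bitscore, (q_row, r_row))


def homology_filter(
    orfs: Iterable[Orf],
    reference_proteins: Mapping[str, str],
    identity_min: float = 90.0,
    evalue_max: float = 0.05,
    keep_refs: Sequence[str] = ("Gag", "Pol"),
) -> list[Orf]:
    """Retain ORFs whose best hit to a kept reference protein meets both
    the identity and the e-value threshold.

    ``keep_refs`` selects references by case-insensitive substring match
    on their record id (so ``Gag`` keeps ``HML2_Gag`` and similar).  The
    e-value search space is the query length times the total length of
    the kept references.  Identity is inclusive at ``identity_min``;
    the e-value threshold is strict.  Each retained ORF carries its best
    hit in ``best_hit``.
    """
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    keep_lower = tuple(k.lower() for k in keep_refs)
    kept_refs = {
        rid: seq
        for rid, seq in reference_proteins.items()
        if any(k in rid.lower() for k in keep_lower)
    }
    if not kept_refs:
        raise ValueError(f"no reference protein matches keep_refs={list(keep_refs)!r}")
    total_ref_len = sum(len(s) for s in kept_refs.values())
    retained = []
    for orf in orfs:
        best: HomologyHit | None = None
        for rid, ref_seq in kept_refs.items():
            hit = local_align(
                orf.aa_seq, ref_seq, rid, search_space=len(orf.aa_seq) * total_ref_len
            )
            if best is None or hit.bitscore > best.bitscore:
                best = hit
        assert best is not None
        if best.percent_identity >= identity_min and best.evalue < evalue_max:
            orf.best_hit = best
            retained.append(orf)
    return retained


# ----------------------------------------------------------------------
# binding prediction
# ----------------------------------------------------------------------

class RankTablePredictor:
    """Percentile-rank lookup from an externally computed table.

    The table has columns peptide, allele, percentile_rank (one row per
    pair).  Peptides absent from the table get a NaN rank, which never
    qualifies as a strong binder.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"peptide", "allele", "percentile_rank"}
        if not required <= set(table.columns):
            raise ValueError(f"rank table needs columns {sorted(required)}")
        self._ranks = {
            (row.peptide, row.allele): float(row.percentile_rank)
            for row in table.itertuples(index=False)
        }

    @classmethod
    def from_tsv(cls, path) -> "RankTablePredictor":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def rank(self, peptide: str, allele: str) -> float:
        return self._ranks.get((peptide, allele), float("nan"))


class AnchorHeuristicPredictor:
    """Toy anchor-residue rule for HLA-A*02:01 nine-mers (test stub).

    A peptide is called strong (rank 0.1) iff position 2 is L or M and
    position 9 is V, L or I, and weak (rank 50) otherwise.  This is a
    deterministic stand-in for a trained MHC-binding predictor and is
    *not* physiological; production runs should supply a rank table
    computed by a real predictor.
    """

    STRONG_RANK = 0.1
    WEAK_RANK = 50.0

    def rank(self, peptide: str, allele: str) -> float:
        if allele not in ("A*02:01", "HLA-A*02:01"):
            raise ValueError(f"anchor heuristic only covers HLA-A*02:01, got {allele!r}")
        if len(peptide) != 9:
            raise ValueError(f"anchor heuristic expects 9-mers, got {peptide!r}")
        if peptide[1] in "LM" and peptide[8] in "VLI":
            return self.STRONG_RANK
        return self.WEAK_RANK


def kmers(aa_seq: str, k: int = 9) -> list[str]:
    return [aa_seq[i : i + k] for i in range(len(aa_seq) - k + 1)]


def predict_binding(
    peptides: Sequence[str],
    allele: str,
    predictor,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Percentile ranks and strong-binder calls for a peptide list.

    ``strong_binder`` is inclusive at the cutoff (rank <= cutoff).
    """
    rows = []
    for pep in peptides:
        rank = predictor.rank(pep, allele)
        rows.append(
            {
                "peptide": pep,
                "allele": allele,
                "percentile_rank": rank,
                "strong_binder": bool(rank <= cutoff) if not np.isnan(rank) else False,
            }
        )
    return pd.DataFrame(rows, columns=["peptide", "allele", "percentile_rank", "strong_binder"])


# ----------------------------------------------------------------------
# relocation / sharing and proteome exclusion
# ----------------------------------------------------------------------

def relocate_epitopes(
    peptides: Sequence[str],
    herv_sequences: Mapping[str, str],
    scope_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Exact-substring search of each peptide across a provirus set.

    Each provirus in scope is translated in six frames with the minimum
    ORF length relaxed to the peptide length; a peptide is present in a
    provirus when it occurs as an exact substring of any such ORF.
    Returns the peptide x provirus boolean presence matrix and the
    per-peptide sharing counts (number of *distinct* proviruses), sorted
    by count descending with ties broken lexicographically by peptide.
    """
    scope = list(scope_ids) if scope_ids is not None else list(herv_sequences)
    if not scope:
        raise ValueError("empty relocation scope")
    missing = [h for h in scope if h not in herv_sequences]
    if missing:
        raise KeyError(f"scope ids without sequence: {missing[:5]}")
    peptides = list(dict.fromkeys(peptides))  # dedupe, keep order
    min_k = min((len(p) for p in peptides), default=9)
    presence = pd.DataFrame(False, index=peptides, columns=scope)
    for herv in scope:
        orfs = six_frame_orfs(herv_sequences[herv], min_len_aa=min_k, herv_id=herv)
        aa_blobs = [o.aa_seq for o in orfs]
        for pep in peptides:
            if any(pep in blob for blob in aa_blobs):
                presence.loc[pep, herv] = True
    sharing = presence.sum(axis=1).astype(int)
    sharing = sharing.iloc[
        sorted(range(len(sharing)), key=lambda i: (-sharing.iloc[i], sharing.index[i]))
    ]
    sharing.name = "sharing_count"
    return presence, sharing


def proteome_exclusion(
    peptides: Sequence[str], proteome: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Split peptides into (kept, self_matching) by exact proteome match.

    A peptide is flagged iff its exact sequence occurs as a substring of
    any proteome record; one mismatch anywhere means no flag.
    """
    records = [seq.upper() for seq in proteome.values()]
    kept, flagged = [], []
    for pep in peptides:
        if any(pep.upper() in rec for rec in records):
            flagged.append(pep)
        else:
            kept.append(pep)
    return kept, flagged
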