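"""Six-frame ORF detection, homology filtering, binding prediction,
relocation and proteome exclusion."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from hervitope.epitopes import (
    AnchorHeuristicPredictor,
    RankTablePredictor,
    homology_filter,
    kmers,
    local_align,
    predict_binding,
    proteome_exclusion,
    relocate_epitopes,
    revcomp,
    six_frame_orfs,
    translate,
)
from hervitope.sim import make_reference_proteins, reverse_translate

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _orf_oracle(dna, min_len):
    """Exhaustive translator: every frame, split on stops."""
    found = set()
    for strand, seq in ((1, dna), (-1, revcomp(dna))):
        for off in range(3):
            aa = translate(seq[off:])
            for seg in aa.split("*"):
                if len(seg) >= min_len:
                    found.add((strand * (off + 1), seg))
    return found


def _sw_oracle(a, b, open_cost=12, extend_cost=1):
    """Quadratic Gotoh local-alignment score with BLOSUM62."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)
    F = np.full((n + 1, m + 1), -1e9)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestSixFrameOrfs:
    def test_poly_a_gives_poly_lysine_in_frame_one(self):
        orfs = six_frame_orfs("A" * 30, min_len_aa=10)
        plus_one = [o for o in orfs if o.frame == 1]
        assert plus_one and plus_one[0].aa_seq == "K" * 10

    def test_min_length_threshold_excludes(self):
        assert all(o.frame != 1 for o in six_frame_orfs("A" * 30, min_len_aa=11))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            dna = _random_dna(rng, 2000)
            mine = {(o.frame, o.aa_seq) for o in six_frame_orfs(dna, 10)}
            assert mine == _orf_oracle(dna, 10)

    def test_coordinates_translate_back_to_aa_seq(self, rng):
        dna = _random_dna(rng, 600)
        for o in six_frame_orfs(dna, 5):
            segment = dna[o.nt_start : o.nt_end]
            if o.frame < 0:
                segment = revcomp(segment)
            assert translate(segment) == o.aa_seq

    def test_revcomp_mirrors_frames(self, rng):
        dna = _random_dna(rng, 900)
        fwd = {(o.frame, o.aa_seq) for o in six_frame_orfs(dna, 8)}
        rev = {(-o.frame, o.aa_seq) for o in six_frame_orfs(revcomp(dna), 8)}
        # reverse-complementing swaps the strand of every ORF; frame indices
        # within a strand may permute, so compare per strand sign and sequence
        assert {(np.sign(f), s) for f, s in fwd} == {(np.sign(f), s) for f, s in rev}

    def test_n_codons_translate_to_x_without_terminating(self):
        orfs = six_frame_orfs("AAANAAAAAAAAAAAAAAAAAAAAAAAAAAAAA", min_len_aa=10)
        plus_one = [o for o in orfs if o.frame == 1]
        assert plus_one and "X" in plus_one[0].aa_seq

    def test_empty_and_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            six_frame_orfs("")
        with pytest.raises(ValueError):
            six_frame_orfs("ACGU")


class TestLocalAlign:
    def test_identical_sequences_full_identity(self):
        hit = local_align("MKVLAWQTESNPDRFG" + "LYHI", "MKVLAWQTESNPDRFGLYHI")
        assert hit.percent_identity == pytest.approx(100.0)

    def test_single_substitution_in_twenty(self):
        a = "MKVLAWQTESNPDRFGLYHI"
        b = a[:10] + "W" + a[11:]
        hit = local_align(a, b)
        assert hit.percent_identity == pytest.approx(95.0)

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(5):
            a, b = _random_protein(rng, 50), _random_protein(rng, 50)
            assert local_align(a, b).score == pytest.approx(_sw_oracle(a, b))

    def test_evalue_decreases_with_score(self):
        short = local_align("MKVLAW", "MKVLAW")
        long = local_align("MKVLAWQTESNPDRFGLYHI", "MKVLAWQTESNPDRFGLYHI")
        assert long.evalue < short.evalue

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKV")


@pytest.fixture(scope="module")
def refs():
    return make_reference_proteins(seed=5)


class TestHomologyFilter:
    def _orf(self, aa, herv="h1"):
        from hervitope.epitopes import Orf

        return Orf(herv, 1, aa, 0, 3 * len(aa))

    def test_exact_gag_fragment_retained(self, refs):
        orf = self._orf(refs["HML2_Gag"][50:110])
        kept = homology_filter([orf], refs)
        assert kept and kept[0].best_hit.ref_protein_id == "HML2_Gag"
        assert kept[0].best_hit.percent_identity == pytest.approx(100.0)

    def test_shuffled_composition_rejected(self, refs, rng):
        frag = list(refs["HML2_Gag"][50:110])
        rejected = 0
        for _ in range(20):
            rng.shuffle(frag)
            if not homology_filter([self._orf("".join(frag))], refs):
                rejected += 1
        assert rejected == 20

    def test_env_only_hit_rejected_by_reference_class(self, refs):
        orf = self._orf(refs["HML2_Env"][40:100])
        assert homology_filter([orf], refs, keep_refs=("Gag", "Pol")) == []
        assert homology_filter([orf], refs, keep_refs=("Env",))

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            homology_filter([], {})


class TestPredictBinding:
    def test_rank_table_lookup_and_inclusive_cutoff(self):
        table = pd.DataFrame(
            {
                "peptide": ["FLQFKTWWI", "AAAAAAAAA", "LLLLLLLLL"],
                "allele": ["A*02:01"] * 3,
                "percentile_rank": [0.2, 12.0, 0.5],
            }
        )
        pred = RankTablePredictor(table)
        out = predict_binding(
            ["FLQFKTWWI", "AAAAAAAAA", "LLLLLLLLL", "MISSINGPEP"], "A*02:01", pred
        ).set_index("peptide")
        assert out.loc["FLQFKTWWI", "strong_binder"]
        assert not out.loc["AAAAAAAAA", "strong_binder"]
        assert out.loc["LLLLLLLLL", "strong_binder"]  # rank exactly 0.5 is strong
        assert not out.loc["MISSINGPEP", "strong_binder"]

    def test_anchor_heuristic_rule(self):
        pred = AnchorHeuristicPredictor()
        out = predict_binding(["ALAAAAAAV", "AAAAAAAAA"], "A*02:01", pred)
        assert out.set_index("peptide").loc["ALAAAAAAV", "strong_binder"]
        assert not out.set_index("peptide").loc["AAAAAAAAA", "strong_binder"]

    def test_anchor_heuristic_validates_length_and_allele(self):
        pred = AnchorHeuristicPredictor()
        with pytest.raises(ValueError, match="9-mers"):
            pred.rank("ALAV", "A*02:01")
        with pytest.raises(ValueError, match="A\\*02:01"):
            pred.rank("ALAAAAAAV", "B*07:02")


class TestRelocation:
    def test_planted_sharing_count_from_ground_truth(self, rng):
        refs = make_reference_proteins(seed=9)
        epitope = refs["HML2_Gag"][120:129]
        herv_ids = [f"h{i}" for i in range(10)]
        embeddings = {h: ("HML2_Gag", 100, 160) for h in herv_ids[:7]}
        from hervitope.sim import simulate_sequences

        seqs, truth = simulate_sequences(refs, embeddings, herv_ids, seed=9)
        presence, sharing = relocate_epitopes([epitope], seqs)
        assert sharing.loc[epitope] == 7
        assert set(presence.columns[presence.loc[epitope]]) == set(herv_ids[:7])

    def test_absent_epitope_counts_zero(self, small_bundle):
        _, sharing = relocate_epitopes(["WWWWWWWWW"], small_bundle.herv_sequences)
        assert sharing.loc["WWWWWWWWW"] == 0

    def test_identical_sequences_count_distinct_ids(self):
        seq = "ATG" + reverse_translate("MKVLAWQTESNP", np.random.default_rng(0)) + "TAA"
        seqs = {"a": seq, "b": seq}
        _, sharing = relocate_epitopes(["KVLAWQTES"], seqs)
        assert sharing.iloc[0] == 2

    def test_counts_monotone_as_scope_widens(self, small_bundle):
        peps = small_bundle.planted_epitopes["peptide"].tolist()
        seqs = small_bundle.herv_sequences
        cyt = list(small_bundle.config.planted_cyt_ids)
        cah = sorted(small_bundle.config.planted_cah_effects)
        _, s_cyt = relocate_epitopes(peps, seqs, cyt)
        _, s_cah = relocate_epitopes(peps, seqs, cah)
        _, s_all = relocate_epitopes(peps, seqs)
        for p in peps:
            assert s_cyt.loc[p] <= s_cah.loc[p] <= s_all.loc[p]

    def test_ties_broken_lexicographically(self):
        rng = np.random.default_rng(1)
        seq = "ATG" + reverse_translate("AAAMKVLAWQTESNPRRR", rng) + "TAA"
        _, sharing = relocate_epitopes(["MKVLAWQTE", "KVLAWQTES"], {"h": seq})
        assert sharing.index.tolist() == ["KVLAWQTES", "MKVLAWQTE"]

    def test_empty_scope_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            relocate_epitopes(["AAAAAAAAA"], small_bundle.herv_sequences, [])


class TestProteomeExclusion:
    def test_exact_substring_flagged_one_mismatch_not(self):
        proteome = {"p1": "MKVLAWQTESNPDRFGLYHI"}
        kept, flagged = proteome_exclusion(["LAWQTESNP", "LAWQTESNQ"], proteome)
        assert flagged == ["LAWQTESNP"]
        assert kept == ["LAWQTESNQ"]

    def test_matches_naive_scan_oracle(self, rng):
        proteome = {f"p{i}": _random_protein(rng, 120) for i in range(15)}
        peptides = [_random_protein(rng, 9) for _ in range(30)]
        # guarantee some true positives
        peptides += [proteome["p3"][10:19], proteome["p7"][50:59]]
        kept, flagged = proteome_exclusion(peptides, proteome)
        oracle_flagged = [
            p for p in peptides if any(p in rec for rec in proteome.values())
        ]
        assert flagged == oracle_flagged
        assert set(kept) | set(flagged) == set(peptides)


def test_kmers_window():
    assert kmers("ABCDEFGHIJ", 9) == ["ABCDEFGHI", "BCDEFGHIJ"]
    assert kmers("SHORT", 9) == []
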