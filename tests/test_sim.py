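"""The synthetic-data generator: reproducibility, planted structure and
ground-truth recoverability."""

import numpy as np
import pandas as pd
import pytest

from hervitope.epitopes import six_frame_orfs, translate
from hervitope.expression import nb_differential, normalize
from hervitope.immune import lasso_fit
from hervitope.sim import (
    SimulationConfig,
    make_proteome,
    make_reference_proteins,
    plant_anchor_epitope,
    reverse_translate,
    simulate_bundle,
    simulate_counts,
    simulate_sequences,
    simulate_signatures,
    simulate_survival,
    write_bundle,
)


class TestConfigValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=0.0)
        with pytest.raises(ValueError, match="n_tumor"):
            SimulationConfig(n_tumor=0)
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(planted_cah_effects={"herv_0001": np.inf})
        with pytest.raises(ValueError, match="library_size"):
            SimulationConfig(library_size_mean=-1)

    def test_cyt_must_be_subset_of_cah(self):
        with pytest.raises(ValueError, match="subset"):
            SimulationConfig(
                planted_cah_effects={"herv_0001": 2.0},
                planted_cyt_ids=("herv_0002",),
            )

    def test_planted_ids_must_exist(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(n_hervs=5, planted_cah_effects={"herv_9999": 2.0},
                             planted_cyt_ids=())


class TestReproducibility:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_bundle(small_config)
        b = simulate_bundle(small_config)
        np.testing.assert_array_equal(a.counts.values, b.counts.values)
        assert a.herv_sequences == b.herv_sequences
        pd.testing.assert_frame_equal(a.phenotype_scores, b.phenotype_scores)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.methylation, b.methylation)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, rng_seed=99)
        a, b = simulate_bundle(small_config), simulate_bundle(other)
        assert not np.array_equal(a.counts.values, b.counts.values)
        assert a.herv_sequences != b.herv_sequences


class TestSimulateCounts:
    def test_null_effects_give_zero_mean_log2fc(self):
        cfg = SimulationConfig(
            n_hervs=100, n_tumor=20, n_normal=20,
            planted_cah_effects={}, planted_cyt_ids=(), rng_seed=5,
        )
        counts, meta = simulate_counts(cfg)
        m = meta[meta["tissue_class"].isin(["tumor", "peritumoral"])]
        de = nb_differential(
            counts.subset_samples(m["sample_id"].tolist()),
            m["tissue_class"].to_numpy(), reference="peritumoral",
        )
        assert abs(de["log2FC"].mean()) < 0.1

    def test_library_size_doubling_leaves_cpm_means_invariant(self):
        import dataclasses

        from hervitope.expression import cpm

        cfg = SimulationConfig(n_hervs=100, n_tumor=30, n_normal=10, rng_seed=8)
        doubled = dataclasses.replace(cfg, library_size_mean=2 * cfg.library_size_mean)
        a, _ = simulate_counts(cfg)
        b, _ = simulate_counts(doubled)
        mean_a = cpm(a).values.mean(axis=1)
        mean_b = cpm(b).values.mean(axis=1)
        # paired draws from the same seed: CPM normalization cancels depth
        np.testing.assert_allclose(mean_a, mean_b, rtol=0.25)
        assert b.values.sum() > 1.5 * a.values.sum()

    def test_metadata_classes_and_shapes(self, small_bundle):
        meta = small_bundle.metadata
        counts = small_bundle.counts
        assert set(meta["tissue_class"]) == {
            "tumor", "peritumoral", "sorted_T", "sorted_NK", "sorted_other"
        }
        assert meta["sample_id"].tolist() == counts.sample_ids
        assert counts.values.min() >= 0


class TestSimulateSignatures:
    def test_zero_noise_single_herv_equals_its_log2cpm(self):
        cfg = SimulationConfig(
            n_hervs=20, n_tumor=10, n_normal=5,
            planted_cah_effects={"herv_0001": 2.0},
            planted_cyt_ids=("herv_0001",), rng_seed=3,
        )
        counts, meta = simulate_counts(cfg)
        log2cpm = normalize(counts)
        sigs = simulate_signatures(log2cpm, meta, ["herv_0001"], 0.0, seed=3)
        tumor_ids = meta.loc[meta["tissue_class"] == "tumor", "sample_id"].tolist()
        expected = log2cpm.subset_samples(tumor_ids).row("herv_0001")
        got = sigs[sigs["signature"] == "CYT"].set_index("sample_id")["value"]
        np.testing.assert_allclose(got.loc[tumor_ids], expected)

    def test_negative_noise_rejected(self, small_bundle):
        log2cpm = normalize(small_bundle.counts)
        with pytest.raises(ValueError):
            simulate_signatures(log2cpm, small_bundle.metadata, ["herv_0001"], -1.0, 0)

    def test_huge_noise_drowns_selection(self):
        """Noise an order of magnitude above the signal: the lasso should
        recover the planted proviruses in fewer than half of replicates."""
        hits, reps = 0, 4
        for seed in range(reps):
            cfg = SimulationConfig(n_hervs=60, n_tumor=40, n_normal=10, rng_seed=60 + seed)
            counts, meta = simulate_counts(cfg)
            log2cpm = normalize(counts)
            sigs = simulate_signatures(
                log2cpm, meta, cfg.planted_cyt_ids, 10.0, seed=60 + seed, relative=True
            )
            tumor = meta[meta["tissue_class"] == "tumor"]["sample_id"].tolist()
            X = log2cpm.subset_samples(tumor).to_dataframe().T
            y = sigs[sigs["signature"] == "CYT"].set_index("sample_id")["value"].reindex(tumor)
            tbl, _ = lasso_fit(X, y, n_folds=5, seed=seed)
            sel = set(tbl.loc[tbl["selected"], "herv_id"])
            hits += len(sel & set(cfg.planted_cyt_ids)) >= 3
        assert hits / reps < 0.5

    def test_permuted_labels_break_selection(self):
        """Permuting the signature's sample labels removes the planted
        association: selected planted proviruses drop to chance level."""
        cfg = SimulationConfig(n_hervs=60, n_tumor=40, n_normal=10, rng_seed=77)
        counts, meta = simulate_counts(cfg)
        log2cpm = normalize(counts)
        sigs = simulate_signatures(log2cpm, meta, cfg.planted_cyt_ids, 0.5, seed=77)
        tumor = meta[meta["tissue_class"] == "tumor"]["sample_id"].tolist()
        X = log2cpm.subset_samples(tumor).to_dataframe().T
        y = sigs[sigs["signature"] == "CYT"].set_index("sample_id")["value"].reindex(tumor)
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        tbl, _ = lasso_fit(X, y_perm, n_folds=5, seed=1)
        sel = set(tbl.loc[tbl["selected"], "herv_id"])
        planted_frac = len(sel & set(cfg.planted_cyt_ids)) / 5
        assert planted_frac <= 0.4


@pytest.fixture(scope="module")
def refs():
    return make_reference_proteins(seed=21)


class TestSimulateSequences:
    def test_embedded_fragment_recovered_as_orf(self, refs):
        seqs, truth = simulate_sequences(
            refs, {"h1": ("HML2_Gag", 100, 160)}, ["h1"], seed=21
        )
        fragment = refs["HML2_Gag"][100:160]
        orfs = six_frame_orfs(seqs["h1"], 10, herv_id="h1")
        hits = [o for o in orfs if fragment in o.aa_seq]
        assert hits
        assert hits[0].frame == truth.loc[0, "frame"]

    def test_reverse_strand_embedding_found_in_negative_frame(self, refs):
        for seed in range(30):
            seqs, truth = simulate_sequences(
                refs, {"h1": ("HML2_Pol", 50, 110)}, ["h1"], seed=seed
            )
            if truth.loc[0, "strand"] == -1:
                fragment = refs["HML2_Pol"][50:110]
                hits = [
                    o for o in six_frame_orfs(seqs["h1"], 10) if fragment in o.aa_seq
                ]
                assert hits and all(o.frame < 0 for o in hits)
                return
        pytest.fail("no reverse-strand embedding over 30 seeds")

    def test_unknown_reference_or_bad_window_rejected(self, refs):
        with pytest.raises(ValueError, match="unknown reference"):
            simulate_sequences(refs, {"h1": ("Nope", 0, 10)}, ["h1"])
        with pytest.raises(ValueError, match="outside"):
            simulate_sequences(refs, {"h1": ("HML2_Env", 0, 10_000)}, ["h1"])

    def test_reverse_translation_is_faithful(self, rng):
        aa = "MKVLAWQTESNPDRFGLYHI"
        assert translate(reverse_translate(aa, rng)) == aa

    def test_anchor_planting(self):
        prot = "A" * 30
        modified, epitope = plant_anchor_epitope(prot, 10)
        assert len(modified) == 30
        assert epitope[1] == "L" and epitope[8] == "V"
        assert modified[10:19] == epitope


class TestBundle:
    def test_planted_epitopes_live_in_declared_hosts(self, small_bundle):
        from hervitope.epitopes import relocate_epitopes

        truth = small_bundle.planted_epitopes
        presence, sharing = relocate_epitopes(
            truth["peptide"].tolist(), small_bundle.herv_sequences
        )
        for row in truth.itertuples(index=False):
            declared = set(row.herv_ids.split(";")) if row.herv_ids else set()
            found = set(presence.columns[presence.loc[row.peptide]])
            assert found == declared

    def test_self_epitope_is_in_proteome(self, small_bundle):
        truth = small_bundle.planted_epitopes.set_index("peptide")
        for pep, row in truth.iterrows():
            occurs = any(pep in rec for rec in small_bundle.proteome.values())
            assert occurs == bool(row["in_proteome"])

    def test_survival_hazard_direction(self):
        scores = pd.Series(np.r_[np.zeros(120), np.full(120, 4.0)],
                           index=[f"s{i}" for i in range(240)])
        surv = simulate_survival(scores, hazard_ratio_per_unit=0.5, seed=4)
        high = surv.iloc[120:]
        low = surv.iloc[:120]
        # protective score: fewer events / longer times in the high group
        assert high["time"].mean() > low["time"].mean()
        assert high["event"].mean() < low["event"].mean()

    def test_write_bundle_round_trip(self, small_bundle, tmp_path):
        from hervitope import io as hio

        paths = write_bundle(small_bundle, tmp_path)
        counts = hio.read_counts(paths["counts"])
        np.testing.assert_array_equal(counts.values, small_bundle.counts.values)
        assert counts.feature_ids == small_bundle.counts.feature_ids
        seqs = hio.read_fasta(paths["sequences"])
        assert seqs == small_bundle.herv_sequences
        gmt = hio.read_gmt(paths["gene_sets"])
        assert gmt == small_bundle.gene_sets
        bed = hio.read_bed(paths["loci"])
        assert bed["name"].tolist() == small_bundle.loci["name"].tolist()

    def test_proteome_embedding_helper(self):
        prot = make_proteome(seed=1, include_peptides=["WWWWLLLLW"])
        assert any("WWWWLLLLW" in rec for rec in prot.values())
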