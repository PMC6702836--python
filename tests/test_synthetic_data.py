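import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from ticklink import abundance, linkage, profile_io
from ticklink.read_qc import QCParams, dereplicate_reads, qc_filter_reads
from ticklink.synthetic_data import (
    GeneratorConfig,
    GroundTruth,
    NoiseModel,
    ReadSimPlan,
    build_ground_truth,
    largest_remainder,
    sample_genus_probabilities,
    simulate_annotation_tables,
    simulate_reads,
)


def small_config(**kw):
    defaults = dict(
        n_species=1,
        n_genera=12,
        n_enzymes=40,
        spectrum_targets={"1": 0.25, "2-4": 0.5, "5-10": 0.25, "11+": 0.0},
        n_diff_genera=2,
        reads_per_sample=2000,
        noise=NoiseModel.all_pass(),
        p_unannotated_function=0.0,
        seed=7,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestGroundTruth:
    def test_exact_allocation_forced_by_rounding(self):
        cfg = small_config(
            n_enzymes=10, spectrum_targets={"1": 0.5, "2-4": 0.5, "5-10": 0.0, "11+": 0.0}
        )
        truth = build_ground_truth(cfg)
        counts = truth.expected_spectrum
        assert (counts == 1).sum() == 5
        assert counts.between(2, 4).sum() == 5

    def test_determinism_same_seed(self):
        t1 = build_ground_truth(small_config())
        t2 = build_ground_truth(small_config())
        pd.testing.assert_frame_equal(t1.repertoire, t2.repertoire)
        assert t1.affected_genera == t2.affected_genera
        for sp in t1.base_abundance:
            pd.testing.assert_series_equal(t1.base_abundance[sp], t2.base_abundance[sp])

    def test_infeasible_spectrum_rejected(self):
        with pytest.raises(ValueError, match="infeasible spectrum"):
            build_ground_truth(
                small_config(
                    n_genera=5,
                    spectrum_targets={"1": 0.5, "2-4": 0.2, "5-10": 0.2, "11+": 0.1},
                )
            )

    def test_largest_remainder_allocation(self):
        alloc = largest_remainder({"a": 0.42, "b": 0.33, "c": 0.25}, 10)
        assert alloc == {"a": 4, "b": 3, "c": 3} and sum(alloc.values()) == 10

    def test_abundance_vectors_sum_to_one(self):
        truth = build_ground_truth(small_config(n_species=3))
        for vec in truth.base_abundance.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_spectrum_is_repertoire_column_sums(self):
        truth = build_ground_truth(small_config())
        assert (truth.expected_spectrum == truth.repertoire.sum(axis=0)).all()

    def test_lineage_spans_multiple_phyla(self):
        truth = build_ground_truth(small_config())
        assert truth.genus_catalog["phylum"].nunique() >= 2
        assert (truth.genus_catalog["domain"] == "Bacteria").all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(spectrum_targets={"1": 0.5, "2-4": 0.2, "5-10": 0.0, "11+": 0.0})
        with pytest.raises(ValueError):
            small_config(n_diff_genera=99)
        with pytest.raises(ValueError):
            small_config(fold_change=0.0)

    def test_ground_truth_json(self, tmp_path):
        truth = build_ground_truth(small_config())
        path = tmp_path / "truth.json"
        truth.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["seed"] == 7
        assert len(payload["enzyme_catalog"]) == 40


class TestAnnotationSimulation:
    def test_noiseless_passes_all_filters(self):
        truth = build_ground_truth(small_config())
        table, meta = simulate_annotation_tables(truth)
        for mode in ("taxonomic", "functional"):
            kept = profile_io.apply_annotation_filters(table, mode=mode)
            assert len(kept) == len(table)
        assert table["func_l4"].notna().all()
        assert set(meta["sample_id"]) == set(table["sample_id"])

    def test_fail_fraction_converges(self):
        truth = build_ground_truth(
            small_config(noise=NoiseModel(p_fail=0.25, p_nonbacterial=0.0),
                         reads_per_sample=20000)
        )
        table, _ = simulate_annotation_tables(truth)
        kept = profile_io.apply_annotation_filters(table, mode="taxonomic")
        frac_fail = 1 - len(kept) / len(table)
        assert frac_fail == pytest.approx(0.25, abs=0.02)

    def test_null_fold_change_symmetric_probabilities(self):
        truth = build_ground_truth(small_config(fold_change=1.0))
        pf = sample_genus_probabilities(truth, "AV", "f")
        pm = sample_genus_probabilities(truth, "AV", "m")
        pd.testing.assert_series_equal(pf, pm)

    def test_planted_odds_ratio_recovered(self):
        # one genus planted at 5% base abundance with an 8-fold female
        # effect; after renormalization the exact invariant is the odds
        # ratio, which should be recovered within 20% at 20k reads/sample
        ratios = []
        for seed in range(20):
            cfg = small_config(
                n_genera=10, n_diff_genera=1, fold_change=8.0,
                reads_per_sample=20000, seed=100 + seed,
            )
            truth = build_ground_truth(cfg)
            genus = next(iter(truth.affected_genera))
            direction = truth.affected_genera[genus]
            base = pd.Series(0.95 / 9, index=truth.genus_catalog.index)
            base[genus] = 0.05
            truth = dataclasses.replace(
                truth, base_abundance={"AV": base / base.sum()}
            )
            table, _ = simulate_annotation_tables(truth)
            m = abundance.aggregate_counts(table, "genus")
            enriched = f"AV{direction}"
            other = "AVm" if direction == "f" else "AVf"
            k1 = m.counts.loc[genus, enriched]
            n1 = m.counts[enriched].sum()
            k2 = m.counts.loc[genus, other]
            n2 = m.counts[other].sum()
            ratios.append((k1 / (n1 - k1)) / (k2 / (n2 - k2)))
        mean_or = float(np.mean(ratios))
        assert abs(mean_or - 8.0) / 8.0 < 0.2

    def test_round_trip_table(self, tmp_path):
        truth = build_ground_truth(small_config(reads_per_sample=200))
        table, _ = simulate_annotation_tables(truth)
        path = tmp_path / "ann.tsv"
        profile_io.write_annotation_table(table, path)
        back = profile_io.read_annotation_table(path)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_noiseless_spectrum_recovered_exactly(self):
        cfg = small_config(reads_per_sample=5000)
        truth = build_ground_truth(cfg)
        # uniform abundance so every genus is sampled with certainty
        uniform = pd.Series(1.0 / cfg.n_genera, index=truth.genus_catalog.index)
        truth = dataclasses.replace(truth, base_abundance={"AV": uniform})
        table, _ = simulate_annotation_tables(truth)
        bh = profile_io.best_hit_classification(
            profile_io.apply_annotation_filters(table, mode="functional")
        )
        res = linkage.build_linkage_edges(bh, set(truth.enzyme_catalog))
        spec = linkage.redundancy_spectrum(res)
        observed = spec.per_enzyme.sort_index()
        planted_counts = truth.expected_spectrum.sort_index()
        assert list(observed.index) == list(planted_counts.index)
        assert (observed.to_numpy() == planted_counts.to_numpy()).all()
        # edge incidence equals the planted repertoire
        incidence = set(map(tuple, res.edges[["genus", "enzyme"]].drop_duplicates().values))
        planted = {
            (g, e)
            for g in truth.repertoire.index
            for e in truth.repertoire.columns
            if truth.repertoire.loc[g, e]
        }
        assert incidence == planted

    def test_seed_determinism(self):
        truth = build_ground_truth(small_config(reads_per_sample=300))
        t1, _ = simulate_annotation_tables(truth)
        t2, _ = simulate_annotation_tables(truth)
        pd.testing.assert_frame_equal(t1, t2)


class TestReadSimulation:
    def test_planted_counts_removed_exactly(self):
        truth = build_ground_truth(small_config())
        plan = ReadSimPlan(n_reads=100, low_quality=13, duplicates=7)
        reads = simulate_reads(truth, {"AVf": plan})["AVf"]
        assert len(reads) == 100
        params = QCParams()
        kept, n_quality = qc_filter_reads(reads, params)
        assert n_quality == 13
        kept2, n_dup = dereplicate_reads(kept, params)
        assert n_dup == 7
        assert len(kept2) == 80

    def test_no_planted_removals(self):
        truth = build_ground_truth(small_config())
        reads = simulate_reads(truth, {"AVf": ReadSimPlan(n_reads=50)})["AVf"]
        kept, n_quality = qc_filter_reads(reads)
        kept, n_dup = dereplicate_reads(kept)
        assert n_quality == 0 and n_dup == 0 and len(kept) == 50

    def test_gc_target_within_binomial_error(self):
        truth = build_ground_truth(small_config())
        plan = ReadSimPlan(n_reads=200, read_len=200, gc_mean=0.35)
        reads = simulate_reads(truth, {"AVf": plan})["AVf"]
        gc = np.mean(
            [
                (str(r.seq).count("G") + str(r.seq).count("C")) / len(r.seq)
                for r in reads
            ]
        )
        n_bases = 200 * 200
        se = np.sqrt(0.35 * 0.65 / n_bases)
        assert abs(gc - 0.35) < 5 * se

    def test_read_len_below_prefix_rejected(self):
        truth = build_ground_truth(small_config())
        plan = ReadSimPlan(n_reads=10, read_len=60, duplicates=2)
        with pytest.raises(ValueError, match="duplicate-prefix"):
            simulate_reads(truth, {"AVf": plan}, QCParams(dup_prefix_len=80, min_len=40))

    def test_planted_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ReadSimPlan(n_reads=10, low_quality=6, duplicates=5)
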