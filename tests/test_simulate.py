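"""Synthetic-data generators: determinism, construction honesty, calibration."""

import numpy as np
import pytest

from hiftargets import (
    SimulationParams,
    SizingError,
    ValidationError,
    make_regulome,
    scan_consensus,
    simulate_deg_tables,
    simulate_metabolome,
    simulate_ortholog_studies,
    simulate_peak_sequences,
)
from hiftargets.simulate import COMPARISON_LABELS


class TestParams:
    def test_defaults_encode_study_conditions(self):
        p = SimulationParams()
        assert p.sites_per_target_distribution[0] == 0.59
        assert p.metab_replicates == 9
        assert p.n_studies == 31
        assert (p.ortholog_fraction_consistent, p.background_fraction_consistent) == (
            0.068, 0.003,
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_direct_targets": 50, "n_genes": 10},
            {"sites_per_target_distribution": (0.5, 0.4)},
            {"hot_decoy_fraction": 1.5},
            {"ortholog_fraction_consistent": 0.001},
            {"effect_direction": "sideways"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationParams(**kwargs)


class TestMakeRegulome:
    def test_single_site_distribution_gives_one_peak_per_target(self, small_params):
        import dataclasses

        params = dataclasses.replace(
            small_params, sites_per_target_distribution=(1.0,), n_direct_targets=20,
            n_genes=400,
        )
        _, _, peaks, _, truth = make_regulome(params)
        assert len(truth.functional_peak_ids) == 20
        assert all(v == 1 for v in truth.sites_per_target.values())

    def test_same_seed_identical(self, small_params):
        a = make_regulome(small_params)
        b = make_regulome(small_params)
        assert a[0] == b[0]
        assert a[2] == b[2]
        assert a[3] == b[3]
        assert a[4].peak_assignment == b[4].peak_assignment

    def test_assigned_peaks_lie_near_their_target_tss(self, small_params):
        _, genes, peaks, _, truth = make_regulome(small_params)
        tss = {g.gene_id: (g.chromosome, g.tss) for g in genes}
        peak_by_id = {p.peak_id: p for p in peaks}
        for pid, gid in truth.peak_assignment.items():
            if gid == "decoy":
                continue
            chrom, t = tss[gid]
            p = peak_by_id[pid]
            assert p.chromosome == chrom
            assert abs(p.center - t) <= small_params.target_peak_max_offset_bp

    def test_no_hot_loci_means_no_hot_anchor(self, small_params):
        import dataclasses

        from hiftargets import cobinding_counts

        params = dataclasses.replace(small_params, n_hot_loci=0)
        _, _, peaks, atlas, _ = make_regulome(params)
        profiles = cobinding_counts(peaks, atlas, 400, 15)
        assert not any(p.is_hot for p in profiles)

    def test_hot_decoys_cobound_by_many_factors(self, small_params):
        from hiftargets import cobinding_counts

        _, _, peaks, atlas, truth = make_regulome(small_params)
        profiles = {p.peak_id: p for p in cobinding_counts(peaks, atlas, 400, 15)}
        hot_count = sum(profiles[pid].is_hot for pid in truth.peak_assignment
                        if truth.peak_assignment[pid] == "decoy")
        expected = round(small_params.hot_decoy_fraction * small_params.n_decoy_peaks)
        assert hot_count >= 0.9 * expected

    def test_infeasible_sizing(self):
        with pytest.raises(SizingError):
            make_regulome(SimulationParams(chromosome_length_bp=15_000))


class TestDegTables:
    def test_four_labeled_tables_full_size(self, small_params):
        _, genes, _, _, truth = make_regulome(small_params)
        comps = simulate_deg_tables(truth, genes, small_params)
        assert [c.label for c in comps] == list(COMPARISON_LABELS)
        assert all(len(c.records) == small_params.n_genes for c in comps)

    def test_null_effect_targets_indistinguishable(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, effect_mean_log2fc=0.0, effect_sd=0.0)
        _, genes, _, _, truth = make_regulome(params)
        comps = simulate_deg_tables(truth, genes, params)
        # raw p-values are uniform for every gene: KS against uniform
        from scipy import stats

        for c in comps:
            assert stats.kstest(c.records["raw_p"], "uniform").pvalue > 1e-3

    def test_effects_shared_across_comparisons(self, small_params):
        _, genes, _, _, truth = make_regulome(small_params)
        comps = simulate_deg_tables(truth, genes, small_params)
        t = sorted(truth.direct_targets)
        fc = np.array(
            [c.records.set_index("gene_id").loc[t, "log2fc"].to_numpy() for c in comps]
        )
        # per-target fold changes correlate strongly across the four tables
        assert np.corrcoef(fc[0], fc[1])[0, 1] > 0.3

    def test_same_seed_identical(self, small_params):
        _, genes, _, _, truth = make_regulome(small_params)
        a = simulate_deg_tables(truth, genes, small_params)
        b = simulate_deg_tables(truth, genes, small_params)
        for x, y in zip(a, b):
            assert x.records.equals(y.records)


class TestPeakSequences:
    def test_certain_planting_in_functional_windows(self, small_params):
        import dataclasses

        params = dataclasses.replace(
            small_params, motif_plant_prob_functional=1.0, motif_plant_prob_decoy=0.0
        )
        _, _, peaks, _, truth = make_regulome(params)
        seqs = simulate_peak_sequences(peaks, truth, params)
        assert truth.functional_peak_ids <= truth.motif_planted
        for pid in truth.functional_peak_ids:
            h = scan_consensus(seqs[pid])
            assert h.plus_hits + h.minus_hits >= 1

    def test_window_length(self, small_params):
        _, _, peaks, _, truth = make_regulome(small_params)
        seqs = simulate_peak_sequences(peaks, truth, small_params)
        assert all(len(s) == 2 * small_params.motif_flank_bp + 1 for s in seqs.values())

    def test_flank_too_small(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, motif_flank_bp=2)
        _, _, peaks, _, truth = make_regulome(params)
        with pytest.raises(SizingError):
            simulate_peak_sequences(peaks, truth, params)

    def test_same_seed_identical(self, small_params):
        _, _, peaks, _, truth = make_regulome(small_params)
        a = simulate_peak_sequences(peaks, truth, small_params)
        truth.motif_planted.clear()
        b = simulate_peak_sequences(peaks, truth, small_params)
        assert a == b


class TestMetabolome:
    def test_study_scale_matrix_shape(self):
        matrix, design, _ = simulate_metabolome(SimulationParams())
        assert matrix.shape == (558, 18)  # 558 metabolites, nine replicates per arm
        assert design.count("cond1") == design.count("cond2") == 9

    def test_null_calibration(self):
        from hiftargets import metabolite_differential

        rates = []
        for seed in range(20):
            p = SimulationParams(seed=seed, metab_n=200, metab_effect_fraction=0.0)
            matrix, design, perturbed = simulate_metabolome(p)
            assert perturbed == []
            _, counts = metabolite_differential(matrix, design)
            rates.append(counts["raw_p_lt_0.05"] / 200)
        se = np.sqrt(0.05 * 0.95 / (200 * 20))
        assert np.mean(rates) == pytest.approx(0.05, abs=3 * se + 0.005)

    def test_same_seed_identical(self):
        p = SimulationParams(metab_n=50)
        a, _, _ = simulate_metabolome(p)
        b, _, _ = simulate_metabolome(p)
        assert a.equals(b)


class TestOrthologStudies:
    def test_panel_structure_and_planted_fractions(self):
        p = SimulationParams(meta_n_genes=4000, meta_n_orthologs=200, n_studies=10)
        panel, orthologs, consistent = simulate_ortholog_studies(p)
        assert len(panel.studies) == 10
        assert len(orthologs) == 200
        n_orth_cons = len(consistent & orthologs)
        assert n_orth_cons == round(0.068 * 200)
        assert len(consistent - orthologs) == round(0.003 * 3800)

    def test_zero_background_consistency(self):
        p = SimulationParams(
            meta_n_genes=2000, meta_n_orthologs=100, background_fraction_consistent=0.0,
            ortholog_fraction_consistent=0.05, n_studies=8,
        )
        _, orthologs, consistent = simulate_ortholog_studies(p)
        assert consistent <= orthologs

    def test_same_seed_identical(self):
        p = SimulationParams(meta_n_genes=500, meta_n_orthologs=50, n_studies=5)
        a, _, _ = simulate_ortholog_studies(p)
        b, _, _ = simulate_ortholog_studies(p)
        for sid in a.studies:
            assert a.studies[sid].equals(b.studies[sid])
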