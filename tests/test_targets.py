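"""Regulatory-potential scoring, KS regulation inference and target calls."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hiftargets import (
    AnalysisConfig,
    GeneModel,
    Peak,
    call_direct_targets,
    ks_regulation_test,
    rank_targets,
    regulatory_potential,
    regulatory_potential_table,
    sites_per_target_summary,
)
from hiftargets.targets import TargetCall


def peak_at(center, chrom="chrI", width=10, pid="p"):
    return Peak(pid, chrom, center - width // 2, center + width // 2)


class TestRegulatoryPotential:
    def test_no_peak_in_window(self, gene):
        assert regulatory_potential(gene, [peak_at(20_000)], 15_000) == 0.0

    def test_peak_at_tss(self, gene):
        # closed form at delta = 0
        s = regulatory_potential(gene, [peak_at(gene.tss)], 15_000)
        assert s == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_peaks_at_tss_and_window_edge(self, gene):
        peaks = [peak_at(gene.tss, pid="a"), peak_at(gene.tss + 15_000, pid="b")]
        s = regulatory_potential(gene, peaks, 15_000)
        assert s == pytest.approx(math.exp(-0.5) + math.exp(-4.5), abs=1e-9)
        assert s == pytest.approx(0.61764, abs=1e-5)

    def test_monotone_in_distance(self, gene):
        window = 15_000
        scores = [
            regulatory_potential(gene, [peak_at(gene.tss + d)], window)
            for d in range(0, window + 1, 500)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_vectorised_matches_scalar(self, small_params):
        from hiftargets import make_regulome

        _, genes, peaks, _, _ = make_regulome(small_params)
        table = regulatory_potential_table(genes, peaks, 15_000)
        for g in genes[::17]:
            assert table[g.gene_id] == pytest.approx(
                regulatory_potential(g, peaks, 15_000), abs=1e-12
            )


class TestRankTargets:
    def test_single_gene(self):
        rp = pd.Series({"g1": 0.5})
        deg = pd.DataFrame({"gene_id": ["g1"], "log2fc": [1.0], "fdr": [0.001]})
        out = rank_targets(rp, deg)
        assert out["rank_product"].iloc[0] == 1.0

    def test_top_in_both_gets_inverse_square(self):
        rp = pd.Series({"g1": 2.0, "g2": 1.0, "g3": 0.0})
        deg = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "log2fc": [3.0, 1.0, 0.5],
             "fdr": [0.001, 0.01, 0.5]}
        )
        out = rank_targets(rp, deg).set_index("gene_id")
        assert out.loc["g1", "rank_product"] == pytest.approx(1 / 9)

    def test_rp_ties_averaged(self):
        rp = pd.Series({"g1": 1.0, "g2": 1.0})
        deg = pd.DataFrame({"gene_id": ["g1", "g2"], "log2fc": [1.0, 2.0],
                            "fdr": [0.01, 0.001]})
        out = rank_targets(rp, deg)
        assert list(out["rp_rank"]) == [1.5, 1.5]

    def test_fdr_tie_broken_by_abs_log2fc(self):
        rp = pd.Series({"g1": 1.0, "g2": 0.5})
        deg = pd.DataFrame({"gene_id": ["g1", "g2"], "log2fc": [1.0, -3.0],
                            "fdr": [0.01, 0.01]})
        out = rank_targets(rp, deg).set_index("gene_id")
        assert out.loc["g2", "de_rank"] < out.loc["g1", "de_rank"]


def ks_enum_oracle(x, y):
    """Exact one-sided two-sample KS p by enumerating all pooled splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])

    def d_stat(xs, ys):
        allv = np.sort(pooled)
        cx = np.searchsorted(np.sort(xs), allv, side="right") / len(xs)
        cy = np.searchsorted(np.sort(ys), allv, side="right") / len(ys)
        return np.max(cy - cx)

    obs = d_stat(x, y)
    count = total = 0
    for comb in combinations(range(len(pooled)), len(x)):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        count += d_stat(pooled[sel], pooled[~sel]) >= obs - 1e-12
        total += 1
    return obs, count / total


class TestKsRegulation:
    def test_identical_groups_not_activator(self):
        bg = list(np.linspace(0, 1, 20))
        v = ks_regulation_test(bg, [], bg, ks_cutoff=0.01)
        assert v.up_ks_stat == pytest.approx(0.0)
        assert v.verdict != "activator"

    def test_maximal_separation_is_activator(self):
        up = [1.0 + i * 1e-6 for i in range(10)]  # tie-free, all above background
        bg = [0.0 + i * 1e-6 for i in range(10)]
        v = ks_regulation_test(up, [], bg, ks_cutoff=0.01)
        assert v.up_ks_stat == pytest.approx(1.0)
        assert v.up_p <= 0.01
        assert v.verdict == "activator"

    def test_both_groups_empty_is_none(self):
        v = ks_regulation_test([], [], [0.1, 0.2, 0.3])
        assert v.verdict == "none"
        assert v.up_p == 1.0 and v.down_p == 1.0

    def test_small_sample_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            up = rng.normal(1.0, 1.0, size=6)
            bg = rng.normal(0.0, 1.0, size=7)
            _, p_oracle = ks_enum_oracle(up, bg)
            v = ks_regulation_test(up, [], bg)
            assert v.up_p == pytest.approx(p_oracle, abs=1e-12)


class TestCallDirectTargets:
    def _genes(self):
        return [
            GeneModel("g1", "chrI", "+", 50_000),
            GeneModel("g2", "chrI", "+", 200_000),
            GeneModel("g3", "chrII", "+", 50_000),
        ]

    def _deg(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "direction", "log2fc", "fdr"])

    def _config(self):
        return AnalysisConfig(seed=0)

    def test_de_gene_with_nearby_peak_called(self):
        deg = self._deg([("g1", "up", 2.0, 0.001)])
        peaks = [peak_at(55_000, pid="p1")]
        calls, _ = call_direct_targets(peaks, deg, self._genes(), self._config())
        (call,) = calls
        assert (call.gene_id, call.direction, call.n_sites, call.peak_ids) == (
            "g1", "up", 1, ["p1"],
        )

    def test_peak_outside_window_not_called(self):
        deg = self._deg([("g1", "up", 2.0, 0.001)])
        peaks = [peak_at(70_001, pid="p1")]  # 20 kb from TSS, window 15 kb
        calls, _ = call_direct_targets(peaks, deg, self._genes(), self._config())
        assert calls == []

    def test_non_de_gene_never_called(self):
        deg = self._deg([])
        peaks = [peak_at(50_000, pid=f"p{i}") for i in range(3)]
        calls, verdict = call_direct_targets(peaks, deg, self._genes(), self._config())
        assert calls == [] and verdict.verdict == "none"

    def test_peak_assignment_is_partition(self):
        # two called genes 6 kb apart; each peak goes to exactly one gene
        genes = [GeneModel("g1", "chrI", "+", 50_000), GeneModel("g2", "chrI", "+", 56_000),
                 GeneModel("g3", "chrII", "+", 10_000)]  # non-DE background
        deg = self._deg([("g1", "up", 2.0, 0.001), ("g2", "up", 2.0, 0.001)])
        peaks = [peak_at(c, pid=f"p{i}") for i, c in enumerate([49_000, 52_000, 55_500, 60_000])]
        calls, _ = call_direct_targets(peaks, deg, genes, self._config())
        assigned = [pid for c in calls for pid in c.peak_ids]
        assert sorted(assigned) == ["p0", "p1", "p2", "p3"]
        assert len(set(assigned)) == len(assigned)
        assert sum(c.n_sites for c in calls) == 4
        by_gene = {c.gene_id: c.peak_ids for c in calls}
        assert by_gene == {"g1": ["p0", "p1"], "g2": ["p2", "p3"]}  # nearest TSS


class TestSitesPerTarget:
    def _call(self, gid, pids):
        return TargetCall(gid, "up", pids, 1.0, 2.0, 0.001)

    def test_histogram(self):
        calls = [self._call("a", ["p1"]), self._call("b", ["p2"]),
                 self._call("c", ["p3", "p4"])]
        out = sites_per_target_summary(calls)
        assert out.set_index("n_sites").loc[1, "fraction"] == pytest.approx(2 / 3)
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_single_call(self):
        out = sites_per_target_summary([self._call("a", ["p1", "p2", "p3"])])
        assert out.set_index("n_sites").loc[3, "fraction"] == 1.0

    def test_empty(self):
        assert len(sites_per_target_summary([])) == 0
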