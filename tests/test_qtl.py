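"""Haley-Knott scan, RI dosage, permutation thresholds, support intervals
and positional candidates."""

import itertools

import numpy as np
import pandas as pd
import pytest

import riphenome as rp
from riphenome.qtl import _lod_matrix, one_lod_interval
from riphenome.simulate import haldane_r, ri_expansion
from riphenome.types import GenotypeMatrix


def _panel_from_calls(calls: np.ndarray, cm: np.ndarray,
                      chrom: str = "1") -> GenotypeMatrix:
    strains = [f"s{i}" for i in range(calls.shape[0])]
    markers = [f"m{j}" for j in range(calls.shape[1])]
    mmap = pd.DataFrame({"marker": markers, "chrom": chrom,
                         "cM": cm, "Mb": cm})
    return GenotypeMatrix(
        calls=pd.DataFrame(np.where(calls == 1, "D", "B"), index=strains,
                           columns=markers),
        marker_map=mmap,
        subpopulation=pd.Series("p", index=strains))


class TestRIDosage:
    def test_coincident_with_typed_marker(self):
        for g in (0.0, 1.0):
            assert rp.ri_expected_dosage(g, 1.0, 0.0, 0.3) == g

    def test_disagreeing_flanks_at_midpoint(self):
        assert rp.ri_expected_dosage(0.0, 1.0, 0.2, 0.2) == pytest.approx(0.5)
        assert rp.ri_expected_dosage(1.0, 0.0, 0.2, 0.2) == pytest.approx(0.5)

    def test_matching_flanks_against_enumeration(self):
        # enumerate the four haplotype classes of the RI Markov chain
        for r1, r2 in [(0.05, 0.05), (0.02, 0.1), (0.2, 0.3)]:
            R1, R2 = ri_expansion(r1), ri_expansion(r2)
            probs = {}
            for x in (0, 1):      # pseudomarker allele given flanks (B, B)
                t1 = R1 if x != 0 else 1 - R1
                t2 = R2 if x != 0 else 1 - R2
                probs[x] = t1 * t2
            expected = probs[1] / (probs[0] + probs[1])
            got = rp.ri_expected_dosage(0.0, 0.0, r1, r2)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got < 0.5

    def test_inconsistent_flanks_at_zero_recombination(self):
        with pytest.raises(ValueError):
            rp.ri_expected_dosage(0.0, 1.0, 0.0, 0.0)


class TestHKScan:
    def test_hand_regression_example(self):
        # y = {1,2,3,4} on dosages {0,0,1,1}: RSS0 = 5, RSS1 = 1
        calls = np.array([[0], [0], [1], [1]])
        geno = _panel_from_calls(calls, np.array([0.0]))
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=geno.strains)
        scan = rp.hk_scan(y, geno, step_cM=None)
        assert scan.loci["lod"].iloc[0] == pytest.approx(
            2.0 * np.log10(5.0), abs=1e-12)

    def test_constant_phenotype_gives_zero_lod(self):
        rng = np.random.default_rng(0)
        calls = (rng.random((12, 8)) < 0.5).astype(int)
        geno = _panel_from_calls(calls, np.linspace(0, 70, 8))
        y = pd.Series(3.14, index=geno.strains)
        scan = rp.hk_scan(y, geno)
        assert np.all(scan.loci["lod"] == 0.0)

    def test_monomorphic_marker_gives_zero_lod(self):
        calls = np.column_stack([np.zeros(10, int),
                                 np.arange(10) % 2])
        geno = _panel_from_calls(calls, np.array([0.0, 50.0]))
        y = pd.Series(np.random.default_rng(1).normal(size=10),
                      index=geno.strains)
        scan = rp.hk_scan(y, geno, step_cM=None)
        assert scan.loci["lod"].iloc[0] == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        calls = (rng.random((20, 15)) < 0.5).astype(int)
        geno = _panel_from_calls(calls, np.linspace(0, 90, 15))
        y = pd.Series(rng.normal(size=20), index=geno.strains)
        lod1 = rp.hk_scan(y, geno).loci["lod"]
        lod2 = rp.hk_scan(-2.5 * y + 7.0, geno).loci["lod"]
        assert lod1.to_numpy() == pytest.approx(lod2.to_numpy(), abs=1e-10)

    def test_matches_full_vs_reduced_rss_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(12, 40))
            m = int(rng.integers(5, 25))
            calls = (rng.random((n, m)) < 0.5).astype(int)
            geno = _panel_from_calls(calls, np.sort(rng.uniform(0, 100, m)))
            y = pd.Series(rng.normal(size=n), index=geno.strains)
            scan = rp.hk_scan(y, geno, step_cM=None)
            yv = y.to_numpy()
            rss0 = float(((yv - yv.mean()) ** 2).sum())
            for j, lod in enumerate(scan.loci["lod"]):
                X = np.column_stack([np.ones(n), calls[:, j]])
                beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
                rss1 = float(((yv - X @ beta) ** 2).sum())
                expected = (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300)) \
                    if calls[:, j].std() > 0 else 0.0
                assert lod == pytest.approx(expected, abs=1e-10)

    def test_pseudomarker_scan_keeps_typed_marker_lods(self):
        rng = np.random.default_rng(4)
        calls = (rng.random((25, 10)) < 0.5).astype(int)
        geno = _panel_from_calls(calls, np.linspace(0, 90, 10))
        y = pd.Series(rng.normal(size=25), index=geno.strains)
        marker_only = rp.hk_scan(y, geno, step_cM=None).loci
        with_grid = rp.hk_scan(y, geno, step_cM=1.0).loci
        typed = with_grid[with_grid["typed"]]
        assert typed["lod"].to_numpy() == pytest.approx(
            marker_only["lod"].to_numpy(), abs=1e-12)

    def test_planted_qtl_recovered(self):
        cfg = rp.SimulationConfig(
            n_strains_per_subpop=(60,), subpop_names=("only",),
            n_chromosomes=5, markers_per_chromosome=30,
            private_locus_count=0, traits={"t": rp.TraitSpec(0, 0, 0, 1.0)},
            seed=11)
        geno = rp.simulate_genotypes(cfg)
        g = 2.0 * geno.dosage()["m03_015"] - 1.0   # QTL mid chromosome 3
        true_cm = float(geno.marker_map.set_index("marker")
                        .loc["m03_015", "cM"])
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            # strain-mean noise sized so the QTL explains ~50% of variance
            y = pd.Series(g + rng.normal(0, 1.0, size=60),
                          index=geno.strains)
            scan = rp.hk_scan(y, geno, step_cM=None)
            peak = scan.loci.loc[scan.loci["lod"].idxmax()]
            hits += (peak["chrom"] == "3"
                     and abs(peak["cM"] - true_cm) <= 10.0)
        assert hits / n_rep >= 0.90


class TestPermutationThresholds:
    def _panel(self, seed=5):
        rng = np.random.default_rng(seed)
        calls = (rng.random((30, 40)) < 0.5).astype(int)
        return _panel_from_calls(calls, np.linspace(0, 100, 40))

    def test_reproducible_and_ordered(self):
        geno = self._panel()
        y = pd.Series(np.random.default_rng(6).normal(size=30),
                      index=geno.strains)
        t1 = rp.permutation_thresholds(y, geno, n_perm=200, seed=9)
        t2 = rp.permutation_thresholds(y, geno, n_perm=200, seed=9)
        assert t1 == t2
        assert t1[0] <= t1[1]       # suggestive <= significant

    def test_too_few_permutations_rejected(self):
        geno = self._panel()
        y = pd.Series(np.zeros(30), index=geno.strains)
        with pytest.raises(ValueError):
            rp.permutation_thresholds(y, geno, n_perm=50)


class TestSupportIntervals:
    def test_hand_interpolation_example(self):
        pos = np.array([0.0, 10.0, 20.0])
        lods = np.array([1.0, 4.0, 1.0])
        lo, hi = one_lod_interval(pos, lods, 1)
        assert lo == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert hi == pytest.approx(40.0 / 3.0, abs=1e-9)

    def test_truncation_at_chromosome_end(self):
        pos = np.array([0.0, 10.0, 20.0])
        lods = np.array([3.8, 4.0, 1.0])
        lo, hi = one_lod_interval(pos, lods, 1)
        assert lo == 0.0            # never drops by 1 on the left
        assert hi < 20.0

    def test_flat_top_extends_to_outermost_grid_point(self):
        pos = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        lods = np.array([1.0, 4.0, 4.0, 4.0, 1.0])
        lo, hi = one_lod_interval(pos, lods, 1)
        lo2, hi2 = one_lod_interval(pos, lods, 3)
        assert lo == lo2 and hi == hi2
        assert lo < 10.0 and hi > 30.0


class TestPeaksAndCandidates:
    def _scan(self):
        loci = pd.DataFrame({
            "locus": [f"m{i}" for i in range(5)],
            "chrom": "1",
            "cM": [0.0, 10.0, 20.0, 30.0, 40.0],
            "Mb": [0.0, 10.0, 20.0, 30.0, 40.0],
            "typed": True,
            "lod": [0.5, 1.0, 4.0, 1.0, 0.2],
        })
        return rp.QTLScanResult(trait_id="t", loci=loci, n_strains=30)

    def test_peak_classification_and_interval(self):
        peaks = rp.find_peaks(self._scan(), suggestive=2.0, significant=3.5)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.classification == "significant"
        assert pk.support_cM[0] < 20.0 < pk.support_cM[1]
        with pytest.raises(ValueError):
            rp.find_peaks(self._scan(), suggestive=4.0, significant=3.0)

    def test_candidates_by_overlap(self, tiled_annotation):
        pk = rp.QTLPeak("1", 12.0, 12.0, 4.0, "significant",
                        (10.5, 14.5), (10.5, 14.5))
        genes = rp.positional_candidates(pk, tiled_annotation)
        assert genes == [f"g{i:03d}" for i in range(10, 15)]

    def test_edge_straddling_gene_included(self, tiled_annotation):
        pk = rp.QTLPeak("1", 11.0, 11.0, 4.0, "suggestive",
                        (10.5, 10.7), (10.5, 10.7))
        assert rp.positional_candidates(pk, tiled_annotation) == ["g010"]

    def test_missing_chromosome_warns_empty(self, tiled_annotation):
        pk = rp.QTLPeak("7", 12.0, 12.0, 4.0, "suggestive",
                        (10.0, 14.0), (10.0, 14.0))
        with pytest.warns(UserWarning):
            assert rp.positional_candidates(pk, tiled_annotation) == []


class TestMarkerEffectByGroup:
    def test_sign_flip_detected_and_masks_combined_scan(self):
        rng = np.random.default_rng(13)
        n = 40
        calls = (rng.random((n, 1)) < 0.5).astype(int)
        geno = _panel_from_calls(calls, np.array([0.0]))
        groups = pd.Series(["g1"] * (n // 2) + ["g2"] * (n // 2),
                           index=geno.strains)
        g = 2.0 * calls[:, 0] - 1.0
        flip = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        y = pd.Series(g * flip + rng.normal(0, 0.3, n), index=geno.strains)
        table = rp.marker_effect_by_group(y, geno, "m0", groups)
        assert table.loc["g1", "D"] > table.loc["g1", "B"]
        assert table.loc["g2", "D"] < table.loc["g2", "B"]
        combined = rp.hk_scan(y, geno, step_cM=None).max_lod()
        within = [rp.hk_scan(y[mask.index[mask]], geno.calls.loc[
            mask.index[mask]].pipe(lambda c: GenotypeMatrix(
                calls=c, marker_map=geno.marker_map,
                subpopulation=geno.subpopulation[mask.index[mask]])),
            step_cM=None).max_lod()
            for mask in (groups.eq("g1"), groups.eq("g2"))]
        assert combined < min(within)

    def test_single_group_reduces_to_allele_means(self):
        calls = np.array([[0], [0], [1], [1]])
        geno = _panel_from_calls(calls, np.array([0.0]))
        y = pd.Series([1.0, 2.0, 5.0, 7.0], index=geno.strains)
        table = rp.marker_effect_by_group(
            y, geno, "m0", pd.Series("all", index=geno.strains))
        assert table.loc["all", "B"] == 1.5
        assert table.loc["all", "D"] == 6.0


def test_suggestive_criterion_constant():
    # one expected false positive per genome scan -> P = 1 - 1/e
    p = rp.genomewide_p_for_expected_false_positives(1.0)
    assert round(p, 2) == 0.63
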