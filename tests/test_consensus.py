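"""Validation mapping, LD computation and cross-dataset consensus."""

import numpy as np
import pandas as pd
import pytest

from regionbvs.consensus import (
    ConsensusError,
    ScanResult,
    ld_r2,
    map_region_to_validation,
    overlap_consensus,
    single_scan,
    validate_regions,
)
from regionbvs.genotypes import PhenotypeVector
from regionbvs.regions import RegionIndex, partition_genome
from regionbvs.sampler import BVSConfig, BVSPriors
from regionbvs.synthetic import BlockSpec, make_platform_subset, simulate_genotypes

from conftest import make_G


def _meta(positions, chrom="1"):
    return pd.DataFrame(
        {
            "snp_id": [f"v{p}" for p in positions],
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "minor": ["A"] * len(positions),
            "major": ["G"] * len(positions),
        }
    )


class TestMapRegion:
    region = RegionIndex("1", 3, 0, 5, 100, 200)

    def test_identity_panel_maps_to_same_interval(self):
        meta = _meta([100, 120, 150, 180, 200])
        mapped = map_region_to_validation(self.region, meta)
        assert (mapped.start, mapped.stop) == (0, 5)
        assert mapped.start_pos == 100 and mapped.end_pos == 200

    def test_inclusive_bounds(self):
        meta = _meta([50, 100, 150, 200, 250])
        mapped = map_region_to_validation(self.region, meta)
        assert (mapped.start, mapped.stop) == (1, 4)
        assert mapped.start_pos == 100 and mapped.end_pos == 200

    def test_absent_chromosome_returns_none(self):
        meta = _meta([100, 150], chrom="7")
        assert map_region_to_validation(self.region, meta) is None

    def test_empty_interval_returns_none(self):
        meta = _meta([500, 600])
        assert map_region_to_validation(self.region, meta) is None

    def test_monotone_in_interval(self):
        meta = _meta(list(range(50, 300, 10)))
        small = map_region_to_validation(self.region, meta)
        wider = map_region_to_validation(
            RegionIndex("1", 3, 0, 5, 80, 240), meta
        )
        assert wider.start <= small.start and wider.stop >= small.stop

    def test_platform_subset_maps_binomially(self):
        G = simulate_genotypes(
            10, [("1", [BlockSpec(1000, 0.0, (0.2, 0.5))])], seed=1
        )
        sub = make_platform_subset(G, 0.5, seed=2)
        region = RegionIndex(
            "1", 1, 0, 1000,
            int(G.snp_meta["pos"].iloc[0]), int(G.snp_meta["pos"].iloc[-1]),
        )
        mapped = map_region_to_validation(region, sub.snp_meta)
        assert mapped.n_snps == sub.n_snps  # all kept SNPs fall inside
        assert mapped.n_snps == pytest.approx(500, abs=1)


class TestLdR2:
    def test_identical_columns(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_matches_pearson_formula(self):
        a = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
        b = np.array([0, 1, 1, 1, 0, 2, 0, 0], dtype=float)
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        expected = (cov / (a.std() * b.std())) ** 2
        assert ld_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_allele_flip_invariance_and_symmetry(self, rng):
        a = rng.integers(0, 3, size=20).astype(float)
        b = rng.integers(0, 3, size=20).astype(float)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a))
        assert ld_r2(2 - a, b) == pytest.approx(ld_r2(a, b))

    def test_constant_vector_rejected(self):
        with pytest.raises(ConsensusError):
            ld_r2(np.ones(5), np.array([0, 1, 2, 1, 0.0]))


def _toy_scan(chrom, positions, pips, sum_pip, rank=1):
    df = pd.DataFrame(
        {
            "snp_id": [f"{chrom}s{p}" for p in positions],
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "pip": pips,
        }
    )
    per_region = pd.DataFrame(
        {
            "chrom": [chrom],
            "region": [rank],
            "start_pos": [min(positions)],
            "end_pos": [max(positions)],
            "n_snps": [len(positions)],
            "sum_pip": [sum_pip],
            "mean_pip": [sum_pip / len(positions)],
        }
    )
    return ScanResult(
        per_region=per_region, per_snp=df, region_pips={(chrom, rank): df}
    )


class TestOverlapConsensus:
    def _reference(self):
        # 6 SNPs on chrom 1: first 3 tightly correlated, last 3 noise
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=50).astype(float)
        dos = np.column_stack(
            [
                base,
                base,
                np.clip(base + (rng.random(50) < 0.1), 0, 2),
                rng.integers(0, 3, size=50),
                rng.integers(0, 3, size=50),
                rng.integers(0, 3, size=50),
            ]
        )
        meta = pd.DataFrame(
            {
                "snp_id": [f"1s{p}" for p in (100, 200, 300, 5000, 6000, 7000)],
                "chrom": ["1"] * 6,
                "pos": [100, 200, 300, 5000, 6000, 7000],
                "minor": ["A"] * 6,
                "major": ["G"] * 6,
            }
        )
        return make_G(dos).dosages, meta

    def _reference_G(self):
        dos, meta = self._reference()
        from regionbvs.genotypes import GenotypeMatrix

        return GenotypeMatrix(dosages=dos, snp_meta=meta)

    def test_self_comparison_gives_full_consensus(self):
        ref = self._reference_G()
        scan = _toy_scan("1", [100, 200, 300], [0.9, 0.8, 0.7], 2.4)
        pairs, summary = overlap_consensus(
            scan, scan, ref, top_region_frac=1.0, top_snp_frac=1.0,
            window_bp=1000, r2_threshold=0.2,
        )
        self_pairs = [p for p in pairs if p.snp_a == p.snp_b]
        assert len(self_pairs) == 3
        assert all(p.r2 == 1.0 and p.distance_bp == 0 for p in self_pairs)
        assert summary["pct_in_ld"] == 100.0

    def test_disjoint_chromosomes_have_no_pairs(self):
        ref = self._reference_G()
        a = _toy_scan("1", [100, 200], [0.9, 0.8], 1.7)
        b = _toy_scan("2", [100, 200], [0.9, 0.8], 1.7)
        pairs, summary = overlap_consensus(
            a, b, ref, top_region_frac=1.0, top_snp_frac=1.0,
            window_bp=1000, r2_threshold=0.2,
        )
        assert pairs == []
        assert summary["n_pairs"] == 0

    def test_correlated_block_enters_consensus(self):
        ref = self._reference_G()
        a = _toy_scan("1", [100, 5000], [0.9, 0.85], 1.75)
        b = _toy_scan("1", [300, 6000], [0.95, 0.8], 1.75)
        pairs, summary = overlap_consensus(
            a, b, ref, top_region_frac=1.0, top_snp_frac=1.0,
            window_bp=1000, r2_threshold=0.2,
        )
        by_key = {(p.snp_a, p.snp_b): p for p in pairs}
        # the LD-block pair is in consensus; the noise pair is not
        assert by_key[("1s100", "1s300")].in_ld
        assert not by_key[("1s5000", "1s6000")].in_ld
        assert summary["n_in_ld"] == 1

    def test_percentage_invariant_to_dataset_order(self):
        ref = self._reference_G()
        a = _toy_scan("1", [100, 5000], [0.9, 0.85], 1.75)
        b = _toy_scan("1", [300, 6000], [0.95, 0.8], 1.75)
        _, s_ab = overlap_consensus(
            a, b, ref, 1.0, 1.0, window_bp=1000, r2_threshold=0.2
        )
        _, s_ba = overlap_consensus(
            b, a, ref, 1.0, 1.0, window_bp=1000, r2_threshold=0.2
        )
        assert s_ab["pct_in_ld"] == pytest.approx(s_ba["pct_in_ld"])
        assert s_ab["n_pairs"] == s_ba["n_pairs"]

    def test_missing_reference_snp_excluded_from_denominator(self):
        ref = self._reference_G()
        a = _toy_scan("1", [100, 999], [0.9, 0.85], 1.75)  # 999 not in reference
        b = _toy_scan("1", [300], [0.95], 0.95)
        pairs, summary = overlap_consensus(
            a, b, ref, 1.0, 1.0, window_bp=1000, r2_threshold=0.2
        )
        assert summary["n_pairs"] == 2
        assert summary["n_with_r2"] == 1
        assert summary["n_missing_reference"] == 1
        assert summary["pct_in_ld"] == 100.0


class TestValidateRegions:
    def test_validated_flag_tracks_permutation_outcome(self, rng):
        # causal block shared by discovery definition and validation cohort
        G = simulate_genotypes(
            300, [("1", [BlockSpec(15, 0.4, (0.2, 0.5))])], seed=3
        )
        liab = (
            1.1 * (G.dosages[:, 7] - G.dosages[:, 7].mean()) / G.dosages[:, 7].std()
            + rng.normal(size=300)
        )
        y = PhenotypeVector((liab > np.median(liab)).astype(int))
        regions = partition_genome(G, window=15)
        records = validate_regions(
            regions, G, y, BVSPriors(h_max=0.5),
            BVSConfig(n_iter=2000, seed=0), B=40, alpha=0.5, master_seed=1,
        )
        assert len(records) == 1
        rec = records[0]
        assert rec.result.statistic == "mean_pip"
        assert rec.validated == rec.result.significant
        assert rec.validated  # strong planted signal, liberal alpha

    def test_unmappable_candidate_reported_with_reason(self, rng):
        G = simulate_genotypes(
            100, [("1", [BlockSpec(10, 0.2, (0.2, 0.5))])], seed=5
        )
        y = PhenotypeVector(rng.permutation(np.repeat([0, 1], 50)))
        ghost = RegionIndex("9", 1, 0, 10, 100, 200)
        records = validate_regions(
            [ghost], G, y, BVSPriors(), BVSConfig(n_iter=1000, seed=0), B=10,
        )
        assert not records[0].validated
        assert records[0].reason
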