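"""EHH decay, iHH integration, iHS standardization and clustering."""

import math

import numpy as np
import pytest

from standscan import ihs
from standscan.types import HaplotypeMatrix

from conftest import random_matrix


def matrix(rows, positions):
    return HaplotypeMatrix(np.array(rows, dtype=np.int8), positions)


class TestEHH:
    def test_unity_at_core(self, rng):
        h = random_matrix(rng, n_hap=12, n_site=9)
        seg = np.flatnonzero(h.is_segregating())
        core = int(seg[len(seg) // 2])
        for allele in ("ancestral", "derived"):
            counts = int(h.haplotypes[:, core].sum())
            if (allele == "derived" and counts < 2) or (
                allele == "ancestral" and h.n_hap - counts < 2
            ):
                continue
            curve = ihs.ehh(h, core, allele)
            assert curve.ehh[curve.distances == 0][0] == 1.0

    def test_three_carrier_enumeration(self):
        # carriers of the derived core allele: two identical, one distinct
        # at the flanking site -> 1 concordant pair of C(3,2)=3
        h = matrix(
            [
                [1, 0],  # flanking site, core site ordering: core at index 1
                [1, 1],
                [1, 1],
                [0, 1],
            ],
            [100, 200],
        )
        curve = ihs.ehh(h, core=1, allele="derived", direction="upstream")
        up = curve.ehh[curve.distances < 0]
        assert up[0] == pytest.approx(1 / 3)

    def test_non_increasing_outward(self, rng):
        for _ in range(5):
            h = random_matrix(rng, n_hap=16, n_site=15)
            seg = np.flatnonzero(h.is_segregating())
            core = int(seg[len(seg) // 2])
            if int(h.haplotypes[:, core].sum()) < 2:
                continue
            curve = ihs.ehh(h, core, "derived")
            for direction in ("upstream", "downstream"):
                _, e = curve.side(direction)
                assert np.all(np.diff(e) <= 1e-12)

    def test_too_few_carriers(self):
        h = matrix([[1, 0], [0, 0], [0, 1], [0, 1]], [1, 2])
        with pytest.raises(ValueError, match="fewer than 2 carriers"):
            ihs.ehh(h, 0, "derived")


class TestIHH:
    def test_trapezoid_arithmetic(self):
        curve = ihs.EHHCurve(0, "derived", np.array([0, 1000]), np.array([1.0, 0.5]))
        area, edge = ihs.ihh(curve)
        assert area == pytest.approx(750.0)
        assert edge  # 0.5 never decays below truncation

    def test_constant_curve_integrates_to_distance(self):
        curve = ihs.EHHCurve(0, "derived", np.array([0, 400]), np.array([1.0, 1.0]))
        area, edge = ihs.ihh(curve)
        assert area == pytest.approx(400.0)
        assert edge

    def test_truncation_interpolates_crossing(self):
        curve = ihs.EHHCurve(
            0,
            "derived",
            np.array([-200, -100, 0, 100, 200]),
            np.array([0.0, 0.5, 1.0, 0.5, 0.0]),
        )
        area, edge = ihs.ihh(curve, truncation=0.25)
        # per side: 75 up to 100 bp, then (0.5+0.25)/2 * 50 to the crossing
        assert area == pytest.approx(2 * (75 + 0.375 * 50))
        assert not edge

    def test_one_sided_curve_flags_edge(self):
        curve = ihs.EHHCurve(
            0, "derived", np.array([0, 100, 200]), np.array([1.0, 0.5, 0.0])
        )
        area, edge = ihs.ihh(curve, truncation=0.25)
        assert area == pytest.approx(75 + 0.375 * 50)
        assert edge  # no upstream data at all


class TestIHS:
    def test_symmetric_classes_score_zero(self):
        # ancestral and derived carriers with mirror-image haplotypes
        rows = [
            [0, 0, 1, 0, 0],
            [1, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
            [1, 1, 0, 1, 1],
        ]
        h = matrix(rows, [10, 20, 30, 40, 50])
        r = ihs.ihs_unstandardized(h, 2)
        assert r is not None
        assert r.ihs_unstd == pytest.approx(0.0, abs=1e-12)

    def test_swept_derived_allele_scores_negative(self, rng):
        # derived carriers identical over a long stretch; ancestral diverse
        n_site = 41
        h = random_matrix(rng, n_hap=30, n_site=n_site)
        core = n_site // 2
        hap = h.haplotypes.copy()
        hap[:, core] = 0
        template = hap[0].copy()
        for i in range(15):
            hap[i] = template
            hap[i, core] = 1
        swept = HaplotypeMatrix(hap, h.positions)
        r = ihs.ihs_unstandardized(swept, core)
        assert r is not None
        assert r.ihs_unstd < 0

    def test_invariant_to_haplotype_order(self, rng):
        h = random_matrix(rng, n_hap=20, n_site=21)
        core = 10
        r1 = ihs.ihs_unstandardized(h, core)
        perm = rng.permutation(h.n_hap)
        r2 = ihs.ihs_unstandardized(
            HaplotypeMatrix(h.haplotypes[perm], h.positions), core
        )
        if r1 is None:
            assert r2 is None
        else:
            assert r1.ihs_unstd == pytest.approx(r2.ihs_unstd)


class TestStandardize:
    def test_bins_have_zero_mean_unit_sd(self, rng):
        results = [
            ihs.IHSResult(i, i * 10, daf=float(rng.uniform(0.05, 0.95)),
                          ihh_a=1, ihh_d=1,
                          ihs_unstd=float(rng.normal()))
            for i in range(500)
        ]
        out = ihs.standardize_ihs(results, n_bins=10)
        dafs = np.array([r.daf for r in out])
        stds = np.array([r.ihs_std for r in out])
        edges = np.linspace(0, 1, 11)
        bins = np.clip(np.digitize(dafs, edges) - 1, 0, 9)
        for b in np.unique(bins):
            sel = stds[bins == b]
            sel = sel[~np.isnan(sel)]
            if len(sel) > 1:
                assert np.mean(sel) == pytest.approx(0.0, abs=1e-9)
                assert np.std(sel, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_singleton_bin_left_unstandardized(self):
        results = [
            ihs.IHSResult(0, 10, daf=0.07, ihh_a=1, ihh_d=1, ihs_unstd=0.5),
            ihs.IHSResult(1, 20, daf=0.93, ihh_a=1, ihh_d=1, ihs_unstd=0.2),
        ]
        out = ihs.standardize_ihs(results, n_bins=20)
        assert all(math.isnan(r.ihs_std) for r in out)

    def test_planted_outlier_keeps_extreme_rank(self, rng):
        scores = list(rng.normal(size=199)) + [8.0]
        results = [
            ihs.IHSResult(i, i, daf=0.5, ihh_a=1, ihh_d=1, ihs_unstd=s)
            for i, s in enumerate(scores)
        ]
        out = ihs.standardize_ihs(results, n_bins=20)
        ranked = sorted(out, key=lambda r: r.ihs_std)
        assert ranked[-1].site == 199
        assert ranked[-1].significant


class TestClusters:
    def make(self, positions, significant):
        return [
            ihs.IHSResult(i, p, 0.5, 1, 1, 0.0, 3.0 if s else 0.0, s)
            for i, (p, s) in enumerate(zip(positions, significant))
        ]

    def test_no_significant_sites(self):
        res = self.make([10, 20, 30], [False] * 3)
        assert ihs.cluster_significant(res, 100) == []

    def test_two_separated_clusters(self):
        res = self.make(
            [100, 200, 5000, 5100], [True, True, True, True]
        )
        clusters = ihs.cluster_significant(res, max_gap=1000)
        assert len(clusters) == 2
        assert [r.position for r in clusters[0]] == [100, 200]

    def test_matches_brute_force_scan(self, rng):
        positions = np.sort(rng.choice(10_000, 50, replace=False))
        flags = rng.random(50) < 0.4
        res = self.make(positions.tolist(), flags.tolist())
        gap = 500
        clusters = ihs.cluster_significant(res, gap)
        # brute force
        sig = sorted(p for p, f in zip(positions, flags) if f)
        brute = []
        for p in sig:
            if brute and p - brute[-1][-1] <= gap:
                brute[-1].append(p)
            else:
                brute.append([p])
        assert [[r.position for r in c] for c in clusters] == brute


class TestEnrichment:
    def test_observed_above_all_background(self):
        assert ihs.gene_enrichment_p(0.9, np.linspace(0, 0.5, 99)) == pytest.approx(
            1 / 100
        )

    def test_observed_at_median(self):
        bg = np.linspace(0, 1, 101)
        assert ihs.gene_enrichment_p(0.5, bg) == pytest.approx(0.5, abs=0.02)

    def test_rank_agrees_with_sort_oracle(self, rng):
        bg = rng.random(200)
        obs = 0.7
        p = ihs.gene_enrichment_p(obs, bg)
        assert p == (1 + np.sum(np.sort(bg) >= obs)) / 201

    def test_empty_background(self):
        with pytest.raises(ValueError):
            ihs.gene_enrichment_p(0.5, np.array([]))
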