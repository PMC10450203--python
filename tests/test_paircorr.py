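"""Pair correlation with geometric null and focus co-localization."""

import numpy as np
import pytest

from rnapalm.geometry import CellGeometry, sample_uniform, sample_uniform_area
from rnapalm.paircorr import (
    ColocConfig,
    coloc_fraction,
    cross_pair_correlation,
    mean_pair_correlation,
    null_pair_histogram,
    pair_correlation_cell,
)


@pytest.fixture
def cell():
    return CellGeometry(3.0, 1.0)


def gr_bruteforce(points, cell, bin_width, r_max, n_null_draws, rng):
    """Independent g(r): explicit double-loop distances, digitize binning,
    its own rejection sampling of the rotated cell volume."""
    n_bins = int(round(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width

    def hist(pts):
        acc = np.zeros(n_bins)
        for i in range(len(pts)):
            d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
            idx = np.digitize(d, edges) - 1
            for j in idx[(idx >= 0) & (idx < n_bins)]:
                acc[j] += 1
        return acc

    def draw_uniform(n):
        out = []
        while len(out) < n:
            x = rng.uniform(-cell.length / 2, cell.length / 2)
            y = rng.uniform(-cell.radius, cell.radius)
            z = rng.uniform(-cell.radius, cell.radius)
            half_cyl = cell.length / 2 - cell.radius
            dx = max(abs(x) - half_cyl, 0.0)
            if dx**2 + y**2 + z**2 <= cell.radius**2:
                out.append((x, y))
        return np.array(out)

    obs = hist(np.asarray(points))
    null = np.mean([hist(draw_uniform(len(points))) for _ in range(n_null_draws)], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(null > 0, obs / null, np.nan)


class TestPairCorrelation:
    def test_uniform_is_flat(self, cell):
        """Projected uniform points self-normalize to g = 1."""
        rng = np.random.default_rng(1)
        pcs = []
        null = null_pair_histogram(cell, 500, 0.01, 50, 40, seed=rng)
        for _ in range(20):
            pts = sample_uniform("cell", cell, 500, seed=rng, project=True)
            pcs.append(
                pair_correlation_cell(pts, cell, r_max=0.5, null_mean=null, seed=rng)
            )
        m = mean_pair_correlation(pcs)
        assert m.mean_g(0.05, 0.5) == pytest.approx(1.0, abs=0.05)

    def test_single_tight_cluster(self, cell):
        rng = np.random.default_rng(2)
        pts = rng.normal(0.0, 0.040, (200, 2))
        pc = pair_correlation_cell(pts, cell, r_max=1.0, n_null_draws=20, seed=3)
        assert pc.mean_g(0.0, 0.1) > 10
        assert pc.mean_g(0.5, 1.0) < 1.0

    def test_matches_bruteforce_oracle(self, cell):
        """20% clustered / 80% uniform mixture against an independent
        implementation with 10x the null draws."""
        rng = np.random.default_rng(4)
        uniform = sample_uniform("cell", cell, 160, seed=rng, project=True)
        cluster = rng.normal([0.5, 0.1], 0.03, (40, 2))
        pts = np.vstack([uniform, cluster])
        pc = pair_correlation_cell(pts, cell, bin_width=0.05, r_max=0.5,
                                   n_null_draws=200, seed=rng)
        g_ref = gr_bruteforce(pts, cell, 0.05, 0.5, 20, np.random.default_rng(5))
        ok = ~np.isnan(pc.g) & ~np.isnan(g_ref) & (g_ref > 0)
        assert ok.sum() >= 8
        assert np.all(np.abs(pc.g[ok] / g_ref[ok] - 1) < 0.05)

    def test_null_convergence(self, cell):
        """Doubling the null draws changes g by < 1% per bin."""
        rng = np.random.default_rng(6)
        pts = sample_uniform("cell", cell, 2000, seed=rng, project=True)
        pc1 = pair_correlation_cell(pts, cell, r_max=0.5, n_null_draws=40, seed=7)
        pc2 = pair_correlation_cell(pts, cell, r_max=0.5, n_null_draws=80, seed=8)
        sel = (pc1.r_centers > 0.05) & (pc1.r_centers < 0.5)
        assert np.nanmax(np.abs(pc1.g[sel] / pc2.g[sel] - 1)) < 0.01

    def test_rigid_motion_invariance(self, cell):
        """Rotating the point set with the cell frame leaves g unchanged:
        distances and the geometric null are frame-independent."""
        rng = np.random.default_rng(9)
        pts = rng.normal([0.3, 0.0], 0.05, (100, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        null = null_pair_histogram(cell, 100, 0.01, 100, 100, seed=10)
        pc1 = pair_correlation_cell(pts, cell, null_mean=null)
        pc2 = pair_correlation_cell(pts @ rot.T, cell, null_mean=null)
        assert np.allclose(pc1.pair_counts, pc2.pair_counts)

    def test_too_few_points(self, cell):
        with pytest.raises(ValueError):
            pair_correlation_cell(np.array([[0.0, 0.0]]), cell)

    def test_rmax_truncated_with_warning(self, cell):
        pts = np.random.default_rng(11).normal(0, 0.1, (50, 2))
        with pytest.warns(RuntimeWarning, match="truncat"):
            pair_correlation_cell(pts, cell, r_max=5.0, n_null_draws=5, seed=12)


class TestMeanPairCorrelation:
    def test_idempotent(self, cell):
        pts = sample_uniform("cell", cell, 200, seed=13, project=True)
        pc = pair_correlation_cell(pts, cell, n_null_draws=5, seed=14)
        m = mean_pair_correlation([pc, pc])
        assert np.allclose(m.g, pc.g, equal_nan=True)

    def test_arithmetic_mean_per_bin(self, cell):
        pts = sample_uniform("cell", cell, 200, seed=15, project=True)
        pc1 = pair_correlation_cell(pts, cell, n_null_draws=5, seed=16)
        pc2 = pair_correlation_cell(pts, cell, n_null_draws=5, seed=17)
        pc2.g = pc1.g + 0.4  # force g = x and x + 0.4
        m = mean_pair_correlation([pc1, pc2])
        ok = ~np.isnan(pc1.g)
        assert np.allclose(m.g[ok], pc1.g[ok] + 0.2)

    def test_binning_mismatch(self, cell):
        pts = sample_uniform("cell", cell, 100, seed=18, project=True)
        pc1 = pair_correlation_cell(pts, cell, bin_width=0.01, n_null_draws=2, seed=19)
        pc2 = pair_correlation_cell(pts, cell, bin_width=0.02, n_null_draws=2, seed=20)
        with pytest.raises(ValueError):
            mean_pair_correlation([pc1, pc2])


class TestColoc:
    def test_points_on_foci(self, cell):
        foci = np.array([[0.5, 0.1], [-0.8, 0.0]])
        assert coloc_fraction(foci.copy(), foci, cell) == 1.0

    def test_far_focus_zero(self, cell):
        pts = np.array([[1.0, 0.0], [0.9, 0.1]])
        foci = np.array([[-1.0, 0.0]])
        assert coloc_fraction(pts, foci, cell) == 0.0

    def test_no_foci_undefined(self, cell):
        with pytest.raises(ValueError):
            coloc_fraction(np.array([[0.0, 0.0]]), np.empty((0, 2)), cell)

    def test_null_fraction_matches_area_integration(self, cell):
        """Monte-Carlo null equals (disc ∪ area within the shrunk nucleoid)
        / nucleoid area, computed by direct numerical integration."""
        foci = np.array([[0.2, 0.0], [-0.9, 0.1]])
        cfg = ColocConfig(radius=0.2)
        frac = coloc_fraction(
            None, foci, cell, cfg, null=True, n_null_points=200_000,
            n_null_draws=3, seed=21,
        )
        # dense-grid integration over the shrunk footprint
        sl, sw = cfg.nucleoid_shrink
        xs = np.linspace(-sl * cell.length / 2, sl * cell.length / 2, 2001)
        ys = np.linspace(-sw * cell.radius, sw * cell.radius, 801)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        inside = cell.contains(pts / np.array([sl, sw]))
        d = np.full(len(pts), np.inf)
        for f in foci:
            d = np.minimum(d, np.hypot(pts[:, 0] - f[0], pts[:, 1] - f[1]))
        expected = (inside & (d <= cfg.radius)).sum() / inside.sum()
        assert frac == pytest.approx(expected, abs=0.005)

    def test_cross_correlation_null_is_flat(self, cell):
        rng = np.random.default_rng(22)
        foci = np.array([[0.5, 0.0], [-0.5, 0.0]])
        queries = sample_uniform_area(cell, 3000, seed=rng, shrink=(0.75, 0.75))
        pc = cross_pair_correlation(
            queries, foci, cell, bin_width=0.05, r_max=0.6,
            n_null_draws=40, n_null_points=3000, seed=rng,
        )
        assert np.nanmean(pc.g) == pytest.approx(1.0, abs=0.05)
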