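"""Four-population cell simulation, cluster-size law and track generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from rnapalm.geometry import CellGeometry, normalize_xy
from rnapalm.simulate import (
    ClusterSizeModel,
    PlacementError,
    RRN_OFFSETS_KB,
    SimulationConfig,
    TrackSimConfig,
    delta5_config,
    place_rrn_sites,
    render_frames,
    sample_cluster_sizes,
    simulate_cell,
    simulate_track_array,
    simulate_tracks,
    wt_config,
)
from rnapalm.spatial import exterior_fraction
from rnapalm.tracking import apparent_D_array


class TestClusterSizes:
    def test_inverse_transform_formula(self):
        # direct evaluation of X = -(1/b) ln(1 - b u / a)
        a, b, u = 1.0, 0.05, 0.5
        x = -(1 / b) * np.log(1 - b * u / a)
        assert x == pytest.approx(0.5064, abs=1e-3)
        # u = 0 gives X = 0, clamped to size 1
        assert -(1 / b) * np.log(1 - 0.0) == 0.0

    def test_sizes_integer_and_clamped(self):
        sizes = sample_cluster_sizes(ClusterSizeModel(a=1.0, b=0.05), 10_000, seed=1)
        assert sizes.dtype.kind == "i"
        assert sizes.min() >= 1
        # a=1, b=0.05 maps u in (0,1) to X < 1.03: nearly all size 1
        assert sizes.max() <= 2

    def test_distribution_matches_numerical_inversion(self):
        """KS distance < 0.01 against brute-force numerical inversion of the
        truncated-exponential CDF implied by the printed transform."""
        model = ClusterSizeModel(a=1.0, b=0.5)
        n = 100_000
        draws = sample_cluster_sizes(model, n, seed=2)

        # oracle: tabulate the CDF of round(X)|clamped by numerically
        # inverting F(x) = (a/b)(1 - exp(-b x)) on the accepted-u region
        u = (np.arange(n) + 0.5) / n
        u = u[model.b * u / model.a < 1]
        grid = np.linspace(0, 60, 600_001)
        cdf_vals = (model.a / model.b) * -np.expm1(-model.b * grid)
        x_oracle = np.interp(u, cdf_vals, grid)
        sizes_oracle = np.maximum(np.rint(x_oracle), 1)

        ks = kstest(draws, sizes_oracle).statistic
        assert ks < 0.01

    def test_unbounded_rejection_is_an_error(self):
        with pytest.raises(ValueError, match="rejection"):
            sample_cluster_sizes(ClusterSizeModel(a=0.001, b=1.0), 10, seed=0)


class TestRrnPlacement:
    def setup_method(self):
        self.cell = CellGeometry(3.0, 1.0)

    def test_single_site_on_surface_at_mapped_position(self):
        for seed in range(200):
            (site,) = place_rrn_sites(self.cell, [306.0], seed=seed)
            a, b = self.cell.nucleoid_semi_long, self.cell.nucleoid_semi_short
            assert abs(site[0]) == pytest.approx(a * (1 - 306 / 2320))
            q = (site[0] / a) ** 2 + (site[1] / b) ** 2 + (site[2] / b) ** 2
            assert q == pytest.approx(1.0, abs=1e-9)

    def test_min_separation_all_seeds(self):
        offsets = [42.0, 110.0, 265.0, 306.0, 497.0, 940.0, 1196.0]
        for seed in range(1000):
            sites = place_rrn_sites(self.cell, offsets, min_sep=0.070, seed=seed)
            d = np.linalg.norm(sites[:, None] - sites[None], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 0.070

    def test_genomic_map_is_monotone(self):
        sites = place_rrn_sites(self.cell, [42.0, 265.0], seed=4)
        folded = np.abs(sites[:, 0])  # distance from mid-cell
        assert folded[0] > folded[1]  # 42 kb strictly more pole-proximal

    def test_impossible_packing_raises(self):
        with pytest.raises(PlacementError):
            place_rrn_sites(self.cell, [306.0] * 8, min_sep=0.6, seed=0)


class TestSimulateCell:
    def test_population_counts_wt(self):
        counts = wt_config().population_counts()
        assert counts["rrn"] + counts["small_cluster"] == 864  # 48% of 1800
        assert counts["mobile"] + counts["noise"] == 936
        assert sum(counts.values()) == 1800

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(50, 3000),
        f_imm=st.floats(0.0, 1.0),
        f_rrn=st.floats(0.0, 1.0),
        f_noise=st.floats(0.0, 1.0),
    )
    def test_counts_conserved(self, n, f_imm, f_rrn, f_noise):
        cfg = SimulationConfig(
            n_molecules=n,
            f_immobile=f_imm,
            f_rrn_of_immobile=f_rrn,
            noise_fraction=f_noise,
        )
        assert sum(cfg.population_counts().values()) == n

    def test_simulated_labels_match_counts(self):
        cfg = delta5_config()
        df = simulate_cell(cfg, seed=8)
        got = df["population"].value_counts().to_dict()
        assert got == {k: v for k, v in cfg.population_counts().items() if v}

    def test_zero_noise_stays_in_nucleoid_or_cell(self):
        cfg = wt_config(noise_fraction=0.0)
        df = simulate_cell(cfg, seed=9)
        cell = cfg.cell
        assert set(df["population"]) == {"rrn", "small_cluster", "mobile"}
        assert cell.contains(df[["x_um", "y_um"]].to_numpy()).all()
        mob = df[df.population == "mobile"][["x_um", "y_um"]].to_numpy()
        # projected mobile points lie within the nucleoid's 2D extent
        assert np.abs(mob[:, 0]).max() <= cell.nucleoid_semi_long
        assert np.abs(mob[:, 1]).max() <= cell.nucleoid_semi_short

    def test_exterior_fraction_monotone_in_rrn_share(self):
        """Sweeping the rrn-bound share of immobile molecules over the
        30-80% range moves immobile mass towards the pole-proximal operon
        sites, so the exterior-25% fraction must not decrease."""
        rng = np.random.default_rng(21)
        fracs = []
        for f_rrn in (0.30, 0.425, 0.55, 0.675, 0.80):
            cfg = delta5_config(f_rrn_of_immobile=f_rrn)
            ls = []
            for _ in range(60):
                df = simulate_cell(cfg, seed=rng)
                imm = df[df.population.isin(["rrn", "small_cluster"])]
                l, _ = normalize_xy(imm[["x_um", "y_um"]].to_numpy(), cfg.cell)
                ls.append(l)
            fracs.append(exterior_fraction(np.concatenate(ls)))
        assert np.all(np.diff(fracs) >= 0)


class TestSimulateTracks:
    def test_immobile_apparent_d_is_error_floor(self):
        """Zero true diffusion: E[D*] = sigma_loc^2 / dt = 0.0817 μm²/s."""
        cfg = TrackSimConfig(
            n_tracks=10_000, f_immobile=1.0, D_immobile_true=0.0,
            loc_error_sigma=0.035, dt=0.015,
        )
        pos, _ = simulate_track_array(cfg, seed=31)
        d = apparent_D_array(pos, dt=cfg.dt)
        assert d.mean() == pytest.approx(0.035**2 / 0.015, abs=0.002)

    def test_mobile_apparent_d_adds_error_floor(self):
        cfg = TrackSimConfig(
            n_tracks=10_000, f_immobile=0.0, D_mobile_true=0.28,
            loc_error_sigma=0.035, dt=0.015,
        )
        pos, _ = simulate_track_array(cfg, seed=32)
        d = apparent_D_array(pos, dt=cfg.dt)
        assert d.mean() == pytest.approx(0.28 + 0.0817, abs=0.01)

    def test_empty_track_list(self):
        pos, imm = simulate_tracks(TrackSimConfig(n_tracks=0), seed=0)
        assert pos == [] and len(imm) == 0

    def test_track_lengths_at_least_five(self):
        pos, _ = simulate_tracks(TrackSimConfig(n_tracks=500), seed=33)
        assert min(len(p) for p in pos) >= 5

    def test_nonpositive_mobile_d_rejected(self):
        with pytest.raises(ValueError):
            TrackSimConfig(D_mobile_true=0.0)


class TestRenderFrames:
    def test_brightest_pixel_at_emitter(self):
        import pandas as pd

        locs = pd.DataFrame({"frame": [0], "x_um": [1.55], "y_um": [2.05]})
        img = render_frames(locs, (40, 40), photons=1000, poisson_noise=False)[0]
        r, c = np.unravel_index(np.argmax(img), img.shape)
        assert (r, c) == (20, 15)

    def test_two_emitters_resolved(self):
        import pandas as pd

        locs = pd.DataFrame(
            {"frame": [0, 0], "x_um": [1.0, 3.0], "y_um": [2.0, 2.0]}
        )
        img = render_frames(locs, (40, 40), photons=1000, poisson_noise=False)[0]
        from scipy.ndimage import maximum_filter

        peaks = (img == maximum_filter(img, 5)) & (img > img.max() / 4)
        assert peaks.sum() == 2

    def test_seeded_determinism(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        locs = pd.DataFrame(
            {
                "frame": np.zeros(100, dtype=int),
                "x_um": rng.uniform(0.5, 3.5, 100),
                "y_um": rng.uniform(0.5, 3.5, 100),
            }
        )
        s1 = render_frames(locs, (40, 40), background=5, seed=42)
        s2 = render_frames(locs, (40, 40), background=5, seed=42)
        assert np.array_equal(s1, s2)
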