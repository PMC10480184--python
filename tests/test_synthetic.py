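"""Tests of the synthetic-data generators: Stokes–Einstein arithmetic,
Brownian/fBm track statistics, mixing bookkeeping and FCS traces."""

import numpy as np
import pytest
from scipy.linalg import toeplitz

from sptfcs import simulate
from sptfcs._fgn import _fgn_from_normals, fgn_autocovariance, fgn_draw_dim, sample_fgn
from sptfcs.fcs import multitau_acf


class TestStokesEinstein:
    def test_codata_value_for_40nm_bead_in_water(self):
        # direct evaluation of kT/(6 pi r mu) at 37 C, 0.8 cP, r = 20 nm
        d = simulate.stokes_einstein_d(20.0, 0.8, 310.15)
        assert d == pytest.approx(14.198, abs=0.01)

    def test_exact_scaling_laws(self):
        d = simulate.stokes_einstein_d(20.0, 3.8, 310.15)
        assert simulate.stokes_einstein_d(20.0, 7.6, 310.15) == pytest.approx(d / 2, rel=1e-12)
        assert simulate.stokes_einstein_d(40.0, 3.8, 310.15) == pytest.approx(d / 2, rel=1e-12)
        # 40 nm vs 100 nm bead: exact radius ratio 2.5
        assert simulate.stokes_einstein_d(50.0, 3.8, 310.15) == pytest.approx(0.4 * d, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate.stokes_einstein_d(*bad)

    def test_reference_table_agreement(self):
        # printed reference values agree within 10% relative, never asking
        # more than the table's own printed precision (0.2 has one digit)
        for frac, (visc, d40_ref, d100_ref) in simulate.BEAD_TABLE_REFERENCE.items():
            for radius, ref in ((20.0, d40_ref), (50.0, d100_ref)):
                d = simulate.stokes_einstein_d(radius, visc, 310.15)
                digits = len(str(ref).split(".")[1]) if "." in str(ref) else 0
                printed_half_ulp = 0.5 * 10.0 ** (-digits)
                tol = max(0.10 * ref, printed_half_ulp)
                assert abs(d - ref) <= tol, (frac, radius, d, ref)


class TestBeadConditions:
    def test_full_table(self):
        conds = simulate.build_bead_conditions()
        assert len(conds) == 10  # 5 viscosities x 2 diameters
        for diam in (40.0, 100.0):
            ds = [c.d_theory for c in conds if c.bead_diameter_nm == diam]
            assert all(a > b for a, b in zip(ds, ds[1:]))  # monotone in glycerol

    def test_empty_diameters(self):
        assert simulate.build_bead_conditions(diameters_nm=()) == []

    def test_duplicate_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate.build_bead_conditions(table=((0.1, 1.0), (0.1, 2.0)))


class TestBrownianTracks:
    def test_zero_diffusion_zero_noise_is_static(self):
        cfg = simulate.SimulationConfig(n_tracks=5, localization_sigma=0.0, rng_seed=3)
        for t in simulate.simulate_brownian_tracks(0.0, cfg):
            assert np.allclose(t.xy, t.xy[0])

    def test_mean_squared_step(self):
        # 2D: E[|dr|^2] = 4 D dt; no localization noise
        cfg = simulate.SimulationConfig(n_tracks=1000, localization_sigma=0.0, rng_seed=5)
        ts = simulate.simulate_brownian_tracks(1.0, cfg)
        sq = np.concatenate([np.sum(np.diff(t.xy, axis=0) ** 2, axis=1) for t in ts])
        expected = 4 * 1.0 * 0.01
        se = sq.std() / np.sqrt(sq.size)
        assert abs(sq.mean() - expected) < 3 * se

    def test_localization_noise_offset(self):
        # lag-1 ensemble MSD = 4 D dt + 4 sigma^2
        cfg = simulate.SimulationConfig(n_tracks=1000, localization_sigma=0.05, rng_seed=6)
        ts = simulate.simulate_brownian_tracks(1.0, cfg)
        sq = np.concatenate([np.sum(np.diff(t.xy, axis=0) ** 2, axis=1) for t in ts])
        expected = 4 * 1.0 * 0.01 + 4 * 0.05**2
        se = sq.std() / np.sqrt(sq.size)
        assert abs(sq.mean() - expected) < 3 * se

    def test_track_length_law(self):
        cfg = simulate.SimulationConfig(n_tracks=3000, rng_seed=8)
        lengths = np.array([len(t) for t in simulate.simulate_brownian_tracks(1.0, cfg)])
        assert lengths.min() >= cfg.min_track_length
        assert abs(lengths.mean() - cfg.mean_track_length) < 3 * lengths.std() / np.sqrt(lengths.size)

    def test_determinism(self):
        cfg = simulate.SimulationConfig(n_tracks=20, rng_seed=9)
        a = simulate.simulate_brownian_tracks(0.7, cfg)
        b = simulate.simulate_brownian_tracks(0.7, cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.xy, tb.xy)


class TestFractionalBrownian:
    @pytest.mark.parametrize("hurst", [0.155, 0.25, 0.475, 0.7])
    def test_sampler_covariance_is_exact(self, hurst):
        # the sampler is linear in its normal draws, so propagating basis
        # vectors reproduces its covariance exactly; compare with the
        # closed-form fGn autocovariance (equivalently the 3-point fBm
        # covariance 0.5(s^2H + t^2H - |t-s|^2H) after differencing)
        n = 3
        basis = np.eye(fgn_draw_dim(n, hurst))
        x = _fgn_from_normals(basis, n, hurst)
        cov = x.T @ x
        assert np.allclose(cov, toeplitz(fgn_autocovariance(n, hurst)), atol=1e-10)

    def test_brownian_limit_uncorrelated_increments(self):
        cfg = simulate.SimulationConfig(
            n_tracks=1, min_track_length=2, mean_track_length=2, localization_sigma=0.0, rng_seed=10
        )
        rng = np.random.default_rng(10)
        x = sample_fgn(rng, 10**5, 0.5, size=1)[0]
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho) < 0.02

    def test_self_similarity(self):
        # TA-MSD(c tau) / TA-MSD(tau) = c^alpha; alpha = 0.5, c = 4
        rng = np.random.default_rng(11)
        paths = np.cumsum(sample_fgn(rng, 10**4, 0.25, size=20), axis=1)
        def ta_msd_1d(x, lag):
            return np.mean((x[:, lag:] - x[:, :-lag]) ** 2)
        ratio = ta_msd_1d(paths, 8) / ta_msd_1d(paths, 2)
        assert ratio == pytest.approx(4.0**0.5, rel=0.02)

    def test_subdiffusive_ensemble_slope(self):
        # slow subdiffusive population parameters: D_alpha = 0.02, alpha = 0.31
        cfg = simulate.SimulationConfig(n_tracks=600, localization_sigma=0.0, rng_seed=12)
        ts = simulate.simulate_fbm_tracks(0.02, 0.31, cfg)
        lags = np.arange(1, 6)
        ens = []
        for lag in lags:
            ens.append(np.mean(np.concatenate(
                [np.sum((t.xy[lag:] - t.xy[:-lag]) ** 2, axis=1) for t in ts if len(t) > lag]
            )))
        slope, intercept = np.polyfit(np.log(lags * 0.01), np.log(ens), 1)
        assert slope == pytest.approx(0.31, abs=0.03)
        assert np.exp(intercept) / 4 == pytest.approx(0.02, rel=0.1)

    def test_alpha_domain(self):
        cfg = simulate.SimulationConfig(n_tracks=2, rng_seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_fbm_tracks(0.1, 0.0, cfg)
        with pytest.raises(ValueError):
            simulate.simulate_fbm_tracks(0.1, 2.5, cfg)


class TestMixing:
    def _two_sets(self):
        a = simulate.simulate_brownian_tracks(
            1.0, simulate.SimulationConfig(n_tracks=300, rng_seed=1), label="a"
        )
        b = simulate.simulate_brownian_tracks(
            0.1, simulate.SimulationConfig(n_tracks=300, rng_seed=2), label="b"
        )
        return a, b

    def test_half_half_counts(self):
        a, b = self._two_sets()
        mix = simulate.mix_track_sets([a, b], [0.5, 0.5], 500, seed=3)
        labels = np.array(mix.labels())
        assert len(mix) == 500
        assert abs((labels == "a").sum() - 250) <= 1

    def test_degenerate_fractions(self):
        a, b = self._two_sets()
        mix = simulate.mix_track_sets([a, b], [1.0, 0.0], 200, seed=4)
        assert set(mix.labels()) == {"a"}

    def test_labels_partition_no_duplicates(self):
        a, b = self._two_sets()
        mix = simulate.mix_track_sets([a, b], [0.3, 0.7], 400, seed=5)
        ids = [t.track_id for t in mix]
        assert len(set(ids)) == len(ids) == 400
        coords = {tuple(t.xy[0]) for t in mix}
        assert len(coords) == 400  # no source track drawn twice

    def test_oversized_request_rejected(self):
        a, b = self._two_sets()
        with pytest.raises(ValueError):
            simulate.mix_track_sets([a, b], [1.0, 0.0], 400, seed=6)


class TestFCSTrace:
    VOL = simulate.FocalVolumeSpec(w0=0.25, z0=1.25)

    def test_zero_brightness_gives_empty_trace(self):
        spec = simulate.FCSSimSpec(
            diffusion_coefficient=5.0, mean_molecules_in_volume=2.0, brightness=0.0,
            duration=0.05, rng_seed=1,
        )
        trace = simulate.simulate_fcs_trace(spec, self.VOL)
        assert trace.counts.sum() == 0

    def test_static_molecules_flat_acf(self):
        spec = simulate.FCSSimSpec(
            diffusion_coefficient=0.0, mean_molecules_in_volume=2.0, brightness=200_000.0,
            duration=0.5, rng_seed=2,
        )
        trace = simulate.simulate_fcs_trace(spec, self.VOL)
        assert trace.counts.sum() > 0
        acf = multitau_acf(trace)
        sel = acf.lags <= 0.01
        # no dynamics: the fluctuation ACF is flat at zero (shot noise only)
        assert np.all(np.abs(acf.g[sel]) < 0.01)

    def test_box_validation(self):
        spec = simulate.FCSSimSpec(
            diffusion_coefficient=5.0, mean_molecules_in_volume=2.0, brightness=1000.0,
            duration=0.1, box_halfwidths=(0.3, 0.3, 0.5), rng_seed=3,
        )
        with pytest.raises(ValueError):
            simulate.simulate_fcs_trace(spec, self.VOL)

    def test_determinism(self):
        spec = simulate.FCSSimSpec(
            diffusion_coefficient=5.0, mean_molecules_in_volume=2.0, brightness=50_000.0,
            duration=0.2, rng_seed=4,
        )
        a = simulate.simulate_fcs_trace(spec, self.VOL)
        b = simulate.simulate_fcs_trace(spec, self.VOL)
        assert np.array_equal(a.counts, b.counts)


class TestRPB1Mixture:
    def test_default_fractions_and_labels(self):
        assert sum(v[0] for v in simulate.RPB1_CLASSES.values()) == pytest.approx(1.0)
        cfg = simulate.SimulationConfig(n_tracks=200, rng_seed=5)
        mix = simulate.simulate_rpb1_like_mixture(cfg, seed=5)
        labels = np.array(mix.labels())
        assert len(mix) == 200
        counts = {k: (labels == k).sum() for k in ("immobile", "subdiffusive", "mobile")}
        assert counts["immobile"] == 40 and counts["subdiffusive"] == 110 and counts["mobile"] == 50

    def test_invalid_fractions_rejected(self):
        cfg = simulate.SimulationConfig(n_tracks=10, rng_seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_rpb1_like_mixture(
                cfg, seed=1, classes={"a": (0.5, 0.0, 1.0), "b": (0.4, 0.5, 0.95)}
            )
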