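"""Synthetic data generators for the SPT/FCS diffusion-analysis pipeline.

Three families of inputs are produced here, matching what the downstream
analysis assumes:

* **Bead-benchmark trajectories** — 2D Brownian (or fractional-Brownian)
  tracks at 100 Hz with ~50 nm static localization error and photobleaching-
  limited track lengths, emulating fluorescent microspheres in water/glycerol
  mixtures whose ground-truth diffusion coefficients follow Stokes–Einstein.
* **Trajectory mixtures** — labelled subsamples from several conditions, the
  substrate for Gaussian-mixture subpopulation discrimination, including an
  RNA-polymerase-II-like three-class mixture (immobile / subdiffusive / mobile).
* **FCS photon traces** — Poisson photon counts from point emitters diffusing
  through a 3D Gaussian focal volume inside a periodic box.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from scipy.constants import Boltzmann

from ._fgn import sample_fgn
from ._tracks import Trajectory, TrajectorySet

__all__ = [
    "BeadCondition",
    "SimulationConfig",
    "FocalVolumeSpec",
    "FCSSimSpec",
    "IntensityTrace",
    "TAKAMURA_VISCOSITY_CP",
    "BEAD_TABLE_REFERENCE",
    "stokes_einstein_d",
    "build_bead_conditions",
    "simulate_brownian_tracks",
    "simulate_fbm_tracks",
    "mix_track_sets",
    "simulate_fcs_trace",
    "simulate_rpb1_like_mixture",
]

#: Dynamic viscosity (cP) of water/glycerol mixtures by glycerol weight
#: fraction, after the Takamura correlation as used for the bead benchmark.
TAKAMURA_VISCOSITY_CP: tuple[tuple[float, float], ...] = (
    (0.0, 0.8),
    (0.1, 1.0),
    (0.2, 1.3),
    (0.5, 3.8),
    (0.8, 27.8),
)

#: Published reference diffusion coefficients (µm²/s) for 40 nm and 100 nm
#: beads in the same mixtures. These carry a ~6% systematic offset relative to
#: a direct CODATA Stokes–Einstein evaluation at 310.15 K (unstated constants
#: in the source); they are used as benchmark ground-truth inputs and checked
#: against the formula at 10% relative tolerance, with their internal radius
#: and viscosity ratios exact.
BEAD_TABLE_REFERENCE: dict[float, tuple[float, float, float]] = {
    # glycerol fraction: (viscosity cP, D 40 nm, D 100 nm)
    0.0: (0.8, 15.1, 6.0),
    0.1: (1.0, 12.1, 4.8),
    0.2: (1.3, 9.0, 3.6),
    0.5: (3.8, 3.2, 1.28),
    0.8: (27.8, 0.4, 0.2),
}

DEFAULT_TEMPERATURE_K = 310.15  # samples kept at 37 °C


def stokes_einstein_d(radius_nm: float, viscosity_cp: float, temperature_k: float) -> float:
    """Stokes–Einstein diffusion coefficient D = kT / (6π r µ), in µm²/s.

    Parameters are the hydrodynamic radius (nm), dynamic viscosity (cP) and
    absolute temperature (K); the CODATA Boltzmann constant is used.
    """
    if radius_nm <= 0 or viscosity_cp <= 0 or temperature_k <= 0:
        raise ValueError("radius, viscosity and temperature must all be positive")
    r_m = radius_nm * 1e-9
    mu_pas = viscosity_cp * 1e-3
    d_m2s = Boltzmann * temperature_k / (6.0 * np.pi * r_m * mu_pas)
    return d_m2s * 1e12  # m²/s → µm²/s


@dataclass(frozen=True)
class BeadCondition:
    """One bead-benchmark condition with its theoretical diffusion coefficient."""

    glycerol_fraction: float
    viscosity_cp: float
    bead_diameter_nm: float
    temperature_k: float
    d_theory: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.glycerol_fraction <= 1.0:
            raise ValueError("glycerol_fraction must be in [0, 1]")
        if self.viscosity_cp <= 0 or self.bead_diameter_nm <= 0 or self.temperature_k <= 0:
            raise ValueError("viscosity, diameter and temperature must be positive")


def build_bead_conditions(
    table=TAKAMURA_VISCOSITY_CP,
    diameters_nm=(40.0, 100.0),
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> list[BeadCondition]:
    """One :class:`BeadCondition` per (viscosity row × bead diameter)."""
    fractions = [row[0] for row in table]
    if len(set(fractions)) != len(fractions):
        raise ValueError("duplicate glycerol fractions in viscosity table")
    out = []
    for frac, visc in table:
        if visc <= 0:
            raise ValueError("viscosities must be positive")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("glycerol fractions must lie in [0, 1]")
        for diam in diameters_nm:
            out.append(
                BeadCondition(
                    glycerol_fraction=frac,
                    viscosity_cp=visc,
                    bead_diameter_nm=diam,
                    temperature_k=temperature_k,
                    d_theory=stokes_einstein_d(diam / 2.0, visc, temperature_k),
                )
            )
    return out


@dataclass
class SimulationConfig:
    """Acquisition-level parameters of the simulated SPT experiment.

    Defaults mirror the benchmark acquisition: 100 Hz frame rate (10 ms frame
    interval), 50 nm static localization error, track lengths from a shifted
    geometric law (memoryless photobleaching) with mean 20 detections,
    truncated at 11, and a 6.5 µm field of view.
    """

    frame_interval: float = 0.01
    localization_sigma: float = 0.05
    min_track_length: int = 11
    mean_track_length: float = 20.0
    n_tracks: int = 500
    field_size: float = 6.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be nonnegative")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.mean_track_length < self.min_track_length:
            raise ValueError("mean_track_length must be >= min_track_length")
        if self.n_tracks < 0 or self.field_size <= 0:
            raise ValueError("n_tracks must be >= 0 and field_size positive")


def _track_lengths(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Shifted geometric track lengths: L = L_min − 1 + Geometric(p), mean as configured."""
    if config.mean_track_length == config.min_track_length:
        return np.full(config.n_tracks, config.min_track_length, dtype=np.int64)
    p = 1.0 / (config.mean_track_length - config.min_track_length + 1.0)
    return config.min_track_length - 1 + rng.geometric(p, size=config.n_tracks)


def _finalize_tracks(
    rng: np.random.Generator,
    paths: list[np.ndarray],
    config: SimulationConfig,
    label: str | None,
) -> TrajectorySet:
    tracks = []
    for i, xy in enumerate(paths):
        if config.localization_sigma > 0:
            xy = xy + rng.normal(0.0, config.localization_sigma, size=xy.shape)
        tracks.append(
            Trajectory(
                track_id=i,
                frames=np.arange(xy.shape[0]),
                xy=xy,
                frame_interval=config.frame_interval,
                label=label,
            )
        )
    return TrajectorySet(tracks=tracks, frame_interval=config.frame_interval)


def simulate_brownian_tracks(
    d: float, config: SimulationConfig, label: str | None = None
) -> TrajectorySet:
    """2D Brownian tracks: per-axis step variance 2·D·Δt, plus localization noise."""
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    lengths = _track_lengths(rng, config)
    step_sigma = np.sqrt(2.0 * d * config.frame_interval)
    paths = []
    for length in lengths:
        start = rng.uniform(0.0, config.field_size, size=2)
        steps = rng.normal(0.0, step_sigma, size=(length - 1, 2)) if step_sigma > 0 else np.zeros((length - 1, 2))
        paths.append(start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]))
    return _finalize_tracks(rng, paths, config, label)


def simulate_fbm_tracks(
    d_alpha: float, alpha: float, config: SimulationConfig, label: str | None = None
) -> TrajectorySet:
    """2D fractional-Brownian tracks with ensemble MSD 4·D_α·τ^α.

    Each coordinate is an independent fBm with Hurst H = α/2, scaled so the
    per-axis variance at lag τ is 2·D_α·τ^α. α = 1 reduces to Brownian motion
    in distribution; α = 2 is the ballistic limit (a random constant velocity).
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (0, 2]")
    if d_alpha < 0:
        raise ValueError("d_alpha must be >= 0")
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    lengths = _track_lengths(rng, config)
    hurst = alpha / 2.0
    dt = config.frame_interval
    # fBm self-similarity: B_H(k·Δt) ≍ Δt^H·B_H(k), so unit-step fGn is rescaled
    # by √(2 D_α)·Δt^(α/2) to give Var[x(τ)] = 2 D_α τ^α per axis.
    scale = np.sqrt(2.0 * d_alpha) * dt**hurst
    paths = []
    for length in lengths:
        start = rng.uniform(0.0, config.field_size, size=2)
        n = int(length) - 1
        if d_alpha == 0:
            disp = np.zeros((n, 2))
        elif alpha == 2.0:
            v = rng.normal(0.0, 1.0, size=2)  # ballistic: perfectly correlated steps
            disp = np.outer(np.ones(n), v)
        else:
            disp = sample_fgn(rng, n, hurst, size=2).T
        xy = start + np.vstack([np.zeros(2), np.cumsum(scale * disp, axis=0)])
        paths.append(xy)
    return _finalize_tracks(rng, paths, config, label)


def mix_track_sets(
    sets: list[TrajectorySet],
    fractions: list[float],
    n_tracks: int,
    seed: int,
) -> TrajectorySet:
    """Random without-replacement mixture of several track sets.

    Per-set counts honor the requested fractions within ±1 track (largest-
    remainder rounding). Source labels are retained; track ids are renumbered
    to stay unique in the output.
    """
    if len(sets) != len(fractions):
        raise ValueError("need one fraction per set")
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must be nonnegative and sum to 1")
    if any(len(s) == 0 for s in sets):
        raise ValueError("each input set must be non-empty")
    exact = fr * n_tracks
    counts = np.floor(exact).astype(int)
    rem = n_tracks - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    rng = np.random.default_rng(seed)
    tracks: list[Trajectory] = []
    next_id = 0
    for s, cnt in zip(sets, counts):
        if cnt > len(s):
            raise ValueError(f"requested {cnt} tracks from a set of {len(s)}")
        idx = rng.choice(len(s), size=cnt, replace=False)
        for i in np.sort(idx):
            src = s.tracks[i]
            tracks.append(
                Trajectory(
                    track_id=next_id,
                    frames=src.frames.copy(),
                    xy=src.xy.copy(),
                    frame_interval=src.frame_interval,
                    label=src.label,
                )
            )
            next_id += 1
    return TrajectorySet(tracks=tracks, frame_interval=sets[0].frame_interval)


# ---------------------------------------------------------------------------
# FCS photon-trace simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FocalVolumeSpec:
    """3D Gaussian focal volume with lateral/axial 1/e² radii w0 and z0 (µm)."""

    w0: float
    z0: float

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.z0 < self.w0:
            raise ValueError("z0 must be >= w0")

    @property
    def structure_parameter(self) -> float:
        """Axial-to-lateral aspect ratio z0/w0."""
        return self.z0 / self.w0

    @property
    def effective_volume(self) -> float:
        """V_eff = π^{3/2} w0² z0 (µm³) of the Gaussian detection profile."""
        return np.pi**1.5 * self.w0**2 * self.z0


@dataclass
class FCSSimSpec:
    """Parameters of one simulated FCS acquisition.

    ``mean_molecules_in_volume`` is the expected occupancy N of the effective
    focal volume (so that the fluctuation ACF amplitude G(0) ≈ 1/N);
    ``brightness`` is the detected photon rate of one molecule at beam center.
    The molecules diffuse in a periodic box (halfwidths in µm) large enough
    that wrap-around re-entry does not correlate with the focal spot.
    """

    diffusion_coefficient: float
    mean_molecules_in_volume: float
    brightness: float
    duration: float
    alpha: float = 1.0
    bin_width: float = 1e-5
    box_halfwidths: tuple[float, float, float] = (1.5, 1.5, 3.0)
    rng_seed: int = 0

    def validate(self, volume: FocalVolumeSpec) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not 0.0 < self.alpha <= 2.0:
            raise ValueError("alpha must lie in (0, 2]")
        if self.mean_molecules_in_volume <= 0:
            raise ValueError("mean_molecules_in_volume must be positive")
        if self.brightness < 0 or self.bin_width <= 0 or self.duration <= 0:
            raise ValueError("brightness, bin_width and duration must be positive")
        hw = np.asarray(self.box_halfwidths, dtype=float)
        required = 3.0 * np.array([volume.w0, volume.w0, volume.z0])
        if np.any(2.0 * hw < required):
            raise ValueError("box must be at least 3×(w0, w0, z0) in each dimension")


@dataclass
class IntensityTrace:
    """Photon counts per time bin from one simulated (or measured) acquisition."""

    bin_width: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.bin_width


# Contributions below exp(−16) ≈ 1e−7 of the center brightness are dropped.
_INTENSITY_CUTOFF = 16.0


@numba.njit(cache=True, fastmath=True)
def _advance_and_collect(inc, pos, out, offset, hx, hy, hz, a_lat, a_ax):  # pragma: no cover
    n = inc.shape[0]
    n_mol = pos.shape[0]
    bx, by, bz = 2.0 * hx, 2.0 * hy, 2.0 * hz
    for i in range(n):
        total = 0.0
        for m in range(n_mol):
            x = pos[m, 0] + inc[i, m, 0]
            y = pos[m, 1] + inc[i, m, 1]
            z = pos[m, 2] + inc[i, m, 2]
            if x > hx:
                x -= bx
            elif x < -hx:
                x += bx
            if y > hy:
                y -= by
            elif y < -hy:
                y += by
            if z > hz:
                z -= bz
            elif z < -hz:
                z += bz
            pos[m, 0] = x
            pos[m, 1] = y
            pos[m, 2] = z
            s = a_lat * (x * x + y * y) + a_ax * z * z
            if s < _INTENSITY_CUTOFF:
                total += np.exp(-s)
        out[offset + i] = total
    return


def _gaussian_intensity(pos: np.ndarray, volume: FocalVolumeSpec) -> np.ndarray:
    """Normalized detection profile exp(−2(x²+y²)/w0² − 2z²/z0²) summed over molecules."""
    s = (2.0 / volume.w0**2) * (pos[..., 0] ** 2 + pos[..., 1] ** 2) + (
        2.0 / volume.z0**2
    ) * pos[..., 2] ** 2
    w = np.where(s < _INTENSITY_CUTOFF, np.exp(-np.minimum(s, _INTENSITY_CUTOFF)), 0.0)
    return w.sum(axis=-1)


def simulate_fcs_trace(spec: FCSSimSpec, volume: FocalVolumeSpec) -> IntensityTrace:
    """Poisson photon trace of point emitters diffusing through a Gaussian volume.

    The number of molecules in the periodic box is set so that the expected
    occupancy of the effective volume π^{3/2}w0²z0 equals
    ``spec.mean_molecules_in_volume``. Brownian motion (α = 1) is advanced bin
    by bin with exact Gaussian increments; anomalous motion (α ≠ 1) uses
    per-axis fractional Gaussian noise and is intended for shorter traces
    (the fGn sampler materializes whole paths).
    """
    spec.validate(volume)
    hw = np.asarray(spec.box_halfwidths, dtype=float)
    box_volume = float(np.prod(2.0 * hw))
    n_mol = max(1, int(round(spec.mean_molecules_in_volume / volume.effective_volume * box_volume)))
    n_bins = int(round(spec.duration / spec.bin_width))
    root = np.random.SeedSequence(spec.rng_seed)
    pos_seed, incr_seed, shot_seed = root.spawn(3)
    init_rng = np.random.default_rng(pos_seed)
    pos = init_rng.uniform(-hw, hw, size=(n_mol, 3))

    d, alpha, dt = spec.diffusion_coefficient, spec.alpha, spec.bin_width
    if d == 0:
        rate = np.full(n_bins, _gaussian_intensity(pos[None, :, :], volume)[0])
    elif alpha == 1.0:
        # chunked: bulk float32 normals (fast bit generator) + fused numba kernel
        rng = np.random.Generator(np.random.SFC64(incr_seed))
        sigma = np.float32(np.sqrt(2.0 * d * dt))
        rate = np.empty(n_bins)
        a_lat, a_ax = 2.0 / volume.w0**2, 2.0 / volume.z0**2
        chunk = 50_000
        for start in range(0, n_bins, chunk):
            n = min(chunk, n_bins - start)
            inc = rng.standard_normal((n, n_mol, 3), dtype=np.float32)
            inc *= sigma
            _advance_and_collect(inc, pos, rate, start, hw[0], hw[1], hw[2], a_lat, a_ax)
    else:
        rng = np.random.default_rng(incr_seed)
        hurst = alpha / 2.0
        scale = np.sqrt(2.0 * d) * dt**hurst
        disp = np.empty((n_bins, n_mol, 3))
        for axis in range(3):
            fgn = sample_fgn(rng, n_bins, hurst, size=n_mol)  # (n_mol, n_bins)
            disp[:, :, axis] = scale * np.cumsum(fgn, axis=1).T
        traj = pos[None, :, :] + disp
        traj -= np.round(traj / (2.0 * hw)) * (2.0 * hw)
        rate = _gaussian_intensity(traj, volume)

    shot_rng = np.random.default_rng(shot_seed)
    counts = shot_rng.poisson(spec.brightness * spec.bin_width * rate)
    return IntensityTrace(bin_width=spec.bin_width, counts=counts)


# ---------------------------------------------------------------------------
# RPB1-like mixture
# ---------------------------------------------------------------------------

#: Default mobility classes of the polymerase-like mixture:
#: label → (fraction, D or D_α in µm²/s^α, α). The immobile class is pure
#: localization noise (D = 0); the subdiffusive and mobile classes take the
#: reported slow (D_α = 0.02, α = 0.31) and fast (D = 0.5, α = 0.95)
#: population parameters.
RPB1_CLASSES: dict[str, tuple[float, float, float]] = {
    "immobile": (0.20, 0.0, 1.0),
    "subdiffusive": (0.55, 0.02, 0.31),
    "mobile": (0.25, 0.5, 0.95),
}


def simulate_rpb1_like_mixture(
    config: SimulationConfig,
    seed: int,
    classes: dict[str, tuple[float, float, float]] | None = None,
) -> TrajectorySet:
    """Three-class labelled mixture emulating nuclear RNA-polymerase-II mobility."""
    classes = RPB1_CLASSES if classes is None else classes
    fractions = np.array([v[0] for v in classes.values()])
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("class fractions must sum to 1")
    root = np.random.SeedSequence(seed)
    subseeds = root.spawn(len(classes) + 1)
    exact = fractions * config.n_tracks
    counts = np.floor(exact).astype(int)
    counts[np.argsort(-(exact - counts))[: config.n_tracks - counts.sum()]] += 1
    sets = []
    for (label, (_, d_val, alpha)), cnt, sub in zip(classes.items(), counts, subseeds):
        cfg = SimulationConfig(
            frame_interval=config.frame_interval,
            localization_sigma=config.localization_sigma,
            min_track_length=config.min_track_length,
            mean_track_length=config.mean_track_length,
            n_tracks=int(cnt),
            field_size=config.field_size,
            rng_seed=int(sub.generate_state(1)[0] % (2**31)),
        )
        if d_val == 0:
            sets.append(simulate_brownian_tracks(0.0, cfg, label=label))
        elif alpha == 1.0:
            sets.append(simulate_brownian_tracks(d_val, cfg, label=label))
        else:
            sets.append(simulate_fbm_tracks(d_val, alpha, cfg, label=label))
    merged: list[Trajectory] = []
    next_id = 0
    for s in sets:
        for t in s.tracks:
            merged.append(
                Trajectory(
                    track_id=next_id,
                    frames=t.frames,
                    xy=t.xy,
                    frame_interval=t.frame_interval,
                    label=t.label,
                )
            )
            next_id += 1
    return TrajectorySet(tracks=merged, frame_interval=config.frame_interval)
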