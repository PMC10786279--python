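"""Synthetic fixtures with known ground truth.

Two generators: multi-embryo fluorescence traces (Gaussian band trains with
controlled channel phases, per-embryo affine axis distortion, per-channel
gain/baseline, additive noise) emulating the sectioned-digit NFI data, and
piecewise-linear element growth series with known initiation times. Both are
bit-reproducible for a fixed seed and return machine-readable ground truth
alongside the data, so every pipeline stage can be tested for parameter
recovery without any imaging input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import ElementLengthSeries
from .profiles import DEFAULT_PIXEL_SIZE_UM, IntensityProfile


@dataclass(frozen=True)
class ProfileGenConfig:
    """Settings for synthetic multi-embryo intensity traces.

    Channels are Gaussian band trains at ``wavelength`` spacing; each
    channel is phase-shifted by its entry in ``phase_offsets`` (fractions of
    a wavelength relative to GDF5). Each embryo's position axis is distorted
    by a random affine map (scale, shift), each channel by a random gain and
    baseline, and Gaussian noise of relative amplitude ``noise_sigma`` is
    added.
    """

    n_embryos: int = 8
    wavelength_um: float = 300.0
    n_bands: int = 4
    phase_offsets: dict = field(
        default_factory=lambda: {"GDF5": 0.0, "NOG": 0.0, "pSMAD": 0.5}
    )
    band_width_frac: float = 0.18
    scale_range: tuple[float, float] = (0.85, 1.18)
    shift_range_um: tuple[float, float] = (-40.0, 40.0)
    gain_range: tuple[float, float] = (0.6, 1.8)
    baseline_range: tuple[float, float] = (0.05, 0.35)
    noise_sigma: float = 0.05
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_sigma <= 0.5:
            raise ValueError("noise_sigma must lie in [0, 0.5]")
        for name, off in self.phase_offsets.items():
            if not 0.0 <= off < 1.0:
                raise ValueError(f"phase offset for {name} must lie in [0, 1)")
        if self.scale_range[0] <= 0:
            raise ValueError("scale range must be positive")
        if self.n_embryos < 1 or self.n_bands < 2:
            raise ValueError("need >= 1 embryo and >= 2 bands")


def _band_train(x_um, wavelength, centers, width, phase_frac):
    """Sum of Gaussian bands at wavelength spacing, shifted by a phase."""
    signal = np.zeros_like(x_um)
    for c in centers:
        mu = c + phase_frac * wavelength
        signal += np.exp(-0.5 * ((x_um - mu) / width) ** 2)
    return signal


def generate_profiles(config: ProfileGenConfig) -> tuple[list[IntensityProfile], dict]:
    """Synthetic embryo traces plus the ground truth that produced them.

    The truth record holds, per embryo, the undistorted band centers (in the
    embryo's own pixel axis), the applied affine distortion and per-channel
    gain/baseline, and globally the channel phase offsets. The two most
    distal GDF5 band centers are the landmark truth.
    """
    rng = np.random.default_rng(config.seed)
    lam = config.wavelength_um
    width = config.band_width_frac * lam
    # one wavelength of margin on each side of the band train
    L = (config.n_bands + 1) * lam
    centers = lam * (0.5 + np.arange(config.n_bands) + 0.5)
    profiles = []
    truth_embryos = []
    for i in range(config.n_embryos):
        scale = rng.uniform(*config.scale_range)
        shift = rng.uniform(*config.shift_range_um)
        n_px = int(round(L / config.pixel_size_um))
        pos_px = np.arange(n_px, dtype=float)
        # embryo axis -> reference axis: x_ref = scale * x_um + shift
        x_ref = scale * pos_px * config.pixel_size_um + shift
        channels = {}
        gains = {}
        baselines = {}
        for name, offset in config.phase_offsets.items():
            gain = rng.uniform(*config.gain_range)
            base = rng.uniform(*config.baseline_range)
            clean = _band_train(x_ref, lam, centers, width, offset)
            noisy = gain * clean + base
            if config.noise_sigma > 0:
                noisy = noisy + gain * config.noise_sigma * rng.standard_normal(n_px)
            channels[name] = np.clip(noisy, 0.0, None)
            gains[name] = gain
            baselines[name] = base
        profiles.append(IntensityProfile(
            position=pos_px,
            channels=channels,
            specimen=f"embryo_{i:02d}",
            pixel_size_um=config.pixel_size_um,
        ))
        # landmark truth: two most distal GDF5 band centers, in pixels
        gdf5_centers_px = (
            (centers + config.phase_offsets.get("GDF5", 0.0) * lam - shift)
            / scale / config.pixel_size_um
        )
        truth_embryos.append({
            "specimen": f"embryo_{i:02d}",
            "scale": scale,
            "shift_um": shift,
            "gains": gains,
            "baselines": baselines,
            "gdf5_band_centers_px": gdf5_centers_px.tolist(),
            "landmarks_px": (
                float(gdf5_centers_px[-2]), float(gdf5_centers_px[-1])
            ),
        })
    truth = {
        "wavelength_um": lam,
        "phase_offsets": dict(config.phase_offsets),
        "band_centers_um": centers.tolist(),
        "embryos": truth_embryos,
    }
    return profiles, truth


@dataclass(frozen=True)
class ElementSchedule:
    """Ground-truth growth schedule of one element."""

    element: str
    initiation_h: float
    initial_length_um: float
    #: (time breakpoints h, slopes μm/h) — piecewise-linear growth from
    #: initiation; breakpoints are absolute times, the first slope applies
    #: from initiation to the first breakpoint.
    slope_breakpoints_h: tuple = ()
    slopes_um_per_h: tuple = (8.0,)

    def length_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        knots = (self.initiation_h,) + tuple(self.slope_breakpoints_h)
        length = np.full(t.shape, np.nan)
        base = self.initial_length_um
        for j, start in enumerate(knots):
            stop = knots[j + 1] if j + 1 < len(knots) else np.inf
            slope = self.slopes_um_per_h[min(j, len(self.slopes_um_per_h) - 1)]
            m = (t >= start) & (t < stop)
            length[m] = base + slope * (t[m] - start)
            if np.isfinite(stop):
                base = base + slope * (stop - start)
        return length


@dataclass(frozen=True)
class GrowthGenConfig:
    """Settings for synthetic element-length growth series."""

    digit: str = "III"
    elements: tuple = ()
    sampling_times_h: tuple = tuple(np.arange(128.0, 232.0, 8.0))
    noise_sigma_um: float = 15.0
    specimens_per_time: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        inits = [e.initiation_h for e in self.elements]
        if any(b < a for a, b in zip(inits, inits[1:])):
            raise ValueError("element initiation times must be non-decreasing")
        if self.noise_sigma_um < 0 or self.specimens_per_time < 1:
            raise ValueError("invalid noise or specimen count")


def generate_growth_series(
    config: GrowthGenConfig,
) -> tuple[dict[str, ElementLengthSeries], dict]:
    """Synthetic length-vs-time series per element, plus ground truth.

    Lengths follow each element's piecewise-linear schedule from its
    initiation, with Gaussian measurement noise; before initiation the
    element is emitted with ``band_present = False`` and a placeholder
    length (the sampled digit still exists; its distal band does not).
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, ElementLengthSeries] = {}
    truth = {"digit": config.digit, "elements": {}}
    for sched in config.elements:
        times = []
        lengths = []
        present = []
        for t in config.sampling_times_h:
            for _ in range(config.specimens_per_time):
                true_len = sched.length_at(np.array([t]))[0]
                is_present = t >= sched.initiation_h
                if not is_present:
                    # element not yet individualized; record a nominal
                    # distal-domain measurement so the table stays rectangular
                    true_len = sched.initial_length_um
                noise = config.noise_sigma_um * rng.standard_normal()
                times.append(t)
                lengths.append(max(true_len + noise, 1.0))
                present.append(is_present)
        out[sched.element] = ElementLengthSeries(
            digit=config.digit,
            element=sched.element,
            time_h=np.array(times),
            length_um=np.array(lengths),
            band_present=np.array(present),
        )
        truth["elements"][sched.element] = {
            "initiation_h": sched.initiation_h,
            "initial_length_um": sched.initial_length_um,
            "slopes_um_per_h": list(sched.slopes_um_per_h),
            "slope_breakpoints_h": list(sched.slope_breakpoints_h),
        }
    return out, truth


def digit_pair_preset(seed: int = 0) -> tuple[dict, dict, dict]:
    """The "digit III vs digit IV" fixture.

    Digit III: four phalanges; digit IV: five phalanges whose initial
    lengths are 0.8x their digit III counterparts (a shorter segmentation
    wavelength), with equal whole-digit growth rates over 144-184 h, the
    active segmentation window. Returns (digit III series, digit IV series,
    truth).
    """
    ratio = 0.8
    p1 = 320.0
    decline = 0.85  # successive phalanges initiate progressively smaller
    slopes = (9.0, 7.5, 6.5, 5.5, 5.0)
    inits_iii = (140.0, 156.0, 172.0, 186.0)
    inits_iv = (140.0, 154.0, 168.0, 182.0, 194.0)

    def schedules(inits, scale):
        els = []
        for j, t0 in enumerate(inits):
            els.append(ElementSchedule(
                element=f"P{j+1}",
                initiation_h=t0,
                initial_length_um=scale * p1 * decline**j,
                slopes_um_per_h=(slopes[j],),
            ))
        return tuple(els)

    whole = ElementSchedule(
        element="digit", initiation_h=128.0, initial_length_um=400.0,
        slope_breakpoints_h=(184.0,), slopes_um_per_h=(16.0, 22.0),
    )
    whole_iv = ElementSchedule(
        element="digit", initiation_h=128.0, initial_length_um=400.0,
        slope_breakpoints_h=(184.0,), slopes_um_per_h=(16.0, 12.0),
    )
    cfg3 = GrowthGenConfig(
        digit="III", elements=(whole,) + schedules(inits_iii, 1.0),
        sampling_times_h=tuple(np.arange(128.0, 232.0, 8.0)), seed=seed,
    )
    cfg4 = GrowthGenConfig(
        digit="IV", elements=(whole_iv,) + schedules(inits_iv, ratio),
        sampling_times_h=tuple(np.arange(128.0, 232.0, 8.0)), seed=seed + 1,
    )
    s3, t3 = generate_growth_series(cfg3)
    s4, t4 = generate_growth_series(cfg4)
    truth = {
        "initial_length_ratio_iv_over_iii": ratio,
        "digit_III": t3,
        "digit_IV": t4,
    }
    return s3, s4, truth
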