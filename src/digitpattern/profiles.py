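"""Quantitative analysis of 1D multi-channel fluorescence-intensity profiles.

Implements the in-vivo quantification used to compare the model against
digit sections: normalized fluorescence intensity (NFI) scaling, GDF5 peak
detection, two-landmark alignment of profiles from multiple embryos onto a
common axis (the two most distal GDF5 peaks — the previously formed joint
and the newly emerging one — map to 0 and 1), and circular phase-offset
statistics between channels. In the landmark frame one unit of position is
one pattern wavelength, because consecutive GDF5 peaks are consecutive
joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: default pixel size of the imaging setup, μm per pixel
DEFAULT_PIXEL_SIZE_UM = 1.243


class LandmarkError(ValueError):
    """Raised when a profile does not contain two usable landmark peaks."""


class DegenerateChannelError(ValueError):
    """Raised when a channel has no dynamic range or variance."""


@dataclass
class IntensityProfile:
    """A multi-channel 1D intensity trace along the proximal-distal axis.

    Positions are in pixels (converted to μm via ``pixel_size_um``),
    strictly increasing; each named channel holds one finite, non-negative
    value per position.
    """

    position: np.ndarray
    channels: dict[str, np.ndarray]
    specimen: str = ""
    digit: str = ""
    stage_h: float = np.nan
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 1 or self.position.size < 2:
            raise ValueError("position must be a 1D array with >= 2 entries")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")
        clean = {}
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.position.shape:
                raise ValueError(f"channel {name} length mismatch")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name} must be finite and >= 0")
            clean[name] = arr
        self.channels = clean

    @property
    def position_um(self) -> np.ndarray:
        return self.position * self.pixel_size_um

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position_px": self.position})
        for name, values in self.channels.items():
            df[name] = values
        return df


@dataclass
class AlignedProfileSet:
    """Profiles resampled onto a shared landmark axis.

    The proximal landmark maps to 0, the distal one to 1; the shared grid
    may extend beyond [0, 1] by a margin. Values outside a specimen's
    measured range are NaN (missing, never extrapolated).
    """

    grid: np.ndarray
    values: dict[str, dict[str, np.ndarray]]  # specimen -> channel -> values
    landmarks: dict[str, tuple[float, float]]  # specimen -> source positions

    def specimens(self) -> list[str]:
        return list(self.values)

    def channel_matrix(self, channel: str) -> np.ndarray:
        """(n_specimens, n_grid) matrix for one channel (NaN = missing)."""
        return np.vstack([self.values[s][channel] for s in self.values])

    def mean_profile(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Cross-specimen mean (NaN-aware) and per-position counts."""
        mat = self.channel_matrix(channel)
        counts = np.sum(np.isfinite(mat), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
        return mean, counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for spec, chans in self.values.items():
            for chan, vals in chans.items():
                rows.append(pd.DataFrame({
                    "specimen": spec,
                    "common_position": self.grid,
                    "channel": chan,
                    "value": vals,
                }))
        return pd.concat(rows, ignore_index=True)


def normalize_nfi(profile: IntensityProfile) -> IntensityProfile:
    """Min-max scale every channel to [0, 1] (normalized fluorescence intensity).

    Idempotent and invariant to per-channel gain and baseline offset, which
    is what makes profiles from different stainings comparable. A constant
    channel is degenerate and rejected by name.
    """
    scaled = {}
    for name, values in profile.channels.items():
        lo, hi = float(values.min()), float(values.max())
        if hi - lo <= 0:
            raise DegenerateChannelError(f"channel {name!r} has no dynamic range")
        scaled[name] = (values - lo) / (hi - lo)
    return IntensityProfile(
        position=profile.position.copy(),
        channels=scaled,
        specimen=profile.specimen,
        digit=profile.digit,
        stage_h=profile.stage_h,
        pixel_size_um=profile.pixel_size_um,
    )


def pick_landmarks(
    profile: IntensityProfile,
    channel: str = "GDF5",
    region: tuple[float, float] | None = None,
    prominence_frac: float = 0.25,
    smoothing_window: int = 15,
) -> tuple[float, float]:
    """The two most distal peaks of a channel, ordered proximal -> distal.

    These demarcate the previously formed joint and the newly emerging one.
    The channel is moving-average smoothed before peak detection so that
    pixel noise cannot masquerade as a landmark; ``region`` optionally
    restricts the search window (positions, same units as
    ``profile.position``).
    """
    values = profile.channels[channel]
    pos = profile.position
    if region is not None:
        mask = (pos >= region[0]) & (pos <= region[1])
        pos, values = pos[mask], values[mask]
    if values.size < 5:
        raise LandmarkError("landmark region holds too few samples")
    w = max(1, min(int(smoothing_window), values.size // 2))
    kernel = np.ones(w) / w
    padded = np.pad(values, (w // 2, w - 1 - w // 2), mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    span = smooth.max() - smooth.min()
    if span <= 0:
        raise LandmarkError(f"channel {channel!r} is flat in the landmark region")
    idx, _ = find_peaks(smooth, prominence=prominence_frac * span)
    if idx.size < 2:
        raise LandmarkError(
            f"found {idx.size} peak(s) of {channel!r}, need at least 2"
        )
    distal_two = idx[np.argsort(pos[idx])][-2:]
    return float(pos[distal_two[0]]), float(pos[distal_two[1]])


def align_profiles(
    profiles: list[IntensityProfile],
    landmarks: list[tuple[float, float]],
    grid_n: int = 201,
    margin: float = 0.0,
) -> AlignedProfileSet:
    """Affinely map each profile's landmark pair to (0, 1) and resample.

    Channels are linearly interpolated onto the shared grid; positions
    outside a specimen's measured range become NaN. The landmark positions
    themselves land exactly on 0 and 1 by construction.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) != len(landmarks):
        raise ValueError("one landmark pair per profile is required")
    grid = np.linspace(-margin, 1.0 + margin, grid_n)
    values: dict[str, dict[str, np.ndarray]] = {}
    marks: dict[str, tuple[float, float]] = {}
    for i, (prof, (p0, p1)) in enumerate(zip(profiles, landmarks)):
        if p1 == p0:
            raise ValueError("coincident landmarks cannot define an axis")
        name = prof.specimen or f"specimen_{i}"
        mapped = (prof.position - p0) / (p1 - p0)
        chans = {}
        for chan, vals in prof.channels.items():
            interp = np.interp(grid, mapped, vals, left=np.nan, right=np.nan)
            chans[chan] = interp
        values[name] = chans
        marks[name] = (p0, p1)
    return AlignedProfileSet(grid=grid, values=values, landmarks=marks)


def phase_offset(
    a: np.ndarray,
    b: np.ndarray,
    grid: np.ndarray | None = None,
    period: float = 1.0,
) -> float:
    """Phase offset between two channels, as a fraction of a wavelength.

    Circular cross-correlation of mean-subtracted, variance-normalized
    channels over one period, with the maximizing lag folded into
    [0, 0.5]: 0 means in phase, 0.5 antiphase. In the landmark frame the
    inter-landmark spacing is one wavelength, so ``period = 1`` covers
    exactly one cycle of the shared grid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a grid")
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        step = grid[1] - grid[0]
        n_period = int(round(period / step))
        mask = np.isfinite(a) & np.isfinite(b)
        # use the longest finite stretch covering >= one period
        a, b = a[mask], b[mask]
        if a.size < n_period:
            raise ValueError("channels must cover at least one wavelength")
        a, b = a[:n_period], b[:n_period]
    n = a.size
    if a.std() <= 0 or b.std() <= 0:
        raise DegenerateChannelError("zero-variance channel in phase_offset")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    corr = np.array([np.mean(a * np.roll(b, lag)) for lag in range(n)])
    frac = (int(np.argmax(corr)) / n) % 1.0
    return min(frac, 1.0 - frac)


# -- delimited-text IO ------------------------------------------------------

def read_profile(path, metadata: dict | None = None) -> IntensityProfile:
    """Read a delimited trace: column position_px then one column per channel."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "position_px" not in df.columns:
        raise ValueError(f"{path} lacks a position_px column")
    channels = {c: df[c].to_numpy() for c in df.columns if c != "position_px"}
    meta = metadata or {}
    return IntensityProfile(
        position=df["position_px"].to_numpy(),
        channels=channels,
        specimen=str(meta.get("specimen", "")),
        digit=str(meta.get("digit", "")),
        stage_h=float(meta.get("stage_h", np.nan)),
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
    )


def write_profile(profile: IntensityProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)
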