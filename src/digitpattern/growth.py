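"""Growth and segmentation analysis of digit elements.

Linear growth models for whole digits, unsegmented distal domains ("dd") and
individual phalanges ("P1", "P2", ...); detection of the time and length at
which each phalanx is first individualized (the appearance of a faint distal
GDF5 band); and side-by-side comparison of two digits. The initial length at
band appearance is the in-vivo proxy for the Turing wavelength, since it
reflects patterning before subsequent growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """Raised when a fit window holds fewer than two observations."""


@dataclass
class ElementLengthSeries:
    """Length-vs-time observations for one element of one digit.

    ``element`` is the whole digit (``"digit"``), the unsegmented distal
    domain (``"dd"``) or a phalanx (``"P1"``..). Multiple specimens may be
    measured at the same time point. ``band_present`` flags whether the
    distal GDF5 band delimiting this element was detected at each
    observation.
    """

    digit: str
    element: str
    time_h: np.ndarray
    length_um: np.ndarray
    band_present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.length_um = np.asarray(self.length_um, dtype=float)
        if self.time_h.shape != self.length_um.shape:
            raise ValueError("time and length must have equal shape")
        if np.any(self.length_um <= 0):
            raise ValueError("lengths must be positive")
        if np.any((self.time_h < 100) | (self.time_h > 400)):
            raise ValueError("times must lie within the sampled window [100, 400] h")
        if self.band_present is not None:
            self.band_present = np.asarray(self.band_present, dtype=bool)
            if self.band_present.shape != self.time_h.shape:
                raise ValueError("band_present must match observations")

    def observed(self) -> "ElementLengthSeries":
        """Only the observations where the element exists (band present)."""
        if self.band_present is None:
            return self
        m = self.band_present
        return ElementLengthSeries(
            self.digit, self.element, self.time_h[m], self.length_um[m],
            self.band_present[m],
        )


@dataclass
class GrowthFit:
    """Ordinary least-squares linear growth model of one element."""

    slope: float  # μm/h
    intercept: float  # μm at t = 0
    window: tuple[float, float]
    residual_sd: float
    n: int
    r_squared: float
    slope_se: float

    def predict(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


def fit_growth(
    series: ElementLengthSeries, window: tuple[float, float] | None = None
) -> GrowthFit:
    """OLS fit of length against time within a window.

    Multiple specimens per time point enter as independent observations.
    Deterministic; raises :class:`InsufficientDataError` below two points.
    """
    s = series.observed()
    t, y = s.time_h, s.length_um
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    else:
        window = (float(t.min()), float(t.max())) if t.size else (np.nan, np.nan)
    if t.size < 2:
        raise InsufficientDataError(
            f"{series.digit}/{series.element}: {t.size} observation(s) in window"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError("all observations at a single time point")
    res = stats.linregress(t, y)
    pred = res.slope * t + res.intercept
    dof = max(t.size - 2, 1)
    return GrowthFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        window=(float(window[0]), float(window[1])),
        residual_sd=float(np.sqrt(np.sum((y - pred) ** 2) / dof)),
        n=int(t.size),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr) if t.size > 2 else 0.0,
    )


@dataclass
class InitiationResult:
    element: str
    initiated: bool
    time_h: float = np.nan
    initial_length_um: float = np.nan
    left_censored: bool = False


def _clean_presence(time_h: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Majority-vote presence per time point, then earliest-present cut.

    Returns the sorted unique times with a cleaned monotone presence flag
    (absent then present)."""
    times = np.unique(time_h)
    flag = np.array([
        np.mean(present[time_h == t]) >= 0.5 for t in times
    ])
    if flag.any():
        first = np.argmax(flag)
        flag[first:] = True  # monotone after first majority presence
    return times, flag


def detect_initiation(series: ElementLengthSeries) -> InitiationResult:
    """Initiation time and initial length of an element.

    Initiation = earliest time point at which the distal GDF5 band is
    present (majority vote across specimens at each time); the initial
    length is the mean measured length at that time. An element already
    present at the first observation is flagged left-censored; one that
    never appears yields a not-initiated result.
    """
    if series.band_present is None:
        raise ValueError("series lacks band_present flags")
    times, flag = _clean_presence(series.time_h, series.band_present)
    if not flag.any():
        return InitiationResult(element=series.element, initiated=False)
    t0 = float(times[np.argmax(flag)])
    length = float(np.mean(series.length_um[series.time_h == t0]))
    return InitiationResult(
        element=series.element,
        initiated=True,
        time_h=t0,
        initial_length_um=length,
        left_censored=bool(flag[0]),
    )


def compare_digits(
    digit_a: dict[str, ElementLengthSeries],
    digit_b: dict[str, ElementLengthSeries],
    early_window_h: float = 40.0,
    whole_digit_window: tuple[float, float] = (144.0, 184.0),
) -> pd.DataFrame:
    """Per-element comparison table for two digits.

    For each element: initiation time, initial length, and the early growth
    rate fitted on [initiation, initiation + ``early_window_h``]. Whole-digit
    entries (element ``"digit"``) are fitted on ``whole_digit_window``, the
    active segmentation phase. Invariant to specimen ordering and to any
    consistent unit rescaling of lengths.
    """
    rows = []
    for label, elements in (("A", digit_a), ("B", digit_b)):
        for name in sorted(elements):
            s = elements[name]
            row = {"digit": s.digit or label, "element": name}
            if name == "digit":
                fit = fit_growth(s, whole_digit_window)
                row.update(
                    initiation_h=np.nan, initial_length_um=np.nan,
                    left_censored=False,
                    growth_rate_um_per_h=fit.slope,
                    growth_rate_se=fit.slope_se, fit_n=fit.n,
                )
            else:
                init = detect_initiation(s)
                row.update(
                    initiation_h=init.time_h,
                    initial_length_um=init.initial_length_um,
                    left_censored=init.left_censored,
                )
                if init.initiated:
                    try:
                        fit = fit_growth(
                            s, (init.time_h, init.time_h + early_window_h)
                        )
                        row.update(
                            growth_rate_um_per_h=fit.slope,
                            growth_rate_se=fit.slope_se, fit_n=fit.n,
                        )
                    except InsufficientDataError:
                        row.update(growth_rate_um_per_h=np.nan,
                                   growth_rate_se=np.nan, fit_n=0)
                else:
                    row.update(growth_rate_um_per_h=np.nan,
                               growth_rate_se=np.nan, fit_n=0)
            rows.append(row)
    return pd.DataFrame(rows)


# -- delimited-text IO ------------------------------------------------------

def read_length_table(path) -> dict[str, dict[str, ElementLengthSeries]]:
    """Read a table with columns digit, element, time_h, length_um[, band_present].

    Returns digit -> element -> series."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"digit", "element", "time_h", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks column(s) {sorted(missing)}")
    out: dict[str, dict[str, ElementLengthSeries]] = {}
    for (digit, element), grp in df.groupby(["digit", "element"], sort=True):
        band = grp["band_present"].to_numpy(dtype=bool) \
            if "band_present" in df.columns else None
        out.setdefault(str(digit), {})[str(element)] = ElementLengthSeries(
            digit=str(digit), element=str(element),
            time_h=grp["time_h"].to_numpy(),
            length_um=grp["length_um"].to_numpy(),
            band_present=band,
        )
    return out


def series_to_frame(series_by_digit: dict[str, dict[str, ElementLengthSeries]]) -> pd.DataFrame:
    rows = []
    for digit, elements in series_by_digit.items():
        for name, s in elements.items():
            df = pd.DataFrame({
                "digit": digit, "element": name,
                "time_h": s.time_h, "length_um": s.length_um,
            })
            if s.band_present is not None:
                df["band_present"] = s.band_present
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
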