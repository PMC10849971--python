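"""CER1/TBXT polarity calling and anterior–posterior axis classification.

Aligned circular profiles are normalized to cell density by pointwise
division by the F-actin profile, smoothed with a circular rolling average
whose half-window is one-eighth of the disc radius of arc in either
direction, and a marker is called polar when the max − min of its smoothed
profile exceeds 0.1 normalized intensity (strictly).  When both CER1 and
TBXT are polar, the compartment's axis configuration is classified from
the circular angle from the CER1 peak to the TBXT peak:

* anti-polar — TBXT peak 135°–225° away (closed interval),
* syn-polar  — TBXT peak within 45° (inclusive),
* unrelated  — everything else.

Profiles with two or more well-separated poles are excluded from axis
classification (the analogue of discarding ambiguous multi-pole islands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .radial import AlignedProfileSet, CER1_CHANNEL
from .scene import DENSITY_CHANNEL, ANTI_POLAR_WINDOW, SYN_POLAR_MAX

TBXT_CHANNEL = "TBXT"
POLARITY_THRESHOLD = 0.1
WINDOW_FRACTION = 0.125  # one-eighth of the disc radius, each direction

AXIS_CLASSES = ("anti_polar", "syn_polar", "unrelated",
                "no_polarity", "excluded_multi_pole")


@dataclass
class MarkerPolarity:
    polar: bool
    peak_index: int
    peak_angle_deg: float
    rolling_range: float
    n_poles: int = 1


@dataclass
class PolarityCall:
    """Per-compartment polarity summary."""

    compartment_id: int
    markers: dict[str, MarkerPolarity]
    axis_class: str
    angular_separation_deg: float = math.nan


def normalize_to_density(profile: AlignedProfileSet, marker: str,
                         density_channel: str = DENSITY_CHANNEL,
                         epsilon: float = 0.0) -> np.ndarray:
    """Pointwise marker / (density + epsilon); missing positions stay missing."""
    if density_channel not in profile.profiles:
        raise KeyError(f"density channel {density_channel!r} absent")
    if marker not in profile.profiles:
        raise KeyError(f"marker channel {marker!r} absent")
    marker_v = profile.profiles[marker]
    density_v = profile.profiles[density_channel]
    if len(marker_v) != len(density_v):
        raise ValueError("marker and density profiles differ in length")
    with np.errstate(divide="ignore", invalid="ignore"):
        return marker_v / (density_v + epsilon)


def half_window_points(n: int, disc_radius: float,
                       window_fraction: float = WINDOW_FRACTION,
                       perimeter: float | None = None) -> int:
    """Rolling half-window in index points for an n-point circular profile.

    The window reaches ``disc_radius * window_fraction`` of arc either
    side; with a circularized perimeter (2πR by default) the arc step per
    index is perimeter/n.
    """
    if perimeter is None:
        perimeter = 2.0 * math.pi * disc_radius
    step = perimeter / n
    return int(math.floor(disc_radius * window_fraction / step))


def rolling_average(profile: np.ndarray,
                    half_window: int | None = None,
                    disc_radius: float | None = None,
                    window_fraction: float = WINDOW_FRACTION) -> np.ndarray:
    """Circular rolling mean over ± half_window points (inclusive).

    Either pass ``half_window`` directly or a ``disc_radius`` from which
    it is derived (arc distance ≤ radius × window_fraction either side).
    Missing values are excluded from each window's mean; a window covering
    the whole circle returns the global-mean constant profile.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 3:
        raise ValueError("profile must have length >= 3")
    if half_window is None:
        if disc_radius is None:
            raise ValueError("pass half_window or disc_radius")
        half_window = half_window_points(n, disc_radius, window_fraction)
    if 2 * half_window + 1 >= n:
        mean = float(np.nanmean(profile))
        return np.full(n, mean)
    out = np.empty(n)
    idx = np.arange(-half_window, half_window + 1)
    for i in range(n):
        window = profile[(i + idx) % n]
        finite = window[np.isfinite(window)]
        out[i] = finite.mean() if finite.size else np.nan
    return out


def call_polarity(smoothed: np.ndarray,
                  threshold: float = POLARITY_THRESHOLD,
                  ) -> tuple[bool, int, float]:
    """(polar, peak_index, rolling_range) of a smoothed circular profile.

    ``rolling_range`` is max − min over non-missing values; polarity
    requires the range to exceed the threshold strictly.  Ties at the
    maximum resolve to the lowest index.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    finite = np.isfinite(smoothed)
    if not finite.any():
        raise ValueError("profile is entirely missing")
    rng = float(np.nanmax(smoothed) - np.nanmin(smoothed))
    peak = int(np.nanargmax(smoothed))
    return rng > threshold, peak, rng


def classify_axis(cer1_peak_angle: float, tbxt_peak_angle: float) -> str:
    """Axis configuration from the two peak angles (degrees in [0, 360))."""
    d = (tbxt_peak_angle - cer1_peak_angle) % 360.0
    if ANTI_POLAR_WINDOW[0] <= d <= ANTI_POLAR_WINDOW[1]:
        return "anti_polar"
    if min(d, 360.0 - d) <= SYN_POLAR_MAX:
        return "syn_polar"
    return "unrelated"


def detect_multiple_poles(smoothed: np.ndarray,
                          threshold: float = POLARITY_THRESHOLD,
                          min_separation: int | None = None) -> int:
    """Count well-separated poles in a smoothed circular profile.

    A pole is a circular local maximum whose prominence — its height above
    the highest saddle connecting it to a larger pole — exceeds
    ``threshold``, so every counted pole rises more than the polarity
    threshold above the profile between it and its neighbours (a second
    true domain passes; noise wiggles riding on a domain's shoulder, or on
    the baseline near the profile minimum, do not).  Poles closer than
    ``min_separation`` indices are merged, keeping the higher.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    n = len(smoothed)
    if min_separation is None:
        min_separation = 1
    finite = np.isfinite(smoothed)
    if not finite.any():
        return 0
    filled = np.where(finite, smoothed, np.nanmin(smoothed))
    if np.ptp(filled) <= threshold:
        return 0  # nothing rises above the polarity threshold
    # circular prominences via the tiled profile; keep the middle copy
    tiled = np.tile(filled, 3)
    peaks, _ = signal.find_peaks(tiled, prominence=threshold,
                                 distance=max(min_separation, 1))
    return int(((peaks >= n) & (peaks < 2 * n)).sum())


def classify_compartment(profile: AlignedProfileSet,
                         cer1_channel: str = CER1_CHANNEL,
                         tbxt_channel: str = TBXT_CHANNEL,
                         density_channel: str = DENSITY_CHANNEL,
                         threshold: float = POLARITY_THRESHOLD,
                         window_fraction: float = WINDOW_FRACTION,
                         epsilon: float = 1e-9,
                         exclude_multi_pole: bool = True) -> PolarityCall:
    """Full per-compartment polarity pipeline on an aligned profile set.

    Normalizes each marker to density, smooths with the one-eighth-radius
    rolling average, calls per-marker polarity, and classifies the axis
    when both markers are polar.  Multi-pole profiles are excluded when
    ``exclude_multi_pole`` (the default, mirroring the manual exclusion
    of ambiguous islands); set False to classify on the global peaks.
    """
    radius = profile.disc_radius_um
    n = profile.length
    hw = max(1, half_window_points(n, radius, window_fraction)) \
        if np.isfinite(radius) else max(1, int(round(n * window_fraction / (2 * math.pi))))

    markers: dict[str, MarkerPolarity] = {}
    multi_pole = False
    for ch in (cer1_channel, tbxt_channel):
        if ch not in profile.profiles:
            continue
        normalized = normalize_to_density(profile, ch, density_channel, epsilon)
        smoothed = rolling_average(normalized, half_window=hw)
        polar, peak, rng = call_polarity(smoothed, threshold)
        # poles must be separated by more than the full rolling window
        n_poles = detect_multiple_poles(smoothed, threshold,
                                        min_separation=2 * hw + 1)
        markers[ch] = MarkerPolarity(
            polar=polar, peak_index=peak,
            peak_angle_deg=profile.angle_at(peak),
            rolling_range=rng, n_poles=n_poles,
        )
        if polar and n_poles >= 2:
            multi_pole = True

    cer1 = markers.get(cer1_channel)
    tbxt = markers.get(tbxt_channel)
    sep = math.nan
    if cer1 is not None and tbxt is not None and cer1.polar and tbxt.polar:
        d = abs(tbxt.peak_angle_deg - cer1.peak_angle_deg) % 360.0
        sep = min(d, 360.0 - d)
        if multi_pole and exclude_multi_pole:
            axis = "excluded_multi_pole"
        else:
            axis = classify_axis(cer1.peak_angle_deg, tbxt.peak_angle_deg)
    else:
        axis = "no_polarity"
    return PolarityCall(compartment_id=profile.compartment_id,
                        markers=markers, axis_class=axis,
                        angular_separation_deg=sep)


def summarize_polarity(calls: list[PolarityCall],
                       cer1_channel: str = CER1_CHANNEL,
                       tbxt_channel: str = TBXT_CHANNEL) -> dict:
    """Cohort summary: marker-polarity counts and axis-class fractions.

    Axis-class fractions are reported among both-polar compartments (the
    denominator used for pie-chart style summaries); fractions are NaN
    when the denominator is zero.
    """
    n = len(calls)
    counts = {cls: 0 for cls in AXIS_CLASSES}
    cer1_polar = tbxt_polar = both_polar = 0
    for c in calls:
        counts[c.axis_class] = counts.get(c.axis_class, 0) + 1
        cp = cer1_channel in c.markers and c.markers[cer1_channel].polar
        tp = tbxt_channel in c.markers and c.markers[tbxt_channel].polar
        cer1_polar += cp
        tbxt_polar += tp
        both_polar += cp and tp

    def frac(k: int, d: int) -> float:
        return k / d if d else math.nan

    return {
        "n_compartments": n,
        "cer1_polar": cer1_polar,
        "tbxt_polar": tbxt_polar,
        "both_polar": both_polar,
        "axis_counts": counts,
        "cer1_polar_fraction": frac(cer1_polar, n),
        "tbxt_polar_fraction": frac(tbxt_polar, n),
        "axis_fractions_of_both_polar": {
            cls: frac(counts[cls], both_polar)
            for cls in ("anti_polar", "syn_polar", "unrelated",
                        "excluded_multi_pole")
        },
    }


def calls_to_frame(calls: list[PolarityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        for marker, mp in sorted(c.markers.items()):
            rows.append({
                "compartment_id": c.compartment_id,
                "marker": marker,
                "polar": mp.polar,
                "peak_index": mp.peak_index,
                "peak_angle_deg": mp.peak_angle_deg,
                "rolling_range": mp.rolling_range,
                "n_poles": mp.n_poles,
                "axis_class": c.axis_class,
                "angular_separation_deg": c.angular_separation_deg,
            })
    return pd.DataFrame(rows)
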