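"""Radial expression profiling along compartment borders.

For each detected compartment, marker intensity is sampled along lines
drawn from every border pixel a fixed distance inward toward the centroid
(1-pixel steps, bilinear interpolation).  Lines that would leave the
compartment mask — e.g. drawn from the outer edge of a concave shape — are
skipped entirely and carry a missing marker, never a zero.  Per-border-
position means over depth give a circular expression profile per channel;
profiles are aligned on the position of maximum CER1 intensity and
resampled (linear interpolation on the circular index) to a common length
so compartments of different sizes can be compared and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scene import MultiChannelScene, pixel_angles_deg
from .segmentation import CompartmentRecord

CER1_CHANNEL = "CER1"


@dataclass
class BorderTrace:
    """Ordered border pixels of a compartment.

    Points are pixel centers in µm, ordered by angle about the centroid
    (counter-clockwise in image coordinates, 0° at +x), so angular
    positions are monotone modulo 360 up to digitization.
    """

    points_um: np.ndarray        # (n, 2) as (x, y)
    pixels: np.ndarray           # (n, 2) as (row, col)
    angles_deg: np.ndarray       # (n,)

    @property
    def border_length(self) -> int:
        return len(self.pixels)


@dataclass
class RadialProfileSet:
    """Inward intensity samples for one compartment.

    ``samples[channel]`` is (border_length, n_steps+1); rows for skipped
    border positions are NaN.  ``mean_profile`` averages over depth,
    yielding the circular per-position profile.
    """

    compartment_id: int
    trace: BorderTrace
    depth_um: float
    samples: dict[str, np.ndarray]
    skipped: np.ndarray  # (border_length,) bool
    equivalent_radius_um: float = float("nan")

    def mean_profile(self, channel: str) -> np.ndarray:
        if channel not in self.samples:
            raise KeyError(f"channel {channel!r} was not sampled")
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.samples[channel], axis=1)

    @property
    def channels(self) -> list[str]:
        return sorted(self.samples)


@dataclass
class AlignedProfileSet:
    """Per-channel circular profiles on a common length.

    After alignment the CER1 maximum sits at index 0 and every channel is
    shifted by the same offset; ``start_angle_deg`` is the border angle
    that index 0 corresponds to, and index→angle is linear around the
    circle (exact for circular borders).
    """

    compartment_id: int
    profiles: dict[str, np.ndarray]
    length: int
    alignment_offset: int
    start_angle_deg: float
    source_border_length: int
    disc_radius_um: float

    def angle_at(self, index: int) -> float:
        return (self.start_angle_deg + 360.0 * index / self.length) % 360.0


def trace_border(record: CompartmentRecord) -> BorderTrace:
    """Border pixels of the mask (4-connected boundary), angle-ordered."""
    mask = record.mask
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1),
        border_value=0,
    )
    border = mask & ~eroded
    rows, cols = np.nonzero(border)
    if rows.size == 0:
        raise ValueError("mask has no border pixels")
    p = record.pixel_size
    cx, cy = record.centroid
    angles = pixel_angles_deg(rows, cols, (cx / p, cy / p))
    order = np.argsort(angles, kind="stable")
    rows, cols, angles = rows[order], cols[order], angles[order]
    points = np.stack([(cols + 0.5) * p, (rows + 0.5) * p], axis=1)
    return BorderTrace(points_um=points,
                       pixels=np.stack([rows, cols], axis=1),
                       angles_deg=angles)


def sample_inward(scene: MultiChannelScene, record: CompartmentRecord,
                  depth: float) -> RadialProfileSet:
    """Sample all channels along inward lines from every border pixel.

    ``depth`` (µm) must be smaller than the compartment's equivalent
    radius.  Samples are taken every pixel along the segment toward the
    centroid with bilinear interpolation; a line is skipped whenever any
    of its sample points falls outside the mask or the image.
    """
    if depth >= record.equivalent_radius:
        raise ValueError(
            f"depth {depth} must be < equivalent radius "
            f"{record.equivalent_radius:.3f}"
        )
    trace = trace_border(record)
    p = scene.pixel_size
    n_steps = int(round(depth / p))
    h, w = record.mask.shape

    cx_px = record.centroid[0] / p - 0.5  # centroid in pixel index coords
    cy_px = record.centroid[1] / p - 0.5
    starts = trace.pixels.astype(float)  # (n, 2) row, col
    targets = np.array([cy_px, cx_px])
    vec = targets - starts
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vec / norms

    steps = np.arange(n_steps + 1, dtype=float)
    # coords: (n_border, n_steps+1, 2) in (row, col) pixel-index space
    coords = starts[:, None, :] + unit[:, None, :] * steps[None, :, None]

    rr = coords[..., 0]
    cc = coords[..., 1]
    inside_img = (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
    nearest_r = np.clip(np.round(rr).astype(int), 0, h - 1)
    nearest_c = np.clip(np.round(cc).astype(int), 0, w - 1)
    inside_mask = record.mask[nearest_r, nearest_c] & inside_img
    skipped = ~inside_mask.all(axis=1)

    flat = np.stack([rr.ravel(), cc.ravel()])
    samples = {}
    for name, image in scene.channels.items():
        vals = ndimage.map_coordinates(image, flat, order=1, mode="nearest")
        vals = vals.reshape(rr.shape).astype(float)
        vals[skipped, :] = np.nan
        samples[name] = vals
    return RadialProfileSet(compartment_id=record.label, trace=trace,
                            depth_um=depth, samples=samples, skipped=skipped,
                            equivalent_radius_um=record.equivalent_radius)


def mean_radial_expression(profiles: RadialProfileSet, channel: str) -> float:
    """Mean marker intensity over all non-skipped positions and depths.

    This is the compartment-level radial expression summary (used e.g.
    for ISL1).  Skipped positions are excluded, not counted as zero.
    """
    vals = profiles.samples[channel] if channel in profiles.samples else None
    if vals is None:
        raise KeyError(f"channel {channel!r} was not sampled")
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("all border positions were skipped")
    return float(finite.mean())


def _resample_circular(profile: np.ndarray, target_length: int) -> np.ndarray:
    """Linear interpolation of a circular profile onto ``target_length``."""
    n = len(profile)
    if n == target_length:
        return profile.copy()
    pos = np.arange(target_length) * n / target_length
    lo = np.floor(pos).astype(int) % n
    hi = (lo + 1) % n
    frac = pos - np.floor(pos)
    return profile[lo] * (1 - frac) + profile[hi] * frac


def align_and_equalize(profile_sets: list[RadialProfileSet],
                       align_channel: str = CER1_CHANNEL,
                       target_length: int | None = None,
                       ) -> list[AlignedProfileSet]:
    """Align mean profiles on the align-channel maximum and equalize lengths.

    The circular shift puts the position of maximum CER1 (lowest index on
    ties) at index 0; all channels of a compartment shift identically.
    Profiles are then resampled to the length of the longest border
    recorded (or ``target_length``).  Compartments lacking the align
    channel are resampled without shifting.
    """
    if not profile_sets:
        return []
    if target_length is None:
        target_length = max(ps.trace.border_length for ps in profile_sets)

    out = []
    for ps in profile_sets:
        mean_profiles = {ch: ps.mean_profile(ch) for ch in ps.channels}
        offset = 0
        if align_channel in mean_profiles:
            prof = mean_profiles[align_channel]
            if np.isfinite(prof).any():
                offset = int(np.nanargmax(prof))
        shifted = {ch: np.roll(v, -offset) for ch, v in mean_profiles.items()}
        resampled = {ch: _resample_circular(v, target_length)
                     for ch, v in shifted.items()}
        n = ps.trace.border_length
        eq_radius = ps.equivalent_radius_um
        out.append(AlignedProfileSet(
            compartment_id=ps.compartment_id,
            profiles=resampled,
            length=target_length,
            alignment_offset=offset,
            start_angle_deg=float(ps.trace.angles_deg[offset]),
            source_border_length=n,
            disc_radius_um=eq_radius,
        ))
    return out


def profiles_to_frame(aligned: list[AlignedProfileSet]):
    """Long-format table (compartment_id, channel, position_index, angle, value)."""
    import pandas as pd

    rows = []
    for ap in aligned:
        for ch, prof in sorted(ap.profiles.items()):
            for i, v in enumerate(prof):
                rows.append({
                    "compartment_id": ap.compartment_id,
                    "channel": ch,
                    "position_index": i,
                    "angle_deg": ap.angle_at(i),
                    "value": v,
                })
    return pd.DataFrame(rows)
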