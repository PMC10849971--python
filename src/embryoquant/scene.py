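"""Synthetic scene generation with ground-truth manifests.

Generators for the four kinds of input the quantification pipeline
consumes: multichannel 2D scenes of disc-like wild-type (WT) compartments
surrounded by an EGFP+ extra-embryonic layer, confocal-style z-stacks with
layered markers, point-cell fields with per-cell marker intensities, and
marker gene lists with controlled overlap structure.

Every generator is a pure function of its spec (including the seed) and
returns, alongside the artifact, a :class:`GroundTruthManifest` recording
the true parameters so downstream estimates can be scored against truth.

Conventions
-----------
* Pixel grid is 0-based ``(row, col)``; physical positions in µm via
  ``pixel_size``; a pixel's physical center is ``(index + 0.5) * pixel_size``.
* Angles are degrees in ``[0, 360)``, counter-clockwise, 0° at the +x
  (column) axis, measured about a compartment's centroid.
* Noise is additive Gaussian clipped at zero.  One seed governs a whole
  scene; per-channel noise draws come from seed-derived child streams so
  that adding a compartment never perturbs the noise field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

DENSITY_CHANNEL = "F-actin"
EGFP_CHANNEL = "EGFP"

# Axis-classification windows shared with the polarity module (the manifest
# records the true class using the same convention the classifier applies).
ANTI_POLAR_WINDOW = (135.0, 225.0)
SYN_POLAR_MAX = 45.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelScene:
    """Named intensity channels aligned on one pixel grid.

    ``channels`` maps channel name to a 2D ``(rows, cols)`` array for plain
    scenes or a 3D ``(z, rows, cols)`` array for stacks.  Intensities are
    arbitrary-unit floats; writers quantize to 16-bit.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_stack(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    def require(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in scene (have {sorted(self.channels)})"
            )
        return self.channels[name]


@dataclass
class DiscSpec:
    """One synthetic WT compartment.

    ``polar_domains`` are angularly localized marker domains on the disc:
    tuples ``(channel, peak_angle_deg, angular_width_deg, amplitude)``.
    Each domain adds a wrapped-Gaussian bump in border angle on top of the
    channel's baseline level inside the mask.  ``egfp_cover_fraction``
    controls the fraction of mask pixels marked EGFP-positive, emulating
    partial coverage by the extra-embryonic layer.
    """

    centroid: tuple[float, float]  # (x, y) in pixels
    radius: float  # µm
    shape: str = "disc"  # disc | ellipse | crescent
    channel_levels: dict[str, float] = field(default_factory=dict)
    polar_domains: list[tuple[str, float, float, float]] = field(default_factory=list)
    egfp_cover_fraction: float = 0.0
    ellipse_aspect: float = 0.6  # minor/major ratio used when shape == "ellipse"

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")
        if self.shape not in {"disc", "ellipse", "crescent"}:
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (0.0 <= self.egfp_cover_fraction <= 1.0):
            raise ValueError("egfp_cover_fraction must be in [0, 1]")
        for ch, ang, width, amp in self.polar_domains:
            if amp < 0:
                raise ValueError(f"domain amplitude must be >= 0 ({ch})")
            if width <= 0:
                raise ValueError(f"domain angular width must be > 0 ({ch})")


@dataclass
class SceneSpec:
    width: int
    height: int
    pixel_size: float = 1.0
    compartments: list[DiscSpec] = field(default_factory=list)
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for disc in self.compartments:
            disc.validate()


class GroundTruthManifest:
    """Ground truth for a generated artifact, JSON round-trippable.

    Holds per-compartment true masks / areas / peak angles / axis classes,
    per-z-slice true means, per-cell true positivity labels, or gene-list
    overlap designs, depending on which generator produced it.
    """

    def __init__(self, data: dict | None = None):
        self.data = data if data is not None else {}

    @property
    def compartments(self) -> list[dict]:
        return self.data.get("compartments", [])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._canonical(), sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(json.loads(Path(path).read_text()))

    def _canonical(self) -> dict:
        def conv(obj):
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, set, frozenset)):
                items = [conv(v) for v in obj]
                if isinstance(obj, (set, frozenset)):
                    items = sorted(items)
                return items
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return conv(obj.tolist())
            return obj

        return conv(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroundTruthManifest) and (
            self._canonical() == other._canonical()
        )

    def __repr__(self) -> str:
        return f"GroundTruthManifest(keys={sorted(self.data)})"


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def pixel_angles_deg(rows: np.ndarray, cols: np.ndarray,
                     centroid_px: tuple[float, float]) -> np.ndarray:
    """Angle of pixel centers about a centroid, degrees CCW from +x, [0, 360)."""
    cx, cy = centroid_px
    dx = cols + 0.5 - cx
    dy = rows + 0.5 - cy
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def circular_difference_deg(a: float, b: float) -> float:
    """Minimal circular distance |a - b| on the 360° circle, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def wrapped_gaussian(delta_deg: np.ndarray, width_deg: float) -> np.ndarray:
    """Unnormalized wrapped-Gaussian bump, peak value 1 at delta = 0."""
    out = np.zeros_like(delta_deg, dtype=float)
    for k in (-1, 0, 1):
        out += np.exp(-0.5 * ((delta_deg + 360.0 * k) / width_deg) ** 2)
    return out


def _rasterize(disc: DiscSpec, height: int, width: int,
               pixel_size: float) -> np.ndarray:
    """Boolean mask of the compartment on the pixel grid."""
    cx, cy = disc.centroid
    r_px = disc.radius / pixel_size
    rows, cols = np.mgrid[0:height, 0:width]
    dx = cols + 0.5 - cx
    dy = rows + 0.5 - cy
    if disc.shape == "disc":
        return dx ** 2 + dy ** 2 <= r_px ** 2
    if disc.shape == "ellipse":
        b = r_px * disc.ellipse_aspect
        return (dx / r_px) ** 2 + (dy / b) ** 2 <= 1.0
    # crescent: disc minus an offset smaller disc
    outer = dx ** 2 + dy ** 2 <= r_px ** 2
    inner = (dx - 0.6 * r_px) ** 2 + dy ** 2 <= (0.8 * r_px) ** 2
    return outer & ~inner


def true_axis_class(disc: DiscSpec, cer1: str = "CER1",
                    tbxt: str = "TBXT") -> str:
    """Axis class implied by a compartment's polar-domain configuration."""
    per_marker: dict[str, list[float]] = {}
    for ch, ang, _w, amp in disc.polar_domains:
        if amp > 0:
            per_marker.setdefault(ch, []).append(ang % 360.0)
    if any(len(v) > 1 for v in per_marker.values()):
        return "excluded_multi_pole"
    if cer1 not in per_marker or tbxt not in per_marker:
        return "no_polarity"
    d = (per_marker[tbxt][0] - per_marker[cer1][0]) % 360.0
    if ANTI_POLAR_WINDOW[0] <= d <= ANTI_POLAR_WINDOW[1]:
        return "anti_polar"
    if min(d, 360.0 - d) <= SYN_POLAR_MAX:
        return "syn_polar"
    return "unrelated"


# ---------------------------------------------------------------------------
# Scene generator
# ---------------------------------------------------------------------------

def make_scene(spec: SceneSpec) -> tuple[MultiChannelScene, GroundTruthManifest]:
    """Render a multichannel 2D scene of WT compartments from ``spec``.

    Every channel named in any compartment is emitted, plus the F-actin
    density channel and (when any compartment has coverage) the EGFP
    channel.  Polar domains are wrapped-Gaussian bumps in border angle
    added to the disc baseline.  Compartments closer than 1 px are
    rejected so that scenes are separable by connected components.
    """
    spec.validate()
    h, w = spec.height, spec.width
    p = spec.pixel_size

    channel_names = {DENSITY_CHANNEL}
    for disc in spec.compartments:
        channel_names.update(disc.channel_levels)
        channel_names.update(ch for ch, *_ in disc.polar_domains)
        if disc.egfp_cover_fraction > 0:
            channel_names.add(EGFP_CHANNEL)

    channels = {
        name: np.full((h, w), spec.background_level, dtype=float)
        for name in sorted(channel_names)
    }

    occupied = np.zeros((h, w), dtype=bool)
    compartments_truth: list[dict] = []
    for i, disc in enumerate(spec.compartments):
        mask = _rasterize(disc, h, w, p)
        if not mask.any():
            raise ValueError(f"compartment {i} rasterizes to an empty mask")
        dilated = np.zeros_like(mask)
        rr, cc = np.nonzero(mask)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r2 = np.clip(rr + dr, 0, h - 1)
                c2 = np.clip(cc + dc, 0, w - 1)
                dilated[r2, c2] = True
        if (dilated & occupied).any():
            raise ValueError(
                f"compartment {i} is closer than 1 px to an earlier compartment"
            )
        occupied |= mask

        rows, cols = np.nonzero(mask)
        angles = pixel_angles_deg(rows, cols, disc.centroid)

        levels = dict(disc.channel_levels)
        levels.setdefault(DENSITY_CHANNEL, 1.0)
        for name, level in levels.items():
            if name == EGFP_CHANNEL:
                continue
            channels[name][rows, cols] = level
        for ch, ang, width, amp in disc.polar_domains:
            delta = (angles - ang + 180.0) % 360.0 - 180.0
            channels[ch][rows, cols] += amp * wrapped_gaussian(delta, width)

        # EGFP coverage: first k mask pixels in row-major order are positive
        n_pos = int(round(disc.egfp_cover_fraction * rows.size))
        if disc.egfp_cover_fraction > 0:
            order = np.lexsort((cols, rows))
            sel = order[:n_pos]
            channels[EGFP_CHANNEL][rows[sel], cols[sel]] = (
                disc.channel_levels.get(EGFP_CHANNEL, 1.0)
            )

        peak_angles = {}
        for ch, ang, width, amp in disc.polar_domains:
            if amp > 0:
                peak_angles.setdefault(ch, []).append(ang % 360.0)
        compartments_truth.append({
            "index": i,
            "mask_pixels": sorted(map(list, zip(rows.tolist(), cols.tolist()))),
            "area_um2": rows.size * p ** 2,
            "centroid_um": [
                float(np.mean(cols + 0.5) * p), float(np.mean(rows + 0.5) * p)
            ],
            "radius_um": disc.radius,
            "shape": disc.shape,
            "peak_angles": peak_angles,
            "axis_class": true_axis_class(disc),
            "egfp_cover_fraction": n_pos / rows.size,
        })

    if spec.noise_sd > 0:
        children = np.random.SeedSequence(spec.seed).spawn(len(channels))
        for child, name in zip(children, sorted(channels)):
            rng = np.random.default_rng(child)
            channels[name] += rng.normal(0.0, spec.noise_sd, size=(h, w))
            np.clip(channels[name], 0.0, None, out=channels[name])

    manifest = GroundTruthManifest({
        "kind": "scene",
        "pixel_size": p,
        "shape": [h, w],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "compartments": compartments_truth,
    })
    return MultiChannelScene(channels, pixel_size=p), manifest


# ---------------------------------------------------------------------------
# Z-stack generator
# ---------------------------------------------------------------------------

def make_zstack(layers: Sequence[tuple[str, float, float, float]],
                n_slices: int,
                noise_sd: float = 0.0,
                seed: int = 0,
                plane_shape: tuple[int, int] = (32, 32),
                pixel_size: float = 1.0,
                ) -> tuple[MultiChannelScene, GroundTruthManifest]:
    """Generate a layered z-stack scene.

    Each layer is ``(channel, z_center, z_sd, mean_intensity)``: the
    channel's true per-slice mean follows a Gaussian profile in slice index
    centered at ``z_center`` with spread ``z_sd`` (``z_sd == 0`` puts all
    intensity in the slice nearest ``z_center``), scaled so the peak slice
    mean equals ``mean_intensity``.  This emulates basal/middle/apical
    marker stratification (e.g. Desmin low-z, CD34 middle, FOXA2 high-z).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    h, w = plane_shape
    z = np.arange(n_slices, dtype=float)

    true_means: dict[str, np.ndarray] = {}
    for ch, z_center, z_sd, mean_intensity in layers:
        profile = np.zeros(n_slices)
        if z_sd == 0:
            profile[int(round(z_center))] = mean_intensity
        else:
            profile = mean_intensity * np.exp(-0.5 * ((z - z_center) / z_sd) ** 2)
        true_means[ch] = true_means.get(ch, np.zeros(n_slices)) + profile

    channels: dict[str, np.ndarray] = {}
    children = np.random.SeedSequence(seed).spawn(max(len(true_means), 1))
    for child, ch in zip(children, sorted(true_means)):
        stack = np.repeat(true_means[ch][:, None, None], h, axis=1)
        stack = np.repeat(stack, w, axis=2).astype(float)
        if noise_sd > 0:
            rng = np.random.default_rng(child)
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
            np.clip(stack, 0.0, None, out=stack)
        channels[ch] = stack

    manifest = GroundTruthManifest({
        "kind": "zstack",
        "n_slices": n_slices,
        "noise_sd": noise_sd,
        "seed": seed,
        "true_slice_means": {ch: m.tolist() for ch, m in true_means.items()},
    })
    return MultiChannelScene(channels, pixel_size=pixel_size), manifest


# ---------------------------------------------------------------------------
# Cell-field generator
# ---------------------------------------------------------------------------

def make_cell_field(n_cells: int,
                    marker_model: Mapping[str, tuple[float, float, float, float]],
                    cluster_geometry: Sequence[tuple[float, float, float]] | None = None,
                    seed: int = 0,
                    field_size: float = 1000.0,
                    ) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Generate a point-cell field with per-cell marker intensities.

    ``marker_model`` maps marker name to ``(positive_fraction, pos_mean,
    neg_mean, sd)``; each cell draws a true positivity label per marker
    (Bernoulli) and a Gaussian intensity around the corresponding mean,
    clipped at 0.  ``cluster_geometry`` is an optional list of
    ``(cx, cy, sd)`` spatial clusters (µm); cells are assigned to clusters
    cyclically, otherwise placed uniformly in a ``field_size`` square.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    for m, (frac, pos_mean, neg_mean, sd) in marker_model.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"positive_fraction for {m} must be in [0, 1]")
        if pos_mean <= neg_mean:
            raise ValueError(f"pos_mean must exceed neg_mean for {m}")
        if sd < 0:
            raise ValueError(f"sd must be >= 0 for {m}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if cluster_geometry:
        idx = np.arange(n_cells) % len(cluster_geometry)
        centers = np.asarray([(c[0], c[1]) for c in cluster_geometry])
        sds = np.asarray([c[2] for c in cluster_geometry])
        xy = centers[idx] + rng.normal(0, 1, size=(n_cells, 2)) * sds[idx, None]
    else:
        xy = rng.uniform(0, field_size, size=(n_cells, 2))

    table = {"cell_id": np.arange(n_cells), "x": xy[:, 0], "y": xy[:, 1]}
    truth_labels: dict[str, list[bool]] = {}
    for m in sorted(marker_model):
        frac, pos_mean, neg_mean, sd = marker_model[m]
        positive = rng.random(n_cells) < frac
        means = np.where(positive, pos_mean, neg_mean)
        table[m] = np.clip(means + rng.normal(0, sd, size=n_cells), 0.0, None)
        table[f"true_{m}_positive"] = positive
        truth_labels[m] = positive.tolist()

    df = pd.DataFrame(table)
    manifest = GroundTruthManifest({
        "kind": "cell_field",
        "n_cells": n_cells,
        "seed": seed,
        "true_positive_counts": {m: int(sum(v)) for m, v in truth_labels.items()},
        "marker_model": {m: list(v) for m, v in marker_model.items()},
    })
    return df, manifest


# ---------------------------------------------------------------------------
# Gene-list generator
# ---------------------------------------------------------------------------

def make_gene_lists(universe_size: int,
                    sizes: tuple[int, int, int],
                    overlap_design: tuple[int, int, int],
                    seed: int = 0,
                    ) -> tuple[dict[str, list[str]], list[str], GroundTruthManifest]:
    """Generate three gene lists C, D, E with an exact overlap design.

    ``overlap_design`` = (|A|, |B|, |C∩D∩E|) where A = (C∩D)\\E is the
    unique C/D overlap and B = (C∩E)\\D the unique C/E overlap.  Genes not
    participating in any designed overlap are distinct across lists, so the
    realized unique overlaps equal the design exactly.  The universe is
    ``g000001 ...``; the seed shuffles which universe genes are used.
    """
    n_c, n_d, n_e = sizes
    n_a, n_b, n_core = overlap_design
    if min(n_c, n_d, n_e) <= 0:
        raise ValueError("list sizes must be positive")
    if min(n_a, n_b, n_core) < 0:
        raise ValueError("overlap sizes must be >= 0")
    c_rest = n_c - n_a - n_b - n_core
    d_rest = n_d - n_a - n_core
    e_rest = n_e - n_b - n_core
    if c_rest < 0:
        raise ValueError("infeasible design: |A| + |B| + |C∩D∩E| exceeds |C|")
    if d_rest < 0:
        raise ValueError("infeasible design: |A| + |C∩D∩E| exceeds |D|")
    if e_rest < 0:
        raise ValueError("infeasible design: |B| + |C∩D∩E| exceeds |E|")
    n_union = n_a + n_b + n_core + c_rest + d_rest + e_rest
    if universe_size < n_union:
        raise ValueError(
            f"infeasible design: universe_size {universe_size} < |C∪D∪E| {n_union}"
        )

    universe = [f"g{i:06d}" for i in range(1, universe_size + 1)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    picks = list(np.array(universe)[rng.permutation(universe_size)[:n_union]])

    picks_iter = iter(picks)

    def draw(n: int) -> list[str]:
        return [next(picks_iter) for _ in range(n)]

    core = draw(n_core)
    a_genes = draw(n_a)
    b_genes = draw(n_b)
    c_only = draw(c_rest)
    d_only = draw(d_rest)
    e_only = draw(e_rest)

    lists = {
        "C": sorted(core + a_genes + b_genes + c_only),
        "D": sorted(core + a_genes + d_only),
        "E": sorted(core + b_genes + e_only),
    }
    manifest = GroundTruthManifest({
        "kind": "gene_lists",
        "universe_size": universe_size,
        "sizes": list(sizes),
        "seed": seed,
        "true_unique_overlap_A": sorted(a_genes),
        "true_unique_overlap_B": sorted(b_genes),
        "true_core": sorted(core),
    })
    return lists, universe, manifest


# ---------------------------------------------------------------------------
# I/O: TIFF scenes + JSON channel maps, CSV tables, plain-text gene lists
# ---------------------------------------------------------------------------

def write_scene(scene: MultiChannelScene, directory: str | Path,
                stem: str = "scene") -> tuple[Path, Path]:
    """Write a scene as a multi-page 16-bit TIFF plus a JSON channel map.

    Intensities are scaled to the 16-bit range by the global max (recorded
    in the channel map so reads can invert the quantization).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = sorted(scene.channels)
    stackmax = max(float(scene.channels[n].max()) for n in names)
    scale = 65535.0 / stackmax if stackmax > 0 else 1.0
    pages = [
        np.round(scene.channels[n] * scale).astype(np.uint16) for n in names
    ]
    tif_path = directory / f"{stem}.tif"
    tifffile.imwrite(tif_path, np.stack(pages))
    map_path = directory / f"{stem}.channels.json"
    map_path.write_text(json.dumps({
        "channels": names,
        "pixel_size": scene.pixel_size,
        "intensity_scale": scale,
        "is_stack": scene.is_stack,
    }, sort_keys=True))
    return tif_path, map_path


def read_scene(tif_path: str | Path,
               channel_map_path: str | Path | None = None) -> MultiChannelScene:
    tif_path = Path(tif_path)
    if channel_map_path is None:
        channel_map_path = tif_path.with_suffix("").with_suffix(".channels.json")
        if not Path(channel_map_path).exists():
            channel_map_path = tif_path.parent / (tif_path.stem + ".channels.json")
    meta = json.loads(Path(channel_map_path).read_text())
    data = tifffile.imread(tif_path).astype(float) / meta["intensity_scale"]
    names = meta["channels"]
    if data.ndim == 2:
        data = data[None]
    return MultiChannelScene(
        {name: data[i] for i, name in enumerate(names)},
        pixel_size=meta["pixel_size"],
    )


def write_gene_lists(lists: Mapping[str, Sequence[str]],
                     directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for label, genes in lists.items():
        path = directory / f"{label}.txt"
        path.write_text("\n".join(genes) + "\n")
        out[label] = path
    return out


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
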