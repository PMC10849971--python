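"""Haematopoietic foci, haemoglobin ratios, CD34 coverage, z-profiles, ΔΔCt.

Blood-lineage quantification operates on per-cell objects: cells are
detected from a marker channel (threshold + connected components + size
gate) and carry the mean intensity of every channel over their pixels.
Foci — spatial clusters of blood cells with a negative border — are
classified by counting rules:

* a focus needs strictly more than 20 cells to be classified at all;
* uni-lineage for marker m if fewer than three member cells lack m, and
  no member cell is positive only for the pan-haematopoietic progenitor
  marker CD43 (CD43 co-expression does not break uni-lineage);
* multilineage if three or more member cells are positive for each of at
  least two assessed lineage markers.

Haemoglobin maturation is tracked by per-cell ε/γ ratios with each
chain normalized to the coverslip-wide mean pan-haemoglobin intensity;
z-stacks are summarized as per-slice mean intensities above the in-focus
bottom slice, expressed as percent of each channel's maximum; qPCR fold
changes use 2^−ΔΔCt against an endogenous control and calibrator sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .scene import MultiChannelScene

PROGENITOR_MARKER = "CD43"
MIN_FOCUS_CELLS = 20  # strictly more than this many cells required
UNI_MAX_NEGATIVE = 3  # "fewer than three" negative cells allowed
MULTI_MIN_POSITIVE = 3


@dataclass
class CellObject:
    id: int
    centroid: tuple[float, float]  # (x, y) µm
    intensities: dict[str, float]


@dataclass
class FocusRecord:
    id: int
    member_cell_ids: list[int]
    n_cells: int
    positive_counts: dict[str, int]
    classification: str            # "uni_lineage" | "multi_lineage" | "unclassified"
    lineage_markers: tuple[str, ...] = ()


@dataclass
class ZProfile:
    """Per-slice marker distribution of a z-stack above the in-focus bottom."""

    slice_means: dict[str, np.ndarray]
    bottom_index: int
    normalized_pct: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.normalized_pct:
            self.normalized_pct = {
                ch: _percent_of_max(m) for ch, m in self.slice_means.items()
            }


def _percent_of_max(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        peak = np.nanmax(values) if np.isfinite(values).any() else np.nan
    if not np.isfinite(peak) or peak == 0:
        return np.zeros_like(values)
    return 100.0 * values / peak


# ---------------------------------------------------------------------------
# Cell detection
# ---------------------------------------------------------------------------

def detect_cells(scene: MultiChannelScene, marker_channel: str,
                 threshold: float | None = None,
                 min_area_px: int = 1) -> list[CellObject]:
    """Detect cell objects on one channel and featurize across all channels.

    Pixels above threshold (Otsu when None) are labelled (8-connectivity);
    components smaller than ``min_area_px`` are dropped.  Each object's
    per-channel mean intensity is recorded; NaN pixels (e.g. masked-out WT
    regions) never seed objects and are excluded from means.
    """
    image = scene.require(marker_channel)
    if image.ndim != 2:
        raise ValueError("detect_cells expects a 2D scene")
    if threshold is None:
        from skimage.filters import threshold_otsu
        finite = image[np.isfinite(image)]
        threshold = float(threshold_otsu(finite))
    with np.errstate(invalid="ignore"):
        binary = np.nan_to_num(image, nan=-np.inf) > threshold
    labelled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    cells: list[CellObject] = []
    p = scene.pixel_size
    next_id = 0
    for lab in range(1, n + 1):
        mask = labelled == lab
        if mask.sum() < min_area_px:
            continue
        rows, cols = np.nonzero(mask)
        intensities = {}
        for ch, img in scene.channels.items():
            vals = img[rows, cols]
            vals = vals[np.isfinite(vals)]
            intensities[ch] = float(vals.mean()) if vals.size else math.nan
        cells.append(CellObject(
            id=next_id,
            centroid=(float((cols.mean() + 0.5) * p),
                      float((rows.mean() + 0.5) * p)),
            intensities=intensities,
        ))
        next_id += 1
    return cells


def exclude_wt_regions(scene: MultiChannelScene,
                       wt_mask: np.ndarray) -> MultiChannelScene:
    """Remove WT compartment pixels from every channel (set to missing)."""
    wt_mask = np.asarray(wt_mask, dtype=bool)
    ref = next(iter(scene.channels.values()))
    if wt_mask.shape != ref.shape:
        raise ValueError(
            f"mask shape {wt_mask.shape} != scene shape {ref.shape}"
        )
    channels = {}
    for name, img in scene.channels.items():
        out = img.astype(float).copy()
        out[wt_mask] = np.nan
        channels[name] = out
    return MultiChannelScene(channels, pixel_size=scene.pixel_size)


# ---------------------------------------------------------------------------
# Haemoglobin ratios and CD34 coverage
# ---------------------------------------------------------------------------

def haemoglobin_ratios(cells: Sequence[CellObject] | pd.DataFrame,
                       eps_channel: str = "HbE",
                       gamma_channel: str = "HbG",
                       pan_channel: str = "HbPan") -> pd.DataFrame:
    """Per-cell normalized ε/γ haemoglobin values and their ratio.

    ``eps_norm`` and ``gamma_norm`` divide each chain by the coverslip-wide
    mean object pan-haemoglobin intensity; ``ratio`` is per-cell ε/γ
    (missing, not dropped, where γ is zero).  All three outputs are
    invariant to a global intensity rescaling.
    """
    if isinstance(cells, pd.DataFrame):
        df = cells
        eps = df[eps_channel].to_numpy(dtype=float)
        gamma = df[gamma_channel].to_numpy(dtype=float)
        pan = df[pan_channel].to_numpy(dtype=float)
        ids = df["cell_id"].to_numpy() if "cell_id" in df else np.arange(len(df))
    else:
        ids = np.array([c.id for c in cells])
        eps = np.array([c.intensities[eps_channel] for c in cells], dtype=float)
        gamma = np.array([c.intensities[gamma_channel] for c in cells], dtype=float)
        pan = np.array([c.intensities[pan_channel] for c in cells], dtype=float)
    if len(ids) == 0:
        return pd.DataFrame(columns=["cell_id", "eps_norm", "gamma_norm", "ratio"])
    pan_mean = float(np.nanmean(pan))
    if pan_mean == 0:
        raise ValueError("pan-haemoglobin mean intensity is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gamma == 0, np.nan, eps / gamma)
    return pd.DataFrame({
        "cell_id": ids,
        "eps_norm": eps / pan_mean,
        "gamma_norm": gamma / pan_mean,
        "ratio": ratio,
    })


def cd34_area_fraction(scene: MultiChannelScene, cd34_channel: str = "CD34",
                       threshold: float = 0.5,
                       wt_mask: np.ndarray | None = None) -> float:
    """Percent of the cropped image area positive for CD34.

    Positive pixels inside ``wt_mask`` are excluded from the numerator;
    the denominator is always the full image pixel count.
    """
    image = scene.require(cd34_channel)
    with np.errstate(invalid="ignore"):
        positive = np.nan_to_num(image, nan=-np.inf) > threshold
    if wt_mask is not None:
        positive &= ~np.asarray(wt_mask, dtype=bool)
    return 100.0 * float(positive.sum()) / image.size


# ---------------------------------------------------------------------------
# Focus grouping and classification
# ---------------------------------------------------------------------------

def group_foci(cells: Sequence[CellObject], link_radius: float) -> list[list[int]]:
    """Spatially group cells: link pairs within ``link_radius`` µm, keep components.

    A reproducible stand-in for the manual partitioning of foci by eye;
    classification also accepts externally supplied groupings.
    """
    if not cells:
        return []
    pts = np.array([c.centroid for c in cells])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    n = len(cells)
    if len(pairs) == 0:
        labels = np.arange(n)
    else:
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = _cc(graph, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(cells[i].id)
    return [sorted(v) for _, v in sorted(groups.items())]


def classify_focus(cells: Sequence[CellObject],
                   positivity_thresholds: Mapping[str, float],
                   assessed_markers: Sequence[str],
                   progenitor_marker: str = PROGENITOR_MARKER,
                   focus_id: int = 0) -> FocusRecord:
    """Classify one candidate focus by the uni-/multilineage counting rules.

    ``assessed_markers`` are the lineage markers under evaluation (CD43 is
    handled separately as the progenitor marker).  A cell is positive for
    a marker when its intensity exceeds that marker's threshold strictly.
    """
    if not cells:
        raise ValueError("empty cell list")
    assessed = [m for m in assessed_markers if m != progenitor_marker]

    def positive(cell: CellObject, marker: str) -> bool:
        thr = positivity_thresholds[marker]
        return cell.intensities.get(marker, 0.0) > thr

    n = len(cells)
    pos_counts = {m: sum(positive(c, m) for c in cells) for m in assessed}
    if progenitor_marker in positivity_thresholds:
        pos_counts[progenitor_marker] = sum(
            positive(c, progenitor_marker) for c in cells
        )

    member_ids = [c.id for c in cells]
    if n <= MIN_FOCUS_CELLS:
        return FocusRecord(focus_id, member_ids, n, pos_counts, "unclassified")

    multi = tuple(sorted(
        m for m in assessed if pos_counts[m] >= MULTI_MIN_POSITIVE
    ))
    if len(multi) >= 2:
        return FocusRecord(focus_id, member_ids, n, pos_counts,
                           "multi_lineage", multi)

    cd43_only_present = (
        progenitor_marker in positivity_thresholds
        and any(
            positive(c, progenitor_marker)
            and not any(positive(c, m) for m in assessed)
            for c in cells
        )
    )
    for m in assessed:
        n_negative = n - pos_counts[m]
        if n_negative < UNI_MAX_NEGATIVE and not cd43_only_present:
            return FocusRecord(focus_id, member_ids, n, pos_counts,
                               "uni_lineage", (m,))
    return FocusRecord(focus_id, member_ids, n, pos_counts, "unclassified")


# ---------------------------------------------------------------------------
# Z-stack profiles
# ---------------------------------------------------------------------------

def z_distribution(stack: MultiChannelScene,
                   channels: Sequence[str] | None = None,
                   focus_metric_threshold: float = 0.0) -> ZProfile:
    """Per-slice mean intensity per channel, percent-of-max normalized.

    The stack bottom is the lowest slice where any requested channel's
    mean exceeds ``focus_metric_threshold`` (the in-focus criterion);
    slices below it are excluded.  Raises when no slice qualifies.
    """
    if channels is None:
        channels = sorted(stack.channels)
    arrays = {ch: stack.require(ch) for ch in channels}
    first = next(iter(arrays.values()))
    if first.ndim != 3:
        raise ValueError("z_distribution expects a z-stack scene")
    n_slices = first.shape[0]
    means = {
        ch: np.array([float(np.nanmean(a[z])) for z in range(n_slices)])
        for ch, a in arrays.items()
    }
    any_signal = np.zeros(n_slices, dtype=bool)
    for m in means.values():
        any_signal |= m > focus_metric_threshold
    if not any_signal.any():
        raise ValueError("no slice passes the in-focus bottom criterion")
    bottom = int(np.argmax(any_signal))
    trimmed = {ch: m[bottom:] for ch, m in means.items()}
    return ZProfile(slice_means=trimmed, bottom_index=bottom)


def average_z_profiles(profiles: Sequence[ZProfile]) -> ZProfile:
    """Average replicate z-profiles index-wise, then renormalize to % of max.

    Profiles are aligned on their bottom slice; per-channel normalized
    percentages are averaged at each index (shorter profiles contribute
    missing values, excluded from that index's mean) and the result is
    rescaled so each channel's maximum is 100%.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    channels = sorted(profiles[0].normalized_pct)
    max_len = max(len(p.normalized_pct[channels[0]]) for p in profiles)
    averaged = {}
    for ch in channels:
        stackv = np.full((len(profiles), max_len), np.nan)
        for i, p in enumerate(profiles):
            v = p.normalized_pct[ch]
            stackv[i, : len(v)] = v
        with np.errstate(invalid="ignore"):
            averaged[ch] = np.nanmean(stackv, axis=0)
    return ZProfile(slice_means=averaged, bottom_index=0,
                    normalized_pct={ch: _percent_of_max(v)
                                    for ch, v in averaged.items()})


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def fold_change_ddct(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_calibrator: float,
                     ct_ref_calibrator: float) -> float:
    """Relative expression by 2^−ΔΔCt.

    ΔCt = Ct(target) − Ct(endogenous control) within each of the sample
    and calibrator; the fold change is 2^−(ΔCt_sample − ΔCt_calibrator).
    """
    for v in (ct_target_sample, ct_ref_sample,
              ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - \
           (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


def fold_changes_from_table(ct_table: pd.DataFrame, target_gene: str,
                            reference_gene: str, calibrator_sample: str,
                            sample_col: str = "sample", gene_col: str = "gene",
                            ct_col: str = "ct") -> pd.DataFrame:
    """2^−ΔΔCt per sample from a long-format Ct table.

    The table needs one Ct per (sample, gene); replicate wells should be
    averaged upstream.  The calibrator sample's fold change is 1 by
    construction.
    """
    pivot = ct_table.pivot_table(index=sample_col, columns=gene_col,
                                 values=ct_col, aggfunc="mean")
    for g in (target_gene, reference_gene):
        if g not in pivot.columns:
            raise KeyError(f"gene {g!r} absent from Ct table")
    if calibrator_sample not in pivot.index:
        raise KeyError(f"calibrator sample {calibrator_sample!r} absent")
    cal_t = pivot.loc[calibrator_sample, target_gene]
    cal_r = pivot.loc[calibrator_sample, reference_gene]
    rows = [
        {sample_col: s,
         "fold_change": fold_change_ddct(
             pivot.loc[s, target_gene], pivot.loc[s, reference_gene],
             cal_t, cal_r)}
        for s in pivot.index
    ]
    return pd.DataFrame(rows)
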