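"""Segmentation and morphometric feature extraction for 4-channel frames.

Frames are ``(4, H, W)`` float arrays in channel order DAPI, CD138, BCMA,
CD45 (see :func:`read_frame_tiff`).  Nuclei are segmented from DAPI by
Otsu thresholding, hole filling and watershed splitting on the distance
transform; cells by a nucleus-seeded watershed over the summed
membrane/cytoplasm channels, capped at a maximum expansion beyond the
nucleus.  Bright objects without a nucleus are retained separately as
candidate artifacts.  Per-cell features use 0-based pixel coordinates with
``x`` = column and ``y`` = row; eccentricity is the second-central-moment
(equivalent-ellipse) definition; channel medians are computed on raw pixel
values over the cell mask; the BCMA membrane score is the median over the
outermost ``band_width`` pixels of the cell mask and the perinuclear score
the median over an ``annulus_width``-pixel band just outside the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "SegmentationResult",
    "segment_nuclei",
    "segment_cells",
    "extract_features",
    "read_frame_tiff",
]

CHANNEL_ORDER = ("dapi", "cd138", "bcma", "cd45")


@dataclass
class SegmentationResult:
    """Label masks from one frame; cell label ids equal their nucleus ids."""

    nuclear_labels: np.ndarray
    cell_labels: np.ndarray
    artifact_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.nuclear_labels.shape != self.cell_labels.shape:
            raise ValueError("nuclear and cell masks must have the same shape")


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[0] != 4:
        raise ValueError("frame must be a (4, H, W) array (DAPI, CD138, BCMA, CD45)")
    return frame.astype(float)


def segment_nuclei(
    frame: np.ndarray,
    min_nuclear_area: int = 30,
    max_nuclear_area: int = 5000,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Label nuclei in the DAPI channel.

    Otsu threshold -> hole fill -> watershed split on the distance
    transform (peak markers at least ``min_peak_distance`` px apart) ->
    area filter.  A blank frame yields zero objects.
    """
    frame = _check_frame(frame)
    dapi = frame[0]
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=np.int32)
    mask = dapi > threshold_otsu(dapi)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, labels=cc_label(mask), min_distance=min_peak_distance,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=mask).astype(np.int32)
    out = np.zeros_like(labels)
    next_id = 1
    for p in regionprops(labels):
        if min_nuclear_area <= p.area <= max_nuclear_area:
            out[labels == p.label] = next_id
            next_id += 1
    return out


def segment_cells(
    frame: np.ndarray,
    nuclear_labels: np.ndarray,
    max_expansion: int = 25,
    min_rim: int = 2,
    artifact_min_area: int = 30,
) -> SegmentationResult:
    """Grow cell masks from nuclei over the membrane/cytoplasm channels.

    A nucleus-seeded watershed runs over the summed CD138 + BCMA + CD45
    signal, restricted to above-background pixels within ``max_expansion``
    px of a nucleus; with no signal beyond the nucleus the cell falls back
    to the nucleus dilated by ``min_rim``.  Bright connected components
    that contain no nucleus are labeled separately as candidate artifacts.
    """
    frame = _check_frame(frame)
    if nuclear_labels.shape != frame.shape[1:]:
        raise ValueError("nuclear mask shape does not match frame")
    signal = frame[1] + frame[2] + frame[3]
    nuc_mask = nuclear_labels > 0
    if np.ptp(signal) == 0:
        fg = np.zeros(signal.shape, dtype=bool)
    else:
        fg = signal > threshold_otsu(signal)
    rim = ndi.binary_dilation(nuc_mask, structure=disk(min_rim))
    near = ndi.distance_transform_edt(~nuc_mask) <= max_expansion
    allowed = (fg & near) | rim | nuc_mask
    cells = watershed(-signal, markers=nuclear_labels, mask=allowed).astype(np.int32)
    # every cell must contain its nucleus
    cells[nuc_mask] = nuclear_labels[nuc_mask]

    orphan = fg & (cells == 0)
    orphan_cc = cc_label(orphan)
    artifacts = np.zeros_like(orphan_cc, dtype=np.int32)
    next_id = 1
    for p in regionprops(orphan_cc):
        if p.area >= artifact_min_area:
            artifacts[orphan_cc == p.label] = next_id
            next_id += 1
    return SegmentationResult(
        nuclear_labels=nuclear_labels.astype(np.int32),
        cell_labels=cells,
        artifact_labels=artifacts,
    )


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def extract_features(
    frame: np.ndarray,
    segmentation: SegmentationResult,
    band_width: int = 3,
    annulus_width: int = 3,
    sample_id: str = "S0",
    slide: int = 0,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Per-cell morphometric and intensity features from one frame.

    One row per nucleus-matched cell, following the event-table schema of
    the generator: areas and eccentricities of the nucleus and cell,
    per-channel medians and MADs over the cell mask, and the BCMA
    membrane-band / perinuclear-annulus scores.
    """
    frame = _check_frame(frame)
    seg = segmentation
    if seg.cell_labels.shape != frame.shape[1:]:
        raise ValueError("segmentation shape does not match frame")
    nuc_props = {p.label: p for p in regionprops(seg.nuclear_labels)}
    rows = []
    for p in regionprops(seg.cell_labels):
        lab = p.label
        np_ = nuc_props.get(lab)
        if np_ is None:
            continue
        cell_mask = seg.cell_labels == lab
        nuc_mask = seg.nuclear_labels == lab
        band = cell_mask & ~ndi.binary_erosion(cell_mask, structure=disk(band_width))
        annulus = ndi.binary_dilation(nuc_mask, structure=disk(annulus_width)) & ~nuc_mask
        bcma = frame[2]
        row = {
            "cell_id": f"{sample_id}:f{frame_index}:{lab}",
            "sample_id": sample_id,
            "slide": slide,
            "frame": frame_index,
            "x": float(p.centroid[1]),
            "y": float(p.centroid[0]),
            "nuclear_area": float(np_.area),
            "nuclear_eccentricity": float(np_.eccentricity),
            "cellular_area": float(p.area),
            "cellular_eccentricity": float(p.eccentricity),
            "nuclear_perimeter": float(np_.perimeter),
            "cellular_solidity": float(p.solidity),
            "bcma_membrane_score": float(np.median(bcma[band])) if band.any() else 0.0,
            "bcma_perinuclear_score": float(np.median(bcma[annulus]))
            if annulus.any()
            else 0.0,
        }
        for ci, name in enumerate(CHANNEL_ORDER):
            med, mad = _median_mad(frame[ci][cell_mask])
            row[f"median_{name}"] = med
            row[f"mad_{name}"] = mad
        rows.append(row)
    return pd.DataFrame(rows)


def read_frame_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF written by the generator as a (4, H, W) array."""
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D multichannel TIFF, got shape {arr.shape}")
    if arr.shape[0] != 4 and arr.shape[-1] == 4:
        arr = np.moveaxis(arr, -1, 0)
    return arr.astype(np.float32)
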