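"""Preprocess, segment and measure cells into the single-cell repository.

The measurement chain mirrors classical image cytometry: flat-field
correction, rolling-ball background subtraction, DNA-channel nuclear
segmentation, then per-cell geometry (area in um^2, circularity
``4*pi*A/P^2``) and per-channel mean and integrated fluorescence.  Spots
(nuclear foci, proximity-assay dots, ...) are detected per channel as
sub-compartments and measured the same way, each assigned to the cell that
contains its centroid.

Circularity uses the Crofton perimeter estimator and is clamped to 1.0:
naive pixel-boundary perimeters make digitized discs exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, restoration, segmentation, transform
from skimage.filters import threshold_otsu

from .io_formats import ImagePlane

__all__ = [
    "SegmentationParams",
    "SpotParams",
    "subtract_background",
    "flatfield_correct",
    "segment_nuclei",
    "measure_cells",
    "detect_spots",
]


@dataclass
class SegmentationParams:
    """Nuclear segmentation knobs.

    threshold: absolute threshold; None selects Otsu's method.
    watershed: split touching objects on distance-transform maxima.
    min_area_px / max_area_px: size filter on labeled objects.
    exclude_border: drop objects touching the image edge (their area and
        intensity are biased); on by default.
    """

    threshold: float | None = None
    watershed: bool = False
    watershed_min_distance_px: int = 10
    min_area_px: int = 50
    max_area_px: int | None = None
    exclude_border: bool = True
    connectivity: int = 2  # 8-connected


@dataclass
class SpotParams:
    """Spot (sub-compartment) detection knobs: difference-of-Gaussians
    band-pass followed by a robust threshold at ``k_mad`` median absolute
    deviations above the local background."""

    sigma_low_px: float = 1.0
    sigma_high_px: float = 5.0
    k_mad: float = 8.0
    min_area_px: int = 3
    max_area_px: int | None = None
    split_touching: bool = True       # watershed on band-pass maxima
    split_min_distance_px: int = 2


def subtract_background(plane: ImagePlane, radius_px: int,
                        downscale: int | None = None) -> ImagePlane:
    """Rolling-ball background subtraction.

    The smooth background is the envelope of a ball of *radius_px* rolled
    under the intensity surface (morphological opening with a ball
    element); it is estimated and subtracted, and the result clamped at 0.
    For large radii the background is estimated on a shrunk copy and
    re-expanded (the standard shrink trick), which is accurate because the
    background varies on the scale of the ball.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px >= min(plane.shape):
        raise ValueError(f"radius {radius_px} exceeds image size {plane.shape}")
    img = plane.pixels.astype(float)
    if downscale is None:
        downscale = max(1, radius_px // 8)
    if downscale > 1:
        small = transform.rescale(img, 1.0 / downscale, order=1,
                                  anti_aliasing=True)
        bg_small = restoration.rolling_ball(small, radius=radius_px / downscale)
        bg = transform.resize(bg_small, img.shape, order=1)
    else:
        bg = restoration.rolling_ball(img, radius=radius_px)
    out = np.clip(img - bg, 0, None)
    return ImagePlane(out, plane.pixel_size_nm, plane.channel,
                      plane.origin_stage_um)


def flatfield_correct(plane: ImagePlane, flatfield: ImagePlane | np.ndarray
                      ) -> ImagePlane:
    """Homogenize illumination: divide by the mean-normalized flat field."""
    ff = flatfield.pixels if isinstance(flatfield, ImagePlane) else np.asarray(flatfield)
    if ff.shape != plane.shape:
        raise ValueError("flatfield shape must match the image")
    if np.any(ff <= 0):
        raise ValueError("flatfield must be strictly positive")
    out = plane.pixels / (ff / ff.mean())
    return ImagePlane(out, plane.pixel_size_nm, plane.channel,
                      plane.origin_stage_um)


def segment_nuclei(dna_plane: ImagePlane,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei on the (preprocessed) DNA channel.

    Global threshold (Otsu unless overridden), hole filling, optional
    watershed split on distance-transform maxima, size filter, and
    border-object removal.  Returns an integer label map with contiguous
    labels 1..N (0 = background); an empty result is a valid 0-label map.
    """
    p = params or SegmentationParams()
    img = dna_plane.pixels
    if p.threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(img)
    else:
        thr = p.threshold
    fg = img > thr
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)

    if p.watershed:
        dist = ndimage.distance_transform_edt(fg)
        from skimage.feature import peak_local_max
        peaks = peak_local_max(dist, min_distance=p.watershed_min_distance_px,
                               labels=fg, exclude_border=False)
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndimage.label(fg, structure=ndimage.generate_binary_structure(
            2, p.connectivity))

    if p.exclude_border:
        labels = segmentation.clear_border(labels)

    # size filter then contiguous relabel
    counts = np.bincount(labels.ravel())
    keep = np.zeros(len(counts), dtype=bool)
    keep[1:] = counts[1:] >= p.min_area_px
    if p.max_area_px is not None:
        keep[1:] &= counts[1:] <= p.max_area_px
    remap = np.zeros(len(counts), dtype=np.int32)
    remap[keep] = np.arange(1, keep.sum() + 1)
    return remap[labels]


def _crofton_circularity(region) -> float:
    perim = region.perimeter_crofton
    if perim <= 0:
        return 1.0
    return min(4 * np.pi * region.area / perim ** 2, 1.0)


def measure_cells(labelmap: np.ndarray, stack, source_file: str = "",
                  tile_index: int = 0) -> pd.DataFrame:
    """Measure every labeled cell across all channels of *stack*.

    Returns one row per label: geometry (centroid px, area um^2,
    circularity) plus ``mean_<channel>`` and ``integrated_<channel>`` for
    every channel plane (z=0).  Integrated = mean x pixel count.
    """
    planes = {ch: stack.plane(ch) for ch in stack.channel_names}
    for ch, pl in planes.items():
        if pl.shape != labelmap.shape:
            raise ValueError(f"channel {ch!r} shape {pl.shape} does not match "
                             f"label map {labelmap.shape}")
    px_um = stack.pixel_size_nm / 1000.0
    regions = measure.regionprops(labelmap)
    rows = []
    for r in regions:
        row = {
            "cell_id": int(r.label),
            "source_file": source_file,
            "tile_index": tile_index,
            "centroid_x_px": float(r.centroid[1]),
            "centroid_y_px": float(r.centroid[0]),
            "area_um2": float(r.area) * px_um ** 2,
            "area_px": int(r.area),
            "circularity": float(_crofton_circularity(r)),
        }
        rows.append(row)
    if not rows:
        cols = ["cell_id", "source_file", "tile_index", "centroid_x_px",
                "centroid_y_px", "area_um2", "area_px", "circularity"]
        cols += [f"mean_{ch}" for ch in planes] + [f"integrated_{ch}" for ch in planes]
        return pd.DataFrame(columns=cols)
    labels = [r["cell_id"] for r in rows]
    for ch, pl in planes.items():
        sums = ndimage.sum_labels(pl.pixels, labelmap, labels)
        counts = ndimage.sum_labels(np.ones_like(pl.pixels), labelmap, labels)
        for row, s, c in zip(rows, sums, counts):
            row[f"mean_{ch}"] = float(s / c)
            row[f"integrated_{ch}"] = float(s)
    return pd.DataFrame(rows)


def detect_spots(plane: ImagePlane, parent_labels: np.ndarray,
                 params: SpotParams | None = None, source_file: str = "",
                 tile_index: int = 0) -> pd.DataFrame:
    """Detect and measure spots (sub-compartments) on one channel.

    Band-pass (difference of Gaussians), robust threshold at
    ``median + k_mad * MAD`` of the band-passed image, size filter, then
    the same geometry and intensity measurements as cells.
    ``parent_cell_id`` is the label containing the spot centroid (0 if
    none).  An empty table is a valid result.
    """
    p = params or SpotParams()
    img = plane.pixels.astype(float)
    band = ndimage.gaussian_filter(img, p.sigma_low_px) \
        - ndimage.gaussian_filter(img, p.sigma_high_px)
    med = np.median(band)
    mad = np.median(np.abs(band - med)) + 1e-12
    mask = band > med + p.k_mad * mad * 1.4826
    if p.split_touching and mask.any():
        # split touching spots on band-pass intensity maxima
        from skimage.feature import peak_local_max
        peaks = peak_local_max(band, min_distance=p.split_min_distance_px,
                               labels=ndimage.label(mask)[0],
                               exclude_border=False)
        markers = np.zeros(band.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-band, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    regions = measure.regionprops(labels, intensity_image=img)
    px_um = plane.pixel_size_nm / 1000.0
    rows = []
    spot_id = 0
    for r in regions:
        if r.area < p.min_area_px:
            continue
        if p.max_area_px is not None and r.area > p.max_area_px:
            continue
        spot_id += 1
        cy, cx = r.centroid
        parent = int(parent_labels[int(round(cy)), int(round(cx))])
        rows.append({
            "spot_id": spot_id,
            "parent_cell_id": parent,
            "channel": plane.channel,
            "source_file": source_file,
            "tile_index": tile_index,
            "centroid_x_px": float(cx),
            "centroid_y_px": float(cy),
            "area_um2": float(r.area) * px_um ** 2,
            "area_px": int(r.area),
            "circularity": float(_crofton_circularity(r)),
            "mean_intensity": float(r.intensity_mean),
            "integrated_intensity": float(r.intensity_mean * r.area),
        })
    cols = ["spot_id", "parent_cell_id", "channel", "source_file", "tile_index",
            "centroid_x_px", "centroid_y_px", "area_um2", "area_px",
            "circularity", "mean_intensity", "integrated_intensity"]
    return pd.DataFrame(rows, columns=cols)
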