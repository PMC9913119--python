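"""Cross-modality registration in physical coordinates.

Widefield, confocal, relay-lens widefield and reconstructed SMLM images are
sampled at different pixel sizes (65 nm for high-resolution widefield and
confocal, 160 nm for the relay-lens camera used during SMLM acquisition).
All transforms here therefore live in physical nanometers, so an estimated
displacement is meaningful regardless of which grid it was measured on.

The model hierarchy is translation < rigid < similarity; a similarity maps
a point ``p`` (nm) to ``scale * R(rotation) @ p + t``.  Similarity fits use
the closed-form least-squares (Procrustes with scale) solution — no
iterative optimizer, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io_formats import ImagePlane

__all__ = [
    "Transform2D",
    "resample_to_common_grid",
    "estimate_translation",
    "estimate_landmark_transform",
    "compose",
    "apply_transform",
]

_MODELS = ("translation", "rigid", "similarity")


@dataclass(frozen=True)
class Transform2D:
    """Similarity transform in physical (nm) coordinates.

    ``p' = scale * R(rotation_rad) @ p + (tx_nm, ty_nm)`` with points as
    (x, y) pairs in nm.
    """

    model: str = "translation"
    tx_nm: float = 0.0
    ty_nm: float = 0.0
    rotation_rad: float = 0.0
    scale: float = 1.0
    residual_rms_nm: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown transform model {self.model!r}")
        if not (self.scale > 0):
            raise ValueError("scale must be > 0")
        if self.model == "translation" and (self.rotation_rad != 0 or self.scale != 1):
            raise ValueError("translation model admits no rotation or scale")
        if self.model == "rigid" and self.scale != 1:
            raise ValueError("rigid model admits no scale")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return np.array([
            [self.scale * c, -self.scale * s, self.tx_nm],
            [self.scale * s, self.scale * c, self.ty_nm],
            [0.0, 0.0, 1.0]])

    def apply(self, points_nm: np.ndarray) -> np.ndarray:
        """Map (N, 2) points in nm through the transform (exact, no
        interpolation)."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out if np.asarray(points_nm).ndim == 2 else out[0]

    def inverse(self) -> "Transform2D":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation_rad
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        tx, ty = -inv_scale * (c * self.tx_nm - s * self.ty_nm), \
                 -inv_scale * (s * self.tx_nm + c * self.ty_nm)
        return Transform2D(self.model, tx, ty,
                           0.0 if self.model == "translation" else inv_rot,
                           1.0 if self.model in ("translation", "rigid") else inv_scale)

    def to_dict(self) -> dict:
        return {"model": self.model, "tx_nm": self.tx_nm, "ty_nm": self.ty_nm,
                "rotation_rad": self.rotation_rad, "scale": self.scale,
                "residual_rms_nm": self.residual_rms_nm,
                "low_confidence": self.low_confidence}

    @staticmethod
    def from_dict(d: dict) -> "Transform2D":
        return Transform2D(d.get("model", "translation"), d.get("tx_nm", 0.0),
                           d.get("ty_nm", 0.0), d.get("rotation_rad", 0.0),
                           d.get("scale", 1.0), d.get("residual_rms_nm"),
                           d.get("low_confidence", False))


def compose(*transforms: Transform2D) -> Transform2D:
    """Single transform equal to applying *transforms* left to right.

    ``compose(T1, T2).apply(p) == T2.apply(T1.apply(p))``.  The result
    model is the widest of the operands (translation < rigid < similarity).
    """
    if not transforms:
        return Transform2D()
    mat = np.eye(3)
    for t in transforms:
        mat = t.matrix @ mat
    model = _MODELS[max(_MODELS.index(t.model) for t in transforms)]
    scale = float(np.hypot(mat[0, 0], mat[1, 0]))
    rot = float(np.arctan2(mat[1, 0], mat[0, 0]))
    if model == "translation":
        rot, scale = 0.0, 1.0
    elif model == "rigid":
        scale = 1.0
    return Transform2D(model, float(mat[0, 2]), float(mat[1, 2]), rot, scale)


# ---------------------------------------------------------------------------
# image-grid geometry
# ---------------------------------------------------------------------------


def _origin_nm(plane: ImagePlane) -> np.ndarray:
    if plane.origin_stage_um is None:
        return np.zeros(2)
    return np.asarray(plane.origin_stage_um, dtype=float) * 1000.0


def resample_to_common_grid(plane_a: ImagePlane, plane_b: ImagePlane
                            ) -> tuple[ImagePlane, ImagePlane]:
    """Bring two calibrated planes onto a common grid.

    The coarser plane is resampled (bilinear) to the finer pixel size over
    the overlapping physical extent; physical origins are preserved.  With
    equal pixel sizes and origins both planes are returned unchanged.
    """
    pa, pb = plane_a, plane_b
    oa, ob = _origin_nm(pa), _origin_nm(pb)
    if pa.pixel_size_nm == pb.pixel_size_nm and np.allclose(oa, ob) \
            and pa.shape == pb.shape:
        return pa, pb
    fine = min(pa.pixel_size_nm, pb.pixel_size_nm)
    # overlapping physical extent (x = columns, y = rows)
    lo = np.maximum(oa, ob)
    hi = np.minimum(oa + np.array([pa.shape[1] * pa.pixel_size_nm,
                                   pa.shape[0] * pa.pixel_size_nm]),
                    ob + np.array([pb.shape[1] * pb.pixel_size_nm,
                                   pb.shape[0] * pb.pixel_size_nm]))
    if np.any(hi <= lo):
        raise ValueError("planes share no physical overlap")
    n_cols = int(np.floor((hi[0] - lo[0]) / fine))
    n_rows = int(np.floor((hi[1] - lo[1]) / fine))

    def sample(plane: ImagePlane, origin: np.ndarray) -> ImagePlane:
        # pixel-center convention: center of (i, j) at origin + (j+.5, i+.5)*px
        jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        x = lo[0] + (jj + 0.5) * fine
        y = lo[1] + (ii + 0.5) * fine
        col = (x - origin[0]) / plane.pixel_size_nm - 0.5
        row = (y - origin[1]) / plane.pixel_size_nm - 0.5
        vals = ndimage.map_coordinates(plane.pixels, [row, col], order=1,
                                       mode="nearest")
        return ImagePlane(vals, fine, plane.channel,
                          tuple(lo / 1000.0))

    return sample(pa, oa), sample(pb, ob)


def estimate_translation(plane_a: ImagePlane, plane_b: ImagePlane,
                         upsample_factor: int = 100,
                         confidence_floor: float = 0.03) -> Transform2D:
    """Estimate the translation carrying *plane_a* onto *plane_b*.

    Planes are first brought onto a common grid; the shift is the
    subpixel-refined phase-correlation peak, returned in nm.  A weak
    correlation peak sets ``low_confidence`` rather than failing.
    """
    a, b = resample_to_common_grid(plane_a, plane_b)
    px = a.pixel_size_nm
    shift, error, _ = phase_cross_correlation(
        b.pixels.astype(float), a.pixels.astype(float),
        upsample_factor=upsample_factor, normalization=None)
    # shift is (row, col) of a relative to b; transform maps a -> b in (x, y)
    tx, ty = float(shift[1] * px), float(shift[0] * px)
    # normalized peak height as a confidence proxy
    conf = 1.0 - float(error) if np.isfinite(error) else 0.0
    return Transform2D("translation", tx, ty,
                       low_confidence=bool(conf < confidence_floor))


def estimate_landmark_transform(points_a_nm: np.ndarray, points_b_nm: np.ndarray,
                                model: str = "translation") -> Transform2D:
    """Least-squares fit of *model* mapping paired landmarks A -> B.

    Uses the closed-form solutions: mean displacement for translation and
    the Procrustes/Umeyama solution for rigid and similarity.  Returns the
    residual RMS in nm.
    """
    A = np.atleast_2d(np.asarray(points_a_nm, dtype=float))
    B = np.atleast_2d(np.asarray(points_b_nm, dtype=float))
    if A.shape != B.shape or A.shape[1] != 2:
        raise ValueError("point sets must be matching (N, 2) arrays")
    n = len(A)
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "translation":
        if n < 1:
            raise ValueError("translation needs >= 1 pair")
        t = B.mean(axis=0) - A.mean(axis=0)
        fitted = Transform2D("translation", float(t[0]), float(t[1]))
    else:
        if n < 2:
            raise ValueError(f"{model} needs >= 2 pairs")
        mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
        Ac, Bc = A - mu_a, B - mu_b
        var_a = (Ac ** 2).sum() / n
        if var_a == 0:
            raise ValueError("degenerate landmark configuration (coincident points)")
        cov = Bc.T @ Ac / n
        U, D, Vt = np.linalg.svd(cov)
        S = np.eye(2)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            S[1, 1] = -1.0
        R = U @ S @ Vt
        scale = float(np.trace(np.diag(D) @ S) / var_a) if model == "similarity" else 1.0
        if scale <= 0:
            raise ValueError("degenerate landmark configuration (non-positive scale)")
        t = mu_b - scale * R @ mu_a
        rot = float(np.arctan2(R[1, 0], R[0, 0]))
        fitted = Transform2D(model, float(t[0]), float(t[1]), rot, scale)
    resid = fitted.apply(A) - B
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return Transform2D(fitted.model, fitted.tx_nm, fitted.ty_nm,
                       fitted.rotation_rad, fitted.scale, residual_rms_nm=rms)


def apply_transform(target, transform: Transform2D):
    """Apply *transform* to an :class:`ImagePlane` or a localization table.

    Localization coordinates are mapped exactly; images are resampled with
    bilinear interpolation onto their own grid (out-of-frame = 0).
    """
    from .io_formats import LocalizationTable  # local to avoid cycle at import

    if isinstance(target, LocalizationTable):
        out = transform.apply(target.xy_nm)
        return target.with_xy(out[:, 0], out[:, 1])
    if isinstance(target, ImagePlane):
        inv = transform.inverse()
        px = target.pixel_size_nm
        origin = _origin_nm(target)
        ii, jj = np.meshgrid(np.arange(target.shape[0]),
                             np.arange(target.shape[1]), indexing="ij")
        x = origin[0] + (jj + 0.5) * px
        y = origin[1] + (ii + 0.5) * px
        src = inv.apply(np.column_stack([x.ravel(), y.ravel()]))
        col = (src[:, 0] - origin[0]) / px - 0.5
        row = (src[:, 1] - origin[1]) / px - 0.5
        vals = ndimage.map_coordinates(target.pixels, [row, col], order=1,
                                       mode="constant", cval=0.0)
        return ImagePlane(np.clip(vals.reshape(target.shape), 0, None), px,
                          target.channel, target.origin_stage_um)
    raise TypeError(f"cannot transform object of type {type(target)!r}")
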