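"""Readers and writers for every external artifact the pipeline touches.

All other modules exchange the in-memory containers defined here
(:class:`ImagePlane`, :class:`ImageStack`, :class:`LocalizationTable`,
:class:`PositionList`) and never parse files themselves.  Conventions fixed
once, used everywhere:

* pixel coordinates are 0-based with a pixel-*center* convention: the
  physical position of the center of pixel ``(row i, col j)`` is
  ``origin + ((j + 0.5), (i + 0.5)) * pixel_size``;
* images are TIFF with pixel-size metadata embedded in the image
  description (plain ``tifffile`` shaped metadata), localization tables are
  CSV in a ThunderSTORM-style dialect, single-cell repositories are
  tab-delimited text, position lists are CSV in micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImagePlane",
    "ImageStack",
    "LocalizationTable",
    "PositionList",
    "CalibrationError",
    "FormatError",
    "SchemaError",
    "read_image",
    "write_image",
    "read_localizations",
    "write_localizations",
    "read_cell_table",
    "write_cell_table",
    "read_position_list",
    "write_position_list",
    "THUNDERSTORM_DIALECT",
]


class CalibrationError(ValueError):
    """Pixel size / stage calibration missing or inconsistent."""


class FormatError(ValueError):
    """File is not in the expected format."""


class SchemaError(ValueError):
    """Tabular input is missing mandatory columns or violates invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImagePlane:
    """A single calibrated 2D image channel.

    Parameters
    ----------
    pixels:
        2D array of finite, non-negative intensities.
    pixel_size_nm:
        Physical edge length of one pixel in nanometers (> 0).
    channel:
        Channel name, e.g. ``"DNA"``.
    origin_stage_um:
        Optional stage position (x, y) in micrometers of the corner of
        pixel (0, 0).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    origin_stage_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if not (self.pixel_size_nm > 0):
            raise CalibrationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (height, width) of the plane in nm."""
        return (self.pixels.shape[0] * self.pixel_size_nm,
                self.pixels.shape[1] * self.pixel_size_nm)


@dataclass
class ImageStack:
    """An ordered collection of :class:`ImagePlane` per (channel, z).

    Planes are stored channel-major: ``planes[c * nz + z]``.  All planes
    share dimensions and pixel size.
    """

    planes: list[ImagePlane]
    z_step_nm: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ImageStack requires at least one plane")
        if not (self.z_step_nm > 0):
            raise CalibrationError("z_step_nm must be > 0")
        first = self.planes[0]
        for p in self.planes:
            if p.shape != first.shape:
                raise ValueError("all planes must share dimensions")
            if p.pixel_size_nm != first.pixel_size_nm:
                raise CalibrationError("all planes must share pixel_size_nm")
        if not self.channel_names:
            seen: list[str] = []
            for p in self.planes:
                if p.channel not in seen:
                    seen.append(p.channel)
            self.channel_names = seen
        if len(self.planes) % max(len(self.channel_names), 1):
            raise ValueError("plane count must be n_channels * n_z")

    @property
    def pixel_size_nm(self) -> float:
        return self.planes[0].pixel_size_nm

    @property
    def n_z(self) -> int:
        return len(self.planes) // len(self.channel_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    def plane(self, channel: str, z: int = 0) -> ImagePlane:
        c = self.channel_names.index(channel)
        return self.planes[c * self.n_z + z]

    def as_array(self) -> np.ndarray:
        """Stack as a (C, Z, Y, X) array."""
        nz = self.n_z
        arr = np.stack([p.pixels for p in self.planes])
        return arr.reshape(len(self.channel_names), nz, *self.shape)


#: ThunderSTORM-style localization CSV column mapping (open, documented
#: dialect; vendor dialects are remapped through the same mechanism).
THUNDERSTORM_DIALECT: dict[str, str] = {
    "channel": "channel",
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "photons": "intensity [photon]",
    "background": "offset [photon]",
    "precision_nm": "uncertainty [nm]",
}

_LOC_COLUMNS = ["channel", "frame", "x_nm", "y_nm", "sigma_nm",
                "photons", "background", "precision_nm"]
_LOC_MANDATORY = ["frame", "x_nm", "y_nm", "photons"]
_LOC_DEFAULTS = {"channel": "ch0", "sigma_nm": 150.0, "background": 0.0,
                 "precision_nm": 10.0}


class LocalizationTable:
    """Per-molecule records: the single-molecule-localization currency.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    columns ``channel, frame, x_nm, y_nm, sigma_nm, photons, background,
    precision_nm`` and the invariants frame >= 0, photons > 0,
    sigma_nm > 0, precision_nm > 0, background >= 0.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col in _LOC_COLUMNS:
            if col not in df.columns:
                if col in _LOC_DEFAULTS:
                    df[col] = _LOC_DEFAULTS[col]
                else:
                    raise SchemaError(f"missing mandatory localization column {col!r}")
        df = df[_LOC_COLUMNS]
        df["frame"] = df["frame"].astype(np.int64)
        for col in _LOC_COLUMNS[2:]:
            df[col] = df[col].astype(float)
        if validate and len(df):
            bad = {}
            if (df["frame"] < 0).any():
                bad["frame"] = df.index[df["frame"] < 0].tolist()
            if (df["photons"] <= 0).any():
                bad["photons"] = df.index[df["photons"] <= 0].tolist()
            if (df["sigma_nm"] <= 0).any():
                bad["sigma_nm"] = df.index[df["sigma_nm"] <= 0].tolist()
            if (df["precision_nm"] <= 0).any():
                bad["precision_nm"] = df.index[df["precision_nm"] <= 0].tolist()
            if (df["background"] < 0).any():
                bad["background"] = df.index[df["background"] < 0].tolist()
            if bad:
                rows = sorted({i for v in bad.values() for i in v})
                raise SchemaError(
                    f"invalid localization records (columns {sorted(bad)}) in rows {rows[:20]}"
                    + ("..." if len(rows) > 20 else ""))
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:  # record-wise comparison
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        return bool(
            (self.df["channel"].values == other.df["channel"].values).all()
            and (self.df["frame"].values == other.df["frame"].values).all()
            and np.allclose(self.df[_LOC_COLUMNS[2:]].values,
                            other.df[_LOC_COLUMNS[2:]].values, atol=1e-9))

    @property
    def xy_nm(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy()

    def select_channel(self, channel: str) -> "LocalizationTable":
        return LocalizationTable(self.df[self.df["channel"] == channel], validate=False)

    def with_xy(self, x_nm: np.ndarray, y_nm: np.ndarray) -> "LocalizationTable":
        df = self.df.copy()
        df["x_nm"] = np.asarray(x_nm, dtype=float)
        df["y_nm"] = np.asarray(y_nm, dtype=float)
        return LocalizationTable(df, validate=False)

    @staticmethod
    def from_arrays(x_nm, y_nm, frame=0, channel="ch0", sigma_nm=150.0,
                    photons=1000.0, background=0.0, precision_nm=10.0
                    ) -> "LocalizationTable":
        x = np.atleast_1d(np.asarray(x_nm, dtype=float))
        n = len(x)

        def bc(v, dtype=float):
            a = np.asarray(v)
            return np.broadcast_to(a, (n,)).astype(dtype).copy()

        df = pd.DataFrame({
            "channel": bc(channel, object), "frame": bc(frame, np.int64),
            "x_nm": x, "y_nm": bc(y_nm), "sigma_nm": bc(sigma_nm),
            "photons": bc(photons), "background": bc(background),
            "precision_nm": bc(precision_nm)})
        return LocalizationTable(df)

    @staticmethod
    def concat(tables: list["LocalizationTable"]) -> "LocalizationTable":
        if not tables:
            return LocalizationTable(pd.DataFrame(
                {c: pd.Series(dtype=object if c == "channel" else float)
                 for c in _LOC_COLUMNS}), validate=False)
        return LocalizationTable(
            pd.concat([t.df for t in tables], ignore_index=True), validate=False)


@dataclass
class PositionList:
    """Ordered stage positions the microscope visits for re-acquisition."""

    df: pd.DataFrame  # columns: label, stage_x_um, stage_y_um[, stage_z_um]

    def __post_init__(self) -> None:
        required = {"label", "stage_x_um", "stage_y_um"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"position list missing columns {sorted(missing)}")
        if self.df["label"].duplicated().any():
            dup = self.df["label"][self.df["label"].duplicated()].tolist()
            raise SchemaError(f"duplicate position labels {dup}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as TIFF with calibration metadata.

    Data layout on disk is (C, Z, Y, X); pixel size, z-step, channel names
    and stage origin travel in the image description.
    """
    arr = stack.as_array()
    origin = stack.planes[0].origin_stage_um
    meta = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "z_step_nm": float(stack.z_step_nm),
        "channel_names": list(stack.channel_names),
        "origin_stage_um": list(origin) if origin is not None else None,
    }
    tifffile.imwrite(path, arr, metadata=meta)


def read_image(path, pixel_size_nm: float | None = None,
               z_step_nm: float | None = None,
               channel_names: list[str] | None = None) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Calibration is taken from the embedded metadata written by
    :func:`write_image`; the keyword overrides act as the side-car config
    for third-party files.  A file without a resolvable pixel size raises
    :class:`CalibrationError`.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from None
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel-size metadata and no override supplied")
    zs = z_step_nm if z_step_nm is not None else meta.get("z_step_nm", 1.0)
    names = channel_names if channel_names is not None else meta.get("channel_names")
    origin = meta.get("origin_stage_um")
    origin = tuple(origin) if origin is not None else None

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:  # ambiguous: treat leading axis as channels
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    nc, nz = arr.shape[:2]
    if names is None:
        names = [f"ch{i}" for i in range(nc)]
    if len(names) != nc:
        raise CalibrationError(
            f"{path}: {nc} channels in data but {len(names)} channel names")
    planes = [ImagePlane(arr[c, z].astype(np.float64), float(px), names[c],
                         origin)
              for c in range(nc) for z in range(nz)]
    return ImageStack(planes, z_step_nm=float(zs), channel_names=list(names))


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------


def write_localizations(table: LocalizationTable, path,
                        dialect: dict[str, str] = THUNDERSTORM_DIALECT) -> None:
    """Write a localization table as CSV using *dialect* column names."""
    out = table.df.rename(columns=dialect)
    out.to_csv(path, index=False)


def read_localizations(path, dialect: dict[str, str] = THUNDERSTORM_DIALECT
                       ) -> LocalizationTable:
    """Read a localization CSV.

    *dialect* maps canonical field names to the file's column headers
    (default ThunderSTORM-style).  Mandatory fields: frame, x, y, photons;
    the rest get documented defaults.  Invalid records raise
    :class:`SchemaError` listing offending rows.
    """
    try:
        raw = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a readable CSV: {exc}") from None
    inverse = {v: k for k, v in dialect.items()}
    df = raw.rename(columns=inverse)
    missing = [dialect[c] for c in _LOC_MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return LocalizationTable(df[[c for c in _LOC_COLUMNS if c in df.columns]])


# ---------------------------------------------------------------------------
# cell / spot tables (tab-delimited single-cell repository)
# ---------------------------------------------------------------------------


def write_cell_table(table: pd.DataFrame, path, id_column: str = "cell_id") -> None:
    """Write the single-cell (or spot) repository as tab-delimited text.

    One row per event, one column per measurement.  Duplicate identifiers
    and embedded tabs are rejected so the file round-trips losslessly.
    """
    if id_column not in table.columns:
        raise SchemaError(f"table lacks identifier column {id_column!r}")
    if table[id_column].duplicated().any():
        dup = table[id_column][table[id_column].duplicated()].tolist()
        raise SchemaError(f"duplicate identifiers: {dup[:10]}")
    for col in table.columns:
        if table[col].dtype == object:
            vals = table[col].astype(str)
            if vals.str.contains("\t").any():
                raise SchemaError(f"column {col!r} contains tab characters")
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_cell_table(path, id_column: str = "cell_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise SchemaError(f"{path}: lacks identifier column {id_column!r}")
    if df[id_column].duplicated().any():
        raise SchemaError(f"{path}: duplicate identifiers")
    return df


# ---------------------------------------------------------------------------
# position lists
# ---------------------------------------------------------------------------

#: Known position-list output formats.  ``generic`` is the documented CSV
#: dialect; per-vendor customization plugs in here.
_POSITION_FORMATS = ("generic",)


def write_position_list(positions: PositionList, path, format: str = "generic") -> None:
    """Emit a position list CSV (micrometer values).

    The *format* tag is the per-setup customization point; unknown tags
    raise a configuration error rather than guessing a vendor schema.
    """
    if format not in _POSITION_FORMATS:
        raise ValueError(
            f"unknown position-list format {format!r}; known: {_POSITION_FORMATS}")
    positions.df.to_csv(path, index=False, float_format="%.9g")


def read_position_list(path) -> PositionList:
    return PositionList(pd.read_csv(path))
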