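"""Convert gated events' image coordinates to absolute stage positions.

This is the correlative hinge of the pipeline: a cell selected in the
high-statistics widefield pass is physically re-positioned under the
objective for confocal / SMLM re-acquisition.  All stage math is in
micrometers (stage native); pixel sizes are in nanometers with a fixed
1000 nm/um conversion.  Tile offsets are the stage position of each
tile's pixel (0, 0) *corner*; pixel centers sit half a pixel in (the
package-wide pixel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_formats import PositionList

__all__ = [
    "StageCalibration",
    "image_to_stage",
    "stage_to_image",
    "build_position_list",
]


@dataclass
class StageCalibration:
    """Per-setup mapping between pixel and stage coordinates.

    tile_offsets_um maps tile_index -> stage (x, y) um of that tile's
    pixel-origin corner.  sign_x / sign_y absorb per-brand stage axis
    conventions; swap_xy (applied last) absorbs transposed cameras.
    """

    pixel_size_nm: float
    tile_offsets_um: dict[int, tuple[float, float]] = field(default_factory=dict)
    sign_x: int = 1
    sign_y: int = 1
    swap_xy: bool = False

    def __post_init__(self) -> None:
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be > 0")
        if self.sign_x not in (1, -1) or self.sign_y not in (1, -1):
            raise ValueError("axis signs must be +1 or -1")

    @staticmethod
    def from_yaml(path) -> "StageCalibration":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        offsets = {int(k): tuple(v) for k, v in d.get("tile_offsets_um", {}).items()}
        return StageCalibration(pixel_size_nm=float(d["pixel_size_nm"]),
                                tile_offsets_um=offsets,
                                sign_x=int(d.get("sign_x", 1)),
                                sign_y=int(d.get("sign_y", 1)),
                                swap_xy=bool(d.get("swap_xy", False)))

    def to_yaml(self, path) -> None:
        d = {"pixel_size_nm": self.pixel_size_nm,
             "tile_offsets_um": {int(k): list(map(float, v))
                                 for k, v in self.tile_offsets_um.items()},
             "sign_x": self.sign_x, "sign_y": self.sign_y,
             "swap_xy": self.swap_xy}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def _offset(self, tile_index: int) -> np.ndarray:
        if tile_index not in self.tile_offsets_um:
            raise KeyError(f"tile {tile_index} not in calibration "
                           f"(known: {sorted(self.tile_offsets_um)})")
        return np.asarray(self.tile_offsets_um[tile_index], dtype=float)


def image_to_stage(centroid_px, tile_index: int,
                   calibration: StageCalibration) -> np.ndarray:
    """Map pixel centroid(s) (x, y) in a tile to stage (x, y) in um.

    ``stage = tile_offset + swap(sign * (centroid_px + 0.5) * pixel_size_um)``:
    the optional axis swap applies to the pixel-to-stage mapping (last step
    of the conversion); tile offsets are stage-native, so translating every
    offset translates every output identically.
    """
    c = np.atleast_2d(np.asarray(centroid_px, dtype=float))
    off = calibration._offset(tile_index)
    px_um = calibration.pixel_size_nm / 1000.0
    signs = np.array([calibration.sign_x, calibration.sign_y], dtype=float)
    term = signs * (c + 0.5) * px_um
    if calibration.swap_xy:
        term = term[:, ::-1]
    stage = off + term
    return stage if np.asarray(centroid_px).ndim == 2 else stage[0]


def stage_to_image(stage_um, tile_index: int,
                   calibration: StageCalibration) -> np.ndarray:
    """Exact inverse of :func:`image_to_stage`."""
    s = np.atleast_2d(np.asarray(stage_um, dtype=float))
    off = calibration._offset(tile_index)
    term = s - off
    if calibration.swap_xy:
        term = term[:, ::-1]
    px_um = calibration.pixel_size_nm / 1000.0
    signs = np.array([calibration.sign_x, calibration.sign_y], dtype=float)
    c = term / (signs * px_um) - 0.5
    return c if np.asarray(stage_um).ndim == 2 else c[0]


def build_position_list(event_ids, cell_table: pd.DataFrame,
                        calibration: StageCalibration
                        ) -> tuple[PositionList, list]:
    """One stage position per selected event, labels = cell ids.

    Events whose tile is missing from the calibration are skipped and
    returned in the second element; order is deterministic (input order of
    *event_ids*).
    """
    indexed = cell_table.set_index("cell_id")
    rows = []
    skipped = []
    for cid in event_ids:
        rec = indexed.loc[cid]
        tile = int(rec["tile_index"])
        if tile not in calibration.tile_offsets_um:
            skipped.append(cid)
            continue
        xy = image_to_stage((float(rec["centroid_x_px"]),
                             float(rec["centroid_y_px"])), tile, calibration)
        rows.append({"label": str(cid), "stage_x_um": float(xy[0]),
                     "stage_y_um": float(xy[1])})
    df = pd.DataFrame(rows, columns=["label", "stage_x_um", "stage_y_um"])
    return PositionList(df), skipped
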