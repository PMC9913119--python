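"""Shared fixtures: phantom datasets pushed through the measurement chain.

The heavier phantoms are session-scoped so module tests and the
whole-pipeline checks share one computation.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from cytocorr import cytometry as cyto
from cytocorr import phantom as ph
from cytocorr.io_formats import ImageStack

ROLLING_BALL_RADIUS = 50
SEG_PARAMS = cyto.SegmentationParams(min_area_px=100)


def run_cytometry_tile(stack: ImageStack, truth_cells: pd.DataFrame,
                       tile_index: int = 0) -> pd.DataFrame:
    """Background-subtract, segment, measure one tile and attach truth by
    nearest-centroid matching."""
    planes = {ch: cyto.subtract_background(stack.plane(ch), ROLLING_BALL_RADIUS)
              for ch in stack.channel_names}
    labels = cyto.segment_nuclei(planes["DNA"], SEG_PARAMS)
    cells = cyto.measure_cells(
        labels, ImageStack(list(planes.values()), channel_names=list(planes)),
        tile_index=tile_index)
    if len(cells):
        tree = cKDTree(truth_cells[["centroid_x_px", "centroid_y_px"]].to_numpy())
        d, idx = tree.query(cells[["centroid_x_px", "centroid_y_px"]].to_numpy())
        cells["match_dist_px"] = d
        cells["phase_true"] = truth_cells["phase"].to_numpy()[idx]
        cells["dna_true"] = truth_cells["dna_integral"].to_numpy()[idx]
        cells["large_focus_true"] = truth_cells["large_focus"].to_numpy()[idx]
        cells["cell_id"] = tile_index * 100000 + cells["cell_id"]
    return cells


@pytest.fixture(scope="session")
def population_500():
    """500 non-touching cells, fixed seed, plus its measured repository."""
    cfg = ph.PhantomConfig(n_cells=500)
    stack, truth = ph.generate_population(cfg, seed=1)
    t0 = time.perf_counter()
    cells = run_cytometry_tile(stack, truth.cells)
    elapsed = time.perf_counter() - t0
    return {"config": cfg, "stack": stack, "truth": truth.cells,
            "cells": cells, "measure_seconds": elapsed}


@pytest.fixture(scope="session")
def classified_2000():
    """2000 cells over 4 tiles (fractions 0.60/0.25/0.15, 20% of G2M
    mitotic), measured and truth-matched."""
    cfg = ph.PhantomConfig(n_cells=500)
    t0 = time.perf_counter()
    tables = []
    truths = []
    for t in range(4):
        stack, truth = ph.generate_population(cfg, seed=2, tile_index=t)
        tables.append(run_cytometry_tile(stack, truth.cells, tile_index=t))
        truths.append(truth.cells)
    elapsed = time.perf_counter() - t0
    return {"cells": pd.concat(tables, ignore_index=True),
            "truth": pd.concat(truths, ignore_index=True),
            "pipeline_seconds": elapsed}


@pytest.fixture(scope="session")
def drift_movie():
    """Single always-on emitter, 15000 frames, 100 nm linear drift,
    3 fiducials every 1000 frames with 2 nm jitter — fitted end to end."""
    from cytocorr import smlm

    cfg = ph.SMLMConfig(n_emitters=1, frames=15000, fov_nm=(3200.0, 3200.0),
                        always_on=True, n_fiducials=3, cadence_k=1000,
                        fiducial_jitter_nm=2.0, drift_model="linear",
                        drift_total_nm=(100.0, 100.0))
    t0 = time.perf_counter()
    frames, truth_locs, truth = ph.generate_smlm_movie(cfg, seed=3)
    locs = smlm.fit_localizations(frames)
    fid = smlm.fit_localizations(truth.fiducial_frames,
                                 smlm.FitParams(channel="fiducial"))
    fid.df["frame"] = np.asarray(truth.anchor_frames)[fid.df["frame"].to_numpy()]
    traj = smlm.track_fiducials(fid, cfg.cadence_k)
    corrected = smlm.correct_drift(locs, traj)
    elapsed = time.perf_counter() - t0
    return {"config": cfg, "truth": truth, "locs": locs, "traj": traj,
            "corrected": corrected, "seconds": elapsed}
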