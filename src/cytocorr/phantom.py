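"""Synthetic phantoms with ground truth for every pipeline stage.

No raw data accompany the imaging protocol this package models, so every
stage is exercised against simulated inputs that emulate the relevant
features of the real experiment:

* asynchronous cell populations with G1/S/G2 DNA-content structure,
  S-phase EdU incorporation, mitotic morphology (condensed DNA, reduced
  area, high circularity, bright damage-marker signal), nuclear foci with
  a G1-restricted large-focus subpopulation, and sparse proximity-assay
  spots;
* blinking-emitter SMLM movies with always-on fiducial markers recorded
  once every ``cadence_k`` frames and global stage drift;
* two-channel point patterns with a controlled colocalized fraction;
* image pairs related by a known physical transform at two pixel sizes.

Every generator takes a single integer seed, expanded into independent
substreams per component so adding one channel never perturbs another,
and returns a :class:`PhantomTruth` carrying the exact ground truth.
Fixed seed means bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import ImagePlane, ImageStack, LocalizationTable
from .registration import Transform2D

__all__ = [
    "PhantomConfig",
    "SMLMConfig",
    "PhantomTruth",
    "generate_population",
    "generate_smlm_movie",
    "generate_two_channel_points",
    "generate_registration_pair",
    "random_blob_image",
    "filament_image",
]

# substream tags (never reorder: regression stability)
_S_PLACE, _S_PHASE, _S_DNA, _S_SHAPE, _S_FOCI, _S_NOISE = range(6)
_S_EMIT, _S_BLINK, _S_DRIFT, _S_CAMERA, _S_FID = range(10, 15)
_S_POINTS = 20
_S_REG = 30


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cell-population phantom.

    Defaults describe an asynchronous, exponentially growing epithelial
    population imaged at moderate magnification: 60 % G1, 25 % S, 15 %
    G2/M with one fifth of the G2/M pool in mitosis; G1 DNA integral
    ``dna_g1_mean`` with coefficient of variation ``dna_cv`` (staining and
    measurement spread), G2 at twice G1, and S-phase integrals uniform
    between the G1 and G2 windows; ~10 um nuclei on a 0.325 um pixel grid.
    """

    n_cells: int = 500
    phase_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)  # G1, S, G2M
    mitotic_fraction: float = 0.20  # of the G2M pool
    dna_g1_mean: float = 45000.0
    dna_cv: float = 0.10
    s_lo: float = 1.30          # S integral window, in units of the G1 mean
    s_hi: float = 1.55
    dna_density: float = 60.0   # interphase chromatin intensity per pixel
    axis_ratio_range: tuple[float, float] = (1.25, 1.6)
    boundary_roughness: float = 0.03
    mitotic_area_factor: float = 0.35  # condensed-chromatin area vs interphase
    edu_s_mean: float = 40.0
    marker_m_mean: float = 60.0
    marker_base_mean: float = 2.0
    foci_rate: float = 5.0
    focus_sigma_px: float = 1.6
    focus_amplitude: float = 120.0
    large_focus_fraction: float = 0.30  # of G1 cells
    large_focus_sigma_px: float = 3.5
    large_focus_amplitude: float = 400.0
    pla_rate: float = 2.0
    image_size: tuple[int, int] = (2048, 2048)
    pixel_size_nm: float = 325.0
    background: float = 10.0
    read_noise: float = 2.0
    camera_noise: bool = True
    touching_cells: bool = False  # robustness mode: jitter cells into contact

    def __post_init__(self) -> None:
        f = self.phase_fractions
        if any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("phase fractions must be non-negative and sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class SMLMConfig:
    """Parameters of the blinking-emitter SMLM movie phantom.

    Defaults follow the acquisition this models: 15000 frames in
    continuous mode with fiducial-marker frames once every 1000 frames,
    camera pixel 160 nm (relay-lens sampling) and a ~150 nm PSF sigma.
    Blinking is a two-state on/off Markov chain; the protocol itself
    reports no quantitative switching rates, so the defaults are free
    parameters chosen for a sparse, fittable phantom.
    """

    n_emitters: int = 20
    frames: int = 15000
    fov_nm: tuple[float, float] = (5120.0, 5120.0)
    pixel_size_nm: float = 160.0
    psf_sigma_nm: float = 150.0
    photons_per_frame: float = 3000.0
    background_photons: float = 5.0
    p_on: float = 0.002   # off -> on per frame
    p_off: float = 0.20   # on -> off per frame
    start_on: bool = False
    always_on: bool = False
    n_fiducials: int = 3
    cadence_k: int = 1000
    fiducial_photons: float = 20000.0
    fiducial_min_separation_nm: float = 1500.0  # resolvable, sparse markers
    fiducial_jitter_nm: float = 0.0  # placement noise per anchor observation
    drift_model: str = "linear"      # "linear" | "random_walk" | "none"
    drift_total_nm: tuple[float, float] = (100.0, 100.0)
    drift_step_nm: float = 0.5       # random-walk step sigma
    camera_noise: bool = True
    margin_nm: float = 600.0

    def __post_init__(self) -> None:
        if self.n_emitters < 1:
            raise ValueError("phantom needs at least one emitter")
        if self.n_fiducials > 0 and self.frames < 2 * self.cadence_k:
            raise ValueError("frames must be >= 2 * cadence_k when fiducials are requested")


@dataclass
class PhantomTruth:
    """Ground-truth labels for a synthetic dataset."""

    cells: pd.DataFrame | None = None       # per-cell phase/morphology truth
    emitters: pd.DataFrame | None = None    # per-emitter true positions / pairing
    drift: pd.DataFrame | None = None       # frame -> (dx, dy) nm
    anchor_frames: list[int] = field(default_factory=list)
    fiducial_positions_nm: np.ndarray | None = None
    fiducial_frames: ImageStack | None = None
    pairs: pd.DataFrame | None = None       # colocalized pairing (symmetric)
    transforms: dict[str, Transform2D] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cell population phantom
# ---------------------------------------------------------------------------


def _nucleus_mask(radius: float, axis_ratio: float, angle: float,
                  roughness_coefs: np.ndarray, patch: int) -> np.ndarray:
    """Rasterize one rough-edged elliptical nucleus on a patch grid."""
    c = (patch - 1) / 2.0
    yy, xx = np.mgrid[0:patch, 0:patch]
    dx, dy = xx - c, yy - c
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / axis_ratio     # major axis shrunk to circle
    v = -sa * dx + ca * dy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bump = np.zeros_like(theta)
    for k, (a, ph) in enumerate(roughness_coefs, start=2):
        bump += a * np.cos(k * theta + ph)
    return rho <= radius * (1.0 + bump)


def generate_population(config: PhantomConfig, seed: int, tile_index: int = 0
                        ) -> tuple[ImageStack, PhantomTruth]:
    """Render one field of synthetic cells with full per-cell truth.

    Channels: ``DNA`` (content + condensation), ``EdU`` (S phase),
    ``marker`` (mitosis-bright damage marker), ``foci`` (nuclear spots,
    with a large bright G1-restricted subpopulation), ``PLA`` (sparse
    proximity spots).  Cells are placed on a jittered grid away from the
    image border, so they never touch and are never clipped.
    """
    cfg = config
    h, w = cfg.image_size
    # nuclear area scales with DNA content at constant chromatin density,
    # so the largest (G2) nuclei set the non-overlap pitch
    max_integral = 2 * cfg.dna_g1_mean * (1 + 4 * cfg.dna_cv)
    r_max = np.sqrt(max_integral * cfg.axis_ratio_range[1]
                    / (cfg.dna_density * np.pi)) \
        * (1 + 3 * cfg.boundary_roughness)
    pitch = int(np.ceil(2 * r_max + 6))
    margin = int(np.ceil(r_max + 4))
    nx = (w - 2 * margin) // pitch
    ny = (h - 2 * margin) // pitch
    if nx * ny < cfg.n_cells:
        raise ValueError(
            f"cannot place {cfg.n_cells} non-overlapping cells in a "
            f"{h}x{w} image (capacity {nx * ny}); enlarge image_size")

    rng_place = _rng(seed, _S_PLACE + 100 * tile_index)
    rng_phase = _rng(seed, _S_PHASE + 100 * tile_index)
    rng_dna = _rng(seed, _S_DNA + 100 * tile_index)
    rng_shape = _rng(seed, _S_SHAPE + 100 * tile_index)
    rng_foci = _rng(seed, _S_FOCI + 100 * tile_index)
    rng_noise = _rng(seed, _S_NOISE + 100 * tile_index)

    slots = rng_place.choice(nx * ny, size=cfg.n_cells, replace=False)
    gx, gy = slots % nx, slots // nx
    # default jitter keeps cells apart by construction; the touching-cells
    # robustness mode jitters up to half a pitch so neighbors can contact
    jit_max = pitch / 2.0 if cfg.touching_cells else 2.0
    jit = rng_place.uniform(-jit_max, jit_max, size=(cfg.n_cells, 2))
    cx = margin + gx * pitch + pitch / 2.0 + jit[:, 0]
    cy = margin + gy * pitch + pitch / 2.0 + jit[:, 1]

    # phases: G1 / S / G2 / M
    u = rng_phase.random(cfg.n_cells)
    f_g1, f_s, f_g2m = cfg.phase_fractions
    phase = np.where(u < f_g1, "G1", np.where(u < f_g1 + f_s, "S", "G2"))
    g2m = np.flatnonzero(phase == "G2")
    mitotic = g2m[rng_phase.random(len(g2m)) < cfg.mitotic_fraction]
    phase = phase.astype(object)
    phase[mitotic] = "M"

    # DNA integrals (G2 and M carry twice the G1 content)
    mu = cfg.dna_g1_mean
    integral = np.empty(cfg.n_cells)
    for i in range(cfg.n_cells):
        if phase[i] == "G1":
            integral[i] = rng_dna.normal(mu, cfg.dna_cv * mu)
        elif phase[i] == "S":
            integral[i] = mu * rng_dna.uniform(cfg.s_lo, cfg.s_hi)
        else:
            integral[i] = rng_dna.normal(2 * mu, cfg.dna_cv * 2 * mu)
    integral = np.clip(integral, 0.05 * mu, None)

    channels = ["DNA", "EdU", "marker", "foci", "PLA"]
    imgs = {ch: np.zeros((h, w)) for ch in channels}

    records = []
    for i in range(cfg.n_cells):
        is_m = phase[i] == "M"
        area_target = integral[i] / cfg.dna_density
        if is_m:
            # condensed chromatin: smaller, rounder, brighter per pixel
            area_target *= cfg.mitotic_area_factor
            axis_ratio = rng_shape.uniform(1.0, 1.08)
            rough = np.column_stack([
                rng_shape.uniform(0, cfg.boundary_roughness / 3, 3),
                rng_shape.uniform(0, 2 * np.pi, 3)])
        else:
            axis_ratio = rng_shape.uniform(*cfg.axis_ratio_range)
            rough = np.column_stack([
                rng_shape.uniform(cfg.boundary_roughness / 2, cfg.boundary_roughness, 3),
                rng_shape.uniform(0, 2 * np.pi, 3)])
        radius = max(np.sqrt(area_target / (np.pi * axis_ratio)), 4.0)
        angle = rng_shape.uniform(0, np.pi)
        patch = int(np.ceil(2 * radius * axis_ratio * (1 + 3 * cfg.boundary_roughness))) + 5
        mask = _nucleus_mask(radius, axis_ratio, angle, rough, patch)
        area_px = int(mask.sum())
        y0, x0 = int(round(cy[i] - (patch - 1) / 2)), int(round(cx[i] - (patch - 1) / 2))
        sl = (slice(y0, y0 + patch), slice(x0, x0 + patch))

        dna_per_px = integral[i] / area_px
        imgs["DNA"][sl][mask] += dna_per_px
        if phase[i] == "S":
            imgs["EdU"][sl][mask] += cfg.edu_s_mean
        imgs["marker"][sl][mask] += cfg.marker_m_mean if is_m else cfg.marker_base_mean

        # nuclear foci (interphase only; condensed mitotic chromatin has
        # none); distinct damage sites never coincide, so positions keep a
        # minimum pairwise separation
        n_foci = 0
        has_large = False
        if not is_m:
            n_foci = int(rng_foci.poisson(cfg.foci_rate))
            large_here = (phase[i] == "G1"
                          and rng_foci.random() < cfg.large_focus_fraction)
            positions = _spot_positions(mask, n_foci + int(large_here),
                                        rng_foci, min_separation_px=7.0)
            n_foci = max(len(positions) - int(large_here), 0)
            has_large = large_here and len(positions) > 0
            for k, (py, px_) in enumerate(positions):
                if has_large and k == 0:
                    _draw_spot(imgs["foci"], sl, py, px_,
                               cfg.large_focus_sigma_px,
                               cfg.large_focus_amplitude)
                else:
                    _draw_spot(imgs["foci"], sl, py, px_,
                               cfg.focus_sigma_px, cfg.focus_amplitude)
        n_pla = int(rng_foci.poisson(cfg.pla_rate))
        for py, px_ in _spot_positions(mask, n_pla, rng_foci,
                                       min_separation_px=7.0):
            _draw_spot(imgs["PLA"], sl, py, px_, cfg.focus_sigma_px,
                       cfg.focus_amplitude)

        # true mask centroid in pixel coordinates (pixel-center convention)
        ys, xs = np.nonzero(mask)
        records.append({
            "cell_id": tile_index * 100000 + i + 1,
            "tile_index": tile_index,
            "phase": phase[i],
            "centroid_x_px": x0 + xs.mean(),
            "centroid_y_px": y0 + ys.mean(),
            "dna_integral": integral[i],
            "area_px": area_px,
            "focus_count": n_foci + int(has_large),
            "large_focus": has_large,
        })

    for ch in channels:
        img = imgs[ch] + cfg.background
        if cfg.camera_noise:
            img = rng_noise.poisson(img).astype(float) \
                + rng_noise.normal(0, cfg.read_noise, size=img.shape)
        imgs[ch] = np.clip(img, 0, None)

    planes = [ImagePlane(imgs[ch], cfg.pixel_size_nm, ch) for ch in channels]
    stack = ImageStack(planes, channel_names=channels)
    truth = PhantomTruth(cells=pd.DataFrame(records))
    return stack, truth


def _spot_positions(mask: np.ndarray, n: int, rng: np.random.Generator,
                    min_separation_px: float, max_tries: int = 60
                    ) -> list[tuple[int, int]]:
    """Sample up to *n* spot centers inside the eroded mask with a minimum
    pairwise separation (rejection sampling)."""
    if n <= 0:
        return []
    interior = ndimage.binary_erosion(mask, iterations=4)
    ys, xs = np.nonzero(interior if interior.any() else mask)
    chosen: list[tuple[int, int]] = []
    for _ in range(n):
        for _ in range(max_tries):
            k = int(rng.integers(len(ys)))
            py, px = int(ys[k]), int(xs[k])
            if all((py - q) ** 2 + (px - r) ** 2 >= min_separation_px ** 2
                   for q, r in chosen):
                chosen.append((py, px))
                break
    return chosen


def _draw_spot(canvas: np.ndarray, sl, py: int, px: int, sigma: float,
               amplitude: float) -> None:
    r = int(np.ceil(4 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    spot = amplitude * np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    patch = canvas[sl]
    y0, y1 = max(py - r, 0), min(py + r + 1, patch.shape[0])
    x0, x1 = max(px - r, 0), min(px + r + 1, patch.shape[1])
    patch[y0:y1, x0:x1] += spot[y0 - (py - r):y1 - (py - r),
                                x0 - (px - r):x1 - (px - r)]


# ---------------------------------------------------------------------------
# SMLM movie phantom
# ---------------------------------------------------------------------------


def anchor_frame_indices(frames: int, cadence_k: int) -> list[int]:
    """Fiducial anchor frame indices: every ``cadence_k`` frames, clipped
    into the movie's frame range."""
    raw = np.arange(0, frames + cadence_k, cadence_k)
    clipped = np.minimum(raw[raw <= frames], frames - 1)
    return sorted(set(int(v) for v in clipped))


def _render_frame(shape: tuple[int, int], px: float, xs_nm, ys_nm, photons,
                  sigma_nm: float) -> np.ndarray:
    """Pixel-integrated Gaussian PSF rendering of point emitters."""
    from scipy.special import erf
    img = np.zeros(shape)
    s = sigma_nm
    for x, y, n in zip(np.atleast_1d(xs_nm), np.atleast_1d(ys_nm),
                       np.atleast_1d(photons)):
        r = int(np.ceil(4 * s / px)) + 1
        cj, ci = int(x // px), int(y // px)
        j0, j1 = max(cj - r, 0), min(cj + r + 1, shape[1])
        i0, i1 = max(ci - r, 0), min(ci + r + 1, shape[0])
        if j0 >= j1 or i0 >= i1:
            continue
        edges_x = np.arange(j0, j1 + 1) * px
        edges_y = np.arange(i0, i1 + 1) * px
        fx = 0.5 * (erf((edges_x[1:] - x) / (s * np.sqrt(2)))
                    - erf((edges_x[:-1] - x) / (s * np.sqrt(2))))
        fy = 0.5 * (erf((edges_y[1:] - y) / (s * np.sqrt(2)))
                    - erf((edges_y[:-1] - y) / (s * np.sqrt(2))))
        img[i0:i1, j0:j1] += n * np.outer(fy, fx)
    return img


def drift_at(frames: int, model: str, total_nm, step_nm: float,
             rng: np.random.Generator | None) -> np.ndarray:
    """Per-frame drift trajectory (frames, 2) in nm, zero at frame 0."""
    t = np.arange(frames)
    if model == "none":
        return np.zeros((frames, 2))
    if model == "linear":
        frac = t / max(frames - 1, 1)
        return np.outer(frac, np.asarray(total_nm, dtype=float))
    if model == "random_walk":
        steps = rng.normal(0, step_nm, size=(frames, 2))
        steps[0] = 0
        return np.cumsum(steps, axis=0)
    raise ValueError(f"unknown drift model {model!r}")


def generate_smlm_movie(config: SMLMConfig, seed: int
                        ) -> tuple[ImageStack, LocalizationTable, PhantomTruth]:
    """Simulate a blinking-emitter movie with fiducials and stage drift.

    Returns the emitter-channel frame stack, the truth localization table
    (drift-free positions, one record per on-event), and a
    :class:`PhantomTruth` carrying the drift trajectory, fiducial anchor
    frames (rendered as a separate fiducial-channel stack) and true
    fiducial positions.
    """
    cfg = config
    rng_e = _rng(seed, _S_EMIT)
    rng_b = _rng(seed, _S_BLINK)
    rng_d = _rng(seed, _S_DRIFT)
    rng_c = _rng(seed, _S_CAMERA)
    rng_f = _rng(seed, _S_FID)

    w_nm, h_nm = cfg.fov_nm
    shape = (int(np.ceil(h_nm / cfg.pixel_size_nm)),
             int(np.ceil(w_nm / cfg.pixel_size_nm)))
    m = cfg.margin_nm
    ex = rng_e.uniform(m, w_nm - m, cfg.n_emitters)
    ey = rng_e.uniform(m, h_nm - m, cfg.n_emitters)

    # two-state blinking Markov chain
    if cfg.always_on:
        on = np.ones((cfg.frames, cfg.n_emitters), dtype=bool)
    else:
        on = np.zeros((cfg.frames, cfg.n_emitters), dtype=bool)
        state = np.full(cfg.n_emitters, cfg.start_on)
        for t in range(cfg.frames):
            u = rng_b.random(cfg.n_emitters)
            state = np.where(state, u >= cfg.p_off, u < cfg.p_on)
            on[t] = state

    drift = drift_at(cfg.frames, cfg.drift_model, cfg.drift_total_nm,
                     cfg.drift_step_nm, rng_d)

    planes = []
    truth_rows = []
    for t in range(cfg.frames):
        idx = np.flatnonzero(on[t])
        img = _render_frame(shape, cfg.pixel_size_nm,
                            ex[idx] + drift[t, 0], ey[idx] + drift[t, 1],
                            np.full(len(idx), cfg.photons_per_frame),
                            cfg.psf_sigma_nm)
        img += cfg.background_photons
        if cfg.camera_noise:
            img = rng_c.poisson(img).astype(float)
        planes.append(ImagePlane(img, cfg.pixel_size_nm, "smlm"))
        for k in idx:
            truth_rows.append((t, ex[k], ey[k], k))
    frames_stack = ImageStack(planes, channel_names=["smlm"])

    truth_df = pd.DataFrame(truth_rows, columns=["frame", "x_nm", "y_nm", "emitter"])
    truth_locs = LocalizationTable.from_arrays(
        truth_df["x_nm"].to_numpy(), truth_df["y_nm"].to_numpy(),
        frame=truth_df["frame"].to_numpy(), channel="smlm",
        sigma_nm=cfg.psf_sigma_nm, photons=cfg.photons_per_frame)

    truth = PhantomTruth(
        emitters=pd.DataFrame({"emitter": np.arange(cfg.n_emitters),
                               "x_nm": ex, "y_nm": ey}),
        drift=pd.DataFrame({"frame": np.arange(cfg.frames),
                            "dx_nm": drift[:, 0], "dy_nm": drift[:, 1]}))

    if cfg.n_fiducials > 0:
        anchors = anchor_frame_indices(cfg.frames, cfg.cadence_k)
        # fiducial markers are sparse and individually resolvable:
        # rejection-sample positions with a minimum pairwise separation
        fx = np.empty(cfg.n_fiducials)
        fy = np.empty(cfg.n_fiducials)
        placed = 0
        for _ in range(200 * cfg.n_fiducials):
            cx_, cy_ = (rng_f.uniform(m, w_nm - m), rng_f.uniform(m, h_nm - m))
            if all(np.hypot(cx_ - fx[k], cy_ - fy[k])
                   >= cfg.fiducial_min_separation_nm for k in range(placed)):
                fx[placed], fy[placed] = cx_, cy_
                placed += 1
                if placed == cfg.n_fiducials:
                    break
        if placed < cfg.n_fiducials:
            raise ValueError(
                "cannot place fiducials at the requested separation; "
                "enlarge fov_nm or lower fiducial_min_separation_nm")
        fid_planes = []
        for t in anchors:
            jx = rng_f.normal(0, cfg.fiducial_jitter_nm, cfg.n_fiducials) \
                if cfg.fiducial_jitter_nm > 0 else 0.0
            jy = rng_f.normal(0, cfg.fiducial_jitter_nm, cfg.n_fiducials) \
                if cfg.fiducial_jitter_nm > 0 else 0.0
            img = _render_frame(shape, cfg.pixel_size_nm,
                                fx + jx + drift[t, 0], fy + jy + drift[t, 1],
                                np.full(cfg.n_fiducials, cfg.fiducial_photons),
                                cfg.psf_sigma_nm)
            img += cfg.background_photons
            if cfg.camera_noise:
                img = rng_c.poisson(img).astype(float)
            fid_planes.append(ImagePlane(img, cfg.pixel_size_nm, "fiducial"))
        truth.anchor_frames = anchors
        truth.fiducial_positions_nm = np.column_stack([fx, fy])
        truth.fiducial_frames = ImageStack(fid_planes, channel_names=["fiducial"])

    return frames_stack, truth_locs, truth


# ---------------------------------------------------------------------------
# two-channel point patterns
# ---------------------------------------------------------------------------


def generate_two_channel_points(n1: int, n2: int, f_true: float,
                                area_um2: float, jitter_nm: float, seed: int
                                ) -> tuple[LocalizationTable, LocalizationTable, PhantomTruth]:
    """Two point patterns with a controlled colocalized fraction.

    ``round(f_true * min(n1, n2))`` channel-2 points sit at a channel-1
    position plus isotropic Gaussian jitter of sigma *jitter_nm*; the rest
    of both channels is uniform over a square field of *area_um2*.  The
    pairing is recorded (symmetrically) in the truth.
    """
    if not 0.0 <= f_true <= 1.0:
        raise ValueError("f_true must be in [0, 1]")
    rng = _rng(seed, _S_POINTS)
    side_nm = np.sqrt(area_um2) * 1000.0
    x1 = rng.uniform(0, side_nm, n1)
    y1 = rng.uniform(0, side_nm, n1)
    n_pair = int(round(f_true * min(n1, n2)))
    partner = rng.choice(n1, size=n_pair, replace=False) if n_pair else np.array([], int)
    x2 = np.empty(n2)
    y2 = np.empty(n2)
    x2[:n_pair] = x1[partner] + rng.normal(0, jitter_nm, n_pair)
    y2[:n_pair] = y1[partner] + rng.normal(0, jitter_nm, n_pair)
    x2[n_pair:] = rng.uniform(0, side_nm, n2 - n_pair)
    y2[n_pair:] = rng.uniform(0, side_nm, n2 - n_pair)
    t1 = LocalizationTable.from_arrays(x1, y1, channel="ch1")
    t2 = LocalizationTable.from_arrays(x2, y2, channel="ch2")
    pairs = pd.DataFrame({"index_ch1": partner.astype(int),
                          "index_ch2": np.arange(n_pair)})
    truth = PhantomTruth(pairs=pairs)
    return t1, t2, truth


# ---------------------------------------------------------------------------
# registration pairs and base images
# ---------------------------------------------------------------------------


def random_blob_image(shape: tuple[int, int] = (512, 512), n_blobs: int = 40,
                      pixel_size_nm: float = 65.0, seed: int = 0,
                      amplitude: float = 1000.0) -> ImagePlane:
    """Smooth random-blob scene used as registration / ICCS test content."""
    rng = _rng(seed, _S_REG)
    img = np.zeros(shape)
    ys = rng.uniform(0, shape[0], n_blobs)
    xs = rng.uniform(0, shape[1], n_blobs)
    sig = rng.uniform(3, 8, n_blobs)
    amp = rng.uniform(0.3, 1.0, n_blobs) * amplitude
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    for y, x, s, a in zip(ys, xs, sig, amp):
        img += a * np.exp(-((ii - y) ** 2 + (jj - x) ** 2) / (2 * s ** 2))
    return ImagePlane(img, pixel_size_nm, "blobs")


def filament_image(shape: tuple[int, int] = (256, 256), n_filaments: int = 6,
                   width_px: float = 2.0, pixel_size_nm: float = 65.0,
                   seed: int = 0, amplitude: float = 500.0
                   ) -> tuple[ImagePlane, np.ndarray]:
    """Tubulin-like filament scene; returns the plane and the true
    filament mask (pixels within the filament width)."""
    rng = _rng(seed, _S_REG + 1)
    dist = np.full(shape, np.inf)
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    for _ in range(n_filaments):
        p0 = rng.uniform(0, shape[0], 2)
        ang = rng.uniform(0, np.pi)
        d = np.array([np.cos(ang), np.sin(ang)])
        # distance from each pixel to the infinite line through p0 along d
        rel = np.stack([ii - p0[0], jj - p0[1]])
        t = rel[0] * d[0] + rel[1] * d[1]
        perp = np.hypot(rel[0] - t * d[0], rel[1] - t * d[1])
        dist = np.minimum(dist, perp)
    img = amplitude * np.exp(-dist ** 2 / (2 * width_px ** 2))
    mask = dist <= width_px
    return ImagePlane(img, pixel_size_nm, "filaments"), mask


def generate_registration_pair(base_image: ImagePlane, transform: Transform2D,
                               pixel_sizes: tuple[float, float] = (65.0, 160.0),
                               noise: float = 0.0, seed: int = 0
                               ) -> tuple[ImagePlane, ImagePlane, Transform2D]:
    """Two views of one scene at two pixel sizes, related by a known
    physical transform.

    A is the base scene resampled at ``pixel_sizes[0]``; B is the scene
    moved by the truth *transform* (in nm) and sampled at
    ``pixel_sizes[1]``, plus optional Gaussian noise.
    """
    rng = _rng(seed, _S_REG + 2)
    ext_y, ext_x = base_image.extent_nm

    def sample(px: float, tf: Transform2D | None) -> ImagePlane:
        n_rows = int(np.floor(ext_y / px))
        n_cols = int(np.floor(ext_x / px))
        plane = ImagePlane(np.zeros((n_rows, n_cols)), px, base_image.channel)
        ii, jj = np.mgrid[0:n_rows, 0:n_cols]
        x = (jj + 0.5) * px
        y = (ii + 0.5) * px
        if tf is not None:
            inv = tf.inverse()
            pts = inv.apply(np.column_stack([x.ravel(), y.ravel()]))
            x, y = pts[:, 0].reshape(x.shape), pts[:, 1].reshape(y.shape)
        col = x / base_image.pixel_size_nm - 0.5
        row = y / base_image.pixel_size_nm - 0.5
        vals = ndimage.map_coordinates(base_image.pixels, [row, col], order=1,
                                       mode="constant", cval=0.0)
        plane.pixels[:] = vals.reshape(plane.shape)
        return plane

    plane_a = sample(pixel_sizes[0], None)
    plane_b = sample(pixel_sizes[1], transform)
    # refuse transforms that push most of the content out of frame
    total = base_image.pixels.sum()
    if total > 0 and plane_b.pixels.sum() * (plane_b.pixel_size_nm /
                                             base_image.pixel_size_nm) ** 2 \
            < 0.5 * total:
        raise ValueError("transform pushes more than half of the content out of frame")
    if noise > 0:
        for p in (plane_a, plane_b):
            p.pixels[:] = np.clip(p.pixels + rng.normal(0, noise, p.shape), 0, None)
    return plane_a, plane_b, transform
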