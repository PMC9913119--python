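"""Flow-cytometry-style analysis of the single-cell repository.

Histograms, 1D/2D regions (range, rectangle, polygon) and boolean gates
over any measured parameters, per-gate population statistics, and the
DNA-content cell-cycle classifier.

The classifier anchors everything to the G1 peak ``P`` of the
kernel-smoothed DNA-integral distribution, so it is invariant to uniform
rescaling of the DNA intensity.  Two modes:

* EdU mode — S phase is called first from the EdU mean (replicating cells
  incorporate the thymidine analog); the remaining cells fall into G1 and
  G2 windows ``[g_lo, g_hi] * P`` and ``[2*g_lo, 2*g_hi] * P``.
* DNA-only mode — the same windows, with S assigned to cells between them.

A mitosis overlay re-labels G2-window cells as M when the condensed-
chromatin phenotype holds (high DNA mean intensity, small area, near-round
shape) or an explicit mitotic-marker channel is bright.  Cells below
``0.5 * P`` (debris) or outside all windows stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import Polygon
from shapely.prepared import prep
from shapely import points as shapely_points, contains

__all__ = [
    "Gate",
    "CellCycleConfig",
    "make_histogram",
    "apply_gates",
    "classify_cell_cycle",
    "select_events",
]


@dataclass
class Gate:
    """A selection region in measurement space, or a boolean combination.

    kind:
        ``range1D`` (axis + (lo, hi)), ``rectangle`` (two axes + corner
        pairs), ``polygon`` (two axes + vertex list), or ``boolean``
        (operator AND/OR/NOT over operand gate names).
    transform:
        optional per-axis value transform, ``linear`` or ``log10``.
    """

    name: str
    kind: str
    axes: list[str] = field(default_factory=list)
    geometry: object = None
    operator: str | None = None
    operands: list[str] = field(default_factory=list)
    transform: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("range1D", "rectangle", "polygon", "boolean"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "boolean":
            if self.operator not in ("AND", "OR", "NOT"):
                raise ValueError(f"unknown boolean operator {self.operator!r}")
            if self.operator == "NOT" and len(self.operands) != 1:
                raise ValueError("NOT takes exactly one operand")
            if self.operator in ("AND", "OR") and len(self.operands) < 2:
                raise ValueError(f"{self.operator} takes >= 2 operands")
        elif self.kind == "polygon":
            poly = Polygon(self.geometry)
            if not poly.is_valid or poly.is_empty:
                raise ValueError(f"gate {self.name!r}: polygon must be simple")

    @staticmethod
    def from_dict(d: dict) -> "Gate":
        return Gate(name=d["name"], kind=d["kind"], axes=list(d.get("axes", [])),
                    geometry=d.get("geometry"), operator=d.get("operator"),
                    operands=list(d.get("operands", [])),
                    transform=list(d.get("transform", [])))


def _axis_values(table: pd.DataFrame, axis: str, transform: str) -> np.ndarray:
    if axis not in table.columns:
        raise KeyError(f"parameter {axis!r} not in table")
    v = table[axis].to_numpy(dtype=float)
    if transform == "log10":
        bad = int(np.sum(v <= 0))
        if bad:
            raise ValueError(f"log transform on {axis!r}: {bad} non-positive values")
        v = np.log10(v)
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    return v


def make_histogram(table: pd.DataFrame, parameter: str, bins: int = 256,
                   transform: str = "linear"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of one parameter; counts sum to the number of finite
    values.  Returns (counts, bin_edges)."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    v = _axis_values(table, parameter, transform)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
    lo, hi = v.min(), v.max()
    if lo == hi:
        hi = lo + 1.0
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    return counts, edges


def _evaluate_gate(gate: Gate, table: pd.DataFrame,
                   memo: dict[str, np.ndarray], registry: dict[str, Gate],
                   visiting: set[str]) -> np.ndarray:
    if gate.name in memo:
        return memo[gate.name]
    if gate.name in visiting:
        raise ValueError(f"gate cycle involving {gate.name!r}")
    visiting.add(gate.name)
    tr = list(gate.transform) + ["linear"] * (len(gate.axes) - len(gate.transform))
    if gate.kind == "range1D":
        v = _axis_values(table, gate.axes[0], tr[0])
        lo, hi = gate.geometry
        member = (v >= lo) & (v <= hi)
    elif gate.kind == "rectangle":
        x = _axis_values(table, gate.axes[0], tr[0])
        y = _axis_values(table, gate.axes[1], tr[1])
        (x0, y0), (x1, y1) = gate.geometry
        x0, x1 = min(x0, x1), max(x0, x1)
        y0, y1 = min(y0, y1), max(y0, y1)
        member = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    elif gate.kind == "polygon":
        x = _axis_values(table, gate.axes[0], tr[0])
        y = _axis_values(table, gate.axes[1], tr[1])
        poly = prep(Polygon(gate.geometry).buffer(0))
        pts = shapely_points(np.column_stack([x, y]))
        member = np.array([poly.intersects(p) for p in pts]) if len(x) else \
            np.zeros(0, dtype=bool)
    else:  # boolean; evaluated purely, no short-circuit over events
        ops = []
        for name in gate.operands:
            if name not in registry:
                raise KeyError(f"gate {gate.name!r} references unknown gate {name!r}")
            ops.append(_evaluate_gate(registry[name], table, memo, registry,
                                      visiting))
        if gate.operator == "NOT":
            member = ~ops[0]
        elif gate.operator == "AND":
            member = np.logical_and.reduce(ops)
        else:
            member = np.logical_or.reduce(ops)
    visiting.discard(gate.name)
    memo[gate.name] = member
    return member


def apply_gates(table: pd.DataFrame, gates: list[Gate],
                parent: dict[str, str] | None = None,
                stat_parameters: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate gates over the table.

    Returns (membership, stats): *membership* is a boolean DataFrame with
    one column per gate, *stats* holds per-gate event count, percent of
    total, percent of parent (if *parent* names one), and the mean of each
    *stat_parameter* over members.
    """
    registry = {g.name: g for g in gates}
    if len(registry) != len(gates):
        raise ValueError("gate names must be unique")
    memo: dict[str, np.ndarray] = {}
    for g in gates:
        _evaluate_gate(g, table, memo, registry, set())
    membership = pd.DataFrame({g.name: memo[g.name] for g in gates},
                              index=table.index)
    total = len(table)
    rows = []
    for g in gates:
        m = memo[g.name]
        count = int(m.sum())
        row = {"gate": g.name, "count": count,
               "percent_total": 100.0 * count / total if total else 0.0}
        pname = (parent or {}).get(g.name)
        if pname is not None:
            pcount = int(memo[pname].sum())
            row["percent_parent"] = 100.0 * count / pcount if pcount else 0.0
        else:
            row["percent_parent"] = row["percent_total"]
        for param in stat_parameters or []:
            vals = table.loc[m, param]
            row[f"mean_{param}"] = float(vals.mean()) if count else np.nan
        rows.append(row)
    return membership, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell-cycle classification
# ---------------------------------------------------------------------------


@dataclass
class CellCycleConfig:
    """Cell-cycle classifier parameters (all relative to the G1 peak P or
    to population medians, so absolute intensity scales drop out)."""

    dna_column: str = "integrated_DNA"
    edu_column: str = "mean_EdU"
    marker_column: str | None = None
    area_column: str = "area_um2"
    circularity_column: str = "circularity"
    g_lo: float = 0.8
    g_hi: float = 1.25
    sub_g1: float = 0.5            # debris guard, in units of P
    edu_threshold: float | None = None   # None -> Otsu on EdU means
    mitosis_overlay: bool = True
    m_condensation: float = 1.5    # DNA mean > c * median interphase DNA mean
    m_area: float = 0.8            # area < a * median
    m_circularity: float = 0.9     # circularity > q
    marker_threshold: float | None = None


def _g1_peak(dna: np.ndarray) -> float:
    """Mode of the kernel-smoothed DNA-integral distribution (Silverman
    bandwidth)."""
    dna = dna[np.isfinite(dna) & (dna > 0)]
    if len(dna) == 0:
        raise ValueError("no positive DNA integrals; cannot locate G1 peak")
    if np.ptp(dna) < 1e-12 * max(abs(dna.mean()), 1.0):
        return float(np.median(dna))
    kde = gaussian_kde(dna)  # Silverman-like (scott) default bandwidth
    grid = np.linspace(dna.min(), dna.max(), 2048)
    dens = kde(grid)
    if not np.any(dens > 0):
        raise ValueError("DNA-integral histogram has no detectable peak")
    return float(grid[np.argmax(dens)])


def _otsu_1d(values: np.ndarray) -> float:
    """Otsu threshold on a 1D sample (for auto EdU positivity)."""
    v = values[np.isfinite(values)]
    hist, edges = np.histogram(v, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    best, thr = -1.0, centers[len(centers) // 2]
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    for i in range(len(centers) - 1):
        w0 = csum[i] / total
        if w0 in (0.0, 1.0):
            continue
        m0 = cmean[i] / csum[i]
        m1 = (cmean[-1] - cmean[i]) / (total - csum[i])
        var_between = w0 * (1 - w0) * (m0 - m1) ** 2
        if var_between > best:
            best, thr = var_between, centers[i]
    return float(thr)


def classify_cell_cycle(table: pd.DataFrame,
                        config: CellCycleConfig | None = None,
                        mode: str = "dna") -> pd.DataFrame:
    """Assign each cell a phase in {G1, S, G2, M, unclassified}.

    mode ``"edu"`` uses the EdU channel for S; mode ``"dna"`` uses DNA
    content only.  Returns a DataFrame with ``cell_id`` and ``phase``.
    """
    cfg = config or CellCycleConfig()
    if mode not in ("edu", "dna"):
        raise ValueError("mode must be 'edu' or 'dna'")
    dna = table[cfg.dna_column].to_numpy(dtype=float)
    peak = _g1_peak(dna)

    g1_lo, g1_hi = cfg.g_lo * peak, cfg.g_hi * peak
    g2_lo, g2_hi = 2 * cfg.g_lo * peak, 2 * cfg.g_hi * peak

    phase = np.full(len(table), "unclassified", dtype=object)
    in_g1 = (dna >= g1_lo) & (dna <= g1_hi)
    in_g2 = (dna >= g2_lo) & (dna <= g2_hi)

    if mode == "edu":
        edu = table[cfg.edu_column].to_numpy(dtype=float)
        thr = cfg.edu_threshold if cfg.edu_threshold is not None else _otsu_1d(edu)
        s_mask = edu > thr
    else:
        s_mask = (dna > g1_hi) & (dna < g2_lo)

    phase[in_g1] = "G1"
    phase[in_g2] = "G2"
    phase[s_mask] = "S"
    phase[dna < cfg.sub_g1 * peak] = "unclassified"

    if cfg.mitosis_overlay:
        interphase = np.isin(phase, ("G1", "S", "G2"))
        area = table[cfg.area_column].to_numpy(dtype=float)
        circ = table[cfg.circularity_column].to_numpy(dtype=float)
        dna_mean_col = cfg.dna_column.replace("integrated_", "mean_")
        if dna_mean_col in table.columns:
            dna_mean = table[dna_mean_col].to_numpy(dtype=float)
        else:
            dna_mean = dna / np.maximum(area, 1e-12)
        med_mean = np.median(dna_mean[interphase]) if interphase.any() else np.median(dna_mean)
        med_area = np.median(area[interphase]) if interphase.any() else np.median(area)
        morpho = (dna_mean > cfg.m_condensation * med_mean) \
            & (area < cfg.m_area * med_area) \
            & (circ > cfg.m_circularity)
        m_mask = in_g2 & morpho
        if cfg.marker_column is not None and cfg.marker_threshold is not None \
                and cfg.marker_column in table.columns:
            marker = table[cfg.marker_column].to_numpy(dtype=float)
            m_mask = in_g2 & (morpho | (marker > cfg.marker_threshold))
        phase[m_mask] = "M"

    return pd.DataFrame({"cell_id": table["cell_id"].to_numpy(), "phase": phase})


def select_events(table: pd.DataFrame, gate_or_phase,
                  gates: list[Gate] | None = None,
                  labels: pd.DataFrame | None = None) -> list:
    """Deterministic event-id list for a gate name or a phase label.

    Ids are ordered by (source_file, cell_id); an empty selection is
    allowed.
    """
    if labels is not None and isinstance(gate_or_phase, str) \
            and gate_or_phase in ("G1", "S", "G2", "M", "unclassified"):
        merged = table.merge(labels, on="cell_id")
        sel = merged[merged["phase"] == gate_or_phase]
    elif gates is not None:
        names = {g.name for g in gates}
        if gate_or_phase not in names:
            raise KeyError(f"unknown gate {gate_or_phase!r}")
        membership, _ = apply_gates(table, gates)
        sel = table[membership[gate_or_phase].to_numpy()]
    else:
        raise KeyError(f"cannot resolve selection {gate_or_phase!r}")
    sort_cols = [c for c in ("source_file", "cell_id") if c in sel.columns]
    sel = sel.sort_values(sort_cols, kind="mergesort")
    return sel["cell_id"].tolist()
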