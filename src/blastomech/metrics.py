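"""Evaluation metrics.

Slice-based scalars quantifying the trophectoderm/epiblast (TE/EPI)
interface — inclination angle theta, interface length L, diameter D and
ratio L/D — plus pushing distances along the maternal axis (-z), lumen
volume, elastic energies, and the normalised fitness combining curvature,
interface ratio and pushing distance over a parameter sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .mechanics import elastic_energy

__all__ = [
    "MetricSeries",
    "interface_extract",
    "interface_curvature",
    "interface_ratio",
    "reference_heights",
    "pushing_distance",
    "lumen_volume",
    "fitness_metric",
]


def interface_extract(pop, interface_ids=None, slab_halfwidth: float = 0.5,
                      n_bins: int = 13):
    """Ordered mid-sagittal polyline of the EPI surface facing the TE.

    ``interface_ids`` are the EPI membrane particles covered by (or linked
    to) the TE; scenarios record them at t=0 so the interface stays
    measurable after detachment.  Particles within a slab of half-width
    ``slab_halfwidth`` around the mid-sagittal (xz) plane through the
    population centre of mass are ordered by angle about a pivot below the
    interface and averaged into up to ``n_bins`` angular bins, giving a
    smooth profile that depends only on geometry, not particle indexing.
    """
    if interface_ids is None:
        interface_ids = getattr(pop, "interface_ids", None)
    if interface_ids is None or len(interface_ids) == 0:
        raise ValueError("no interface particles recorded between TE and EPI")
    pts = pop.pos[np.asarray(interface_ids, dtype=np.int64)]
    y0 = pop.pos[pop.is_membrane][:, 1].mean()
    keep = np.abs(pts[:, 1] - y0) <= slab_halfwidth
    if keep.sum() < 5:  # degenerate slab: fall back to the full interface set
        keep = np.ones(len(pts), dtype=bool)
    pts = pts[keep].copy()
    pts[:, 1] = y0  # project onto the mid-sagittal plane
    # order along the arc: by angle about a pivot well below the interface,
    # so both flat and strongly bulging interfaces order cleanly
    pivot = np.array([pts[:, 0].mean(),
                      pts[:, 2].min() - max(np.ptp(pts[:, 0]), 1.0)])
    ang = np.arctan2(pts[:, 2] - pivot[1], pts[:, 0] - pivot[0])
    order = np.lexsort((pts[:, 2], ang))
    pts, ang = pts[order], ang[order]
    if len(pts) <= n_bins:
        return pts
    edges = np.linspace(ang[0], ang[-1] + 1e-12, n_bins + 1)
    which = np.clip(np.searchsorted(edges, ang, side="right") - 1,
                    0, n_bins - 1)
    binned = [pts[which == k].mean(axis=0) for k in range(n_bins)
              if np.any(which == k)]
    return np.asarray(binned)


def _central_index(polyline: np.ndarray) -> int:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return int(np.argmin(np.abs(arc - arc[-1] / 2.0)))


def interface_curvature(polyline: np.ndarray) -> float:
    """Inclination angle theta (degrees) of the interface.

    The angle at the polyline's central point subtended by its two endpoints;
    a flat interface gives 180 degrees, a semicircular arc (apex central)
    gives 90.
    """
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 3:
        raise ValueError("need at least 3 points to measure curvature")
    c = _central_index(polyline)
    if c in (0, len(polyline) - 1):
        c = len(polyline) // 2
    v1 = polyline[0] - polyline[c]
    v2 = polyline[-1] - polyline[c]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate interface: endpoint coincides with centre")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interface_ratio(polyline: np.ndarray) -> tuple[float, float, float]:
    """Interface length L (arc length), diameter D (endpoint distance), L/D."""
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 2:
        raise ValueError("need at least 2 points")
    L = float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())
    D = float(np.linalg.norm(polyline[-1] - polyline[0]))
    if D < 1e-12:
        raise ValueError("degenerate interface: zero diameter")
    return L, D, L / D


def reference_heights(pop) -> dict:
    """Reference state for pushing distances, recorded at t=0."""
    epi = pop.tissue_particles("EPI")
    return {
        "epi_lowest_z": float(pop.pos[epi][:, 2].min()),
        "epi_com_z": float(pop.pos[epi][:, 2].mean()),
        "pop_com_z": float(pop.pos[:, 2].mean()),
    }


def pushing_distance(pop, reference: dict) -> dict:
    """Signed displacement toward the maternal side (-z positive).

    Three variants: lowest EPI point, EPI centre of mass, and whole-population
    centre of mass.
    """
    now = reference_heights(pop)
    return {
        "push_lowest": reference["epi_lowest_z"] - now["epi_lowest_z"],
        "push_epi_com": reference["epi_com_z"] - now["epi_com_z"],
        "push_pop_com": reference["pop_com_z"] - now["pop_com_z"],
    }


def lumen_volume(pop) -> float:
    """Volume of the cavity around the lumen source(s).

    Convex-hull volume of the repulsion target particles (the cavity is
    star-shaped around the source in all observed regimes).  Zero before
    lumenogenesis is activated.
    """
    total = 0.0
    for source in getattr(pop, "lumen_sources", ()):
        pts = pop.pos[source.target_idx]
        if len(pts) < 4:
            continue
        try:
            total += float(ConvexHull(pts).volume)
        except QhullError:
            continue
    return total


def fitness_metric(theta: float, ir: float, h: float, sweep_optima: dict,
                   degenerate: str = "error") -> float:
    """Normalised fitness M in [0, 1] combining theta, L/D and pushing.

    M = 1/3 [ ((theta - theta_max)/(theta_max - theta_min))^2
            + ((Ir - Ir_min)/(Ir_max - Ir_min))^2
            + ((H - H_max)/(H_max - H_min))^2 ]

    The optima are taken over the sweep's own data; M = 0 only where a run
    attains the best curvature, interface ratio and pushing distance at once.
    A zero metric range across the sweep raises by default
    (``degenerate="error"``); with ``degenerate="tied-zero"`` such a term
    contributes 0, the continuous limit when every run ties at the optimum.
    """
    o = sweep_optima
    terms = ((theta, o["theta_max"], o["theta_max"] - o["theta_min"]),
             (ir, o["ir_min"], o["ir_max"] - o["ir_min"]),
             (h, o["h_max"], o["h_max"] - o["h_min"]))
    total = 0.0
    for value, best, span in terms:
        if abs(span) < 1e-15:
            if degenerate == "tied-zero":
                continue
            raise ValueError(
                f"degenerate sweep: zero metric range in {sweep_optima}")
        total += ((value - best) / span) ** 2 / 3.0
    return float(total)


@dataclass
class MetricSeries:
    """Time-indexed record of all evaluation quantities."""

    rows: list = field(default_factory=list)

    def sample(self, pop, params, reference: dict,
               interface_ids=None) -> dict:
        row = {"t": int(pop.t)}
        row["E_total"] = elastic_energy(pop)
        for tissue in ("TE", "EPI"):
            ids = [c.id for c in pop.cells if c.cell_type == tissue]
            row[f"E_{tissue}"] = elastic_energy(pop, ids) if ids else 0.0
        try:
            poly = interface_extract(pop, interface_ids)
            row["theta"] = interface_curvature(poly)
            L, D, ratio = interface_ratio(poly)
            row.update(L=L, D=D, LD=ratio)
        except ValueError:
            row.update(theta=np.nan, L=np.nan, D=np.nan, LD=np.nan)
        row.update(pushing_distance(pop, reference))
        row["lumen_volume"] = lumen_volume(pop)
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
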