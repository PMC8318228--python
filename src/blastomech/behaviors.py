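"""Programmed single-cell behaviours.

All cell dynamics arise from editing spring equilibrium lengths: a behaviour
constructs the target geometry of the cell in its canonical frame and resets
every spring's equilibrium length to the inter-particle distance in that
target; particle positions are never touched directly — the overdamped
relaxation moves the cell toward the new rest shape.  The one exception is
lumen repulsion, a "specific" force from a virtual source at the rosette
centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_mesh import APICAL, CellShapeSpec, layout_local
from .mechanics import SimParams, morse_scalar
from .neighborhoods import CellRecord, Population

__all__ = [
    "ConstrictionSpec",
    "LumenSource",
    "retarget_shape",
    "apical_constriction_targets",
    "positional_constriction_profile",
    "lumen_repulsion_force",
    "open_lumen",
]


@dataclass
class ConstrictionSpec:
    """Per-cell apical shrinkage lengths over a sheet (cell id -> d)."""

    profile: dict[int, float]

    def validate(self, pop: Population) -> None:
        for cid, d in self.profile.items():
            R = pop.cells[cid].spec.apical_radius
            if not 0.0 <= d <= R + 1e-12:
                raise ValueError(f"cell {cid}: d={d} outside [0, R={R}]")


def _set_cell_targets(pop: Population, cell: CellRecord,
                      target_local: np.ndarray) -> None:
    """Reset the cell's spring equilibrium lengths from a target geometry.

    ``target_local`` holds the membrane particle coordinates in the canonical
    frame; the intracellular particle sits at their centroid.  Spring lengths
    are frame-invariant, so no rotation to world coordinates is needed.
    """
    coords = np.vstack([target_local, target_local.mean(axis=0)[None, :]])
    sl = slice(cell.sp_start, cell.sp_stop)
    li = pop.sp_i[sl] - cell.m_start
    lj = pop.sp_j[sl] - cell.m_start
    pop.sp_req[sl] = np.linalg.norm(coords[lj] - coords[li], axis=1)


def retarget_shape(pop: Population, cell_id: int,
                   target_spec: CellShapeSpec) -> None:
    """Set spring equilibrium lengths to those of a new cell shape.

    Used for the cuboidal-to-columnar elongation of trophectoderm cells.
    Positions are untouched; relaxation does the motion.
    """
    cell = pop.cells[cell_id]
    if target_spec.basis != cell.spec.basis or target_spec.n_vertices != cell.spec.n_vertices:
        raise ValueError(
            f"incompatible mesh family: cell is ({cell.spec.n_vertices}, "
            f"{cell.spec.basis!r}), target is ({target_spec.n_vertices}, "
            f"{target_spec.basis!r})"
        )
    # preserve any accumulated apical constriction in the new target
    shrink = cell.current_spec.apical_radius - cell.apical_radius_now
    new_apical = max(target_spec.apical_radius - shrink, 0.0)
    _set_cell_targets(pop, cell, layout_local(target_spec, apical_radius=new_apical))
    cell.current_spec = target_spec
    cell.apical_radius_now = new_apical


def apical_constriction_targets(pop: Population, cell_id: int, d: float) -> None:
    """Shrink the target apical ring radius by ``d`` (cumulative).

    The target geometry moves the apical ring particles toward the apical
    pole axis; new equilibrium lengths follow for apical and apico-lateral
    springs while basal springs are unchanged (their target distances are
    identical).  A negative ``d`` re-expands, so constricting by ``d`` and
    then by ``-d`` restores the original equilibrium lengths exactly.
    """
    cell = pop.cells[cell_id]
    R = cell.current_spec.apical_radius
    if d > R + 1e-12:
        raise ValueError(f"d={d} exceeds apical radius R={R}")
    new_radius = cell.apical_radius_now - d
    if not -1e-12 <= new_radius <= R + 1e-12:
        raise ValueError(
            f"constriction would take apical radius to {new_radius}, "
            f"outside [0, {R}]")
    new_radius = min(max(new_radius, 0.0), R)
    _set_cell_targets(pop, cell,
                      layout_local(cell.current_spec, apical_radius=new_radius))
    cell.apical_radius_now = new_radius


def positional_constriction_profile(pop: Population, cell_ids,
                                    mode: str = "step") -> ConstrictionSpec:
    """Step profile of apical shrinkage over a sheet.

    Cells in the middle of the sheet constrict completely (``d = R``), cells
    on the sheet boundary do not (``d = 0``).  Boundary = extremal lattice
    row/column of the sheet; a single-cell sheet is its own middle.
    """
    if mode != "step":
        raise ValueError(f"unknown profile mode {mode!r}")
    cell_ids = list(cell_ids)
    if not cell_ids:
        raise ValueError("empty sheet")
    coords = np.array([pop.cells[c].lattice for c in cell_ids])
    profile: dict[int, float] = {}
    if len(cell_ids) == 1:
        cid = cell_ids[0]
        return ConstrictionSpec({cid: pop.cells[cid].spec.apical_radius})
    lo = coords[:, :2].min(axis=0)
    hi = coords[:, :2].max(axis=0)
    for cid, xy in zip(cell_ids, coords[:, :2]):
        on_boundary = bool(np.any(xy == lo) or np.any(xy == hi))
        profile[cid] = 0.0 if on_boundary else pop.cells[cid].spec.apical_radius
    return ConstrictionSpec(profile)


def apply_constriction_profile(pop: Population, spec: ConstrictionSpec) -> None:
    spec.validate(pop)
    for cid, d in spec.profile.items():
        if d != 0.0:
            apical_constriction_targets(pop, cid, d)


def lumen_repulsion_force(source: "LumenSource", particle_position: np.ndarray,
                          params: SimParams) -> np.ndarray:
    """Morse-form radial force from the lumen source on one particle.

    Equilibrium at distance ``R_lum`` from the source origin ``O``:
    particles closer than ``R_lum`` are pushed outward, farther ones are
    pulled back; the force vanishes on the target sphere.
    """
    d = np.asarray(particle_position, dtype=float) - source.origin
    r = float(np.linalg.norm(d))
    cap = params.force_cap_factor * params.j_epi * params.rho
    if r <= 1e-12:
        return np.zeros(3)
    s = float(morse_scalar(params.j_epi, params.rho, r, source.r_lum, cap=cap))
    # s > 0 (attraction toward O) when r > R_lum; the force acts along -d/r then
    return -s * d / r


@dataclass
class LumenSource:
    """Virtual repulsion source opening a lumen at the rosette centre."""

    origin: np.ndarray
    r_lum: float
    target_idx: np.ndarray  # apical particles subject to the force

    def __post_init__(self) -> None:
        if not self.r_lum > 0:
            raise ValueError(f"R_lum must be > 0, got {self.r_lum}")
        self.origin = np.asarray(self.origin, dtype=float)
        self.target_idx = np.asarray(self.target_idx, dtype=np.int64)

    def forces(self, pop: Population, params: SimParams):
        d = pop.pos[self.target_idx] - self.origin[None, :]
        r = np.linalg.norm(d, axis=1)
        r_safe = np.where(r > 1e-12, r, 1.0)
        cap = params.force_cap_factor * params.j_epi * params.rho
        s = morse_scalar(params.j_epi, params.rho, r, self.r_lum, cap=cap)
        s = np.where(r > 1e-12, s, 0.0)
        return self.target_idx, -(s / r_safe)[:, None] * d


def open_lumen(pop: Population, rosette_cells=None, r_lum: float = 0.25,
               target: str = "broken-links") -> LumenSource:
    """Start hollowing-driven lumenogenesis at the centre of the rosette.

    Deactivates (permanently) the external links joining apical particles of
    the rosette cells — the apposed apical membranes lose adhesion, so linked
    particle pairs are no longer forced to move together — and installs a
    repulsion source at the centroid of the rosette's apical particles.
    ``target`` selects which particles feel the repulsion: the particles
    whose links were broken (default) or ``"all-apical"``.
    """
    if rosette_cells is None:
        rosette_cells = [c.id for c in pop.cells_of_type("EPI")]
    rosette_cells = set(int(c) for c in rosette_cells)
    apical = np.concatenate(
        [pop.cells[c].particles_with_label(APICAL) for c in sorted(rosette_cells)])
    if len(apical) == 0:
        raise ValueError("no apical particles found in the rosette cells")
    apical_set = set(int(x) for x in apical)
    pairs = [(int(a), int(b)) for a, b in zip(pop.link_a, pop.link_b)
             if int(a) in apical_set and int(b) in apical_set]
    if target == "broken-links":
        idx = sorted({p for pair in pairs for p in pair})
        if not idx:
            raise ValueError(
                "no apical-apical adhesion links to break; the rosette apical "
                "surfaces are not in contact")
        target_idx = np.asarray(idx, dtype=np.int64)
    elif target == "all-apical":
        target_idx = np.sort(apical)
    else:
        raise ValueError(f"unknown target mode {target!r}")
    pop.deactivate_links(pairs)
    origin = pop.pos[np.sort(apical)].mean(axis=0)
    source = LumenSource(origin=origin, r_lum=r_lum, target_idx=target_idx)
    pop.lumen_sources.append(source)
    return source
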