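"""Embryo construction and the implantation experiments.

Builds the initial configurations — an oval rosette-shaped epiblast (EPI) and
a cuboidal trophectoderm (TE) monolayer resting on top of it — and runs the
scheduled experiments: TE elongation (cuboidal to columnar), TE invagination
by position-dependent apical constriction, lumenogenesis in the EPI, and
optional TE/EPI detachment.  The maternal side is -z; the TE sits at +z above
the EPI and pushing distances are measured along z.

Default schedule (step counts): t=0 elongation targets; t=3000 apical
constriction (step profile); t=4000 lumen opening; t=6000 TE/EPI detachment;
end t=9000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import behaviors, mechanics
from .cell_mesh import APICAL, BASAL, CellShapeSpec, build_epithelial_cell
from .mechanics import SimParams, SimulationError
from .metrics import MetricSeries, reference_heights
from .neighborhoods import Population

__all__ = [
    "Scenario",
    "build_rosette_epiblast",
    "build_te_monolayer",
    "default_implantation_scenario",
    "run_scenario",
]

# perimeter of a 3x3 lattice square, walked counter-clockwise: the logical
# grid coordinates of one 8-cell rosette layer
_PERIMETER_3X3 = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


@dataclass
class Scenario:
    """Event schedule for one experiment.

    ``events`` maps a step count to a list of (action, kwargs) pairs; actions
    are ``retarget_elongation``, ``apical_constriction``, ``open_lumen`` and
    ``break_adhesion``.
    """

    events: dict[int, list] = field(default_factory=dict)
    n_steps: int = 9000
    sample_interval: int = 50
    snapshot_times: tuple = (0, 3000, 6000, 9000)

    def add(self, t: int, action: str, **kwargs) -> "Scenario":
        self.events.setdefault(int(t), []).append((action, kwargs))
        return self

    def sorted_events(self):
        return sorted(self.events.items())


def build_rosette_epiblast(
    n_cells: int = 18,
    spec: CellShapeSpec = CellShapeSpec(apical_radius=0.5, height=2.0),
    params: SimParams = SimParams(),
    apex_radius: float = 0.15,
    tilt_deg: float = 40.0,
    oval_scale: tuple = (1.0, 1.0, 1.3),
    constriction_fraction: float = 0.9,
    build_steps: int = 1000,
    center=(0.0, 0.0, 0.0),
) -> Population:
    """Build the oval rosette-shaped epiblast.

    Two layers of ``n_cells/2`` polarised cells are arranged around the
    rosette centre with apical faces inward (a double epithelial layer whose
    apical surfaces converge).  Each cell is built directly in its apically
    constricted rest shape (apical ring radius ``(1 - constriction_fraction)
    * R``) so the wedges pack without interpenetrating; the assembled rosette
    is then relaxed under adhesion until the elastic energy stabilises.  The
    result is an oval rosette with apical particles convergent at the centre
    and no lumen.  ``tilt_deg`` is the polar tilt of each layer's polarity
    away from the rosette axis; ``oval_scale`` stretches the arrangement
    along z.
    """
    if n_cells < 4:
        raise ValueError(f"n_cells={n_cells} too small to close a rosette (>= 4)")
    if not 0.0 <= constriction_fraction < 1.0:
        raise ValueError("constriction_fraction must be in [0, 1)")
    # two ring layers, plus one polar cap cell per layer when there is room:
    # without the caps the rosette surface dips at the poles and the
    # trophectoderm would rest in a dimple instead of on a smooth dome
    polar_caps = n_cells >= 18 and n_cells % 2 == 0
    per_layer = (n_cells - 2) // 2 if polar_caps else n_cells // 2
    center = np.asarray(center, dtype=float)
    oval = np.asarray(oval_scale, dtype=float)
    pop = Population()
    r_apical = (1.0 - constriction_fraction) * spec.apical_radius
    for layer in (0, 1):
        polar = np.radians(tilt_deg if layer == 1 else 180.0 - tilt_deg)
        directions = []
        for k in range(per_layer):
            az = 2.0 * np.pi * (k + 0.5 * layer) / per_layer
            directions.append((np.array([np.sin(polar) * np.cos(az),
                                         np.sin(polar) * np.sin(az),
                                         np.cos(polar)]),
                               _PERIMETER_3X3[k] if per_layer ==
                               len(_PERIMETER_3X3) else (k, 0)))
        if polar_caps:
            pole = np.array([0.0, 0.0, 1.0 if layer == 1 else -1.0])
            directions.append((pole, (1, 1)))
        for direction, (lx, ly) in directions:
            polarity = oval * direction
            polarity /= np.linalg.norm(polarity)
            # apical pole anchored at apex_radius from the centre; the oval
            # stretch acts on the anchor ring, not on cell shapes
            apex = center + oval * (apex_radius * direction)
            c = apex + polarity * (spec.height / 2.0)
            mesh = build_epithelial_cell(spec, center=c, polarity=polarity,
                                         apical_radius=r_apical)
            rec = pop.add_cell(mesh, "EPI", (lx, ly, layer))
            rec.apical_radius_now = r_apical
    pop.rebuild_cell_pairs()
    pop.refresh_links(params)
    mechanics.relax(pop, params, max_steps=build_steps, tol=0.0,
                    refresh_links=True)
    return pop


def build_te_monolayer(
    rows: int = 5,
    cols: int = 5,
    spec: CellShapeSpec = CellShapeSpec(apical_radius=0.5, height=1.0),
    on_top_of: Population | None = None,
    params: SimParams = SimParams(),
    gap: float = 0.1,
    drape_max: float = 1.5,
) -> Population:
    """Add a single-layer TE sheet of cuboidal cells draped over the epiblast.

    The sheet is apical-side down (toward the EPI, the folding direction) on
    a lattice of pitch 2R centred over the rosette.  Because the epiblast
    surface is curved, each cell keeps its vertical polarity but is lowered
    individually until its closest membrane particle is ``gap`` away from
    the epiblast (descending at most ``drape_max`` below the apex), so
    TE-EPI adhesion links exist across the shared interface before any
    event.  Cells keep vertical polarity — a sheet wrapped radially around
    the epiblast would turn apical constriction into a drawstring that
    extrudes the epiblast upward instead of folding onto it.  Raises if a
    cell cannot be placed without overlapping the epiblast.
    """
    if on_top_of is None or not on_top_of.cells_of_type("EPI"):
        raise ValueError("build_te_monolayer requires an existing epiblast")
    if not gap > 0:
        raise ValueError("gap must be > 0 (cells may not overlap the epiblast)")
    pop = on_top_of
    epi_pos = pop.pos[pop.tissue_particles("EPI")]
    epi_top = float(epi_pos[:, 2].max())
    xy0 = epi_pos[:, :2].mean(axis=0)
    pitch = 2.0 * spec.apical_radius
    epi_lat_top = max(c.lattice[2] for c in pop.cells_of_type("EPI"))
    z_high = epi_top + drape_max + spec.height
    for i in range(rows):
        for j in range(cols):
            x = (i - (rows - 1) / 2.0) * pitch + xy0[0]
            y = (j - (cols - 1) / 2.0) * pitch + xy0[1]
            mesh = build_epithelial_cell(spec, center=(x, y, z_high),
                                         polarity=(0.0, 0.0, 1.0))
            # largest vertical drop keeping every particle >= gap from the EPI
            dxy = np.linalg.norm(mesh.positions[:, None, :2]
                                 - epi_pos[None, :, :2], axis=2)
            dz = mesh.positions[:, None, 2] - epi_pos[None, :, 2]
            close = dxy < gap
            if close.any():
                drop = float(np.min(dz[close]
                                    - np.sqrt(gap ** 2 - dxy[close] ** 2)))
            else:
                drop = z_high - spec.height / 2.0 - (epi_top - drape_max)
            drop = min(drop, z_high - spec.height / 2.0
                       - (epi_top - drape_max))
            if drop < 0:
                raise ValueError(
                    f"TE cell at ({x:.2f}, {y:.2f}) would overlap the "
                    f"epiblast beyond tolerance")
            mesh.positions[:, 2] -= drop
            mesh.nucleus_position[2] -= drop
            lat = (i - rows // 2 + 1, j - cols // 2 + 1, epi_lat_top + 1)
            pop.add_cell(mesh, "TE", lat)
    pop.rebuild_cell_pairs()
    pop.refresh_links(params)
    return pop


def default_implantation_scenario(
    lumen: bool = True,
    detach: bool = True,
    n_steps: int | None = None,
    columnar_spec: CellShapeSpec = CellShapeSpec(apical_radius=0.5, height=2.0),
    time_scale: float = 1.0,
) -> Scenario:
    """The reference implantation schedule, optionally time-compressed.

    ``time_scale`` < 1 compresses all event times and the total duration
    proportionally (used for desk-scale sweeps).
    """
    ts = lambda t: int(round(t * time_scale))  # noqa: E731
    if n_steps is None:
        n_steps = ts(9000 if detach else 6000)
    sc = Scenario(n_steps=n_steps,
                  snapshot_times=(0, ts(3000), ts(6000), ts(9000)))
    sc.add(0, "retarget_elongation", tissue="TE", spec=columnar_spec)
    sc.add(ts(3000), "apical_constriction", tissue="TE")
    if lumen:
        sc.add(ts(4000), "open_lumen", tissue="EPI")
    if detach:
        sc.add(ts(6000), "break_adhesion", tissue_a="TE", tissue_b="EPI")
    return sc


def _apply_event(pop: Population, params: SimParams, action: str, kw: dict,
                 log=None) -> None:
    if log:
        log(f"t={pop.t}: {action} {kw}")
    if action == "retarget_elongation":
        for cell in pop.cells_of_type(kw.get("tissue", "TE")):
            behaviors.retarget_shape(pop, cell.id, kw["spec"])
    elif action == "apical_constriction":
        cells = [c.id for c in pop.cells_of_type(kw.get("tissue", "TE"))]
        profile = kw.get("profile")
        if profile is None:
            profile = behaviors.positional_constriction_profile(pop, cells)
        behaviors.apply_constriction_profile(pop, profile)
    elif action == "open_lumen":
        behaviors.open_lumen(pop, r_lum=kw.get("r_lum", 0.25),
                             target=kw.get("target", "broken-links"))
    elif action == "break_adhesion":
        pop.break_adhesion(kw["tissue_a"], kw["tissue_b"])
    else:
        raise ValueError(f"unknown scenario action {action!r}")


def run_scenario(scenario: Scenario, pop: Population, params: SimParams,
                 out_dir=None, log=None) -> MetricSeries:
    """Execute a scenario in place, recording metrics every sample interval.

    The TE/EPI interface particle set and pushing-distance reference are
    recorded at t=0 (after the initial adhesion pass).  Cell count is
    constant throughout: there is no division, fusion or extrusion.  On
    numeric blow-up the last good snapshot is written (when ``out_dir`` is
    given) before the error propagates.
    """
    from . import io_cli  # snapshot export; deferred to avoid cycles

    pop.t = 0
    pop.refresh_links(params)
    te_ids = {c.id for c in pop.cells_of_type("TE")}
    link_holders = {
        int(p) for a, b in zip(pop.link_a, pop.link_b)
        for p, q in ((a, b), (b, a))
        if int(pop.particle_cell[p]) not in te_ids
        and int(pop.particle_cell[q]) in te_ids
    }
    # the epiblast surface covered by the trophectoderm at t=0: outward EPI
    # membrane in the upper half, inside the TE footprint, plus any particle
    # holding a TE link; fixed for the whole run so the interface stays
    # measurable (and smoothly sampled) after detachment
    covered = set()
    te_particles = pop.tissue_particles("TE")
    if len(te_particles):
        te_xy = pop.pos[te_particles][:, :2]
        lo, hi = te_xy.min(axis=0), te_xy.max(axis=0)
        epi_idx = pop.tissue_particles("EPI")
        z_mid = float(pop.pos[epi_idx][:, 2].mean())
        for c in pop.cells_of_type("EPI"):
            outer = c.particles_with_label(BASAL)  # the rosette's outer shell
            for idx in outer:
                x, y, z = pop.pos[idx]
                if z > z_mid and lo[0] <= x <= hi[0] and lo[1] <= y <= hi[1]:
                    covered.add(int(idx))
    pop.interface_ids = np.asarray(sorted(covered | link_holders),
                                   dtype=np.int64)
    reference = reference_heights(pop)
    series = MetricSeries()
    events = dict(scenario.events)
    snapshots = set(scenario.snapshot_times)

    def maybe_snapshot(t):
        if out_dir is not None and t in snapshots:
            io_cli.export_snapshot(pop, t, out_dir)

    try:
        for t in range(scenario.n_steps + 1):
            if t in events:
                for action, kw in events[t]:
                    _apply_event(pop, params, action, kw, log=log)
            if t % scenario.sample_interval == 0:
                series.sample(pop, params, reference)
                mechanics.assert_finite(pop)
            maybe_snapshot(t)
            if t < scenario.n_steps:
                if t % params.link_refresh == 0:
                    pop.refresh_links(params)
                mechanics.step(pop, params)
    except SimulationError:
        if out_dir is not None:
            io_cli.export_snapshot(pop, int(pop.t), out_dir, suffix="-lastgood")
        raise
    return series
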