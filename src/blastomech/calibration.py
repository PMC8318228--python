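"""In-silico materials testing and parameter sweeps.

The stiffness of a simulated cell is an emergent property of its spring
network.  It is measured with a stress-strain protocol: equal and opposite
axial forces of increasing magnitude F are applied to the apical and basal
faces of a single isolated cell, the cell is relaxed to equilibrium at each
load, stress sigma = F/S (S the face area) is plotted against strain
epsilon = dL/L0 (L the apico-basal height), and the Young modulus Y is the
slope of the fitted line.

Because every spring force is linear in the interaction strength J, scaling J
by c > 0 and the force schedule by the same c leaves all equilibrium shapes
unchanged and multiplies every stress by c: Y(cJ) = c Y(J) exactly.  The
default force schedule is therefore proportional to J (10 magnitudes linearly
spaced up to the force that produces a target maximum strain of about 0.2,
found from a small trial load), which keeps the fit inside the linear regime
at every J.

Three sweeps build on the protocol: Y versus J, Y versus the friction ratio
lambda_chi / lambda_med (with a discontinuity flag where the forward-Euler
dynamics of the intracellular particle lose stability and the cell stops
behaving like a physical material), and the implantation sweep over the
trophectoderm interaction strength J_TE scored by the normalised fitness M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import behaviors, embryo_scenarios, mechanics
from .cell_mesh import APICAL, BASAL, CellShapeSpec, build_epithelial_cell, face_area
from .mechanics import SimParams, SimulationError
from .metrics import fitness_metric
from .neighborhoods import Population

__all__ = [
    "StressStrainResult",
    "stress_strain_protocol",
    "sweep_young_vs_J",
    "sweep_friction_ratio",
    "find_critical_ratio",
    "sweep_jte",
]


@dataclass
class StressStrainResult:
    """Outcome of one stress-strain measurement."""

    forces: np.ndarray
    stresses: np.ndarray
    strains: np.ndarray
    young_modulus: float = np.nan
    intercept: float = np.nan
    r_value: float = np.nan
    failed: bool = False
    failure_reason: str = ""

    @property
    def defined(self) -> bool:
        return not self.failed and np.isfinite(self.young_modulus)


class ProtocolError(RuntimeError):
    """Stress-strain relaxation failed (non-convergence or blow-up)."""


def _single_cell_population(spec: CellShapeSpec) -> Population:
    pop = Population()
    mesh = build_epithelial_cell(spec, center=(0.0, 0.0, 0.0),
                                 polarity=(0.0, 0.0, 1.0))
    pop.add_cell(mesh, "EPI", (0, 0, 0))
    pop.rebuild_cell_pairs()
    return pop


def _face_loads(pop: Population, total_force: float, mode: str):
    """Equal split of the total face force, directed along the polarity axis."""
    cell = pop.cells[0]
    api = cell.particles_with_label(APICAL)
    bas = cell.particles_with_label(BASAL)
    sign = 1.0 if mode == "tension" else -1.0
    axis = np.array([0.0, 0.0, 1.0])
    f = np.vstack([
        np.tile(-sign * axis * (total_force / len(api)), (len(api), 1)),
        np.tile(+sign * axis * (total_force / len(bas)), (len(bas), 1)),
    ])
    return np.concatenate([api, bas]), f


def _height(pop: Population) -> float:
    cell = pop.cells[0]
    return float(abs(pop.pos[cell.m_stop - 1, 2] - pop.pos[cell.m_start, 2]))


def _relax_under_load(pop, params, extra, tol, patience, max_steps):
    try:
        converged, steps = mechanics.relax(
            pop, params, extra=extra, tol=tol, patience=patience,
            max_steps=max_steps)
    except SimulationError as exc:
        raise ProtocolError(f"blow-up under load: {exc}") from exc
    if not converged:
        raise ProtocolError(
            f"no equilibrium within {max_steps} steps "
            f"(|dE| tolerance {tol})")
    return steps


def stress_strain_protocol(
    spec: CellShapeSpec = CellShapeSpec(),
    params: SimParams = SimParams(),
    force_magnitudes=None,
    n_points: int = 10,
    target_strain: float = 0.2,
    mode: str = "tension",
    tol: float = 1e-8,
    patience: int = 100,
    max_steps: int = 100_000,
    protocol_dt: float | None = None,
) -> StressStrainResult:
    """Measure the stress-strain curve and Young modulus of one cell.

    When ``force_magnitudes`` is omitted, a trial load proportional to J sets
    the force scale so the largest strain is about ``target_strain``, and
    ``n_points`` magnitudes are linearly spaced from zero.  Loads are applied
    incrementally (each equilibrium seeds the next) for speed; strain is
    measured on the pole-to-pole height, stress uses the undeformed face
    area.  Raises :class:`ProtocolError` naming the offending force when a
    load does not converge.
    """
    if mode not in ("tension", "compression"):
        raise ValueError(f"mode must be tension|compression, got {mode!r}")
    if protocol_dt is not None:
        params = params.with_(dt=protocol_dt)
    pop = _single_cell_population(spec)
    mesh0 = build_epithelial_cell(spec)
    S = face_area(mesh0, APICAL)
    L0 = _height(pop)

    if force_magnitudes is None:
        J = params.j_epi
        trial = 0.2 * J
        probe = _single_cell_population(spec)
        idx, f = _face_loads(probe, trial, mode)
        try:
            _relax_under_load(probe, params, (idx, f), tol, patience, max_steps)
        except ProtocolError as exc:
            raise ProtocolError(f"trial load F={trial}: {exc}") from exc
        eps_trial = abs(_height(probe) - L0) / L0
        if eps_trial <= 0:
            raise ProtocolError("trial load produced no deformation")
        f_max = trial * target_strain / eps_trial
        force_magnitudes = np.linspace(0.0, f_max, n_points)
    forces = np.asarray(force_magnitudes, dtype=float)
    if np.any(np.diff(forces) < 0):
        raise ValueError("force magnitudes must be sorted ascending")

    stresses, strains = [], []
    for F in forces:
        if F > 0:
            idx, f = _face_loads(pop, F, mode)
            try:
                _relax_under_load(pop, params, (idx, f), tol, patience, max_steps)
            except ProtocolError as exc:
                return StressStrainResult(
                    forces=forces, stresses=np.asarray(stresses),
                    strains=np.asarray(strains), failed=True,
                    failure_reason=f"F={F:g}: {exc}")
        strains.append(abs(_height(pop) - L0) / L0)
        stresses.append(F / S)
    stresses = np.asarray(stresses)
    strains = np.asarray(strains)

    # a physical material deforms monotonically under monotone loading;
    # a non-monotone or wildly jumping strain sequence marks a compromised cell
    d_eps = np.diff(strains)
    discontinuous = np.any(d_eps < -1e-9)
    if len(d_eps) > 2:
        med = np.median(d_eps[d_eps > 0]) if np.any(d_eps > 0) else 0.0
        if med > 0 and np.max(d_eps) > 10.0 * med:
            discontinuous = True
    if discontinuous:
        return StressStrainResult(
            forces=forces, stresses=stresses, strains=strains, failed=True,
            failure_reason="discontinuous stress-strain curve")

    fit = linregress(strains, stresses)
    return StressStrainResult(
        forces=forces, stresses=stresses, strains=strains,
        young_modulus=float(fit.slope), intercept=float(fit.intercept),
        r_value=float(fit.rvalue))


def sweep_young_vs_J(
    spec: CellShapeSpec = CellShapeSpec(),
    j_values=None,
    params: SimParams = SimParams(),
    **protocol_kw,
) -> pd.DataFrame:
    """Table of Young modulus versus interaction strength J."""
    if j_values is None:
        j_values = np.linspace(0.1, 5.0, 50)
    rows = []
    for J in np.asarray(j_values, dtype=float):
        try:
            res = stress_strain_protocol(
                spec, params.with_(j_epi=float(J), j_te=float(J)), **protocol_kw)
        except ProtocolError as exc:
            res = StressStrainResult(forces=np.zeros(0), stresses=np.zeros(0),
                                     strains=np.zeros(0), failed=True,
                                     failure_reason=str(exc))
        rows.append(dict(J=float(J), Y=res.young_modulus,
                         r_value=res.r_value, defined=res.defined,
                         reason=res.failure_reason))
    return pd.DataFrame(rows)


def sweep_friction_ratio(
    spec: CellShapeSpec = CellShapeSpec(),
    ratio_values=(0.25, 0.5, 1.0, 2.0),
    lambda_med_fixed: float = 2.0,
    params: SimParams = SimParams(),
    **protocol_kw,
) -> pd.DataFrame:
    """Young modulus versus friction ratio lambda_chi / lambda_med.

    Failures (discontinuous stress-strain curves, diverging relaxations) are
    data, flagged with ``defined=False``: below a critical ratio the
    intracellular dynamics destabilise and the cell stops behaving like a
    physical material.
    """
    rows = []
    for ratio in ratio_values:
        if not ratio > 0:
            raise ValueError(f"friction ratio must be > 0, got {ratio}")
        p = params.with_(lambda_med=lambda_med_fixed,
                         lambda_chi=float(ratio) * lambda_med_fixed)
        try:
            res = stress_strain_protocol(spec, p, **protocol_kw)
        except ProtocolError as exc:
            res = StressStrainResult(forces=np.zeros(0), stresses=np.zeros(0),
                                     strains=np.zeros(0), failed=True,
                                     failure_reason=str(exc))
        rows.append(dict(ratio=float(ratio), lambda_chi=p.lambda_chi,
                         Y=res.young_modulus, r_value=res.r_value,
                         defined=res.defined, reason=res.failure_reason))
    return pd.DataFrame(rows)


def find_critical_ratio(
    spec: CellShapeSpec = CellShapeSpec(),
    grid=None,
    lambda_med_fixed: float = 2.0,
    params: SimParams = SimParams(),
    **protocol_kw,
) -> tuple[float, pd.DataFrame]:
    """Locate the smallest friction ratio with a defined Young modulus.

    Scans ``grid`` (ascending) and reports the midpoint between the largest
    undefined and the smallest defined ratio; if every ratio is defined the
    lower grid edge is returned.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 0.325, 0.025), 4)
    table = sweep_friction_ratio(spec, grid, lambda_med_fixed, params,
                                 **protocol_kw)
    defined = table["defined"].to_numpy()
    if defined.all():
        return float(table["ratio"].iloc[0]), table
    if not defined.any():
        raise ProtocolError("no friction ratio in the grid yields a defined Y")
    last_bad = np.flatnonzero(~defined).max()
    first_good_after = last_bad + 1
    if first_good_after >= len(table):
        raise ProtocolError("largest grid ratio is still undefined")
    critical = 0.5 * (table["ratio"].iloc[last_bad]
                      + table["ratio"].iloc[first_good_after])
    return float(critical), table


def sweep_jte(
    jte_values=None,
    j_epi_fixed: float = 2.5,
    params: SimParams = SimParams(),
    time_scale: float = 1.0,
    rosette_kw: dict | None = None,
    sheet_kw: dict | None = None,
) -> pd.DataFrame:
    """Implantation sweep over trophectoderm stiffness J_TE.

    For each J_TE the full implantation scenario runs with lumenogenesis and
    detachment disabled; the final interface curvature theta, interface ratio
    Ir = L/D, and pushing distance H (lowest EPI point) are recorded, and the
    normalised fitness M is computed against the sweep's own optima.
    """
    if jte_values is None:
        jte_values = np.round(np.arange(0.0, 5.01, 0.1), 3)
    jte_values = np.asarray(jte_values, dtype=float)
    rows = []
    for jte in jte_values:
        p = params.with_(j_te=float(jte), j_epi=float(j_epi_fixed))
        pop = embryo_scenarios.build_rosette_epiblast(params=p,
                                                      **(rosette_kw or {}))
        embryo_scenarios.build_te_monolayer(on_top_of=pop, params=p,
                                            **(sheet_kw or {}))
        sc = embryo_scenarios.default_implantation_scenario(
            lumen=False, detach=False, time_scale=time_scale)
        series = embryo_scenarios.run_scenario(sc, pop, p).to_frame()
        final = series.iloc[-1]
        rows.append(dict(j_te=float(jte), theta=float(final["theta"]),
                         ir=float(final["LD"]), h=float(final["push_lowest"])))
    df = pd.DataFrame(rows)
    optima = dict(theta_min=df["theta"].min(), theta_max=df["theta"].max(),
                  ir_min=df["ir"].min(), ir_max=df["ir"].max(),
                  h_min=df["h"].min(), h_max=df["h"].max())
    df["m"] = [fitness_metric(r.theta, r.ir, r.h, optima,
                              degenerate="tied-zero")
               for r in df.itertuples()]
    for k, v in optima.items():
        df.attrs[k] = float(v)
    return df
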