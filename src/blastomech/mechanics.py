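"""Forces and overdamped dynamics.

Every interaction is a non-linear spring derived from a Morse potential.  The
force particle ``j`` exerts on particle ``i`` is

    F_ji = 2 J rho (exp(2 rho (r - r_eq)) - exp(rho (r - r_eq))) u_ij

with ``u_ij`` the unit vector from ``i`` toward ``j``: a stretched spring
(r > r_eq) attracts, a compressed one repels, and the force vanishes exactly
at ``r = r_eq``.  Motion is first-order overdamped: the net force on a
particle equals a friction coefficient times its velocity.  Membrane
particles feel internal (membrane-membrane) springs, the cytoskeleton spring
to the intracellular particle, transmitted external forces from adhering
particles of neighbouring cells, and optional specific forces (lumen
repulsion).  The intracellular particle feels the reaction of the
cytoskeleton springs (Newton's third law).

The integrator is explicit forward Euler; a configurable cap on the Morse
force magnitude guards against the exponential blow-up of transiently
near-coincident particles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SimParams",
    "SimulationError",
    "morse_scalar",
    "morse_force",
    "internal_and_cytoskeleton_forces",
    "external_forces",
    "specific_forces",
    "total_forces",
    "step",
    "elastic_energy",
    "relax",
]

_EXP_CLIP = 40.0  # clip rho*(r - r_eq) before exponentiation


class SimulationError(RuntimeError):
    """Numeric failure during integration (non-finite state, blow-up)."""


@dataclass(frozen=True)
class SimParams:
    """Global physical constants of a simulation.

    All quantities are dimensionless model units.

    j_te, j_epi:
        Morse interaction strengths for trophectoderm / epiblast springs.
    rho:
        Morse scaling factor (inverse length).
    lambda_med:
        Friction coefficient of membrane particles against the medium.
    lambda_chi:
        Friction coefficient of the intracellular particle.
    dt:
        Forward-Euler time step; event times in scenarios count steps.  The
        default keeps the integration stable when adhesion links stack
        transmitted forces on top of constriction-stiffened springs.
    force_cap_factor:
        Per-spring force magnitude is clamped at ``force_cap_factor * J * rho``.
    link_cutoff:
        Distance below which particles of neighbouring cells adhere
        (external links); default 0.9 * R with R = 0.5 — small enough that
        diagonally offset lattice cells (nearest particles ~1.2 R apart)
        never adhere, large enough that the curved epiblast surface (membrane
        particle spacing ~R) binds the draped trophectoderm sheet.
    max_links:
        Maximum external partners per membrane particle; the default admits
        one junctional bond along the particle's own epithelium plus one
        bond across a tissue interface.
    link_refresh:
        External links are recomputed every this many steps.
    """

    j_te: float = 2.5
    j_epi: float = 2.5
    rho: float = 1.0
    lambda_med: float = 2.0
    lambda_chi: float = 2.0
    dt: float = 0.005
    force_cap_factor: float = 100.0
    link_cutoff: float = 0.45
    max_links: int = 2
    link_refresh: int = 10

    def __post_init__(self) -> None:
        for name in ("rho", "lambda_med", "lambda_chi", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("j_te", "j_epi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def morse_scalar(J, rho, r, r_eq, cap: float | None = None):
    """Signed magnitude of the Morse spring force (positive = attraction).

    Vectorised over any broadcastable combination of arguments.
    """
    delta = np.clip(rho * (np.asarray(r) - np.asarray(r_eq)), -_EXP_CLIP, _EXP_CLIP)
    s = 2.0 * np.asarray(J) * rho * (np.exp(2.0 * delta) - np.exp(delta))
    if cap is not None:
        s = np.clip(s, -cap, cap)
    return s


def morse_force(J: float, rho: float, r: float, r_eq: float, u: np.ndarray,
                cap: float | None = None) -> np.ndarray:
    """Morse force on a particle, ``u`` pointing toward the other end.

    Zero exactly at ``r = r_eq``; attraction (along +u) for ``r > r_eq``.
    """
    if r <= 0:
        raise ValueError(f"coincident particles (r={r}); force direction undefined")
    if r_eq < 0:
        raise ValueError(f"r_eq must be >= 0, got {r_eq}")
    return morse_scalar(J, rho, r, r_eq, cap=cap) * np.asarray(u, dtype=float)


def _spring_J(pop, params: SimParams) -> np.ndarray:
    return np.where(pop.sp_is_te, params.j_te, params.j_epi)


def internal_and_cytoskeleton_forces(pop, params: SimParams) -> np.ndarray:
    """Per-particle accumulator of internal + cytoskeleton spring forces.

    For membrane particles this is the sum over internal neighbours plus the
    cytoskeleton spring; intracellular particles accumulate the reaction
    ``-sum_i F_i_chi`` automatically because every spring contributes equal
    and opposite forces to its two endpoints.
    """
    pos = pop.pos
    d = pos[pop.sp_j] - pos[pop.sp_i]
    r = np.linalg.norm(d, axis=1)
    r_safe = np.where(r > 1e-12, r, 1.0)
    u = d / r_safe[:, None]
    J = _spring_J(pop, params)
    s = morse_scalar(J, params.rho, r, pop.sp_req,
                     cap=params.force_cap_factor * params.rho * np.maximum(J, 1e-300))
    s = np.where(r > 1e-12, s, 0.0)  # coincident endpoints: no direction
    f = s[:, None] * u
    acc = np.zeros_like(pos)
    n = len(pos)
    for k in range(3):
        acc[:, k] += np.bincount(pop.sp_i, weights=f[:, k], minlength=n)
        acc[:, k] -= np.bincount(pop.sp_j, weights=f[:, k], minlength=n)
    return acc


def external_forces(pop, params: SimParams, internal: np.ndarray | None = None) -> np.ndarray:
    """Transmitted forces across adhesion links.

    Each linked particle receives a copy of its partner's internal +
    cytoskeleton force sum, so that adhering particles of neighbouring cells
    are submitted to equal forces.  Particles with no external neighbours get
    zero.
    """
    if internal is None:
        internal = internal_and_cytoskeleton_forces(pop, params)
    ext = np.zeros_like(pop.pos)
    la, lb = pop.link_a, pop.link_b
    if len(la):
        n = len(pop.pos)
        for k in range(3):
            ext[:, k] += np.bincount(la, weights=internal[lb, k], minlength=n)
            ext[:, k] += np.bincount(lb, weights=internal[la, k], minlength=n)
    return ext


def specific_forces(pop, params: SimParams) -> np.ndarray:
    """Sum of optional behaviour forces (lumen repulsion) per particle."""
    f = np.zeros_like(pop.pos)
    for source in getattr(pop, "lumen_sources", ()):
        idx, fs = source.forces(pop, params)
        np.add.at(f, idx, fs)
    return f


def total_forces(pop, params: SimParams,
                 extra: tuple[np.ndarray, np.ndarray] | None = None,
                 include_specific: bool = True) -> np.ndarray:
    internal = internal_and_cytoskeleton_forces(pop, params)
    f = internal + external_forces(pop, params, internal)
    if include_specific:
        f += specific_forces(pop, params)
    if extra is not None:
        idx, fe = extra
        np.add.at(f, idx, fe)
    return f


def step(pop, params: SimParams, n: int = 1,
         extra: tuple[np.ndarray, np.ndarray] | None = None,
         include_specific: bool = True) -> None:
    """Advance the population ``n`` forward-Euler steps in place.

    Membrane particles move by ``dt * F / lambda_med``, intracellular
    particles by ``dt * F / lambda_chi``.  ``extra`` is an optional
    ``(indices, forces)`` pair of constant applied forces (used by the
    materials-testing protocol).
    """
    inv_lam = pop.inv_friction(params)
    for _ in range(n):
        f = total_forces(pop, params, extra=extra, include_specific=include_specific)
        pop.pos += params.dt * f * inv_lam[:, None]
        pop.t += 1


def assert_finite(pop) -> None:
    """Raise SimulationError naming the offending particle pair if state blew up."""
    bad = ~np.isfinite(pop.pos).all(axis=1)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        # most-stretched spring touching i is the usual culprit
        mask = (pop.sp_i == i) | (pop.sp_j == i)
        pair = None
        if mask.any():
            k = int(np.flatnonzero(mask)[0])
            pair = (int(pop.sp_i[k]), int(pop.sp_j[k]))
        raise SimulationError(
            f"non-finite coordinates at particle {i} (cell "
            f"{int(pop.particle_cell[i])}); first incident spring pair {pair}"
        )


def elastic_energy(pop, cell_ids=None) -> float:
    """Total elastic energy: sum over springs of (r_eq - r)^2.

    Zero exactly when every spring is at its equilibrium length (resting
    state).  ``cell_ids`` restricts the sum to the springs of those cells.
    """
    r = np.linalg.norm(pop.pos[pop.sp_j] - pop.pos[pop.sp_i], axis=1)
    e = (pop.sp_req - r) ** 2
    if cell_ids is not None:
        mask = np.isin(pop.sp_cell, np.asarray(list(cell_ids)))
        e = e[mask]
    return float(e.sum())


def per_cell_elastic_energy(pop) -> np.ndarray:
    r = np.linalg.norm(pop.pos[pop.sp_j] - pop.pos[pop.sp_i], axis=1)
    return np.bincount(pop.sp_cell, weights=(pop.sp_req - r) ** 2,
                       minlength=len(pop.cells))


def relax(pop, params: SimParams,
          extra: tuple[np.ndarray, np.ndarray] | None = None,
          tol: float = 1e-8, patience: int = 100, max_steps: int = 100_000,
          refresh_links: bool = False,
          energy_limit: float = 1e9) -> tuple[bool, int]:
    """Step until the elastic energy stops changing.

    Convergence: ``|dE|`` per step below ``tol`` for ``patience`` consecutive
    steps.  Returns ``(converged, steps_used)``; raises
    :class:`SimulationError` on numeric blow-up (non-finite state or energy
    beyond ``energy_limit``).
    """
    e_prev = elastic_energy(pop)
    stable = 0
    for s in range(1, max_steps + 1):
        step(pop, params, extra=extra)
        if refresh_links and s % params.link_refresh == 0:
            pop.refresh_links(params)
        e = elastic_energy(pop)
        if not np.isfinite(e) or e > energy_limit:
            assert_finite(pop)
            raise SimulationError(f"elastic energy diverged (E={e}) after {s} steps")
        stable = stable + 1 if abs(e - e_prev) < tol else 0
        e_prev = e
        if stable >= patience:
            return True, s
    return False, max_steps
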