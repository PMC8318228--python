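"""Cell populations, lattice neighbourhoods and adhesion links.

Cells live on an integer lattice; two cells may adhere only if they are Moore
neighbours (coordinates differing by at most 1 on every axis — up to 26
neighbours: 8 in plane, 9 above, 9 below).  Within an approved cell pair,
membrane particles closer than a cutoff are linked pairwise; a link transmits
forces (see :mod:`blastomech.mechanics`), it is not an energy term.  Adhesion
can be broken per cell-type pair (tissue detachment) or per particle pair
(lumen opening); broken links never reactivate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .cell_mesh import (
    NUCLEUS,
    CellMesh,
    CellShapeSpec,
    internal_neighbors,
)

CELL_TYPES = ("TE", "EPI")


@dataclass
class CellRecord:
    """Bookkeeping for one cell inside a Population."""

    id: int
    cell_type: str
    spec: CellShapeSpec
    lattice: tuple[int, int, int]
    m_start: int            # first membrane particle (global index)
    m_stop: int             # one past last membrane particle
    nucleus: int            # global index of the intracellular particle
    triangles: np.ndarray   # local indices
    labels: np.ndarray      # membrane labels
    polarity: np.ndarray
    sp_start: int = 0
    sp_stop: int = 0
    # mutable behaviour state
    current_spec: CellShapeSpec = None
    apical_radius_now: float = None

    @property
    def membrane_idx(self) -> np.ndarray:
        return np.arange(self.m_start, self.m_stop)

    def particles_with_label(self, label: str) -> np.ndarray:
        return self.m_start + np.flatnonzero(self.labels == label)


def moore_cell_neighbors(lattice_coords) -> set[tuple[int, int]]:
    """Pairs of cell indices whose lattice coordinates are Chebyshev-adjacent.

    Raises on duplicate coordinates.
    """
    coords = [tuple(int(x) for x in c) for c in lattice_coords]
    if len(set(coords)) != len(coords):
        raise ValueError("duplicate lattice coordinates in population")
    arr = np.asarray(coords)
    pairs = set()
    for a, b in combinations(range(len(coords)), 2):
        if np.max(np.abs(arr[a] - arr[b])) <= 1:
            pairs.add((a, b))
    return pairs


class Population:
    """All cells of a simulation: flat particle/spring arrays plus records.

    Particle order: for each cell, its membrane particles then its
    intracellular particle.  Springs: internal-neighbour edges of the
    triangulation plus one cytoskeleton spring per membrane particle; at
    construction every equilibrium length equals the built length, so a
    freshly assembled population is exactly at rest.
    """

    def __init__(self) -> None:
        self.pos = np.zeros((0, 3))
        self.cells: list[CellRecord] = []
        self.particle_cell = np.zeros(0, dtype=np.int64)
        self.is_membrane = np.zeros(0, dtype=bool)
        self.labels = np.zeros(0, dtype="<U7")
        self.sp_i = np.zeros(0, dtype=np.int64)
        self.sp_j = np.zeros(0, dtype=np.int64)
        self.sp_req = np.zeros(0)
        self.sp_cell = np.zeros(0, dtype=np.int64)
        self.sp_is_te = np.zeros(0, dtype=bool)
        self.link_a = np.zeros(0, dtype=np.int64)
        self.link_b = np.zeros(0, dtype=np.int64)
        self.cell_pairs: set[tuple[int, int]] = set()
        self.broken_type_pairs: set[frozenset] = set()
        self._blacklist: set[tuple[int, int]] = set()
        self.lumen_sources: list = []
        self.t = 0

    # ------------------------------------------------------------------ build
    def add_cell(self, mesh: CellMesh, cell_type: str,
                 lattice: tuple[int, int, int]) -> CellRecord:
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r}; known: {CELL_TYPES}")
        cid = len(self.cells)
        m_start = len(self.pos)
        n_mem = mesh.n_particles
        nucleus = m_start + n_mem
        self.pos = np.vstack([self.pos, mesh.positions, mesh.nucleus_position[None, :]])
        self.particle_cell = np.concatenate(
            [self.particle_cell, np.full(n_mem + 1, cid, dtype=np.int64)])
        self.is_membrane = np.concatenate(
            [self.is_membrane, np.ones(n_mem, dtype=bool), [False]])
        self.labels = np.concatenate(
            [self.labels, mesh.labels, np.array([NUCLEUS], dtype="<U7")])

        edges = internal_neighbors(mesh)  # local
        cyto = np.stack([np.arange(n_mem), np.full(n_mem, n_mem)], axis=1)
        local = np.vstack([edges, cyto])
        gi = local[:, 0] + m_start
        gj = local[:, 1] + m_start
        sp_start = len(self.sp_i)
        self.sp_i = np.concatenate([self.sp_i, gi])
        self.sp_j = np.concatenate([self.sp_j, gj])
        req = np.linalg.norm(self.pos[gj] - self.pos[gi], axis=1)
        self.sp_req = np.concatenate([self.sp_req, req])
        self.sp_cell = np.concatenate(
            [self.sp_cell, np.full(len(gi), cid, dtype=np.int64)])
        self.sp_is_te = np.concatenate(
            [self.sp_is_te, np.full(len(gi), cell_type == "TE")])

        rec = CellRecord(
            id=cid, cell_type=cell_type, spec=mesh.spec,
            lattice=tuple(int(x) for x in lattice),
            m_start=m_start, m_stop=m_start + n_mem, nucleus=nucleus,
            triangles=mesh.triangles, labels=mesh.labels.copy(),
            polarity=np.asarray(mesh.polarity, dtype=float),
            sp_start=sp_start, sp_stop=len(self.sp_i),
            current_spec=mesh.spec, apical_radius_now=mesh.spec.apical_radius,
        )
        self.cells.append(rec)
        return rec

    def rebuild_cell_pairs(self) -> None:
        self.cell_pairs = moore_cell_neighbors([c.lattice for c in self.cells])

    # ------------------------------------------------------------- properties
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_of_type(self, cell_type: str) -> list[CellRecord]:
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r}; known: {CELL_TYPES}")
        return [c for c in self.cells if c.cell_type == cell_type]

    def membrane_idx_of(self, cell_ids) -> np.ndarray:
        return np.concatenate([self.cells[c].membrane_idx for c in cell_ids])

    def tissue_particles(self, cell_type: str) -> np.ndarray:
        """All particles (membrane + intracellular) of a tissue."""
        ids = [c.id for c in self.cells_of_type(cell_type)]
        if not ids:
            return np.zeros(0, dtype=np.int64)
        return np.flatnonzero(np.isin(self.particle_cell, ids))

    def inv_friction(self, params) -> np.ndarray:
        inv = np.where(self.is_membrane, 1.0 / params.lambda_med,
                       1.0 / params.lambda_chi)
        return inv

    # ------------------------------------------------------------------ links
    def _pair_allowed(self, ca: int, cb: int) -> bool:
        ta, tb = self.cells[ca].cell_type, self.cells[cb].cell_type
        return frozenset((ta, tb)) not in self.broken_type_pairs

    def candidate_links(self, cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All membrane particle pairs of Moore-approved cell pairs within cutoff.

        Returns ``(a, b, distance)`` with a < b, before the per-particle cap.
        """
        mem = np.flatnonzero(self.is_membrane)
        if len(mem) == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0)
        tree = cKDTree(self.pos[mem])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0)
        a = mem[pairs[:, 0]]
        b = mem[pairs[:, 1]]
        ca, cb = self.particle_cell[a], self.particle_cell[b]
        keep = ca != cb
        a, b, ca, cb = a[keep], b[keep], ca[keep], cb[keep]
        if len(a):
            approved = np.zeros((self.n_cells, self.n_cells), dtype=bool)
            for (x, y) in self.cell_pairs:
                if self._pair_allowed(x, y):
                    approved[x, y] = approved[y, x] = True
            keep = approved[ca, cb]
            a, b = a[keep], b[keep]
        if len(a) and self._blacklist:
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            bl = np.asarray(sorted(self._blacklist), dtype=np.int64)
            keys = lo.astype(np.int64) * len(self.pos) + hi
            blk = bl[:, 0] * len(self.pos) + bl[:, 1]
            keep = ~np.isin(keys, blk)
            a, b = a[keep], b[keep]
        d = np.linalg.norm(self.pos[a] - self.pos[b], axis=1)
        return a, b, d

    @staticmethod
    def _directed_rank_filter(a, b, d, group_extra, k: int) -> np.ndarray:
        """Keep pairs where both directed entries rank < k in their group.

        A directed entry's group is ``(owner particle, group_extra)``; within
        each group entries are ranked by distance (ties broken by partner
        index for determinism).
        """
        owners = np.concatenate([a, b])
        partners = np.concatenate([b, a])
        extra = np.concatenate([group_extra, group_extra])
        dist = np.concatenate([d, d])
        order = np.lexsort((partners, dist, extra, owners))
        key = owners[order] * (extra.max() + 1 if len(extra) else 1) + extra[order]
        first = np.concatenate([[0], np.flatnonzero(np.diff(key)) + 1])
        sizes = np.diff(np.concatenate([first, [len(key)]]))
        ranks = np.arange(len(key)) - np.repeat(first, sizes)
        ok_dir = np.zeros(len(owners), dtype=bool)
        ok_dir[order] = ranks < k
        return ok_dir[: len(a)] & ok_dir[len(a):]

    def refresh_links(self, params) -> None:
        """Recompute external links: mutual nearest per tissue relation.

        Same-tissue adhesion is junctional: only apical-apical particle
        pairs bond (the apical junction belt of an epithelium), which keeps
        a sheet cohesive while leaving basal sides free to splay — the hinge
        motion apical constriction needs to fold a sheet.  Cross-tissue
        adhesion binds any particle pair of the apposed surfaces.  Within
        each class every particle links to its mutual nearest candidate
        (both endpoints must rank each other first in that class), and a
        final mutual-rank cap enforces at most ``max_links`` partners per
        particle.  Symmetric and deterministic.
        """
        a, b, d = self.candidate_links(params.link_cutoff)
        if len(a) == 0:
            self.link_a = np.zeros(0, dtype=np.int64)
            self.link_b = np.zeros(0, dtype=np.int64)
            return
        ta = np.array([self.cells[c].cell_type for c in self.particle_cell[a]])
        tb = np.array([self.cells[c].cell_type for c in self.particle_cell[b]])
        cross = (ta != tb).astype(np.int64)
        apical = (self.labels[a] == "apical") & (self.labels[b] == "apical")
        keep = (cross == 1) | apical
        a, b, d, cross = a[keep], b[keep], d[keep], cross[keep]
        if len(a) == 0:
            self.link_a = np.zeros(0, dtype=np.int64)
            self.link_b = np.zeros(0, dtype=np.int64)
            return
        ok = self._directed_rank_filter(a, b, d, cross, 1)
        a, b, d = a[ok], b[ok], d[ok]
        if len(a):
            ok = self._directed_rank_filter(
                a, b, d, np.zeros(len(a), dtype=np.int64), params.max_links)
            a, b = a[ok], b[ok]
        self.link_a = a
        self.link_b = b

    def deactivate_links(self, pairs) -> None:
        """Permanently break specific particle pairs (never re-linked)."""
        for (x, y) in pairs:
            self._blacklist.add((min(int(x), int(y)), max(int(x), int(y))))
        if len(self.link_a):
            lo = np.minimum(self.link_a, self.link_b)
            hi = np.maximum(self.link_a, self.link_b)
            keep = np.array([(int(l), int(h)) not in self._blacklist
                             for l, h in zip(lo, hi)])
            self.link_a = self.link_a[keep]
            self.link_b = self.link_b[keep]

    def break_adhesion(self, type_a: str, type_b: str) -> None:
        """Detach two tissues: drop and forbid all cross-type links.

        Intra-type mechanics are untouched; each tissue keeps its own
        dynamics.
        """
        for t in (type_a, type_b):
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r}; known: {CELL_TYPES}")
        self.broken_type_pairs.add(frozenset((type_a, type_b)))
        if len(self.link_a):
            ta = np.array([self.cells[c].cell_type for c in
                           self.particle_cell[self.link_a]])
            tb = np.array([self.cells[c].cell_type for c in
                           self.particle_cell[self.link_b]])
            fs = frozenset((type_a, type_b))
            keep = np.array([frozenset((x, y)) != fs for x, y in zip(ta, tb)])
            self.link_a = self.link_a[keep]
            self.link_b = self.link_b[keep]

    # ------------------------------------------------------------------ misc
    def adhesion_table(self):
        """Active links as plain records (cell_a, particle_a, cell_b, particle_b, t)."""
        return [
            dict(cell_a=int(self.particle_cell[a]), particle_a=int(a),
                 cell_b=int(self.particle_cell[b]), particle_b=int(b),
                 active=True, t=int(self.t))
            for a, b in zip(self.link_a, self.link_b)
        ]

    def copy(self) -> "Population":
        import copy as _copy
        return _copy.deepcopy(self)


def brute_force_links(pop: Population, cutoff: float):
    """O(n^2) oracle for :meth:`Population.candidate_links` (tests)."""
    mem = np.flatnonzero(pop.is_membrane)
    out = []
    approved = {frozenset(p) for p in pop.cell_pairs
                if pop._pair_allowed(*p)}
    for ii in range(len(mem)):
        for jj in range(ii + 1, len(mem)):
            a, b = int(mem[ii]), int(mem[jj])
            ca, cb = int(pop.particle_cell[a]), int(pop.particle_cell[b])
            if ca == cb or frozenset((ca, cb)) not in approved:
                continue
            if (min(a, b), max(a, b)) in pop._blacklist:
                continue
            if np.linalg.norm(pop.pos[a] - pop.pos[b]) <= cutoff:
                out.append((a, b))
    return out
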