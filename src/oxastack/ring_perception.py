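"""Perception and chemical classification of planar 5- and 6-membered rings.

A ring is accepted when it is a chordless cycle of size 5 or 6 in the
covalent bond graph, fits a least-squares plane with RMSD at or below the
planarity threshold (default 0.10 A — aromatic rings sit well below, chair
cyclohexane at ~0.25 A is rejected), and contains no saturated member (every
ring atom has at most three non-hydrogen neighbours).

Aromaticity is deliberately approximated by planarity plus that degree
heuristic rather than electron counting: downstream screening operates on
ring identity and geometry only.  Fused systems contribute one ring per
smallest cycle (naphthalene = two six-rings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structure_io import AtomSite, BondGraph

__all__ = ["Ring", "fit_plane", "find_rings", "classify_ring", "perceive_rings",
           "PLANARITY_RMSD_DEFAULT"]

PLANARITY_RMSD_DEFAULT = 0.10  # A

RING_CLASSES = ("oxadiazole-1,2,4", "oxadiazole-1,3,4", "pyridine", "phenyl",
                "other-5", "other-6")

OXADIAZOLE_CLASSES = ("oxadiazole-1,2,4", "oxadiazole-1,3,4")


@dataclass
class Ring:
    """A perceived planar ring.

    ``atom_indices`` is the cycle in bond order; ``role_labels`` aligns with
    it (e.g. O1,N2,C3,N4,C5 for a 1,2,4-oxadiazole).
    """

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rmsd: float
    ring_class: str = "other-6"
    role_labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def size(self) -> int:
        return len(self.atom_indices)

    @property
    def is_oxadiazole(self) -> bool:
        return self.ring_class in OXADIAZOLE_CLASSES

    def role_of(self, atom_index: int) -> str:
        return self.role_labels[self.atom_indices.index(atom_index)]

    def with_coordinates(self, coords: np.ndarray) -> "Ring":
        """The same ring re-fitted on mapped member coordinates (e.g. a
        symmetry image); class and roles carry over."""
        centroid, normal, rmsd = fit_plane(coords)
        return Ring(self.atom_indices, centroid, normal, rmsd,
                    self.ring_class, self.role_labels)


def fit_plane(points) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through ``points``.

    Returns (centroid, unit normal, rmsd).  The normal is the principal
    direction of the smallest moment; its sign is fixed to have a positive z
    component (ties broken toward +x, then +y) so results are reproducible.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("points are collinear or degenerate; no unique plane")
    normal = vt[2]
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-10:
            if normal[comp] < 0:
                normal = -normal
            break
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal / np.linalg.norm(normal), rmsd


def _is_chordless(graph: nx.Graph, cycle: list[int]) -> bool:
    n = len(cycle)
    members = set(cycle)
    for idx, u in enumerate(cycle):
        for v in graph.neighbors(u):
            if v in members and v not in (cycle[(idx - 1) % n], cycle[(idx + 1) % n]):
                return False
    return True


def find_rings(graph: BondGraph, sites: list[AtomSite],
               planarity_rmsd: float = PLANARITY_RMSD_DEFAULT) -> list[Ring]:
    """All chordless 5-/6-cycles passing the planarity and saturation filters.

    Rings come back unclassified (``ring_class`` left at its default) in a
    deterministic order (sorted by their smallest atom index).
    """
    g = graph.graph
    seen: set[frozenset] = set()
    rings: list[Ring] = []
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) not in (5, 6):
            continue
        key = frozenset(cycle)
        if key in seen or not _is_chordless(g, cycle):
            continue
        seen.add(key)
        if any(graph.degree_heavy(i, sites) > 3 for i in cycle):
            continue
        coords = np.array([sites[i].cart for i in cycle])
        try:
            centroid, normal, rmsd = fit_plane(coords)
        except ValueError:
            continue
        if rmsd > planarity_rmsd:
            continue
        cycle = _canonical_cycle(cycle)
        rings.append(Ring(tuple(cycle), centroid, normal, rmsd))
    rings.sort(key=lambda r: r.atom_indices)
    return rings


def _canonical_cycle(cycle: list[int]) -> list[int]:
    """Rotate/orient the cycle to start at its smallest index, smaller
    neighbour second — removes dependence on traversal direction/offset."""
    n = len(cycle)
    start = cycle.index(min(cycle))
    rot = cycle[start:] + cycle[:start]
    if rot[1] > rot[-1]:
        rot = [rot[0]] + rot[:0:-1]
    return rot


def classify_ring(ring: Ring, sites: list[AtomSite], graph: BondGraph | None = None) -> Ring:
    """Assign ``ring_class`` and per-atom role labels from the element cycle.

    Five-rings: O,N,C,N,C with an N adjacent to O -> 1,2,4-oxadiazole
    (roles O1,N2,C3,N4,C5); O,C,N,N,C with both N away from O ->
    1,3,4-oxadiazole (roles O1,C2,N3,N4,C5).  Six-rings: C6 -> phenyl,
    C5N -> pyridine.  Anything else -> other-5 / other-6.
    """
    idx = list(ring.atom_indices)
    elems = [sites[i].element for i in idx]
    n = len(idx)

    def rotations():
        seq = list(range(n))
        for start in range(n):
            fwd = [(start + k) % n for k in range(n)]
            rev = [(start - k) % n for k in range(n)]
            yield fwd
            yield rev
        del seq

    ring_class = f"other-{n}"
    roles: tuple[str, ...] = tuple(f"{e}{i+1}" for i, e in enumerate(elems))

    if n == 5 and sorted(elems) == ["C", "C", "N", "N", "O"]:
        matches_124 = []
        matches_134 = []
        for order in rotations():
            pat = [elems[k] for k in order]
            if pat == ["O", "N", "C", "N", "C"]:
                matches_124.append(order)
            elif pat == ["O", "C", "N", "N", "C"]:
                matches_134.append(order)
        if matches_124:
            order = _pick_order(matches_124, idx)
            ring_class = "oxadiazole-1,2,4"
            role_seq = ("O1", "N2", "C3", "N4", "C5")
        elif matches_134:
            order = _pick_order(matches_134, idx)
            ring_class = "oxadiazole-1,3,4"
            role_seq = ("O1", "C2", "N3", "N4", "C5")
        else:
            order = None
        if ring_class.startswith("oxadiazole"):
            reordered = [idx[k] for k in order]
            inv = {atom: role for atom, role in zip(reordered, role_seq)}
            roles = tuple(inv[i] for i in idx)
    elif n == 6:
        if elems == ["C"] * 6:
            ring_class = "phenyl"
            roles = tuple(f"C{i+1}" for i in range(6))
        elif sorted(elems) == ["C", "C", "C", "C", "C", "N"]:
            ring_class = "pyridine"
            at_n = elems.index("N")
            roles = tuple(f"{elems[k % 6]}{(k - at_n) % 6 + 1}" for k in range(6))

    return Ring(ring.atom_indices, ring.centroid, ring.normal,
                ring.planarity_rmsd, ring_class, roles)


def _pick_order(orders: list[list[int]], idx: list[int]) -> list[int]:
    """Deterministic tie-break among symmetry-equivalent role assignments:
    smallest atom-index sequence wins."""
    return min(orders, key=lambda order: [idx[k] for k in order])


def perceive_rings(sites: list[AtomSite], graph: BondGraph,
                   planarity_rmsd: float = PLANARITY_RMSD_DEFAULT) -> list[Ring]:
    """find + classify in one call."""
    return [classify_ring(r, sites, graph)
            for r in find_rings(graph, sites, planarity_rmsd)]
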