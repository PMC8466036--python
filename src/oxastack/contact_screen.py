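"""Distance/angle screening of (oxadiazole)...pi contacts and their census.

The screen re-implements, over locally supplied structure files, the classic
database-survey criterion for ring-atom...pi contacts:

* distance d1 between a query oxadiazole ring atom Q and a partner atom X
  (any non-hydrogen atom belonging to a 5- or 6-membered pi-ring) no larger
  than the Bondi vdW-radius sum + 0.5 A;
* the two angles a1, a2 subtended at Q between the contact vector and Q's
  two in-ring bonds both within [65, 115] deg (near 90 deg means X sits
  roughly along the local ring normal).  The same window is also enforced at
  the X end when X has two in-ring bonds (both readings of the published
  two-angle construction must pass).
* when several contacts qualify for the same (structure, query ring, partner
  ring), only the shortest is kept for totals.

An alternative angular convention (contact vector within 25 deg of the ring
plane normal) is available through ``ScreenCriteria.angle_convention``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._elements import vdw_radius
from .ring_perception import OXADIAZOLE_CLASSES, Ring, perceive_rings
from .stacking_geometry import _vec_angle_deg
from .structure_io import (
    IDENTITY_CODE,
    BondGraph,
    CrystalStructure,
    build_bond_graph,
    molecule_ids,
    symmetry_cart_transforms,
)

__all__ = ["ScreenCriteria", "ContactRecord", "CensusTable",
           "screen_structure", "screen_protein_complex",
           "select_shortest", "census"]

PROTEIN_AROMATIC_RESIDUES = ("PHE", "TYR", "TRP", "HIS")

R_FACTOR_MAX = 0.1  # corpus-ingestion quality filter


@dataclass
class ScreenCriteria:
    distance_slack: float = 0.5        # A beyond the Bondi vdW sum
    angle_lo: float = 65.0             # deg
    angle_hi: float = 115.0            # deg
    exclude_hydrogen: bool = True
    partner_ring_sizes: tuple[int, ...] = (5, 6)
    angle_convention: str = "in-ring-bonds"   # or "normal"
    normal_tilt_max: float = 25.0      # deg, for the "normal" convention

    def __post_init__(self) -> None:
        if self.angle_lo >= self.angle_hi:
            raise ValueError("angle_lo must be below angle_hi")
        if self.distance_slack < 0:
            raise ValueError("distance_slack must be non-negative")
        if self.angle_convention not in ("in-ring-bonds", "normal"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


@dataclass
class ContactRecord:
    """One qualifying atom-atom contact between a query oxadiazole ring atom
    and a partner pi-ring atom."""

    structure: str
    query_ring_class: str
    query_ring_id: int
    query_atom_label: str
    query_atom_role: str
    query_element: str
    partner_ring_class: str
    partner_ring_id: int
    partner_ring_size: int
    partner_atom_label: str
    partner_element: str
    d1: float
    a1: float
    a2: float
    symmetry_code: tuple[int, int, int, int] = IDENTITY_CODE

    def __post_init__(self) -> None:
        self.symmetry_code = tuple(self.symmetry_code)  # JSON round-trip

    @property
    def pair_key(self) -> tuple:
        # symmetry images fold together: of several contacts between the same
        # two rings, only the shortest is selected
        return (self.structure, self.query_ring_id, self.partner_ring_id)


def _in_ring_bond_vectors(ring: Ring, pos_in_cycle: int, coords: np.ndarray
                          ) -> list[np.ndarray]:
    n = ring.size
    here = coords[pos_in_cycle]
    return [coords[(pos_in_cycle - 1) % n] - here,
            coords[(pos_in_cycle + 1) % n] - here]


def _angles_pass(criteria: ScreenCriteria, contact_vec: np.ndarray,
                 ring: Ring, pos_in_cycle: int, coords: np.ndarray
                 ) -> tuple[bool, float, float]:
    if criteria.angle_convention == "normal":
        tilt = min(_vec_angle_deg(contact_vec, ring.normal),
                   _vec_angle_deg(contact_vec, -ring.normal))
        return tilt <= criteria.normal_tilt_max, tilt, tilt
    b1, b2 = _in_ring_bond_vectors(ring, pos_in_cycle, coords)
    a1 = _vec_angle_deg(contact_vec, b1)
    a2 = _vec_angle_deg(contact_vec, b2)
    ok = (criteria.angle_lo <= a1 <= criteria.angle_hi
          and criteria.angle_lo <= a2 <= criteria.angle_hi)
    return ok, a1, a2


def _screen_rings(structure: CrystalStructure, query_rings: list[Ring],
                  partner_rings: list[Ring], criteria: ScreenCriteria,
                  graph: BondGraph, expand: bool) -> list[ContactRecord]:
    sites = structure.sites
    cart = structure.cart
    mol = molecule_ids(graph)
    ring_mol = {id(r): int(mol[r.atom_indices[0]]) for r in query_rings + partner_rings}

    max_d = 2 * 1.80 + criteria.distance_slack  # S is the largest supported vdW here
    transforms = symmetry_cart_transforms(structure, max_d + 3.0) if expand \
        else [(IDENTITY_CODE, np.eye(3), np.zeros(3))]

    records: list[ContactRecord] = []
    for code, A, b in transforms:
        mapped = cart @ A.T + b
        for pj, pring in enumerate(partner_rings):
            if pring.size not in criteria.partner_ring_sizes:
                continue
            p_coords = mapped[list(pring.atom_indices)]
            p_ring_img = pring.with_coordinates(p_coords)
            for qj, qring in enumerate(query_rings):
                if code == IDENTITY_CODE and (
                        ring_mol[id(qring)] == ring_mol[id(pring)]):
                    continue
                if code == IDENTITY_CODE and set(qring.atom_indices) & set(pring.atom_indices):
                    continue
                q_coords = cart[list(qring.atom_indices)]
                for qpos, qi in enumerate(qring.atom_indices):
                    qsite = sites[qi]
                    for ppos, pi_ in enumerate(pring.atom_indices):
                        psite = sites[pi_]
                        if criteria.exclude_hydrogen and psite.is_hydrogen:
                            continue
                        vec = p_coords[ppos] - q_coords[qpos]
                        d1 = float(np.linalg.norm(vec))
                        limit = (vdw_radius(qsite.element)
                                 + vdw_radius(psite.element)
                                 + criteria.distance_slack)
                        if d1 > limit or d1 < 1e-6:
                            continue
                        ok_q, a1, a2 = _angles_pass(criteria, vec, qring, qpos, q_coords)
                        if not ok_q:
                            continue
                        ok_p, _, _ = _angles_pass(criteria, -vec, p_ring_img, ppos, p_coords)
                        if not ok_p:
                            continue
                        records.append(ContactRecord(
                            structure=structure.name,
                            query_ring_class=qring.ring_class,
                            query_ring_id=qj,
                            query_atom_label=qsite.label,
                            query_atom_role=qring.role_labels[qpos],
                            query_element=qsite.element,
                            partner_ring_class=pring.ring_class,
                            partner_ring_id=pj,
                            partner_ring_size=pring.size,
                            partner_atom_label=psite.label,
                            partner_element=psite.element,
                            d1=d1, a1=float(a1), a2=float(a2),
                            symmetry_code=code))
    records.sort(key=lambda r: (r.structure, r.d1))
    return records


def screen_structure(structure: CrystalStructure,
                     criteria: ScreenCriteria | None = None,
                     rings: list[Ring] | None = None,
                     graph: BondGraph | None = None) -> list[ContactRecord]:
    """Screen one (small-molecule) structure for oxadiazole...pi contacts.

    Query rings are the perceived oxadiazoles; partners are all perceived
    pi-rings of the allowed sizes.  Crystal symmetry images are included
    when the structure is periodic.
    """
    criteria = criteria or ScreenCriteria()
    if structure.r_factor is not None and structure.r_factor > R_FACTOR_MAX:
        import warnings
        warnings.warn(f"{structure.name}: R-factor {structure.r_factor:.3f} "
                      f"> {R_FACTOR_MAX}; structure skipped", stacklevel=2)
        return []
    graph = graph or build_bond_graph(structure.sites)
    rings = rings if rings is not None else perceive_rings(structure.sites, graph)
    queries = [r for r in rings if r.is_oxadiazole]
    return _screen_rings(structure, queries, rings, criteria, graph,
                         expand=structure.is_periodic)


def screen_protein_complex(structure: CrystalStructure,
                           criteria: ScreenCriteria | None = None
                           ) -> list[ContactRecord]:
    """Screen a protein-ligand complex across the interface.

    Query rings: oxadiazoles among HETATM ligand rings.  Partner rings:
    aromatic side chains (PHE/TYR/TRP/HIS) and any other perceived pi-ring
    not belonging to the ligand.  No symmetry expansion is attempted unless
    the file carries a cell with more than the identity operator.
    """
    criteria = criteria or ScreenCriteria()
    graph = build_bond_graph(structure.sites)
    rings = perceive_rings(structure.sites, graph)
    sites = structure.sites

    def ring_is_ligand(r: Ring) -> bool:
        return all(sites[i].is_hetero for i in r.atom_indices)

    queries = [r for r in rings if r.is_oxadiazole and ring_is_ligand(r)]
    if not queries:
        import warnings
        warnings.warn(f"{structure.name}: no oxadiazole-containing hetero "
                      "ligand ring found", stacklevel=2)
        return []
    partners = [r for r in rings if not ring_is_ligand(r)
                and (sites[r.atom_indices[0]].residue in PROTEIN_AROMATIC_RESIDUES
                     or r.ring_class in ("phenyl", "pyridine", "other-5", "other-6"))]
    expand = structure.is_periodic and len(structure.ops) > 1
    return _screen_rings(structure, queries, partners, criteria, graph, expand)


def select_shortest(records: list[ContactRecord]) -> list[ContactRecord]:
    """One record per (structure, query ring, partner ring, image): the
    minimal d1, ties broken by lowest atom labels."""
    groups: dict[tuple, ContactRecord] = {}
    for rec in records:
        key = rec.pair_key
        prev = groups.get(key)
        if prev is None:
            groups[key] = rec
            continue
        cand = min(prev, rec, key=lambda r: (r.d1, r.query_atom_label,
                                             r.partner_atom_label))
        groups[key] = cand
    return sorted(groups.values(), key=lambda r: (r.structure, r.d1))


@dataclass
class CensusTable:
    """Counts of screened contacts in the shape of a survey table.

    ``totals`` counts structures (one per structure per cell, via the
    shortest-contact rule); ``role_counts`` counts participating query-atom
    roles over all qualifying contacts; ``homoleptic`` counts structures
    whose five-ring partner is itself an oxadiazole.
    """

    totals: dict[tuple[str, int], int] = field(default_factory=dict)
    role_counts: dict[tuple[str, int, str], int] = field(default_factory=dict)
    element_counts: dict[tuple[str, int, str], int] = field(default_factory=dict)
    homoleptic: dict[str, int] = field(default_factory=dict)
    n_shortest_records: int = 0

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (iso, size), total in sorted(self.totals.items()):
            row = {"oxadiazole": iso, "partner_size": size, "total": total,
                   "homoleptic": self.homoleptic.get(iso, 0) if size == 5 else 0}
            for el in ("C", "N", "O"):
                row[el] = self.element_counts.get((iso, size, el), 0)
            rows.append(row)
        return pd.DataFrame(rows)


def census(records: list[ContactRecord],
           shortest: list[ContactRecord] | None = None) -> CensusTable:
    """Tabulate screened contacts; ``shortest`` defaults to
    :func:`select_shortest` over ``records``."""
    shortest = select_shortest(records) if shortest is None else shortest
    table = CensusTable(n_shortest_records=len(shortest))

    structures_per_cell: dict[tuple[str, int], set] = defaultdict(set)
    homoleptic_structs: dict[str, set] = defaultdict(set)
    for rec in shortest:
        cell = (rec.query_ring_class, rec.partner_ring_size)
        structures_per_cell[cell].add((rec.structure, rec.query_ring_id))
        if rec.partner_ring_class in OXADIAZOLE_CLASSES and rec.partner_ring_size == 5:
            homoleptic_structs[rec.query_ring_class].add((rec.structure, rec.query_ring_id))
    table.totals = {cell: len(s) for cell, s in structures_per_cell.items()}
    table.homoleptic = {iso: len(s) for iso, s in homoleptic_structs.items()}

    for rec in records:
        key = (rec.query_ring_class, rec.partner_ring_size, rec.query_atom_role)
        table.role_counts[key] = table.role_counts.get(key, 0) + 1
        ekey = (rec.query_ring_class, rec.partner_ring_size, rec.query_element)
        table.element_counts[ekey] = table.element_counts.get(ekey, 0) + 1
    return table
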