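"""Ring-pair stacking descriptors, pi-stack classification, lp...pi contacts.

For two rings with centroids cA, cB and unit plane normals nA, nB the
descriptor set is

* ``R``  = |cA - cB|, the centroid-centroid distance;
* ``h1`` = |(cA - cB) . nB|, distance from centroid A to plane B
  (``h2`` symmetrically from B to plane A);
* ``r1`` = in-plane slip: distance from the projection of cA onto plane B to
  cB (``r2`` symmetrically), so that r_i^2 + h_i^2 = R^2 holds exactly;
* ``theta`` = interplanar angle, folded to [0, 90] deg;
* ``phi``  = twist angle between the rings' in-plane reference axes
  (centroid -> highest-priority atom, O > N > C then lexicographic label),
  folded to [0, 90] deg.  For homocyclic rings (phenyl) the reference atom is
  a pure convention and phi is flagged accordingly.

The slip pairing (r_i measured in plane j against centroid j) is the reading
of the descriptor set that makes the right-triangle identity exact; it is
the construction consistent with published descriptor tables for
parallel-displaced stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._elements import vdw_radius
from .ring_perception import Ring
from .structure_io import (
    IDENTITY_CODE,
    AtomSite,
    BondGraph,
    CrystalStructure,
    invert_code,
    molecule_ids,
    symmetry_cart_transforms,
)

__all__ = [
    "RingPairGeometry", "LpPiContact", "StackThresholds", "LpPiParams",
    "pair_geometry", "classify_stack", "enumerate_stacking_pairs", "find_lp_pi",
    "fold_angle",
]


def fold_angle(deg: float) -> float:
    """Fold an angle in degrees into [0, 90] (a and 180 - a are equivalent)."""
    a = abs(deg) % 180.0
    return 180.0 - a if a > 90.0 else a


def _vec_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Numerically robust angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)), float(u @ v)))


@dataclass
class RingPairGeometry:
    """The full descriptor tuple for one ring pair."""

    R: float
    h1: float
    h2: float
    r1: float
    r2: float
    phi: float
    theta: float
    ring_a: Ring | None = None
    ring_b: Ring | None = None
    symmetry_code: tuple[int, int, int, int] = IDENTITY_CODE
    classification: str = "none"
    phi_convention_dependent: bool = False

    def swapped(self) -> "RingPairGeometry":
        return replace(self, h1=self.h2, h2=self.h1, r1=self.r2, r2=self.r1,
                       ring_a=self.ring_b, ring_b=self.ring_a)


@dataclass
class StackThresholds:
    """Defaults bracket typical parallel / parallel-displaced stacks; they are
    screening defaults, not physical claims."""

    R_max: float = 4.0       # A
    theta_max: float = 25.0  # deg
    h_min: float = 2.8       # A


@dataclass
class LpPiParams:
    distance_tolerance: float = 0.1   # A beyond the vdW sum
    elevation_min: float = 45.0       # deg above the ring plane
    donor_elements: tuple[str, ...] = ("N", "O")


@dataclass
class LpPiContact:
    """A lone-pair...pi contact: N/O donor above the face of a ring."""

    donor_index: int
    donor_element: str
    donor_label: str
    acceptor_atom_index: int
    acceptor_atom_label: str
    acceptor_ring_class: str
    d: float                 # donor -> closest ring atom, A
    d_centroid: float        # donor -> ring centroid, A
    elevation: float         # deg between donor->centroid and ring plane
    symmetry_code: tuple[int, int, int, int] = IDENTITY_CODE


_PRIORITY = {"O": 0, "N": 1, "C": 2}


def _reference_axis(ring: Ring, coords: np.ndarray, sites: list[AtomSite] | None = None
                    ) -> tuple[np.ndarray, bool]:
    """centroid -> highest-priority atom; returns (axis, convention_dependent)."""
    if sites is not None:
        elems = [sites[i].element for i in ring.atom_indices]
        labels = [sites[i].label for i in ring.atom_indices]
    else:
        elems = [role.rstrip("0123456789") for role in ring.role_labels] or \
            ["C"] * ring.size
        labels = list(ring.role_labels) or [f"C{i}" for i in range(ring.size)]
    order = sorted(range(ring.size),
                   key=lambda k: (_PRIORITY.get(elems[k], 9), labels[k]))
    best = order[0]
    convention_dependent = len(set(elems)) == 1
    axis = coords[best] - ring.centroid
    return axis, convention_dependent


def pair_geometry(ring_a: Ring, ring_b: Ring,
                  coords_a: np.ndarray, coords_b: np.ndarray,
                  sites: list[AtomSite] | None = None) -> RingPairGeometry:
    """Descriptors for a ring pair given each ring's member coordinates.

    ``coords_a``/``coords_b`` are the Cartesian coordinates of the ring
    members (in cycle order), so symmetry images can be fed directly.
    """
    cA, cB = ring_a.centroid, ring_b.centroid
    nA, nB = ring_a.normal, ring_b.normal
    dvec = cA - cB
    R = float(np.linalg.norm(dvec))
    if R < 1e-6:
        raise ValueError("ring centroids coincide; descriptors undefined")
    h1 = abs(float(dvec @ nB))
    h2 = abs(float(dvec @ nA))
    proj_a_on_b = cA - (dvec @ nB) * nB
    proj_b_on_a = cB + (dvec @ nA) * nA
    r1 = float(np.linalg.norm(proj_a_on_b - cB))
    r2 = float(np.linalg.norm(proj_b_on_a - cA))
    theta = fold_angle(_vec_angle_deg(nA, nB))

    axis_a, conv_a = _reference_axis(ring_a, np.asarray(coords_a, float), sites)
    axis_b, conv_b = _reference_axis(ring_b, np.asarray(coords_b, float), sites)
    # project both axes into plane A before comparing
    pa = axis_a - (axis_a @ nA) * nA
    pb = axis_b - (axis_b @ nA) * nA
    if np.linalg.norm(pa) < 1e-9 or np.linalg.norm(pb) < 1e-9:
        phi = 0.0
    else:
        phi = fold_angle(_vec_angle_deg(pa, pb))

    return RingPairGeometry(R=R, h1=h1, h2=h2, r1=r1, r2=r2, phi=phi,
                            theta=theta, ring_a=ring_a, ring_b=ring_b,
                            phi_convention_dependent=conv_a or conv_b)


def classify_stack(g: RingPairGeometry,
                   thresholds: StackThresholds | None = None) -> str:
    """'pi_stack' iff R <= R_max, theta <= theta_max and min(h1,h2) >= h_min."""
    t = thresholds or StackThresholds()
    ok = (g.R <= t.R_max) and (g.theta <= t.theta_max) and (min(g.h1, g.h2) >= t.h_min)
    return "pi_stack" if ok else "none"


def _ring_coords(ring: Ring, cart: np.ndarray) -> np.ndarray:
    return cart[list(ring.atom_indices)]


def enumerate_stacking_pairs(crystal: CrystalStructure, rings: list[Ring],
                             R_max: float = 4.0,
                             graph: BondGraph | None = None,
                             thresholds: StackThresholds | None = None,
                             sites_override=None) -> list[RingPairGeometry]:
    """All distinct ring pairs with R <= R_max, including symmetry images.

    Pairs of rings on the same molecule related by the identity operator are
    intramolecular and skipped.  Each pair is reported once: pair
    (i -> j, code) is folded with its mate (j -> i, inverse code).
    """
    cart = crystal.cart
    sites = crystal.sites if sites_override is None else sites_override
    if graph is not None:
        mol = molecule_ids(graph)
    else:
        mol = np.arange(len(crystal.sites))
    ring_mol = [int(mol[r.atom_indices[0]]) for r in rings]

    out: list[RingPairGeometry] = []
    seen: set = set()
    # margin: two centroids can be R_max apart while atoms are ~ring radius
    # farther; 2 x 1.5 A covers 5-/6-ring circumradii.
    transforms = symmetry_cart_transforms(crystal, R_max + 3.0)
    for code, A, b in transforms:
        mapped_cart = cart @ A.T + b
        for jb, rb in enumerate(rings):
            coords_b = _ring_coords(rb, mapped_cart)
            rb_img = rb.with_coordinates(coords_b)
            for ja, ra in enumerate(rings):
                if code == IDENTITY_CODE:
                    if ja >= jb or ring_mol[ja] == ring_mol[jb]:
                        continue
                    key = (ja, jb, IDENTITY_CODE)
                else:
                    inv = invert_code(crystal.ops, code)
                    key = min((ja, jb, code), (jb, ja, inv))
                if key in seen:
                    continue
                dist = float(np.linalg.norm(ra.centroid - rb_img.centroid))
                if dist > R_max or dist < 1e-6:
                    continue
                seen.add(key)
                geom = pair_geometry(ra, rb_img, _ring_coords(ra, cart),
                                     coords_b, sites)
                geom.symmetry_code = code
                geom.classification = classify_stack(geom, thresholds)
                out.append(geom)
    out.sort(key=lambda g: g.R)
    return out


def find_lp_pi(structure: CrystalStructure, rings: list[Ring],
               params: LpPiParams | None = None,
               graph: BondGraph | None = None) -> list[LpPiContact]:
    """Lone-pair...pi contacts: an N/O donor above a ring face, closer than
    the vdW sum (+ tolerance) to a ring atom, elevated >= the threshold.

    For periodic structures, symmetry-image donors against asymmetric-unit
    rings are included; each contact appears once with its image code.
    Donors on the same molecule as the ring (identity image) are skipped, as
    are donors that are members of the acceptor ring.
    """
    p = params or LpPiParams()
    cart = structure.cart
    sites = structure.sites
    mol = molecule_ids(graph) if graph is not None else np.arange(len(sites))
    ring_mol = [int(mol[r.atom_indices[0]]) for r in rings]

    donor_idx = [i for i, s in enumerate(sites) if s.element in p.donor_elements]
    max_sum = max((vdw_radius(e) for e in p.donor_elements), default=0) + 1.80 \
        + p.distance_tolerance

    contacts: list[LpPiContact] = []
    transforms = symmetry_cart_transforms(structure, max_sum + 3.0) \
        if structure.is_periodic else [(IDENTITY_CODE, np.eye(3), np.zeros(3))]
    for code, A, b in transforms:
        mapped = cart @ A.T + b
        for jr, ring in enumerate(rings):
            members = set(ring.atom_indices)
            ring_coords = cart[list(ring.atom_indices)]
            for di in donor_idx:
                if code == IDENTITY_CODE:
                    if di in members or mol[di] == ring_mol[jr]:
                        continue
                donor_pos = mapped[di]
                rel = donor_pos - ring.centroid
                d_cen = float(np.linalg.norm(rel))
                if d_cen < 1e-6 or d_cen > max_sum + 2.0:
                    continue
                elevation = 90.0 - _vec_angle_deg(rel, ring.normal)
                if abs(elevation) < p.elevation_min:
                    continue
                dists = np.linalg.norm(ring_coords - donor_pos, axis=1)
                r_donor = vdw_radius(sites[di].element)
                limits = np.array([r_donor + vdw_radius(sites[j].element)
                                   + p.distance_tolerance
                                   for j in ring.atom_indices])
                qualifying = np.nonzero(dists <= limits)[0]
                if qualifying.size == 0:
                    continue
                best = int(qualifying[np.argmin(dists[qualifying])])
                ai = ring.atom_indices[best]
                contacts.append(LpPiContact(
                    donor_index=di, donor_element=sites[di].element,
                    donor_label=sites[di].label,
                    acceptor_atom_index=int(ai),
                    acceptor_atom_label=sites[ai].label,
                    acceptor_ring_class=ring.ring_class,
                    d=float(dists[best]), d_centroid=d_cen,
                    elevation=float(abs(elevation)), symmetry_code=code))
    contacts.sort(key=lambda c: c.d)
    return contacts
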