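"""Synthetic fixtures with known ground truth for every pipeline stage.

Idealized planar rings (regular polygons; C-C 1.39 A for six-rings, 1.36 A
for five-rings) are placed at prescribed perpendicular separation h, in-plane
slip, twist and tilt, optionally jittered with seeded Gaussian noise, and
written out as P1 CIF or as PDB (ligand + phenylalanine side chain) so the
readers, ring perception, descriptors and screens can all be exercised
against analytically known answers.  Regular polygons are an idealization -
real five-ring heterocycles are slightly irregular - but none of the
descriptors depend on ring regularity.

A companion generator produces diffusion series with a known infinite-
dilution coefficient and association trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .association_analysis import DiffusionSeries
from .structure_io import AtomSite, CrystalStructure, SymmetryOp, UnitCell

__all__ = [
    "PairSpec", "RING_KINDS", "make_ideal_ring", "place_pair",
    "emit_cif_p1", "emit_pdb", "make_diffusion_series",
    "slope_for_ratio", "make_screen_corpus", "random_pair_specs",
]

BOND_6 = 1.39  # A
BOND_5 = 1.36  # A

RING_KINDS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # kind -> (element cycle, role labels)
    "phenyl": (("C",) * 6, ("C1", "C2", "C3", "C4", "C5", "C6")),
    "pyridine": (("N", "C", "C", "C", "C", "C"),
                 ("N1", "C2", "C3", "C4", "C5", "C6")),
    "oxadiazole-1,2,4": (("O", "N", "C", "N", "C"),
                         ("O1", "N2", "C3", "N4", "C5")),
    "oxadiazole-1,3,4": (("O", "C", "N", "N", "C"),
                         ("O1", "C2", "N3", "N4", "C5")),
}


def make_ideal_ring(kind: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Regular planar ring: (coords (n,3), elements, labels).

    Centroid at the origin, normal +z, first atom on +x.
    """
    try:
        elements, labels = RING_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown ring kind {kind!r}; "
                         f"choose from {sorted(RING_KINDS)}") from None
    n = len(elements)
    bond = BOND_6 if n == 6 else BOND_5
    radius = bond / (2.0 * math.sin(math.pi / n))
    angles = 2.0 * math.pi * np.arange(n) / n
    coords = np.stack([radius * np.cos(angles), radius * np.sin(angles),
                       np.zeros(n)], axis=1)
    return coords, list(elements), list(labels)


@dataclass
class PairSpec:
    """Prescription for a two-ring stack.

    Ring A sits in z = 0 centred at the origin; ring B is twisted by
    ``twist`` deg about +z, tilted by ``tilt`` deg about the x axis through
    its centroid, and its centroid placed at (slip, 0, h).  For tilt = 0 the
    exact descriptors are R = sqrt(h^2 + slip^2), h1 = h2 = h,
    r1 = r2 = slip, theta = 0, phi = fold(twist).
    """

    kind_a: str = "oxadiazole-1,2,4"
    kind_b: str = "phenyl"
    h: float = 3.4
    slip: float = 0.0
    twist: float = 0.0
    tilt: float = 0.0
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")

    @property
    def expected(self) -> dict[str, float]:
        if self.tilt != 0.0:
            raise ValueError("closed-form descriptors are for tilt = 0 only")
        from .stacking_geometry import fold_angle
        return {"R": math.hypot(self.h, self.slip), "h1": self.h,
                "h2": self.h, "r1": self.slip, "r2": self.slip,
                "theta": 0.0, "phi": fold_angle(self.twist)}


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a), 0],
                     [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[1.0, 0, 0], [0, math.cos(a), -math.sin(a)],
                     [0, math.sin(a), math.cos(a)]])


def place_pair(spec: PairSpec, name: str = "pair") -> CrystalStructure:
    """Build the two-ring structure prescribed by ``spec`` (no unit cell)."""
    coords_a, elems_a, labels_a = make_ideal_ring(spec.kind_a)
    coords_b, elems_b, labels_b = make_ideal_ring(spec.kind_b)
    coords_b = coords_b @ _rot_z(spec.twist).T
    coords_b = coords_b @ _rot_x(spec.tilt).T
    coords_b = coords_b + np.array([spec.slip, 0.0, spec.h])
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords_a = coords_a + rng.normal(0.0, spec.jitter_sigma, coords_a.shape)
        coords_b = coords_b + rng.normal(0.0, spec.jitter_sigma, coords_b.shape)
    sites = [AtomSite(label=f"{lab}A", element=el, cart=xyz)
             for lab, el, xyz in zip(labels_a, elems_a, coords_a)]
    sites += [AtomSite(label=f"{lab}B", element=el, cart=xyz)
              for lab, el, xyz in zip(labels_b, elems_b, coords_b)]
    return CrystalStructure(name=name, sites=sites, cell=None)


# ---------------------------------------------------------------------------
# file emission


def emit_cif_p1(structure: CrystalStructure, path,
                cell_margin: float = 8.0,
                cell: UnitCell | None = None) -> Path:
    """Write ``structure`` as a P1 CIF.

    Without an explicit ``cell``, a box (bounding box + 2*margin) isolates
    the molecules from their periodic images; passing a short axis instead
    plants periodic contacts deliberately.
    """
    path = Path(path)
    cart = structure.cart
    if cell is None:
        extent = cart.max(axis=0) - cart.min(axis=0)
        a, b, c = (extent + 2.0 * cell_margin).tolist()
        cell = UnitCell(max(a, 4.0), max(b, 4.0), max(c, 4.0))
    offset = cart.min(axis=0)
    frac = cell.fractionalize(cart - offset + cell_margin * 0.5)
    lines = [
        f"data_{structure.name}",
        "_symmetry_space_group_name_H-M   'P 1'",
        f"_cell_length_a   {cell.a:.4f}",
        f"_cell_length_b   {cell.b:.4f}",
        f"_cell_length_c   {cell.c:.4f}",
        f"_cell_angle_alpha   {cell.alpha:.4f}",
        f"_cell_angle_beta   {cell.beta:.4f}",
        f"_cell_angle_gamma   {cell.gamma:.4f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "  'x, y, z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for site, f in zip(structure.sites, frac):
        lines.append(f"  {site.label:<6s} {site.element:<2s} "
                     f"{f[0]:10.6f} {f[1]:10.6f} {f[2]:10.6f} "
                     f"{site.occupancy:6.3f}")
    path.write_text("\n".join(lines) + "\n")
    return path


_PHE_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def emit_pdb(structure: CrystalStructure, path,
             as_ligand_and_phe: bool = False) -> Path:
    """Write ``structure`` as a PDB file.

    With ``as_ligand_and_phe`` the first ring (first 5 or 6 atoms, by label
    suffix 'A') becomes a HETATM ligand (residue LIG) and the second a
    phenylalanine side-chain ring (residue PHE) - the protein-screen fixture.
    Requires a six-carbon second ring in that mode.
    """
    path = Path(path)
    lines = []
    if structure.cell is not None:
        c = structure.cell
        lines.append(f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
                     f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1")
    serial = 1
    if as_ligand_and_phe:
        ring_a = [s for s in structure.sites if s.label.endswith("A")]
        ring_b = [s for s in structure.sites if s.label.endswith("B")]
        if len(ring_b) != 6 or any(s.element != "C" for s in ring_b):
            raise ValueError("ligand+PHE emission needs a phenyl second ring")
        for name, s in zip(_PHE_RING_NAMES, ring_b):
            lines.append(_pdb_line("ATOM", serial, name, "PHE", "A", 1,
                                   s.cart, s.element))
            serial += 1
        for s in ring_a:
            lines.append(_pdb_line("HETATM", serial, s.label[:4], "LIG", "A",
                                   901, s.cart, s.element))
            serial += 1
    else:
        for i, s in enumerate(structure.sites):
            lines.append(_pdb_line("HETATM", serial, s.label[:4], "LIG", "A",
                                   i // 26 + 1, s.cart, s.element))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _pdb_line(record: str, serial: int, name: str, res: str, chain: str,
              seq: int, xyz: np.ndarray, element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record:<6s}{serial:>5d} {name_field}{'':1s}{res:<3s} {chain}"
            f"{seq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}")


# ---------------------------------------------------------------------------
# screening corpus with planted ground truth


def _corpus_structure(isomer: str, variant: str, name: str) -> CrystalStructure:
    """One P1 crystal containing an oxadiazole and a phenyl ring.

    variant: 'hit' (C...C 3.85 A along the local normal, angles 90/90),
    'far' (distance violator at 3.95 A), 'angle' (in-plane exterior contact,
    3.40 A, angles ~126 deg outside the window), 'inert' (rings 10 A apart).
    """
    coords_a, elems_a, labels_a = make_ideal_ring(isomer)
    coords_f, elems_f, labels_f = make_ideal_ring("phenyl")
    r6 = BOND_6 / (2.0 * math.sin(math.pi / 6.0))
    # query: the first ring carbon (role C3 for 1,2,4-, C2 for 1,3,4-)
    qpos = elems_a.index("C")
    q = coords_a[qpos]
    radial = q / np.linalg.norm(q)

    if variant in ("hit", "far"):
        height = 3.85 if variant == "hit" else 3.95
        target = q + np.array([0.0, 0.0, height])
        center = target - r6 * np.array([1.0, 0.0, 0.0])
        coords_f = coords_f + center
    elif variant == "angle":
        # in-plane exterior contact: X along the radial (exterior-bisector)
        # direction, 3.40 A out; both angles at the query atom are ~126 deg,
        # outside the 65-115 window.  The partner phenyl stands perpendicular
        # to the contact so its own angles pass (the rejection is at Q).
        target = q + 3.40 * radial
        e_z = np.array([0.0, 0.0, 1.0])
        w = np.cross(radial, e_z)
        w /= np.linalg.norm(w)
        ring = []
        for k in range(6):
            ang = 2.0 * math.pi * k / 6.0
            ring.append(target + r6 * ((math.cos(ang) - 1.0) * e_z
                                       + math.sin(ang) * w))
        coords_f = np.array(ring)
    elif variant == "inert":
        coords_f = coords_f + np.array([10.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown corpus variant {variant!r}")

    sites = [AtomSite(label=f"{lab}A", element=el, cart=xyz)
             for lab, el, xyz in zip(labels_a, elems_a, coords_a)]
    sites += [AtomSite(label=f"{lab}B", element=el, cart=xyz)
              for lab, el, xyz in zip(labels_f, elems_f, coords_f)]
    struct = CrystalStructure(name=name, sites=sites, cell=None)
    return struct


def make_screen_corpus(seed: int = 0, n_structures: int = 10, n_hits: int = 3,
                       n_violators: int = 2, out_dir=None
                       ) -> list[CrystalStructure]:
    """A corpus of P1 crystals with known screening ground truth.

    ``n_hits`` structures carry one valid planted contact each, the
    violators split between a distance violator (3.95 A > the 3.90 A C...C
    threshold) and an angle-window violator, and the rest are inert.  The
    order of variants is shuffled deterministically by ``seed``.  With
    ``out_dir`` the structures are also written as CIFs.
    """
    if n_hits + n_violators > n_structures:
        raise ValueError("more planted structures than corpus size")
    variants = (["hit"] * n_hits
                + ["far", "angle"] * (n_violators // 2)
                + (["far"] if n_violators % 2 else [])
                + ["inert"] * (n_structures - n_hits - n_violators))
    rng = np.random.default_rng(seed)
    rng.shuffle(variants)
    isomers = ["oxadiazole-1,2,4", "oxadiazole-1,3,4"]
    corpus = []
    for i, variant in enumerate(variants):
        struct = _corpus_structure(isomers[i % 2], variant, f"synth{i:03d}")
        cell = UnitCell(30.0, 30.0, 30.0)
        cart = struct.cart
        shift = -cart.min(axis=0) + 5.0
        for s in struct.sites:
            s.cart = s.cart + shift
            s.frac = cell.fractionalize(s.cart)
        struct.cell = cell
        struct.ops = [SymmetryOp.from_triplet("x,y,z")]
        struct.spacegroup = "P 1"
        corpus.append(struct)
        if out_dir is not None:
            emit_cif_p1(struct, Path(out_dir) / f"{struct.name}.cif",
                        cell=cell)
    return corpus


# ---------------------------------------------------------------------------
# diffusion series


DEFAULT_CONCENTRATIONS = np.array([6.0, 12.0, 24.0, 48.0, 96.0, 191.0,
                                   382.0, 611.0])  # mM, a dilution ladder


def slope_for_ratio(d0: float, c: float, ratio: float) -> float:
    """Linear slope such that D_obs(c)/D0 == 1/ratio (so N(c) = ratio^3)."""
    return (d0 / ratio - d0) / c


def make_diffusion_series(d0: float = 6.0, slope: float | None = None,
                          noise_sigma: float = 0.0, seed: int = 0,
                          concentrations: np.ndarray | None = None,
                          d_ref0: float = 14.0, ref_slope: float = 0.0
                          ) -> DiffusionSeries:
    """D_obs = D0 + slope*c + noise; constant D_ref unless ``ref_slope`` set.

    The default slope reproduces a weak association: D0/D_obs = 1.1241 at
    611 mM, i.e. an aggregation number of 1.42 at the top concentration.
    """
    c = np.asarray(concentrations if concentrations is not None
                   else DEFAULT_CONCENTRATIONS, dtype=float)
    if slope is None:
        slope = slope_for_ratio(d0, 611.0, 1.1241)
    d_obs = d0 + slope * c
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        d_obs = d_obs + rng.normal(0.0, noise_sigma, c.shape)
    d_ref = d_ref0 + ref_slope * c
    return DiffusionSeries(concentration=c, d_obs=d_obs, d_ref=d_ref)


def random_pair_specs(n: int, seed: int = 0, tilt_max: float = 0.0,
                      jitter_sigma: float = 0.0) -> list[PairSpec]:
    """Seeded random PairSpecs over realistic stacking ranges:
    h in [3.0, 4.0] A, slip in [0, 2] A, twist in [0, 90) deg."""
    rng = np.random.default_rng(seed)
    kinds = list(RING_KINDS)
    specs = []
    for k in range(n):
        specs.append(PairSpec(
            kind_a=kinds[int(rng.integers(len(kinds)))],
            kind_b=kinds[int(rng.integers(len(kinds)))],
            h=float(rng.uniform(3.0, 4.0)),
            slip=float(rng.uniform(0.0, 2.0)),
            twist=float(rng.uniform(0.0, 90.0)),
            tilt=float(rng.uniform(0.0, tilt_max)) if tilt_max > 0 else 0.0,
            jitter_sigma=jitter_sigma,
            seed=int(rng.integers(2 ** 31 - 1))))
    return specs
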