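"""Structure file I/O, bond graphs and crystallographic symmetry expansion.

Readers are thin wrappers over :mod:`gemmi` (CIF / PDB / mmCIF, gzipped or
not) that normalize everything into a single light-weight container,
:class:`CrystalStructure`.  Downstream geometry works exclusively in
Cartesian angstroms; fractional coordinates and symmetry operators live only
here.

Conventions adopted for ambiguous input:

* PDB altloc duplicates: the highest-occupancy conformer is kept, ties go to
  altloc ``A`` (then alphabetically) so a file always yields one geometry.
* CIF disorder (duplicate labels with partial occupancy): the
  higher-occupancy branch is kept and a warning is emitted.
* Symmetry image codes are ``(op_index, t1, t2, t3)`` with the identity
  ``(0, 0, 0, 0)``; ``op_index`` indexes the parsed operator list and the
  ``t`` components are unit-cell translations.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ._elements import (
    UnknownElementError,
    atomic_number,
    covalent_radius,
    normalize_symbol,
    vdw_radius,
)
from .grids import VolumetricGrid, read_cube, write_cube

__all__ = [
    "AtomSite", "UnitCell", "SymmetryOp", "CrystalStructure", "BondGraph",
    "ImageAtom", "StructureParseError",
    "read_cif", "read_pdb", "read_structure",
    "build_bond_graph", "molecule_ids", "expand_symmetry",
    "symmetry_cart_transforms", "invert_code", "compose_code",
    "vdw_radius", "covalent_radius", "atomic_number",
    "write_cube", "read_cube", "write_report", "read_report",
    "VolumetricGrid",
]

DEFAULT_BOND_TOLERANCE = 0.40  # A added to the covalent-radius sum

IDENTITY_CODE = (0, 0, 0, 0)


class StructureParseError(ValueError):
    """A structure file is missing required content."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class AtomSite:
    """One atom: label, element, Cartesian (and optionally fractional) coords."""

    label: str
    element: str
    cart: np.ndarray
    frac: np.ndarray | None = None
    occupancy: float = 1.0
    residue: str | None = None
    chain: str | None = None
    res_seq: int | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.element = normalize_symbol(self.element)
        self.cart = np.asarray(self.cart, dtype=float).reshape(3)
        if self.frac is not None:
            self.frac = np.asarray(self.frac, dtype=float).reshape(3)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix M with cart = M @ frac."""
        return np.array(self.gemmi_cell.orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self.gemmi_cell.frac.mat.tolist(), dtype=float)

    def orthogonalize(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, cart) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.frac_matrix.T


class SymmetryOp:
    """A crystallographic symmetry operator, frac' = R @ frac + t."""

    def __init__(self, op: gemmi.Op):
        self._op = op
        self.rotation = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        self.translation = np.array(op.tran, dtype=float) / gemmi.Op.DEN

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        return cls(gemmi.Op(triplet))

    @property
    def triplet(self) -> str:
        return self._op.triplet()

    @property
    def is_identity(self) -> bool:
        return self._op == gemmi.Op("x,y,z")

    def apply(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "SymmetryOp":
        return SymmetryOp(self._op.inverse())

    def __eq__(self, other) -> bool:
        return isinstance(other, SymmetryOp) and self._op == other._op

    def __hash__(self) -> int:
        return hash(self.triplet)

    def __repr__(self) -> str:
        return f"SymmetryOp({self.triplet!r})"


@dataclass
class CrystalStructure:
    """Sites + optional cell and symmetry; the common container for all inputs."""

    name: str
    sites: list[AtomSite]
    cell: UnitCell | None = None
    ops: list[SymmetryOp] = field(default_factory=lambda: [SymmetryOp.from_triplet("x,y,z")])
    spacegroup: str | None = None
    r_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise StructureParseError(f"structure {self.name!r} has no atom sites")
        if not self.ops:
            self.ops = [SymmetryOp.from_triplet("x,y,z")]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def cart(self) -> np.ndarray:
        return np.array([s.cart for s in self.sites], dtype=float)

    @property
    def frac(self) -> np.ndarray:
        if self.cell is None:
            raise ValueError("structure has no unit cell")
        if all(s.frac is not None for s in self.sites):
            return np.array([s.frac for s in self.sites], dtype=float)
        return self.cell.fractionalize(self.cart)

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    @property
    def is_periodic(self) -> bool:
        return self.cell is not None


@dataclass
class ImageAtom:
    """A symmetry image of an asymmetric-unit atom, tagged with its code."""

    source_index: int
    element: str
    label: str
    cart: np.ndarray
    code: tuple[int, int, int, int]

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


class BondGraph:
    """Covalent connectivity as an undirected graph with per-edge distances."""

    def __init__(self, graph: nx.Graph, tolerance: float):
        self.graph = graph
        self.tolerance = tolerance

    def __contains__(self, edge) -> bool:
        return self.graph.has_edge(*edge)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))

    def distance(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["distance"]

    def degree_heavy(self, i: int, sites: list[AtomSite]) -> int:
        return sum(1 for j in self.graph.neighbors(i) if not sites[j].is_hydrogen)


# ---------------------------------------------------------------------------
# CIF reading


def _cif_number(value: str, tag: str) -> float:
    num = gemmi.cif.as_number(value)
    if math.isnan(num):
        raise StructureParseError(f"cannot parse numeric value {value!r} for {tag}")
    return num


def _element_from_label(label: str) -> str | None:
    """Derive an element symbol from a crystallographic label like 'N2A'."""
    m = re.match(r"([A-Za-z]{1,2})", label)
    if not m:
        return None
    head = m.group(1)
    for cand in (head[:2], head[:1]):
        try:
            sym = normalize_symbol(cand)
        except UnknownElementError:
            continue
        try:
            covalent_radius(sym)
            return sym
        except UnknownElementError:
            continue
    return None


def read_cif(path) -> CrystalStructure:
    """Read a small-molecule CIF (optionally gzipped) into a CrystalStructure.

    Requires a unit cell, symmetry (operator loop or space-group name) and an
    atom-site loop with fractional coordinates.
    """
    path = Path(path)
    doc = gemmi.cif.read(str(path))
    block = None
    for b in doc:
        if b.find_value("_cell_length_a") is not None or b.find_loop("_atom_site_label"):
            block = b
            break
    if block is None:
        block = doc.sole_block()

    cell_vals = []
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        raw = block.find_value(tag)
        if raw is None:
            raise StructureParseError(f"{path.name}: missing required CIF tag {tag}")
        cell_vals.append(_cif_number(raw, tag))
    cell = UnitCell(*cell_vals)

    ops: list[SymmetryOp] = []
    for loop_tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(loop_tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            ops = [SymmetryOp.from_triplet(t) for t in triplets]
            break
    sg_name = None
    for tag in ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt",
                "_space_group_name_Hall"):
        raw = block.find_value(tag)
        if raw is not None:
            sg_name = gemmi.cif.as_string(raw).strip()
            if sg_name:
                break
    if not ops:
        if sg_name:
            sg = gemmi.find_spacegroup_by_name(sg_name)
            if sg is None:
                raise StructureParseError(f"{path.name}: unknown space group {sg_name!r}")
            ops = [SymmetryOp(op) for op in sg.operations()]
        else:
            raise StructureParseError(
                f"{path.name}: missing symmetry "
                "(_symmetry_equiv_pos_as_xyz loop or space-group name tag)")
    if sg_name is None and len(ops) == 1:
        sg_name = "P 1"

    table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z",
                                       "?type_symbol", "?occupancy"])
    if len(table) == 0:
        raise StructureParseError(f"{path.name}: missing _atom_site_ loop")
    raw_sites: list[AtomSite] = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        frac = np.array([_cif_number(row[i], "_atom_site_fract") for i in (1, 2, 3)])
        if row.has(4):
            sym = gemmi.cif.as_string(row[4]).rstrip("+-0123456789")
        else:
            sym = None
        if not sym:
            sym = _element_from_label(label)
        if sym is None:
            raise StructureParseError(
                f"{path.name}: cannot determine element for atom label {label!r}")
        try:
            element = normalize_symbol(sym)
            covalent_radius(element)
        except UnknownElementError:
            raise StructureParseError(
                f"{path.name}: unknown element {sym!r} for atom label {label!r}") from None
        occ = _cif_number(row[5], "_atom_site_occupancy") if row.has(5) else 1.0
        raw_sites.append(AtomSite(label=label, element=element, frac=frac,
                                  cart=cell.orthogonalize(frac), occupancy=occ))

    sites = _resolve_cif_disorder(raw_sites, path.name)

    r_factor = None
    for tag in ("_refine_ls_R_factor_gt", "_refine_ls_R_factor_all"):
        raw = block.find_value(tag)
        if raw is not None:
            try:
                r_factor = _cif_number(raw, tag)
                break
            except StructureParseError:
                pass

    return CrystalStructure(name=path.name.removesuffix(".gz").removesuffix(".cif"),
                            sites=sites, cell=cell, ops=ops,
                            spacegroup=sg_name, r_factor=r_factor)


def _resolve_cif_disorder(sites: list[AtomSite], name: str) -> list[AtomSite]:
    by_label: dict[str, AtomSite] = {}
    dropped = 0
    for s in sites:
        prev = by_label.get(s.label)
        if prev is None:
            by_label[s.label] = s
        else:
            dropped += 1
            if s.occupancy > prev.occupancy:
                by_label[s.label] = s
    if dropped:
        warnings.warn(
            f"{name}: {dropped} disordered duplicate atom site(s) dropped "
            "(kept the higher-occupancy branch)", stacklevel=3)
    return list(by_label.values())


# ---------------------------------------------------------------------------
# PDB / mmCIF reading


def read_pdb(path) -> CrystalStructure:
    """Read a PDB or mmCIF file (optionally gzipped).

    Protein atoms and HETATM ligand atoms are both kept and distinguishable
    through ``AtomSite.is_hetero`` / ``residue`` / ``chain``.  Altloc
    duplicates collapse to the highest-occupancy conformer (tie: altloc 'A').
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no models")
    model = st[0]

    cell = None
    if st.cell and st.cell.a > 1.0 and st.cell.volume > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    ops = [SymmetryOp.from_triplet("x,y,z")]
    sg_name = st.spacegroup_hm or None
    if cell is not None and sg_name:
        sg = gemmi.find_spacegroup_by_name(sg_name)
        if sg is not None:
            ops = [SymmetryOp(op) for op in sg.operations()]

    sites: list[AtomSite] = []
    for chain in model:
        for residue in chain:
            chosen: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = chosen.get(atom.name)
                if prev is None:
                    chosen[atom.name] = atom
                    continue
                if atom.occ > prev.occ or (
                        atom.occ == prev.occ and (atom.altloc or "Z") < (prev.altloc or "Z")):
                    chosen[atom.name] = atom
            for atom in chosen.values():
                el = atom.element.name if atom.element else ""
                if not el or el == "X":
                    el = _element_from_label(atom.name) or ""
                if not el:
                    raise StructureParseError(
                        f"{path.name}: unknown element for atom {atom.name!r}")
                cart = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                sites.append(AtomSite(
                    label=atom.name, element=el, cart=cart,
                    frac=cell.fractionalize(cart) if cell else None,
                    occupancy=atom.occ,
                    residue=residue.name, chain=chain.name,
                    res_seq=residue.seqid.num,
                    is_hetero=residue.het_flag == "H"))
    if not sites:
        raise StructureParseError(f"{path.name}: no atoms found")
    return CrystalStructure(name=path.name.removesuffix(".gz").rsplit(".", 1)[0],
                            sites=sites, cell=cell, ops=ops, spacegroup=sg_name)


def read_structure(path) -> CrystalStructure:
    """Dispatch to :func:`read_cif` or :func:`read_pdb` by file extension."""
    name = Path(path).name.removesuffix(".gz").lower()
    if name.endswith(".cif") and not name.endswith((".mmcif",)):
        # Small-molecule CIFs carry _atom_site_fract_*; macromolecular mmCIF
        # does not.  Peek to decide.
        try:
            return read_cif(path)
        except StructureParseError:
            return read_pdb(path)
    if name.endswith((".pdb", ".ent", ".mmcif")):
        return read_pdb(path)
    raise StructureParseError(f"unrecognized structure file type: {path}")


# ---------------------------------------------------------------------------
# bond graph and molecules


def build_bond_graph(sites: list[AtomSite], tolerance: float = DEFAULT_BOND_TOLERANCE) -> BondGraph:
    """Bond i-j iff |ri - rj| <= r_cov(i) + r_cov(j) + tolerance."""
    g = nx.Graph()
    g.add_nodes_from(range(len(sites)))
    if len(sites) >= 2:
        coords = np.array([s.cart for s in sites])
        radii = np.array([covalent_radius(s.element) for s in sites])
        tree = cKDTree(coords)
        max_cut = 2.0 * radii.max() + tolerance
        for i, j in tree.query_pairs(max_cut):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if 0.0 < d <= radii[i] + radii[j] + tolerance:
                g.add_edge(i, j, distance=d)
    return BondGraph(g, tolerance)


def molecule_ids(graph: BondGraph) -> np.ndarray:
    """Connected-component (molecule) id per atom index."""
    n = graph.graph.number_of_nodes()
    ids = np.full(n, -1, dtype=int)
    for mol, comp in enumerate(nx.connected_components(graph.graph)):
        for i in comp:
            ids[i] = mol
    return ids


# ---------------------------------------------------------------------------
# symmetry expansion


def _op_index(ops: list[SymmetryOp], op: gemmi.Op) -> tuple[int, np.ndarray]:
    """Locate ``op`` in ``ops`` modulo lattice translation.

    Returns (index, integer lattice translation) such that
    ops[index] + lattice == op.
    """
    for i, cand in enumerate(ops):
        if cand._op.rot == op.rot:
            dt = (np.array(op.tran) - np.array(cand._op.tran)) / gemmi.Op.DEN
            rt = np.rint(dt)
            if np.allclose(dt, rt, atol=1e-9):
                return i, rt.astype(int)
    raise ValueError(f"operator {op.triplet()} not in the parsed group")


def compose_code(ops: list[SymmetryOp], code_a: tuple[int, int, int, int],
                 code_b: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Code of applying ``code_a`` after ``code_b`` (a o b)."""
    op_a, ta = ops[code_a[0]], np.array(code_a[1:], dtype=float)
    op_b, tb = ops[code_b[0]], np.array(code_b[1:], dtype=float)
    rot = op_a.rotation @ op_b.rotation
    tran = op_a.rotation @ (op_b.translation + tb) + op_a.translation + ta
    for idx, cand in enumerate(ops):
        if np.allclose(cand.rotation, rot, atol=1e-9):
            t = tran - cand.translation
            rt = np.rint(t)
            if np.allclose(t, rt, atol=1e-9):
                return (idx, int(rt[0]), int(rt[1]), int(rt[2]))
    raise ValueError("composed operator not in the parsed group")


def invert_code(ops: list[SymmetryOp], code: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Inverse of a symmetry code (op index + lattice translation)."""
    i, t = code[0], np.array(code[1:], dtype=float)
    inv = ops[i]._op.inverse()
    idx, extra = _op_index(ops, inv)
    rot_inv = np.array(inv.rot, dtype=float) / gemmi.Op.DEN
    t_inv = -rot_inv @ t + extra
    rt = np.rint(t_inv).astype(int)
    return (idx, int(rt[0]), int(rt[1]), int(rt[2]))


def _translation_ranges(frac: np.ndarray, images_frac: np.ndarray,
                        margins: np.ndarray) -> list[range]:
    lo = np.floor(frac.min(axis=0) - images_frac.max(axis=0) - margins).astype(int)
    hi = np.ceil(frac.max(axis=0) - images_frac.min(axis=0) + margins).astype(int)
    return [range(lo[k], hi[k] + 1) for k in range(3)]


def symmetry_cart_transforms(crystal: CrystalStructure, d_max: float
                             ) -> list[tuple[tuple[int, int, int, int], np.ndarray, np.ndarray]]:
    """All Cartesian affine maps (code, A, b) whose image of the asymmetric
    unit comes within ``d_max`` of it.  The identity (0,0,0,0) comes first.

    cart_image = A @ cart + b.
    """
    if d_max < 0:
        raise ValueError("d_max must be non-negative")
    ident = (IDENTITY_CODE, np.eye(3), np.zeros(3))
    if crystal.cell is None:
        return [ident]
    M = crystal.cell.orth_matrix
    Minv = crystal.cell.frac_matrix
    frac = crystal.frac
    cart = crystal.cart
    tree = cKDTree(cart)
    margins = d_max * np.linalg.norm(Minv, axis=1)
    out = [ident]
    for i, op in enumerate(crystal.ops):
        base = frac @ op.rotation.T + op.translation
        r1, r2, r3 = _translation_ranges(frac, base, margins)
        for t1 in r1:
            for t2 in r2:
                for t3 in r3:
                    t = np.array([t1, t2, t3], dtype=float)
                    if i == 0 and op.is_identity and not t.any():
                        continue
                    img_cart = (base + t) @ M.T
                    dmin, _ = tree.query(img_cart, k=1)
                    if dmin.min() <= d_max:
                        A = M @ op.rotation @ Minv
                        b = M @ (op.translation + t)
                        out.append(((i, t1, t2, t3), A, b))
    return out


def expand_symmetry(crystal: CrystalStructure, cutoff: float) -> list[ImageAtom]:
    """Symmetry-image atoms within ``cutoff`` A of any asymmetric-unit atom.

    Each image carries its canonical ``(op_index, t1, t2, t3)`` code; the
    identity copy itself is never returned.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if crystal.cell is None:
        return []
    cart = crystal.cart
    tree = cKDTree(cart)
    images: list[ImageAtom] = []
    for code, A, b in symmetry_cart_transforms(crystal, cutoff):
        if code == IDENTITY_CODE:
            continue
        img = cart @ A.T + b
        dmin, _ = tree.query(img, k=1)
        for k in np.nonzero(dmin <= cutoff)[0]:
            s = crystal.sites[k]
            images.append(ImageAtom(source_index=int(k), element=s.element,
                                    label=s.label, cart=img[k], code=code))
    return images


# ---------------------------------------------------------------------------
# reports


def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec):
        d = dataclasses.asdict(rec)
    elif isinstance(rec, dict):
        d = dict(rec)
    else:
        raise TypeError(f"cannot serialize record of type {type(rec)}")
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


def write_report(records, path, format: str = "csv", fieldnames: list[str] | None = None) -> None:
    """Write a list of flat dataclass records to CSV or JSON (lossless)."""
    import pandas as pd

    path = Path(path)
    dicts = [_record_to_dict(r) for r in records]
    if format == "json":
        path.write_text(json.dumps(dicts, indent=1, default=str) + "\n")
    elif format == "csv":
        if dicts:
            df = pd.DataFrame(dicts)
        else:
            df = pd.DataFrame(columns=fieldnames or [])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path, cls=None):
    """Read a JSON report back; with ``cls`` given, rebuild dataclass records."""
    dicts = json.loads(Path(path).read_text())
    if cls is None:
        return dicts
    return [cls(**d) for d in dicts]
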