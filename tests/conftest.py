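"""Shared fixtures: small analytic structures with known geometry."""

from __future__ import annotations

import math

import numpy as np
import pytest

from oxastack.structure_io import AtomSite, CrystalStructure, build_bond_graph


def sites_from(coords, elements, labels=None):
    labels = labels or [f"{e}{i+1}" for i, e in enumerate(elements)]
    return [AtomSite(label=l, element=e, cart=np.asarray(c, dtype=float))
            for c, e, l in zip(coords, elements, labels)]


def hexagon(radius: float = 1.39, z: float = 0.0, offset: float = 0.0) -> np.ndarray:
    ang = 2 * np.pi * np.arange(6) / 6 + offset
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.full(6, float(z))], axis=1)


@pytest.fixture
def benzene_sites():
    return sites_from(hexagon(), ["C"] * 6)


@pytest.fixture
def benzene_graph(benzene_sites):
    return build_bond_graph(benzene_sites)


@pytest.fixture
def naphthalene_sites():
    """Two fused ideal hexagons sharing an edge: 10 atoms, 11 bonds."""
    a = hexagon(offset=math.pi / 6)
    b = hexagon(offset=math.pi / 6) + np.array(
        [2 * 1.39 * math.cos(math.pi / 6), 0.0, 0.0])
    coords = [a[i] for i in range(6)]
    for row in b:
        if not any(np.linalg.norm(row - c) < 1e-6 for c in coords):
            coords.append(row)
    assert len(coords) == 10
    return sites_from(coords, ["C"] * 10)


@pytest.fixture
def chair_cyclohexane_sites():
    """Ideal chair: C-C 1.54 A, ring-puckering z = +/-0.25 A."""
    delta = 0.25
    bond = 1.54
    radius = math.sqrt(bond ** 2 - (2 * delta) ** 2 - 0.0)
    # bond^2 = (2 r sin(pi/6))^2 + (2 delta)^2 = r^2 + 4 delta^2
    radius = math.sqrt(bond ** 2 - 4 * delta ** 2)
    ang = 2 * np.pi * np.arange(6) / 6
    coords = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                       delta * (-1.0) ** np.arange(6)], axis=1)
    return sites_from(coords, ["C"] * 6)


def rigid_motion(rng: np.random.Generator):
    """A random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    trans = rng.uniform(-10, 10, 3)
    return rot, trans


def transformed_structure(struct: CrystalStructure, rot, trans) -> CrystalStructure:
    sites = [AtomSite(label=s.label, element=s.element,
                      cart=rot @ s.cart + trans, residue=s.residue,
                      chain=s.chain, res_seq=s.res_seq, is_hetero=s.is_hetero)
             for s in struct.sites]
    return CrystalStructure(name=struct.name, sites=sites, cell=None)
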