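"""Solvent-accessible surface areas, buried interfaces, coordination shells.

SASA uses Shrake-Rupley sphere sampling with a deterministic golden-spiral
point set (no RNG): a sample point on the expanded sphere of an atom counts
as exposed unless it falls inside any neighbour's expanded sphere.  Buried
interface area is SASA(A) + SASA(B) - SASA(AB), computed over non-hydrogen,
non-water atoms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BONDI, StructureModel

logger = logging.getLogger(__name__)

__all__ = ["InterfaceArea", "CoordinationShell", "sasa", "interface_area",
           "coordination_shell", "SurfaceError", "SelectionError"]

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


class SurfaceError(ValueError):
    pass


class SelectionError(SurfaceError):
    pass


@dataclass
class InterfaceArea:
    group_a: str
    group_b: str
    sasa_a: float
    sasa_b: float
    sasa_ab: float

    @property
    def buried_total(self) -> float:
        return self.sasa_a + self.sasa_b - self.sasa_ab

    @property
    def buried_per_side(self) -> float:
        return 0.5 * self.buried_total


@dataclass
class CoordinationShell:
    center: tuple                  # (residue key, atom name)
    ligands: list                  # [(residue key, atom name, distance)]
    cutoff: float

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def distances(self) -> list:
        return [d for _, _, d in self.ligands]


def golden_spiral(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def _gather(model: StructureModel, include=None):
    positions, radii = [], []
    for res, atom in model.atoms():
        if atom.element.upper() == "H" or res.category == "water":
            continue
        if include is not None and not include(res):
            continue
        positions.append(atom.position)
        radii.append(atom.vdw_radius if atom.vdw_radius is not None
                     else BONDI.get(atom.element.upper(), 1.6))
    return np.asarray(positions, float), np.asarray(radii, float)


def sasa(model: StructureModel, probe_radius: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_POINTS, include=None) -> float:
    """Shrake-Rupley solvent-accessible surface area (square angstrom)."""
    positions, radii = _gather(model, include)
    if positions.size == 0:
        raise SurfaceError("empty selection for SASA")
    return _sasa_arrays(positions, radii, probe_radius, n_points)


def _sasa_arrays(positions, radii, probe_radius, n_points) -> float:
    expanded = radii + probe_radius
    sphere = golden_spiral(n_points)
    tree = cKDTree(positions)
    total = 0.0
    rmax = expanded.max()
    for i in range(len(positions)):
        pts = positions[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(positions[i],
                                                       expanded[i] + rmax)
                      if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - positions[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def interface_area(model: StructureModel, group_a: Sequence[str],
                   group_b: Sequence[str], probe_radius: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_POINTS) -> InterfaceArea:
    """Buried solvent-accessible area between two chain groups."""
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise SelectionError(f"overlapping groups: {sorted(group_a & group_b)}")
    pa, ra = _gather(model, lambda r: r.chain_id in group_a)
    pb, rb = _gather(model, lambda r: r.chain_id in group_b)
    if pa.size == 0 or pb.size == 0:
        raise SelectionError("both chain groups must be non-empty")
    sa = _sasa_arrays(pa, ra, probe_radius, n_points)
    sb = _sasa_arrays(pb, rb, probe_radius, n_points)
    sab = _sasa_arrays(np.vstack([pa, pb]), np.concatenate([ra, rb]),
                       probe_radius, n_points)
    return InterfaceArea(group_a="".join(sorted(group_a)),
                         group_b="".join(sorted(group_b)),
                         sasa_a=sa, sasa_b=sb, sasa_ab=sab)


def coordination_shell(model: StructureModel, center: str | tuple,
                       cutoff: float = 3.0) -> CoordinationShell:
    """Non-hydrogen atoms within ``cutoff`` of a uniquely selected center.

    ``center`` is "chain/seqid/atomname" (e.g. ``"C/301/CA"``) or an
    equivalent tuple.
    """
    if isinstance(center, str):
        parts = center.split("/")
        if len(parts) != 3:
            raise SelectionError("center selector must be chain/seqid/atom")
        center = (parts[0], int(parts[1]), parts[2])
    chain_id, seq_id, atom_name = center
    matches = []
    for res, atom in model.atoms():
        if res.chain_id == chain_id and res.seq_id == seq_id and \
                atom.name == atom_name:
            matches.append((res, atom))
    if len(matches) != 1:
        raise SelectionError(f"selector matches {len(matches)} atoms, need 1")
    cres, catom = matches[0]
    ligands = []
    for res, atom in model.atoms():
        if atom is catom or atom.element.upper() == "H":
            continue
        d = float(np.linalg.norm(atom.position - catom.position))
        if d <= cutoff:
            ligands.append((res.key, atom.name, d))
    ligands.sort(key=lambda t: t[2])
    return CoordinationShell(center=(cres.key, catom.name), ligands=ligands,
                             cutoff=cutoff)
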