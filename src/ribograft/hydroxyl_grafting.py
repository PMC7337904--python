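"""In-silico grafting of a 2'-hydroxyl oxygen onto 2'-deoxyriboses.

The O2' is placed by direct ideal geometry: at the configured C2'-O2' bond
length, completing the tetrahedral coordination of C2' given its C1' and
C3' neighbours, on the ribose face (the face that carries O2' in RNA,
opposite H2'').  No existing atom moves, so the sugar pucker before and
after grafting is identical by construction; each graft is evaluated one
at a time, so no grafted hydroxyl ever sees another one.

Chirality is enforced twice: the sugar itself must be D-configured (checked
by the signed volume at C3' against the template convention), and the
placed O2' must reproduce the ribose signed volume at C2'.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import base_geometry as bg
from .structure_io import Residue

logger = logging.getLogger(__name__)

__all__ = ["GraftGeometry", "GraftResult", "GraftReport", "graft_o2prime",
           "graft_duplex", "o2prime_geometry", "GraftError",
           "AlreadyRiboseError", "IncompleteSugarError", "ChiralityError"]


class GraftError(ValueError):
    pass


class AlreadyRiboseError(GraftError):
    pass


class IncompleteSugarError(GraftError):
    pass


class ChiralityError(GraftError):
    pass


@dataclass
class GraftGeometry:
    """Ideal-geometry parameters for O2' placement."""
    bond_length: float = 1.413          # C2'-O2' (angstrom)
    bond_angle: float = 110.7           # C1'-C2'-O2' ~ C3'-C2'-O2' (deg)
    angle_tolerance: float = 15.0       # acceptance window on the check (deg)


@dataclass
class GraftResult:
    residue: Residue
    o2prime_position: np.ndarray
    chirality_ok: bool
    pucker_before: bg.PuckerResult
    pucker_after: bg.PuckerResult
    direction: np.ndarray = None        # outward C2'->O2' unit vector
    level: int = -1                     # base-pair index within the duplex
    strand: int = 0                     # 1 or 2 within the duplex


@dataclass
class GraftReport:
    results: list = field(default_factory=list)
    skipped: list = field(default_factory=list)   # (residue, reason)


_RIBO_SIGN = None       # sign of det[C1'-C2', C3'-C2', O2'-C2'] in RNA
_SUGAR_SIGN = None      # sign of det[C2'-C3', C4'-C3', O3'-C3'] in D-sugars


def _template_signs():
    global _RIBO_SIGN, _SUGAR_SIGN
    if _RIBO_SIGN is None:
        tmpl = bg.load_templates()
        bb = {k: np.array(v) for k, v in tmpl["backbones"]["A"].items()}
        bb["C1'"] = np.array(tmpl["c1_anchor"])
        _RIBO_SIGN = float(np.sign(np.linalg.det(np.array([
            bb["C1'"] - bb["C2'"], bb["C3'"] - bb["C2'"], bb["O2'"] - bb["C2'"]]))))
        _SUGAR_SIGN = float(np.sign(np.linalg.det(np.array([
            bb["C2'"] - bb["C3'"], bb["C4'"] - bb["C3'"], bb["O3'"] - bb["C3'"]]))))
    return _RIBO_SIGN, _SUGAR_SIGN


def _sugar_chirality_ok(residue: Residue) -> bool:
    _, want = _template_signs()
    pos = {n: residue.atom(n).position for n in ("C2'", "C3'", "C4'", "O3'")}
    got = np.sign(np.linalg.det(np.array([
        pos["C2'"] - pos["C3'"], pos["C4'"] - pos["C3'"], pos["O3'"] - pos["C3'"]])))
    return got == want


def o2prime_geometry(residue: Residue,
                     geometry: GraftGeometry = GraftGeometry()) -> tuple:
    """Ideal O2' position and outward unit direction for a deoxyribose.

    Raises the graft errors but does not modify the residue.
    """
    if residue.has_atom("O2'"):
        raise AlreadyRiboseError(
            f"residue {residue.chain_id}/{residue.seq_id} already has O2'")
    needed = ["C1'", "C2'", "C3'"]
    witness = ["C4'", "O3'"]
    missing = [n for n in needed if not residue.has_atom(n)]
    if missing:
        raise IncompleteSugarError(
            f"residue {residue.chain_id}/{residue.seq_id} missing sugar "
            f"atoms: {', '.join(missing)}")
    have_witness = all(residue.has_atom(n) for n in witness)
    if have_witness and not _sugar_chirality_ok(residue):
        raise ChiralityError(
            f"residue {residue.chain_id}/{residue.seq_id}: sugar is not "
            f"D-configured (mirror image?)")

    c1 = residue.atom("C1'").position
    c2 = residue.atom("C2'").position
    c3 = residue.atom("C3'").position
    u1 = (c1 - c2) / np.linalg.norm(c1 - c2)
    u2 = (c3 - c2) / np.linalg.norm(c3 - c2)
    bis = -(u1 + u2)
    nb = np.linalg.norm(bis)
    if nb < 1e-8:
        raise IncompleteSugarError("degenerate C1'-C2'-C3' geometry")
    bis /= nb
    nrm = np.cross(u1, u2)
    nn = np.linalg.norm(nrm)
    if nn < 1e-8:
        raise IncompleteSugarError("collinear C1'-C2'-C3' geometry")
    nrm /= nn
    cos_t = np.cos(np.radians(geometry.bond_angle))
    a = cos_t / np.dot(bis, u1)
    if a * a > 1.0:
        raise ChiralityError("sugar geometry too distorted for tetrahedral "
                             "O2' placement")
    c = np.sqrt(1.0 - a * a)
    ribo_sign, _ = _template_signs()
    d = a * bis + c * nrm
    if np.sign(np.linalg.det(np.array([u1, u2, d]))) != ribo_sign:
        d = a * bis - c * nrm
    if np.sign(np.linalg.det(np.array([u1, u2, d]))) != ribo_sign:
        raise ChiralityError("cannot satisfy ribose chirality at C2'")
    return c2 + geometry.bond_length * d, d


def graft_o2prime(residue: Residue,
                  geometry: GraftGeometry = GraftGeometry()) -> GraftResult:
    """Compute the grafted O2' for a DNA nucleotide.

    The residue itself is never modified; the graft is returned as a
    :class:`GraftResult` whose clash context downstream contains no other
    grafted hydroxyl (one-at-a-time evaluation).
    """
    try:
        pucker_before = bg.sugar_pucker(residue)
    except bg.IncompleteBaseError as exc:
        raise IncompleteSugarError(str(exc)) from exc
    pos, direction = o2prime_geometry(residue, geometry)

    c1 = residue.atom("C1'").position
    c2 = residue.atom("C2'").position
    c3 = residue.atom("C3'").position
    ang1 = _angle(c1, c2, pos)
    ang2 = _angle(c3, c2, pos)
    ok = (abs(ang1 - geometry.bond_angle) < geometry.angle_tolerance and
          abs(ang2 - geometry.bond_angle) < geometry.angle_tolerance)
    if not ok:
        raise ChiralityError(
            f"post-placement check failed: angles {ang1:.1f}/{ang2:.1f} deg")
    pucker_after = bg.sugar_pucker(residue)   # no atom moved, identical
    return GraftResult(residue=residue, o2prime_position=pos,
                       chirality_ok=True, pucker_before=pucker_before,
                       pucker_after=pucker_after, direction=direction)


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def graft_duplex(duplex, which: str = "both_strands",
                 geometry: GraftGeometry = GraftGeometry()) -> GraftReport:
    """Graft every eligible deoxyribose of a paired duplex.

    ``which`` selects the nucleotides: "both_strands" / "all" (synonyms),
    "strand1", "strand2", or "site_only" (both strands of the annotated
    recognition site).
    """
    if which not in ("both_strands", "all", "strand1", "strand2", "site_only"):
        raise GraftError(f"unknown selection {which!r}")
    targets = []
    for idx, pair in enumerate(duplex.pairs):
        if which == "site_only":
            if duplex.site_span is None:
                raise GraftError("site_only requested but no site annotated")
            lo, hi = duplex.site_span
            if not lo <= idx <= hi:
                continue
        if which in ("both_strands", "all", "strand1", "site_only"):
            targets.append((idx, 1, pair.res_i))
        if which in ("both_strands", "all", "strand2", "site_only"):
            targets.append((idx, 2, pair.res_j))
    report = GraftReport()
    for idx, strand, res in targets:
        try:
            result = graft_o2prime(res, geometry)
        except GraftError as exc:
            report.skipped.append((res, f"{type(exc).__name__}: {exc}"))
            continue
        result.level = idx
        result.strand = strand
        report.results.append(result)
    return report
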