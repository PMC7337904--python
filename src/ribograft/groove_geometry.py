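"""Minor- and major-groove width and depth profiles along a duplex.

Widths follow the standard refined convention: the closest cross-strand
P-P distance on the groove's side of the helix, minus 5.8 angstrom for the
two phosphate group radii.

Depths use the calibrated operational definition ``cross_rim_v1``.  The
quantity a crystallographer reads off a space-filling model as "groove
depth" spans a large fraction of the helix, so the definition measures
across the duplex, from a phosphate rim to the groove floor:

* minor depth at level i: the largest distance from the major-side rim
  line (through P_I(i) and the closest cross-strand P on the major side)
  to any minor-groove-edge base atom within +-3 levels;
* major depth at level i: the largest distance from the midpoint of the
  fixed-offset minor rim pair (P_I(i), P_II(i-2); El Hassan-Calladine
  style indexing) to any phosphorus within +-1 levels.

Both depths are evaluated from each strand's perspective and averaged, so
palindromic duplexes give exactly symmetric profiles.  Levels where the
construction does not fit inside the duplex are flagged undefined rather
than extrapolated.  The free parameters of the definition were fixed once
by calibration against idealized A- and B-form fiber duplexes; residual
deviations are reported alongside (see docs/methods.md).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import base_geometry as bg

logger = logging.getLogger(__name__)

__all__ = ["GrooveProfile", "groove_profile", "GrooveError",
           "DEFAULT_GROOVE_DEFINITION"]

DEFAULT_GROOVE_DEFINITION = "cross_rim_v1"
PHOSPHATE_CORRECTION = 5.8      # two phosphate-group radii (angstrom)

MINOR_EDGE = {"G": ["N3", "C2", "N2"], "A": ["N3", "C2"],
              "C": ["O2"], "T": ["O2"], "U": ["O2"]}

_MINOR_OFFSETS = range(-7, 0)    # strand-II level offsets on the minor side
_MAJOR_OFFSETS = range(1, 9)     # ... and on the major side
_MAJOR_RIM_OFFSET = -2           # fixed EC-style rim pair for the major depth
_MINOR_WINDOW = 3                # floor window (levels) for the minor depth
_MAJOR_WINDOW = 1                # floor window (levels) for the major depth


class GrooveError(ValueError):
    pass


@dataclass
class GrooveProfile:
    levels: pd.DataFrame
    definition_id: str = DEFAULT_GROOVE_DEFINITION

    def summary(self, span: Optional[tuple] = None) -> dict:
        """Mean groove dimensions over fully defined levels.

        Levels flagged undefined (duplex ends, where the rim construction
        does not fit) are excluded; ``span`` optionally restricts to a
        level interval such as the recognition site.
        """
        df = self.levels[self.levels["defined"]]
        if span is not None:
            df = df[(df["level"] >= span[0]) & (df["level"] <= span[1])]
        out = {"definition_id": self.definition_id}
        for col in ("minor_width", "major_width", "minor_depth", "major_depth"):
            vals = df[col].dropna()
            out[col] = float(vals.mean()) if len(vals) else float("nan")
        return out


def _dist_point_line(p, a, b):
    u = b - a
    u = u / np.linalg.norm(u)
    v = p - a
    return float(np.linalg.norm(v - np.dot(v, u) * u))


def _collect(duplex):
    """Phosphate and minor-edge positions per level, per strand."""
    n = len(duplex.pairs)
    P = {1: [None] * n, 2: [None] * n}
    minor_edge = [[] for _ in range(n)]
    for i, pair in enumerate(duplex.pairs):
        for strand, res in ((1, pair.res_i), (2, pair.res_j)):
            atom = res.atom("P")
            if atom is not None:
                P[strand][i] = atom.position
            code = bg.base_code(res)
            for name in MINOR_EDGE.get(code, []):
                a = res.atom(name)
                if a is not None:
                    minor_edge[i].append(a.position)
    return P, minor_edge


def _raw_profile(P, minor_edge, n):
    """Depth/width profile from the strand-I perspective."""
    minor_w = np.full(n, np.nan)
    major_w = np.full(n, np.nan)
    minor_d = np.full(n, np.nan)
    major_d = np.full(n, np.nan)
    for i in range(n):
        p1 = P[1][i]
        if p1 is None:
            continue
        # widths: closest cross-strand P-P on each side, minus 5.8
        for offsets, out in ((_MINOR_OFFSETS, minor_w), (_MAJOR_OFFSETS, major_w)):
            ds = [np.linalg.norm(p1 - P[2][i + j]) for j in offsets
                  if 0 <= i + j < n and P[2][i + j] is not None]
            if len(ds) >= 4:
                out[i] = min(ds) - PHOSPHATE_CORRECTION
        # minor depth: major-side rim line -> minor-edge floor atoms
        major_rims = [(np.linalg.norm(p1 - P[2][i + j]), i + j) for j in
                      _MAJOR_OFFSETS if 0 <= i + j < n and P[2][i + j] is not None]
        if len(major_rims) >= 4 and i - _MINOR_WINDOW >= 0 and \
                i + _MINOR_WINDOW < n:
            _, jbest = min(major_rims)
            floor = [p for L in range(i - _MINOR_WINDOW, i + _MINOR_WINDOW + 1)
                     for p in minor_edge[L]]
            if floor:
                minor_d[i] = max(_dist_point_line(p, p1, P[2][jbest])
                                 for p in floor)
        # major depth: minor-rim midpoint -> phosphate envelope
        j2 = i + _MAJOR_RIM_OFFSET
        if 0 <= j2 < n and P[2][j2] is not None and \
                i - _MAJOR_WINDOW >= 0 and i + _MAJOR_WINDOW < n:
            mid = 0.5 * (p1 + P[2][j2])
            phos = [P[s][L] for s in (1, 2)
                    for L in range(i - _MAJOR_WINDOW, i + _MAJOR_WINDOW + 1)
                    if P[s][L] is not None]
            if len(phos) >= 4:
                major_d[i] = max(np.linalg.norm(p - mid) for p in phos)
    return minor_w, major_w, minor_d, major_d


def groove_profile(duplex, definition: str = DEFAULT_GROOVE_DEFINITION) -> GrooveProfile:
    """Groove width/depth profile of a paired duplex.

    Requires at least 4 base pairs with phosphates present (5'-terminal
    residues may lack P).
    """
    if definition != DEFAULT_GROOVE_DEFINITION:
        raise GrooveError(f"unknown groove definition {definition!r}")
    n = len(duplex.pairs)
    if n < 4:
        raise GrooveError("need at least 4 base pairs for a groove profile")
    P, minor_edge = _collect(duplex)
    n_phos = sum(p is not None for s in (1, 2) for p in P[s])
    if n_phos < 4:
        raise GrooveError("insufficient backbone: fewer than 4 phosphates")
    fwd = _raw_profile(P, minor_edge, n)

    rev = duplex.reversed()
    Pr, minor_edge_r = _collect(rev)
    bwd = _raw_profile(Pr, minor_edge_r, n)
    bwd = tuple(arr[::-1] for arr in bwd)

    cols = {}
    for name, f, b in zip(("minor_width", "major_width",
                           "minor_depth", "major_depth"), fwd, bwd):
        both = np.vstack([f, b])
        valid = ~np.all(np.isnan(both), axis=0)
        merged = np.full(both.shape[1], np.nan)
        if valid.any():
            merged[valid] = np.nanmean(both[:, valid], axis=0)
        cols[name] = merged
    df = pd.DataFrame({"level": np.arange(n), **cols})
    df["defined"] = ~df[["minor_width", "major_width", "minor_depth",
                         "major_depth"]].isna().any(axis=1)
    return GrooveProfile(levels=df, definition_id=definition)
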