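"""Van-der-Waals clash scoring of grafted 2'-hydroxyls.

The clash of two atoms is the positive overlap of their van-der-Waals
spheres, ``max(0, r_a + r_b - d)``.  For each grafted O2' the maximal and
cumulative (per partner atom) clashes are recorded, split into protein and
nucleic-acid partners.  Excluded from scoring: atoms of the same nucleotide
within two covalent bonds of O2' (C2', C1', C3' and their hydrogens), all
hydrogens, waters and monoatomic ions.

A cKDTree neighbour search bounds the candidate partners; the contact
cutoff only affects speed, never results (guaranteed by the brute-force
equivalence tests).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hydroxyl_grafting import GraftReport, GraftResult
from .structure_io import BONDI, StructureModel

logger = logging.getLogger(__name__)

__all__ = ["ClashRecord", "ClashContext", "pair_clash", "score_graft",
           "score_duplex", "DEFAULT_CLASH_THRESHOLD"]

DEFAULT_CLASH_THRESHOLD = 1.1   # angstrom; compensable overlap limit
O2PRIME_RADIUS = BONDI["O"]

#: atoms of the grafted nucleotide within two covalent bonds of O2'
BONDED_EXCLUSIONS = {"C2'", "C1'", "C3'", "H2'", "H2''", "H1'", "H3'"}


@dataclass
class ClashRecord:
    residue_key: tuple
    max_clash: float = 0.0
    cumulative_clash: float = 0.0
    max_clash_protein: float = 0.0
    max_clash_nucleic: float = 0.0
    cumulative_protein: float = 0.0
    cumulative_nucleic: float = 0.0
    worst_partner: Optional[tuple] = None     # (residue key, atom name)
    threshold: float = DEFAULT_CLASH_THRESHOLD

    @property
    def above_threshold(self) -> bool:
        return self.max_clash > self.threshold


def pair_clash(radius_a: float, pos_a, radius_b: float, pos_b) -> float:
    """Positive van-der-Waals overlap of two atoms (angstrom)."""
    d = float(np.linalg.norm(np.asarray(pos_a, float) - np.asarray(pos_b, float)))
    return max(0.0, radius_a + radius_b - d)


class ClashContext:
    """Pre-indexed model atoms eligible as clash partners."""

    def __init__(self, model: StructureModel, cutoff: float = 4.8):
        self.cutoff = cutoff
        positions, radii, keys, names, categories = [], [], [], [], []
        for res, atom in model.atoms():
            if atom.element.upper() == "H":
                continue
            if res.category in ("water", "metal", "other"):
                continue
            positions.append(atom.position)
            radii.append(atom.vdw_radius if atom.vdw_radius is not None
                         else BONDI.get(atom.element.upper(), 1.6))
            keys.append(res.key)
            names.append(atom.name)
            categories.append("protein" if res.category == "protein"
                              else "nucleic")
        if not positions:
            raise ValueError("model has no scorable atoms")
        self.positions = np.asarray(positions)
        self.radii = np.asarray(radii)
        self.keys = keys
        self.names = names
        self.categories = np.asarray(categories)
        self.tree = cKDTree(self.positions)

    def neighbours(self, point: np.ndarray):
        return self.tree.query_ball_point(point, self.cutoff)


def score_graft(graft: GraftResult, model: StructureModel,
                context: Optional[ClashContext] = None,
                threshold: float = DEFAULT_CLASH_THRESHOLD,
                brute_force: bool = False) -> ClashRecord:
    """Clash record of one grafted O2' against the whole model."""
    ctx = context if context is not None else ClashContext(model)
    pos = np.asarray(graft.o2prime_position, float)
    rec = ClashRecord(residue_key=graft.residue.key, threshold=threshold)
    idx = range(len(ctx.positions)) if brute_force else ctx.neighbours(pos)
    protein, nucleic = [], []
    for i in idx:
        if ctx.keys[i] == graft.residue.key and ctx.names[i] in BONDED_EXCLUSIONS:
            continue
        clash = O2PRIME_RADIUS + ctx.radii[i] - np.linalg.norm(ctx.positions[i] - pos)
        if clash <= 0.0:
            continue
        (protein if ctx.categories[i] == "protein" else nucleic).append(clash)
        if clash > rec.max_clash:
            rec.max_clash = clash
            rec.worst_partner = (ctx.keys[i], ctx.names[i])
    # sorted accumulation keeps sums independent of the search order
    rec.cumulative_protein = float(sum(sorted(protein)))
    rec.cumulative_nucleic = float(sum(sorted(nucleic)))
    rec.cumulative_clash = float(sum(sorted(protein + nucleic)))
    rec.max_clash_protein = max(protein, default=0.0)
    rec.max_clash_nucleic = max(nucleic, default=0.0)
    return rec


def score_duplex(duplex, model: StructureModel,
                 which: str = "both_strands",
                 threshold: float = DEFAULT_CLASH_THRESHOLD,
                 graft_report: Optional[GraftReport] = None) -> pd.DataFrame:
    """Per-base-pair clash table in the two-strand + strand-averaged layout.

    Grafts are evaluated one at a time: each graft is scored against the
    ungrafted model, so no O2'-O2' cross terms arise.  Positions whose graft
    failed are reported as NaN, not zero.
    """
    from .hydroxyl_grafting import graft_duplex
    if graft_report is None:
        graft_report = graft_duplex(duplex, which=which)
    ctx = ClashContext(model)
    by_pos = {}
    for g in graft_report.results:
        rec = score_graft(g, model, context=ctx, threshold=threshold)
        by_pos[(g.level, g.strand)] = rec
    rows = []
    for level, pair in enumerate(duplex.pairs):
        row = {"position": level,
               "pair": f"{pair.bases[0]}:{pair.bases[1]}"}
        for strand in (1, 2):
            rec = by_pos.get((level, strand))
            tag = f"s{strand}"
            row[f"max_{tag}"] = rec.max_clash if rec else np.nan
            row[f"cum_{tag}"] = rec.cumulative_clash if rec else np.nan
            row[f"max_protein_{tag}"] = rec.max_clash_protein if rec else np.nan
            row[f"max_nucleic_{tag}"] = rec.max_clash_nucleic if rec else np.nan
            row[f"cum_protein_{tag}"] = rec.cumulative_protein if rec else np.nan
            row[f"cum_nucleic_{tag}"] = rec.cumulative_nucleic if rec else np.nan
        for quantity in ("max", "cum", "max_protein", "max_nucleic",
                         "cum_protein", "cum_nucleic"):
            row[f"{quantity}_mean"] = np.nanmean(
                [row[f"{quantity}_s1"], row[f"{quantity}_s2"]]) \
                if not (np.isnan(row[f"{quantity}_s1"]) and
                        np.isnan(row[f"{quantity}_s2"])) else np.nan
        row["above_threshold"] = (
            max(row["max_s1"] if not np.isnan(row["max_s1"]) else 0.0,
                row["max_s2"] if not np.isnan(row["max_s2"]) else 0.0)
            > threshold)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["threshold"] = threshold
    df.attrs["which"] = which
    return df
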