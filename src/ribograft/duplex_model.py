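"""Base pairing into antiparallel duplexes and IUPAC site annotation.

Pairing criteria (all must hold):

* C1'-C1' distance within 10.4 +- 1.5 angstrom,
* at least one canonical Watson-Crick donor-acceptor pair closer than
  3.5 angstrom,
* anti-aligned base normals (dot of the two base-frame z axes < -0.5).

The reference strand of the resulting :class:`Duplex` is the strand on
which an annotated recognition pattern reads 5'->3'.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import base_geometry as bg
from .structure_io import Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = ["BasePair", "Duplex", "pair_bases", "annotate_site",
           "iupac_match", "complement", "DuplexError", "EmptyDuplexError",
           "PatternError"]


class DuplexError(ValueError):
    pass


class EmptyDuplexError(DuplexError):
    pass


class PatternError(DuplexError):
    pass


IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T", "U"}, "U": {"U", "T"},
    "R": {"A", "G"}, "Y": {"C", "T", "U"}, "W": {"A", "T", "U"},
    "S": {"G", "C"}, "K": {"G", "T", "U"}, "M": {"A", "C"},
    "B": {"C", "G", "T", "U"}, "D": {"A", "G", "T", "U"},
    "H": {"A", "C", "T", "U"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "U"},
}

WC_PARTNERS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
               ("A", "U"), ("U", "A")}

#: canonical WC donor/acceptor heavy-atom pairs, keyed by (purine, pyrimidine)
WC_HBOND_ATOMS = {
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("A", "T"): [("N6", "O4"), ("N1", "N3")],
    ("A", "U"): [("N6", "O4"), ("N1", "N3")],
}


def complement(base: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}[base]


def iupac_match(pattern: str, sequence: str) -> bool:
    if len(pattern) != len(sequence):
        return False
    return all(s in IUPAC[p] for p, s in zip(pattern, sequence))


@dataclass
class BasePair:
    res_i: Residue
    res_j: Residue
    pair_type: str = "WC"
    frame_i: Optional[bg.BaseFrame] = None
    frame_j: Optional[bg.BaseFrame] = None

    @property
    def frame(self) -> bg.BaseFrame:
        return bg.pair_frame(self.frame_i, self.frame_j)

    @property
    def bases(self) -> tuple:
        return (bg.base_code(self.res_i), bg.base_code(self.res_j))


@dataclass
class Duplex:
    pairs: list = field(default_factory=list)
    site_span: Optional[tuple] = None       # (start, end) inclusive indices
    site_pattern: str = ""
    model: Optional[StructureModel] = None

    def __len__(self):
        return len(self.pairs)

    @property
    def sequence(self) -> str:
        """Reference-strand sequence, 5'->3'."""
        return "".join(bg.base_code(p.res_i) or "N" for p in self.pairs)

    def pair_frames(self) -> list:
        return [p.frame for p in self.pairs]

    def reversed(self) -> "Duplex":
        """The same duplex read from the complementary strand."""
        pairs = [BasePair(p.res_j, p.res_i, p.pair_type, p.frame_j, p.frame_i)
                 for p in reversed(self.pairs)]
        return Duplex(pairs=pairs, model=self.model)


def _hbond_ok(res_a: Residue, res_b: Residue, cutoff: float = 3.5) -> bool:
    a, b = bg.base_code(res_a), bg.base_code(res_b)
    if a is None or b is None:
        return False
    for (pur, pyr), atom_pairs in WC_HBOND_ATOMS.items():
        for (ra, rb), flip in (((a, b), False), ((b, a), True)):
            if (ra, rb) != (pur, pyr):
                continue
            pur_res, pyr_res = (res_b, res_a) if flip else (res_a, res_b)
            for n1, n2 in atom_pairs:
                a1, a2 = pur_res.atom(n1), pyr_res.atom(n2)
                if a1 is not None and a2 is not None and \
                        np.linalg.norm(a1.position - a2.position) < cutoff:
                    return True
    return False


def pair_bases(model: StructureModel,
               chain_pair: Optional[tuple] = None) -> Duplex:
    """Pair nucleotides of a model into the longest antiparallel duplex."""
    nts = [r for r in model.residues() if r.category in ("DNA", "RNA")]
    if chain_pair is not None:
        nts = [r for r in nts if r.chain_id in chain_pair]
    if len(nts) < 2:
        raise EmptyDuplexError("fewer than two nucleotide residues")

    frames = {}
    for res in nts:
        try:
            frames[res.key] = bg.fit_base_frame(res)
        except bg.GeometryError as exc:
            logger.warning("skipping %s/%s: %s", res.chain_id, res.seq_id, exc)

    candidates = []
    for i, ri in enumerate(nts):
        for rj in nts[i + 1:]:
            if ri.chain_id == rj.chain_id and chain_pair is None and \
                    len({r.chain_id for r in nts}) > 1:
                continue
            if ri.key not in frames or rj.key not in frames:
                continue
            c1i, c1j = ri.atom("C1'"), rj.atom("C1'")
            if c1i is None or c1j is None:
                continue
            d = np.linalg.norm(c1i.position - c1j.position)
            if not (10.4 - 1.5 <= d <= 10.4 + 1.5):
                continue
            if np.dot(frames[ri.key].z, frames[rj.key].z) >= -0.5:
                continue
            if not _hbond_ok(ri, rj):
                continue
            candidates.append((ri, rj))

    if not candidates:
        raise EmptyDuplexError("no base pairs satisfy the pairing criteria")

    # each nucleotide in at most one pair: greedy by hbond quality is not
    # needed for in-scope substrates -- first-come on residue order suffices,
    # but guard against double assignment.
    used = set()
    pairs = []
    for ri, rj in candidates:
        if ri.key in used or rj.key in used:
            continue
        used.update((ri.key, rj.key))
        pairs.append((ri, rj))

    # order along the helix: sort by the reference strand's residue order
    ref_chain = pairs[0][0].chain_id
    chain_order = {r.key: n for n, r in enumerate(
        [res for res in model.residues() if res.chain_id == ref_chain])}
    oriented = []
    for ri, rj in pairs:
        if ri.chain_id != ref_chain and rj.chain_id == ref_chain:
            ri, rj = rj, ri
        oriented.append((ri, rj))
    oriented.sort(key=lambda p: chain_order.get(p[0].key, 10 ** 9))

    bp = [BasePair(ri, rj, "WC" if (bg.base_code(ri), bg.base_code(rj))
                   in WC_PARTNERS else "non-WC",
                   frames[ri.key], frames[rj.key]) for ri, rj in oriented]
    return Duplex(pairs=bp, model=model)


def annotate_site(duplex: Duplex, pattern: str) -> Duplex:
    """Annotate the first IUPAC match of ``pattern``; searches both strands.

    If the match lies on the complementary strand the duplex is re-oriented
    so the site reads 5'->3' on the reference strand.
    """
    pattern = pattern.upper()
    bad = [c for c in pattern if c not in IUPAC]
    if bad:
        raise PatternError(f"illegal IUPAC character(s): {''.join(bad)}")
    for dpx in (duplex, duplex.reversed()):
        seq = dpx.sequence
        matches = [i for i in range(len(seq) - len(pattern) + 1)
                   if iupac_match(pattern, seq[i:i + len(pattern)])]
        if matches:
            if len(matches) > 1:
                logger.warning("pattern %s matches at %s; using the first",
                               pattern, matches)
            dpx.site_span = (matches[0], matches[0] + len(pattern) - 1)
            dpx.site_pattern = pattern
            return dpx
    logger.warning("pattern %s not found on either strand", pattern)
    duplex.site_span = None
    duplex.site_pattern = pattern
    return duplex
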