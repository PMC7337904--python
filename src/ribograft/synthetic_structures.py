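"""Synthetic idealized duplexes and controlled clash-probe environments.

Fiber duplexes are assembled from the frozen nucleotide templates in
``ribograft/data/fiber_templates.json``: per-base standard-frame base
templates plus per-form (A / B) sugar-phosphate backbones that were solved
under each form's helical symmetry.  Three builders are provided:

* helical builds (``form="A"``/``"B"``), placing every base pair by the
  form's twist / rise / x-displacement / inclination;
* interpolated builds (:func:`interpolate_conformation`), linear in both
  the helical parameters and the backbone template coordinates, so t = 0
  reproduces the B build and t = 1 the A build exactly;
* custom builds from explicit local step parameters
  (``FiberSpec(form="custom", steps=[...])``), composed with the exact
  inverse of the analyzer's step algebra.

Ground truth (sequence, pairing, helical parameters, target puckers) is
recorded in the returned model's ``provenance``.

:func:`place_probes` adds pseudo-protein probe atoms at controlled
distances from the would-be grafted O2' positions, so that the expected
steric clash of a grafted hydroxyl is known exactly by construction.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import base_geometry as bg
from .structure_io import (AtomRecord, Residue, StructureModel, BONDI,
                           PROBE_COMP, classify_residue)

logger = logging.getLogger(__name__)

__all__ = ["FiberSpec", "ProbeSpec", "build_fiber_duplex",
           "interpolate_conformation", "place_probes", "SequenceError",
           "ProbePlacementError", "form_spec"]


class SequenceError(ValueError):
    pass


class ProbePlacementError(ValueError):
    pass


BACKBONE_ORDER = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                  "O3'", "C2'", "O2'", "C1'"]
_DYAD = np.diag([1.0, -1.0, -1.0])
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}
_DNA_COMP = {"A": "DA", "G": "DG", "C": "DC", "T": "DT"}
_RNA_COMP = {"A": "A", "G": "G", "C": "C", "U": "U"}


@dataclass
class FiberSpec:
    """Helical recipe for an idealized duplex.

    For ``form`` "A" or "B" unset parameters default to the classic fiber
    values shipped with the templates.  ``form="custom"`` builds from the
    explicit local ``steps`` (a list of :class:`~ribograft.base_geometry.
    StepParameters`), with sugars taken from ``sugar_form``.
    """
    form: str = "B"
    twist: Optional[float] = None          # deg / step
    rise: Optional[float] = None           # angstrom / step
    xdisp: Optional[float] = None          # angstrom
    inclination: Optional[float] = None    # deg
    sugar_form: Optional[str] = None       # template set for custom builds
    steps: Optional[list] = None

    def resolved(self) -> "FiberSpec":
        spec = dataclasses.replace(self)
        if spec.form in ("A", "B"):
            defaults = bg.load_templates()["forms"][spec.form]
            spec.twist = defaults["twist"] if spec.twist is None else spec.twist
            spec.rise = defaults["rise"] if spec.rise is None else spec.rise
            spec.xdisp = defaults["xdisp"] if spec.xdisp is None else spec.xdisp
            spec.inclination = (defaults["inclination"]
                                if spec.inclination is None else spec.inclination)
            spec.sugar_form = spec.sugar_form or spec.form
        elif spec.form == "custom":
            if spec.steps is None and spec.twist is None:
                raise SequenceError("custom FiberSpec needs steps or helical "
                                    "parameters")
            spec.sugar_form = spec.sugar_form or "B"
        else:
            raise SequenceError(f"unknown form {spec.form!r}")
        if spec.rise is not None and spec.rise <= 0:
            raise SequenceError("rise must be positive")
        if spec.twist is not None and not (0.0 < spec.twist < 60.0):
            raise SequenceError("twist must lie in (0, 60) degrees")
        return spec


@dataclass
class ProbeSpec:
    """A pseudo-protein probe atom aimed at one nucleotide's future O2'.

    The probe is placed on the outward ray from the would-be O2' position
    (along C2'->O2') at distance ``r_O2' + r_probe - intended_clash +
    margin``, so a grafted hydroxyl will clash with it by exactly
    ``intended_clash``.
    """
    index: int                       # base-pair level (0-based)
    intended_clash: float            # angstrom, >= 0
    strand: int = 1                  # 1 or 2
    element: str = "C"
    margin: float = 0.0              # extra separation beyond contact

    def __post_init__(self):
        if self.intended_clash < 0:
            raise ProbePlacementError("intended_clash must be >= 0")
        if self.strand not in (1, 2):
            raise ProbePlacementError("strand must be 1 or 2")
        if self.margin and self.intended_clash > 0:
            raise ProbePlacementError("margin only applies to clash-free probes")


def form_spec(form: str) -> FiberSpec:
    return FiberSpec(form=form).resolved()


def _backbone_coords(templates: dict, spec: FiberSpec, t: Optional[float] = None) -> dict:
    c1 = np.array(templates["c1_anchor"])
    if t is None:
        bb = {k: np.array(v) for k, v in templates["backbones"][spec.sugar_form].items()}
    else:
        bbB = templates["backbones"]["B"]
        bbA = templates["backbones"]["A"]
        bb = {k: (1.0 - t) * np.array(bbB[k]) + t * np.array(bbA[k]) for k in bbA}
    bb["C1'"] = c1
    return bb


def _pair_placements(spec: FiberSpec, n: int) -> list:
    """Pair frames (BaseFrame) for each level of the duplex."""
    if spec.form == "custom" and spec.steps is not None:
        frames = [bg.BaseFrame(np.zeros(3), np.eye(3))]
        for step in spec.steps:
            frames.append(bg.compose_step(frames[-1], step))
        if len(frames) != n:
            raise SequenceError(f"{len(frames)} frames from steps but "
                                f"{n} base pairs requested")
        return frames
    incl = bg.rotation_about([1, 0, 0], spec.inclination)
    shift = np.array([spec.xdisp, 0.0, 0.0])
    frames = []
    for i in range(n):
        Rz = bg.rotation_about([0, 0, 1], i * spec.twist)
        axes = Rz @ incl
        origin = Rz @ shift + np.array([0.0, 0.0, i * spec.rise])
        frames.append(bg.BaseFrame(origin, axes))
    return frames


def _validate_sequence(sequence: str, hybrid: str) -> str:
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise SequenceError("sequence must have length >= 2")
    allowed = set("ACGTU")
    bad = [c for c in sequence if c not in allowed]
    if bad:
        raise SequenceError(f"invalid nucleotide character(s): {''.join(bad)}")
    if "U" in sequence and hybrid != "strand1_rna":
        raise SequenceError("U only allowed when strand 1 is RNA")
    return sequence


def build_fiber_duplex(sequence: str, spec: FiberSpec | str = "B",
                       hybrid: str = "none",
                       interpolation_t: Optional[float] = None) -> StructureModel:
    """Build an idealized duplex of ``sequence`` (strand I, 5'->3').

    ``hybrid`` marks one strand as RNA ("strand1_rna" / "strand2_rna"):
    that strand carries O2' atoms and U replaces T.
    """
    if isinstance(spec, str):
        spec = FiberSpec(form=spec)
    spec = spec.resolved()
    if hybrid not in ("none", "strand1_rna", "strand2_rna"):
        raise SequenceError(f"unknown hybrid mode {hybrid!r}")
    sequence = _validate_sequence(sequence, hybrid)
    templates = bg.load_templates()
    bases = {b: {k: np.array(v) for k, v in d.items()}
             for b, d in templates["bases"].items()}
    bb = _backbone_coords(templates, spec, interpolation_t)
    frames = _pair_placements(spec, len(sequence))

    n = len(sequence)
    model = StructureModel(source_id=f"fiber-{spec.form}")
    seq1 = sequence.replace("T", "U") if hybrid == "strand1_rna" else \
        sequence.replace("U", "T")
    seq2 = "".join(_COMPLEMENT[c] for c in sequence.replace("U", "T"))
    if hybrid == "strand2_rna":
        seq2 = seq2.replace("T", "U")

    def residue_atoms(base: str, strand: int, level: int, is_rna: bool,
                      is_5prime: bool) -> list:
        local = dict(bb)
        local.update(bases[base])
        flip = _DYAD if strand == 2 else np.eye(3)
        frame = frames[level]
        atoms = []
        order = BACKBONE_ORDER + [a for a in bases[base] if a != "C1'"]
        for name in order:
            if name not in local:
                continue
            if name == "O2'" and not is_rna:
                continue
            if is_5prime and name in ("P", "OP1", "OP2"):
                continue
            pos = frame.axes @ (flip @ local[name]) + frame.origin
            elem = name[0]
            atoms.append(AtomRecord(name=name, element=elem, position=pos))
        return atoms

    truth_pairs = []
    for level in range(n):
        base = seq1[level]
        res = Residue(chain_id="A", seq_id=level + 1,
                      comp_id=(_RNA_COMP if hybrid == "strand1_rna" else
                               _DNA_COMP)[base])
        res.atoms = residue_atoms(base, 1, level, hybrid == "strand1_rna",
                                  level == 0)
        res.category = classify_residue(res)
        model.add_residue(res)
    for k in range(n):
        level = n - 1 - k           # strand II runs antiparallel
        base = seq2[level]
        res = Residue(chain_id="B", seq_id=k + 1,
                      comp_id=(_RNA_COMP if hybrid == "strand2_rna" else
                               _DNA_COMP)[base])
        res.atoms = residue_atoms(base, 2, level, hybrid == "strand2_rna",
                                  k == 0)
        res.category = classify_residue(res)
        model.add_residue(res)
    for level in range(n):
        truth_pairs.append((("A", level + 1), ("B", n - level)))

    model.provenance.update({
        "generator": "fiber",
        "sequence": sequence,
        "hybrid": hybrid,
        "form": spec.form,
        "helical": {"twist": spec.twist, "rise": spec.rise,
                    "xdisp": spec.xdisp, "inclination": spec.inclination},
        "interpolation_t": interpolation_t,
        "sugar_form": spec.sugar_form,
        "pairs": truth_pairs,
        "pucker_target": (templates["forms"][spec.sugar_form]["pucker_P"]
                          if spec.sugar_form in ("A", "B") and
                          interpolation_t is None else None),
    })
    return model


def interpolate_conformation(spec_a: FiberSpec | str, spec_b: FiberSpec | str,
                             t: float, sequence: str,
                             hybrid: str = "none") -> StructureModel:
    """Duplex interpolated between the B build (t=0) and the A build (t=1)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"interpolation fraction t={t} outside [0, 1]")
    sa = (FiberSpec(form=spec_a) if isinstance(spec_a, str) else spec_a).resolved()
    sb = (FiberSpec(form=spec_b) if isinstance(spec_b, str) else spec_b).resolved()
    mix = FiberSpec(
        form=sa.form if t == 1.0 else sb.form if t == 0.0 else "custom",
        twist=(1 - t) * sb.twist + t * sa.twist,
        rise=(1 - t) * sb.rise + t * sa.rise,
        xdisp=(1 - t) * sb.xdisp + t * sa.xdisp,
        inclination=(1 - t) * sb.inclination + t * sa.inclination,
        sugar_form=sa.sugar_form if t == 1.0 else sb.sugar_form,
    )
    # exact endpoint identity: reuse the pure-form backbone at t in {0, 1}
    t_bb = None if t in (0.0, 1.0) else t
    if mix.form == "custom":
        mix.sugar_form = "B"
    model = build_fiber_duplex(sequence, mix if mix.form != "custom" else
                               dataclasses.replace(mix, form="custom",
                                                   steps=None),
                               hybrid=hybrid, interpolation_t=t_bb)
    model.provenance["interpolation_t"] = t
    return model


def _graft_position(residue: Residue) -> tuple:
    """Would-be O2' position and outward direction for a deoxyribose."""
    from .hydroxyl_grafting import o2prime_geometry
    pos, direction = o2prime_geometry(residue)
    return pos, direction


def place_probes(model: StructureModel, probes: Sequence[ProbeSpec],
                 seed: int = 0) -> StructureModel:
    """Place pseudo-protein probe atoms with construction-known clashes.

    The placement is deterministic; ``seed`` is recorded in provenance for
    bookkeeping of downstream randomized workflows.
    """
    out = model.copy()
    chains = {1: "A", 2: "B"}
    probe_res = Residue(chain_id="X", seq_id=1, comp_id=PROBE_COMP)
    r_o2 = BONDI["O"]
    excluded = {"C1'", "C2'", "C3'", "H2'", "H2''"}
    for k, probe in enumerate(probes):
        chain = chains[probe.strand]
        residues = out.chains.get(chain, [])
        if not 0 <= probe.index < len(residues):
            raise ProbePlacementError(f"no nucleotide at index {probe.index} "
                                      f"on strand {probe.strand}")
        target = residues[probe.index] if probe.strand == 1 else \
            residues[len(residues) - 1 - probe.index]
        o2_pos, direction = _graft_position(target)
        r_probe = BONDI.get(probe.element.upper(), 1.70)
        dist = r_o2 + r_probe - probe.intended_clash + probe.margin
        pos = o2_pos + dist * direction
        # two placement invariants keep the clash oracle exact:
        # (1) no prior probe may already clash with this O2' position, and
        # (2) the new probe centre must not sit inside an existing atom.
        existing = list(out.atoms()) + [(probe_res, a) for a in probe_res.atoms]
        for res, atom in existing:
            if res is target and atom.name in excluded:
                continue
            if atom.element.upper() == "H":
                continue
            r_atom = BONDI.get(atom.element.upper(), 1.6)
            if res.comp_id == PROBE_COMP:
                o2_overlap = r_o2 + r_atom - np.linalg.norm(atom.position - o2_pos)
                if o2_overlap > 1e-9:
                    raise ProbePlacementError(
                        f"probe {k} at bp {probe.index}: earlier probe "
                        f"{atom.name} already clashes its O2' site by "
                        f"{o2_overlap:.2f} A")
            if np.linalg.norm(atom.position - pos) < r_atom:
                raise ProbePlacementError(
                    f"probe {k} at bp {probe.index} buried inside "
                    f"{res.comp_id}/{res.seq_id}:{atom.name}")
        probe_res.atoms.append(AtomRecord(name=f"X{k + 1}",
                                          element=probe.element.upper(),
                                          position=pos))
    if probe_res.atoms:
        probe_res.category = "protein"
        out.add_residue(probe_res)
    out.provenance["probes"] = [dataclasses.asdict(p) for p in probes]
    out.provenance["probe_seed"] = seed
    return out
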