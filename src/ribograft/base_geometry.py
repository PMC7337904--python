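"""Base reference frames, base-pair step parameters, Zp and sugar puckers.

Conventions
-----------
Base frames follow the standard nucleic-acid reference frame: the base pair
lies in the frame's xy plane, +x points into the major groove, +y runs along
the pair towards the reference (strand I) base, +z advances along the helix.
Frames are obtained by least-squares superposition of idealized base
templates (shipped in ``ribograft/data``) onto the observed ring atoms.

Step parameters use the CEHS / mid-step convention: shift, slide and rise
are the inter-pair translation expressed in the mid-step frame; tilt, roll
and twist decompose the inter-pair rotation symmetrically about the
"hinge" axis.  ``compose_step`` is the exact algebraic inverse of
``step_parameters`` and is what the synthetic generator uses, so
analyze(generate(p)) recovers p to machine precision.

Helical parameters (x-displacement, inclination, tip, helical twist/rise)
come from the screw-axis decomposition of each step transform, and Zp is
the mean z coordinate of the two step phosphates in the mid-step helical
frame -- the quantity used to separate A-like from B-like steps.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_io import Residue

logger = logging.getLogger(__name__)

__all__ = [
    "BaseFrame", "StepParameters", "PuckerResult", "StepThresholds",
    "superpose", "fit_base_frame", "pair_frame", "step_parameters",
    "compose_step", "helical_parameters", "classify_step", "pseudorotation",
    "sugar_pucker", "fit_helix_axis", "GeometryError", "DegenerateFitError",
    "IncompleteBaseError", "UndefinedPuckerError", "load_templates",
]

RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

COMP_TO_BASE = {
    "DA": "A", "DG": "G", "DC": "C", "DT": "T", "DU": "U",
    "A": "A", "G": "G", "C": "C", "U": "U", "T": "T",
    "ADE": "A", "GUA": "G", "CYT": "C", "THY": "T", "URA": "U",
}

#: Five endocyclic sugar torsions nu0..nu4 (Altona-Sundaralingam ordering).
NU_DEFS = [
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
]

PUCKER_WEDGES = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]

_FLIP = np.diag([1.0, -1.0, -1.0])  # strand-II frame flip (pi about x)


class GeometryError(ValueError):
    pass


class DegenerateFitError(GeometryError):
    pass


class IncompleteBaseError(GeometryError):
    pass


class UndefinedPuckerError(GeometryError):
    pass


def load_templates() -> dict:
    """Load the idealized nucleotide templates shipped with the package."""
    text = resources.files("ribograft").joinpath("data/fiber_templates.json").read_text()
    return json.loads(text)


_TEMPLATES = None


def _templates() -> dict:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = load_templates()
    return _TEMPLATES


@dataclass
class BaseFrame:
    origin: np.ndarray
    axes: np.ndarray          # 3x3, columns are the x/y/z axes in global coords
    rmsd: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)

    @property
    def x(self):
        return self.axes[:, 0]

    @property
    def y(self):
        return self.axes[:, 1]

    @property
    def z(self):
        return self.axes[:, 2]

    def flipped(self) -> "BaseFrame":
        """The same frame viewed from the complementary strand."""
        return BaseFrame(self.origin.copy(), self.axes @ _FLIP, self.rmsd)


@dataclass
class StepParameters:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    x_displacement: float = float("nan")
    y_displacement: float = float("nan")
    inclination: float = float("nan")
    tip: float = float("nan")
    helical_twist: float = float("nan")
    helical_rise: float = float("nan")
    zp: float = float("nan")
    classification: str = ""


@dataclass
class PuckerResult:
    phase: float        # degrees in [0, 360)
    amplitude: float    # degrees
    conformer: str


@dataclass
class StepThresholds:
    """Zp thresholds separating A-like from B-like steps (angstrom)."""
    zp_a: float = 1.5
    zp_b: float = 0.5


# ---------------------------------------------------------------------------
# elementary geometry

def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise GeometryError("zero-length rotation axis")
    x, y, z = axis / n
    a = np.radians(angle_deg)
    c, s, C = np.cos(a), np.sin(a), 1.0 - np.cos(a)
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def torsion(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))))


def superpose(reference: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid transform carrying ``reference`` onto ``mobile``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (no reflection), so that ``rotation @ reference[i] + translation`` best
    matches ``mobile[i]``.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("point sets must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise DegenerateFitError("need at least 3 points")
    cr, cm = ref.mean(0), mob.mean(0)
    A = ref - cr
    # collinearity check: rank of the centered reference
    if np.linalg.matrix_rank(A, tol=1e-8) < 2:
        raise DegenerateFitError("reference points are collinear")
    H = A.T @ (mob - cm)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cm - R @ cr
    rmsd = float(np.sqrt(np.mean(np.sum((ref @ R.T + t - mob) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# base frames

def base_code(residue: Residue) -> Optional[str]:
    return COMP_TO_BASE.get(residue.comp_id.upper())


def fit_base_frame(residue: Residue, templates: Optional[dict] = None) -> BaseFrame:
    """Fit the standard base template to the observed ring atoms."""
    code = base_code(residue)
    if code is None:
        raise IncompleteBaseError(f"{residue.comp_id} is not a standard nucleotide")
    tmpl = (templates or _templates())["bases"][code]
    names = RING_ATOMS[code]
    missing = [n for n in names if not residue.has_atom(n)]
    if missing:
        raise IncompleteBaseError(
            f"residue {residue.chain_id}/{residue.seq_id} ({residue.comp_id}) "
            f"missing ring atoms: {', '.join(missing)}")
    ref = np.array([tmpl[n] for n in names])
    mob = np.array([residue.atom(n).position for n in names])
    R, t, rmsd = superpose(ref, mob)
    return BaseFrame(origin=t, axes=R, rmsd=rmsd)


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def pair_frame(frame_i: BaseFrame, frame_j: BaseFrame) -> BaseFrame:
    """Mean base-pair frame from the two base frames (strand II flipped)."""
    fj = frame_j.flipped()
    R = _nearest_rotation(frame_i.axes + fj.axes)
    origin = 0.5 * (frame_i.origin + fj.origin)
    return BaseFrame(origin=origin, axes=R)


# ---------------------------------------------------------------------------
# CEHS step parameters and their inverse

def step_parameters(frame1: BaseFrame, frame2: BaseFrame) -> StepParameters:
    """Local step parameters between two consecutive base-pair frames."""
    z1, z2 = frame1.z, frame2.z
    if np.linalg.norm(frame2.origin - frame1.origin) < 1e-9 and \
            np.allclose(frame1.axes, frame2.axes, atol=1e-12):
        raise GeometryError("coincident frames: degenerate step")
    cosg = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    gamma = np.degrees(np.arccos(cosg))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-10:
        # parallel z axes: pure twist step, hinge is irrelevant
        R1p, R2p = frame1.axes, frame2.axes
        gamma = 0.0
        hinge = z1
    else:
        R1p = rotation_about(hinge, +gamma / 2.0) @ frame1.axes
        R2p = rotation_about(hinge, -gamma / 2.0) @ frame2.axes
    zm = R1p[:, 2]
    x1p, x2p = R1p[:, 0], R2p[:, 0]
    twist = _signed_angle(x1p, x2p, zm)
    xm = x1p + x2p
    xm = xm - np.dot(xm, zm) * zm
    if np.linalg.norm(xm) < 1e-10:   # |twist| = 180 deg; pick x1p direction
        xm = x1p - np.dot(x1p, zm) * zm
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    Rm = np.column_stack([xm, ym, zm])
    shift, slide, rise = Rm.T @ (frame2.origin - frame1.origin)
    phi = _signed_angle(hinge, ym, zm) if gamma > 1e-10 else 0.0
    roll = gamma * np.cos(np.radians(phi))
    tilt = gamma * np.sin(np.radians(phi))
    return StepParameters(shift=float(shift), slide=float(slide),
                          rise=float(rise), tilt=float(tilt),
                          roll=float(roll), twist=float(twist))


def _signed_angle(u, v, about) -> float:
    u = u - np.dot(u, about) * about
    v = v - np.dot(v, about) * about
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    u, v = u / nu, v / nv
    return float(np.degrees(np.arctan2(np.dot(np.cross(u, v), about),
                                       np.clip(np.dot(u, v), -1, 1))))


def compose_step(frame1: BaseFrame, params: StepParameters) -> BaseFrame:
    """Exact inverse of :func:`step_parameters`: build the next pair frame."""
    tau, roll, tilt = params.twist, params.roll, params.tilt
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.degrees(np.arctan2(tilt, roll)))
    Rz = lambda a: rotation_about([0, 0, 1], a)
    Ry = lambda a: rotation_about([0, 1, 0], a)
    T = Rz(tau / 2.0 - phi) @ Ry(gamma) @ Rz(tau / 2.0 + phi)
    R2 = frame1.axes @ T
    Rm = frame1.axes @ Rz(tau / 2.0 - phi) @ Ry(gamma / 2.0) @ Rz(phi)
    origin2 = frame1.origin + Rm @ np.array([params.shift, params.slide, params.rise])
    return BaseFrame(origin=origin2, axes=R2)


# ---------------------------------------------------------------------------
# helical (screw-axis) parameters

def _screw_axis(frame1: BaseFrame, frame2: BaseFrame):
    """Screw decomposition of the step: (direction, point, angle_deg, rise)."""
    A = frame2.axes @ frame1.axes.T        # global rotation of the step
    w = np.array([A[2, 1] - A[1, 2], A[0, 2] - A[2, 0], A[1, 0] - A[0, 1]])
    s = np.linalg.norm(w) / 2.0
    c = (np.trace(A) - 1.0) / 2.0
    angle = np.degrees(np.arctan2(s, c))
    if s < 1e-10:
        raise GeometryError("untwisted step: helical axis undefined")
    h = w / np.linalg.norm(w)
    d = frame2.origin - frame1.origin
    if np.dot(h, d) < 0 and abs(np.dot(h, d)) > 1e-9:
        # orient the axis along the direction of advance
        h, angle = -h, -angle
    rise = float(np.dot(d, h))
    # axis point p: (I - A) p = o2 - A o1 - rise*h, solved in the plane "|_" h
    rhs = frame2.origin - A @ frame1.origin - rise * h
    B = np.eye(3) - A
    # project out the null direction h
    basis = _plane_basis(h)
    M = basis.T @ B @ basis
    p2 = np.linalg.solve(M, basis.T @ rhs)
    p = basis @ p2
    return h, p, float(angle), rise


def _plane_basis(n: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.column_stack([u, v])


def helical_parameters(frame1: BaseFrame, frame2: BaseFrame,
                       phosphates: Sequence[np.ndarray] = ()) -> dict:
    """Helical parameters of the step and Zp of its phosphates.

    ``phosphates`` are the positions of the two step phosphorus atoms (one
    per strand); Zp is their mean z coordinate in the mid-step helical frame.
    """
    h, p, angle, rise = _screw_axis(frame1, frame2)
    xh1 = frame1.x - np.dot(frame1.x, h) * h
    xh1 /= np.linalg.norm(xh1)
    yh1 = np.cross(h, xh1)
    r1 = frame1.origin - p
    out = {
        "helical_twist": angle,
        "helical_rise": rise,
        "x_displacement": float(np.dot(r1, xh1)),
        "y_displacement": float(np.dot(r1, yh1)),
        "inclination": float(np.degrees(np.arcsin(np.clip(np.dot(frame1.y, h), -1, 1)))),
        "tip": float(np.degrees(np.arcsin(np.clip(-np.dot(frame1.x, h), -1, 1)))),
        "axis_direction": h,
        "axis_point": p,
    }
    if phosphates:
        mid = 0.5 * (frame1.origin + frame2.origin)
        origin = p + np.dot(mid - p, h) * h
        # each strand's phosphate z is measured along its own 5'->3' helix
        # advance: +h for strand I, -h for strand II
        signs = (1.0, -1.0)
        zp = [float(np.dot(np.asarray(P, float) - origin, s * h))
              for P, s in zip(phosphates, signs) if P is not None]
        out["zp"] = float(np.mean(zp)) if zp else float("nan")
    else:
        out["zp"] = float("nan")
    return out


def classify_step(step: StepParameters, thresholds: StepThresholds = StepThresholds()) -> str:
    """A / B / intermediate classification of a step from its Zp."""
    if np.isnan(step.zp):
        raise GeometryError("step has no Zp; phosphates missing")
    if step.zp >= thresholds.zp_a:
        return "A"
    if step.zp <= thresholds.zp_b:
        return "B"
    return "intermediate"


# ---------------------------------------------------------------------------
# sugar pucker

def pseudorotation(nus: Sequence[float]) -> PuckerResult:
    """Altona-Sundaralingam pseudorotation from the five ring torsions."""
    nus = [float(v) for v in nus]
    if len(nus) != 5:
        raise GeometryError("need exactly five endocyclic torsions")
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    if max(abs(v) for v in nus) < 1e-3:
        raise UndefinedPuckerError("planar ring: pucker undefined")
    P = np.degrees(np.arctan2(num, den))
    if nus[2] < 0:
        # arctan2 already handles the quadrant via the signed denominator
        pass
    P %= 360.0
    amplitude = nus[2] / np.cos(np.radians(P))
    if abs(amplitude) < 1e-3:
        raise UndefinedPuckerError("vanishing pucker amplitude")
    conformer = PUCKER_WEDGES[int(P // 36.0) % 10]
    return PuckerResult(phase=float(P), amplitude=float(abs(amplitude)),
                        conformer=conformer)


def sugar_pucker(residue: Residue) -> PuckerResult:
    """Pseudorotation analysis of a nucleotide's sugar ring."""
    names = {"C1'", "C2'", "C3'", "C4'", "O4'"}
    missing = sorted(n for n in names if not residue.has_atom(n))
    if missing:
        raise IncompleteBaseError(
            f"residue {residue.chain_id}/{residue.seq_id} missing sugar "
            f"atoms: {', '.join(missing)}")
    pos = {n: residue.atom(n).position for n in names}
    nus = [torsion(pos[a], pos[b], pos[c], pos[d]) for a, b, c, d in NU_DEFS]
    return pseudorotation(nus)


# ---------------------------------------------------------------------------
# global axis and displacement

def fit_helix_axis(pair_frames: Sequence[BaseFrame]) -> tuple:
    """Global linear helix axis from the per-step screw axes.

    Returns ``(point, direction)``.  For an ideal fiber every per-step axis
    coincides; for real duplexes the directions and axis points are averaged.
    """
    if len(pair_frames) < 2:
        raise GeometryError("need at least two pair frames to fit an axis")
    dirs, pts = [], []
    for f1, f2 in zip(pair_frames[:-1], pair_frames[1:]):
        h, p, _, _ = _screw_axis(f1, f2)
        dirs.append(h)
        pts.append(p)
    d = np.mean(dirs, axis=0)
    d /= np.linalg.norm(d)
    p0 = np.mean(pts, axis=0)
    return p0, d


def point_axis_distance(point: np.ndarray, axis_point: np.ndarray,
                        axis_dir: np.ndarray) -> float:
    v = np.asarray(point, float) - axis_point
    return float(np.linalg.norm(v - np.dot(v, axis_dir) * axis_dir))


#: Candidate operational definitions for the "displacement from the helix
#: axis" of a base pair; the default is the calibrated one.
DISPLACEMENT_DEFINITIONS = ("c1c1_midpoint", "glyco_n_midpoint", "pair_origin",
                            "helical_xdisp")
DEFAULT_DISPLACEMENT_DEFINITION = "c1c1_midpoint"

GLYCO_ATOMS = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}


def base_pair_displacement(duplex, definition: str = DEFAULT_DISPLACEMENT_DEFINITION,
                           interior_only: bool = True) -> dict:
    """Displacement of each base pair from the global helix axis.

    The default (calibrated) definition measures the perpendicular distance
    from the fitted global axis to the C1'-C1' midpoint of the pair; the
    alternatives use the glycosidic-N midpoint, the standard-frame pair
    origin, or the mean magnitude of the per-step helical x-displacement.
    Returns per-pair values and their mean over interior pairs (terminal
    pairs dropped when ``interior_only``).
    """
    if definition not in DISPLACEMENT_DEFINITIONS:
        raise GeometryError(f"unknown displacement definition {definition!r}")
    frames = duplex.pair_frames()
    if definition == "helical_xdisp":
        vals = []
        for f1, f2 in zip(frames[:-1], frames[1:]):
            vals.append(abs(helical_parameters(f1, f2)["x_displacement"]))
        values = np.asarray(vals)
        mean = float(values.mean()) if len(values) else float("nan")
        return {"definition": definition, "per_pair": values, "mean": mean}
    p0, d = fit_helix_axis(frames)
    landmarks = []
    for pair, frame in zip(duplex.pairs, frames):
        if definition == "pair_origin":
            landmarks.append(frame.origin)
            continue
        if definition == "c1c1_midpoint":
            names = ("C1'", "C1'")
        else:
            names = (GLYCO_ATOMS.get(base_code(pair.res_i), "N9"),
                     GLYCO_ATOMS.get(base_code(pair.res_j), "N9"))
        a_i = pair.res_i.atom(names[0])
        a_j = pair.res_j.atom(names[1])
        landmarks.append(0.5 * (a_i.position + a_j.position)
                         if a_i is not None and a_j is not None else None)
    values = np.array([point_axis_distance(lm, p0, d) if lm is not None
                       else np.nan for lm in landmarks])
    sel = values[1:-1] if interior_only and len(values) > 2 else values
    mean = float(np.nanmean(sel)) if np.any(~np.isnan(sel)) else float("nan")
    return {"definition": definition, "per_pair": values, "mean": mean}


def analyze_duplex(duplex, thresholds: StepThresholds = StepThresholds()):
    """Per-step parameter table of a paired duplex.

    Columns: the six local CEHS parameters, the helical parameters, Zp,
    the A/B/intermediate classification and the sugar pucker phases of the
    two strands' 3'-side nucleotides.
    """
    import pandas as pd

    frames = duplex.pair_frames()
    if len(frames) < 2:
        raise GeometryError("need at least two base pairs")
    rows = []
    for i, (f1, f2) in enumerate(zip(frames[:-1], frames[1:])):
        step = step_parameters(f1, f2)
        p_i = duplex.pairs[i + 1].res_i.atom("P")     # strand I, 3' residue
        p_j = duplex.pairs[i].res_j.atom("P")         # strand II counterpart
        phosphates = [p_i.position if p_i is not None else None,
                      p_j.position if p_j is not None else None]
        if all(p is None for p in phosphates):
            phosphates = []
        hel = helical_parameters(f1, f2, phosphates)
        for key in ("x_displacement", "y_displacement", "inclination", "tip",
                    "helical_twist", "helical_rise", "zp"):
            setattr(step, key, hel[key])
        step.classification = classify_step(step, thresholds) \
            if not np.isnan(step.zp) else ""
        row = {"step": i,
               "dinucleotide": duplex.sequence[i:i + 2]}
        for key in ("shift", "slide", "rise", "tilt", "roll", "twist",
                    "x_displacement", "y_displacement", "inclination", "tip",
                    "helical_twist", "helical_rise", "zp", "classification"):
            row[key] = getattr(step, key)
        for label, res in (("pucker_1", duplex.pairs[i].res_i),
                           ("pucker_2", duplex.pairs[i].res_j)):
            try:
                row[label] = sugar_pucker(res).phase
            except GeometryError:
                row[label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
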