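#!/usr/bin/env python
"""Derive the idealized nucleotide templates shipped in ribograft/data/.

This is a maintainer tool, not part of the runtime package.  It re-derives
``fiber_templates.json`` from scratch and overwrites it.  The derivation has
two stages:

1.  Watson-Crick base-pair templates.  Idealized planar base geometries are
    taken from the Chemical Component Dictionary copies bundled with biotite
    and assembled into coplanar G:C, A:T and A:U pairs by rigid-body least
    squares against standard hydrogen-bond lengths, with the two glycosidic
    attachment points constrained to be related by the in-plane pair dyad.
    The resulting frame follows the standard nucleic-acid reference-frame
    convention: the pair lies in z = 0, +x points into the major groove, the
    pseudo-dyad is the x axis, and the frame is anchored so that C1' sits at
    x = -2.476 angstrom.

2.  Per-form sugar-phosphate backbone templates.  For each helical form
    (A and B) the eleven backbone heavy atoms plus the ribose O2' are solved
    for by restrained least squares: standard bond lengths and angles, ring
    pseudorotation restrained to the form's sugar pucker, glycosidic torsion
    restrained to the form's chi, loose canonical backbone-torsion priors,
    and -- decisively -- the inter-nucleotide O3'(i)-P(i+1) linkage geometry
    evaluated under the form's actual helical symmetry operation.  This is a
    small-scale re-derivation of a linked-atom fiber model.

The frozen output is synthetic model data (no experimental coordinates).
"""
from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

import biotite.structure.info as info

OUT = Path(__file__).resolve().parents[1] / "src" / "ribograft" / "data" / "fiber_templates.json"

BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}
GLYCO = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
COMP = {"A": "DA", "G": "DG", "C": "DC", "T": "DT", "U": "U"}
C1X = -2.476  # standard-frame C1' x anchor

# Watson-Crick donor-acceptor target distances (angstrom)
HBONDS = {
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
    ("A", "T"): [("N6", "O4", 2.95), ("N1", "N3", 2.82)],
    ("A", "U"): [("N6", "O4", 2.95), ("N1", "N3", 2.82)],
}

# Helical parameters of the two fiber forms.  Twist/rise are the classic
# fiber-diffraction values; x-displacement and inclination follow the fiber
# survey conventions with the sign convention of the standard reference frame
# (negative x-displacement = helix axis on the major-groove side).
FORMS = {
    "A": {"twist": 32.7, "rise": 2.548, "xdisp": -4.4, "inclination": 19.0,
          "pucker_P": 18.0, "pucker_amp": 38.0, "chi": -157.0,
          "torsion_priors": {"alpha": -52.0, "beta": 175.0, "gamma": 42.0,
                             "epsilon": -148.0, "zeta": -75.0}},
    "B": {"twist": 36.0, "rise": 3.375, "xdisp": 0.2, "inclination": -6.0,
          "pucker_P": 155.0, "pucker_amp": 38.0, "chi": -98.0,
          "torsion_priors": {"alpha": -30.0, "beta": 136.0, "gamma": 31.0,
                             "epsilon": -141.0, "zeta": -160.0},
          # anchor the phosphorus to the classical fiber cylindrical position
          # (r, phi deg, z), resolving the flat directions of the solve
          "p_anchor": [8.91, 95.2, -2.08]},
}

# Standard restraint targets (small-molecule/refinement dictionaries).
BOND_TARGETS = [
    ("P", "OP1", 1.485), ("P", "OP2", 1.485), ("P", "O5'", 1.593),
    ("O5'", "C5'", 1.440), ("C5'", "C4'", 1.510), ("C4'", "O4'", 1.453),
    ("C4'", "C3'", 1.524), ("O4'", "C1'", 1.414), ("C3'", "O3'", 1.423),
    ("C3'", "C2'", 1.525), ("C2'", "C1'", 1.528), ("C2'", "O2'", 1.413),
]
ANGLE_TARGETS = [
    ("OP1", "P", "OP2", 119.6), ("OP1", "P", "O5'", 108.1), ("OP2", "P", "O5'", 108.3),
    ("P", "O5'", "C5'", 120.9), ("O5'", "C5'", "C4'", 111.0),
    ("C5'", "C4'", "O4'", 109.2), ("C5'", "C4'", "C3'", 115.5), ("O4'", "C4'", "C3'", 105.5),
    ("C4'", "O4'", "C1'", 109.7), ("C4'", "C3'", "O3'", 110.3), ("C2'", "C3'", "O3'", 111.0),
    ("C4'", "C3'", "C2'", 102.6), ("C3'", "C2'", "C1'", 101.5),
    ("C2'", "C1'", "O4'", 106.1), ("C1'", "C2'", "O2'", 110.8), ("C3'", "C2'", "O2'", 110.6),
]
LINK_BOND = ("O3'", "P", 1.607)          # O3'(i) - P(i+1)
LINK_ANGLES = [("C3'", "O3'", "P+", 119.7), ("O3'", "P+", "O5'+", 104.0),
               ("O3'", "P+", "OP1+", 108.0), ("O3'", "P+", "OP2+", 108.3)]
RING = ["C4'", "O4'", "C1'", "C2'", "C3'"]
BACKBONE_ATOMS = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'"]


def rot2(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def rotz(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotx(t):
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def torsion(p0, p1, p2, p3):
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return np.degrees(np.arctan2(y, x))


def angle(p0, p1, p2):
    u, v = p0 - p1, p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def ccd_base(code):
    """Base heavy atoms + C1', projected into their best plane (2D)."""
    res = info.residue(COMP[code])
    names = BASE_ATOMS[code] + ["C1'"]
    xyz = {n: res.coord[np.where(res.atom_name == n)[0][0]].astype(float) for n in names}
    ring = np.array([xyz[n] for n in BASE_ATOMS[code]])
    c = ring.mean(0)
    _, _, vt = np.linalg.svd(ring - c)
    return {n: (xyz[n] - c) @ vt[:2].T for n in names}


def kabsch2(src, dst):
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    return R, cd - R @ cs


def init_pose(coords, anchors):
    src = np.array([coords[k] for k in anchors])
    dst = np.array(list(anchors.values()))
    R, t = kabsch2(src, dst)
    return t, np.arctan2(R[1, 0], R[0, 0])


def build_pair(pur, pyr):
    """Coplanar WC pair in the standard frame (purine = strand I, y > 0)."""
    d1 = ccd_base(pur)
    d2raw = ccd_base(pyr)
    g1, g2 = GLYCO[pur], GLYCO[pyr]
    best = None
    for flip in (1.0, -1.0):
        d2 = {k: v * np.array([1.0, flip]) for k, v in d2raw.items()}
        t1, a1 = init_pose(d1, {"C1'": np.array([0.0, 5.3]), g1: np.array([1.0, 4.9])})
        t2, a2 = init_pose(d2, {"C1'": np.array([0.0, -5.3]), g2: np.array([1.0, -4.9])})

        def resid(p):
            P1 = {k: rot2(p[2]) @ v + p[0:2] for k, v in d1.items()}
            P2 = {k: rot2(p[5]) @ v + p[3:5] for k, v in d2.items()}
            res = [np.linalg.norm(P1[x] - P2[y]) - d0 for x, y, d0 in HBONDS[(pur, pyr)]]
            # pair dyad: C1' and glycosidic N of the two strands mirror in y
            res += list(P1["C1'"] - P2["C1'"] * np.array([1.0, -1.0]))
            res += list(P1[g1] - P2[g2] * np.array([1.0, -1.0]))
            res.append(P1["C1'"][0] + P2["C1'"][0])  # gauge: mean C1' x = 0
            return np.asarray(res)

        sol = least_squares(resid, np.concatenate([t1, [a1], t2, [a2]]),
                            xtol=1e-15, ftol=1e-15)
        p = sol.x
        P1 = {k: rot2(p[2]) @ v + p[0:2] for k, v in d1.items()}
        P2 = {k: rot2(p[5]) @ v + p[3:5] for k, v in d2.items()}
        c1c1 = np.linalg.norm(P1["C1'"] - P2["C1'"])
        score = np.abs(sol.fun).max() + abs(c1c1 - 10.5)  # reject reversed-WC minima
        if best is None or score < best[0]:
            best = (score, P1, P2)
    _, P1, P2 = best
    # orientation check: major-groove edge must be on +x
    major = P1.get("O6", P1.get("N6"))
    assert major[0] > P1["N3"][0], "major groove edge not on +x"
    shift = np.array([C1X - P1["C1'"][0], 0.0])
    P1 = {k: v + shift for k, v in P1.items()}
    P2 = {k: v + shift for k, v in P2.items()}
    return P1, P2


def to3d(d2):
    return {k: np.array([v[0], v[1], 0.0]) for k, v in d2.items()}


def backbone_template(form, base_anchor):
    """Solve the per-form backbone by restrained least squares under the
    helical symmetry operation.  Returns dict atom -> xyz (strand I frame)."""
    spec = FORMS[form]
    om, h = np.radians(spec["twist"]), spec["rise"]
    B = lambda r: rotx(np.radians(spec["inclination"])) @ r + np.array([spec["xdisp"], 0.0, 0.0])
    g0 = lambda r: B(r)
    g1 = lambda r: rotz(om) @ B(r) + np.array([0.0, 0.0, h])

    n_pos, c_pos = base_anchor["N"], base_anchor["C"]  # glycosidic N, chi reference atom
    c1_pos = np.array([C1X, base_anchor["c1y"], 0.0])

    # initial coordinates: CCD deoxyadenosine posed so C1'/N9 match the anchor
    res = info.residue("DA")
    xyz = {n: res.coord[np.where(res.atom_name == n)[0][0]].astype(float)
           for n in BACKBONE_ATOMS[:-1] + ["C1'", "N9", "C4"]}
    rib = info.residue("A")
    xyz["O2'"] = rib.coord[np.where(rib.atom_name == "O2'")[0][0]].astype(float) \
        - rib.coord[np.where(rib.atom_name == "C2'")[0][0]].astype(float) \
        + xyz["C2'"]
    src = np.array([xyz["C1'"], xyz["N9"], xyz["C4"]])
    dst = np.array([c1_pos, n_pos, c_pos])
    cs, cd = src.mean(0), dst.mean(0)
    U, S, Vt = np.linalg.svd((src - cs).T @ (dst - cd))
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    start = {k: R @ (v - cs) + cd for k, v in xyz.items()}

    names = BACKBONE_ATOMS

    def unpack(x):
        pos = {n: x[3 * i:3 * i + 3] for i, n in enumerate(names)}
        pos["C1'"] = c1_pos
        return pos

    nus_def = [(RING[i % 5], RING[(i + 1) % 5], RING[(i + 2) % 5], RING[(i + 3) % 5])
               for i in range(5)]  # nu_? ordering handled via targets below
    # standard pseudorotation: nu_j = amp * cos(P + 144*(j-2)), with
    # nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', ..., nu4 = C3'-C4'-O4'-C1'
    nu_defs = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
               ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
               ("C3'", "C4'", "O4'", "C1'")]
    P0, amp = spec["pucker_P"], spec["pucker_amp"]
    nu_targets = [amp * np.cos(np.radians(P0 + 144.0 * (j - 2))) for j in range(5)]

    pri = spec["torsion_priors"]

    def residuals(x):
        p = unpack(x)
        pn = {k + "+": g1(v) for k, v in p.items()}
        q = {k: g0(v) for k, v in p.items()}
        q.update(pn)
        out = []
        for a, b, t in BOND_TARGETS:
            out.append(10.0 * (np.linalg.norm(p[a] - p[b]) - t))
        out.append(10.0 * (np.linalg.norm(q[LINK_BOND[0]] - q[LINK_BOND[1] + "+"]) - LINK_BOND[2]))
        for a, b, c, t in ANGLE_TARGETS:
            out.append(0.04 * (angle(p[a], p[b], p[c]) - t))
        for a, b, c, t in LINK_ANGLES:
            out.append(0.04 * (angle(q[a], q[b], q[c]) - t))
        for (ta, tb, tc, td), t in zip(nu_defs, nu_targets):
            out.append(0.05 * (torsion(p[ta], p[tb], p[tc], p[td]) - t))
        # glycosidic torsion chi: O4'-C1'-N-C(ref)
        chi = torsion(p["O4'"], p["C1'"], n_pos, c_pos)
        out.append(0.06 * ((chi - spec["chi"] + 180.0) % 360.0 - 180.0))
        # loose canonical backbone torsion priors
        tors = {
            "alpha": torsion(q["O3'"], q["P+"], q["O5'+"], q["C5'+"]),
            "beta": torsion(q["P+"], q["O5'+"], q["C5'+"], q["C4'+"]),
            "gamma": torsion(q["O5'+"], q["C5'+"], q["C4'+"], q["C3'+"]),
            "epsilon": torsion(q["C4'"], q["C3'"], q["O3'"], q["P+"]),
            "zeta": torsion(q["C3'"], q["O3'"], q["P+"], q["O5'+"]),
        }
        for k, t in pri.items():
            out.append(0.05 * ((tors[k] - t + 180.0) % 360.0 - 180.0))
        # optional classical-fiber phosphorus anchor (cylindrical, global frame)
        if "p_anchor" in spec:
            ra, pa, za = spec["p_anchor"]
            Pg = q["P"]
            out.append(2.0 * (np.hypot(Pg[0], Pg[1]) - ra))
            out.append(0.05 * ((np.degrees(np.arctan2(Pg[1], Pg[0])) - pa + 180.0) % 360.0 - 180.0))
            out.append(2.0 * (Pg[2] - za))
        # ribose chirality at C2': sign of det must match ribo configuration
        u1, u2, u3 = p["C1'"] - p["C2'"], p["C3'"] - p["C2'"], p["O2'"] - p["C2'"]
        vol = np.linalg.det(np.array([u1, u2, u3]))
        out.append(5.0 * min(0.0, -vol - 0.2))  # require vol <= -0.2 (ribo face)
        return np.asarray(out)

    x0 = np.concatenate([start[n] for n in names])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, max_nfev=20000)
    pos = unpack(sol.x)
    # report residual quality
    p = pos
    q = {k: g0(v) for k, v in p.items()}
    q.update({k + "+": g1(v) for k, v in p.items()})
    link = np.linalg.norm(q["O3'"] - q["P+"])
    nus = [torsion(p[a], p[b], p[c], p[d]) for a, b, c, d in nu_defs]
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    P = np.degrees(np.arctan2(num, den * np.sign(nus[2]))) % 360.0 if nus[2] != 0 else 0.0
    # simple P from standard formula
    P_std = np.degrees(np.arctan2((nus[4] + nus[1]) - (nus[3] + nus[0]), den)) % 360.0
    chi_val = torsion(p["O4'"], p["C1'"], n_pos, c_pos)
    print(f"[{form}] link O3'-P = {link:.3f} A, ring P = {P_std:.1f} deg, "
          f"chi = {chi_val:.1f}, max|resid| = {np.abs(sol.fun).max():.3f}")
    return {k: v.tolist() for k, v in pos.items() if k != "C1'"}, c1_pos.tolist()


def main():
    pairs = {}
    pairs["G", "C"] = build_pair("G", "C")
    pairs["A", "T"] = build_pair("A", "T")
    pairs["A", "U"] = build_pair("A", "U")

    # per-base strand-I templates (pyrimidines flipped through the pair dyad)
    bases = {}
    flip = np.array([1.0, -1.0])
    bases["G"] = to3d(pairs["G", "C"][0])
    bases["A"] = to3d(pairs["A", "T"][0])
    bases["C"] = to3d({k: v * flip for k, v in pairs["G", "C"][1].items()})
    bases["T"] = to3d({k: v * flip for k, v in pairs["A", "T"][1].items()})
    bases["U"] = to3d({k: v * flip for k, v in pairs["A", "U"][1].items()})

    # common anchor for backbone derivation: mean purine glycosidic geometry
    n_pos = np.mean([bases["G"]["N9"], bases["A"]["N9"]], axis=0)
    c_pos = np.mean([bases["G"]["C4"], bases["A"]["C4"]], axis=0)
    c1y = float(np.mean([bases[b]["C1'"][1] for b in "GACTU"]))
    anchor = {"N": n_pos, "C": c_pos, "c1y": c1y}

    backbones = {}
    c1 = None
    for form in ("A", "B"):
        bb, c1 = backbone_template(form, anchor)
        backbones[form] = bb

    out = {
        "comment": "Synthetic idealized fiber templates derived by restrained "
                   "least squares from CCD ideal base geometry and standard "
                   "nucleic-acid restraint dictionaries. Standard reference "
                   "frame: pair plane z=0, +x into the major groove, pair "
                   "dyad = x axis, C1' anchored at x = -2.476. Backbone "
                   "solved under each form's helical symmetry (see "
                   "scripts/build_templates.py). No experimental coordinates.",
        "c1_anchor": c1,
        "forms": {k: {kk: vv for kk, vv in v.items() if kk != "torsion_priors"}
                  for k, v in FORMS.items()},
        "bases": {b: {k: v.tolist() for k, v in d.items()} for b, d in bases.items()},
        "backbones": backbones,
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(out, indent=1))
    print("wrote", OUT)


if __name__ == "__main__":
    sys.exit(main())
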