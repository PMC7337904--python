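"""Reading, writing and annotating macromolecular structure models.

The in-memory model is a light hierarchy (:class:`StructureModel` ->
:class:`Residue` -> :class:`AtomRecord`) populated from PDB or mmCIF files
via gemmi.  Residues are categorized (DNA / RNA / protein / water / metal /
other) at load time and atoms can be assigned van-der-Waals radii from a
named radius table, which downstream clash and surface calculations rely on.

Alternate conformations are reduced at parse time: for each atom name the
highest-occupancy conformer is kept (ties broken by altloc identifier).
Conformer averaging, where wanted, is done downstream on separately parsed
models, not here.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "Residue", "StructureModel", "RadiusSet", "BONDI",
    "read_structure", "write_structure", "classify_residue", "assign_radii",
    "StructureError", "EmptyStructureError", "FormatError",
]


class StructureError(ValueError):
    """Base error for structure I/O problems."""


class EmptyStructureError(StructureError):
    """File parsed but contained no atoms (or an empty model was supplied)."""


class FormatError(StructureError):
    """Unreadable or syntactically invalid structure file."""


#: Bondi van-der-Waals radii (angstrom); community default.
BONDI = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Elements treated as metals when they appear as single-atom residues.
METAL_ELEMENTS = {
    "NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG",
    "SR", "BA", "CS", "LI", "RB", "AL",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: Pseudo-protein probe component emitted by the synthetic generator.
PROBE_COMP = "PRB"


@dataclass
class RadiusSet:
    """A named van-der-Waals radius table with a fallback default."""

    name: str = "bondi"
    radii: dict = field(default_factory=lambda: dict(BONDI))
    default: float = 1.60

    def radius(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            logger.warning("no vdW radius for element %r; using default %.2f",
                           element, self.default)
            return self.default
        return r


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    vdw_radius: Optional[float] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1] "
                                 f"for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    comp_id: str
    atoms: list = field(default_factory=list)
    insertion_code: str = ""
    category: str = "other"

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    @property
    def key(self):
        return (self.chain_id, self.seq_id, self.insertion_code)


@dataclass
class StructureModel:
    chains: dict = field(default_factory=dict)   # chain_id -> [Residue]
    cell: Optional[tuple] = None                  # (a, b, c, alpha, beta, gamma)
    space_group: Optional[str] = None
    source_id: str = ""
    provenance: dict = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple]:
        """Yield (residue, atom) pairs over the whole model."""
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def copy(self) -> "StructureModel":
        out = StructureModel(cell=self.cell, space_group=self.space_group,
                             source_id=self.source_id,
                             provenance=dict(self.provenance))
        for res in self.residues():
            new = Residue(res.chain_id, res.seq_id, res.comp_id,
                          insertion_code=res.insertion_code,
                          category=res.category)
            new.atoms = [AtomRecord(a.name, a.element, a.position.copy(),
                                    a.occupancy, a.altloc, a.bfactor,
                                    a.vdw_radius) for a in res.atoms]
            out.add_residue(new)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy (rotation then translation)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, atom in out.atoms():
            atom.position = R @ atom.position + t
        return out


def classify_residue(residue: Residue, metals: Optional[set] = None) -> str:
    """Assign one of {DNA, RNA, protein, water, metal, other}.

    A nucleotide is recognized by its sugar/base scaffold; the presence of a
    ribose O2' distinguishes RNA from DNA.  Proteins are recognized by the
    N/CA/C backbone, waters by component name, metals as single-atom ions of
    an element in ``metals`` (default: the configured METAL_ELEMENTS list).
    """
    if not residue.atoms:
        raise StructureError("cannot classify a residue with no atoms")
    if residue.comp_id.upper() in WATER_NAMES:
        return "water"
    if residue.comp_id.upper() == PROBE_COMP:
        return "protein"
    if len(residue.atoms) == 1:
        elem = residue.atoms[0].element.upper()
        if elem in (METAL_ELEMENTS if metals is None else set(metals)):
            return "metal"
    names = {a.name for a in residue.atoms}
    is_nucleotide = "C1'" in names and ("N9" in names or "N1" in names) \
        and ("C4'" in names or "O4'" in names)
    if is_nucleotide:
        return "RNA" if "O2'" in names else "DNA"
    if {"N", "CA", "C"}.issubset(names):
        return "protein"
    logger.warning("residue %s %s/%s classified as 'other'",
                   residue.comp_id, residue.chain_id, residue.seq_id)
    return "other"


def _dedupe_altlocs(raw_atoms):
    """Keep the highest-occupancy conformer per atom name (ties: altloc order)."""
    best = {}
    for atom in raw_atoms:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > \
                (prev.occupancy, _altloc_rank(prev.altloc)):
            best[atom.name] = atom
    return list(best.values())


def _altloc_rank(altloc: str) -> int:
    # earlier altloc identifiers win ties, so rank them higher
    return -ord(altloc) if altloc else 1


def _guess_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are loaded; the unit cell and
    space group are captured when present; residue categories are assigned.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _guess_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    model = StructureModel(source_id=path.stem)
    cell = st.cell
    if cell and cell.a > 0 and not (cell.a == cell.b == cell.c == 1.0):
        model.cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = st.spacegroup_hm
    if sg and sg != "P 1" or (sg == "P 1" and model.cell is not None):
        model.space_group = sg or None

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    first = st[0]
    for chain in first:
        for res in chain:
            raw = []
            for atom in res:
                raw.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    bfactor=atom.b_iso,
                ))
            if not raw:
                continue
            residue = Residue(chain_id=chain.name, seq_id=res.seqid.num,
                              comp_id=res.name,
                              insertion_code=res.seqid.icode.strip())
            residue.atoms = _dedupe_altlocs(raw)
            residue.category = classify_residue(residue)
            model.add_residue(residue)
    if model.n_atoms == 0:
        raise EmptyStructureError(f"{path}: structure contains zero atoms")
    return model


def assign_radii(model: StructureModel, radius_set: RadiusSet | str = "bondi") -> StructureModel:
    """Assign van-der-Waals radii in place (and return the model)."""
    if isinstance(radius_set, str):
        if radius_set.lower() != "bondi":
            raise StructureError(f"unknown radius set {radius_set!r}")
        radius_set = RadiusSet()
    for _, atom in model.atoms():
        atom.vdw_radius = radius_set.radius(atom.element)
    model.provenance["radius_set"] = radius_set.name
    return model


def write_structure(model: StructureModel, path, format: str = "auto") -> None:
    """Write the model as PDB or mmCIF; the output re-reads equivalently."""
    if model.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty model")
    path = Path(path)
    fmt = _guess_format(path, format)
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        ch = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.comp_id
            gr.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gr.het_flag = "A" if res.category in ("DNA", "RNA", "protein") else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def parse_config(path) -> dict:
    """Parse a simple ``key = value`` configuration file.

    Recognized keys include ``radius_set``, ``metal_elements`` (comma list),
    ``zp_a``, ``zp_b``, ``clash_threshold``, ``a_fraction_min``.
    """
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise StructureError(f"bad config line: {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if "," in value:
            out[key] = [v.strip() for v in value.split(",")]
        else:
            try:
                out[key] = float(value) if "." in value else int(value)
            except ValueError:
                out[key] = value
    return out
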