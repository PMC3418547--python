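"""Coordinate handling and geometric primitives for ribosome/release-factor analysis.

The analyses downstream (decoding-center state classification, switch-loop
interaction inventories, binding-compatibility verdicts) all reduce to four
primitives over atomic models:

* minimum distance between two atom selections,
* hydrogen-bond detection from heavy-atom donor/acceptor geometry,
* steric-clash detection from van der Waals overlap,
* least-squares rigid superposition (Kabsch).

Models are parsed from fixed-column PDB files via biotite and wrapped in a
thin :class:`StructureModel` that adds pattern-based atom selection
(``"chain:resnum[icode]:atomname"``).

Hydrogen-bond criteria follow common crystallographic practice for
hydrogen-free models: a donor and an acceptor heavy atom within
[2.4, 3.5] Å counts as bonded; a D-H...A angle cutoff (default 120 deg) is
applied only when the donor actually carries hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "HBond",
    "Clash",
    "RigidTransform",
    "HBondGeometry",
    "StructureFormatError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "min_distance",
    "detect_hbonds",
    "detect_clashes",
    "superpose",
    "match_atoms",
    "VDW_RADII",
    "SEVERE_CLASH_OVERLAP",
]

#: van der Waals radii (Angstrom) used for steric-clash overlap.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
#: default overlap (Angstrom) beyond which a contact counts as a severe clash.
SEVERE_CLASH_OVERLAP = 0.4


class StructureFormatError(ValueError):
    """Raised for unparseable coordinate files."""


class SelectionError(ValueError):
    """Raised for empty or unresolvable atom selections."""


# ---------------------------------------------------------------------------
# donor / acceptor chemistry (heavy atoms only)

_AA_SIDECHAIN: dict[str, dict[str, str]] = {
    "SER": {"OG": "DA"},
    "THR": {"OG1": "DA"},
    "TYR": {"OH": "DA"},
    "CYS": {"SG": "DA"},
    "ASN": {"OD1": "A", "ND2": "D"},
    "GLN": {"OE1": "A", "NE2": "D"},
    "ASP": {"OD1": "A", "OD2": "A"},
    "GLU": {"OE1": "A", "OE2": "A"},
    "LYS": {"NZ": "D"},
    "ARG": {"NE": "D", "NH1": "D", "NH2": "D"},
    "HIS": {"ND1": "DA", "NE2": "DA"},
    "TRP": {"NE1": "D"},
    "MET": {},
    "ALA": {}, "GLY": {}, "ILE": {}, "LEU": {}, "PHE": {}, "PRO": {}, "VAL": {},
}

_SUGAR_PHOSPHATE: dict[str, str] = {
    "O2'": "DA", "O3'": "A", "O4'": "A", "O5'": "A",
    "OP1": "A", "OP2": "A", "OP3": "A",
}

_BASE: dict[str, dict[str, str]] = {
    "A": {"N6": "D", "N1": "A", "N3": "A", "N7": "A"},
    "G": {"N1": "D", "N2": "D", "O6": "A", "N3": "A", "N7": "A"},
    "C": {"N4": "D", "N3": "A", "O2": "A"},
    "U": {"N3": "D", "O2": "A", "O4": "A"},
    "T": {"N3": "D", "O2": "A", "O4": "A"},
}

_NUC_ALIASES = {
    "A": "A", "G": "G", "C": "C", "U": "U", "T": "T", "I": "A",
    "DA": "A", "DG": "G", "DC": "C", "DT": "T", "DU": "U",
    "RA": "A", "RG": "G", "RC": "C", "RU": "U",
}

_warned_residues: set[str] = set()


def donor_acceptor_role(res_name: str, atom_name: str) -> str:
    """Return 'D', 'A', 'DA' or '' for a heavy atom's hydrogen-bond role.

    Unknown residue types are skipped with a single logged warning per type.
    """
    res_name = res_name.strip().upper()
    atom_name = atom_name.strip().upper().replace("*", "'")
    if res_name in _AA_SIDECHAIN:
        if atom_name == "N" and res_name != "PRO":
            return "D"
        if atom_name in ("O", "OXT"):
            return "A"
        return _AA_SIDECHAIN[res_name].get(atom_name, "")
    if res_name in _NUC_ALIASES:
        if atom_name in _SUGAR_PHOSPHATE:
            return _SUGAR_PHOSPHATE[atom_name]
        return _BASE[_NUC_ALIASES[res_name]].get(atom_name, "")
    if res_name == "HOH":
        return "DA" if atom_name == "O" else ""
    if atom_name and atom_name[0] in "NOS" and res_name not in _warned_residues:
        _warned_residues.add(res_name)
        logger.warning("unknown residue type %r: polar atoms skipped in H-bond chemistry", res_name)
    return ""


# ---------------------------------------------------------------------------
# model container

@dataclass
class StructureModel:
    """Atoms with chain/residue/atom identity and coordinates, supporting
    pattern selections.

    Wraps a biotite :class:`AtomArray` for identity annotations but keeps a
    float64 coordinate array alongside it (the AtomArray stores float32,
    which is file precision but too coarse for the geometric invariants
    guaranteed here).
    """

    atoms: bst.AtomArray
    coords64: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coords64 is None:
            self.coords64 = np.array(self.atoms.coord, dtype=np.float64)
        else:
            self.coords64 = np.asarray(self.coords64, dtype=np.float64)
        if self.coords64.shape != (self.atoms.array_length(), 3):
            raise StructureFormatError("coordinate array does not match atom count")
        if not np.all(np.isfinite(self.coords64)):
            raise StructureFormatError("non-finite coordinates in model")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(cls, records: list[dict]) -> "StructureModel":
        """Build a model from dicts with keys chain, res_id, res_name,
        atom_name, element, coord and optional ins_code/occupancy/hetero."""
        n = len(records)
        array = bst.AtomArray(n)
        array.add_annotation("occupancy", dtype=float)
        coords = np.empty((n, 3), dtype=np.float64)
        for i, rec in enumerate(records):
            array.chain_id[i] = rec["chain"]
            array.res_id[i] = rec["res_id"]
            array.ins_code[i] = rec.get("ins_code", "")
            array.res_name[i] = rec["res_name"]
            array.atom_name[i] = rec["atom_name"]
            array.element[i] = rec["element"]
            array.hetero[i] = rec.get("hetero", False)
            array.occupancy[i] = rec.get("occupancy", 1.0)
            coords[i] = np.asarray(rec["coord"], dtype=np.float64)
            array.coord[i] = coords[i]
        return cls(array, coords)

    # -- basic accessors -----------------------------------------------------
    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.coords64

    def atom_id(self, i: int) -> str:
        a = self.atoms
        icode = a.ins_code[i].strip()
        return f"{a.chain_id[i]}:{a.res_id[i]}{icode}:{a.atom_name[i]}"

    def residue_key(self, i: int) -> tuple[str, int, str]:
        a = self.atoms
        return (a.chain_id[i], int(a.res_id[i]), a.ins_code[i].strip())

    # -- selection -----------------------------------------------------------
    def mask(self, pattern: str) -> np.ndarray:
        """Boolean mask for a ``chain:resnum[icode]:atomname`` pattern.

        Fields may be '*' (or omitted); the residue field accepts a single
        number, a number+insertion-code (``115A``) or a range (``286-301``);
        atom names support shell-style wildcards; comma-separated terms union.
        """
        a = self.atoms
        total = np.zeros(len(self), dtype=bool)
        for term in pattern.split(","):
            parts = (term.strip().split(":") + ["*", "*", "*"])[:3]
            chain_pat, res_pat, atom_pat = (p if p else "*" for p in parts)
            m = np.ones(len(self), dtype=bool)
            if chain_pat != "*":
                m &= np.char.strip(a.chain_id.astype(str)) == chain_pat
            if res_pat != "*":
                m &= self._res_mask(res_pat)
            if atom_pat != "*":
                names = np.char.strip(a.atom_name.astype(str))
                m &= np.array([fnmatchcase(nm, atom_pat.upper()) for nm in names])
            total |= m
        return total

    def _res_mask(self, res_pat: str) -> np.ndarray:
        a = self.atoms
        if "-" in res_pat[1:]:
            lo_s, hi_s = res_pat.rsplit("-", 1)
            lo, hi = int(lo_s), int(hi_s)
            return (a.res_id >= lo) & (a.res_id <= hi)
        icode = ""
        num = res_pat
        if res_pat and res_pat[-1].isalpha():
            icode, num = res_pat[-1].upper(), res_pat[:-1]
        try:
            res_id = int(num)
        except ValueError:
            raise SelectionError(f"cannot parse residue pattern {res_pat!r}") from None
        m = a.res_id == res_id
        if icode:
            m &= np.char.strip(a.ins_code.astype(str)) == icode
        return m

    def select(self, pattern: str) -> "StructureModel":
        m = self.mask(pattern)
        if not m.any():
            raise SelectionError(f"selection {pattern!r} matches no atoms")
        return StructureModel(self.atoms[m], self.coords64[m])

    def try_select(self, pattern: str) -> "StructureModel | None":
        m = self.mask(pattern)
        return StructureModel(self.atoms[m], self.coords64[m]) if m.any() else None

    def subset(self, indices: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms[indices], self.coords64[indices])

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        out = self.atoms.copy()
        moved = transform.apply(self.coords64)
        out.coord = moved.astype(np.float32)
        return StructureModel(out, moved)


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class HBond:
    donor: str
    acceptor: str
    distance: float
    angle: float | None = None  # D-H...A angle, absent when donor has no hydrogens


@dataclass(frozen=True)
class Clash:
    atom_a: str
    atom_b: str
    distance: float
    overlap: float


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3), determinant +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# io

def read_structure(path: str | Path, model: int = 1) -> StructureModel:
    """Parse a fixed-column PDB file (ATOM and HETATM retained).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A'); insertion codes are kept as part of
    residue identity.
    """
    path = Path(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(
        model=model, altloc="all", extra_fields=["occupancy"]
    )
    array = _resolve_altloc(array)
    return StructureModel(array)


def _prevalidate_pdb(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise StructureFormatError(
                    f"{path}:{lineno}: malformed coordinate field"
                ) from None


def _resolve_altloc(array: bst.AtomArray) -> bst.AtomArray:
    if "altloc_id" not in array.get_annotation_categories():
        return array
    altloc = np.char.strip(array.altloc_id.astype(str))
    occ = array.occupancy if "occupancy" in array.get_annotation_categories() else np.ones(len(altloc))
    keep = np.ones(array.array_length(), dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for i in range(array.array_length()):
        key = (array.chain_id[i], int(array.res_id[i]), array.ins_code[i], array.atom_name[i])
        groups.setdefault(key, []).append(i)
    for idxs in groups.values():
        if len(idxs) <= 1:
            continue
        # highest occupancy wins; ties break toward 'A' (lexicographic)
        best = min(idxs, key=lambda i: (-occ[i], altloc[i] or "A"))
        for i in idxs:
            keep[i] = i == best
    out = array[keep]
    if "altloc_id" in out.get_annotation_categories():
        out.del_annotation("altloc_id")
    return out


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB."""
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# geometry

def _as_model(model: StructureModel, selection: "str | StructureModel | None") -> StructureModel:
    if selection is None:
        return model
    if isinstance(selection, StructureModel):
        return selection
    return model.select(selection)


def min_distance(model: StructureModel, selection_a: str | StructureModel,
                 selection_b: str | StructureModel) -> float:
    """Minimum Euclidean distance (Angstrom) over the atom-pair cross product."""
    sub_a, sub_b = _as_model(model, selection_a), _as_model(model, selection_b)
    return float(cdist(sub_a.coords, sub_b.coords).min())


@dataclass(frozen=True)
class HBondGeometry:
    """Heavy-atom hydrogen-bond window and angular cutoff."""

    min_distance: float = 2.4
    max_distance: float = 3.5
    min_angle: float = 120.0  # deg, applied only when donor hydrogens exist


def _donor_hydrogens(model: StructureModel, donor_idx: int) -> np.ndarray:
    """Coordinates of hydrogens covalently attached to the donor (same
    residue, element H, within 1.3 Angstrom)."""
    a = model.atoms
    key = model.residue_key(donor_idx)
    out = []
    for i in range(len(model)):
        if a.element[i].strip().upper() != "H":
            continue
        if model.residue_key(i) != key:
            continue
        if np.linalg.norm(model.coords[i] - model.coords[donor_idx]) <= 1.3:
            out.append(model.coords[i])
    return np.array(out)


def detect_hbonds(
    model: StructureModel,
    selection_a: str | StructureModel,
    selection_b: str | StructureModel,
    geometry: HBondGeometry | None = None,
) -> list[HBond]:
    """All donor/acceptor pairs between the two selections (either direction)
    whose heavy-atom distance falls in the configured window.

    Pairs within one residue are ignored.  When the donor carries hydrogens,
    the best D-H...A angle must exceed the angular cutoff.  Output is sorted
    by (donor id, acceptor id).
    """
    geom = geometry or HBondGeometry()
    sub_a, sub_b = _as_model(model, selection_a), _as_model(model, selection_b)
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise SelectionError("empty selection in detect_hbonds")

    def roles(sub: StructureModel) -> list[str]:
        return [
            donor_acceptor_role(sub.atoms.res_name[i], sub.atoms.atom_name[i])
            for i in range(len(sub))
        ]

    roles_a, roles_b = roles(sub_a), roles(sub_b)
    dmat = cdist(sub_a.coords, sub_b.coords)
    found: dict[tuple[str, str], HBond] = {}
    for i in range(len(sub_a)):
        for j in range(len(sub_b)):
            d = dmat[i, j]
            if not (geom.min_distance <= d <= geom.max_distance):
                continue
            if sub_a.residue_key(i) == sub_b.residue_key(j):
                continue
            for donor_sub, di, acc_sub, aj, rd, ra in (
                (sub_a, i, sub_b, j, roles_a[i], roles_b[j]),
                (sub_b, j, sub_a, i, roles_b[j], roles_a[i]),
            ):
                if "D" not in rd or "A" not in ra:
                    continue
                angle = None
                hydros = _donor_hydrogens(donor_sub, di)
                if len(hydros):
                    dc = donor_sub.coords[di]
                    ac = acc_sub.coords[aj]
                    angle = max(_angle(h, dc, ac) for h in hydros)
                    # angle at H between donor and acceptor
                    if angle < geom.min_angle:
                        continue
                key = (donor_sub.atom_id(di), acc_sub.atom_id(aj))
                if key not in found:
                    found[key] = HBond(key[0], key[1], float(d), angle)
    return [found[k] for k in sorted(found)]


def _angle(apex: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p1 - apex, p2 - apex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_clashes(
    model: StructureModel,
    selection_a: str | StructureModel,
    selection_b: str | StructureModel,
    overlap_threshold: float = SEVERE_CLASH_OVERLAP,
) -> list[Clash]:
    """All cross pairs whose van der Waals overlap r_a + r_b - d exceeds the
    threshold.

    Pairs within one residue, and pairs in sequence-adjacent residues of the
    same chain (covalently linked backbone neighbors), are excluded.
    Hydrogens are ignored; any other element missing from the radius table
    raises a lookup error naming the element.
    """
    sub_a, sub_b = _as_model(model, selection_a), _as_model(model, selection_b)
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise SelectionError("empty selection in detect_clashes")

    def radii(sub: StructureModel) -> np.ndarray:
        out = np.empty(len(sub))
        for i in range(len(sub)):
            elem = sub.atoms.element[i].strip().upper()
            if elem == "H":
                out[i] = np.nan  # hydrogens skipped
                continue
            try:
                out[i] = VDW_RADII[elem]
            except KeyError:
                raise KeyError(f"element {elem!r} missing from van der Waals radius table") from None
        return out

    ra, rb = radii(sub_a), radii(sub_b)
    dmat = cdist(sub_a.coords, sub_b.coords)
    overlap = ra[:, None] + rb[None, :] - dmat
    clashes: dict[tuple[str, str], Clash] = {}
    for i, j in zip(*np.where(overlap > overlap_threshold)):
        ka, kb = sub_a.residue_key(i), sub_b.residue_key(j)
        if ka == kb:
            continue
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= 1:
            continue  # covalently bonded neighbors
        key = tuple(sorted((sub_a.atom_id(i), sub_b.atom_id(j))))
        if key not in clashes:
            clashes[key] = Clash(key[0], key[1], float(dmat[i, j]), float(overlap[i, j]))
    return [clashes[k] for k in sorted(clashes)]


# ---------------------------------------------------------------------------
# superposition

def superpose(mobile: "np.ndarray | StructureModel",
              reference: "np.ndarray | StructureModel") -> RigidTransform:
    """Least-squares rigid superposition (Kabsch) of matched coordinate sets.

    ``mobile`` and ``reference`` must list corresponding atoms in the same
    order.  The returned rotation has determinant +1 (no reflection) and the
    rmsd is the post-fit root-mean-square deviation.
    """
    xm = mobile.coords if isinstance(mobile, StructureModel) else np.asarray(mobile, float)
    xr = reference.coords if isinstance(reference, StructureModel) else np.asarray(reference, float)
    if xm.shape != xr.shape or xm.ndim != 2 or xm.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = xm.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atom pairs")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    am, ar = xm - cm, xr - cr
    if np.linalg.matrix_rank(ar, tol=1e-8) < 2 or np.linalg.matrix_rank(am, tol=1e-8) < 2:
        raise ValueError("superposition correspondence is collinear or degenerate")
    h = am.T @ ar
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = xm @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - xr) ** 2, axis=1))))
    return RigidTransform(rot, trans, rmsd)


def match_atoms(model_a: StructureModel, model_b: StructureModel,
                pattern: str = "*") -> tuple[StructureModel, StructureModel]:
    """1:1 atom correspondence between two models by (chain, residue, atom
    name) identity, optionally restricted to a selection pattern; returns the
    matched sub-models in a common deterministic order."""
    def keys(m: StructureModel) -> dict[tuple, int]:
        out = {}
        mask = m.mask(pattern)
        for i in range(len(m)):
            if not mask[i]:
                continue
            key = (*m.residue_key(i), m.atoms.atom_name[i].strip())
            out.setdefault(key, i)
        return out

    ka, kb = keys(model_a), keys(model_b)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise SelectionError(f"no common atoms for pattern {pattern!r}")
    ia = np.array([ka[k] for k in common])
    ib = np.array([kb[k] for k in common])
    return model_a.subset(ia), model_b.subset(ib)
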