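"""Deterministic synthetic fixtures with machine-readable planted truth.

Every downstream analysis in this package is exercised on generated data:

* :func:`gen_alignment` — two-subfamily protein alignments with planted
  discriminating columns and subfamily-specific insertions, emulating the
  17-species mtRF1/mtRF1a alignment with a bacterial RF1 reference.
* :func:`gen_structure` — PDB coordinate models with planted hydrogen
  bonds, steric clashes and an optional decoding-center conformation.
* :func:`gen_complex` — an idealized release-factor switch-loop fragment
  posed against a synthetic ribosomal decoding center, in two protein
  variants (bacterial-RF1-like and mtRF1-like with the RT-insert arginine)
  and three decoding-center states (stacked / unstacked / recognized).
* :func:`gen_mitogenome` — annotated GenBank mitogenomes with controlled
  CDS termini and preceding bases.

Coordinates use idealized rigid templates: geometry detectors, not
chemistry, are under test.  Each generator returns ``(object, manifest)``
where the manifest is a JSON-serializable record of everything planted,
so tests assert against planted truth rather than re-derived truth.
Identical recipe + seed always produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from scipy.optimize import brentq

from .alignment import LabeledAlignment, map_to_reference
from .structure import (
    SEVERE_CLASH_OVERLAP,
    VDW_RADII,
    StructureModel,
    donor_acceptor_role,
    write_structure,
)

__all__ = [
    "RecipeError",
    "AlignmentRecipe",
    "InsertionSpec",
    "StructureRecipe",
    "AtomSpec",
    "ComplexRecipe",
    "GenomeRecipe",
    "GeneSpec",
    "gen_alignment",
    "gen_structure",
    "gen_complex",
    "gen_mitogenome",
    "decoding_templates",
    "write_alignment",
    "write_label_map",
    "write_manifest",
    "study_alignment_recipe",
    "study_genome_recipe",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_DNA = "ACGT"


class RecipeError(ValueError):
    """Raised when a fixture recipe violates its invariants."""


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


# ===========================================================================
# alignments
# ===========================================================================

@dataclass(frozen=True)
class InsertionSpec:
    """A planted subfamily-specific insert.

    The block occupies alignment columns ``anchor_column+1 ..
    anchor_column+length`` and is all-gap in the reference and in the
    non-carrying subfamily.
    """

    anchor_column: int
    length: int
    subfamily: str
    consensus: str | None = None  # fixed inserted residues; random if None

    def columns(self) -> range:
        return range(self.anchor_column + 1, self.anchor_column + 1 + self.length)


@dataclass(frozen=True)
class AlignmentRecipe:
    """Recipe for a two-subfamily labeled alignment with planted truth."""

    n_per_subfamily: int = 5
    length: int = 60
    k_discriminating: int = 0
    insertions: tuple[InsertionSpec, ...] = ()
    background_conservation: float = 0.8
    seed: int = 0
    subfamily_names: tuple[str, str] = ("A", "B")
    reference_id: str = "reference"
    discriminating_columns: tuple[int, ...] | None = None
    discriminating_residues: tuple[tuple[str, str], ...] | None = None

    def validate(self) -> None:
        if self.n_per_subfamily < 2:
            raise RecipeError("each subfamily needs at least 2 members")
        if not 0.0 <= self.background_conservation <= 1.0:
            raise RecipeError("background_conservation must be in [0, 1]")
        if len(set(self.subfamily_names)) != 2:
            raise RecipeError("two distinct subfamily names required")
        insert_cols: set[int] = set()
        for ins in self.insertions:
            if ins.length < 1:
                raise RecipeError("insertion length must be >= 1")
            if ins.subfamily not in self.subfamily_names:
                raise RecipeError(f"unknown insertion subfamily {ins.subfamily!r}")
            if ins.consensus is not None and len(ins.consensus) != ins.length:
                raise RecipeError("insertion consensus length mismatch")
            cols = set(ins.columns())
            if cols & insert_cols:
                raise RecipeError("insertion blocks overlap")
            if min(cols) < 1 or max(cols) >= self.length:
                raise RecipeError("insertion block out of alignment range")
            insert_cols |= cols
        if self.k_discriminating + len(insert_cols) > self.length:
            raise RecipeError("planted columns exceed alignment length")
        if self.discriminating_columns is not None:
            if len(self.discriminating_columns) != self.k_discriminating:
                raise RecipeError("discriminating_columns count != k_discriminating")
            if len(set(self.discriminating_columns)) != self.k_discriminating:
                raise RecipeError("duplicate discriminating columns")
            if set(self.discriminating_columns) & insert_cols:
                raise RecipeError("discriminating columns collide with insertion columns")
            for col in self.discriminating_columns:
                if not 0 <= col < self.length:
                    raise RecipeError(f"discriminating column {col} out of range")
        if self.discriminating_residues is not None:
            if self.discriminating_columns is None:
                raise RecipeError("discriminating_residues requires discriminating_columns")
            if len(self.discriminating_residues) != self.k_discriminating:
                raise RecipeError("discriminating_residues count mismatch")
            for res_a, res_b in self.discriminating_residues:
                if res_a == res_b or res_a not in AA20 or res_b not in AA20:
                    raise RecipeError(f"bad discriminating residue pair {(res_a, res_b)!r}")


def gen_alignment(recipe: AlignmentRecipe) -> tuple[LabeledAlignment, dict]:
    """Generate a labeled alignment with exactly the planted discriminating
    columns and insertion blocks; returns the alignment and its manifest."""
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    fam_a, fam_b = recipe.subfamily_names
    n, length = recipe.n_per_subfamily, recipe.length

    insert_of: dict[int, InsertionSpec] = {}
    for ins in recipe.insertions:
        for col in ins.columns():
            insert_of[col] = ins

    if recipe.discriminating_columns is not None:
        disc_cols = list(recipe.discriminating_columns)
    else:
        free = [c for c in range(length) if c not in insert_of]
        disc_cols = sorted(rng.choice(len(free), size=recipe.k_discriminating, replace=False))
        disc_cols = [free[i] for i in disc_cols]
    disc_set = set(disc_cols)

    disc_pairs: dict[int, tuple[str, str]] = {}
    if recipe.discriminating_residues is not None:
        disc_pairs = dict(zip(recipe.discriminating_columns, recipe.discriminating_residues))
    else:
        for col in disc_cols:
            i, j = rng.choice(20, size=2, replace=False)
            disc_pairs[col] = (AA20[i], AA20[j])

    cols_a = np.empty((length, n), dtype="U1")
    cols_b = np.empty((length, n), dtype="U1")
    ref = np.empty(length, dtype="U1")

    for col in range(length):
        if col in insert_of:
            ins = insert_of[col]
            if ins.consensus is not None:
                res = ins.consensus[col - ins.anchor_column - 1]
            else:
                res = AA20[rng.integers(20)]
            carrier = cols_a if ins.subfamily == fam_a else cols_b
            absent = cols_b if ins.subfamily == fam_a else cols_a
            carrier[col] = res
            absent[col] = "-"
            ref[col] = "-"
        elif col in disc_set:
            res_a, res_b = disc_pairs[col]
            cols_a[col] = res_a
            cols_b[col] = res_b
            ref[col] = res_a
        else:
            res = AA20[rng.integers(20)]
            cols_a[col] = res
            cols_b[col] = res
            ref[col] = res
            if rng.random() >= recipe.background_conservation:
                # break conservation in one subfamily so the column can
                # never satisfy the discrimination criterion
                other = AA20[(AA20.index(res) + 1 + rng.integers(19)) % 20]
                fam_cols = cols_a if rng.random() < 0.5 else cols_b
                fam_cols[col, rng.integers(n)] = other

    ids_a = [f"{fam_a}_sp{i:02d}" for i in range(n)]
    ids_b = [f"{fam_b}_sp{i:02d}" for i in range(n)]
    records = [(recipe.reference_id, "".join(ref))]
    records += [(rid, "".join(cols_a[:, i])) for i, rid in enumerate(ids_a)]
    records += [(rid, "".join(cols_b[:, i])) for i, rid in enumerate(ids_b)]
    labels = {rid: fam_a for rid in ids_a} | {rid: fam_b for rid in ids_b}
    aln = LabeledAlignment(records=records, labels=labels, reference_id=recipe.reference_id)

    manifest = {
        "kind": "alignment",
        "seed": recipe.seed,
        "subfamilies": list(recipe.subfamily_names),
        "reference_id": recipe.reference_id,
        "n_per_subfamily": n,
        "length": length,
        "discriminating": [
            {
                "column": int(col),
                "ref_position": map_to_reference(aln, int(col)),
                "residue_a": disc_pairs[col][0],
                "residue_b": disc_pairs[col][1],
            }
            for col in sorted(disc_cols)
        ],
        "insertions": [
            {
                "subfamily": ins.subfamily,
                "anchor_column": ins.anchor_column,
                "anchor_ref_position": _anchor_ref(aln, ins),
                "length": ins.length,
                "start_column": ins.anchor_column + 1,
                "consensus": "".join(
                    aln.sequence(
                        (ids_a if ins.subfamily == fam_a else ids_b)[0]
                    )[c]
                    for c in ins.columns()
                ),
            }
            for ins in recipe.insertions
        ],
    }
    return aln, manifest


def _anchor_ref(aln: LabeledAlignment, ins: InsertionSpec) -> int:
    ref = aln.reference_sequence
    return sum(1 for c in ref[: ins.anchor_column + 1] if c not in "-.")


def write_alignment(aln: LabeledAlignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write the alignment as aligned FASTA or Clustal."""
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records
    )
    AlignIO.write(msa, str(path), fmt)


def write_label_map(aln: LabeledAlignment, path: str | Path) -> None:
    lines = [f"{rid}\t{fam}" for rid, fam in sorted(aln.labels.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ===========================================================================
# structures
# ===========================================================================

#: idealized planar adenine base (x, y in Angstrom); C1' marks the sugar link.
ADENINE_2D: dict[str, tuple[float, float]] = {
    "C1'": (-1.200, -0.800),
    "N9": (0.000, 0.000),
    "C8": (0.694, 1.176),
    "N7": (2.007, 0.984),
    "C5": (2.182, -0.370),
    "C4": (0.958, -0.926),
    "N3": (0.716, -2.245),
    "C2": (1.800, -2.986),
    "N1": (3.026, -2.562),
    "C6": (3.284, -1.250),
    "N6": (4.502, -0.821),
}

DECODING_STATES = ("stacked", "unstacked", "recognized")


@dataclass(frozen=True)
class AtomSpec:
    """Identity of one planted atom: chain, residue number, residue name,
    atom name and element."""

    chain: str
    res_id: int
    res_name: str
    atom_name: str
    element: str

    def record(self, coord, **kw) -> dict:
        return {
            "chain": self.chain,
            "res_id": self.res_id,
            "res_name": self.res_name,
            "atom_name": self.atom_name,
            "element": self.element,
            "coord": coord,
            **kw,
        }

    @property
    def atom_id(self) -> str:
        return f"{self.chain}:{self.res_id}:{self.atom_name}"


@dataclass(frozen=True)
class StructureRecipe:
    """Recipe for a coordinate model with planted interactions.

    ``planted_hbonds``: (donor AtomSpec, acceptor AtomSpec, distance, angle
    or None).  When an angle is given a hydrogen is placed on the donor to
    realize that D-H...A angle.  ``planted_clashes``: (AtomSpec, AtomSpec,
    overlap).  ``decoding_state`` embeds a decoding-center block in the
    requested conformation.
    """

    planted_hbonds: tuple[tuple[AtomSpec, AtomSpec, float, float | None], ...] = ()
    planted_clashes: tuple[tuple[AtomSpec, AtomSpec, float], ...] = ()
    decoding_state: str | None = None
    seed: int = 0

    def validate(self) -> None:
        pairs: set[tuple[str, str]] = set()
        for donor, acceptor, dist, angle in self.planted_hbonds:
            if not 2.4 <= dist <= 3.5:
                raise RecipeError(f"planted H-bond distance {dist} outside [2.4, 3.5]")
            if angle is not None and not 120.0 <= angle <= 180.0:
                raise RecipeError(
                    f"planted H-bond angle {angle} below the detection cutoff"
                )
            if "D" not in donor_acceptor_role(donor.res_name, donor.atom_name):
                raise RecipeError(f"{donor.atom_id} is not a donor in the chemistry table")
            if "A" not in donor_acceptor_role(acceptor.res_name, acceptor.atom_name):
                raise RecipeError(f"{acceptor.atom_id} is not an acceptor in the chemistry table")
            _check_separation(donor, acceptor)
            pairs.add(tuple(sorted((donor.atom_id, acceptor.atom_id))))
        for a, b, overlap in self.planted_clashes:
            if overlap <= SEVERE_CLASH_OVERLAP:
                raise RecipeError(f"planted clash overlap {overlap} not above severe threshold")
            for spec in (a, b):
                if spec.element.upper() not in VDW_RADII:
                    raise RecipeError(f"no van der Waals radius for element {spec.element!r}")
            _check_separation(a, b)
            if tuple(sorted((a.atom_id, b.atom_id))) in pairs:
                raise RecipeError("same atom pair planted as both bond and clash")
        if self.decoding_state is not None and self.decoding_state not in DECODING_STATES:
            raise RecipeError(f"unknown decoding state {self.decoding_state!r}")


def _check_separation(a: AtomSpec, b: AtomSpec) -> None:
    if a.chain == b.chain and abs(a.res_id - b.res_id) <= 1:
        raise RecipeError(
            f"planted pair {a.atom_id} / {b.atom_id} must be in non-adjacent residues"
        )


def _hydrogen_position(donor: np.ndarray, acceptor: np.ndarray, angle: float) -> np.ndarray:
    """Place H at 1.0 A from the donor so the D-H...A angle equals ``angle``."""
    axis = acceptor - donor
    dist = np.linalg.norm(axis)
    axis = axis / dist
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    def dha(alpha: float) -> float:
        h = donor + np.cos(alpha) * axis + np.sin(alpha) * perp
        v1, v2 = donor - h, acceptor - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    if angle >= 180.0 - 1e-9:
        return donor + axis
    alpha = brentq(lambda a: dha(a) - angle, 1e-9, np.pi - 1e-3)
    return donor + np.cos(alpha) * axis + np.sin(alpha) * perp


def _base_records(chain: str, res_id: int, pose: dict[str, np.ndarray],
                  hetero: bool = False) -> list[dict]:
    out = []
    for name, coord in pose.items():
        element = name[0]
        out.append({
            "chain": chain, "res_id": res_id, "res_name": "A",
            "atom_name": name, "element": element, "coord": coord,
            "hetero": hetero,
        })
    return out


def _place_base(translation_xy: tuple[float, float], z: float,
                flip: bool = False) -> dict[str, np.ndarray]:
    pose = {}
    for name, (bx, by) in ADENINE_2D.items():
        if flip:
            by = -by
        pose[name] = np.array([translation_xy[0] + bx, translation_xy[1] + by, z])
    return pose


# --- decoding-center layout (shared between templates and complexes) -------

_FRAME_ATOMS: list[tuple[int, str, tuple[float, float, float]]] = [
    (1491, "P", (30.0, 10.0, 7.0)),
    (1491, "O5'", (31.0, 11.0, 7.0)),
    (1491, "C1'", (32.5, 10.5, 8.0)),
    (1494, "P", (36.0, 10.0, 9.0)),
    (1494, "O5'", (37.0, 11.0, 9.0)),
    (1494, "C1'", (38.5, 10.5, 10.0)),
]

# switch-loop backbone layout: residues 286-301 along x
_LOOP_RANGE = range(286, 302)


def _ca(i: int) -> np.ndarray:
    return np.array([(i - 286) * 3.5, 0.0, 0.0])


def _bb(i: int) -> dict[str, np.ndarray]:
    ca = _ca(i)
    return {
        "N": ca + np.array([-1.2, 0.8, 0.0]),
        "CA": ca,
        "C": ca + np.array([1.2, 0.8, 0.0]),
        "O": ca + np.array([1.2, 2.0, 0.0]),
    }


_O295 = _bb(295)["O"]
_O296 = _bb(296)["O"]
_O298 = _bb(298)["O"]
_OG1_295 = _ca(295) + np.array([0.0, -2.2, 1.2])


def _decoding_poses(state: str) -> dict[int, dict[str, np.ndarray]]:
    """Global poses of A-1492/A-1493 for each decoding-center state.

    The recognized-state A-1493 is anchored so that its C2 atom sits 3.7 A
    directly above the backbone carbonyl oxygen of switch-loop residue 295,
    reproducing the close approach seen in release-factor termination
    complexes; the stacked state parks both bases away from the factor; the
    unstacked state flips A-1493 into the A-site region.
    """
    c2 = ADENINE_2D["C2"]
    if state == "stacked":
        return {
            1492: _place_base((31.0, 7.0), 6.5),
            1493: _place_base((31.3, 6.2), 9.9),
        }
    if state == "unstacked":
        return {
            1492: _place_base((26.0, 4.0), 5.0, flip=True),
            1493: _place_base((33.5, 3.0), 2.5, flip=True),
        }
    if state == "recognized":
        return {
            1492: _place_base((28.0, 6.0), 7.5),
            1493: _place_base((_O295[0] - c2[0], _O295[1] - c2[1]), _O295[2] + 3.7),
        }
    raise RecipeError(f"unknown decoding state {state!r}")


def _decoding_records(state: str, chain: str = "A",
                      offset: np.ndarray | None = None) -> list[dict]:
    off = np.zeros(3) if offset is None else np.asarray(offset, float)
    records: list[dict] = []
    for res_id, name, coord in _FRAME_ATOMS:
        records.append({
            "chain": chain, "res_id": res_id, "res_name": "A",
            "atom_name": name, "element": name[0], "coord": np.array(coord) + off,
        })
    for res_id, pose in _decoding_poses(state).items():
        shifted = {name: coord + off for name, coord in pose.items()}
        records.extend(_base_records(chain, res_id, shifted))
    return records


def decoding_templates() -> dict[str, StructureModel]:
    """The three labeled decoding-center conformations used as templates by
    the state classifier (frame residues 1491/1494 plus A-1492/A-1493)."""
    return {
        state: StructureModel.from_records(_decoding_records(state))
        for state in DECODING_STATES
    }


def gen_structure(recipe: StructureRecipe) -> tuple[StructureModel, dict]:
    """Generate a coordinate model realizing exactly the planted geometry.

    Planted atom pairs are laid out on a 40 A grid so nothing interacts
    except as requested; the optional decoding-center block is placed at a
    large offset.
    """
    recipe.validate()
    records: list[dict] = []
    manifest_bonds, manifest_clashes = [], []
    slot = 0
    for donor, acceptor, dist, angle in recipe.planted_hbonds:
        origin = np.array([40.0 * slot, 0.0, 0.0])
        d_coord = origin
        a_coord = origin + np.array([dist, 0.0, 0.0])
        records.append(donor.record(d_coord))
        records.append(acceptor.record(a_coord))
        if angle is not None:
            h = _hydrogen_position(d_coord, a_coord, angle)
            records.append({
                "chain": donor.chain, "res_id": donor.res_id,
                "res_name": donor.res_name, "atom_name": "H" + donor.atom_name[1:],
                "element": "H", "coord": h,
            })
        manifest_bonds.append({
            "donor": donor.atom_id, "acceptor": acceptor.atom_id,
            "distance": dist, "angle": angle,
        })
        slot += 1
    for a, b, overlap in recipe.planted_clashes:
        origin = np.array([40.0 * slot, 0.0, 0.0])
        dist = VDW_RADII[a.element.upper()] + VDW_RADII[b.element.upper()] - overlap
        records.append(a.record(origin))
        records.append(b.record(origin + np.array([dist, 0.0, 0.0])))
        manifest_clashes.append({
            "atom_a": a.atom_id, "atom_b": b.atom_id,
            "distance": dist, "overlap": overlap,
        })
        slot += 1
    if recipe.decoding_state is not None:
        records.extend(
            _decoding_records(recipe.decoding_state, chain="D",
                              offset=np.array([0.0, 200.0, 0.0]))
        )
    if not records:
        # an empty recipe still yields a valid, parseable file
        records.append({
            "chain": "Z", "res_id": 1, "res_name": "GLY",
            "atom_name": "CA", "element": "C", "coord": np.zeros(3),
        })
    model = StructureModel.from_records(records)
    manifest = {
        "kind": "structure",
        "seed": recipe.seed,
        "hbonds": manifest_bonds,
        "clashes": manifest_clashes,
        "decoding_state": recipe.decoding_state,
        "decoding_chain": "D" if recipe.decoding_state else None,
    }
    return model, manifest


# ===========================================================================
# release factor / ribosome complex
# ===========================================================================

@dataclass(frozen=True)
class ComplexRecipe:
    """A synthetic termination-complex fragment.

    ``variant``: ``"rf1"`` (bacterial-like: Glu-297 side chain, Arg-298,
    Lys-301, no insert) or ``"mtrf1"`` (RT-insert arginine at 115A, Gly-297,
    Gln-298, Arg-301).  ``state`` selects the decoding-center conformation.
    The protein fragment spans switch-loop residues 286-301 on chain R;
    rRNA chain A holds the decoding center, chain B holds helix-69 A-1914.
    """

    variant: str = "rf1"
    state: str = "recognized"
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in ("rf1", "mtrf1"):
            raise RecipeError(f"unknown variant {self.variant!r}")
        if self.state not in DECODING_STATES:
            raise RecipeError(f"unknown decoding state {self.state!r}")


def _loop_residue_name(i: int, variant: str) -> str:
    special = {
        295: "THR",
        297: "GLU" if variant == "rf1" else "GLY",
        298: "ARG" if variant == "rf1" else "GLN",
        301: "LYS" if variant == "rf1" else "ARG",
    }
    return special.get(i, "ALA")


def gen_complex(recipe: ComplexRecipe) -> tuple[StructureModel, dict]:
    """Build the synthetic release-factor/decoding-center complex.

    Planted geometry (exact by construction):

    * Thr-295 OG1 donates a 2.9 A hydrogen bond to N7 of A-1914 (both variants).
    * recognized state: A-1493 C2 sits exactly 3.7 A above the Thr-295
      backbone carbonyl oxygen; in the rf1 variant Glu-297 OE1 accepts a
      2.9 A bond from A-1493 N6; in the mtrf1 variant the RT-insert
      guanidinium overlaps the flipped base (severe clashes).
    * mtrf1 variant (all states): RT-insert arginine NH1/NH2 donate 2.9 A
      bonds to the backbone carbonyls of loop residues 295 and 296.
    * helix capping: the 301 side-chain amine (Lys NZ or Arg NH1) donates a
      2.9 A bond to the backbone carbonyl of residue 298.
    """
    recipe.validate()
    records: list[dict] = []
    # switch-loop backbone
    for i in _LOOP_RANGE:
        res_name = _loop_residue_name(i, recipe.variant)
        for atom_name, coord in _bb(i).items():
            records.append({
                "chain": "R", "res_id": i, "res_name": res_name,
                "atom_name": atom_name, "element": atom_name[0], "coord": coord,
            })
    # Thr-295 side chain (points toward helix 69)
    records += [
        {"chain": "R", "res_id": 295, "res_name": "THR", "atom_name": "CB",
         "element": "C", "coord": _ca(295) + np.array([0.0, -1.5, 0.0])},
        {"chain": "R", "res_id": 295, "res_name": "THR", "atom_name": "OG1",
         "element": "O", "coord": _OG1_295},
        {"chain": "R", "res_id": 295, "res_name": "THR", "atom_name": "CG2",
         "element": "C", "coord": _ca(295) + np.array([-1.3, -1.9, -0.5])},
    ]
    planted = [
        {"donor": "R:295:OG1", "acceptor": "B:1914:N7", "distance": 2.9,
         "partner_class": "decoding_center", "loop_position": 295},
    ]

    recognized_pose = _decoding_poses("recognized")[1493]
    if recipe.variant == "rf1":
        n6, c6 = recognized_pose["N6"], recognized_pose["C6"]
        direction = (n6 - c6) / np.linalg.norm(n6 - c6)
        oe1 = n6 + 2.9 * direction
        records += [
            {"chain": "R", "res_id": 297, "res_name": "GLU", "atom_name": "CB",
             "element": "C", "coord": _ca(297) + np.array([0.1, 1.5, 0.8])},
            {"chain": "R", "res_id": 297, "res_name": "GLU", "atom_name": "CG",
             "element": "C", "coord": _ca(297) + np.array([0.3, 3.2, 1.3])},
            {"chain": "R", "res_id": 297, "res_name": "GLU", "atom_name": "CD",
             "element": "C", "coord": oe1 + np.array([0.6, 0.6, -0.8])},
            {"chain": "R", "res_id": 297, "res_name": "GLU", "atom_name": "OE1",
             "element": "O", "coord": oe1},
            {"chain": "R", "res_id": 297, "res_name": "GLU", "atom_name": "OE2",
             "element": "O", "coord": oe1 + np.array([1.7, 0.8, -0.5])},
        ]
        # Arg-298 side chain points away from the decoding site
        records += [
            {"chain": "R", "res_id": 298, "res_name": "ARG", "atom_name": "CB",
             "element": "C", "coord": _ca(298) + np.array([0.0, -1.5, 0.0])},
            {"chain": "R", "res_id": 298, "res_name": "ARG", "atom_name": "NH1",
             "element": "N", "coord": _ca(298) + np.array([0.0, -5.3, 4.3])},
        ]
        cap_spec = ("LYS", "NZ")
        if recipe.state == "recognized":
            planted.append({
                "donor": "A:1493:N6", "acceptor": "R:297:OE1", "distance": 2.9,
                "partner_class": "decoding_center", "loop_position": 297,
            })
    else:
        # RT-insert arginine (residue 115, insertion code A on the factor chain)
        nh1 = _O295 + np.array([0.0, 0.0, 2.9])
        nh2 = _O296 + np.array([0.0, 0.0, 2.9])
        cz = (nh1 + nh2) / 2 + np.array([0.0, 0.0, 0.7])
        for atom_name, coord in (
            ("NH1", nh1), ("NH2", nh2), ("CZ", cz),
            ("NE", cz + np.array([0.0, -1.5, 0.8])),
            ("CD", cz + np.array([0.0, -2.2, 1.6])),
            ("CG", cz + np.array([0.0, -2.9, 2.8])),
            ("CB", cz + np.array([0.0, -3.5, 4.0])),
        ):
            records.append({
                "chain": "R", "res_id": 115, "ins_code": "A", "res_name": "ARG",
                "atom_name": atom_name, "element": atom_name[0], "coord": coord,
            })
        planted += [
            {"donor": "R:115A:NH1", "acceptor": "R:295:O", "distance": 2.9,
             "partner_class": "insert", "loop_position": 295},
            {"donor": "R:115A:NH2", "acceptor": "R:296:O", "distance": 2.9,
             "partner_class": "insert", "loop_position": 296},
        ]
        # Gln-298 packs against the insert arginine (van der Waals, no bond)
        records += [
            {"chain": "R", "res_id": 298, "res_name": "GLN", "atom_name": "CB",
             "element": "C", "coord": _ca(298) + np.array([0.0, -1.5, 0.0])},
            {"chain": "R", "res_id": 298, "res_name": "GLN", "atom_name": "CG",
             "element": "C", "coord": _ca(298) + np.array([-1.0, -1.8, 1.0])},
            {"chain": "R", "res_id": 298, "res_name": "GLN", "atom_name": "CD",
             "element": "C", "coord": _ca(298) + np.array([-2.0, -1.5, 2.0])},
            {"chain": "R", "res_id": 298, "res_name": "GLN", "atom_name": "OE1",
             "element": "O", "coord": _ca(298) + np.array([-2.8, -1.0, 2.6])},
            {"chain": "R", "res_id": 298, "res_name": "GLN", "atom_name": "NE2",
             "element": "N", "coord": _ca(298) + np.array([-2.2, -2.3, 2.9])},
        ]
        cap_spec = ("ARG", "NH1")

    # helix-alpha7 capping: 301 side-chain amine to backbone O of 298
    cap_res, cap_atom = cap_spec
    cap_n = _O298 + np.array([0.0, 0.0, 2.9])
    records += [
        {"chain": "R", "res_id": 301, "res_name": cap_res, "atom_name": cap_atom,
         "element": "N", "coord": cap_n},
        {"chain": "R", "res_id": 301, "res_name": cap_res,
         "atom_name": "CE" if cap_res == "LYS" else "CZ",
         "element": "C", "coord": cap_n + np.array([0.5, 0.5, 1.3])},
    ]
    planted.append({
        "donor": f"R:301:{cap_atom}", "acceptor": "R:298:O", "distance": 2.9,
        "partner_class": "helix_capping", "loop_position": 301,
    })

    # decoding center (chain A) in the requested state, helix-69 A-1914 (chain B)
    records.extend(_decoding_records(recipe.state, chain="A"))
    n7 = ADENINE_2D["N7"]
    pose_1914 = _place_base(
        (_OG1_295[0] - n7[0], _OG1_295[1] - 2.9 - n7[1]), _OG1_295[2]
    )
    records.extend(_base_records("B", 1914, pose_1914))

    model = StructureModel.from_records(records)
    manifest = {
        "kind": "complex",
        "seed": recipe.seed,
        "variant": recipe.variant,
        "state": recipe.state,
        "hbonds": planted,
        "rf_chain": "R",
        "decoding_chain": "A",
        "helix69_chain": "B",
        "insert_residue": "R:115A" if recipe.variant == "mtrf1" else None,
        "thr295_a1493_min_distance": 3.7 if recipe.state == "recognized" else None,
        "expect_decoding_clash": (
            recipe.variant == "mtrf1" and recipe.state in ("recognized", "unstacked")
        ) or (recipe.variant == "rf1" and recipe.state == "unstacked"),
    }
    return model, manifest


# ===========================================================================
# mitogenomes
# ===========================================================================

_FILLER_CODONS = ("GCA", "GCC", "CTA", "CTT", "GGA", "GGC", "ATC", "GTA")
_TERMINI = {"TAA", "TAG", "TGA", "AGA", "AGG", "T", "TA"}


@dataclass(frozen=True)
class GeneSpec:
    """One planted protein-coding gene: terminal codon (DNA triplet, or the
    incomplete stops 'T'/'TA') and the base immediately 5' of it."""

    name: str
    strand: int = 1
    terminal: str = "TAA"
    preceding_base: str = "A"
    pseudo: bool = False

    def validate(self) -> None:
        if self.strand not in (1, -1):
            raise RecipeError(f"{self.name}: strand must be +1 or -1")
        if self.terminal not in _TERMINI:
            raise RecipeError(f"{self.name}: unsupported terminus {self.terminal!r}")
        if self.preceding_base not in _DNA:
            raise RecipeError(f"{self.name}: preceding base {self.preceding_base!r} not DNA")


@dataclass(frozen=True)
class GenomeRecipe:
    """Recipe for an annotated circular mitogenome fixture."""

    genes: tuple[GeneSpec, ...] = ()
    circular: bool = True
    origin_span: str | None = None  # name of a plus-strand gene wrapped over the origin
    seed: int = 0
    locus_name: str = "SYNMITO"

    def validate(self) -> None:
        if not self.genes:
            raise RecipeError("at least one gene required")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise RecipeError("duplicate gene names")
        for gene in self.genes:
            gene.validate()
        if self.origin_span is not None:
            if not self.circular:
                raise RecipeError("origin-spanning gene requires a circular genome")
            match = [g for g in self.genes if g.name == self.origin_span]
            if not match:
                raise RecipeError(f"origin_span names unknown gene {self.origin_span!r}")
            if match[0].strand != 1:
                raise RecipeError("origin-spanning gene must be on the plus strand")


def _expected_class(terminal: str, preceding: str) -> str:
    # independent miniature decision table recorded as planted truth
    if terminal in ("TAA", "TAG"):
        return "standard"
    if terminal in ("AGA", "AGG") and preceding == "T":
        return "frameshift_terminable"
    if terminal in ("T", "TA"):
        return "polyA_completed"
    return "not_terminable"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gen_mitogenome(recipe: GenomeRecipe) -> tuple[SeqRecord, dict]:
    """Generate an annotated GenBank-style mitogenome record plus manifest.

    Gene coding sequences are ATG + filler codons; the final filler codon is
    chosen so its third base is the requested preceding base, then the
    requested terminus is appended (full stop triplet, or 'T'/'TA' for
    incomplete, polyadenylation-completed stops).  Genes never overlap.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    pieces: list[str] = []
    placements: list[tuple[GeneSpec, str]] = []
    manifest_genes = []

    for gene in recipe.genes:
        n_filler = int(rng.integers(40, 80))
        codons = ["ATG"]
        codons += [_FILLER_CODONS[rng.integers(len(_FILLER_CODONS))] for _ in range(n_filler)]
        codons.append("GC" + gene.preceding_base)
        coding = "".join(codons) + gene.terminal
        placements.append((gene, coding))

    features: list[SeqFeature] = []
    span_gene = None
    span_second = ""
    pos = 0
    if recipe.origin_span is not None:
        # the 5' half of the wrapped gene goes at the very end of the
        # sequence, its 3' half occupies the start
        idx = next(i for i, (g, _) in enumerate(placements) if g.name == recipe.origin_span)
        span_gene = placements.pop(idx)
        coding = span_gene[1]
        split = (len(coding) // 2 // 3) * 3  # split on a codon boundary
        span_second = coding[split:]
        pieces.append(span_second)
        pos += len(span_second)
    for gene, coding in placements:
        spacer = "".join(_DNA[rng.integers(4)] for _ in range(int(rng.integers(5, 30))))
        pieces.append(spacer)
        pos += len(spacer)
        start = pos
        genomic = coding if gene.strand == 1 else _revcomp(coding)
        pieces.append(genomic)
        pos += len(genomic)
        location = FeatureLocation(start, pos, strand=gene.strand)
        features.append(_cds_feature(gene, location))
        manifest_genes.append(_manifest_gene(gene, coding, f"{start + 1}..{pos}"))

    tail_spacer = "".join(_DNA[rng.integers(4)] for _ in range(int(rng.integers(5, 30))))
    pieces.append(tail_spacer)
    pos += len(tail_spacer)
    if span_gene is not None:
        gene, coding = span_gene
        first = coding[: len(coding) - len(span_second)]
        pieces.append(first)
        total = pos + len(first)
        location = CompoundLocation([
            FeatureLocation(pos, total, strand=1),
            FeatureLocation(0, len(span_second), strand=1),
        ])
        features.insert(0, _cds_feature(gene, location))
        manifest_genes.insert(0, _manifest_gene(
            gene, coding, f"join({pos + 1}..{total},1..{len(span_second)})"
        ))
    genome_seq = "".join(pieces)

    record = SeqRecord(
        Seq(genome_seq),
        id=f"{recipe.locus_name}.1",
        name=recipe.locus_name,
        description="synthetic vertebrate-like mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if recipe.circular else "linear",
            "data_file_division": "VRT",
            "date": "01-JAN-2000",
            "accessions": [recipe.locus_name],
        },
        features=sorted(features, key=lambda f: int(f.location.start)),
    )
    manifest = {
        "kind": "mitogenome",
        "seed": recipe.seed,
        "circular": recipe.circular,
        "length": len(genome_seq),
        "genes": manifest_genes,
        "all_terminable": all(
            g["expected_class"] != "not_terminable" for g in manifest_genes
            if not g["pseudo"]
        ),
    }
    return record, manifest


def _cds_feature(gene: GeneSpec, location) -> SeqFeature:
    qualifiers = {"gene": [gene.name], "transl_table": ["2"]}
    if gene.pseudo:
        qualifiers["pseudo"] = [None]
    return SeqFeature(location, type="CDS", qualifiers=qualifiers)


def _manifest_gene(gene: GeneSpec, coding: str, location: str) -> dict:
    return {
        "name": gene.name,
        "strand": "+" if gene.strand == 1 else "-",
        "terminal": gene.terminal,
        "preceding_base": gene.preceding_base,
        "expected_class": (
            "excluded" if gene.pseudo
            else _expected_class(gene.terminal, gene.preceding_base)
        ),
        "pseudo": gene.pseudo,
        "location": location,
        "coding_length": len(coding),
    }


def write_mitogenome(record: SeqRecord, path: str | Path) -> None:
    SeqIO.write(record, str(path), "genbank")


# ===========================================================================
# study-condition recipes
# ===========================================================================

#: reference positions of the planted discriminating sites, region by region,
#: emulating the reported 20 / 2 / 1 / 1 split over the release-factor fold
#: (codon-recognition domain 2, switch loop, domain 1, domain 3).  The named
#: substitutions at 119 (Glu->Ile), 186 (Thr->Val), 195 (Ser->Gly),
#: 298 (Arg->Gln) and 301 (Lys->Arg) are pinned to their reported identities.
STUDY_POSITIONS: dict[int, tuple[str, str]] = {
    57: ("D", "N"),
    108: ("Q", "L"), 112: ("N", "K"), 118: ("S", "A"), 119: ("E", "I"),
    121: ("T", "M"), 125: ("K", "F"), 131: ("R", "W"), 140: ("D", "H"),
    147: ("E", "P"), 153: ("Y", "C"), 160: ("N", "D"), 166: ("L", "V"),
    172: ("H", "Y"), 178: ("M", "T"), 186: ("T", "V"), 189: ("A", "S"),
    192: ("G", "E"), 195: ("S", "G"), 198: ("V", "A"), 201: ("I", "R"),
    240: ("K", "E"),
    298: ("R", "Q"), 301: ("K", "R"),
}

_REF_LENGTH = 360  # residues in the ungapped reference
_RT_ANCHOR_REF = 115  # RT insert between reference 115 and 116
_GLS_ANCHOR_REF = 186  # GLS insert directly after the PXT motif (Pro-184..Thr-186)


def _ref_to_column(pos: int) -> int:
    """Alignment column of a reference position under the study insert layout."""
    col = pos - 1
    if pos > _RT_ANCHOR_REF:
        col += 2
    if pos > _GLS_ANCHOR_REF:
        col += 3
    return col


def study_alignment_recipe(seed: int = 0) -> AlignmentRecipe:
    """The default study conditions: 17 sequences per subfamily, 24 planted
    discriminating positions in the reported regional distribution, and the
    two-residue 'RT' and three-residue 'GLS' inserts carried by the mtRF1
    subfamily at their reported anchors."""
    positions = sorted(STUDY_POSITIONS)
    columns = tuple(_ref_to_column(p) for p in positions)
    residues = tuple(STUDY_POSITIONS[p] for p in positions)
    return AlignmentRecipe(
        n_per_subfamily=17,
        length=_REF_LENGTH + 5,
        k_discriminating=len(positions),
        insertions=(
            InsertionSpec(_ref_to_column(_RT_ANCHOR_REF), 2, "mtRF1", "RT"),
            InsertionSpec(_ref_to_column(_GLS_ANCHOR_REF), 3, "mtRF1", "GLS"),
        ),
        background_conservation=0.85,
        seed=seed,
        subfamily_names=("mtRF1a", "mtRF1"),
        reference_id="Tth_RF1",
        discriminating_columns=columns,
        discriminating_residues=residues,
    )


#: vertebrate-like 13-CDS composition: mostly standard UAA/UAG stops, two
#: U-preceded AGA/AGG stops, three incomplete (polyadenylation-completed)
#: termini, and the NADH-dehydrogenase-6 gene on the minus strand.
STUDY_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("ND1", 1, "TA", "A"),
    GeneSpec("ND2", 1, "T", "C"),
    GeneSpec("COX1", 1, "AGA", "T"),
    GeneSpec("COX2", 1, "TAA", "G"),
    GeneSpec("ATP8", 1, "TAG", "A"),
    GeneSpec("ATP6", 1, "TAA", "C"),
    GeneSpec("COX3", 1, "T", "G"),
    GeneSpec("ND3", 1, "TAA", "A"),
    GeneSpec("ND4L", 1, "TAA", "T"),
    GeneSpec("ND4", 1, "TAA", "A"),
    GeneSpec("ND5", 1, "TAA", "G"),
    GeneSpec("ND6", -1, "AGG", "T"),
    GeneSpec("CYTB", 1, "TAA", "C"),
)


def study_genome_recipe(seed: int = 0) -> GenomeRecipe:
    """A synthetic 13-gene vertebrate-like mitogenome whose termini are all
    terminable by the canonical mitochondrial release factor."""
    return GenomeRecipe(genes=STUDY_GENES, circular=True, seed=seed)


def recipe_to_dict(recipe) -> dict:
    return dataclasses.asdict(recipe)
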