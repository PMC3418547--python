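"""Interpretation of subfamily divergence in the ribosome context.

This layer places discriminating positions onto the release-factor fold
(region assignment and per-region counts), quantifies their spatial
clustering, classifies the decoding-center conformation of a model
(A-1492/A-1493 stacked, unstacked, or stop-codon recognized), derives
binding-compatibility verdicts from steric clashes against the decoding
nucleotides, and inventories switch-loop hydrogen bonds by partner class.

Region boundaries for the four-domain release-factor fold are shipped as
editable defaults; only the switch loop (reference positions 286-301) is a
fixed literature interval.  The domain intervals are editorial defaults
derived from the domain architecture of the bacterial RF1 template
structures and can be overridden in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import DiscriminatingPosition, InsertionEvent
from .structure import (
    Clash,
    HBond,
    HBondGeometry,
    SEVERE_CLASH_OVERLAP,
    SelectionError,
    StructureModel,
    detect_clashes,
    detect_hbonds,
    superpose,
)

__all__ = [
    "RegionTable",
    "DecodingCenterSpec",
    "CompatibilityVerdict",
    "InteractionInventoryRecord",
    "assign_region",
    "primary_region",
    "divergence_report",
    "clustering_pvalue",
    "classify_decoding_state",
    "binding_compatibility",
    "switch_loop_interactions",
    "interaction_replacement",
    "DEFAULT_REGION_TABLE",
]

PARTNER_CLASSES = ("decoding_center", "intramolecular", "insert", "helix_capping")


@dataclass(frozen=True)
class RegionTable:
    """Named intervals over reference numbering (1-based, inclusive).

    Intervals may overlap: a position can belong to a domain and to a loop
    within it.  For counting, loops take precedence over their parent
    domain (see :func:`primary_region`).
    """

    intervals: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_INTERVALS)
    )
    motifs: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_MOTIFS)
    )
    #: regions that outrank the domains in primary assignment, first wins
    precedence: tuple[str, ...] = ("switch_loop",)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"region {name!r}: empty interval [{lo}, {hi}]")
        for name, positions in self.motifs.items():
            for pos in positions:
                if not self.labels(pos):
                    raise ValueError(f"motif {name!r} position {pos} in no declared region")

    def labels(self, ref_position: int) -> set[str]:
        return {
            name
            for name, (lo, hi) in self.intervals.items()
            if lo <= ref_position <= hi
        }


# Switch loop 286-301 is the fixed literature interval; the domain spans are
# editorial defaults for a ~360-residue bacterial RF1 fold.
_DEFAULT_INTERVALS: dict[str, tuple[int, int]] = {
    "domain1": (1, 104),
    "domain2": (105, 203),
    "domain3": (204, 285),
    "domain4": (302, 360),
    "switch_loop": (286, 301),
    "recognition_loop": (180, 197),
    "helix_alpha5_tip": (110, 122),
    "helix_alpha7": (297, 325),
}

_DEFAULT_MOTIFS: dict[str, tuple[int, ...]] = {
    "GGQ": (231, 232, 233),
    "PXT": (184, 185, 186),
}

DEFAULT_REGION_TABLE = RegionTable()


@dataclass(frozen=True)
class DecodingCenterSpec:
    """Chain/residue identities of the decoding nucleotides and the local
    rRNA frame used for superposition."""

    a1492: tuple[str, int] = ("A", 1492)
    a1493: tuple[str, int] = ("A", 1493)
    a1914: tuple[str, int] = ("B", 1914)
    frame_selection: str = "A:1491,A:1494"

    @property
    def nucleotide_selection(self) -> str:
        return ",".join(f"{c}:{r}" for c, r in (self.a1492, self.a1493, self.a1914))

    @property
    def base_selection(self) -> str:
        return ",".join(f"{c}:{r}" for c, r in (self.a1492, self.a1493))


@dataclass(frozen=True)
class CompatibilityVerdict:
    """Binding verdict: compatible iff no severe clash against the decoding
    nucleotides."""

    state: str
    clashes: tuple[Clash, ...]
    compatible: bool

    def __post_init__(self) -> None:
        if self.compatible != (len(self.clashes) == 0):
            raise ValueError("compatible flag must mirror an empty clash list")


# ---------------------------------------------------------------------------
# region assignment and divergence reporting

def _anchor(ref_position: int | str | None) -> int | None:
    """Reduce a reference coordinate to its integer anchor ('115+1' -> 115)."""
    if ref_position is None:
        return None
    if isinstance(ref_position, int):
        return ref_position
    return int(str(ref_position).split("+")[0])


def assign_region(ref_position: int | str, table: RegionTable | None = None) -> set[str]:
    """All declared region labels containing the position (empty set if none).

    Insert coordinates like ``"115+1"`` are assigned via their anchor.
    """
    table = table or DEFAULT_REGION_TABLE
    anchor = _anchor(ref_position)
    return set() if anchor is None else table.labels(anchor)


def primary_region(ref_position: int | str, table: RegionTable | None = None) -> str:
    """Single region used for counting: precedence regions (the switch loop)
    outrank domains; otherwise the containing domain; else 'unassigned'."""
    table = table or DEFAULT_REGION_TABLE
    labels = assign_region(ref_position, table)
    for name in table.precedence:
        if name in labels:
            return name
    for name in sorted(labels):
        if name.startswith("domain"):
            return name
    return "unassigned"


def divergence_report(
    positions: Sequence[DiscriminatingPosition],
    insertions: Sequence[InsertionEvent] = (),
    table: RegionTable | None = None,
    model: StructureModel | None = None,
    chain: str | None = None,
) -> dict:
    """Structured per-region summary of subfamily divergence.

    Returns ``{"positions": DataFrame, "region_counts": {region: n},
    "insertions": DataFrame, "total": n}``; counts are over the disjoint
    primary-region assignment and always sum to the number of input
    positions.  When a model and chain are given, each row records whether
    the mapped residue is present in the model (unmappable rows are flagged,
    never dropped).
    """
    table = table or DEFAULT_REGION_TABLE
    rows = []
    counts: dict[str, int] = {}
    for pos in positions:
        primary = primary_region(pos.ref_position, table) if pos.ref_position is not None else "unassigned"
        counts[primary] = counts.get(primary, 0) + 1
        row = {
            "ref_position": pos.ref_position,
            "column": pos.column,
            "residue_a": pos.residue_a,
            "residue_b": pos.residue_b,
            "primary_region": primary,
            "regions": ",".join(sorted(assign_region(pos.ref_position, table)))
            if pos.ref_position is not None else "",
        }
        if model is not None and chain is not None:
            anchor = _anchor(pos.ref_position)
            present = (
                anchor is not None
                and bool(model.mask(f"{chain}:{anchor}".strip()).any())
            )
            row["in_model"] = present
        rows.append(row)
    ins_rows = [
        {
            "subfamily": e.subfamily,
            "anchor": e.anchor_ref_position,
            "length": e.length,
            "consensus": e.consensus,
            "anchor_region": primary_region(e.anchor_ref_position, table),
        }
        for e in insertions
    ]
    return {
        "positions": pd.DataFrame(rows),
        "insertions": pd.DataFrame(ins_rows),
        "region_counts": counts,
        "total": len(positions),
    }


# ---------------------------------------------------------------------------
# spatial clustering

def clustering_pvalue(
    model: StructureModel,
    chain: str,
    residues: Sequence[int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for spatial clustering of a residue set.

    Statistic: mean pairwise C-alpha distance of the set.  Null: same-size
    uniform subsets of the chain's C-alpha residues.  Small p means the set
    is more tightly clustered than random subsets;
    p = (1 + #{null <= observed}) / (1 + n_permutations), hence p in (0, 1].
    """
    if len(set(residues)) < 3:
        raise ValueError("clustering requires at least 3 distinct residues")
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    ca = model.select(f"{chain}:*:CA")
    res_ids = ca.atoms.res_id
    coords_by_res: dict[int, np.ndarray] = {}
    for i in range(len(ca)):
        coords_by_res.setdefault(int(res_ids[i]), ca.coords[i])
    missing = [r for r in residues if r not in coords_by_res]
    if missing:
        raise SelectionError(f"no C-alpha for residues {missing} in chain {chain!r}")
    all_res = np.array(sorted(coords_by_res))
    all_xyz = np.array([coords_by_res[r] for r in all_res])

    def mean_pairwise(xyz: np.ndarray) -> float:
        diff = xyz[:, None, :] - xyz[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        n = len(xyz)
        return float(dist[np.triu_indices(n, 1)].mean())

    observed = mean_pairwise(np.array([coords_by_res[r] for r in set(residues)]))
    k = len(set(residues))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        idx = rng.choice(len(all_res), size=k, replace=False)
        if mean_pairwise(all_xyz[idx]) <= observed:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# decoding-center state and binding compatibility

def _match_by_residue_atom(
    sub_m: StructureModel, sub_t: StructureModel
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 correspondence by (residue number, insertion code, atom name),
    ignoring chain ids, so templates and models may use different chains."""
    def keys(sub: StructureModel) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for i in range(len(sub)):
            _, res, icode = sub.residue_key(i)
            out.setdefault((res, icode, sub.atoms.atom_name[i].strip()), i)
        return out

    km, kt = keys(sub_m), keys(sub_t)
    common = sorted(set(km) & set(kt))
    if len(common) < 3:
        raise SelectionError("fewer than 3 matched atoms between model and template")
    return (
        sub_m.coords[[km[k] for k in common]],
        sub_t.coords[[kt[k] for k in common]],
    )


def classify_decoding_state(
    model: StructureModel,
    templates: Mapping[str, StructureModel],
    spec: DecodingCenterSpec | None = None,
    template_spec: DecodingCenterSpec | None = None,
) -> str:
    """Label the decoding-center conformation by nearest template.

    The model's local rRNA frame is superposed onto each template's frame;
    the rmsd over the A-1492/A-1493 base atoms (after applying the frame
    transform) picks the winning label.  Atoms are matched by residue
    number and atom name, so model and template chains may differ
    (``template_spec`` defaults to the shipped template layout).  Ties break
    in the order stacked < unstacked < recognized.
    """
    spec = spec or DecodingCenterSpec()
    template_spec = template_spec or DecodingCenterSpec()
    checks = [spec.frame_selection] + [
        f"{c}:{r}" for c, r in (spec.a1492, spec.a1493)
    ]
    for sel in checks:
        if not model.mask(sel).any():
            raise SelectionError(f"model does not resolve {sel!r}")
    order = {"stacked": 0, "unstacked": 1, "recognized": 2}
    scores: list[tuple[float, int, str]] = []
    for label, template in templates.items():
        frame_m, frame_t = _match_by_residue_atom(
            model.select(spec.frame_selection),
            template.select(template_spec.frame_selection),
        )
        transform = superpose(frame_m, frame_t)
        base_m, base_t = _match_by_residue_atom(
            model.select(spec.base_selection),
            template.select(template_spec.base_selection),
        )
        moved = transform.apply(base_m)
        rmsd = float(np.sqrt(np.mean(np.sum((moved - base_t) ** 2, axis=1))))
        scores.append((rmsd, order.get(label, 99), label))
    scores.sort()
    return scores[0][2]


def binding_compatibility(
    rf_model: StructureModel,
    ribosome_model: StructureModel,
    templates: Mapping[str, StructureModel] | None = None,
    spec: DecodingCenterSpec | None = None,
    rf_selection: str = "*",
    state: str | None = None,
    overlap_threshold: float = SEVERE_CLASH_OVERLAP,
) -> CompatibilityVerdict:
    """Steric verdict for a release-factor model posed in the ribosome frame.

    ``rf_model`` and ``ribosome_model`` must share coordinates (pose them
    with :func:`~mtrfkit.structure.superpose` beforehand if needed).  The
    clash list is restricted to factor atoms against the decoding
    nucleotides; the verdict is compatible iff it is empty.
    """
    spec = spec or DecodingCenterSpec()
    nucleotides = ribosome_model.try_select(spec.nucleotide_selection)
    if nucleotides is None:
        raise SelectionError(
            f"ribosome model does not resolve decoding nucleotides "
            f"{spec.nucleotide_selection!r}"
        )
    if state is None:
        if templates is None:
            raise ValueError("either a state label or templates must be given")
        state = classify_decoding_state(ribosome_model, templates, spec)
    rf_atoms = rf_model.select(rf_selection)
    clashes = tuple(detect_clashes(rf_model, rf_atoms, nucleotides, overlap_threshold))
    return CompatibilityVerdict(state=state, clashes=clashes, compatible=not clashes)


# ---------------------------------------------------------------------------
# switch-loop interaction inventory

@dataclass(frozen=True)
class InteractionInventoryRecord:
    """One switch-loop hydrogen bond, labeled by partner class."""

    loop_position: int
    donor: str
    acceptor: str
    partner: str
    partner_class: str
    distance: float

    def __post_init__(self) -> None:
        if self.partner_class not in PARTNER_CLASSES:
            raise ValueError(f"unknown partner class {self.partner_class!r}")


def _atom_residue(atom_id: str) -> tuple[str, str]:
    chain, res, _ = atom_id.split(":")
    return chain, res


def switch_loop_interactions(
    model: StructureModel,
    rf_chain: str,
    table: RegionTable | None = None,
    spec: DecodingCenterSpec | None = None,
    geometry: HBondGeometry | None = None,
) -> list[InteractionInventoryRecord]:
    """All hydrogen bonds involving switch-loop residues, by partner class.

    Partner classes: ``decoding_center`` (A-1492/A-1493/A-1914),
    ``insert`` (factor residues carrying an insertion code, e.g. the
    RT-insert arginine), ``helix_capping`` (side-chain amine of loop
    position 298 or 301 to a backbone carbonyl in helix alpha-7) and
    ``intramolecular`` (everything else on the factor chain).
    """
    table = table or DEFAULT_REGION_TABLE
    spec = spec or DecodingCenterSpec()
    lo, hi = table.intervals["switch_loop"]
    loop_sel = f"{rf_chain}:{lo}-{hi}"
    loop = model.try_select(loop_sel)
    if loop is None:
        raise SelectionError(f"switch loop {loop_sel!r} not resolvable in model")
    bonds = detect_hbonds(model, loop, model, geometry)
    decoding_residues = {
        (c, str(r)) for c, r in (spec.a1492, spec.a1493, spec.a1914)
    }
    alpha7_lo, alpha7_hi = table.intervals.get("helix_alpha7", (297, 325))
    records = []
    seen = set()
    for bond in bonds:
        sides = {bond.donor: "donor", bond.acceptor: "acceptor"}
        loop_atoms = [
            a for a in sides
            if _in_loop(a, rf_chain, lo, hi)
        ]
        if not loop_atoms:
            continue
        partner_atom = None
        for atom in (bond.donor, bond.acceptor):
            if atom not in loop_atoms:
                partner_atom = atom
        record = _classify_bond(
            bond, loop_atoms, partner_atom, rf_chain, lo, hi,
            decoding_residues, (alpha7_lo, alpha7_hi),
        )
        key = (record.donor, record.acceptor)
        if key not in seen:
            seen.add(key)
            records.append(record)
    records.sort(key=lambda r: (r.loop_position, r.donor, r.acceptor))
    return records


def _in_loop(atom_id: str, rf_chain: str, lo: int, hi: int) -> bool:
    chain, res = _atom_residue(atom_id)
    num = int("".join(ch for ch in res if ch.isdigit() or ch == "-"))
    icode = res.lstrip("-0123456789")
    return chain == rf_chain and lo <= num <= hi and not icode


def _classify_bond(
    bond: HBond,
    loop_atoms: list[str],
    partner_atom: str | None,
    rf_chain: str,
    lo: int,
    hi: int,
    decoding_residues: set[tuple[str, str]],
    alpha7: tuple[int, int],
) -> InteractionInventoryRecord:
    def resnum(atom_id: str) -> int:
        _, res = _atom_residue(atom_id)
        return int("".join(ch for ch in res if ch.isdigit() or ch == "-"))

    loop_position = resnum(sorted(loop_atoms)[0])
    if partner_atom is None:
        # bond internal to the loop: capping if a 298/301 side-chain amine
        # donates to a backbone carbonyl inside helix alpha-7
        donor_res, acceptor_res = resnum(bond.donor), resnum(bond.acceptor)
        donor_atom = bond.donor.split(":")[2]
        acceptor_atom = bond.acceptor.split(":")[2]
        if (
            donor_res in (298, 301)
            and donor_atom not in ("N",)
            and acceptor_atom in ("O", "OXT")
            and alpha7[0] <= acceptor_res <= alpha7[1]
        ):
            return InteractionInventoryRecord(
                donor_res, bond.donor, bond.acceptor, bond.acceptor,
                "helix_capping", bond.distance,
            )
        return InteractionInventoryRecord(
            loop_position, bond.donor, bond.acceptor, bond.acceptor,
            "intramolecular", bond.distance,
        )
    loop_position = resnum(loop_atoms[0])
    chain, res = _atom_residue(partner_atom)
    icode = res.lstrip("-0123456789")
    if (chain, res) in decoding_residues or (chain, res.rstrip("ABCDEFGHIJ")) in decoding_residues:
        cls = "decoding_center"
    elif chain == rf_chain and icode:
        cls = "insert"
    elif chain == rf_chain:
        cls = "intramolecular"
    else:
        cls = "decoding_center" if not chain == rf_chain else "intramolecular"
    return InteractionInventoryRecord(
        loop_position, bond.donor, bond.acceptor, partner_atom, cls, bond.distance
    )


def interaction_replacement(
    inventory_a: Sequence[InteractionInventoryRecord],
    inventory_b: Sequence[InteractionInventoryRecord],
) -> dict:
    """Compare two switch-loop inventories position by position.

    For every loop position bonded in A, report whether B also has a bond at
    that position (matched, with the partner identities) or not; the
    symmetric difference is reported both ways.
    """
    by_pos_a: dict[int, list[InteractionInventoryRecord]] = {}
    by_pos_b: dict[int, list[InteractionInventoryRecord]] = {}
    for rec in inventory_a:
        by_pos_a.setdefault(rec.loop_position, []).append(rec)
    for rec in inventory_b:
        by_pos_b.setdefault(rec.loop_position, []).append(rec)
    matched = []
    for pos in sorted(by_pos_a):
        if pos in by_pos_b:
            partners_a = sorted({r.partner for r in by_pos_a[pos]})
            partners_b = sorted({r.partner for r in by_pos_b[pos]})
            matched.append({
                "loop_position": pos,
                "partners_a": partners_a,
                "partners_b": partners_b,
                "same_partner": bool(set(partners_a) & set(partners_b)),
            })
    return {
        "matched": matched,
        "only_in_a": sorted(set(by_pos_a) - set(by_pos_b)),
        "only_in_b": sorted(set(by_pos_b) - set(by_pos_a)),
    }
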