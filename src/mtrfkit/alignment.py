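"""Two-subfamily alignment analysis for paralog subfunctionalization studies.

A gene duplication that splits an orthologous group into two subfamilies
(here: the vertebrate mitochondrial release factors mtRF1 and mtRF1a)
leaves two kinds of sequence footprints once the subfamilies have diverged
under different constraints:

* **discriminating positions** — alignment columns in which every member of
  subfamily A carries one residue, every member of subfamily B carries a
  single *different* residue, and neither is a gap.  These are the strictest
  possible subfamily-specific residues: perfectly conserved within each
  subfamily, different between them.
* **subfamily-specific insertions** — maximal column runs that are all-gap
  in one subfamily while the other subfamily carries residues there.

Both are reported in the numbering of an optional *reference* sequence
(e.g. Thermus thermophilus RF1), the convention used throughout the
structural literature on class I release factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO

__all__ = [
    "LabeledAlignment",
    "DiscriminatingPosition",
    "InsertionEvent",
    "AlignmentFormatError",
    "LabelError",
    "read_labeled_alignment",
    "read_label_map",
    "detect_discriminating_positions",
    "detect_insertions",
    "map_to_reference",
    "pairwise_identity",
    "positions_to_frame",
    "insertions_to_frame",
    "write_positions",
    "write_insertions",
]

GAP_CHARS = frozenset("-.")
#: IUPAC ambiguity codes that disqualify a column from perfect conservation.
AMBIGUOUS = frozenset("XBZJ")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class AlignmentFormatError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


class LabelError(ValueError):
    """Raised when records and subfamily labels do not match up."""


def _normalise(seq: str) -> str:
    # case-insensitive; '.' and '-' both read as gap
    return seq.upper().replace(".", "-")


@dataclass(frozen=True)
class DiscriminatingPosition:
    """An alignment column perfectly conserved within each subfamily but
    different between them."""

    column: int  # 0-based alignment column
    ref_position: int | str | None  # 1-based reference numbering, "anchor+offset", or None
    residue_a: str
    residue_b: str

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("discriminating residues must differ")
        for res in (self.residue_a, self.residue_b):
            if res not in STANDARD_AA:
                raise ValueError(f"non-standard residue {res!r} in discriminating position")


@dataclass(frozen=True)
class InsertionEvent:
    """A maximal insert carried by one subfamily and absent (all-gap) in the other.

    ``anchor_ref_position`` is the reference position immediately preceding
    the insert (0 when the insert precedes the first reference residue).
    """

    subfamily: str
    anchor_ref_position: int
    length: int
    consensus: str
    start_column: int  # 0-based first alignment column of the insert

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("insertion length must be >= 1")


@dataclass
class LabeledAlignment:
    """An alignment partitioned into exactly two named subfamilies, plus an
    optional reference sequence used only for coordinate mapping."""

    records: list[tuple[str, str]]
    labels: dict[str, str]
    reference_id: str | None = None
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = [(rid, _normalise(seq)) for rid, seq in self.records]
        self._index = dict(self.records)
        if len(self._index) != len(self.records):
            raise AlignmentFormatError("duplicate record ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"aligned sequences differ in length: {sorted(lengths)}")
        if self.reference_id is not None and self.reference_id not in self._index:
            raise LabelError(f"reference id {self.reference_id!r} not in alignment")
        for rid in self._index:
            if rid not in self.labels and rid != self.reference_id:
                raise LabelError(f"record {rid!r} has no subfamily label")
        for rid in self.labels:
            if rid not in self._index:
                raise LabelError(f"label for unknown record {rid!r}")
        if self.reference_id is not None and self.reference_id in self.labels:
            raise LabelError("reference sequence must not carry a subfamily label")
        fams = self.subfamilies
        if len(fams) != 2:
            raise LabelError(f"exactly two subfamilies required, got {sorted(fams)}")
        for fam in fams:
            if len(self.members(fam)) < 2:
                raise LabelError(f"subfamily {fam!r} has fewer than 2 members")

    @property
    def subfamilies(self) -> tuple[str, str]:
        return tuple(sorted(set(self.labels.values())))  # type: ignore[return-value]

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def sequence(self, rid: str) -> str:
        try:
            return self._index[rid]
        except KeyError:
            raise KeyError(f"no record {rid!r} in alignment") from None

    def members(self, subfamily: str) -> list[str]:
        return [rid for rid, _ in self.records if self.labels.get(rid) == subfamily]

    def column(self, col: int, ids: Iterable[str]) -> list[str]:
        if not 0 <= col < self.length:
            raise IndexError(f"column {col} out of range [0, {self.length})")
        return [self._index[rid][col] for rid in ids]

    @property
    def reference_sequence(self) -> str:
        if self.reference_id is None:
            raise LabelError("alignment has no reference sequence")
        return self._index[self.reference_id]


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (record id, subfamily name)."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LabelError(f"{path}:{lineno}: expected 2 tab-separated fields")
        labels[parts[0]] = parts[1]
    return labels


def read_labeled_alignment(
    alignment_path: str | Path,
    labels: str | Path | Mapping[str, str],
    reference_id: str | None = None,
    fmt: str | None = None,
) -> LabeledAlignment:
    """Read an aligned FASTA or Clustal file plus a subfamily label map.

    ``fmt`` may be ``"fasta"`` or ``"clustal"``; when omitted it is guessed
    from the file suffix (``.aln``/``.clustal`` -> clustal, else fasta).
    """
    path = Path(alignment_path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(labels, Mapping):
        labels = read_label_map(labels)
    records = [(rec.id, str(rec.seq)) for rec in msa]
    return LabeledAlignment(records=records, labels=dict(labels), reference_id=reference_id)


def _family_state(residues: Sequence[str]) -> str | None:
    """Return the single residue a subfamily carries in a column, or None if
    the column is not perfectly conserved (gaps and ambiguity codes disqualify)."""
    state = set(residues)
    if len(state) != 1:
        return None
    (res,) = state
    if res in GAP_CHARS or res in AMBIGUOUS or res not in STANDARD_AA:
        return None
    return res


def detect_discriminating_positions(aln: LabeledAlignment) -> list[DiscriminatingPosition]:
    """All columns perfectly conserved within each subfamily but different
    between them, sorted by column.

    Columns containing any gap within a subfamily are never reported here;
    columns all-gap in one subfamily belong to :func:`detect_insertions`.
    Reference positions are attached when the alignment has a reference.
    """
    fam_a, fam_b = aln.subfamilies
    ids_a, ids_b = aln.members(fam_a), aln.members(fam_b)
    out: list[DiscriminatingPosition] = []
    for col in range(aln.length):
        res_a = _family_state(aln.column(col, ids_a))
        res_b = _family_state(aln.column(col, ids_b))
        if res_a is None or res_b is None or res_a == res_b:
            continue
        ref_pos = map_to_reference(aln, col) if aln.reference_id is not None else None
        out.append(DiscriminatingPosition(col, ref_pos, res_a, res_b))
    return out


def map_to_reference(aln: LabeledAlignment, column: int) -> int | str:
    """Map an alignment column to reference numbering.

    Returns the 1-based ungapped reference index when the reference carries a
    residue in the column; otherwise ``"<anchor>+<offset>"`` where anchor is
    the last reference position before the column (0 if none) and offset
    counts reference-gap columns since that anchor.
    """
    ref = aln.reference_sequence
    if not 0 <= column < len(ref):
        raise IndexError(f"column {column} out of range [0, {len(ref)})")
    pos = sum(1 for c in ref[: column + 1] if c not in GAP_CHARS)
    if ref[column] not in GAP_CHARS:
        return pos
    offset = 1
    col = column - 1
    while col >= 0 and ref[col] in GAP_CHARS:
        offset += 1
        col -= 1
    return f"{pos}+{offset}"


def detect_insertions(aln: LabeledAlignment) -> list[InsertionEvent]:
    """Maximal runs of columns all-gap in one subfamily and majority-residue
    in the other, anchored at the preceding reference position.

    The consensus is the per-column majority residue of the carrying family
    (ties broken alphabetically).  Requires a reference sequence.
    """
    if aln.reference_id is None:
        raise LabelError("insertion detection requires a reference sequence")
    fam_a, fam_b = aln.subfamilies
    ids = {fam_a: aln.members(fam_a), fam_b: aln.members(fam_b)}

    def carrier(col: int) -> str | None:
        """Subfamily carrying an insert at this column, if any."""
        for absent, present in ((fam_a, fam_b), (fam_b, fam_a)):
            col_absent = aln.column(col, ids[absent])
            if not all(c in GAP_CHARS for c in col_absent):
                continue
            col_present = aln.column(col, ids[present])
            non_gap = [c for c in col_present if c not in GAP_CHARS]
            if len(non_gap) * 2 > len(col_present):
                return present
        return None

    events: list[InsertionEvent] = []
    col = 0
    ref = aln.reference_sequence
    while col < aln.length:
        fam = carrier(col)
        if fam is None:
            col += 1
            continue
        start = col
        while col < aln.length and carrier(col) == fam:
            col += 1
        anchor = sum(1 for c in ref[:start] if c not in GAP_CHARS)
        consensus = "".join(_majority(aln.column(c, ids[fam])) for c in range(start, col))
        events.append(InsertionEvent(fam, anchor, col - start, consensus, start))
    return events


def _majority(residues: Sequence[str]) -> str:
    counts: dict[str, int] = {}
    for res in residues:
        if res not in GAP_CHARS:
            counts[res] = counts.get(res, 0) + 1
    return min(counts, key=lambda r: (-counts[r], r))


def pairwise_identity(seq_a: str, seq_b: str, aln: LabeledAlignment) -> int:
    """Percent identity over jointly non-gap columns, rounded to nearest int.

    The denominator is the number of columns where *both* sequences carry a
    residue; identical residues in those columns form the numerator.
    """
    sa, sb = aln.sequence(seq_a), aln.sequence(seq_b)
    joint = ident = 0
    for ca, cb in zip(sa, sb):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        joint += 1
        if ca == cb:
            ident += 1
    if joint == 0:
        raise ValueError(f"{seq_a!r} and {seq_b!r} share no jointly aligned columns")
    return round(100 * ident / joint)


# ---------------------------------------------------------------------------
# tabular output

def positions_to_frame(
    positions: Sequence[DiscriminatingPosition],
    subfamily_a: str = "A",
    subfamily_b: str = "B",
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "column": p.column,
                "ref_position": p.ref_position,
                f"residue_{subfamily_a}": p.residue_a,
                f"residue_{subfamily_b}": p.residue_b,
            }
            for p in positions
        ],
        columns=["column", "ref_position", f"residue_{subfamily_a}", f"residue_{subfamily_b}"],
    )


def insertions_to_frame(insertions: Sequence[InsertionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subfamily": e.subfamily,
                "anchor": e.anchor_ref_position,
                "length": e.length,
                "consensus": e.consensus,
                "start_column": e.start_column,
            }
            for e in insertions
        ],
        columns=["subfamily", "anchor", "length", "consensus", "start_column"],
    )


def write_positions(positions: Sequence[DiscriminatingPosition], path: str | Path, **kw) -> None:
    path = Path(path)
    frame = positions_to_frame(positions, **kw)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        frame.to_csv(path, sep="\t", index=False)


def write_insertions(insertions: Sequence[InsertionEvent], path: str | Path) -> None:
    path = Path(path)
    frame = insertions_to_frame(insertions)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        frame.to_csv(path, sep="\t", index=False)
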