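"""Terminability scan of annotated mitochondrial genomes.

Vertebrate mitochondria translate with genetic code table 2: UGA encodes
tryptophan, leaving UAA and UAG as the only stop codons a canonical
mitochondrial release factor (mtRF1a) reads directly.  Two further routes
can still terminate a protein-coding gene with those factors:

* **−1 frameshift**: a CDS ending in AGA or AGG that is preceded by a U can
  present UAG in the A-site after a one-nucleotide backward shift of the
  ribosome (U | AGA -> UAG; U | AGG -> UAG).
* **polyadenylation completion**: vertebrate mitochondrial mRNAs ending in
  an incomplete stop (U or UA at the annotated 3' end) are completed to UAA
  by polyadenylation of the transcript.

:func:`classify_termination` applies these rules in fixed priority order to
one gene; :func:`scan_genome` aggregates a per-gene report and the verdict
of whether *every* CDS is terminable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MitoGene",
    "TerminationCall",
    "GenomeScan",
    "MitogenomeFormatError",
    "read_mitogenome",
    "classify_termination",
    "scan_genome",
    "scan_to_frame",
    "STANDARD_STOPS",
    "FRAMESHIFT_STOPS",
]

STANDARD_STOPS = frozenset({"UAA", "UAG"})
FRAMESHIFT_STOPS = frozenset({"AGA", "AGG"})
_CLASSES = ("standard", "frameshift_terminable", "polyA_completed", "not_terminable")


class MitogenomeFormatError(ValueError):
    """Raised for unusable GenBank input."""


@dataclass(frozen=True)
class MitoGene:
    """A protein-coding mitochondrial gene with its spliced, strand-corrected
    coding sequence (DNA alphabet, 5'->3')."""

    name: str
    strand: str  # '+' or '-'
    coding_sequence: str
    location: str = ""

    def __post_init__(self) -> None:
        if not self.coding_sequence:
            raise MitogenomeFormatError(f"{self.name}: empty coding sequence")
        if self.strand not in "+-":
            raise MitogenomeFormatError(f"{self.name}: bad strand {self.strand!r}")
        bad = set(self.coding_sequence.upper()) - set("ACGTN")
        if bad:
            raise MitogenomeFormatError(f"{self.name}: non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class TerminationCall:
    """Per-gene terminability classification (RNA alphabet in the report)."""

    gene: str
    terminal_codon: str
    preceding_base: str
    call: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.call not in _CLASSES:
            raise ValueError(f"unknown class {self.call!r}")
        if self.call == "standard" and self.terminal_codon not in STANDARD_STOPS:
            raise ValueError("standard call requires a UAA/UAG terminus")
        if self.call == "frameshift_terminable" and not (
            self.terminal_codon in FRAMESHIFT_STOPS and self.preceding_base == "U"
        ):
            raise ValueError("frameshift call requires U-preceded AGA/AGG")
        if self.call == "polyA_completed" and self.terminal_codon not in ("U", "UA"):
            raise ValueError("polyA call requires a U/UA incomplete terminus")


@dataclass(frozen=True)
class GenomeScan:
    genome_id: str
    calls: tuple[TerminationCall, ...]
    all_terminable: bool


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_mitogenome(path: str | Path) -> tuple[SeqRecord, list[MitoGene]]:
    """Read a GenBank flat file and extract spliced coding sequences of all
    non-pseudo CDS features.

    join/complement locations, including circular origin-spanning joins, are
    resolved by Biopython's feature extraction; pseudogenes are excluded.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise MitogenomeFormatError(f"cannot parse {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise MitogenomeFormatError(f"{path}: missing sequence block")
    genes: list[MitoGene] = []
    for feature in record.features:
        if feature.type != "CDS":
            continue
        if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
            continue
        if int(feature.location.end) > len(record.seq):
            raise MitogenomeFormatError(
                f"{path}: feature end {int(feature.location.end)} beyond sequence "
                f"length {len(record.seq)}"
            )
        name = (
            feature.qualifiers.get("gene", [None])[0]
            or feature.qualifiers.get("locus_tag", [None])[0]
            or feature.qualifiers.get("product", ["CDS"])[0]
        )
        coding = str(feature.extract(record.seq)).upper()
        strand = "+" if (feature.location.strand or 1) >= 0 else "-"
        genes.append(MitoGene(name, strand, coding, location=str(feature.location)))
    return record, genes


def classify_termination(gene: MitoGene, polyA_completion: bool = True) -> TerminationCall:
    """Classify one gene terminus; exactly one class applies.

    Decision order: (1) UAA/UAG terminus -> ``standard``; (2) AGA/AGG
    terminus with U immediately 5' -> ``frameshift_terminable``; (3) with
    ``polyA_completion`` on, a CDS whose length mod 3 is 1 or 2 ending in
    U or UA -> ``polyA_completed``; (4) otherwise ``not_terminable``.
    """
    seq = _to_rna(gene.coding_sequence)
    if len(seq) < 4:
        raise MitogenomeFormatError(
            f"{gene.name}: coding sequence too short to read terminus"
        )
    remainder = len(seq) % 3
    if remainder == 0:
        codon, preceding = seq[-3:], seq[-4]
        if codon in STANDARD_STOPS:
            return TerminationCall(gene.name, codon, preceding, "standard")
        if codon in FRAMESHIFT_STOPS and preceding == "U":
            shifted = preceding + codon[:2]
            return TerminationCall(
                gene.name, codon, preceding, "frameshift_terminable",
                note=f"-1 shift presents {shifted}",
            )
        note = "UGA read as Trp in the vertebrate mitochondrial code" if codon == "UGA" else ""
        return TerminationCall(gene.name, codon, preceding, "not_terminable", note=note)
    terminus = seq[-remainder:]
    preceding = seq[-remainder - 1]
    if terminus in ("U", "UA"):
        if polyA_completion:
            return TerminationCall(
                gene.name, terminus, preceding, "polyA_completed",
                note="completed to UAA by polyadenylation",
            )
        return TerminationCall(
            gene.name, terminus, preceding, "not_terminable",
            note="incomplete stop; polyA completion disabled",
        )
    return TerminationCall(
        gene.name, terminus, preceding, "not_terminable",
        note="out-of-frame terminus is not an incomplete stop",
    )


def scan_genome(
    genes: list[MitoGene],
    genome_id: str = "",
    polyA_completion: bool = True,
) -> GenomeScan:
    """Classify every gene; the genome verdict is the AND over genes of
    (class != not_terminable)."""
    if not genes:
        raise MitogenomeFormatError("no CDS features to scan")
    calls = tuple(classify_termination(g, polyA_completion) for g in genes)
    return GenomeScan(
        genome_id=genome_id,
        calls=calls,
        all_terminable=all(c.call != "not_terminable" for c in calls),
    )


def scan_to_frame(scan: GenomeScan, genes: list[MitoGene] | None = None) -> pd.DataFrame:
    strands = {g.name: g.strand for g in genes} if genes else {}
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "strand": strands.get(c.gene, ""),
                "terminal_codon": c.terminal_codon,
                "preceding_base": c.preceding_base,
                "class": c.call,
                "note": c.note,
            }
            for c in scan.calls
        ]
    )
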