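#!/usr/bin/env python
"""Fetch the small external reference inputs used by the published-number
acceptance tests (network access required; nothing is fetched implicitly by
the package itself).

Populates ``data/external/`` with:

* ``NC_012920.gb`` — human reference mitochondrial genome (NCBI efetch).
* ``rf1_trio.fasta`` — human mtRF1 (UniProt O75570), human mtRF1a
  (UniProt Q9UGC7) and Thermus thermophilus HB8 RF1 (UniProt gene prfA,
  organism 300852), renamed to mtRF1_HUMAN / mtRF1a_HUMAN / RF1_THET8.
* ``3mr8_excerpt.pdb`` — from PDB entry 3MR8 (T. thermophilus 70S
  termination complex): the release-factor chain's residues 280-310 plus
  16S rRNA residues 1485-1498 and 23S helix-69 residues 1910-1918.
* ``mtrf_families.fasta`` / ``mtrf_families_labels.tsv`` — mtRF1 (gene
  MTRF1) and mtRF1a (gene MTRF1L) orthologs for the 17 vertebrate species
  of the original dataset, fetched from UniProt, aligned with mafft
  together with the RF1 reference.  Ortholog retrieval by gene symbol is a
  best effort; inspect the result before trusting it.
* ``table_s1_positions.tsv`` — cannot be scraped reliably: copy the
  reference positions of the published supplementary residue table into a
  one-position-per-line TSV by hand (instructions printed).
"""

from __future__ import annotations

import subprocess
import sys
import urllib.parse
import urllib.request
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "data" / "external"

SPECIES = {
    "Tetraodon nigroviridis": 99883,
    "Platichthys flesus": 8260,
    "Danio rerio": 7955,
    "Gallus gallus": 9031,
    "Taeniopygia guttata": 59729,
    "Ornithorhynchus anatinus": 9258,
    "Monodelphis domestica": 13616,
    "Mus musculus": 10090,
    "Rattus norvegicus": 10116,
    "Homo sapiens": 9606,
    "Pan troglodytes": 9598,
    "Macaca mulatta": 9544,
    "Ailuropoda melanoleuca": 9646,
    "Bos taurus": 9913,
    "Canis familiaris": 9615,
    "Equus caballus": 9796,
    "Sus scrofa": 9823,
}


def get(url: str) -> bytes:
    print(f"  GET {url}", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def fetch_human_mitogenome() -> None:
    url = (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        "?db=nuccore&id=NC_012920.1&rettype=gb&retmode=text"
    )
    (OUT / "NC_012920.gb").write_bytes(get(url))


def uniprot_fasta(query: str) -> str:
    url = (
        "https://rest.uniprot.org/uniprotkb/search?format=fasta&size=1&query="
        + urllib.parse.quote(query)
    )
    return get(url).decode()


def rename_fasta(fasta: str, name: str) -> str:
    lines = fasta.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise RuntimeError(f"no sequence returned for {name}")
    return ">" + name + "\n" + "\n".join(lines[1:]) + "\n"


def fetch_rf1_trio() -> None:
    parts = [
        rename_fasta(uniprot_fasta("accession:O75570"), "mtRF1_HUMAN"),
        rename_fasta(uniprot_fasta("accession:Q9UGC7"), "mtRF1a_HUMAN"),
        rename_fasta(
            uniprot_fasta("gene:prfA AND organism_id:300852 AND reviewed:true"),
            "RF1_THET8",
        ),
    ]
    (OUT / "rf1_trio.fasta").write_text("".join(parts))


def fetch_3mr8_excerpt() -> None:
    raw = get("https://files.rcsb.org/download/3MR8.pdb").decode()
    # find the release-factor chain: a protein chain containing THR 295
    rf_chains = set()
    rrna_chain = None
    helix69_chain = None
    for line in raw.splitlines():
        if not line.startswith("ATOM"):
            continue
        res_name = line[17:20].strip()
        chain = line[21]
        res_id = line[22:26].strip()
        if res_name == "THR" and res_id == "295":
            rf_chains.add(chain)
        if res_name in ("A", "G", "C", "U"):
            if res_id == "1493":
                rrna_chain = chain
            if res_id == "1914":
                helix69_chain = chain
    if not rf_chains or rrna_chain is None:
        raise RuntimeError("could not locate RF chain or 16S chain in 3MR8")
    rf_chain = sorted(rf_chains)[0]
    keep = []
    for line in raw.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        chain = line[21]
        try:
            res_id = int(line[22:26])
        except ValueError:
            continue
        if chain == rf_chain and 280 <= res_id <= 310:
            keep.append(line)
        elif chain == rrna_chain and 1485 <= res_id <= 1498:
            keep.append(line)
        elif helix69_chain and chain == helix69_chain and 1910 <= res_id <= 1918:
            keep.append(line)
    (OUT / "3mr8_excerpt.pdb").write_text("\n".join(keep) + "\nEND\n")


def fetch_family_alignment() -> None:
    records = []
    labels = []
    for species, taxid in SPECIES.items():
        tag = species.split()[0][:3] + species.split()[1][:3]
        for gene, family in (("MTRF1", "mtRF1"), ("MTRF1L", "mtRF1a")):
            fasta = uniprot_fasta(f"gene:{gene} AND organism_id:{taxid}")
            try:
                name = f"{family}_{tag}"
                records.append(rename_fasta(fasta, name))
                labels.append(f"{name}\t{family}")
            except RuntimeError:
                print(f"  WARNING: no {gene} hit for {species}", file=sys.stderr)
    records.append(
        rename_fasta(
            uniprot_fasta("gene:prfA AND organism_id:300852 AND reviewed:true"),
            "RF1_THET8",
        )
    )
    unaligned = OUT / "mtrf_families_unaligned.fasta"
    unaligned.write_text("".join(records))
    aligned = subprocess.run(
        ["mafft", "--auto", "--anysymbol", str(unaligned)],
        capture_output=True, text=True, check=True,
    ).stdout
    (OUT / "mtrf_families.fasta").write_text(aligned)
    (OUT / "mtrf_families_labels.tsv").write_text("\n".join(labels) + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    steps = [
        ("human mitogenome", fetch_human_mitogenome),
        ("RF1/mtRF1/mtRF1a trio", fetch_rf1_trio),
        ("3MR8 excerpt", fetch_3mr8_excerpt),
        ("17-species family alignment", fetch_family_alignment),
    ]
    failures = 0
    for label, step in steps:
        print(f"fetching {label} ...", file=sys.stderr)
        try:
            step()
        except Exception as exc:  # best effort per step
            failures += 1
            print(f"  FAILED: {exc}", file=sys.stderr)
    print(
        "\nmanual step: create data/external/table_s1_positions.tsv with one\n"
        "reference position per line (24 lines) transcribed from the\n"
        "published supplementary residue table.",
        file=sys.stderr,
    )
    sys.exit(1 if failures else 0)


if __name__ == "__main__":
    main()
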