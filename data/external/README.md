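# External reference inputs

This directory is empty in a fresh checkout. The published-number
acceptance tests read small reference files from here; populate it with
`python scripts/fetch_external.py` on a machine with network access (plus
one manual transcription step for the supplementary residue table — the
script prints instructions). Expected files:

| file | content | source |
| --- | --- | --- |
| `NC_012920.gb` | human reference mitochondrial genome | NCBI nuccore |
| `rf1_trio.fasta` | human mtRF1 (O75570), human mtRF1a (Q9UGC7), T. thermophilus RF1 | UniProt |
| `3mr8_excerpt.pdb` | switch loop + decoding center excerpt of PDB 3MR8 | RCSB |
| `mtrf_families.fasta`, `mtrf_families_labels.tsv` | 17-species mtRF1/mtRF1a alignment + labels | UniProt + mafft |
| `table_s1_positions.tsv` | 24 reference positions, one per line | published supplement (manual) |

Nothing in the package reads these implicitly; they are inputs for the
reference-number tests only.
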