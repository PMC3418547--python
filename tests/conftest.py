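"""Shared fixtures: synthetic alignments, complexes and mitogenomes."""

from __future__ import annotations

import pytest

from mtrfkit import synthetic as syn


@pytest.fixture(scope="session")
def study_alignment():
    aln, manifest = syn.gen_alignment(syn.study_alignment_recipe(seed=1))
    return aln, manifest


@pytest.fixture(scope="session")
def templates():
    return syn.decoding_templates()


@pytest.fixture(scope="session")
def complexes():
    """All variant x state complexes with manifests."""
    out = {}
    for variant in ("rf1", "mtrf1"):
        for state in syn.DECODING_STATES:
            out[(variant, state)] = syn.gen_complex(
                syn.ComplexRecipe(variant=variant, state=state, seed=0)
            )
    return out


@pytest.fixture(scope="session")
def study_genome():
    record, manifest = syn.gen_mitogenome(syn.study_genome_recipe(seed=1))
    return record, manifest


@pytest.fixture
def genome_on_disk(tmp_path, study_genome):
    record, manifest = study_genome
    path = tmp_path / "mito.gb"
    syn.write_mitogenome(record, path)
    return path, manifest
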