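"""Fixture generators: determinism, manifest soundness, round-trips, validation."""

from __future__ import annotations

import pytest

from mtrfkit import alignment as al
from mtrfkit import mitoterm as mt
from mtrfkit import structure as st
from mtrfkit import synthetic as syn


class TestDeterminism:
    def test_alignment_files_byte_identical_for_same_seed(self, tmp_path):
        recipe = syn.AlignmentRecipe(n_per_subfamily=4, length=50,
                                     k_discriminating=3, seed=11)
        paths = []
        for tag in ("x", "y"):
            aln, manifest = syn.gen_alignment(recipe)
            p = tmp_path / f"{tag}.fasta"
            syn.write_alignment(aln, p)
            syn.write_manifest(manifest, tmp_path / f"{tag}.json")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "x.json").read_bytes() == (tmp_path / "y.json").read_bytes()

    def test_different_seed_changes_output(self):
        a1, _ = syn.gen_alignment(syn.AlignmentRecipe(seed=1, k_discriminating=2))
        a2, _ = syn.gen_alignment(syn.AlignmentRecipe(seed=2, k_discriminating=2))
        assert dict(a1.records) != dict(a2.records)

    def test_structure_and_genome_byte_identical(self, tmp_path):
        recipe = syn.StructureRecipe(decoding_state="recognized", seed=5)
        for tag in ("x", "y"):
            model, _ = syn.gen_structure(recipe)
            st.write_structure(model, tmp_path / f"{tag}.pdb")
            record, _ = syn.gen_mitogenome(syn.study_genome_recipe(5))
            syn.write_mitogenome(record, tmp_path / f"{tag}.gb")
        assert (tmp_path / "x.pdb").read_bytes() == (tmp_path / "y.pdb").read_bytes()
        assert (tmp_path / "x.gb").read_bytes() == (tmp_path / "y.gb").read_bytes()


class TestAlignmentGenerator:
    def test_zero_planted_zero_detected(self):
        aln, manifest = syn.gen_alignment(
            syn.AlignmentRecipe(n_per_subfamily=5, length=50, k_discriminating=0, seed=1)
        )
        assert manifest["discriminating"] == []
        assert al.detect_discriminating_positions(aln) == []

    def test_manifest_lists_planted_columns_and_detector_recovers(self):
        aln, manifest = syn.gen_alignment(
            syn.AlignmentRecipe(n_per_subfamily=8, length=120, k_discriminating=5, seed=7)
        )
        assert len(manifest["discriminating"]) == 5
        found = al.detect_discriminating_positions(aln)
        assert [p.column for p in found] == [d["column"] for d in manifest["discriminating"]]

    def test_insertion_block_all_gap_in_other_family(self):
        recipe = syn.AlignmentRecipe(
            n_per_subfamily=4, length=130,
            insertions=(syn.InsertionSpec(115, 2, "A"),), seed=0,
        )
        aln, manifest = syn.gen_alignment(recipe)
        for rid in aln.members("B"):
            assert aln.sequence(rid)[116:118] == "--"
        for rid in aln.members("A"):
            assert "-" not in aln.sequence(rid)[116:118]
        assert manifest["insertions"][0]["length"] == 2

    def test_invalid_recipes_rejected(self):
        with pytest.raises(syn.RecipeError):
            syn.gen_alignment(syn.AlignmentRecipe(n_per_subfamily=1))
        with pytest.raises(syn.RecipeError):
            syn.gen_alignment(syn.AlignmentRecipe(length=10, k_discriminating=11))
        with pytest.raises(syn.RecipeError):
            syn.gen_alignment(syn.AlignmentRecipe(
                length=20,
                insertions=(syn.InsertionSpec(5, 3, "A"), syn.InsertionSpec(6, 2, "B")),
            ))
        with pytest.raises(syn.RecipeError):
            syn.gen_alignment(syn.AlignmentRecipe(background_conservation=1.5))

    def test_round_trip_write_read_idempotent(self, tmp_path, study_alignment):
        aln, _ = study_alignment
        p1, p2 = tmp_path / "a1.fasta", tmp_path / "a2.fasta"
        labels = tmp_path / "labels.tsv"
        syn.write_alignment(aln, p1)
        syn.write_label_map(aln, labels)
        back = al.read_labeled_alignment(p1, labels, reference_id=aln.reference_id)
        syn.write_alignment(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestStructureGenerator:
    def test_planted_bond_detected_exactly(self):
        recipe = syn.StructureRecipe(planted_hbonds=(
            (syn.AtomSpec("A", 1, "ALA", "N", "N"),
             syn.AtomSpec("A", 3, "ALA", "O", "O"), 2.9, None),
        ))
        model, manifest = syn.gen_structure(recipe)
        bonds = st.detect_hbonds(model, model, model)
        assert [(b.donor, b.acceptor) for b in bonds] == [("A:1:N", "A:3:O")]
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-3)
        assert manifest["hbonds"][0]["distance"] == 2.9

    def test_empty_recipe_yields_valid_interaction_free_file(self, tmp_path):
        model, manifest = syn.gen_structure(syn.StructureRecipe())
        path = tmp_path / "empty.pdb"
        st.write_structure(model, path)
        back = st.read_structure(path)
        assert len(back) >= 1
        assert manifest["hbonds"] == [] and manifest["clashes"] == []

    def test_planted_geometry_reproduced_after_file_round_trip(self, tmp_path):
        recipe = syn.StructureRecipe(
            planted_hbonds=(
                (syn.AtomSpec("A", 1, "THR", "OG1", "O"),
                 syn.AtomSpec("A", 4, "GLU", "OE1", "O"), 3.2, None),
            ),
            planted_clashes=(
                (syn.AtomSpec("B", 1, "ALA", "CB", "C"),
                 syn.AtomSpec("B", 5, "ALA", "CB", "C"), 1.0),
            ),
        )
        model, _ = syn.gen_structure(recipe)
        path = tmp_path / "m.pdb"
        st.write_structure(model, path)
        back = st.read_structure(path)
        bonds = st.detect_hbonds(back, back, back)
        clashes = st.detect_clashes(back, back, back)
        assert bonds[0].distance == pytest.approx(3.2, abs=1e-3)
        assert clashes[0].overlap == pytest.approx(1.0, abs=1e-3)

    def test_unsatisfiable_recipes_rejected(self):
        donor = syn.AtomSpec("A", 1, "ALA", "N", "N")
        acceptor = syn.AtomSpec("A", 3, "ALA", "O", "O")
        with pytest.raises(syn.RecipeError):  # distance outside window
            syn.StructureRecipe(planted_hbonds=((donor, acceptor, 5.0, None),)).validate()
        with pytest.raises(syn.RecipeError):  # overlap below severe threshold
            syn.StructureRecipe(planted_clashes=((donor, acceptor, 0.1),)).validate()
        with pytest.raises(syn.RecipeError):  # bond and clash on same pair
            syn.StructureRecipe(
                planted_hbonds=((donor, acceptor, 2.9, None),),
                planted_clashes=((donor, acceptor, 1.0),),
            ).validate()
        with pytest.raises(syn.RecipeError):  # carbon is not a donor
            syn.StructureRecipe(planted_hbonds=(
                (syn.AtomSpec("A", 1, "ALA", "CB", "C"), acceptor, 2.9, None),
            )).validate()

    def test_soundness_no_extra_interactions(self):
        """Detectors find exactly the manifest entries, nothing else."""
        recipe = syn.StructureRecipe(
            planted_hbonds=(
                (syn.AtomSpec("A", 1, "LYS", "NZ", "N"),
                 syn.AtomSpec("A", 5, "ASP", "OD1", "O"), 2.8, None),
                (syn.AtomSpec("B", 2, "SER", "OG", "O"),
                 syn.AtomSpec("B", 9, "GLN", "OE1", "O"), 3.4, None),
            ),
            planted_clashes=(
                (syn.AtomSpec("C", 1, "ALA", "CB", "C"),
                 syn.AtomSpec("C", 7, "LYS", "NZ", "N"), 0.8),
            ),
            decoding_state="stacked",
        )
        model, manifest = syn.gen_structure(recipe)
        bonds = {(b.donor, b.acceptor) for b in st.detect_hbonds(model, model, model)}
        clashes = {tuple(sorted((c.atom_a, c.atom_b)))
                   for c in st.detect_clashes(model, model, model)}
        assert bonds == {(h["donor"], h["acceptor"]) for h in manifest["hbonds"]}
        assert clashes == {
            tuple(sorted((c["atom_a"], c["atom_b"]))) for c in manifest["clashes"]
        }


class TestGenomeGenerator:
    def test_thirteen_genes_round_trip(self, genome_on_disk):
        path, manifest = genome_on_disk
        record, genes = mt.read_mitogenome(path)
        assert len(genes) == 13
        assert {g.name for g in genes} == {g["name"] for g in manifest["genes"]}

    def test_each_gene_ends_with_requested_terminus(self, genome_on_disk):
        path, manifest = genome_on_disk
        _, genes = mt.read_mitogenome(path)
        by_name = {g.name: g for g in genes}
        for planted in manifest["genes"]:
            gene = by_name[planted["name"]]
            assert gene.coding_sequence.endswith(planted["terminal"])
            terminal_len = len(planted["terminal"])
            assert gene.coding_sequence[-terminal_len - 1] == planted["preceding_base"]

    def test_minus_strand_gene_reverse_complemented(self, genome_on_disk):
        path, _ = genome_on_disk
        _, genes = mt.read_mitogenome(path)
        nd6 = next(g for g in genes if g.name == "ND6")
        assert nd6.strand == "-"
        assert nd6.coding_sequence.startswith("ATG")
        assert nd6.coding_sequence.endswith("AGG")

    def test_origin_spanning_cds_contiguous(self, tmp_path):
        recipe = syn.GenomeRecipe(
            genes=(syn.GeneSpec("WRAP", 1, "TAA", "A"),
                   syn.GeneSpec("PLAIN", 1, "TAG", "C")),
            circular=True, origin_span="WRAP", seed=4,
        )
        record, manifest = syn.gen_mitogenome(recipe)
        path = tmp_path / "wrap.gb"
        syn.write_mitogenome(record, path)
        _, genes = mt.read_mitogenome(path)
        wrap = next(g for g in genes if g.name == "WRAP")
        assert wrap.coding_sequence.startswith("ATG")
        assert wrap.coding_sequence.endswith("TAA")
        assert manifest["genes"][0]["location"].startswith("join(")

    def test_pseudogene_excluded_by_reader(self, tmp_path):
        recipe = syn.GenomeRecipe(genes=(
            syn.GeneSpec("REAL", 1, "TAA", "A"),
            syn.GeneSpec("FAKE", 1, "TGA", "C", pseudo=True),
            syn.GeneSpec("REAL2", 1, "TAG", "G"),
        ), seed=0)
        record, _ = syn.gen_mitogenome(recipe)
        path = tmp_path / "ps.gb"
        syn.write_mitogenome(record, path)
        _, genes = mt.read_mitogenome(path)
        assert {g.name for g in genes} == {"REAL", "REAL2"}

    def test_invalid_recipes_rejected(self):
        with pytest.raises(syn.RecipeError):
            syn.GenomeRecipe(genes=()).validate()
        with pytest.raises(syn.RecipeError):
            syn.GenomeRecipe(genes=(syn.GeneSpec("X", 1, "XYZ", "A"),)).validate()
        with pytest.raises(syn.RecipeError):
            syn.GenomeRecipe(genes=(syn.GeneSpec("X", 1, "TAA", "Q"),)).validate()
        with pytest.raises(syn.RecipeError):
            syn.GenomeRecipe(
                genes=(syn.GeneSpec("X", -1, "TAA", "A"),),
                origin_span="X",
            ).validate()


class TestComplexGenerator:
    def test_recognized_state_plants_the_reported_geometry(self, complexes):
        model, manifest = complexes[("rf1", "recognized")]
        assert manifest["thr295_a1493_min_distance"] == 3.7
        assert st.min_distance(model, "R:295:O", "A:1493") == pytest.approx(3.7, abs=1e-6)

    def test_planted_bonds_all_detected(self, complexes):
        for (variant, state), (model, manifest) in complexes.items():
            bonds = {(b.donor, b.acceptor)
                     for b in st.detect_hbonds(model, model, model)}
            for planted in manifest["hbonds"]:
                assert (planted["donor"], planted["acceptor"]) in bonds, (variant, state)

    def test_insert_arginine_only_in_mtrf1(self, complexes):
        mtrf1, _ = complexes[("mtrf1", "stacked")]
        rf1, _ = complexes[("rf1", "stacked")]
        assert mtrf1.try_select("R:115A") is not None
        assert rf1.try_select("R:115A") is None
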