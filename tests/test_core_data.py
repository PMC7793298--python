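"""Gut-content standardization: parsing, crosswalk, filtering, diet matrix."""

import numpy as np
import pandas as pd
import pytest

from trophoguild import core_data
from trophoguild.core_data import (PREY_GROUPS, PreyCrosswalk, SchemaError,
                                   ValidationError, apply_crosswalk,
                                   build_diet_matrix, filter_min_guts,
                                   read_gut_contents)


class TestReadGutContents:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,location,prey_item,value\n"
                     "i1,spA,loc1,shrimp,0.6\ni1,spA,loc1,algae,0.4\n")
        rec = read_gut_contents(p)
        assert len(rec) == 2
        assert rec["individual_id"].nunique() == 1
        assert rec["value"].sum() == pytest.approx(1.0)

    def test_percent_dialect_rescales(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,location,prey_item,value\n"
                     "i1,spA,loc1,shrimp,60\ni1,spA,loc1,algae,40\n")
        rec = read_gut_contents(p, dialect={"percent": True})
        assert sorted(rec["value"]) == [pytest.approx(0.4), pytest.approx(0.6)]

    def test_column_mapping_dialect(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("fish_id\tsp\tsite\titem\tprop\ni1\tspA\tloc1\tshrimp\t0.5\n")
        rec = read_gut_contents(p, dialect={
            "sep": "\t",
            "columns": {"individual_id": "fish_id", "species": "sp",
                        "location": "site", "prey_item": "item",
                        "value": "prop"}})
        assert rec.loc[0, "species"] == "spA"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,location,prey_item,value\n")
        with pytest.raises(SchemaError, match="empty"):
            read_gut_contents(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,prey_item,value\ni1,spA,x,0.5\n")
        with pytest.raises(SchemaError, match="location"):
            read_gut_contents(p)

    def test_negative_value_errors_with_row(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,location,prey_item,value\n"
                     "i1,spA,loc1,shrimp,-0.2\n")
        with pytest.raises(ValidationError, match="row"):
            read_gut_contents(p)


class TestCrosswalk:
    def test_split_label_divided_equally(self):
        rec = pd.DataFrame(
            [("i1", "spA", "loc1", "Algae & Detritus", 0.40)],
            columns=list(core_data.GUT_RECORD_COLUMNS))
        xw = PreyCrosswalk(mapping={"Algae & Detritus": [
            ("detritus", 0.5), ("benthic autotroph", 0.5)]})
        out = apply_crosswalk(rec, xw)
        got = dict(zip(out["prey_item"], out["value"]))
        assert got == {"detritus": pytest.approx(0.20),
                       "benthic autotroph": pytest.approx(0.20)}

    def test_one_to_one_and_discard(self):
        rec = pd.DataFrame(
            [("i1", "spA", "loc1", "shrimp", 0.6),
             ("i1", "spA", "loc1", "unidentified fragments", 0.1)],
            columns=list(core_data.GUT_RECORD_COLUMNS))
        xw = PreyCrosswalk(mapping={"shrimp": [("Decapoda", 1.0)]},
                           discard={"unidentified fragments"})
        out = apply_crosswalk(rec, xw)
        assert list(out["prey_item"]) == ["Decapoda"]
        assert out["value"].iloc[0] == pytest.approx(0.6)

    def test_unmapped_label_listed(self):
        rec = pd.DataFrame([("i1", "spA", "loc1", "mystery", 0.6)],
                           columns=list(core_data.GUT_RECORD_COLUMNS))
        with pytest.raises(ValidationError, match="mystery"):
            apply_crosswalk(rec, PreyCrosswalk(mapping={}))

    def test_value_conservation_outside_discards(self, gut_records):
        xw = PreyCrosswalk.identity()
        xw.mapping["Decapoda"] = [("Decapoda", 0.5), ("Stomatopoda", 0.5)]
        out = apply_crosswalk(gut_records, xw)
        before = gut_records.groupby("individual_id")["value"].sum()
        after = out.groupby("individual_id")["value"].sum()
        pd.testing.assert_series_equal(before, after, check_like=True)

    def test_non_canonical_target_rejected(self):
        with pytest.raises(ValidationError, match="canonical"):
            PreyCrosswalk(mapping={"x": [("NotAGroup", 1.0)]})

    def test_split_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            PreyCrosswalk(mapping={"x": [("Decapoda", 0.5),
                                         ("Stomatopoda", 0.2)]})

    def test_read_write_roundtrip(self, tmp_path):
        xw = PreyCrosswalk(
            mapping={"shrimp": [("Decapoda", 1.0)],
                     "Algae & Detritus": [("detritus", 0.5),
                                          ("benthic autotroph", 0.5)]},
            discard={"junk"})
        path = tmp_path / "xw.csv"
        xw.write(path)
        back = PreyCrosswalk.read(path)
        assert back.discard == {"junk"}
        assert dict(back.mapping["Algae & Detritus"]) == {
            "detritus": 0.5, "benthic autotroph": 0.5}


class TestFilterMinGuts:
    def test_threshold_rule(self):
        rows = [(f"a{i}", "spA", "l", "Decapoda", 1.0) for i in range(12)]
        rows += [(f"b{i}", "spB", "l", "Decapoda", 1.0) for i in range(9)]
        rec = pd.DataFrame(rows, columns=list(core_data.GUT_RECORD_COLUMNS))
        out = filter_min_guts(rec, min_guts=10)
        assert set(out["species"]) == {"spA"}

    def test_min_guts_one_is_identity(self, gut_records):
        out = filter_min_guts(gut_records, min_guts=1)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), gut_records.reset_index(drop=True))

    def test_all_below_threshold_gives_empty(self, gut_records):
        out = filter_min_guts(gut_records, min_guts=5)
        assert out.empty

    def test_min_guts_below_one_rejected(self, gut_records):
        with pytest.raises(ValueError):
            filter_min_guts(gut_records, min_guts=0)


class TestDietMatrix:
    def test_single_individual_row(self):
        rec = pd.DataFrame(
            [("i1", "spA", "l", "Decapoda", 0.6),
             ("i1", "spA", "l", "benthic autotroph", 0.4)],
            columns=list(core_data.GUT_RECORD_COLUMNS))
        diet = build_diet_matrix(rec)
        assert diet.matrix.at["spA", "Decapoda"] == pytest.approx(0.6)
        assert diet.matrix.at["spA", "benthic autotroph"] == pytest.approx(0.4)

    def test_equal_weight_average_of_renormalized_individuals(self):
        # (1.0 Decapoda) and (0.5 Decapoda, 0.5 Actinopterygii) -> (0.75, 0.25)
        rec = pd.DataFrame(
            [("i1", "spA", "l", "Decapoda", 1.0),
             ("i2", "spA", "l", "Decapoda", 0.5),
             ("i2", "spA", "l", "Actinopterygii", 0.5)],
            columns=list(core_data.GUT_RECORD_COLUMNS))
        diet = build_diet_matrix(rec)
        assert diet.matrix.at["spA", "Decapoda"] == pytest.approx(0.75)
        assert diet.matrix.at["spA", "Actinopterygii"] == pytest.approx(0.25)

    def test_by_location_keys_nodes(self, gut_records):
        rec = gut_records.copy()
        rec.loc[rec["individual_id"] == "i2", "location"] = "loc9"
        diet = build_diet_matrix(rec, by_location=True)
        assert "spA@loc1" in diet.consumers and "spA@loc9" in diet.consumers

    def test_row_sums_one_on_synthetic_inputs(self):
        from trophoguild import synthetic_data as sd
        tree = sd.simulate_tree(12, seed=5)
        trait = sd.simulate_clade_guilds(tree, 3)
        rec = sd.simulate_diets(trait, sd.default_guild_profiles(3),
                                guts_per_species=(3, 6), seed=6)
        diet = build_diet_matrix(rec)
        assert np.abs(diet.matrix.sum(axis=1) - 1.0).max() < 1e-9

    def test_empty_gut_excluded(self, gut_records):
        rec = pd.concat([gut_records, pd.DataFrame(
            [("i9", "spA", "loc1", "Decapoda", 0.0)],
            columns=list(core_data.GUT_RECORD_COLUMNS))], ignore_index=True)
        diet = build_diet_matrix(rec)
        assert diet.meta.at["spA", "n_guts"] == 2

    def test_non_crosswalked_labels_rejected(self):
        rec = pd.DataFrame([("i1", "spA", "l", "shrimp", 1.0)],
                           columns=list(core_data.GUT_RECORD_COLUMNS))
        with pytest.raises(ValidationError, match="crosswalk"):
            build_diet_matrix(rec)

    def test_write_read_roundtrip(self, gut_records, tmp_path):
        diet = build_diet_matrix(gut_records, by_location=True)
        path = tmp_path / "diet.csv"
        diet.write(path)
        back = core_data.read_diet_matrix(path)
        pd.testing.assert_frame_equal(back.matrix, diet.matrix)
        assert list(back.meta["n_guts"]) == list(diet.meta["n_guts"])


class TestTrees:
    def test_parse_and_patristic(self, small_tree):
        from trophoguild._phylo import PhyloArrays
        arr = PhyloArrays.from_dendropy(small_tree)
        d = pd.DataFrame(arr.patristic_distances(), index=arr.labels,
                         columns=arr.labels)
        assert d.at["A", "B"] == pytest.approx(2.0)
        assert d.at["A", "C"] == pytest.approx(4.0)

    def test_prune_preserves_distances(self, small_tree):
        from trophoguild._phylo import PhyloArrays
        pruned = core_data.prune_to(small_tree, ["A", "C"])
        arr = PhyloArrays.from_dendropy(pruned)
        d = pd.DataFrame(arr.patristic_distances(), index=arr.labels,
                         columns=arr.labels)
        assert d.at["A", "C"] == pytest.approx(4.0)

    def test_prune_missing_species_listed(self, small_tree):
        with pytest.raises(ValueError, match="spZ"):
            core_data.prune_to(small_tree, ["A", "spZ"])

    def test_malformed_newick_errors(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1:2;")
        with pytest.raises(Exception):
            core_data.read_tree(p)

    def test_multi_tree_file(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n((A:2,C:2):1,B:3);\n")
        trees = core_data.read_trees(p)
        assert len(trees) == 2


def test_gut_record_roundtrip(gut_records, tmp_path):
    path = tmp_path / "rec.csv"
    core_data.write_gut_records(gut_records, path)
    back = read_gut_contents(path)
    pd.testing.assert_frame_equal(back, gut_records)


def test_prey_group_catalog_is_canonical():
    assert len(PREY_GROUPS) == 38
    assert len(set(PREY_GROUPS)) == 38


def test_species_attributes_validation(tmp_path):
    p = tmp_path / "attrs.csv"
    p.write_text("species,max_size_cm,family\nspA,-3,F1\n")
    with pytest.raises(ValidationError):
        core_data.read_species_attributes(p)
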