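import numpy as np
import pytest

from regset.data_model import AnnotationDatabase, InputList, Interactome, Universe
from regset.id_mapping import (
    MirnaMap,
    convert_mirna_ids,
    project_to_targets,
    qc_report,
    read_mirna_map,
    transform_db_to_mirnas,
)


@pytest.fixture
def small_map() -> MirnaMap:
    return MirnaMap.from_pairs([
        ("P1", "P1-3p"), ("P1", "P1-5p"),
        ("P2", "P2-5p"),
    ])


class TestConvertMirnaIds:
    def test_precursor_expands_to_matures(self, small_map):
        expanded, unmapped = convert_mirna_ids(["P1"], small_map)
        assert expanded == ["P1", "P1-3p", "P1-5p"] and unmapped == []

    def test_mature_gains_precursor(self, small_map):
        expanded, _ = convert_mirna_ids(["P2-5p"], small_map)
        assert expanded == ["P2-5p", "P2"]

    def test_complete_list_unchanged(self, small_map):
        ids = ["P1", "P1-3p", "P1-5p"]
        assert convert_mirna_ids(ids, small_map)[0] == ids

    def test_idempotent(self, small_map):
        once, _ = convert_mirna_ids(["P1", "P2-5p"], small_map)
        twice, _ = convert_mirna_ids(once, small_map)
        assert twice == once

    def test_unknown_id_kept_and_flagged(self, small_map):
        expanded, unmapped = convert_mirna_ids(["P1", "oddball"], small_map)
        assert "oddball" in expanded and unmapped == ["oddball"]

    def test_arrhythmia_precursor_list_gains_all_mature_forms(self):
        # use-case input: eight arrhythmia-associated precursors (the miR-1
        # family covering both mir-1-1 and mir-1-2), fixture map with the
        # standard -5p/-3p arms
        precursors = [
            "hsa-mir-1-1", "hsa-mir-1-2", "hsa-mir-133a-1", "hsa-mir-133a-2",
            "hsa-mir-133b", "hsa-mir-328", "hsa-mir-212", "hsa-mir-208a",
        ]
        pairs = []
        for p in precursors:
            stem = p.replace("mir", "miR")
            pairs += [(p, f"{stem}-5p"), (p, f"{stem}-3p")]
        expanded, unmapped = convert_mirna_ids(precursors, MirnaMap.from_pairs(pairs))
        assert unmapped == []
        assert expanded[: len(precursors)] == precursors
        for p in precursors:
            assert p.replace("mir", "miR") + "-5p" in expanded
            assert p.replace("mir", "miR") + "-3p" in expanded

    def test_map_inverse_consistency_enforced(self):
        with pytest.raises(ValueError):
            MirnaMap(precursor_to_mature={"P": frozenset({"m"})}, mature_to_precursor={})

    def test_read_map_roundtrip(self, tmp_path):
        f = tmp_path / "map.tsv"
        f.write_text("#pre\tmat\nP1\tP1-5p\nP1\tP1-3p\n")
        mm = read_mirna_map(f)
        assert mm.precursor_to_mature["P1"] == {"P1-5p", "P1-3p"}


class TestProjectToTargets:
    def _input(self, ids, interactome):
        return InputList.from_ids(ids, "mirna", known=interactome.regulators())

    def test_union_of_targets_with_provenance(self):
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1"), ("m2", "g1"), ("m2", "g2")}))
        proj = project_to_targets(self._input(["m1", "m2"], i), i)
        assert proj.target_genes == {"g1", "g2"}
        assert proj.contributing["g1"] == {"m1", "m2"}
        assert proj.contributing["g2"] == {"m2"}

    def test_unmapped_only_input_is_an_error(self):
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1")}))
        with pytest.raises(ValueError, match="empty target set"):
            project_to_targets(self._input(["m3"], i), i)

    def test_duplicate_input_regulator_is_idempotent(self):
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1")}))
        once = project_to_targets(self._input(["m1"], i), i)
        twice = project_to_targets(self._input(["m1", "m1"], i), i)
        assert once.target_genes == twice.target_genes

    def test_kind_mismatch_rejected(self, toy_interactome):
        il = InputList.from_ids(["m1"], "tf", known={"m1"})
        with pytest.raises(ValueError, match="kind"):
            project_to_targets(il, toy_interactome)

    def test_target_count_bounded_by_total_out_degree(self, toy_interactome):
        il = InputList.from_ids(["m1", "m2"], "mirna", known=toy_interactome.regulators())
        proj = project_to_targets(il, toy_interactome)
        total = sum(len(toy_interactome.targets_of(m)) for m in ["m1", "m2"])
        assert len(proj.target_genes) <= total


class TestTransformDbToMirnas:
    def test_term_becomes_its_targeting_mirnas(self):
        db = AnnotationDatabase("db", {"T": ("t", frozenset({"g1", "g3"}))})
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1"), ("m2", "g2"), ("m2", "g3")}))
        out = transform_db_to_mirnas(db, i)
        assert out.term_elements("T") == {"m1", "m2"}
        assert out.element_kind == "mirna"

    def test_term_without_regulated_genes_dropped(self):
        db = AnnotationDatabase("db", {
            "T1": ("a", frozenset({"g1"})),
            "T2": ("b", frozenset({"gX"})),
        })
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1")}))
        assert set(transform_db_to_mirnas(db, i).terms) == {"T1"}

    def test_mirna_counted_once_however_many_genes_it_targets(self):
        genes = frozenset(f"g{i}" for i in range(5))
        db = AnnotationDatabase("db", {"T": ("t", genes)})
        i = Interactome(kind="mirna", edges=frozenset(("m1", g) for g in genes))
        assert transform_db_to_mirnas(db, i).term_elements("T") == {"m1"}

    def test_all_terms_empty_is_an_error(self):
        db = AnnotationDatabase("db", {"T": ("t", frozenset({"gX"}))})
        i = Interactome(kind="mirna", edges=frozenset({("m1", "g1")}))
        with pytest.raises(ValueError):
            transform_db_to_mirnas(db, i)

    def test_matches_brute_force_double_loop_on_random_toys(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            genes = [f"g{i}" for i in range(rng.integers(3, 9))]
            mirnas = [f"m{i}" for i in range(rng.integers(2, 6))]
            edges = {
                (m, g) for m in mirnas for g in genes if rng.random() < 0.4
            }
            if not edges:
                continue
            term_genes = frozenset(g for g in genes if rng.random() < 0.5) or frozenset(genes[:1])
            db = AnnotationDatabase("db", {"T": ("t", term_genes)})
            i = Interactome(kind="mirna", edges=frozenset(edges))
            try:
                got = transform_db_to_mirnas(db, i).term_elements("T")
            except ValueError:
                got = frozenset()
            expected = frozenset(
                m for m in mirnas
                if any((m, g) in edges for g in term_genes)
            )
            assert got == expected


class TestQcReport:
    def test_counts_arithmetic(self):
        il = InputList.from_ids([f"x{i}" for i in range(8)] + ["x0", "x1"], "gene",
                                known={f"x{i}" for i in range(7)})
        u = Universe(scope="custom", elements=frozenset({f"x{i}" for i in range(5)}))
        rep = qc_report(il, u)
        assert rep["raw"] == 10 and rep["duplicates"] == 2 and rep["distinct"] == 8
        assert rep["mapped"] == 7 and rep["unmapped"] == 1 and rep["in_universe"] == 5

    def test_target_section_only_with_projection(self, toy_interactome, universe10):
        il = InputList.from_ids(["m1"], "mirna", known=toy_interactome.regulators())
        assert "target_genes" not in qc_report(il, universe10)
        proj = project_to_targets(il, toy_interactome)
        rep = qc_report(il, universe10, proj)
        assert rep["target_genes"] == sorted(proj.target_genes)

    def test_fully_unknown_input_reports_zero_mapped(self, universe10):
        il = InputList.from_ids(["nope"], "gene", known={"g1"})
        assert qc_report(il, universe10)["mapped"] == 0
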