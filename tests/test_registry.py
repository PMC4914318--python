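"""Registry parsing, name resolution, harmonization and grouping."""

import pytest

from mirmeta.registry import (
    group_mirnas,
    harmonize_signature,
    load_registry,
    normalize_name,
    resolve_name,
)
from mirmeta.simulate import SimulationSpec, make_registry


class TestLoadRegistry:
    def test_last_alias_is_current_name(self, tmp_path):
        a = tmp_path / "a.txt"
        g = tmp_path / "g.gff3"
        a.write_text("MIMAT0000X1\thsa-miR-9001;hsa-miR-9001-5p;\n")
        g.write_text("##gff-version 3\n")
        reg = load_registry(a, g)
        rec = reg.matures["MIMAT0000X1"]
        assert rec.current_name == "hsa-miR-9001-5p"
        assert rec.previous_names == ["hsa-miR-9001"]
        assert rec.arm == "5p"

    def test_empty_alias_table_errors(self, tmp_path):
        a = tmp_path / "a.txt"
        g = tmp_path / "g.gff3"
        a.write_text("")
        g.write_text("")
        with pytest.raises(ValueError, match="no mature records"):
            load_registry(a, g)

    def test_duplicate_accession_is_hard_error(self, tmp_path):
        a = tmp_path / "a.txt"
        g = tmp_path / "g.gff3"
        a.write_text(
            "MIMAT0000001\thsa-miR-1;\nMIMAT0000001\thsa-miR-2;\n"
        )
        g.write_text("")
        with pytest.raises(ValueError, match="duplicate accession"):
            load_registry(a, g)

    def test_malformed_accession_reports_line_number(self, tmp_path):
        a = tmp_path / "a.txt"
        g = tmp_path / "g.gff3"
        a.write_text("MIMAT0000001\thsa-miR-1;\nMIRWRONG\thsa-miR-2;\n")
        g.write_text("")
        with pytest.raises(ValueError, match=":2:"):
            load_registry(a, g)

    def test_rename_chain_resolvable_by_both_names(self, small_registry):
        # the miR-451 -> miR-451a rename: one accession, two eras of names
        for name in ("miR-451", "hsa-miR-451a", "hsa-mir-451A"):
            res = resolve_name(name, small_registry)
            assert res.status == "resolved"
            assert res.accession == "MIMAT0000001"


class TestResolveName:
    def test_legacy_name_resolves(self, small_registry):
        res = resolve_name("miR-144*", small_registry)
        assert res.status == "resolved" and res.accession == "MIMAT0000003"

    def test_planted_collision_is_ambiguous(self, small_registry):
        res = resolve_name("miR-222", small_registry)
        assert res.status == "ambiguous"
        assert set(res.accessions) == {"MIMAT0000006", "MIMAT0000007"}

    def test_unknown_name(self, small_registry):
        res = resolve_name("miR-00000", small_registry)
        assert res.status == "unknown" and res.accessions == []

    def test_armless_name_is_never_arm_guessed(self, small_registry):
        # hsa-miR-221-3p never recorded "hsa-miR-221" as an alias, only the
        # -5p mature did; exact alias tracking must send the legacy name there
        res = resolve_name("miR-221", small_registry)
        assert res.status == "resolved" and res.accession == "MIMAT0000004"

    def test_empty_query_raises(self, small_registry):
        with pytest.raises(ValueError):
            resolve_name("  ", small_registry)

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("hsa-miR-451a", "mir-451a"),
            ("MIR-451A", "mir-451a"),
            ("mmu-let-7a", "let-7a"),
            ("hsa-miR-222*", "mir-222*"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_name(raw) == expected


class TestHarmonizeSignature:
    def test_previous_and_current_names_merge(self, small_registry):
        sig, report = harmonize_signature(
            [("miR-146b", "up"), ("hsa-miR-146b-5p", "up")], small_registry
        )
        assert sig.accessions == ["MIMAT0000008"]
        assert sig.direction_of("MIMAT0000008") == "up"

    def test_merge_keeps_largest_magnitude_fc(self, small_registry):
        sig, _ = harmonize_signature(
            [("miR-146b", "up", 1.7), ("hsa-miR-146b-5p", "up", -3.2)],
            small_registry,
        )
        assert sig.table.at["MIMAT0000008", "linear_fc"] == -3.2

    def test_empty_input(self, small_registry):
        sig, report = harmonize_signature([], small_registry)
        assert len(sig) == 0 and len(report) == 0

    def test_intra_study_conflict_excluded_and_reported(self, small_registry):
        sig, report = harmonize_signature(
            [("hsa-miR-451a", "up"), ("miR-451", "down")], small_registry
        )
        assert len(sig) == 0
        conflicts = report[report["status"] == "intra-study conflict"]
        assert len(conflicts) == 1
        assert conflicts.iloc[0]["candidates"] == "MIMAT0000001"

    def test_ambiguous_and_unknown_reported_not_silently_dropped(
        self, small_registry
    ):
        sig, report = harmonize_signature(
            [("miR-222", "up"), ("miR-999999", "down"), ("miR-451a", "down")],
            small_registry,
        )
        assert sig.accessions == ["MIMAT0000001"]
        assert set(report["status"]) == {"ambiguous", "unknown", "resolved"}


class TestGroupMirnas:
    def test_shared_precursor_pair(self, small_registry):
        table = group_mirnas(
            ["MIMAT0000004", "MIMAT0000005"], small_registry
        )
        prec = table[table["group_type"] == "precursor"]
        assert set(prec["accession"]) == {"MIMAT0000004", "MIMAT0000005"}
        assert prec["group_id"].unique().tolist() == ["MI0000003"]

    def test_cluster_within_window(self, small_registry):
        # mir-451a and mir-144 hairpins 100 bp apart on the same strand
        table = group_mirnas(
            ["MIMAT0000001", "MIMAT0000002", "MIMAT0000003"],
            small_registry,
            cluster_window_bp=10000,
        )
        clusters = table[table["group_type"] == "cluster"]
        assert set(clusters["accession"]) == {
            "MIMAT0000001", "MIMAT0000002", "MIMAT0000003",
        }
        assert clusters["group_id"].nunique() == 1

    def test_opposite_strands_never_cluster(self, small_registry):
        table = group_mirnas(
            ["MIMAT0000009", "MIMAT0000010"], small_registry,
            cluster_window_bp=10**9,
        )
        assert (table["group_type"] != "cluster").all()

    def test_family_groups(self, small_registry):
        table = group_mirnas(
            ["MIMAT0000004", "MIMAT0000005", "MIMAT0000008"], small_registry
        )
        fam = table[table["group_type"] == "family"]
        assert set(fam["accession"]) == {
            "MIMAT0000004", "MIMAT0000005", "MIMAT0000008",
        }

    def test_unknown_accession_named_in_error(self, small_registry):
        with pytest.raises(ValueError, match="MIMAT0009999"):
            group_mirnas(["MIMAT0009999"], small_registry)

    def test_grouping_invariant_to_input_order(self, small_registry):
        accs = ["MIMAT0000001", "MIMAT0000002", "MIMAT0000003",
                "MIMAT0000004", "MIMAT0000005"]
        a = group_mirnas(accs, small_registry)
        b = group_mirnas(accs[::-1], small_registry)
        assert a.equals(b)


class TestGeneratedRegistryRoundTrip:
    def test_all_names_resolve_to_generating_accession(self):
        reg, truth = make_registry(SimulationSpec(seed=11, n_mirnas=120))
        for rec in reg.matures.values():
            for name in rec.all_names:
                res = reg.resolve(name)
                assert res.status == "resolved"
                assert res.accession == rec.accession

    def test_planted_collisions_always_ambiguous(self):
        reg, truth = make_registry(
            SimulationSpec(seed=12, n_mirnas=120, collision_count=6)
        )
        assert len(truth.collisions) == 6
        for name, a, b in truth.collisions:
            res = reg.resolve(name)
            assert res.status == "ambiguous"
            assert {a, b} <= set(res.accessions)

    def test_planted_shared_precursor_recovered_by_grouping(self):
        reg, truth = make_registry(SimulationSpec(seed=13, n_mirnas=60))
        a, b = truth.shared_precursor_pairs[0]
        table = group_mirnas([a, b], reg)
        prec = table[table["group_type"] == "precursor"]
        assert set(prec["accession"]) == {a, b}

    def test_rename_fraction_zero_gives_single_name_lists(self):
        reg, truth = make_registry(
            SimulationSpec(seed=14, n_mirnas=50, rename_fraction=0.0)
        )
        assert len(truth.renames) == 0
        assert all(not r.previous_names for r in reg.matures.values())
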