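"""Typing-matrix loading, cross-resistance classification and summaries."""

import itertools

import pandas as pd
import pytest

from phageres.panel import DEFAULT_PANEL, DEFAULT_STRAINS, PhageDef, StrainDef
from phageres.typing_matrix import (
    TypingFormatError,
    classify_clone,
    load_typing,
    summarize_cross_resistance,
    unique_patterns,
)

from conftest import make_matrix


def write_csv(tmp_path, panel, rows):
    cols = ["clone_id", "strain", "origin", "treatment"] + [p.name for p in panel]
    df = pd.DataFrame(rows, columns=cols)
    path = tmp_path / "typing.csv"
    df.to_csv(path, index=False)
    return path


def all_s(panel):
    return {p.name: "S" for p in panel}


class TestLoadTyping:
    def test_all_sensitive_matrix_has_zero_acquired(self, tmp_path, small_panel):
        path = write_csv(
            tmp_path,
            small_panel,
            [
                ["c1", "S1", "biofilm", "pA", "S", "S", "S", "S"],
                ["c2", "S1", "biofilm", "pA", "S", "S", "S", "S"],
                ["wt", "S1", "wild_type", "", "S", "S", "S", "S"],
            ],
        )
        m = load_typing(path, small_panel, (StrainDef("S1"),))
        assert all(
            not classify_clone(m, c).acquired for c in ("c1", "c2")
        )

    def test_wild_type_resistance_marks_not_evaluable(self, tmp_path):
        # A5803's wild type resists KT28, so KT28 is never an acquired
        # resistance for A5803 clones
        rows = [
            ["a1", "A5803", "biofilm", "LUZ7"]
            + ["R" if p.name in ("KT28", "LUZ7") else "S" for p in DEFAULT_PANEL],
            ["a_wt", "A5803", "wild_type", ""]
            + ["R" if p.name == "KT28" else "S" for p in DEFAULT_PANEL],
        ]
        path = write_csv(tmp_path, DEFAULT_PANEL, rows)
        m = load_typing(path, DEFAULT_PANEL, DEFAULT_STRAINS)
        call = classify_clone(m, "a1")
        assert "KT28" in call.not_evaluable
        assert "KT28" not in call.acquired

    def test_illegal_cell_rejected_with_location(self, tmp_path, small_panel):
        path = write_csv(
            tmp_path,
            small_panel,
            [
                ["c1", "S1", "biofilm", "pA", "S", "X", "S", "S"],
                ["wt", "S1", "wild_type", "", "S", "S", "S", "S"],
            ],
        )
        with pytest.raises(TypingFormatError, match="pB"):
            load_typing(path, small_panel, (StrainDef("S1"),))

    def test_missing_wild_type_row_rejected(self, tmp_path, small_panel):
        path = write_csv(
            tmp_path,
            small_panel,
            [["c1", "S1", "biofilm", "pA", "S", "S", "S", "S"]],
        )
        with pytest.raises(TypingFormatError, match="wild_type"):
            load_typing(path, small_panel, (StrainDef("S1"),))

    def test_declared_wt_resistance_typed_sensitive_rejected(self, tmp_path):
        rows = [
            ["a_wt", "A5803", "wild_type", ""] + ["S"] * len(DEFAULT_PANEL),
        ]
        path = write_csv(tmp_path, DEFAULT_PANEL, rows)
        with pytest.raises(TypingFormatError, match="KT28"):
            load_typing(path, DEFAULT_PANEL, DEFAULT_STRAINS)

    def test_unknown_phage_column_rejected(self, tmp_path, small_panel):
        path = write_csv(
            tmp_path,
            small_panel,
            [["wt", "S1", "wild_type", "", "S", "S", "S", "S"]],
        )
        df = pd.read_csv(path)
        df["pZ"] = "S"
        df.to_csv(path, index=False)
        with pytest.raises(TypingFormatError, match="pZ"):
            load_typing(path, small_panel, (StrainDef("S1"),))


def oracle_category(acquired, treatment, panel):
    """Independent re-derivation of the category from first principles."""
    by = {p.name: p for p in panel}
    hit_lps = any("LPS" in by[n].receptors for n in acquired)
    hit_t4p = any("T4P" in by[n].receptors for n in acquired)
    app_lps = any("LPS" in by[n].receptors for n in treatment)
    app_t4p = any("T4P" in by[n].receptors for n in treatment)
    if not acquired:
        return "none"
    if hit_lps and hit_t4p:
        return "both_groups"
    if hit_lps:
        return "same_receptor_only" if app_lps else "alternative_receptor_only"
    return "same_receptor_only" if app_t4p else "alternative_receptor_only"


class TestClassifyClone:
    def test_pan_resistant_clone_is_both_groups(self):
        clones = [
            {
                "clone_id": "c1",
                "strain": "PAO1",
                "origin": "biofilm",
                "treatment": {"LUZ7"},
                "calls": {p.name: "R" for p in DEFAULT_PANEL},
            }
        ]
        m = make_matrix(DEFAULT_PANEL, clones, strains=("PAO1",))
        call = classify_clone(m, "c1")
        assert call.category == "both_groups"
        assert len(call.acquired) == len(DEFAULT_PANEL)

    def test_t4p_sweep_after_t4p_phage_is_same_receptor_only(self):
        # phiKZ (T4P) treatment selecting resistance to all T4P phages
        calls = {p.name: "S" for p in DEFAULT_PANEL}
        calls.update({"phiKZ": "R", "KTN4": "R", "LUZ19": "R"})
        m = make_matrix(
            DEFAULT_PANEL,
            [{"clone_id": "c1", "strain": "PAO1", "origin": "biofilm",
              "treatment": {"phiKZ"}, "calls": calls}],
            strains=("PAO1",),
        )
        call = classify_clone(m, "c1")
        assert call.category == "same_receptor_only"
        assert call.self_resistant_to == {"phiKZ"}

    def test_dual_receptor_phage_alone_counts_toward_both_groups(self, small_panel):
        calls = {p.name: "S" for p in small_panel}
        calls["pD"] = "R"  # the LPS/T4P dual-receptor phage
        m = make_matrix(
            small_panel,
            [{"clone_id": "c1", "strain": "S1", "origin": "biofilm",
              "treatment": {"pA"}, "calls": calls}],
        )
        assert classify_clone(m, "c1").category == "both_groups"

    @pytest.mark.parametrize(
        "treatment", [{"pA"}, {"pC"}, {"pD"}, {"pA", "pC"}]
    )
    def test_all_patterns_match_enumeration_oracle(self, small_panel, treatment):
        names = [p.name for p in small_panel]
        clones = []
        for i, bits in enumerate(itertools.product("SR", repeat=len(names))):
            clones.append(
                {
                    "clone_id": f"c{i:02d}",
                    "strain": "S1",
                    "origin": "biofilm",
                    "treatment": treatment,
                    "calls": dict(zip(names, bits)),
                }
            )
        m = make_matrix(small_panel, clones)
        for clone in clones:
            call = classify_clone(m, clone["clone_id"])
            acquired = {n for n in names if clone["calls"][n] == "R"}
            assert call.acquired == acquired
            assert call.category == oracle_category(acquired, treatment, small_panel)

    def test_adding_resistance_never_shrinks_acquired(self, small_panel):
        names = [p.name for p in small_panel]
        for bits in itertools.product("SR", repeat=len(names)):
            base = dict(zip(names, bits))
            m0 = make_matrix(
                small_panel,
                [{"clone_id": "c", "strain": "S1", "origin": "biofilm",
                  "treatment": {"pA"}, "calls": base}],
            )
            a0 = classify_clone(m0, "c").acquired
            for n in names:
                if base[n] == "S":
                    more = dict(base, **{n: "R"})
                    m1 = make_matrix(
                        small_panel,
                        [{"clone_id": "c", "strain": "S1", "origin": "biofilm",
                          "treatment": {"pA"}, "calls": more}],
                    )
                    assert a0 <= classify_clone(m1, "c").acquired


class TestUniquePatterns:
    def test_identical_clones_form_one_group(self, small_panel):
        clones = [
            {"clone_id": f"c{i}", "strain": "S1", "origin": "biofilm",
             "treatment": {"pA"}, "calls": {"pA": "R", "pB": "S", "pC": "S", "pD": "S"}}
            for i in range(10)
        ]
        groups = unique_patterns(make_matrix(small_panel, clones))
        assert len(groups) == 1
        assert groups.iloc[0]["n_clones"] == 10
        assert groups.iloc[0]["representative"] == "c0"

    def test_groups_partition_the_clone_set(self, small_panel):
        import numpy as np

        rng = np.random.default_rng(5)
        clones = [
            {"clone_id": f"c{i:02d}", "strain": "S1", "origin": "biofilm",
             "treatment": {"pA"},
             "calls": {p.name: "SR"[rng.integers(2)] for p in small_panel}}
            for i in range(20)
        ]
        m = make_matrix(small_panel, clones)
        groups = unique_patterns(m)
        members = [c for ms in groups["members"] for c in ms]
        assert sorted(members) == sorted(c["clone_id"] for c in clones)
        assert len(set(members)) == len(members)
        assert len(groups) == len({tuple(c["calls"].items()) for c in clones})


class TestSummarize:
    def test_counts_equal_brute_force_recount(self, small_panel):
        import numpy as np

        rng = np.random.default_rng(17)
        treatments = [{"pA"}, {"pC"}, {"pA", "pC"}]
        clones = [
            {"clone_id": f"c{i:02d}", "strain": "S1", "origin": "biofilm",
             "treatment": treatments[rng.integers(3)],
             "calls": {p.name: "SR"[rng.integers(2)] for p in small_panel}}
            for i in range(30)
        ]
        m = make_matrix(small_panel, clones)
        summary = summarize_cross_resistance(m)
        # brute force: recount categories per arity from scratch
        for _, row in summary.iterrows():
            arm = [
                c for c in clones
                if (len(c["treatment"]) == 1) == (row["arity"] == "monovalent")
            ]
            assert row["n_clones"] == len(arm)
            for cat in ("none", "both_groups", "same_receptor_only",
                        "alternative_receptor_only"):
                expected = sum(
                    1 for c in arm
                    if oracle_category(
                        {n for n, v in c["calls"].items() if v == "R"},
                        c["treatment"], small_panel) == cat
                )
                assert row[f"n_{cat}"] == expected

    def test_clone_order_does_not_change_summary(self, small_panel):
        clones = [
            {"clone_id": f"c{i}", "strain": "S1", "origin": "biofilm",
             "treatment": {"pA"},
             "calls": {"pA": "R" if i % 2 else "S", "pB": "S", "pC": "R",
                       "pD": "S"}}
            for i in range(8)
        ]
        a = summarize_cross_resistance(make_matrix(small_panel, clones))
        b = summarize_cross_resistance(make_matrix(small_panel, clones[::-1]))
        pd.testing.assert_frame_equal(
            a.drop(columns="still_sensitive"), b.drop(columns="still_sensitive")
        )
        assert a["still_sensitive"].tolist() == b["still_sensitive"].tolist()

    def test_absent_arm_is_not_reported_as_zero(self, small_panel):
        clones = [
            {"clone_id": "c0", "strain": "S1", "origin": "biofilm",
             "treatment": {"pA"}, "calls": all_s(small_panel)}
        ]
        summary = summarize_cross_resistance(make_matrix(small_panel, clones))
        assert set(summary["arity"]) == {"monovalent"}  # no fabricated 0% rows
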