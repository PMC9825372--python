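import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primeseq.de import DEGSets
from primeseq.priming import (
    GROUP_ELE_3MIN,
    GROUP_ELE_ALONE,
    GROUP_SED_3MIN,
    GROUP_SED_10MIN,
    MarkDynamics,
    classify_game,
    intersect_dynamics_degs,
    mark_dynamics,
    priming_fractions,
    round_half_up_percent,
    run_study,
    write_study_report,
    zscore_concordance,
)
from primeseq.simulate import make_fixture_study

GROUPS = (GROUP_ELE_ALONE, GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN)


def _degs(up=(), down=(), contrast="x"):
    return DEGSets(up=set(up), down=set(down), contrast=contrast,
                   lfc_cut=0.3785, p_cut=0.05)


class TestMarkDynamics:
    def test_set_algebra(self):
        presence = {("H4K8ac", "ELE"): {"a", "b"}, ("H4K8ac", "SED"): {"b", "c"}}
        dyn = mark_dynamics(presence, "H4K8ac")
        assert dyn.new == {"a"} and dyn.lost == {"c"} and dyn.shared == {"b"}

    def test_equal_conditions(self):
        presence = {("H4K8ac", "ELE"): {"a"}, ("H4K8ac", "SED"): {"a"}}
        dyn = mark_dynamics(presence, "H4K8ac")
        assert dyn.new == set() and dyn.lost == set() and dyn.shared == {"a"}

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="lacks condition"):
            mark_dynamics({("H4K8ac", "ELE"): set()}, "H4K8ac")

    @given(
        st.sets(st.integers(min_value=0, max_value=1000), max_size=200),
        st.sets(st.integers(min_value=0, max_value=1000), max_size=200),
    )
    def test_matches_brute_force_membership(self, ele, sed):
        ele = {f"g{i}" for i in ele}
        sed = {f"g{i}" for i in sed}
        dyn = mark_dynamics({("m", "ELE"): ele, ("m", "SED"): sed}, "m")
        universe = ele | sed
        for g in universe:
            if g in ele and g not in sed:
                assert g in dyn.new
            elif g in sed and g not in ele:
                assert g in dyn.lost
            else:
                assert g in dyn.shared


class TestIntersectDynamicsDegs:
    def test_counts_and_lists(self):
        dyn = {"H4K8ac": MarkDynamics("H4K8ac", new={"a", "b", "c"}, lost=set(),
                                      shared=set())}
        table, _ = intersect_dynamics_degs(dyn, _degs(up={"b", "c", "d"}))
        row = table[(table["status"] == "new") & (table["direction"] == "up")].iloc[0]
        assert row["count"] == 2 and row["genes"] == "b,c"

    def test_disjoint_inputs_all_zero(self):
        dyn = {"H4K8ac": MarkDynamics("H4K8ac", new={"a"}, lost={"b"}, shared={"c"})}
        table, co = intersect_dynamics_degs(dyn, _degs(up={"x"}, down={"y"}))
        assert (table["count"] == 0).all()
        assert co.empty

    def test_co_occurrence_supports_also_had_statements(self):
        dyn = {
            "H4K8ac": MarkDynamics("H4K8ac", new={"a", "b"}, lost=set(), shared=set()),
            "H3K27me3": MarkDynamics("H3K27me3", new={"b"}, lost=set(), shared=set()),
        }
        _, co = intersect_dynamics_degs(dyn, _degs(up={"a", "b"}))
        row = co.iloc[0]
        assert row["count"] == 1 and row["genes"] == "b"

    def test_planted_overlap_recovered_exactly(self):
        # 93 planted up-genes with a new permissive mark
        genes = {f"g{i}" for i in range(93)}
        dyn = {"H4K8ac": MarkDynamics("H4K8ac", new=set(genes), lost=set(),
                                      shared=set())}
        table, _ = intersect_dynamics_degs(dyn, _degs(up=set(genes) | {"other"}))
        row = table[(table["status"] == "new") & (table["direction"] == "up")].iloc[0]
        assert row["count"] == 93


def _expected_class(in_ele_alone, in_ele3, in_sed3, in_sed10):
    """Independent set-formula oracle for one membership pattern."""
    out = set()
    if in_ele3 and in_sed10:
        out.add("cGAMES")
    if in_ele3 and not (in_ele_alone or in_sed3 or in_sed10):
        out.add("cGAME")
    if in_sed10 and not (in_ele_alone or in_sed3 or in_ele3):
        out.add("cGAMS")
    return out


class TestClassifyGame:
    def test_cgames_membership(self):
        degs = {
            GROUP_ELE_ALONE: _degs(),
            GROUP_ELE_3MIN: _degs(up={"g"}),
            GROUP_SED_3MIN: _degs(),
            GROUP_SED_10MIN: _degs(up={"g"}),
        }
        c = classify_game(degs)
        assert c.members("up", "cGAMES") == {"g"}
        assert c.members("up", "cGAME") == set()

    def test_cgame_membership(self):
        degs = {
            GROUP_ELE_ALONE: _degs(),
            GROUP_ELE_3MIN: _degs(up={"g"}),
            GROUP_SED_3MIN: _degs(),
            GROUP_SED_10MIN: _degs(),
        }
        assert classify_game(degs).members("up", "cGAME") == {"g"}

    def test_ele_alone_exclusion_flag(self):
        degs = {
            GROUP_ELE_ALONE: _degs(up={"g"}),
            GROUP_ELE_3MIN: _degs(up={"g"}),
            GROUP_SED_3MIN: _degs(),
            GROUP_SED_10MIN: _degs(),
        }
        assert classify_game(degs).members("up", "cGAME") == set()
        lax = classify_game(degs, exclude_ele_alone=False)
        assert lax.members("up", "cGAME") == {"g"}

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_game({GROUP_ELE_3MIN: _degs()})

    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_exhaustive_sixteen_pattern_truth_table(self, direction):
        for pattern in itertools.product([0, 1], repeat=4):
            gene = "g"
            kwargs = dict.fromkeys(GROUPS)
            for grp, flag in zip(GROUPS, pattern):
                members = {gene} if flag else set()
                kwargs[grp] = (
                    _degs(up=members) if direction == "up" else _degs(down=members)
                )
            c = classify_game(kwargs)
            expected = _expected_class(*pattern)
            got = {
                cls
                for cls in ("cGAME", "cGAMES", "cGAMS")
                if gene in c.members(direction, cls)
            }
            assert got == expected, pattern


class TestPrimingFractions:
    def _classification(self, up_cgames=(), up_cgame=()):
        from primeseq.priming import GameClassification

        return GameClassification(
            classes={
                "up": {"cGAME": set(up_cgame), "cGAMES": set(up_cgames),
                       "cGAMS": set()},
                "down": {"cGAME": set(), "cGAMES": set(), "cGAMS": set()},
            }
        )

    def test_display_rounding_58_of_145(self):
        genes = [f"g{i}" for i in range(145)]
        cls = self._classification(up_cgames=genes)
        dyn = {
            "H4K8ac": MarkDynamics("H4K8ac", new=set(genes[:58]), lost=set(),
                                   shared=set()),
            "H3K27me3": MarkDynamics("H3K27me3", new=set(), lost=set(), shared=set()),
        }
        report = priming_fractions(cls, dyn)
        row = report.rows[
            (report.rows["direction"] == "up") & (report.rows["class"] == "cGAMES")
        ].iloc[0]
        assert row["total"] == 145 and row["n_primed"] == 58
        assert row["percent_primed"] == 40

    def test_display_rounding_76_of_256(self):
        assert round_half_up_percent(76 / 256) == 30

    def test_no_overlap_is_zero_percent(self):
        cls = self._classification(up_cgames={"a", "b"})
        dyn = {"H4K8ac": MarkDynamics("H4K8ac", new={"z"}, lost=set(), shared=set())}
        report = priming_fractions(cls, dyn)
        row = report.rows.iloc[1]
        assert row["fraction_primed"] == 0.0 and row["percent_primed"] == 0

    def test_empty_class_is_nan_with_zero_count(self):
        report = priming_fractions(self._classification(), {})
        assert report.rows["total"].eq(0).all()
        assert report.rows["fraction_primed"].isna().all()

    def test_count_bounds_invariant(self, study_report):
        rows = study_report.priming.rows
        assert (rows["n_primed"] <= rows["total"]).all()
        component_cols = [c for c in rows.columns if c.startswith("n_") and c != "n_primed"]
        assert (rows["n_primed"] <= rows[component_cols].sum(axis=1)).all()


class TestZScores:
    def test_hand_computed_row(self):
        lfc = pd.DataFrame(
            [[1.0, 0.0, 1.0]],
            index=["g"],
            columns=[GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN],
        )
        z, conc, n_excl = zscore_concordance(lfc, {"g"})
        assert np.allclose(z.loc["g"], [0.57735, -1.1547, 0.57735], atol=1e-4)
        assert conc == 1.0 and n_excl == 0

    def test_constant_row_excluded(self):
        lfc = pd.DataFrame(
            [[0.5, 0.5, 0.5], [1.0, 0.0, 1.0]],
            index=["flat", "g"],
            columns=[GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN],
        )
        z, conc, n_excl = zscore_concordance(lfc, {"flat", "g"})
        assert "flat" not in z.index and n_excl == 1
        assert conc == 1.0

    def test_all_constant_gives_nan(self):
        lfc = pd.DataFrame(
            [[1.0, 1.0, 1.0]],
            index=["g"],
            columns=[GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN],
        )
        _, conc, _ = zscore_concordance(lfc, {"g"})
        assert math.isnan(conc)

    def test_planted_concordance_is_one_on_truth(self, study):
        # cGAMES genes are planted with identical fold change in the two
        # threshold-learning groups, so their z signs must agree exactly
        truth = study.truth
        cgames = truth.class_members("up", "cGAMES") | truth.class_members(
            "down", "cGAMES"
        )
        lfc = truth.lfc[[GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN]]
        _, conc, _ = zscore_concordance(lfc, cgames)
        assert conc == 1.0


class TestPipeline:
    def test_noise_free_recovery_is_exact(self, noise_free_study, noise_free_report):
        truth = noise_free_study.truth
        for direction in ("up", "down"):
            for cls in ("cGAME", "cGAMES", "cGAMS"):
                assert noise_free_report.classification.members(direction, cls) == \
                    truth.class_members(direction, cls)
        # priming counts exact
        for _, row in noise_free_report.priming.rows.iterrows():
            members = truth.class_members(row["direction"], row["class"])
            marks = (
                (("H4K8ac", "new"), ("H3K27me3", "lost"))
                if row["direction"] == "up"
                else (("H3K27me3", "new"), ("H4K8ac", "lost"))
            )
            planted = set()
            for ab, status in marks:
                planted |= truth.mark_dynamics[ab][status] & members
            assert row["n_primed"] == len(planted)

    def test_default_noise_recovery(self, study, study_report):
        truth = study.truth
        tp = fp = fn = 0
        for d in ("up", "down"):
            for cls in ("cGAME", "cGAMES", "cGAMS"):
                t = truth.class_members(d, cls)
                r = study_report.classification.members(d, cls)
                tp += len(t & r)
                fp += len(r - t)
                fn += len(t - r)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.85  # 20-seed median >= 0.9 is asserted in acceptance
        rows = study_report.priming.rows
        r = rows[(rows["direction"] == "up") & (rows["class"] == "cGAMES")].iloc[0]
        assert abs(r["n_new_H4K8ac"] / r["total"] - 0.40) <= 0.08

    def test_qc_passes_on_default_fixture(self, study_report):
        assert study_report.qc_exclusions == []
        for ps in study_report.peaksets.values():
            assert ps.empirical_fdr is not None and ps.empirical_fdr <= 0.1

    def test_report_writing_deterministic(self, tmp_path):
        st1 = make_fixture_study(11)
        st2 = make_fixture_study(11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study_report(run_study(st1.genome, st1.counts, st1.tracks, st1.igg), d1)
        write_study_report(run_study(st2.genome, st2.counts, st2.tracks, st2.igg), d2)
        files1 = sorted(p.name for p in d1.iterdir())
        files2 = sorted(p.name for p in d2.iterdir())
        assert files1 == files2
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_coverage_completes(self, noise_free_study):
        from primeseq.io import CoverageTrack

        st = noise_free_study
        empty = {k: CoverageTrack(sample=None, data={}) for k in st.tracks}
        with pytest.warns(UserWarning, match="no signal blocks"):
            rep = run_study(
                st.genome, st.counts, empty, None,
                peak_threshold="numeric", numeric_fraction=1.0,
            )
        for dyn in rep.dynamics.values():
            assert dyn.new == dyn.lost == dyn.shared == set()
        assert (rep.priming.rows["n_primed"] == 0).all()
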