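"""Population statistics: counts, proportions, death enrichment, CV,
neighborhoods, founder clones and developmental speed."""

import numpy as np
import pandas as pd
import pytest

from blastotrack.errors import StatisticsError
from blastotrack.identity import AnnotatedLineage, annotate_lineage, classify_divisions, collect_deaths
from blastotrack.stats import (
    asymmetric_division_proportion,
    attach_normalized_age,
    coefficient_of_variation,
    counts_by_type,
    counts_on_grid,
    founder_clone_summary,
    make_bins,
    neighborhood_composition,
    normalized_death_ratio,
    proportion_inner,
    relative_developmental_speed,
)
from blastotrack.stats import DivisionRecord
from blastotrack.synthetic import generate_embryo
from blastotrack.timescale import TimeScale

from conftest import fast_params, node


def _division(mother_identity, daughters, time_na):
    return DivisionRecord(
        mother_track_id=0, time_hp=time_na, mother_identity=mother_identity,
        daughter_identities=daughters, daughter_track_ids=(1, 2),
        division_type="asymmetric" if daughters[0] != daughters[1] else "symmetric",
        time_na=time_na)


class TestCountsAndPic:
    def test_inner_plus_outer_equals_total_everywhere(self, wt_embryo):
        lin, truth, _ = wt_embryo
        ann = annotate_lineage(lin, leaf_identities=dict(truth.identities))
        counts = counts_by_type(ann)
        assert (counts["n_inner"] + counts["n_outer"] == counts["n_total"]).all()

    def test_symmetric_division_steps_count_up(self, make_lineage):
        lin = make_lineage([node(0, None, 0), node(1, 0, 1), node(2, 0, 1)])
        t = lin.node_track
        identities = {t[0]: "outer", t[1]: "outer", t[2]: "outer"}
        ann = AnnotatedLineage(lin, identities)
        counts = counts_by_type(ann)
        assert counts["n_outer"].tolist() == [1, 2]

    def test_inner_death_decrements_by_one(self, make_lineage):
        rows = [node(0, None, 0), node(1, None, 0),
                node(2, 0, 1, death=True), node(3, 1, 1),
                node(4, 3, 2)]
        lin = make_lineage(rows)
        t = lin.node_track
        identities = {t[0]: "inner", t[1]: "outer"}
        counts = counts_by_type(AnnotatedLineage(lin, identities))
        # dying nucleus is observed through its terminal frame
        assert counts["n_inner"].tolist() == [1, 1, 0]

    @pytest.mark.parametrize("inner,outer,expected", [
        (0, 10, 0.0),
        (9, 23, 0.28125),
        (7, 7, 0.5),
    ])
    def test_proportion_inner(self, inner, outer, expected):
        counts = pd.DataFrame({"n_inner": [inner], "n_total": [inner + outer]})
        assert proportion_inner(counts)[0] == pytest.approx(expected)

    def test_zero_total_flagged_not_zero(self):
        counts = pd.DataFrame({"n_inner": [0], "n_total": [0]})
        assert np.isnan(proportion_inner(counts)[0])


class TestBinnedAsymmetry:
    def test_quarter_asymmetric_bin(self):
        divs = [_division("outer", ("outer", "inner"), 0.81)] + \
            [_division("outer", ("outer", "outer"), 0.82 + i * 0.001) for i in range(3)]
        binned = asymmetric_division_proportion(divs, "outer", np.array([0.8, 0.85]))
        assert binned.proportion[0] == pytest.approx(0.25)
        assert binned.denominator[0] == 4

    def test_empty_bin_flagged_nan(self):
        divs = [_division("outer", ("outer", "outer"), 0.81)]
        binned = asymmetric_division_proportion(divs, "inner", np.array([0.8, 0.85]))
        assert np.isnan(binned.proportion[0])

    def test_all_asymmetric_is_one(self):
        divs = [_division("inner", ("inner", "outer"), 0.82) for _ in range(5)]
        binned = asymmetric_division_proportion(divs, "inner", np.array([0.8, 0.85]))
        assert binned.proportion[0] == 1.0

    def test_edge_event_belongs_to_right_bin(self):
        divs = [_division("outer", ("outer", "outer"), 0.85)]
        binned = asymmetric_division_proportion(
            divs, "outer", np.array([0.80, 0.85, 0.90]))
        assert binned.denominator.tolist() == [0, 1]

    def test_make_bins_cover_window(self):
        edges = make_bins(0.768, 1.073, 0.05)
        assert edges[0] == pytest.approx(0.768)
        assert edges[-1] >= 1.073 - 1e-12
        assert np.allclose(np.diff(edges), 0.05)


def _death_ratio_toy(make_lineage, n_inner=5, n_outer=15, inner_deaths=2, outer_deaths=1):
    rows = []
    nid = 0
    identities = {}
    kinds = ["inner"] * n_inner + ["outer"] * n_outer
    death_budget = {"inner": inner_deaths, "outer": outer_deaths}
    for kind in kinds:
        dies = death_budget[kind] > 0
        if dies:
            death_budget[kind] -= 1
        rows.append(node(nid, None, 0))
        rows.append(node(nid + 1, nid, 1, death=dies))
        nid += 2
    lin = make_lineage(rows)
    for i, kind in enumerate(kinds):
        identities[lin.node_track[2 * i]] = kind
    deaths = collect_deaths(lin, identities)
    return AnnotatedLineage(lin, identities, deaths=deaths)


class TestNormalizedDeathRatio:
    def test_hand_computed_toy(self, make_lineage):
        ann = _death_ratio_toy(make_lineage)
        ts = TimeScale(t_collapse_hp=1.0)
        r_inner = normalized_death_ratio(ann, ts, "inner", (0.0, 1.0))
        r_outer = normalized_death_ratio(ann, ts, "outer", (0.0, 1.0))
        assert r_inner["value"] == pytest.approx((2 / 3) / (5 / 20))   # 2.667
        assert r_outer["value"] == pytest.approx((1 / 3) / (15 / 20))  # 0.444

    def test_proportional_allocation_gives_exactly_one(self, make_lineage):
        # deaths proportional to abundance: 1 of 5 inner, 3 of 15 outer
        ann = _death_ratio_toy(make_lineage, inner_deaths=1, outer_deaths=3)
        ts = TimeScale(t_collapse_hp=1.0)
        for kind in ("inner", "outer"):
            assert normalized_death_ratio(ann, ts, kind, (0.0, 1.0))["value"] == 1.0

    def test_type_weighted_identity_sums_to_one(self, make_lineage):
        ann = _death_ratio_toy(make_lineage)
        ts = TimeScale(t_collapse_hp=1.0)
        total = 0.0
        for kind in ("inner", "outer"):
            r = normalized_death_ratio(ann, ts, kind, (0.0, 1.0))
            total += (r["n_tracks_type"] / r["n_tracks"]) * r["value"]
        assert total == pytest.approx(1.0)

    def test_no_deaths_excludes_embryo(self, make_lineage):
        ann = _death_ratio_toy(make_lineage, inner_deaths=0, outer_deaths=0)
        with pytest.raises(StatisticsError, match="no deaths"):
            normalized_death_ratio(ann, TimeScale(1.0), "inner", (0.0, 1.0))


class TestCoefficientOfVariation:
    def test_identical_embryos_have_zero_cv(self):
        mat = np.tile([3.0, 5.0, 9.0], (4, 1))
        assert np.allclose(coefficient_of_variation(mat), 0.0)

    def test_hand_arithmetic_sample_sd(self):
        cv = coefficient_of_variation(np.array([[2.0], [4.0]]))
        assert cv[0] == pytest.approx(np.sqrt(2.0) / 3.0)  # 0.4714

    def test_zero_mean_flagged(self):
        cv = coefficient_of_variation(np.array([[0.0], [0.0]]))
        assert np.isnan(cv[0])

    def test_single_embryo_rejected(self):
        with pytest.raises(StatisticsError):
            coefficient_of_variation(np.array([[1.0, 2.0]]))


class TestNeighborhood:
    def _toy(self, make_lineage):
        # mother at origin + five neighbors at printed coordinates
        pos = {
            1: (2.0, 0.1, 0.0), 2: (4.0, -0.1, 0.0), 3: (6.0, 0.2, 0.0),
            4: (8.0, 0.0, 0.1), 5: (10.0, -0.2, 0.0),
        }
        rows = [node(0, None, 0)]
        rows += [node(i, None, 0, *pos[i]) for i in pos]
        rows += [node(6, 0, 1, x=-0.5), node(7, 0, 1, x=0.5)]
        rows += [node(7 + i, i, 1, *pos[i]) for i in pos]
        lin = make_lineage(rows)
        t = lin.node_track
        identities = {t[0]: "inner", t[6]: "inner", t[7]: "inner"}
        neighbor_kinds = {1: "outer", 2: "inner", 3: "outer", 4: "outer", 5: "outer"}
        for i, kind in neighbor_kinds.items():
            identities[t[i]] = kind
        divisions = classify_divisions(lin, identities)
        return AnnotatedLineage(lin, identities, divisions), pos, neighbor_kinds

    def test_matches_brute_force_knn(self, make_lineage):
        ann, pos, kinds = self._toy(make_lineage)
        for k in (2, 3, 4):
            table = neighborhood_composition(ann, k=k)
            # brute force: neighbors sorted by distance from the origin
            order = sorted(pos, key=lambda i: np.linalg.norm(pos[i]))
            expected = np.mean([kinds[i] != "inner" for i in order[:k]])
            assert table["frac_other_type"].iloc[0] == pytest.approx(expected)

    def test_k4_with_one_other_type_neighbor(self, make_lineage):
        ann, pos, kinds = self._toy(make_lineage)
        # swap identities so exactly one of the 4 nearest differs
        ident = dict(ann.identities)
        t = ann.lineage.node_track
        for i in (2, 3, 4):
            ident[t[i]] = "inner"
        ann2 = AnnotatedLineage(ann.lineage, ident, ann.divisions)
        table = neighborhood_composition(ann2, k=4)
        assert table["frac_other_type"].iloc[0] == pytest.approx(0.25)

    def test_fewer_than_k_neighbors_flagged(self, make_lineage):
        rows = [node(0, None, 0), node(1, None, 0, x=3.0),
                node(2, 0, 1, x=-0.5), node(3, 0, 1, x=0.5), node(4, 1, 1, x=3.0)]
        lin = make_lineage(rows)
        t = lin.node_track
        identities = {t[0]: "inner", t[1]: "outer", t[2]: "inner", t[3]: "inner"}
        ann = AnnotatedLineage(lin, identities, classify_divisions(lin, identities))
        table = neighborhood_composition(ann, k=8)
        assert bool(table["flagged"].iloc[0])
        assert table["n_neighbors"].iloc[0] == 1


class TestFounderClones:
    def test_never_dividing_founder(self, make_lineage):
        lin = make_lineage([node(0, None, 0), node(1, 0, 1)])
        t = lin.node_track
        ann = AnnotatedLineage(lin, {t[0]: "outer"})
        (summary,) = founder_clone_summary(ann)
        assert summary.n_mitoses == 0
        assert (summary.n_final_inner, summary.n_final_outer) == (0, 1)

    def test_two_generations_give_three_mitoses(self, make_lineage):
        rows = [node(0, None, 0), node(1, 0, 1), node(2, 0, 1),
                node(3, 1, 2), node(4, 1, 2), node(5, 2, 2), node(6, 2, 2)]
        lin = make_lineage(rows)
        identities = {tid: "outer" for tid in lin.tracks}
        (summary,) = founder_clone_summary(AnnotatedLineage(lin, identities))
        assert summary.n_mitoses == 3
        assert summary.n_final == 4

    @pytest.mark.parametrize("seed", [0, 5])
    def test_tree_identity_on_synthetic(self, seed):
        """n_mitoses = final cells + deaths - 1 for every founder clone."""
        lin, truth = generate_embryo(fast_params(), seed)
        ann = annotate_lineage(lin, leaf_identities=dict(truth.identities))
        summaries = founder_clone_summary(ann)
        n0 = len(lin.frame_nodes(int(lin.timesteps[0])))
        assert len(summaries) == n0
        for s in summaries:
            assert s.n_mitoses == s.n_final + s.n_dead - 1


class TestDevelopmentalSpeed:
    def test_identical_collapse_times_give_zero(self):
        assert relative_developmental_speed(80.0, [80.0, 80.0]) == 0.0

    def test_printed_collapse_time_arithmetic(self):
        wt = [80.7, 77.7, 86.8]
        assert relative_developmental_speed(92.3, wt) == pytest.approx(12.93, abs=0.01)
        assert relative_developmental_speed(96.0, wt) == pytest.approx(17.45, abs=0.01)

    def test_empty_reference_rejected(self):
        with pytest.raises(StatisticsError):
            relative_developmental_speed(90.0, [])
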