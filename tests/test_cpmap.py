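"""Two-point estimation, grouping, ordering, Kosambi positions."""

import math

import numpy as np
import pandas as pd
import pytest

from radmap import cpmap, simcross
from radmap.cpmap import (
    TwoPointTable,
    build_map,
    estimate_rf,
    estimate_rf_general,
    group_markers,
    kosambi_cm,
    map_positions,
    merge_external_markers,
    order_group,
    pairwise_table,
    lod_testcross,
)
from radmap.genocall import MISSING, SEG_INTERCROSS, SEG_PATERNAL, GenotypeMatrix
from radmap.mapfunc import inverse_kosambi


def tc_calls(pattern, one="np", zero="nn"):
    return [one if c == "1" else zero if c == "0" else MISSING for c in pattern]


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.10) == pytest.approx(10.14, abs=0.005)
        assert kosambi_cm(0.25) == pytest.approx(27.47, abs=0.005)

    def test_matches_direct_evaluation_at_100_points(self):
        for r in np.linspace(0.0, 0.49, 100):
            direct = 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))
            assert kosambi_cm(float(r)) == pytest.approx(direct, abs=1e-9)

    def test_strictly_increasing_and_convex(self):
        r = np.linspace(0.0, 0.49, 200)
        d = kosambi_cm(r)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > -1e-9)
        # map distance always exceeds 100r (in cM) except at 0
        assert np.all(d[1:] >= 100 * r[1:])

    def test_half_maps_to_cap(self):
        assert kosambi_cm(0.5) >= 1e5

    def test_inverse_roundtrip(self):
        for cm in (0.5, 5.0, 20.0, 60.0):
            assert kosambi_cm(inverse_kosambi(cm)) == pytest.approx(cm, rel=1e-9)


class TestEstimateRf:
    def test_fifty_progeny_five_recombinants(self):
        a = tc_calls("0" * 50)
        b = tc_calls("1" * 5 + "0" * 45)
        est = estimate_rf(a, b)
        assert est.r_hat == pytest.approx(0.10)
        assert est.lod == pytest.approx(7.99, abs=0.01)
        assert est.n_informative == 50

    def test_independence_gives_zero_lod(self):
        a = tc_calls("0" * 50)
        b = tc_calls("0" * 25 + "1" * 25)  # exactly half recombinant
        est = estimate_rf(a, b)
        assert est.r_hat == pytest.approx(0.5)
        assert est.lod == 0.0

    def test_zero_recombinants_forty_progeny(self):
        a = tc_calls("01" * 20)
        est = estimate_rf(a, a)
        assert est.r_hat == 0.0
        assert est.lod == pytest.approx(40 * math.log10(2), abs=1e-6)
        assert est.lod == pytest.approx(12.04, abs=0.005)

    def test_phase_chosen_to_minimize_r(self):
        a = tc_calls("01" * 20)
        b = tc_calls("10" * 20)  # repulsion, zero recombinants
        est = estimate_rf(a, b)
        assert est.r_hat == 0.0 and est.phase == "repulsion"

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        a = tc_calls("".join(rng.choice(list("01"), 40)))
        b = tc_calls("".join(rng.choice(list("01"), 40)))
        e1, e2 = estimate_rf(a, b), estimate_rf(b, a)
        assert e1.r_hat == e2.r_hat and e1.lod == e2.lod

    def test_missing_pairs_excluded(self):
        a = tc_calls("0" * 10 + "-" * 5)
        b = tc_calls("0" * 15)
        assert estimate_rf(a, b).n_informative == 10

    def test_cross_parent_testcross_unlinked(self):
        a = tc_calls("01" * 10)
        b = tc_calls("01" * 10, one="lm", zero="ll")
        est = estimate_rf(a, b, SEG_PATERNAL, "lmxll")
        assert est.r_hat == 0.5 and est.lod == 0.0

    def test_grid_search_oracle(self):
        """ML closed form vs exhaustive likelihood grid, 500 pairs."""
        rng = np.random.default_rng(11)
        grid = np.arange(0.0, 0.5001, 0.001)
        for _ in range(500):
            n = int(rng.integers(20, 52))
            r_true = float(rng.uniform(0.0, 0.5))
            a = rng.integers(0, 2, n)
            flips = rng.random(n) < r_true
            b = a ^ flips
            est = estimate_rf(
                tc_calls("".join(map(str, a))), tc_calls("".join(map(str, b)))
            )
            # likelihood over the grid (phase-minimized recombinant count)
            d = int((a != b).sum())
            rec = min(d, n - d)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = rec * np.log(np.maximum(grid, 1e-300)) + (
                    n - rec
                ) * np.log(np.maximum(1 - grid, 1e-300))
            r_grid = grid[int(np.argmax(ll))]
            assert abs(est.r_hat - r_grid) <= 0.001

    def test_intercross_pair_recovers_r(self):
        # hk x hk pair simulated at a known recombination fraction
        rng = np.random.default_rng(21)
        r_true = 0.15
        n = 2000
        codes = {(0, 0): "hh", (1, 1): "kk", (0, 1): "hk", (1, 0): "hk"}
        a_calls, b_calls = [], []
        for _ in range(n):
            gam = []
            for _parent in range(2):
                x = int(rng.integers(0, 2))
                y = x ^ (rng.random() < r_true)
                gam.append((x, y))
            a_calls.append(codes[(gam[0][0], gam[1][0])])
            b_calls.append(codes[(gam[0][1], gam[1][1])])
        est = estimate_rf_general(
            pd.Series(a_calls), pd.Series(b_calls),
            SEG_INTERCROSS, SEG_INTERCROSS,
        )
        assert est.r_hat == pytest.approx(r_true, abs=0.02)
        assert est.lod > 50


class TestGrouping:
    def _table(self, markers, edges):
        m = len(markers)
        r = np.full((m, m), 0.5)
        lod = np.zeros((m, m))
        nmat = np.full((m, m), 50)
        idx = {mk: i for i, mk in enumerate(markers)}
        for a, b, rr, ll in edges:
            i, j = idx[a], idx[b]
            r[i, j] = r[j, i] = rr
            lod[i, j] = lod[j, i] = ll
        np.fill_diagonal(r, 0.0)
        return TwoPointTable(markers=markers, r=r, lod=lod, n=nmat)

    def test_chain_components(self):
        table = self._table(
            ["A", "B", "C", "D"],
            [("A", "B", 0.1, 6), ("B", "C", 0.2, 7), ("C", "D", 0.1, 2)],
        )
        groups = group_markers(table)
        assert sorted(map(len, groups)) == [1, 3]
        assert ["A", "B", "C"] in groups and ["D"] in groups

    def test_fully_linked_single_group(self):
        table = self._table(
            ["A", "B", "C"],
            [("A", "B", 0.05, 9), ("B", "C", 0.05, 9), ("A", "C", 0.1, 8)],
        )
        assert len(group_markers(table)) == 1

    def test_rf_threshold_excludes_loose_pairs(self):
        table = self._table(["A", "B"], [("A", "B", 0.3, 9)])  # r > 0.25
        assert len(group_markers(table)) == 2


class TestOrdering:
    def test_three_markers_additive_distances(self):
        table = TestGrouping()._table(
            ["A", "B", "C"],
            [("A", "B", 0.05, 10), ("B", "C", 0.05, 10), ("A", "C", 0.10, 8)],
        )
        order = order_group(["A", "B", "C"], table)
        assert order in (["A", "B", "C"], ["C", "B", "A"])

    def test_two_markers(self):
        table = TestGrouping()._table(["A", "B"], [("A", "B", 0.1, 9)])
        assert sorted(order_group(["A", "B"], table)) == ["A", "B"]

    def test_simulated_group_order_recovered(self):
        ds = simcross.simulate_testcross_dataset(
            n_lgs=1, markers_per_lg=20, spacing_cm=4.0, n_progeny=51,
            seed=13, missing_rate=0.0, scaffolds_per_lg=1,
        )
        info = ds["info"].copy()
        info["source"] = "radseq"
        matrix = GenotypeMatrix(
            calls=ds["calls"], info=info[["scaffold", "pos", "seg_type", "source"]]
        )
        table = pairwise_table(matrix, "paternal")
        order = order_group(list(matrix.calls.index), table)
        truth = info.loc[order, "cm_true"].to_numpy()
        from scipy.stats import kendalltau
        tau = abs(kendalltau(np.arange(len(order)), truth).statistic)
        assert tau >= 0.9


class TestMapPositions:
    def test_cumulative_kosambi_positions(self):
        table = TestGrouping()._table(
            ["A", "B", "C"],
            [("A", "B", 0.05, 10), ("B", "C", 0.05, 10)],
        )
        pos = map_positions(["A", "B", "C"], table)
        assert pos[0] == 0.0
        assert pos[1] == pytest.approx(5.02, abs=0.005)
        assert pos[2] == pytest.approx(10.03, abs=0.005)

    def test_single_marker_at_zero(self):
        table = TestGrouping()._table(["A"], [])
        assert map_positions(["A"], table) == [0.0]

    def test_missing_adjacent_bridged_by_path(self):
        markers = ["A", "B", "C"]
        m = len(markers)
        r = np.full((m, m), 0.5)
        lod = np.zeros((m, m))
        nmat = np.zeros((m, m), dtype=int)
        for i, j, rr in ((0, 1, 0.1), (1, 2, 0.1)):
            r[i, j] = r[j, i] = rr
            lod[i, j] = lod[j, i] = 8.0
            nmat[i, j] = nmat[j, i] = 50
        table = TwoPointTable(markers=markers, r=r, lod=lod, n=nmat)
        pos = map_positions(["A", "C", "B"], table)  # A-C pair has n=0
        # A->C goes through B: 2 x kosambi(0.1)
        assert pos[1] == pytest.approx(2 * kosambi_cm(0.1), abs=1e-6)


class TestMapAssembly:
    def test_progeny_relabeling_invariance(self):
        ds = simcross.simulate_testcross_dataset(
            n_lgs=2, markers_per_lg=15, spacing_cm=4.0, n_progeny=40,
            seed=19, missing_rate=0.02, scaffolds_per_lg=1,
        )
        info = ds["info"].copy()
        info["source"] = "radseq"
        matrix = GenotypeMatrix(
            calls=ds["calls"], info=info[["scaffold", "pos", "seg_type", "source"]]
        )
        gm1, _ = build_map(matrix, "paternal")
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(matrix.calls.columns))
        matrix2 = GenotypeMatrix(calls=matrix.calls[perm], info=matrix.info)
        gm2, _ = build_map(matrix2, "paternal")
        assert gm1.total_length_cm == pytest.approx(gm2.total_length_cm)
        orders1 = sorted(tuple(g.markers) for g in gm1.groups)
        orders2 = sorted(tuple(g.markers) for g in gm2.groups)
        assert orders1 == orders2


class TestExternalMarkers:
    def _matrix(self, n_markers=5, n_progeny=20):
        rows = {
            f"r{i}": ["nn", "np"] * (n_progeny // 2) for i in range(n_markers)
        }
        calls = pd.DataFrame.from_dict(rows, orient="index")
        calls.columns = [f"p{j+1:02d}" for j in range(n_progeny)]
        info = pd.DataFrame(
            {"scaffold": "s1", "pos": range(n_markers), "seg_type": "nnxnp",
             "source": "radseq"},
            index=pd.Index(list(rows), name="marker"),
        )
        return GenotypeMatrix(calls=calls, info=info)

    def test_external_markers_appended_and_flagged(self):
        matrix = self._matrix()
        ext = pd.DataFrame(
            [["ll", "lm"] * 10, ["lm", "ll"] * 10, ["ll"] * 20],
            index=["e1", "e2", "e3"], columns=matrix.calls.columns,
        )
        # e3 is monomorphic-looking but typed by caller metadata
        merged = merge_external_markers(matrix, ext.iloc[:2])
        assert merged.n_markers == 7
        assert (merged.info.loc[["e1", "e2"], "source"] == "external").all()

    def test_counts_add_up_like_bins_plus_ssrs(self):
        # 634 mapping units + 136 external = 770
        matrix = self._matrix(n_markers=634, n_progeny=10)
        ext = pd.DataFrame(
            [["ll", "lm"] * 5] * 136,
            index=[f"ssr{i}" for i in range(136)],
            columns=matrix.calls.columns,
        )
        merged = merge_external_markers(matrix, ext)
        assert merged.n_markers == 770

    def test_empty_external_table_is_identity(self):
        matrix = self._matrix()
        merged = merge_external_markers(matrix, pd.DataFrame())
        assert merged is matrix

    def test_high_missing_external_dropped(self):
        matrix = self._matrix()
        row = ["ll", "lm"] * 8 + [MISSING] * 4  # 20% missing
        ext = pd.DataFrame([row], index=["e1"], columns=matrix.calls.columns)
        merged = merge_external_markers(matrix, ext)
        assert "e1" not in merged.calls.index

    def test_progeny_mismatch_rejected(self):
        matrix = self._matrix()
        ext = pd.DataFrame([["ll"] * 5], index=["e1"],
                           columns=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            merge_external_markers(matrix, ext)


def test_lod_testcross_reference_points():
    assert lod_testcross(50, 25) == 0.0
    assert lod_testcross(0, 0) == 0.0
    assert lod_testcross(50, 5) == pytest.approx(7.99, abs=0.01)
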