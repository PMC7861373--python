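import itertools

import numpy as np
import pandas as pd
import pytest

from msatpop.bruvo import DistanceMatrix, distance_matrix
from msatpop.delineation import (DelineationError, collapse_mlgs,
                                 exclude_incomplete, match_to_reference,
                                 rarefy_isolates, suggest_threshold,
                                 threshold_scan)
from msatpop.genotype_io import MISSING

from conftest import make_table


def dm_from(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"g{i}" for i in range(len(values))]
    return DistanceMatrix(labels, values)


def ultrametric_chain(gaps):
    """n-point matrix where d(i,j) = max consecutive gap between i and j;
    its agglomerative merge heights are exactly the gap values."""
    n = len(gaps) + 1
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = max(gaps[i:j])
    return dm_from(d)


def transitive_closure_groups(values, threshold):
    """Brute-force oracle: connected components of the graph linking pairs
    with distance < threshold (valid when groups are cleanly separated)."""
    n = len(values)
    groups = [{i} for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if values[i][j] < threshold:
            gi = next(g for g in groups if i in g)
            gj = next(g for g in groups if j in g)
            if gi is not gj:
                groups.remove(gj)
                gi |= gj
    return {frozenset(g) for g in groups}


class TestCollapse:
    def test_threshold_zero_one_strain_per_unique_mlg(self):
        t = make_table([[(10, 10)], [(10, 10)], [(11, 11)], [(12, 12)]])
        a = collapse_mlgs(distance_matrix(t), 0.0)
        assert a.n_strains == 3
        assert a.isolate_to_strain["iso1"] == a.isolate_to_strain["iso2"]

    def test_threshold_one_single_strain(self):
        t = make_table([[(10, 10)], [(20, 20)], [(30, 30)]])
        a = collapse_mlgs(distance_matrix(t), 1.0)
        assert a.n_strains == 1

    def test_two_separated_pairs_at_threshold(self):
        d = [[0.0, 0.1, 0.6, 0.5],
             [0.1, 0.0, 0.5, 0.7],
             [0.6, 0.5, 0.0, 0.1],
             [0.5, 0.7, 0.1, 0.0]]
        a = collapse_mlgs(dm_from(d, list("ABCD")), 0.3)
        assert a.n_strains == 2
        assert a.isolate_to_strain["A"] == a.isolate_to_strain["B"]
        assert a.isolate_to_strain["C"] == a.isolate_to_strain["D"]

    def test_strain_ids_follow_first_appearance(self):
        d = [[0.0, 0.9, 0.1], [0.9, 0.0, 0.9], [0.1, 0.9, 0.0]]
        a = collapse_mlgs(dm_from(d, list("XYZ")), 0.3)
        assert a.isolate_to_strain == {"X": 0, "Y": 1, "Z": 0}

    def test_threshold_comparison_is_strict(self):
        d = [[0.0, 0.3], [0.3, 0.0]]
        assert collapse_mlgs(dm_from(d), 0.3).n_strains == 2

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(DelineationError):
            collapse_mlgs(dm_from([[0.0, 0.1], [0.1, 0.0]]), 1.5)

    @pytest.mark.parametrize("algorithm", ["farthest", "nearest", "average"])
    def test_separated_groups_recovered_for_every_linkage(self, algorithm):
        rng = np.random.default_rng(7)
        # 8 entities in 3 groups: within < 0.2, between > 0.5
        sizes = [3, 3, 2]
        n = sum(sizes)
        labels = np.repeat(np.arange(3), sizes)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            v = (rng.uniform(0.01, 0.19) if labels[i] == labels[j]
                 else rng.uniform(0.51, 0.95))
            d[i, j] = d[j, i] = v
        dm = dm_from(d)
        a = collapse_mlgs(dm, 0.35, algorithm)
        got = {frozenset(np.flatnonzero(
            a.labels_for(dm.labels) == s).tolist())
            for s in set(a.isolate_to_strain.values())}
        assert got == transitive_closure_groups(d, 0.35)

    def test_representative_minimizes_summed_distance(self):
        d = [[0.0, 0.1, 0.2], [0.1, 0.0, 0.1], [0.2, 0.1, 0.0]]
        a = collapse_mlgs(dm_from(d, list("abc")), 0.5)
        assert a.representatives[0] == "b"


class TestThresholdScan:
    def test_equidistant_triple(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        scan = threshold_scan(dm_from(d))
        assert scan.n_strains_at(0.39) == 3
        assert scan.n_strains_at(0.4) == 3      # strict: 0.4 not merged
        assert scan.n_strains_at(0.41) == 1
        assert list(scan.critical_values) == [0.4]
        assert list(scan.n_strains) == [1]

    def test_all_zero_matrix_single_strain_everywhere(self):
        scan = threshold_scan(dm_from(np.zeros((4, 4))))
        assert scan.n_strains_at(0.5) == 1
        assert scan.n_strains_at(1.0) == 1

    def test_scan_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        pts = rng.random(12)
        d = np.abs(pts[:, None] - pts[None, :])
        scan = threshold_scan(dm_from(d))
        counts = [scan.n_strains_at(t) for t in np.linspace(0, 1, 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSuggestThreshold:
    def test_midpoint_of_largest_gap(self):
        dm = ultrametric_chain([0.05, 0.06, 0.07, 0.45, 0.50])
        sug = suggest_threshold(dm, "nearest")
        assert sug.threshold == pytest.approx(0.26)
        assert sug.gap == (pytest.approx(0.07), pytest.approx(0.45))

    def test_single_gap_midpoint(self):
        dm = ultrametric_chain([0.1, 0.9])
        assert suggest_threshold(dm).threshold == pytest.approx(0.5)

    def test_recovers_ground_truth_grouping(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 5)
        d = np.zeros((10, 10))
        for i, j in itertools.combinations(range(10), 2):
            v = (rng.uniform(0.0, 0.1) if labels[i] == labels[j]
                 else rng.uniform(0.6, 0.9))
            d[i, j] = d[j, i] = v
        dm = dm_from(d)
        sug = suggest_threshold(dm)
        a = collapse_mlgs(dm, sug.threshold)
        assert a.n_strains == 2
        assert 0.1 < sug.threshold < 0.6

    def test_all_distances_equal_is_error(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        with pytest.raises(DelineationError, match="no gap"):
            suggest_threshold(dm_from(d))


class TestMatchToReference:
    def _assignment(self, genos, ids):
        t = make_table(genos, ids=ids)
        return collapse_mlgs(distance_matrix(t), 0.3, table=t)

    def _reference(self, genos, names):
        meta = pd.DataFrame({"strain_name": names,
                             "origin": ["x"] * len(names)})
        return make_table(genos, ids=names, metadata=meta)

    def test_identical_query_matches(self):
        a = self._assignment([[(10, 10), (5, 5)], [(20, 20), (9, 9)]],
                             ["q1", "q2"])
        ref = self._reference([[(10, 10), (5, 5)]], ["2015 Strain 2"])
        names = match_to_reference(a, ref, 0.3)
        assert names[a.isolate_to_strain["q1"]] == "2015 Strain 2"
        assert names[a.isolate_to_strain["q2"]].startswith("2017 Strain")

    def test_distance_beyond_threshold_is_new_strain(self):
        # genotype distance (0.375 + 0.4375) / 2 = 0.40625 >= 0.3
        a = self._assignment([[(10, 12), (5, 8)], [(30, 30), (25, 25)]],
                             ["q1", "q2"])
        ref = self._reference([[(10, 14), (5, 5)]], ["ref1"])
        names = match_to_reference(a, ref, 0.3)
        assert names[a.isolate_to_strain["q1"]] == "2017 Strain 1"
        assert names[a.isolate_to_strain["q2"]] == "2017 Strain 2"

    def test_tie_broken_by_reference_name_order(self, caplog):
        a = self._assignment([[(10, 10), (5, 5)], [(30, 30), (25, 25)]],
                             ["q1", "q2"])
        # both references at the same distance (one repeat step at L1)
        ref = self._reference([[(10, 11), (5, 5)], [(9, 10), (5, 5)]],
                              ["B_ref", "A_ref"])
        with caplog.at_level("INFO"):
            names = match_to_reference(a, ref, 0.5)
        assert names[a.isolate_to_strain["q1"]] == "A_ref"
        assert "tie" in caplog.text.lower()


class TestRarefy:
    def _table(self, counts, n_loci=1):
        genos, meta_rows, ids = [], [], []
        k = 0
        for (v, b, s), c in counts.items():
            for _ in range(c):
                iid = f"i{k}"
                ids.append(iid)
                genos.append([(10, 10)] * n_loci)
                meta_rows.append({"isolate_id": iid, "vintage": "2017",
                                  "vineyard": v, "barrel": b, "stage": s})
                k += 1
        return make_table(genos, ids=ids, metadata=pd.DataFrame(meta_rows))

    def test_subsamples_to_n(self):
        t = self._table({("V2", "B1", "early"): 40, ("V2", "B1", "mid"): 35})
        r = rarefy_isolates(t, 32, seed=0)
        assert len(r) == 64

    def test_exact_n_sample_unchanged(self):
        t = self._table({("V2", "B1", "early"): 32})
        r = rarefy_isolates(t, 32, seed=0)
        assert sorted(r.ids) == sorted(t.ids)

    def test_same_seed_identical_subsample(self):
        t = self._table({("V2", "B1", "early"): 47})
        assert rarefy_isolates(t, 32, seed=9).ids == \
            rarefy_isolates(t, 32, seed=9).ids

    def test_undersized_sample_named_in_error(self):
        t = self._table({("V8", "B3", "late"): 10})
        with pytest.raises(DelineationError, match="V8.B3.late"):
            rarefy_isolates(t, 32, seed=0)


def test_exclude_incomplete_drops_partial_mlgs():
    t = make_table([[(1, 1), (2, 2)], [(1, 1), None], [(3, 3), (4, 4)]])
    kept = exclude_incomplete(t)
    assert kept.ids == ["iso1", "iso3"]
    assert not (kept.alleles == MISSING).any()
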