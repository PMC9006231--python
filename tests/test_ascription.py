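"""Strain ascription, min-linkage distances and the adaptive-decay purge."""

import itertools

import numpy as np
import pytest

from wolsweep.ascription import (
    PURGE_DISABLED,
    UNINFECTED,
    PutativeDistanceTable,
    ascribe,
    community_distance_tables,
    min_linkage_distance,
    purge,
    threshold_grid,
)
from wolsweep.design import Community, HostFig, StudyDesign
from wolsweep.enumeration import PSC, PutativeSpecies
from wolsweep.io import PhyloDistances


def _distances(labels, pairs):
    n = len(labels)
    mat = np.zeros((n, n))
    for (a, b), d in pairs.items():
        i, j = labels.index(a), labels.index(b)
        mat[i, j] = mat[j, i] = d
    return PhyloDistances(tuple(labels), mat)


def _psp(host, occ, tips):
    return PutativeSpecies(host, occ, frozenset(tips))


class TestMinLinkage:
    def test_five_by_three_takes_min_over_fifteen_pairs(self):
        tips_a = [f"A{i}" for i in range(5)]
        tips_b = [f"B{j}" for j in range(3)]
        labels = tips_a + tips_b
        rng = np.random.default_rng(3)
        pairs = {
            (a, b): rng.uniform(0.1, 1.0)
            for a, b in itertools.combinations(labels, 2)
        }
        dist = _distances(labels, pairs)
        cross = [(a, b) for a in tips_a for b in tips_b]
        assert len(cross) == 15
        expected = min(dist.between(a, b) for a, b in cross)
        got = min_linkage_distance(
            _psp("h", (1, 0), tips_a), _psp("h", (0, 1), tips_b), dist
        )
        assert got == pytest.approx(expected)

    def test_singletons_reduce_to_the_single_distance(self):
        dist = _distances(["A", "B"], {("A", "B"): 0.42})
        got = min_linkage_distance(
            _psp("h", (1, 0), ["A"]), _psp("h", (0, 1), ["B"]), dist
        )
        assert got == pytest.approx(0.42)

    def test_empty_member_set_rejected(self):
        dist = _distances(["A"], {})
        with pytest.raises(ValueError):
            min_linkage_distance(
                PutativeSpecies("h", (1, 0), frozenset()),
                _psp("h", (0, 1), ["A"]),
                dist,
            )

    def test_equals_exhaustive_scan_on_synthetic_clades(self, study, study_distances):
        records = study.records
        by_species = {}
        for r in records:
            by_species.setdefault(study.truth.species_of_tip[r.tip_id], []).append(
                r.tip_id
            )
        names = sorted(by_species)[:3]
        a = _psp("h", (1, 0), by_species[names[0]])
        b = _psp("h", (0, 1), by_species[names[1]])
        brute = min(
            study_distances.between(x, y)
            for x in by_species[names[0]]
            for y in by_species[names[1]]
        )
        assert min_linkage_distance(a, b, study_distances) == pytest.approx(brute)


def _one_host_design(n_sites=4, community="arf", host="F_arf"):
    return StudyDesign(
        communities=(
            Community(community, (HostFig(host, tuple(str(i) for i in range(n_sites))),)),
        )
    )


class TestAscribe:
    def test_three_species_get_three_distinct_strains(self):
        design = _one_host_design()
        sps = (
            _psp("F_arf", (1, 0, 0, 0), ["T1"]),
            _psp("F_arf", (0, 1, 0, 0), ["T2"]),
            _psp("F_arf", (0, 0, 1, 1), ["T3", "T4"]),
        )
        asc = ascribe(PSC(0, {"F_arf": sps}), design)
        labels = [asc.label_of(sp) for sp in sps]
        assert labels == ["w1", "w2", "w3"]
        assert asc.by_tip["T3"] == asc.by_tip["T4"] == "w3"

    def test_single_species_community_is_uninfected(self):
        design = _one_host_design()
        sp = _psp("F_arf", (1, 1, 1, 1), ["T1", "T2"])
        asc = ascribe(PSC(0, {"F_arf": (sp,)}), design)
        assert asc.label_of(sp) == UNINFECTED

    def test_species_complex_counts_at_community_level(self):
        """Three hosts with one species each in a single community: every
        species is infected with its own strain."""
        design = StudyDesign(
            communities=(
                Community(
                    "complex",
                    (
                        HostFig("F_u", ("200",)),
                        HostFig("F_i", ("200",)),
                        HostFig("F_m", ("200",)),
                    ),
                ),
            )
        )
        sps = {
            h: (_psp(h, (1,), [f"T_{h}"]),) for h in ("F_u", "F_i", "F_m")
        }
        asc = ascribe(PSC(0, sps), design)
        labels = {asc.label_of(sp[0]) for sp in sps.values()}
        assert labels == {"w1", "w2", "w3"}


def _three_species_table():
    sps = (
        _psp("F_arf", (1, 0, 0, 0), ["T1"]),
        _psp("F_arf", (0, 1, 0, 0), ["T2"]),
        _psp("F_arf", (0, 0, 1, 1), ["T3"]),
    )
    mat = np.array(
        [
            [0.0, 0.03, 0.06],
            [0.03, 0.0, 0.06],
            [0.06, 0.06, 0.0],
        ]
    )
    return sps, {"arf": PutativeDistanceTable("arf", sps, mat)}


class TestPurge:
    def test_worked_example_purges_only_the_distant_species(self):
        """Threshold 0.05 with d12 = 0.03, d13 = d23 = 0.06: the first two
        species keep their strains (a neighbour within threshold), only the
        third is purged."""
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        purged = purge(asc, tables, 0.05)
        assert purged.label_of(sps[0]) == "w1"
        assert purged.label_of(sps[1]) == "w2"
        assert purged.label_of(sps[2]) == UNINFECTED
        assert purged.by_tip["T3"] == UNINFECTED

    def test_threshold_at_maximum_distance_purges_nothing(self):
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        purged = purge(asc, tables, 0.06)
        assert purged.labels == asc.labels

    def test_disabled_is_identity(self):
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        assert purge(asc, tables, PURGE_DISABLED) is asc

    def test_two_tight_pairs_survive_intermediate_threshold(self):
        """Each species has a near neighbour, so a threshold between the
        within-pair and between-pair distances purges nothing."""
        sps = tuple(
            _psp("F_arf", occ, [f"T{i}"])
            for i, occ in enumerate([(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)])
        )
        mat = np.full((4, 4), 0.5)
        mat[0, 1] = mat[1, 0] = 0.01
        mat[2, 3] = mat[3, 2] = 0.01
        np.fill_diagonal(mat, 0.0)
        tables = {"arf": PutativeDistanceTable("arf", sps, mat)}
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        purged = purge(asc, tables, 0.1)
        assert purged.labels == asc.labels

    def test_negative_threshold_rejected(self):
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        with pytest.raises(ValueError):
            purge(asc, tables, -0.1)

    def test_threshold_beyond_tree_max_rejected(self):
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        with pytest.raises(ValueError):
            purge(asc, tables, 0.5, max_distance=0.2)

    def test_purged_set_shrinks_as_threshold_grows(self):
        """Monotonicity of the purge across an increasing threshold ladder."""
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        previous = None
        for thr in [0.0, 0.02, 0.04, 0.05, 0.06]:
            purged_set = {
                key
                for key, lab in purge(asc, tables, thr).labels.items()
                if lab == UNINFECTED
            }
            if previous is not None:
                assert purged_set <= previous
            previous = purged_set

    def test_surviving_labels_unchanged(self):
        sps, tables = _three_species_table()
        asc = ascribe(PSC(0, {"F_arf": sps}), _one_host_design())
        purged = purge(asc, tables, 0.05)
        for sp in sps[:2]:
            assert purged.label_of(sp) == asc.label_of(sp)


class TestThresholdGrid:
    def test_linear_spacing_with_disabled_head(self):
        labels = ("A", "B", "C")
        mat = np.array([[0, 0.2, 1.0], [0.2, 0, 0.6], [1.0, 0.6, 0]])
        grid = threshold_grid(PhyloDistances(labels, mat), n_steps=5)
        assert grid[0] is PURGE_DISABLED
        assert grid[1:] == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])

    def test_two_steps_gives_min_and_max(self):
        labels = ("A", "B")
        mat = np.array([[0, 0.3], [0.3, 0]])
        grid = threshold_grid(PhyloDistances(labels, mat), n_steps=2)
        assert grid == [PURGE_DISABLED, pytest.approx(0.3), pytest.approx(0.3)]

    def test_degenerate_tree_yields_sentinel_only(self):
        labels = ("A", "B")
        grid = threshold_grid(PhyloDistances(labels, np.zeros((2, 2))), n_steps=5)
        assert grid == [PURGE_DISABLED]

    def test_fixture_grid_within_tree_extremes(self, study_distances):
        grid = threshold_grid(study_distances, n_steps=10)
        values = grid[1:]
        assert min(values) == pytest.approx(study_distances.min_positive)
        assert max(values) == pytest.approx(study_distances.max_distance)


class TestCommunityDistanceTables:
    def test_tables_are_symmetric_with_zero_diagonal(self, study, study_distances):
        from wolsweep.enumeration import enumerate_study_pscs

        psc = next(enumerate_study_pscs(study.design, study.records))
        tables = community_distance_tables(psc, study.design, study_distances)
        assert set(tables) == {c.name for c in study.design.communities}
        for t in tables.values():
            assert np.allclose(t.matrix, t.matrix.T)
            assert np.allclose(np.diag(t.matrix), 0.0)
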