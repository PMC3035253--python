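"""The ten distance functions and the pairwise-matrix driver."""

import math
import warnings

import numpy as np
import pytest

from ggdist.distances import (
    ALL_INDICES,
    DistanceComponents,
    DistanceSpec,
    IdentityOnlyWarning,
    compute_components,
    distance_matrix,
    ggd,
)
from ggdist.genome_io import genome_from_sequences
from ggdist.matchset import DirectedMatchSet, Match
from ggdist.pipeline import internal_matcher_provider
from ggdist.trimming import greedy_trim

from conftest import mutate, random_sequence

COMPONENTS = DistanceComponents(400, 500, 360, 450, 1000, 800)


class TestIndexNumbering:
    def test_round_trip_bijection(self):
        for idx in ALL_INDICES:
            assert DistanceSpec.from_index(idx).gbdp_index == idx

    def test_family_blocks(self):
        fams = [DistanceSpec.from_index(i).family for i in ALL_INDICES]
        assert fams == [1, 1, 1, 1, 2, 2, 3, 3, 3, 3]

    def test_denominator_assignment(self):
        for idx in (0, 2, 6, 8):
            assert DistanceSpec.from_index(idx).denominator == "sum_lengths"
        for idx in (1, 3, 7, 9):
            assert DistanceSpec.from_index(idx).denominator == "twice_min_length"

    def test_log_assignment(self):
        logged = {i for i in ALL_INDICES if DistanceSpec.from_index(i).log_transform}
        assert logged == {2, 3, 5, 8, 9}

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            DistanceSpec.from_index(10)


class TestFormulas:
    @pytest.mark.parametrize(
        "index,expected",
        [(0, 0.5), (1, 0.4375), (4, 0.1), (6, 0.55), (7, 0.49375)],
    )
    def test_non_log_values(self, index, expected):
        res = ggd(COMPONENTS, DistanceSpec.from_index(index))
        assert res.distance == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("base,logged", [(0, 2), (1, 3), (4, 5), (6, 8), (7, 9)])
    def test_log_variant_is_neg_log_one_minus(self, base, logged):
        d = ggd(COMPONENTS, DistanceSpec.from_index(base)).distance
        dl = ggd(COMPONENTS, DistanceSpec.from_index(logged)).distance
        assert dl == pytest.approx(-math.log(1.0 - d), rel=1e-12)

    def test_family2_log_closed_form(self):
        dl = ggd(COMPONENTS, DistanceSpec.from_index(5)).distance
        assert dl == pytest.approx(-math.log(0.9), rel=1e-12)

    def test_self_comparison_all_zero(self):
        c = DistanceComponents(1000, 1000, 1000, 1000, 1000, 1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentityOnlyWarning)
            for idx in ALL_INDICES:
                assert ggd(c, DistanceSpec.from_index(idx)).distance == 0.0

    def test_no_matches_maximal_distance(self):
        c = DistanceComponents(0, 0, 0, 0, 1000, 800)
        for idx in (0, 1, 4, 6, 7):
            assert ggd(c, DistanceSpec.from_index(idx)).distance == 1.0

    def test_similarity_above_one_clamps_to_zero(self):
        # raw-sum coverage with repeats can push H beyond lambda
        c = DistanceComponents(2000, 2000, 1800, 1800, 1000, 800)
        assert ggd(c, DistanceSpec.from_index(0)).distance == 0.0

    def test_identity_only_warning_for_family2(self):
        c = DistanceComponents(500, 500, 500, 500, 1000, 1000)
        with pytest.warns(IdentityOnlyWarning):
            ggd(c, DistanceSpec.from_index(4))

    def test_monotone_in_identities(self):
        lo = DistanceComponents(400, 500, 300, 400, 1000, 800)
        hi = DistanceComponents(400, 500, 360, 450, 1000, 800)
        for idx in (4, 6, 7):
            spec = DistanceSpec.from_index(idx)
            assert ggd(hi, spec).distance < ggd(lo, spec).distance

    def test_families_1_and_3_monotone_in_h(self):
        lo = DistanceComponents(300, 400, 280, 380, 1000, 800)
        hi = DistanceComponents(400, 500, 280, 380, 1000, 800)
        for idx in (0, 1):
            spec = DistanceSpec.from_index(idx)
            assert ggd(hi, spec).distance < ggd(lo, spec).distance

    def test_mum_degeneracy_family1_equals_family3(self):
        """Exact-match input (I == H): families 1 and 3 coincide, family 2
        is identically zero."""
        c = DistanceComponents(600, 700, 600, 700, 2000, 1800)
        for a, b in [(0, 6), (1, 7), (2, 8), (3, 9)]:
            assert (
                ggd(c, DistanceSpec.from_index(a)).distance
                == ggd(c, DistanceSpec.from_index(b)).distance
            )
        with pytest.warns(IdentityOnlyWarning):
            assert ggd(c, DistanceSpec.from_index(4)).distance == 0.0


class TestComponents:
    def test_direct_summation(self):
        gx = genome_from_sequences("x", [("xc", "A" * 1000)])
        gy = genome_from_sequences("y", [("yc", "A" * 800)])
        xy = DirectedMatchSet(
            "x", "y",
            [Match("xc", "yc", 0, 400, 0, 400, "+", 400, 360, 10.0)],
            1000, 800,
        )
        yx = DirectedMatchSet(
            "y", "x",
            [Match("yc", "xc", 0, 500, 0, 500, "+", 500, 450, 10.0)],
            800, 1000,
        )
        c = compute_components(xy, yx, gx, gy)
        assert (c.h_xy, c.h_yx, c.i_xy, c.i_yx) == (400, 500, 360, 450)
        assert (c.len_x, c.len_y) == (1000, 800)

    def test_empty_sets_zero_components(self):
        gx = genome_from_sequences("x", [("xc", "ACGT" * 10)])
        gy = genome_from_sequences("y", [("yc", "ACGT" * 10)])
        xy = DirectedMatchSet("x", "y", [], 40, 40)
        yx = DirectedMatchSet("y", "x", [], 40, 40)
        c = compute_components(xy, yx, gx, gy)
        assert (c.h_xy, c.h_yx, c.i_xy, c.i_yx) == (0, 0, 0, 0)

    def test_genome_id_mismatch_rejected(self):
        gx = genome_from_sequences("x", [("xc", "ACGT")])
        gy = genome_from_sequences("y", [("yc", "ACGT")])
        xy = DirectedMatchSet("other", "y", [], 4, 4)
        yx = DirectedMatchSet("y", "x", [], 4, 4)
        with pytest.raises(ValueError, match="do not match"):
            compute_components(xy, yx, gx, gy)


class TestDistanceMatrix:
    def test_three_genomes_symmetric(self, rng):
        genomes = [
            genome_from_sequences(f"g{i}", [(f"g{i}c", random_sequence(rng, 2000))])
            for i in range(3)
        ]
        df, results, failures = distance_matrix(
            genomes, internal_matcher_provider(12), DistanceSpec.from_index(6)
        )
        assert failures == []
        assert len(results) == 3
        assert np.allclose(df.values, df.values.T)
        assert np.all(np.diag(df.values) == 0)

    def test_duplicated_genome_distance_zero(self, rng):
        seq = random_sequence(rng, 3000)
        g1 = genome_from_sequences("g1", [("g1c", seq)])
        g2 = genome_from_sequences("g2", [("g2c", seq)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentityOnlyWarning)
            df, _, _ = distance_matrix(
                [g1, g2], internal_matcher_provider(20),
                DistanceSpec.from_index(4),
            )
        assert df.loc["g1", "g2"] == 0.0

    def test_provider_failure_marks_pair_missing(self, rng):
        genomes = [
            genome_from_sequences(f"g{i}", [(f"g{i}c", random_sequence(rng, 1500))])
            for i in range(3)
        ]
        inner = internal_matcher_provider(12)

        def flaky(query, subject):
            if {query.genome_id, subject.genome_id} == {"g0", "g2"}:
                raise RuntimeError("aligner crashed")
            return inner(query, subject)

        df, results, failures = distance_matrix(
            genomes, flaky, DistanceSpec.from_index(6)
        )
        assert len(failures) == 1
        assert np.isnan(df.loc["g0", "g2"])
        assert not np.isnan(df.loc["g0", "g1"])
        assert len(results) == 2


def test_trimmed_pipeline_matches_hand_component_sum(rng):
    """End-to-end: matcher -> trim -> components equals manual totals."""
    base = random_sequence(rng, 2000)
    gx = genome_from_sequences("x", [("xc", base)])
    gy = genome_from_sequences("y", [("yc", mutate(rng, base, 0.02))])
    provider = internal_matcher_provider(15)
    t_xy = greedy_trim(provider(gx, gy))
    t_yx = greedy_trim(provider(gy, gx))
    c = compute_components(t_xy, t_yx, gx, gy)
    assert c.h_xy == sum(m.length for m in t_xy.matches)
    assert c.i_yx == sum(m.identities for m in t_yx.matches)
    d = ggd(c, DistanceSpec.from_index(6)).distance
    assert 0.0 < d < 1.0
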