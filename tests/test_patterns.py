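import itertools

import numpy as np
import pandas as pd
import pytest

from tabletrade import (
    SherdRecord,
    TimeGrid,
    annual_weight,
    empirical_patterns,
    parse_records,
    presence_probability,
)
from tabletrade.patterns import read_pattern, write_patterns


def frame(rows):
    return pd.DataFrame(rows, columns=["site", "ware", "year_from", "year_to"])


class TestParseRecords:
    def test_direct_mapping(self):
        recs = parse_records(frame([("S1", "ESA", 1, 10)]))
        assert recs == [SherdRecord("S1", "ESA", 1, 10)]

    def test_backwards_range_rejected_with_diagnostic(self):
        df = frame([("S1", "ESA", 50, 10), ("S1", "ESB", 1, 5)])
        with pytest.warns(UserWarning, match="backwards"):
            recs = parse_records(df)
        assert len(recs) == 1
        with pytest.raises(ValueError, match="backwards"):
            parse_records(df, on_error="raise")

    def test_unknown_ware_rejected(self):
        df = frame([("S1", "AMPHORA", 1, 10), ("S1", "ESA", 1, 10)])
        with pytest.warns(UserWarning, match="unknown ware"):
            recs = parse_records(df)
        assert len(recs) == 1

    def test_count_preserved(self, tmp_path):
        path = tmp_path / "sherds.csv"
        frame([("S1", "ESA", 1, 10), ("S2", "ESB", 0, 99), ("S1", "ITS", -30, 20)]).to_csv(
            path, index=False
        )
        assert len(parse_records(path)) == 3

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            parse_records(frame([]))


class TestAnnualWeight:
    @pytest.mark.parametrize(
        "y0, y1, expected",
        [(1, 10, 0.10), (1, 100, 0.01), (5, 5, 1.0), (-200, -101, 0.01)],
    )
    def test_uniform_spread(self, y0, y1, expected):
        assert annual_weight(SherdRecord("S", "ESA", y0, y1)) == pytest.approx(expected)

    def test_backwards_range_unconstructible(self):
        with pytest.raises(ValueError):
            SherdRecord("S", "ESA", 10, 1)


class TestPresenceProbability:
    grid = TimeGrid(1, 11, 10)  # one bin covering AD 1-10

    def test_single_decade_record(self):
        recs = [SherdRecord("S1", "ESA", 1, 10)]
        assert presence_probability(recs, "S1", "ESA", self.grid) == pytest.approx([0.1])

    def test_two_identical_records_sum(self):
        recs = [SherdRecord("S1", "ESA", 1, 10)] * 2
        assert presence_probability(recs, "S1", "ESA", self.grid) == pytest.approx([0.2])

    def test_cap_at_one(self):
        recs = [SherdRecord("S1", "ESA", 1, 10)] * 20
        assert presence_probability(recs, "S1", "ESA", self.grid) == pytest.approx([1.0])

    def test_no_records_is_zero(self):
        assert presence_probability([], "S1", "ESA", self.grid) == pytest.approx([0.0])

    def test_record_outside_grid_contributes_zero(self):
        recs = [SherdRecord("S1", "ESA", 500, 600)]
        assert presence_probability(recs, "S1", "ESA", self.grid) == pytest.approx([0.0])


from hypothesis import given, settings
from hypothesis import strategies as st

from tabletrade.patterns import _poisson_binomial


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=5))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_poisson_binomial_matches_enumeration(probs):
    """The diversity-count expansion agrees with exhaustive enumeration and
    always sums to one."""
    dist = _poisson_binomial(np.array(probs))
    expected = brute_force_diversity(probs)
    np.testing.assert_allclose(dist, expected, atol=1e-9)
    assert dist.sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_diversity(probs):
    """Poisson-binomial by exhaustive enumeration over presence outcomes."""
    n = len(probs)
    out = np.zeros(n + 1)
    for outcome in itertools.product([0, 1], repeat=n):
        p = 1.0
        for present, q in zip(outcome, probs):
            p *= q if present else 1 - q
        out[sum(outcome)] += p
    return out


class TestEmpiricalPatterns:
    def test_single_site_single_ware(self):
        grid = TimeGrid(0, 20, 10)
        recs = [SherdRecord("S1", "ESA", 0, 9)]
        A, B = empirical_patterns(recs, grid=grid)
        assert A.values[0, 0] == pytest.approx(0.1)
        assert B.values[0, 1] == pytest.approx(0.1)  # P(exactly one ware)
        assert B.values[1, 0] == pytest.approx(1.0)  # empty bin: all mass at k=0

    def test_no_records_with_declared_sites(self):
        grid = TimeGrid(0, 20, 10)
        A, B = empirical_patterns([], grid=grid, sites=["S1", "S2"])
        assert np.all(A.values == 0)
        assert np.all(B.values[:, 0] == 1.0)

    def test_empty_site_list_is_error(self):
        with pytest.raises(ValueError, match="site"):
            empirical_patterns([], sites=[])

    def test_matches_poisson_binomial_enumeration(self):
        grid = TimeGrid(0, 10, 10)
        recs = [
            SherdRecord("S1", "ESA", 0, 3),  # presence 4/10 * 1/4 summed.. see below
            SherdRecord("S1", "ESB", 0, 9),
            SherdRecord("S2", "ESA", 2, 6),
        ]
        A, B = empirical_patterns(recs, grid=grid, wares=("ESA", "ESB"))
        # per-site presence probabilities computed independently
        p = {
            (s, w): presence_probability(recs, s, w, grid)[0]
            for s in ("S1", "S2")
            for w in ("ESA", "ESB")
        }
        expected_B = (
            brute_force_diversity([p[("S1", "ESA")], p[("S1", "ESB")]])
            + brute_force_diversity([p[("S2", "ESA")], p[("S2", "ESB")]])
        ) / 2
        np.testing.assert_allclose(B.values[0], expected_B, atol=1e-12)
        np.testing.assert_allclose(
            A.values[0],
            [(p[("S1", "ESA")] + p[("S2", "ESA")]) / 2, (p[("S1", "ESB")] + p[("S2", "ESB")]) / 2],
            atol=1e-12,
        )

    def test_rows_of_B_sum_to_one(self):
        rng = np.random.default_rng(7)
        recs = [
            SherdRecord(f"S{rng.integers(5)}", w, int(y), int(y + rng.integers(1, 120)))
            for w in ("ESA", "ESB", "ESC")
            for y in rng.integers(-200, 250, 8)
        ]
        _, B = empirical_patterns(recs)
        np.testing.assert_allclose(B.values.sum(axis=1), 1.0, atol=1e-9)

    def test_binary_presence_reduces_to_histogram(self):
        # with presence probabilities in {0,1} the diversity distribution is
        # the empirical histogram of per-site ware counts
        grid = TimeGrid(0, 10, 10)
        recs = [
            SherdRecord("S1", "ESA", 0, 9),
            SherdRecord("S1", "ESB", 0, 9),
            SherdRecord("S2", "ESA", 0, 9),
        ]
        A, B = empirical_patterns(recs, grid=grid, wares=("ESA", "ESB"), presence="threshold")
        np.testing.assert_allclose(B.values[0], [0.0, 0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(A.values[0], [1.0, 0.5], atol=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        recs = []
        for _ in range(40):
            y0 = int(rng.integers(-200, 250))
            recs.append(
                SherdRecord(f"S{rng.integers(4)}", "ESA", y0, y0 + int(rng.integers(0, 50)))
            )
        shift = 30  # whole bins
        shifted = [
            SherdRecord(r.site_id, r.ware, r.year_from + shift, r.year_to + shift)
            for r in recs
        ]
        grid = TimeGrid(-200, 300, 10)
        grid2 = TimeGrid(-200 + shift, 300 + shift, 10)
        A1, B1 = empirical_patterns(recs, grid=grid, wares=("ESA",))
        A2, B2 = empirical_patterns(shifted, grid=grid2, wares=("ESA",))
        np.testing.assert_allclose(A1.values, A2.values, atol=1e-12)
        np.testing.assert_allclose(B1.values, B2.values, atol=1e-12)

    def test_entries_bounded(self):
        rng = np.random.default_rng(11)
        recs = [
            SherdRecord("S0", "ESA", int(y), int(y) + 9)
            for y in rng.integers(-200, 290, 200)
        ]
        A, B = empirical_patterns(recs)
        for M in (A, B):
            assert np.all(M.values >= 0) and np.all(M.values <= 1)


class TestPatternIO:
    def test_round_trip(self, tmp_path):
        grid = TimeGrid(0, 20, 10)
        recs = [SherdRecord("S1", "ESA", 0, 9), SherdRecord("S2", "ESB", 10, 19)]
        A, B = empirical_patterns(recs, grid=grid)
        paths = write_patterns(A, B, tmp_path)
        A2 = read_pattern(paths["A"], "A")
        B2 = read_pattern(paths["B"], "B")
        np.testing.assert_allclose(A2.values, A.values)
        np.testing.assert_allclose(B2.values, B.values)
        assert A2.grid == grid
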