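"""Chain coding: rediscretization, normalization, symbols, distance, tortuosity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from p300shape import (
    Chain,
    Curve,
    chain_distance,
    default_segment_count,
    encode_chain,
    format_chain,
    normalize_curve,
    parse_chains,
    resample_curve,
    tortuosity,
)

from conftest import random_curve

symbols = st.integers(-99, 99).map(lambda i: i / 100.0)
chains16 = st.lists(symbols, min_size=16, max_size=16).map(lambda s: Chain(np.array(s)))


class TestResample:
    def test_reference_regime_indices(self):
        # 204 samples at 16 segments: spacing 12.0, endpoints 1,13,...,193
        c = random_curve(204)
        r = resample_curve(c, 16)
        np.testing.assert_array_equal(r.x, np.arange(1, 194, 12))
        assert len(r) == 17

    def test_max_segments_keeps_every_sample(self):
        c = random_curve(30)
        r = resample_curve(c, 29)
        np.testing.assert_array_equal(r.x, c.x)
        np.testing.assert_array_equal(r.y, c.y)

    def test_two_point_case(self):
        r = resample_curve(Curve(np.arange(1, 11), np.arange(10.0)), 1)
        np.testing.assert_array_equal(r.x, [1, 6])

    def test_segments_must_be_fewer_than_samples(self):
        with pytest.raises(ValueError, match="S < T"):
            resample_curve(random_curve(10), 10)

    def test_selected_points_are_existing_samples(self):
        c = random_curve(97, seed=3)
        r = resample_curve(c, 11)
        pos = {x: y for x, y in zip(c.x, c.y)}
        assert all(pos[x] == y for x, y in zip(r.x, r.y))


class TestNormalize:
    def test_affine_case(self):
        nc = normalize_curve(Curve([1, 2, 3], [-5.0, 0.0, 5.0]))
        np.testing.assert_allclose(nc.x, [0, 0.5, 1])
        np.testing.assert_allclose(nc.y, [0, 0.5, 1])

    def test_idempotent_on_normalized(self):
        nc = normalize_curve(Curve([1, 2, 5], [0.25, 1.0, 0.0]))
        again = normalize_curve(Curve(nc.x * 4 + 1, nc.y))  # x strictly increasing ints
        np.testing.assert_allclose(again.y, nc.y)
        assert nc.x.min() == 0 and nc.x.max() == 1

    def test_flat_curve_maps_to_zero(self):
        nc = normalize_curve(Curve([1, 2, 3], [4.0, 4.0, 4.0]))
        np.testing.assert_array_equal(nc.y, [0, 0, 0])


class TestEncode:
    def test_horizontal_curve_gives_zero_chain(self):
        c = Curve(np.arange(1, 51), np.full(50, 3.3))
        chain = encode_chain(c, 8)
        np.testing.assert_array_equal(chain.symbols, np.zeros(8))

    def test_straight_ramp_codes_the_diagonal(self):
        # a line maps to the unit-square diagonal: every segment at 45 degrees
        c = Curve(np.arange(1, 205), 0.37 * np.arange(204) - 5.0)
        chain = encode_chain(c, 16)
        expected = round(np.degrees(np.arctan2(1.0, 1.0)) / 90.0, 2)
        np.testing.assert_allclose(chain.symbols, expected)
        assert expected == 0.5

    def test_y_mirror_negates_chain(self):
        c = random_curve(204, seed=5)
        mirrored = Curve(c.x, -c.y)
        np.testing.assert_allclose(
            encode_chain(mirrored, 16).symbols, -encode_chain(c, 16).symbols
        )

    @given(st.integers(0, 20), st.floats(-500, 500))
    def test_translation_invariance(self, seed, offset):
        c = random_curve(100, seed=seed)
        shifted = Curve(c.x, c.y + offset)
        np.testing.assert_array_equal(
            encode_chain(c, 10).symbols, encode_chain(shifted, 10).symbols
        )

    def test_dy_mode_codes_normalized_rise(self):
        c = random_curve(100, seed=1)
        nc = normalize_curve(resample_curve(c, 10))
        chain = encode_chain(c, 10, mode="dy")
        expected = np.clip(np.round(np.diff(nc.y), 2), -0.99, 0.99)
        np.testing.assert_allclose(chain.symbols, expected, atol=5e-3)

    def test_locality_of_endpoint_perturbation(self):
        # spacing 10: resampling keeps samples 1,11,...,91 of 100
        rng = np.random.default_rng(2)
        y = rng.uniform(-0.4, 0.4, 100)
        y[0], y[49] = -1.0, 1.0  # pin the extremes away from the edit site
        base = encode_chain(Curve(np.arange(1, 101), y), 9).symbols
        bumped = y.copy()
        bumped[30] += 0.2  # sample 31 = endpoint m=3, shared by segments 3 and 4
        pert = encode_chain(Curve(np.arange(1, 101), bumped), 9).symbols
        changed = np.flatnonzero(base != pert)
        assert set(changed) <= {2, 3}

    def test_non_endpoint_perturbation_changes_nothing(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(-0.4, 0.4, 100)
        base = encode_chain(Curve(np.arange(1, 101), y), 9).symbols
        y2 = y.copy()
        y2[35] += 0.1  # sample 36 is discarded by the rediscretization
        pert = encode_chain(Curve(np.arange(1, 101), y2), 9).symbols
        np.testing.assert_array_equal(base, pert)


class TestChainInvariants:
    def test_symbols_must_be_quantized_and_bounded(self):
        with pytest.raises(ValueError, match="two decimals"):
            Chain(np.array([0.123]))
        with pytest.raises(ValueError, match=r"\(-1, 1\)"):
            Chain(np.array([1.0]))

    def test_text_dialect_roundtrip(self, fixture_chains):
        for chain in fixture_chains.values():
            assert parse_chains(format_chain(chain))[0] == chain

    def test_comments_and_parentheses_tolerated(self):
        text = "# a comment\n(0.05 -0.02 0)  # trailing\n"
        (chain,) = parse_chains(text)
        np.testing.assert_array_equal(chain.symbols, [0.05, -0.02, 0.0])


class TestDistance:
    def test_published_worked_examples(self, fixture_chains):
        fx = fixture_chains
        assert chain_distance(fx["template"], fx["p300"]) == pytest.approx(0.55)
        assert chain_distance(fx["template"], fx["nonp300"]) == pytest.approx(0.92)

    def test_self_distance_zero(self, fixture_chains):
        assert chain_distance(fixture_chains["fig1"], fixture_chains["fig1"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            chain_distance(Chain(np.array([0.1])), Chain(np.array([0.1, 0.2])))

    @given(chains16, chains16, chains16)
    def test_metric_axioms(self, a, b, c):
        dab = chain_distance(a, b)
        assert dab >= 0
        assert dab == chain_distance(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= chain_distance(a, c) + chain_distance(c, b) + 1e-9


class TestTortuosity:
    def test_published_value(self, fixture_chains):
        assert tortuosity(fixture_chains["fig1"]) == pytest.approx(0.64)

    def test_flat_chain_zero(self):
        assert tortuosity(Chain(np.zeros(16))) == 0.0

    def test_forced_arithmetic(self):
        assert tortuosity(Chain(np.array([0.5, -0.5]))) == pytest.approx(1.0)

    @given(chains16)
    def test_bounded_by_max_symbol(self, chain):
        assert tortuosity(chain) <= 16 * np.abs(chain.symbols).max() + 1e-12

    @given(chains16)
    def test_monotone_in_symbol_magnitude(self, chain):
        grown = Chain(
            np.clip(
                np.round(chain.symbols + 0.01 * np.sign(chain.symbols), 2), -0.99, 0.99
            )
        )
        assert tortuosity(grown) >= tortuosity(chain) - 1e-12


def test_default_segment_count_matches_resampling_rate():
    # 20 Hz effective resampling of an 800 ms epoch: 16 segments
    assert default_segment_count(800.0, 20.0) == 16
    assert default_segment_count(1000.0, 20.0) == 20
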