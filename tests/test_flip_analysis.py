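"""%FL statistic, Monte-Carlo null, significance calls and propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncytia.compartment_model import (
    SyntheticMovie,
    closed_form_two_compartment,
    make_fixture,
    make_null_movie,
)
from syncytia.flip_analysis import (
    ROI,
    IntensityTrace,
    NullDistribution,
    SignificanceCall,
    classify_loss,
    converted_signal_detected,
    count_connected_nuclei,
    measure_zone_trace,
    monte_carlo_null,
    most_stringent_threshold,
    percent_fluorescence_loss,
    propagation_fraction,
    zone_roi,
)


def _uniform_movie(value: float, t: int = 4, hw: int = 16) -> SyntheticMovie:
    return SyntheticMovie(
        data=np.full((t, 1, hw, hw, 1), value, dtype=float),
        channel_names=["green"],
        pixel_size=0.5,
        frame_interval=1.0,
    )


def test_trace_on_constant_image_and_single_pixel_roi():
    movie = _uniform_movie(7.0)
    roi = ROI(id="r", shape="rectangle", vertices=((2, 2), (8, 8)))
    trace = measure_zone_trace(movie, roi, "green")
    np.testing.assert_array_equal(trace.values, 7.0)
    movie.data[:, 0, 3, 3, 0] = [1.0, 2.0, 3.0, 4.0]
    one = ROI(id="p", shape="rectangle", vertices=((3, 3), (4, 4)))
    np.testing.assert_array_equal(
        measure_zone_trace(movie, one, "green").values, [1, 2, 3, 4]
    )


def test_roi_shift_tracks_drifted_zone():
    """An integer-pixel ROI shift from a given frame onward follows a zone
    that drifted late in the movie."""
    movie = _uniform_movie(0.0, t=6, hw=16)
    movie.data[:3, 0, 2:6, 2:6, 0] = 9.0  # zone at (2, 2) early
    movie.data[3:, 0, 2:6, 8:12, 0] = 9.0  # zone moved 6 px right
    roi = ROI(id="z", shape="rectangle", vertices=((2, 2), (6, 6)))
    drifting = measure_zone_trace(movie, roi, "green")
    corrected = measure_zone_trace(movie, roi, "green", shift=(3, (0, 6)))
    assert drifting.values[-1] == 0.0
    np.testing.assert_array_equal(corrected.values, 9.0)


def test_polygon_roi_mask_and_bounds():
    movie = _uniform_movie(1.0)
    tri = ROI(id="t", shape="polygon", vertices=((1, 1), (1, 10), (10, 1)))
    assert measure_zone_trace(movie, tri, "green").values[0] == 1.0
    with pytest.raises(ValueError, match="bounds"):
        ROI(id="o", shape="rectangle", vertices=((0, 0), (99, 99))).mask((16, 16))


def test_percent_loss_formula():
    tr = IntensityTrace("r", "green", np.array([100.0, 80.0, 50.0]), np.arange(3.0))
    assert percent_fluorescence_loss(tr, 0, -1).percent_loss == pytest.approx(0.5)
    tr2 = IntensityTrace("r", "green", np.array([5.0, 5.0]), np.arange(2.0))
    assert percent_fluorescence_loss(tr2, 0, -1).percent_loss == pytest.approx(0.0)
    with pytest.raises(ValueError, match="positive"):
        percent_fluorescence_loss(
            IntensityTrace("r", "green", np.array([0.0, 1.0]), np.arange(2.0)), 0, -1
        )


def test_bleached_zone_loss_matches_closed_form(two_open_movie):
    """On the two-compartment fixture the bleached-zone %FL agrees with the
    analytic two-compartment solution (decay and background corrected)."""
    movie = two_open_movie
    proto = movie.truth_protocol
    graph = movie.truth_graph
    k = graph.edges[0].rate
    beta = proto.event_rate
    trace = measure_zone_trace(movie, zone_roi(movie, "n1"), "green")
    meas = percent_fluorescence_loss(trace, t_start=(0, proto.pre_frames))
    # analytic concentration at Tend, including per-frame decay and offsets
    t_bleach = proto.event_frames * proto.frame_interval
    c1, _ = closed_form_two_compartment(k, beta, t_bleach)
    n_end = proto.n_frames - 1
    decay_end = (1 - proto.decay_for("green")) ** n_end
    start_frames = np.arange(proto.pre_frames)
    decay_start = np.mean((1 - proto.decay_for("green")) ** start_frames)
    gain, background = 100.0, 10.0
    i_start = background + gain * decay_start
    i_end = background + gain * decay_end * c1
    expected = 1.0 - i_end / i_start
    assert meas.percent_loss == pytest.approx(expected, abs=1e-3)


def test_null_threshold_equals_uniform_decay_loss():
    """Noise-free uniform per-frame decay: every square samples the same %FL,
    so the threshold equals that value."""
    t = 11
    data = np.ones((t, 1, 64, 64, 1)) * (0.99 ** np.arange(t))[:, None, None, None, None]
    movie = SyntheticMovie(data=data, channel_names=["green"], pixel_size=0.5,
                           frame_interval=1.0)
    null = monte_carlo_null(movie, "green", n_squares=1000, square_size_um=5.0, seed=1,
                            t_start=0)
    expected = 1.0 - 0.99 ** (t - 1)
    assert null.threshold == pytest.approx(expected, abs=1e-12)
    assert np.allclose(null.samples, expected)


def test_null_threshold_matches_brute_force_resampling():
    """For pure i.i.d. Gaussian pixel noise the square-%FL quantile agrees
    with a direct large-sample simulation of the same statistic."""
    rng = np.random.default_rng(5)
    t, hw, sd, mean = 8, 100, 5.0, 100.0
    data = rng.normal(mean, sd, size=(t, 1, hw, hw, 1))
    movie = SyntheticMovie(data=data, channel_names=["g"], pixel_size=1.0,
                           frame_interval=1.0)
    side = 10
    null = monte_carlo_null(movie, "g", n_squares=10_000, square_size_um=side,
                            seed=2, t_start=0)
    # oracle: %FL of a square mean = 1 - end/start with independent means
    m = 200_000
    sq_sd = sd / side
    start = rng.normal(mean, sq_sd, m)
    end = rng.normal(mean, sq_sd, m)
    oracle = np.quantile(1.0 - end / start, 0.95)
    assert null.threshold == pytest.approx(oracle, abs=0.005)


def test_null_requires_square_to_fit_and_enough_samples():
    movie = _uniform_movie(1.0, hw=8)
    with pytest.raises(ValueError, match="does not fit"):
        monte_carlo_null(movie, "green", n_squares=1000, square_size_um=100.0, seed=0)
    with pytest.raises(ValueError, match="1000"):
        monte_carlo_null(movie, "green", n_squares=10, square_size_um=2.0, seed=0)


def test_exclusion_mask_respected():
    movie = make_null_movie(shape=(64, 64), n_frames=6, seed=3, pixel_size=1.0)
    mask = np.zeros((64, 64), dtype=bool)
    mask[:, 32:] = True
    null = monte_carlo_null(movie, "green", n_squares=1000, square_size_um=8.0,
                            seed=4, exclusion_mask=mask, t_start=0)
    assert null.n_squares == 1000  # all squares found a place in the free half


def test_classification_is_strict_at_threshold():
    null = NullDistribution(channel="green", samples=np.zeros(1), square_size_um=10,
                            confidence=0.95, threshold=0.191, n_squares=10_000)
    sig = classify_loss(_meas(0.47), null)
    assert sig.significant
    assert not classify_loss(_meas(0.13), null).significant
    assert not classify_loss(_meas(0.191), null).significant  # boundary: not significant
    with pytest.raises(ValueError, match="channel"):
        classify_loss(_meas(0.3, channel="red"), null)


def _meas(pfl, channel="green"):
    from syncytia.flip_analysis import FLIPMeasurement

    return FLIPMeasurement(roi_id="z", channel=channel, t_start=(0, 1), t_end=5,
                           percent_loss=pfl)


def test_most_stringent_threshold_keeps_largest():
    mk = lambda thr: NullDistribution("green", np.zeros(1), 10, 0.95, thr, 10_000)
    assert most_stringent_threshold([mk(0.12), mk(0.191), mk(0.15)]) == 0.191
    with pytest.raises(ValueError, match="different channels"):
        most_stringent_threshold(
            [mk(0.1), NullDistribution("red", np.zeros(1), 10, 0.95, 0.2, 10_000)]
        )


def test_connected_nuclei_matches_reachability_oracle(chain3_movie):
    """All-open chain: every nucleus is reachable from the bleached end, so
    the count equals the graph-reachability total."""
    movie = chain3_movie
    proto = movie.truth_protocol
    null = monte_carlo_null(movie, "red", seed=9)
    calls = []
    for zone in ("n2", "n3"):
        tr = measure_zone_trace(movie, zone_roi(movie, zone), "green")
        meas = percent_fluorescence_loss(tr, t_start=(0, proto.pre_frames))
        calls.append(SignificanceCall(zone, "green", meas.percent_loss,
                                      null.threshold, meas.percent_loss > null.threshold))
    nuclei = [
        (f"nuc{i}_{n.id}", n.id)
        for n in movie.truth_graph.nodes
        for i in range(n.nuclei_count)
    ]
    got = count_connected_nuclei(calls, nuclei, bleached_zone="n1")
    reachable = next(
        c for c in movie.truth_graph.connected_components() if "n1" in c
    )
    oracle = sum(n.nuclei_count for n in movie.truth_graph.nodes if n.id in reachable)
    assert got == oracle == 7


def test_connected_nuclei_closed_bridge(two_closed_movie):
    movie = two_closed_movie
    proto = movie.truth_protocol
    null = monte_carlo_null(movie, "red", seed=9)
    tr = measure_zone_trace(movie, zone_roi(movie, "n2"), "green")
    meas = percent_fluorescence_loss(tr, t_start=(0, proto.pre_frames))
    call = SignificanceCall("n2", "green", meas.percent_loss, null.threshold,
                            meas.percent_loss > null.threshold)
    nuclei = [("a", "n1"), ("b", "n1"), ("c", "n2"), ("d", "n2"), ("e", "n2")]
    assert count_connected_nuclei([call], nuclei, bleached_zone="n1") == 2
    with pytest.raises(ValueError, match="zone"):
        count_connected_nuclei([call], [("x", None)], bleached_zone="n1")


def test_propagation_fraction_trivia_and_errors():
    assert propagation_fraction([False, False, False]) == 0.0
    assert propagation_fraction([True, True, True]) == 100.0
    assert propagation_fraction([True, False]) == 50.0
    with pytest.raises(ValueError):
        propagation_fraction([])


def test_converted_detection_requires_signal():
    rng = np.random.default_rng(0)
    flat = IntensityTrace("z", "kaede_converted", rng.normal(50, 1, 40), np.arange(40.0))
    rising = IntensityTrace("z", "kaede_converted",
                            np.concatenate([rng.normal(50, 1, 10), np.full(30, 500.0)]),
                            np.arange(40.0))
    assert not converted_signal_detected(flat, background_frames=(0, 10))
    assert converted_signal_detected(rising, background_frames=(0, 10))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gain=st.floats(min_value=0.1, max_value=100.0))
def test_percent_loss_gain_invariance(gain):
    """%FL is invariant to a multiplicative gain (but not to an offset)."""
    vals = np.array([120.0, 110.0, 60.0])
    tr = IntensityTrace("r", "g", vals, np.arange(3.0))
    tr_scaled = IntensityTrace("r", "g", vals * gain, np.arange(3.0))
    a = percent_fluorescence_loss(tr, 0, -1).percent_loss
    b = percent_fluorescence_loss(tr_scaled, 0, -1).percent_loss
    assert a == pytest.approx(b, rel=1e-12)
    offset = percent_fluorescence_loss(
        IntensityTrace("r", "g", vals + 100.0, np.arange(3.0)), 0, -1
    ).percent_loss
    assert offset != pytest.approx(a, rel=1e-6)


def test_null_coverage_by_construction():
    """The nearest-rank threshold covers exactly the confidence fraction of
    its own samples (up to ties)."""
    movie = make_null_movie(shape=(128, 128), n_frames=20, seed=21, pixel_size=0.5)
    null = monte_carlo_null(movie, "green", n_squares=2000, seed=22, t_start=0)
    assert null.coverage() == pytest.approx(0.95, abs=1.0 / 2000)


def test_null_determinism():
    movie = make_null_movie(shape=(96, 96), n_frames=10, seed=2, pixel_size=0.5)
    a = monte_carlo_null(movie, "green", n_squares=1500, seed=5, t_start=0)
    b = monte_carlo_null(movie, "green", n_squares=1500, seed=5, t_start=0)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert a.threshold == b.threshold
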