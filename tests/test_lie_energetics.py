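"""XVG parsing, trace means, and the LIE estimator with replica SEM."""

import math

import numpy as np
import pytest
from scipy import stats

from achescreen.lie_energetics import (
    EnergyTrace,
    LIEParameters,
    lie_estimate,
    lie_with_uncertainty,
    read_xvg,
    trace_mean,
    write_xvg,
)
from achescreen.synthetic_data import TraceSpec, make_energy_traces


def make_trace(v_vdw, v_cou=None, state="bound", replica=1, dt=1.0):
    v_vdw = np.asarray(v_vdw, dtype=float)
    v_cou = v_vdw.copy() if v_cou is None else np.asarray(v_cou, dtype=float)
    return EnergyTrace(
        times=np.arange(len(v_vdw)) * dt, v_vdw=v_vdw, v_cou=v_cou,
        state=state, replica=replica,
    )


# ---------------------------------------------------------------------------
# XVG I/O

def test_read_xvg_converts_kj_to_kcal(tmp_path):
    p = tmp_path / "e.xvg"
    p.write_text(
        "# comment\n"
        '@    yaxis  label "(kJ/mol)"\n'
        '@ s0 legend "LJ (SR)"\n'
        '@ s1 legend "Coulomb (SR)"\n'
        "0.0 4.184 -8.368\n"
        "1.0 4.184 -8.368\n"
        "2.0 4.184 -8.368\n"
    )
    tr = read_xvg(p, state="bound")
    assert np.allclose(tr.v_vdw, 1.0)
    assert np.allclose(tr.v_cou, -2.0)
    assert tr.source_units == "kJ/mol"


def test_read_xvg_only_comments_is_error(tmp_path):
    p = tmp_path / "empty.xvg"
    p.write_text("# a\n@ title\n")
    with pytest.raises(ValueError, match="fewer than 2"):
        read_xvg(p)


def test_read_xvg_requires_column_mapping(tmp_path):
    p = tmp_path / "bare.xvg"
    p.write_text("0.0 1.0 2.0\n1.0 1.0 2.0\n")
    with pytest.raises(ValueError, match="column_map"):
        read_xvg(p)
    tr = read_xvg(p, column_map={"vdw": 0, "cou": 1}, source_units="kcal/mol")
    assert tr.v_vdw[0] == 1.0 and tr.v_cou[0] == 2.0


def test_xvg_roundtrip_exact(tmp_path):
    rng = np.random.default_rng(1)
    tr = make_trace(rng.normal(-45, 3, 50), rng.normal(-30, 3, 50))
    for units in ("kcal/mol", "kJ/mol"):
        p = tmp_path / "t.xvg"
        write_xvg(tr, p, units=units)
        back = read_xvg(p, state="bound")
        assert np.allclose(back.v_vdw, tr.v_vdw, atol=1e-10)
        assert np.allclose(back.v_cou, tr.v_cou, atol=1e-10)


def test_trace_rejects_non_monotone_times():
    with pytest.raises(ValueError, match="increasing"):
        EnergyTrace(
            times=[0.0, 2.0, 1.0], v_vdw=[1, 2, 3], v_cou=[1, 2, 3], state="bound"
        )


# ---------------------------------------------------------------------------
# trace_mean

def test_trace_mean_constant_any_fraction():
    tr = make_trace([3.5] * 10)
    for frac in (0.0, 0.2, 0.9):
        assert trace_mean(tr, frac) == (3.5, 3.5)


def test_trace_mean_discard_window():
    tr = make_trace([0.0, 0.0, 10.0, 10.0])
    assert trace_mean(tr, 0.5) == (10.0, 10.0)


def test_trace_mean_autocorrelated_within_analytic_sem():
    """Sample mean of an AR(1) trace lands within 3x the closed-form SEM.

    For AR(1) with marginal sd s and lag-1 phi, var(mean) ~ (s^2/n) *
    (1+phi)/(1-phi) for n >> tau.
    """
    spec = TraceSpec(n_frames=25_000, n_replicas=1, marginal_sd=3.0,
                     autocorr_time=10.0, dt=2.0, seed=123)
    traces, _ = make_energy_traces(spec)
    bound = [t for t in traces if t.state == "bound"][0]
    phi = math.exp(-spec.dt / spec.autocorr_time)
    sem = spec.marginal_sd * math.sqrt((1 + phi) / ((1 - phi) * spec.n_frames))
    mv, _ = trace_mean(bound, 0.2)
    assert abs(mv - spec.means[0]) <= 3 * sem


def test_trace_mean_rejects_bad_fraction():
    tr = make_trace([1.0, 2.0])
    with pytest.raises(ValueError):
        trace_mean(tr, 1.0)


# ---------------------------------------------------------------------------
# lie_estimate

def test_identical_states_give_gamma():
    assert lie_estimate((-40.0, -30.0), (-40.0, -30.0)) == pytest.approx(-5.88)


def test_lie_arithmetic_on_printed_constants():
    # 0.288*(-10) + (-0.049)*(-5) + (-5.88)
    assert lie_estimate((-10.0, -5.0), (0.0, 0.0)) == pytest.approx(-8.515)
    assert lie_estimate((1.0, 0.0), (0.0, 0.0)) == pytest.approx(-5.592)


def test_lie_linear_in_each_input():
    p = LIEParameters()
    base = lie_estimate((-10.0, -5.0), (0.0, 0.0), p)
    doubled_alpha = LIEParameters(alpha=2 * p.alpha, beta=p.beta, gamma=p.gamma)
    d2 = lie_estimate((-10.0, -5.0), (0.0, 0.0), doubled_alpha)
    assert d2 - p.beta * (-5.0) - p.gamma == pytest.approx(
        2 * (base - p.beta * (-5.0) - p.gamma)
    )


def test_estimate_invariant_to_frame_order_and_time_rescaling():
    rng = np.random.default_rng(7)
    v, c = rng.normal(-40, 2, 100), rng.normal(-30, 2, 100)
    tr = make_trace(v, c)
    m1 = trace_mean(tr, 0.0)
    perm = rng.permutation(100)
    m2 = trace_mean(make_trace(v[perm], c[perm]), 0.0)
    assert m1 == pytest.approx(m2)
    m3 = trace_mean(make_trace(v, c, dt=7.3), 0.0)
    assert m1 == pytest.approx(m3)


# ---------------------------------------------------------------------------
# replica aggregation

def test_two_replica_mean_and_sem():
    # per-replica dG of exactly {-10, -11}: constant traces chosen to produce them
    traces = []
    for rep, dvdw in ((1, (-10.0 + 5.88) / 0.288), (2, (-11.0 + 5.88) / 0.288)):
        traces.append(make_trace([dvdw] * 4, [0.0] * 4, "bound", rep))
        traces.append(make_trace([0.0] * 4, [0.0] * 4, "unbound", rep))
    est = lie_with_uncertainty(traces)
    assert est.dg == pytest.approx(-10.5)
    assert est.sem == pytest.approx(0.5)
    assert est.per_replica == pytest.approx((-10.0, -11.0))


def test_single_replica_flagged_with_zero_sem():
    traces = [
        make_trace([-40.0] * 4, [-30.0] * 4, "bound", 1),
        make_trace([-40.0] * 4, [-30.0] * 4, "unbound", 1),
    ]
    with pytest.warns(UserWarning, match="single replica"):
        est = lie_with_uncertainty(traces)
    assert est.single_replica and est.sem == 0.0


def test_mismatched_replica_sets_rejected():
    traces = [
        make_trace([-40.0] * 4, state="bound", replica=1),
        make_trace([-40.0] * 4, state="bound", replica=2),
        make_trace([-10.0] * 4, state="unbound", replica=1),
    ]
    with pytest.raises(ValueError, match="mismatched"):
        lie_with_uncertainty(traces)
    # but a single shared unbound trace is allowed when flagged
    est = lie_with_uncertainty(traces, allow_shared_unbound=True)
    assert est.n_replicas == 2


def test_four_replica_estimate_brackets_analytic_value():
    traces, dg_true = make_energy_traces(TraceSpec(seed=2024))
    est = lie_with_uncertainty(traces)
    assert dg_true == pytest.approx(-11.02, abs=0.001)
    assert abs(est.dg - dg_true) <= 3 * est.sem


def test_sem_calibration_matches_student_t_prediction():
    """Empirical coverage of dg +- 3*sem across many synthetic campaigns.

    With 4 replicas the standardized error (dg - truth)/sem follows
    Student-t with 3 df, whose +-3 coverage is 94.2%; the observed rate over
    100 worlds must sit inside a generous binomial band around that.
    """
    cover = 0
    for seed in range(100):
        traces, dg_true = make_energy_traces(
            TraceSpec(n_frames=2_500, seed=seed)
        )
        est = lie_with_uncertainty(traces)
        cover += abs(est.dg - dg_true) <= 3 * est.sem
    expected = stats.t.cdf(3, df=3) - stats.t.cdf(-3, df=3)  # 0.9423
    band = 3.5 * math.sqrt(expected * (1 - expected) * 100)  # ~8.2
    assert abs(cover - 100 * expected) <= band


def test_pooled_mode_agrees_for_equal_length_replicas():
    traces, _ = make_energy_traces(TraceSpec(n_frames=2_000, seed=5))
    a = lie_with_uncertainty(traces)
    b = lie_with_uncertainty(traces, pooled=True)
    # equal-length equal-spacing replicas: pooling frames == averaging means
    assert a.dg == pytest.approx(b.dg, abs=1e-9)
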