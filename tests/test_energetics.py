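"""Jump work/power demands and actuation feasibility."""

import numpy as np
import pytest

from antjump import (
    ActuationClass,
    PhysiologicalConstants,
    SpeciesRecord,
    TakeoffMetrics,
    ValidationError,
    classify_actuation,
    energetics_pipeline,
    jump_power,
    jump_work,
    required_volume_from_power,
    required_volume_from_work,
)
from antjump.units import round_sig


def test_jump_work_examples():
    assert jump_work(2.0, 1.0) == pytest.approx(1.0)
    assert jump_work(1.55e-5, 0.6) == pytest.approx(2.79e-6, rel=1e-6)
    assert jump_work(3.2e-5, 0.7) == pytest.approx(7.84e-6, rel=1e-6)
    with pytest.raises(ValidationError):
        jump_work(0.0, 1.0)


def test_jump_work_optional_potential_energy():
    base = jump_work(1e-5, 0.5)
    lifted = jump_work(1e-5, 0.5, height_m=0.01)
    assert lifted - base == pytest.approx(1e-5 * 9.81 * 0.01, rel=1e-12)


def test_jump_power_examples():
    assert jump_power(1.0, 1.0) == 1.0
    assert jump_power(2.79e-6, 0.0275) == pytest.approx(1.0145e-4, rel=1e-4)
    assert jump_power(7.84e-6, 0.02) == pytest.approx(3.92e-4, rel=1e-9)


def test_required_volume_unit_cancellation(constants):
    w_unit = constants.work_density_j_per_kg * constants.muscle_density_kg_per_m3
    assert required_volume_from_work(w_unit, constants) == pytest.approx(3.0)
    p_unit = constants.power_density_w_per_kg * constants.muscle_density_kg_per_m3
    assert required_volume_from_power(p_unit, constants) == pytest.approx(1.0)


def test_required_volume_printed_examples(constants):
    assert required_volume_from_work(2.79e-6, constants) == pytest.approx(
        1.15e-10, rel=5e-3
    )
    assert required_volume_from_work(2.575e-6, constants) == pytest.approx(
        1.06e-10, rel=5e-3
    )
    assert required_volume_from_power(1.0145e-4, constants) == pytest.approx(
        2.79e-10, rel=5e-3
    )
    assert required_volume_from_power(3.92e-4, constants) == pytest.approx(
        1.08e-9, rel=5e-3
    )


def test_elastic_factor_one_is_direct_work_demand(constants):
    unbounded = PhysiologicalConstants(elastic_storage_factor=1.0)
    w = 2.5e-6
    assert required_volume_from_work(w, unbounded) == pytest.approx(
        w / (70.0 * 1040.0), rel=1e-12
    )
    assert required_volume_from_work(w, constants) == pytest.approx(
        3 * required_volume_from_work(w, unbounded), rel=1e-12
    )


def test_classification_ordering_and_monotonicity():
    req_w, req_p = 1.15e-10, 2.79e-10
    assert classify_actuation(4.1e-10, req_w, req_p) is (
        ActuationClass.DIRECT_AND_ELASTIC_FEASIBLE
    )
    assert classify_actuation(2e-10, req_w, req_p) is ActuationClass.ELASTIC_ONLY
    assert classify_actuation(1e-11, req_w, req_p) is ActuationClass.INFEASIBLE
    assert classify_actuation(None, req_w, req_p) is ActuationClass.UNKNOWN
    # monotone non-decreasing in measured volume
    order = [
        classify_actuation(v, req_w, req_p)
        for v in np.linspace(1e-11, 5e-10, 40)
    ]
    rank = {
        ActuationClass.INFEASIBLE: 0,
        ActuationClass.ELASTIC_ONLY: 1,
        ActuationClass.DIRECT_AND_ELASTIC_FEASIBLE: 2,
    }
    assert all(rank[a] <= rank[b] for a, b in zip(order, order[1:]))


def _pipeline(mass, v, t, measured=None, constants=None):
    sp = SpeciesRecord("sp", jumping=True, body_length_mm=10.0, body_mass_kg=mass)
    kin = TakeoffMetrics(t, v, v, v / t)
    return energetics_pipeline(sp, kin, measured_volume_m3=measured,
                               constants=constants)


def test_pipeline_reproduces_full_observed_column(constants):
    res = _pipeline(2.66e-5, 0.44, 0.0199, measured=4.94e-10, constants=constants)
    assert round_sig(res.work_j, 2) == pytest.approx(2.6e-6)
    assert round_sig(res.power_w, 2) == pytest.approx(1.3e-4)
    assert round_sig(res.required_volume_work_m3, 3) == pytest.approx(1.06e-10)
    assert round_sig(res.required_volume_power_m3, 3) == pytest.approx(3.55e-10)
    assert res.classification is ActuationClass.DIRECT_AND_ELASTIC_FEASIBLE


def test_pipeline_power_time_identity_and_mass_proxy(rng):
    for _ in range(20):
        mass = float(rng.uniform(1e-6, 1e-4))
        v = float(rng.uniform(0.1, 2.0))
        t = float(rng.uniform(0.005, 0.05))
        res = _pipeline(mass, v, t)
        assert res.power_w * res.takeoff_time_s == pytest.approx(
            res.work_j, rel=1e-12
        )
        # one-line independent recomputation oracles
        assert res.required_volume_work_m3 == pytest.approx(
            3 * (0.5 * mass * v**2) / (70 * 1040), rel=1e-12
        )
        assert res.required_volume_power_m3 == pytest.approx(
            (0.5 * mass * v**2 / t) / (350 * 1040), rel=1e-12
        )
    # mass via the thorax-volume proxy
    sp = SpeciesRecord("proxy", jumping=True, body_length_mm=10.0,
                       thorax_volume_m3=1.4903846153846154e-8)
    kin = TakeoffMetrics(0.02, 0.5, 0.5, 25.0)
    res = energetics_pipeline(sp, kin)
    assert res.mass_kg == pytest.approx(1.55e-5, rel=1e-9)
    assert res.classification is ActuationClass.UNKNOWN


def test_pipeline_velocity_choice():
    res_mean = _pipeline(2.66e-5, 0.44, 0.0199)
    sp = SpeciesRecord("sp", jumping=True, body_length_mm=10.0,
                       body_mass_kg=2.66e-5)
    kin = TakeoffMetrics(0.0199, 0.3, 0.44, 22.1)
    assert energetics_pipeline(sp, kin, velocity="mean").work_j < res_mean.work_j
    with pytest.raises(ValidationError):
        energetics_pipeline(sp, kin, velocity="peak")
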