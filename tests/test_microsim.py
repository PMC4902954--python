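"""State-transition model: rate conversion, transitions, biologic uptake,
accrual and the background track."""

import numpy as np
import pytest

from earlycea.cohort import PatientState
from earlycea.microsim import (
    TransitionModel,
    convert_probability,
    cycle_accrual,
    run_background,
    run_microsim,
    step_patient,
)


def make_ra_patients(n, state=3, label="TP", dip=False):
    return [
        PatientState(id=i, label=label, das28_state=state, dip_prone=dip)
        for i in range(n)
    ]


class TestConvertProbability:
    def test_published_biologic_uptake_conversion(self):
        p = convert_probability(0.15, 24, 3)
        assert p == pytest.approx(0.0201, abs=5e-5)
        assert round(p * 100) == 2  # the printed per-cycle percentage

    def test_identity_when_periods_match(self):
        assert convert_probability(0.3, 6, 6) == pytest.approx(0.3)

    def test_zero_probability(self):
        assert convert_probability(0.0, 24, 3) == 0.0

    def test_certainty_rejected(self):
        with pytest.raises(ValueError):
            convert_probability(1.0, 24, 3)


class TestStepPatient:
    def test_identity_matrix_never_moves(self):
        tm = TransitionModel(nonbio=np.eye(3), bio=np.eye(3))
        p = PatientState(id=0, label="TP", das28_state=2)
        rng = np.random.default_rng(0)
        for _ in range(50):
            step_patient(p, tm, rng)
        assert p.das28_state == 2

    def test_absorbing_state_reached_in_one_cycle(self):
        absorbing = np.array([[0, 0, 1.0]] * 3)
        tm = TransitionModel(nonbio=absorbing, bio=absorbing)
        p = PatientState(id=0, label="TP", das28_state=1)
        step_patient(p, tm, np.random.default_rng(0))
        assert p.das28_state == 3

    def test_long_run_occupancy_matches_stationary_distribution(self, params):
        """10,000 steps of the fixture chain reproduce its left eigenvector."""
        mat = np.asarray(params.transition_matrix_nonbio)
        w, v = np.linalg.eig(mat.T)
        stat = np.real(v[:, np.argmax(np.real(w))])
        stat = stat / stat.sum()
        tm = TransitionModel.from_params(params)
        p = PatientState(id=0, label="TP", das28_state=1)
        rng = np.random.default_rng(42)
        n = 10_000
        visits = np.zeros(3)
        for _ in range(n):
            step_patient(p, tm, rng)
            visits[p.das28_state - 1] += 1
        freq = visits / n
        for s in range(3):
            se = np.sqrt(stat[s] * (1 - stat[s]) / n)
            # serial correlation inflates the naive SE; allow a wide factor
            assert abs(freq[s] - stat[s]) < 10 * se

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            TransitionModel(nonbio=np.ones((3, 3)), bio=np.eye(3))


class TestBiologicUptake:
    def test_24_month_uptake_recovers_registry_calibration(self, params):
        """2 % per cycle among always-eligible patients accumulates to
        ~15 % by 24 months (8 cycles), within Monte-Carlo error."""
        patients = make_ra_patients(10_000, state=3)
        result = run_microsim(patients, params, seed=13)
        # index 7 = after the eighth quarterly start opportunity
        uptake_24m = result.biologic_per_cycle[7] / 10_000
        se = np.sqrt(0.15 * 0.85 / 10_000)
        assert abs(uptake_24m - (1 - 0.98**8)) < 3 * se

    def test_biologic_prevalence_never_decreases(self, params):
        patients = make_ra_patients(500, state=3)
        result = run_microsim(patients, params, seed=3)
        assert (np.diff(result.biologic_per_cycle) >= 0).all()

    def test_state3_weighting_starts_more_biologics_in_state3(self, params):
        """With 1-3-6 weights, starters are concentrated in the worst state."""
        n = 6000
        patients = make_ra_patients(n, state=3)
        # freeze states with an identity transition matrix, spread over states
        frozen = params.replace(
            transition_matrix_nonbio=np.eye(3).tolist(),
            transition_matrix_bio=np.eye(3).tolist(),
        )
        for i, p in enumerate(patients):
            p.das28_state = (i % 3) + 1
            p.ever_eligible = True
        result = run_microsim(patients, frozen, seed=21)
        started = result.on_biologic
        states = np.array([(i % 3) + 1 for i in range(n)])
        s1 = started[states == 1].mean()
        s3 = started[states == 3].mean()
        assert s3 > 4 * s1  # 6:1 in expectation per cycle

    def test_overall_start_rate_matches_2pct_regardless_of_occupancy(self, params):
        """The weighted allocation renormalises so the expected per-cycle
        start probability among eligible patients stays at 2 %."""
        from earlycea.microsim import _start_probabilities

        states = np.array([1] * 100 + [2] * 300 + [3] * 600)
        candidates = np.ones(1000, dtype=bool)
        probs = _start_probabilities(states, candidates, params)
        assert probs[candidates].mean() == pytest.approx(0.02)


class TestAccrualAndConservation:
    def test_biologic_adds_quarterly_drug_cost(self, params):
        undiscounted = params.replace(discount_costs=0.0, discount_effects=0.0)
        off = PatientState(id=0, label="TP", das28_state=2)
        on = PatientState(id=1, label="TP", das28_state=2, on_biologic=True)
        cost_off, _ = cycle_accrual(off, undiscounted, 0)
        cost_on, _ = cycle_accrual(on, undiscounted, 0)
        assert cost_on - cost_off == pytest.approx(14000.0 / 4)

    def test_constant_utility_no_discounting_gives_4u(self, params):
        frozen = params.replace(
            discount_costs=0.0,
            discount_effects=0.0,
            transition_matrix_nonbio=np.eye(3).tolist(),
            transition_matrix_bio=np.eye(3).tolist(),
            biologic_cycle_start_prob=0.0,
        )
        patients = make_ra_patients(10, state=1)
        result = run_microsim(patients, frozen, seed=1)
        u = frozen.utility(1, False, False)
        assert result.qalys == pytest.approx(4.0 * u)

    def test_discounting_contracts_the_stream(self, params):
        frozen = params.replace(
            transition_matrix_nonbio=np.eye(3).tolist(),
            transition_matrix_bio=np.eye(3).tolist(),
            biologic_cycle_start_prob=0.0,
        )
        patients = make_ra_patients(10, state=1)
        result = run_microsim(patients, frozen, seed=1)
        u = frozen.utility(1, False, False)
        assert result.total_qaly < 10 * 4.0 * u

    def test_occupancy_conserves_entrants_every_cycle(self, params, cohort):
        patients = make_ra_patients(299, state=2)
        result = run_microsim(patients, params, seed=5)
        assert (result.occupancy.sum(axis=1) == 299).all()
        assert result.occupancy.shape == (16, 3)  # 4 years x 4 cycles

    def test_same_seed_identical_totals(self, params):
        a = run_microsim(make_ra_patients(200), params, seed=9)
        b = run_microsim(make_ra_patients(200), params, seed=9)
        assert a.total_cost == b.total_cost
        assert a.total_qaly == b.total_qaly

    def test_background_track_values(self, params):
        tn = [PatientState(id=i, label="TN") for i in range(10)]
        undiscounted = params.replace(discount_costs=0.0, discount_effects=0.0)
        res = run_background(tn, undiscounted)
        assert res.total_qaly == pytest.approx(10 * 0.75 * 4.0)
        assert res.total_cost == 0.0
        res_d = run_background(
            [PatientState(id=i, label="TN") for i in range(10)], params
        )
        assert res_d.total_qaly < 10 * 3.0

    def test_ra_patients_rejected_from_background_and_vice_versa(self, params):
        with pytest.raises(ValueError):
            run_background(make_ra_patients(3), params)
        with pytest.raises(ValueError):
            run_microsim([PatientState(id=0, label="TN")], params, seed=0)
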