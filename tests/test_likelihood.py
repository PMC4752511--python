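"""Closed-form prosaccade likelihood and the KDE-based PDA objective."""

import numpy as np
import pytest
from scipy import integrate

from antirace import (
    ModelParams,
    SubjectData,
    anti_loglik,
    build_pda,
    build_pro_pda,
    prosaccade_loglik,
    total_loglik,
)
from antirace.simulate import simulate_pro
from antirace.wald import DENSITY_FLOOR
from tests.conftest import make_subject


def test_single_trial_matches_density_example():
    p = ModelParams(v_pre=1.0, v_inhib=1.0, v_exec=1.0, a_mean=1.0, t=0.2)
    # rt - t = 1 at mu = lam = 1: log(1/sqrt(2 pi))
    assert prosaccade_loglik(p, [1.2]) == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)))


def test_empty_trials_score_zero(ref_params):
    assert prosaccade_loglik(ref_params, []) == 0.0
    pda = build_pda(ref_params, n_sims=500, seed=0)
    assert anti_loglik(pda, [], []) == 0.0


def test_rt_below_nondecision_time_floors_not_nan(ref_params):
    ll = prosaccade_loglik(ref_params, [0.01])
    assert np.isfinite(ll)
    assert ll == pytest.approx(np.log(DENSITY_FLOOR))


def test_closed_form_peaks_near_generating_drift(control_params):
    """Truth beats +/-50% v_pre perturbations in >=95% of 100 replicates."""
    wins = 0
    for rep in range(100):
        rts = simulate_pro(control_params, 200, np.random.default_rng(1000 + rep))
        ll_true = prosaccade_loglik(control_params, rts)
        ll_lo = prosaccade_loglik(control_params.replace(v_pre=control_params.v_pre * 0.5), rts)
        ll_hi = prosaccade_loglik(control_params.replace(v_pre=control_params.v_pre * 1.5), rts)
        wins += ll_true >= max(ll_lo, ll_hi)
    assert wins >= 95


class TestPda:
    def test_proportions_partition(self, control_params):
        pda = build_pda(control_params, n_sims=2000, seed=1)
        assert pda.p_correct + pda.p_error == pytest.approx(1.0)
        assert 0.0 <= pda.p_correct <= 1.0

    def test_instant_inhibition_all_correct(self, ref_params):
        pda = build_pda(ref_params.replace(v_inhib=1e4), n_sims=2000, seed=2)
        assert pda.p_correct >= 0.999
        # the starved error channel is degenerate and floors
        assert pda.channel_density([0.3], correct=False)[0] == DENSITY_FLOOR

    def test_p_correct_tracks_large_n_oracle(self, ref_params):
        from tests.test_simulate import REFERENCE_ERROR_RATE

        pda = build_pda(ref_params, n_sims=10**4, seed=3)
        assert pda.p_correct == pytest.approx(1.0 - REFERENCE_ERROR_RATE, abs=0.02)

    def test_far_outside_support_hits_floor(self, control_params):
        pda = build_pda(control_params, n_sims=2000, seed=4)
        ll = anti_loglik(pda, [100.0], [True])
        assert ll == pytest.approx(np.log(DENSITY_FLOOR))

    def test_too_few_sims_rejected(self, control_params):
        with pytest.raises(ValueError):
            build_pda(control_params, n_sims=50, seed=0)

    def test_defective_densities_integrate_to_one(self, control_params):
        pda = build_pda(control_params, n_sims=4000, seed=5)
        total = 0.0
        for flag in (True, False):
            val, _ = integrate.quad(
                lambda x, f=flag: pda.channel_density([x], f)[0], 1e-6, 10.0, limit=200
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_pro_pda_converges_to_closed_form(self, control_params):
        """Mean absolute per-trial error is nonincreasing in n_sims."""
        rts = simulate_pro(control_params, 200, np.random.default_rng(6))
        closed = np.array([prosaccade_loglik(control_params, [r]) for r in rts])
        errs = []
        for n in (10**3, 10**4, 10**5):
            pda = build_pro_pda(control_params, n_sims=n, seed=7)
            approx = np.log(pda.channel_density(rts, True))
            errs.append(np.abs(approx - closed).mean())
        assert errs[0] >= errs[1] >= errs[2]


def test_silverman_kde_matches_scipy_reference():
    """The windowed KDE agrees with scipy's gaussian_kde (Silverman rule)."""
    from scipy.stats import gaussian_kde

    from antirace.likelihood import SilvermanKde

    data = np.random.default_rng(77).normal(0.4, 0.1, size=500)
    grid = np.linspace(0.0, 0.8, 101)
    ours = SilvermanKde(data)(grid)
    ref = gaussian_kde(data, bw_method="silverman")(grid)
    np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestTotalLoglik:
    def test_pro_only_subject_equals_closed_form(self, control_params):
        rts = simulate_pro(control_params, 50, np.random.default_rng(8))
        sub = SubjectData("p", rts, [], [])
        assert total_loglik(control_params, sub, n_sims=500, seed=0) == prosaccade_loglik(
            control_params, rts
        )

    def test_deterministic_given_seed(self, control_params, small_subject):
        a = total_loglik(control_params, small_subject, n_sims=1000, seed=9)
        b = total_loglik(control_params, small_subject, n_sims=1000, seed=9)
        assert a == b  # bitwise

    def test_zero_trial_subject_rejected(self, control_params):
        with pytest.raises(ValueError):
            total_loglik(control_params, SubjectData("z", [], [], []))

    def test_truth_beats_halved_v_exec(self, control_params):
        """Generating params outscore halved v_exec in >=90% of 50 replicates."""
        wins = 0
        halved = control_params.replace(v_exec=control_params.v_exec / 2)
        for rep in range(50):
            sub = make_subject(control_params, 500, 500, seed=2000 + rep)
            ll_true = total_loglik(control_params, sub, n_sims=2000, seed=rep)
            ll_half = total_loglik(halved, sub, n_sims=2000, seed=rep)
            wins += ll_true > ll_half
        assert wins >= 45
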