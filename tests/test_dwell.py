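"""Dwell-time theory vs stochastic simulation, censoring, MLE, bursts."""

import numpy as np
import pytest

from gabakin import (
    DwellSequence,
    apply_modulation,
    burst_analysis,
    critical_shut_time,
    fit_exp_mixture,
    gillespie_simulate,
    impose_dead_time,
    load_fixture,
    load_modulation,
    mean_open_time,
    q_matrix,
    steady_state,
    theoretical_dwell_mixture,
)


class TestTheory:
    def test_two_state_open_lifetime(self, two_state):
        mix = theoretical_dwell_mixture(two_state, klass="open")
        assert mix.taus_ms == pytest.approx((125.0,))
        assert mix.fractions == pytest.approx((1.0,))
        assert mean_open_time(two_state) == pytest.approx(125.0)

    def test_two_open_state_mixture(self, two_open):
        """Entry-rate-weighted components: 10 and 100 ms at 2/3 and 1/3."""
        mix = theoretical_dwell_mixture(two_open, klass="open")
        assert mix.taus_ms == pytest.approx((10.0, 100.0), rel=1e-10)
        assert mix.fractions == pytest.approx((2 / 3, 1 / 3), rel=1e-10)
        assert mix.mean_ms() == pytest.approx(40.0, rel=1e-10)

    def test_modulator_prolongs_open_components_preserving_fractions(self, spont_wt):
        base = theoretical_dwell_mixture(spont_wt, klass="open")
        flu = theoretical_dwell_mixture(
            apply_modulation(spont_wt, load_modulation("flu_spont")),
            klass="open")
        assert all(f > b for f, b in zip(flu.taus_ms, base.taus_ms))
        assert flu.fractions == pytest.approx(base.fractions, rel=1e-9)

    def test_mixture_mean_equals_flux_mean(self):
        """Mean of the open mixture equals total open occupancy divided by
        the steady-state entry flux, computed independently from Q."""
        for name in ("two_state", "spont_wt", "spont_cys", "glig_leu"):
            scheme = load_fixture(name)
            conc = {lig: 0.1 for lig in scheme.ligands}
            Q = q_matrix(scheme, conc)
            p = steady_state(Q, scheme.state_names)
            mask = scheme.open_mask
            flux = float(p[~mask] @ Q[np.ix_(~mask, mask)].sum(axis=1))
            flux_mean_ms = p[mask].sum() / flux * 1e3
            mix_mean = theoretical_dwell_mixture(scheme, conc, "open").mean_ms()
            assert mix_mean == pytest.approx(flux_mean_ms, rel=1e-9)

    def test_empty_class_rejected(self, two_state):
        with pytest.raises(ValueError, match="klass"):
            theoretical_dwell_mixture(two_state, klass="sideways")


class TestGillespie:
    def test_seed_reproducibility(self, spont_wt):
        a = gillespie_simulate(spont_wt, n_events=500, seed=3)
        b = gillespie_simulate(spont_wt, n_events=500, seed=3)
        assert np.array_equal(a.durations_ms, b.durations_ms)
        assert np.array_equal(a.states, b.states)

    def test_law_of_large_numbers_mean_open(self, two_state):
        seq = gillespie_simulate(two_state, n_openings=50_000, seed=9)
        emp = seq.class_durations(True).mean()
        assert emp == pytest.approx(125.0, rel=0.01)

    def test_zero_concentration_confines_to_unliganded_states(self, glig_wt):
        seq = gillespie_simulate(glig_wt, {"GABA": 0.0}, duration_s=1.0,
                                 seed=1, start_state="R")
        assert set(seq.states) == {glig_wt.state_index("R")}

    def test_empirical_matches_theory_ks(self, spont_wt, rng):
        from scipy.stats import kstest

        seq = gillespie_simulate(spont_wt, n_openings=20_000, seed=21)
        mix = theoretical_dwell_mixture(spont_wt, klass="open")
        stat = kstest(seq.class_durations(True), mix.cdf)
        assert stat.pvalue > 0.01


class TestDeadTime:
    def test_zero_dead_time_is_identity(self, spont_wt):
        seq = gillespie_simulate(spont_wt, n_events=200, seed=5)
        out = impose_dead_time(seq, 0.0)
        alt = seq.alternating()
        assert np.array_equal(out.durations_ms, alt.durations_ms)

    def test_merge_rule_example(self):
        seq = DwellSequence(
            durations_ms=np.array([5.0, 0.05, 5.0]),
            open=np.array([True, False, True]),
            states=np.array([1, 0, 1]))
        out = impose_dead_time(seq, 0.1)
        assert len(out) == 1
        assert out.durations_ms[0] == pytest.approx(10.05)
        assert bool(out.open[0])

    def test_idempotent(self, spont_wt):
        seq = gillespie_simulate(spont_wt, n_events=5000, seed=6)
        once = impose_dead_time(seq, 0.1)
        twice = impose_dead_time(once, 0.1)
        assert np.array_equal(once.durations_ms, twice.durations_ms)
        assert np.array_equal(once.open, twice.open)

    def test_longer_openings_survive_censoring_more(self, spont_wt):
        """Prolonging openings raises the apparent event frequency."""
        flu = apply_modulation(spont_wt, load_modulation("flu_spont"))
        frac = {}
        for name, scheme in (("ctrl", spont_wt), ("flu", flu)):
            seq = gillespie_simulate(scheme, n_openings=5000, seed=8)
            n_before = int(seq.open.sum())
            n_after = int(impose_dead_time(seq, 0.5).open.sum())
            frac[name] = n_after / n_before
        assert frac["flu"] > frac["ctrl"]


class TestMixtureMLE:
    def test_single_component_recovery(self, rng):
        x = rng.exponential(10.0, 5000)
        mix = fit_exp_mixture(x, 1)
        se = 10.0 / np.sqrt(5000)
        assert abs(mix.taus_ms[0] - 10.0) < 3 * se

    def test_two_component_recovery(self, rng):
        fast = rng.random(10_000) < 2 / 3
        x = np.where(fast, rng.exponential(10.0, 10_000),
                     rng.exponential(100.0, 10_000))
        mix = fit_exp_mixture(x, 2, seed=0)
        assert mix.taus_ms[0] == pytest.approx(10.0, rel=0.10)
        assert mix.taus_ms[1] == pytest.approx(100.0, rel=0.10)
        assert mix.fractions[0] == pytest.approx(2 / 3, rel=0.10)

    def test_truncated_fit_matches_untruncated_tau(self, rng):
        x = rng.exponential(10.0, 20_000)
        censored = x[x > 0.5]
        mix = fit_exp_mixture(censored, 1, dead_time_ms=0.5)
        se = 10.0 / np.sqrt(censored.size)
        assert abs(mix.taus_ms[0] - 10.0) < 3 * se

    def test_overfitting_single_exponential_is_flagged_by_lr(self, rng):
        from scipy.stats import chi2

        x = rng.exponential(10.0, 5000)
        one = fit_exp_mixture(x, 1)
        two = fit_exp_mixture(x, 2, seed=0)
        lr = 2.0 * (two.loglik - one.loglik)
        merged = two.taus_ms[1] / two.taus_ms[0] < 1.5
        assert merged or lr < chi2.ppf(0.95, df=2)

    def test_bias_shrinks_with_sample_size(self):
        """Censored-MLE bias ladder: average |tau_hat - tau| falls with n."""
        errs = []
        for n in (100, 1000, 10_000):
            rel = []
            for rep in range(5):
                r = np.random.default_rng(1000 * n + rep)
                fast = r.random(n) < 2 / 3
                x = np.where(fast, r.exponential(10.0, n),
                             r.exponential(100.0, n))
                x = x[x > 0.1]
                mix = fit_exp_mixture(x, 2, dead_time_ms=0.1, seed=0)
                rel.append(abs(mix.taus_ms[1] - 100.0) / 100.0)
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]
        assert errs[1] < 2.0 * errs[0]  # allow noise, require overall shrink

    def test_preconditions(self, rng):
        with pytest.raises(ValueError, match="dead time"):
            fit_exp_mixture(np.array([0.05, 1.0] * 10), 1, dead_time_ms=0.1)
        with pytest.raises(ValueError, match="at least"):
            fit_exp_mixture(rng.exponential(10.0, 15), 2)


class TestBursts:
    def test_all_long_gaps_single_openings(self):
        seq = DwellSequence(
            durations_ms=np.array([1.0, 50.0, 2.0, 60.0, 3.0]),
            open=np.array([True, False, True, False, True]),
            states=np.zeros(5, dtype=int))
        bursts = burst_analysis(seq, t_crit_ms=10.0)
        assert np.all(bursts.n_openings == 1)
        assert bursts.mean_openings_per_burst == 1.0

    def test_short_gap_groups_openings(self):
        seq = DwellSequence(
            durations_ms=np.array([1.0, 0.1, 2.0]),
            open=np.array([True, False, True]),
            states=np.zeros(3, dtype=int))
        bursts = burst_analysis(seq, t_crit_ms=1.0)
        assert len(bursts.n_openings) == 1
        assert bursts.n_openings[0] == 2
        assert bursts.durations_ms[0] == pytest.approx(3.1)

    def test_spontaneous_activity_is_burst_free(self, spont_wt):
        """Solitary openings: about one opening per burst at default t_crit."""
        raw = gillespie_simulate(spont_wt, n_openings=2000, seed=7)
        seq = impose_dead_time(raw, 0.1)
        t_crit = critical_shut_time(
            theoretical_dwell_mixture(spont_wt, klass="shut"))
        bursts = burst_analysis(seq, t_crit)
        assert bursts.mean_openings_per_burst == pytest.approx(1.0, abs=0.05)

    def test_critical_time_separated_components(self):
        from gabakin.dwell import ExpMixture

        mix = ExpMixture(taus_ms=(1.0, 1000.0), fractions=(0.5, 0.5))
        tc = critical_shut_time(mix)
        assert 1.0 < tc < 1000.0
        # equal numbers misclassified on each side
        mis_fast = 0.5 * np.exp(-tc / 1.0)
        mis_slow = 0.5 * (1.0 - np.exp(-tc / 1000.0))
        assert mis_fast == pytest.approx(mis_slow, rel=1e-6)

    def test_critical_time_fallback_for_single_component(self):
        from gabakin.dwell import ExpMixture

        mix = ExpMixture(taus_ms=(4000.0,), fractions=(1.0,))
        tc = critical_shut_time(mix)
        assert tc == pytest.approx(-4000.0 * np.log(0.99))
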