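import numpy as np
import pytest

from ovismt import coalescent as coal
from ovismt.coalescent import DemographySpec
from ovismt.mismatch import (
    MismatchDistribution,
    _counts_to_mismatch,
    equilibrium_mismatch,
    expected_mismatch,
    fit_expansion,
    observed_mismatch,
    ssd_test,
)
from ovismt.neutrality import theta_pi_abs


class TestObservedMismatch:
    def test_identical_sequences_mass_at_zero(self):
        d = observed_mismatch(["ACGT"] * 4)
        assert d.freqs[0] == 1.0 and d.mean == 0.0

    def test_single_pair_three_diffs(self):
        d = observed_mismatch(["AAAAAA", "TTTAAA"])
        assert d.freqs[3] == 1.0 and d.mean == 3.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_equals_theta_pi(self, seed):
        """The mean mismatch IS the mean pairwise difference count — the
        identity behind 'mean mismatch tracks nucleotide diversity'."""
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGTN"), 40)) for _ in range(8)]
        d = observed_mismatch(seqs)
        assert d.mean == pytest.approx(theta_pi_abs(seqs), abs=1e-10)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            observed_mismatch(["ACGT"])


class TestExpectedMismatch:
    def test_tau_zero_is_pre_expansion_equilibrium(self):
        """At tau=0 the expansion has only just happened: every pairwise
        coalescence predates it, so the distribution is the theta0
        geometric (checked term by term)."""
        f = expected_mismatch(0.0, 1.0, 100.0, 25)
        eq = equilibrium_mismatch(1.0, 25)
        eq = eq / eq.sum()
        assert np.abs(f - eq).max() < 1e-10

    def test_equal_sizes_reduce_to_equilibrium(self):
        for tau in (0.5, 3.0, 10.0):
            f = expected_mismatch(tau, 2.0, 2.0, 25)
            eq = equilibrium_mismatch(2.0, 25)
            eq = eq / eq.sum()
            assert np.abs(f - eq).max() < 1e-10

    @pytest.mark.parametrize(
        "tau,th0,th1", [(1.0, 0.5, 10.0), (4.0, 1.0, 100.0), (8.0, 2.0, 50.0)]
    )
    def test_normalized(self, tau, th0, th1):
        f = expected_mismatch(tau, th0, th1, 60)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f >= 0).all()

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError):
            expected_mismatch(np.nan, 1.0, 10.0, 10)

    def test_matches_coalescent_simulation(self):
        """The closed form is validated against the simulator (the source
        of truth for the transient solution): total variation < 0.03."""
        tau, th0, th1 = 4.0, 1.0, 100.0
        dem = DemographySpec("sudden_expansion", th0, th1, tau, n=10)
        rng = np.random.default_rng(42)
        agg = np.zeros(400)
        reps = 2000
        iu = np.triu_indices(10, k=1)
        for _ in range(reps):
            D = coal.sim_mismatch_counts(dem, rng)
            cnt = np.bincount(D[iu], minlength=400)
            agg += cnt[:400]
        emp = agg / agg.sum()
        theo = expected_mismatch(tau, th0, th1, 399)
        tv = 0.5 * np.abs(emp - theo).sum()
        assert tv < 0.03


class TestFitExpansion:
    def test_recovers_exact_model(self):
        obs = MismatchDistribution(
            expected_mismatch(4.0, 1.0, 100.0, 40), n_pairs=1000, n=50
        )
        fit = fit_expansion(obs)
        assert fit.ssd < 1e-8
        assert fit.tau == pytest.approx(4.0, abs=0.05)

    def test_degenerate_input_boundary_fit(self):
        obs = observed_mismatch(["ACGT"] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_expansion(obs)
        assert fit.tau == 0.0

    def test_theta_ordering_enforced(self):
        rng = np.random.default_rng(3)
        dem = DemographySpec("sudden_expansion", 1.0, 50.0, 3.0, n=25)
        m = _counts_to_mismatch(coal.sim_mismatch_counts(dem, rng))
        fit = fit_expansion(m)
        assert 0 <= fit.theta0 <= fit.theta1

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        dem = DemographySpec("sudden_expansion", 1.0, 50.0, 3.0, n=20)
        m = _counts_to_mismatch(coal.sim_mismatch_counts(dem, rng))
        f1, f2 = fit_expansion(m), fit_expansion(m)
        assert (f1.tau, f1.theta0, f1.theta1) == (f2.tau, f2.theta0, f2.theta1)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(11)
    dem = DemographySpec("sudden_expansion", 1.0, 100.0, 4.0, n=25)
    m = _counts_to_mismatch(coal.sim_mismatch_counts(dem, rng))
    return m, fit_expansion(m)


class TestSsdTest:
    def test_p_in_unit_interval(self, fitted):
        m, fit = fitted
        p = ssd_test(m, fit, n_boot=120, seed=7)
        assert 0.0 <= p <= 1.0

    def test_seeded_reproducibility(self, fitted):
        m, fit = fitted
        assert ssd_test(m, fit, n_boot=120, seed=7) == ssd_test(
            m, fit, n_boot=120, seed=7
        )

    def test_small_n_boot_rejected(self, fitted):
        m, fit = fitted
        with pytest.raises(ValueError, match="n_boot"):
            ssd_test(m, fit, n_boot=50, seed=0)

    def test_power_against_gross_tau_mismatch(self):
        """Constant-size data held against an expansion model with a badly
        wrong tau: the goodness-of-fit p collapses far more often than the
        nominal rate (directional power check)."""
        from ovismt.mismatch import MismatchFit, _ssd

        small = 0
        n_tests = 12
        for s in range(n_tests):
            rng = np.random.default_rng(300 + s)
            dem = DemographySpec("constant", 3.0, n=25)
            m = _counts_to_mismatch(coal.sim_mismatch_counts(dem, rng))
            params = (30.0, 0.1, 200.0)  # expansion wave nowhere near the data
            wrong = MismatchFit(*params, ssd=_ssd(np.array(params), m.freqs))
            p = ssd_test(m, wrong, n_boot=100, seed=400 + s)
            if p < 0.05:
                small += 1
        assert small >= n_tests // 2
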