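import numpy as np
import pytest
import scipy.linalg

import dmncausal as dc
from dmncausal.synthetic import CohortSpec, CouplingSpec, Edge, make_default_coupling
from dmncausal.timeseries import DEFAULT_HUB_LABELS, DEFAULT_NODE_LABELS


def _coeff_dict(spec):
    return {(e.source, e.target, e.lag): e.coefficient for e in spec.edges}


class TestDefaultCoupling:
    def test_pcc_is_a_pure_sink_with_seven_inputs(self, control_spec):
        incoming = [e for e in control_spec.edges if e.target == "PCC"]
        outgoing = [e for e in control_spec.edges if e.source == "PCC"]
        assert len(incoming) == 7 and not outgoing
        assert {e.source for e in incoming} == set(DEFAULT_NODE_LABELS) - {"PCC"}

    def test_required_pair_coverage(self, control_spec):
        """Every hub-hub and hub-non-hub pair is coupled; non-hub pairs are not."""
        hubs = set(control_spec.hub_labels)
        coupled = {frozenset((e.source, e.target)) for e in control_spec.edges}
        for a in DEFAULT_NODE_LABELS:
            for b in DEFAULT_NODE_LABELS:
                if a >= b:
                    continue
                expected = a in hubs or b in hubs
                assert (frozenset((a, b)) in coupled) == expected

    def test_attenuation_identity_at_factor_one(self, control_spec):
        att = make_default_coupling("attenuated", 1.0)
        assert _coeff_dict(att) == _coeff_dict(control_spec)

    def test_attenuation_annihilates_non_pcc_hub_couplings(self, control_spec):
        att = make_default_coupling("attenuated", 0.0)
        ctrl = _coeff_dict(control_spec)
        for e in att.edges:
            if "PCC" in (e.source, e.target):
                assert e.coefficient == ctrl[(e.source, e.target, e.lag)]
            else:
                assert e.coefficient == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_default_coupling("attenuated", 1.5)
        with pytest.raises(ValueError):
            make_default_coupling("young")

    @pytest.mark.parametrize("group", ["control", "attenuated"])
    def test_stationarity_gate(self, group):
        spec = make_default_coupling(group)
        assert spec.spectral_radius() < 1.0


class TestSimulateSubject:
    def test_seed_reproducibility(self, control_spec):
        a = dc.simulate_subject(control_spec, 295, seed=7)
        b = dc.simulate_subject(control_spec, 295, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = dc.simulate_subject(control_spec, 295, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_nonstationary_coupling_rejected(self):
        bad = CouplingSpec(
            node_labels=("a", "b"),
            hub_labels=("a",),
            edges=(Edge("a", "b", 1, 0.4),),
            self_coefficients={"a": (1.05,)},
        )
        with pytest.raises(ValueError, match="spectral radius"):
            dc.simulate_subject(bad, 200, seed=0)

    def test_null_coupling_gives_independent_noise(self):
        spec = CouplingSpec(self_coefficients={}, edges=())
        ts = dc.simulate_subject(spec, 5000, seed=3)
        corr = np.corrcoef(ts.values.T)
        off = corr[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 0.06  # ~4 standard errors at T=5000

    def test_lag1_cross_covariance_matches_yule_walker(self, control_spec):
        """Empirical lag-1 cross-covariances match the population solution
        of the Yule-Walker (discrete Lyapunov) equations."""
        comp = control_spec.companion_matrix()
        r = len(control_spec.node_labels)
        q = np.zeros_like(comp)
        sd = np.array([control_spec.sd_of(n) for n in control_spec.node_labels])
        q[:r, :r] = np.diag(sd**2)
        gamma = scipy.linalg.solve_discrete_lyapunov(comp, q)
        pop_lag1 = gamma[:r, r : 2 * r]  # cov(x_t, x_{t-1})

        ts = dc.simulate_subject(control_spec, 20000, seed=5)
        x = ts.values - ts.values.mean(axis=0)
        emp_lag1 = x[1:].T @ x[:-1] / (x.shape[0] - 1)
        # sampling error of a covariance entry scales with the variances:
        # allow ~4 standard errors at T = 20000 on every entry
        sd_prod = np.sqrt(np.outer(np.diag(gamma[:r, :r]), np.diag(gamma[:r, :r])))
        tol = 4.0 * sd_prod / np.sqrt(x.shape[0])
        assert np.all(np.abs(emp_lag1 - pop_lag1) < tol)

    def test_hrf_convolution_flag(self, control_spec):
        plain = dc.simulate_subject(control_spec, 295, seed=2)
        smooth = dc.simulate_subject(control_spec, 295, seed=2, hrf_convolve=True)
        assert smooth.values.shape == plain.values.shape
        assert not np.allclose(smooth.values, plain.values)
        # convolution with a smooth kernel raises lag-1 autocorrelation
        def ac1(v):
            return np.corrcoef(v[1:], v[:-1])[0, 1]
        assert ac1(smooth.values[:, 4]) > ac1(plain.values[:, 4])


class TestSimulateCohort:
    def test_cohort_reproducible_and_graphs_match_truth(self, control_spec):
        spec = CohortSpec(coupling=control_spec, n_subjects=4, seed=9)
        mats1, graphs1 = dc.simulate_cohort(spec)
        mats2, graphs2 = dc.simulate_cohort(spec)
        assert len(mats1) == 4
        for a, b in zip(mats1, mats2):
            np.testing.assert_array_equal(a.values, b.values)
        truth = control_spec.ground_truth_graph().edges
        for g in graphs1:
            assert g.edges == truth  # jitter preserves sign, hence topology
            assert ("MPFC", "PCC") in g.edges
        assert graphs1 == graphs2

    def test_singleton_cohort(self, control_spec):
        spec = CohortSpec(coupling=control_spec, n_subjects=1, seed=0)
        mats, graphs = dc.simulate_cohort(spec)
        assert len(mats) == 1 and len(graphs) == 1

    def test_invalid_cohort_specs(self, control_spec):
        with pytest.raises(ValueError):
            CohortSpec(coupling=control_spec, n_subjects=0)
        with pytest.raises(ValueError):
            CohortSpec(coupling=control_spec, n_timepoints=15)
        with pytest.raises(ValueError):
            CohortSpec(coupling=control_spec, between_subject_jitter=-0.1)

    def test_write_read_round_trip(self, tmp_path, control_spec):
        spec = CohortSpec(coupling=control_spec, n_subjects=2, n_timepoints=120, seed=4)
        mats, graphs = dc.simulate_cohort(spec)
        dc.write_cohort(tmp_path / "cohort", spec, mats, graphs)
        spec2, mats2, graphs2 = dc.read_cohort(tmp_path / "cohort")
        assert spec2 == spec
        assert [g.edges for g in graphs2] == [g.edges for g in graphs]
        for a, b in zip(mats, mats2):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-8)
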