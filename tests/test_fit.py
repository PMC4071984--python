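import numpy as np
import pytest

from emuflux import build_emu_network
from emuflux.datasets import (INST_FRAGMENTS, STATIONARY_FRAGMENTS,
                              simulate_dataset)
from emuflux.fit import (FitOptions, FluxInfeasibleError, FreeFluxParam,
                         compute_ssd, fit_fluxes, generate_initial_flux)
from emuflux.model import parse_config


class TestInitialFlux:
    def test_feasible_and_balanced(self, tca):
        v = generate_initial_flux(tca.model, seed=0)
        assert np.max(np.abs(tca.model.S @ v)) < 1e-9
        for fid, val in tca.model.fixed_fluxes.items():
            assert v[tca.model.flux_index(fid)] == pytest.approx(val)
        assert v.min() >= 0

    def test_different_seeds_differ(self, tca):
        v1 = generate_initial_flux(tca.model, seed=1)
        v2 = generate_initial_flux(tca.model, seed=2)
        assert not np.allclose(v1, v2)

    def test_contradictory_fixed_fluxes_detected(self):
        m = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,Subs_A -> B,0,a -> a\n"
                         "R2,B -> [B_B],0,\n")
        m.set_fixed_fluxes({"R1": 1.0, "R2": 2.0})  # violates B balance
        with pytest.raises(FluxInfeasibleError):
            generate_initial_flux(m, seed=0)

    def test_forced_negative_flux_detected(self):
        # two drains whose fixed demand exceeds the fixed supply
        m = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,Subs_A -> B,0,a -> a\n"
                         "R2,B -> [B_B],0,\n"
                         "R3,B -> [C_B],0,\n")
        m.set_fixed_fluxes({"R1": 1.0, "R2": 2.0})  # R3 must be -1
        with pytest.raises(FluxInfeasibleError):
            generate_initial_flux(m, seed=0)


class TestFreeFluxParam:
    def test_parameterization_spans_feasible_points(self, tca):
        param = FreeFluxParam(tca.model)
        assert param.n_free == 3  # 16 reactions - 6 balances - 7 fixed
        v = generate_initial_flux(tca.model, seed=5)
        assert np.allclose(param.v(param.u(v)), v, atol=1e-9)

    def test_extra_fixed_reduces_freedom(self, tca):
        param = FreeFluxParam(tca.model, {"R7": 0.25})
        assert param.n_free == 2


class TestComputeSSD:
    def test_noise_free_self_consistency(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.0)
        phi, D = compute_ssd(tca.model, tca_net_stationary, tca.truth, mset,
                             tca.labeling, mode="stationary")
        assert phi < 1e-10

    def test_sd_scaling_quarters_phi(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.01, seed=3)
        phi1, _ = compute_ssd(tca.model, tca_net_stationary, tca.truth, mset,
                              tca.labeling)
        for l in mset.sd:
            mset.sd[l] = 2 * mset.sd[l]
        phi2, _ = compute_ssd(tca.model, tca_net_stationary, tca.truth, mset,
                              tca.labeling)
        assert phi2 == pytest.approx(phi1 / 4)

    def test_matches_naive_loop(self, tca, tca_net_stationary):
        from emuflux.fit import _simulate_fragments
        mset = simulate_dataset(tca, "stationary", noise_sd=0.01, seed=4)
        phi, _ = compute_ssd(tca.model, tca_net_stationary, tca.truth, mset,
                             tca.labeling)
        sims = _simulate_fragments(tca_net_stationary, tca.truth, mset,
                                   tca.labeling, "stationary", None, None)
        naive = 0.0
        for label in mset.labels:
            for k in range(mset.n_samples):
                for i in range(mset.spectra[label].shape[1]):
                    d = mset.spectra[label][k, i] - sims[label][k, i]
                    naive += (d / mset.sd[label][k, i]) ** 2
        assert phi == pytest.approx(naive, abs=1e-10)


class TestFitFluxes:
    def test_stationary_recovery_noise_free(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.0)
        res = fit_fluxes(tca.model, tca_net_stationary, mset, tca.labeling,
                         options=FitOptions(seed=1, restarts=4))
        rel = np.abs(res.v_opt - tca.truth_vector) / tca.truth_vector
        assert res.phi < 1e-8
        assert rel.max() < 1e-4
        assert res.converged

    def test_start_at_optimum_stays_there(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.0)
        res = fit_fluxes(tca.model, tca_net_stationary, mset, tca.labeling,
                         options=FitOptions(seed=1, restarts=1,
                                            init_v=tca.truth_vector))
        assert res.n_iter <= 1
        assert res.phi < 1e-18

    def test_feasibility_maintained_along_iterates(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.01, seed=9)
        res = fit_fluxes(tca.model, tca_net_stationary, mset, tca.labeling,
                         options=FitOptions(seed=2, restarts=2))
        assert np.max(np.abs(tca.model.S @ res.v_opt)) < 1e-9
        assert res.v_opt.min() >= -1e-12

    def test_noise_consistency_toward_truth(self, tca, tca_net_stationary):
        """Estimates approach the truth as the noise level shrinks."""
        errs = []
        for sd in (0.02, 0.002, 0.0002):
            mset = simulate_dataset(tca, "stationary", noise_sd=sd, seed=21)
            res = fit_fluxes(tca.model, tca_net_stationary, mset, tca.labeling,
                             options=FitOptions(seed=3, restarts=3))
            errs.append(np.abs(res.v_opt - tca.truth_vector).max())
        assert errs[2] < errs[0]
        assert errs[2] < 5e-3

    def test_inst_recovery_within_sd(self, tca, tca_net_inst):
        mset = simulate_dataset(tca, "inst", noise_sd=0.01, seed=7)
        res = fit_fluxes(tca.model, tca_net_inst, mset, tca.labeling,
                         mode="inst", X=tca.pools, h=0.01,
                         options=FitOptions(seed=1, restarts=2))
        assert res.converged
        free = [f for f in tca.model.flux_ids if f not in tca.model.fixed_fluxes]
        for fid in free:
            i = tca.model.flux_index(fid)
            assert abs(res.v_opt[i] - tca.truth_vector[i]) < 3 * res.sd[i]

    def test_phi_not_worse_than_restart_starts(self, tca, tca_net_stationary):
        mset = simulate_dataset(tca, "stationary", noise_sd=0.01, seed=5)
        opts = FitOptions(seed=4, restarts=3)
        res = fit_fluxes(tca.model, tca_net_stationary, mset, tca.labeling,
                         options=opts)
        for k in range(opts.restarts):
            v0 = generate_initial_flux(tca.model, opts.seed + 1000 * k)
            phi0, _ = compute_ssd(tca.model, tca_net_stationary, v0, mset,
                                  tca.labeling)
            assert res.phi <= phi0 + 1e-9
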