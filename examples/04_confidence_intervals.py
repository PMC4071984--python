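"""Grid-search 95% confidence intervals for two estimated fluxes.

Each flux is fixed at perturbed values and the fit reoptimized; the
interval is where the reoptimized SSD stays under the
F-distribution threshold.  Printed bounds bracket the true value.
"""

import emuflux as ef
from emuflux.datasets import INST_FRAGMENTS, make_tca_bundle, simulate_dataset
from emuflux.uncertainty import FluxProfileProblem, grid_search_ci

exp = make_tca_bundle(seed=7)
mset = simulate_dataset(exp, "inst", noise_sd=0.01)
frags = exp.fragment_set(INST_FRAGMENTS)
net = ef.build_emu_network(exp.model,
                           sorted({e for f in frags for e in f.terms}))

opts = ef.FitOptions(seed=1, restarts=3)
res = ef.fit_fluxes(exp.model, net, mset, exp.labeling, mode="inst",
                    X=exp.pools, h=exp.step_size, options=opts)
problem = FluxProfileProblem(exp.model, net, mset, exp.labeling, res,
                             mode="inst", X=exp.pools, h=exp.step_size,
                             fit_options=opts)
print(f"Phi_res = {res.phi:.1f}\n")
for fid in ("R7", "R6"):
    ci = grid_search_ci(problem, fid)
    print(f"{fid}: v_opt = {res.fluxes[fid]:.4f}, true = {exp.truth[fid]}, "
          f"95% CI = [{ci.lower:.4f}, {ci.upper:.4f}] "
          f"(threshold Phi = {ci.threshold:.1f})")
print("\nA narrow interval means the time-course data pin that flux "
      "tightly; the profile points are available in ci.profile for "
      "plotting the SSD parabola.")
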