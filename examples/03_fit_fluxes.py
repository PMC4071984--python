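"""Estimate fluxes from a simulated nonstationary labeling experiment.

A 17 x 5 s time course of OAA and SUC MDVs with 1% Gaussian noise is
generated from known fluxes, then refit by constrained
Levenberg-Marquardt (S v = 0 held exactly through a null-space
parameterization).  The table compares recovered and true fluxes; |z| is
the deviation in units of the linearized standard error.
"""

import numpy as np

import emuflux as ef
from emuflux.datasets import INST_FRAGMENTS, make_tca_bundle, simulate_dataset

exp = make_tca_bundle(seed=7)
mset = simulate_dataset(exp, "inst", noise_sd=0.01)
frags = exp.fragment_set(INST_FRAGMENTS)
net = ef.build_emu_network(exp.model,
                           sorted({e for f in frags for e in f.terms}))

res = ef.fit_fluxes(exp.model, net, mset, exp.labeling, mode="inst",
                    X=exp.pools, h=exp.step_size,
                    options=ef.FitOptions(seed=1, restarts=3))
print(f"Phi_res = {res.phi:.1f} with n = {res.n} data points, "
      f"p = {res.p} free fluxes (converged: {res.converged})\n")
print("  flux    fitted    true      sd     |z|")
for fid in exp.model.flux_ids:
    i = exp.model.flux_index(fid)
    if fid in exp.model.fixed_fluxes:
        continue
    z = abs(res.v_opt[i] - exp.truth[fid]) / res.sd[i]
    print(f"  {fid:>4s}  {res.v_opt[i]:8.4f}  {exp.truth[fid]:6.2f} "
          f" {res.sd[i]:8.5f}  {z:5.2f}")
print("\nEvery free flux lands within ~2 standard errors of the value "
      "that generated the data.")
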