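"""Independent brute-force oracles used to validate the EMU machinery.

The isotopomer oracle never builds an EMU decomposition: it iterates the
full positional-isotopomer balance (2^c states per metabolite) to its
fixed point and reads MDVs off the converged distributions.  Feasible for
the small test networks only.
"""

from __future__ import annotations

from itertools import product as iproduct

import numpy as np

from emuflux.model import MetabolicModel


def _source_distribution(model, labeling, met):
    c = model.role(met).carbons
    dist = np.zeros(2 ** c)
    if labeling is not None and labeling.has(met):
        for bits, frac in labeling._mix[met]:
            idx = sum(b << i for i, b in enumerate(bits))
            dist[idx] += frac
    else:
        dist[0] = 1.0
    return dist


def _symmetrize(dist, c):
    out = np.zeros_like(dist)
    for idx, pr in enumerate(dist):
        bits = [(idx >> i) & 1 for i in range(c)]
        ridx = sum(b << i for i, b in enumerate(reversed(bits)))
        out[idx] += 0.5 * pr
        out[ridx] += 0.5 * pr
    return out


def isotopomer_steady_state(
    model: MetabolicModel,
    v,
    labeling,
    *,
    tol: float = 1e-14,
    max_iter: int = 200000,
):
    """Fixed-point positional-isotopomer distributions of every balanced,
    carbon-bearing metabolite (dict metabolite -> length-2^c probability
    vector, bit i of the index = atom i+1 labeled)."""
    if not isinstance(v, dict):
        v = dict(zip(model.flux_ids, np.asarray(v, float)))
    mets = [m for m in model.balanced_metabolites if model.role(m).carbons > 0]
    carbons = {m: model.role(m).carbons for m in mets}
    dists = {m: _source_distribution(model, None, m) for m in mets}  # unlabeled
    consumption = {m: model.consumption(m, v) for m in mets}

    def substrate_dist(met):
        if met in dists:
            d = dists[met]
        else:
            d = _source_distribution(model, labeling, met)
        if model.role(met).is_symmetric:
            d = _symmetrize(d, model.role(met).carbons)
        return d

    for _ in range(max_iter):
        new = {}
        for m in mets:
            c = carbons[m]
            inflow = np.zeros(2 ** c)
            for rxn in model.producing_reactions(m):
                if rxn.atom_map is None:
                    raise ValueError(f"{rxn.flux_id} produces {m} without atom map")
                subs = [s for s, _ in rxn.substrates]
                sstrings = rxn.atom_map.reactant_strings
                pstrings = rxn.atom_map.product_strings
                pnames = [p for p, _ in rxn.products]
                sdists = [substrate_dist(s) for s in subs]
                for occ, pname in enumerate(pnames):
                    if pname != m:
                        continue
                    pstr = pstrings[occ]
                    for combo in iproduct(*[range(d.size) for d in sdists]):
                        pr = 1.0
                        for d, idx in zip(sdists, combo):
                            pr *= d[idx]
                        if pr == 0.0:
                            continue
                        labeled = {}
                        for s_i, (sstr, idx) in enumerate(zip(sstrings, combo)):
                            for pos, letter in enumerate(sstr):
                                labeled[letter] = (idx >> pos) & 1
                        pidx = sum(labeled[letter] << pos
                                   for pos, letter in enumerate(pstr))
                        inflow[pidx] += v[rxn.flux_id] * pr
            d = inflow / consumption[m]
            if model.role(m).is_symmetric:
                d = _symmetrize(d, c)
            new[m] = d
        delta = max(np.max(np.abs(new[m] - dists[m])) for m in mets)
        dists = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")
    return dists


def isotopomer_mdv(dist: np.ndarray, carbons: int, atoms) -> np.ndarray:
    """MDV of the EMU at 1-based *atoms* from an isotopomer distribution."""
    atoms = list(atoms)
    out = np.zeros(len(atoms) + 1)
    for idx, pr in enumerate(dist):
        k = sum((idx >> (a - 1)) & 1 for a in atoms)
        out[k] += pr
    return out
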