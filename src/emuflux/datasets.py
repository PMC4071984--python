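"""Synthetic labeling experiments for a simplified TCA-cycle network.

The bundled model is a 16-reaction TCA cycle fed by pyruvate and
glutamate: pyruvate dehydrogenase (R2), citrate synthase (R3), the
oxidative decarboxylations (R4, R5), a reversible succinate<->OAA pair
(R6/R15), reversible anaplerosis PYR + CO2 <-> OAA (R7/R16), six biomass
drains (R8-R13) and the two substrate uptakes (R1, R14).  Succinate is
rotationally symmetric (``Sym_SUC``) and CO2 an unbalanced pool
(``Ind_CO2``).

Ground-truth fluxes are a documented feasible point of the network (the
published flux map for this model exists only graphically, so recovery
tests are stated against this fixture truth): one substrate influx and
the six drains are predetermined, leaving three free flux directions.
Pool sizes are fixed so that labeling turnover times span ~2-17 s,
transient across a 17 x 5 s sampling window.

Datasets emulate mass-spectrometric measurement of carbon-skeleton MDVs:
additive Gaussian noise per mass channel (SD given as an absolute
fraction, default 1%), negative channels clipped to zero, then
renormalized.  Real spectra additionally carry natural-isotope
contributions and intensity-dependent noise; see the correction module
for the former.

Everything is seeded and regenerates byte-identically; ``write=True``
emits the full CSV bundle layout::

    Metabolic_network.csv  MSReac.csv  Substrate.csv  Mass_balance.csv
    efflux.csv  Initial_pool.csv  Time_course.csv  Components.csv
    Abundance_list_###.csv
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .measurements import (FragmentSpec, MeasurementSet, fragment_mdv,
                           load_fragments, load_measurements, parse_fragment_spec)
from .mdv import SubstrateLabeling
from .model import MetabolicModel, parse_config, serialize_config
from .simulate import simulate_inst, simulate_stationary

__all__ = [
    "TCA_NETWORK_CSV",
    "SimulatedExperiment",
    "make_tca_bundle",
    "simulate_dataset",
    "load_bundle",
    "load_substrate_csv",
    "make_chain_network",
]

#: the 16-reaction TCA-cycle configuration worksheet
TCA_NETWORK_CSV = """\
FluxID,Rxns,Net flux,Carbon_transitions
R1,Subs_PYR_EX -> PYR,0,abc -> abc
R2,PYR -> ACCOA + Ind_CO2,0,abc -> bc + a
R3,ACCOA + OAA -> IsoCit,0,ab + cdef -> fedbac
R4,IsoCit -> AKG + Ind_CO2,0,abcdef -> abcde + f
R5,AKG -> Sym_SUC + Ind_CO2,0,abcde -> abcd + e
R6,Sym_SUC -> OAA,1,abcd -> abcd
R7,PYR + Ind_CO2 -> OAA,2,abc + d -> abcd
R8,AKG -> [AKG_B],0,
R9,OAA -> [OAA_B],0,
R10,OAA -> [LYS_B],0,
R11,PYR -> [PYR_B],0,
R12,PYR -> [LYS_B],0,
R13,PYR -> [VAL_B],0,
R14,Subs_GLU_EX -> AKG,0,abcde -> abcde
R15,OAA -> Sym_SUC,1,abcd -> abcd
R16,OAA -> PYR + Ind_CO2,2,abcd -> abc + d
"""

#: ground-truth fluxes (µmol gDCW^-1 s^-1); satisfies S v = 0
TCA_TRUE_FLUXES = {
    "R1": 1.0, "R2": 0.5, "R3": 0.5, "R4": 0.5, "R5": 0.5,
    "R6": 0.58, "R7": 0.25, "R8": 0.1, "R9": 0.1, "R10": 0.1,
    "R11": 0.1, "R12": 0.1, "R13": 0.1, "R14": 0.1, "R15": 0.08,
    "R16": 0.05,
}

#: predetermined fluxes: the substrate influx and the six drains
TCA_FIXED_IDS = ("R1", "R8", "R9", "R10", "R11", "R12", "R13")

#: pool sizes of the six intermediates (µmol gDCW^-1)
TCA_POOL_SIZES = {
    "PYR": 5.0, "ACCOA": 2.0, "IsoCit": 3.0,
    "AKG": 8.0, "Sym_SUC": 10.0, "OAA": 10.0,
}

#: substrate labeling: 50% [1-13C] + 50% [U-13C] pyruvate, 100% [1-13C] glutamate
TCA_SUBSTRATE_ROWS = [
    ("Subs_PYR_EX", "1-13C", 0.5),
    ("Subs_PYR_EX", "U-13C", 0.5),
    ("Subs_GLU_EX", "1-13C", 1.0),
]

#: measured fragments: proteinogenic readouts of the stationary experiment
#: (valine and lysine assembled from their precursor skeletons) and the two
#: intermediates sampled in the time-course experiment
TCA_FRAGMENTS = {
    "Val": "PYR:1-3 + PYR:2-3",
    "Lys": "OAA:1-4 + PYR:2-3",
    "Asp": "OAA:1-4",
    "Suc": "Sym_SUC:1-4",
    "OAA": "OAA:1-4",
    "SUC": "Sym_SUC:1-4",
}

STATIONARY_FRAGMENTS = ("Val", "Lys", "Asp", "Suc")
INST_FRAGMENTS = ("OAA", "SUC")


@dataclass
class SimulatedExperiment:
    """A fully specified in-silico labeling experiment."""

    model: MetabolicModel
    labeling: SubstrateLabeling
    truth: dict[str, float]
    pools: dict[str, float]
    times: np.ndarray
    fragments: dict[str, FragmentSpec]
    noise_sd: float = 0.01
    seed: int = 0
    step_size: float = 0.01
    outdir: Path | None = None

    @property
    def truth_vector(self) -> np.ndarray:
        return np.array([self.truth[f] for f in self.model.flux_ids])

    def fragment_set(self, labels: Sequence[str]) -> list[FragmentSpec]:
        return [self.fragments[l] for l in labels]


def make_tca_bundle(
    outdir=None,
    *,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SimulatedExperiment:
    """Build the TCA-cycle experiment; write the CSV bundle if *outdir* given."""
    model = parse_config(TCA_NETWORK_CSV)
    model.set_fixed_fluxes({f: TCA_TRUE_FLUXES[f] for f in TCA_FIXED_IDS})
    carbons = {m: r.carbons for m, r in model.metabolites.items()}
    labeling = SubstrateLabeling(
        {
            "Subs_PYR_EX": [("1-13C", 0.5), ("U-13C", 0.5)],
            "Subs_GLU_EX": [("1-13C", 1.0)],
        },
        carbons=carbons,
    )
    fragments = {
        label: parse_fragment_spec(label, spec)
        for label, spec in TCA_FRAGMENTS.items()
    }
    times = np.arange(17) * 5.0  # 17 samples at 5-second intervals
    exp = SimulatedExperiment(
        model=model, labeling=labeling, truth=dict(TCA_TRUE_FLUXES),
        pools=dict(TCA_POOL_SIZES), times=times, fragments=fragments,
        noise_sd=noise_sd, seed=seed,
        outdir=Path(outdir) if outdir is not None else None,
    )
    # the fixture truth must be a steady state
    resid = model.S @ exp.truth_vector
    assert np.max(np.abs(resid)) < 1e-9, "fixture fluxes violate S v = 0"
    if outdir is not None:
        _write_bundle(exp)
    return exp


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _write_bundle(exp: SimulatedExperiment) -> None:
    out = exp.outdir
    out.mkdir(parents=True, exist_ok=True)
    _fmt(serialize_config(exp.model), out / "Metabolic_network.csv")
    _fmt(pd.DataFrame(
        [(l, TCA_FRAGMENTS.get(l) or _spec_str(f)) for l, f in exp.fragments.items()],
        columns=["Fragment", "EMU"]), out / "MSReac.csv")
    _fmt(pd.DataFrame(TCA_SUBSTRATE_ROWS,
                      columns=["Metabolite", "Pattern", "Fraction"]),
         out / "Substrate.csv")
    _fmt(pd.DataFrame({"Balanced_metabolite": exp.model.balanced_metabolites}),
         out / "Mass_balance.csv")
    _fmt(pd.DataFrame(sorted(exp.model.fixed_fluxes.items()),
                      columns=["FluxID", "Value"]), out / "efflux.csv")
    _fmt(pd.DataFrame(sorted(exp.pools.items()), columns=["Metabolite", "Pool"]),
         out / "Initial_pool.csv")
    _fmt(pd.DataFrame({"Time": exp.times}), out / "Time_course.csv")
    comp_rows = []
    for label, frag in exp.fragments.items():
        comp_rows.append({"Fragment": label, "C": frag.carbons, "H": 0, "N": 0,
                          "O": 0, "S": 0, "Si": 0, "Skeleton_C": frag.carbons})
    _fmt(pd.DataFrame(comp_rows), out / "Components.csv")


def _spec_str(frag: FragmentSpec) -> str:
    return " + ".join(
        f"{e.metabolite}:{e.atoms[0]}-{e.atoms[-1]}" for e in frag.terms
    )


def _noisy(rng: np.random.Generator, mdv: np.ndarray, sd: float) -> np.ndarray:
    """Additive Gaussian noise per channel, clipped at 0 and renormalized."""
    noisy = mdv + rng.normal(0.0, sd, size=mdv.shape) if sd > 0 else mdv.copy()
    noisy = np.clip(noisy, 0.0, None)
    return noisy / noisy.sum()


def simulate_dataset(
    exp: SimulatedExperiment,
    mode: str = "inst",
    *,
    fragment_labels: Sequence[str] | None = None,
    replicates: int = 1,
    noise_sd: float | None = None,
    seed: int | None = None,
    write: bool = False,
) -> MeasurementSet:
    """Generate a measured dataset from the experiment's ground truth.

    ``mode='inst'`` samples every fragment at the experiment's time points
    (one Abundance_list per time point when writing); ``mode='stationary'``
    emits *replicates* noisy copies of the steady-state MDVs.
    """
    if noise_sd is None:
        noise_sd = exp.noise_sd
    rng = np.random.default_rng(exp.seed if seed is None else seed)
    from .emu import build_emu_network

    labels = list(fragment_labels) if fragment_labels is not None else (
        list(INST_FRAGMENTS if mode == "inst" else STATIONARY_FRAGMENTS))
    frags = exp.fragment_set(labels)
    targets = sorted({e for f in frags for e in f.terms})
    net = build_emu_network(exp.model, targets)
    v = exp.truth

    spectra: dict[str, np.ndarray] = {}
    if mode == "stationary":
        solved = simulate_stationary(net, v, exp.labeling)
        for frag in frags:
            clean = fragment_mdv(solved, frag)
            spectra[frag.label] = np.vstack(
                [_noisy(rng, clean, noise_sd) for _ in range(replicates)])
        times = None
    elif mode == "inst":
        traj = simulate_inst(net, v, exp.labeling, exp.pools, exp.times,
                             exp.step_size)
        times = exp.times
        for frag in frags:
            rows = []
            for k in range(len(times)):
                clean = fragment_mdv(
                    {e: traj.values[e][k] for e in frag.terms}, frag)
                rows.append(_noisy(rng, clean, noise_sd))
            spectra[frag.label] = np.vstack(rows)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sd = {l: np.full_like(a, noise_sd if noise_sd > 0 else 1e-4)
          for l, a in spectra.items()}
    mset = MeasurementSet(
        fragments={f.label: f for f in frags}, spectra=spectra, sd=sd,
        times=times, corrected=True,
    )
    if write:
        if exp.outdir is None:
            raise ValueError("experiment has no output directory")
        _write_abundances(exp, mset)
    return mset


def _write_abundances(exp: SimulatedExperiment, mset: MeasurementSet) -> None:
    out = exp.outdir
    out.mkdir(parents=True, exist_ok=True)
    width = max(a.shape[1] for a in mset.spectra.values())
    for k in range(mset.n_samples):
        rows = []
        for label, arr in mset.spectra.items():
            padded = list(arr[k]) + [np.nan] * (width - arr.shape[1])
            rows.append([label] + padded)
        df = pd.DataFrame(rows, columns=["Fragment"] + [f"m{i}" for i in range(width)])
        _fmt(df, out / f"Abundance_list_{k + 1:03d}.csv")


def load_substrate_csv(path, carbons: Mapping[str, int]) -> SubstrateLabeling:
    """Read Substrate.csv (Metabolite, Pattern, Fraction) into a labeling."""
    df = pd.read_csv(path, skipinitialspace=True)
    mixtures: dict[str, list] = {}
    for _, r in df.iterrows():
        mixtures.setdefault(str(r["Metabolite"]).strip(), []).append(
            (str(r["Pattern"]).strip(), float(r["Fraction"])))
    return SubstrateLabeling(mixtures, carbons=carbons)


def load_bundle(path):
    """Load a written bundle directory back into model, labeling, pools, etc.

    Returns a dict with keys ``model``, ``labeling``, ``pools``, ``times``,
    ``fragments`` and ``measurements`` (the latter None when no
    Abundance_list files are present).
    """
    path = Path(path)
    model = parse_config(path / "Metabolic_network.csv")
    eff = pd.read_csv(path / "efflux.csv", skipinitialspace=True)
    model.set_fixed_fluxes({str(r["FluxID"]).strip(): float(r["Value"])
                            for _, r in eff.iterrows()})
    carbons = {m: r.carbons for m, r in model.metabolites.items()}
    labeling = load_substrate_csv(path / "Substrate.csv", carbons)
    pools_df = pd.read_csv(path / "Initial_pool.csv", skipinitialspace=True)
    pools = {str(r["Metabolite"]).strip(): float(r["Pool"])
             for _, r in pools_df.iterrows()}
    times = pd.read_csv(path / "Time_course.csv")["Time"].to_numpy(dtype=float)
    fragments = load_fragments(path / "MSReac.csv")
    abundance = sorted(path.glob("Abundance_list_*.csv"))
    measurements = None
    if abundance:
        tc = times if len(abundance) == len(times) else None
        measurements = load_measurements(
            abundance, components=path / "Components.csv",
            time_course=tc, fragments=fragments,
        )
    return {
        "model": model, "labeling": labeling, "pools": pools,
        "times": times, "fragments": fragments, "measurements": measurements,
    }


def make_chain_network(n_steps: int, carbons: int = 3) -> str:
    """Worksheet text for a linear chain Subs_A -> M1 -> ... -> Mn -> [SINK]
    with identity carbon maps; a scalable stress-test network."""
    letters = "abcdefghijklmnopqrstuvwxyz"[:carbons]
    lines = ["FluxID,Rxns,Net flux,Carbon_transitions",
             f"R0,Subs_A -> M1,0,{letters} -> {letters}"]
    for i in range(1, n_steps):
        lines.append(f"R{i},M{i} -> M{i + 1},0,{letters} -> {letters}")
    lines.append(f"R{n_steps},M{n_steps} -> [M_B],0,")
    return "\n".join(lines) + "\n"
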