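"""Forward simulation of isotopic labeling through an EMU network.

Two regimes:

* **Isotopically stationary** — the size-stratified linear systems
  ``A_s Z_s = B_s Y_s`` are solved in ascending size order; labeling is at
  its steady state and depends only on flux *ratios* (homogeneous of
  degree 0 in ``v``).

* **Isotopically nonstationary (INST)** — each unknown EMU's MDV relaxes
  at a rate set by its metabolite's pool size ``X_j``:

      dMDV_j/dt = (1/X_j) [ sum_i v_i_in MDV_i  -  sum_l v_l_out MDV_j ]

  integrated by fixed-step explicit Euler without adaptive step-size
  control; after every step each MDV is renormalized to sum 1 to prevent
  drift.  Condensation inflows are convolved at the current state.  The
  integrator exists twice with identical semantics: a numba-jitted kernel
  (used by default, needed for fitting workloads) and a pure-numpy
  reference loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .emu import EMU, EMUNetwork, assemble_balance_matrices, source_mdv
from .mdv import SubstrateLabeling, unlabeled_mdv

__all__ = [
    "simulate_stationary",
    "simulate_inst",
    "LabelingTrajectory",
    "slowest_turnover",
    "relaxation_time",
]


def simulate_stationary(
    net: EMUNetwork,
    v,
    labeling: SubstrateLabeling,
) -> dict[EMU, np.ndarray]:
    """Steady-state MDVs of every EMU in the network (sources included)."""
    solved: dict[EMU, np.ndarray] = {
        e: source_mdv(labeling, e) for e in net.sources
    }
    for s in net.sizes:
        A, B, Y, unknowns, _ = assemble_balance_matrices(net, s, v, solved)
        try:
            Z = scipy.linalg.solve(A, B @ Y)
        except scipy.linalg.LinAlgError:
            names = sorted({e.metabolite for e in unknowns})
            raise ValueError(
                f"size-{s} EMU balance is singular; check flux through {names}"
            ) from None
        for emu, row in zip(unknowns, Z):
            row = np.where(np.abs(row) < 1e-15, 0.0, row)
            solved[emu] = row / row.sum()
    return solved


@dataclass
class LabelingTrajectory:
    """Time-indexed MDVs from an INST simulation."""

    times: np.ndarray
    values: dict[EMU, np.ndarray]  # EMU -> (n_times, size+1)
    h: float

    def mdv(self, emu: EMU, k: int) -> np.ndarray:
        return self.values[emu][k]

    def final(self) -> dict[EMU, np.ndarray]:
        return {e: arr[-1] for e, arr in self.values.items()}


def slowest_turnover(net: EMUNetwork, v, X: Mapping[str, float]) -> float:
    """Largest pool-size / consumption ratio among traced metabolites (s).

    A lower bound on the time to isotopic stationarity; when label
    recycles through a cycle the true approach is slower — use
    :func:`relaxation_time` for the governing time scale.
    """
    cons = net.consumption(v)
    return max(X[m] / c for m, c in cons.items())


def relaxation_time(net: EMUNetwork, v, X: Mapping[str, float]) -> float:
    """Slowest relaxation time (s) of the labeling ODE.

    The INST dynamics of each EMU size are linear with system matrix
    ``diag(1/X) A_s`` (given the smaller sizes); the labeling approaches
    its stationary state as ``exp(-t/tau)`` with ``tau`` the reciprocal
    of the smallest eigenvalue magnitude over all sizes.  Exceeds
    :func:`slowest_turnover` whenever label re-enters a pool (cycles,
    reversible exchange).
    """
    if not isinstance(v, Mapping):
        vmap = dict(zip(net.model.flux_ids, np.asarray(v, float)))
    else:
        vmap = v
    cons = net.consumption(vmap)
    tau = 0.0
    # eigenvalues involve only A_s, never the solved MDVs
    for s in net.sizes:
        unknowns = net.unknowns_by_size[s]
        idx = {e: i for i, e in enumerate(unknowns)}
        A = np.zeros((len(unknowns), len(unknowns)))
        for e in unknowns:
            i = idx[e]
            A[i, i] -= cons[e.metabolite]
            for er in net.reactions_by_product[e]:
                pres = er.precursor_emus
                if len(pres) == 1 and pres[0] in idx:
                    A[i, idx[pres[0]]] += vmap[er.flux_id] * er.weight
        M = np.diag([1.0 / X[e.metabolite] for e in unknowns]) @ A
        lam = np.linalg.eigvals(M)
        tau = max(tau, float(1.0 / np.abs(lam.real).min()))
    return tau


# ---------------------------------------------------------------------------
# INST integration


def _compile_problem(net: EMUNetwork, v, labeling: SubstrateLabeling,
                     X: Mapping[str, float]):
    """Flatten the EMU network into array form for the Euler kernels."""
    if not isinstance(v, Mapping):
        v = dict(zip(net.model.flux_ids, np.asarray(v, float)))
    unknowns = net.unknowns
    uidx = {e: i for i, e in enumerate(unknowns)}
    sources = sorted(net.sources)
    sidx = {e: i for i, e in enumerate(sources)}

    ln = np.array([e.size + 1 for e in unknowns], dtype=np.int64)
    off = np.concatenate(([0], np.cumsum(ln)[:-1])).astype(np.int64)
    total = int(ln.sum())

    src_ln = np.array([e.size + 1 for e in sources], dtype=np.int64)
    soff = np.concatenate(([0], np.cumsum(src_ln)[:-1])).astype(np.int64) \
        if sources else np.zeros(0, dtype=np.int64)
    src = np.zeros(int(src_ln.sum()) if sources else 0)
    for e in sources:
        src[soff[sidx[e]]:soff[sidx[e]] + e.size + 1] = source_mdv(labeling, e)

    cons = net.consumption(v)
    for m, c in cons.items():
        if c <= 0:
            raise ValueError(f"metabolite {m!r} has zero consumption flux")
        if m not in X:
            raise ValueError(f"pool size missing for metabolite {m!r}")
        if X[m] <= 0:
            raise ValueError(f"pool size of {m!r} must be strictly positive")
    out = np.array([cons[e.metabolite] for e in unknowns])
    invX = np.array([1.0 / X[e.metabolite] for e in unknowns])

    tgt, flx, k1, i1, l1, k2, i2, l2 = [], [], [], [], [], [], [], []
    for e in unknowns:
        for er in net.reactions_by_product[e]:
            ops = []
            for p in er.precursor_emus:
                if p in uidx:
                    ops.append((0, uidx[p], p.size + 1))
                else:
                    ops.append((1, sidx[p], p.size + 1))
            tgt.append(uidx[e])
            flx.append(v[er.flux_id] * er.weight)
            ops.sort(key=lambda o: -o[2])  # longer operand first
            k1.append(ops[0][0]); i1.append(ops[0][1]); l1.append(ops[0][2])
            if len(ops) == 2:
                k2.append(ops[1][0]); i2.append(ops[1][1]); l2.append(ops[1][2])
            else:
                k2.append(-1); i2.append(0); l2.append(0)

    arrays = dict(
        off=off, ln=ln, total=total,
        out=out, invX=invX,
        src=src, soff=soff,
        tgt=np.array(tgt, dtype=np.int64),
        flx=np.array(flx, dtype=np.float64),
        k1=np.array(k1, dtype=np.int64), i1=np.array(i1, dtype=np.int64),
        l1=np.array(l1, dtype=np.int64),
        k2=np.array(k2, dtype=np.int64), i2=np.array(i2, dtype=np.int64),
        l2=np.array(l2, dtype=np.int64),
    )
    return unknowns, arrays


def _euler_numpy(state, deriv_buf, arr, h, rec_steps, rec_out):
    """Reference Euler loop; mirrors the jitted kernel exactly."""
    off, ln = arr["off"], arr["ln"]
    src, soff = arr["src"], arr["soff"]
    tgt, flx = arr["tgt"], arr["flx"]
    k1, i1, l1 = arr["k1"], arr["i1"], arr["l1"]
    k2, i2, l2 = arr["k2"], arr["i2"], arr["l2"]
    out, invX = arr["out"], arr["invX"]
    ri = 0
    nsteps = rec_steps[-1]
    for step in range(1, nsteps + 1):
        deriv_buf[:] = 0.0
        for t in range(tgt.shape[0]):
            ti = tgt[t]
            to = off[ti]
            a = state if k1[t] == 0 else src
            ao = off[i1[t]] if k1[t] == 0 else soff[i1[t]]
            if k2[t] < 0:
                deriv_buf[to:to + ln[ti]] += flx[t] * a[ao:ao + ln[ti]]
            else:
                b = state if k2[t] == 0 else src
                bo = off[i2[t]] if k2[t] == 0 else soff[i2[t]]
                conv = np.convolve(a[ao:ao + l1[t]], b[bo:bo + l2[t]])
                deriv_buf[to:to + ln[ti]] += flx[t] * conv
        for i in range(off.shape[0]):
            sl = slice(off[i], off[i] + ln[i])
            state[sl] += h * invX[i] * (deriv_buf[sl] - out[i] * state[sl])
            ssum = state[sl].sum()
            # fractions must stay near [0, 1]; an oscillatory Euler
            # instability can explode while the sum stays normalized
            if not ssum > 0.0 or np.max(np.abs(state[sl])) > 10.0:
                return -step
            state[sl] /= ssum
        if ri < rec_steps.shape[0] and rec_steps[ri] == step:
            rec_out[ri] = state
            ri += 1
    return 0


_euler_jit = None


def _get_jit_kernel():
    global _euler_jit
    if _euler_jit is not None:
        return _euler_jit
    import numba

    @numba.njit(cache=True)
    def kernel(state, off, ln, src, soff, tgt, flx, k1, i1, l1, k2, i2, l2,
               out, invX, h, rec_steps, rec_out):
        deriv = np.zeros_like(state)
        buf = np.zeros(64)
        ri = 0
        nsteps = rec_steps[-1]
        for step in range(1, nsteps + 1):
            for q in range(deriv.shape[0]):
                deriv[q] = 0.0
            for t in range(tgt.shape[0]):
                ti = tgt[t]
                to = off[ti]
                if k1[t] == 0:
                    a = state
                    ao = off[i1[t]]
                else:
                    a = src
                    ao = soff[i1[t]]
                if k2[t] < 0:
                    for q in range(ln[ti]):
                        deriv[to + q] += flx[t] * a[ao + q]
                else:
                    if k2[t] == 0:
                        b = state
                        bo = off[i2[t]]
                    else:
                        b = src
                        bo = soff[i2[t]]
                    for q in range(ln[ti]):
                        buf[q] = 0.0
                    for qa in range(l1[t]):
                        av = a[ao + qa]
                        if av != 0.0:
                            for qb in range(l2[t]):
                                buf[qa + qb] += av * b[bo + qb]
                    for q in range(ln[ti]):
                        deriv[to + q] += flx[t] * buf[q]
            for i in range(off.shape[0]):
                o = off[i]
                ssum = 0.0
                amax = 0.0
                for q in range(ln[i]):
                    val = state[o + q] + h * invX[i] * (
                        deriv[o + q] - out[i] * state[o + q])
                    state[o + q] = val
                    ssum += val
                    if abs(val) > amax:
                        amax = abs(val)
                if not ssum > 0.0 or amax > 10.0:
                    return -step
                for q in range(ln[i]):
                    state[o + q] /= ssum
            if ri < rec_steps.shape[0] and rec_steps[ri] == step:
                for q in range(state.shape[0]):
                    rec_out[ri, q] = state[q]
                ri += 1
        return 0

    _euler_jit = kernel
    return kernel


def simulate_inst(
    net: EMUNetwork,
    v,
    labeling: SubstrateLabeling,
    X: Mapping[str, float],
    times: Sequence[float],
    h: float,
    *,
    use_numba: bool | None = None,
) -> LabelingTrajectory:
    """Integrate the labeling ODE and record states at sampling times.

    The recorded state for ``t_k`` is the Euler grid point landing on (or
    the latest before) ``t_k``; no interpolation.  At ``t = 0`` every
    intracellular MDV is fully unlabeled; substrate labeling applies from
    the first step.  ``h`` must be positive and no larger than the
    smallest sampling interval.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("sampling times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("sampling times must be nonnegative")
    if h <= 0:
        raise ValueError("step size must be positive")
    spacing = np.diff(np.concatenate(([0.0], times)))
    min_gap = spacing[spacing > 0].min()
    if h > min_gap + 1e-12:
        raise ValueError(f"step size {h} exceeds the sampling spacing {min_gap}")

    unknowns, arr = _compile_problem(net, v, labeling, X)
    state = np.concatenate([unlabeled_mdv(e.size) for e in unknowns]) \
        if unknowns else np.zeros(0)

    steps = np.array([int(np.floor(t / h + 1e-9)) for t in times], dtype=np.int64)
    rec_out = np.zeros((times.size, state.size))
    # a sampling time of 0 (or < h) records the initial state
    nonzero = steps > 0
    for k in np.where(~nonzero)[0]:
        rec_out[k] = state
    status = 0
    if np.any(nonzero):
        rec_steps = np.unique(steps[nonzero])
        rec_tmp = np.zeros((rec_steps.size, state.size))
        if use_numba is None:
            use_numba = True
        if use_numba:
            kernel = _get_jit_kernel()
            status = kernel(state, arr["off"], arr["ln"], arr["src"], arr["soff"],
                            arr["tgt"], arr["flx"], arr["k1"], arr["i1"], arr["l1"],
                            arr["k2"], arr["i2"], arr["l2"], arr["out"], arr["invX"],
                            h, rec_steps, rec_tmp)
        else:
            status = _euler_numpy(state, np.zeros_like(state), arr, h,
                                  rec_steps, rec_tmp)
        if status < 0:
            raise RuntimeError(
                f"INST integration diverged at step {-status} "
                f"(t = {-status * h:.4g}); reduce the step size h"
            )
        lookup = {s: i for i, s in enumerate(rec_steps)}
        for k in np.where(nonzero)[0]:
            rec_out[k] = rec_tmp[lookup[steps[k]]]

    values: dict[EMU, np.ndarray] = {}
    offs = arr["off"]
    for i, e in enumerate(unknowns):
        values[e] = rec_out[:, offs[i]:offs[i] + e.size + 1].copy()
    # sources are constant in time
    for e in sorted(net.sources):
        values[e] = np.tile(source_mdv(labeling, e), (times.size, 1))
    return LabelingTrajectory(times=times, values=values, h=h)
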