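"""Flux estimation: covariance-weighted least squares under Sv = 0.

The flux vector is parameterized exactly on the constraint set: with
``C v = c`` collecting the steady-state balances ``S v = 0`` and every
predetermined flux, any feasible vector is ``v = v_p + K u`` where ``K``
is an orthonormal null-space basis of ``C`` and ``u`` the free-flux
coordinates.  Levenberg-Marquardt then minimizes

    Phi(v) = sum_k sum_j D^T C_meas^-1 D,   D = observed - simulated MDV

over ``u``; every iterate is feasible by construction, and
irreversibility (v >= 0) is kept by shortening trial steps to the
boundary.  The Jacobian is formed by forward finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .emu import EMUNetwork
from .mdv import SubstrateLabeling
from .measurements import MeasurementSet, fragment_mdv
from .model import MetabolicModel
from .simulate import simulate_inst, simulate_stationary

__all__ = [
    "FluxInfeasibleError",
    "FreeFluxParam",
    "FitOptions",
    "FitResult",
    "generate_initial_flux",
    "compute_ssd",
    "fit_fluxes",
]

_RANK_TOL = 1e-10


class FluxInfeasibleError(ValueError):
    """The predetermined fluxes admit no feasible flux vector."""


def _constraint_system(
    model: MetabolicModel,
    extra_fixed: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack S v = 0 with equality rows for fixed (and extra-fixed) fluxes."""
    n = len(model.reactions)
    rows = [model.S]
    rhs = [np.zeros(model.S.shape[0])]
    names = [f"balance[{m}]" for m in model.balanced_metabolites]
    fixed = dict(model.fixed_fluxes)
    if extra_fixed:
        fixed.update(extra_fixed)
    for fid, val in fixed.items():
        e = np.zeros(n)
        e[model.flux_index(fid)] = 1.0
        rows.append(e[None, :])
        rhs.append([val])
        names.append(f"fixed[{fid}]")
    return np.vstack(rows), np.concatenate(rhs), names


class FreeFluxParam:
    """Exact parameterization of the feasible affine set ``{v : C v = c}``."""

    def __init__(self, model: MetabolicModel,
                 extra_fixed: Mapping[str, float] | None = None):
        self.model = model
        self.C, self.c, self.row_names = _constraint_system(model, extra_fixed)
        self.v_particular, res, rank, _ = scipy.linalg.lstsq(self.C, self.c)
        misfit = self.C @ self.v_particular - self.c
        if np.max(np.abs(misfit)) > 1e-8 * max(1.0, np.max(np.abs(self.c))):
            worst = int(np.argmax(np.abs(misfit)))
            raise FluxInfeasibleError(
                f"predetermined fluxes are inconsistent; largest violation "
                f"{misfit[worst]:.3g} in {self.row_names[worst]}"
            )
        self.K = scipy.linalg.null_space(self.C, rcond=_RANK_TOL)
        self.rank = np.linalg.matrix_rank(self.C, tol=_RANK_TOL)

    @property
    def n_free(self) -> int:
        return self.K.shape[1]

    def v(self, u: np.ndarray) -> np.ndarray:
        return self.v_particular + self.K @ u

    def u(self, v: np.ndarray) -> np.ndarray:
        """Free coordinates of the feasible point closest to *v*."""
        return self.K.T @ (np.asarray(v, float) - self.v_particular)


def generate_initial_flux(
    model: MetabolicModel,
    seed: int,
    *,
    upper: float | None = None,
    extra_fixed: Mapping[str, float] | None = None,
    max_retries: int = 1000,
) -> np.ndarray:
    """Random feasible flux vector: free fluxes uniform in (0, upper],
    dependent fluxes solved from the constraints, resampled until every
    flux is nonnegative."""
    rng = np.random.default_rng(seed)
    C, c, names = _constraint_system(model, extra_fixed)
    n = C.shape[1]
    if upper is None:
        fixed_mag = [abs(x) for x in model.fixed_fluxes.values()]
        upper = 10.0 * max(fixed_mag) if fixed_mag else 10.0

    # column-pivoted QR picks a dependent column set; the rest are sampled
    _, R, piv = scipy.linalg.qr(C, pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > _RANK_TOL * max(diag.max(), 1.0)))
    dep = piv[:rank]
    free = piv[rank:]

    last_violation = None
    for _ in range(max_retries):
        v = np.zeros(n)
        v[free] = rng.uniform(0.0, upper, size=free.size)
        rhs = c - C[:, free] @ v[free]
        sol, *_ = scipy.linalg.lstsq(C[:, dep], rhs)
        v[dep] = sol
        misfit = C @ v - c
        if np.max(np.abs(misfit)) > 1e-8 * max(1.0, np.max(np.abs(c))):
            worst = int(np.argmax(np.abs(misfit)))
            raise FluxInfeasibleError(
                f"constraints are inconsistent; violation in {names[worst]}"
            )
        if v.min() >= -1e-9:
            return np.clip(v, 0.0, None)
        last_violation = model.flux_ids[int(np.argmin(v))]
    raise FluxInfeasibleError(
        f"no nonnegative feasible flux vector found in {max_retries} draws; "
        f"flux {last_violation} is forced negative by the predetermined values"
    )


def compute_ssd(
    model: MetabolicModel,
    net: EMUNetwork,
    v,
    measurements: MeasurementSet,
    labeling: SubstrateLabeling,
    mode: str = "stationary",
    X: Mapping[str, float] | None = None,
    h: float | None = None,
) -> tuple[float, dict]:
    """Covariance-weighted SSD between measured and simulated MDVs.

    Returns ``(Phi, D)`` where ``D[(label, k)]`` is the raw residual
    (observed minus simulated) for fragment *label* at sampling point
    *k*.  ``Phi`` weights each residual channel by its measurement SD.
    """
    sims = _simulate_fragments(net, v, measurements, labeling, mode, X, h)
    phi = 0.0
    D = {}
    for label, obs in measurements.spectra.items():
        sd = measurements.sd[label]
        for k in range(obs.shape[0]):
            d = obs[k] - sims[label][k]
            D[(label, k)] = d
            phi += float(np.sum((d / sd[k]) ** 2))
    return phi, D


def _simulate_fragments(net, v, measurements, labeling, mode, X, h):
    """Simulated MDV rows per fragment, matching the measurement layout."""
    out = {}
    if mode == "stationary":
        solved = simulate_stationary(net, v, labeling)
        for label, frag in measurements.fragments.items():
            sim = fragment_mdv(solved, frag)
            out[label] = np.tile(sim, (measurements.n_samples, 1))
    elif mode == "inst":
        if X is None or h is None or measurements.times is None:
            raise ValueError("INST mode needs pool sizes X, step h and sampling times")
        traj = simulate_inst(net, v, labeling, X, measurements.times, h)
        for label, frag in measurements.fragments.items():
            rows = [
                fragment_mdv({e: traj.values[e][k] for e in frag.terms}, frag)
                for k in range(len(measurements.times))
            ]
            out[label] = np.vstack(rows)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _weighted_residual(net, param, u, measurements, labeling, mode, X, h):
    v = param.v(u)
    sims = _simulate_fragments(net, v, measurements, labeling, mode, X, h)
    parts = []
    for label, obs in measurements.spectra.items():
        sd = measurements.sd[label]
        parts.append(((obs - sims[label]) / sd).ravel())
    return np.concatenate(parts)


@dataclass
class FitOptions:
    seed: int = 0
    restarts: int = 10
    max_iter: int = 200
    lam0: float = 1e-3
    lam_accept: float = 0.1
    lam_reject: float = 10.0
    ftol: float = 1e-8
    gtol: float = 1e-6
    fd_rel: float = 1e-6
    fd_abs: float = 1e-8
    upper: float | None = None
    init_v: np.ndarray | None = None  # warm start for the first restart


@dataclass
class FitResult:
    flux_ids: list[str]
    v_opt: np.ndarray
    phi: float
    residuals: dict
    u_opt: np.ndarray
    param: FreeFluxParam
    n: int
    p: int
    sd: np.ndarray  # linearized per-reaction flux SDs
    converged: bool
    n_iter: int
    log: list = field(default_factory=list)

    @property
    def fluxes(self) -> dict[str, float]:
        return dict(zip(self.flux_ids, self.v_opt))

    def flux_sd(self, flux_id: str) -> float:
        return float(self.sd[self.flux_ids.index(flux_id)])


def _max_feasible_step(v, dv, lower=0.0, upper=np.inf):
    """Largest alpha in (0, 1] keeping lower <= v + alpha dv <= upper."""
    alpha = 1.0
    mask = dv < -1e-300
    if np.any(mask):
        room = (v[mask] - lower) / (-dv[mask])
        alpha = min(alpha, float(room.min()) * 0.999999)
    if np.isfinite(upper):
        mask = dv > 1e-300
        if np.any(mask):
            room = (upper - v[mask]) / dv[mask]
            alpha = min(alpha, float(room.min()) * 0.999999)
    return max(alpha, 0.0)


def _levenberg_marquardt(resid_fn, param, u0, opts: FitOptions, upper=np.inf):
    u = u0.copy()
    r = resid_fn(u)
    phi = float(r @ r)
    lam = opts.lam0
    log = [(0, phi, lam)]
    converged = False
    it = 0
    p = u.size
    J = None
    while it < opts.max_iter and p > 0:
        it += 1
        J = _fd_jacobian(resid_fn, param, u, r, opts)
        JtJ = J.T @ J
        g = J.T @ r
        if np.max(np.abs(g)) < opts.gtol:
            converged = True
            break
        Dscale = np.clip(np.diag(JtJ), 1e-12, None)
        accepted = False
        while lam <= 1e12:
            try:
                step = scipy.linalg.solve(
                    JtJ + lam * np.diag(Dscale), -g, assume_a="pos")
            except scipy.linalg.LinAlgError:
                lam *= opts.lam_reject
                continue
            dv = param.K @ step
            alpha = _max_feasible_step(param.v(u), dv, upper=upper)
            if alpha <= 1e-14:
                lam *= opts.lam_reject
                continue
            u_trial = u + alpha * step
            try:
                r_trial = resid_fn(u_trial)
                phi_trial = float(r_trial @ r_trial)
            except (RuntimeError, ValueError):
                # simulator rejected the trial point (e.g. Euler divergence
                # at an extreme flux); damp harder and retry
                lam *= opts.lam_reject
                continue
            if not np.isfinite(phi_trial):
                lam *= opts.lam_reject
                continue
            if phi_trial < phi:
                drop = phi - phi_trial
                u, r, phi = u_trial, r_trial, phi_trial
                lam = max(lam * opts.lam_accept, 1e-12)
                log.append((it, phi, lam))
                accepted = True
                if drop <= opts.ftol * max(phi, 1e-300):
                    converged = True
                break
            lam *= opts.lam_reject
        if not accepted:
            break
        if converged:
            break
    if p == 0:
        converged = True
    return u, r, phi, converged, it, log, J


def _fd_jacobian(resid_fn, param, u, r0, opts: FitOptions):
    p = u.size
    J = np.empty((r0.size, p))
    v0 = param.v(u)
    for i in range(p):
        du = max(opts.fd_rel * abs(u[i]), opts.fd_abs)
        step = np.zeros(p)
        step[i] = du
        if np.min(v0 + param.K @ step) < -1e-12:
            step[i] = -du  # backward difference near the boundary
        r1 = resid_fn(u + step)
        J[:, i] = (r1 - r0) / step[i]
    return J


def fit_fluxes(
    model: MetabolicModel,
    net: EMUNetwork,
    measurements: MeasurementSet,
    labeling: SubstrateLabeling,
    mode: str = "stationary",
    X: Mapping[str, float] | None = None,
    h: float | None = None,
    options: FitOptions | None = None,
    *,
    extra_fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """Estimate fluxes by Levenberg-Marquardt from random feasible starts.

    Runs ``options.restarts`` independent starts (seeded) and returns the
    best.  ``extra_fixed`` adds equality constraints beyond the model's
    predetermined fluxes (used by the grid-search confidence intervals).
    """
    opts = options or FitOptions()
    param = FreeFluxParam(model, extra_fixed)
    n = measurements.n_independent()
    p = param.n_free

    def resid(u):
        return _weighted_residual(net, param, u, measurements, labeling, mode, X, h)

    if opts.upper is not None:
        ub = opts.upper
    else:
        fixed_mag = [abs(x) for x in model.fixed_fluxes.values()]
        ub = 10.0 * max(fixed_mag) if fixed_mag else 10.0
    # trial iterates stay inside [0, 2*ub]; starts are sampled within [0, ub]
    ub_step = 2.0 * ub

    best = None
    rng_seeds = [opts.seed + 1000 * k for k in range(max(opts.restarts, 1))]
    for k, s in enumerate(rng_seeds):
        if k == 0 and opts.init_v is not None:
            v0 = np.asarray(opts.init_v, float)
            # projecting a warm start onto new constraints can leave the
            # feasible orthant; fall back to a random feasible point then
            if np.min(param.v(param.u(v0))) < -1e-9:
                v0 = generate_initial_flux(model, s, upper=opts.upper,
                                           extra_fixed=extra_fixed)
        else:
            v0 = generate_initial_flux(model, s, upper=opts.upper,
                                       extra_fixed=extra_fixed)
        u0 = param.u(v0)
        # dependent fluxes at a random start may exceed the sampling bound
        ub_run = max(ub_step, 2.0 * float(np.max(v0)))
        u, r, phi, conv, it, log, J = _levenberg_marquardt(
            resid, param, u0, opts, upper=ub_run)
        if best is None or phi < best[2]:
            best = (u, r, phi, conv, it, log, J)

    u, r, phi, conv, it, log, J = best
    v_opt = np.clip(param.v(u), 0.0, None)
    _, D = compute_ssd(model, net, v_opt, measurements, labeling, mode, X, h)

    sd_v = np.full(len(model.reactions), np.nan)
    if p > 0:
        if J is None:
            J = _fd_jacobian(resid, param, u, r, opts)
        try:
            cov_u = scipy.linalg.inv(J.T @ J)
            cov_v = param.K @ cov_u @ param.K.T
            sd_v = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))
        except scipy.linalg.LinAlgError:
            pass
    else:
        sd_v = np.zeros(len(model.reactions))

    return FitResult(
        flux_ids=model.flux_ids, v_opt=v_opt, phi=phi, residuals=D,
        u_opt=u, param=param, n=n, p=p, sd=sd_v, converged=conv,
        n_iter=it, log=log,
    )
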