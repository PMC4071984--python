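"""Grid-search (profile) confidence intervals for estimated fluxes.

One flux ``r`` at a time is fixed to perturbed values ``v_opt_r + d`` and
the objective is reoptimized over all remaining free fluxes.  The 1-alpha
confidence interval is the range of fixed values whose reoptimized SSD
stays below the F-test threshold

    Phi_thr = Phi_res * (1 + F_alpha(1, n - p) / (n - p))

with ``n`` independent data points and ``p`` free fluxes in the original
fit.  The search grows ``|d|`` geometrically until the threshold is
crossed, then bisects to the crossing; reoptimizations warm-start from the
neighboring grid point.

The search itself is written against a small "profile problem" interface
so the same code path serves both the full MFA problem
(:class:`FluxProfileProblem`) and analytically tractable test problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol

import numpy as np
import scipy.stats

from .emu import EMUNetwork
from .fit import FitOptions, FitResult, FluxInfeasibleError, FreeFluxParam, fit_fluxes
from .mdv import SubstrateLabeling
from .measurements import MeasurementSet
from .model import MetabolicModel

__all__ = [
    "ci_threshold",
    "ConfidenceInterval",
    "GridOptions",
    "ProfileProblem",
    "FluxProfileProblem",
    "grid_search_ci",
]


def ci_threshold(phi_res: float, n: int, p: int, alpha: float = 0.95) -> float:
    """SSD cutoff for a (1-alpha-quantile) grid-search confidence interval."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= p:
        raise ValueError(
            f"n = {n} independent data points with p = {p} free fluxes: "
            f"model not identifiable for an F-based interval"
        )
    return phi_res * (1.0 + scipy.stats.f.ppf(alpha, 1, n - p) / (n - p))


class ProfileProblem(Protocol):
    """What the grid search needs from a fitted estimation problem."""

    phi_res: float
    n: int
    p: int

    def optimum(self, flux_id: str) -> float: ...
    def bounds(self, flux_id: str) -> tuple[float, float]: ...
    def is_determined(self, flux_id: str) -> bool: ...
    def profile_phi(self, flux_id: str, value: float, warm=None): ...


@dataclass
class GridOptions:
    alpha: float = 0.95
    initial_rel: float = 0.01   # starting |d| as a fraction of |v_opt_r|
    initial_abs: float = 1e-4   # absolute floor on the starting |d|
    growth: float = 2.0
    bisect_rel: float = 1e-4    # relative bisection tolerance on the endpoint
    max_grow: int = 60


@dataclass
class ConfidenceInterval:
    flux_id: str
    alpha: float
    lower: float
    upper: float
    threshold: float
    profile: list = field(default_factory=list)  # (fixed value, reoptimized phi)
    lower_unbounded: bool = False
    upper_unbounded: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


def grid_search_ci(
    problem: ProfileProblem,
    flux_id: str,
    options: GridOptions | None = None,
) -> ConfidenceInterval:
    """Profile one flux and bracket the threshold crossings on both sides."""
    opts = options or GridOptions()
    thr = ci_threshold(problem.phi_res, problem.n, problem.p, opts.alpha)
    center = problem.optimum(flux_id)
    profile: list[tuple[float, float]] = [(center, problem.phi_res)]

    if problem.is_determined(flux_id):
        return ConfidenceInterval(
            flux_id=flux_id, alpha=opts.alpha, lower=center, upper=center,
            threshold=thr, profile=profile,
        )

    lo_b, hi_b = problem.bounds(flux_id)
    scale = max(abs(center), opts.initial_abs)
    endpoints = {}
    flags = {}
    for side in (+1.0, -1.0):
        bound = hi_b if side > 0 else lo_b
        d = max(opts.initial_rel * abs(center), opts.initial_abs)
        inner_val, inner_phi = center, problem.phi_res
        warm = None
        outer_val = None
        unbounded = False
        for _ in range(opts.max_grow):
            val = center + side * d
            clipped = (side > 0 and val >= bound) or (side < 0 and val <= bound)
            if clipped:
                val = bound
            phi, warm = problem.profile_phi(flux_id, val, warm)
            profile.append((val, phi))
            if phi > thr:
                outer_val = val
                break
            inner_val, inner_phi = val, phi
            if clipped:
                unbounded = True
                break
            d *= opts.growth
        if unbounded or outer_val is None:
            endpoints[side] = inner_val
            flags[side] = True
            continue
        # bisect between the last value below threshold and the first above
        lo_v, hi_v = inner_val, outer_val
        tol = opts.bisect_rel * scale
        while abs(hi_v - lo_v) > tol:
            mid = 0.5 * (lo_v + hi_v)
            phi, warm = problem.profile_phi(flux_id, mid, warm)
            profile.append((mid, phi))
            if phi > thr:
                hi_v = mid
            else:
                lo_v = mid
        endpoints[side] = 0.5 * (lo_v + hi_v)
        flags[side] = False

    profile.sort(key=lambda t: t[0])
    return ConfidenceInterval(
        flux_id=flux_id, alpha=opts.alpha,
        lower=endpoints[-1.0], upper=endpoints[+1.0], threshold=thr,
        profile=profile,
        lower_unbounded=flags[-1.0], upper_unbounded=flags[+1.0],
    )


class FluxProfileProblem:
    """Profile-problem adapter around a completed flux fit.

    Fixing flux ``r`` is implemented by adding the equality row ``e_r^T``
    to the constraint system and recomputing the null-space basis; each
    reoptimization warm-starts from the neighboring grid point's solution.
    """

    def __init__(
        self,
        model: MetabolicModel,
        net: EMUNetwork,
        measurements: MeasurementSet,
        labeling: SubstrateLabeling,
        fit: FitResult,
        mode: str = "stationary",
        X: Mapping[str, float] | None = None,
        h: float | None = None,
        fit_options: FitOptions | None = None,
        upper: float | None = None,
    ):
        if not fit.converged:
            raise ValueError("confidence intervals require a converged fit")
        self.model = model
        self.net = net
        self.measurements = measurements
        self.labeling = labeling
        self.fit = fit
        self.mode = mode
        self.X = X
        self.h = h
        base = fit_options or FitOptions()
        self.refit_options = replace(base, restarts=1)
        self.phi_res = fit.phi
        self.n = fit.n
        self.p = fit.p
        fixed_mag = [abs(x) for x in model.fixed_fluxes.values()]
        self.upper = upper if upper is not None else (
            10.0 * max(fixed_mag) if fixed_mag else 10.0 * max(fit.v_opt.max(), 1.0)
        )

    def optimum(self, flux_id: str) -> float:
        return self.fit.fluxes[flux_id]

    def bounds(self, flux_id: str) -> tuple[float, float]:
        return 0.0, self.upper

    def is_determined(self, flux_id: str) -> bool:
        if flux_id in self.model.fixed_fluxes:
            raise ValueError(f"{flux_id} is predetermined; no interval to search")
        pinned = FreeFluxParam(
            self.model, {flux_id: self.optimum(flux_id)}
        ).n_free
        return pinned == self.p  # e_r already in the row span

    def profile_phi(self, flux_id: str, value: float, warm=None):
        opts = replace(self.refit_options,
                       init_v=warm if warm is not None else self.fit.v_opt)
        try:
            res = fit_fluxes(
                self.model, self.net, self.measurements, self.labeling,
                mode=self.mode, X=self.X, h=self.h, options=opts,
                extra_fixed={flux_id: value},
            )
        except FluxInfeasibleError:
            return math.inf, warm
        return res.phi, res.v_opt
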