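"""Long-run h-scores selected by forward dynamics from the shared h0.

All coordinates obey one-dimensional autonomous polynomial ODEs once the
faster/upstream coordinates are at rest, so the forward-time limit from an
initial condition is the first polynomial root encountered in the
direction of the initial derivative.  Equilibria are therefore computed by
*directional root selection* (the exact limit of forward integration),
with an optional explicit integrator retained as a cross-check and for
convergence diagnostics.

Degenerate directions — a derivative that vanishes identically, e.g. the
resident opinion of an unconditional-defector mutant under ``d11=1,
d01=0`` tables — are genuine lines of fixed points: the coordinate simply
stays at the initial value ``h0``.  The resident coordinate is
pre-equilibrated before the mutant coordinates are solved (the resident
equation is autonomous), which is what makes those marginal coordinates
remain exactly at ``h0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mean_field import (
    HState,
    ModelParams,
    act_prob,
    assess_prob_good,
    dimorphic_derivatives,
    monomorphic_derivative,
    monomorphic_poly,
    _q,
)
from .strategies import Strategy

__all__ = [
    "EquilibriumResult",
    "monomorphic_equilibrium",
    "dimorphic_equilibrium",
    "resident_mutant_equilibria",
]

#: |derivative| below which a point counts as a fixed point.
RESIDUAL_TOL = 1e-10
#: |coefficient| below which a polynomial direction counts as identically zero.
MARGINAL_TOL = 1e-12
#: eigenvalue / slope threshold separating stable from marginal.
STABILITY_TOL = 1e-7


@dataclass
class EquilibriumResult:
    """A fixed point plus stability and convergence diagnostics."""

    h_star: float | HState
    stable: str  # "stable" | "marginal" | "unstable"
    converged: bool
    residual: float
    steps: int
    method: str = "cascade"
    flag: str | None = None


def _real_unit_roots(coeffs_asc: np.ndarray) -> np.ndarray:
    """Real roots of the polynomial that lie in [0, 1] (sorted)."""
    c = np.trim_zeros(np.asarray(coeffs_asc, dtype=float), "b")
    if c.size <= 1:
        return np.array([])
    roots = np.roots(c[::-1])
    real = roots[np.abs(roots.imag) < 1e-5].real
    real = real[(real > -1e-4) & (real < 1 + 1e-4)]
    real = list(np.clip(real, 0.0, 1.0))
    # np.roots is inaccurate at multiple roots; the boundaries 0 and 1 are
    # frequent exact roots of these probability polynomials, so snap any
    # nearby numerical root onto them.
    pv = np.polynomial.polynomial.polyval
    for boundary in (0.0, 1.0):
        if abs(pv(boundary, coeffs_asc)) < 1e-12:
            real = [boundary if abs(r - boundary) < 1e-4 else r for r in real]
            real.append(boundary)
    return np.unique(np.round(np.sort(np.array(real)), 12))


def _directional_root(coeffs_asc: np.ndarray, x0: float) -> tuple[float, bool]:
    """Limit of ``dx/dt = poly(x)`` from ``x0``; second value flags a
    marginal (identically zero) polynomial."""
    coeffs_asc = np.asarray(coeffs_asc, dtype=float)
    if np.all(np.abs(coeffs_asc) < MARGINAL_TOL):
        return x0, True
    f0 = float(np.polynomial.polynomial.polyval(x0, coeffs_asc))
    if abs(f0) < MARGINAL_TOL:
        return x0, False
    roots = _real_unit_roots(coeffs_asc)
    if f0 > 0:
        ahead = roots[roots >= x0 - 1e-9]
        return (float(ahead[0]) if ahead.size else 1.0), False
    behind = roots[roots <= x0 + 1e-9]
    return (float(behind[-1]) if behind.size else 0.0), False


def _integrate_scalar(f, x0: float, *, dt: float, stop_tol: float, max_time: float):
    """Clipped explicit Euler until |f| < stop_tol; returns (x, steps)."""
    x, t, steps = float(x0), 0.0, 0
    while t < max_time:
        d = f(x)
        if abs(d) < stop_tol:
            break
        x = min(1.0, max(0.0, x + dt * d))
        t += dt
        steps += 1
    return x, steps


def monomorphic_equilibrium(
    strategy: Strategy,
    params: ModelParams,
    *,
    h0: float | None = None,
    tol: float = RESIDUAL_TOL,
    dt: float = 0.2,
    max_time: float = 1e6,
    integrate: bool = True,
) -> EquilibriumResult:
    """Fixed point of the monomorphic h-score dynamics reached from ``h0``.

    The endpoint is the directional root of the degree-<=3 derivative
    polynomial (the exact forward-time limit); when ``integrate`` is true
    an explicit Euler run from ``h0`` provides the step count and a
    cross-check that the root lies in the same basin.  A derivative that
    is identically zero yields ``h0`` with stability ``"marginal"``.
    """
    h0 = params.h0 if h0 is None else float(h0)
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"h0 must lie in [0, 1], got {h0}")
    poly = monomorphic_poly(strategy, params)
    root, marginal = _directional_root(poly, h0)
    steps = 0
    flag = None
    if integrate and not marginal:
        f = lambda x: float(np.polynomial.polynomial.polyval(x, poly))
        x_end, steps = _integrate_scalar(f, h0, dt=dt, stop_tol=1e-6, max_time=max_time)
        if abs(f(x_end)) >= 1e-6:
            flag = "no_convergence"
        # snap only if integration corroborates the analytic basin
        if abs(x_end - root) > 0.05 and flag is None:
            root2, _ = _directional_root(poly, x_end)
            root = root2
    residual = abs(float(np.polynomial.polynomial.polyval(root, poly)))
    if marginal:
        stable = "marginal"
    else:
        slope = float(np.polynomial.polynomial.polyval(root, np.polynomial.polynomial.polyder(poly)))
        if slope < -STABILITY_TOL:
            stable = "stable"
        elif slope > STABILITY_TOL:
            stable = "unstable"
        else:
            stable = "marginal"
    return EquilibriumResult(
        h_star=float(root),
        stable=stable,
        converged=residual < tol and flag is None,
        residual=residual,
        steps=steps,
        method="cascade+integrate" if integrate else "cascade",
        flag=flag,
    )


# ---------------------------------------------------------------------------
# dimorphic (resident + rare mutant) system
# ---------------------------------------------------------------------------

def _rm_poly(mutant_C, mutant_D, p_rr_coop: float, mu_a: float) -> np.ndarray:
    """Ascending quadratic coefficients of d(h_rm)/dt as a function of
    x = h_rm, with the resident pre-equilibrated (p_rr_coop fixed).

    The mutant observes resident-resident interactions; both of its
    opinions are Bernoulli(x), so for a table t the expected output is
    x^2 q(t11) + x(1-x)(q(t10)+q(t01)) + (1-x)^2 q(t00).
    """

    def tab(table):
        t11, t10, t01, t00 = (_q(t, mu_a) for t in table)
        a2 = t11 - t10 - t01 + t00
        a1 = t10 + t01 - 2.0 * t00
        a0 = t00
        return np.array([a0, a1, a2])

    poly = p_rr_coop * tab(mutant_C) + (1.0 - p_rr_coop) * tab(mutant_D)
    poly[1] -= 1.0  # subtract x
    poly[np.abs(poly) < MARGINAL_TOL] = 0.0
    return poly


def _mr_affine(resident_C, resident_D, p_m_coop: float, h_rr: float, mu_a: float):
    """(slope, intercept) of d(h_mr)/dt as a function of x = h_mr.

    A resident observer judges the mutant donor; its opinion of the donor
    is Bernoulli(x), of the (resident) recipient Bernoulli(h_rr), so the
    expected table output is affine in x.
    """

    def uv(table):
        t11, t10, t01, t00 = (_q(t, mu_a) for t in table)
        u = h_rr * t11 + (1.0 - h_rr) * t10  # donor deemed good
        v = h_rr * t01 + (1.0 - h_rr) * t00  # donor deemed bad
        return u, v

    uC, vC = uv(resident_C)
    uD, vD = uv(resident_D)
    w_u = p_m_coop * uC + (1.0 - p_m_coop) * uD
    w_v = p_m_coop * vC + (1.0 - p_m_coop) * vD
    return (w_u - w_v - 1.0), w_v


def resident_mutant_equilibria(
    resident: Strategy,
    mutants: list[Strategy],
    params: ModelParams,
    h0: float | None = None,
) -> dict:
    """Equilibria of the resident + rare-mutant system for many mutants.

    The cascade solves, in order: the autonomous resident coordinate
    ``h_rr`` (directional root of the monomorphic cubic from ``h0``), then
    per mutant the autonomous ``h_rm`` (directional root of a quadratic)
    and finally the affine ``h_mr`` (a globally attracting root, or ``h0``
    when the direction is marginal).  Returns arrays aligned with
    ``mutants`` plus the scalar ``h_rr``.
    """
    h0 = params.h0 if h0 is None else float(h0)
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"h0 must lie in [0, 1], got {h0}")
    poly_rr = monomorphic_poly(resident, params)
    h_rr, rr_marginal = _directional_root(poly_rr, h0)
    p_rr = float(act_prob(resident.a1, resident.a0, h_rr, params.mu_e))

    n = len(mutants)
    h_rm = np.empty(n)
    h_mr = np.empty(n)
    mr_marginal = np.zeros(n, dtype=bool)
    rm_marginal = np.zeros(n, dtype=bool)
    for j, m in enumerate(mutants):
        poly_rm = _rm_poly(m.C, m.D, p_rr, params.mu_a)
        x_rm, marg = _directional_root(poly_rm, h0)
        h_rm[j] = x_rm
        rm_marginal[j] = marg
        p_m = float(act_prob(m.a1, m.a0, x_rm, params.mu_e))
        slope, intercept = _mr_affine(resident.C, resident.D, p_m, h_rr, params.mu_a)
        if abs(slope) < MARGINAL_TOL:
            h_mr[j] = h0
            mr_marginal[j] = True
        else:
            h_mr[j] = min(1.0, max(0.0, -intercept / slope))
    return {
        "h_rr": float(h_rr),
        "h_rr_marginal": rr_marginal,
        "h_mr": h_mr,
        "h_rm": h_rm,
        "mr_marginal": mr_marginal,
        "rm_marginal": rm_marginal,
        "p_rr": p_rr,
    }


def _dimorphic_jacobian(resident, mutant, state: HState, params, eps: float = 1e-6):
    """Central finite-difference Jacobian of the joint 3-coordinate RHS."""
    J = np.empty((3, 3))
    x = np.array(state, dtype=float)
    for j in range(3):
        hi = x.copy()
        lo = x.copy()
        hi[j] = min(1.0, x[j] + eps)
        lo[j] = max(0.0, x[j] - eps)
        fh = np.array(dimorphic_derivatives(resident, mutant, HState(*hi), params))
        fl = np.array(dimorphic_derivatives(resident, mutant, HState(*lo), params))
        J[:, j] = (fh - fl) / (hi[j] - lo[j])
    return J


def dimorphic_equilibrium(
    resident: Strategy,
    mutant: Strategy,
    params: ModelParams,
    *,
    h0: float | None = None,
    tol: float = RESIDUAL_TOL,
    method: str = "cascade",
    dt: float = 0.1,
    max_time: float = 1e5,
) -> EquilibriumResult:
    """Fixed point of the resident + rare-mutant system from ``(h0, h0, h0)``.

    ``method="cascade"`` (default) uses exact directional root selection;
    ``method="integrate"`` forward-integrates the mutant coordinates with
    the resident pre-equilibrated and then snaps to the cascade roots,
    reporting step counts and flagging non-convergence or residuals that
    stop decreasing (a limit-cycle suspect) instead of silently returning.
    """
    if method not in ("cascade", "integrate"):
        raise ValueError(f"unknown method {method!r}")
    h0 = params.h0 if h0 is None else float(h0)
    eq = resident_mutant_equilibria(resident, [mutant], params, h0=h0)
    state = HState(eq["h_rr"], float(eq["h_mr"][0]), float(eq["h_rm"][0]))
    steps = 0
    flag = None
    if method == "integrate":
        h_rr = eq["h_rr"]
        p_rr = eq["p_rr"]
        x_mr, x_rm = h0, h0
        t = 0.0
        best = np.inf
        while t < max_time:
            poly_rm = _rm_poly(mutant.C, mutant.D, p_rr, params.mu_a)
            d_rm = float(np.polynomial.polynomial.polyval(x_rm, poly_rm))
            p_m = float(act_prob(mutant.a1, mutant.a0, x_rm, params.mu_e))
            slope, intercept = _mr_affine(
                resident.C, resident.D, p_m, h_rr, params.mu_a
            )
            d_mr = slope * x_mr + intercept
            res = max(abs(d_rm), abs(d_mr))
            best = min(best, res)
            if res < 1e-8:
                break
            x_rm = min(1.0, max(0.0, x_rm + dt * d_rm))
            x_mr = min(1.0, max(0.0, x_mr + dt * d_mr))
            t += dt
            steps += 1
        else:
            if best < np.inf and res > 100.0 * best and res > tol:
                flag = "possible_limit_cycle"
            elif res > tol:
                flag = "no_convergence"
        if abs(x_mr - state.h_mr) > 0.05 or abs(x_rm - state.h_rm) > 0.05:
            # integration disagrees with the analytic basin; keep the
            # integrated point, re-snapped from where it landed
            eq2 = resident_mutant_equilibria(resident, [mutant], params, h0=x_rm)
            state = HState(eq["h_rr"], x_mr, float(eq2["h_rm"][0]))
    rhs = dimorphic_derivatives(resident, mutant, state, params)
    residual = float(np.max(np.abs(rhs)))
    J = _dimorphic_jacobian(resident, mutant, state, params)
    lead = float(np.max(np.linalg.eigvals(J).real))
    if lead < -STABILITY_TOL:
        stable = "stable"
    elif lead > STABILITY_TOL:
        stable = "unstable"
    else:
        stable = "marginal"
    return EquilibriumResult(
        h_star=state,
        stable=stable,
        converged=residual < max(tol, 1e-9) and flag is None,
        residual=residual,
        steps=steps,
        method=method,
        flag=flag,
    )
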