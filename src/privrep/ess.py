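"""Evolutionary invasion analysis over the canonical strategy set.

The invasion fitness of a rare mutant in a resident population is

    delta_w = p_mr * b - p_rm * c - p_rr * (b - c)

where the three cooperation probabilities are evaluated at the equilibrium
h-scores reached from the shared initial condition ``h0``.  Because the
h-score dynamics carry no payoffs, equilibria are independent of ``b`` and
``c``: each (resident, mutant, h0, errors) combination is solved once and
``delta_w`` is affine in ``b`` (cost normalized to 1), which makes the
exhaustive 258 x 257 x 3 scan cheap and makes ESS regions in ``b`` exact
intervals rather than grid artefacts.

A mutant invades iff ``delta_w`` exceeds the fitness tolerance (1e-4 by
default); exact ties resist invasion (no drift in an infinite population).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import resident_mutant_equilibria
from .mean_field import ModelParams, act_prob
from .strategies import Strategy, canonical_set, encode

__all__ = [
    "FITNESS_TOL",
    "InvasionOutcome",
    "ESSRecord",
    "ESSScanResult",
    "invasion_fitness",
    "is_ess",
    "min_bc_threshold",
    "classify",
    "ess_scan",
    "polymorphism_check",
]

#: fitness differences below this are treated as exactly zero.
FITNESS_TOL = 1e-4

#: classification width: cooperator iff p_rr >= 1 - EPS_CLASS, defector iff <= EPS_CLASS.
EPS_CLASS = 1e-3

#: default benefit grid with cost normalized to 1 (covers (1, 20]).
DEFAULT_BC_GRID = np.round(np.arange(1.25, 20.0 + 1e-9, 0.25), 10)

DEFAULT_H0_SET = (0.1, 0.5, 0.9)


@dataclass(frozen=True)
class InvasionOutcome:
    """Result of one mutant-vs-resident invasion test."""

    delta_w: float
    invades: bool
    p_mr: float  #: resident cooperating with the mutant, at equilibrium
    p_rm: float  #: mutant cooperating with residents, at equilibrium
    p_rr: float  #: resident-resident cooperation, at equilibrium


def _slopes_intercepts(resident, mutants, params, h0):
    """Per-mutant affine form delta_w(b) = slope * b + intercept (c = params.c)."""
    eq = resident_mutant_equilibria(resident, mutants, params, h0=h0)
    p_rr = eq["p_rr"]
    p_mr = np.asarray(act_prob(resident.a1, resident.a0, eq["h_mr"], params.mu_e))
    a1 = np.array([m.a1 for m in mutants])
    a0 = np.array([m.a0 for m in mutants])
    raw = eq["h_rm"] * a1 + (1.0 - eq["h_rm"]) * a0
    p_rm = raw * (1.0 - params.mu_e) + (1.0 - raw) * params.mu_e
    slope = p_mr - p_rr
    intercept = params.c * (p_rr - p_rm)
    return slope, intercept, p_mr, p_rm, p_rr, eq


def invasion_fitness(
    resident: Strategy,
    mutant: Strategy,
    params: ModelParams,
    *,
    h0: float | None = None,
    tol: float = FITNESS_TOL,
) -> InvasionOutcome:
    """Fitness difference (mutant - resident) at the dimorphic equilibrium."""
    h0 = params.h0 if h0 is None else h0
    slope, intercept, p_mr, p_rm, p_rr, _ = _slopes_intercepts(
        resident, [mutant], params, h0
    )
    if mutant == resident:
        delta_w = 0.0  # identical rates by construction; avoid round-off
    else:
        delta_w = float(slope[0] * params.b + intercept[0])
    return InvasionOutcome(
        delta_w=delta_w,
        invades=delta_w > tol,
        p_mr=float(p_mr[0]),
        p_rm=float(p_rm[0]),
        p_rr=float(p_rr),
    )


def _other_canonical(resident: Strategy) -> list[Strategy]:
    return [s for s in canonical_set() if s != resident]


def is_ess(
    resident: Strategy,
    params: ModelParams,
    h0: float | None = None,
    *,
    mutants: list[Strategy] | None = None,
    tol: float = FITNESS_TOL,
) -> tuple[bool, list[Strategy]]:
    """Whether the resident resists every canonical mutant at ``params.b``.

    Returns the verdict and the list of successful invaders (empty when
    the resident is an ESS at this benefit/cost and ``h0``).
    """
    h0 = params.h0 if h0 is None else h0
    mutants = _other_canonical(resident) if mutants is None else mutants
    slope, intercept, *_ = _slopes_intercepts(resident, mutants, params, h0)
    delta_w = slope * params.b + intercept
    invaders = [m for m, d in zip(mutants, delta_w) if d > tol]
    return (len(invaders) == 0), invaders


def _ess_interval(slope, intercept, c, bc_max, tol):
    """Benefit interval [lo, hi] on (c, bc_max] where no mutant invades,
    or None.  Constraints ``slope*b + intercept <= tol`` are half-lines;
    their intersection is an interval."""
    lo = np.nextafter(c, np.inf)
    hi = float(bc_max)
    for s, d in zip(slope, intercept):
        if abs(s) < 1e-12:
            if d > tol:
                return None
        elif s > 0:
            hi = min(hi, (tol - d) / s)
        else:
            lo = max(lo, (tol - d) / s)
        if lo > hi:
            return None
    return (float(lo), hi)


def min_bc_threshold(
    resident: Strategy,
    h0: float,
    params: ModelParams | None = None,
    *,
    bc_max: float = 20.0,
    tol: float = FITNESS_TOL,
    mutants: list[Strategy] | None = None,
) -> float | None:
    """Smallest benefit (cost 1) beyond which no canonical mutant invades.

    The critical benefit for each mutant solves ``delta_w = 0`` exactly
    (delta_w is affine in b).  Returns ``None`` when some mutant still
    invades at ``bc_max`` or no benefit in the scan range is safe.
    """
    params = ModelParams(b=2.0, c=1.0, h0=h0) if params is None else params
    if params.c != 1.0:
        params = params.replace(b=max(params.b, 2.0), c=1.0)
    mutants = _other_canonical(resident) if mutants is None else mutants
    slope, intercept, *_ = _slopes_intercepts(resident, mutants, params, h0)
    interval = _ess_interval(slope, intercept, 1.0, bc_max, tol)
    if interval is None or interval[1] < bc_max - 1e-9:
        return None
    # exact delta_w = 0 crossings of the mutants that invade at low benefit
    crossings = [-d / s for s, d in zip(slope, intercept) if s < -1e-12 and d > 0]
    return float(max([1.0] + crossings))


def classify(
    resident: Strategy,
    params: ModelParams,
    h0: float | None = None,
    *,
    eps: float = EPS_CLASS,
) -> str:
    """Cooperation class from the monomorphic equilibrium cooperation rate."""
    h0 = params.h0 if h0 is None else h0
    eq = resident_mutant_equilibria(resident, [], params, h0=h0)
    p_rr = eq["p_rr"]
    if p_rr >= 1.0 - eps:
        return "cooperator"
    if p_rr <= eps:
        return "defector"
    return "intermediate"


@dataclass
class ESSRecord:
    """Per-resident scan outcome across initial h-scores."""

    strategy: Strategy
    code: int
    #: per-h0 ESS benefit interval (lo, hi) on (c, bc_max], or None
    intervals: dict[float, tuple[float, float] | None]
    #: per-h0 cooperation class
    classes: dict[float, str]
    #: per-h0 affine coefficients vs every mutant (for grid verdicts)
    slopes: dict[float, np.ndarray] = field(repr=False, default_factory=dict)
    intercepts: dict[float, np.ndarray] = field(repr=False, default_factory=dict)
    p_rr: dict[float, float] = field(default_factory=dict)
    #: grid benefits at which the resident is ESS at every scanned h0
    common_grid: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def common_interval(self) -> tuple[float, float] | None:
        """Exact benefit interval where the resident is ESS at every h0
        (continuum diagnostic; headline verdicts use the grid)."""
        lo, hi = -np.inf, np.inf
        for iv in self.intervals.values():
            if iv is None:
                return None
            lo, hi = max(lo, iv[0]), min(hi, iv[1])
        return (lo, hi) if lo <= hi else None

    def headline_class(self) -> str | None:
        """Class if the resident is ESS at all h0 for a common benefit
        (exact-interval rule) and its class is consistent across h0; else
        None."""
        if self.common_interval() is None:
            return None
        classes = set(self.classes.values())
        if classes == {"cooperator"}:
            return "cooperator"
        if classes == {"defector"}:
            return "defector"
        return "intermediate"


@dataclass
class ESSScanResult:
    records: list[ESSRecord]
    bc_grid: np.ndarray
    h0_set: tuple[float, ...]
    params: ModelParams
    tol: float
    mutant_codes: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def cooperators(self) -> list[ESSRecord]:
        return [r for r in self.records if r.headline_class() == "cooperator"]

    def defectors(self) -> list[ESSRecord]:
        return [r for r in self.records if r.headline_class() == "defector"]

    def headline_counts(self) -> dict[str, int]:
        """Counts of residents that are ESS at every scanned h0 for at
        least one common benefit-to-cost ratio, split by class."""
        return {
            "cooperator": len(self.cooperators()),
            "defector": len(self.defectors()),
        }

    def ess_codes(self) -> list[int]:
        """Residents that are ESS at every scanned h0 for at least one
        common benefit grid point."""
        return sorted(r.code for r in self.records if r.common_grid.size > 0)

    def robust_ess_codes(self, min_fraction: float = 0.05) -> list[int]:
        """Residents that are ESS (at every h0) on more than
        ``min_fraction`` of the benefit grid.

        Strategies other than unconditional defection can retain hair-thin
        ESS windows (one or two isolated grid points) once errors are
        switched on; this filter separates those slivers from strategies
        that are stable across the benefit range.
        """
        cutoff = min_fraction * self.bc_grid.size
        return sorted(
            r.code for r in self.records if r.common_grid.size > cutoff
        )

    def summary(self) -> dict:
        counts = self.headline_counts()
        return {
            "n_residents": len(self.records),
            "h0_set": list(self.h0_set),
            "bc_min": float(self.bc_grid[0]),
            "bc_max": float(self.bc_grid[-1]),
            "mu_e": self.params.mu_e,
            "mu_a": self.params.mu_a,
            "tol": self.tol,
            "cooperator_ess": counts["cooperator"],
            "defector_ess": counts["defector"],
            "robust_ess_codes": self.robust_ess_codes(),
            "cooperator_codes": sorted(r.code for r in self.cooperators()),
            "defector_codes": sorted(r.code for r in self.defectors()),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(strategy, h0, bc) table sorted by (code, h0, bc)."""
        rows = []
        for rec in self.records:
            mut_codes = self.mutant_codes[rec.code]
            for h0 in self.h0_set:
                s = rec.slopes[h0]
                d = rec.intercepts[h0]
                delta = np.outer(s, self.bc_grid) + d[:, None]
                worst = np.argmax(delta, axis=0)
                dmax = delta[worst, np.arange(len(self.bc_grid))]
                for k, bc in enumerate(self.bc_grid):
                    rows.append(
                        {
                            "code": rec.code,
                            "bits": rec.strategy.bitstring,
                            "h0": h0,
                            "bc": float(bc),
                            "is_ess": bool(dmax[k] <= self.tol),
                            "class": rec.classes[h0],
                            "delta_w_max": float(dmax[k]),
                            "worst_invader": int(mut_codes[worst[k]]),
                        }
                    )
        df = pd.DataFrame(rows)
        return df.sort_values(["code", "h0", "bc"], ignore_index=True)


def ess_scan(
    bc_grid=None,
    h0_set=DEFAULT_H0_SET,
    params: ModelParams | None = None,
    *,
    residents: list[Strategy] | None = None,
    tol: float = FITNESS_TOL,
    progress: bool = False,
) -> ESSScanResult:
    """Exhaustive invasion analysis of every canonical resident.

    For each resident and each initial h-score the 257 dimorphic
    equilibria are solved once; ESS verdicts across the benefit grid (and
    the exact ESS benefit intervals) follow from the affine dependence of
    the fitness difference on ``b``.  ``params.b``/``params.c`` are only
    used through the normalization ``c = 1``.
    """
    bc_grid = DEFAULT_BC_GRID if bc_grid is None else np.asarray(bc_grid, dtype=float)
    if bc_grid.ndim != 1 or bc_grid.size == 0 or np.any(np.diff(bc_grid) <= 0):
        raise ValueError("bc_grid must be a non-empty increasing 1-d array")
    params = ModelParams(b=2.0, c=1.0) if params is None else params.replace(b=2.0, c=1.0)
    pool = canonical_set()
    residents = pool if residents is None else residents
    bc_max = float(bc_grid[-1])

    records = []
    mutant_codes: dict[int, np.ndarray] = {}
    iterator = residents
    if progress:
        from tqdm import tqdm

        iterator = tqdm(residents, desc="ess scan")
    for resident in iterator:
        mutants = [s for s in pool if s != resident]
        mutant_codes[encode(resident)] = np.array([encode(m) for m in mutants])
        intervals, classes, slopes, intercepts, p_rr_map = {}, {}, {}, {}, {}
        grid_ok = np.ones(bc_grid.size, dtype=bool)
        for h0 in h0_set:
            s, d, p_mr, p_rm, p_rr, _ = _slopes_intercepts(
                resident, mutants, params, h0
            )
            intervals[h0] = _ess_interval(s, d, params.c, bc_max, tol)
            if s.size:
                dmax = np.max(np.outer(s, bc_grid) + d[:, None], axis=0)
                grid_ok &= dmax <= tol
            if p_rr >= 1.0 - EPS_CLASS:
                classes[h0] = "cooperator"
            elif p_rr <= EPS_CLASS:
                classes[h0] = "defector"
            else:
                classes[h0] = "intermediate"
            slopes[h0], intercepts[h0], p_rr_map[h0] = s, d, float(p_rr)
        records.append(
            ESSRecord(
                strategy=resident,
                code=encode(resident),
                intervals=intervals,
                classes=classes,
                slopes=slopes,
                intercepts=intercepts,
                p_rr=p_rr_map,
                common_grid=bc_grid[grid_ok],
            )
        )
    return ESSScanResult(
        records=records,
        bc_grid=bc_grid,
        h0_set=tuple(h0_set),
        params=params,
        tol=tol,
        mutant_codes=mutant_codes,
    )


def polymorphism_check(
    resident: Strategy,
    mutant: Strategy,
    params: ModelParams,
    *,
    h0: float | None = None,
    tol: float = FITNESS_TOL,
) -> bool:
    """True iff the two strategies can mutually invade (stable coexistence)."""
    if resident == mutant:
        return False
    fwd = invasion_fitness(resident, mutant, params, h0=h0, tol=tol)
    rev = invasion_fitness(mutant, resident, params, h0=h0, tol=tol)
    return fwd.invades and rev.invades
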