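"""Agent-based Monte-Carlo implementation of the interaction protocol.

Used as an independent oracle for the mean-field model: a finite
population holds a private binary opinion matrix; each step one donor
donates (or not) to one recipient and one observer (neither donor nor
recipient) updates its opinion of the donor according to the shared
assessment tables.  Exactly one opinion-matrix entry can change per step
and the recipient's reputation is never touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .equilibrium import monomorphic_equilibrium
from .mean_field import ModelParams, act_prob
from .strategies import Strategy, encode

try:  # pragma: no cover - numba is present in the supported environments
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = ["SimConfig", "SimResult", "PopulationState", "init_population",
           "interaction_step", "run", "compare_to_analytic"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol parameters.

    Defaults follow the reference protocol: 100 individuals, 4e5
    interactions per replicate with statistics over the final 1e5, a
    single observer per interaction and 30 replicates.
    """

    n: int = 100
    total_interactions: int = 400_000
    averaging_window: int = 100_000
    replicates: int = 30
    observers_per_interaction: int = 1
    h0: float = 0.5
    mu_e: float = 1e-4
    mu_a: float = 1e-4
    seed: int = 0
    observer_can_be_recipient: bool = False

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"population size must be >= 3, got {self.n}")
        if not 0 < self.averaging_window <= self.total_interactions:
            raise ValueError(
                "averaging_window must lie in (0, total_interactions]; got "
                f"{self.averaging_window} / {self.total_interactions}"
            )
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        max_obs = self.n - 1 if self.observer_can_be_recipient else self.n - 2
        if not 1 <= self.observers_per_interaction <= max_obs:
            raise ValueError(
                f"observers_per_interaction must lie in [1, {max_obs}], got "
                f"{self.observers_per_interaction}"
            )
        for name in ("mu_e", "mu_a"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")
        if not 0.0 <= self.h0 <= 1.0:
            raise ValueError(f"h0 must lie in [0, 1], got {self.h0}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimResult:
    """Replicate-averaged simulation output."""

    strategy: Strategy
    mean_h: float
    mean_coop: float
    per_replicate_h: np.ndarray
    per_replicate_coop: np.ndarray
    config: SimConfig


@dataclass
class PopulationState:
    """Mutable state of one replicate (reference implementation)."""

    strategy: Strategy
    opinions: np.ndarray  # (n, n) int8; the diagonal is never read or written
    last_action: int | None = None


def init_population(
    strategy: Strategy, config: SimConfig, rng: np.random.Generator | None = None
) -> PopulationState:
    """Draw every off-diagonal opinion i.i.d. Bernoulli(h0)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    opinions = (rng.random((n, n)) < config.h0).astype(np.int8)
    np.fill_diagonal(opinions, 0)
    return PopulationState(strategy=strategy, opinions=opinions)


def interaction_step(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """One donation + observation event (pure-Python reference).

    Donor and recipient are drawn uniformly without replacement; each
    observer is drawn uniformly among the remaining individuals (the
    recipient may be allowed to observe via the config switch).  Only the
    observers' opinions of the donor can change.
    """
    n = config.n
    s = state.strategy
    donor, recipient = rng.choice(n, size=2, replace=False)
    intended = s.a1 if state.opinions[donor, recipient] == 1 else s.a0
    action = intended if rng.random() >= config.mu_e else 1 - intended
    excluded = {donor} if config.observer_can_be_recipient else {donor, recipient}
    eligible = np.array([i for i in range(n) if i not in excluded])
    observers = rng.choice(
        eligible, size=config.observers_per_interaction, replace=False
    )
    table_c = s.C
    table_d = s.D
    for obs in observers:
        i = state.opinions[obs, donor]
        k = state.opinions[obs, recipient]
        idx = (1 - i) * 2 + (1 - k)
        new = table_c[idx] if action == 1 else table_d[idx]
        if rng.random() < config.mu_a:
            new = 1 - new
        state.opinions[obs, donor] = new
    state.last_action = int(action)
    return state


@njit(cache=True)
def _run_replicate(
    a1, a0, cc, dd, n, steps, window, n_obs, h0, mu_e, mu_a, seed
):  # pragma: no cover - exercised through run()
    np.random.seed(seed)
    opinions = np.empty((n, n), dtype=np.int8)
    ones = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                opinions[i, j] = 0
            else:
                v = 1 if np.random.random() < h0 else 0
                opinions[i, j] = v
                ones += v
    burn = steps - window
    h_acc = 0.0
    coop_acc = 0
    chosen = np.empty(n_obs, dtype=np.int64)
    for t in range(steps):
        donor = np.random.randint(0, n)
        recipient = np.random.randint(0, n - 1)
        if recipient >= donor:
            recipient += 1
        intended = a1 if opinions[donor, recipient] == 1 else a0
        action = intended
        if np.random.random() < mu_e:
            action = 1 - intended
        lo = donor if donor < recipient else recipient
        hi = recipient if donor < recipient else donor
        for m in range(n_obs):
            while True:
                obs = np.random.randint(0, n - 2)
                if obs >= lo:
                    obs += 1
                if obs >= hi:
                    obs += 1
                fresh = True
                for mm in range(m):
                    if chosen[mm] == obs:
                        fresh = False
                        break
                if fresh:
                    break
            chosen[m] = obs
            i = opinions[obs, donor]
            k = opinions[obs, recipient]
            idx = (1 - i) * 2 + (1 - k)
            new = cc[idx] if action == 1 else dd[idx]
            if np.random.random() < mu_a:
                new = 1 - new
            ones += new - opinions[obs, donor]
            opinions[obs, donor] = new
        if t >= burn:
            coop_acc += action
            h_acc += ones
    mean_h = h_acc / (window * n * (n - 1.0))
    mean_coop = coop_acc / window
    return mean_h, mean_coop


def _replicate_seeds(seed: int, replicates: int) -> np.ndarray:
    """Independent per-replicate substreams from one master seed."""
    return np.random.SeedSequence(seed).generate_state(replicates)


def run(strategy: Strategy, config: SimConfig) -> SimResult:
    """Simulate all replicates; fully reproducible from ``config.seed``."""
    seeds = _replicate_seeds(config.seed, config.replicates)
    cc = np.array(strategy.C, dtype=np.int8)
    dd = np.array(strategy.D, dtype=np.int8)
    hs = np.empty(config.replicates)
    coops = np.empty(config.replicates)
    for r, s in enumerate(seeds):
        hs[r], coops[r] = _run_replicate(
            strategy.a1,
            strategy.a0,
            cc,
            dd,
            config.n,
            config.total_interactions,
            config.averaging_window,
            config.observers_per_interaction,
            config.h0,
            config.mu_e,
            config.mu_a,
            int(s),
        )
    return SimResult(
        strategy=strategy,
        mean_h=float(hs.mean()),
        mean_coop=float(coops.mean()),
        per_replicate_h=hs,
        per_replicate_coop=coops,
        config=config,
    )


def compare_to_analytic(
    strategies: list[Strategy],
    config: SimConfig,
    params: ModelParams,
    *,
    progress: bool = False,
) -> tuple[dict, "pd.DataFrame"]:
    """Mean absolute simulated-vs-analytic discrepancy over strategies.

    The simulation runs at the (small, nonzero) error rates in ``config``
    while the analytic prediction uses ``params`` (typically error-free),
    both starting from the same initial h-score; a mismatch in ``h0`` is
    rejected.  Returns a summary dict and a per-strategy table.
    """
    import pandas as pd

    if abs(config.h0 - params.h0) > 1e-12:
        raise ValueError(
            f"simulation h0 ({config.h0}) and analytic h0 ({params.h0}) differ"
        )
    rows = []
    iterator = strategies
    if progress:
        from tqdm import tqdm

        iterator = tqdm(strategies, desc="abm vs analytic")
    for k, strat in enumerate(iterator):
        eq = monomorphic_equilibrium(strat, params, integrate=False)
        h_pred = float(eq.h_star)
        coop_pred = float(act_prob(strat.a1, strat.a0, h_pred, params.mu_e))
        # decorrelate replicate streams across strategies
        res = run(strat, config.replace(seed=config.seed + encode(strat)))
        rows.append(
            {
                "code": encode(strat),
                "bits": strat.bitstring,
                "h_analytic": h_pred,
                "h_simulated": res.mean_h,
                "coop_analytic": coop_pred,
                "coop_simulated": res.mean_coop,
                "abs_dh": abs(res.mean_h - h_pred),
                "abs_dcoop": abs(res.mean_coop - coop_pred),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_strategies": len(df),
        "mean_abs_dh": float(df["abs_dh"].mean()),
        "mean_abs_dcoop": float(df["abs_dcoop"].mean()),
    }
    return summary, df
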