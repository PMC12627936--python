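"""Individual-path microsimulation used as an independent test oracle.

Simulates patients one cycle at a time with the same per-cycle transition
matrices as the cohort engine, but by sampling state paths rather than
propagating occupancy fractions.  Exists only for tests (not a package
feature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from asthma_adherence.adherence import build_matrix
from asthma_adherence.engine import _state_utilities
from asthma_adherence.parameters import ControlState, LifeTable, ParameterSet

_EXAC = int(ControlState.EXACERBATION)
_DEAD = int(ControlState.DEAD)


@dataclass
class MicrosimResult:
    occupancy: np.ndarray            # (n_cycles + 1, 5) state fractions
    exacerbations: np.ndarray        # per-path cumulative exacerbation count
    life_years: np.ndarray           # per-path undiscounted life years
    qalys_undiscounted: np.ndarray   # per-path undiscounted QALYs
    n_paths: int

    def se_occupancy(self, cycle: int, state: int) -> float:
        f = self.occupancy[cycle, state]
        return float(np.sqrt(f * (1.0 - f) / self.n_paths))

    @staticmethod
    def _mean_se(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def simulate_paths(
    p: ParameterSet, a: float, lt: LifeTable, n_paths: int, seed: int
) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    cpy = int(p.cycles_per_year)
    n_cycles = int(round(p.horizon_years * cpy))

    states = rng.choice(3, size=n_paths, p=p.initial_distribution)
    occupancy = np.zeros((n_cycles + 1, 5))
    occupancy[0] = np.bincount(states, minlength=5) / n_paths

    exac_counts = np.zeros(n_paths)
    life_weeks = np.zeros(n_paths)
    qaly_weeks = np.zeros(n_paths)
    utilities = _state_utilities(p)

    cum_cache: dict[int, np.ndarray] = {}
    for c in range(n_cycles):
        age = int(p.cohort_start_age + c / cpy)
        cum = cum_cache.get(age)
        if cum is None:
            cum = np.cumsum(build_matrix(p, a, float(age), lt).probs, axis=1)
            cum_cache[age] = cum

        alive = states != _DEAD
        life_weeks += alive
        qaly_weeks += utilities[states] * p.utility_adjustment(float(age)) * alive

        u = rng.random(n_paths)
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        exac_counts += (states != _EXAC) & alive & (nxt == _EXAC)
        states = nxt
        occupancy[c + 1] = np.bincount(states, minlength=5) / n_paths

    return MicrosimResult(
        occupancy=occupancy,
        exacerbations=exac_counts,
        life_years=life_weeks / cpy,
        qalys_undiscounted=qaly_weeks / cpy,
        n_paths=n_paths,
    )
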