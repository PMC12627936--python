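"""Probabilistic sensitivity analysis over the adherence grid.

One parameter draw per iteration is shared across every adherence level
(common random numbers), so pairwise level comparisons are paired.  Each
iteration consumes an independent substream spawned from the master seed,
so increasing ``n_iter`` never reshuffles earlier iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_cohort, summarize
from .parameters import (
    DistributionSpec,
    LifeTable,
    ParameterSet,
    set_by_path,
    validate_parameters,
)

__all__ = [
    "OUTPUT_NAMES",
    "SamplingError",
    "PsaResult",
    "sample_parameters",
    "run_psa",
    "summarize_psa",
    "compare_levels",
    "write_psa_summary",
    "write_psa_draws",
]

#: Outcome columns recorded per draw, in order.
OUTPUT_NAMES = (
    "exacerbations",
    "life_years",
    "qalys",
    "cost_total",
    "cost_maintenance",
    "cost_outpatient",
    "cost_rescue",
    "cost_exacerbation_nonadmitted",
    "cost_exacerbation_admitted",
)

#: The four headline outputs reported in comparisons.
HEADLINE_OUTPUTS = ("exacerbations", "life_years", "qalys", "cost_total")

_MAX_REDRAWS = 100


class SamplingError(RuntimeError):
    """A tagged parameter could not produce a valid draw within the cap."""


def sample_parameters(p: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint draw of every tagged parameter (untagged values carried
    at their means).  Invalid joint draws are redrawn, capped at 100."""
    for attempt in range(_MAX_REDRAWS):
        drawn = p.copy()
        for path in sorted(p.distributions):  # fixed order for determinism
            spec: DistributionSpec = p.distributions[path]
            if spec.family == "fixed":
                continue
            set_by_path(drawn, path, spec.sample(rng))
        violations = validate_parameters(drawn)
        if not violations:
            return drawn
    raise SamplingError(
        f"no valid draw after {_MAX_REDRAWS} attempts; last violations: {violations}"
    )


@dataclass
class PsaResult:
    """Per-iteration outcomes per adherence level, plus run metadata.

    ``draws[name]`` is an ``(n_iterations, n_levels)`` array for each
    output in :data:`OUTPUT_NAMES`.
    """

    adherence_levels: np.ndarray
    draws: dict[str, np.ndarray]
    seed: int
    n_iterations: int
    summary: pd.DataFrame = field(default=None, repr=False)

    def level_index(self, a: float) -> int:
        idx = np.nonzero(np.isclose(self.adherence_levels, a, atol=1e-12))[0]
        if len(idx) == 0:
            raise KeyError(
                f"adherence level {a} not on grid {self.adherence_levels.tolist()}"
            )
        return int(idx[0])


def run_psa(
    p: ParameterSet,
    levels: "np.ndarray | list[float]",
    n_iter: int,
    seed: int,
    lt: LifeTable,
) -> PsaResult:
    """Run ``n_iter`` Monte Carlo iterations of the cohort model at every
    adherence level, sharing each iteration's parameter draw across levels."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0 or np.any((levels < 0) | (levels > 1)):
        raise ValueError(f"adherence levels must be nonempty and in [0, 1]: {levels}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")

    draws = {name: np.empty((n_iter, len(levels))) for name in OUTPUT_NAMES}
    substreams = np.random.SeedSequence(seed).spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(substreams[it])
        try:
            sampled = sample_parameters(p, rng)
            for j, a in enumerate(levels):
                trace = run_cohort(sampled, float(a), lt)
                s = summarize(trace, sampled, float(a))
                c = s.costs_discounted
                row = (
                    s.total_exacerbations,
                    s.life_years,
                    s.qalys_discounted,
                    c.total,
                    c.maintenance,
                    c.outpatient,
                    c.rescue,
                    c.exacerbation_nonadmitted,
                    c.exacerbation_admitted,
                )
                for name, value in zip(OUTPUT_NAMES, row):
                    draws[name][it, j] = value
        except Exception as exc:
            raise RuntimeError(
                f"PSA iteration {it} (level {float(a)}) failed: {exc}"
            ) from exc

    result = PsaResult(
        adherence_levels=levels, draws=draws, seed=int(seed), n_iterations=int(n_iter)
    )
    result.summary = summarize_psa(result)
    return result


def summarize_psa(r: PsaResult) -> pd.DataFrame:
    """Per-level, per-output mean with empirical 95% percentile bounds of
    the draw distribution, plus a standard-error CI for the mean itself."""
    rows = []
    for name in OUTPUT_NAMES:
        arr = r.draws[name]
        mean = arr.mean(axis=0)
        lower = np.percentile(arr, 2.5, axis=0)
        upper = np.percentile(arr, 97.5, axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(r.n_iterations) if r.n_iterations > 1 else np.zeros(arr.shape[1])
        for j, a in enumerate(r.adherence_levels):
            rows.append(
                {
                    "level": float(a),
                    "output": name,
                    "mean": float(mean[j]),
                    "lower": float(lower[j]),
                    "upper": float(upper[j]),
                    "mean_se": float(se[j]),
                    "mean_lower": float(mean[j] - 1.959963984540054 * se[j]),
                    "mean_upper": float(mean[j] + 1.959963984540054 * se[j]),
                }
            )
    return pd.DataFrame(rows)


def compare_levels(r: PsaResult, a_from: float, a_to: float) -> pd.DataFrame:
    """Paired per-iteration differences (``a_to`` minus ``a_from``) for the
    four headline outputs, summarized as mean and 95% percentile interval.

    Pairing relies on the shared draws (common random numbers)."""
    i_from = r.level_index(a_from)
    i_to = r.level_index(a_to)
    rows = []
    for name in HEADLINE_OUTPUTS:
        diff = r.draws[name][:, i_to] - r.draws[name][:, i_from]
        se = diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1 else 0.0
        rows.append(
            {
                "output": name,
                "mean": float(diff.mean()),
                "lower": float(np.percentile(diff, 2.5)),
                "upper": float(np.percentile(diff, 97.5)),
                "mean_se": float(se),
            }
        )
    return pd.DataFrame(rows)


def write_psa_summary(r: PsaResult, path, header_lines: "list[str] | None" = None) -> None:
    """Delimited-text export: one row per (level, output)."""
    from pathlib import Path

    lines = [f"# {h}" for h in (header_lines or [])]
    lines.append("level\toutput\tmean\tlower\tupper\tmean_se\tmean_lower\tmean_upper")
    for _, row in r.summary.iterrows():
        vals = [
            float(row[k])
            for k in ("level",)
        ] + [row["output"]] + [
            float(row[k])
            for k in ("mean", "lower", "upper", "mean_se", "mean_lower", "mean_upper")
        ]
        lines.append(
            f"{vals[0]!r}\t{vals[1]}\t" + "\t".join(repr(v) for v in vals[2:])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_psa_draws(r: PsaResult, path, header_lines: "list[str] | None" = None) -> None:
    """Long-format export of every draw (iteration x level x output)."""
    from pathlib import Path

    lines = [f"# {h}" for h in (header_lines or [])]
    lines.append("iteration\tlevel\t" + "\t".join(OUTPUT_NAMES))
    for it in range(r.n_iterations):
        for j, a in enumerate(r.adherence_levels):
            vals = "\t".join(repr(float(r.draws[name][it, j])) for name in OUTPUT_NAMES)
            lines.append(f"{it}\t{float(a)!r}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
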