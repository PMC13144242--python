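"""Monte Carlo study driver: replicate loops, difficulty classification,
relative bias / RMSE aggregation, and paper-style report tables.

Each replicate of a condition generates a panel, computes stage-1/2
statistics and fits the growth model; the outcome is classified as
``converged``, ``improper`` (negative variance estimate or non-PSD factor
covariance), ``nonconverged`` (optimizer failure or boundary polychoric) or
``degenerate`` (an empty category made the statistics undefined).  Relative
bias and RMSE are computed over converged, proper replicates by default; the
difficulty rate is the percentage of replicates that did not converge
properly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import FitOptions, LgmModelSpec, fit_dwls
from .exceptions import DegenerateCategoryError
from .model import true_deltas
from .moments import sample_moments
from .simulate import (
    CATEGORY_COUNTS,
    PATTERNS,
    SAMPLE_SIZES,
    SLOPES,
    SLOPE_MEANS,
    Condition,
    categorize,
    condition_to_spec,
    generate_latent_panel,
)

__all__ = [
    "ReplicateResult",
    "ConditionReport",
    "relative_bias",
    "rmse",
    "true_parameters",
    "run_replicate",
    "run_condition",
    "run_grid",
    "report_tables",
    "write_reports",
    "read_reports",
]

PARAMETERS = ("alpha10", "psi11", "delta_2", "delta_3", "delta_4")
OUTCOMES = ("converged", "improper", "nonconverged", "degenerate")


def relative_bias(estimates, true: float) -> float:
    """(mean(estimates) - true) / true; undefined for a zero true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    if true == 0:
        raise ValueError("relative bias is undefined for a zero true value")
    return float((est.mean() - true) / true)


def rmse(estimates, true: float) -> float:
    """Root mean squared deviation of the estimates from the true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((est - true) ** 2)))


def true_parameters(condition: Condition) -> dict:
    """True values targeted by the fit: slope mean/variance and the scale
    factors Delta_t = sqrt(sigma*_1 / sigma*_t) from the implied variances."""
    spec = condition_to_spec(condition)
    deltas = true_deltas(spec)
    out = {"alpha10": SLOPE_MEANS[condition.slope], "psi11": spec.psi11}
    for t in range(1, spec.n_times):
        out[f"delta_{t + 1}"] = float(deltas[t])
    return out


@dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    status: str
    estimates: dict = field(default_factory=dict)
    iterations: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "replicate": self.replicate,
                "status": self.status,
                "estimates": self.estimates,
                "iterations": self.iterations,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "ReplicateResult":
        d = json.loads(line)
        return cls(
            replicate=int(d["replicate"]),
            status=str(d["status"]),
            estimates=dict(d["estimates"]),
            iterations=int(d.get("iterations", 0)),
        )


@dataclass(frozen=True)
class ConditionReport:
    """Aggregated outcome of one design cell."""

    condition: Condition
    attempted: int
    converged: int
    improper: int
    nonconverged: int
    degenerate: int
    rb: dict
    rmse: dict
    mc_se: dict
    true_values: dict

    def __post_init__(self):
        total = self.converged + self.improper + self.nonconverged + self.degenerate
        if total != self.attempted:
            raise ValueError("outcome classes must sum to attempted replicates")

    @property
    def difficulty_rate(self) -> float:
        """Percent of replicates that did not end in a proper converged fit."""
        return 100.0 * (self.attempted - self.converged) / self.attempted

    def to_row(self) -> dict:
        row = {
            "pattern": self.condition.pattern,
            "slope": self.condition.slope,
            "categories": self.condition.categories,
            "n": self.condition.n,
            "attempted": self.attempted,
            "converged": self.converged,
            "improper": self.improper,
            "nonconverged": self.nonconverged,
            "degenerate": self.degenerate,
            "difficulty_rate": self.difficulty_rate,
        }
        for p in PARAMETERS:
            row[f"rb_{p}"] = self.rb.get(p, np.nan)
            row[f"rmse_{p}"] = self.rmse.get(p, np.nan)
            row[f"mc_se_rb_{p}"] = self.mc_se.get(p, np.nan)
            row[f"true_{p}"] = self.true_values.get(p, np.nan)
        return row


def run_replicate(
    condition: Condition, replicate: int, options: FitOptions = FitOptions()
) -> ReplicateResult:
    """Generate, summarise and fit one replicate; never raises on failure
    modes that the study classifies."""
    spec = condition_to_spec(condition)
    latent = generate_latent_panel(spec, condition.n, condition.seed_sequence(replicate))
    panel = categorize(latent, condition.thresholds())
    try:
        moments = sample_moments(panel)
    except DegenerateCategoryError:
        return ReplicateResult(replicate=replicate, status="degenerate")
    if moments.boundary:
        # a polychoric pinned at +-1 leaves the fit undefined in practice
        return ReplicateResult(replicate=replicate, status="nonconverged")
    model = LgmModelSpec(n_times=panel.n_times, n_categories=panel.n_categories)
    fit = fit_dwls(moments, model, options)
    est = {
        "alpha10": fit.alpha10,
        "psi11": fit.psi11,
        "psi00": fit.psi00,
        "psi10": fit.psi10,
    }
    for t in range(1, panel.n_times):
        est[f"delta_{t + 1}"] = float(fit.deltas[t])
    return ReplicateResult(
        replicate=replicate, status=fit.status, estimates=est, iterations=fit.iterations
    )


def _aggregate(
    condition: Condition,
    results: list[ReplicateResult],
    include_improper: bool = False,
) -> ConditionReport:
    counts = {k: 0 for k in OUTCOMES}
    for r in results:
        counts[r.status] += 1
    keep = {"converged"} | ({"improper"} if include_improper else set())
    used = [r for r in results if r.status in keep]
    truth = true_parameters(condition)
    rb_d, rmse_d, se_d = {}, {}, {}
    for p in PARAMETERS:
        est = np.array([r.estimates[p] for r in used if p in r.estimates])
        if est.size == 0:
            rb_d[p] = rmse_d[p] = se_d[p] = np.nan
            continue
        tv = truth[p]
        rb_d[p] = relative_bias(est, tv)
        rmse_d[p] = rmse(est, tv)
        # Monte Carlo standard error of the RB estimate
        se_d[p] = float(est.std(ddof=1) / (np.sqrt(est.size) * abs(tv))) if est.size > 1 else np.nan
    return ConditionReport(
        condition=condition,
        attempted=len(results),
        converged=counts["converged"],
        improper=counts["improper"],
        nonconverged=counts["nonconverged"],
        degenerate=counts["degenerate"],
        rb=rb_d,
        rmse=rmse_d,
        mc_se=se_d,
        true_values=truth,
    )


def run_condition(
    condition: Condition,
    reps: int | None = None,
    include_improper: bool = False,
    options: FitOptions = FitOptions(),
    n_jobs: int = 1,
    cache_dir: str | Path | None = None,
) -> ConditionReport:
    """Run all replicates of one condition and aggregate.

    Deterministic given the condition's base seed; results are identical
    regardless of worker count (replicates use independent substreams and the
    reduction sorts on replicate index).  With ``cache_dir``, per-replicate
    results are appended to a JSON-lines file and reruns resume from it.
    """
    reps = condition.reps if reps is None else reps
    done: dict[int, ReplicateResult] = {}
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"{condition.label}-seed{condition.base_seed}.jsonl"
        if cache_path.exists():
            for line in cache_path.read_text().splitlines():
                if line.strip():
                    r = ReplicateResult.from_json(line)
                    done[r.replicate] = r
    todo = [i for i in range(reps) if i not in done]
    if todo:
        if n_jobs != 1:
            from joblib import Parallel, delayed

            fresh = Parallel(n_jobs=n_jobs)(
                delayed(run_replicate)(condition, i, options) for i in todo
            )
        else:
            fresh = [run_replicate(condition, i, options) for i in todo]
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            with open(cache_path, "a", encoding="utf-8") as fh:
                for r in fresh:
                    fh.write(r.to_json() + "\n")
        for r in fresh:
            done[r.replicate] = r
    results = [done[i] for i in sorted(done)[:reps]]
    return _aggregate(condition, results, include_improper=include_improper)


def run_grid(
    conditions: list[Condition],
    reps: int | None = None,
    include_improper: bool = False,
    options: FitOptions = FitOptions(),
    n_jobs: int = 1,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> list[ConditionReport]:
    reports = []
    for cond in conditions:
        if progress:
            print(f"[catlgm] running {cond.label} ...", flush=True)
        reports.append(
            run_condition(
                cond,
                reps=reps,
                include_improper=include_improper,
                options=options,
                n_jobs=n_jobs,
                cache_dir=cache_dir,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# report tables


def write_reports(reports: list[ConditionReport], path) -> None:
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)


def read_reports(path) -> pd.DataFrame:
    return pd.read_csv(path)


def report_tables(reports: list[ConditionReport]) -> dict[str, pd.DataFrame]:
    """Paper-shaped summaries: one difficulties table plus one RB/RMSE table
    per change pattern.  Cells for conditions that were not run carry NaN gap
    markers rather than being dropped."""
    df = pd.DataFrame([r.to_row() for r in reports])
    full_index = pd.MultiIndex.from_product(
        [PATTERNS, SLOPES, SAMPLE_SIZES], names=["pattern", "slope", "n"]
    )
    if df.empty:
        diff = pd.DataFrame(index=full_index, columns=list(CATEGORY_COUNTS))
        out = {"difficulties": diff}
        for p in PATTERNS:
            out[p] = pd.DataFrame()
        return out
    diff = (
        df.pivot_table(
            index=["pattern", "slope", "n"],
            columns="categories",
            values="difficulty_rate",
        )
        .reindex(full_index)
        .reindex(columns=list(CATEGORY_COUNTS))
    )
    tables: dict[str, pd.DataFrame] = {"difficulties": diff.round(1)}
    for pattern in PATTERNS:
        sub = df[df["pattern"] == pattern]
        rows = []
        for slope in SLOPES:
            for n in SAMPLE_SIZES:
                for param in PARAMETERS:
                    row = {"slope": slope, "n": n, "parameter": param}
                    for c in CATEGORY_COUNTS:
                        cell = sub[(sub["slope"] == slope) & (sub["n"] == n) & (sub["categories"] == c)]
                        if cell.empty:
                            row[f"rb_c{c}"] = np.nan
                            row[f"rmse_c{c}"] = np.nan
                        else:
                            row[f"rb_c{c}"] = round(float(cell[f"rb_{param}"].iloc[0]), 3)
                            row[f"rmse_c{c}"] = round(float(cell[f"rmse_{param}"].iloc[0]), 3)
                    rows.append(row)
        tables[pattern] = pd.DataFrame(rows)
    return tables
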