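"""End-to-end orchestration and report assembly.

``run_evaluate`` wires the stages together — load/validate, PCA, membership,
weights, D, classification, ranking, indicator screening — and emits
publication-style tables (CSV) plus a JSON summary; everything is
deterministic given inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import IndexMatrix
from .fuzzy import DEFAULT_CLASS_BOUNDARIES, ColdToleranceEvaluator
from .phenotype_io import load_index_table
from .selection import correlate_with_d, stepwise_select

logger = logging.getLogger("coldeval")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full evaluation run.

    ``from_ci`` switches to precomputed-CI mode (skipping standardization and
    PCA), in which case ``contribution_rates`` must list the percent rates of
    the CI columns — the mode needed to rerun a published worked example from
    its printed comprehensive-index table.
    """

    input_path: str | Path | None = None
    polarity_config: str | Path | dict | None = None
    from_ci: bool = False
    contribution_rates: list[float] | None = None
    cumulative_threshold: float = 85.0
    class_boundaries: tuple[float, float, float] = DEFAULT_CLASS_BOUNDARIES
    alpha: float = 0.05
    alpha_enter: float = 0.05
    alpha_stay: float = 0.05
    precision: int = 3
    output_dir: str | Path | None = None
    seed: int = 0
    run_selection: bool = True

    def __post_init__(self) -> None:
        b = tuple(self.class_boundaries)
        if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] < 1.0):
            raise ValueError(f"class boundaries must be strictly increasing in (0,1): {b}")
        if not 0.0 < self.cumulative_threshold <= 100.0:
            raise ValueError("cumulative_threshold must lie in (0, 100]")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("input_path", "polarity_config", "output_dir"):
            if isinstance(d[key], Path):
                d[key] = str(d[key])
        return d


def summarize_population(d_scores, boundaries=DEFAULT_CLASS_BOUNDARIES) -> dict:
    """Population summary: share of varieties above each D boundary, per-class counts.

    Percentages are rounded to 1 decimal place for display; raw counts are
    reported alongside.
    """
    d = np.asarray(d_scores, dtype=float)
    if d.size == 0:
        raise ValueError("empty result set")
    b = tuple(boundaries)
    n = d.size
    above = {f"pct_above_{t:g}": round(100.0 * float((d > t).sum()) / n, 1) for t in b}
    classes = ("weak", "moderate", "strong", "very_strong")
    idx = np.searchsorted(b, d, side="right")
    counts = {c: int((idx == i).sum()) for i, c in enumerate(classes)}
    return {"n_varieties": n, **above, "class_counts": counts}


def _load_input(config: PipelineConfig) -> IndexMatrix | pd.DataFrame:
    if config.input_path is None:
        raise ValueError("no input path configured")
    if config.from_ci:
        df = pd.read_csv(config.input_path, index_col=0)
        return df
    if config.polarity_config is None:
        raise ValueError("polarity config is required for raw index tables")
    return load_index_table(config.input_path, config.polarity_config)


def run_evaluate(
    config: PipelineConfig,
    matrix: IndexMatrix | pd.DataFrame | None = None,
) -> tuple[ColdToleranceEvaluator, dict]:
    """Run the full evaluation chain and assemble reports.

    Returns the fitted :class:`ColdToleranceEvaluator` and a dict of report
    objects (DataFrames and the JSON-ready summary); when
    ``config.output_dir`` is set, the reports are also written to disk.
    """
    if matrix is None:
        matrix = _load_input(config)
    evaluator = ColdToleranceEvaluator(
        cumulative_threshold=config.cumulative_threshold,
        class_boundaries=config.class_boundaries,
        precomputed_ci=config.from_ci,
        contribution_rates=config.contribution_rates,
    ).fit(matrix)

    prec = config.precision
    reports: dict = {}
    if evaluator.pca_ is not None:
        reports["ci_table"] = evaluator.pca_.report_table(prec)
        logger.info(
            "retained %d/%d components (cumulative %.3f%% at threshold %.1f%%)",
            evaluator.pca_.n_retained_,
            len(evaluator.pca_.eigenvalues_),
            evaluator.pca_.cumulative_rates_[evaluator.pca_.n_retained_ - 1],
            config.cumulative_threshold,
        )
    logger.info(
        "weights: %s", np.array2string(evaluator.weights_, precision=3, separator=", ")
    )
    reports["membership_table"] = evaluator.results_.drop(columns=["tolerance_class", "rank"]).round(prec)
    reports["evaluation"] = evaluator.results_[["D", "tolerance_class", "rank"]].sort_values("rank")
    summary = {
        "weights": [round(float(w), prec) for w in evaluator.weights_],
        "contribution_rates": [round(float(p), prec) for p in evaluator.contribution_rates_],
        "population": summarize_population(evaluator.d_, config.class_boundaries),
        "config": config.echo(),
    }
    reports["summary"] = summary

    if config.run_selection and not config.from_ci and matrix.data.shape[0] >= 4:
        reports["correlation"] = correlate_with_d(matrix, evaluator.d_, config.alpha)
        selector = stepwise_select(
            matrix, evaluator.d_, config.alpha_enter, config.alpha_stay
        )
        reports["stepwise"] = {
            "selected": [str(s) for s in selector.selected_],
            "equation": selector.equation(),
            "intercept": selector.intercept_,
            "coefficients": {str(k): float(v) for k, v in selector.coef_.items()},
            "r_squared": selector.r_squared_,
        }
        logger.info("stepwise selection: %s", reports["stepwise"]["equation"])

    if config.output_dir is not None:
        _write_reports(reports, Path(config.output_dir))
    return evaluator, reports


def _write_reports(reports: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("ci_table", "membership_table", "evaluation", "correlation"):
        if name in reports:
            reports[name].to_csv(outdir / f"{name}.csv")
    payload = {k: reports[k] for k in ("summary", "stepwise") if k in reports}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    logger.info("reports written to %s", outdir)
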