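"""End-to-end analysis pipeline and report serialization.

:func:`run_analysis` chains the whole instar determination: mixture model
selection → intersection boundaries → instar assignment → per-instar
statistics → Brooks'/Crosby's indices and criteria → Dyar's-rule
regression. Downstream failures never discard upstream results: the
report records a status per stage and keeps whatever completed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .data_io import HCWDataset, make_histogram
from .mixture import (
    BoundaryError,
    DegenerateFitError,
    InstarPartition,
    MixtureModel,
    assign_instars,
    fit_mixture_histogram,
    intersection_boundaries,
    select_components,
)
from .validation import (
    DyarRegressionResult,
    InstarValidationReport,
    dyar_regression,
    instar_stats,
    validation_report,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the pipeline in one place.

    ``fit_mode`` selects maximum-likelihood EM on raw values (``"em"``,
    default) or least-squares curve fitting to histogram counts
    (``"histogram"``). ``boundary_mode`` intersects weighted (default) or
    unit-weight normal curves.
    """

    k_min: int = 1
    k_max: int = 5
    seed: int = 0
    bin_width: float | str = "auto"
    cv_threshold: float = 15.0
    crosby_threshold: float = 0.1
    fit_mode: str = "em"
    boundary_mode: str = "weighted"

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.cv_threshold <= 0 or self.crosby_threshold <= 0:
            raise ValueError("criteria thresholds must be > 0")
        if self.fit_mode not in ("em", "histogram"):
            raise ValueError("fit_mode must be 'em' or 'histogram'")
        if self.boundary_mode not in ("weighted", "unweighted"):
            raise ValueError("boundary_mode must be 'weighted' or 'unweighted'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**doc)


@dataclass(frozen=True)
class AnalysisReport:
    """Aggregated results of one pipeline run, with per-stage status."""

    config: AnalysisConfig
    n: int
    model: MixtureModel | None = None
    partition: InstarPartition | None = None
    validation: InstarValidationReport | None = None
    dyar: DyarRegressionResult | None = None
    stages: dict[str, str] = field(default_factory=dict)
    source: str | None = None

    @property
    def selected_k(self) -> int | None:
        return self.model.k if self.model is not None else None


def run_analysis(data: HCWDataset, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full instar-determination pipeline on a dataset.

    Stage errors are caught and recorded under ``stages`` with the stage
    name; every stage that completed keeps its results. Degenerate paths
    are handled explicitly: with one selected component there are no
    boundaries and everything is a single instar, and the Dyar regression
    is skipped (with the reason recorded) whenever fewer than three
    instars are available.
    """
    config = config or AnalysisConfig()
    stages: dict[str, str] = {}
    model = partition = report = dyar = None

    try:
        if config.fit_mode == "histogram":
            hist = make_histogram(data, bin_width=config.bin_width)
            candidates = []
            for k in range(config.k_min, config.k_max + 1):
                try:
                    candidates.append(fit_mixture_histogram(hist, k, seed=config.seed))
                except (DegenerateFitError, ValueError):
                    continue
            if not candidates:
                raise DegenerateFitError("histogram fit failed for every k")
            model = min(candidates, key=lambda m: m.bic)
        else:
            model = select_components(
                data, k_min=config.k_min, k_max=config.k_max, seed=config.seed
            )
        stages["fit"] = "ok"
    except (DegenerateFitError, ValueError) as err:
        stages["fit"] = f"error: {err}"
        return AnalysisReport(config=config, n=len(data), stages=stages, source=data.source)

    try:
        if model.k >= 2:
            boundaries = intersection_boundaries(
                model, weighted=config.boundary_mode == "weighted"
            )
        else:
            boundaries = np.empty(0)
        partition = assign_instars(data, boundaries)
        stages["boundaries"] = "ok"
    except BoundaryError as err:
        stages["boundaries"] = f"error: {err}"
        return AnalysisReport(
            config=config, n=len(data), model=model, stages=stages, source=data.source
        )

    try:
        stats = instar_stats(data, partition)
        report = validation_report(
            stats,
            cv_threshold=config.cv_threshold,
            crosby_threshold=config.crosby_threshold,
        )
        stages["validation"] = "ok"
    except ValueError as err:
        stages["validation"] = f"error: {err}"
        return AnalysisReport(
            config=config, n=len(data), model=model, partition=partition,
            stages=stages, source=data.source,
        )

    if model.k >= 3:
        try:
            dyar = dyar_regression([s.mean for s in report.per_instar])
            stages["dyar"] = "ok"
        except ValueError as err:
            stages["dyar"] = f"error: {err}"
    else:
        stages["dyar"] = f"skipped: k < 3 (k = {model.k})"

    return AnalysisReport(
        config=config, n=len(data), model=model, partition=partition,
        validation=report, dyar=dyar, stages=stages, source=data.source,
    )


def _report_to_dict(report: AnalysisReport) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "provenance": {
            "source": report.source,
            "config": {**asdict(report.config)},
            "version": __version__,
        },
        "n": report.n,
        "selected_k": report.selected_k,
        "stages": dict(report.stages),
    }
    m = report.model
    if m is not None:
        doc["model"] = {
            "k": m.k,
            "weights": m.weights.tolist(),
            "means": m.means.tolist(),
            "sds": m.sds.tolist(),
            "loglik": m.loglik,
            "bic": m.bic,
            "converged": m.converged,
        }
        if m.selection_table is not None:
            doc["model"]["selection_table"] = [dict(row) for row in m.selection_table]
    if report.partition is not None:
        doc["boundaries"] = report.partition.boundaries.tolist()
        doc["instar_counts"] = report.partition.counts().tolist()
    v = report.validation
    if v is not None:
        doc["validation"] = json.loads(v.to_json())
    d = report.dyar
    if d is not None:
        doc["dyar"] = asdict(d)
    return doc


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report as ``"json"``, ``"tsv"``, or ``"text"``.

    JSON keeps full float precision and round-trips byte-identically
    (sorted keys, fixed separators). TSV and text round numbers to four
    decimal places, matching the precision instar tables are printed at.
    """
    if format == "json":
        return json.dumps(_report_to_dict(report), indent=2, sort_keys=True)
    if format == "tsv":
        if report.validation is None:
            raise ValueError("no validation table to render (pipeline incomplete)")
        return report.validation.to_frame().round(4).to_csv(sep="\t", index=False)
    if format == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {format!r}; expected json, tsv, or text")


def _render_text(report: AnalysisReport) -> str:
    lines = [f"Instar analysis (n = {report.n})"]
    if report.selected_k is not None:
        lines.append(f"Selected components: k = {report.selected_k}")
    if report.model is not None and report.model.selection_table is not None:
        for row in report.model.selection_table:
            bic = row.get("bic")
            bic_text = f"{bic:.4f}" if bic is not None else f"failed: {row.get('error')}"
            lines.append(f"  k = {row['k']}: BIC = {bic_text}")
    if report.partition is not None and report.partition.boundaries.size:
        edges = ", ".join(f"{b:.4f}" for b in report.partition.boundaries)
        lines.append(f"Instar boundaries (μm): {edges}")
    v = report.validation
    if v is not None:
        lines.append("instar\tn\tmean±SE (μm)\tCV%\tBrooks\tCrosby")
        for i, s in enumerate(v.per_instar):
            brooks = f"{v.brooks[i - 1]:.4f}" if i >= 1 else "—"
            crosby = f"{v.crosby[i - 2]:.4f}" if i >= 2 else "—"
            lines.append(
                f"{s.instar}\t{s.count}\t{s.mean:.4f} ± {s.se:.4f}\t"
                f"{s.cv:.4f}\t{brooks}\t{crosby}"
            )
        verdict = "PASS" if v.overall_pass else "FAIL"
        lines.append(
            f"Criteria (CV < {v.cv_threshold:g}%, |Crosby| < "
            f"{v.crosby_threshold:g}): {verdict}"
        )
    d = report.dyar
    if d is not None:
        lines.append(
            f"Dyar regression: slope = {d.slope:.4f} (growth factor "
            f"{np.exp(d.slope):.4f}), R² = {d.r_squared:.4f}, "
            f"F = {d.f_stat:.4f}, p = {d.p_value:.4f}"
        )
    for stage, status in report.stages.items():
        if status != "ok":
            lines.append(f"[{stage}] {status}")
    return "\n".join(lines) + "\n"
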