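"""End-to-end report generation: rates, pairwise tests, folds, spectra.

Mirrors the figure/table conventions of the assay literature: medians with
95% CIs, detection limits rendered with "<", significance stars
(**** <=1e-4, *** <=1e-3, ** <=1e-2, * <=0.05, ns otherwise), fold changes
against a baseline strain, and class-percentage spectrum tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import compare, rates, spectra
from .rates import FluctuationExperiment, RateEstimate
from .simulate import AssayDesign, CloneRecord

__all__ = ["RunConfig", "significance_stars", "run_report", "render_report_text"]

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one report run."""

    baseline_strain: str | None = None
    estimator_variant: str = "per_culture_median"
    ci_level: float = 0.95
    interaction_convention: str = "sum"
    interaction_tolerance: float = 0.10
    rate_display_scale: float = rates.RATE_DISPLAY_SCALE


def _per_culture_mus(exp: FluctuationExperiment) -> list[float]:
    mus, _, _ = rates._per_culture_rates(exp)
    return mus


def run_report(
    experiments: Sequence[FluctuationExperiment],
    clones_by_strain: Mapping[str, Sequence[CloneRecord]] | None = None,
    designs_by_tract: Mapping[str, AssayDesign] | None = None,
    config: RunConfig = RunConfig(),
) -> dict[str, pd.DataFrame]:
    """Assemble the full report as a dict of deterministic DataFrames.

    ``rates``: one row per experiment (rate, CI, display string).
    ``comparisons``: per tract, every strain against the baseline strain
    (the first strain seen unless configured): Mann--Whitney U on the
    per-culture rates, stars, fold change over the baseline estimate.
    ``spectra``: class-percentage rows, when clone data is supplied.
    """
    if not experiments:
        raise ValueError("run_report requires at least one experiment")
    estimates: dict[tuple[str, str], RateEstimate] = {}
    rate_rows = []
    for exp in experiments:
        est = rates.estimate_rate(
            exp, variant=config.estimator_variant, level=config.ci_level
        )
        estimates[(exp.strain, exp.tract_id)] = est
        rate_rows.append(
            {
                "strain": exp.strain,
                "tract_id": exp.tract_id,
                "n_cultures": est.n_cultures,
                "mu": est.mu,
                "mu_scaled": est.mu * config.rate_display_scale,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "is_upper_bound": est.is_upper_bound,
                "display": est.display(config.rate_display_scale),
                "method": est.method,
            }
        )
    rates_df = pd.DataFrame(rate_rows).sort_values(["tract_id", "strain"]).reset_index(drop=True)

    by_tract: dict[str, list[FluctuationExperiment]] = {}
    for exp in experiments:
        by_tract.setdefault(exp.tract_id, []).append(exp)
    comp_rows = []
    for tract_id in sorted(by_tract):
        group = by_tract[tract_id]
        baseline = config.baseline_strain or group[0].strain
        base_exp = next((e for e in group if e.strain == baseline), None)
        if base_exp is None:
            continue
        base_est = estimates[(baseline, tract_id)]
        base_mus = _per_culture_mus(base_exp)
        for exp in group:
            if exp.strain == baseline:
                continue
            res = compare.mann_whitney(_per_culture_mus(exp), base_mus)
            est = estimates[(exp.strain, tract_id)]
            if est.is_upper_bound:
                fold, qualifier = float("nan"), "undefined"
            else:
                fold, qualifier = compare.fold_change(est, base_est)
            comp_rows.append(
                {
                    "tract_id": tract_id,
                    "strain": exp.strain,
                    "baseline": baseline,
                    "U": res.statistic,
                    "p": res.p_value,
                    "stars": significance_stars(res.p_value),
                    "exact": res.exact,
                    "fold_vs_baseline": fold,
                    "fold_qualifier": qualifier,
                }
            )
    comparisons_df = pd.DataFrame(
        comp_rows,
        columns=[
            "tract_id",
            "strain",
            "baseline",
            "U",
            "p",
            "stars",
            "exact",
            "fold_vs_baseline",
            "fold_qualifier",
        ],
    )

    spectrum_rows = []
    if clones_by_strain:
        designs_by_tract = designs_by_tract or {}
        for strain in sorted(clones_by_strain):
            clones = clones_by_strain[strain]
            by_tract_clones: dict[str, list[CloneRecord]] = {}
            for c in clones:
                by_tract_clones.setdefault(c.tract_id, []).append(c)
            for tract_id in sorted(by_tract_clones):
                design = designs_by_tract.get(tract_id)
                if design is None:
                    raise ValueError(f"no assay design supplied for tract {tract_id!r}")
                table = spectra.spectrum_table(
                    by_tract_clones[tract_id], design, strain=strain
                )
                row = {"tract_id": tract_id, "strain": strain, "n": table.n_clones}
                row.update(table.percentages)
                spectrum_rows.append(row)
    spectra_df = pd.DataFrame(
        spectrum_rows,
        columns=["tract_id", "strain", "n", *spectra.CLASS_LABELS],
    )

    return {"rates": rates_df, "comparisons": comparisons_df, "spectra": spectra_df}


def render_report_text(report: Mapping[str, pd.DataFrame]) -> str:
    """Human-readable rendering of :func:`run_report` output."""
    chunks = []
    for name in ("rates", "comparisons", "spectra"):
        df = report.get(name)
        if df is None or df.empty:
            continue
        chunks.append(f"== {name} ==")
        chunks.append(df.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
        chunks.append("")
    return "\n".join(chunks)
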