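"""Flat-file interchange formats.

* culture TSV: one row per culture with header
  ``strain  tract_id  culture_id  sel_colonies  sel_plating_fraction
  ns_colonies  ns_dilution_fraction``; leading ``#`` lines carry
  provenance metadata (seed, simulation parameters).
* peak CSV: ``clone_id,tract_id,size_bp`` — already-sized capillary peaks.
  Simulated peak files get a ``.truth.tsv`` sidecar with the planted
  ground truth for round-trip tests.
* estimates TSV: one row per strain x tract with the rate, CI, and bound
  flag, both in native units and scaled x1e8 for display.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .rates import RATE_DISPLAY_SCALE, CultureObservation, FluctuationExperiment, RateEstimate
from .simulate import CloneRecord

__all__ = [
    "read_cultures",
    "write_cultures",
    "read_peaks",
    "write_peaks",
    "write_estimates",
]

logger = logging.getLogger(__name__)

CULTURE_COLUMNS = [
    "strain",
    "tract_id",
    "culture_id",
    "sel_colonies",
    "sel_plating_fraction",
    "ns_colonies",
    "ns_dilution_fraction",
]

PEAK_COLUMNS = ["clone_id", "tract_id", "size_bp"]


def _metadata_header(metadata: Mapping[str, object] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {key} = {value}\n" for key, value in sorted(metadata.items()))


def read_cultures(path: str | Path) -> list[FluctuationExperiment]:
    """Read a culture TSV and group rows into experiments by (strain, tract).

    Malformed rows raise with the offending line number; experiments with
    fewer than ten cultures are logged as a warning by the experiment
    constructor.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in CULTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    # line numbers: header is line 1 + any leading comment lines
    with open(path, encoding="utf-8") as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    experiments: dict[tuple[str, str], list[CultureObservation]] = {}
    for idx, row in df.iterrows():
        line_no = n_comment + int(idx) + 2
        try:
            obs = CultureObservation(
                culture_id=str(row["culture_id"]),
                sel_colonies=float(row["sel_colonies"]),
                sel_plating_fraction=float(row["sel_plating_fraction"]),
                ns_colonies=float(row["ns_colonies"]),
                ns_dilution_fraction=float(row["ns_dilution_fraction"]),
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}, line {line_no}: {err}") from err
        experiments.setdefault((str(row["strain"]), str(row["tract_id"])), []).append(obs)
    out = [
        FluctuationExperiment(strain=strain, tract_id=tract, cultures=tuple(obs_list))
        for (strain, tract), obs_list in experiments.items()
    ]
    logger.info("%s: read %d cultures in %d experiments", path, len(df), len(out))
    return out


def write_cultures(
    experiments: Iterable[FluctuationExperiment],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = [
        {
            "strain": exp.strain,
            "tract_id": exp.tract_id,
            "culture_id": obs.culture_id,
            "sel_colonies": obs.sel_colonies,
            "sel_plating_fraction": obs.sel_plating_fraction,
            "ns_colonies": obs.ns_colonies,
            "ns_dilution_fraction": obs.ns_dilution_fraction,
        }
        for exp in experiments
        for obs in exp.cultures
    ]
    df = pd.DataFrame(rows, columns=CULTURE_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        df.to_csv(fh, sep="\t", index=False)


def read_peaks(path: str | Path) -> list[CloneRecord]:
    """Read a peak CSV into clone records (no ground truth)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                CloneRecord(
                    clone_id=str(row["clone_id"]),
                    tract_id=str(row["tract_id"]),
                    size_bp=float(row["size_bp"]),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}, line {int(idx) + 2}: {err}") from err
    return out


def write_peaks(
    clones: Sequence[CloneRecord],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    truth_sidecar: bool = True,
) -> None:
    """Write a peak CSV; planted truth goes to a ``.truth.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {"clone_id": c.clone_id, "tract_id": c.tract_id, "size_bp": round(c.size_bp, 4)}
            for c in clones
        ],
        columns=PEAK_COLUMNS,
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        df.to_csv(fh, index=False)
    if truth_sidecar and any(c.true_delta_units is not None for c in clones):
        truth = pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "true_delta_units": c.true_delta_units,
                    "coding_hit": c.coding_hit,
                }
                for c in clones
            ]
        )
        truth.to_csv(path.with_suffix(path.suffix + ".truth.tsv"), sep="\t", index=False)


def write_estimates(
    estimates: Mapping[tuple[str, str], RateEstimate], path: str | Path
) -> None:
    """Write per-experiment rate estimates as TSV, keyed by (strain, tract)."""
    rows = []
    for (strain, tract_id), est in sorted(estimates.items()):
        rows.append(
            {
                "strain": strain,
                "tract_id": tract_id,
                "n_cultures": est.n_cultures,
                "mu": est.mu,
                "mu_x1e8": est.mu * RATE_DISPLAY_SCALE,
                "ci_low": est.ci_low if est.ci_low is not None else "",
                "ci_high": est.ci_high if est.ci_high is not None else "",
                "is_upper_bound": est.is_upper_bound,
                "method": est.method,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
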