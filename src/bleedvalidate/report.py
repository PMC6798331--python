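"""One-shot study runner and report rendering.

``run_full_study`` ties the stages together: read (or accept) a cohort,
apply the index test, apply the two-step reference, cross-tabulate, compute
accuracy statistics, profile discordance, and write a machine-readable JSON
report plus a human-readable markdown summary. Every run writes a manifest
(command, input hashes, seed, package version, timestamp) next to its
outputs; all JSON outputs are byte-stable across reruns with identical
inputs (the timestamp lives only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .accuracy import (
    TypedContingency,
    build_contingency,
    category_ppv,
    diagnostic_metrics,
    round_half_up,
)
from .classify import classify_cohort, code_frequency_report
from .codesets import BLEED_CATEGORIES, BleedTypeMap, Category, ScreenCodeSet, load_codeset
from .codesets import default_index_map, default_screen_set
from .cohort import Cohort, read_cohort
from .discordance import profile_discordance
from .reference import label_cohort

__all__ = ["StageError", "RunManifest", "run_full_study", "render_summary"]

log = logging.getLogger("bleedvalidate")


class StageError(RuntimeError):
    """A pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    command: str
    inputs: dict[str, str]
    input_hashes: dict[str, str]
    outputs: list[str]
    seed: Optional[int]
    version: str
    timestamp: str
    status: str = "ok"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _hash_file(path: Union[str, Path, None]) -> str:
    if path is None:
        return ""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def render_summary(report, table: TypedContingency, alpha: float) -> str:
    """Markdown rendering of the contingency table and accuracy measures."""

    def pct(est, nd=1):
        if est is None:
            return "n/a"
        p, lo, hi = est.as_percent(nd)
        return f"{p}% (95% CI {lo} to {hi})" if abs(alpha - 0.05) < 1e-12 else (
            f"{p}% ({100 * (1 - alpha):g}% CI {lo} to {hi})"
        )

    lines = [
        "# Validation summary",
        "",
        "## Contingency table (index category x reference status)",
        "",
        "| Index test | Reference positive | Reference negative | Total |",
        "|---|---|---|---|",
    ]
    for cat in Category:
        p, n = table.positives(cat), table.negatives(cat)
        label = cat.value if cat is not Category.NONE else "Negative"
        lines.append(f"| {label} | {p} | {n} | {p + n} |")
    lines.append(
        f"| Total | {table.tp + table.fn} | {table.fp + table.tn} | {table.n} |"
    )
    lines += [
        "",
        "## Accuracy",
        "",
        f"- Sensitivity {pct(report.se)}",
        f"- Specificity {pct(report.sp)}",
        f"- PPV {pct(report.ppv)}",
        f"- NPV {pct(report.npv)}",
    ]
    if report.lr_pos is not None:
        lines.append(
            f"- LR+ {round_half_up(report.lr_pos.point, 1)}"
            f" (log-normal 95% CI {round_half_up(report.lr_pos.lower, 1)}"
            f" to {round_half_up(report.lr_pos.upper, 1)})"
        )
    else:
        lines.append("- LR+ n/a")
    if report.lr_neg is not None:
        lines.append(
            f"- LR- {round_half_up(report.lr_neg.point, 2)}"
            f" (log-normal 95% CI {round_half_up(report.lr_neg.lower, 2)}"
            f" to {round_half_up(report.lr_neg.upper, 2)})"
        )
    else:
        lines.append("- LR- n/a")
    return "\n".join(lines) + "\n"


def run_full_study(
    cohort: Union[str, Path, Cohort],
    out_dir: Union[str, Path],
    index_map: Union[str, Path, BleedTypeMap, None] = None,
    screen: Union[str, Path, ScreenCodeSet, None] = None,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    command: str = "run_full_study",
) -> dict:
    """Run every stage on one cohort and write the full report bundle.

    Returns the report payload (also written to ``report.json``). Raises
    :class:`StageError` naming the failing stage; partial outputs written
    before the failure are retained and the manifest records the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        inputs={},
        input_hashes={},
        outputs=[],
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    stage = "setup"
    try:
        stage = "read_cohort"
        if isinstance(cohort, (str, Path)):
            manifest.inputs["cohort"] = str(cohort)
            manifest.input_hashes["cohort"] = _hash_file(cohort)
            cohort = read_cohort(cohort)
        stage = "load_codesets"
        if isinstance(index_map, (str, Path)):
            manifest.inputs["index_map"] = str(index_map)
            manifest.input_hashes["index_map"] = _hash_file(index_map)
            index_map = load_codeset(index_map)
        if isinstance(screen, (str, Path)):
            manifest.inputs["screen"] = str(screen)
            manifest.input_hashes["screen"] = _hash_file(screen)
            screen = load_codeset(screen)
        index_map = index_map or default_index_map()
        screen = screen or default_screen_set()

        stage = "classify"
        log.info("classifying %d stays", len(cohort))
        labeling = classify_cohort(cohort, index_map)
        labels_path = out / "labels.csv"
        pd.DataFrame(
            [{"stay_id": sid, "category": cat.value} for sid, cat in labeling.labels.items()]
        ).to_csv(labels_path, index=False)
        manifest.outputs.append(str(labels_path))

        stage = "reference"
        log.info("applying two-step reference standard")
        reference = label_cohort(cohort, screen)
        ref_path = out / "reference.csv"
        pd.DataFrame(
            [
                {
                    "stay_id": sid,
                    "selected": int(r.screen.selected),
                    "verdict": r.verdict,
                    "pathway": r.pathway,
                    "criteria_met": ";".join(sorted(r.criteria_met)),
                }
                for sid, r in reference.items()
            ]
        ).to_csv(ref_path, index=False)
        manifest.outputs.append(str(ref_path))

        stage = "contingency"
        table = build_contingency(labeling, reference)
        table_path = out / "contingency.csv"
        table.to_frame().to_csv(table_path, index=False)
        manifest.outputs.append(str(table_path))

        stage = "accuracy"
        report = diagnostic_metrics(table, alpha=alpha)
        payload = report.to_dict()
        payload["per_category_ppv"] = {}
        for cat in BLEED_CATEGORIES:
            est = category_ppv(table, cat, alpha=alpha)
            payload["per_category_ppv"][cat.value] = (
                None
                if est is None
                else {"point": est.point, "lower": est.lower, "upper": est.upper, "k": est.k, "n": est.n}
            )
        freq = code_frequency_report(cohort, labeling, aggregation="3-char")
        payload["code_frequency_3char"] = freq.to_dict("records")

        stage = "discordance"
        profiles = profile_discordance(cohort, labeling, reference)
        disc_payload = {cell: prof.to_dict() for cell, prof in profiles.items()}
        disc_path = out / "discordance.json"
        _write_json(disc_payload, disc_path)
        manifest.outputs.append(str(disc_path))

        stage = "report"
        report_path = out / "report.json"
        _write_json(payload, report_path)
        manifest.outputs.append(str(report_path))
        summary_path = out / "summary.md"
        summary_path.write_text(render_summary(report, table, alpha))
        manifest.outputs.append(str(summary_path))
    except Exception as exc:
        manifest.status = f"failed at {stage}: {exc}"
        manifest.write(out / "manifest.json")
        raise StageError(stage, exc) from exc
    manifest.write(out / "manifest.json")
    return payload
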