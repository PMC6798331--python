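"""Synthetic emergency-admission cohorts with known latent truth.

Two modes:

* **Stochastic** (:func:`generate_cohort`): each stay draws a latent true
  bleeding status, a bleeding type, a primary discharge code subject to
  configurable coding error rates, and screen/chart data consistent with
  the truth. Used for parameter-recovery experiments
  (:func:`recovery_experiment`) where the generator's own truth is the
  oracle.
* **Deterministic** (:func:`cohort_from_contingency`): expand an explicit
  per-cell specification into a cohort that reproduces a given typed
  contingency table exactly — the packaged :func:`table2_spec` rebuilds the
  validation study's full 16,012-stay contingency structure, which makes
  the published cross-table the end-to-end test oracle.

Reproducibility uses a single global seed with per-stay counter-based
substreams (``default_rng([seed, stay_index])``), so a cohort is identical
however generation is chunked.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .accuracy import build_contingency, clopper_pearson, diagnostic_metrics
from .classify import classify_cohort
from .codesets import (
    BLEED_CATEGORIES,
    BleedTypeMap,
    Category,
    ICDCode,
    ScreenCodeSet,
    default_index_map,
    default_screen_set,
    normalize_code,
)
from .cohort import ChartFeatures, Cohort, HospitalStay
from .reference import label_cohort

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "ContingencySpec",
    "Stratum",
    "cohort_from_contingency",
    "load_contingency_spec",
    "table2_spec",
    "recovery_experiment",
    "RecoverySummary",
    "ContingencySpecError",
]


def _filler_codes() -> list[str]:
    raw = yaml.safe_load(
        resources.files("bleedvalidate.data").joinpath("filler_codes.yaml").read_text()
    )
    return list(raw["filler"])


# emergency-ward codes used as screen signals for stays whose discharge
# coding does not itself point at bleeding (all members of the default
# screen list)
_EW_SIGNAL = ("D64.9", "R57.1", "S39.0", "T81.0", "S00.0")

_TYPE_LOCATION = {
    Category.ICH: "intracranial",
    Category.GI: "acute_gi",
    Category.OTHER: "retroperitoneal",
}


@dataclass
class GeneratorConfig:
    """Parameters of the stochastic cohort generator.

    Defaults are the validation study's observed operating conditions:
    16,012 stays, major-bleeding prevalence 736/16,012, index-positive type
    mix 46/31/23 (ICH/GI/other), discharge-coding sensitivity 0.655 and
    false-positive coding rate 0.0101, a perfectly sensitive screen with
    specificity 0.92 (=1 - 1223/15,276 screened-in negatives), age 61.7
    (SD 22.7) years truncated at 18, and 52.2% men.
    """

    n_stays: int = 16012
    prevalence: float = 736 / 16012
    type_mix: tuple[float, float, float] = (0.46, 0.31, 0.23)  # ICH, GI, OTHER
    coding_sensitivity: float = 0.655
    coding_fpr: float = 0.0101
    screen_sensitivity: float = 1.0
    screen_specificity: float = 0.92
    seed: int = 0
    age_mean: float = 61.7
    age_sd: float = 22.7
    male_fraction: float = 0.522

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        probs = {
            "prevalence": self.prevalence,
            "coding_sensitivity": self.coding_sensitivity,
            "coding_fpr": self.coding_fpr,
            "screen_sensitivity": self.screen_sensitivity,
            "screen_specificity": self.screen_specificity,
            "male_fraction": self.male_fraction,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or min(self.type_mix) < 0:
            raise ValueError(f"type_mix must be a distribution, got {self.type_mix}")

    def operating_point(self) -> dict[str, float]:
        """True index-test operating values against the two-step reference.

        Sensitivity against the reference equals the coding sensitivity
        (screening is independent of discharge coding). Reference negatives
        include screen-missed true bleeds, whose coding behaves like a true
        bleed, so the operating false-positive rate mixes the two sources.
        """
        p, ssens = self.prevalence, self.screen_sensitivity
        miss = p * (1 - ssens)
        neg = miss + (1 - p)
        fpr = (miss * self.coding_sensitivity + (1 - p) * self.coding_fpr) / neg if neg else 0.0
        return {"se": self.coding_sensitivity, "sp": 1.0 - fpr}


def _major_chart(rng: np.random.Generator, bleed_type: Category) -> ChartFeatures:
    pick = rng.random()
    if pick < 0.5:
        return ChartFeatures(location=_TYPE_LOCATION[bleed_type])
    if pick < 0.8:
        return ChartFeatures(transfusion=True)
    return ChartFeatures(sbp=float(rng.integers(60, 90)))


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> Cohort:
    """Draw a cohort with latent truth; identical for identical (config, seed).

    Every MAJOR stay's chart satisfies at least one adjudication criterion;
    the automated screen is the only configured leak between latent truth
    and the reference label.
    """
    base_seed = config.seed if seed is None else seed
    bleed_map = default_index_map()
    by_cat: dict[Category, list[str]] = {c: [] for c in BLEED_CATEGORIES}
    for norm, cat in sorted(bleed_map.categories().items()):
        by_cat[cat].append(norm)
    all_bleed = sorted(bleed_map.categories())
    filler = _filler_codes()
    stays: list[HospitalStay] = []
    for i in range(config.n_stays):
        rng = np.random.default_rng([base_seed, i])
        # truncated-normal age: redraw below 18, cap retries
        a = 18.0
        for _ in range(64):
            a = rng.normal(config.age_mean, config.age_sd)
            if a >= 18:
                break
        age = int(max(a, 18))
        sex = "M" if rng.random() < config.male_fraction else "F"
        is_major = rng.random() < config.prevalence
        ew: tuple[ICDCode, ...] = ()
        therapies: frozenset[str] = frozenset()
        chart: Optional[ChartFeatures] = None
        if is_major:
            bleed_type = BLEED_CATEGORIES[
                rng.choice(3, p=np.asarray(config.type_mix, dtype=float))
            ]
            if rng.random() < config.coding_sensitivity:
                primary = normalize_code(str(rng.choice(by_cat[bleed_type])))
            else:
                primary = normalize_code(str(rng.choice(filler)))
            chart = _major_chart(rng, bleed_type)
            if rng.random() < config.screen_sensitivity:
                ew_code = (
                    primary.normalized
                    if bleed_map.match(primary) is not Category.NONE
                    else str(rng.choice(_EW_SIGNAL))
                )
                ew = (normalize_code(ew_code),)
                if chart.transfusion:
                    therapies = frozenset({"rbc_transfusion"})
            truth = "MAJOR"
        else:
            if rng.random() < config.coding_fpr:
                primary = normalize_code(str(rng.choice(all_bleed)))
            else:
                primary = normalize_code(str(rng.choice(filler)))
            if rng.random() > config.screen_specificity:
                ew = (normalize_code(str(rng.choice(_EW_SIGNAL))),)
            truth = "NOT_MAJOR"
        stays.append(
            HospitalStay(
                stay_id=f"G{i:06d}",
                age=age,
                sex=sex,
                primary_dx=primary,
                ew_codes=ew,
                therapies=therapies,
                chart=chart,
                latent_truth=truth,
            )
        )
    digest = hashlib.sha256(repr(asdict(config)).encode()).hexdigest()[:12]
    return Cohort(stays, provenance=f"generator:{digest}:seed={base_seed}")


class ContingencySpecError(ValueError):
    """A contingency spec whose strata contradict its declared margins."""


@dataclass(frozen=True)
class Stratum:
    """A block of identical stays in a deterministic cohort spec."""

    n: int
    primary_dx: str
    truth: str
    ew_code: Optional[str] = None
    therapies: tuple[str, ...] = ()
    chart: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ContingencySpecError(f"stratum with negative n: {self}")


@dataclass
class ContingencySpec:
    """Explicit per-cell construction recipe plus the margins it must hit.

    ``expected`` declares the typed contingency cells
    (``{"ICH": [pos, neg], ...}``) and the screen split
    (``screened_in`` / ``adjudicated_major`` / ``adjudicated_not_major`` /
    ``screened_out``); :func:`cohort_from_contingency` verifies the
    constructed cohort against every declared margin.
    """

    strata: list[Stratum]
    expected: dict = field(default_factory=dict)
    name: str = "contingency-spec"

    @property
    def n_stays(self) -> int:
        return sum(s.n for s in self.strata)


def load_contingency_spec(source: Union[str, Path]) -> ContingencySpec:
    """Load a spec from YAML (keys ``strata``, optional ``expected``, ``name``)."""
    raw = yaml.safe_load(Path(source).read_text())
    return _parse_spec(raw, name=str(source))


def _parse_spec(raw: dict, name: str) -> ContingencySpec:
    strata = [
        Stratum(
            n=int(s["n"]),
            primary_dx=str(s["primary_dx"]),
            truth=str(s["truth"]),
            ew_code=s.get("ew_code"),
            therapies=tuple(s.get("therapies", ())),
            chart=s.get("chart"),
        )
        for s in raw.get("strata", [])
    ]
    return ContingencySpec(
        strata=strata, expected=raw.get("expected", {}), name=raw.get("name", name)
    )


def table2_spec() -> ContingencySpec:
    """The packaged deterministic spec reconstructing the validation study's
    full contingency structure (16,012 stays)."""
    raw = yaml.safe_load(
        resources.files("bleedvalidate.data").joinpath("table2_fixture.yaml").read_text()
    )
    return _parse_spec(raw, name="packaged:table2_fixture.yaml")


def cohort_from_contingency(
    spec: ContingencySpec,
    index_map: Optional[BleedTypeMap] = None,
    screen: Optional[ScreenCodeSet] = None,
    validate: bool = True,
) -> Cohort:
    """Expand a spec into a cohort and verify its declared margins.

    Ages and sexes are cosmetic deterministic patterns (no operation
    consumes them). With ``validate=True`` the full pipeline (classify,
    screen, adjudicate, cross-tabulate) is run against the declared
    ``expected`` block; any violated margin raises
    :class:`ContingencySpecError` naming it.
    """
    stays: list[HospitalStay] = []
    i = 0
    for stratum in spec.strata:
        chart = ChartFeatures(**stratum.chart) if stratum.chart else None
        for _ in range(stratum.n):
            stays.append(
                HospitalStay(
                    stay_id=f"S{i:06d}",
                    age=18 + (i * 37) % 70,
                    sex="M" if (i % 1000) < 522 else "F",
                    primary_dx=normalize_code(stratum.primary_dx),
                    ew_codes=(normalize_code(stratum.ew_code),) if stratum.ew_code else (),
                    therapies=frozenset(stratum.therapies),
                    chart=chart,
                    latent_truth=stratum.truth,
                )
            )
            i += 1
    cohort = Cohort(stays, provenance=spec.name)
    if validate and spec.expected:
        _check_margins(cohort, spec, index_map or default_index_map(), screen or default_screen_set())
    return cohort


def _check_margins(
    cohort: Cohort, spec: ContingencySpec, index_map: BleedTypeMap, screen: ScreenCodeSet
) -> None:
    labeling = classify_cohort(cohort, index_map)
    reference = label_cohort(cohort, screen)
    table = build_contingency(labeling, reference)
    exp = spec.expected
    for cat in Category:
        want = exp.get("cells", {}).get(cat.value)
        if want is None:
            continue
        got = [table.positives(cat), table.negatives(cat)]
        if got != list(want):
            raise ContingencySpecError(
                f"{spec.name}: cell margin {cat.value} is {got}, declared {list(want)}"
            )
    pathways = [r.pathway for r in reference.values()]
    verdicts = [r.verdict for r in reference.values()]
    checks = {
        "screened_in": sum(p == "adjudicated" for p in pathways),
        "screened_out": sum(p == "screened_out" for p in pathways),
        "adjudicated_major": sum(v == "MAJOR" for v in verdicts),
        "adjudicated_not_major": sum(
            v == "NOT_MAJOR" and p == "adjudicated" for v, p in zip(verdicts, pathways)
        ),
    }
    for key, got in checks.items():
        want = exp.get(key)
        if want is not None and got != int(want):
            raise ContingencySpecError(f"{spec.name}: margin {key} is {got}, declared {want}")


@dataclass
class RecoverySummary:
    """Aggregate of a parameter-recovery experiment.

    For sensitivity and specificity: the generator's true operating value,
    the mean pipeline estimate, bias, RMSE, and the fraction of replicates
    whose exact interval covered the true value.
    """

    n_replicates: int
    truth: dict[str, float]
    estimates: dict[str, list[float]]
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "truth": self.truth,
            "bias": self.bias,
            "rmse": self.rmse,
            "coverage": self.coverage,
        }


def recovery_experiment(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
) -> RecoverySummary:
    """Repeatedly generate, run the full pipeline, and compare estimates to
    the generator's operating point.

    Replicate r uses seed ``seed + r``. Replicates with an empty reference
    margin (no estimate) are skipped in the aggregates; at realistic
    prevalence and n this does not occur.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth = config.operating_point()
    index_map = default_index_map()
    screen = default_screen_set()
    estimates: dict[str, list[float]] = {"se": [], "sp": []}
    covered = {"se": 0, "sp": 0}
    used = {"se": 0, "sp": 0}
    for r in range(n_replicates):
        cohort = generate_cohort(config, seed=seed + r)
        labeling = classify_cohort(cohort, index_map)
        reference = label_cohort(cohort, screen)
        report = diagnostic_metrics(build_contingency(labeling, reference), alpha=alpha)
        for key, est in (("se", report.se), ("sp", report.sp)):
            if est is None:
                continue
            used[key] += 1
            estimates[key].append(est.point)
            if est.lower <= truth[key] <= est.upper:
                covered[key] += 1
    bias = {k: float(np.mean(v) - truth[k]) if v else float("nan") for k, v in estimates.items()}
    rmse = {
        k: float(np.sqrt(np.mean((np.asarray(v) - truth[k]) ** 2))) if v else float("nan")
        for k, v in estimates.items()
    }
    coverage = {k: covered[k] / used[k] if used[k] else float("nan") for k in covered}
    return RecoverySummary(
        n_replicates=n_replicates,
        truth=truth,
        estimates=estimates,
        bias=bias,
        rmse=rmse,
        coverage=coverage,
    )
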