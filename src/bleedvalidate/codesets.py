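"""ICD-10 code lists defining the index algorithm and the emergency-ward screen.

ICD-10 diagnosis codes appear in administrative extracts in two spellings:
dotted ("K27.2") and undotted ("K272"). Everything here works on a
normalized form — uppercased, dot removed — so the two spellings compare
equal. Code lists carry entries at two granularities: a 3-character entry
(e.g. ``I61``) stands for the whole category and matches every extension,
while a 4-character entry (e.g. ``S06.3``) matches exactly, so that listing
``S06.3``–``S06.6`` does not swallow the other ``S06`` subcodes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "Category",
    "ICDCode",
    "BleedTypeMap",
    "ScreenCodeSet",
    "THERAPIES",
    "MalformedCodeError",
    "CodesetConfigError",
    "normalize_code",
    "match_category",
    "load_codeset",
    "default_index_map",
    "default_screen_set",
]

#: The six emergency therapies used as screening signals: red blood cell and
#: platelet transfusion, the reversal agents vitamin K and protamine sulfate,
#: prothrombin complex concentrate (PCC), and activated anti-inhibitor
#: coagulant complex (FEIBA).
THERAPIES = frozenset(
    {
        "rbc_transfusion",
        "platelet_transfusion",
        "vitamin_k",
        "protamine_sulfate",
        "pcc",
        "feiba",
    }
)


class Category(str, enum.Enum):
    """Index-test bleeding category: the three bleeding types plus the
    complement class NONE ("no bleeding event")."""

    ICH = "ICH"
    GI = "GI"
    OTHER = "OTHER"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


BLEED_CATEGORIES = (Category.ICH, Category.GI, Category.OTHER)


class MalformedCodeError(ValueError):
    """A string that cannot be normalized into an ICD-10 code."""


class CodesetConfigError(ValueError):
    """A code-list configuration violating its invariants."""


_CODE_RE = re.compile(r"^[A-Z][A-Z0-9]+$")


@dataclass(frozen=True, eq=False)
class ICDCode:
    """An ICD-10 code with its raw spelling and normalized form.

    ``granularity`` is the character count of the normalized form; hospital
    discharge extracts carry 3- or 4-character codes. Equality and hashing
    are on the normalized form, so ``"K27.2"`` and ``"K272"`` compare equal.
    """

    raw: str
    normalized: str
    granularity: int

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ICDCode):
            return self.normalized == other.normalized
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.normalized)

    def __str__(self) -> str:
        return self.normalized


def normalize_code(raw: str) -> ICDCode:
    """Normalize an ICD-10 code string: trim, uppercase, strip the dot.

    >>> normalize_code("K27.2").normalized
    'K272'

    Raises :class:`MalformedCodeError` for empty input or anything that is
    not a letter followed by alphanumerics after normalization.
    """
    if not isinstance(raw, str):
        raise MalformedCodeError(f"ICD-10 code must be a string, got {raw!r}")
    stripped = raw.strip()
    if not stripped:
        raise MalformedCodeError("empty ICD-10 code")
    norm = stripped.upper().replace(".", "")
    if not _CODE_RE.match(norm):
        raise MalformedCodeError(f"malformed ICD-10 code: {raw!r}")
    return ICDCode(raw=stripped, normalized=norm, granularity=len(norm))


def _as_code(code: Union[str, ICDCode]) -> ICDCode:
    return code if isinstance(code, ICDCode) else normalize_code(code)


_PRECEDENCE = {Category.ICH: 0, Category.GI: 1, Category.OTHER: 2}


@dataclass
class BleedTypeMap:
    """Assignment of ICD-10 codes to bleeding categories (the index code list).

    Invariants enforced on construction (``on_overlap="error"``, the
    default): no normalized code appears under two categories, and no entry
    is a strict prefix of an entry in a different category. With
    ``on_overlap="precedence"`` (user-supplied maps only) collisions are
    resolved by the fixed order ICH > GI > OTHER instead of rejected.
    """

    entries: list[tuple[ICDCode, Category]]
    source_label: str = ""
    on_overlap: str = "error"
    _exact: dict[str, Category] = field(init=False, repr=False)
    _prefix3: dict[str, Category] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.on_overlap not in ("error", "precedence"):
            raise CodesetConfigError(f"unknown overlap policy {self.on_overlap!r}")
        seen: dict[str, Category] = {}
        collisions: list[str] = []
        for code, cat in self.entries:
            cat = Category(cat)
            prev = seen.get(code.normalized)
            if prev is not None and prev is not cat:
                if self.on_overlap == "error":
                    collisions.append(code.normalized)
                elif _PRECEDENCE[cat] < _PRECEDENCE[prev]:
                    seen[code.normalized] = cat
                continue
            seen[code.normalized] = cat
        if collisions:
            raise CodesetConfigError(
                "codes assigned to more than one category: " + ", ".join(sorted(set(collisions)))
            )
        # cross-category prefix nesting (a 3-char entry swallowing a 4-char
        # entry of another category) makes matching ambiguous
        if self.on_overlap == "error":
            shorts = {n: c for n, c in seen.items() if len(n) == 3}
            for norm, cat in seen.items():
                pre = shorts.get(norm[:3])
                if pre is not None and norm[:3] != norm and pre is not cat:
                    raise CodesetConfigError(
                        f"entry {norm} ({cat}) nested under {norm[:3]} ({pre})"
                    )
        self._exact = {n: c for n, c in seen.items() if len(n) != 3}
        self._prefix3 = {n: c for n, c in seen.items() if len(n) == 3}

    def categories(self) -> Mapping[str, Category]:
        """Normalized code string -> declared category, for every entry."""
        out = dict(self._prefix3)
        out.update(self._exact)
        return out

    def match(self, code: Union[str, ICDCode]) -> Category:
        code = _as_code(code)
        cat = self._exact.get(code.normalized)
        if cat is not None:
            return cat
        cat = self._prefix3.get(code.normalized[:3])
        if cat is not None:
            return cat
        return Category.NONE

    def __len__(self) -> int:
        return len(self._exact) + len(self._prefix3)


def match_category(code: Union[str, ICDCode], bleed_map: BleedTypeMap) -> Category:
    """Category of ``code`` under ``bleed_map``: the unique entry equal to
    its normalized form, or a 3-character entry that prefixes it; NONE
    otherwise."""
    return bleed_map.match(code)


@dataclass
class ScreenCodeSet:
    """Codes and therapies driving the automated first-step screen."""

    ew_codes: list[ICDCode]
    therapies: frozenset[str] = THERAPIES
    source_label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.therapies) - THERAPIES
        if unknown:
            raise CodesetConfigError(f"unknown therapy identifiers: {sorted(unknown)}")
        # reuse the map machinery for prefix-aware code matching
        self._matcher = BleedTypeMap(
            [(c, Category.OTHER) for c in self.ew_codes], source_label=self.source_label
        )

    def matches_code(self, code: Union[str, ICDCode]) -> bool:
        return self._matcher.match(code) is not Category.NONE


def _parse_code_list(values: object, where: str) -> list[ICDCode]:
    if not isinstance(values, (list, tuple)):
        raise CodesetConfigError(f"{where}: expected a list of code strings")
    return [normalize_code(v) for v in values]


def load_codeset(path: Union[str, Path]) -> Union[BleedTypeMap, ScreenCodeSet]:
    """Load a codeset config (YAML or JSON-compatible YAML).

    An index map has keys ``intracranial`` / ``gastrointestinal`` / ``other``;
    a screen set has ``ew_codes`` and optionally ``therapies``.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return parse_codeset(raw, source_label=str(path))


def parse_codeset(raw: object, source_label: str = "") -> Union[BleedTypeMap, ScreenCodeSet]:
    if not isinstance(raw, dict) or not raw:
        raise CodesetConfigError(f"{source_label or 'codeset'}: empty or non-mapping config")
    index_keys = {"intracranial", "gastrointestinal", "other"}
    if index_keys & raw.keys():
        missing = index_keys - raw.keys()
        if missing:
            raise CodesetConfigError(f"{source_label}: missing categories {sorted(missing)}")
        entries: list[tuple[ICDCode, Category]] = []
        for key, cat in (
            ("intracranial", Category.ICH),
            ("gastrointestinal", Category.GI),
            ("other", Category.OTHER),
        ):
            entries.extend((c, cat) for c in _parse_code_list(raw[key], key))
        return BleedTypeMap(entries, source_label=source_label)
    if "ew_codes" in raw:
        codes = _parse_code_list(raw["ew_codes"], "ew_codes")
        therapies = frozenset(raw.get("therapies", sorted(THERAPIES)))
        return ScreenCodeSet(codes, therapies=therapies, source_label=source_label)
    raise CodesetConfigError(
        f"{source_label}: expected index-map keys {sorted(index_keys)} or screen key 'ew_codes'"
    )


def _data_path(name: str):
    return resources.files("bleedvalidate.data").joinpath(name)


def default_index_map() -> BleedTypeMap:
    """The packaged index code list: 7 intracranial, 22 gastrointestinal and
    23 other-bleeding ICD-10 primary discharge codes."""
    raw = yaml.safe_load(_data_path("index_codes.yaml").read_text())
    return parse_codeset(raw, source_label="packaged:index_codes.yaml")


def default_screen_set() -> ScreenCodeSet:
    """The packaged emergency-ward screen: index codes plus hemorrhage-related
    emergency-ward codes, and the six emergency therapies.

    The emergency-ward part of the list is a documented stand-in (the original
    screening request's code list is not public) and is replaceable via
    :func:`load_codeset`.
    """
    raw = yaml.safe_load(_data_path("screen_codes.yaml").read_text())
    return parse_codeset(raw, source_label="packaged:screen_codes.yaml")
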