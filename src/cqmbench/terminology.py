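"""Value sets and cross-terminology code mapping.

A value set is a named list of clinical codes that defines a concept for
measure logic (e.g. the two SNOMED-CT codes Synthea uses for COPD).
Because source data may be coded in ICD-10 or CPT while the EHR tables
use SNOMED-CT, a :class:`CodeMap` translates foreign codes; unmapped
codes never abort a run — they are recorded in a report.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterator, Mapping
from importlib import resources
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

SNOMED = "SNOMED-CT"
SYSTEMS = (SNOMED, "ICD-10", "CPT", "other")


class ConfigError(ValueError):
    """A configuration file is missing, malformed, or violates the schema."""


@dataclasses.dataclass(frozen=True)
class ValueSet:
    """A named, non-empty set of clinical codes from one coding system."""

    name: str
    system: str
    codes: frozenset[str]

    def __post_init__(self):
        if not self.codes:
            raise ConfigError(f"value set {self.name!r} is empty")
        if self.system not in SYSTEMS:
            raise ConfigError(f"value set {self.name!r}: unknown system {self.system!r}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


class CodeMap:
    """(source system, source code) -> set of SNOMED-CT codes; may be one-to-many.

    Lookups of codes already in SNOMED-CT are the identity.  Codes with no
    mapping translate to the empty set and are appended to
    :attr:`unmapped_report`.
    """

    def __init__(self, entries: Mapping[tuple[str, str], frozenset[str]] | None = None):
        self._entries: dict[tuple[str, str], frozenset[str]] = {
            (sys, code): frozenset(targets) for (sys, code), targets in (entries or {}).items()
        }
        self.unmapped_report: list[tuple[str, str]] = []

    def translate(self, system: str, code: str) -> frozenset[str]:
        if system == SNOMED:
            return frozenset({code})
        mapped = self._entries.get((system, code))
        if mapped is None:
            self.unmapped_report.append((system, code))
            return frozenset()
        return mapped

    def __len__(self) -> int:
        return len(self._entries)


def translate(code_map: CodeMap, system: str, code: str) -> frozenset[str]:
    """Map a source code to SNOMED-CT (identity for SNOMED input)."""
    return code_map.translate(system, code)


class ValueSetLibrary(Mapping):
    """Named value sets plus the code map loaded from one config file."""

    def __init__(self, valuesets: dict[str, ValueSet], codemap: CodeMap):
        self._valuesets = dict(valuesets)
        self.codemap = codemap

    def __getitem__(self, name: str) -> ValueSet:
        try:
            return self._valuesets[name]
        except KeyError:
            raise ConfigError(f"no value set named {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._valuesets)

    def __len__(self) -> int:
        return len(self._valuesets)

    def codes(self, *names: str) -> frozenset[str]:
        """Union of the codes of the named value sets."""
        out: set[str] = set()
        for name in names:
            out |= self[name].codes
        return frozenset(out)


def _default_config_text() -> str:
    return resources.files("cqmbench").joinpath("data/valuesets.yaml").read_text()


def load_valuesets(config_path=None) -> ValueSetLibrary:
    """Load value sets and the code map from YAML (shipped defaults if None).

    Schema: ``{valuesets: [{name, system, codes: [...]}],
    codemap: [{from_system, from_code, to_snomed: [...]}]}``.
    Duplicate codes inside one set are deduplicated with a warning; an
    empty set or an unknown system is a :class:`ConfigError`.
    """
    if config_path is None:
        text = _default_config_text()
        source = "<shipped defaults>"
    else:
        path = Path(config_path)
        if not path.exists():
            raise ConfigError(f"value-set config not found: {path}")
        text = path.read_text()
        source = str(path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{source}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "valuesets" not in doc:
        raise ConfigError(f"{source}: expected a mapping with a 'valuesets' list")

    valuesets: dict[str, ValueSet] = {}
    for i, entry in enumerate(doc["valuesets"]):
        try:
            name = str(entry["name"])
            system = str(entry["system"])
            raw_codes = [str(c) for c in entry["codes"]]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{source}: valuesets[{i}]: {exc!r}") from exc
        codes = frozenset(raw_codes)
        if len(codes) < len(raw_codes):
            log.warning("%s: value set %r contains duplicate codes; deduplicated", source, name)
        if name in valuesets:
            raise ConfigError(f"{source}: duplicate value set name {name!r}")
        valuesets[name] = ValueSet(name=name, system=system, codes=codes)

    entries: dict[tuple[str, str], frozenset[str]] = {}
    for i, entry in enumerate(doc.get("codemap") or []):
        try:
            key = (str(entry["from_system"]), str(entry["from_code"]))
            targets = frozenset(str(c) for c in entry["to_snomed"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{source}: codemap[{i}]: {exc!r}") from exc
        if not targets or any(not t.strip() for t in targets):
            raise ConfigError(f"{source}: codemap[{i}]: empty target code")
        entries[key] = entries.get(key, frozenset()) | targets
    return ValueSetLibrary(valuesets, CodeMap(entries))
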