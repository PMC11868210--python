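"""ICD-10 code normalization and include/exclude code-list matching.

Diagnosis codes in administrative registers arrive in mixed notations
("T40.1", "t401", SKS-dialect "DT401").  Everything downstream works on a
canonical form: uppercase, dot-free, optionally with the national "D"
prefix stripped.  Code lists are expressed as :class:`CodeSpec` objects
holding inclusive three-character ranges (``X60-X84``) and code prefixes
(``T39``), with optional exclusion prefixes (``T401``); matching is
prefix-closed, so ``X631`` matches ``X60-X84``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "InvalidCodeError",
    "normalize_code",
    "CodeSpec",
    "load_code_config",
    "default_code_config",
]

_ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]*$")
_BLOCK_PATTERN = re.compile(r"^([A-Z])([0-9]{2})$")


class InvalidCodeError(ValueError):
    """Raised for empty or non-alphanumeric diagnosis codes."""


def normalize_code(raw: str, strip_national_prefix: bool = False) -> str:
    """Return the canonical form of an ICD-10 code.

    Uppercases, removes dots and whitespace.  With ``strip_national_prefix``
    the Danish SKS "D" prefix is removed, but only when what follows is
    itself a plausible ICD-10 code (a chapter letter followed by two
    digits), so genuine D-chapter codes such as ``D12`` are untouched.
    Normalization is idempotent.
    """
    if raw is None:
        raise InvalidCodeError("missing diagnosis code")
    code = re.sub(r"[.\s]", "", str(raw)).upper()
    if not code:
        raise InvalidCodeError(f"empty diagnosis code: {raw!r}")
    if not code.isalnum():
        raise InvalidCodeError(f"non-alphanumeric diagnosis code: {raw!r}")
    if strip_national_prefix and code.startswith("D") and _ICD_PATTERN.match(code[1:]):
        code = code[1:]
    return code


def _parse_block(token: str) -> tuple[str, int]:
    m = _BLOCK_PATTERN.match(token)
    if m is None:
        raise ValueError(f"not a three-character ICD block: {token!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class CodeSpec:
    """A set of ICD-10 codes defined by include ranges/prefixes and exclude prefixes.

    ``includes`` entries are either inclusive ranges of three-character
    blocks ("X60-X84", both endpoints included) or plain prefixes ("T39").
    ``excludes`` entries are prefixes; a code matching any exclude never
    matches the spec, regardless of includes.
    """

    includes: tuple[str, ...]
    excludes: tuple[str, ...] = ()
    _ranges: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = field(
        init=False, repr=False, compare=False
    )
    _prefixes: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.includes:
            raise ValueError("CodeSpec requires at least one include entry")
        ranges = []
        prefixes = []
        for entry in self.includes:
            entry = normalize_code(entry) if "-" not in entry else entry
            if "-" in entry:
                lo_s, hi_s = (normalize_code(p) for p in entry.split("-", 1))
                lo, hi = _parse_block(lo_s), _parse_block(hi_s)
                if hi < lo:
                    raise ValueError(f"range end before start: {entry!r}")
                ranges.append((lo, hi))
            else:
                prefixes.append(entry)
        object.__setattr__(self, "_ranges", tuple(ranges))
        object.__setattr__(self, "_prefixes", tuple(prefixes))
        object.__setattr__(
            self, "excludes", tuple(normalize_code(e) for e in self.excludes)
        )

    def matches(self, code: str) -> bool:
        """True iff ``code`` (canonical form) belongs to this code set."""
        if any(code.startswith(exc) for exc in self.excludes):
            return False
        if any(code.startswith(pre) for pre in self._prefixes):
            return True
        if self._ranges:
            m = _BLOCK_PATTERN.match(code[:3])
            if m is not None:
                block = (m.group(1), int(m.group(2)))
                return any(lo <= block <= hi for lo, hi in self._ranges)
        return False

    def __contains__(self, code: str) -> bool:
        return self.matches(code)


@dataclass(frozen=True)
class CodeConfig:
    """The full ascertainment code configuration (suicide + definitions a-d)."""

    version: str
    suicide_cause: CodeSpec
    attempt_main_or_sub_a: CodeSpec  # definition (a): X-codes, main or supplementary
    attempt_main_b: CodeSpec  # definition (b): accidental intoxication main dx
    psychiatric_main: CodeSpec  # definitions (c)/(d): psychiatric main dx
    intoxication_sub_c: CodeSpec  # definition (c): intoxication sub-dx
    forearm_sub_d: CodeSpec  # definition (d): lower-forearm injury sub-dx


def _spec_from(node: dict) -> CodeSpec:
    return CodeSpec(
        includes=tuple(node["includes"]), excludes=tuple(node.get("excludes", ()))
    )


def load_code_config(mapping: dict) -> CodeConfig:
    """Build a :class:`CodeConfig` from a parsed YAML mapping."""
    defs = mapping["attempt_definitions"]
    return CodeConfig(
        version=str(mapping.get("version", "unversioned")),
        suicide_cause=_spec_from(mapping["suicide_cause"]),
        attempt_main_or_sub_a=_spec_from(defs["a"]["main_or_sub"]),
        attempt_main_b=_spec_from(defs["b"]["main"]),
        psychiatric_main=_spec_from(defs["c"]["main"]),
        intoxication_sub_c=_spec_from(defs["c"]["sub"]),
        forearm_sub_d=_spec_from(defs["d"]["sub"]),
    )


def default_code_config() -> CodeConfig:
    """The packaged code lists for the Danish probable-suicide-attempt algorithm."""
    text = resources.files("icecohort.data").joinpath("attempt_algorithm_codes.yaml").read_text()
    return load_code_config(yaml.safe_load(text))
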