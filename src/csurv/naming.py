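"""Object (variable) naming grammar.

A canonical variable name uniquely places a measurement in the dataspace of a
longitudinal study with four elements joined by underscores::

    COHORT_MEASUREMENT[q<item>]_<serial>_<wave>

* ``COHORT`` — exactly three alphabetic characters identifying the study
  (e.g. ``GEN`` for Generation Scotland).
* ``MEASUREMENT`` — an upper-case alphanumeric abbreviation of the measure
  (``PAINCHESTEVR`` for "Do you ever get pain or discomfort in your chest?").
  Lower-case characters are reserved for the constant markers ``q``
  (question/item), ``r`` (range) and ``d`` (decimal point), as in
  ``AVG08H00r08H59`` (average acceleration between 08h00 and 08h59).
  Survey abbreviations are limited to 12 characters; imaging, omics and
  device abbreviations to 17.  A measurement that can be either self-reported
  or formally diagnosed carries the suffix ``DX`` in its diagnosed form
  (``PTSD`` vs ``PTSDDX``).
* ``q<item>`` — optional questionnaire-item suffix (``SPQq1`` = item 1 of the
  Schizotypal Personality Questionnaire).
* ``serial`` — position within a run of repeat measurements inside one data
  capture period; ``0`` means the measurement was not repeated (``0`` and
  ``1`` are distinct states).
* ``wave`` — data-capture episode, 1-based (``1`` = recruitment).

Parsing is case-insensitive; formatting emits the canonical case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

from .errors import CohortCodeError, GrammarError, LengthError, NamingError

__all__ = [
    "MODALITIES",
    "LENGTH_LIMITS",
    "CONSTANT_MARKERS",
    "ObjectName",
    "parse_object_name",
    "format_object_name",
    "validate_abbreviation",
    "mark_diagnosed",
]

MODALITIES = ("survey", "imaging", "omics", "device")

#: Maximum measurement-abbreviation length per data modality.  The
#: questionnaire-item suffix ``q<digits>`` never counts toward the budget
#: (it is grammar, not abbreviation); a ``DX`` suffix does count by default.
LENGTH_LIMITS = {"survey": 12, "imaging": 17, "omics": 17, "device": 17}

#: The only characters that are lower-case in a canonical name.
CONSTANT_MARKERS = frozenset("qrd")

_COHORT_RE = re.compile(r"^[A-Za-z]{3}$")
_ITEM_RE = re.compile(r"[qQ](\d+)$")
_INT_RE = re.compile(r"^\d+$")


def _check_modality(modality: str) -> str:
    if modality not in LENGTH_LIMITS:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return modality


def _canonical_measurement(meas: str) -> str:
    """Upper-case a measurement while preserving constant markers.

    Markers are inferred only from MIXED-case input: a lower-case q/r/d amid
    upper-case characters is a marker and stays lower.  Single-cased input
    (all-lower or all-upper) carries no case information, so it is upper-cased
    wholesale — ``painchestevr`` canonicalises to ``PAINCHESTEVR`` even though
    it contains an ``r``.
    """
    has_lower = any(c.islower() for c in meas)
    has_upper = any(c.isupper() for c in meas)
    if has_lower and has_upper:
        return "".join(c if (c.islower() and c in CONSTANT_MARKERS) else c.upper() for c in meas)
    return meas.upper()


def abbreviation_length(measurement: str, *, count_q_suffix: bool = False) -> int:
    """Length of an abbreviation for the 12/17 budget.

    A trailing ``q<digits>`` item suffix is excluded unless *count_q_suffix*;
    everything else (including a ``DX`` suffix) counts.
    """
    if not count_q_suffix:
        measurement = _ITEM_RE.sub("", measurement)
    return len(measurement)


@dataclass(frozen=True)
class ObjectName:
    """Parsed form of a canonical variable name.

    Fields are canonicalised at construction (cohort/measurement case, marker
    preservation), so equality between two ObjectNames is the grammar's
    case-insensitive name equality.  Invalid combinations raise at
    construction: the type cannot hold an ungrammatical name.
    """

    cohort: str
    measurement: str
    serial: int
    wave: int
    item: int | None = None
    modality: str = "survey"
    diagnosed: bool = False

    def __post_init__(self) -> None:
        if not _COHORT_RE.match(self.cohort):
            raise CohortCodeError(
                f"cohort code must be exactly 3 alphabetic characters, got {self.cohort!r}"
            )
        object.__setattr__(self, "cohort", self.cohort.upper())
        _check_modality(self.modality)
        if not self.measurement:
            raise GrammarError("measurement abbreviation must be non-empty")
        canon = _canonical_measurement(self.measurement)
        violations = validate_abbreviation(canon, self.modality)
        if violations:
            exc = LengthError if any("length" in v for v in violations) else GrammarError
            raise exc(f"invalid measurement {self.measurement!r}: " + "; ".join(violations))
        if _ITEM_RE.search(canon):
            raise GrammarError(
                f"measurement {canon!r} ends in q<digits>, which is reserved for the "
                f"questionnaire-item suffix; pass item= instead"
            )
        object.__setattr__(self, "measurement", canon)
        if self.serial < 0:
            raise GrammarError(f"serial must be >= 0 (0 = unrepeated), got {self.serial}")
        if self.wave < 1:
            raise GrammarError(f"wave is 1-based (1 = recruitment), got {self.wave}")
        if self.item is not None and self.item < 1:
            raise GrammarError(f"item must be >= 1 when present, got {self.item}")
        if self.diagnosed and not canon.endswith("DX"):
            raise NamingError(
                f"diagnosed=True requires the measurement to end in DX, got {canon!r} "
                f"(use mark_diagnosed to append it)"
            )

    @property
    def name(self) -> str:
        return format_object_name(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_object_name(
    name: str,
    modality: str = "survey",
    *,
    diagnosed_exempt: bool = False,
) -> ObjectName:
    """Parse a variable name into its components.

    ``diagnosed_exempt`` suppresses the DX-suffix inference for the rare
    measurement that legitimately ends in the letters DX without the
    diagnostic meaning (such exemptions are declared in the mapping spec —
    the grammar alone cannot distinguish them).

    >>> parse_object_name("Gen_painchestevr_0_1").measurement
    'PAINCHESTEVR'
    >>> parse_object_name("GEN_SPQq1_0_1").item
    1
    """
    _check_modality(modality)
    if not name:
        raise GrammarError("empty name")
    tokens = name.split("_")
    if len(tokens) != 4:
        raise GrammarError(
            f"{name!r}: expected COHORT_MEASUREMENT_SERIAL_WAVE "
            f"(4 underscore-separated elements), got {len(tokens)}"
        )
    cohort_tok, meas_tok, serial_tok, wave_tok = tokens
    if not _COHORT_RE.match(cohort_tok):
        raise CohortCodeError(
            f"{name!r}: cohort code must be exactly 3 alphabetic characters, got {cohort_tok!r}"
        )
    if not _INT_RE.match(serial_tok):
        raise GrammarError(f"{name!r}: serial element {serial_tok!r} is not an integer")
    if not _INT_RE.match(wave_tok):
        raise GrammarError(f"{name!r}: wave element {wave_tok!r} is not an integer")
    if not meas_tok:
        raise GrammarError(f"{name!r}: empty measurement element")

    item: int | None = None
    m = _ITEM_RE.search(meas_tok)
    if m:
        item = int(m.group(1))
        if item < 1:
            raise GrammarError(f"{name!r}: questionnaire item must be >= 1, got q{m.group(1)}")
        meas_tok = meas_tok[: m.start()]
        if not meas_tok:
            raise GrammarError(f"{name!r}: measurement consists only of an item suffix")

    meas = _canonical_measurement(meas_tok)
    diagnosed = meas.endswith("DX") and not diagnosed_exempt

    limit = LENGTH_LIMITS[modality]
    if abbreviation_length(meas) > limit:
        raise LengthError(
            f"{name!r}: measurement {meas!r} is {len(meas)} characters; "
            f"the {modality} limit is {limit}"
        )
    return ObjectName(
        cohort=cohort_tok,
        measurement=meas,
        serial=int(serial_tok),
        wave=int(wave_tok),
        item=item,
        modality=modality,
        diagnosed=diagnosed,
    )


def format_object_name(parts: ObjectName) -> str:
    """Emit the canonical text form; inverse of :func:`parse_object_name`."""
    item = f"q{parts.item}" if parts.item is not None else ""
    return f"{parts.cohort}_{parts.measurement}{item}_{parts.serial}_{parts.wave}"


def validate_abbreviation(
    abbrev: str,
    modality: str = "survey",
    *,
    count_q_suffix: bool = False,
) -> list[str]:
    """Check a measurement abbreviation; returns violations (empty = valid).

    Checks the modality length limit (item suffix excluded by default) and the
    character set: alphanumeric, with lower-case restricted to the constant
    markers q, r and d.
    """
    _check_modality(modality)
    violations: list[str] = []
    if not abbrev:
        violations.append("empty abbreviation")
        return violations
    limit = LENGTH_LIMITS[modality]
    eff = abbreviation_length(abbrev, count_q_suffix=count_q_suffix)
    if eff > limit:
        violations.append(f"length {eff} exceeds the {modality} limit of {limit}")
    bad_chars = sorted({c for c in abbrev if not c.isalnum()})
    if bad_chars:
        violations.append(f"non-alphanumeric characters: {bad_chars}")
    bad_lower = sorted({c for c in abbrev if c.islower() and c not in CONSTANT_MARKERS})
    if bad_lower:
        violations.append(
            f"lower-case characters {bad_lower} are not constant markers "
            f"(only q, r, d may be lower-case)"
        )
    return violations


def mark_diagnosed(parts: ObjectName) -> ObjectName:
    """Append the DX suffix, flagging a formally diagnosed (rather than
    self-reported) measure; e.g. PTSD -> PTSDDX.

    Requires ``diagnosed`` to be false on input, and the suffixed abbreviation
    to still fit the modality's length budget.
    """
    if parts.diagnosed:
        raise NamingError(f"{parts.measurement!r} already carries the DX suffix")
    new_meas = parts.measurement + "DX"
    limit = LENGTH_LIMITS[parts.modality]
    if abbreviation_length(new_meas) > limit:
        raise LengthError(
            f"appending DX to {parts.measurement!r} gives {len(new_meas)} characters, "
            f"over the {parts.modality} limit of {limit}"
        )
    return replace(parts, measurement=new_meas, diagnosed=True)


def marker_positions(measurement: str) -> list[tuple[int, str]]:
    """0-based positions of constant markers (lower-case q/r/d) within a
    canonical measurement string."""
    return [(i, c) for i, c in enumerate(measurement) if c in CONSTANT_MARKERS and c.islower()]
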