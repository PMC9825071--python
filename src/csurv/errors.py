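"""Exception hierarchy.

Every error raised by the package derives from :class:`CSurvError`, so callers
(and the CLI) can distinguish validation failures (exit 1) from usage errors.
"""


class CSurvError(Exception):
    """Base class for all toolkit errors."""


# --- taxonomy -------------------------------------------------------------

class TaxonomyError(CSurvError):
    """Base class for taxonomy problems."""


class TaxonomyParseError(TaxonomyError):
    """The taxonomy document could not be parsed (malformed YAML/JSON or a
    missing/ill-typed key); the message names the offending key or line."""


class TaxonomyStructureError(TaxonomyError):
    """A structural invariant is violated (level skipping, nesting deeper than
    four, a non-leaf object node); the message names the node path."""


class DuplicateLabelError(TaxonomyError):
    """Two siblings carry the same (case-insensitive) label."""


class PathNotFoundError(TaxonomyError):
    """A node path does not resolve; carries the nearest candidate labels."""

    def __init__(self, message: str, candidates: tuple[str, ...] = ()):
        super().__init__(message)
        self.candidates = candidates


class AmbiguousPathError(TaxonomyError):
    """A partial node path matches more than one node."""


# --- naming ---------------------------------------------------------------

class NamingError(CSurvError):
    """Base class for object-name grammar problems."""


class GrammarError(NamingError):
    """The name does not fit the COHORT_MEASUREMENT_SERIAL_WAVE shape."""


class CohortCodeError(NamingError):
    """The cohort token is not exactly three alphabetic characters."""


class LengthError(NamingError):
    """A measurement abbreviation exceeds the modality's length limit."""


# --- recode ---------------------------------------------------------------

class RecodeError(CSurvError):
    """Base class for recoding problems."""


class RecodeConfigError(RecodeError):
    """A rule or value-label map is internally inconsistent (e.g. a code listed
    as both missing and non-response)."""


class GenderMapError(RecodeError):
    """No recognisable female/male labels; an explicit custom_map is needed."""


class UnitRegistryError(RecodeError):
    """Unknown source/target unit pair."""


class DatumError(RecodeError):
    """A cell could not be processed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


# --- curate / explorer ----------------------------------------------------

class MappingSpecError(CSurvError):
    """A mapping spec violates its own invariants (duplicate targets,
    inconsistent cohort codes, unresolvable taxonomy paths)."""


class CurationError(CSurvError):
    """Applying a mapping spec to a native table failed; the message lists
    every missing native variable when run in collect-all mode."""


class IntegrityError(CSurvError):
    """A curated dataset violates a dataset-level invariant (e.g. duplicate
    participant identifiers)."""


class FilterConfigError(CSurvError):
    """A funnel step's predicate is type-incompatible with its variable."""


class DegenerateScaleError(CSurvError):
    """A standardising transform was asked of a column with zero spread or
    fewer than two non-missing values."""


class SynthConfigError(CSurvError):
    """A synthetic-cohort configuration violates its invariants."""
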