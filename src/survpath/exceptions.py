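"""Exception hierarchy for survpath."""


class SurvpathError(Exception):
    """Base class for all survpath errors."""


class CohortFormatError(SurvpathError):
    """Interchange file is structurally malformed (e.g. a required column is missing)."""


class CohortIntegrityError(SurvpathError):
    """Cross-table referential problem (e.g. observations without an outcome row)."""


class CohortValidationError(SurvpathError):
    """A value violates a declared invariant (range, time window, event coding)."""


class ConfigurationError(SurvpathError):
    """A configuration object is incomplete or inconsistent (e.g. missing cutoff)."""


class ModelConstructionError(SurvpathError):
    """A model cannot be built from the given inputs (e.g. empty first slice)."""


class ScoringError(SurvpathError):
    """Prediction requested with incompatible inputs (e.g. a missing feature column)."""


class EvaluationError(SurvpathError):
    """An evaluation quantity is undefined for every resampling draw."""
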