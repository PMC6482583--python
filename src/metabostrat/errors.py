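"""Exception hierarchy shared across the package."""


class MetaboStratError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MetaboStratError):
    """A required column is missing or the column mapping is invalid."""


class CohortValidationError(MetaboStratError):
    """A cohort table violates an invariant (bad value, duplicate id, unknown subtype)."""


class DegenerateTrainingError(MetaboStratError):
    """The training set lacks the classes needed to fit the classifier."""


class UndefinedMetricError(MetaboStratError):
    """A performance metric is undefined on this validation set (e.g. no cancer samples)."""


class UndefinedNormalizationError(MetaboStratError):
    """Relative mutual information is undefined: the reference labelling has zero entropy."""


class EstimationError(MetaboStratError):
    """Cross-validation produced no valid realisations."""


class QuantificationError(MetaboStratError):
    """Internal-standard quantification failed (nonpositive corrected standard area)."""


class QuantificationRangeWarning(UserWarning):
    """A quantified concentration falls outside the validated assay range."""
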