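"""Cohort data structures and delimited-text I/O.

The pipeline operates on per-sample biomarker tables.  Each record carries a
circulating formate concentration (mM), a glucose signal (integrated
mass-spectrometry peak area, arbitrary units) and, optionally, further
metabolite intensities.  Samples are annotated with one of five study
subtypes, which collapse onto three merged classes used by the classifiers:

=========  ==========================================  ============
subtype    description                                 merged class
=========  ==========================================  ============
H          healthy control                             h
BC         breast cancer                               c
LC         lung cancer                                 c
ODminus    severe obesity without type 2 diabetes      o
ODplus     severe obesity with type 2 diabetes         o
=========  ==========================================  ============

Glucose is deliberately kept in raw peak-area units: the decision thresholds
the downstream classifiers report live on that scale, and converting to molar
units would require an external calibration the tables do not carry.

Files are CSV with a header row (UTF-8, decimal point).  Columns are
addressed by header name, never by position; the default header names are in
:data:`DEFAULT_SCHEMA` and can be remapped per file.  Extra metabolite
columns are preserved; empty cells there mean "not measured" and are
permitted, whereas a missing or non-numeric formate or glucose value is a
hard row-level error, because the core classifiers cannot run without them.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

#: The five study subtypes, in canonical display order.
SUBTYPES: tuple[str, ...] = ("H", "BC", "LC", "ODminus", "ODplus")

#: Merged class labels: healthy / cancer / obesity.
MERGED_CLASSES: tuple[str, ...] = ("h", "c", "o")

_SUBTYPE_TO_MERGED = {"H": "h", "BC": "c", "LC": "c", "ODminus": "o", "ODplus": "o"}

#: Logical field -> default CSV header name.
DEFAULT_SCHEMA: dict[str, str] = {
    "sample_id": "sample_id",
    "subtype": "subtype",
    "formate": "formate_mM",
    "glucose": "glucose_area",
}


def merge_class(subtype: str) -> str:
    """Collapse a study subtype onto its merged class.

    BC and LC map to ``c`` (cancer), ODminus and ODplus to ``o`` (obesity),
    H to ``h`` (healthy).  Raises :class:`CohortValidationError` for anything
    outside the five-subtype enumeration.
    """
    try:
        return _SUBTYPE_TO_MERGED[subtype]
    except KeyError:
        raise CohortValidationError(
            f"unknown subtype {subtype!r}; expected one of {SUBTYPES}"
        ) from None


def _check_biomarker(name: str, value: float, sample_id: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise CohortValidationError(
            f"sample {sample_id!r}: {name} must be a finite nonnegative number, got {value!r}"
        )
    return value


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One sample: id, subtype, the two core biomarkers and optional extras.

    ``formate`` is in mM; ``glucose`` in peak-area units.  ``extra`` maps
    metabolite name to a nonnegative intensity; absent keys mean the
    metabolite was not measured for this sample.
    """

    sample_id: str
    subtype: str
    formate: float
    glucose: float
    extra: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in _SUBTYPE_TO_MERGED:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: unknown subtype {self.subtype!r}; "
                f"expected one of {SUBTYPES}"
            )
        object.__setattr__(
            self, "formate", _check_biomarker("formate", self.formate, self.sample_id)
        )
        object.__setattr__(
            self, "glucose", _check_biomarker("glucose", self.glucose, self.sample_id)
        )
        extra = dict(self.extra)
        for name, value in extra.items():
            extra[name] = _check_biomarker(name, value, self.sample_id)
        object.__setattr__(self, "extra", extra)

    @property
    def merged_class(self) -> str:
        return _SUBTYPE_TO_MERGED[self.subtype]


class CohortTable:
    """An ordered, validated collection of :class:`SampleRecord`.

    Sample ids are unique.  The merged h/c/o view is always derived from the
    subtype column, never stored independently, so the two can not drift.
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self._records: tuple[SampleRecord, ...] = tuple(records)
        ids = [r.sample_id for r in self._records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise CohortValidationError(f"duplicate sample ids: {dupes}")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, i: int) -> SampleRecord:
        return self._records[i]

    @property
    def records(self) -> tuple[SampleRecord, ...]:
        return self._records

    # -- column views -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self._records]

    @property
    def subtypes(self) -> np.ndarray:
        return np.array([r.subtype for r in self._records], dtype=object)

    @property
    def formate(self) -> np.ndarray:
        return np.array([r.formate for r in self._records], dtype=float)

    @property
    def glucose(self) -> np.ndarray:
        return np.array([r.glucose for r in self._records], dtype=float)

    @property
    def merged(self) -> np.ndarray:
        """Per-record merged class label in {h, c, o}."""
        return np.array([r.merged_class for r in self._records], dtype=object)

    @property
    def extra_names(self) -> list[str]:
        names: set[str] = set()
        for r in self._records:
            names.update(r.extra)
        return sorted(names)

    def extra(self, name: str) -> np.ndarray:
        """Values of one extra metabolite, NaN where not measured."""
        return np.array(
            [r.extra.get(name, math.nan) for r in self._records], dtype=float
        )

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in MERGED_CLASSES}
        for r in self._records:
            counts[r.merged_class] += 1
        return counts

    def subtype_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SUBTYPES}
        for r in self._records:
            counts[r.subtype] += 1
        return counts

    # -- subsetting ---------------------------------------------------------

    def subset(self, index) -> "CohortTable":
        """New cohort from a boolean mask or an integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortTable(self._records[i] for i in index)

    def restrict(self, classes: Iterable[str]) -> "CohortTable":
        """Samples whose merged class is in ``classes``."""
        wanted = set(classes)
        return CohortTable(r for r in self._records if r.merged_class in wanted)

    # -- frame conversion ---------------------------------------------------

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        schema = dict(DEFAULT_SCHEMA, **(schema or {}))
        data: dict[str, list] = {
            schema["sample_id"]: self.sample_ids,
            schema["subtype"]: [r.subtype for r in self._records],
            schema["formate"]: [r.formate for r in self._records],
            schema["glucose"]: [r.glucose for r in self._records],
        }
        for name in self.extra_names:
            data[name] = [r.extra.get(name, math.nan) for r in self._records]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: Mapping[str, str] | None = None
    ) -> "CohortTable":
        schema = dict(DEFAULT_SCHEMA, **(schema or {}))
        missing = [col for col in schema.values() if col not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        core = set(schema.values())
        extra_cols = [c for c in frame.columns if c not in core]

        records: list[SampleRecord] = []
        problems: list[str] = []
        for _, row in frame.iterrows():
            sample_id = str(row[schema["sample_id"]])
            try:
                extras: dict[str, float] = {}
                for col in extra_cols:
                    raw = row[col]
                    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                        continue  # not measured
                    try:
                        extras[col] = float(raw)
                    except (TypeError, ValueError):
                        raise CohortValidationError(
                            f"sample {sample_id!r}: non-numeric value {raw!r} for {col!r}"
                        ) from None
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        subtype=str(row[schema["subtype"]]),
                        formate=_parse_number(
                            row[schema["formate"]], "formate", sample_id
                        ),
                        glucose=_parse_number(
                            row[schema["glucose"]], "glucose", sample_id
                        ),
                        extra=extras,
                    )
                )
            except CohortValidationError as exc:
                problems.append(str(exc))
        if problems:
            raise CohortValidationError("; ".join(problems))
        return cls(records)


def _parse_number(raw, name: str, sample_id: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"sample {sample_id!r}: non-numeric {name} value {raw!r}"
        ) from None
    if math.isnan(value):
        raise CohortValidationError(f"sample {sample_id!r}: missing {name} value")
    return value


def read_cohort(path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV.

    ``schema`` remaps logical field names (``sample_id``, ``subtype``,
    ``formate``, ``glucose``) to header names for files that use different
    headers.  Extra numeric columns become per-sample extra metabolites.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    return CohortTable.from_frame(frame, schema=schema)


def write_cohort(
    cohort: CohortTable, path, schema: Mapping[str, str] | None = None
) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips exactly.

    Floats are serialised at full repr precision so numeric columns survive a
    write/read cycle bit-identically.
    """
    cohort.to_frame(schema=schema).to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class ClassAssignment:
    """Imputed labels for a sample set, with classifier provenance.

    ``labels`` holds one imputed merged-class label per sample id, drawn from
    {h, c, o}; ``provenance`` records which classifier and thresholds
    produced the assignment.
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.sample_ids) != len(self.labels):
            raise CohortValidationError("one imputed label per sample is required")
        bad = sorted({l for l in self.labels if l not in MERGED_CLASSES})
        if bad:
            raise CohortValidationError(f"imputed labels outside {{h,c,o}}: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array(self.labels, dtype=object)
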