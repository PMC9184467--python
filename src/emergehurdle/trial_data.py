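"""Data model, I/O and validation for emergence-trial datasets.

One :class:`TrialRecord` is a single trial of a single individual: did it
emerge within the observation window, and if so, after how many seconds.
A :class:`Dataset` is an ordered collection of records plus a derived
per-individual index.  Files are plain CSV with a header; column names and
categorical codings are configurable through :class:`TableDialect` so that
externally deposited files with arbitrary headers can be read without
touching the code.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

__all__ = [
    "Group",
    "Sex",
    "TrialRecord",
    "Dataset",
    "IndividualInfo",
    "TableDialect",
    "Violation",
    "ValidationReport",
    "FormatError",
    "read_trials",
    "write_trials",
    "validate_dataset",
    "load_dialect",
]

#: Inclusive latency bounds implied by a 600 s observation window: emergence
#: is recorded in whole seconds from 1 to 599; at >= 600 s the window has
#: closed and the trial is recorded as "did not emerge".
LATENCY_MIN = 1.0
LATENCY_MAX = 599.0


class Group(str, enum.Enum):
    """Treatment group of an individual."""

    VIRUS_FREE = "virus_free"
    INFECTED = "infected"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class FormatError(ValueError):
    """Raised when an input table cannot be mapped onto trial records."""


@dataclass(frozen=True)
class TrialRecord:
    """A single experimental trial of one individual.

    Parameters
    ----------
    individual_id
        Opaque identifier, unique per animal.
    group
        Treatment group.
    sex
        Sex if known; ``None`` is tolerated at read time and only rejected
        by sex-disaggregated summaries.
    trial_index
        The individual's cumulative experience count (1, 2, 3, ...), not a
        calendar date.
    emerged
        Whether the animal left the shelter within the observation window.
    latency_s
        Seconds until emergence; present iff ``emerged``.
    """

    individual_id: str
    group: Group
    sex: Optional[Sex]
    trial_index: int
    emerged: bool
    latency_s: Optional[float] = None


@dataclass(frozen=True)
class IndividualInfo:
    group: Group
    sex: Optional[Sex]
    trial_indices: frozenset[int]


class Dataset:
    """Ordered collection of :class:`TrialRecord` with a per-individual index.

    The record order of the source is preserved; ``individuals`` maps each
    ``individual_id`` to its (group, sex, trial indices), using the first
    record's group/sex (inconsistencies are reported by
    :func:`validate_dataset`, not hidden here).
    """

    def __init__(self, records: Iterable[TrialRecord]):
        self.records: list[TrialRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Dataset({len(self.records)} records, "
            f"{len(self.individuals)} individuals)"
        )

    @property
    def individuals(self) -> dict[str, IndividualInfo]:
        index: dict[str, dict] = {}
        for rec in self.records:
            entry = index.setdefault(
                rec.individual_id,
                {"group": rec.group, "sex": rec.sex, "trials": set()},
            )
            entry["trials"].add(rec.trial_index)
        return {
            iid: IndividualInfo(e["group"], e["sex"], frozenset(e["trials"]))
            for iid, e in index.items()
        }

    @property
    def groups(self) -> list[Group]:
        """Groups present, in order of first appearance."""
        seen: list[Group] = []
        for rec in self.records:
            if rec.group not in seen:
                seen.append(rec.group)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "group": rec.group.value,
                    "sex": rec.sex.value if rec.sex is not None else "",
                    "trial": rec.trial_index,
                    "emerged": int(rec.emerged),
                    "latency_s": rec.latency_s,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["individual_id", "group", "sex", "trial", "emerged", "latency_s"],
        )


# ---------------------------------------------------------------------------
# Table dialect
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "group": "group",
    "sex": "sex",
    "trial_index": "trial",
    "emerged": "emerged",
    "latency_s": "latency_s",
}

_DEFAULT_GROUP_VALUES = {
    "virus_free": Group.VIRUS_FREE,
    "virus-free": Group.VIRUS_FREE,
    "infected": Group.INFECTED,
}

_DEFAULT_SEX_VALUES = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
}

_TRUE_VALUES = {"1", "true", "yes", "y", "t"}
_FALSE_VALUES = {"0", "false", "no", "n", "f"}


@dataclass
class TableDialect:
    """CSV dialect: column-name mapping and categorical value codings.

    ``columns`` maps the canonical field names (``individual_id``, ``group``,
    ``sex``, ``trial_index``, ``emerged``, ``latency_s``) to the header names
    used in the file.  ``group_values`` / ``sex_values`` map cell strings
    (lower-cased) to the canonical enums.
    """

    columns: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    group_values: dict[str, Group] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_VALUES)
    )
    sex_values: dict[str, Sex] = field(default_factory=lambda: dict(_DEFAULT_SEX_VALUES))
    delimiter: str = ","

    def merged_columns(self) -> dict[str, str]:
        cols = dict(_DEFAULT_COLUMNS)
        cols.update(self.columns)
        return cols


def load_dialect(path: Union[str, Path]) -> TableDialect:
    """Load a :class:`TableDialect` from a YAML config file.

    Recognised keys: ``columns`` (mapping), ``group_values`` (mapping of cell
    string to ``virus_free``/``infected``), ``sex_values`` (mapping of cell
    string to ``male``/``female``) and ``delimiter``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    dialect = TableDialect()
    if "columns" in cfg:
        dialect.columns.update({str(k): str(v) for k, v in cfg["columns"].items()})
    if "group_values" in cfg:
        dialect.group_values.update(
            {str(k).lower(): Group(v) for k, v in cfg["group_values"].items()}
        )
    if "sex_values" in cfg:
        dialect.sex_values.update(
            {str(k).lower(): Sex(v) for k, v in cfg["sex_values"].items()}
        )
    if "delimiter" in cfg:
        dialect.delimiter = str(cfg["delimiter"])
    return dialect


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _parse_bool(raw: str, row: int, column: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUE_VALUES:
        return True
    if s in _FALSE_VALUES:
        return False
    raise FormatError(f"row {row}: cannot parse {column}={raw!r} as boolean")


def read_trials(
    path: Union[str, Path], dialect: Optional[TableDialect] = None
) -> Dataset:
    """Read a delimited trial table into a :class:`Dataset`.

    Row order is preserved.  Structural problems (missing columns,
    unparseable cells) raise :class:`FormatError`; rule violations such as
    out-of-bounds latencies are left to :func:`validate_dataset`.
    """
    dialect = dialect or TableDialect()
    cols = dialect.merged_columns()
    try:
        frame = pd.read_csv(
            path, sep=dialect.delimiter, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc

    for canonical, name in cols.items():
        if canonical == "sex":
            continue  # optional column
        if name not in frame.columns:
            raise FormatError(
                f"{path}: missing required column {name!r} (maps to {canonical})"
            )
    has_sex = cols["sex"] in frame.columns

    records: list[TrialRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        row_map = dict(zip(frame.columns, row))
        iid = str(row_map[cols["individual_id"]]).strip()
        if not iid:
            raise FormatError(f"row {pos}: empty individual id")

        raw_group = str(row_map[cols["group"]]).strip().lower()
        if raw_group not in dialect.group_values:
            raise FormatError(f"row {pos}: unknown group value {raw_group!r}")
        group = dialect.group_values[raw_group]

        sex: Optional[Sex] = None
        if has_sex:
            raw_sex = str(row_map[cols["sex"]]).strip().lower()
            if raw_sex:
                if raw_sex not in dialect.sex_values:
                    raise FormatError(f"row {pos}: unknown sex value {raw_sex!r}")
                sex = dialect.sex_values[raw_sex]

        raw_trial = str(row_map[cols["trial_index"]]).strip()
        try:
            trial_index = int(raw_trial)
        except ValueError as exc:
            raise FormatError(
                f"row {pos}: cannot parse trial index {raw_trial!r} as integer"
            ) from exc

        emerged = _parse_bool(str(row_map[cols["emerged"]]), pos, cols["emerged"])

        raw_lat = str(row_map[cols["latency_s"]]).strip()
        latency: Optional[float] = None
        if raw_lat not in ("", "na", "NA", "NaN", "nan"):
            try:
                latency = float(raw_lat)
            except ValueError as exc:
                raise FormatError(
                    f"row {pos}: cannot parse latency {raw_lat!r} as number"
                ) from exc

        records.append(
            TrialRecord(
                individual_id=iid,
                group=group,
                sex=sex,
                trial_index=trial_index,
                emerged=emerged,
                latency_s=latency,
            )
        )
    return Dataset(records)


def _format_latency(value: Optional[float]) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_trials(ds: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset as CSV using the default dialect.

    Round-trip property: ``read_trials(write_trials(ds))`` reproduces ``ds``
    record for record.  Latencies that are whole numbers are written as
    integers, others with full ``repr`` precision.
    """
    path = Path(path)
    lines = ["individual_id,group,sex,trial,emerged,latency_s"]
    for rec in ds.records:
        lines.append(
            ",".join(
                [
                    rec.individual_id,
                    rec.group.value,
                    rec.sex.value if rec.sex is not None else "",
                    str(rec.trial_index),
                    "1" if rec.emerged else "0",
                    _format_latency(rec.latency_s),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One validation failure.

    ``record_index`` is the 0-based position in ``Dataset.records`` or
    ``None`` for dataset-level rules.  ``rule`` is a stable identifier so
    tests and callers can match on it.
    """

    rule: str
    message: str
    record_index: Optional[int] = None


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def rules(self) -> set[str]:
        return {v.rule for v in self.violations}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "ValidationReport(ok)"
        return f"ValidationReport({len(self.violations)} violations)"


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check every record and dataset invariant, reporting all violations.

    Rules
    -----
    ``latency_bounds``       emerged latency outside [1, 599]
    ``latency_missing``      emerged record without a latency
    ``latency_unexpected``   non-emerged record with a latency
    ``trial_index_positive`` trial index < 1
    ``duplicate_trial``      same (individual, trial index) twice
    ``inconsistent_group``   one individual with two groups
    ``inconsistent_sex``     one individual with two non-missing sexes
    """
    report = ValidationReport()
    seen_trials: dict[str, set[int]] = {}
    group_of: dict[str, Group] = {}
    sex_of: dict[str, Sex] = {}
    flagged_group: set[str] = set()
    flagged_sex: set[str] = set()

    for idx, rec in enumerate(ds.records):
        if rec.emerged:
            if rec.latency_s is None:
                report.violations.append(
                    Violation(
                        "latency_missing",
                        f"record {idx} ({rec.individual_id}, trial "
                        f"{rec.trial_index}): emerged without a latency",
                        idx,
                    )
                )
            elif not (LATENCY_MIN <= rec.latency_s <= LATENCY_MAX):
                report.violations.append(
                    Violation(
                        "latency_bounds",
                        f"record {idx} ({rec.individual_id}, trial "
                        f"{rec.trial_index}): latency out of bounds "
                        f"({rec.latency_s} not in [{LATENCY_MIN:g}, "
                        f"{LATENCY_MAX:g}])",
                        idx,
                    )
                )
        elif rec.latency_s is not None:
            report.violations.append(
                Violation(
                    "latency_unexpected",
                    f"record {idx} ({rec.individual_id}, trial "
                    f"{rec.trial_index}): latency present but not emerged",
                    idx,
                )
            )

        if rec.trial_index < 1:
            report.violations.append(
                Violation(
                    "trial_index_positive",
                    f"record {idx} ({rec.individual_id}): trial index "
                    f"{rec.trial_index} < 1",
                    idx,
                )
            )

        trials = seen_trials.setdefault(rec.individual_id, set())
        if rec.trial_index in trials:
            report.violations.append(
                Violation(
                    "duplicate_trial",
                    f"record {idx}: duplicate trial index {rec.trial_index} "
                    f"for individual {rec.individual_id}",
                    idx,
                )
            )
        trials.add(rec.trial_index)

        prev_group = group_of.setdefault(rec.individual_id, rec.group)
        if rec.group != prev_group and rec.individual_id not in flagged_group:
            report.violations.append(
                Violation(
                    "inconsistent_group",
                    f"record {idx}: individual {rec.individual_id} appears in "
                    f"both {prev_group.value} and {rec.group.value}",
                    idx,
                )
            )
            flagged_group.add(rec.individual_id)

        if rec.sex is not None:
            prev_sex = sex_of.setdefault(rec.individual_id, rec.sex)
            if rec.sex != prev_sex and rec.individual_id not in flagged_sex:
                report.violations.append(
                    Violation(
                        "inconsistent_sex",
                        f"record {idx}: individual {rec.individual_id} "
                        f"recorded as both {prev_sex.value} and "
                        f"{rec.sex.value}",
                        idx,
                    )
                )
                flagged_sex.add(rec.individual_id)

    return report
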