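"""Data model, validation and I/O for ordinal phenotype score tables.

A *phenotypic vector* holds 12 ordinal scores (0-3), six general-morphology
parameters followed by six segmentation parameters, describing how treated
embryos differ from untreated controls of the same genotype.  Score tables
are long-format TSV files with one row per (compound, concentration,
experiment) treatment; embryo-level tables additionally carry one row per
embryo and are reduced to well vectors by consensus calling.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import (
    DuplicateTreatmentError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MORPHOLOGY_CODES = ("E", "H", "Y", "D", "A", "T")
SEGMENTATION_CODES = ("S", "BD", "AD", "TD", "PD", "BS")

#: Canonical experiment order: two wild-type replicates, then the two mutants.
EXPERIMENTS = ("wt_A", "wt_B", "her1", "hes6")
WILD_TYPE_EXPERIMENTS = ("wt_A", "wt_B")

METADATA_COLUMNS = (
    "compound_id",
    "plate",
    "well",
    "concentration_uM",
    "experiment",
    "lethal",
    "n_embryos",
    "n_scoreable",
)


def format_concentration(value: float) -> str:
    """Canonical text form of a concentration (integers without '.0')."""
    f = float(value)
    if f == int(f):
        return str(int(f))
    return repr(f)


@dataclass(frozen=True)
class ParameterSchema:
    """Fixed ordering of the 6 morphology + 6 segmentation parameter codes."""

    morphology_codes: tuple = MORPHOLOGY_CODES
    segmentation_codes: tuple = SEGMENTATION_CODES
    max_score: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "morphology_codes", tuple(self.morphology_codes))
        object.__setattr__(self, "segmentation_codes", tuple(self.segmentation_codes))
        if len(self.morphology_codes) != 6 or len(self.segmentation_codes) != 6:
            raise ValidationError(
                "schema requires exactly 6 morphology and 6 segmentation codes"
            )
        codes = self.morphology_codes + self.segmentation_codes
        if len(set(codes)) != len(codes):
            raise ValidationError("parameter codes must be distinct")
        if self.max_score < 1:
            raise ValidationError("max_score must be >= 1")

    @property
    def codes(self) -> tuple:
        return self.morphology_codes + self.segmentation_codes

    @property
    def n_parameters(self) -> int:
        return len(self.codes)


DEFAULT_SCHEMA = ParameterSchema()


def _coerce_score(value, max_score: int):
    """Coerce one score to int; raise ValidationError for anything non-ordinal."""
    if isinstance(value, bool):
        raise ValidationError(f"score must be an integer, got bool {value!r}")
    if isinstance(value, float) or isinstance(value, np.floating):
        if not float(value).is_integer():
            raise ValidationError(f"score must be an integer, got {value!r}")
        value = int(value)
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"score must be an integer, got {value!r}") from None
    if not 0 <= iv <= max_score:
        raise ValidationError(f"score {iv} outside [0, {max_score}]")
    return iv


@dataclass(frozen=True)
class PhenotypicVector:
    """The 12 ordinal parameter scores of one treatment, morphology half first."""

    scores: tuple
    schema: ParameterSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        schema = self.schema
        scores = tuple(_coerce_score(s, schema.max_score) for s in self.scores)
        if len(scores) != schema.n_parameters:
            raise ValidationError(
                f"vector has {len(scores)} scores, expected {schema.n_parameters}"
            )
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, int], schema: ParameterSchema = DEFAULT_SCHEMA
    ) -> "PhenotypicVector":
        missing = [c for c in schema.codes if c not in mapping]
        if missing:
            raise ValidationError(f"missing scores for codes: {missing}")
        return cls(tuple(mapping[c] for c in schema.codes), schema)

    def __getitem__(self, code: str) -> int:
        return self.scores[self.schema.codes.index(code)]

    def as_dict(self) -> dict:
        return dict(zip(self.schema.codes, self.scores))

    @property
    def morphology_scores(self) -> tuple:
        return self.scores[: len(self.schema.morphology_codes)]

    @property
    def segmentation_scores(self) -> tuple:
        return self.scores[len(self.schema.morphology_codes):]

    @property
    def is_constant(self) -> bool:
        return len(set(self.scores)) == 1

    @property
    def any_defect(self) -> bool:
        return any(s > 0 for s in self.scores)


@dataclass(frozen=True)
class TreatmentRecord:
    """One scored treatment: metadata plus an optional phenotypic vector.

    An absent vector means *unscored* and is distinct from an all-zero vector
    (scored, indistinguishable from control).
    """

    compound_id: str
    concentration: float
    experiment: str
    plate: str = ""
    well: str = ""
    lethal: bool = False
    n_embryos: int = 5
    n_scoreable: int = 5
    vector: Optional[PhenotypicVector] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentration", float(self.concentration))
        if self.n_embryos < 0 or self.n_scoreable < 0:
            raise ValidationError("embryo counts must be >= 0")
        if self.n_scoreable > self.n_embryos:
            raise ValidationError(
                f"n_scoreable ({self.n_scoreable}) > n_embryos ({self.n_embryos})"
            )
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")

    @property
    def key(self) -> tuple:
        return (self.compound_id, self.concentration, self.experiment)

    @property
    def treatment_id(self) -> str:
        return (
            f"{self.compound_id}@{format_concentration(self.concentration)}"
            f"@{self.experiment}"
        )

    @property
    def analyzable(self) -> bool:
        return (not self.lethal) and self.vector is not None


def _experiment_sort_key(name: str):
    try:
        return (0, EXPERIMENTS.index(name))
    except ValueError:
        return (1, name)


@dataclass(frozen=True)
class ScreenTable:
    """A full screen: a deterministic, duplicate-free sequence of records.

    Records are stored sorted by (compound_id, concentration, experiment)
    so that every downstream ranking or clustering tie-break is reproducible.
    """

    records: tuple
    schema: ParameterSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        recs = tuple(
            sorted(
                self.records,
                key=lambda r: (
                    r.compound_id,
                    r.concentration,
                    _experiment_sort_key(r.experiment),
                ),
            )
        )
        seen = set()
        for r in recs:
            if r.key in seen:
                raise DuplicateTreatmentError(
                    f"duplicate treatment {r.key!r}"
                )
            seen.add(r.key)
        object.__setattr__(self, "records", recs)

    def __iter__(self) -> Iterator[TreatmentRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compounds(self) -> tuple:
        return tuple(sorted({r.compound_id for r in self.records}))

    @property
    def concentrations(self) -> tuple:
        return tuple(sorted({r.concentration for r in self.records}))

    @property
    def experiments(self) -> tuple:
        return tuple(
            sorted({r.experiment for r in self.records}, key=_experiment_sort_key)
        )

    def get(
        self, compound_id: str, concentration: float, experiment: str
    ) -> Optional[TreatmentRecord]:
        key = (compound_id, float(concentration), experiment)
        for r in self.records:  # table sizes are small; linear scan is fine
            if r.key == key:
                return r
        return None

    def subset(
        self,
        experiment: Optional[str] = None,
        concentration: Optional[float] = None,
    ) -> "ScreenTable":
        recs = [
            r
            for r in self.records
            if (experiment is None or r.experiment == experiment)
            and (concentration is None or r.concentration == float(concentration))
        ]
        return ScreenTable(records=tuple(recs), schema=self.schema)

    def analyzable_records(self) -> tuple:
        return tuple(r for r in self.records if r.analyzable)

    def record_map(self) -> dict:
        """Map treatment_id -> record."""
        return {r.treatment_id: r for r in self.records}

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "compound_id": r.compound_id,
                "plate": r.plate,
                "well": r.well,
                "concentration_uM": r.concentration,
                "experiment": r.experiment,
                "lethal": int(r.lethal),
                "n_embryos": r.n_embryos,
                "n_scoreable": r.n_scoreable,
            }
            for code in self.schema.codes:
                row[code] = r.vector[code] if r.vector is not None else None
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        save_score_table(self, path)


def _check_header(header: Sequence[str], schema: ParameterSchema) -> None:
    expected = list(METADATA_COLUMNS) + list(schema.codes)
    counts = {}
    for col in header:
        counts[col] = counts.get(col, 0) + 1
    for col in expected:
        if counts.get(col, 0) == 0:
            raise FormatError(f"missing column {col!r}")
        if counts[col] > 1:
            raise FormatError(f"duplicated column {col!r}")
    unknown = [c for c in header if c not in expected and c != "embryo_index"]
    if unknown:
        raise FormatError(f"unknown columns: {unknown}")


def _parse_bool(text: str, row: int, column: str) -> bool:
    t = text.strip().lower()
    if t in ("0", "false"):
        return False
    if t in ("1", "true"):
        return True
    raise ValidationError(f"row {row}: column {column!r} must be 0/1, got {text!r}")


def _parse_int(text: str, row: int, column: str) -> int:
    try:
        return int(text.strip())
    except ValueError:
        raise ValidationError(
            f"row {row}: column {column!r} must be an integer, got {text!r}"
        ) from None


def _parse_scores(
    cells: Mapping[str, str], schema: ParameterSchema, row: int
) -> Optional[PhenotypicVector]:
    raw = {c: cells[c].strip() for c in schema.codes}
    if any(v == "" for v in raw.values()):
        # A row with any blank score cell is treated as unscored.
        return None
    scores = []
    for code in schema.codes:
        text = raw[code]
        try:
            value = int(text)
        except ValueError:
            raise ValidationError(
                f"row {row}: score in column {code!r} must be an integer, "
                f"got {text!r}"
            ) from None
        if not 0 <= value <= schema.max_score:
            raise ValidationError(
                f"row {row}: score {value} in column {code!r} outside "
                f"[0, {schema.max_score}]"
            )
        scores.append(value)
    return PhenotypicVector(tuple(scores), schema)


def load_score_table(
    path, schema: ParameterSchema = DEFAULT_SCHEMA
) -> ScreenTable:
    """Load a treatment-level score TSV into a validated ScreenTable."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        _check_header(header, schema)
        records = []
        for i, row in enumerate(reader, start=1):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"row {i}: expected {len(header)} fields, got {len(row)}"
                )
            cells = dict(zip(header, row))
            vector = _parse_scores(cells, schema, i)
            records.append(
                TreatmentRecord(
                    compound_id=cells["compound_id"].strip(),
                    plate=cells["plate"].strip(),
                    well=cells["well"].strip(),
                    concentration=float(cells["concentration_uM"]),
                    experiment=cells["experiment"].strip(),
                    lethal=_parse_bool(cells["lethal"], i, "lethal"),
                    n_embryos=_parse_int(cells["n_embryos"], i, "n_embryos"),
                    n_scoreable=_parse_int(cells["n_scoreable"], i, "n_scoreable"),
                    vector=vector,
                )
            )
    return ScreenTable(records=tuple(records), schema=schema)


def save_score_table(table: ScreenTable, path) -> None:
    """Write a ScreenTable in canonical (normalized) TSV form."""
    path = Path(path)
    header = list(METADATA_COLUMNS) + list(table.schema.codes)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in table.records:
            row = [
                r.compound_id,
                r.plate,
                r.well,
                format_concentration(r.concentration),
                r.experiment,
                "1" if r.lethal else "0",
                str(r.n_embryos),
                str(r.n_scoreable),
            ]
            if r.vector is None:
                row.extend([""] * table.schema.n_parameters)
            else:
                row.extend(str(s) for s in r.vector.scores)
            writer.writerow(row)


def filter_analyzable(table: ScreenTable) -> ScreenTable:
    """Drop lethal and unscored treatments; idempotent."""
    kept = table.analyzable_records()
    removed = len(table) - len(kept)
    if removed:
        logger.info("filter_analyzable: removed %d non-analyzable records", removed)
    if not kept:
        logger.warning("filter_analyzable: no analyzable records remain")
    return ScreenTable(records=kept, schema=table.schema)


# ---------------------------------------------------------------------------
# Embryo-level scores and consensus calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbryoScores:
    """Per-embryo vectors for one well."""

    vectors: tuple
    schema: ParameterSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        object.__setattr__(self, "vectors", tuple(self.vectors))
        for v in self.vectors:
            if v.schema.codes != self.schema.codes:
                raise ValidationError("embryo vector schema mismatch")

    @property
    def n_embryos(self) -> int:
        return len(self.vectors)

    def score_matrix(self) -> np.ndarray:
        return np.array([v.scores for v in self.vectors], dtype=int)


def consensus_scores(matrix: np.ndarray, support: int) -> np.ndarray:
    """Per column, the largest score reached by at least `support` rows.

    Equivalent to the `support`-th largest value in each column.
    """
    n = matrix.shape[0]
    support = min(max(support, 1), n)
    ordered = np.sort(matrix, axis=0)  # ascending
    return ordered[n - support, :]


def consensus_vector(
    well: EmbryoScores, min_embryos: int = 3
) -> PhenotypicVector:
    """Consensus well vector: per parameter, the largest score supported by
    at least `min_embryos` embryos.

    For wells with fewer than `min_embryos` embryos the required support is
    relaxed to ceil(0.6 * n_embryos), which reproduces the 3-of-5 criterion
    at the default well size.
    """
    if min_embryos < 1:
        raise ValidationError("min_embryos must be >= 1")
    n = well.n_embryos
    if n == 0:
        raise ValidationError("cannot form a consensus for an empty well")
    support = min_embryos if n >= min_embryos else math.ceil(0.6 * n)
    scores = consensus_scores(well.score_matrix(), support)
    return PhenotypicVector(tuple(int(s) for s in scores), well.schema)


def load_embryo_table(
    path, schema: ParameterSchema = DEFAULT_SCHEMA
) -> dict:
    """Load an embryo-level TSV; returns {(compound, conc, experiment): EmbryoScores}.

    Embryo rows with blank score cells are skipped with a warning.
    """
    path = Path(path)
    wells: dict = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if "embryo_index" not in header:
            raise FormatError("embryo-level table requires an embryo_index column")
        _check_header(header, schema)
        for i, row in enumerate(reader, start=1):
            if not row or all(c.strip() == "" for c in row):
                continue
            cells = dict(zip(header, row))
            vector = _parse_scores(cells, schema, i)
            key = (
                cells["compound_id"].strip(),
                float(cells["concentration_uM"]),
                cells["experiment"].strip(),
            )
            if vector is None:
                logger.warning("row %d: unscored embryo skipped", i)
                continue
            wells.setdefault(key, []).append(vector)
    return {
        key: EmbryoScores(vectors=tuple(vs), schema=schema)
        for key, vs in wells.items()
    }


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class CheckResult:
    passed: bool
    n_problems: int
    problems: list = field(default_factory=list)


@dataclass
class ValidationReport:
    checks: dict

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def to_dict(self) -> dict:
        return {
            name: {
                "passed": c.passed,
                "n_problems": c.n_problems,
                "problems": list(c.problems),
            }
            for name, c in self.checks.items()
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def validate_table(
    table: ScreenTable,
    expected_concentrations: Optional[Sequence[float]] = None,
    expected_experiments: Optional[Sequence[str]] = None,
) -> ValidationReport:
    """Run all consistency checks; problems are reported, never raised."""
    checks: dict = {}

    # score range
    problems = []
    for r in table.records:
        if r.vector is None:
            continue
        for code, s in zip(r.vector.schema.codes, r.vector.scores):
            if not 0 <= s <= table.schema.max_score:
                problems.append(f"{r.treatment_id}: {code}={s}")
    checks["score_range"] = CheckResult(not problems, len(problems), problems)

    # duplicates (guaranteed absent by construction, re-checked defensively)
    seen, problems = set(), []
    for r in table.records:
        if r.key in seen:
            problems.append(str(r.key))
        seen.add(r.key)
    checks["duplicates"] = CheckResult(not problems, len(problems), problems)

    # schema conformity
    problems = []
    for r in table.records:
        if r.vector is None:
            continue
        if r.vector.schema.codes != table.schema.codes:
            missing = [
                c for c in table.schema.codes if c not in r.vector.schema.codes
            ]
            problems.append(
                f"{r.treatment_id}: vector schema mismatch, missing codes {missing}"
            )
    checks["schema_conformity"] = CheckResult(not problems, len(problems), problems)

    # design completeness against the expected concentration x experiment grid
    concs = tuple(
        sorted(float(c) for c in (expected_concentrations or table.concentrations))
    )
    exps = tuple(expected_experiments or table.experiments)
    present = {r.key for r in table.records}
    problems = []
    for compound in table.compounds:
        for conc in concs:
            for exp in exps:
                if (compound, conc, exp) not in present:
                    problems.append(
                        f"missing ({compound}, "
                        f"{format_concentration(conc)} uM, {exp})"
                    )
    n_expected = len(table.compounds) * len(concs) * len(exps)
    check = CheckResult(not problems, len(problems), problems)
    checks["design_completeness"] = check
    if n_expected:
        completeness = 100.0 * (n_expected - len(problems)) / n_expected
        logger.info("design completeness: %.1f%%", completeness)

    return ValidationReport(checks=checks)
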