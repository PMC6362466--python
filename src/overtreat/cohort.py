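"""Case-listing containers and CSV I/O for breast-cancer registry cohorts.

The analyses in this package operate on *case listings*: one row per woman
diagnosed with in situ or invasive breast cancer, carrying the covariates a
cancer registry records at diagnosis (age, AJCC stage, tumor size, nodal
status, grade, receptor status, histology, local-invasion flags, first-course
surgery, region, race, plus any extra categorical covariates).

Two containers are provided:

``CaseRecord``
    a single validated case.  Missing values are represented as ``None`` in
    records and as the literal string ``"NA"`` on disk; ``"NA"`` is treated
    everywhere downstream as an explicit category level (missingness can be
    informative of surgical choices, so nothing is imputed).

``Cohort``
    an ordered, id-unique collection of cases backed by a typed
    :class:`pandas.DataFrame`, with helpers to derive the categorical
    covariate frame used for modelling and descriptive tables.

Eligibility filtering (age >= 40, known surgery) happens in
:func:`read_cohort`, which mirrors how registry extracts are cleaned before
analysis and reports the exclusions it makes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CaseRecord",
    "Cohort",
    "CohortError",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "classify_surgery",
    "load_surgery_code_map",
    "STAGES",
    "GRADES",
    "SURGERY_CLASSES",
    "BEHAVIORS",
    "AGE_GROUPS",
    "SIZE_GROUPS",
    "NODES_GROUPS",
    "MOLECULAR_GROUPS",
]

STAGES = ("0", "I", "II", "III", "IV", "NA")
GRADES = ("I", "II", "III", "IV", "NA")
TRISTATE = ("pos", "neg", "NA")
BEHAVIORS = ("in_situ", "invasive")
SURGERY_CLASSES = ("mastectomy", "bcs", "other", "none")

MIN_AGE = 40

# Ordered level sets for the derived (binned) covariates; "NA" is always a
# level of its own.
AGE_GROUPS = ("40-49", "50-64", "65-84", "85+")
SIZE_GROUPS = ("0.0-0.9", "1.0-1.9", "2.0-2.9", "3.0-3.9", "4.0-4.9", "5.0+", "NA")
NODES_GROUPS = ("0", "1", "2+", "NA")
MOLECULAR_GROUPS = ("HER2-/HR-", "HER2-/HR+", "HER2+/HR-", "HER2+/HR+", "NA")

CORE_COLUMNS = (
    "case_id",
    "age_years",
    "stage",
    "tumor_size_cm",
    "nodes_positive",
    "grade",
    "her2",
    "hr",
    "histology_icdo3",
    "behavior",
    "invades_fascia_muscle_chestwall",
    "skin_ulceration_or_adjacent_skin",
    "distant_metastasis",
    "surgery_class",
    "region",
    "race",
)

#: covariates entering the default propensity model, in order; extra
#: covariates found on the cohort are appended after these.
DEFAULT_MODEL_COVARIATES = (
    "age_group",
    "stage",
    "size_group",
    "nodes_group",
    "grade",
    "her2",
    "hr",
    "behavior",
    "region",
    "race",
)


class CohortError(ValueError):
    """Raised for malformed case listings or inconsistent cohorts."""


@dataclass
class CaseRecord:
    """One registry case.

    ``None`` encodes an unknown value for the optional fields; the
    ``overdiagnosed`` flag is latent and only ever populated on synthetic
    cohorts, where it is the simulation ground truth.
    """

    case_id: str
    age_years: int
    stage: str
    tumor_size_cm: float | None
    nodes_positive: int | None
    grade: str
    her2: str
    hr: str
    histology_icdo3: int
    behavior: str
    invades_fascia_muscle_chestwall: bool | None
    skin_ulceration_or_adjacent_skin: bool | None
    distant_metastasis: bool | None
    surgery_class: str
    region: str
    race: str
    extra_covariates: dict[str, str] = field(default_factory=dict)
    overdiagnosed: bool | None = None

    def validate(self) -> None:
        if not self.case_id:
            raise CohortError("case_id must be a non-empty string")
        if self.age_years < MIN_AGE:
            raise CohortError(f"case {self.case_id}: age {self.age_years} < {MIN_AGE}")
        if self.stage not in STAGES:
            raise CohortError(f"case {self.case_id}: bad stage {self.stage!r}")
        if self.tumor_size_cm is not None and self.tumor_size_cm < 0:
            raise CohortError(f"case {self.case_id}: negative tumor size")
        if self.nodes_positive is not None and self.nodes_positive < 0:
            raise CohortError(f"case {self.case_id}: negative node count")
        if self.grade not in GRADES:
            raise CohortError(f"case {self.case_id}: bad grade {self.grade!r}")
        if self.her2 not in TRISTATE or self.hr not in TRISTATE:
            raise CohortError(f"case {self.case_id}: bad receptor status")
        if self.behavior not in BEHAVIORS:
            raise CohortError(f"case {self.case_id}: bad behavior {self.behavior!r}")
        if self.surgery_class not in SURGERY_CLASSES:
            raise CohortError(
                f"case {self.case_id}: bad surgery class {self.surgery_class!r}"
            )

    # -- derived categorical views ------------------------------------

    @property
    def age_group(self) -> str:
        return _age_group_scalar(self.age_years)

    @property
    def size_group(self) -> str:
        return _size_group_scalar(self.tumor_size_cm)

    @property
    def nodes_group(self) -> str:
        return _nodes_group_scalar(self.nodes_positive)


def _age_group_scalar(age: int) -> str:
    if age < 50:
        return "40-49"
    if age < 65:
        return "50-64"
    if age < 85:
        return "65-84"
    return "85+"


def _size_group_scalar(size: float | None) -> str:
    if size is None or (isinstance(size, float) and math.isnan(size)):
        return "NA"
    for hi, label in ((1, "0.0-0.9"), (2, "1.0-1.9"), (3, "2.0-2.9"),
                      (4, "3.0-3.9"), (5, "4.0-4.9")):
        if size < hi:
            return label
    return "5.0+"


def _nodes_group_scalar(nodes: int | None) -> str:
    if nodes is None or (isinstance(nodes, float) and math.isnan(nodes)):
        return "NA"
    if nodes == 0:
        return "0"
    if nodes == 1:
        return "1"
    return "2+"


@dataclass
class ExclusionReport:
    """Bookkeeping for rows dropped while reading a case listing."""

    n_input: int = 0
    n_retained: int = 0
    age_excluded: int = 0
    surgery_excluded: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "age_excluded": self.age_excluded,
            "surgery_excluded": self.surgery_excluded,
        }


class Cohort:
    """Validated, ordered collection of cases.

    Internally a typed DataFrame (one row per case) for vectorised work;
    iteration yields :class:`CaseRecord` views.  The empirical distribution
    over covariate patterns of the cohort is what stands in for Pr(X = x_i)
    in the bounding step.
    """

    def __init__(self, frame: pd.DataFrame, extra_names: tuple[str, ...] = ()):
        missing = [c for c in CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortError(f"cohort frame missing columns: {missing}")
        ids = frame["case_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate case_id {dup!r}")
        if len(frame) and (frame["age_years"] < MIN_AGE).any():
            raise CohortError(f"cohort contains cases younger than {MIN_AGE}")
        if len(frame) and not frame["surgery_class"].isin(SURGERY_CLASSES).all():
            raise CohortError("cohort contains unknown surgery classes")
        self.frame = frame.reset_index(drop=True)
        self.extra_names = tuple(extra_names)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CaseRecord]) -> "Cohort":
        records = list(records)
        extra_names: list[str] = []
        for r in records:
            r.validate()
            for k in r.extra_covariates:
                if k not in extra_names:
                    extra_names.append(k)
        cols: dict[str, list] = {c: [] for c in CORE_COLUMNS}
        for name in extra_names:
            cols[name] = []
        any_flag = any(r.overdiagnosed is not None for r in records)
        if any_flag and not all(r.overdiagnosed is not None for r in records):
            raise CohortError("overdiagnosed flag must be set for all cases or none")
        if any_flag:
            cols["overdiagnosed"] = []
        for r in records:
            for c in CORE_COLUMNS:
                cols[c].append(getattr(r, c))
            for name in extra_names:
                cols[name].append(r.extra_covariates.get(name, "NA"))
            if any_flag:
                cols["overdiagnosed"].append(r.overdiagnosed)
        frame = pd.DataFrame(cols)
        return cls(_coerce_types(frame), tuple(extra_names))

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[CaseRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def record(self, i: int) -> CaseRecord:
        row = self.frame.iloc[i]
        extras = {k: row[k] for k in self.extra_names}
        over = None
        if "overdiagnosed" in self.frame.columns:
            over = bool(row["overdiagnosed"])
        return CaseRecord(
            case_id=row["case_id"],
            age_years=int(row["age_years"]),
            stage=row["stage"],
            tumor_size_cm=_opt_float(row["tumor_size_cm"]),
            nodes_positive=_opt_int(row["nodes_positive"]),
            grade=row["grade"],
            her2=row["her2"],
            hr=row["hr"],
            histology_icdo3=int(row["histology_icdo3"]),
            behavior=row["behavior"],
            invades_fascia_muscle_chestwall=_opt_bool(
                row["invades_fascia_muscle_chestwall"]
            ),
            skin_ulceration_or_adjacent_skin=_opt_bool(
                row["skin_ulceration_or_adjacent_skin"]
            ),
            distant_metastasis=_opt_bool(row["distant_metastasis"]),
            surgery_class=row["surgery_class"],
            region=row["region"],
            race=row["race"],
            extra_covariates=extras,
            overdiagnosed=over,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.extra_names != other.extra_names:
            return False
        if set(self.frame.columns) != set(other.frame.columns):
            return False
        return self.frame.equals(other.frame[self.frame.columns])

    # -- accessors -------------------------------------------------------

    @property
    def case_ids(self) -> pd.Series:
        return self.frame["case_id"]

    @property
    def has_overdiagnosis_flags(self) -> bool:
        return "overdiagnosed" in self.frame.columns

    @property
    def mastectomy(self) -> np.ndarray:
        """Boolean outcome vector: first-course surgery was total mastectomy."""
        return (self.frame["surgery_class"] == "mastectomy").to_numpy()

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.frame.loc[np.asarray(mask, bool)].copy(), self.extra_names)

    def model_covariates(self) -> tuple[str, ...]:
        return DEFAULT_MODEL_COVARIATES + self.extra_names

    def variable(self, name: str) -> pd.Series:
        """A categorical Series for ``name``, which may be a raw column, an
        extra covariate, or a derived view (age_group, size_group,
        nodes_group, molecular_status)."""
        f = self.frame
        if name == "age_group":
            return pd.Series(
                np.select(
                    [f["age_years"] < 50, f["age_years"] < 65, f["age_years"] < 85],
                    ["40-49", "50-64", "65-84"],
                    "85+",
                ),
                index=f.index,
                name=name,
            )
        if name == "size_group":
            s = f["tumor_size_cm"].to_numpy(float)
            out = np.full(len(f), "NA", dtype=object)
            ok = ~np.isnan(s)
            labels = np.array(SIZE_GROUPS[:-1], dtype=object)
            idx = np.clip(np.floor(s[ok]).astype(int), 0, 5)
            out[ok] = labels[idx]
            return pd.Series(out, index=f.index, name=name)
        if name == "nodes_group":
            n = f["nodes_positive"].to_numpy(float)
            out = np.full(len(f), "NA", dtype=object)
            ok = ~np.isnan(n)
            out[ok & (n == 0)] = "0"
            out[ok & (n == 1)] = "1"
            out[ok & (n >= 2)] = "2+"
            return pd.Series(out, index=f.index, name=name)
        if name == "molecular_status":
            her2, hr = f["her2"], f["hr"]
            out = np.full(len(f), "NA", dtype=object)
            known = (her2 != "NA") & (hr != "NA")
            tag = np.where(her2 == "pos", "HER2+", "HER2-")
            tag = np.char.add(tag.astype(str), np.where(hr == "pos", "/HR+", "/HR-"))
            out[known.to_numpy()] = tag[known.to_numpy()]
            return pd.Series(out, index=f.index, name=name)
        if name in f.columns:
            return f[name].astype(str).rename(name)
        raise KeyError(f"unknown variable {name!r}")

    def covariate_frame(self, covariates: Iterable[str] | None = None) -> pd.DataFrame:
        """Categorical (string) covariate frame used by the propensity model
        and descriptive tables; defaults to the model covariate list."""
        names = tuple(covariates) if covariates is not None else self.model_covariates()
        return pd.DataFrame({n: self.variable(n) for n in names})


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def _opt_bool(v) -> bool | None:
    if v is None or v is pd.NA or (isinstance(v, float) and math.isnan(v)):
        return None
    return bool(v)


def _coerce_types(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["case_id"] = frame["case_id"].astype(str)
    frame["age_years"] = frame["age_years"].astype(np.int64)
    frame["tumor_size_cm"] = pd.to_numeric(frame["tumor_size_cm"]).astype(float)
    frame["nodes_positive"] = pd.to_numeric(frame["nodes_positive"]).astype(float)
    frame["histology_icdo3"] = frame["histology_icdo3"].astype(np.int64)
    for c in (
        "invades_fascia_muscle_chestwall",
        "skin_ulceration_or_adjacent_skin",
        "distant_metastasis",
    ):
        frame[c] = frame[c].astype("boolean")
    if "overdiagnosed" in frame.columns:
        frame["overdiagnosed"] = frame["overdiagnosed"].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# CSV I/O.  UTF-8, comma separated, header row; the literal "NA" encodes a
# missing value; booleans are written "1"/"0".
# ---------------------------------------------------------------------------

_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False}


def _parse_row(row: Mapping[str, str], extra_names: tuple[str, ...],
               has_flag: bool, rownum: int) -> CaseRecord:
    def bad(fld: str, msg: str):
        return CohortError(f"row {rownum}, field {fld!r}: {msg}")

    def opt_float(fld: str) -> float | None:
        v = row[fld]
        if v == "NA":
            return None
        try:
            return float(v)
        except ValueError:
            raise bad(fld, f"cannot parse {v!r} as a number") from None

    def opt_int(fld: str) -> int | None:
        v = row[fld]
        if v == "NA":
            return None
        try:
            return int(v)
        except ValueError:
            raise bad(fld, f"cannot parse {v!r} as an integer") from None

    def opt_bool(fld: str) -> bool | None:
        v = row[fld]
        if v == "NA":
            return None
        try:
            return _BOOL_TOKENS[v.strip().lower()]
        except KeyError:
            raise bad(fld, f"cannot parse {v!r} as a 0/1 flag") from None

    try:
        age = int(row["age_years"])
    except ValueError:
        raise bad("age_years", f"cannot parse {row['age_years']!r}") from None
    try:
        hist = int(row["histology_icdo3"])
    except ValueError:
        raise bad("histology_icdo3", f"cannot parse {row['histology_icdo3']!r}") from None

    rec = CaseRecord(
        case_id=row["case_id"],
        age_years=age,
        stage=row["stage"],
        tumor_size_cm=opt_float("tumor_size_cm"),
        nodes_positive=opt_int("nodes_positive"),
        grade=row["grade"],
        her2=row["her2"],
        hr=row["hr"],
        histology_icdo3=hist,
        behavior=row["behavior"],
        invades_fascia_muscle_chestwall=opt_bool("invades_fascia_muscle_chestwall"),
        skin_ulceration_or_adjacent_skin=opt_bool("skin_ulceration_or_adjacent_skin"),
        distant_metastasis=opt_bool("distant_metastasis"),
        surgery_class=row["surgery_class"],
        region=row["region"],
        race=row["race"],
        extra_covariates={k: row[k] for k in extra_names},
        overdiagnosed=(opt_bool("overdiagnosed") if has_flag else None),
    )
    return rec


def read_cohort(path: str | Path,
                schema: Iterable[str] | None = None) -> tuple[Cohort, ExclusionReport]:
    """Read a case-listing CSV into a validated :class:`Cohort`.

    Rows with age below 40 and rows whose surgery class is unknown or
    unparseable are dropped (these mirror the standard eligibility exclusions
    applied to registry extracts) and tallied in the returned
    :class:`ExclusionReport`.  Any other malformed field raises
    :class:`CohortError` naming the row and field.

    Parameters
    ----------
    path
        CSV file with a header row; ``"NA"`` is the missing-value literal.
    schema
        Optional expected list of extra-covariate column names.  A mismatch
        between this list and the columns found raises an error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    has_flag = "overdiagnosed" in raw.columns
    extra_names = tuple(
        c for c in raw.columns if c not in CORE_COLUMNS and c != "overdiagnosed"
    )
    if schema is not None and tuple(schema) != extra_names:
        raise CohortError(
            f"extra covariate columns {list(extra_names)} do not match the "
            f"expected schema {list(schema)}"
        )
    missing = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortError(f"case listing missing columns: {missing}")

    report = ExclusionReport(n_input=len(raw))
    records: list[CaseRecord] = []
    for i, row in enumerate(raw.to_dict("records")):
        try:
            age = int(row["age_years"])
        except ValueError:
            raise CohortError(
                f"row {i}, field 'age_years': cannot parse {row['age_years']!r}"
            ) from None
        if age < MIN_AGE:
            report.age_excluded += 1
            continue
        if row["surgery_class"] not in SURGERY_CLASSES:
            report.surgery_excluded += 1
            continue
        rec = _parse_row(row, extra_names, has_flag, i)
        rec.validate()
        records.append(rec)
    report.n_retained = len(records)
    if records:
        cohort = Cohort.from_records(records)
        # preserve the file's column order for extras
        cohort.extra_names = extra_names
    else:
        frame = pd.DataFrame({c: pd.Series(dtype=object) for c in CORE_COLUMNS})
        frame["age_years"] = frame["age_years"].astype(np.int64)
        cohort = Cohort(_coerce_types(frame), extra_names)
    return cohort, report


def write_cohort(cohort: Cohort, path: str | Path, include_latent: bool = True) -> None:
    """Write ``cohort`` to CSV (header always written, ``NA`` literal for
    missing values, ``1``/``0`` for booleans).  ``include_latent=False``
    drops the synthetic ``overdiagnosed`` column so the file looks like a
    plain registry extract."""
    f = cohort.frame
    out = pd.DataFrame(index=f.index)
    for c in CORE_COLUMNS + cohort.extra_names:
        if c == "age_years":
            out[c] = f[c].astype(str)
        elif c == "tumor_size_cm":
            out[c] = f[c].map(lambda v: "NA" if math.isnan(v) else repr(float(v)))
        elif c == "nodes_positive":
            out[c] = f[c].map(lambda v: "NA" if math.isnan(v) else str(int(v)))
        elif c in (
            "invades_fascia_muscle_chestwall",
            "skin_ulceration_or_adjacent_skin",
            "distant_metastasis",
        ):
            out[c] = f[c].map(lambda v: "NA" if v is pd.NA else ("1" if v else "0"))
        else:
            out[c] = f[c].astype(str)
    if include_latent and cohort.has_overdiagnosis_flags:
        out["overdiagnosed"] = f["overdiagnosed"].map(lambda v: "1" if v else "0")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Surgery recoding.  Registries record a most-extensive-procedure code; the
# analysis needs only four classes.  The default map covers the procedure
# names of the standard definitions (total mastectomy = simple or modified
# radical mastectomy; breast-conserving surgery = lumpectomy and related
# partial resections; everything else, e.g. subcutaneous mastectomy, is
# "other").  Site-specific numeric codes can be supplied via a YAML map.
# ---------------------------------------------------------------------------

_DEFAULT_CODE_MAP: dict[str, str] | None = None


def load_surgery_code_map(path: str | Path | None = None) -> dict[str, str]:
    """Load a surgery code map (code/label -> class); default ships with the
    package."""
    global _DEFAULT_CODE_MAP
    if path is None:
        if _DEFAULT_CODE_MAP is None:
            text = resources.files("overtreat.data").joinpath(
                "surgery_codes.yaml"
            ).read_text()
            _DEFAULT_CODE_MAP = {
                str(k).strip().lower(): v for k, v in yaml.safe_load(text).items()
            }
        return _DEFAULT_CODE_MAP
    with open(path) as fh:
        return {str(k).strip().lower(): v for k, v in yaml.safe_load(fh).items()}


def classify_surgery(raw_code: str | int,
                     code_map: Mapping[str, str] | None = None) -> str:
    """Map a raw registry surgery code or procedure label to one of
    ``mastectomy``/``bcs``/``other``/``none``.

    Raises :class:`CohortError` for codes absent from the map.
    """
    if code_map is None:
        code_map = load_surgery_code_map()
    key = str(raw_code).strip().lower()
    try:
        cls = code_map[key]
    except KeyError:
        raise CohortError(f"unknown surgery code {raw_code!r}") from None
    if cls not in SURGERY_CLASSES:
        raise CohortError(f"surgery code {raw_code!r} maps to invalid class {cls!r}")
    return cls
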