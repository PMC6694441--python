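"""Cohort I/O: subject-by-region uptake tables joined with subject metadata.

Two delimited text files define a cohort:

* a values file — column 1 ``subject_id``, remaining columns one per atlas
  region, one row per subject, cells are regional tracer uptake;
* a metadata file — keyed by ``subject_id`` with group label, age, sex,
  diagnosis, FAQ, MMSE, CSF total-tau and amyloid status.

Both comma- and tab-delimited files are accepted (sniffed from the header).
Subjects present in only one of the two files are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, load_aal90

log = logging.getLogger(__name__)

#: canonical group labels: APOE-e4 carriage (+/-) crossed with CSF T-Tau
#: abnormality (T+/T-) at the 320 ng/L cut-off
GROUPS = ("A4-T-", "A4+T+", "A4+T-", "A4-T+")

#: CSF total-tau abnormality cut-off, ng/L
TTAU_CUTOFF = 320.0

_META_COLUMNS = ["subject_id", "group", "age", "sex", "diagnosis",
                 "faq", "mmse", "csf_ttau", "abeta_status"]


class CohortFormatError(ValueError):
    """A cohort file violates the expected table layout."""


@dataclass
class SubjectRecord:
    """One subject's metadata.

    sex is coded 0 = female, 1 = male; faq is the Functional Assessment
    Questionnaire total (0 no impairment .. 30 severe); csf_ttau in ng/L.
    faq, mmse, csf_ttau and abeta_status may be missing (None) at ingest and
    are excluded per-analysis.
    """

    id: str
    group: str
    age: float
    sex: int
    diagnosis: str
    faq: float | None = None
    mmse: float | None = None
    csf_ttau: float | None = None
    abeta_status: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be coded 0 (female) or 1 (male), got {self.sex!r}")
        if self.diagnosis not in ("MCI", "NC"):
            raise ValueError(f"diagnosis must be 'MCI' or 'NC', got {self.diagnosis!r}")
        if self.faq is not None and not np.isnan(self.faq):
            if not 0 <= self.faq <= 30:
                raise ValueError(f"FAQ {self.faq} outside [0, 30] for subject {self.id}")
        if self.csf_ttau is not None and not np.isnan(self.csf_ttau):
            if self.csf_ttau < 0:
                raise ValueError(f"negative CSF T-Tau for subject {self.id}")
            # group suffix must agree with the 320 ng/L cut-off
            abnormal = self.csf_ttau >= TTAU_CUTOFF
            if abnormal != self.group.endswith("T+"):
                raise ValueError(
                    f"subject {self.id}: CSF T-Tau {self.csf_ttau} ng/L inconsistent "
                    f"with group {self.group} at the {TTAU_CUTOFF:g} ng/L cut-off")

    @property
    def tau_status(self) -> str | None:
        if self.csf_ttau is None or np.isnan(self.csf_ttau):
            return None
        return "positive" if self.csf_ttau >= TTAU_CUTOFF else "negative"


@dataclass
class CohortTable:
    """Subject x region measurements plus per-subject metadata.

    values has shape (n_subjects, len(atlas)), columns in atlas order.
    """

    atlas: RegionAtlas
    subjects: list[SubjectRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.subjects), len(self.atlas)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.atlas)} regions")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in cohort")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at subject {ids[bad[0]]!r}, "
                f"region {self.atlas.names[bad[1]]!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def meta(self, attr: str) -> np.ndarray:
        """Vector of one metadata field over subjects (None -> NaN)."""
        vals = [getattr(s, attr) for s in self.subjects]
        if attr in ("id", "group", "diagnosis", "abeta_status"):
            return np.asarray(vals, dtype=object)
        return np.asarray([np.nan if v is None else v for v in vals], dtype=float)

    def global_uptake(self) -> np.ndarray:
        """Per-subject mean uptake over all atlas regions."""
        return self.values.mean(axis=1)

    def subset(self, index) -> "CohortTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortTable(self.atlas,
                           [self.subjects[i] for i in index],
                           self.values[index])

    def metadata_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
                 "diagnosis": s.diagnosis, "faq": s.faq, "mmse": s.mmse,
                 "csf_ttau": s.csf_ttau, "abeta_status": s.abeta_status}
                for s in self.subjects]
        return pd.DataFrame(rows, columns=_META_COLUMNS)

    def values_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.atlas.names))
        df.insert(0, "subject_id", self.ids)
        return df


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"subject_id": str},
                       float_precision="round_trip")


def read_cohort(values_path: str | Path, metadata_path: str | Path,
                atlas: RegionAtlas | None = None) -> CohortTable:
    """Read and validate a cohort from a values file and a metadata file.

    Region columns must match the atlas labels exactly (any column order);
    subjects present in only one file are dropped with a logged warning.
    """
    atlas = atlas or load_aal90()
    raw = pd.read_csv(values_path, sep=None, engine="python", dtype=str)
    if raw.columns[0] != "subject_id":
        raise CohortFormatError(
            f"first column of values file must be 'subject_id', got {raw.columns[0]!r}")
    region_cols = list(raw.columns[1:])
    dup = [c for c in region_cols if c.endswith(".1") and c[:-2] in region_cols]
    if dup or len(set(region_cols)) != len(region_cols):
        raise CohortFormatError(f"duplicated region columns in values file: {sorted(dup)}")
    missing = set(atlas.names) - set(region_cols)
    extra = set(region_cols) - set(atlas.names)
    if missing or extra:
        raise CohortFormatError(
            f"region columns do not match atlas (missing {sorted(missing)[:5]}, "
            f"unexpected {sorted(extra)[:5]})")
    vals = np.empty((len(raw), len(atlas)))
    for j, name in enumerate(atlas.names):
        col = raw[name]
        try:
            vals[:, j] = col.astype(float)
        except ValueError as exc:
            bad = col[pd.to_numeric(col, errors="coerce").isna()]
            row = bad.index[0]
            raise CohortFormatError(
                f"non-numeric cell {bad.iloc[0]!r} at row {row + 2}, "
                f"column {name!r} of values file") from exc
    value_ids = raw["subject_id"].astype(str).tolist()
    if len(set(value_ids)) != len(value_ids):
        raise CohortFormatError("duplicate subject ids in values file")

    meta = _read_table(metadata_path)
    missing_cols = set(_META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise CohortFormatError(f"metadata file lacks columns {sorted(missing_cols)}")
    meta = meta.set_index("subject_id", verify_integrity=True)

    common = [i for i in value_ids if i in meta.index]
    dropped = sorted(set(value_ids).symmetric_difference(meta.index))
    if dropped:
        log.warning("dropping %d subject(s) present in only one file: %s",
                    len(dropped), dropped)
    keep = [k for k, i in enumerate(value_ids) if i in meta.index]

    def _opt(v):
        return None if pd.isna(v) else v

    subjects = []
    for k in keep:
        sid = value_ids[k]
        row = meta.loc[sid]
        subjects.append(SubjectRecord(
            id=sid, group=str(row["group"]), age=float(row["age"]),
            sex=int(row["sex"]), diagnosis=str(row["diagnosis"]),
            faq=_opt(row["faq"]), mmse=_opt(row["mmse"]),
            csf_ttau=_opt(row["csf_ttau"]),
            abeta_status=None if pd.isna(row["abeta_status"]) else str(row["abeta_status"])))
    return CohortTable(atlas, subjects, vals[keep])


def write_cohort(cohort: CohortTable, out_dir: str | Path,
                 stem: str = "cohort") -> tuple[Path, Path]:
    """Write a cohort as <stem>_values.csv and <stem>_metadata.csv.

    Values are written at full repr precision, so read_cohort o write_cohort
    is the identity on the value matrix.
    """
    # re-validate: values may have been mutated since construction
    CohortTable(cohort.atlas, cohort.subjects, cohort.values)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values_path = out_dir / f"{stem}_values.csv"
    metadata_path = out_dir / f"{stem}_metadata.csv"
    cohort.values_frame().to_csv(values_path, index=False)
    cohort.metadata_frame().to_csv(metadata_path, index=False)
    return values_path, metadata_path


def split_by_group(cohort: CohortTable) -> dict[str, CohortTable]:
    """Partition a cohort by group label; disjoint and exhaustive."""
    groups = cohort.meta("group")
    out: dict[str, CohortTable] = {}
    for g in GROUPS:
        mask = groups == g
        if mask.any():
            out[g] = cohort.subset(mask)
    counts = {g: c.n_subjects for g, c in out.items()}
    log.info("split cohort of %d subjects into groups %s", cohort.n_subjects, counts)
    return out
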