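"""Data model and I/O for ASV count tables, taxonomy and sample/subject metadata.

Count tables are stored as dense integer matrices (samples x ASVs).  Counts
stay integral end-to-end; relative abundances are derived on demand so that
hypergeometric rarefaction always operates on true read counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("S", "A", "W")
SAMPLE_TYPES = ("mat", "saliva", "skin", "feces", "negative_control")
HUMAN_TYPES = ("saliva", "skin", "feces")

GARDENING_LEVELS = ("rarely", "at_least_monthly")
PETS_LEVELS = ("yes", "no")
HANDWASHING_LEVELS = ("max_once_a_day", "many_times_a_day")
URBAN_LEVELS = ("u", "r")

_BOOTSTRAP_RE = re.compile(r"\(\d+\)")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class AsvTable:
    """Integer count matrix with sample rows and ASV columns."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.asv_ids = list(self.asv_ids)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.asv_ids, "ASV")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise FormatError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise FormatError("counts must be integral")
        if arr.size and np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
            )
        self.counts = arr.astype(np.int64)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._asv_index = {a: j for j, a in enumerate(self.asv_ids)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.counts[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample ID: {sample_id!r}") from None

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sample_index

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, ids: Iterable[str]) -> "AsvTable":
        """Restrict to the given samples, preserving this table's row order."""
        keep = set(ids)
        unknown = keep - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample IDs: {sorted(unknown)}")
        rows = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return AsvTable(
            [self.sample_ids[i] for i in rows], list(self.asv_ids), self.counts[rows]
        )

    def subset_asvs(self, ids: Iterable[str]) -> "AsvTable":
        keep = set(ids)
        cols = [j for j, a in enumerate(self.asv_ids) if a in keep]
        return AsvTable(
            list(self.sample_ids), [self.asv_ids[j] for j in cols], self.counts[:, cols]
        )

    def drop_asvs(self, ids: Iterable[str]) -> "AsvTable":
        drop = set(ids)
        return self.subset_asvs(a for a in self.asv_ids if a not in drop)

    # -- conversion ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.sample_ids), columns=list(self.asv_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AsvTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def write_tsv(self, path: str | Path, dialect: str = "plain_tsv") -> None:
        path = Path(path)
        if dialect == "plain_tsv":
            df = self.to_dataframe()
            df.index.name = "sample_id"
            df.to_csv(path, sep="\t")
        elif dialect == "mothur_shared":
            df = self.to_dataframe()
            out = pd.DataFrame(
                {
                    "label": ["asv"] * self.n_samples,
                    "Group": self.sample_ids,
                    "numOtus": [self.n_asvs] * self.n_samples,
                }
            )
            out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
            out.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subject_id: str | None
    sample_type: str
    timepoint: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown sample_type {self.sample_type!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
            )
        is_control = self.sample_type == "negative_control"
        if is_control != (self.subject_id is None):
            raise FormatError(
                f"sample {self.sample_id!r}: subject_id must be empty exactly for "
                "negative controls"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class SubjectCovariates:
    """Per-subject explanatory variables; ``None`` marks a missing value.

    ``real_mat_days`` and ``antibiotics_last_6mo`` vary by timepoint and are
    stored as timepoint-keyed mappings.
    """

    subject_id: str
    built: float | None = None
    outdoor: float | None = None
    gardening: str | None = None
    pets: str | None = None
    handwashing: str | None = None
    number_of_persons: int | None = None
    urban: str | None = None
    real_mat_days: dict[str, int] = field(default_factory=dict)
    antibiotics_last_6mo: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.built is not None and not 0 <= self.built <= 100:
            raise FormatError(f"subject {self.subject_id!r}: built must be in [0,100]")
        if self.outdoor is not None and not 0 <= self.outdoor <= 4:
            raise FormatError(f"subject {self.subject_id!r}: outdoor must be in [0,4]")
        if self.number_of_persons is not None and self.number_of_persons not in range(1, 6):
            raise FormatError(
                f"subject {self.subject_id!r}: number_of_persons must be in 1..5"
            )
        for name, levels in (
            ("gardening", GARDENING_LEVELS),
            ("pets", PETS_LEVELS),
            ("handwashing", HANDWASHING_LEVELS),
            ("urban", URBAN_LEVELS),
        ):
            val = getattr(self, name)
            if val is not None and val not in levels:
                raise FormatError(
                    f"subject {self.subject_id!r}: {name}={val!r} not in {levels}"
                )


@dataclass
class TaxonomyTable:
    """ASV -> ordered lineage labels (domain to genus)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for asv, lin in self.lineages.items():
            if not lin:
                raise FormatError(f"ASV {asv!r} has an empty lineage")

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.lineages

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return self.lineages[asv_id]


@dataclass
class AlignReport:
    table_only: list[str]
    metadata_only: list[str]

    @property
    def empty(self) -> bool:
        return not self.table_only and not self.metadata_only


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_count_frame(df: pd.DataFrame) -> np.ndarray:
    """Validate and convert a string-valued frame of counts, naming offenders."""
    arr = df.to_numpy()
    out = np.zeros(arr.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df.iloc[:, j], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric count at sample {row!r}, ASV {col!r}"
            )
        fvals = vals.to_numpy(dtype=float)
        if np.any(fvals != np.floor(fvals)):
            row = df.index[int(np.argmax(fvals != np.floor(fvals)))]
            raise FormatError(f"non-integer count at sample {row!r}, ASV {col!r}")
        if np.any(fvals < 0):
            row = df.index[int(np.argmax(fvals < 0))]
            raise FormatError(f"negative count at sample {row!r}, ASV {col!r}")
        out[:, j] = fvals.astype(np.int64)
    return out


def read_count_table(path: str | Path, dialect: str = "plain_tsv") -> AsvTable:
    """Read a samples x ASVs count table.

    ``plain_tsv``: header row of ASV IDs, first column sample IDs.
    ``mothur_shared``: mothur 'shared' layout with label/Group/numOtus
    prefix columns, which are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no columns")
    if dialect == "plain_tsv":
        sample_col = df.columns[0]
        df = df.set_index(sample_col)
    elif dialect == "mothur_shared":
        expected = {"label", "Group", "numOtus"}
        if not expected.issubset(df.columns[:3]):
            raise FormatError(
                f"{path}: mothur_shared requires leading columns label/Group/numOtus, "
                f"got {list(df.columns[:3])}"
            )
        df = df.set_index("Group").drop(columns=["label", "numOtus"])
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    sample_ids = [str(s) for s in df.index]
    asv_ids = [str(a) for a in df.columns]
    _check_unique(sample_ids, "sample")
    _check_unique(asv_ids, "ASV")
    counts = _parse_count_frame(df)
    return AsvTable(sample_ids, asv_ids, counts)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column taxonomy TSV (asv_id TAB semicolon-joined lineage).

    Bootstrap confidence suffixes like ``(97)`` are stripped from labels.
    """
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.split("\t")[0].lower() in (
                "asv_id", "otu_id", "asv", "otu", "id",
            ):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            asv_id, lineage_str = parts[0], parts[1]
            if asv_id in lineages:
                raise FormatError(f"{path}:{lineno}: duplicate ASV ID {asv_id!r}")
            labels = tuple(
                _BOOTSTRAP_RE.sub("", tok).strip()
                for tok in lineage_str.strip().rstrip(";").split(";")
                if tok.strip()
            )
            if not labels:
                raise FormatError(f"{path}:{lineno}: empty lineage for {asv_id!r}")
            lineages[asv_id] = labels
    return TaxonomyTable(lineages)


_METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "sample_type",
    "timepoint",
    "replicate",
    "built",
    "outdoor",
    "gardening",
    "pets",
    "handwashing",
    "number_of_persons",
    "real_mat_days",
    "urban",
    "antibiotics_last_6mo",
]


def _cell(row: Mapping[str, str], name: str) -> str | None:
    val = row.get(name, "")
    if val is None:
        return None
    val = str(val).strip()
    return val if val not in ("", "NA", "nan") else None


def read_metadata(path: str | Path) -> tuple[list[SampleRecord], list[SubjectCovariates]]:
    """Read the combined sample/subject metadata TSV.

    Empty cells become missing values, never zeros.  Subject covariates are
    assembled from the first non-missing value per subject; the per-timepoint
    fields (real_mat_days, antibiotics_last_6mo) are keyed by each row's
    timepoint.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "subject_id", "sample_type", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    records: list[SampleRecord] = []
    covs: dict[str, SubjectCovariates] = {}
    seen_keys: set[tuple] = set()
    for idx, raw in df.iterrows():
        row = raw.to_dict()
        sample_id = _cell(row, "sample_id")
        if sample_id is None:
            raise FormatError(f"{path}: row {idx + 2}: empty sample_id")
        subject_id = _cell(row, "subject_id")
        sample_type = _cell(row, "sample_type") or ""
        timepoint = _cell(row, "timepoint") or ""
        rep = _cell(row, "replicate")
        try:
            rec = SampleRecord(
                sample_id=sample_id,
                subject_id=subject_id,
                sample_type=sample_type,
                timepoint=timepoint,
                replicate=int(rep) if rep is not None else 1,
            )
        except FormatError as exc:
            raise FormatError(f"{path}: row {idx + 2}: {exc}") from None
        key = (rec.subject_id, rec.sample_type, rec.timepoint, rec.replicate)
        if rec.subject_id is not None and key in seen_keys:
            raise FormatError(
                f"{path}: row {idx + 2}: duplicate (subject, type, timepoint, replicate) {key}"
            )
        seen_keys.add(key)
        records.append(rec)

        if subject_id is None:
            continue
        cov = covs.setdefault(subject_id, SubjectCovariates(subject_id=subject_id))
        for name, conv in (
            ("built", float),
            ("outdoor", float),
            ("gardening", str),
            ("pets", str),
            ("handwashing", str),
            ("number_of_persons", lambda v: int(float(v))),
            ("urban", str),
        ):
            val = _cell(row, name)
            if val is not None and getattr(cov, name) is None:
                setattr(cov, name, conv(val))
        days = _cell(row, "real_mat_days")
        if days is not None and timepoint not in cov.real_mat_days:
            cov.real_mat_days[timepoint] = int(float(days))
        ab = _cell(row, "antibiotics_last_6mo")
        if ab is not None and timepoint not in cov.antibiotics_last_6mo:
            cov.antibiotics_last_6mo[timepoint] = ab.lower() in ("1", "true", "yes", "t")
    for cov in covs.values():
        cov.__post_init__()  # re-validate after incremental fill
    return records, list(covs.values())


def write_metadata(
    path: str | Path,
    records: Sequence[SampleRecord],
    covariates: Sequence[SubjectCovariates],
) -> None:
    cov_by_subject = {c.subject_id: c for c in covariates}
    rows = []
    for rec in records:
        cov = cov_by_subject.get(rec.subject_id) if rec.subject_id else None

        def fmt(val):
            return "" if val is None else val

        row = {
            "sample_id": rec.sample_id,
            "subject_id": fmt(rec.subject_id),
            "sample_type": rec.sample_type,
            "timepoint": rec.timepoint,
            "replicate": rec.replicate,
        }
        if cov is not None:
            row.update(
                built=fmt(cov.built),
                outdoor=fmt(cov.outdoor),
                gardening=fmt(cov.gardening),
                pets=fmt(cov.pets),
                handwashing=fmt(cov.handwashing),
                number_of_persons=fmt(cov.number_of_persons),
                real_mat_days=fmt(cov.real_mat_days.get(rec.timepoint)),
                urban=fmt(cov.urban),
                antibiotics_last_6mo=fmt(
                    None
                    if rec.timepoint not in cov.antibiotics_last_6mo
                    else str(cov.antibiotics_last_6mo[rec.timepoint]).lower()
                ),
            )
        else:
            row.update({c: "" for c in _METADATA_COLUMNS[5:]})
        rows.append(row)
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_taxonomy(path: str | Path, taxonomy: TaxonomyTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\tlineage\n")
        for asv, lin in taxonomy.lineages.items():
            fh.write(f"{asv}\t{';'.join(lin)}\n")


def align(
    table: AsvTable, records: Sequence[SampleRecord]
) -> tuple[AsvTable, list[SampleRecord], AlignReport]:
    """Restrict table and metadata to their common sample set.

    Never raises on a partial mismatch; mismatches are returned in the
    report.  An empty intersection is an error.
    """
    table_ids = set(table.sample_ids)
    meta_ids = {r.sample_id for r in records}
    common = table_ids & meta_ids
    if not common:
        raise ValueError("no samples in common between count table and metadata")
    report = AlignReport(
        table_only=sorted(table_ids - meta_ids),
        metadata_only=sorted(meta_ids - table_ids),
    )
    new_table = table.subset_samples(common)
    new_records = [r for r in records if r.sample_id in common]
    return new_table, new_records, report
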