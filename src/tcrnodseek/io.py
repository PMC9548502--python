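"""Clonotype tables, subject metadata and feature tables.

A repertoire is a set of CDR3β clonotypes with read counts for one subject.
Input tables follow the AIRR Rearrangement column convention by default
(``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``); a custom
column map can be supplied for other dialects.  All tabular formats are
plain TSV with one header row; missing optional values are empty strings.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default mapping from internal field names to AIRR column names
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "count": "duplicate_count",
}

#: default clonotype identity: amino-acid sequence alone (sequence-level
#: sharing); ("cdr3_aa", "v_gene", "j_gene") is also supported.
DEFAULT_CLONE_KEY: tuple[str, ...] = ("cdr3_aa",)

LABELS = ("benign", "malignant")
STAGES = ("I", "II", "III")
SEXES = ("M", "F")

METADATA_COLUMNS = (
    "subject_id", "label", "stage", "ggn", "nodule_size_mm", "age_years", "sex",
)


def validate_cdr3(seq: str, allow_special: bool = False) -> None:
    """Raise :class:`ValidationError` unless *seq* is a valid CDR3β aa string.

    ``allow_special`` additionally admits ``*`` and ``_`` (stop codon /
    frameshift markers used by some clonotype callers).
    """
    if not seq:
        raise ValidationError("empty CDR3 amino-acid sequence")
    allowed = AA_ALPHABET | ({"*", "_"} if allow_special else set())
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(
            f"CDR3 sequence {seq!r} contains non-amino-acid characters: "
            f"{''.join(sorted(bad))}"
        )


@dataclass(frozen=True)
class ClonotypeRecord:
    """One CDR3β clonotype with its read (or clone copy) count."""

    cdr3_aa: str
    count: int
    v_gene: str | None = None
    j_gene: str | None = None

    def __post_init__(self):
        if int(self.count) < 1:
            raise ValidationError(
                f"clonotype {self.cdr3_aa!r} has count {self.count} < 1"
            )

    def key(self, fields: Sequence[str] = DEFAULT_CLONE_KEY) -> tuple:
        return tuple(getattr(self, f) for f in fields)


@dataclass
class Repertoire:
    """A subject's clonotype set with normalised clonal fractions.

    Records are unique under the clone key used at construction and are
    sorted by (count desc, sequence, v, j) for deterministic output.
    """

    subject_id: str
    records: tuple[ClonotypeRecord, ...]
    clone_key_fields: tuple[str, ...] = DEFAULT_CLONE_KEY

    @classmethod
    def from_records(
        cls,
        subject_id: str,
        records: Iterable[ClonotypeRecord],
        clone_key: Sequence[str] = DEFAULT_CLONE_KEY,
    ) -> "Repertoire":
        """Aggregate duplicate clonotypes (summing counts) and normalise."""
        agg: dict[tuple, dict] = {}
        for rec in records:
            k = rec.key(clone_key)
            if k in agg:
                agg[k]["count"] += rec.count
            else:
                agg[k] = dataclasses.asdict(rec)
        merged = [ClonotypeRecord(**d) for d in agg.values()]
        merged.sort(key=lambda r: (-r.count, r.cdr3_aa, r.v_gene or "", r.j_gene or ""))
        if not merged:
            raise ValidationError(f"repertoire {subject_id!r} has no records")
        return cls(subject_id, tuple(merged), tuple(clone_key))

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=np.int64)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        c = self.counts
        return c / c.sum()

    def clone_keys(self) -> list[tuple]:
        return [r.key(self.clone_key_fields) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SubjectMetadata:
    """Clinical annotation of one subject."""

    subject_id: str
    label: str
    stage: str | None = None
    ggn: bool = False
    nodule_size_mm: float | None = None
    age_years: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValidationError(
                f"subject {self.subject_id!r}: label {self.label!r} not in {LABELS}"
            )
        if self.stage is not None:
            if self.stage not in STAGES:
                raise ValidationError(
                    f"subject {self.subject_id!r}: unknown stage {self.stage!r}"
                )
            if self.label != "malignant":
                raise ValidationError(
                    f"subject {self.subject_id!r}: stage set on a benign subject"
                )
        if self.nodule_size_mm is not None and not self.nodule_size_mm > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: nodule_size_mm must be > 0"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id!r}: sex {self.sex!r} not in {SEXES}"
            )


def read_clonotype_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    subject_id: str | None = None,
    clone_key: Sequence[str] = DEFAULT_CLONE_KEY,
    allow_special_chars: bool = False,
) -> Repertoire:
    """Read an AIRR-style clonotype TSV into a validated :class:`Repertoire`.

    Rows with identical clone keys are aggregated by summing counts.  The
    subject id defaults to the file stem.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in ("cdr3_aa", "count"):
        if cmap[field] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {cmap[field]!r} (field {field})"
            )
    seqs = df[cmap["cdr3_aa"]].tolist()
    counts = df[cmap["count"]].tolist()
    vs = df[cmap["v_gene"]].tolist() if cmap["v_gene"] in df.columns else [""] * len(df)
    js = df[cmap["j_gene"]].tolist() if cmap["j_gene"] in df.columns else [""] * len(df)
    records = []
    # data rows are numbered from 2 (row 1 is the header)
    for i, (seq, cnt, v, j) in enumerate(zip(seqs, counts, vs, js), start=2):
        try:
            count = int(cnt)
        except ValueError as exc:
            raise ValidationError(f"{path} row {i}: non-integer count {cnt!r}") from exc
        if count < 1:
            raise ValidationError(f"{path} row {i}: count {count} < 1")
        try:
            validate_cdr3(seq, allow_special=allow_special_chars)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        records.append(
            ClonotypeRecord(cdr3_aa=seq, count=count, v_gene=v or None, j_gene=j or None)
        )
    return Repertoire.from_records(
        subject_id or path.stem, records, clone_key=clone_key
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR-style clonotype TSV."""
    df = pd.DataFrame(
        {
            "junction_aa": [r.cdr3_aa for r in rep.records],
            "v_call": [r.v_gene or "" for r in rep.records],
            "j_call": [r.j_gene or "" for r in rep.records],
            "duplicate_count": [r.count for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_optional_float(value, field, subject):
    if value in ("", None) or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(
            f"subject {subject!r}: cannot parse {field}={value!r}"
        ) from exc


_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no", ""}


def _parse_bool(value, subject):
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"subject {subject!r}: cannot parse ggn={value!r}")


def read_metadata(path: str | Path) -> list[SubjectMetadata]:
    """Read subject metadata from a CSV/TSV file (sep inferred from suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
        raise ValidationError(f"{path}: duplicate subject_id(s): {dups}")
    out = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        out.append(
            SubjectMetadata(
                subject_id=sid,
                label=row["label"],
                stage=(row.get("stage") or None),
                ggn=_parse_bool(row.get("ggn", ""), sid),
                nodule_size_mm=_parse_optional_float(
                    row.get("nodule_size_mm", ""), "nodule_size_mm", sid
                ),
                age_years=_parse_optional_float(
                    row.get("age_years", ""), "age_years", sid
                ),
                sex=(row.get("sex") or None),
            )
        )
    return out


def write_metadata(metadata: Sequence[SubjectMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "subject_id": m.subject_id,
                "label": m.label,
                "stage": m.stage or "",
                "ggn": int(m.ggn),
                "nodule_size_mm": "" if m.nodule_size_mm is None else repr(float(m.nodule_size_mm)),
                "age_years": "" if m.age_years is None else repr(float(m.age_years)),
                "sex": m.sex or "",
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort feature table (subjects × features) as TSV.

    The index must hold subject ids.  Column order is preserved and values
    round-trip at full precision; missing values serialise as empty strings.
    """
    if table.empty:
        raise ValidationError("refusing to write an empty feature table")
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=True, index_label="subject_id", na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="subject_id", float_precision="round_trip"
    )
    return df
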