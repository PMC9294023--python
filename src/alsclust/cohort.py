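"""Ingestion and reduction of the raw per-subject metric tables.

Reads the four CSV tables (thickness, volumes + TIV, FA, clinical metadata),
validates them against the column vocabulary, normalises volumes by total
intracranial volume, and averages bilateral structures pairwise to produce the
74-variable reduced feature matrix (34 thickness + 17 volume-fraction + 23 FA
columns) that feeds the composite regional scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .vocabulary import TableVocabulary, load_vocabulary

METADATA_COLUMNS = [
    "age", "sex", "handedness", "education", "onset_site",
    "alsfrs_r", "ecas_impaired", "als_ftd", "c9orf72",
]
#: metadata columns where missing values are legitimate (instrument not
#: administered / subject not genotyped), not a data error
METADATA_MISSABLE = {"ecas_impaired", "c9orf72"}


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort input tables."""


@dataclass
class RawCohort:
    """Aligned raw metric tables for one cohort, indexed by subject id."""

    thickness: pd.DataFrame
    volumes: pd.DataFrame
    tiv: pd.Series
    fa: pd.DataFrame
    metadata: pd.DataFrame
    volumes_normalized: bool = False

    @property
    def subject_ids(self) -> list[str]:
        return list(self.thickness.index)

    @property
    def n_subjects(self) -> int:
        return len(self.thickness)


@dataclass
class ReducedFeatureMatrix:
    """N x 74 matrix after TIV normalisation and bilateral averaging."""

    values: pd.DataFrame
    column_roles: dict[str, str]          # column -> thickness | volume_fraction | fa
    pairing_provenance: dict[str, tuple[str, ...]]  # column -> source raw columns

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.values.columns if self.column_roles[c] == role]

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix with '#'-prefixed provenance header lines."""
        with open(path, "w") as fh:
            fh.write("# reduced feature matrix: 74 variables "
                     "(34 thickness, 17 volume-fraction, 23 FA)\n")
            for col in self.values.columns:
                src = ", ".join(self.pairing_provenance[col])
                fh.write(f"# {col} [{self.column_roles[col]}] <- {src}\n")
            self.values.to_csv(fh, index_label="subject_id")


@dataclass
class ValidationReport:
    """Outcome of structural validation of a raw cohort."""

    table_shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    missing_cells: list[tuple[str, str, str]] = field(default_factory=list)
    range_violations: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "fail" if (self.missing_cells or self.range_violations) else "pass"


def _read_table(path: str | Path, expected: list[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"{table} table not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    if df.columns[0] != "subject_id":
        raise CohortError(f"{table} table {path}: first column must be 'subject_id'")
    df = df.set_index("subject_id")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise CohortError(f"{table} table: duplicate subject ids {dups}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortError(f"{table} table: missing columns {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise CohortError(f"{table} table: unknown columns {unknown}")
    return df[expected]


def _coerce_numeric(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = df.notna() & out.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise CohortError(
            f"{table} table: non-numeric value {df.iloc[r, c]!r} "
            f"at subject {df.index[r]!r}, column {df.columns[c]!r}")
    return out


def read_feature_tables(
    thickness_path: str | Path,
    volumes_path: str | Path,
    fa_path: str | Path,
    metadata_path: str | Path,
    vocabulary: dict[str, TableVocabulary] | None = None,
) -> RawCohort:
    """Read and align the four cohort tables by subject id (inner join).

    Subjects absent from any table are dropped with a warning, as are subjects
    with missing metric cells (the pipeline does not impute).  Raises
    :class:`CohortError` on structural problems (missing files, unknown or
    missing columns, duplicate ids, non-numeric cells, out-of-range values).
    """
    vocab = vocabulary or load_vocabulary()
    th = _coerce_numeric(_read_table(thickness_path, vocab["thickness"].raw_columns,
                                     "thickness"), "thickness")
    vol_cols = vocab["volumes"].raw_columns
    vol_full = _read_table(volumes_path, vol_cols + ["tiv"], "volumes")
    vol_full = _coerce_numeric(vol_full, "volumes")
    fa = _coerce_numeric(_read_table(fa_path, vocab["fa"].raw_columns, "fa"), "fa")
    meta = _read_table(metadata_path, METADATA_COLUMNS, "metadata")

    ids = [set(t.index) for t in (th, vol_full, fa, meta)]
    common = sorted(set.intersection(*ids))
    dropped = sorted(set.union(*ids) - set(common))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} subjects absent from some tables: "
                      f"{dropped}", stacklevel=2)
    if not common:
        raise CohortError("no subjects common to all four tables")

    th, vol_full, fa, meta = (t.loc[common] for t in (th, vol_full, fa, meta))

    # reject (do not impute) subjects with missing metric cells
    complete = th.notna().all(axis=1) & vol_full.notna().all(axis=1) & fa.notna().all(axis=1)
    incomplete = sorted(th.index[~complete])
    if incomplete:
        warnings.warn(f"dropping {len(incomplete)} subjects with missing metric "
                      f"values: {incomplete}", stacklevel=2)
        th, vol_full, fa, meta = (t.loc[complete] for t in (th, vol_full, fa, meta))
    if th.empty:
        raise CohortError("no subjects with complete metric data")

    cohort = RawCohort(
        thickness=th,
        volumes=vol_full[vol_cols],
        tiv=vol_full["tiv"],
        fa=fa,
        metadata=meta,
    )
    report = validate_cohort(cohort)
    if report.verdict == "fail":
        raise CohortError(f"cohort validation failed: {report.range_violations or report.missing_cells}")
    return cohort


def validate_cohort(cohort: RawCohort) -> ValidationReport:
    """Structural validation: shapes, missing metric cells, physical ranges."""
    rep = ValidationReport()
    for name, df in (("thickness", cohort.thickness), ("volumes", cohort.volumes),
                     ("fa", cohort.fa), ("metadata", cohort.metadata)):
        rep.table_shapes[name] = df.shape
        if name != "metadata":
            for sid, col in zip(*np.where(df.isna().values)):
                rep.missing_cells.append((name, df.index[sid], df.columns[col]))
    if (cohort.tiv <= 0).any():
        bad = list(cohort.tiv.index[cohort.tiv <= 0])
        rep.range_violations.append(f"non-positive TIV for subjects {bad}")
    if (cohort.thickness.values <= 0).any():
        rep.range_violations.append("non-positive cortical thickness values")
    if ((cohort.fa.values < 0) | (cohort.fa.values > 1)).any():
        rep.range_violations.append("FA values outside [0, 1]")
    if not cohort.volumes_normalized and (cohort.volumes.values <= 0).any():
        rep.range_violations.append("non-positive volumes")
    meta_required = [c for c in METADATA_COLUMNS if c not in METADATA_MISSABLE]
    meta_missing = cohort.metadata[meta_required].isna()
    for sid, col in zip(*np.where(meta_missing.values)):
        rep.missing_cells.append(("metadata", meta_missing.index[sid],
                                  meta_missing.columns[col]))
    return rep


def normalize_volumes_by_tiv(cohort: RawCohort) -> RawCohort:
    """Express every volume as a fraction of the subject's intracranial volume.

    Stored as a fraction; the reporting layer renders percentages.  The TIV
    vector itself is passed through unchanged.
    """
    if cohort.volumes_normalized:
        return cohort
    if cohort.tiv.isna().any() or (cohort.tiv <= 0).any():
        raise CohortError("TIV missing or non-positive; cannot normalise volumes")
    fractions = cohort.volumes.div(cohort.tiv, axis=0)
    return replace(cohort, volumes=fractions, volumes_normalized=True)


def average_bilateral(
    cohort: RawCohort,
    vocabulary: dict[str, TableVocabulary] | None = None,
) -> ReducedFeatureMatrix:
    """Average left/right pairs and pass midline singletons through.

    Requires TIV-normalised volumes so the reduced volume columns are
    head-size-free fractions.  Produces exactly 74 columns
    (34 thickness, 17 volume-fraction, 23 FA).
    """
    if not cohort.volumes_normalized:
        raise CohortError("volumes must be TIV-normalised before bilateral averaging")
    vocab = vocabulary or load_vocabulary()
    role_of_table = {"thickness": "thickness", "volumes": "volume_fraction", "fa": "fa"}

    pieces, roles, provenance = [], {}, {}
    for table, df in (("thickness", cohort.thickness), ("volumes", cohort.volumes),
                      ("fa", cohort.fa)):
        pairing = vocab[table].pairing_map()
        reduced = {}
        for red_col, sources in pairing.items():
            for s in sources:
                if s not in df.columns:
                    raise CohortError(f"pairing map references unknown column {s!r} "
                                      f"in {table} table")
            reduced[red_col] = df[list(sources)].mean(axis=1)
            roles[red_col] = role_of_table[table]
            provenance[red_col] = sources
        covered = {s for srcs in pairing.values() for s in srcs}
        uncovered = [c for c in df.columns if c not in covered]
        if uncovered:
            raise CohortError(f"{table} columns not covered by pairing map: {uncovered}")
        pieces.append(pd.DataFrame(reduced, index=df.index))

    values = pd.concat(pieces, axis=1)
    assert values.shape[1] == 74, values.shape
    return ReducedFeatureMatrix(values=values, column_roles=roles,
                                pairing_provenance=provenance)
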