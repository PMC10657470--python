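"""Readers and writers for the tabular interchange formats.

Three formats move data in and out of the pipeline:

* MetaPhlAn-style merged species profiles — TSV, taxa in rows (full
  ``k__...|s__...`` lineages or bare species names), samples in columns,
  values on the percent scale.
* HUMAnN-style pathway abundance tables — TSV, ``PWY: name`` community
  rows plus ``PWY: name|g__X.s__Y`` taxon-stratified rows, and the
  special UNMAPPED / UNINTEGRATED rows.
* Plain CSV for subject metadata and longitudinal outcomes.

Tables are held as thin dataclasses around pandas DataFrames oriented
samples x features; validation enforces the compositional invariants at
construction.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SpeciesAbundanceTable",
    "PathwayAbundanceTable",
    "CohortTable",
    "read_species_table",
    "read_pathway_table",
    "read_cohort_table",
    "read_outcome_panel",
    "write_tables",
    "retention_percent",
    "STRATUM_SEP",
    "NON_PATHWAY_KEYS",
]

STRATUM_SEP = "|"
#: HUMAnN bookkeeping rows that are not metabolic pathways.
NON_PATHWAY_KEYS = frozenset({"UNMAPPED", "UNINTEGRATED"})

_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Raised when a file does not parse as the expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a table invariant."""


# ---------------------------------------------------------------------------
# table containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesAbundanceTable:
    """Samples x species relative abundances on the percent scale [0, 100]."""

    data: pd.DataFrame  # index: sample ids, columns: species names

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate species names")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite abundance value")
        if (values < 0).any():
            raise ValidationError("negative abundance value")
        sums = values.sum(axis=1)
        bad = sums > 100.0 + _SUM_TOL
        if bad.any():
            which = df.index[bad][0]
            raise ValidationError(
                f"sample {which!r}: species abundances sum to {sums[bad][0]:.6f} > 100"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.data.columns)

    def to_proportions(self) -> pd.DataFrame:
        """Percent -> proportion scale used by all internal analyses."""
        return self.data / 100.0


@dataclass
class PathwayAbundanceTable:
    """Samples x pathway rows (community totals and ``pathway|taxon`` strata)."""

    data: pd.DataFrame  # index: sample ids, columns: row keys

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate row keys")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite pathway abundance")
        if (values < 0).any():
            raise ValidationError("negative pathway abundance")
        for pwy in self.pathway_keys:
            strata = self.stratified_keys(pwy)
            if not strata:
                continue
            strat_sum = df[strata].sum(axis=1)
            total = df[pwy]
            tol = _SUM_TOL + 1e-9 * np.maximum(total, 1.0)
            bad = strat_sum > total + tol
            if bad.any():
                which = df.index[bad][0]
                raise ValidationError(
                    f"pathway {pwy!r}, sample {which!r}: stratified sum "
                    f"{strat_sum[bad].iloc[0]:.6f} exceeds community total "
                    f"{total[bad].iloc[0]:.6f}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def row_keys(self) -> list[str]:
        return list(self.data.columns)

    @property
    def pathway_keys(self) -> list[str]:
        """Community-total rows, excluding UNMAPPED/UNINTEGRATED bookkeeping."""
        return [
            key
            for key in self.data.columns
            if STRATUM_SEP not in key and _pathway_id(key) not in NON_PATHWAY_KEYS
        ]

    def stratified_keys(self, pathway_key: str) -> list[str]:
        prefix = pathway_key + STRATUM_SEP
        return [key for key in self.data.columns if key.startswith(prefix)]


@dataclass
class CohortTable:
    """One row per subject: demographics, BMI and days since trauma."""

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("age", "sex", "bmi", "race_ethnicity", "days_since_trauma", "sample_id")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.name != "subject_id":
            raise ValidationError("cohort table must be indexed by subject_id")
        if df.index.has_duplicates:
            raise ValidationError("duplicate subject ids")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if (df["days_since_trauma"].astype(float) < 0).any():
            raise ValidationError("negative days_since_trauma")
        bad_sex = set(df["sex"].unique()) - {"female", "male"}
        if bad_sex:
            raise ValidationError(f"unrecognized sex values: {sorted(bad_sex)}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("a sample id is linked to more than one subject")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _read_tsv_lines(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Split a TSV into (header fields, data rows), honouring '#' comments.

    A leading comment line that itself contains tabs is treated as the
    header (HUMAnN writes ``# Pathway\\t<sample>...``; MetaPhlAn writes
    ``#clade_name\\t<sample>...``).
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#"):
                    if "\t" in line:
                        header = line.lstrip("#").strip().split("\t")
                    continue  # plain comment before the header
                header = line.split("\t")
                continue
            if line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if header is None or len(header) < 2:
        raise FormatError(f"{path}: no tab-separated header with sample columns found")
    width = len(header)
    for row in rows:
        if len(row) != width:
            raise FormatError(
                f"{path}: row {row[0]!r} has {len(row)} fields, header has {width}"
            )
    return header, rows


def _parse_values(rows: list[list[str]], path: str | Path) -> tuple[list[str], np.ndarray]:
    keys = [r[0] for r in rows]
    try:
        values = np.array([[float(x) for x in r[1:]] for r in rows], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from None
    return keys, values


_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")


def is_species_level(lineage: str) -> bool:
    """True for rows whose deepest rank is species (s__ present, no t__).

    Bare names without any rank prefix (``Escherichia coli``) count as
    species-level: merged profiles sometimes carry terminal names only.
    """
    parts = lineage.split("|")
    last = parts[-1]
    if not any(last.startswith(p) for p in _RANK_PREFIXES):
        return "__" not in last
    return last.startswith("s__")


def read_species_table(path: str | Path) -> SpeciesAbundanceTable:
    """Parse a merged species-profile TSV, keeping species-level rows only."""
    header, rows = _read_tsv_lines(path)
    sample_ids = header[1:]
    rows = [r for r in rows if is_species_level(r[0])]
    keys, values = _parse_values(rows, path)
    df = pd.DataFrame(values.T, index=pd.Index(sample_ids, name="sample_id"), columns=keys)
    return SpeciesAbundanceTable(df)


def read_pathway_table(path: str | Path) -> PathwayAbundanceTable:
    """Parse a pathway-abundance TSV with '|'-stratified taxon rows."""
    header, rows = _read_tsv_lines(path)
    sample_ids = header[1:]
    keys, values = _parse_values(rows, path)
    df = pd.DataFrame(values.T, index=pd.Index(sample_ids, name="sample_id"), columns=keys)
    return PathwayAbundanceTable(df)


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing subject_id column")
    return CohortTable(df.set_index("subject_id"))


def read_outcome_panel(path: str | Path) -> pd.DataFrame:
    """Long-format outcomes CSV: subject_id, week, pcl5_raw, promis_t, somatic_count."""
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "week"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: outcome panel needs columns {sorted(required)}")
    if df.duplicated(["subject_id", "week"]).any():
        raise ValidationError(f"{path}: duplicate (subject, week) rows")
    return df


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _write_feature_table(df: pd.DataFrame, path: Path, first_col: str) -> None:
    # features in rows, samples in columns, full float precision for an
    # exact read(write(x)) round trip
    out = df.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(first_col + "".join("\t" + str(s) for s in df.index) + "\n")
        for key, row in out.iterrows():
            fh.write(str(key) + "".join(f"\t{float(v)!r}" for v in row.to_numpy()) + "\n")


def write_tables(tables: dict[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write any mix of the pipeline's tables to ``out_dir``.

    Keys become file stems; formats follow the table type (TSV for
    abundance tables, CSV otherwise). Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        if isinstance(table, SpeciesAbundanceTable):
            p = out_dir / f"{name}.tsv"
            _write_feature_table(table.data, p, "#clade_name")
        elif isinstance(table, PathwayAbundanceTable):
            p = out_dir / f"{name}.tsv"
            _write_feature_table(table.data, p, "# Pathway")
        elif isinstance(table, CohortTable):
            p = out_dir / f"{name}.csv"
            table.data.reset_index().to_csv(p, index=False)
        elif isinstance(table, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            table.to_csv(p, index=False)
        else:
            raise TypeError(f"{name}: cannot write object of type {type(table).__name__}")
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# cohort accounting
# ---------------------------------------------------------------------------


def retention_percent(numerator: int, denominator: int) -> float:
    """Retention as a percent, half-up rounded to one decimal.

    ``retention_percent(74, 106) == 69.8`` — the kind of cohort-flow
    number reported in enrollment accounting.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    pct = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    return float(pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def _pathway_id(key: str) -> str:
    return key.split(":", 1)[0].strip()
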