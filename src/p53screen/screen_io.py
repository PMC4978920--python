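"""Data model and tabular I/O for arrayed siRNA expression screens.

The screen measures three p53 target transcripts (CDKN1A/p21, BBC3/puma and
TP53/p53) under two treatments (DMSO vehicle and the DNA-damaging agent
etoposide), each normalized to the reference transcript LMNA.  The central
in-memory object is :class:`ScreenMatrix`: a gene x 6-condition grid of
reference-normalized expression ratios, with an accompanying per-gene role
annotation that distinguishes library siRNAs from dedicated control wells.

Interchange formats are plain CSV/TSV: a tidy long table is canonical, a wide
per-gene matrix is accepted for convenience.  Missing values are written as
``NA`` and accepted as ``NA`` or an empty field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, VocabularyError

READOUTS: tuple[str, ...] = ("CDKN1A", "BBC3", "TP53")
TREATMENTS: tuple[str, ...] = ("DMSO", "etoposide")
REFERENCE_GENE = "LMNA"

#: The six (readout, treatment) conditions in fixed column order.
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    (r, t) for r in READOUTS for t in TREATMENTS
)

ROLES: tuple[str, ...] = (
    "library",
    "nontargeting_control",
    "tp53_control",
    "mdm2_control",
)

#: Role tokens allowed in long Ct tables in addition to sample roles.
CT_EXTRA_ROLES: tuple[str, ...] = ("standard",)


def condition_label(readout: str, treatment: str) -> str:
    """Column label for a (readout, treatment) condition, e.g. ``"CDKN1A:DMSO"``."""
    return f"{readout}:{treatment}"


def parse_condition(label: str) -> tuple[str, str]:
    """Inverse of :func:`condition_label`; validates both tokens."""
    try:
        readout, treatment = label.split(":")
    except ValueError:
        raise VocabularyError(f"malformed condition label {label!r}") from None
    if readout not in READOUTS:
        raise VocabularyError(f"unknown readout {readout!r}")
    if treatment not in TREATMENTS:
        raise VocabularyError(f"unknown treatment {treatment!r}")
    return readout, treatment


#: Fixed column order of every ScreenMatrix.
COLUMN_LABELS: tuple[str, ...] = tuple(condition_label(r, t) for r, t in CONDITIONS)


@dataclass(frozen=True)
class SiRNAEntry:
    """One physical well in the arrayed library.

    Parameters
    ----------
    gene_symbol : str
        Target gene (or control identifier for dedicated control wells).
    role : str
        One of :data:`ROLES`.
    plate_id, well_id : str
        Physical location, e.g. plate ``"P03"``, well ``"A01"``.
    """

    gene_symbol: str
    role: str
    plate_id: str
    well_id: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise SchemaError("gene_symbol must be non-empty")
        if self.role not in ROLES:
            raise VocabularyError(f"unknown siRNA role {self.role!r}")


def validate_library(entries: Sequence[SiRNAEntry]) -> None:
    """Check plate-map invariants.

    Raises
    ------
    SchemaError
        If a (plate, well) position is duplicated, or a plate that carries
        library siRNAs lacks any of the three control roles (every screening
        plate carries a nontargeting, a TP53 and an MDM2 control).
    """
    seen: set[tuple[str, str]] = set()
    plates: dict[str, set[str]] = {}
    for e in entries:
        pos = (e.plate_id, e.well_id)
        if pos in seen:
            raise SchemaError(f"duplicate well {e.well_id} on plate {e.plate_id}")
        seen.add(pos)
        plates.setdefault(e.plate_id, set()).add(e.role)
    required = {"nontargeting_control", "tp53_control", "mdm2_control"}
    for plate_id, roles in plates.items():
        if "library" in roles and not required <= roles:
            missing = ", ".join(sorted(required - roles))
            raise SchemaError(f"plate {plate_id} lacks control roles: {missing}")


@dataclass
class ScreenMatrix:
    """Gene x condition grid of reference-normalized expression values.

    Attributes
    ----------
    values : pandas.DataFrame
        Index = gene symbols in first-appearance order, columns =
        :data:`COLUMN_LABELS`.  Missing cells are NaN; all present values are
        finite and non-negative (expression ratios cannot be negative).
    roles : pandas.Series
        Gene -> role (one of :data:`ROLES`); defaults to ``"library"``.
    """

    values: pd.DataFrame
    roles: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.roles is None:
            self.roles = pd.Series("library", index=self.values.index)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if tuple(self.values.columns) != COLUMN_LABELS:
            raise SchemaError(
                f"matrix columns must be {list(COLUMN_LABELS)}, "
                f"got {list(self.values.columns)}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate gene symbols: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if not np.isfinite(arr[present]).all():
            raise ParseError("non-finite expression value in matrix")
        if (arr[present] < 0).any():
            raise ParseError("negative expression value in matrix")
        unknown = set(self.roles.unique()) - set(ROLES)
        if unknown:
            raise VocabularyError(f"unknown roles {sorted(unknown)}")
        if not self.roles.index.equals(self.values.index):
            self.roles = self.roles.reindex(self.values.index).fillna("library")

    # -- convenience --------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def library_genes(self) -> list[str]:
        return list(self.values.index[self.roles == "library"])

    def subset(self, genes: Iterable[str]) -> "ScreenMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ScreenMatrix(self.values.loc[genes].copy(), self.roles.loc[genes].copy())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_LONG_REQUIRED = ("gene", "readout", "treatment", "value")
_CT_REQUIRED = ("gene", "readout", "treatment", "replicate", "ct")


def _read_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty input file: {path}") from None
    if df.empty and df.columns.empty:
        raise SchemaError(f"empty input file: {path}")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    """Parse a string column to float; '' and 'NA' become NaN, else strict."""
    raw = df[col].str.strip()
    missing = (raw == "") | (raw.str.upper() == "NA")
    parsed = pd.to_numeric(raw.where(~missing, np.nan), errors="coerce")
    bad = parsed.isna() & ~missing
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric {col!r} value {raw.iloc[row]!r} "
            f"at data row {row + 1}"
        )
    return parsed


def _check_vocab(df: pd.DataFrame, path: Path, *, allow_reference: bool) -> None:
    readouts = set(READOUTS) | ({REFERENCE_GENE} if allow_reference else set())
    bad_r = set(df["readout"]) - readouts
    if bad_r:
        raise VocabularyError(f"{path}: unknown readout token(s) {sorted(bad_r)}")
    bad_t = set(df["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise VocabularyError(f"{path}: unknown treatment token(s) {sorted(bad_t)}")
    if "role" in df.columns:
        allowed = set(ROLES) | set(CT_EXTRA_ROLES) | {""}
        bad_role = set(df["role"]) - allowed
        if bad_role:
            raise VocabularyError(f"{path}: unknown role token(s) {sorted(bad_role)}")


def read_screen_table(
    path: str | Path,
    schema: str = "normalized_long",
    column_map: Mapping[str, str] | None = None,
) -> ScreenMatrix | pd.DataFrame:
    """Read a screen table.

    Parameters
    ----------
    path : path
        CSV (comma) or TSV (tab, by extension) file.
    schema : {"normalized_long", "ct_long", "matrix"}
        ``normalized_long``: tidy table with columns gene, readout, treatment,
        value [, role] -> returns a :class:`ScreenMatrix`.
        ``ct_long``: raw Ct records with columns gene, readout, treatment,
        replicate, ct [, role, quantity] -> returns a DataFrame of records
        (LMNA rows and ``standard`` curve rows allowed).
        ``matrix``: wide table, one row per gene, condition columns named as in
        :data:`COLUMN_LABELS` -> returns a :class:`ScreenMatrix`.
    column_map : mapping, optional
        Rename map applied to file columns before validation, so tables with
        different headers can be ingested without editing the file.
    """
    path = Path(path)
    df = _read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))

    if schema == "normalized_long":
        _require_columns(df, _LONG_REQUIRED, path)
        _check_vocab(df, path, allow_reference=False)
        df = df.assign(value=_numeric(df, "value", path))
        key = ["gene", "readout", "treatment"]
        dup = df.duplicated(subset=key)
        if dup.any():
            row = df.loc[dup, key].iloc[0].tolist()
            raise SchemaError(f"{path}: duplicate (gene, readout, treatment) row {row}")
        genes = list(dict.fromkeys(df["gene"]))  # first-appearance order
        values = pd.DataFrame(np.nan, index=genes, columns=list(COLUMN_LABELS))
        labels = df["readout"].str.cat(df["treatment"], sep=":")
        for gene, label, value in zip(df["gene"], labels, df["value"]):
            values.at[gene, label] = value
        roles = pd.Series("library", index=genes)
        if "role" in df.columns:
            per_gene = df.groupby("gene", sort=False)["role"].first()
            roles.update(per_gene.replace("", "library"))
        return ScreenMatrix(values, roles)

    if schema == "ct_long":
        _require_columns(df, _CT_REQUIRED, path)
        _check_vocab(df, path, allow_reference=True)
        out = df.copy()
        out["replicate"] = _numeric(df, "replicate", path).astype("Int64")
        out["ct"] = _numeric(df, "ct", path)
        if "quantity" in df.columns:
            out["quantity"] = _numeric(df, "quantity", path)
        if "role" not in out.columns:
            out["role"] = "library"
        out["role"] = out["role"].replace("", "library")
        samples = out[out["role"] != "standard"]
        key = ["gene", "readout", "treatment", "replicate"]
        dup = samples.duplicated(subset=key)
        if dup.any():
            row = samples.loc[dup, key].iloc[0].tolist()
            raise SchemaError(f"{path}: duplicate Ct record {row}")
        return out

    if schema == "matrix":
        gene_col = df.columns[0] if "gene" not in df.columns else "gene"
        missing = [c for c in COLUMN_LABELS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing condition column {missing[0]!r}")
        values = pd.DataFrame(
            {c: _numeric(df, c, path).to_numpy() for c in COLUMN_LABELS},
            index=list(df[gene_col]),
        )
        if values.index.has_duplicates:
            raise SchemaError(f"{path}: duplicate gene rows")
        roles = pd.Series("library", index=values.index)
        if "role" in df.columns:
            roles = df.set_index(gene_col)["role"].replace("", "library")
        return ScreenMatrix(values, roles)

    raise ValueError(f"unknown schema {schema!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_screen_table(
    matrix: ScreenMatrix, path: str | Path, format: str = "long"
) -> Path:
    """Write a :class:`ScreenMatrix` as tidy long CSV (default) or wide TSV.

    Values are written at full precision (``%.17g``); NaN becomes ``NA``.
    ``read_screen_table(write_screen_table(m))`` is the identity on values,
    gene order and missingness.
    """
    path = Path(path)
    if format == "long":
        rows = []
        for gene in matrix.genes:
            role = matrix.roles[gene]
            for (readout, treatment), label in zip(CONDITIONS, COLUMN_LABELS):
                rows.append(
                    (gene, readout, treatment, matrix.values.at[gene, label], role)
                )
        out = pd.DataFrame(
            rows, columns=["gene", "readout", "treatment", "value", "role"]
        )
        out.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    elif format == "matrix":
        out = matrix.values.copy()
        out.insert(0, "role", matrix.roles)
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


_HIT_TABLE_FILES = {
    "joint": "joint_regulators.tsv",
    "CDKN1A_specific": "CDKN1A_specific_regulators.tsv",
    "BBC3_specific": "BBC3_specific_regulators.tsv",
    "TP53_specific": "TP53_specific_regulators.tsv",
}
_HIT_TABLE_COLUMNS = (
    "direction",
    "condition",
    "gene",
    "z",
    "secondary_flag",
    "low_expression_flag",
)


def write_hit_tables(classification, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per regulator category (joint / per-readout specific).

    Within each (direction, condition) group genes are ordered by decreasing
    |z|, i.e. strongest to weakest phenotypic effect.  Returns a mapping
    category -> written path.  An empty classification yields header-only
    files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    for category, fname in _HIT_TABLE_FILES.items():
        rows = classification.category_rows(category)
        df = pd.DataFrame(rows, columns=list(_HIT_TABLE_COLUMNS))
        if not df.empty:
            df = df.sort_values(
                ["direction", "condition", "z"],
                key=lambda s: s.abs() if s.name == "z" else s,
                ascending=[True, True, False],
                kind="mergesort",
            )
        path = out_dir / fname
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[category] = path
    return written


def write_manifest(path: str | Path, manifest: Mapping) -> Path:
    """Serialize a run manifest (inputs, hashes, thresholds, seed) as JSON."""
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
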