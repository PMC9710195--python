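"""Domain tables and the delimited-text / BED / JSON artifacts.

The package is DataFrame-centric: SNPs, eQTL annotations, differential
expression (DE) gene sets and the sample design are plain ``pandas``
tables with documented column schemas, validated at the I/O boundary.
All coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read.

SNP table columns
-----------------
snp_id        opaque string key (unique)
arm           chromosome arm, one of {2L, 2R, 3L, 3R}
pos           1-based position in base pairs
het           expected heterozygosity in [0, 0.5]
clinal_p      p-value of the cross-population latitude model, in (0, 1]
clinal_beta   signed change of focal-allele frequency per degree latitude
seasonal_p    p-value of the cross-population spring/fall model, in (0, 1]
seasonal_beta signed spring-minus-fall effect on focal-allele frequency
is_eqtl       boolean eQTL flag
freq_<sample> optional focal-allele frequency columns, one per sample

Every signed per-SNP quantity (frequency, beta, allelic effect) is
polarized to a single designated focal allele per SNP, fixed at input
time; the ``dialect`` mapping of :func:`read_snp_table` lets callers
rename columns from whatever their upstream model produced.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

ARMS = ("2L", "2R", "3L", "3R")
SEX_CLASSES = ("female", "male", "non_sex_biased")
DE_LABELS = (
    "latitudinal",
    "heat_shock",
    "chill_coma",
    "starvation",
    "high_temp",
    "low_temp",
)

SNP_REQUIRED_COLUMNS = (
    "snp_id",
    "arm",
    "pos",
    "het",
    "clinal_p",
    "clinal_beta",
    "seasonal_p",
    "seasonal_beta",
)
SNP_NUMERIC_COLUMNS = (
    "pos",
    "het",
    "clinal_p",
    "clinal_beta",
    "seasonal_p",
    "seasonal_beta",
)

FREQ_PREFIX = "freq_"


@dataclasses.dataclass(frozen=True)
class InversionDef:
    """A cosmopolitan inversion: arm, 1-based inclusive span, breakpoint margin.

    ``margin`` is the half-width of the breakpoint zone around each
    endpoint (default 0.5 Mb).
    """

    name: str
    arm: str
    start: int
    end: int
    margin: int = 500_000

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"inversion {self.name!r}: unknown arm {self.arm!r}")
        if not self.start < self.end:
            raise DataError(
                f"inversion {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.margin < 0:
            raise DataError(f"inversion {self.name!r}: margin must be >= 0")


@dataclasses.dataclass(frozen=True)
class DeGeneSet:
    """A differential-expression gene set with per-gene direction signs.

    ``entries`` maps gene_id -> de_sign, where +1 means higher expression
    in the north (latitudinal set) or upregulated by the treatment, and
    -1 the converse.
    """

    label: str
    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.label not in DE_LABELS:
            raise ConfigError(
                f"unknown DE set label {self.label!r}; expected one of {DE_LABELS}"
            )
        bad = {g: s for g, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise DataError(f"DE set {self.label!r}: de_sign must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.entries)


def _delimiter_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_snp_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a SNP statistics table (TSV default, CSV by suffix).

    ``dialect`` maps internal column names to the names used in the file,
    e.g. ``{"clinal_p": "clinal.p"}``.  Rows violating an invariant are
    reported with their 1-based data row numbers and the offending field.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={"snp_id": str, "arm": str})
    if dialect:
        rename = {file_col: internal for internal, file_col in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in SNP_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"SNP table {path} is missing required column(s): {missing}")
    for col in SNP_NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 1
        if len(bad):
            raise DataError(
                f"SNP table {path}: non-numeric value in column {col!r} "
                f"at row(s) {list(bad[:10])}"
            )
        if coerced.isna().any():
            rows = list((df.index[coerced.isna()] + 1)[:10])
            raise DataError(f"SNP table {path}: missing value in {col!r} at row(s) {rows}")
        df[col] = coerced
    if "is_eqtl" not in df.columns:
        df["is_eqtl"] = False
    df["is_eqtl"] = df["is_eqtl"].astype(bool)
    df["pos"] = df["pos"].astype(np.int64)
    validate_snp_table(df, source=str(path))
    return df.reset_index(drop=True)


def validate_snp_table(df: pd.DataFrame, source: str = "SNP table") -> None:
    """Enforce the SNP-table invariants; raise ``DataError`` naming rows."""

    def _reject(mask: pd.Series, field: str, rule: str) -> None:
        if mask.any():
            rows = list((df.index[mask] + 1)[:10])
            raise DataError(f"{source}: {field} {rule} at row(s) {rows}")

    _reject(~df["arm"].isin(ARMS), "arm", f"must be one of {ARMS}")
    _reject(df["pos"] < 1, "pos", "must be >= 1")
    _reject((df["het"] < 0) | (df["het"] > 0.5), "het", "must lie in [0, 0.5]")
    for col in ("clinal_p", "seasonal_p"):
        _reject((df[col] <= 0) | (df[col] > 1), col, "must lie in (0, 1]")
    for col in df.columns:
        if col.startswith(FREQ_PREFIX):
            _reject((df[col] < 0) | (df[col] > 1), col, "must lie in [0, 1]")
    dup = df.duplicated(subset=["arm", "pos"], keep=False)
    _reject(dup, "(arm, pos)", "must be unique")
    if df["snp_id"].duplicated().any():
        raise DataError(f"{source}: snp_id values must be unique")


def read_eqtl_table(path) -> pd.DataFrame:
    """Read an eQTL annotation table: snp_id, gene_id, sex_class, effect_sign."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={"snp_id": str, "gene_id": str})
    missing = [c for c in ("snp_id", "gene_id", "sex_class", "effect_sign") if c not in df.columns]
    if missing:
        raise ConfigError(f"eQTL table {path} is missing required column(s): {missing}")
    df["effect_sign"] = pd.to_numeric(df["effect_sign"], errors="raise").astype(int)
    validate_eqtl_table(df, source=str(path))
    return df.reset_index(drop=True)


def validate_eqtl_table(df: pd.DataFrame, snps: pd.DataFrame | None = None,
                        source: str = "eQTL table") -> None:
    """Check eQTL annotation invariants, optionally against a SNP table."""
    if not df["sex_class"].isin(SEX_CLASSES).all():
        bad = sorted(set(df["sex_class"]) - set(SEX_CLASSES))
        raise DataError(f"{source}: unknown sex_class value(s) {bad}")
    if not df["effect_sign"].isin([1, -1]).all():
        raise DataError(f"{source}: effect_sign must be +1 or -1")
    if df.duplicated(subset=["snp_id", "gene_id"]).any():
        raise DataError(f"{source}: duplicate (snp_id, gene_id) pairs")
    if snps is not None:
        eqtl_ids = set(snps.loc[snps["is_eqtl"], "snp_id"])
        orphans = set(df["snp_id"]) - eqtl_ids
        if orphans:
            raise DataError(
                f"{source}: {len(orphans)} snp_id(s) absent from the SNP table "
                f"or not flagged is_eqtl, e.g. {sorted(orphans)[:5]}"
            )


def read_de_sets(path) -> dict[str, DeGeneSet]:
    """Read DE gene sets from a long TSV with columns label, gene_id, de_sign."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={"gene_id": str, "label": str})
    missing = [c for c in ("label", "gene_id", "de_sign") if c not in df.columns]
    if missing:
        raise ConfigError(f"DE set table {path} is missing required column(s): {missing}")
    out: dict[str, DeGeneSet] = {}
    for label, grp in df.groupby("label", sort=True):
        out[label] = DeGeneSet(
            label=label,
            entries=dict(zip(grp["gene_id"], grp["de_sign"].astype(int))),
        )
    return out


def read_sample_design(path) -> pd.DataFrame:
    """Read the sample design: sample_id, locality, role, latitude, pair_id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    missing = [c for c in ("sample_id", "locality", "role") if c not in df.columns]
    if missing:
        raise ConfigError(f"sample design {path} is missing required column(s): {missing}")
    if "latitude" in df.columns:
        df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    else:
        df["latitude"] = np.nan
    if "pair_id" not in df.columns:
        df["pair_id"] = None
    validate_sample_design(df, source=str(path))
    return df.reset_index(drop=True)


def validate_sample_design(df: pd.DataFrame, source: str = "sample design") -> None:
    if not df["role"].isin(["clinal", "spring", "fall"]).all():
        raise DataError(f"{source}: role must be clinal, spring or fall")
    clinal = df[df["role"] == "clinal"]
    if clinal["latitude"].isna().any():
        raise DataError(f"{source}: clinal samples must carry a latitude")
    seasonal = df[df["role"].isin(["spring", "fall"])]
    for pair_id, grp in seasonal.groupby("pair_id"):
        roles = sorted(grp["role"])
        if roles != ["fall", "spring"]:
            raise DataError(
                f"{source}: pair {pair_id!r} must have exactly one spring and "
                f"one fall sample, got roles {roles}"
            )


def read_inversions_bed(path) -> list[InversionDef]:
    """Read inversion spans from a BED3+ file (chrom = arm, optional name col).

    BED coordinates are 0-based half-open; internal coordinates are
    1-based inclusive, so start = BED start + 1 and end = BED end.
    Interval length is preserved: end - start + 1 == BED end - BED start.
    """
    out: list[InversionDef] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: BED line needs >= 3 fields")
            arm, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{arm}:{bed_start}-{bed_end}"
            start, end = bed_start + 1, bed_end
            if start >= end + 1 or bed_start >= bed_end:
                raise DataError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"({bed_start}, {bed_end})"
                )
            out.append(InversionDef(name=name, arm=arm, start=start, end=end))
    return out


def write_inversions_bed(inversions: Sequence[InversionDef], path) -> None:
    with open(path, "w") as fh:
        for inv in inversions:
            fh.write(f"{inv.arm}\t{inv.start - 1}\t{inv.end}\t{inv.name}\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result/input table as TSV with 12-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_de_sets(de_sets: Mapping[str, DeGeneSet], path) -> None:
    rows = [
        {"label": s.label, "gene_id": g, "de_sign": sign}
        for s in de_sets.values()
        for g, sign in sorted(s.entries.items())
    ]
    write_table(pd.DataFrame(rows, columns=["label", "gene_id", "de_sign"]), path)


def write_results(results: Iterable, path) -> pd.DataFrame:
    """Serialize a collection of result records (dataclasses) to one TSV.

    Returns the frame written.  Array-valued fields (the raw null
    distributions) are dropped from the tabular form; they remain
    available on the in-memory objects.
    """
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        rows.append(
            {
                k: (",".join(map(str, v)) if isinstance(v, (tuple, list)) else v)
                for k, v in d.items()
                if v is not None and not isinstance(v, np.ndarray)
            }
        )
    df = pd.DataFrame(rows)
    write_table(df, path)
    return df


def write_run_summary(summary: Mapping, path) -> None:
    """Write the JSON run summary (parameters, seed, counts, decision flags)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_run_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
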