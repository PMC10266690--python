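"""Readers, writers and run configuration for the survey tables.

All on-disk formats are plain TSV/CSV. The metabarcoding observation unit
is an ASV-by-replicate read table whose column labels encode the replicate
key ``site / bottle / pcr / marker`` joined by a configurable delimiter
(default ``__``). In memory the table is a :class:`pandas.DataFrame` with a
4-level column MultiIndex carrying the parsed keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

DEFAULT_DELIMITER = "__"

#: Column-level names of a read table's replicate-key MultiIndex.
KEY_FIELDS = ("site", "bottle", "pcr", "marker")

#: Survey methods understood by the long-format survey-record reader.
KNOWN_METHODS = ("seine", "bruv", "edna")


class FormatError(ValueError):
    """A table or label does not conform to the expected format."""


@dataclass(frozen=True)
class ReplicateKey:
    """Identity of one technical PCR replicate.

    ``bottle`` indexes the replicate water sample taken at a site and
    ``pcr`` the replicate amplification of that bottle's extract;
    ``marker`` names the primer set (e.g. teleost vs elasmobranch).
    """

    site: str
    bottle: int
    pcr: int
    marker: str

    def __post_init__(self) -> None:
        if not str(self.site).strip():
            raise FormatError("replicate key: site must be non-empty")
        if not str(self.marker).strip():
            raise FormatError("replicate key: marker must be non-empty")
        for name in ("bottle", "pcr"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise FormatError(
                    f"replicate key: {name} must be an integer >= 1, got {value!r}"
                )

    def format(self, delimiter: str = DEFAULT_DELIMITER) -> str:
        return delimiter.join(
            [self.site, str(self.bottle), str(self.pcr), self.marker]
        )


def parse_replicate_key(label: str, delimiter: str = DEFAULT_DELIMITER) -> ReplicateKey:
    """Parse a replicate column label into a :class:`ReplicateKey`.

    Raises :class:`FormatError` naming the offending field on malformed
    labels; round-trips through :meth:`ReplicateKey.format`.
    """
    parts = str(label).split(delimiter)
    if len(parts) != 4:
        raise FormatError(
            f"replicate label {label!r}: expected 4 fields "
            f"site{delimiter}bottle{delimiter}pcr{delimiter}marker, got {len(parts)}"
        )
    site, bottle_s, pcr_s, marker = parts
    values: dict[str, int] = {}
    for name, raw in (("bottle", bottle_s), ("pcr", pcr_s)):
        try:
            values[name] = int(raw)
        except ValueError:
            raise FormatError(
                f"replicate label {label!r}: field {name!r} is not an integer: {raw!r}"
            ) from None
    return ReplicateKey(site=site, bottle=values["bottle"], pcr=values["pcr"], marker=marker)


def format_replicate_key(key: ReplicateKey, delimiter: str = DEFAULT_DELIMITER) -> str:
    return key.format(delimiter)


def keys_to_columns(keys: Iterable[ReplicateKey]) -> pd.MultiIndex:
    keys = list(keys)
    tuples = [(k.site, k.bottle, k.pcr, k.marker) for k in keys]
    if len(set(tuples)) != len(tuples):
        raise FormatError("duplicate replicate keys in table")
    return pd.MultiIndex.from_tuples(tuples, names=list(KEY_FIELDS))


def read_read_table(
    path: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read an ASV-by-replicate read-count table.

    First column holds ASV identifiers, the remaining column headers are
    replicate labels. Cells must be nonnegative integers; offending cells
    are reported with row/column coordinates.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "asv_id"
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate ASV ids: {dups}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = numeric.index[numeric.isna()][0]
            raise FormatError(f"non-numeric read count at row {row!r}, column {col!r}")
        if (numeric % 1 != 0).any():
            row = numeric.index[numeric % 1 != 0][0]
            raise FormatError(f"non-integer read count at row {row!r}, column {col!r}")
        if (numeric < 0).any():
            row = numeric.index[numeric < 0][0]
            raise FormatError(f"negative read count at row {row!r}, column {col!r}")
        df[col] = numeric.astype("int64")
    keys = [parse_replicate_key(c, delimiter) for c in df.columns]
    df.columns = keys_to_columns(keys)
    return df


def write_read_table(
    table: pd.DataFrame,
    path: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
    sep: str | None = None,
) -> None:
    """Write a read table with replicate keys flattened into column labels."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    out = table.copy()
    out.columns = [
        ReplicateKey(site=str(s), bottle=int(b), pcr=int(p), marker=str(m)).format(delimiter)
        for s, b, p, m in table.columns
    ]
    out.index.name = "asv_id"
    out.to_csv(path, sep=sep)


def read_survey_records(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read long-format capture/visual survey records.

    Columns: ``site, method, replicate, species, value``. ``value`` is a
    seine catch per haul or a BRUV MaxN per deployment and must be a
    nonnegative integer.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = ["site", "method", "replicate", "species", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"survey records missing columns: {missing}")
    df = df[required].copy()
    if len(df) == 0:
        return df.astype({"replicate": int, "value": int}, errors="ignore")
    unknown = sorted(set(df["method"]) - set(KNOWN_METHODS))
    if unknown:
        raise FormatError(
            f"unknown survey method(s) {unknown}; allowed: {list(KNOWN_METHODS)}"
        )
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = pd.to_numeric(df["value"])
    if (df["value"] < 0).any():
        row = df.index[df["value"] < 0][0]
        raise FormatError(f"negative survey value at row {row}")
    if (df["replicate"] < 1).any():
        row = df.index[df["replicate"] < 1][0]
        raise FormatError(f"replicate index < 1 at row {row}")
    df["species"] = df["species"].astype(str).str.strip()
    return df


def write_survey_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_taxonomy(path: str | Path) -> pd.Series:
    """Read a two-column TSV (asv_id, semicolon-delimited ranked path)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("taxonomy table needs two columns: asv_id, path")
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="path")
    series.index.name = "asv_id"
    if series.isna().any() or (series.str.strip() == "").any():
        raise FormatError("taxonomy table contains empty paths")
    return series


def write_taxonomy(taxonomy: pd.Series, path: str | Path) -> None:
    out = taxonomy.rename("path").rename_axis("asv_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


@dataclass
class SamplerSettings:
    """MCMC settings for the occupancy model."""

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000

    def __post_init__(self) -> None:
        for name in ("chains", "iterations", "warmup"):
            if getattr(self, name) < 1:
                raise ValueError(f"sampler setting {name} must be >= 1")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    seed: int = 0
    min_replicates: int = 2
    detection_threshold: int = 1
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    n_permutations: int = 999
    min_joint_sites: int = 3
    delimiter: str = DEFAULT_DELIMITER

    def __post_init__(self) -> None:
        for name in ("min_replicates", "detection_threshold", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"config {name} must be >= 1")
        if self.min_joint_sites < 2:
            raise ValueError("min_joint_sites must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sampler = SamplerSettings(**data.pop("sampler", {}))
        return cls(sampler=sampler, **data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(path: str | Path, config: RunConfig, seed: int, **extra) -> None:
    """Write the JSON sidecar recording the seed and config hash of a run."""
    meta = {
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
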