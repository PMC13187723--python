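"""Readers, writers and validated containers for the pipeline's file formats.

Formats handled: tab-separated count matrices (isoforms x samples, first
column ``isoform_id``), transcript-to-gene maps (two-column TSV or GTF
transcript records), sample metadata tables, and YAML analysis configs.
Newick trees are handled in :mod:`splicerad.trees`.

GTF handling is deliberately minimal: only ``transcript`` records are
consulted and only their ``gene_id`` / ``transcript_id`` attributes are
read.  Genomic coordinates are never used anywhere in the pipeline, so the
0/1-based convention question does not arise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

TISSUES = ("OJ", "PJ")
GUILDS = ("herbivore", "carnivore", "other")

METADATA_COLUMNS = ("sample_id", "species", "clade", "tissue", "guild", "replicate")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent containers."""


@dataclass
class CountMatrix:
    """Non-negative isoform x sample abundance matrix with a gene map.

    Attributes
    ----------
    values
        DataFrame indexed by isoform id, columns are sample ids.
    iso2gene
        Series mapping every isoform id in ``values`` to exactly one gene id.
    """

    values: pd.DataFrame
    iso2gene: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = sorted(v.index[v.index.duplicated()].unique())
            raise FormatError(f"duplicate isoform rows: {dupes}")
        if v.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count matrix contains non-numeric entries")
        if np.isnan(arr).any():
            raise FormatError("count matrix contains missing values")
        if (arr < 0).any():
            bad = v.index[(arr < 0).any(axis=1)][:5].tolist()
            raise FormatError(f"negative abundance values (e.g. {bad})")
        self.iso2gene = pd.Series(self.iso2gene)
        missing = v.index.difference(self.iso2gene.index)
        if len(missing):
            raise FormatError(
                "isoforms missing from the transcript-to-gene map: "
                f"{sorted(missing)}"
            )
        self.iso2gene = self.iso2gene.reindex(v.index)

    @property
    def isoform_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def gene_counts(self) -> pd.DataFrame:
        """Gene-level matrix: sum of member isoform rows."""
        return self.values.groupby(self.iso2gene).sum()


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_iso2gene(path: str | Path) -> pd.Series:
    """Extract transcript_id -> gene_id from GTF ``transcript`` records."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if parts[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise FormatError(
                    f"{path}:{lineno}: transcript record lacks "
                    "transcript_id/gene_id attributes"
                )
            mapping[attrs["transcript_id"]] = attrs["gene_id"]
    if not mapping:
        raise FormatError(f"no transcript records found in {path}")
    return pd.Series(mapping, name="gene_id")


def read_iso2gene(path: str | Path) -> pd.Series:
    """Read a transcript-to-gene map (GTF or two-column TSV)."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return read_gtf_iso2gene(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise FormatError(
            f"{path}: transcript-to-gene TSV must have exactly two columns"
        )
    df.columns = ["isoform_id", "gene_id"]
    if list(df.iloc[0]) == ["isoform_id", "gene_id"]:
        df = df.iloc[1:]
    if df["isoform_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate isoform ids in map")
    return df.set_index("isoform_id")["gene_id"]


def read_counts(path: str | Path, map_path: str | Path) -> CountMatrix:
    """Read an isoform count TSV plus a transcript-to-gene map.

    The TSV is tab-separated UTF-8 with a header of sample ids and a first
    column named ``isoform_id`` (any first-column name is accepted; it is
    taken as the isoform id column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty count matrix")
    return CountMatrix(values=df, iso2gene=read_iso2gene(map_path))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write the counts TSV (round-trips bit-exactly through read_counts)."""
    out = cm.values.copy()
    out.index.name = "isoform_id"
    # shortest round-trip float repr so read_counts(write_counts(x)) == x
    out.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def write_iso2gene(iso2gene: pd.Series, path: str | Path) -> None:
    iso2gene.rename("gene_id").rename_axis("isoform_id").to_csv(
        path, sep="\t", header=True
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Required columns: sample_id, species, clade, tissue, guild, replicate.
    Returns a DataFrame indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty metadata table")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicated sample_id values: {dupes}")
    bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise FormatError(
            f"unknown tissue level(s) {bad_tissue}; expected one of {TISSUES}"
        )
    bad_guild = sorted(set(df["guild"]) - set(GUILDS))
    if bad_guild:
        raise FormatError(
            f"unknown guild level(s) {bad_guild}; expected one of {GUILDS}"
        )
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise FormatError("replicate numbers must be >= 1")
    key = df[["species", "tissue", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise FormatError("(species, tissue, replicate) combinations not unique")
    for col in ("species", "clade", "tissue", "guild"):
        log.info("metadata factor %s: %s", col, sorted(df[col].unique()))
    return df.set_index("sample_id", drop=False)


def check_counts_metadata(cm: CountMatrix, metadata: pd.DataFrame) -> None:
    """Every count-matrix sample must have a metadata row."""
    missing = sorted(set(cm.sample_ids) - set(metadata.index))
    if missing:
        raise FormatError(f"samples without metadata rows: {missing}")


@dataclass
class AnalysisConfig:
    """Tunable thresholds shared across analysis stages.

    presence_threshold
        Expression level (in the chosen normalization's units, CPM by
        default) a sample must exceed for a feature to count as detected.
    presence_min_fraction
        Fraction of a group's samples that must exceed the threshold for the
        feature to be called present in the group.
    psi_delta_threshold
        PSI-difference threshold separating "similar" from "gained/lost"
        isoform usage in trajectory classification.
    """

    presence_threshold: float = 1.0
    presence_min_fraction: float = 0.4
    psi_delta_threshold: float = 0.2
    fdr_level: float = 0.05
    n_permutations: int = 1000
    rng_seed: int = 0
    linkage_method: str = "average"
    normalization: str = "cpm"

    def __post_init__(self) -> None:
        if self.presence_threshold < 0:
            raise FormatError("presence_threshold must be >= 0")
        if not 0 < self.presence_min_fraction <= 1:
            raise FormatError("presence_min_fraction must be in (0, 1]")
        if not 0 <= self.psi_delta_threshold <= 1:
            raise FormatError("psi_delta_threshold must be in [0, 1]")
        if not 0 < self.fdr_level < 1:
            raise FormatError("fdr_level must be in (0, 1)")
        if self.n_permutations < 1:
            raise FormatError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    *,
    command: str,
    config: dict,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    """Write a machine-readable run manifest (config + seed + input hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in (inputs or {}).items()
        },
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
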