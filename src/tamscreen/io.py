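"""Readers and writers for the tabular and gene-set formats the pipeline touches.

Measurement tables are long-format CSV/TSV (one row per donor x cell line x
analyte observation, concentrations in pg/mL); expression matrices are TSV
with genes as rows and samples as columns; gene sets come in as GMT. Results
go out as CSV with a reproducibility header (config hash + seed) and floats
at 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tamscreen")

__all__ = [
    "SchemaError",
    "ValidationError",
    "AnalyteMeasurementTable",
    "ExpressionBundle",
    "GeneSetCollection",
    "read_measurement_table",
    "read_expression_bundle",
    "read_gmt",
    "write_results_table",
    "write_manifest",
]


class SchemaError(ValueError):
    """Input file does not have the expected columns/structure."""


class ValidationError(ValueError):
    """Input file parsed but violates a content invariant."""


@dataclass
class AnalyteMeasurementTable:
    """Long-format donor x unit x analyte concentration table.

    records has columns donor, unit, analyte, concentration (pg/mL),
    below_lloq; lloq_map gives each analyte's assay lower limit of
    quantification; metadata maps unit -> tumor type. Each
    (donor, unit, analyte) triple is unique and below_lloq is true iff
    concentration < lloq_map[analyte].
    """

    records: pd.DataFrame
    lloq_map: dict[str, float]
    metadata: dict[str, str] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            self._check()

    def _check(self) -> None:
        req = ["donor", "unit", "analyte", "concentration", "below_lloq"]
        for col in req:
            if col not in self.records.columns:
                raise SchemaError(f"measurement table missing column {col!r}")
        conc = self.records["concentration"].to_numpy(float)
        if np.any(conc < 0):
            bad = int(np.flatnonzero(conc < 0)[0])
            raise ValidationError(f"negative concentration at row {bad}")
        dup = self.records.duplicated(subset=["donor", "unit", "analyte"])
        if dup.any():
            row = self.records.loc[dup.idxmax()]
            raise ValidationError(
                "duplicate (donor, unit, analyte) triple: "
                f"({row['donor']}, {row['unit']}, {row['analyte']})"
            )

    @property
    def analytes(self) -> list[str]:
        return sorted(self.records["analyte"].unique())

    @property
    def units(self) -> list[str]:
        return sorted(self.records["unit"].unique())


@dataclass
class ExpressionBundle:
    """Paired raw-count and normalized gene x sample matrices.

    counts holds non-negative integers; normalized holds TPM- or RUVg-style
    non-negative reals. Both share an identical gene/sample index order and
    sample ids match the unit ids of the scoring output.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.normalized.index):
            raise ValidationError("counts/normalized gene index mismatch")
        if list(self.counts.columns) != list(self.normalized.columns):
            raise ValidationError("counts/normalized sample order mismatch")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any() or (self.normalized.to_numpy() < 0).any():
            raise ValidationError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def items(self):
        return ((name, members) for name, (_, members) in self.sets.items())


def read_measurement_table(
    path: str | Path,
    lloq_map: dict[str, float],
    metadata: dict[str, str] | None = None,
    column_names: dict[str, str] | None = None,
) -> AnalyteMeasurementTable:
    """Read a long-format measurement CSV/TSV and compute below-LLoQ flags.

    ``column_names`` remaps {donor, unit, analyte, concentration} to the
    file's actual header names. Row count is preserved; flags are computed
    from ``lloq_map``, not trusted from the file.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty measurement file: {path}") from exc
    rename = {v: k for k, v in (column_names or {}).items()}
    df = df.rename(columns=rename)
    for col in ("donor", "unit", "analyte", "concentration"):
        if col not in df.columns:
            raise SchemaError(f"measurement table {path} missing column {col!r}")
    df = df[["donor", "unit", "analyte", "concentration"]].copy()
    missing = sorted(set(df["analyte"]) - set(lloq_map))
    if missing:
        raise ValidationError(f"analytes missing from lloq_map: {missing}")
    df["below_lloq"] = df["concentration"].to_numpy(float) < df["analyte"].map(lloq_map).to_numpy(float)
    table = AnalyteMeasurementTable(records=df, lloq_map=dict(lloq_map), metadata=dict(metadata or {}))
    logger.info("read_measurement_table: %d rows, %d analytes from %s", len(df), df["analyte"].nunique(), path)
    return table


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = pd.DataFrame(np.asarray(mmread(path).todense()))
        m.index = m.index.map(lambda i: f"g{i}")
        m.columns = m.columns.map(lambda j: f"s{j}")
        return m
    sep = "\t" if path.suffix in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression_bundle(counts_path: str | Path, normalized_path: str | Path) -> ExpressionBundle:
    """Read paired counts/normalized matrices, aligning on shared genes.

    Genes present in only one matrix are dropped with a logged warning;
    disjoint sample sets are an error. Counts within 1e-6 of an integer are
    rounded; anything else is a validation error.
    """
    counts = _read_matrix(counts_path)
    norm = _read_matrix(normalized_path)
    shared_samples = [s for s in counts.columns if s in set(norm.columns)]
    if not shared_samples:
        raise ValidationError("counts and normalized matrices share no samples")
    shared_genes = counts.index.intersection(norm.index)
    dropped = (len(counts) - len(shared_genes)) + (len(norm) - len(shared_genes))
    if dropped:
        logger.warning("read_expression_bundle: dropped %d gene(s) absent from one matrix", dropped)
    counts = counts.loc[shared_genes, shared_samples]
    norm = norm.loc[shared_genes, shared_samples]
    vals = counts.to_numpy(float)
    rounded = np.rint(vals)
    if np.max(np.abs(vals - rounded)) > 1e-6:
        bad = np.argwhere(np.abs(vals - rounded) > 1e-6)[0]
        raise ValidationError(
            f"non-integer count {vals[tuple(bad)]} at gene {counts.index[bad[0]]!r}, "
            f"sample {counts.columns[bad[1]]!r}"
        )
    counts = pd.DataFrame(rounded.astype(np.int64), index=counts.index, columns=counts.columns)
    return ExpressionBundle(counts=counts, normalized=norm.astype(float))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise SchemaError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            sets[name] = (desc, frozenset(members))
    return GeneSetCollection(sets=sets)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results_table(
    result: pd.DataFrame,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a result table as CSV with a reproducibility header comment.

    Column order is preserved deterministically, floats use 10 significant
    digits, and the first line records the config hash and seed so two runs
    with identical inputs produce byte-identical files.
    """
    if result is None or len(result) == 0:
        raise ValidationError("refusing to write empty results table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# tamscreen config_hash={config_hash(config or {})} seed={seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        result.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    return path


def write_manifest(path: str | Path, inputs: dict, config: dict, seed: int | None) -> Path:
    """JSON run-manifest accompanying every pipeline output file."""
    import tamscreen

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": tamscreen.__version__,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
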