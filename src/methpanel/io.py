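"""Domain containers and tabular readers/writers.

All pipeline artifacts are plain text: sample sheets (CSV), beta-value
matrices (TSV, probes x samples), probe annotation tables (TSV),
pyrosequencing percent-methylation tables (long CSV), YAML run
configuration and JSON diagnostic reports.  Containers are thin,
validated wrappers around :class:`pandas.DataFrame`.

Conventions: UTF-8, '.' decimal separator, mandatory header row.
Genomic coordinates, where present, are 1-based inclusive on GRCh37.
Missing beta values are encoded as NA cells (never out-of-range
numbers); downstream statistics drop them pairwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FINDINGS",
    "NN_FINDINGS",
    "AN_FINDINGS",
    "SchemaError",
    "ValidationError",
    "CohortTable",
    "BetaMatrix",
    "ProbeAnnotation",
    "PyroTable",
    "RunConfig",
    "derive_label",
    "read_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "read_pyro_table",
    "write_pyro_table",
    "write_report",
    "read_report",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates its schema."""


class ValidationError(ValueError):
    """A table parses but violates a domain invariant."""


# Closed category sets ------------------------------------------------------

NN_FINDINGS = ("NCF", "BEN_hemorrhoids", "BEN_diverticula", "NAA")
AN_FINDINGS = ("AA", "CRC")
FINDINGS = NN_FINDINGS + AN_FINDINGS

SEXES = ("male", "female")
STAGES = ("I", "II", "III", "IV", "none")
LOCATIONS = ("distal", "proximal", "none")
COHORTS = ("discovery", "evaluation", "validation", "external_tumor", "unassigned")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
GENIC_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")

_SHEET_REQUIRED = ["subject_id", "sex", "age", "hospital", "finding"]
_SHEET_OPTIONAL = {
    "aa_histology": "none",
    "aa_dysplasia": "none",
    "stage": "none",
    "location": "none",
    "cohort": "unassigned",
    "tumor_type": "none",
}


def derive_label(finding: str) -> str:
    """Binary class label from the colorectal finding.

    NN ("no neoplasia") covers no colorectal findings, benign pathology
    (hemorrhoids, diverticula) and non-advanced adenomas; AN ("advanced
    neoplasia") covers advanced adenomas and colorectal cancer.
    """
    if finding in NN_FINDINGS:
        return "NN"
    if finding in AN_FINDINGS:
        return "AN"
    raise ValidationError(f"unknown colorectal finding: {finding!r}")


@dataclass
class CohortTable:
    """Per-subject clinical metadata with cohort assignments.

    Wraps a DataFrame with one row per subject.  The binary NN/AN label
    is derived, never stored as primary data.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet missing required column(s): {', '.join(missing)}")
        for col, default in _SHEET_OPTIONAL.items():
            if col not in df.columns:
                df[col] = default
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicated subject ids: {dups}")
        bad = set(df["finding"]) - set(FINDINGS)
        if bad:
            raise ValidationError(f"unknown finding value(s): {sorted(bad)}")
        bad = set(df["sex"]) - set(SEXES)
        if bad:
            raise ValidationError(f"unknown sex value(s): {sorted(bad)}")
        ages = pd.to_numeric(df["age"], errors="raise")
        if ((ages < 18) | (ages > 120)).any():
            raise ValidationError("age outside [18, 120]")
        df["age"] = ages.astype(int)
        # screening subjects (everything except external tumor sera) must be 50-75
        screening = df["cohort"] != "external_tumor"
        out = screening & ((df["age"] < 50) | (df["age"] > 75))
        if out.any():
            raise ValidationError(
                f"{int(out.sum())} screening subject(s) with age outside [50, 75]"
            )
        bad = set(df["stage"]) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage value(s): {sorted(bad)}")
        bad = set(df["location"]) - set(LOCATIONS)
        if bad:
            raise ValidationError(f"unknown location value(s): {sorted(bad)}")
        bad = set(df["cohort"]) - set(COHORTS)
        if bad:
            raise ValidationError(f"unknown cohort value(s): {sorted(bad)}")
        # stage != none iff CRC; location != none iff AA or CRC
        crc = df["finding"] == "CRC"
        if (crc & (df["stage"] == "none")).any():
            raise ValidationError("CRC subject with stage = none")
        if ((~crc) & (df["stage"] != "none")).any():
            raise ValidationError("non-CRC subject with a tumor stage")
        lesion = df["finding"].isin(["AA", "CRC"])
        if (lesion & (df["location"] == "none")).any():
            raise ValidationError("AA/CRC subject with location = none")
        if ((~lesion) & (df["location"] != "none")).any():
            raise ValidationError("non-lesion subject with a lesion location")

    @property
    def labels(self) -> pd.Series:
        """NN/AN label per subject, indexed like the table."""
        return self.df["finding"].map(derive_label)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True).copy())

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    ``level`` records whether columns are individual subjects or cfDNA
    pools.  NA cells mark missing measurements ("failed positions").
    """

    values: pd.DataFrame
    level: str = "individual"

    def __post_init__(self) -> None:
        if self.level not in ("individual", "pool"):
            raise ValidationError(f"unknown beta matrix level: {self.level!r}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicated probe ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {v.index[i]!r}, sample {v.columns[j]!r}: "
                f"{arr[i, j]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path, float_format: str = "%.6f") -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


@dataclass
class ProbeAnnotation:
    """Probe -> genomic annotation (GRCh37, 1-based positions)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "chrom", "pos", "gene_symbol", "island_relation", "genic_feature"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"annotation missing column(s): {', '.join(missing)}")
        if self.df["probe_id"].duplicated().any():
            raise ValidationError("duplicated probe_id in annotation")
        bad = set(self.df["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise ValidationError(f"unknown island relation(s): {sorted(bad)}")
        bad = set(self.df["genic_feature"]) - set(GENIC_FEATURES)
        if bad:
            raise ValidationError(f"unknown genic feature(s): {sorted(bad)}")

    def lookup(self, probe_ids: Iterable[str]) -> pd.DataFrame:
        idx = self.df.set_index("probe_id")
        return idx.reindex(list(probe_ids))


@dataclass
class PyroTable:
    """Long-format pyrosequencing percent-methylation measurements."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "marker_id", "percent_methylation"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"pyro table missing column(s): {', '.join(missing)}")
        if self.df.duplicated(["sample_id", "marker_id"]).any():
            raise ValidationError("duplicated (sample, marker) pairs in pyro table")
        vals = self.df["percent_methylation"]
        ok = vals.isna() | ((vals >= 0) & (vals <= 100))
        if not ok.all():
            row = self.df.loc[~ok].iloc[0]
            raise ValidationError(
                f"percent methylation out of [0,100] for sample {row['sample_id']!r}, "
                f"marker {row['marker_id']!r}: {row['percent_methylation']}"
            )

    def wide(self) -> pd.DataFrame:
        """Samples x markers matrix of percents (NaN where missing)."""
        return self.df.pivot(index="sample_id", columns="marker_id", values="percent_methylation")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Run-level knobs shared across pipeline stages.

    Every stage derives its own substream seed from ``seed`` so stages
    can be rerun independently; there is no implicit global randomness.
    """

    seed: int = 0
    fdr: float = 0.10
    shapiro_alpha: float = 0.01
    ses_alpha: float = 0.05
    ses_max_k: int = 3
    cv_folds: int = 5
    cv_repeats: int = 10
    rf_trees: int = 500
    n_lambda: int = 50
    enet_l1_ratio: float = 0.5
    transform: str = "log10"
    out_dir: str = "results"
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fdr", "shapiro_alpha", "ses_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0,1), got {v}")
        if self.transform not in ("raw", "log10"):
            raise ValidationError(f"transform must be 'raw' or 'log10', got {self.transform!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an explicit integer")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed (< 2**31)."""
        h = 2166136261
        for b in f"{stage}:{self.seed}".encode():
            h = ((h ^ b) * 16777619) % 2**32
        return h % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# Readers / writers ---------------------------------------------------------


def read_sample_sheet(path) -> CohortTable:
    """Read and validate a subject sample sheet (CSV)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return CohortTable(df)


def read_beta_matrix(path, level: str = "individual") -> BetaMatrix:
    """Read a probes-x-samples beta matrix from TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric cell in beta matrix {path}: {exc}") from exc
    values.index = values.index.astype(str)
    return BetaMatrix(values, level=level)


def write_beta_matrix(beta: BetaMatrix, path, decimals: int = 6) -> None:
    beta.to_tsv(path, float_format=f"%.{decimals}f")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return ProbeAnnotation(df)


def read_pyro_table(path) -> PyroTable:
    df = pd.read_csv(path, dtype={"sample_id": str, "marker_id": str})
    return PyroTable(df)


def write_pyro_table(table: PyroTable, path) -> None:
    table.to_csv(path)


# Diagnostic report ---------------------------------------------------------

_REPORT_SCHEMA_VERSION = 1
_REPORT_REQUIRED = ["auc", "auc_ci", "youden_cutoff", "confusion"]
_CONFUSION_REQUIRED = ["tp", "fp", "tn", "fn"]


def write_report(report: Mapping, path) -> None:
    """Serialize a diagnostic report to versioned JSON.

    The report must carry AUC with its CI, the Youden cutoff and the
    confusion counts; subgroup detection rates are passed through as-is.
    """
    missing = [k for k in _REPORT_REQUIRED if k not in report]
    if missing:
        raise SchemaError(f"report missing field(s): {', '.join(missing)}")
    conf = report["confusion"]
    missing = [k for k in _CONFUSION_REQUIRED if k not in conf]
    if missing:
        raise SchemaError(f"report confusion counts missing: {', '.join(missing)}")
    doc = {"schema_version": _REPORT_SCHEMA_VERSION, **report}

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=2, default=_default) + "\n")


def read_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != _REPORT_SCHEMA_VERSION:
        raise SchemaError(f"unsupported report schema version: {doc.get('schema_version')}")
    doc.pop("schema_version")
    missing = [k for k in _REPORT_REQUIRED if k not in doc]
    if missing:
        raise SchemaError(f"report missing field(s): {', '.join(missing)}")
    return doc
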