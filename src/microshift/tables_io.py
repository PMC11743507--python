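"""Reading, validating and writing the pipeline's tabular artifacts.

All tables are plain TSV (UTF-8, tab delimiter, "." decimal). Count tables
are oriented samples × genera: header row of genus names, first column
``sample_id``. Genus names are opaque strings; no taxonomy-string parsing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, JoinError, SchemaError, ValidationError

UNASSIGNED = "Unassigned"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenusCountTable:
    """Samples × genera table of non-negative integer counts.

    ``taxonomy`` maps each genus to a phylum; genera absent from the
    provided taxonomy are mapped to ``"Unassigned"`` with a warning.
    """

    sample_ids: list[str]
    genus_ids: list[str]
    counts: np.ndarray  # (n_samples, n_genera), integer
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples × genera matrix")
        n, g = self.counts.shape
        if n < 1 or g < 1:
            raise ValidationError("count table needs at least 1 sample and 1 genus")
        if len(self.sample_ids) != n or len(self.genus_ids) != g:
            raise ValidationError("identifier lists do not match counts shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.genus_ids)) != g:
            raise ValidationError("duplicate genus identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"genus {self.genus_ids[j]!r}"
            )
        # every genus with nonzero column sum must be mapped (or Unassigned)
        colsums = self.counts.sum(axis=0)
        missing = [
            gid for gid, s in zip(self.genus_ids, colsums)
            if s > 0 and gid not in self.taxonomy
        ]
        if missing:
            warnings.warn(
                f"{len(missing)} genera missing from taxonomy, assigned "
                f"{UNASSIGNED!r}: {missing[:5]}",
                stacklevel=2,
            )
            for gid in missing:
                self.taxonomy[gid] = UNASSIGNED

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.genus_ids)


@dataclass
class SampleMetadata:
    """Per-sample design labels: mouse, group and week."""

    df: pd.DataFrame  # columns: sample_id, mouse_id, group, week

    REQUIRED = ("sample_id", "mouse_id", "group", "week")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise SchemaError(f"metadata missing columns: {missing}")
        self.df = self.df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        self.df["week"] = pd.to_numeric(self.df["week"], errors="raise").astype(int)
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id in metadata: {dups}")
        dup = self.df.duplicated(subset=["mouse_id", "week"])
        if dup.any():
            pairs = self.df.loc[dup, ["mouse_id", "week"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (mouse_id, week) pairs: {pairs}")

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique().tolist())

    @property
    def weeks(self) -> list[int]:
        return sorted(self.df["week"].unique().tolist())

    def samples_in(self, group: str, week: int | None = None) -> list[str]:
        m = self.df["group"] == group
        if week is not None:
            m &= self.df["week"] == week
        return self.df.loc[m, "sample_id"].tolist()

    def mice_in(self, group: str) -> list[str]:
        return sorted(self.df.loc[self.df["group"] == group, "mouse_id"].unique().tolist())

    def mouse_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["mouse_id"]))

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["group"]))

    def validate_against(self, table: GenusCountTable) -> None:
        a, b = set(self.sample_ids), set(table.sample_ids)
        if a != b:
            raise JoinError(
                "metadata/count-table sample_id mismatch; symmetric difference: "
                f"{sorted(a ^ b)}"
            )


@dataclass
class PhenotypeTable:
    """Per-mouse weekly body weight (g) and fasting blood glucose (mmol/L)."""

    df: pd.DataFrame  # columns: mouse_id, week, bw, fbg

    REQUIRED = ("mouse_id", "week", "bw", "fbg")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        self.df = self.df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        self.df["week"] = pd.to_numeric(self.df["week"], errors="raise").astype(int)
        for col in ("bw", "fbg"):
            vals = pd.to_numeric(self.df[col], errors="raise")
            if (vals <= 0).any():
                bad = self.df.loc[vals <= 0, "mouse_id"].tolist()
                raise ValidationError(f"non-positive {col} for mice {bad}")
            self.df[col] = vals.astype(float)
        if self.df.duplicated(subset=["mouse_id", "week"]).any():
            raise ValidationError("duplicate (mouse_id, week) in phenotype table")

    def at(self, mouse_id: str, week: int, measure: str) -> float:
        m = (self.df["mouse_id"] == mouse_id) & (self.df["week"] == week)
        sub = self.df.loc[m, measure]
        if sub.empty:
            raise ValidationError(f"no {measure} for mouse {mouse_id} at week {week}")
        return float(sub.iloc[0])


@dataclass
class GlucoseCurve:
    """One mouse's tolerance-test curve: glucose (mmol/L) at minutes post-dose."""

    mouse_id: str
    minutes: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.minutes.shape != self.glucose.shape:
            raise ValidationError("minutes and glucose lengths differ")
        if self.minutes.size < 1 or self.minutes[0] != 0:
            raise ValidationError("first time point must be 0 min")
        if np.any(np.diff(self.minutes) <= 0):
            raise ValidationError("minutes must be strictly increasing")
        if np.any(self.minutes < 0):
            raise ValidationError("minutes must be non-negative")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, taxonomy_path: str | Path | None = None) -> GenusCountTable:
    """Read a samples × genera TSV plus an optional genus→phylum taxonomy TSV.

    Column and row order are preserved exactly as read. Non-integer or
    negative cells raise :class:`FormatError` naming the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.name is None or raw.empty:
        raise SchemaError(f"{path}: expected sample_id index column and ≥1 genus column")
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, (sid, cell) in enumerate(zip(raw.index, raw[col])):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell at sample {sid!r}, genus {col!r}: {cell!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count at sample {sid!r}, genus {col!r}: {v}"
                )
            counts[i, j] = v
    taxonomy: dict[str, str] = {}
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
    return GenusCountTable(
        sample_ids=[str(s) for s in raw.index],
        genus_ids=[str(c) for c in raw.columns],
        counts=counts,
        taxonomy=taxonomy,
    )


def read_taxonomy(path: str | Path) -> dict[str, str]:
    tax = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("genus", "phylum") if c not in tax.columns]
    if missing:
        raise SchemaError(f"{path}: taxonomy missing columns {missing}")
    if tax["genus"].duplicated().any():
        raise ValidationError(f"{path}: duplicate genus rows in taxonomy")
    return dict(zip(tax["genus"], tax["phylum"]))


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mouse_id": str, "group": str})
    return SampleMetadata(df)


def read_phenotype(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", dtype={"mouse_id": str}))


def read_glucose(path: str | Path) -> list[GlucoseCurve]:
    """Read a long-format glucose TSV (mouse_id, minutes, glucose)."""
    df = pd.read_csv(path, sep="\t", dtype={"mouse_id": str})
    missing = [c for c in ("mouse_id", "minutes", "glucose") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: glucose table missing columns {missing}")
    curves = []
    for mid, sub in df.groupby("mouse_id", sort=True):
        sub = sub.sort_values("minutes")
        curves.append(GlucoseCurve(str(mid), sub["minutes"].to_numpy(),
                                   sub["glucose"].to_numpy()))
    return curves


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_count_table(table: GenusCountTable, path: str | Path,
                      taxonomy_path: str | Path | None = None) -> None:
    table.to_dataframe().to_csv(path, sep="\t")
    if taxonomy_path is not None:
        write_taxonomy(table.taxonomy, taxonomy_path)


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"genus": list(taxonomy.keys()), "phylum": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.df.to_csv(path, sep="\t", index=False)


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.df.to_csv(path, sep="\t", index=False)


def write_glucose(curves: list[GlucoseCurve], path: str | Path) -> None:
    rows = [
        {"mouse_id": c.mouse_id, "minutes": int(m), "glucose": g}
        for c in curves for m, g in zip(c.minutes, c.glucose)
    ]
    pd.DataFrame(rows, columns=["mouse_id", "minutes", "glucose"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result bundle output
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_outputs(bundle: dict[str, object], out_dir: str | Path) -> dict[str, str]:
    """Write a bundle of pipeline results to ``out_dir``.

    DataFrames (and edge lists) become TSV, everything else JSON.
    Returns a manifest mapping file name → sha256 of its content; the
    manifest itself is written as ``manifest.json``. Re-running with the
    same bundle yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for key in sorted(bundle):
        value = bundle[key]
        if isinstance(value, pd.DataFrame):
            fname = f"{key}.tsv"
            value.to_csv(out / fname, sep="\t", index=False)
        elif (isinstance(value, list) and value
              and dataclasses.is_dataclass(value[0])):
            # e.g. a list of NetworkEdge records → Cytoscape-importable TSV
            fname = f"{key}.tsv"
            pd.DataFrame([dataclasses.asdict(v) for v in value]).to_csv(
                out / fname, sep="\t", index=False)
        else:
            fname = f"{key}.json"
            (out / fname).write_text(
                json.dumps(_jsonable(value), indent=2, sort_keys=True) + "\n")
        manifest[fname] = hashlib.sha256((out / fname).read_bytes()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
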