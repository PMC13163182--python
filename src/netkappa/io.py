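"""File formats, configuration and the bundled node table.

All on-disk artifacts are plain text: time series as TSV (one row per
region), correlation matrices and result tables as CSV, edge lists as TSV,
manifests and sidecars as JSON, configuration as YAML/JSON.  Every write
has a matching read with round-trip fidelity to ~1e-12, and schema
violations raise :class:`SchemaError` naming the offending column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import RegionalTimeSeriesSet
from .graphs import BrainGraph
from .wavelets import WaveletCorrelationMatrix

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "FORMAT_VERSION",
    "load_node_table",
    "make_synthetic_node_table",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_correlation_csv",
    "read_correlation_csv",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "write_kappa_table",
    "read_kappa_table",
    "write_manifest",
]

FORMAT_VERSION = "1"

NODE_TABLE_COLUMNS = ["region_id", "region_name", "mni_x", "mni_y", "mni_z", "network"]


class SchemaError(ValueError):
    """A file did not match its documented schema."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with study-condition defaults."""

    node_table: str | None = None  # None -> bundled 89-region fixture
    wavelet: str = "sym4"
    scale: int = 3
    edge_budgets: tuple[int, ...] = (400,)
    comparisons: tuple[tuple[str, str], ...] = (("TSD", "RW"), ("CSR", "RW"), ("CSR", "TSD"))
    n_perm: int = 10_000
    q_global: float = 0.05
    q_nodal: float = 0.1
    ccml_k: int = 6
    ccml_dim: int = 2
    seed: int = 0
    output_dir: str = "netkappa_out"

    def __post_init__(self) -> None:
        if self.scale not in (1, 2, 3, 4):
            raise ValueError("scale must be in 1..4")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        self.edge_budgets = tuple(int(e) for e in self.edge_budgets)
        self.comparisons = tuple((str(a), str(b)) for a, b in self.comparisons)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["edge_budgets"] = list(self.edge_budgets)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# -- node tables -------------------------------------------------------------

def _validate_node_table(df: pd.DataFrame, expect_rows: int | None = None) -> pd.DataFrame:
    for col in NODE_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"node table missing required column {col!r}")
    if df["region_id"].duplicated().any():
        raise SchemaError("node table region_id values must be unique")
    for col in ("mni_x", "mni_y", "mni_z"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"node table column {col!r} must be numeric")
    if expect_rows is not None and len(df) != expect_rows:
        raise SchemaError(f"node table has {len(df)} rows, expected {expect_rows}")
    return df


def load_node_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a node table CSV; by default the bundled 89-region fixture.

    The bundled table carries the 19 regions with printed names and MNI
    centroids plus 70 synthetic rows (standard AAL-style names, approximate
    placeholder centroids and network labels) - adequate for plumbing and
    plots, not for anatomical claims.
    """
    if path is None:
        ref = resources.files("netkappa.data").joinpath("aal89_nodes_synthetic.csv")
        with resources.as_file(ref) as p:
            return _validate_node_table(pd.read_csv(p), expect_rows=89)
    return _validate_node_table(pd.read_csv(path))


def make_synthetic_node_table(n_regions: int = 391, seed: int = 0) -> pd.DataFrame:
    """Synthetic node table for functional-parcellation-sized runs."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform([-70, -100, -60], [70, 70, 80], size=(n_regions, 3)).round(1)
    return pd.DataFrame(
        {
            "region_id": [f"P{i:03d}" for i in range(n_regions)],
            "region_name": [f"Synthetic Parcel {i}" for i in range(n_regions)],
            "mni_x": xyz[:, 0],
            "mni_y": xyz[:, 1],
            "mni_z": xyz[:, 2],
            "network": "synthetic",
        }
    )


# -- time series -------------------------------------------------------------

def write_timeseries_tsv(ts: RegionalTimeSeriesSet, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    n_vol = ts.values.shape[1]
    df = pd.DataFrame(
        ts.values,
        index=pd.Index(ts.region_ids, name="region_id"),
        columns=[f"volume_{k + 1:04d}" for k in range(n_vol)],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {
        "format_version": FORMAT_VERSION,
        "subject_id": ts.subject_id,
        "condition": ts.condition,
        "tr_seconds": ts.tr_seconds,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_timeseries_tsv(path: str | Path) -> RegionalTimeSeriesSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar JSON for {path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("subject_id", "condition", "tr_seconds"):
        if key not in meta:
            raise SchemaError(f"time-series sidecar missing key {key!r}")
    return RegionalTimeSeriesSet(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        values=df.values,
        region_ids=[str(r) for r in df.index],
        tr_seconds=float(meta["tr_seconds"]),
    )


# -- correlation matrices ----------------------------------------------------

def write_correlation_csv(cm: WaveletCorrelationMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(cm.values, index=cm.region_ids, columns=cm.region_ids).to_csv(
        path, float_format="%.15g", index_label="region_id"
    )
    sidecar = {
        "format_version": FORMAT_VERSION,
        "scale": cm.scale,
        "band_hz": list(cm.band_hz),
        "effective_df": cm.effective_df,
        "subject_id": cm.subject_id,
        "condition": cm.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_correlation_csv(path: str | Path) -> WaveletCorrelationMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="region_id")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise SchemaError("correlation CSV row and column labels differ")
    meta = json.loads(path.with_suffix(".json").read_text())
    return WaveletCorrelationMatrix(
        values=df.values,
        scale=int(meta["scale"]),
        band_hz=tuple(meta["band_hz"]),
        effective_df=int(meta["effective_df"]),
        region_ids=[str(r) for r in df.index],
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
    )


# -- graphs ------------------------------------------------------------------

def write_edgelist_tsv(bg: BrainGraph, path: str | Path) -> None:
    rows = bg.edge_list()
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.15g"
    )


def read_edgelist_tsv(path: str | Path, node_table: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("node_a", "node_b", "weight"):
        if col not in df.columns:
            raise SchemaError(f"edge list missing column {col!r}")
    if node_table is not None:
        known = set(node_table["region_id"].astype(str))
        seen = set(df["node_a"].astype(str)) | set(df["node_b"].astype(str))
        orphans = seen - known
        if orphans:
            raise SchemaError(f"edge list references unknown nodes: {sorted(orphans)[:5]}")
    return df


# -- kappa tables and manifests ----------------------------------------------

KAPPA_COLUMNS = ["subject_id", "comparison", "metric", "kappa", "intercept", "r_squared"]


def write_kappa_table(table: pd.DataFrame, path: str | Path) -> None:
    table[KAPPA_COLUMNS].to_csv(path, index=False, float_format="%.15g")


def read_kappa_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in KAPPA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"kappa table missing column {col!r}")
    return df


def write_manifest(path: str | Path, **entries) -> None:
    payload = {"format_version": FORMAT_VERSION, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
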