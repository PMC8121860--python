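"""Readers/writers, run configuration, seeding and manifests.

All tables are UTF-8 comma-separated CSV with a header and '.' decimals.
Day labels are constrained to D4-D7.  Every pipeline stage derives its own
seed deterministically from the single top-level run seed (stage-name
hashing), so stages can be re-run in isolation and identical (config, seed)
pairs reproduce identical outputs, recorded as SHA-256 checksums in the run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "load_config",
    "derive_seed",
    "read_cell_records",
    "write_cell_records",
    "read_spot_clouds",
    "write_spot_clouds",
    "read_expression",
    "write_expression",
    "file_checksum",
    "write_manifest",
]

DAY_VOCAB = ("D4", "D5", "D6", "D7")
LINE_VOCAB = ("WT", "ND1")
PROTOCOL_VOCAB = ("conventional-20pct", "modified-3pct")
GATE_VOCAB = ("BV+", "BVSC+", "BVSC-")

CELL_COLUMNS = (
    "cell_id", "line", "protocol", "day", "gate", "heteroplasmy", "copies",
)

_DEFAULTS = {
    "iterations": 50_000,
    "q": 0.1,
    "min_genes": 200,
    "min_cells": 3,
    "target": 10_000,
    "nucleoid_size": 1.4,
    "ref_day": "D4",
    "n_cells": 1000,
}

_KNOWN_KEYS = set(_DEFAULTS) | {
    "stages", "out_dir", "seed", "cells_csv", "spots_csv", "refs_csv",
    "matrix", "annotations", "gene_lists_dir", "sim",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    stages: list[str] = field(default_factory=lambda: ["simulate", "hetstats"])
    out_dir: str = "out"
    seed: int | None = None
    cells_csv: str | None = None
    spots_csv: str | None = None
    refs_csv: str | None = None
    matrix: str | None = None
    annotations: str | None = None
    gene_lists_dir: str | None = None
    sim: dict = field(default_factory=dict)
    iterations: int = _DEFAULTS["iterations"]
    q: float = _DEFAULTS["q"]
    min_genes: int = _DEFAULTS["min_genes"]
    min_cells: int = _DEFAULTS["min_cells"]
    target: float = _DEFAULTS["target"]
    nucleoid_size: float = _DEFAULTS["nucleoid_size"]
    ref_day: str = _DEFAULTS["ref_day"]
    n_cells: int = _DEFAULTS["n_cells"]

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.ref_day not in DAY_VOCAB:
            raise ValueError(f"ref_day must be one of {DAY_VOCAB}")
        for attr in ("cells_csv", "spots_csv", "refs_csv", "matrix", "annotations"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def derive_seed(seed: int | None, stage: str) -> int | None:
    """Deterministic per-stage seed below 2**31 from the top-level seed."""
    if seed is None:
        return None
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# cell records


def read_cell_records(path) -> pd.DataFrame:
    """Tidy per-cell measurement table; validates the closed vocabularies."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell records missing columns: {missing}")
    for col, vocab in (("day", DAY_VOCAB), ("line", LINE_VOCAB),
                       ("protocol", PROTOCOL_VOCAB), ("gate", GATE_VOCAB)):
        bad = set(df[col].dropna().unique()) - set(vocab)
        if bad:
            raise ValueError(f"unexpected {col} values: {sorted(bad)}")
    h = df["heteroplasmy"].dropna()
    if ((h < 0) | (h > 1)).any():
        raise ValueError("heteroplasmy must lie in [0, 1] (fraction scale)")
    if (df["copies"].dropna() < 0).any():
        raise ValueError("copies must be non-negative")
    return df


def write_cell_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spot clouds


def read_spot_clouds(spots_path, refs_path):
    """Spots CSV (cell_id, spot_id, x_um, y_um, z_um) + reference CSV."""
    from .bottleneck_sim import SpotCloud

    spots = pd.read_csv(spots_path)
    refs = pd.read_csv(refs_path).set_index("cell_id")
    clouds = []
    for cell_id, sub in spots.groupby("cell_id", sort=True):
        if cell_id not in refs.index:
            raise ValueError(f"no reference point for cell {cell_id!r}")
        ref = refs.loc[cell_id, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        clouds.append(
            SpotCloud(
                cell_id=str(cell_id),
                points=sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                reference=ref,
            )
        )
    return clouds


def write_spot_clouds(clouds, spots_path, refs_path) -> None:
    spot_rows, ref_rows = [], []
    for cloud in clouds:
        for i, (x, y, z) in enumerate(cloud.points):
            spot_rows.append(
                {"cell_id": cloud.cell_id, "spot_id": i,
                 "x_um": x, "y_um": y, "z_um": z}
            )
        rx, ry, rz = cloud.reference
        ref_rows.append({"cell_id": cloud.cell_id, "x_um": rx, "y_um": ry, "z_um": rz})
    pd.DataFrame(spot_rows).to_csv(spots_path, index=False)
    pd.DataFrame(ref_rows).to_csv(refs_path, index=False)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(matrix_path, annotations_path=None):
    """Counts as AnnData from MTX triplet (with sidecars) or dense CSV.

    For ``counts.mtx`` the sidecar files ``genes.tsv`` and ``barcodes.tsv``
    are expected next to it (cells x genes orientation).  Dense CSV is
    cells x genes with the cell id in the first column.
    """
    import anndata as ad
    from scipy.io import mmread

    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        X = mmread(matrix_path).toarray()
        genes = pd.read_csv(
            matrix_path.with_name("genes.tsv"), sep="\t", header=None
        )[0].tolist()
        barcodes = pd.read_csv(
            matrix_path.with_name("barcodes.tsv"), sep="\t", header=None
        )[0].tolist()
        adata = ad.AnnData(
            X=np.asarray(X),
            obs=pd.DataFrame(index=barcodes),
            var=pd.DataFrame(index=genes),
        )
    else:
        df = pd.read_csv(matrix_path, index_col=0)
        adata = ad.AnnData(
            X=df.to_numpy(dtype=float),
            obs=pd.DataFrame(index=df.index.astype(str)),
            var=pd.DataFrame(index=df.columns.astype(str)),
        )
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path).set_index("cell_id")
        adata.obs = adata.obs.join(ann, how="left")
    return adata


def write_expression(adata, matrix_path) -> None:
    """Write counts as an MTX triplet with genes/barcodes sidecars."""
    from scipy import sparse
    from scipy.io import mmwrite

    matrix_path = Path(matrix_path)
    X = adata.X
    mmwrite(str(matrix_path), sparse.csr_matrix(X))
    pd.Series(adata.var_names).to_csv(
        matrix_path.with_name("genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        matrix_path.with_name("barcodes.tsv"), sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(
    config: RunConfig, outputs: dict[str, str], path, status: str = "ok"
) -> dict:
    """JSON run manifest: version, config hash, seed, output checksums."""
    from . import __version__

    manifest = {
        "tool": "mtbottleneck",
        "version": __version__,
        "status": status,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in outputs.items()
            if Path(p).exists()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
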