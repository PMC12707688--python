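"""Readers and writers for the on-disk formats used by the CLI.

Counts travel as Matrix Market (.mtx) with sidecar CSVs: ``locations.csv``
(id, x, y and, when known, the domain label) and ``genes.csv`` (id and gene
class).  Results are CSV matrices aligned to location ids plus a JSON run
manifest recording the full configuration, seeds, input digests and the
package version, so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .synthdata import CountMatrix, TissueLayout

__all__ = [
    "write_counts",
    "read_counts",
    "write_matrix_csv",
    "write_manifest",
    "file_digest",
]


def write_counts(outdir: str | Path, counts: CountMatrix) -> None:
    """Write counts.mtx + locations.csv + genes.csv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "counts.mtx"), counts.counts.astype(int))
    loc = pd.DataFrame({"id": counts.location_ids})
    if counts.layout is not None:
        loc["x"] = counts.layout.coords[:, 0]
        loc["y"] = counts.layout.coords[:, 1]
        loc["domain"] = counts.layout.domain_labels
    loc.to_csv(outdir / "locations.csv", index=False)
    pd.DataFrame({"id": counts.gene_ids, "class": counts.gene_class}).to_csv(
        outdir / "genes.csv", index=False
    )


def read_counts(
    counts_path: str | Path,
    locations_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> CountMatrix:
    """Read a Matrix Market count matrix with optional sidecar CSVs.

    When ``locations_path`` carries x/y (and optionally domain) columns a
    :class:`~rasp.synthdata.TissueLayout` is attached.
    """
    counts_path = Path(counts_path)
    X = sparse.csr_matrix(spio.mmread(str(counts_path)))
    n, m = X.shape
    if locations_path is None:
        cand = counts_path.parent / "locations.csv"
        locations_path = cand if cand.exists() else None
    if genes_path is None:
        cand = counts_path.parent / "genes.csv"
        genes_path = cand if cand.exists() else None
    layout = None
    if locations_path is not None:
        loc = pd.read_csv(locations_path)
        location_ids = loc["id"].to_numpy()
        if {"x", "y"}.issubset(loc.columns):
            labels = (
                loc["domain"].to_numpy()
                if "domain" in loc.columns
                else np.zeros(n, dtype=int)
            )
            coords = loc[["x", "y"]].to_numpy(dtype=float)
            extent = (float(coords[:, 0].max()), float(coords[:, 1].max()))
            layout = TissueLayout(coords, labels, "loaded", 0, extent)
    else:
        location_ids = np.array([f"loc_{i:05d}" for i in range(n)])
    if genes_path is not None:
        genes = pd.read_csv(genes_path)
        gene_ids = genes["id"].to_numpy()
        gene_class = (
            genes["class"].to_numpy()
            if "class" in genes.columns
            else np.array(["unknown"] * m)
        )
    else:
        gene_ids = np.array([f"gene_{i:04d}" for i in range(m)])
        gene_class = np.array(["unknown"] * m)
    return CountMatrix(X, location_ids, gene_ids, gene_class, layout)


def write_matrix_csv(
    path: str | Path,
    M: np.ndarray,
    location_ids: np.ndarray | None = None,
    prefix: str = "PC",
) -> None:
    """Write an n x k score matrix as CSV with location ids as the index."""
    M = np.asarray(M)
    df = pd.DataFrame(M, columns=[f"{prefix}{i + 1}" for i in range(M.shape[1])])
    if location_ids is not None:
        df.insert(0, "id", location_ids)
    df.to_csv(path, index=False)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    """Write the run manifest (command, config, seeds, digests, version)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": _jsonable(config),
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
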