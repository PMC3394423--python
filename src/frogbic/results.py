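"""Serialization of run outputs: archive JSON/TSV, logs and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .bicluster import Bicluster, decode, msr, row_variance
from .engine import RunResult
from .expression import ExpressionMatrix
from .pareto import EpsArchive

__all__ = [
    "archive_biclusters",
    "archive_records",
    "write_archive_json",
    "write_archive_tsv",
    "write_log_csv",
    "write_manifest",
    "read_archive_json",
]


def archive_biclusters(archive: EpsArchive, matrix: ExpressionMatrix) -> list[Bicluster]:
    """Decode every archive member's stored position into a bicluster."""
    return [decode(m.payload["position"], matrix.n, matrix.m) for m in archive.members]


def archive_records(archive: EpsArchive, matrix: ExpressionMatrix) -> list[dict]:
    """One JSON-ready record per archive member, with labels and statistics."""
    records = []
    for member, b in zip(archive.members, archive_biclusters(archive, matrix)):
        records.append(
            {
                "gene_ids": [matrix.gene_ids[i] for i in b.gene_indices],
                "condition_ids": [matrix.condition_ids[j] for j in b.condition_indices],
                "msr": msr(matrix, b),
                "row_variance": row_variance(matrix, b),
                "size": b.size,
                "objectives": [float(v) for v in member.objectives],
            }
        )
    return records


def write_archive_json(archive: EpsArchive, matrix: ExpressionMatrix,
                       path: str | Path) -> None:
    Path(path).write_text(json.dumps(archive_records(archive, matrix), indent=1) + "\n")


def read_archive_json(path: str | Path, matrix: ExpressionMatrix) -> list[Bicluster]:
    """Load archived biclusters back as index sets against *matrix*'s labels."""
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cond_pos = {c: j for j, c in enumerate(matrix.condition_ids)}
    out = []
    for rec in json.loads(Path(path).read_text()):
        out.append(
            Bicluster(
                tuple(gene_pos[g] for g in rec["gene_ids"]),
                tuple(cond_pos[c] for c in rec["condition_ids"]),
            )
        )
    return out


def write_archive_tsv(archive: EpsArchive, matrix: ExpressionMatrix,
                      path: str | Path) -> None:
    """Summary table: one bicluster per row with counts, residue, row variance."""
    rows = [
        {
            "bicluster": i + 1,
            "genes": len(rec["gene_ids"]),
            "conditions": len(rec["condition_ids"]),
            "residue": rec["msr"],
            "row_variance": rec["row_variance"],
            "size": rec["size"],
        }
        for i, rec in enumerate(archive_records(archive, matrix))
    ]
    pd.DataFrame(rows, columns=["bicluster", "genes", "conditions", "residue",
                                "row_variance", "size"]).to_csv(path, sep="\t", index=False)


def write_log_csv(result: RunResult, path: str | Path) -> None:
    result.log.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(result: RunResult, inputs: dict[str, str | Path],
                   path: str | Path) -> None:
    """Write a reproducibility manifest: config, seed, version, input checksums."""
    from . import __version__

    manifest = {
        "software": "frogbic",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": result.config.seed,
        "config": asdict(result.config),
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                   for name, p in inputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n")
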