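"""Readers and writers for interchange formats, plus run manifests.

Panels are read from GCT 1.2/1.3 text or plain TSV (first column = gene id,
remaining columns = drugs). Signatures are TSV with columns ``gene``,
``stat`` and optionally ``significant``. Annotations are CSV: AUC mode has
columns ``drug,label``; ES mode is a single ``drug`` column. All numeric
output is serialized at 6 significant digits so reruns diff cleanly across
platforms, and every result directory gets a manifest recording file
hashes, the configuration hash, the seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .benchmark import EFFECTIVE, INEFFECTIVE, AnnotationSet
from .errors import InputError
from .signature import GeneSignature, ReferencePanel

__all__ = [
    "read_signature",
    "write_signature",
    "read_panel",
    "write_panel_tsv",
    "write_panel_gct",
    "read_auc_annotation",
    "read_es_annotation",
    "write_annotation",
    "read_mapping",
    "write_results",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.6g"


def read_signature(path: str | Path) -> GeneSignature:
    """Read a signature TSV with header columns gene, stat [, significant]."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise InputError(f"cannot parse signature TSV {path}: {exc}") from exc
    if "gene" not in df.columns or "stat" not in df.columns:
        raise InputError(f"{path}: signature TSV needs 'gene' and 'stat' columns")
    return GeneSignature.from_frame(df)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _read_gct(path: Path, version: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise InputError(f"{path}: truncated GCT file")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (IndexError, ValueError) as exc:
        raise InputError(f"{path}:2: malformed GCT dimension line {lines[1]!r}") from exc
    if version == "1.3":
        n_rmeta = int(dims[2]) if len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if len(dims) > 3 else 0
    else:
        n_rmeta, n_cmeta = 1, 0  # GCT 1.2 always has the Description column
    header = lines[2].split("\t")
    data_start = 3 + n_cmeta  # column-metadata rows sit between header and data
    body = [ln.split("\t") for ln in lines[data_start:] if ln]
    if len(body) != n_rows:
        raise InputError(
            f"{path}: expected {n_rows} data rows, found {len(body)} "
            f"(first data line is line {data_start + 1})"
        )
    drug_cols = header[1 + n_rmeta :]
    if len(drug_cols) != n_cols:
        raise InputError(
            f"{path}:3: header declares {len(drug_cols)} data columns, "
            f"dimension line says {n_cols}"
        )
    genes, values = [], []
    for i, parts in enumerate(body):
        line_no = data_start + 1 + i
        if len(parts) != 1 + n_rmeta + n_cols:
            raise InputError(f"{path}:{line_no}: wrong field count ({len(parts)})")
        genes.append(parts[0])
        try:
            values.append([float(x) for x in parts[1 + n_rmeta :]])
        except ValueError as exc:
            raise InputError(f"{path}:{line_no}: non-numeric cell ({exc})") from exc
    return pd.DataFrame(values, index=genes, columns=drug_cols)


def read_panel(path: str | Path) -> ReferencePanel:
    """Read a reference panel from GCT 1.2/1.3 text or TSV.

    TSV layout: header row, first column gene ids, remaining columns one
    drug each. Duplicate gene rows and non-numeric cells are rejected with
    the offending location."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first in ("#1.2", "#1.3"):
        df = _read_gct(path, first[1:])
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"cannot parse panel TSV {path}: {exc}") from exc
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}: non-numeric panel cell: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate gene rows: {dupes[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ReferencePanel(df)


def write_panel_tsv(panel: ReferencePanel, path: str | Path) -> None:
    panel.data.to_csv(
        path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT
    )


def write_panel_gct(panel: ReferencePanel, path: str | Path) -> None:
    """Write GCT 1.2 text (Description column filled with the gene id)."""
    df = panel.data
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            vals = "\t".join(FLOAT_FORMAT % v for v in row.to_numpy())
            fh.write(f"{gene}\t{gene}\t{vals}\n")


def read_auc_annotation(path: str | Path) -> AnnotationSet:
    """Read an AUC-mode annotation CSV with columns drug,label."""
    df = pd.read_csv(path)
    if not {"drug", "label"} <= set(df.columns):
        raise InputError(f"{path}: AUC annotation needs 'drug' and 'label' columns")
    bad = set(df["label"]) - {EFFECTIVE, INEFFECTIVE}
    if bad:
        raise InputError(f"{path}: labels must be Effective/Ineffective, got {bad}")
    return AnnotationSet.from_labels(dict(zip(df["drug"].astype(str), df["label"])))


def read_es_annotation(path: str | Path) -> AnnotationSet:
    """Read an ES-mode annotation CSV with a single drug column."""
    df = pd.read_csv(path)
    if "drug" not in df.columns:
        raise InputError(f"{path}: ES annotation needs a 'drug' column")
    return AnnotationSet.from_effective(df["drug"].astype(str))


def write_annotation(ann: AnnotationSet, path: str | Path) -> None:
    if ann.mode == "AUC":
        pd.DataFrame(
            sorted(ann.labels.items()), columns=["drug", "label"]
        ).to_csv(path, index=False)
    else:
        pd.DataFrame({"drug": sorted(ann.effective_set)}).to_csv(path, index=False)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read an identifier mapping TSV with columns old_id, new_id."""
    df = pd.read_csv(path, sep="\t")
    if not {"old_id", "new_id"} <= set(df.columns):
        raise InputError(f"{path}: mapping TSV needs 'old_id' and 'new_id' columns")
    if df["old_id"].duplicated().any():
        dupes = df.loc[df["old_id"].duplicated(), "old_id"].tolist()
        raise InputError(f"{path}: duplicate old_id keys: {dupes[:5]}")
    return dict(zip(df["old_id"].astype(str), df["new_id"].astype(str)))


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    jsons: Mapping[str, Any] | None = None,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Write TSV/JSON outputs plus a manifest; returns the manifest.

    Identical inputs yield byte-identical files: floats are written at
    fixed precision, JSON keys are sorted, and the manifest carries no
    timestamps — only file hashes, the configuration hash, the seed and
    library versions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in (tables or {}).items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(p)
    for name, obj in (jsons or {}).items():
        p = outdir / f"{name}.json"
        p.write_text(
            json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
            encoding="utf-8",
        )
        written.append(p)
    from . import __version__

    config_blob = json.dumps(config or {}, sort_keys=True, default=_json_default)
    manifest = {
        "files": {p.name: _sha256(p) for p in sorted(written)},
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "sigsearch": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
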