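"""File formats and run manifests.

Ancestry-call TSV: one row per marker, columns ``chrom``, ``pos``, then
one dosage column per individual with values 0/1/2 (count of parent-1
ancestry alleles) or NA for missing.  Which species is parent 1 is a
property of the upstream ancestry calls and is recorded in the manifest,
not in the matrix.

Phased haplotype TSV: two rows per individual (columns ``individual``,
``hap`` in {1, 2}, then one 0/1 column per marker named ``chrom:pos``).

Every CLI run writes a JSON manifest with the resolved configuration and
the master seed, sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import MISSING, AncestryMatrix

__all__ = [
    "read_ancestry_table",
    "write_ancestry_table",
    "read_phased_table",
    "write_phased_table",
    "write_table",
    "write_json",
    "write_manifest",
]


def read_ancestry_table(path) -> AncestryMatrix:
    """Read and validate an ancestry-call TSV into an AncestryMatrix."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValueError(f"{path}: first columns must be 'chrom' and 'pos'")
    individuals = list(df.columns[2:])
    if not individuals:
        raise ValueError(f"{path}: no individual columns")
    values = df[individuals].to_numpy()
    dosage = np.full(values.shape, MISSING, dtype=np.int8)
    for col_i in range(values.shape[1]):
        col = values[:, col_i]
        for row_i, v in enumerate(col):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                iv = int(v)
                valid = float(v) == iv and iv in (0, 1, 2)
            except (TypeError, ValueError):
                valid = False
            if not valid:
                raise ValueError(
                    f"{path}: invalid dosage {v!r} at marker row {row_i + 1}, "
                    f"column {individuals[col_i]!r}"
                )
            dosage[row_i, col_i] = iv
    markers = df[["chrom", "pos"]].copy()
    markers["pos"] = markers["pos"].astype(np.int64)
    # AncestryMatrix sorts (with a warning) and rejects duplicates
    return AncestryMatrix(dosage=dosage.T, markers=markers, individuals=individuals)


def write_ancestry_table(matrix: AncestryMatrix, path) -> None:
    dosage = matrix.dosage.T.astype(object)
    dosage[dosage == MISSING] = "NA"
    df = pd.concat(
        [matrix.markers[["chrom", "pos"]],
         pd.DataFrame(dosage, columns=matrix.individuals)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def write_phased_table(matrix: AncestryMatrix, path) -> None:
    if matrix.haplotypes is None:
        raise ValueError("matrix has no phased haplotypes")
    marker_ids = [
        f"{c}:{p}" for c, p in zip(matrix.markers["chrom"], matrix.markers["pos"])
    ]
    rows = []
    for i, name in enumerate(matrix.individuals):
        for h in (0, 1):
            rows.append([name, h + 1, *matrix.haplotypes[2 * i + h].tolist()])
    pd.DataFrame(rows, columns=["individual", "hap", *marker_ids]).to_csv(
        path, sep="\t", index=False
    )


def read_phased_table(path, matrix: AncestryMatrix) -> AncestryMatrix:
    """Attach phased haplotypes from a phased TSV to an ancestry matrix.

    Marker columns must match the matrix's (chrom, pos) set; individuals
    must appear in the same order with two rows each.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["individual", "hap"]:
        raise ValueError(f"{path}: first columns must be 'individual' and 'hap'")
    marker_ids = [
        f"{c}:{p}" for c, p in zip(matrix.markers["chrom"], matrix.markers["pos"])
    ]
    missing_cols = [m for m in marker_ids if m not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing marker columns, e.g. {missing_cols[0]}")
    expected = [n for n in matrix.individuals for _ in (0, 1)]
    if list(df["individual"]) != expected:
        raise ValueError(f"{path}: individuals do not match the ancestry matrix")
    hap = df[marker_ids].to_numpy()
    if not np.isin(hap, [0, 1]).all():
        raise ValueError(f"{path}: haplotype labels must be 0/1")
    matrix.haplotypes = hap.astype(np.uint8)
    return matrix


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with stable column order (empty tables keep their header)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def write_manifest(path, command: str, params: dict, seed=None) -> None:
    from . import __version__

    write_json(
        {"tool": "dmiscan", "version": __version__, "command": command,
         "seed": seed, "parameters": params},
        path,
    )
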