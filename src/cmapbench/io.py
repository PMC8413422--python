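"""Text I/O for the ecosystem's interchange formats.

GCT 1.2 / 1.3 text matrices (gene x sample, with Name/Description columns),
GRP gene lists (one id per line, '#' comments), and TSV tables for sample
metadata, DE profiles and signature manifests.  Values round-trip at six
significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .de import DEProfile
from .signatures import Signature
from .synth import ConditionKey, ExpressionMatrix

__all__ = [
    "GctParseError",
    "read_gct",
    "write_gct",
    "read_grp",
    "write_grp",
    "write_signature_grp",
    "write_sample_meta",
    "read_sample_meta",
    "read_expression_matrix",
    "profiles_to_frame",
    "frame_to_profiles",
]

FLOAT_FMT = "%.6g"


class GctParseError(ValueError):
    """Malformed GCT content; message carries the offending line number."""


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 or 1.3 text file into a gene x sample DataFrame.

    Row/column metadata fields in 1.3 files are skipped; only the Name
    (id) column and the data block are retained.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise GctParseError(f"{path}:1: expected a '#1.2' or '#1.3' version line")
    version = lines[0].strip()
    if len(lines) < 3:
        raise GctParseError(f"{path}:2: truncated file")
    dims = lines[1].split("\t")
    try:
        nums = [int(x) for x in dims]
    except ValueError as exc:
        raise GctParseError(f"{path}:2: non-integer dimension field") from exc
    if version == "#1.2":
        if len(nums) != 2:
            raise GctParseError(f"{path}:2: GCT 1.2 needs 2 dimension fields")
        nrow, ncol = nums
        n_rhd, n_chd = 1, 0  # the Description column
    elif version == "#1.3":
        if len(nums) != 4:
            raise GctParseError(f"{path}:2: GCT 1.3 needs 4 dimension fields")
        nrow, ncol, n_rhd, n_chd = nums
    else:
        raise GctParseError(f"{path}:1: unsupported version {version!r}")

    header = lines[2].split("\t")
    expected_cols = 1 + n_rhd + ncol
    if len(header) != expected_cols:
        raise GctParseError(
            f"{path}:3: header has {len(header)} fields, expected {expected_cols}"
        )
    sample_ids = header[1 + n_rhd :]
    body_start = 3 + n_chd  # 1.3 column-metadata rows are skipped
    body = lines[body_start : body_start + nrow]
    if len(body) != nrow:
        raise GctParseError(
            f"{path}:{body_start + len(body) + 1}: expected {nrow} data rows, found {len(body)}"
        )
    ids: list[str] = []
    data = np.empty((nrow, ncol))
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != expected_cols:
            raise GctParseError(
                f"{path}:{body_start + i + 1}: row has {len(fields)} fields, "
                f"expected {expected_cols}"
            )
        ids.append(fields[0])
        try:
            data[i] = [float(x) for x in fields[1 + n_rhd :]]
        except ValueError as exc:
            raise GctParseError(f"{path}:{body_start + i + 1}: non-numeric value") from exc
    return pd.DataFrame(
        data, index=pd.Index(ids, name="gene_id"), columns=pd.Index(sample_ids, name="sample_id")
    )


def write_gct(matrix: pd.DataFrame, path) -> None:
    """Write a gene x sample DataFrame as GCT 1.2 text."""
    path = Path(path)
    nrow, ncol = matrix.shape
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{nrow}\t{ncol}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            vals = "\t".join(FLOAT_FMT % v for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


def read_grp(path) -> list[str]:
    """Read a GRP gene list: one id per line, '#' comments and blanks skipped."""
    out: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            out.append(s)
    return out


def write_grp(gene_ids: Sequence[str], path, comment: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for g in gene_ids:
            fh.write(f"{g}\n")


def write_signature_grp(sig: Signature, stem) -> tuple[Path, Path]:
    """Write a signature as paired UP/DN GRP files; returns the two paths."""
    stem = Path(stem)
    up = stem.with_name(stem.name + "_UP.grp")
    dn = stem.with_name(stem.name + "_DN.grp")
    label = str(sig.source_condition) if sig.source_condition else sig.method
    write_grp(sig.up_genes, up, comment=f"{label} [{sig.method}] up")
    write_grp(sig.down_genes, dn, comment=f"{label} [{sig.method}] down")
    return up, dn


META_COLUMNS = [
    "compound",
    "concentration_uM",
    "cell_line",
    "duration_h",
    "role",
    "plate_pool",
    "replicate_group",
]


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", columns=META_COLUMNS, index_label="sample_id")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta["compound"] = meta["compound"].fillna("")
    return meta


def read_expression_matrix(gct_path, meta_path, landmark_path=None) -> ExpressionMatrix:
    values = read_gct(gct_path)
    meta = read_sample_meta(meta_path)
    landmark = pd.Index(read_grp(landmark_path)) if landmark_path else values.index[:0]
    return ExpressionMatrix(values=values, sample_meta=meta, landmark_ids=landmark)


def profiles_to_frame(profiles: Sequence[DEProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pack DE profiles into a gene x profile matrix plus a profile metadata table."""
    if not profiles:
        raise ValueError("no profiles to pack")
    ids = [p.replicate_id or f"profile{i}" for i, p in enumerate(profiles)]
    mat = pd.DataFrame(
        {pid: p.values for pid, p in zip(ids, profiles)},
    )
    mat.index.name = "gene_id"
    meta = pd.DataFrame(
        [
            dict(
                profile_id=pid,
                compound=p.condition.compound,
                concentration_uM=p.condition.concentration_uM,
                cell_line=p.condition.cell_line,
                duration_h=p.condition.duration_h,
                kind=p.kind,
                n_contributing_replicates=p.n_contributing_replicates,
            )
            for pid, p in zip(ids, profiles)
        ]
    ).set_index("profile_id")
    return mat, meta


def frame_to_profiles(mat: pd.DataFrame, meta: pd.DataFrame) -> list[DEProfile]:
    profiles = []
    for pid, row in meta.iterrows():
        cond = ConditionKey(
            str(row["compound"]),
            float(row["concentration_uM"]),
            str(row["cell_line"]),
            float(row["duration_h"]),
        )
        profiles.append(
            DEProfile(
                condition=cond,
                kind=str(row["kind"]),
                values=mat[pid],
                n_contributing_replicates=int(row["n_contributing_replicates"]),
                replicate_id=str(pid),
            )
        )
    return profiles
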