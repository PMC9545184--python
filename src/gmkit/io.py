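"""Reading and writing landmark data: TPS files, CSV tables, covariates.

The TPS format is the field-standard plain-text container: each record starts
with ``LM=p`` (2D) or ``LM3=p`` (3D), followed by one coordinate line per
landmark, with optional ``ID=``, ``IMAGE=``, and ``SCALE=`` keys. SCALE is
applied multiplicatively on read. Coordinates are stored exactly as given;
no axis flipping is performed (image-origin conventions are the caller's
concern).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import LandmarkConfiguration, LandmarkError, LandmarkSample, make_sample

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"LM", "LM3", "ID", "IMAGE", "SCALE"}


class TpsFormatError(LandmarkError):
    """Raised for malformed TPS files."""


def read_tps(path) -> LandmarkSample:
    """Read a TPS landmark file into a :class:`LandmarkSample`.

    ``ID=`` (preferred) or ``IMAGE=`` fields become specimen ids; ``SCALE=``
    is applied multiplicatively to the record's coordinates. Mixed 2D/3D
    records or inconsistent landmark counts raise :class:`TpsFormatError`.
    """
    text = Path(path).read_text()
    records = _parse_tps_records(text, str(path))
    configs = []
    for i, rec in enumerate(records):
        cid = rec.get("ID") or rec.get("IMAGE") or f"case_{i + 1}"
        coords = rec["coords"] * rec.get("SCALE", 1.0)
        configs.append(LandmarkConfiguration(cid, coords))
    sample = LandmarkSample(configs)
    return sample


def _parse_tps_records(text: str, name: str):
    records = []
    current = None
    dim_seen = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^([A-Za-z][A-Za-z0-9_]*)=(.*)$", line)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key in ("LM", "LM3"):
                k = 2 if key == "LM" else 3
                if dim_seen is not None and k != dim_seen:
                    raise TpsFormatError(f"{name}: mixed LM= and LM3= records")
                dim_seen = k
                current = {"p": int(value), "k": k, "rows": []}
                records.append(current)
            elif key in ("ID", "IMAGE"):
                if current is None:
                    raise TpsFormatError(f"{name}: {key}= before any LM record")
                current[key] = value
            elif key == "SCALE":
                if current is None:
                    raise TpsFormatError(f"{name}: SCALE= before any LM record")
                current["SCALE"] = float(value)
            else:
                logger.warning("%s: ignoring unknown TPS key %s=", name, key)
        else:
            if current is None:
                raise TpsFormatError(f"{name}: coordinate line before any LM record")
            vals = [float(v) for v in line.split()]
            if len(vals) != current["k"]:
                raise TpsFormatError(
                    f"{name}: expected {current['k']} coordinates, got line {line!r}"
                )
            current["rows"].append(vals)
    if not records:
        raise TpsFormatError(f"{name}: no LM= records found")
    p0 = records[0]["p"]
    for rec in records:
        if len(rec["rows"]) != rec["p"]:
            raise TpsFormatError(
                f"{name}: record declares {rec['p']} landmarks but has {len(rec['rows'])}"
            )
        if rec["p"] != p0:
            raise TpsFormatError(
                f"{name}: inconsistent landmark counts ({rec['p']} vs {p0})"
            )
        rec["coords"] = np.asarray(rec["rows"], float)
    return records


def write_tps(sample: LandmarkSample, path) -> None:
    """Write a sample as a TPS file (one LM=/LM3= record per configuration).

    Coordinates are written with 6 decimals, so write/read round trips are
    exact to that precision.
    """
    if sample.n == 0:
        raise LandmarkError("refusing to write an empty sample")
    key = "LM" if sample.k == 2 else "LM3"
    lines = []
    for cfg in sample:
        lines.append(f"{key}={cfg.p}")
        for row in cfg.coords:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append(f"ID={cfg.id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmark_table(path, layout: str = "wide") -> LandmarkSample:
    """Read landmarks from CSV.

    ``wide``: one row per specimen, an ``id`` column and coordinate columns
    named ``<landmark>_x``, ``<landmark>_y`` (and ``_z`` for 3D).
    ``long``: one row per landmark with columns ``id``, ``landmark``,
    ``x``, ``y`` (and ``z``).
    """
    df = pd.read_csv(path)
    if layout == "wide":
        return _from_wide(df, str(path))
    if layout == "long":
        return _from_long(df, str(path))
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def _check_nan(df, name, cols):
    bad = df[cols].isna().to_numpy()
    if bad.any():
        cells = [f"row {r}, column {cols[c]!r}" for r, c in zip(*np.where(bad))]
        raise LandmarkError(f"{name}: missing coordinates at " + "; ".join(cells))


def _from_wide(df: pd.DataFrame, name: str) -> LandmarkSample:
    id_col = df.columns[0] if "id" not in df.columns else "id"
    suffix_re = re.compile(r"^(.*)_([xyz])$")
    by_lm = {}
    for col in df.columns:
        m = suffix_re.match(col)
        if m:
            by_lm.setdefault(m.group(1), {})[m.group(2)] = col
    if not by_lm:
        raise LandmarkError(f"{name}: no coordinate columns with _x/_y/_z suffixes")
    k = 3 if all("z" in axes for axes in by_lm.values()) else 2
    axes = "xyz"[:k]
    lm_names = list(by_lm)
    cols = [by_lm[lm][a] for lm in lm_names for a in axes]
    _check_nan(df, name, cols)
    coords = df[cols].to_numpy(float).reshape(len(df), len(lm_names), k)
    ids = df[id_col].astype(str).tolist()
    return make_sample(coords, ids=ids, landmark_names=lm_names)


def _from_long(df: pd.DataFrame, name: str) -> LandmarkSample:
    required = {"id", "landmark", "x", "y"}
    if not required.issubset(df.columns):
        raise LandmarkError(f"{name}: long layout needs columns {sorted(required)}")
    k = 3 if "z" in df.columns else 2
    axes = list("xyz"[:k])
    _check_nan(df, name, axes)
    ids = df["id"].astype(str)
    lm_names = df["landmark"].astype(str).unique().tolist()
    configs = []
    for cid in ids.unique():
        sub = df[ids == cid]
        sub = sub.set_index(sub["landmark"].astype(str)).loc[lm_names]
        configs.append(
            LandmarkConfiguration(cid, sub[axes].to_numpy(float), lm_names)
        )
    return LandmarkSample(configs)


def write_landmark_table(sample: LandmarkSample, path) -> None:
    """Write a sample as a wide CSV (inverse of ``read_landmark_table``)."""
    axes = "xyz"[: sample.k]
    cols = [f"{lm}_{a}" for lm in sample.landmark_names for a in axes]
    df = pd.DataFrame(sample.as_flat(), columns=cols)
    df.insert(0, "id", sample.ids)
    df.to_csv(path, index=False)


def read_obj_mesh(path):
    """Read a triangulated OBJ surface mesh (for semilandmark projection).

    Returns a trimesh ``Trimesh`` with ``vertices`` and ``faces``.
    """
    import trimesh

    mesh = trimesh.load(str(path), file_type="obj", force="mesh", process=False)
    if len(mesh.faces) == 0:
        raise LandmarkError(f"{path}: mesh has no faces")
    return mesh


def read_covariates(path, id_column: str = "id") -> pd.DataFrame:
    """Read a covariate table keyed by specimen id."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise LandmarkError(f"covariate table lacks id column {id_column!r}")
    return df.rename(columns={id_column: "id"})


def attach_covariates(sample: LandmarkSample, table: pd.DataFrame) -> LandmarkSample:
    """Join a covariate table to a sample by id, re-ordered to sample order.

    Every configuration id must appear exactly once in the table.
    """
    table = table.copy()
    if "id" not in table.columns:
        raise LandmarkError("covariate table needs an 'id' column")
    table["id"] = table["id"].astype(str)
    indexed = table.set_index("id")
    missing = [cid for cid in sample.ids if cid not in indexed.index]
    if missing:
        raise LandmarkError(f"covariate table missing ids: {missing}")
    aligned = indexed.loc[sample.ids].reset_index()
    return LandmarkSample(sample.configurations, covariates=aligned)
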