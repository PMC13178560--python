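"""Particle-table I/O: RELION-3.0-dialect STAR, canonical CSV, JSON reports.

Internal units are Angstrom and degrees.  STAR files store coordinates in
voxels, so every dialect carries an explicit pixel size for the conversion;
unknown loop columns are preserved opaquely through a round trip.  The
dependency-free interchange twin of every table is a plain CSV with the
canonical column names (``particle_id, tomo_id, tube_id, x_A, y_A, z_A,
rot_deg, tilt_deg, psi_deg, score``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .geometry import TABLE_COLUMNS

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StarDialect:
    """Column naming + unit convention of a RELION 3.0 particle STAR file."""

    pixel_size_A: float = 1.0
    coord_cols: tuple = ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ")
    angle_cols: tuple = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
    tomo_col: str = "_rlnMicrographName"
    tube_col: str = "_rlnHelicalTubeID"
    score_col: str = "_rlnAutopickFigureOfMerit"
    id_col: str = "_coatParticleId"

    def __post_init__(self):
        if not self.pixel_size_A > 0:
            raise ValueError("pixel size must be positive")


RELION30 = StarDialect()


# --------------------------------------------------------------------------
# STAR
# --------------------------------------------------------------------------


def _parse_star_loop(path: Path):
    """Return (tags, rows) of the first loop_ block; rows are token lists."""
    tags, rows = [], []
    state = "scan"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if state == "rows" and not line:
                    break
                continue
            if state == "scan":
                if line == "loop_":
                    state = "tags"
            elif state == "tags":
                if line.startswith("_"):
                    tags.append(line.split()[0])
                else:
                    state = "rows"
                    rows.append((lineno, line.split()))
            elif state == "rows":
                if line.startswith(("data_", "loop_")):
                    break
                rows.append((lineno, line.split()))
    if not tags:
        raise FormatError(f"{path}: no loop_ block found")
    return tags, rows


def read_star(path, dialect: StarDialect = RELION30) -> pd.DataFrame:
    """Read a RELION-3.0-dialect particle STAR file into a canonical table.

    Coordinates are converted voxels -> Angstrom via the dialect pixel
    size; angles are kept in degrees.  Unknown columns are preserved under
    their STAR tag names.  Missing id / tomo / tube / score columns fall
    back to row order, empty strings and zero scores.
    """
    path = Path(path)
    tags, rows = _parse_star_loop(path)
    for col in (*dialect.coord_cols, *dialect.angle_cols):
        if col not in tags:
            raise FormatError(f"{path}: missing required column {col}")
    for lineno, toks in rows:
        if len(toks) != len(tags):
            raise FormatError(
                f"{path}:{lineno}: expected {len(tags)} fields, got {len(toks)}"
            )
    raw = pd.DataFrame(
        [toks for _, toks in rows], columns=tags, dtype=str
    )
    linenos = [lineno for lineno, _ in rows]

    def numeric(col):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}:{linenos[i]}: non-numeric value {raw[col].iloc[i]!r} "
                f"in column {col}"
            )
        return vals.to_numpy(dtype=float)

    n = len(raw)
    table = pd.DataFrame(
        {
            "particle_id": (
                numeric(dialect.id_col).astype(int)
                if dialect.id_col in tags
                else np.arange(n)
            ),
            "tomo_id": raw[dialect.tomo_col] if dialect.tomo_col in tags else "",
            "tube_id": raw[dialect.tube_col] if dialect.tube_col in tags else "",
            "x_A": numeric(dialect.coord_cols[0]) * dialect.pixel_size_A,
            "y_A": numeric(dialect.coord_cols[1]) * dialect.pixel_size_A,
            "z_A": numeric(dialect.coord_cols[2]) * dialect.pixel_size_A,
            "rot_deg": numeric(dialect.angle_cols[0]),
            "tilt_deg": numeric(dialect.angle_cols[1]),
            "psi_deg": numeric(dialect.angle_cols[2]),
            "score": (
                numeric(dialect.score_col) if dialect.score_col in tags else 0.0
            ),
        }
    )
    known = {
        *dialect.coord_cols,
        *dialect.angle_cols,
        dialect.tomo_col,
        dialect.tube_col,
        dialect.score_col,
        dialect.id_col,
    }
    for tag in tags:
        if tag not in known:
            table[tag] = raw[tag]
    tilt = table["tilt_deg"].to_numpy()
    if np.any((tilt < -1e-6) | (tilt > 180.0 + 1e-6)):
        raise FormatError(f"{path}: tilt angles outside [0, 180]")
    return table


def write_star(table: pd.DataFrame, path, dialect: StarDialect = RELION30) -> None:
    """Write a canonical table as a RELION-3.0 particle STAR file.

    Coordinates are converted Angstrom -> voxels.  Extra (non-canonical)
    columns are appended after the standard loop columns in deterministic
    order."""
    path = Path(path)
    extras = [c for c in table.columns if c not in TABLE_COLUMNS]
    cols = [
        (dialect.coord_cols[0], table["x_A"] / dialect.pixel_size_A),
        (dialect.coord_cols[1], table["y_A"] / dialect.pixel_size_A),
        (dialect.coord_cols[2], table["z_A"] / dialect.pixel_size_A),
        (dialect.angle_cols[0], table["rot_deg"]),
        (dialect.angle_cols[1], table["tilt_deg"]),
        (dialect.angle_cols[2], table["psi_deg"]),
        (dialect.tomo_col, table["tomo_id"]),
        (dialect.tube_col, table["tube_id"]),
        (dialect.score_col, table["score"]),
        (dialect.id_col, table["particle_id"]),
    ] + [(c, table[c]) for c in extras]
    with open(path, "w") as fh:
        fh.write("# written by coatlattice\n\ndata_particles\n\nloop_\n")
        for i, (tag, _) in enumerate(cols, start=1):
            fh.write(f"{tag} #{i}\n")
        for i in range(len(table)):
            fields = []
            for _, series in cols:
                v = series.iloc[i]
                if isinstance(v, (float, np.floating)):
                    fields.append(f"{v:.6f}")
                else:
                    fields.append(str(v))
            fh.write(" ".join(fields) + "\n")


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------


def write_csv(table: pd.DataFrame, path) -> None:
    """Canonical-column CSV twin of a particle table (Angstrom, degrees)."""
    cols = TABLE_COLUMNS + [c for c in table.columns if c not in TABLE_COLUMNS]
    table[cols].to_csv(path, index=False, float_format="%.6f")


def read_csv(path) -> pd.DataFrame:
    """Read a canonical particle-table CSV."""
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    table["tomo_id"] = table["tomo_id"].fillna("").astype(str)
    table["tube_id"] = table["tube_id"].fillna("").astype(str)
    return table


def read_table(path, dialect: StarDialect = RELION30) -> pd.DataFrame:
    """Dispatch on extension: .star -> STAR, anything else -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".star":
        return read_star(path, dialect)
    return read_csv(path)


def write_table(table: pd.DataFrame, path, dialect: StarDialect = RELION30) -> None:
    path = Path(path)
    if path.suffix.lower() == ".star":
        write_star(table, path, dialect)
    else:
        write_csv(table, path)


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["tube_id", "point_index", "x_A", "y_A", "z_A", "radius_A"]


def read_annotations(path) -> list:
    """Read tube annotations (one :class:`TubeAnnotation` per tube id).

    CSV columns: ``tube_id, point_index, x_A, y_A, z_A, radius_A``."""
    from .seeding import build_annotation

    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = []
    for tube_id, grp in df.groupby("tube_id", sort=True):
        grp = grp.sort_values("point_index")
        out.append(
            build_annotation(
                grp[["x_A", "y_A", "z_A"]].to_numpy(dtype=float),
                radius_A=float(grp["radius_A"].iloc[0]),
                tube_id=str(tube_id),
            )
        )
    return out


def write_annotations(annotations, path) -> None:
    rows = []
    for ann in annotations:
        for i, p in enumerate(ann.centerline):
            rows.append((ann.tube_id, i, p[0], p[1], p[2], ann.radius_A))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# JSON reports
# --------------------------------------------------------------------------


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_report(obj, path) -> None:
    """Serialize a report dataclass (or dict) as schema-versioned JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        kind = type(obj).__name__
        payload = dataclasses.asdict(obj)
    elif isinstance(obj, dict):
        kind = obj.get("kind", "dict")
        payload = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as a report")
    doc = {"schema_version": SCHEMA_VERSION, "kind": kind, "payload": payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_report(path) -> dict:
    """Read a schema-versioned JSON report; returns the payload dict."""
    with open(path) as fh:
        doc = json.load(fh)
    if "payload" not in doc:
        raise FormatError(f"{path}: not a coatlattice report")
    return doc["payload"]


def write_linkages(records, path) -> None:
    """Linkage records as CSV (ids, sides, class, parallel, angle, confidence)."""
    rows = [dataclasses.asdict(r) for r in records]
    cols = [
        "id_a", "id_b", "side_a", "side_b", "link_class",
        "parallel", "inplane_angle_deg", "confidence", "ambiguous",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_linkages(path):
    from .linkage import LinkageRecord

    df = pd.read_csv(path)
    return [
        LinkageRecord(
            id_a=int(r.id_a),
            id_b=int(r.id_b),
            side_a=str(r.side_a),
            side_b=str(r.side_b),
            link_class=str(r.link_class),
            parallel=bool(r.parallel),
            inplane_angle_deg=float(r.inplane_angle_deg),
            confidence=float(r.confidence),
            ambiguous=bool(r.ambiguous),
        )
        for r in df.itertuples()
    ]
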