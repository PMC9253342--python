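"""Reading, validation, filtering and serialisation of 3D filament traces.

The native interchange format is a plain-text *track table* (TSV) with columns
``filament_id  point_index  x_nm  y_nm  z_nm``; ``point_index`` is 0-based and
defines point order along the filament.  Coordinates are always stored in
nanometres.  An Amira ASCII spatial-graph importer is provided on a best-effort
basis for traces exported from tomogram segmentation software.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_TSV_COLUMNS = ["filament_id", "point_index", "x_nm", "y_nm", "z_nm"]

__all__ = [
    "FilamentTrack",
    "FilamentNetwork",
    "MembranePlane",
    "PodosomeFrame",
    "TrackParseError",
    "TrackValidationError",
    "read_track_table",
    "write_track_table",
    "filter_min_length",
    "write_report",
    "read_report",
]


class TrackValidationError(ValueError):
    """A trace violates a structural invariant (too few points, NaNs, ...)."""


class TrackParseError(ValueError):
    """A track-table or spatial-graph file could not be parsed."""


@dataclass(frozen=True)
class FilamentTrack:
    """One traced filament as an ordered 3D polyline in nm.

    Invariants: at least two points, all coordinates finite, consecutive
    points distinct.
    """

    filament_id: str
    points: np.ndarray  # (n, 3) float64, nm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise TrackValidationError(
                f"filament {self.filament_id!r}: points must be (n, 3), got {pts.shape}"
            )
        if pts.shape[0] < 2:
            raise TrackValidationError(
                f"filament {self.filament_id!r}: needs at least 2 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise TrackValidationError(
                f"filament {self.filament_id!r}: non-finite coordinates"
            )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0.0):
            raise TrackValidationError(
                f"filament {self.filament_id!r}: consecutive points must be distinct"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def contour_length(self) -> float:
        """Sum of segment lengths of the raw polyline, nm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def end_to_end(self) -> float:
        """Euclidean distance between the two endpoints, nm."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def reversed(self) -> "FilamentTrack":
        return FilamentTrack(self.filament_id, self.points[::-1].copy())


@dataclass(frozen=True)
class MembranePlane:
    """The basal membrane: a plane given by a point and a unit normal.

    The normal points from the substrate into the cell; filament orientations
    are measured against this plane.
    """

    origin: np.ndarray  # (3,), nm
    normal: np.ndarray  # (3,), unit vector

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
            raise TrackValidationError("membrane normal must have unit length (1e-9)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "normal", normal)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points to the plane (positive on the cell side)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.normal

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal vectors spanning the plane."""
        n = self.normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass(frozen=True)
class PodosomeFrame:
    """Cylindrical reference frame: membrane plane plus core centre.

    The core axis is the line through ``core_center`` along the membrane
    normal; radial distances are measured from that axis.
    """

    membrane: MembranePlane
    core_center: np.ndarray  # (3,), nm

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "core_center", np.asarray(self.core_center, dtype=float).reshape(3)
        )


@dataclass
class FilamentNetwork:
    """A collection of filament traces plus provenance metadata."""

    tracks: list[FilamentTrack]
    length_unit: str = "nm"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.filament_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate filament ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[FilamentTrack]:
        return iter(self.tracks)

    @property
    def n_points(self) -> int:
        return sum(t.n_points for t in self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            n = t.n_points
            rows.append(
                pd.DataFrame(
                    {
                        "filament_id": [t.filament_id] * n,
                        "point_index": np.arange(n),
                        "x_nm": t.points[:, 0],
                        "y_nm": t.points[:, 1],
                        "z_nm": t.points[:, 2],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=TRACK_TSV_COLUMNS)
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# track-tsv


def _read_track_tsv(path: Path) -> FilamentNetwork:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"filament_id": str})
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise TrackParseError(f"{path}: cannot read TSV ({exc})") from exc
    missing = [c for c in TRACK_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing columns {missing}")
    for col in ("point_index", "x_nm", "y_nm", "z_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 0-based
            raise TrackParseError(
                f"{path}: malformed value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise TrackParseError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = coerced
    if df.duplicated(subset=["filament_id", "point_index"]).any():
        row = df[df.duplicated(subset=["filament_id", "point_index"])].iloc[0]
        raise TrackValidationError(
            f"{path}: duplicate (filament_id, point_index) = "
            f"({row['filament_id']!r}, {int(row['point_index'])})"
        )
    tracks = []
    for fid, grp in df.groupby("filament_id", sort=False):  # keep file order
        grp = grp.sort_values("point_index")
        tracks.append(
            FilamentTrack(str(fid), grp[["x_nm", "y_nm", "z_nm"]].to_numpy(float))
        )
    return FilamentNetwork(
        tracks=tracks,
        provenance={"source": str(path), "dialect": "track-tsv", "filters": []},
    )


def write_track_table(network: FilamentNetwork, path: str | Path) -> None:
    """Write a network as a track-tsv file (full float precision)."""
    df = network.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Amira ASCII spatial graph (best-effort)

_AMIRA_DECL = re.compile(
    r"^\s*(VERTEX|EDGE|POINT)\s*\{\s*(?:float|int)\s*(?:\[\s*(\d+)\s*\])?\s*(\w+)\s*\}\s*@(\d+)"
)
_AMIRA_DEFINE = re.compile(r"^\s*define\s+(\w+)\s+(\d+)")


def _read_amira_ascii(path: Path, voxel_size_nm: float = 1.0) -> FilamentNetwork:
    """Parse an Amira/HxSpatialGraph ASCII file: each edge's point chain
    becomes one filament.  Unknown sections are ignored with a warning.
    Coordinates are multiplied by ``voxel_size_nm``.
    """
    text = Path(path).read_text().splitlines()
    counts: dict[str, int] = {}
    decls: dict[str, tuple[str, int]] = {}  # field name -> (section, width)
    markers: dict[str, str] = {}  # "@k" -> field name
    for line in text:
        m = _AMIRA_DEFINE.match(line)
        if m:
            counts[m.group(1)] = int(m.group(2))
            continue
        m = _AMIRA_DECL.match(line)
        if m:
            section, width, name, marker = m.groups()
            decls[name] = (section, int(width) if width else 1)
            markers[f"@{marker}"] = name

    wanted = {"EdgeConnectivity", "NumEdgePoints", "EdgePointCoordinates"}
    unknown = set(decls) - wanted - {"VertexCoordinates"}
    if unknown:
        warnings.warn(f"{path}: ignoring unknown spatial-graph sections {sorted(unknown)}")

    data: dict[str, list[float]] = {name: [] for name in decls}
    current: str | None = None
    for line in text:
        stripped = line.strip()
        if stripped.startswith("@"):
            current = markers.get(stripped.split()[0])
            continue
        if current is None or not stripped or stripped.startswith("#"):
            continue
        try:
            data[current].extend(float(tok) for tok in stripped.split())
        except ValueError:
            current = None  # left the data block (e.g. Parameters section)

    if "NumEdgePoints" not in data or "EdgePointCoordinates" not in data:
        raise TrackParseError(
            f"{path}: not a recognisable spatial graph (need NumEdgePoints and "
            "EdgePointCoordinates sections)"
        )
    n_per_edge = np.asarray(data["NumEdgePoints"], dtype=int)
    coords = np.asarray(data["EdgePointCoordinates"], dtype=float).reshape(-1, 3)
    if n_per_edge.sum() != coords.shape[0]:
        raise TrackParseError(
            f"{path}: NumEdgePoints sums to {n_per_edge.sum()} but "
            f"{coords.shape[0]} edge points found"
        )
    coords = coords * float(voxel_size_nm)
    tracks = []
    offset = 0
    skipped = 0
    for i, n in enumerate(n_per_edge):
        chunk = coords[offset : offset + n]
        offset += n
        # collapse exact duplicate consecutive points (common at edge vertices)
        if len(chunk) >= 2:
            keep = np.ones(len(chunk), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(chunk, axis=0), axis=1) > 0.0
            chunk = chunk[keep]
        if len(chunk) < 2:
            skipped += 1
            continue
        tracks.append(FilamentTrack(f"edge_{i}", chunk))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} degenerate edges (<2 distinct points)")
    return FilamentNetwork(
        tracks=tracks,
        provenance={
            "source": str(path),
            "dialect": "amira-ascii",
            "voxel_size_nm": float(voxel_size_nm),
            "filters": [],
        },
    )


def read_track_table(
    path: str | Path, dialect: str = "track-tsv", voxel_size_nm: float = 1.0
) -> FilamentNetwork:
    """Read a filament network from disk.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"track-tsv"`` (native) or ``"amira-ascii"`` (best-effort spatial
        graph import).
    voxel_size_nm:
        Scale factor applied to amira-ascii coordinates (ignored for
        track-tsv, which is already in nm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "track-tsv":
        return _read_track_tsv(path)
    if dialect == "amira-ascii":
        return _read_amira_ascii(path, voxel_size_nm=voxel_size_nm)
    raise ValueError(f"unknown dialect {dialect!r}; use 'track-tsv' or 'amira-ascii'")


# ---------------------------------------------------------------------------
# filtering


def filter_min_length(network: FilamentNetwork, min_length: float) -> FilamentNetwork:
    """Drop filaments whose raw contour length is below ``min_length`` nm.

    Mirrors the segmentation-stage noise filter (60 nm default, 50 nm for
    unroofed preparations).  The threshold and removal count are recorded in
    provenance.  Contour length is computed on the raw, pre-resampling
    polyline.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [t for t in network.tracks if t.contour_length >= min_length]
    removed = len(network.tracks) - len(kept)
    provenance = dict(network.provenance)
    filters = list(provenance.get("filters", []))
    filters.append({"min_length_nm": float(min_length), "removed": removed})
    provenance["filters"] = filters
    logger.info("filter_min_length(%g nm): removed %d of %d filaments",
                min_length, removed, len(network.tracks))
    return FilamentNetwork(tracks=kept, length_unit=network.length_unit,
                           provenance=provenance)


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a report (dataclass or mapping) to JSON or TSV.

    JSON keys / TSV headers carry units in their names (the report types name
    every numeric field with its unit).  Objects exposing ``to_frame()`` (e.g.
    radial profiles) are written as TSV tables.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if format == "tsv":
        if hasattr(report, "to_frame"):
            report.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
            return
        flat = _jsonable(report)
        if isinstance(flat, Mapping):
            df = pd.DataFrame(
                {"key": list(flat.keys()), "value": [flat[k] for k in flat]}
            )
            df.to_csv(path, sep="\t", index=False)
            return
        raise TypeError(f"cannot write {type(report).__name__} as TSV")
    raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report as a plain dictionary."""
    with open(path) as fh:
        return json.load(fh)
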