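"""Readers and writers for the on-disk formats the pipeline touches.

Formats: scan-log CSV (one row per beam), NMEA 0183 text, binary
little-endian PLY with per-vertex scan/beam provenance, and whitespace XYZ.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nmea import GnssFix, gga_to_fixes, parse_gga  # noqa: F401  (re-exported)
from .simulate import ScanFrame

__all__ = [
    "PointCloud",
    "read_scan_log",
    "write_scan_log",
    "read_nmea",
    "write_nmea",
    "parse_gga",
    "read_cloud",
    "write_cloud",
]

SCAN_LOG_HEADER = "scan_index,timestamp_s,angle_deg,range_m,valid"


@dataclass
class PointCloud:
    """Georeferenced 3D points with per-point scan/beam provenance.

    Local metric frame: X = travel, Y = crop depth, Z = up.
    """

    points: np.ndarray  # (N, 3) float64
    scan_index: np.ndarray  # (N,) int32
    beam_index: np.ndarray  # (N,) int32
    label: np.ndarray | None = field(default=None)  # optional per-point tag

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.scan_index = np.asarray(self.scan_index, dtype=np.int32)
        self.beam_index = np.asarray(self.beam_index, dtype=np.int32)
        n = len(self.points)
        if len(self.scan_index) != n or len(self.beam_index) != n:
            raise ValueError("provenance arrays must match point count")
        if self.label is not None and len(self.label) != n:
            raise ValueError("label array must match point count")
        if n and not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.points[mask], self.scan_index[mask],
                          self.beam_index[mask],
                          None if self.label is None else self.label[mask])

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(np.empty((0, 3)), np.empty(0, np.int32), np.empty(0, np.int32))


# ---------------------------------------------------------------------------
# scan logs

def write_scan_log(frames: list[ScanFrame], path: str | Path) -> None:
    """CSV, one row per beam; timestamps at microsecond precision."""
    with open(path, "w") as fh:
        fh.write(SCAN_LOG_HEADER + "\n")
        for fr in frames:
            t = f"{fr.timestamp:.6f}"
            for a, r, v in zip(fr.angles, fr.ranges, fr.valid):
                fh.write(f"{fr.scan_index},{t},{a:.3f},{r:.4f},{int(v)}\n")


def read_scan_log(path: str | Path, range_min: float = 0.5,
                  range_max: float = 20.0) -> list[ScanFrame]:
    """Load frames, re-applying the range window on load.

    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    frames: list[ScanFrame] = []
    cur: int | None = None
    ts = 0.0
    angles: list[float] = []
    ranges: list[float] = []
    valid: list[bool] = []

    def flush():
        if cur is not None:
            frames.append(ScanFrame(cur, ts, np.array(angles), np.array(ranges),
                                    np.array(valid, dtype=bool)))

    with open(path) as fh:
        header = fh.readline()
        if header.strip() != SCAN_LOG_HEADER:
            raise ValueError(f"line 1: bad scan-log header {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            try:
                idx = int(parts[0])
                t = float(parts[1])
                ang = float(parts[2])
                rng = float(parts[3])
                v = bool(int(parts[4]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if idx != cur:
                flush()
                cur, ts = idx, t
                angles, ranges, valid = [], [], []
            angles.append(ang)
            ranges.append(rng)
            valid.append(v and np.isfinite(rng) and range_min <= rng <= range_max)
    flush()
    return frames


# ---------------------------------------------------------------------------
# NMEA streams

def write_nmea(sentences: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sentences) + "\n")


def read_nmea(path: str | Path,
              origin: tuple[float, float, float] | None = None) -> list[GnssFix]:
    """Parse a GGA text stream to ENU fixes about ``origin`` (default: first fix)."""
    return gga_to_fixes(Path(path).read_text().splitlines(), origin)


# ---------------------------------------------------------------------------
# point clouds

_PLY_HEADER = """ply
format binary_little_endian 1.0
comment vinescan point cloud
element vertex {n}
property double x
property double y
property double z
property int scan_index
property int beam_index
end_header
"""

_VERTEX = struct.Struct("<dddii")
_PLY_DTYPE = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                       ("scan_index", "<i4"), ("beam_index", "<i4")])


def write_cloud(cloud: PointCloud, path: str | Path, format: str = "PLY") -> None:
    """Write PLY (binary LE, with provenance) or whitespace XYZ."""
    fmt = format.upper()
    if fmt == "PLY":
        rec = np.empty(len(cloud), dtype=_PLY_DTYPE)
        rec["x"], rec["y"], rec["z"] = cloud.points.T
        rec["scan_index"] = cloud.scan_index
        rec["beam_index"] = cloud.beam_index
        with open(path, "wb") as fh:
            fh.write(_PLY_HEADER.format(n=len(cloud)).encode("ascii"))
            fh.write(rec.tobytes())
    elif fmt == "XYZ":
        np.savetxt(path, cloud.points, fmt="%.6f")
    else:
        raise ValueError(f"unknown cloud format {format!r}")


def read_cloud(path: str | Path) -> PointCloud:
    """Read a PLY written by :func:`write_cloud`; rejects truncated files."""
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            if not line:
                raise ValueError("truncated PLY header")
            header_lines.append(line)
            if line == "end_header":
                break
        if header_lines[0] != "ply" or "format binary_little_endian 1.0" not in header_lines:
            raise ValueError("not a binary little-endian PLY file")
        n = None
        for line in header_lines:
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
        if n is None:
            raise ValueError("PLY header lacks a vertex element")
        payload = fh.read()
    if len(payload) != n * _VERTEX.size:
        raise ValueError(f"truncated PLY payload: expected {n * _VERTEX.size} bytes, "
                         f"got {len(payload)}")
    rec = np.frombuffer(payload, dtype=_PLY_DTYPE)
    pts = np.stack([rec["x"], rec["y"], rec["z"]], axis=1)
    return PointCloud(pts, rec["scan_index"].copy(), rec["beam_index"].copy())
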