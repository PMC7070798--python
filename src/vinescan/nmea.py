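"""NMEA 0183 GGA encoding/decoding and the local tangent-plane frame.

The RTK-GNSS stream is the travel-axis encoder of the rig: GGA sentences carry
fix time, latitude/longitude, quality and altitude.  Positions are mapped to a
local east/north/up (ENU) frame about a declared origin using a spherical
tangent-plane approximation (adequate over a <200 m vineyard row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GnssFix",
    "nmea_checksum",
    "format_gga",
    "parse_gga",
    "gga_to_fixes",
    "enu_to_lla",
    "lla_to_enu",
]

EARTH_RADIUS = 6_371_000.0  # m, spherical model; must match in both directions


@dataclass(frozen=True)
class GnssFix:
    """A timestamped position in the local ENU frame."""

    timestamp: float  # seconds of day
    east: float
    north: float
    up: float
    quality: int = 4  # 4 = RTK fixed


def nmea_checksum(body: str) -> str:
    """XOR of all characters between '$' and '*', as two uppercase hex digits."""
    cs = 0
    for ch in body:
        cs ^= ord(ch)
    return f"{cs:02X}"


def _deg_to_dm(value: float, width: int) -> tuple[str, str]:
    """Decimal degrees -> (ddmm.mmmmmmm, hemisphere sign handled by caller)."""
    v = abs(value)
    d = int(v)
    m = (v - d) * 60.0
    # 7 decimal places of minutes ~ 0.2 mm; RTK receivers print 6-8.
    return f"{d * 100 + m:0{width + 10}.7f}", ("+" if value >= 0 else "-")


def format_gga(t: float, lat: float, lon: float, alt: float,
               quality: int = 4, nsat: int = 10, hdop: float = 0.8) -> str:
    """Build a $GPGGA sentence with a correct checksum.

    ``t`` is seconds of day; latitude/longitude in signed decimal degrees.
    """
    hh = int(t // 3600) % 24
    mm = int(t // 60) % 60
    ss = t % 60.0
    time_s = f"{hh:02d}{mm:02d}{ss:05.2f}"
    lat_s, lat_sign = _deg_to_dm(lat, 2)
    lon_s, lon_sign = _deg_to_dm(lon, 3)
    body = (f"GPGGA,{time_s},{lat_s},{'N' if lat_sign == '+' else 'S'},"
            f"{lon_s},{'E' if lon_sign == '+' else 'W'},{quality},{nsat:02d},"
            f"{hdop:.1f},{alt:.3f},M,0.0,M,,")
    return f"${body}*{nmea_checksum(body)}"


def _dm_to_deg(dm: str, hemi: str) -> float:
    v = float(dm)
    d = int(v // 100)
    deg = d + (v - d * 100) / 60.0
    return -deg if hemi in ("S", "W") else deg


def parse_gga(sentence: str):
    """Decode one GGA sentence; returns ``None`` for non-GGA sentence types.

    Raises ``ValueError`` on a bad checksum or malformed fields.  The result is
    a dict with ``t`` (seconds of day), ``lat``/``lon`` (decimal degrees),
    ``alt`` (m) and ``quality``.
    """
    s = sentence.strip()
    if not s.startswith("$") or "*" not in s:
        raise ValueError(f"not an NMEA sentence: {s[:20]!r}")
    body, _, cs = s[1:].partition("*")
    if nmea_checksum(body) != cs.strip().upper():
        raise ValueError("NMEA checksum mismatch")
    fields = body.split(",")
    if not fields[0].endswith("GGA"):
        return None
    time_s = fields[1]
    t = int(time_s[0:2]) * 3600 + int(time_s[2:4]) * 60 + float(time_s[4:])
    lat = _dm_to_deg(fields[2], fields[3])
    lon = _dm_to_deg(fields[4], fields[5])
    quality = int(fields[6])
    alt = float(fields[9])
    return {"t": t, "lat": lat, "lon": lon, "alt": alt, "quality": quality}


def enu_to_lla(e, n, u, origin: tuple[float, float, float]):
    """Local ENU (m) -> latitude/longitude/altitude about ``origin`` (deg, deg, m)."""
    lat0, lon0, alt0 = origin
    lat = lat0 + np.degrees(np.asarray(n) / EARTH_RADIUS)
    lon = lon0 + np.degrees(np.asarray(e) / (EARTH_RADIUS * math.cos(math.radians(lat0))))
    return lat, lon, alt0 + np.asarray(u)


def lla_to_enu(lat, lon, alt, origin: tuple[float, float, float]):
    lat0, lon0, alt0 = origin
    n = math.radians(1.0) * EARTH_RADIUS * (np.asarray(lat) - lat0)
    e = (math.radians(1.0) * EARTH_RADIUS * math.cos(math.radians(lat0))
         * (np.asarray(lon) - lon0))
    return e, n, np.asarray(alt) - alt0


def gga_to_fixes(sentences, origin: tuple[float, float, float] | None = None) -> list[GnssFix]:
    """Parse a GGA stream into ENU fixes about ``origin``.

    With ``origin=None`` the first fix anchors the frame at (0, 0, 0).
    Non-GGA sentences are skipped; timestamps must be strictly increasing.
    """
    records = [r for r in (parse_gga(s) for s in sentences if s.strip()) if r is not None]
    if not records:
        return []
    if origin is None:
        origin = (records[0]["lat"], records[0]["lon"], records[0]["alt"])
    fixes = []
    last_t = -math.inf
    for r in records:
        if r["t"] <= last_t:
            raise ValueError("GNSS fix timestamps are not strictly increasing")
        last_t = r["t"]
        e, n, u = lla_to_enu(r["lat"], r["lon"], r["alt"], origin)
        fixes.append(GnssFix(r["t"], float(e), float(n), float(u), r["quality"]))
    return fixes
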