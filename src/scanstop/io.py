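"""Reading and writing tracked-cell data.

Two input dialects are supported:

* **TrackMate model XML** — the export of ImageJ/TrackMate tracking, where
  each spot carries its segmented outline as an ROI vertex list stored
  *relative to the spot position* in calibrated units.  Only spots that
  belong to a track are kept (untracked spots are dropped with a logged
  count).
* **Canonical tracks CSV** — this package's own plain-text dialect, used by
  the synthetic generator and the test-suite.  Grammar (header required)::

      track_id,frame,x_um,y_um,vertices

  where ``vertices`` is a semicolon-separated list of ``x y`` pairs in
  absolute micrometres (e.g. ``"1.5 2.0;3.5 2.0;3.5 4.0"``), or empty for a
  centroid-only observation.  The writer emits fixed 9-decimal coordinates in
  frame-major, vertex order, so re-writing a read file is byte-stable.

Outputs are written as ``contacts.csv`` (one row per contact),
``cells.csv`` (per-T-cell metrics) and ``summary.json`` (field-level
percentages plus the exact parameters used).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from lxml import etree

from .geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "Observation",
    "Track",
    "FieldMetadata",
    "FieldDataset",
    "read_trackmate_xml",
    "read_tracks_csv",
    "write_tracks_csv",
    "write_trackmate_xml",
    "write_results",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

Population = Literal["tcell", "target"]


@dataclass(frozen=True)
class Observation:
    """One tracked cell at one frame: centroid position and outline."""

    frame: int
    centroid: tuple[float, float]
    polygon: Optional[Polygon] = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        x, y = self.centroid
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("centroid must be finite")
        if self.polygon is not None:
            xmin, ymin, xmax, ymax = self.polygon.bounds
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                raise ValueError(
                    "centroid outside polygon bounding box "
                    f"({x:.3f}, {y:.3f}) vs {self.polygon.bounds}"
                )


@dataclass(frozen=True)
class Track:
    """An identity-linked, frame-sorted sequence of observations."""

    track_id: int
    population: Population
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"track {self.track_id}: no observations")
        frames = [o.frame for o in self.observations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(
                f"track {self.track_id}: frames not strictly increasing"
            )

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.observations]

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame

    def observation_at(self, frame: int) -> Optional[Observation]:
        i = np.searchsorted([o.frame for o in self.observations], frame)
        if i < len(self.observations) and self.observations[i].frame == frame:
            return self.observations[i]
        return None

    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates in observation order."""
        return np.array([o.centroid for o in self.observations])


@dataclass(frozen=True)
class FieldMetadata:
    """Acquisition geometry of one imaging field."""

    frame_interval_s: float = 60.0
    n_frames: int = 91
    pixel_size_um: float = 1.0
    field_width_um: float = 400.0
    field_height_um: float = 400.0
    field_id: str = "field-0"
    group_id: str = "group-0"

    def __post_init__(self) -> None:
        for name in ("frame_interval_s", "pixel_size_um", "field_width_um",
                     "field_height_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def final_frame(self) -> int:
        return self.n_frames - 1


@dataclass(frozen=True)
class FieldDataset:
    """All tracks of one field: motile T cells plus adherent target cells."""

    metadata: FieldMetadata
    tcell_tracks: tuple[Track, ...]
    target_tracks: tuple[Track, ...]

    def __post_init__(self) -> None:
        for tracks, pop in ((self.tcell_tracks, "tcell"),
                            (self.target_tracks, "target")):
            ids = [t.track_id for t in tracks]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate track_ids in {pop} population")
            if any(t.population != pop for t in tracks):
                raise ValueError(f"misassigned population in {pop} tracks")


# ---------------------------------------------------------------------------
# TrackMate model XML
# ---------------------------------------------------------------------------

def read_trackmate_xml(
    path: str | Path,
    population: Population,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Read tracks from a TrackMate model XML file.

    Spot positions and ROI vertex offsets are multiplied by ``pixel_size`` to
    obtain absolute micrometre coordinates (pass 1.0 for files already
    calibrated in microns, the TrackMate default).  Spots without an ROI
    yield centroid-only observations with a per-spot warning; spots not
    assigned to any track are dropped and counted in the log.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed TrackMate XML {path}: {exc}") from exc
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise ValueError(f"{path}: no <Model> element found")
    version = root.get("version", "unknown")
    logger.info("reading %s (TrackMate model version %s)", path.name, version)

    spots: dict[int, Observation] = {}
    n_missing_roi = 0
    all_spots = model.find("AllSpots")
    if all_spots is None:
        raise ValueError(f"{path}: no <AllSpots> element found")
    for spot in all_spots.iter("Spot"):
        sid = int(spot.get("ID"))
        frame = int(float(spot.get("FRAME")))
        x = float(spot.get("POSITION_X")) * pixel_size
        y = float(spot.get("POSITION_Y")) * pixel_size
        poly = None
        roi_text = (spot.text or "").strip()
        n_points = spot.get("ROI_N_POINTS")
        if roi_text and n_points and int(n_points) >= 3:
            vals = np.fromstring(roi_text, sep=" ") * pixel_size
            offsets = vals.reshape(-1, 2)
            poly = Polygon(offsets + np.array([x, y]))
        else:
            n_missing_roi += 1
            logger.warning("spot %d (frame %d): no ROI, centroid-only",
                           sid, frame)
        spots[sid] = Observation(frame=frame, centroid=(x, y), polygon=poly)

    tracks: list[Track] = []
    used: set[int] = set()
    all_tracks = model.find("AllTracks")
    if all_tracks is not None:
        for trk in all_tracks.iter("Track"):
            tid = int(trk.get("TRACK_ID"))
            member_ids: set[int] = set()
            for edge in trk.iter("Edge"):
                member_ids.add(int(edge.get("SPOT_SOURCE_ID")))
                member_ids.add(int(edge.get("SPOT_TARGET_ID")))
            obs = sorted((spots[s] for s in member_ids if s in spots),
                         key=lambda o: o.frame)
            if obs:
                tracks.append(Track(tid, population, tuple(obs)))
                used |= member_ids
    n_dropped = len(spots) - len(used & set(spots))
    if n_dropped:
        logger.info("%d spot(s) dropped (not assigned to any track)",
                    n_dropped)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def write_trackmate_xml(
    tracks: Sequence[Track],
    path: str | Path,
    n_frames: int,
    frame_interval_s: float = 60.0,
) -> None:
    """Write tracks as a minimal TrackMate model XML (reader round-trip)."""
    root = etree.Element("TrackMate", version="7.11.1")
    model = etree.SubElement(root, "Model", spatialunits="micron",
                             timeunits="sec")
    all_spots = etree.SubElement(model, "AllSpots")
    frames_el: dict[int, etree._Element] = {}
    sid = 0
    spot_ids: dict[tuple[int, int], int] = {}
    n_spots = 0
    for trk in tracks:
        for obs in trk.observations:
            f = obs.frame
            if f not in frames_el:
                frames_el[f] = etree.SubElement(all_spots, "SpotsInFrame",
                                                frame=str(f))
            x, y = obs.centroid
            attrs = {
                "ID": str(sid), "name": f"ID{sid}",
                "POSITION_X": f"{x:.9f}", "POSITION_Y": f"{y:.9f}",
                "POSITION_T": f"{f * frame_interval_s:.1f}",
                "FRAME": str(f), "QUALITY": "1.0", "VISIBILITY": "1",
            }
            if obs.polygon is not None:
                v = obs.polygon.vertices - np.array([x, y])
                attrs["ROI_N_POINTS"] = str(len(v))
            el = etree.SubElement(frames_el[f], "Spot", **attrs)
            if obs.polygon is not None:
                el.text = " ".join(f"{c:.9f}" for c in v.ravel())
            spot_ids[(trk.track_id, f)] = sid
            sid += 1
            n_spots += 1
    all_spots.set("nspots", str(n_spots))
    all_tracks = etree.SubElement(model, "AllTracks")
    filtered = etree.SubElement(model, "FilteredTracks")
    for trk in tracks:
        tel = etree.SubElement(all_tracks, "Track",
                               TRACK_ID=str(trk.track_id),
                               name=f"Track_{trk.track_id}")
        frames = trk.frames
        if len(frames) == 1:
            # single-spot track: self-edge so the member spot is recoverable
            s = spot_ids[(trk.track_id, frames[0])]
            etree.SubElement(tel, "Edge", SPOT_SOURCE_ID=str(s),
                             SPOT_TARGET_ID=str(s))
        for a, b in zip(frames, frames[1:]):
            etree.SubElement(
                tel, "Edge",
                SPOT_SOURCE_ID=str(spot_ids[(trk.track_id, a)]),
                SPOT_TARGET_ID=str(spot_ids[(trk.track_id, b)]),
            )
        etree.SubElement(filtered, "TrackID", TRACK_ID=str(trk.track_id))
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Canonical CSV dialect
# ---------------------------------------------------------------------------

_CSV_HEADER = ["track_id", "frame", "x_um", "y_um", "vertices"]


def _format_vertices(poly: Optional[Polygon]) -> str:
    if poly is None:
        return ""
    return ";".join(f"{x:.9f} {y:.9f}" for x, y in poly.vertices)


def _parse_vertices(text: str) -> Optional[Polygon]:
    text = text.strip()
    if not text:
        return None
    pts = [tuple(float(c) for c in pair.split()) for pair in text.split(";")]
    return Polygon(pts)


def write_tracks_csv(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks in the canonical dialect (fixed 9-decimal precision)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for trk in sorted(tracks, key=lambda t: t.track_id):
            for obs in trk.observations:
                x, y = obs.centroid
                w.writerow([trk.track_id, obs.frame, f"{x:.9f}", f"{y:.9f}",
                            _format_vertices(obs.polygon)])


def read_tracks_csv(path: str | Path, population: Population) -> list[Track]:
    """Read the canonical tracks CSV dialect.

    Duplicate ``(track_id, frame)`` rows are a hard error; out-of-order rows
    are sorted silently with a warning.
    """
    rows: dict[int, dict[int, Observation]] = {}
    order_violation = False
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            tid = int(row["track_id"])
            frame = int(row["frame"])
            per_track = rows.setdefault(tid, {})
            if frame in per_track:
                raise ValueError(
                    f"{path}: duplicate observation for track_id={tid} "
                    f"frame={frame}"
                )
            if per_track and frame < max(per_track):
                order_violation = True
            per_track[frame] = Observation(
                frame=frame,
                centroid=(float(row["x_um"]), float(row["y_um"])),
                polygon=_parse_vertices(row["vertices"]),
            )
    if order_violation:
        logger.warning("%s: rows not frame-sorted; sorted on read", path)
    return [
        Track(tid, population,
              tuple(obs[f] for f in sorted(obs)))
        for tid, obs in sorted(rows.items())
    ]


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(results, out_dir: str | Path) -> dict[str, Path]:
    """Write contacts.csv, cells.csv and summary.json for a fitted field.

    ``results`` is a :class:`scanstop.assay.FieldResults`.  Returns the paths
    written.  CSV bodies are deterministic for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contacts": out / "contacts.csv",
        "cells": out / "cells.csv",
        "summary": out / "summary.json",
    }

    with open(paths["contacts"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tcell_id", "target_id", "first_frame", "last_frame",
                    "n_touches", "duration_frames", "classification",
                    "cumulative_intersection_area_um2", "track_truncated"])
        for c in sorted(results.contacts,
                        key=lambda c: (c.tcell_id, c.target_id, c.first_frame)):
            w.writerow([c.tcell_id, c.target_id, c.first_frame, c.last_frame,
                        c.n_touches, c.duration_frames, c.classification,
                        f"{c.cumulative_intersection_area:.6f}",
                        int(c.track_truncated)])

    results.cells.to_csv(paths["cells"], index=False, float_format="%.9f")

    summary = dict(results.field_summary.to_dict())
    summary["schema_version"] = SCHEMA_VERSION
    summary["parameters"] = results.params.to_dict()
    summary["filter_report"] = results.filter_report.to_dict()
    from . import __version__
    summary["software_version"] = __version__
    if results.seed is not None:
        summary["seed"] = results.seed
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
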