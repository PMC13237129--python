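"""Touch detection, gap-tolerant contact assembly and stable/transient
classification.

The measurement paradigm: motile T cells scan a confluent monolayer in which
a sparse subset of cells presents cognate peptide-MHC.  Arrest is read out
geometrically, frame by frame:

* A **touch** is a single-frame overlap between the (upscaled) T-cell
  polygon and a target-cell polygon covering at least 10 % of the T-cell
  surface.
* A **contact** is a maximal run of touches between one T cell and one
  target in which interruptions of up to five consecutive frames are
  tolerated (segmentation flicker at cell edges).
* A **stable contact** persists until the end of the acquisition; all other
  contacts are **transient**.  A T cell engaged with several targets at the
  end of the movie contributes exactly one stable contact — its longest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from shapely.strtree import STRtree

from .io import FieldMetadata, Track

__all__ = [
    "AnalysisParameters",
    "Touch",
    "Contact",
    "detect_touches",
    "assemble_contacts",
    "classify_contacts",
    "targets_visited",
]


@dataclass(frozen=True)
class AnalysisParameters:
    """Every threshold of the contact-calling procedure.

    Defaults are the assay's published operating point: touches require the
    intersection to cover >= 10 % of the (0.2 %-upscaled) T-cell surface,
    contacts tolerate gaps of up to 5 frames, dead tracks displace < 15 um
    net, drifters have persistence > 0.5, and the acquisition runs 91 frames
    at 1 frame/min (final frame index 90).
    """

    overlap_fraction_min: float = 0.10
    max_gap_frames: int = 5
    upscale_factor: float = 1.002
    min_displacement_um: float = 15.0
    max_persistence: float = 0.5
    final_frame: int = 90
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction_min <= 1.0):
            raise ValueError("overlap_fraction_min must be in (0, 1]")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not self.upscale_factor > 0:
            raise ValueError("upscale_factor must be > 0")

    @classmethod
    def from_metadata(cls, metadata: FieldMetadata,
                      **overrides) -> "AnalysisParameters":
        base = dict(final_frame=metadata.final_frame,
                    frame_interval_s=metadata.frame_interval_s)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return {
            "overlap_fraction_min": self.overlap_fraction_min,
            "max_gap_frames": self.max_gap_frames,
            "upscale_factor": self.upscale_factor,
            "min_displacement_um": self.min_displacement_um,
            "max_persistence": self.max_persistence,
            "final_frame": self.final_frame,
            "frame_interval_s": self.frame_interval_s,
        }


@dataclass(frozen=True)
class Touch:
    """A single-frame qualifying overlap between one T cell and one
    target.

    ``overlap_fraction`` is the intersection area divided by the area of the
    *upscaled* T-cell polygon of that frame (the object intersected).
    """

    frame: int
    tcell_id: int
    target_id: int
    intersection_area: float
    overlap_fraction: float


@dataclass(frozen=True)
class Contact:
    """A gap-tolerant maximal run of touches for one (T cell, target)
    pair."""

    tcell_id: int
    target_id: int
    touch_frames: tuple[int, ...]
    cumulative_intersection_area: float
    classification: str = "unclassified"   # stable | transient | unclassified
    track_truncated: bool = False

    @property
    def first_frame(self) -> int:
        return self.touch_frames[0]

    @property
    def last_frame(self) -> int:
        return self.touch_frames[-1]

    @property
    def n_touches(self) -> int:
        return len(self.touch_frames)

    @property
    def duration_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


def detect_touches(
    tcells: Sequence[Track],
    targets: Sequence[Track],
    params: AnalysisParameters,
) -> list[Touch]:
    """Frame-wise overlap test between filtered T cells and target cells.

    For every frame and every co-present (T cell, target) pair the T-cell
    polygon is upscaled about its centroid and intersected with the target
    polygon; a touch is emitted iff the intersection covers at least
    ``overlap_fraction_min`` of the upscaled T-cell area (inclusive).  A T
    cell may touch several targets in the same frame.  Frames where either
    track lacks a polygon are skipped (no interpolation).
    """
    # frame -> (target ids, STRtree of shapely geometries)
    by_frame: dict[int, tuple[list[int], list]] = {}
    for trg in targets:
        for obs in trg.observations:
            if obs.polygon is None:
                continue
            ids, geoms = by_frame.setdefault(obs.frame, ([], []))
            ids.append(trg.track_id)
            geoms.append(obs.polygon._shapely)
    trees = {f: STRtree(geoms) for f, (ids, geoms) in by_frame.items()}

    touches: list[Touch] = []
    for tc in tcells:
        for obs in tc.observations:
            if obs.polygon is None or obs.frame not in trees:
                continue
            scaled = obs.polygon.scale_about_centroid(params.upscale_factor)
            t_area = scaled.area
            shp = scaled._shapely
            ids, geoms = by_frame[obs.frame]
            for j in trees[obs.frame].query(shp):
                inter = shp.intersection(geoms[j]).area
                if inter < 1e-9:
                    continue
                frac = inter / t_area
                if frac >= params.overlap_fraction_min:
                    touches.append(Touch(obs.frame, tc.track_id, ids[j],
                                         inter, frac))
    touches.sort(key=lambda t: (t.tcell_id, t.target_id, t.frame))
    return touches


def assemble_contacts(
    touches: Sequence[Touch],
    params: AnalysisParameters,
) -> list[Contact]:
    """Merge touches into maximal gap-tolerant runs per (T cell, target)
    pair.

    Successive touch frames differing by at most ``max_gap_frames + 1``
    belong to the same contact (i.e. up to ``max_gap_frames`` consecutive
    frames without overlap are tolerated); single-touch contacts are
    allowed.
    """
    out: list[Contact] = []
    touches = sorted(touches, key=lambda t: (t.tcell_id, t.target_id,
                                             t.frame))
    run: list[Touch] = []

    def _flush() -> None:
        if run:
            out.append(Contact(
                tcell_id=run[0].tcell_id,
                target_id=run[0].target_id,
                touch_frames=tuple(t.frame for t in run),
                cumulative_intersection_area=sum(t.intersection_area
                                                 for t in run),
            ))

    for t in touches:
        if (run
                and t.tcell_id == run[-1].tcell_id
                and t.target_id == run[-1].target_id
                and t.frame - run[-1].frame <= params.max_gap_frames + 1):
            run.append(t)
        else:
            _flush()
            run = [t]
    _flush()
    return out


def classify_contacts(
    contacts: Sequence[Contact],
    params: AnalysisParameters,
    tcell_last_frames: Optional[dict[int, int]] = None,
) -> list[Contact]:
    """Label every contact stable or transient.

    A contact is *end-reaching* iff ``final_frame - last_frame <=
    max_gap_frames`` (the same flicker tolerance used during assembly).
    Among a T cell's end-reaching contacts exactly one — the longest by
    ``duration_frames``, ties broken by larger cumulative intersection area,
    then smaller target id — is stable; every other contact is transient.

    ``tcell_last_frames`` (track_id -> last observed frame) lets contacts of
    tracks that were lost before ``final_frame - max_gap_frames`` be flagged
    ``track_truncated`` in the output.
    """
    by_cell: dict[int, list[Contact]] = {}
    for c in contacts:
        by_cell.setdefault(c.tcell_id, []).append(c)

    out: list[Contact] = []
    for tcell_id, cell_contacts in by_cell.items():
        end_reaching = [
            c for c in cell_contacts
            if params.final_frame - c.last_frame <= params.max_gap_frames
        ]
        stable = None
        if end_reaching:
            stable = max(
                end_reaching,
                key=lambda c: (c.duration_frames,
                               c.cumulative_intersection_area,
                               -c.target_id),
            )
        truncated = False
        if tcell_last_frames is not None:
            last_obs = tcell_last_frames.get(tcell_id)
            truncated = (last_obs is not None and
                         last_obs < params.final_frame - params.max_gap_frames)
        for c in cell_contacts:
            label = "stable" if c is stable else "transient"
            out.append(replace(c, classification=label,
                               track_truncated=truncated))
    out.sort(key=lambda c: (c.tcell_id, c.target_id, c.first_frame))
    return out


def targets_visited(contacts: Sequence[Contact], tcell_id: int) -> int:
    """Number of distinct targets a T cell contacted, regardless of contact
    count or classification.  Unknown T cells yield 0."""
    ids = {c.target_id for c in contacts if c.tcell_id == tcell_id}
    return len(ids)
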