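"""Track-quality filtering of T-cell trajectories.

Two gates are applied before any contact analysis, in this order:

1. **Dead-cell filter** — a living motile T cell should displace more than
   twice its own diameter over the movie; trajectories whose net (Euclidean)
   displacement is smaller than 15 um are excluded as dead or non-motile.
2. **Drift filter** — T cells that are not adhering but passively drifting
   move in nearly straight lines; trajectories with persistence (confinement
   ratio: net displacement / total path length) above 0.5 are excluded.

Both thresholds are strict inequalities.  Only T-cell tracks are ever
filtered; adherent target cells are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Track

__all__ = ["TrackKinematics", "FilterReport", "kinematics", "apply_filters"]


@dataclass(frozen=True)
class TrackKinematics:
    """Whole-track migration statistics (computed over all frames,
    including frames of contact)."""

    track_id: int
    total_path_length: float      # um
    euclidean_displacement: float  # um
    persistence: float             # net / total path, in [0, 1]
    mean_speed: float              # um/s
    duration: float                # s
    flagged_single_observation: bool = False


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the two-stage gate; the three id lists partition the
    input."""

    kept: tuple[int, ...]
    removed_dead: tuple[int, ...]
    removed_drifting: tuple[int, ...]
    min_displacement_um: float
    max_persistence: float

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "removed_dead": list(self.removed_dead),
            "removed_drifting": list(self.removed_drifting),
            "min_displacement_um": self.min_displacement_um,
            "max_persistence": self.max_persistence,
        }


def kinematics(track: Track, frame_interval_s: float) -> TrackKinematics:
    """Compute path length, net displacement, persistence and mean speed.

    ``duration`` spans first to last observed frame.  A single-observation
    track yields all-zero kinematics, flagged.  Zero-path-length tracks get
    persistence 0 (avoids 0/0; such tracks fail the dead filter anyway).
    """
    pts = track.centroids()
    if len(pts) < 2:
        return TrackKinematics(track.track_id, 0.0, 0.0, 0.0, 0.0, 0.0,
                               flagged_single_observation=True)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(steps.sum())
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    duration = (track.last_frame - track.first_frame) * frame_interval_s
    persistence = net / total if total > 0 else 0.0
    mean_speed = total / duration if duration > 0 else 0.0
    return TrackKinematics(track.track_id, total, net, persistence,
                           mean_speed, duration)


def apply_filters(
    tracks: Sequence[Track],
    frame_interval_s: float,
    min_displacement_um: float = 15.0,
    max_persistence: float = 0.5,
) -> tuple[FilterReport, dict[int, TrackKinematics]]:
    """Run the dead filter then the drift filter on T-cell tracks.

    Returns the partition report and per-track kinematics (for all input
    tracks, kept or not).  A track failing both criteria is reported dead,
    not drifting, because the dead filter runs first.
    """
    kin = {t.track_id: kinematics(t, frame_interval_s) for t in tracks}
    kept, dead, drifting = [], [], []
    for t in tracks:
        k = kin[t.track_id]
        if k.euclidean_displacement < min_displacement_um:
            dead.append(t.track_id)
        elif k.persistence > max_persistence:
            drifting.append(t.track_id)
        else:
            kept.append(t.track_id)
    report = FilterReport(tuple(kept), tuple(dead), tuple(drifting),
                          min_displacement_um, max_persistence)
    return report, kin
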