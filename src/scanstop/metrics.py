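"""Per-cell and per-field summary statistics.

Stopping speed quantifies how rapidly a T cell comes to a complete halt
after first touching the target it eventually arrests on: the distance from
the first-touch position is tracked across all subsequent frames, and the
maximum displacement divided by the time taken to reach it (earliest
attaining frame) is the stopping speed in um/s.

Field-level arrest percentages are corrected for plating variation with a
density factor: each field's activating-target count divided by the group
mean of that count; raw stable percentages are divided by this factor, so a
field that happened to receive more targets is not credited with more
arrest.  Group summaries report mean +/- sample (n-1) SD, no inferential
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .contacts import AnalysisParameters, Contact
from .io import Track

__all__ = [
    "StoppingProfile",
    "FieldSummary",
    "stopping_speed",
    "density_factors",
    "summarize_field",
    "summarize_group",
]


@dataclass(frozen=True)
class StoppingProfile:
    """Displacement-from-first-touch series of one stable contact."""

    tcell_id: int
    target_id: int
    displacement_series: tuple[tuple[int, float], ...]  # (frame, um)
    max_displacement: float   # um
    time_to_max: float        # s
    stopping_speed: float     # um/s
    flagged_instantaneous: bool = False
    flagged_missing_first_touch: bool = False


@dataclass(frozen=True)
class FieldSummary:
    """Field-level readout: arrest percentages, density correction and
    migration summaries (each as (mean, sd) over analyzed cells)."""

    field_id: str
    group_id: str
    n_tcells_total: int
    n_tcells_analyzed: int
    n_stable: int
    n_transient_cells: int          # cells with >= 1 transient contact
    n_transient_contacts: int
    raw_stable_percent: Optional[float]
    raw_transient_percent: Optional[float]
    n_targets_in_field: int
    density_factor: float
    normalized_stable_percent: Optional[float]
    mean_targets_visited: Optional[float]
    mean_stable_contacts: Optional[float]
    mean_stopping_speed: Optional[float]
    total_distance_um: tuple[Optional[float], Optional[float]]
    euclidean_distance_um: tuple[Optional[float], Optional[float]]
    mean_speed_um_s: tuple[Optional[float], Optional[float]]
    persistence: tuple[Optional[float], Optional[float]]

    def to_dict(self) -> dict:
        d = {
            "field_id": self.field_id,
            "group_id": self.group_id,
            "n_tcells_total": self.n_tcells_total,
            "n_tcells_analyzed": self.n_tcells_analyzed,
            "n_stable": self.n_stable,
            "n_transient_cells": self.n_transient_cells,
            "n_transient_contacts": self.n_transient_contacts,
            "raw_stable_percent": self.raw_stable_percent,
            "raw_transient_percent": self.raw_transient_percent,
            "n_targets_in_field": self.n_targets_in_field,
            "density_factor": self.density_factor,
            "normalized_stable_percent": self.normalized_stable_percent,
            "mean_targets_visited": self.mean_targets_visited,
            "mean_stable_contacts": self.mean_stable_contacts,
            "mean_stopping_speed": self.mean_stopping_speed,
        }
        for name in ("total_distance_um", "euclidean_distance_um",
                     "mean_speed_um_s", "persistence"):
            mean, sd = getattr(self, name)
            d[f"{name}_mean"] = mean
            d[f"{name}_sd"] = sd
        return d


def stopping_speed(
    contact: Contact,
    track: Track,
    params: AnalysisParameters,
) -> StoppingProfile:
    """Stopping speed of a stable contact.

    The reference point is the T-cell centroid at the contact's first touch
    frame (earliest observation >= first touch frame if that frame lacks an
    observation, flagged).  For every observed frame from there to the
    acquisition end, the distance to the reference is recorded; the maximum
    and the *earliest* frame attaining it give ``time_to_max``.  An
    immediately arrested cell (max attained at the reference frame itself)
    has stopping speed 0, flagged instantaneous.
    """
    if contact.classification != "stable":
        raise ValueError("stopping speed is defined for stable contacts")
    first = contact.first_frame
    obs = [o for o in track.observations
           if first <= o.frame <= params.final_frame]
    if not obs:
        raise ValueError(
            f"track {track.track_id}: no observations at/after first touch "
            f"frame {first}"
        )
    flagged_missing = obs[0].frame != first
    ref = np.array(obs[0].centroid)
    ref_frame = obs[0].frame
    series = tuple(
        (o.frame, float(np.linalg.norm(np.array(o.centroid) - ref)))
        for o in obs
    )
    dists = np.array([d for _, d in series])
    i_max = int(np.argmax(dists))     # argmax -> earliest attaining frame
    max_disp = float(dists[i_max])
    time_to_max = (series[i_max][0] - ref_frame) * params.frame_interval_s
    instantaneous = time_to_max == 0.0
    speed = 0.0 if instantaneous else max_disp / time_to_max
    return StoppingProfile(
        tcell_id=contact.tcell_id,
        target_id=contact.target_id,
        displacement_series=series,
        max_displacement=max_disp,
        time_to_max=time_to_max,
        stopping_speed=speed,
        flagged_instantaneous=instantaneous,
        flagged_missing_first_touch=flagged_missing,
    )


def density_factors(target_counts: Sequence[int]) -> list[float]:
    """Per-field density factors: count / group mean of counts.

    The group mean of the returned factors is exactly 1.  Raises if no field
    in the group has any targets.
    """
    counts = np.asarray(target_counts, dtype=float)
    if len(counts) == 0:
        raise ValueError("empty group")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("no targets in any field of the group")
    return [float(c / mean) for c in counts]


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float],
                                               Optional[float]]:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        return (None, None)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return (mean, sd)


def summarize_field(
    dataset,
    filter_report,
    kinematics_by_id: dict,
    contacts: Sequence[Contact],
    stopping_profiles: Sequence[StoppingProfile],
    params: AnalysisParameters,
    density_factor: float = 1.0,
) -> FieldSummary:
    """Assemble the field-level summary from the pipeline stages.

    Denominators use the number of T cells surviving both filters.  The
    transient percentage counts cells with at least one transient contact
    (the per-contact count is reported alongside).  With zero analyzed
    cells, percentages are reported as missing (None).
    """
    import logging

    kept = list(filter_report.kept)
    n_analyzed = len(kept)
    stable_cells = {c.tcell_id for c in contacts
                    if c.classification == "stable"}
    transient_cells = {c.tcell_id for c in contacts
                       if c.classification == "transient"}
    n_transient_contacts = sum(
        1 for c in contacts if c.classification == "transient")
    if n_analyzed == 0:
        logging.getLogger(__name__).warning(
            "field %s: zero analyzed T cells; percentages undefined",
            dataset.metadata.field_id)
        raw_stable = raw_transient = normalized = None
        mean_visited = mean_stable = None
    else:
        raw_stable = 100.0 * len(stable_cells) / n_analyzed
        raw_transient = 100.0 * len(transient_cells) / n_analyzed
        normalized = raw_stable / density_factor
        from .contacts import targets_visited
        mean_visited = float(np.mean(
            [targets_visited(contacts, tid) for tid in kept]))
        mean_stable = float(np.mean(
            [1 if tid in stable_cells else 0 for tid in kept]))
    speeds = [p.stopping_speed for p in stopping_profiles]
    mean_stop = float(np.mean(speeds)) if speeds else None
    kin_kept = [kinematics_by_id[tid] for tid in kept]
    return FieldSummary(
        field_id=dataset.metadata.field_id,
        group_id=dataset.metadata.group_id,
        n_tcells_total=len(dataset.tcell_tracks),
        n_tcells_analyzed=n_analyzed,
        n_stable=len(stable_cells),
        n_transient_cells=len(transient_cells),
        n_transient_contacts=n_transient_contacts,
        raw_stable_percent=raw_stable,
        raw_transient_percent=raw_transient,
        n_targets_in_field=len(dataset.target_tracks),
        density_factor=density_factor,
        normalized_stable_percent=normalized,
        mean_targets_visited=mean_visited,
        mean_stable_contacts=mean_stable,
        mean_stopping_speed=mean_stop,
        total_distance_um=_mean_sd([k.total_path_length for k in kin_kept]),
        euclidean_distance_um=_mean_sd(
            [k.euclidean_displacement for k in kin_kept]),
        mean_speed_um_s=_mean_sd([k.mean_speed for k in kin_kept]),
        persistence=_mean_sd([k.persistence for k in kin_kept]),
    )


def summarize_group(field_summaries: Sequence[FieldSummary]):
    """Mean +/- sample SD of each field-level metric, per condition.

    Returns a DataFrame with one row per group_id.  Density factors are
    recomputed across the supplied fields of each group, and normalized
    percentages re-derived, so that grouping is defined by what is passed in.
    """
    import pandas as pd

    if not field_summaries:
        raise ValueError("no field summaries supplied")
    rows = []
    by_group: dict[str, list[FieldSummary]] = {}
    for fs in field_summaries:
        by_group.setdefault(fs.group_id, []).append(fs)
    for group_id in sorted(by_group):
        fields = sorted(by_group[group_id], key=lambda f: f.field_id)
        factors = density_factors([f.n_targets_in_field for f in fields])
        normalized = [
            (f.raw_stable_percent / df_
             if f.raw_stable_percent is not None else None)
            for f, df_ in zip(fields, factors)
        ]
        row = {"group_id": group_id, "n_fields": len(fields)}
        for name, values in [
            ("raw_stable_percent", [f.raw_stable_percent for f in fields]),
            ("normalized_stable_percent", normalized),
            ("raw_transient_percent",
             [f.raw_transient_percent for f in fields]),
            ("mean_targets_visited",
             [f.mean_targets_visited for f in fields]),
            ("mean_stable_contacts",
             [f.mean_stable_contacts for f in fields]),
            ("mean_stopping_speed",
             [f.mean_stopping_speed for f in fields]),
            ("total_distance_um", [f.total_distance_um[0] for f in fields]),
            ("euclidean_distance_um",
             [f.euclidean_distance_um[0] for f in fields]),
            ("mean_speed_um_s", [f.mean_speed_um_s[0] for f in fields]),
            ("persistence", [f.persistence[0] for f in fields]),
        ]:
            mean, sd = _mean_sd([v for v in values if v is not None])
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
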