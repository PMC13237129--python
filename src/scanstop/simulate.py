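"""Seeded synthetic fields with the statistical structure the analysis
assumes.

The generator emulates a confluent monolayer of adherent target-cell
polygons in which a sparse subset (default 1 in 16, i.e. a 1:15
activating:non-activating mix) presents cognate antigen, plus motile T-cell
agents that scan it:

* **monolayer** — a centroidal Voronoi mosaic of convex polygons tiling the
  field; each mosaic cell is independently labelled activating with
  probability ``activating_fraction``; only activating cells are emitted as
  target tracks (non-activating monolayer cells carry no fluorescent label
  in the assay and are invisible to the analysis).  Targets are static
  (adherent), with optional sub-micron jitter.
* **T cells** — migrators follow a persistent random walk (per-frame speed
  drawn from a normal truncated at zero; heading rotated by a wrapped-normal
  deviate whose concentration is set by ``turn_persistence``), carry a rigid
  regular-16-gon footprint, reflect off field boundaries, and on every frame
  where their footprint overlaps an activating target by at least
  ``arrest_overlap_fraction`` of their area they arrest forever with
  probability ``p_arrest_per_encounter`` (first Bernoulli success; frozen
  thereafter with <= 0.3 um jitter).  Planted **dead** cells are stationary
  (<= 1 um jitter); planted **drifters** move ballistically at
  ``drifter_speed``.

Every cell carries a ground-truth label, enabling filter-recovery and
parameter-recovery tests without any imaging data.  Randomness is organised
as a seed tree rooted at ``config.seed``: one child stream for the mosaic
(points, then activating labels), one for the T-cell class assignment, and
three per T cell (motion, arrest decisions, observation dropout).  Identical
seed + config give bit-identical exports, and because each cell's arrest
Bernoulli draws come from their own stream, runs that differ only in
``p_arrest_per_encounter`` are coupled: the set of arrested cells at a
higher p is a superset of the set at a lower p (common random numbers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np
from scipy.spatial import Voronoi
from scipy.stats import binomtest
from shapely.geometry import Polygon as _ShapelyPolygon, box as _box
from shapely.strtree import STRtree

from .geometry import Polygon
from .io import FieldDataset, FieldMetadata, Observation, Track

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_monolayer",
    "generate_tcells",
    "generate_field",
    "expected_stable_fraction",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic field.

    Acquisition geometry defaults match the assay (91 frames at 1 frame/min);
    the 1:15 activating mix gives ``activating_fraction = 1/16``.  Kinematic
    defaults (speed ~8 um/min, turn persistence 0.7, T-cell radius 3.75 um,
    i.e. a 7.5 um diameter cell) are generator choices of plausible
    magnitude, exposed here, not measured constants.
    """

    seed: int = 0
    field_width_um: float = 400.0
    field_height_um: float = 400.0
    n_frames: int = 91
    frame_interval_s: float = 60.0
    target_density_per_mm2: float = 1600.0
    activating_fraction: float = 1.0 / 16.0
    n_tcells: int = 60
    tcell_radius_um: float = 3.75
    speed_mean_um_min: float = 8.0
    speed_sd_um_min: float = 3.0
    turn_persistence: float = 0.7
    arrest_overlap_fraction: float = 0.10
    p_arrest_per_encounter: float = 0.02
    fraction_dead: float = 0.05
    fraction_drifter: float = 0.05
    drifter_speed_um_min: float = 8.0
    dead_jitter_um: float = 0.5
    arrest_jitter_um: float = 0.15
    target_jitter_um: float = 0.0
    p_dropout: float = 0.0
    field_id: str = "sim-field"
    group_id: str = "sim-group"

    def __post_init__(self) -> None:
        for name in ("activating_fraction",):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("p_arrest_per_encounter", "fraction_dead",
                     "fraction_drifter", "p_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.turn_persistence < 1.0):
            raise ValueError("turn_persistence must be in [0, 1)")
        for name in ("field_width_um", "field_height_um", "tcell_radius_um",
                     "target_density_per_mm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def metadata(self) -> FieldMetadata:
        return FieldMetadata(
            frame_interval_s=self.frame_interval_s,
            n_frames=self.n_frames,
            pixel_size_um=1.0,
            field_width_um=self.field_width_um,
            field_height_um=self.field_height_um,
            field_id=self.field_id,
            group_id=self.group_id,
        )


@dataclass
class GroundTruth:
    """Per-cell labels planted by the generator.

    ``tcell_class`` maps each T-cell id to one of ``migrator`` / ``arrested``
    / ``dead`` / ``drifter``; arrested cells also carry the arrest frame and
    target.  ``n_mosaic_cells`` counts all monolayer cells, of which
    ``activating_target_ids`` were labelled activating (and emitted).
    """

    n_mosaic_cells: int = 0
    activating_target_ids: tuple[int, ...] = ()
    tcell_class: dict[int, str] = dc_field(default_factory=dict)
    arrest_frame: dict[int, int] = dc_field(default_factory=dict)
    arrest_target_id: dict[int, int] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_mosaic_cells": self.n_mosaic_cells,
            "activating_target_ids": list(self.activating_target_ids),
            "tcell_class": {str(k): v for k, v in self.tcell_class.items()},
            "arrest_frame": {str(k): v for k, v in self.arrest_frame.items()},
            "arrest_target_id": {str(k): v
                                 for k, v in self.arrest_target_id.items()},
        }


# ---------------------------------------------------------------------------
# Monolayer
# ---------------------------------------------------------------------------

def _bounded_voronoi(points: np.ndarray, w: float, h: float) -> list[np.ndarray]:
    """Voronoi cells of ``points`` clipped to [0,w]x[0,h], via mirroring."""
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, w), (1, 0.0), (1, h)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    rect = _box(0.0, 0.0, w, h)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        cell = _ShapelyPolygon(verts).intersection(rect)
        cells.append(np.asarray(cell.exterior.coords)[:-1])
    return cells


def generate_monolayer(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Track], GroundTruth]:
    """Generate the activating-target tracks of a confluent mosaic.

    A Poisson-like set of seed points is relaxed with two Lloyd iterations
    into a centroidal Voronoi tessellation; each mosaic cell is labelled
    activating with probability ``activating_fraction`` and only activating
    cells become (static) target tracks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w, h = config.field_width_um, config.field_height_um
    n_mosaic = max(1, int(round(config.target_density_per_mm2 * w * h / 1e6)))
    pts = rng.uniform([0, 0], [w, h], size=(n_mosaic, 2))
    for _ in range(2):  # Lloyd relaxation -> near-centroidal mosaic
        cells = _bounded_voronoi(pts, w, h)
        pts = np.array([Polygon(c).centroid for c in cells])
    cells = _bounded_voronoi(pts, w, h)

    activating = rng.random(n_mosaic) < config.activating_fraction
    if activating.sum() < 1:
        logger.warning(
            "expected < 1 activating cell (density %.0f/mm2, fraction %.4f)",
            config.target_density_per_mm2, config.activating_fraction)

    gt = GroundTruth(n_mosaic_cells=n_mosaic)
    tracks: list[Track] = []
    act_ids = []
    for i in np.flatnonzero(activating):
        poly = Polygon(cells[i])
        tid = int(i)
        act_ids.append(tid)
        if config.target_jitter_um > 0:
            jit = rng.uniform(-config.target_jitter_um,
                              config.target_jitter_um,
                              size=(config.n_frames, 2))
        else:
            jit = np.zeros((config.n_frames, 2))
        obs = tuple(
            Observation(frame=f,
                        centroid=tuple(np.array(poly.centroid) + jit[f]),
                        polygon=poly.translate(*jit[f]))
            for f in range(config.n_frames)
        )
        tracks.append(Track(tid, "target", obs))
    gt.activating_target_ids = tuple(act_ids)
    return tracks, gt


# ---------------------------------------------------------------------------
# T cells
# ---------------------------------------------------------------------------

def _footprint(center: np.ndarray, radius: float) -> Polygon:
    ang = np.linspace(0.0, 2 * np.pi, 16, endpoint=False)
    return Polygon(center + radius * np.column_stack([np.cos(ang),
                                                      np.sin(ang)]))


def _reflect(p: np.ndarray, w: float, h: float) -> np.ndarray:
    # reflective boundaries (single bounce is enough at these step sizes)
    x, y = p
    if x < 0:
        x = -x
    elif x > w:
        x = 2 * w - x
    if y < 0:
        y = -y
    elif y > h:
        y = 2 * h - y
    return np.array([min(max(x, 0.0), w), min(max(y, 0.0), h)])


def generate_tcells(
    config: SimulationConfig,
    monolayer: list[Track],
    ground_truth: GroundTruth,
    seed_sequence: Optional[np.random.SeedSequence] = None,
) -> list[Track]:
    """Simulate T-cell agents over the (already generated) monolayer.

    Updates ``ground_truth`` in place with per-cell class labels and arrest
    events.  Cell ids are 0..n_tcells-1 (the target id space is separate).
    Each cell draws motion, arrest decisions and dropout from its own
    substreams of ``seed_sequence`` so that changing only the arrest
    probability leaves every trajectory identical up to the moment of
    arrest.
    """
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(config.seed + 1)
    class_ss, *cell_ss = seed_sequence.spawn(1 + 3 * config.n_tcells)
    w, h = config.field_width_um, config.field_height_um
    step_scale = config.frame_interval_s / 60.0  # um/min -> um/frame

    target_geoms = []
    target_ids = []
    for trg in monolayer:
        target_geoms.append(trg.observations[0].polygon._shapely)
        target_ids.append(trg.track_id)
    tree = STRtree(target_geoms) if target_geoms else None
    target_centroids = {tid: np.array(trg.observations[0].polygon.centroid)
                        for tid, trg in zip(target_ids, monolayer)}

    n = config.n_tcells
    n_dead = int(round(config.fraction_dead * n))
    n_drift = int(round(config.fraction_drifter * n))
    classes = (["dead"] * n_dead + ["drifter"] * n_drift
               + ["migrator"] * (n - n_dead - n_drift))
    classes = list(np.random.default_rng(class_ss).permutation(classes))

    # wrapped-normal turning: mean resultant length rho = exp(-sigma^2/2)
    rho = config.turn_persistence
    turn_sigma = math.sqrt(-2.0 * math.log(rho)) if rho > 0 else math.pi

    foot_area = _footprint(np.zeros(2), config.tcell_radius_um).area
    tracks: list[Track] = []
    for cid in range(n):
        cls = classes[cid]
        rng = np.random.default_rng(cell_ss[3 * cid])
        arrest_rng = np.random.default_rng(cell_ss[3 * cid + 1])
        dropout_rng = np.random.default_rng(cell_ss[3 * cid + 2])
        pos = rng.uniform([0, 0], [w, h])
        heading = rng.uniform(0.0, 2 * np.pi)
        arrested = False
        arrest_target = None
        positions = np.empty((config.n_frames, 2))
        for f in range(config.n_frames):
            if f > 0:
                if cls == "dead":
                    pos = pos0 + rng.uniform(-config.dead_jitter_um / 2,
                                             config.dead_jitter_um / 2, 2)
                elif cls == "drifter":
                    step = config.drifter_speed_um_min * step_scale
                    pos = pos + step * np.array([math.cos(heading),
                                                 math.sin(heading)])
                elif arrested:
                    pos = arrest_pos + rng.uniform(
                        -config.arrest_jitter_um / 2,
                        config.arrest_jitter_um / 2, 2)
                else:
                    speed = max(0.0, rng.normal(config.speed_mean_um_min,
                                                config.speed_sd_um_min))
                    heading = heading + rng.normal(0.0, turn_sigma)
                    pos = pos + speed * step_scale * np.array(
                        [math.cos(heading), math.sin(heading)])
                    pos = _reflect(pos, w, h)
            else:
                pos0 = pos.copy()
            positions[f] = pos
            # encounter-triggered arrest, first Bernoulli success wins
            if cls == "migrator" and not arrested and tree is not None:
                foot = _footprint(pos, config.tcell_radius_um)
                shp = foot._shapely
                for j in tree.query(shp):
                    inter = shp.intersection(target_geoms[j]).area
                    if inter / foot_area >= config.arrest_overlap_fraction:
                        if arrest_rng.random() < config.p_arrest_per_encounter:
                            arrested = True
                            arrest_target = target_ids[j]
                            # settle onto the APC: small shift toward its
                            # centroid deepens the overlap
                            d = target_centroids[arrest_target] - pos
                            dist = np.linalg.norm(d)
                            if dist > 1e-9:
                                pos = pos + d / dist * min(1.5, dist)
                            positions[f] = pos
                            arrest_pos = pos.copy()
                            ground_truth.arrest_frame[cid] = f
                            ground_truth.arrest_target_id[cid] = arrest_target
                            break
        ground_truth.tcell_class[cid] = ("arrested" if arrested else cls)

        keep = np.ones(config.n_frames, dtype=bool)
        if config.p_dropout > 0:
            keep = dropout_rng.random(config.n_frames) >= config.p_dropout
            if not keep.any():
                keep[0] = True
        obs = tuple(
            Observation(frame=f, centroid=tuple(positions[f]),
                        polygon=_footprint(positions[f],
                                           config.tcell_radius_um))
            for f in range(config.n_frames) if keep[f]
        )
        tracks.append(Track(cid, "tcell", obs))
    return tracks


def generate_field(
    config: SimulationConfig,
) -> tuple[FieldDataset, GroundTruth]:
    """Generate one complete synthetic field (targets + T cells + labels)."""
    root = np.random.SeedSequence(config.seed)
    mono_ss, cells_ss = root.spawn(2)
    targets, gt = generate_monolayer(config, np.random.default_rng(mono_ss))
    tcells = generate_tcells(config, targets, gt, cells_ss)
    dataset = FieldDataset(metadata=config.metadata(),
                           tcell_tracks=tuple(tcells),
                           target_tracks=tuple(targets))
    return dataset, gt


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def expected_stable_fraction(
    config: SimulationConfig,
    n_rep: int = 10,
    seed: int = 0,
) -> dict:
    """Monte-Carlo expectation of the pipeline's raw stable percentage.

    Runs generator + full analysis ``n_rep`` times with seeds derived from
    ``seed`` and aggregates stable calls over all kept cells into a single
    binomial 95% (Wilson) confidence interval.  Returns mean percent, CI
    bounds and counts.
    """
    from dataclasses import replace as _dc_replace

    from .assay import ScanStopAssay

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(n_rep)]
    n_stable_total = 0
    n_kept_total = 0
    n_arrested_kept = 0
    per_rep = []
    for s in rep_seeds:
        cfg = _dc_replace(config, seed=s)
        assay = ScanStopAssay.from_simulation(cfg)
        res = assay.fit()
        fs = res.field_summary
        n_stable_total += fs.n_stable
        n_kept_total += fs.n_tcells_analyzed
        n_arrested_kept += sum(
            1 for tid in res.filter_report.kept
            if assay.ground_truth.tcell_class.get(tid) == "arrested")
        per_rep.append(fs.raw_stable_percent)
    if n_kept_total == 0:
        raise ValueError("no kept cells in any replicate")
    ci = binomtest(n_stable_total, n_kept_total).proportion_ci(
        confidence_level=0.95, method="wilson")
    return {
        "mean_percent": 100.0 * n_stable_total / n_kept_total,
        "ci_low_percent": 100.0 * ci.low,
        "ci_high_percent": 100.0 * ci.high,
        "n_stable": n_stable_total,
        "n_kept": n_kept_total,
        "arrested_percent": 100.0 * n_arrested_kept / n_kept_total,
        "per_rep_percent": per_rep,
    }
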