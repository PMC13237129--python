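"""Model/Results facade over the full analysis pipeline.

``ScanStopAssay`` is constructed from a :class:`~scanstop.io.FieldDataset`
(directly, from files, or from a simulation config) together with
:class:`~scanstop.contacts.AnalysisParameters`; calling :meth:`fit` runs
filtering -> touch detection -> contact assembly -> classification ->
metrics and returns a :class:`FieldResults` carrying the filter report, the
classified contacts, a per-cell metrics DataFrame, the field summary and a
printable ``summary()`` table.

Example
-------
>>> from scanstop import ScanStopAssay, SimulationConfig
>>> res = ScanStopAssay.from_simulation(SimulationConfig(seed=1)).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import filters as _filters
from . import io as _io
from .contacts import (AnalysisParameters, Contact, Touch, assemble_contacts,
                       classify_contacts, detect_touches, targets_visited)
from .io import FieldDataset, FieldMetadata, Track
from .metrics import (FieldSummary, StoppingProfile, stopping_speed,
                      summarize_field)

logger = logging.getLogger(__name__)

__all__ = ["ScanStopAssay", "FieldResults"]


class ScanStopAssay:
    """Contact-calling model for one imaging field.

    Parameters
    ----------
    dataset
        Tracks of both populations plus acquisition metadata.
    params
        Analysis thresholds; defaults are taken from the dataset metadata
        (final frame, frame interval) with the published operating point for
        everything else.
    seed
        Recorded provenance only (e.g. the simulation seed); the analysis
        itself is deterministic.
    """

    def __init__(
        self,
        dataset: FieldDataset,
        params: Optional[AnalysisParameters] = None,
        seed: Optional[int] = None,
    ) -> None:
        self.dataset = dataset
        self.params = params or AnalysisParameters.from_metadata(
            dataset.metadata)
        self.seed = seed

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        tcell_path: str | Path,
        target_path: str | Path,
        metadata: Optional[FieldMetadata] = None,
        params: Optional[AnalysisParameters] = None,
    ) -> "ScanStopAssay":
        """Build from two canonical tracks CSV files."""
        metadata = metadata or FieldMetadata()
        ds = FieldDataset(
            metadata=metadata,
            tcell_tracks=tuple(_io.read_tracks_csv(tcell_path, "tcell")),
            target_tracks=tuple(_io.read_tracks_csv(target_path, "target")),
        )
        return cls(ds, params)

    @classmethod
    def from_trackmate(
        cls,
        tcell_xml: str | Path,
        target_xml: str | Path,
        metadata: Optional[FieldMetadata] = None,
        params: Optional[AnalysisParameters] = None,
        pixel_size: float = 1.0,
    ) -> "ScanStopAssay":
        """Build from a TrackMate T-cell export and a target-cell export."""
        metadata = metadata or FieldMetadata()
        ds = FieldDataset(
            metadata=metadata,
            tcell_tracks=tuple(_io.read_trackmate_xml(
                tcell_xml, "tcell", pixel_size)),
            target_tracks=tuple(_io.read_trackmate_xml(
                target_xml, "target", pixel_size)),
        )
        return cls(ds, params)

    @classmethod
    def from_files(
        cls,
        tcell_path: str | Path,
        target_path: str | Path,
        metadata: Optional[FieldMetadata] = None,
        params: Optional[AnalysisParameters] = None,
        pixel_size: float = 1.0,
    ) -> "ScanStopAssay":
        """Auto-detect input format by extension (.xml or .csv)."""
        suffix = Path(tcell_path).suffix.lower()
        if suffix == ".xml":
            return cls.from_trackmate(tcell_path, target_path, metadata,
                                      params, pixel_size)
        if suffix == ".csv":
            return cls.from_csv(tcell_path, target_path, metadata, params)
        raise ValueError(f"unrecognised input extension: {suffix}")

    @classmethod
    def from_simulation(cls, config,
                        params: Optional[AnalysisParameters] = None
                        ) -> "ScanStopAssay":
        """Generate a synthetic field and wrap it for analysis.

        The ground truth is attached as ``assay.ground_truth``.
        """
        from .simulate import generate_field
        dataset, gt = generate_field(config)
        assay = cls(dataset, params, seed=config.seed)
        assay.ground_truth = gt
        return assay

    # -- fitting -----------------------------------------------------------

    def fit(self, density_factor: float = 1.0) -> "FieldResults":
        """Run the full pipeline and return the results object.

        ``density_factor`` defaults to 1 (single-field analysis); group-level
        re-normalisation across fields is done by
        :func:`scanstop.metrics.summarize_group` or ``scanstop group``.
        """
        ds, params = self.dataset, self.params
        report, kin = _filters.apply_filters(
            ds.tcell_tracks,
            frame_interval_s=params.frame_interval_s,
            min_displacement_um=params.min_displacement_um,
            max_persistence=params.max_persistence,
        )
        kept_ids = set(report.kept)
        kept_tracks = [t for t in ds.tcell_tracks if t.track_id in kept_ids]
        logger.info(
            "field %s: %d T-cell tracks in, %d removed dead, %d removed "
            "drifting, %d kept", ds.metadata.field_id,
            len(ds.tcell_tracks), len(report.removed_dead),
            len(report.removed_drifting), len(report.kept))

        touches = detect_touches(kept_tracks, ds.target_tracks, params)
        contacts = assemble_contacts(touches, params)
        last_frames = {t.track_id: t.last_frame for t in kept_tracks}
        contacts = classify_contacts(contacts, params, last_frames)
        logger.info("field %s: %d touches, %d contacts, %d stable",
                    ds.metadata.field_id, len(touches), len(contacts),
                    sum(c.classification == "stable" for c in contacts))

        tracks_by_id = {t.track_id: t for t in kept_tracks}
        profiles = [
            stopping_speed(c, tracks_by_id[c.tcell_id], params)
            for c in contacts if c.classification == "stable"
        ]
        summary = summarize_field(ds, report, kin, contacts, profiles,
                                  params, density_factor)
        cells = self._cells_table(report, kin, contacts, profiles)
        return FieldResults(
            model=self, params=params, filter_report=report,
            kinematics=kin, touches=touches, contacts=contacts,
            stopping_profiles=profiles, field_summary=summary,
            cells=cells, seed=self.seed,
        )

    def _cells_table(self, report, kin, contacts, profiles) -> pd.DataFrame:
        speed_by_cell = {p.tcell_id: p.stopping_speed for p in profiles}
        rows = []
        status = {tid: "kept" for tid in report.kept}
        status.update({tid: "removed_dead" for tid in report.removed_dead})
        status.update({tid: "removed_drifting"
                       for tid in report.removed_drifting})
        for t in self.dataset.tcell_tracks:
            tid = t.track_id
            k = kin[tid]
            cell_contacts = [c for c in contacts if c.tcell_id == tid]
            n_stable = sum(c.classification == "stable"
                           for c in cell_contacts)
            n_transient = sum(c.classification == "transient"
                              for c in cell_contacts)
            rows.append({
                "track_id": tid,
                "status": status[tid],
                "total_distance_um": k.total_path_length,
                "euclidean_distance_um": k.euclidean_displacement,
                "mean_speed_um_s": k.mean_speed,
                "persistence": k.persistence,
                "n_stable_contacts": n_stable,
                "n_transient_contacts": n_transient,
                "targets_visited": targets_visited(contacts, tid),
                "stopping_speed_um_s": speed_by_cell.get(tid),
            })
        return pd.DataFrame(rows)


@dataclass
class FieldResults:
    """Everything the pipeline measured on one field."""

    model: ScanStopAssay
    params: AnalysisParameters
    filter_report: _filters.FilterReport
    kinematics: dict[int, _filters.TrackKinematics]
    touches: list[Touch]
    contacts: list[Contact]
    stopping_profiles: list[StoppingProfile]
    field_summary: FieldSummary
    cells: pd.DataFrame
    seed: Optional[int] = None

    def summary(self) -> str:
        """Human-readable field report."""
        fs = self.field_summary
        rep = self.filter_report

        def fmt(v, unit=""):
            return "n/a" if v is None else f"{v:.2f}{unit}"

        lines = [
            "Scan-and-stop field analysis",
            "=" * 60,
            f"field: {fs.field_id}    group: {fs.group_id}",
            f"T-cell tracks:        {fs.n_tcells_total}",
            f"  removed dead:       {len(rep.removed_dead)}"
            f"  (net displacement < {rep.min_displacement_um:g} um)",
            f"  removed drifting:   {len(rep.removed_drifting)}"
            f"  (persistence > {rep.max_persistence:g})",
            f"  analyzed:           {fs.n_tcells_analyzed}",
            f"activating targets:   {fs.n_targets_in_field}",
            f"touches / contacts:   {len(self.touches)} / "
            f"{len(self.contacts)}",
            "-" * 60,
            f"stable contacts:      {fs.n_stable} cells "
            f"({fmt(fs.raw_stable_percent, ' %')})",
            f"transient contacts:   {fs.n_transient_cells} cells "
            f"({fmt(fs.raw_transient_percent, ' %')}), "
            f"{fs.n_transient_contacts} contacts",
            f"density factor:       {fs.density_factor:.4f}",
            f"normalized stable %:  {fmt(fs.normalized_stable_percent)}",
            f"mean targets visited: {fmt(fs.mean_targets_visited)}",
            f"mean stopping speed:  {fmt(fs.mean_stopping_speed, ' um/s')}",
            "-" * 60,
            "migration (kept cells, mean +/- SD):",
            f"  total distance:     {fmt(fs.total_distance_um[0], ' um')}"
            f" +/- {fmt(fs.total_distance_um[1])}",
            f"  Euclidean distance: {fmt(fs.euclidean_distance_um[0], ' um')}"
            f" +/- {fmt(fs.euclidean_distance_um[1])}",
            f"  mean speed:         {fmt(fs.mean_speed_um_s[0], ' um/s')}"
            f" +/- {fmt(fs.mean_speed_um_s[1])}",
            f"  persistence:        {fmt(fs.persistence[0])}"
            f" +/- {fmt(fs.persistence[1])}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write contacts.csv, cells.csv and summary.json."""
        return _io.write_results(self, out_dir)
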