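"""End-to-end convenience wrappers: recording -> averaged beat -> variables.

These functions compose the module-level operations in the order the analysis
runs: segment cycles (ED at R-peak, ES at max negative LV dP/dt), average the
first 4 usable consecutive beats on the normalized cycle grid, then measure
geometry at end-diastole.
"""

from __future__ import annotations

import numpy as np

from .cycles import AveragedBeat, average_beats, hemodynamic_summary, segment_cycles
from .geometry import (
    annular_area,
    cross_sectional_area,
    radius_of_curvature,
    rv_hull_volume,
)
from .recording import ChannelRecording, CrystalLayout

__all__ = ["averaged_beat", "recording_variables"]


def averaged_beat(
    rec: ChannelRecording,
    n_beats: int = 4,
    grid_points: int = 101,
    **segment_kwargs,
) -> AveragedBeat:
    """Segment ``rec`` and average its first ``n_beats`` usable cycles."""
    cycles = segment_cycles(rec, **segment_kwargs)
    return average_beats(rec, cycles, n=n_beats, grid_points=grid_points)


def recording_variables(
    rec: ChannelRecording,
    layout: CrystalLayout,
    n_beats: int = 4,
    timepoint: str = "ED",
) -> dict[str, float]:
    """Per-recording scalar variables: haemodynamics + geometry at ``timepoint``.

    Keys match :data:`rvk.stats.REPORT_VARIABLES` so the output feeds
    :func:`rvk.stats.build_report` directly.
    """
    cycles = segment_cycles(rec)
    beat = average_beats(rec, cycles, n=n_beats)
    out = dict(hemodynamic_summary(rec, cycles, n=n_beats))
    out["taa_mm2"] = annular_area(beat, layout, timepoint)
    out["edv_ml"] = rv_hull_volume(beat, layout, timepoint)
    for row in ("basal", "mid", "lower"):
        if row in layout.parallels and len(layout.parallels[row]) >= 3:
            out[f"csa_{row}_mm2"] = cross_sectional_area(beat, layout, row, timepoint)
            out[f"roc_{row}_mm"] = radius_of_curvature(beat, layout, row, timepoint)
    return out
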