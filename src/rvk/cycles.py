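"""Cardiac-cycle landmarking, segmentation, and beat averaging.

Landmark conventions follow standard haemodynamic practice: end-diastole (ED)
is the R-wave peak on the ECG, end-systole (ES) the time of maximum negative
dP/dt of LV pressure.  Two further phase labels are provided as explicit
conventions of this package (the field names them but gives no operational
definition): end of isovolumic contraction (EIVC) as the maximum positive LV
dP/dt within the beat, and end of isovolumic relaxation (EIVR) as the first
sample after ES where LV pressure falls back below its ED value.

Beats are averaged after linear resampling onto a common 0-100 % cycle grid
(ED to next ED); by default the first 4 usable consecutive cycles are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import CycleError, ParameterError
from .recording import ChannelRecording

__all__ = [
    "CycleLandmarks",
    "AveragedBeat",
    "detect_r_peaks",
    "compute_dpdt",
    "segment_cycles",
    "average_beats",
    "hemodynamic_summary",
]


@dataclass(frozen=True)
class CycleLandmarks:
    """Per-beat landmark sample indices; the beat spans ``[ed, next_ed)``."""

    ed_index: int
    es_index: int
    next_ed_index: int
    eivc_index: int | None = None
    eivr_index: int | None = None
    usable: bool = True

    def __post_init__(self):
        if not self.ed_index < self.es_index < self.next_ed_index:
            raise ParameterError(
                f"landmarks must satisfy ed < es < next_ed, got "
                f"{self.ed_index}, {self.es_index}, {self.next_ed_index}"
            )

    @property
    def cycle_span(self) -> tuple[int, int]:
        return (self.ed_index, self.next_ed_index)

    @property
    def n_samples(self) -> int:
        return self.next_ed_index - self.ed_index


def detect_r_peaks(
    ecg: np.ndarray,
    sample_rate: float,
    *,
    refractory_s: float = 0.2,
    detrend_window_s: float = 0.6,
    threshold_frac: float = 0.6,
    amplitude_percentile: float = 98.0,
) -> np.ndarray:
    """Detect R-wave peaks; returns strictly increasing sample indices.

    Pipeline: moving-median detrend (window ``detrend_window_s``), threshold at
    ``threshold_frac`` of the ``amplitude_percentile``-th percentile of the
    detrended signal, peak picking with a ``refractory_s`` refractory period,
    then parabolic sub-sample refinement rounded back to the nearest sample.
    An empty array (with a warning) is returned when nothing clears threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.ndim != 1:
        raise ParameterError("ecg must be 1-D")
    if sample_rate <= 0:
        raise ParameterError("sample_rate must be > 0")
    n = len(ecg)
    k = int(round(detrend_window_s * sample_rate)) | 1
    k = min(k, (n - 1) | 1)
    detrended = ecg - signal.medfilt(ecg, kernel_size=k) if k >= 3 else ecg - ecg.mean()
    level = np.percentile(detrended, amplitude_percentile)
    threshold = threshold_frac * level
    scale = np.max(np.abs(detrended)) if n else 0.0
    if scale == 0 or threshold <= 1e-12 * scale:
        warnings.warn("no R-peaks found: signal flat or below threshold")
        return np.empty(0, dtype=int)
    distance = max(1, int(round(refractory_s * sample_rate)))
    peaks, _ = signal.find_peaks(detrended, height=threshold, distance=distance)
    if len(peaks) == 0:
        warnings.warn("no R-peaks found above threshold")
        return peaks
    refined = []
    for p in peaks:
        if 0 < p < n - 1:
            y0, y1, y2 = detrended[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            p = int(round(p + np.clip(delta, -0.5, 0.5)))
        refined.append(p)
    return np.unique(refined)


def compute_dpdt(
    pressure: np.ndarray, sample_rate: float, smooth_window: int = 5
) -> np.ndarray:
    """dP/dt in mmHg/s: central difference of the moving-average-smoothed trace.

    Endpoints use one-sided differences; the moving average uses nearest-edge
    padding so the output has the input's length.
    """
    p = np.asarray(pressure, dtype=float)
    if p.ndim != 1:
        raise ParameterError("pressure must be 1-D")
    if not 1 <= smooth_window <= len(p):
        raise ParameterError(
            f"smooth_window must be in [1, {len(p)}], got {smooth_window}"
        )
    if smooth_window > 1:
        from scipy.ndimage import uniform_filter1d

        p = uniform_filter1d(p, size=smooth_window, mode="nearest")
    return np.gradient(p) * sample_rate


def segment_cycles(
    rec: ChannelRecording,
    *,
    smooth_window: int = 5,
    detector_kwargs: Mapping | None = None,
) -> list[CycleLandmarks]:
    """Segment a recording into beats with ED/ES (+EIVC/EIVR) landmarks.

    ES is the argmin of LV dP/dt strictly inside ``(ed, next_ed)``; a beat
    whose ES candidate sits at the interval boundary is flagged unusable.
    """
    peaks = detect_r_peaks(rec.ecg, rec.sample_rate, **(detector_kwargs or {}))
    if len(peaks) < 2:
        raise CycleError(f"need >= 2 R-peaks to segment cycles, found {len(peaks)}")
    dpdt = compute_dpdt(rec.lvp, rec.sample_rate, smooth_window)
    out: list[CycleLandmarks] = []
    for ed, next_ed in zip(peaks[:-1], peaks[1:]):
        ed, next_ed = int(ed), int(next_ed)
        if next_ed - ed < 3:
            continue
        interior = dpdt[ed + 1 : next_ed]
        es = ed + 1 + int(np.argmin(interior))
        eivc = ed + 1 + int(np.argmax(interior))
        usable = (ed + 1) < es < (next_ed - 1)
        eivr = None
        after = np.nonzero(rec.lvp[es + 1 : next_ed] < rec.lvp[ed])[0]
        if len(after):
            eivr = es + 1 + int(after[0])
        out.append(
            CycleLandmarks(
                ed_index=ed,
                es_index=es,
                next_ed_index=next_ed,
                eivc_index=eivc if eivc != es else None,
                eivr_index=eivr,
                usable=usable,
            )
        )
    return out


@dataclass(frozen=True)
class AveragedBeat:
    """Channels of several consecutive beats averaged on a 0-100 % cycle grid."""

    grid: np.ndarray  # percent of cycle, strictly increasing 0..100
    crystals: Mapping[str, np.ndarray]  # label -> (G, 3) mm
    lvp: np.ndarray
    rvp: np.ndarray
    cvp: np.ndarray
    ecg: np.ndarray
    n_beats_averaged: int
    es_phase_pct: float
    period_s: float
    source_landmarks: tuple[CycleLandmarks, ...] = field(default_factory=tuple)
    eivc_phase_pct: float | None = None
    eivr_phase_pct: float | None = None
    state_tag: str = "other"

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if len(g) < 2 or not np.all(np.diff(g) > 0) or g[0] != 0 or g[-1] != 100:
            raise ParameterError("grid must increase strictly from 0 to 100")
        if self.n_beats_averaged < 1:
            raise ParameterError("n_beats_averaged must be >= 1")

    @property
    def n_grid(self) -> int:
        return len(self.grid)

    def grid_index(self, timepoint: str | float) -> int:
        """Nearest grid index to a named ('ED'/'ES'/'EIVC'/'EIVR') or % timepoint."""
        named = {
            "ED": 0.0,
            "ES": self.es_phase_pct,
            "EIVC": self.eivc_phase_pct,
            "EIVR": self.eivr_phase_pct,
        }
        if isinstance(timepoint, str):
            key = timepoint.upper()
            if key not in named:
                raise ParameterError(f"unknown timepoint {timepoint!r}")
            phase = named[key]
            if phase is None:
                raise ParameterError(f"timepoint {timepoint!r} not available")
        else:
            phase = float(timepoint)
        if not 0 <= phase <= 100:
            raise ParameterError(f"timepoint {phase} outside [0, 100] %")
        return int(np.argmin(np.abs(self.grid - phase)))

    def frame(self, timepoint: str | float) -> dict[str, np.ndarray]:
        """Crystal positions at a timepoint, label -> (3,) mm."""
        i = self.grid_index(timepoint)
        return {lab: arr[i] for lab, arr in self.crystals.items()}


def _resample(channel: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Linear interpolation of a 1-D or (N, 3) channel at float sample positions."""
    idx0 = np.floor(positions).astype(int)
    idx0 = np.clip(idx0, 0, len(channel) - 2)
    w = positions - idx0
    if channel.ndim == 1:
        return (1 - w) * channel[idx0] + w * channel[idx0 + 1]
    return (1 - w)[:, None] * channel[idx0] + w[:, None] * channel[idx0 + 1]


def average_beats(
    rec: ChannelRecording,
    cycles: Sequence[CycleLandmarks],
    n: int = 4,
    grid_points: int = 101,
    start: int = 0,
) -> AveragedBeat:
    """Average ``n`` consecutive usable beats on a normalized 0-100 % grid.

    Each beat is linearly resampled from its ED to the next ED; channels are
    averaged pointwise and landmark phases averaged in normalized time.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if grid_points < 2:
        raise ParameterError("grid_points must be >= 2")
    usable = [c for c in cycles if c.usable][start : start + n]
    if len(usable) < n:
        raise CycleError(
            f"need {n} usable cycles, only {len(usable)} available from start={start}"
        )
    grid = np.linspace(0.0, 100.0, grid_points)
    tau = grid / 100.0

    chan_names = ("lvp", "rvp", "cvp", "ecg")
    acc_chan = {name: np.zeros(grid_points) for name in chan_names}
    acc_cry = {lab: np.zeros((grid_points, 3)) for lab in rec.crystals}
    es_phases, eivc_phases, eivr_phases, periods = [], [], [], []
    for c in usable:
        positions = c.ed_index + tau * (c.next_ed_index - c.ed_index)
        for name in chan_names:
            acc_chan[name] += _resample(getattr(rec, name), positions)
        for lab, arr in rec.crystals.items():
            acc_cry[lab] += _resample(arr, positions)
        span = c.next_ed_index - c.ed_index
        es_phases.append(100.0 * (c.es_index - c.ed_index) / span)
        if c.eivc_index is not None:
            eivc_phases.append(100.0 * (c.eivc_index - c.ed_index) / span)
        if c.eivr_index is not None:
            eivr_phases.append(100.0 * (c.eivr_index - c.ed_index) / span)
        periods.append(span / rec.sample_rate)

    k = float(len(usable))
    return AveragedBeat(
        grid=grid,
        crystals={lab: acc / k for lab, acc in acc_cry.items()},
        lvp=acc_chan["lvp"] / k,
        rvp=acc_chan["rvp"] / k,
        cvp=acc_chan["cvp"] / k,
        ecg=acc_chan["ecg"] / k,
        n_beats_averaged=len(usable),
        es_phase_pct=float(np.mean(es_phases)),
        eivc_phase_pct=float(np.mean(eivc_phases)) if eivc_phases else None,
        eivr_phase_pct=float(np.mean(eivr_phases)) if eivr_phases else None,
        period_s=float(np.mean(periods)),
        source_landmarks=tuple(usable),
        state_tag=rec.state_tag,
    )


def hemodynamic_summary(
    rec: ChannelRecording, cycles: Sequence[CycleLandmarks], n: int = 4
) -> dict[str, float]:
    """Per-recording haemodynamics over the first ``n`` usable beats.

    Conventions: HR from the mean RR interval; LVP and RVP as the mean of
    per-cycle peaks; CVP as the mean of per-cycle means.
    """
    usable = [c for c in cycles if c.usable][:n]
    if not usable:
        raise CycleError("no usable cycles for haemodynamic summary")
    rr = np.array([c.n_samples for c in usable]) / rec.sample_rate
    lvp_peaks = [rec.lvp[c.ed_index : c.next_ed_index].max() for c in usable]
    rvp_peaks = [rec.rvp[c.ed_index : c.next_ed_index].max() for c in usable]
    cvp_means = [rec.cvp[c.ed_index : c.next_ed_index].mean() for c in usable]
    return {
        "hr_bpm": 60.0 / float(np.mean(rr)),
        "lvp_mmhg": float(np.mean(lvp_peaks)),
        "rvp_mmhg": float(np.mean(rvp_peaks)),
        "cvp_mmhg": float(np.mean(cvp_means)),
    }
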