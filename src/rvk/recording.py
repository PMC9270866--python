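"""Recording bundles: synchronized crystal trajectories + pressure/ECG channels.

A recording is stored on disk as a two-file *bundle*:

``<name>.header.json``
    units, sample rate, state tag (``Baseline`` / ``TRA`` / other), crystal
    layout, and the expected sample count.
``<name>.channels.csv``
    one row per sample; columns ``time``, ``<label>_x/_y/_z`` for every
    crystal, then ``lvp``, ``rvp``, ``cvp``, ``ecg``.

Both files are plain text, human-inspectable and diff-able.  Internally all
lengths are millimetres, pressures mmHg, time seconds; headers may declare
``cm``/``m``, ``kPa`` or ``ms`` and are converted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SchemaError, StructuralError

__all__ = [
    "CrystalLayout",
    "ChannelRecording",
    "read_recording",
    "write_recording",
    "validate_layout",
]

PRESSURE_CHANNELS = ("lvp", "rvp", "cvp")
ROW_ORDER = ("basal", "mid", "lower")

_LENGTH_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_PRESSURE_FACTORS = {"mmhg": 1.0, "kpa": 7.500616827}
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}


@dataclass(frozen=True)
class CrystalLayout:
    """Roles and circumferential ordering of the implanted crystals.

    The array comprises 6 crystals around the tricuspid annulus (ordered
    circumferentially), 13 free-wall epicardial crystals on three parallels
    (basal / mid / lower, each ordered circumferentially), and 1 apex crystal.
    Per-row counts on the free wall are a configurable convention (default
    5/4/4); only the total of 13 is anatomically fixed.
    """

    annular: tuple[str, ...]
    parallels: Mapping[str, tuple[str, ...]]
    apex: str
    region_of_row: Mapping[str, str] = field(
        default_factory=lambda: {"basal": "basal", "mid": "mid", "lower": "lower"}
    )

    @classmethod
    def default(cls, row_sizes: Sequence[int] = (5, 4, 4)) -> "CrystalLayout":
        """Canonical label scheme: TA1..TA6, B*, M*, L*, APEX."""
        if len(row_sizes) != 3:
            raise ParameterError("row_sizes must give counts for basal, mid, lower")
        prefixes = ("B", "M", "L")
        parallels = {
            row: tuple(f"{p}{i + 1}" for i in range(n))
            for row, p, n in zip(ROW_ORDER, prefixes, row_sizes)
        }
        return cls(
            annular=tuple(f"TA{i + 1}" for i in range(6)),
            parallels=parallels,
            apex="APEX",
        )

    @property
    def rows(self) -> tuple[str, ...]:
        return tuple(r for r in ROW_ORDER if r in self.parallels)

    @property
    def free_wall_labels(self) -> tuple[str, ...]:
        return tuple(lab for row in self.rows for lab in self.parallels[row])

    @property
    def all_labels(self) -> tuple[str, ...]:
        return tuple(self.annular) + self.free_wall_labels + (self.apex,)

    def violations(self) -> list[str]:
        """Internal-consistency report; empty iff the layout is valid."""
        out: list[str] = []
        if len(self.annular) != 6:
            out.append(f"annular count {len(self.annular)} != 6")
        n_wall = sum(len(v) for v in self.parallels.values())
        if n_wall != 13:
            out.append(f"free-wall count {n_wall} != 13")
        if not self.apex:
            out.append("apex label empty")
        seen: set[str] = set()
        for lab in self.all_labels:
            if lab in seen:
                out.append(f"label {lab!r} reused")
            seen.add(lab)
        for row in self.parallels:
            if row not in ROW_ORDER:
                out.append(f"unknown row {row!r}")
        return out

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise SchemaError("invalid layout: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return {
            "annular": list(self.annular),
            "parallels": {k: list(v) for k, v in self.parallels.items()},
            "apex": self.apex,
            "region_of_row": dict(self.region_of_row),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CrystalLayout":
        try:
            return cls(
                annular=tuple(d["annular"]),
                parallels={k: tuple(v) for k, v in d["parallels"].items()},
                apex=str(d["apex"]),
                region_of_row=dict(d.get("region_of_row", {r: r for r in ROW_ORDER})),
            )
        except KeyError as e:  # pragma: no cover - message path
            raise SchemaError(f"layout missing field {e.args[0]!r}") from e


@dataclass(frozen=True)
class ChannelRecording:
    """Synchronized multichannel recording at a fixed sampling rate.

    ``crystals`` maps label -> (N, 3) coordinates in mm; ``lvp``/``rvp``/``cvp``
    are mmHg, ``ecg`` arbitrary units, ``time`` seconds.  All channels share
    length N >= 2 and must be finite.
    """

    sample_rate: float
    time: np.ndarray
    crystals: Mapping[str, np.ndarray]
    lvp: np.ndarray
    rvp: np.ndarray
    cvp: np.ndarray
    ecg: np.ndarray
    state_tag: str = "other"

    def __post_init__(self):
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        n = len(self.time)
        if n < 2:
            raise StructuralError(f"recording needs >= 2 samples, got {n}")
        for name in ("time", "lvp", "rvp", "cvp", "ecg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or len(arr) != n:
                raise StructuralError(f"channel {name!r} length {arr.shape} != {n}")
            _check_finite(arr, name)
            object.__setattr__(self, name, arr)
        crystals = {}
        for lab, arr in self.crystals.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise StructuralError(
                    f"crystal {lab!r} shape {arr.shape} != ({n}, 3)"
                )
            _check_finite(arr, f"crystal {lab}")
            crystals[lab] = arr
        object.__setattr__(self, "crystals", crystals)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Recording span in seconds, ``N / fs``."""
        return self.n_samples / self.sample_rate

    def crystal_matrix(self, labels: Sequence[str]) -> np.ndarray:
        """Stack trajectories for ``labels`` into an (n_labels, N, 3) array."""
        missing = [lab for lab in labels if lab not in self.crystals]
        if missing:
            raise SchemaError(f"recording missing crystal(s) {missing}")
        return np.stack([self.crystals[lab] for lab in labels])

    def frame(self, index: int) -> dict[str, np.ndarray]:
        """Crystal positions at one sample index, label -> (3,)."""
        if not 0 <= index < self.n_samples:
            raise ParameterError(f"sample index {index} outside [0, {self.n_samples})")
        return {lab: arr[index] for lab, arr in self.crystals.items()}

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "ChannelRecording":
        """Apply a rigid motion ``x -> R x + t`` to every crystal trajectory."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        crystals = {lab: arr @ R.T + t for lab, arr in self.crystals.items()}
        return replace(self, crystals=crystals)


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.argwhere(bad)[0][0])
        raise DataError(f"non-finite value in {name} at sample {idx}")


def validate_layout(layout: CrystalLayout, rec: ChannelRecording) -> list[str]:
    """Report every layout invariant or layout/recording mismatch.

    Returns an empty list iff the layout is internally valid and every layout
    label has a trajectory in the recording.
    """
    report = layout.violations()
    for lab in layout.all_labels:
        if lab not in rec.crystals:
            report.append(f"recording missing crystal {lab!r}")
    return report


# ---------------------------------------------------------------------------
# bundle I/O


def _bundle_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    name = p.name
    for suffix in (".header.json", ".channels.csv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    base = p.with_name(name)
    return base.with_name(base.name + ".header.json"), base.with_name(
        base.name + ".channels.csv"
    )


def write_recording(rec: ChannelRecording, path: str | Path,
                    layout: CrystalLayout | None = None) -> Path:
    """Write ``rec`` as a header+CSV bundle; returns the header path.

    ``path`` is the bundle base name (with or without a bundle suffix).  The
    header records units, sample rate, state tag and, when given, the layout,
    so that :func:`read_recording` can re-validate the bundle standalone.
    """
    header_path, csv_path = _bundle_paths(path)
    labels = list(rec.crystals)
    header = {
        "format": "rvk-bundle",
        "version": 1,
        "sample_rate": rec.sample_rate,
        "n_samples": rec.n_samples,
        "state_tag": rec.state_tag,
        "units": {"length": "mm", "pressure": "mmHg", "time": "s"},
        "crystals": labels,
        "layout": layout.to_dict() if layout is not None else None,
    }
    cols: dict[str, np.ndarray] = {"time": rec.time}
    for lab in labels:
        arr = rec.crystals[lab]
        for j, ax in enumerate("xyz"):
            cols[f"{lab}_{ax}"] = arr[:, j]
    for ch in PRESSURE_CHANNELS:
        cols[ch] = getattr(rec, ch)
    cols["ecg"] = rec.ecg
    header_path.parent.mkdir(parents=True, exist_ok=True)
    header_path.write_text(json.dumps(header, indent=1))
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.12g")
    return header_path


def read_recording(path: str | Path,
                   layout: CrystalLayout | None = None) -> ChannelRecording:
    """Read and validate a bundle written by :func:`write_recording`.

    ``layout`` overrides the header's layout; one of the two must be present.
    Units declared in the header are converted to mm / mmHg / seconds.
    """
    header_path, csv_path = _bundle_paths(path)
    if not header_path.exists():
        raise SchemaError(f"missing bundle header {header_path}")
    if not csv_path.exists():
        raise SchemaError(f"missing bundle channel table {csv_path}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"unreadable header JSON: {e}") from e
    for key in ("sample_rate", "units", "crystals"):
        if key not in header:
            raise SchemaError(f"header missing field {key!r}")

    units = header["units"]
    try:
        len_f = _LENGTH_FACTORS[str(units.get("length", "mm")).lower()]
        prs_f = _PRESSURE_FACTORS[str(units.get("pressure", "mmHg")).lower()]
        tim_f = _TIME_FACTORS[str(units.get("time", "s")).lower()]
    except KeyError as e:
        raise SchemaError(f"unsupported unit {e.args[0]!r}") from e

    if layout is None and header.get("layout") is not None:
        layout = CrystalLayout.from_dict(header["layout"])
    if layout is not None:
        layout.validate()

    table = pd.read_csv(csv_path)
    labels = list(header["crystals"])
    if layout is not None:
        for lab in layout.all_labels:
            if lab not in labels:
                raise SchemaError(f"bundle missing crystal {lab!r} required by layout")
    required = ["time"] + [f"{lab}_{ax}" for lab in labels for ax in "xyz"] + list(
        PRESSURE_CHANNELS
    ) + ["ecg"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"channel table missing column(s) {missing}")

    n_expected = header.get("n_samples")
    if n_expected is not None and len(table) != int(n_expected):
        raise StructuralError(
            f"channel table has {len(table)} rows, header declares {n_expected}"
        )

    crystals = {
        lab: np.column_stack([table[f"{lab}_{ax}"].to_numpy(float) for ax in "xyz"])
        * len_f
        for lab in labels
    }
    return ChannelRecording(
        sample_rate=float(header["sample_rate"]),
        time=table["time"].to_numpy(float) * tim_f,
        crystals=crystals,
        lvp=table["lvp"].to_numpy(float) * prs_f,
        rvp=table["rvp"].to_numpy(float) * prs_f,
        cvp=table["cvp"].to_numpy(float) * prs_f,
        ecg=table["ecg"].to_numpy(float),
        state_tag=str(header.get("state_tag", "other")),
    )
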