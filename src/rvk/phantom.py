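"""Synthetic two-state phantom with exact ground truth for every pipeline output.

The right ventricle is surrogated by a half-ellipsoid (semi-axes ``a0, b0,
c0`` mm, base in the z = 0 plane, apex at ``(0, 0, -c0)``).  Crystals are
material points in the documented layout: a regular hexagonal ring of radius
``ring_radius`` in the base plane for the annulus, three free-wall parallels
spanning ``wall_span_deg`` of azimuth at fixed latitudes, and one apex point.

Systole deforms the surface by a time-varying affine map ``A(t) =
diag(alpha(t), alpha(t), gamma(t))`` with alpha interpolating 1 -> lambda_c
and gamma 1 -> lambda_l over a raised-cosine activation that peaks at the
configured end-systolic phase.  Because the deformation is affine, every
directional and areal strain has a closed form, which :func:`analytic_truth`
evaluates on any reference mesh.  An optional non-affine long-axis twist is
available for robustness checks (no closed-form strain).

The TRA state re-scales the annular ring by ``tra_ring_scale`` (area ratio
``s^2``), emulating reductive ring annuloplasty; free-wall mechanics are
unchanged by default.  ECG R-spikes mark the cycle starts (end-diastole), and
the LV pressure pulse is shaped so that its maximum negative derivative falls
exactly at the configured ES phase.  Coordinate noise is iid Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .recording import ChannelRecording, CrystalLayout

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_phantom",
    "analytic_truth",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters; defaults emulate the study conditions.

    Heart rate 106 b/min and an annular ring radius of 19.58 mm (hexagon area
    ~996 mm^2) set the baseline scale; ``tra_ring_scale = sqrt(0.53)``
    prescribes a 47 % annular area reduction.  Systolic stretch targets
    ``lambda_c = 0.92`` / ``lambda_l = 0.95`` give high-single-digit-percent
    peak strains.  Coordinate noise of 0.1 mm reflects sub-millimetre
    transit-time localization error.
    """

    a0: float = 50.0  # mm, base semi-axis (x)
    b0: float = 50.0  # mm, base semi-axis (y)
    c0: float = 70.0  # mm, long-axis depth
    ring_radius: float = 19.58  # mm, annular hexagon circumradius
    heart_rate: float = 106.0  # beats/min
    sample_rate: float = 128.0  # Hz
    n_cycles: int = 6
    lambda_c: float = 0.92  # peak circumferential stretch
    lambda_l: float = 0.95  # peak longitudinal stretch
    es_phase: float = 0.35  # fraction of cycle, location of max -dLVP/dt
    tra_ring_scale: float = math.sqrt(0.53)
    noise_sd: float = 0.1  # mm, iid per coordinate per sample
    lead_in_s: float = 0.25
    tail_s: float = 0.2
    row_phi_deg: tuple[float, float, float] = (75.0, 50.0, 25.0)
    row_sizes: tuple[int, int, int] = (5, 4, 4)
    wall_span_deg: float = 180.0
    ecg_r_width_s: float = 0.010
    lvp_dia: float = 10.0
    lvp_pulse: float = 80.0
    rvp_dia: float = 8.0
    rvp_pulse: float = 35.0
    cvp_mean: float = 12.0
    cvp_pulse: float = 1.0
    twist_deg: float = 0.0  # non-affine apex twist amplitude (robustness option)
    dropout_rate: float = 0.0  # fraction of samples held at previous value
    rigid_motion: Mapping[str, tuple] | None = None  # state -> (rotvec_rad, translation)
    seed: int = 0

    def __post_init__(self):
        positive = ("a0", "b0", "c0", "ring_radius", "heart_rate", "sample_rate",
                    "es_phase", "ecg_r_width_s")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        for name in ("lambda_c", "lambda_l"):
            lam = getattr(self, name)
            if not 0 < lam <= 1.2:
                raise ParameterError(f"{name} must be in (0, 1.2]")
        if not 0 < self.tra_ring_scale <= 1:
            raise ParameterError("tra_ring_scale must be in (0, 1]")
        if not 0 < self.es_phase < 1:
            raise ParameterError("es_phase must be in (0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")

    @property
    def rr_s(self) -> float:
        return 60.0 / self.heart_rate

    def layout(self) -> CrystalLayout:
        return CrystalLayout.default(self.row_sizes)


def _reference_positions(config: PhantomConfig, ring_scale: float) -> dict[str, np.ndarray]:
    """Material (end-diastolic) crystal positions, label -> (3,) mm."""
    layout = config.layout()
    pos: dict[str, np.ndarray] = {}
    r = config.ring_radius * ring_scale
    for k, lab in enumerate(layout.annular):
        th = math.radians(-90.0 + 60.0 * k)
        pos[lab] = np.array([r * math.cos(th), r * math.sin(th), 0.0])
    half = config.wall_span_deg / 2.0
    for row, phi_deg in zip(layout.rows, config.row_phi_deg):
        labels = layout.parallels[row]
        phi = math.radians(phi_deg)
        for lab, th_deg in zip(labels, np.linspace(-half, half, len(labels))):
            th = math.radians(th_deg)
            pos[lab] = np.array(
                [
                    config.a0 * math.sin(phi) * math.cos(th),
                    config.b0 * math.sin(phi) * math.sin(th),
                    -config.c0 * math.cos(phi),
                ]
            )
    pos[layout.apex] = np.array([0.0, 0.0, -config.c0])
    return pos


def activation(config: PhantomConfig, tau: np.ndarray) -> np.ndarray:
    """Raised-cosine activation: 0 at ED, 1 at the ES phase, 0 at the next ED."""
    tau = np.asarray(tau, dtype=float)
    w = np.zeros_like(tau)
    te = config.es_phase
    up = (tau >= 0) & (tau <= te)
    down = (tau > te) & (tau <= 1)
    w[up] = 0.5 * (1.0 - np.cos(np.pi * tau[up] / te))
    w[down] = 0.5 * (1.0 + np.cos(np.pi * (tau[down] - te) / (1.0 - te)))
    return w


def deformation_matrix(config: PhantomConfig, tau) -> np.ndarray:
    """Affine free-wall deformation A(tau) = diag(alpha, alpha, gamma)."""
    w = activation(config, np.atleast_1d(np.asarray(tau, dtype=float)))
    alpha = 1.0 + (config.lambda_c - 1.0) * w
    gamma = 1.0 + (config.lambda_l - 1.0) * w
    A = np.zeros(w.shape + (3, 3))
    A[..., 0, 0] = alpha
    A[..., 1, 1] = alpha
    A[..., 2, 2] = gamma
    return A[0] if np.isscalar(tau) or np.ndim(tau) == 0 else A


def _lvp_shape(config: PhantomConfig, tau: np.ndarray) -> np.ndarray:
    """Unit pressure pulse; the steepest fall is exactly at the ES phase."""
    te = config.es_phase
    r0, r1 = 0.03, min(0.18, te - 0.10)
    f0, f1 = te - 0.08, te + 0.08
    g = np.zeros_like(tau)
    rise = (tau >= r0) & (tau < r1)
    g[rise] = 0.5 * (1.0 - np.cos(np.pi * (tau[rise] - r0) / (r1 - r0)))
    g[(tau >= r1) & (tau < f0)] = 1.0
    fall = (tau >= f0) & (tau < f1)
    g[fall] = 0.5 * (1.0 + np.cos(np.pi * (tau[fall] - f0) / (f1 - f0)))
    # end-diastolic atrial kick (~2 % of pulse) so mid-diastolic pressure sits
    # below the ED value and the EIVR crossing is well defined
    g += 0.02 * (np.exp(-((tau / 0.06) ** 2)) + np.exp(-(((tau - 1.0) / 0.06) ** 2)))
    return g


@dataclass(frozen=True)
class GroundTruth:
    """Everything the pipeline should recover, exact by construction."""

    config: PhantomConfig
    layout: CrystalLayout
    ed_indices: np.ndarray  # sample index of every R-peak (cycle boundaries)
    es_indices: np.ndarray  # per complete cycle
    rr_s: float
    ref_positions: dict[str, dict[str, np.ndarray]]  # state -> label -> (3,)
    annular_area_mm2: dict[str, float]
    taa_reduction_pct: float
    hull_volume_bound_ml: float  # half-ellipsoid volume, upper bound for the hull
    long_axis: np.ndarray

    def deformation(self, tau) -> np.ndarray:
        return deformation_matrix(self.config, tau)


def _hexagon_area(circumradius: float) -> float:
    return 1.5 * math.sqrt(3.0) * circumradius**2


def _state_recording(
    config: PhantomConfig,
    state: str,
    ring_scale: float,
    rng: np.random.Generator,
) -> tuple[ChannelRecording, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    layout = config.layout()
    fs = config.sample_rate
    rr = config.rr_s
    n = int(math.ceil((config.lead_in_s + config.n_cycles * rr + config.tail_s) * fs)) + 1
    t = np.arange(n) / fs
    tau_raw = (t - config.lead_in_s) / rr
    cycle_phase = np.mod(tau_raw, 1.0)
    active = tau_raw >= 0
    tau = np.where(active, cycle_phase, 0.0)

    ref = _reference_positions(config, ring_scale)
    labels = layout.all_labels
    X = np.array([ref[lab] for lab in labels])  # (20, 3)
    A = deformation_matrix(config, tau)  # (n, 3, 3)
    pts = np.einsum("tij,lj->tli", A, X)  # (n, 20, 3)

    if config.twist_deg != 0.0:
        w = activation(config, tau)
        ang = np.radians(config.twist_deg) * (-pts[..., 2] / config.c0) * w[:, None]
        ca, sa = np.cos(ang), np.sin(ang)
        x, y = pts[..., 0].copy(), pts[..., 1].copy()
        pts[..., 0] = ca * x - sa * y
        pts[..., 1] = sa * x + ca * y

    if config.rigid_motion and state in config.rigid_motion:
        rotvec, trans = config.rigid_motion[state]
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        pts = pts @ R.T + np.asarray(trans, dtype=float)

    if config.noise_sd > 0:
        pts = pts + rng.normal(0.0, config.noise_sd, size=pts.shape)
    if config.dropout_rate > 0:
        mask = rng.random(n) < config.dropout_rate
        mask[0] = False
        for i in np.nonzero(mask)[0]:
            pts[i] = pts[i - 1]

    r_times = config.lead_in_s + rr * np.arange(config.n_cycles + 1)
    ecg = np.zeros(n)
    for tk in r_times:
        ecg += np.exp(-0.5 * ((t - tk) / config.ecg_r_width_s) ** 2)
    ecg += rng.normal(0.0, 0.01, size=n)

    g = np.where(active, _lvp_shape(config, tau), 0.0)
    lvp = config.lvp_dia + config.lvp_pulse * g
    rvp = config.rvp_dia + config.rvp_pulse * g
    cvp = config.cvp_mean + config.cvp_pulse * np.sin(2 * np.pi * tau)

    crystals = {lab: pts[:, i, :] for i, lab in enumerate(labels)}
    rec = ChannelRecording(
        sample_rate=fs, time=t, crystals=crystals,
        lvp=lvp, rvp=rvp, cvp=cvp, ecg=ecg, state_tag=state,
    )
    ed_idx = np.array([int(round(tk * fs)) for tk in r_times])
    es_idx = np.array(
        [int(round((tk + config.es_phase * rr) * fs)) for tk in r_times[:-1]]
    )
    return rec, ref, ed_idx, es_idx


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ChannelRecording, ChannelRecording, GroundTruth]:
    """Generate matched Baseline and TRA recordings plus their ground truth.

    The same config seed always yields bitwise-identical output; Baseline and
    TRA carry independent noise streams (each state is a separate acquisition).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_tra = (np.random.default_rng(s) for s in ss.spawn(2))
    baseline, ref_base, ed_idx, es_idx = _state_recording(
        config, "Baseline", 1.0, rng_base
    )
    tra, ref_tra, _, _ = _state_recording(
        config, "TRA", config.tra_ring_scale, rng_tra
    )
    s2 = config.tra_ring_scale**2
    truth = GroundTruth(
        config=config,
        layout=config.layout(),
        ed_indices=ed_idx,
        es_indices=es_idx,
        rr_s=config.rr_s,
        ref_positions={"Baseline": ref_base, "TRA": ref_tra},
        annular_area_mm2={
            "Baseline": _hexagon_area(config.ring_radius),
            "TRA": _hexagon_area(config.ring_radius) * s2,
        },
        taa_reduction_pct=100.0 * (1.0 - s2),
        hull_volume_bound_ml=(2.0 / 3.0) * math.pi * config.a0 * config.b0
        * config.c0 / 1000.0,
        long_axis=np.array([0.0, 0.0, -1.0]),
    )
    return baseline, tra, truth


def analytic_truth(
    config: PhantomConfig,
    ref_vertices: np.ndarray,
    faces: np.ndarray,
    tau: float,
    long_axis: np.ndarray = (0.0, 0.0, -1.0),
) -> dict[str, np.ndarray]:
    """Closed-form per-face strains of the affine phantom deformation at ``tau``.

    For each face of the (noise-free, end-diastolic) reference mesh the
    directional strain along an in-plane unit direction d is
    ``(|A(tau) d|^2 - 1)/2`` and the areal strain is the exact triangle-area
    ratio under A minus 1.  Returns arrays keyed ``e_cc``, ``e_ll``, ``areal``.
    """
    if config.twist_deg != 0.0:
        raise ParameterError("analytic truth requires the affine phantom (twist off)")
    from .mesh import SurfaceMesh
    from .strain import material_directions

    ref_vertices = np.asarray(ref_vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    mesh = SurfaceMesh(
        vertices=ref_vertices,
        faces=faces,
        face_region=tuple("?" for _ in range(len(faces))),
        vertex_labels=tuple(str(i) for i in range(len(ref_vertices))),
    )
    _, _, c3, l3 = material_directions(mesh, np.asarray(long_axis, dtype=float))
    A = deformation_matrix(config, float(tau))
    out = {}
    for name, d3 in (("e_cc", c3), ("e_ll", l3)):
        lam2 = np.einsum("ij,ij->i", d3 @ A.T, d3 @ A.T)
        out[name] = 0.5 * (lam2 - 1.0)
    u = ref_vertices[faces[:, 1]] - ref_vertices[faces[:, 0]]
    w = ref_vertices[faces[:, 2]] - ref_vertices[faces[:, 0]]
    area0 = np.linalg.norm(np.cross(u, w), axis=1)
    area1 = np.linalg.norm(np.cross(u @ A.T, w @ A.T), axis=1)
    out["areal"] = area1 / area0 - 1.0
    return out


def generate_cohort(
    n_pairs: int,
    seed: int,
    base_config: PhantomConfig | None = None,
    *,
    null: bool = False,
    heart_rate_sd: float = 20.0,
    ring_radius_sd: float = 1.5,
    size_cv: float = 0.05,
) -> list[tuple[ChannelRecording, ChannelRecording, GroundTruth]]:
    """A cohort of paired recordings with across-animal parameter variation.

    Each pair shares one animal's anatomy and heart rate (its own control);
    ``null=True`` removes the annuloplasty effect (``tra_ring_scale = 1``) so
    Baseline and TRA differ only by acquisition noise.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    cfg = base_config if base_config is not None else PhantomConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for k in range(n_pairs):
        hr = float(np.clip(rng.normal(cfg.heart_rate, heart_rate_sd), 60.0, 180.0))
        ring = float(max(rng.normal(cfg.ring_radius, ring_radius_sd), 5.0))
        scale = float(max(rng.normal(1.0, size_cv), 0.5))
        pair_cfg = replace(
            cfg,
            heart_rate=hr,
            ring_radius=ring,
            a0=cfg.a0 * scale,
            b0=cfg.b0 * scale,
            c0=cfg.c0 * scale,
            tra_ring_scale=1.0 if null else cfg.tra_ring_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(pair_cfg))
    return out
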