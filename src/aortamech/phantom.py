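"""Synthetic pulsating-vessel phantoms and simulated tensile records.

The cine phantom emulates an axial cine acquisition at the level of the
pulmonary trunk: 256x256 frames at ~1.1-1.25 mm/px, a bright quasi-elliptical
lumen of aneurysmal size (defaults: 28 x 24 mm semi-axes, i.e. a ~56 mm
vessel, slightly off-center and tilted as in a real field of view) whose
semi-axes follow a single-peaked cardiac cycle (fast systolic rise, slow
diastolic decay), Gaussian noise, optional flow-artifact corruption
(intra-lumen dropout patches and ghosting streaks) and an optional
neighbouring vessel abutting the lumen. Ground truth is analytic: the mask is
the exact rasterisation of the ellipse, areas are pi*a*b, perimeters use
Ramanujan's second approximation, and per-quadrant areas/arcs come from
elliptic-sector geometry, so every downstream stage can be verified against
closed-form values. ``sample_cohort`` draws a cohort of exams with randomised
geometry (size, tilt, position, pulsation, pixel spacing) for training and
agreement studies.

The tensile simulator inverts the engineering stress/strain relations: a
piecewise-linear sigma(eps) with configurable segment moduli is sampled on a
uniform strain grid and converted to force-displacement through
F = sigma * A0, l = l0 * (1 + eps), with optional additive stress noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elasticity import DEFAULT_LABEL_CYCLE
from .io import CineSequence, MaskSequence, PressurePair
from .tensile import TensileRecord

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "TensileSimConfig",
    "generate_phantom",
    "generate_tensile",
    "sample_cohort",
    "pulsation_waveform",
    "ellipse_perimeter_ramanujan",
]


def pulsation_waveform(n_frames: int, rise_fraction: float = 0.35) -> np.ndarray:
    """Normalised single-peaked cardiac waveform s(k) in [0, 1], length n_frames.

    Raised-cosine rise to the systolic peak followed by a slower raised-cosine
    decay back to diastole. Frame 0 is exact diastole (s=0) and the peak lands
    exactly on a sampled frame, so the sampled extrema equal the analytic ones.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    k_peak = max(1, round(rise_fraction * n_frames))
    k = np.arange(n_frames, dtype=float)
    s = np.empty(n_frames)
    rise = k <= k_peak
    s[rise] = 0.5 * (1 - np.cos(np.pi * k[rise] / k_peak))
    s[~rise] = 0.5 * (1 + np.cos(np.pi * (k[~rise] - k_peak) / (n_frames - k_peak)))
    return s


def ellipse_perimeter_ramanujan(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter (error ~1e-10 here)."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def _elliptic_sector_areas(a: float, b: float, start_deg: float) -> np.ndarray:
    """Areas of four 90-degree sectors of an ellipse about its center.

    Sector k spans geometric angles [start + 90k, start + 90(k+1)) in the
    ellipse frame. Uses the eccentric-anomaly substitution
    t = atan2(a sin(theta), b cos(theta)), under which the swept area is
    (a*b/2) * delta_t.
    """
    bounds = np.deg2rad(start_deg + 90.0 * np.arange(5))
    t = np.unwrap(np.arctan2(a * np.sin(bounds), b * np.cos(bounds)))
    return 0.5 * a * b * np.diff(t)


def _elliptic_sector_arcs(
    a: float, b: float, start_deg: float, n_steps: int = 16384
) -> np.ndarray:
    """Arc lengths of the four 90-degree sectors by dense polyline integration."""
    theta = np.deg2rad(start_deg) + np.linspace(0, 2 * np.pi, n_steps + 1)
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    x, y = r * np.cos(theta), r * np.sin(theta)
    seg = np.hypot(np.diff(x), np.diff(y))
    sector_of_seg = np.minimum((np.arange(n_steps) * 4) // n_steps, 3)
    return np.bincount(sector_of_seg, weights=seg, minlength=4)


@dataclass(frozen=True)
class PhantomConfig:
    """One synthetic exam; defaults are the emulated study conditions.

    256x256 frames at 1.17 mm/px (inside the 1.09-1.25 mm/px acquisition
    range), 30 frames per cardiac cycle, a pre-surgical aneurysmal lumen
    (semi-axes 28 x 24 mm at diastole, ~56 mm vessel), wall strain amplitude
    0.09 (the cohort's reported quadrant strains span ~0.07-0.10), cuff
    pressure 120/80 mmHg. The vessel sits slightly off-center and tilted, as
    in a real field of view. ``seed`` drives noise and artifacts only;
    geometry is explicit, so ground truth is deterministic given the config.
    """

    grid_size: int = 256
    pixel_spacing: float = 1.17
    n_frames: int = 30
    semi_axes_dia: tuple[float, float] = (28.0, 24.0)
    pulsation_fraction: float = 0.09
    tilt_deg: float = 25.0
    center_offset_px: tuple[float, float] = (-3.2, 2.7)
    noise_sd: float = 0.05
    artifact_level: float = 0.2
    neighbor_structures: bool = True
    pressures: tuple[float, float] = (120.0, 80.0)
    rotation_deg: float = 60.0
    rise_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 <= self.pulsation_fraction < 0.5):
            raise ValueError("pulsation_fraction must be in [0, 0.5)")
        sys_p, dia_p = self.pressures
        if not (sys_p > dia_p > 0):
            raise ValueError("require systolic > diastolic > 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        a, b = self.semi_axes_dia
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        peak_px = max(a, b) * (1 + self.pulsation_fraction) / self.pixel_spacing
        reach = peak_px + max(abs(self.center_offset_px[0]), abs(self.center_offset_px[1]))
        if reach > self.grid_size / 2 - 2:
            raise ValueError(
                f"vessel exceeds grid at peak dilation: reach {reach:.1f} px vs "
                f"half-grid {self.grid_size / 2} px"
            )

    @property
    def pressure_pair(self) -> PressurePair:
        return PressurePair(*self.pressures)

    @property
    def center(self) -> tuple[float, float]:
        """Lumen center (row, col) in px."""
        half = (self.grid_size - 1) / 2.0
        return (half + self.center_offset_px[0], half + self.center_offset_px[1])


def sample_cohort(
    n_exams: int, seed: int = 0, base: PhantomConfig | None = None
) -> list[PhantomConfig]:
    """Draw a cohort of exam configs with randomised patient geometry.

    Per exam: pixel spacing U(1.09, 1.25) mm/px, each semi-axis scaled
    U(0.9, 1.1), tilt U(0, 180) deg, center offset U(-8, 8) px per axis, and
    pulsation fraction U(0.06, 0.12) — vessels of different size, stiffness,
    orientation and position, which is what a segmentation model must cope
    with and what gives agreement statistics their between-subject variance.
    """
    base = base or PhantomConfig()
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_exams):
        a = base.semi_axes_dia[0] * rng.uniform(0.9, 1.1)
        b = base.semi_axes_dia[1] * rng.uniform(0.9, 1.1)
        configs.append(
            replace(
                base,
                pixel_spacing=float(rng.uniform(1.09, 1.25)),
                semi_axes_dia=(float(a), float(b)),
                tilt_deg=float(rng.uniform(0.0, 180.0)),
                center_offset_px=(float(rng.uniform(-8, 8)), float(rng.uniform(-8, 8))),
                pulsation_fraction=float(rng.uniform(0.06, 0.12)),
                seed=seed + i,
            )
        )
    return configs


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom exam.

    Areas in mm^2, perimeters/arcs in mm, centroids in (row, col) px.
    ``true_compliance`` and ``true_strain`` are derived exactly from the
    per-frame curves and the configured pressures.
    """

    area_per_frame: np.ndarray
    outer_perimeter_per_frame: np.ndarray
    centroid_per_frame: np.ndarray
    quadrant_areas: dict[str, np.ndarray]
    quadrant_arcs: dict[str, np.ndarray]
    pressures: PressurePair
    true_compliance: float = field(init=False)
    true_strain: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_compliance = float(
            (self.area_per_frame.max() - self.area_per_frame.min()) / self.pressures.pulse
        )
        p_min = self.outer_perimeter_per_frame.min()
        self.true_strain = float((self.outer_perimeter_per_frame.max() - p_min) / p_min)

    @property
    def quadrant_compliance(self) -> dict[str, float]:
        return {
            lab: float((a.max() - a.min()) / self.pressures.pulse)
            for lab, a in self.quadrant_areas.items()
        }

    @property
    def quadrant_strain(self) -> dict[str, float]:
        return {
            lab: float((p.max() - p.min()) / p.min()) for lab, p in self.quadrant_arcs.items()
        }


def _render_frame(
    cfg: PhantomConfig,
    a_px: float,
    b_px: float,
    rho: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One intensity frame: soft-edged bright lumen over tissue background."""
    n = cfg.grid_size
    bg, fg = 0.15, 0.9
    # soft edge ~1 px wide on the normalized elliptical radius
    edge_scale = 1.0 / max(min(a_px, b_px), 1.0)
    frame = bg + (fg - bg) / (1.0 + np.exp((rho - 1.0) / edge_scale))

    cr, c0 = cfg.center
    t = np.deg2rad(cfg.tilt_deg)
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    if cfg.neighbor_structures:
        # pulmonary-artery analog: a circle abutting the lumen on its -a side
        r_nb = 0.55 * b_px
        gap = a_px + r_nb + 1.0
        nb = (cr + gap * np.sin(t), c0 - gap * np.cos(t))
        d = np.hypot(rr - nb[0], cc - nb[1]) / r_nb
        frame += (0.75 - bg) / (1.0 + np.exp((d - 1.0) * r_nb))

    if cfg.artifact_level > 0:
        # intra-lumen dropout patches (turbulent-flow signal voids)
        for _ in range(int(rng.integers(1, 4))):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.0, 0.6)
            pr = cr + rad * b_px * np.sin(ang)
            pc = c0 + rad * a_px * np.cos(ang)
            size = rng.uniform(0.1, 0.3) * min(a_px, b_px)
            d2 = ((rr - pr) ** 2 + (cc - pc) ** 2) / size**2
            frame -= cfg.artifact_level * 0.6 * np.exp(-d2)
        # ghosting streak: faint shifted replica along the phase-encode (row) axis
        shift = int(rng.integers(n // 8, n // 3))
        frame = frame + cfg.artifact_level * 0.15 * np.roll(frame, shift, axis=0)

    if cfg.noise_sd > 0:
        frame = frame + rng.normal(0.0, cfg.noise_sd, size=frame.shape)
    return np.clip(frame, 0.0, 1.5)


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[CineSequence, MaskSequence, PhantomTruth]:
    """Generate one phantom exam: cine frames, exact masks, analytic truth.

    The mask of each frame is the exact rasterisation of the analytic tilted
    ellipse (pixel centers inside); noise, artifacts and neighbouring
    structures only affect intensities, never the masks or the truth.
    Identical configs (same seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.grid_size
    s = pulsation_waveform(cfg.n_frames, cfg.rise_fraction)
    scale = 1.0 + cfg.pulsation_fraction * s
    a_mm = cfg.semi_axes_dia[0] * scale
    b_mm = cfg.semi_axes_dia[1] * scale
    cr, c0 = cfg.center
    t = np.deg2rad(cfg.tilt_deg)

    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    dx = cc - c0
    dy = -(rr - cr)  # y-up image convention, same as the quadrant partition
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    frames = np.empty((cfg.n_frames, n, n), dtype=np.float32)
    masks = np.empty((cfg.n_frames, n, n), dtype=np.uint8)
    for k in range(cfg.n_frames):
        a_px = a_mm[k] / cfg.pixel_spacing
        b_px = b_mm[k] / cfg.pixel_spacing
        rho = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
        masks[k] = (rho <= 1.0).astype(np.uint8)
        frames[k] = _render_frame(cfg, a_px, b_px, rho, rng)

    areas = np.pi * a_mm * b_mm
    perimeters = np.array(
        [ellipse_perimeter_ramanujan(a_mm[k], b_mm[k]) for k in range(cfg.n_frames)]
    )
    # sector boundaries sit at rotation_deg + 90k in image angles; in the
    # ellipse frame that is rotation_deg - tilt_deg + 90k
    start = cfg.rotation_deg - cfg.tilt_deg
    quad_areas = {lab: np.empty(cfg.n_frames) for lab in DEFAULT_LABEL_CYCLE}
    quad_arcs = {lab: np.empty(cfg.n_frames) for lab in DEFAULT_LABEL_CYCLE}
    for k in range(cfg.n_frames):
        sector_areas = _elliptic_sector_areas(a_mm[k], b_mm[k], start)
        sector_arcs = _elliptic_sector_arcs(a_mm[k], b_mm[k], start)
        for j, lab in enumerate(DEFAULT_LABEL_CYCLE):
            quad_areas[lab][k] = sector_areas[j]
            quad_arcs[lab][k] = sector_arcs[j]

    exam_id = f"phantom-{cfg.seed:04d}"
    spacing = (cfg.pixel_spacing, cfg.pixel_spacing)
    seq = CineSequence(
        frames=frames,
        pixel_spacing=spacing,
        frame_times=np.arange(cfg.n_frames) * 30.0,  # ~30 ms temporal resolution
        exam_id=exam_id,
    )
    mask_seq = MaskSequence(frames=masks, pixel_spacing=spacing, exam_id=exam_id)
    truth = PhantomTruth(
        area_per_frame=areas,
        outer_perimeter_per_frame=perimeters,
        centroid_per_frame=np.tile((cr, c0), (cfg.n_frames, 1)),
        quadrant_areas=quad_areas,
        quadrant_arcs=quad_arcs,
        pressures=cfg.pressure_pair,
    )
    return seq, mask_seq, truth


@dataclass(frozen=True)
class TensileSimConfig:
    """Piecewise-linear stress-strain simulator settings.

    ``modulus_segments`` lists ((eps_start, eps_end), E_MPa) pieces that must
    tile [0, ...] contiguously; the last piece extends to ``strain_max``.
    Sample geometry defaults to the 15 mm square cut with 2 mm wall thickness.
    The default bilinear curve (soft elastin branch, stiffer collagen branch)
    is in the reported range of aneurysmal wall moduli (~0.3-1.2 MPa).
    """

    modulus_segments: tuple[tuple[tuple[float, float], float], ...] = (
        ((0.0, 0.1), 0.3),
        ((0.1, 0.3), 1.2),
    )
    strain_max: float = 0.3
    n_samples: int = 300
    l0: float = 15.0
    thickness: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modulus_segments:
            raise ValueError("modulus_segments must not be empty")
        prev_end = 0.0
        for (start, end), e_mod in self.modulus_segments:
            if not np.isclose(start, prev_end):
                raise ValueError("strain intervals must be contiguous from 0")
            if end <= start:
                raise ValueError("strain intervals must have positive width")
            if e_mod <= 0:
                raise ValueError("segment moduli must be positive")
            prev_end = end
        if self.l0 <= 0 or self.thickness <= 0:
            raise ValueError("l0 and thickness must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.strain_max <= 0:
            raise ValueError("strain_max must be positive")


def piecewise_linear_stress(strain: np.ndarray, cfg: TensileSimConfig) -> np.ndarray:
    """Noise-free sigma(eps) implied by the configured segment moduli, MPa."""
    strain = np.asarray(strain, dtype=float)
    stress = np.zeros_like(strain)
    base_stress = 0.0
    last_end, last_e = 0.0, cfg.modulus_segments[-1][1]
    for (start, end), e_mod in cfg.modulus_segments:
        sel = (strain >= start) & (strain <= end)
        stress[sel] = base_stress + e_mod * (strain[sel] - start)
        base_stress += e_mod * (end - start)
        last_end = end
    beyond = strain > last_end
    stress[beyond] = base_stress + last_e * (strain[beyond] - last_end)
    return stress


def generate_tensile(cfg: TensileSimConfig) -> TensileRecord:
    """Simulate one tensile pull consistent with the configured moduli.

    The strain grid is uniform on [0, strain_max]; stress noise (MPa, Gaussian,
    seeded) is added before inversion to force F = sigma * A0 and displacement
    l - l0 = eps * l0, so downstream analysis sees realistic machine records.
    """
    rng = np.random.default_rng(cfg.seed)
    strain = np.linspace(0.0, cfg.strain_max, cfg.n_samples)
    stress = piecewise_linear_stress(strain, cfg)
    if cfg.noise_sd > 0:
        stress = stress + rng.normal(0.0, cfg.noise_sd, size=stress.shape)
    a0 = cfg.thickness * cfg.l0
    return TensileRecord(
        displacement_mm=strain * cfg.l0,
        force_n=stress * a0,
        l0=cfg.l0,
        thickness=cfg.thickness,
        axis="axis1",
    )
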