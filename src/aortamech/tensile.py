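"""Ex-vivo biaxial tensile analysis of aortic wall samples.

Square wall samples (15 x 15 mm, preconditioned by repeated 10% stretch
cycles) are pulled to rupture; the machine records force vs displacement per
axis. Engineering strain and stress are

    eps = (l - l0) / l0          sigma = F / A0,   A0 = thickness * l0,

so sigma is in MPa when F is in N and lengths in mm. The Young's modulus
curve E(eps) is the tangent modulus d(sigma)/d(eps) (the literal secant ratio
sigma/eps is available as an option). Two summary moduli are reported:

* ``E_max`` — the maximum of the modulus curve, reached on the stiff
  collagen-dominated branch;
* ``E_phys`` — the mean modulus over the physiological stress window, the
  wall stresses spanned by the patient's diastolic-to-systolic pressure
  under a thin-wall (Laplace) hoop-stress mapping sigma = P r / t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import PressurePair

__all__ = [
    "MMHG_TO_MPA",
    "TensileRecord",
    "StressStrainCurve",
    "ModulusResult",
    "engineering_strain",
    "engineering_stress",
    "stress_strain_curve",
    "modulus_curve",
    "max_youngs_modulus",
    "physiological_youngs_modulus",
    "hoop_stress_mpa",
    "trim_preconditioning",
    "load_tensile_csv",
    "save_tensile_csv",
]

#: 1 mmHg in MPa.
MMHG_TO_MPA = 1.33322e-4


def engineering_strain(l: np.ndarray | float, l0: float) -> np.ndarray | float:
    """Engineering strain (l - l0) / l0 for deformed length l and rest length l0."""
    if l0 <= 0:
        raise ValueError("rest length l0 must be positive")
    return (np.asarray(l, dtype=float) - l0) / l0 if np.ndim(l) else (l - l0) / l0


def engineering_stress(force: np.ndarray | float, a0: float) -> np.ndarray | float:
    """Engineering stress F / A0 in MPa (N over mm^2)."""
    if a0 <= 0:
        raise ValueError("reference cross-section A0 must be positive")
    return np.asarray(force, dtype=float) / a0 if np.ndim(force) else force / a0


@dataclass
class TensileRecord:
    """Raw force-displacement samples for one stretch axis of one sample.

    ``l0`` is the post-preconditioning rest length (mm) and ``thickness`` the
    load-free wall thickness (mm); the reference section is A0 = thickness*l0.
    """

    displacement_mm: np.ndarray
    force_n: np.ndarray
    l0: float = 15.0
    thickness: float = 2.0
    axis: str = "axis1"

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.displacement_mm.shape != self.force_n.shape or self.displacement_mm.ndim != 1:
            raise ValueError("displacement and force must be 1D arrays of equal length")
        if np.any(np.diff(self.displacement_mm) < 0):
            raise ValueError("displacement must be non-decreasing (monotone stretch)")
        if self.l0 <= 0 or self.thickness <= 0:
            raise ValueError("l0 and thickness must be positive")

    @property
    def a0(self) -> float:
        """Reference cross-sectional area thickness * l0, mm^2."""
        return self.thickness * self.l0


@dataclass
class StressStrainCurve:
    """Paired engineering strain (dimensionless) and stress (MPa), strain strictly increasing."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1D arrays of equal length")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress contains non-finite values")


def stress_strain_curve(record: TensileRecord) -> StressStrainCurve:
    """Convert a force-displacement record into an engineering stress-strain curve.

    Samples sharing the same strain (machine dwell points) are collapsed by
    averaging their stress, so the returned strain grid is strictly increasing.
    """
    strain = engineering_strain(record.l0 + record.displacement_mm, record.l0)
    stress = engineering_stress(record.force_n, record.a0)
    uniq, inverse = np.unique(np.round(strain, 12), return_inverse=True)
    if uniq.size < 2:
        raise ValueError("record collapses to a single strain value")
    mean_stress = np.bincount(inverse, weights=stress) / np.bincount(inverse)
    return StressStrainCurve(strain=uniq, stress=mean_stress)


@dataclass
class ModulusResult:
    """Tangent-modulus curve with its summary values.

    ``modulus`` is E(eps) on the ``strain`` grid; ``stress`` is the (smoothed)
    stress at the same samples, used to locate the physiological window.
    """

    strain: np.ndarray
    stress: np.ndarray
    modulus: np.ndarray
    smoothing_window: int
    mode: str = "tangent"

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "smoothing_window": self.smoothing_window,
            "e_max_mpa": max_youngs_modulus(self),
            "n_samples": int(self.strain.size),
        }


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def modulus_curve(
    curve: StressStrainCurve, smoothing_window: int = 11, mode: str = "tangent"
) -> ModulusResult:
    """Young's modulus along the stress-strain curve.

    ``tangent`` (default): central finite differences of the moving-average
    smoothed stress — the local slope d(sigma)/d(eps). ``secant``: the literal
    ratio sigma/eps (zero-strain sample excluded from the max by +0 there).
    """
    if curve.strain.size < 3:
        raise ValueError("need at least 3 samples for a modulus curve")
    if mode not in ("tangent", "secant"):
        raise ValueError(f"mode must be 'tangent' or 'secant', got {mode!r}")
    stress_s = _moving_average(curve.stress, smoothing_window)
    if mode == "tangent":
        modulus = np.gradient(stress_s, curve.strain)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            modulus = np.where(curve.strain > 0, stress_s / curve.strain, 0.0)
    return ModulusResult(
        strain=curve.strain.copy(),
        stress=stress_s,
        modulus=modulus,
        smoothing_window=smoothing_window,
        mode=mode,
    )


def max_youngs_modulus(result: ModulusResult) -> float:
    """Maximum of the modulus curve (stiffest branch), MPa."""
    return float(np.max(result.modulus))


def hoop_stress_mpa(pressure_mmhg: float, radius_mm: float, wall_thickness_mm: float) -> float:
    """Thin-wall (Laplace) circumferential stress sigma = P r / t, in MPa."""
    if radius_mm <= 0 or wall_thickness_mm <= 0:
        raise ValueError("radius and wall thickness must be positive")
    return pressure_mmhg * MMHG_TO_MPA * radius_mm / wall_thickness_mm


def physiological_youngs_modulus(
    result: ModulusResult,
    pressures: PressurePair,
    radius_mm: float,
    wall_thickness_mm: float,
) -> float:
    """Mean modulus over the blood-pressure-derived stress window, MPa.

    The window is [sigma(P_dia), sigma(P_sys)] with the thin-wall hoop-stress
    mapping; samples whose (smoothed) stress falls inside are averaged. An
    empty window means the tensile curve never reaches physiological stresses.
    """
    lo = hoop_stress_mpa(pressures.diastolic, radius_mm, wall_thickness_mm)
    hi = hoop_stress_mpa(pressures.systolic, radius_mm, wall_thickness_mm)
    inside = (result.stress >= lo) & (result.stress <= hi)
    if not inside.any():
        raise ValueError(
            f"no stress samples inside the physiological window [{lo:.4f}, {hi:.4f}] MPa; "
            f"curve spans [{result.stress.min():.4f}, {result.stress.max():.4f}] MPa — "
            "check the curve extent or the radius/thickness geometry"
        )
    return float(result.modulus[inside].mean())


def trim_preconditioning(
    displacement_mm: np.ndarray, force_n: np.ndarray, force_floor_n: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Drop leading preconditioning cycles from a raw machine record.

    Finds the last sample where force returns to (near) zero before the final
    monotone pull and keeps everything from there on, rebasing displacement
    to start at zero.
    """
    displacement_mm = np.asarray(displacement_mm, dtype=float)
    force_n = np.asarray(force_n, dtype=float)
    near_zero = np.nonzero(force_n <= force_floor_n)[0]
    start = int(near_zero[-1]) if near_zero.size else 0
    return displacement_mm[start:] - displacement_mm[start], force_n[start:]


def save_tensile_csv(record: TensileRecord, path: str | Path) -> Path:
    """Write ``displacement_mm, force_N`` CSV plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"displacement_mm": record.displacement_mm, "force_N": record.force_n}
    ).to_csv(path, index=False)
    meta = {"l0_mm": record.l0, "thickness_mm": record.thickness, "axis": record.axis}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def load_tensile_csv(path: str | Path) -> TensileRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return TensileRecord(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_n=df["force_N"].to_numpy(),
        l0=float(meta.get("l0_mm", 15.0)),
        thickness=float(meta.get("thickness_mm", 2.0)),
        axis=str(meta.get("axis", "axis1")),
    )


def modulus_report_json(result: ModulusResult, path: str | Path, **extra: float) -> Path:
    path = Path(path)
    payload = result.to_json_dict() | extra
    path.write_text(json.dumps(payload, indent=2))
    return path
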