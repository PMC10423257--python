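"""Activity partitioning, LED dose maps, VOI dosimetry and partition-model planning.

The dose model is local energy deposition (LED): each voxel's 90Y activity
deposits its energy entirely within that voxel, so absorbed dose is simply
``50 Gy per GBq/kg`` of local activity concentration.  The administered
activity is partitioned over the whole grid proportionally to voxel
intensity, which makes dosimetry invariant to the emission image's absolute
calibration; the fraction of signal falling outside the liver VOI is
reported as a spill-out diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import ImageGrid

#: LED conversion constant for 90Y, Gy per (GBq of activity per kg of tissue)
LED_GY_PER_GBQ_KG = 50.0

#: physical half-life of 90Y in hours
Y90_HALF_LIFE_HOURS = 64.05

#: default soft-tissue density, g/mL
DEFAULT_DENSITY_G_PER_ML = 1.03


@dataclass
class ActivityMap:
    """Voxelized activity (GBq per voxel) after partitioning."""

    voxel_activity_GBq: np.ndarray
    spacing_mm: tuple[float, float, float]
    administered_GBq: float
    out_of_liver_fraction: float
    decay_corrected: bool = True

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class DoseMap:
    """Voxelized absorbed dose (Gy) under LED."""

    voxel_dose_Gy: np.ndarray
    spacing_mm: tuple[float, float, float]
    density_g_per_mL: float
    conversion_factor_Gy_kg_per_GBq: float = LED_GY_PER_GBQ_KG

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class DoseRecord:
    """Per-VOI dosimetry summary."""

    voi_id: int
    role: str
    volume_mL: float
    mass_kg: float
    mean_dose_Gy_uncorrected: float
    source: str = "delivered"  # predicted | delivered
    rc_applied: float | None = None
    mean_dose_Gy_corrected: float | None = None

    def with_rc(self, rc: float) -> "DoseRecord":
        """Return a copy with the recovery coefficient applied to the mean dose."""
        from .pvc import correct_dose

        return replace(self, rc_applied=rc,
                       mean_dose_Gy_corrected=correct_dose(
                           self.mean_dose_Gy_uncorrected, rc))

    @property
    def mean_dose_Gy(self) -> float:
        """RC-corrected mean dose when available, else uncorrected."""
        if self.mean_dose_Gy_corrected is not None:
            return self.mean_dose_Gy_corrected
        return self.mean_dose_Gy_uncorrected


@dataclass
class PartitionPlan:
    """Compartmental split of administered activity among tumor and normal liver."""

    administered_GBq: float
    shunt_fraction: float
    tn_ratio: float
    tumor_mass_kg: float
    normal_mass_kg: float
    tumor_activity_GBq: float
    normal_activity_GBq: float
    tumor_dose_Gy: float
    normal_dose_Gy: float


def decay_correct(measured_GBq: float, delta_t_hours: float,
                  half_life_hours: float = Y90_HALF_LIFE_HOURS) -> float:
    """Correct a measured activity back to administration time.

    ``measured * 2**(delta_t / half_life)`` — activity measured
    ``delta_t_hours`` after administration is scaled up by the decay that
    occurred in between.
    """
    if measured_GBq < 0:
        raise ValueError("measured activity must be non-negative")
    if delta_t_hours < 0:
        raise ValueError("delta_t_hours must be non-negative")
    if half_life_hours <= 0:
        raise ValueError("half life must be positive")
    return measured_GBq * 2.0 ** (delta_t_hours / half_life_hours)


def build_activity_map(image: ImageGrid, administered_GBq: float,
                       liver_mask: np.ndarray | None = None,
                       decay_corrected: bool = True) -> ActivityMap:
    """Partition the administered activity proportionally to voxel intensity.

    Partitioning runs over the *whole* grid; signal imaged outside the liver
    therefore dilutes in-liver doses, and the spilled fraction is reported
    in ``out_of_liver_fraction`` so it can be checked against the expected
    few-percent level.
    """
    if administered_GBq <= 0:
        raise ValueError("administered activity must be positive")
    values = image.values
    if np.any(values < 0):
        raise ValueError("emission image must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("emission image has zero total signal")
    activity = administered_GBq * (values / total)
    if liver_mask is not None:
        spill = float(activity[~np.asarray(liver_mask, bool)].sum()) / administered_GBq
    else:
        spill = 0.0
    return ActivityMap(activity, image.spacing_mm, administered_GBq, spill,
                       decay_corrected=decay_corrected)


def led_dose_map(am: ActivityMap,
                 density_g_per_mL: float = DEFAULT_DENSITY_G_PER_ML) -> DoseMap:
    """Convert an activity map to absorbed dose under local energy deposition."""
    if density_g_per_mL <= 0:
        raise ValueError("density must be positive")
    voxel_mass_kg = density_g_per_mL * am.voxel_volume_mL / 1000.0
    dose = LED_GY_PER_GBQ_KG * am.voxel_activity_GBq / voxel_mass_kg
    return DoseMap(dose, am.spacing_mm, density_g_per_mL)


def voi_dose(dm: DoseMap, mask: np.ndarray, voi_id: int = 0,
             role: str = "lesion", source: str = "delivered") -> DoseRecord:
    """Mean absorbed dose, volume and mass over one VOI mask."""
    mask = np.asarray(mask, bool)
    if mask.shape != dm.voxel_dose_Gy.shape:
        raise ValueError("mask and dose map shapes differ")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty VOI mask")
    volume_mL = n * dm.voxel_volume_mL
    mass_kg = volume_mL * dm.density_g_per_mL / 1000.0
    return DoseRecord(voi_id=voi_id, role=role, volume_mL=volume_mL,
                      mass_kg=mass_kg,
                      mean_dose_Gy_uncorrected=float(dm.voxel_dose_Gy[mask].mean()),
                      source=source)


def tumor_to_normal_ratio(am: ActivityMap, tumor_mask: np.ndarray,
                          normal_mask: np.ndarray) -> float:
    """Ratio of mean activity concentration, tumor over normal liver."""
    tumor_mask = np.asarray(tumor_mask, bool)
    normal_mask = np.asarray(normal_mask, bool)
    if not tumor_mask.any() or not normal_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(tumor_mask & normal_mask):
        raise ValueError("tumor and normal masks overlap")
    normal = am.voxel_activity_GBq[normal_mask].mean()
    if normal <= 0:
        raise ValueError("normal-liver uptake is zero")
    return float(am.voxel_activity_GBq[tumor_mask].mean() / normal)


def partition_model_plan(administered_GBq: float, tn_ratio: float,
                         tumor_mass_kg: float, normal_mass_kg: float,
                         shunt_fraction: float = 0.0) -> PartitionPlan:
    """Split activity between tumor and normal liver by the partition model.

    With uptake ratio ``r`` and masses ``m_T``, ``m_N``, the non-shunted
    activity divides as ``A_T : A_N = r m_T : m_N``; doses follow from the
    LED constant, so ``D_T / D_N = r`` always.
    """
    if administered_GBq <= 0:
        raise ValueError("administered activity must be positive")
    if tn_ratio <= 0:
        raise ValueError("tn_ratio must be positive")
    if tumor_mass_kg <= 0 or normal_mass_kg <= 0:
        raise ValueError("compartment masses must be positive")
    if not 0 <= shunt_fraction < 1:
        raise ValueError("shunt fraction must be in [0, 1)")
    in_liver = administered_GBq * (1.0 - shunt_fraction)
    denom = tn_ratio * tumor_mass_kg + normal_mass_kg
    a_t = in_liver * tn_ratio * tumor_mass_kg / denom
    a_n = in_liver * normal_mass_kg / denom
    return PartitionPlan(administered_GBq, shunt_fraction, tn_ratio,
                         tumor_mass_kg, normal_mass_kg, a_t, a_n,
                         LED_GY_PER_GBQ_KG * a_t / tumor_mass_kg,
                         LED_GY_PER_GBQ_KG * a_n / normal_mass_kg)


def activity_for_normal_dose(target_normal_dose_Gy: float, tn_ratio: float,
                             tumor_mass_kg: float, normal_mass_kg: float,
                             shunt_fraction: float = 0.0) -> float:
    """Inverse planning: administered activity reaching a normal-liver dose."""
    if target_normal_dose_Gy <= 0:
        raise ValueError("target dose must be positive")
    if tn_ratio <= 0 or tumor_mass_kg <= 0 or normal_mass_kg <= 0:
        raise ValueError("degenerate plan parameters")
    if not 0 <= shunt_fraction < 1:
        raise ValueError("shunt fraction must be in [0, 1)")
    denom = tn_ratio * tumor_mass_kg + normal_mass_kg
    return target_normal_dose_Gy * denom / (
        LED_GY_PER_GBQ_KG * (1.0 - shunt_fraction))
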