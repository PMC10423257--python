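"""Recovery-coefficient partial-volume correction.

Recovery coefficients (RC) are measured on phantom acquisitions as the
ratio of measured to expected mean activity concentration in each sphere
insert; equivalently the ratio of measured to expected total activity over
the same mask, since both share the identical mask volume.  Lesion mean
doses are then divided by the RC interpolated at the lesion volume.  Only
VOI mean values are corrected — there is no voxel-level deconvolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .grids import ImageGrid, VOISet


@dataclass
class RCNode:
    diameter_mm: float
    volume_mL: float
    rc: float


@dataclass
class RCCurve:
    """Size-indexed recovery coefficients for one modality.

    Nodes are stored as measured (noisy acquisitions may exceed 1 at large
    spheres); :func:`rc_lookup` clamps its output to (0, 1].
    """

    modality: str
    nodes: list[RCNode]
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = sorted(self.nodes, key=lambda n: n.volume_mL)
        vols = [n.volume_mL for n in self.nodes]
        if any(v <= 0 for v in vols) or any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("node volumes must be positive and strictly increasing")
        if any(n.rc <= 0 for n in self.nodes):
            raise ValueError("recovery coefficients must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "modality": self.modality,
            "acquisition": self.acquisition,
            "nodes": [{"diameter_mm": n.diameter_mm, "volume_mL": n.volume_mL,
                       "rc": n.rc} for n in self.nodes],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RCCurve":
        data = json.loads(Path(path).read_text())
        nodes = [RCNode(n["diameter_mm"], n["volume_mL"], n["rc"])
                 for n in data["nodes"]]
        return cls(data["modality"], nodes, data.get("acquisition", {}))


def sphere_volume_mL(diameter_mm: float) -> float:
    """Analytic volume of a sphere, (pi/6) d^3, in mL."""
    return float(np.pi / 6.0 * diameter_mm ** 3 / 1000.0)


def compute_rc(measured: ImageGrid, truth_vois: VOISet,
               expected_conc: Mapping[int, float], modality: str | None = None,
               acquisition: dict | None = None) -> RCCurve:
    """Derive an RC curve from a phantom acquisition.

    One RC per sphere insert: mean measured concentration over the true
    sphere mask divided by the expected fill concentration.  The stated
    equivalence with the total-activity ratio over the same mask is checked
    as an internal consistency guard.
    """
    truth_vois.check_alignment(measured)
    nodes = []
    insert_ids = truth_vois.ids_by_role("sphere_insert")
    if not insert_ids:
        raise ValueError("VOI set contains no sphere inserts")
    for lid in insert_ids:
        mask = truth_vois.mask(lid)
        n = int(np.count_nonzero(mask))
        if n == 0:
            raise ValueError(f"sphere insert {lid} has an empty mask")
        expected = float(expected_conc[lid])
        if expected <= 0:
            raise ValueError(f"expected concentration for insert {lid} must be > 0")
        mean_meas = float(measured.values[mask].mean())
        rc = mean_meas / expected
        mask_volume = n * measured.voxel_volume_mL
        total_ratio = (float(measured.values[mask].sum()) * measured.voxel_volume_mL
                       ) / (expected * mask_volume)
        if not np.isclose(rc, total_ratio, rtol=1e-9, atol=0.0):
            raise AssertionError("mean-concentration and total-activity RC differ")
        diameter = truth_vois.labels[lid].diameter_mm
        volume = sphere_volume_mL(diameter) if diameter else mask_volume
        nodes.append(RCNode(diameter or 0.0, volume, rc))
    return RCCurve(modality or measured.modality, nodes, acquisition or {})


def rc_lookup(curve: RCCurve, lesion_volume_mL: float) -> float:
    """Interpolate an RC at a lesion volume.

    Linear in log-volume between nodes; clamped to the end nodes outside the
    calibrated range and to at most 1 (noisy large-sphere nodes can measure
    slightly above unity).
    """
    if not curve.nodes:
        raise ValueError("empty RC curve")
    if lesion_volume_mL <= 0:
        raise ValueError("lesion volume must be positive")
    log_v = np.log([n.volume_mL for n in curve.nodes])
    rcs = np.array([n.rc for n in curve.nodes])
    rc = float(np.interp(np.log(lesion_volume_mL), log_v, rcs))
    return min(rc, 1.0)


def correct_dose(mean_dose_Gy: float, rc: float) -> float:
    """Partial-volume correct a VOI mean dose: dose / RC.

    Because dose is linear in activity, this equals applying the RC to the
    VOI activity before the dose conversion.
    """
    if not 0 < rc <= 1:
        raise ValueError(f"rc must be in (0, 1], got {rc}")
    if mean_dose_Gy < 0:
        raise ValueError("mean dose must be non-negative")
    return mean_dose_Gy / rc
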