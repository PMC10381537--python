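"""Architectural root measures: RL, recovery rate, RLD, HMD, r_mean, CNR.

Definitions (reported units in parentheses):

* RL (cm) — total root length, the sum of node-to-node Euclidean segment
  lengths of the reconstruction.
* recovery rate (%) — 100 * RL / RL_ref, with RL_ref an independent
  reference length (a flatbed-scanner measurement, or the synthetic
  ground truth).
* RLD (cm cm^-3) — root length density, RL divided by the container
  volume.
* HMD (cm) — half-mean distance between neighboring roots, for randomly
  placed parallel roots (pi * RLD)^(-1/2).
* r_mean (mm) — length-weighted mean root radius (robust to uneven node
  spacing between reconstruction methods).
* CNR (-) — contrast-to-noise ratio of an intensity volume,
  (mean root signal - mean background) / background standard deviation,
  the background being the complement of a 1-voxel-dilated root mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .rootsystem import RootSystem
from .volume import Volume3D

__all__ = [
    "MeasureSet",
    "DEFAULT_CONTAINER_VOLUME_CM3",
    "compute_measures",
    "recovery_rate",
    "compute_cnr",
    "half_mean_distance",
]

# default experimental container: cylinder height 21 cm, inner diameter 5.6 cm
DEFAULT_CONTAINER_VOLUME_CM3 = float(np.pi * 2.8**2 * 21.0)


@dataclass
class MeasureSet:
    RL_cm: float
    RLD_cm_per_cm3: float
    HMD_cm: float
    r_mean_mm: float
    counts_per_order: dict[int, int]
    n_roots: int
    recovery_pct: Optional[float] = None
    CNR: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "RL": self.RL_cm,
            "RLD": self.RLD_cm_per_cm3,
            "HMD": self.HMD_cm,
            "r_mean": self.r_mean_mm,
            "# of roots": self.n_roots,
        }
        for order, n in sorted(self.counts_per_order.items()):
            d[f"# of order-{order} roots"] = n
        if self.recovery_pct is not None:
            d["Recovery rate"] = self.recovery_pct
        if self.CNR is not None:
            d["CNR"] = self.CNR
        return d


def half_mean_distance(rld_cm_per_cm3: float) -> float:
    """HMD = (pi * RLD)^(-1/2), in cm."""
    if rld_cm_per_cm3 <= 0:
        return float("inf")
    return float(1.0 / np.sqrt(np.pi * rld_cm_per_cm3))


def recovery_rate(rl_cm: float, rl_ref_cm: float) -> float:
    """Recovered root length against a reference measurement, in %."""
    if rl_ref_cm <= 0:
        raise ValidationError("reference root length must be positive")
    return 100.0 * rl_cm / rl_ref_cm


def compute_measures(
    rs: RootSystem,
    container_volume_cm3: float = DEFAULT_CONTAINER_VOLUME_CM3,
    reference_length_cm: Optional[float] = None,
    volume: Optional[Volume3D] = None,
    root_mask: Optional[Volume3D] = None,
) -> MeasureSet:
    """Compute the standard measure set for one reconstruction."""
    if container_volume_cm3 <= 0:
        raise ValidationError("container volume must be positive")
    rs.validate()
    rl_cm = rs.total_length_cm()
    rld = rl_cm / container_volume_cm3

    # length-weighted mean radius over segments (mm)
    wsum, lsum = 0.0, 0.0
    for _r, _i, a, b in rs.iter_segments():
        seg_len = float(np.linalg.norm(np.subtract(b.position, a.position)))
        wsum += seg_len * (a.radius + b.radius) / 2.0
        lsum += seg_len
    r_mean = wsum / lsum if lsum > 0 else 0.0

    counts = rs.counts_per_order()
    ms = MeasureSet(
        RL_cm=rl_cm,
        RLD_cm_per_cm3=rld,
        HMD_cm=half_mean_distance(rld),
        r_mean_mm=r_mean,
        counts_per_order=counts,
        n_roots=len(rs.roots),
    )
    if reference_length_cm is not None:
        ms.recovery_pct = recovery_rate(rl_cm, reference_length_cm)
    if volume is not None and root_mask is not None:
        ms.CNR = compute_cnr(volume, root_mask)
    return ms


def compute_cnr(vol: Volume3D, root_mask: Volume3D) -> float:
    """Contrast-to-noise ratio of an intensity image.

    Background = complement of the root mask dilated by one voxel (the
    margin excludes partial-volume boundary voxels).
    """
    mask = np.asarray(root_mask.data) > 0.5
    if not mask.any():
        raise ValidationError("empty root mask")
    dilated = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool))
    background = ~dilated
    if not background.any():
        raise ValidationError("empty background after dilation")
    data = np.asarray(vol.data, dtype=float)
    mu_root = float(data[mask].mean())
    mu_bg = float(data[background].mean())
    sd_bg = float(data[background].std())
    if sd_bg == 0:
        raise ValidationError("zero background variance: CNR undefined")
    return (mu_root - mu_bg) / sd_bg
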