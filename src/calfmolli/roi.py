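"""Per-compartment metrics from T1 maps and region masks.

The mid-calf analysis uses five muscle compartments — anterior (AM),
lateral (LM) and deep posterior (DM) muscle groups, soleus (SM) and
gastrocnemius (GM) — and three arteries: anterior tibial (AT), posterior
tibial (PT) and peroneal (PE).  For each compartment the map yields

* peak T1: the maximum T1 over valid in-mask voxels,
* mean T1: the arithmetic mean over valid in-mask voxels,
* min T1: the minimum,
* cross-sectional area: valid voxel count times the pixel area.

The averaged peak muscle T1 is the arithmetic mean of the five compartment
peaks; the blood-pool T1 is the mean of the per-artery peak T1 values over
whichever arteries have voxels.  Subject-level metrics default to the
bilateral average when both sides are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .t1fit import T1Map

logger = logging.getLogger(__name__)

MUSCLE_COMPARTMENTS = ("AM", "LM", "DM", "SM", "GM")
ARTERIES = ("AT", "PT", "PE")

__all__ = [
    "MUSCLE_COMPARTMENTS",
    "ARTERIES",
    "RegionSet",
    "CompartmentMetrics",
    "EmptyRegionError",
    "compartment_metrics",
    "average_peak_t1",
    "blood_pool_t1",
    "bilateral_average",
]


class EmptyRegionError(ValueError):
    """A region mask holds no valid voxels."""


class IncompleteSetError(ValueError):
    """A composite metric was requested without all five muscle compartments."""


@dataclass(frozen=True)
class RegionSet:
    """Named boolean masks on the map grid.

    ``labels`` maps region names (muscles from AM/LM/DM/SM/GM, arteries
    from AT/PT/PE, optionally ``leg``) to 2-D boolean rasters of a common
    shape; masks must be pairwise disjoint.
    """

    labels: Mapping[str, np.ndarray]
    pixel_spacing_mm: tuple[float, float] = (1.48, 1.48)
    side: str = "bilateral"

    def __post_init__(self) -> None:
        labels = {k: np.asarray(v, dtype=bool) for k, v in self.labels.items()}
        object.__setattr__(self, "labels", labels)
        shapes = {m.shape for m in labels.values()}
        if len(shapes) > 1:
            raise ValueError("all region masks must share one shape")
        stack = np.zeros(next(iter(shapes)), dtype=int) if shapes else None
        for name, m in labels.items():
            if stack is not None:
                stack += m
        if stack is not None and (stack > 1).any():
            raise ValueError("region masks overlap; regions must be disjoint")
        if self.side not in {"left", "right", "bilateral"}:
            raise ValueError(f"unknown side {self.side!r}")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.labels[name]

    def muscles(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.labels.items() if k in MUSCLE_COMPARTMENTS}

    def arteries(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.labels.items() if k in ARTERIES}

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass(frozen=True)
class CompartmentMetrics:
    compartment: str
    peak_t1_ms: float
    mean_t1_ms: float
    min_t1_ms: float
    csa_mm2: float
    n_voxels: int
    side: str = "bilateral"


def compartment_metrics(
    t1map: T1Map, mask: np.ndarray, pixel_spacing_mm: tuple[float, float],
    compartment: str = "", side: str = "bilateral",
) -> CompartmentMetrics:
    """Peak/mean/min T1 and cross-sectional area over one region.

    Invalid voxels are excluded from all statistics and from the voxel
    count (and hence from the area).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1map.shape:
        raise ValueError("mask shape must match the T1 map")
    sel = mask & t1map.valid
    vals = t1map.t1_ms[sel]
    if vals.size == 0:
        raise EmptyRegionError(
            f"region {compartment or '<unnamed>'} has no valid voxels"
        )
    area = vals.size * pixel_spacing_mm[0] * pixel_spacing_mm[1]
    return CompartmentMetrics(
        compartment=compartment,
        peak_t1_ms=float(vals.max()),
        mean_t1_ms=float(vals.mean()),
        min_t1_ms=float(vals.min()),
        csa_mm2=float(area),
        n_voxels=int(vals.size),
        side=side,
    )


def average_peak_t1(metrics: Iterable[CompartmentMetrics]) -> float:
    """Mean of the peak T1 over exactly the five muscle compartments."""
    by_name = {m.compartment: m for m in metrics}
    missing = [c for c in MUSCLE_COMPARTMENTS if c not in by_name]
    if missing or len(by_name) != len(MUSCLE_COMPARTMENTS):
        raise IncompleteSetError(
            f"need exactly {MUSCLE_COMPARTMENTS}, missing {missing}, "
            f"got {sorted(by_name)}"
        )
    return float(np.mean([by_name[c].peak_t1_ms for c in MUSCLE_COMPARTMENTS]))


def blood_pool_t1(t1map: T1Map, regions: RegionSet) -> tuple[float, int]:
    """Averaged peak blood-pool T1 over the available arteries.

    The peak is taken per artery, then averaged over arteries with at
    least one valid voxel.  Returns ``(t1_ms, n_arteries_used)``.
    """
    peaks = []
    for name, mask in regions.arteries().items():
        sel = mask & t1map.valid
        if sel.any():
            peaks.append(float(t1map.t1_ms[sel].max()))
        else:
            logger.warning("artery %s has no valid voxels; skipped", name)
    if not peaks:
        raise EmptyRegionError("no artery mask holds valid voxels")
    if len(peaks) < len(ARTERIES):
        warnings.warn(
            f"blood pool averaged over {len(peaks)} of {len(ARTERIES)} arteries",
            stacklevel=2,
        )
    return float(np.mean(peaks)), len(peaks)


def bilateral_average(left: CompartmentMetrics, right: CompartmentMetrics) -> CompartmentMetrics:
    """Element-wise mean of the two sides of one compartment."""
    if left.compartment != right.compartment:
        raise ValueError(
            f"compartment mismatch: {left.compartment!r} vs {right.compartment!r}"
        )
    return CompartmentMetrics(
        compartment=left.compartment,
        peak_t1_ms=0.5 * (left.peak_t1_ms + right.peak_t1_ms),
        mean_t1_ms=0.5 * (left.mean_t1_ms + right.mean_t1_ms),
        min_t1_ms=0.5 * (left.min_t1_ms + right.min_t1_ms),
        csa_mm2=0.5 * (left.csa_mm2 + right.csa_mm2),
        n_voxels=int(round(0.5 * (left.n_voxels + right.n_voxels))),
        side="bilateral",
    )
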