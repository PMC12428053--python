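"""Tissue-at-risk / core segmentation algorithms and hemisphere utilities.

Three algorithms partition brain tissue into hypoperfused (tissue at risk)
and core (non-viable) compartments:

``threshold``
    Hypoperfused = Tmax > 6 s.  Baseline = *mean* CBF over the entire
    brain-masked contralateral hemisphere; core = hypoperfused voxels with
    CBF below 30% of that mean.

``mirror``
    Hypoperfused as above.  The hypoperfusion lesion is mirrored across the
    midline into the contralateral hemisphere; baseline = *median* CBF inside
    that mirror ROI; core = hypoperfused voxels with CBF below 30% of the
    median.  (This is the published mirror-median procedure behind the
    vendor's "AI" product; no learned model is involved here.)

``isp``
    MTT-lesion = rMTT > 150%.  The lesion is split into disjoint
    compartments by the CBV cutoff (2 mL/100 g).  Dialect ``conventional``
    (default): core = low CBV (< cutoff), hypoperfused = high CBV — the
    standard core physiology.  Dialect ``as-printed`` swaps the two
    inequalities exactly as the source product description prints them;
    both are shipped because the printed rule inverts the conventional
    definition and the intended direction is unclear.

All inequalities are strict, exactly as printed.  "left" is the lower-index
half of the last array axis (array convention, not radiological).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .maps import PerfusionMaps, RelativeMaps

Side = Literal["left", "right"]

OUTSIDE = 0
LEFT = 1
RIGHT = 2

LR_AXIS = -1


@dataclass(frozen=True)
class HemisphereLabels:
    """Left/right partition of the brain mask about a mid-sagittal plane."""

    labels: np.ndarray  # int: OUTSIDE / LEFT / RIGHT
    midline: float      # voxel index along the left-right (last) axis

    def side_mask(self, side: Side) -> np.ndarray:
        return self.labels == (LEFT if side == "left" else RIGHT)

    def reflect_mask(self, mask: np.ndarray) -> np.ndarray:
        """Mirror a boolean mask across the midline plane."""
        mask = np.asarray(mask, dtype=bool)
        out = np.zeros_like(mask)
        idx = np.argwhere(mask)
        if idx.size == 0:
            return out
        nx = mask.shape[LR_AXIS]
        mirrored = np.rint(2.0 * self.midline - idx[:, -1]).astype(int)
        ok = (mirrored >= 0) & (mirrored < nx)
        idx = idx[ok]
        idx[:, -1] = mirrored[ok]
        out[tuple(idx.T)] = True
        return out


def split_hemispheres(
    brain_mask: np.ndarray,
    midline: float | None = None,
) -> HemisphereLabels:
    """Label brain voxels left/right of the mid-sagittal plane.

    The midline defaults to the mid-plane of the mask's bounding box along
    the last axis.  Voxels exactly on an integer midline plane are assigned
    to the left (rounding toward left).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    xs = np.nonzero(mask.any(axis=tuple(range(mask.ndim - 1))))[0]
    if midline is None:
        midline = (xs[0] + xs[-1]) / 2.0
    x_idx = np.arange(mask.shape[LR_AXIS])
    left_line = x_idx <= midline + 1e-9  # plane voxels round toward left
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask & left_line[np.newaxis, np.newaxis, :]] = LEFT
    labels[mask & ~left_line[np.newaxis, np.newaxis, :]] = RIGHT
    return HemisphereLabels(labels=labels, midline=float(midline))


def mask_volume_ml(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Volume of a boolean mask in mL (voxel count x voxel volume)."""
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds shared by the three segmentation algorithms."""

    tmax_threshold_s: float = 6.0
    rcbf_fraction: float = 0.30
    rmtt_threshold: float = 1.50
    cbv_cutoff: float = 2.0        # mL/100 g
    isp_dialect: Literal["conventional", "as-printed"] = "conventional"

    def __post_init__(self) -> None:
        if self.tmax_threshold_s <= 0 or self.rmtt_threshold <= 0 or self.cbv_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.rcbf_fraction < 1:
            raise ValueError("rCBF fraction must be in (0, 1)")
        if self.isp_dialect not in ("conventional", "as-printed"):
            raise ValueError(f"unknown ISP dialect {self.isp_dialect!r}")


@dataclass(frozen=True)
class LesionResult:
    """Hypoperfused and core masks + volumes from one algorithm."""

    algorithm: str
    side: Side
    hypo_mask: np.ndarray
    core_mask: np.ndarray
    hypo_ml: float
    core_ml: float
    baseline_cbf: float | None = None  # contralateral mean or mirror median
    union_ml: float | None = None      # ISP only: both compartments together
    flags: tuple[str, ...] = ()


def identify_pathological_side(
    tmax: np.ndarray,
    labels: HemisphereLabels,
    config: AlgorithmConfig | None = None,
    brain_mask: np.ndarray | None = None,
) -> tuple[Side, tuple[str, ...]]:
    """Side whose hemisphere holds the larger Tmax-threshold lesion volume.

    Ties are broken by the larger summed Tmax over the hemisphere, then
    "left".  Always returns a side; a ``no_lesion`` flag is raised when no
    voxel exceeds the threshold.
    """
    cfg = config or AlgorithmConfig()
    mask = brain_mask if brain_mask is not None else labels.labels != OUTSIDE
    lesion = (tmax > cfg.tmax_threshold_s) & mask
    flags: list[str] = []
    counts = {s: int(np.count_nonzero(lesion & labels.side_mask(s))) for s in ("left", "right")}
    if counts["left"] == counts["right"] == 0:
        flags.append("no_lesion")
    if counts["left"] != counts["right"]:
        side: Side = "left" if counts["left"] > counts["right"] else "right"
    else:
        sums = {s: float(tmax[mask & labels.side_mask(s)].sum()) for s in ("left", "right")}
        side = "left" if sums["left"] >= sums["right"] else "right"
    return side, tuple(flags)


def _contralateral(side: Side) -> Side:
    return "right" if side == "left" else "left"


def segment_cercare_threshold(
    maps: PerfusionMaps,
    labels: HemisphereLabels,
    config: AlgorithmConfig | None = None,
) -> LesionResult:
    """Tmax-lesion segmentation with a contralateral-hemisphere-mean CBF core."""
    cfg = config or AlgorithmConfig()
    mask = maps.brain_mask
    side, flags = identify_pathological_side(maps.tmax, labels, cfg, mask)
    hypo = (maps.tmax > cfg.tmax_threshold_s) & mask
    contra = labels.side_mask(_contralateral(side)) & mask
    if not contra.any():
        raise ValueError("empty contralateral hemisphere")
    baseline = float(maps.cbf[contra].mean())
    core = hypo & (maps.cbf < cfg.rcbf_fraction * baseline)
    return LesionResult(
        algorithm="threshold",
        side=side,
        hypo_mask=hypo,
        core_mask=core,
        hypo_ml=mask_volume_ml(hypo, maps.spacing),
        core_ml=mask_volume_ml(core, maps.spacing),
        baseline_cbf=baseline,
        flags=flags,
    )


def segment_cercare_mirror(
    maps: PerfusionMaps,
    labels: HemisphereLabels,
    config: AlgorithmConfig | None = None,
) -> LesionResult:
    """Tmax-lesion segmentation with a mirror-ROI-median CBF core.

    If the hypoperfusion lesion is empty the result is all-zero; if the
    mirrored ROI falls entirely outside the brain mask (midline lesions),
    the baseline falls back to the contralateral-hemisphere median and the
    result is flagged ``mirror_fallback``.
    """
    cfg = config or AlgorithmConfig()
    mask = maps.brain_mask
    side, flags = identify_pathological_side(maps.tmax, labels, cfg, mask)
    hypo = (maps.tmax > cfg.tmax_threshold_s) & mask
    flags = list(flags)
    if not hypo.any():
        core = np.zeros_like(hypo)
        baseline = None
    else:
        mirror_roi = labels.reflect_mask(hypo) & mask
        if mirror_roi.any():
            baseline = float(np.median(maps.cbf[mirror_roi]))
        else:
            contra = labels.side_mask(_contralateral(side)) & mask
            if not contra.any():
                raise ValueError("empty contralateral hemisphere")
            baseline = float(np.median(maps.cbf[contra]))
            flags.append("mirror_fallback")
        core = hypo & (maps.cbf < cfg.rcbf_fraction * baseline)
    return LesionResult(
        algorithm="mirror",
        side=side,
        hypo_mask=hypo,
        core_mask=core,
        hypo_ml=mask_volume_ml(hypo, maps.spacing),
        core_ml=mask_volume_ml(core, maps.spacing),
        baseline_cbf=baseline,
        flags=tuple(flags),
    )


def segment_isp(
    maps: PerfusionMaps,
    relative: RelativeMaps,
    labels: HemisphereLabels,
    config: AlgorithmConfig | None = None,
) -> LesionResult:
    """rMTT/CBV segmentation into disjoint core and hypoperfused compartments."""
    cfg = config or AlgorithmConfig()
    mask = maps.brain_mask
    side, flags = identify_pathological_side(maps.tmax, labels, cfg, mask)
    mtt_lesion = (relative.rmtt > cfg.rmtt_threshold) & mask
    low_cbv = maps.cbv < cfg.cbv_cutoff
    high_cbv = maps.cbv > cfg.cbv_cutoff
    if cfg.isp_dialect == "conventional":
        core = mtt_lesion & low_cbv
        hypo = mtt_lesion & ~low_cbv
    else:  # as-printed: core = high CBV, hypoperfused = low CBV
        core = mtt_lesion & high_cbv
        hypo = mtt_lesion & ~high_cbv
    union = mtt_lesion
    return LesionResult(
        algorithm="isp",
        side=side,
        hypo_mask=hypo,
        core_mask=core,
        hypo_ml=mask_volume_ml(hypo, maps.spacing),
        core_ml=mask_volume_ml(core, maps.spacing),
        baseline_cbf=None,
        union_ml=mask_volume_ml(union, maps.spacing),
        flags=flags,
    )
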