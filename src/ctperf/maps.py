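"""Voxelwise perfusion-map estimation from a 4D CTP series.

Pipeline per voxel, after baseline subtraction and linear resampling of all
curves to a common 1-s grid:

* CBV = (integral of the tissue curve / integral of the AIF) / k, mL/100 g
  (optionally with the AIF area rescaled to the VOF area as a partial-volume
  correction);
* CBF = 60 * max_t of the deconvolved scaled residue / k, mL/100 g/min;
* MTT = 60 * CBV / CBF where CBF > 0, else 0 (so the central volume
  principle holds in the output by construction);
* TTP = argmax of the tissue curve, s from scan start;
* Tmax = argmax of the residue curve, s (block-circulant mode makes this the
  tracer arrival delay);
* CTH = sd of the transit-time density of the residue, normalised at its
  peak so the estimate is delay-robust.

Voxels with no measurable contrast passage (non-positive curve area) get all
parameters 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .deconv import Mode, residue_matrix
from .simulate import CTPSeries, VascularInput


@dataclass(frozen=True)
class MapConfig:
    """Tunable parameters of the map-estimation stage."""

    grid_dt: float = 1.0            # s, common resampling grid
    truncation: float = 0.2         # SVD truncation fraction
    mode: Mode = "block-circulant"
    k: float = 1.0                  # density/hematocrit unit constant
    pvc: bool = False               # rescale AIF area to VOF area
    clip_negative_tac: bool = False
    compute_cth: bool = True
    arrival_fraction: float = 0.10  # AIF fraction defining bolus arrival


@dataclass(frozen=True)
class PerfusionMaps:
    """Voxelwise hemodynamic parameter maps on the series grid."""

    cbf: np.ndarray   # mL/100 g/min
    cbv: np.ndarray   # mL/100 g
    mtt: np.ndarray   # s
    ttp: np.ndarray   # s from scan start
    tmax: np.ndarray  # s
    brain_mask: np.ndarray
    spacing: tuple[float, float, float]
    cth: np.ndarray | None = None  # s

    def __post_init__(self) -> None:
        shape = self.brain_mask.shape
        for name in ("cbf", "cbv", "mtt", "ttp", "tmax"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} map does not share the mask grid")
            if np.any(arr[self.brain_mask] < 0):
                raise ValueError(f"{name} map has negative values inside the mask")


@dataclass(frozen=True)
class RelativeMaps:
    """Side-relative maps: each voxel divided by the mean of the parameter
    over the brain-masked contralateral hemisphere."""

    rcbf: np.ndarray
    rmtt: np.ndarray
    defined: np.ndarray                  # bool, False where the reference is 0
    reference_cbf: dict[str, float]      # per-side contralateral means
    reference_mtt: dict[str, float]


def tac_preprocess(
    series: CTPSeries,
    vascular: VascularInput | None = None,
    clip_negative: bool = False,
    arrival_fraction: float = 0.10,
) -> tuple[CTPSeries, slice]:
    """Subtract the pre-bolus baseline from every voxel curve.

    The baseline window is the set of frames acquired before the AIF first
    reaches ``arrival_fraction`` of its peak.  Without a vascular input the
    arrival is detected on the mean brain curve instead.  Returns the
    baseline-subtracted series and the window as a slice.

    Raises
    ------
    ValueError
        If no pre-bolus frame exists (the acquisition must start before
        contrast arrival; acquire a longer baseline).
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 time points")
    if vascular is not None:
        ref = np.interp(series.times, vascular.times, vascular.aif)
    else:
        ref = series.data[:, series.brain_mask].mean(axis=1)
        ref = ref - ref.min()
    peak = ref.max()
    if peak <= 0:
        window = slice(0, series.n_frames)  # flat series: everything is baseline
    else:
        above = np.nonzero(ref >= arrival_fraction * peak)[0]
        first = int(above[0])
        if first == 0:
            raise ValueError(
                "no pre-bolus frame: contrast arrives at or before the first "
                "sample; acquire a longer baseline"
            )
        window = slice(0, first)
    baseline = series.data[window].mean(axis=0)
    data = series.data - baseline[None]
    if clip_negative:
        data = np.clip(data, 0.0, None)
    out = CTPSeries(
        data=data,
        times=series.times,
        spacing=series.spacing,
        brain_mask=series.brain_mask,
        noise_sd=series.noise_sd,
        seed=series.seed,
    )
    return out, window


def compute_perfusion_maps(
    series: CTPSeries,
    vascular: VascularInput,
    config: MapConfig | None = None,
) -> PerfusionMaps:
    """Estimate CBF/CBV/MTT/TTP/Tmax (+ CTH) maps by deconvolution."""
    cfg = config or MapConfig()
    if not series.brain_mask.any():
        raise ValueError("empty brain mask")

    pre, window = tac_preprocess(
        series, vascular, clip_negative=cfg.clip_negative_tac,
        arrival_fraction=cfg.arrival_fraction,
    )

    t0, t1 = series.times[0], series.times[-1]
    grid = np.arange(t0, t1 + 0.5 * cfg.grid_dt, cfg.grid_dt)
    dt = cfg.grid_dt

    aif = np.interp(grid, vascular.times, vascular.aif)
    aif = aif - aif[: max(window.stop, 1)].mean() if window.stop < series.n_frames else aif
    aif = np.clip(aif, 0.0, None)
    aif_area = np.trapezoid(aif, grid)
    if aif_area <= 0:
        raise ValueError("AIF has non-positive area")
    if cfg.pvc:
        vof = np.interp(grid, vascular.times, vascular.vof)
        vof_area = np.trapezoid(np.clip(vof, 0.0, None), grid)
        if vof_area <= 0:
            raise ValueError("VOF has non-positive area (required for partial-volume correction)")
        aif = aif * (vof_area / aif_area)
        aif_area = vof_area

    mask = series.brain_mask
    tacs = pre.data[:, mask]                                 # (n_frames, M)
    # linear resampling to the common grid, vectorised over voxels
    weights_idx = np.searchsorted(series.times, grid, side="right") - 1
    weights_idx = np.clip(weights_idx, 0, series.n_frames - 2)
    frac = (grid - series.times[weights_idx]) / (
        series.times[weights_idx + 1] - series.times[weights_idx]
    )
    frac = np.clip(frac, 0.0, 1.0)[:, None]
    curves = (1.0 - frac) * tacs[weights_idx] + frac * tacs[weights_idx + 1]

    area = np.trapezoid(curves, grid, axis=0)
    has_contrast = area > 0

    cbv = np.where(has_contrast, area / aif_area / cfg.k, 0.0)
    cbv = np.clip(cbv, 0.0, None)

    residues = residue_matrix(curves, aif, dt, truncation=cfg.truncation, mode=cfg.mode)
    n = grid.size
    body = residues[:n]                                      # ignore wrap-around tail
    peak_idx = np.argmax(body, axis=0)
    peak_val = np.take_along_axis(body, peak_idx[None], axis=0)[0]
    cbf = np.where(has_contrast, 60.0 * np.clip(peak_val, 0.0, None) / cfg.k, 0.0)
    mtt = np.divide(60.0 * cbv, cbf, out=np.zeros_like(cbv), where=cbf > 0)
    tmax = np.where(has_contrast, peak_idx * dt, 0.0)
    ttp = np.where(has_contrast, (np.argmax(curves, axis=0)) * dt + (grid[0] - 0.0), 0.0)

    def fill(values: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape, dtype=np.float64)
        out[mask] = values
        return out

    cth_map = None
    if cfg.compute_cth:
        # normalise each residue at its peak (delay-robust), transit-time
        # density = clipped negative derivative, CTH = its sd
        norm = np.where(peak_val > 0, peak_val, 1.0)
        rhat = np.clip(body, 0.0, None) / norm[None]
        # zero everything before the peak so pre-arrival oscillations do not
        # contribute spurious transit times
        before_peak = np.arange(n)[:, None] < peak_idx[None]
        rhat = np.where(before_peak, 1.0, rhat)
        h = np.clip(-np.diff(rhat, axis=0), 0.0, None)
        h_area = h.sum(axis=0)
        h_area = np.where(h_area > 0, h_area, 1.0)
        h = h / h_area[None]
        t_mid = (0.5 * (grid[:-1] + grid[1:]) - grid[0])[:, None]
        mean_tt = np.sum(t_mid * h, axis=0)
        var_tt = np.sum((t_mid - mean_tt[None]) ** 2 * h, axis=0)
        cth = np.where(has_contrast & (peak_val > 0), np.sqrt(var_tt), 0.0)
        cth_map = fill(cth)

    return PerfusionMaps(
        cbf=fill(cbf),
        cbv=fill(cbv),
        mtt=fill(mtt),
        ttp=fill(ttp),
        tmax=fill(tmax),
        brain_mask=mask,
        spacing=series.spacing,
        cth=cth_map,
    )


def maps_from_phantom(phantom, noise_sd: float = 0.0, seed: int | None = None) -> PerfusionMaps:
    """Perfusion maps taken directly from a phantom's ground truth.

    Bypasses acquisition and deconvolution: CBF/CBV/MTT come from the class
    hemodynamics, Tmax from the arrival delay and TTP from delay + MTT.
    Optional multiplicative Gaussian jitter (relative sd ``noise_sd``)
    emulates map noise.  Useful for exercising the segmentation rules
    against designed values, free of estimation bias.
    """
    cbf = phantom.parameter_map("cbf")
    mtt = np.where(cbf > 0, phantom.parameter_map("mtt"), 0.0)
    cbv = phantom.parameter_map("cbv")
    tmax = phantom.parameter_map("delay")
    ttp = np.where(cbf > 0, tmax + mtt, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        jitter = lambda a: np.clip(a * rng.normal(1.0, noise_sd, a.shape), 0.0, None)
        cbf, cbv, mtt = jitter(cbf), jitter(cbv), jitter(mtt)
    return PerfusionMaps(
        cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, tmax=tmax,
        brain_mask=phantom.brain_mask, spacing=phantom.spacing,
    )


def compute_relative_maps(maps: PerfusionMaps, labels) -> RelativeMaps:
    """rCBF and rMTT against the contralateral-hemisphere mean.

    ``labels`` is a :class:`~ctperf.segment.HemisphereLabels`.  For each
    voxel the reference is the mean of the parameter over the brain-masked
    voxels of the *other* hemisphere; voxels with CBF = 0 are excluded from
    the reference means (they carry no perfusion signal).
    """
    from .segment import LEFT, RIGHT  # local import to avoid a cycle

    mask = maps.brain_mask
    ref_cbf: dict[str, float] = {}
    ref_mtt: dict[str, float] = {}
    for side, other in (("left", RIGHT), ("right", LEFT)):
        sel = (labels.labels == other) & mask & (maps.cbf > 0)
        if not sel.any():
            raise ValueError(f"empty contralateral hemisphere for side {side!r}")
        ref_cbf[side] = float(maps.cbf[sel].mean())
        ref_mtt[side] = float(maps.mtt[sel].mean())

    rcbf = np.zeros_like(maps.cbf)
    rmtt = np.zeros_like(maps.mtt)
    defined = np.zeros(mask.shape, dtype=bool)
    for side, code in (("left", LEFT), ("right", RIGHT)):
        sel = (labels.labels == code) & mask
        if ref_cbf[side] > 0:
            rcbf[sel] = maps.cbf[sel] / ref_cbf[side]
            defined |= sel
        if ref_mtt[side] > 0:
            rmtt[sel] = maps.mtt[sel] / ref_mtt[side]
    return RelativeMaps(
        rcbf=rcbf, rmtt=rmtt, defined=defined,
        reference_cbf=ref_cbf, reference_mtt=ref_mtt,
    )
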