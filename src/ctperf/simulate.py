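"""Synthetic CT-perfusion data.

Digital perfusion phantoms, vascular input curves, noisy 4D acquisitions and
cohort-level volume tables.  Every downstream stage of the pipeline (map
estimation, lesion segmentation, diagnostic evaluation) is testable against
the ground truth carried by these objects, without patient data.

The tissue model is the standard indicator-dilution one: for a voxel of
tissue class ``c`` the time–attenuation curve is

    C(t) = k * (CBF_c / 60) * (AIF (*) R_c)(t - delay_c)

with residue function ``R_c(t) = exp(-t / MTT_c)`` (mono-exponential default)
or a box of width ``MTT_c``, and ``k`` a unit constant folding tissue density
and hematocrit correction (default 1 so that map recovery is exact).  The
central volume principle ``CBV = CBF * MTT / 60`` then holds by construction.

Array convention: volumes are indexed ``(z, y, x)`` and 4D series
``(t, z, y, x)``; the last axis is the left–right axis, lower indices being
"left".  This is an array convention, not a radiological one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

Side = Literal["left", "right"]

#: Tissue-class label values used by the default phantom.
BACKGROUND = 0
NORMAL = 1
LESION = 2

#: Algorithm / compartment identifiers shared across the package.
ALGORITHMS = ("threshold", "mirror", "isp")
COMPARTMENTS = ("hypoperfused", "core")


# --------------------------------------------------------------------------
# ground-truth phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassHemodynamics:
    """Ground-truth hemodynamics of one tissue class.

    Parameters
    ----------
    cbf : float
        Cerebral blood flow, mL/100 g/min.  Must be >= 0.
    mtt : float
        Mean transit time, s.  Must be > 0.
    delay : float
        Bolus arrival delay relative to the arterial input, s.
    """

    cbf: float
    mtt: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError(f"CBF must be >= 0, got {self.cbf}")
        if self.mtt <= 0:
            raise ValueError(f"MTT must be > 0, got {self.mtt}")
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")

    @property
    def cbv(self) -> float:
        """Cerebral blood volume, mL/100 g (central volume principle)."""
        return self.cbf * self.mtt / 60.0


#: Normal grey/white compromise tissue plus a hypoperfused, delayed lesion.
#: The lesion satisfies every default segmentation rule strictly
#: (rCBF 0.24, rMTT 2.0, CBV 1.6 mL/100 g, Tmax ~ 7 s) while keeping the
#: convolution tail inside a 60-s acquisition.
DEFAULT_HEMODYNAMICS: dict[int, ClassHemodynamics] = {
    BACKGROUND: ClassHemodynamics(cbf=0.0, mtt=1.0),
    NORMAL: ClassHemodynamics(cbf=50.0, mtt=4.0, delay=0.0),
    LESION: ClassHemodynamics(cbf=12.0, mtt=8.0, delay=7.0),
}


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion placed in one hemisphere of the phantom."""

    side: Side = "right"
    center: tuple[int, int, int] | None = None  # voxel index, auto if None
    radius_mm: float = 10.0
    class_id: int = LESION

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.radius_mm < 0:
            raise ValueError("lesion radius must be >= 0")


@dataclass(frozen=True)
class GroundTruthPhantom:
    """Label grid + per-class hemodynamics; the simulation ground truth."""

    labels: np.ndarray                       # (z, y, x) int
    hemodynamics: Mapping[int, ClassHemodynamics]
    spacing: tuple[float, float, float]      # mm per axis
    brain_mask: np.ndarray                   # (z, y, x) bool
    lesion: LesionSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        mask = np.asarray(self.brain_mask, dtype=bool)
        if labels.shape != mask.shape:
            raise ValueError("labels and brain mask shapes differ")
        present = set(np.unique(labels).tolist())
        unknown = present - set(self.hemodynamics)
        if unknown:
            raise ValueError(f"unknown tissue class id(s): {sorted(unknown)}")
        if self.hemodynamics.get(BACKGROUND, ClassHemodynamics(0.0, 1.0)).cbf != 0:
            raise ValueError("background class must have CBF = 0")
        if np.any((labels != BACKGROUND) & ~mask):
            raise ValueError("tissue voxels must lie inside the brain mask")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def parameter_map(self, name: str) -> np.ndarray:
        """Ground-truth 3D map of ``cbf``, ``cbv``, ``mtt`` or ``delay``."""
        out = np.zeros(self.labels.shape, dtype=float)
        for cid, h in self.hemodynamics.items():
            value = getattr(h, name)
            out[self.labels == cid] = value
        return out


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    lesion: LesionSpec | None = LesionSpec(),
    hemodynamics: Mapping[int, ClassHemodynamics] | None = None,
    seed: int | None = None,
) -> GroundTruthPhantom:
    """Build a two-hemisphere ellipsoidal brain with an optional spherical lesion.

    The brain mask is a single ellipsoid centred in the grid; the mid-sagittal
    plane is the grid's mid-plane along the last (left–right) axis, so the
    mask is mirror-symmetric.  Tissue is homogeneous normal tissue except for
    one spherical lesion on the requested side.  Deterministic; the seed is
    stored for provenance of any derived stochastic simulation.

    Raises
    ------
    ValueError
        If the lesion sphere does not fit inside the brain mask.
    """
    hemo = dict(hemodynamics) if hemodynamics is not None else dict(DEFAULT_HEMODYNAMICS)
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)

    zz, yy, xx = np.indices(shape, dtype=float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s * sp for s, sp in zip(shape, spacing)]  # mm
    mask = (
        ((zz - center[0]) * spacing[0] / semi[0]) ** 2
        + ((yy - center[1]) * spacing[1] / semi[1]) ** 2
        + ((xx - center[2]) * spacing[2] / semi[2]) ** 2
    ) <= 1.0

    labels = np.where(mask, NORMAL, BACKGROUND).astype(np.int16)

    if lesion is not None and lesion.radius_mm > 0:
        if lesion.class_id not in hemo:
            raise ValueError(f"unknown lesion class id {lesion.class_id}")
        if lesion.center is not None:
            cz, cy, cx = lesion.center
        else:
            # centroid of the requested hemisphere's brain voxels
            mid = (shape[2] - 1) / 2.0
            hemi = mask & ((xx < mid) if lesion.side == "left" else (xx > mid))
            if not hemi.any():
                raise ValueError("requested hemisphere contains no brain voxels")
            cz, cy, cx = (int(round(c)) for c in np.mean(np.argwhere(hemi), axis=0))
        dist2 = (
            ((zz - cz) * spacing[0]) ** 2
            + ((yy - cy) * spacing[1]) ** 2
            + ((xx - cx) * spacing[2]) ** 2
        )
        sphere = dist2 <= lesion.radius_mm**2
        if np.any(sphere & ~mask):
            raise ValueError("lesion extends outside the brain mask")
        labels[sphere] = lesion.class_id

    return GroundTruthPhantom(
        labels=labels,
        hemodynamics=hemo,
        spacing=spacing,
        brain_mask=mask,
        lesion=lesion,
        seed=seed,
    )


# --------------------------------------------------------------------------
# vascular input curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VascularInput:
    """Arterial and venous reference curves (HU above baseline)."""

    times: np.ndarray
    aif: np.ndarray
    vof: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.aif, dtype=float)
        v = np.asarray(self.vof, dtype=float)
        if not (t.shape == a.shape == v.shape):
            raise ValueError("times, AIF and VOF must have equal lengths")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0) or np.any(v < 0):
            raise ValueError("vascular curves must be non-negative after baseline subtraction")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "aif", a)
        object.__setattr__(self, "vof", v)


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate contrast bolus.  Scan start is t = 0; the bolus arrives
    at ``t0`` (default 4 s, the injection-to-scan lead time emulated here)."""

    t0: float = 4.0
    alpha: float = 3.0
    beta: float = 1.5       # s
    amplitude: float = 300.0  # HU
    venous_factor: float = 1.0
    venous_delay: float = 3.0  # s


def _gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float, amplitude: float) -> np.ndarray:
    # normalised so the curve peaks at `amplitude` exactly at t0 + alpha*beta
    out = np.zeros_like(t, dtype=float)
    rising = t > t0
    tt = (t[rising] - t0) / (alpha * beta)
    out[rising] = amplitude * tt**alpha * np.exp(alpha - (t[rising] - t0) / beta)
    return out


def gamma_variate_aif(
    times: Sequence[float] | np.ndarray,
    t0: float = 4.0,
    alpha: float = 3.0,
    beta: float = 1.5,
    amplitude: float = 300.0,
    venous_factor: float = 1.0,
    venous_delay: float = 3.0,
) -> VascularInput:
    """Gamma-variate AIF with a delayed, scaled VOF.

    ``AIF(t) = A * ((t - t0)/(alpha*beta))^alpha * exp(alpha - (t - t0)/beta)``
    for t > t0 and 0 before; peak value ``A`` at ``t = t0 + alpha*beta``.
    The VOF is the same curve delayed by ``venous_delay`` and scaled by
    ``venous_factor``.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if alpha <= 0 or beta <= 0 or amplitude <= 0:
        raise ValueError("alpha, beta and amplitude must be positive")
    aif = _gamma_variate(t, t0, alpha, beta, amplitude)
    vof = venous_factor * _gamma_variate(t, t0 + venous_delay, alpha, beta, amplitude)
    return VascularInput(times=t, aif=aif, vof=vof)


# --------------------------------------------------------------------------
# 4D series simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CTPSeries:
    """Time-resolved attenuation volume with geometry, timing and mask."""

    data: np.ndarray                      # (t, z, y, x), HU above baseline
    times: np.ndarray                     # s, strictly increasing
    spacing: tuple[float, float, float]   # mm
    brain_mask: np.ndarray                # (z, y, x) bool
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        t = np.asarray(self.times, dtype=float)
        mask = np.asarray(self.brain_mask, dtype=bool)
        if data.ndim != 4:
            raise ValueError("series data must be 4D (t, z, y, x)")
        if data.shape[0] != t.size:
            raise ValueError("number of frames and sample times differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if data.shape[1:] != mask.shape:
            raise ValueError("grid shape inconsistent with brain mask")
        object.__setattr__(self, "times", t)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])


def simulate_series(
    phantom: GroundTruthPhantom,
    bolus: BolusParams | None = None,
    dt: float = 4.0,
    duration: float = 60.0,
    noise_sd: float = 2.0,
    k: float = 1.0,
    residue_model: Literal["exponential", "box"] = "exponential",
    seed: int | None = None,
    dt_fine: float = 0.1,
) -> tuple[CTPSeries, VascularInput]:
    """Simulate a noisy 4D CTP acquisition of a phantom.

    Tissue curves are computed per class on a fine grid (``dt_fine``) by
    discrete convolution of the gamma-variate AIF with the class residue
    function, shifted by the class arrival delay, then sampled at the
    acquisition times ``0, dt, 2*dt, ... <= duration``.  The default 4-s
    interval and 60-s duration emulate a clinical DCI screening acquisition.
    i.i.d. Gaussian HU noise (sd ``noise_sd``) is added voxelwise, seeded.

    Returns the series together with the vascular curves sampled at the same
    acquisition times.
    """
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    bolus = bolus or BolusParams()

    times = np.arange(0.0, duration + 0.5 * dt, dt)
    tf = np.arange(0.0, duration + dt_fine, dt_fine)
    aif_fine = _gamma_variate(tf, bolus.t0, bolus.alpha, bolus.beta, bolus.amplitude)

    class_curves: dict[int, np.ndarray] = {}
    tail_warned = False
    for cid, h in phantom.hemodynamics.items():
        if h.cbf == 0:
            class_curves[cid] = np.zeros_like(times)
            continue
        if residue_model == "exponential":
            residue = np.exp(-tf / h.mtt)
        elif residue_model == "box":
            # anti-aliased edge so the discrete area equals the box width
            residue = np.clip((h.mtt - tf) / dt_fine + 0.5, 0.0, 1.0)
        else:
            raise ValueError(f"unknown residue model {residue_model!r}")
        # trapezoid-corrected discrete convolution (second-order quadrature)
        conv = np.convolve(aif_fine, residue)[: tf.size]
        conv = (conv - 0.5 * (aif_fine * residue[0] + aif_fine[0] * residue)) * dt_fine
        curve = k * (h.cbf / 60.0) * np.interp(times - h.delay, tf, conv, left=0.0)
        if not tail_warned and conv[-1] > 0.02 * conv.max():
            warnings.warn(
                "acquisition duration may truncate the bolus tail "
                f"(class {cid}: final curve value {conv[-1] / conv.max():.1%} of peak)",
                stacklevel=2,
            )
            tail_warned = True
        class_curves[cid] = curve

    data = np.zeros((times.size, *phantom.shape), dtype=float)
    for cid, curve in class_curves.items():
        sel = phantom.labels == cid
        if sel.any():
            data[:, sel] = curve[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)

    vascular = gamma_variate_aif(
        times,
        t0=bolus.t0,
        alpha=bolus.alpha,
        beta=bolus.beta,
        amplitude=bolus.amplitude,
        venous_factor=bolus.venous_factor,
        venous_delay=bolus.venous_delay,
    )
    series = CTPSeries(
        data=data,
        times=times,
        spacing=phantom.spacing,
        brain_mask=phantom.brain_mask,
        noise_sd=noise_sd,
        seed=seed,
    )
    return series, vascular


def simulate_followup_ct(
    phantom: GroundTruthPhantom,
    infarct_mask: np.ndarray | None = None,
    brain_hu: float = 35.0,
    infarct_hu: float = 20.0,
    background_hu: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Plain follow-up CT: homogeneous brain with a hypodense infarct.

    By default the infarct is the phantom's lesion (the region whose
    hypoperfusion is simulated to progress to infarction).
    """
    if infarct_mask is None:
        cid = phantom.lesion.class_id if phantom.lesion is not None else LESION
        infarct_mask = phantom.labels == cid
    ct = np.full(phantom.shape, background_hu, dtype=float)
    ct[phantom.brain_mask] = brain_hu
    ct[np.asarray(infarct_mask, dtype=bool)] = infarct_hu
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct += rng.normal(0.0, noise_sd, size=ct.shape)
    return ct


# --------------------------------------------------------------------------
# cohort-level volume tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortRecord:
    """Per-examination predicted volumes, final infarct volume, treatment flag."""

    dataset_id: str
    thr_hypo_ml: float
    thr_core_ml: float
    mir_hypo_ml: float
    mir_core_ml: float
    isp_hypo_ml: float
    isp_core_ml: float
    infarct_ml: float
    treatment: Literal["treated", "untreated", "excluded"]

    def __post_init__(self) -> None:
        for name in (
            "thr_hypo_ml", "thr_core_ml", "mir_hypo_ml", "mir_core_ml",
            "isp_hypo_ml", "isp_core_ml", "infarct_ml",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.treatment not in ("treated", "untreated", "excluded"):
            raise ValueError(f"unknown treatment flag {self.treatment!r}")

    def volume(self, algorithm: str, compartment: str) -> float:
        """Predicted volume for one algorithm/compartment."""
        prefix = {"threshold": "thr", "mirror": "mir", "isp": "isp"}[algorithm]
        suffix = {"hypoperfused": "hypo", "core": "core"}[compartment]
        return getattr(self, f"{prefix}_{suffix}_ml")


Mixture = tuple[float, float, float, float]  # (no_abn, underest, reversible, progressive)

#: Four-category mixtures per algorithm x compartment, as fractions of the
#: published 123-examination DCI cohort this generator is calibrated to.
DEFAULT_CATEGORY_MIXTURES: dict[tuple[str, str], Mixture] = {
    ("threshold", "hypoperfused"): (33 / 123, 9 / 123, 49 / 123, 32 / 123),
    ("mirror", "hypoperfused"): (4 / 123, 0 / 123, 78 / 123, 41 / 123),
    ("isp", "hypoperfused"): (0 / 123, 0 / 123, 82 / 123, 41 / 123),
    ("threshold", "core"): (54 / 123, 15 / 123, 28 / 123, 26 / 123),
    ("mirror", "core"): (46 / 123, 7 / 123, 36 / 123, 34 / 123),
    ("isp", "core"): (4 / 123, 4 / 123, 78 / 123, 37 / 123),
}

#: Cohort mean volumes (mL, including zero-volume examinations) per
#: algorithm x compartment, matching the published cohort.
DEFAULT_MEAN_VOLUMES_ML: dict[tuple[str, str], float] = {
    ("threshold", "hypoperfused"): 13.7,
    ("mirror", "hypoperfused"): 38.0,
    ("isp", "hypoperfused"): 41.6,
    ("threshold", "core"): 2.7,
    ("mirror", "core"): 6.4,
    ("isp", "core"): 9.8,
}

DEFAULT_INFARCT_MEAN_ML = 9.0
DEFAULT_TREATMENT_FRACTIONS = {"treated": 56 / 123, "untreated": 51 / 123, "excluded": 16 / 123}


def _normalize_mixtures(
    mixtures: Mixture | Mapping[tuple[str, str], Mixture] | None,
) -> dict[tuple[str, str], Mixture]:
    if mixtures is None:
        out = dict(DEFAULT_CATEGORY_MIXTURES)
    elif isinstance(mixtures, Mapping):
        out = {key: tuple(mixtures[key]) for key in mixtures}  # type: ignore[misc]
    else:
        mix = tuple(float(p) for p in mixtures)
        out = {(a, c): mix for a in ALGORITHMS for c in COMPARTMENTS}
    for key, mix in out.items():
        if len(mix) != 4 or any(p < 0 for p in mix):
            raise ValueError(f"mixture for {key} must be 4 non-negative proportions")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions for {key} must sum to 1")
    p_inf = {key: mix[1] + mix[3] for key, mix in out.items()}
    if max(p_inf.values()) - min(p_inf.values()) > 1e-6:
        raise ValueError(
            "mixtures imply inconsistent infarct-positive rates across "
            "algorithms/compartments (the final infarct is shared)"
        )
    return out


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    # log-normal parameterised by its arithmetic mean
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def simulate_cohort(
    n: int,
    mixtures: Mixture | Mapping[tuple[str, str], Mixture] | None = None,
    mean_volumes_ml: Mapping[tuple[str, str], float] | None = None,
    infarct_mean_ml: float = DEFAULT_INFARCT_MEAN_ML,
    sigma: float = 1.0,
    treatment_fractions: Mapping[str, float] | None = None,
    seed: int | None = None,
    return_categories: bool = False,
):
    """Draw a synthetic cohort of per-examination volume records.

    Each examination first draws final-infarct positivity (shared across
    algorithms), then per algorithm x compartment draws predicted positivity
    conditional on infarct status so that the joint four-category mixture is
    matched.  Nonzero volumes are log-normal; the configured
    ``mean_volumes_ml`` are cohort means *including* zeros, so the nonzero
    component mean is ``mean / positive_fraction``.  The widely different
    means across algorithms produce the variance heterogeneity that motivates
    Welch-type statistics downstream.

    With ``return_categories=True`` also returns the generator's own tally of
    categories per algorithm x compartment (an independent bookkeeping oracle
    for the contingency builder).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixes = _normalize_mixtures(mixtures)
    means = dict(DEFAULT_MEAN_VOLUMES_ML if mean_volumes_ml is None else mean_volumes_ml)
    fractions = dict(DEFAULT_TREATMENT_FRACTIONS if treatment_fractions is None else treatment_fractions)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("treatment fractions must sum to 1")

    keys = [(a, c) for a in ALGORITHMS for c in COMPARTMENTS]
    for key in keys:
        if key not in mixes:
            raise ValueError(f"missing mixture for {key}")
    p_inf = mixes[keys[0]][1] + mixes[keys[0]][3]

    rng = np.random.default_rng(seed)
    flags = list(fractions)
    flag_p = np.array([fractions[f] for f in flags])

    records: list[CohortRecord] = []
    tally: dict[tuple[str, str], dict[str, int]] = {
        key: {"no_abnormality": 0, "underestimated_progressive_infarct": 0,
              "reversible_perfusion_deficit": 0, "progressive_infarct": 0}
        for key in keys
    }
    for i in range(n):
        infarct_pos = rng.random() < p_inf
        infarct_ml = (
            _lognormal_mean(rng, infarct_mean_ml / p_inf, sigma) if infarct_pos else 0.0
        )
        volumes: dict[tuple[str, str], float] = {}
        for key in keys:
            p_no, p_under, p_rev, p_prog = mixes[key]
            if infarct_pos:
                p_pos = p_prog / p_inf if p_inf > 0 else 0.0
            else:
                p_pos = p_rev / (1.0 - p_inf) if p_inf < 1 else 0.0
            pred_pos = rng.random() < p_pos
            if pred_pos:
                pos_frac = p_rev + p_prog
                volumes[key] = _lognormal_mean(rng, means[key] / pos_frac, sigma)
            else:
                volumes[key] = 0.0
            if pred_pos and infarct_pos:
                cat = "progressive_infarct"
            elif pred_pos:
                cat = "reversible_perfusion_deficit"
            elif infarct_pos:
                cat = "underestimated_progressive_infarct"
            else:
                cat = "no_abnormality"
            tally[key][cat] += 1
        treatment = flags[int(rng.choice(len(flags), p=flag_p))]
        records.append(
            CohortRecord(
                dataset_id=f"sim{i:05d}",
                thr_hypo_ml=volumes[("threshold", "hypoperfused")],
                thr_core_ml=volumes[("threshold", "core")],
                mir_hypo_ml=volumes[("mirror", "hypoperfused")],
                mir_core_ml=volumes[("mirror", "core")],
                isp_hypo_ml=volumes[("isp", "hypoperfused")],
                isp_core_ml=volumes[("isp", "core")],
                infarct_ml=infarct_ml,
                treatment=treatment,  # type: ignore[arg-type]
            )
        )
    if return_categories:
        return records, tally
    return records
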