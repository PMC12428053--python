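"""Final-infarct segmentation from a follow-up plain CT.

The reference standard for evaluating the perfusion-based predictions is the
final infarct visible as hypodensity on the follow-up non-contrast CT.  The
interactive region-of-interest workflow a neuroradiologist would use is
emulated non-interactively: HU thresholding inside the brain mask, removal
of prior (pre-existing post-hemorrhagic or ischemic) lesions via a supplied
exclusion mask, and suppression of small connected components standing in
for manual clean-up.  The HU cutoff is a configurable stand-in (default
25 HU, typical subacute infarct attenuation), always passed explicitly by
callers that care about it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segment import mask_volume_ml


@dataclass(frozen=True)
class InfarctSegmentation:
    """Hypodensity mask and volume from a plain CT."""

    mask: np.ndarray
    volume_ml: float
    threshold_hu: float
    prior_excluded: bool
    n_components: int


def segment_infarct(
    ct: np.ndarray,
    brain_mask: np.ndarray,
    spacing: tuple[float, float, float],
    prior_mask: np.ndarray | None = None,
    threshold_hu: float = 25.0,
    min_component_ml: float = 0.5,
) -> InfarctSegmentation:
    """Segment hypodense (infarcted) tissue below a HU threshold.

    Candidate voxels are brain-masked voxels with HU strictly below
    ``threshold_hu``; the prior-lesion mask is subtracted; 26-connected
    components smaller than ``min_component_ml`` are removed.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise ValueError("empty brain mask")
    if not -100.0 <= threshold_hu <= 80.0:
        raise ValueError(f"HU threshold {threshold_hu} outside the plausible range [-100, 80]")
    ct = np.asarray(ct, dtype=float)
    if ct.shape != brain.shape:
        raise ValueError("CT and brain mask must share one grid")

    candidate = brain & (ct < threshold_hu)
    if prior_mask is not None:
        candidate &= ~np.asarray(prior_mask, dtype=bool)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(candidate, structure=structure)
    voxel_ml = float(np.prod(spacing)) / 1000.0
    min_voxels = min_component_ml / voxel_ml
    kept = np.zeros_like(candidate)
    n_kept = 0
    if n:
        sizes = ndimage.sum_labels(candidate, labeled, index=np.arange(1, n + 1))
        keep_ids = np.nonzero(sizes >= min_voxels)[0] + 1
        n_kept = keep_ids.size
        if n_kept:
            kept = np.isin(labeled, keep_ids)
    return InfarctSegmentation(
        mask=kept,
        volume_ml=mask_volume_ml(kept, spacing),
        threshold_hu=float(threshold_hu),
        prior_excluded=prior_mask is not None,
        n_components=int(n_kept),
    )
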