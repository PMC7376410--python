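"""Seeded synthetic multimodal glioma phantoms with ground truth.

Each phantom is an elliptical "brain" on a dark background holding four
nested elliptical tumor subregions — peritumoral edema (ED), non-enhancing
core (NET), enhancing core (ET) and necrotic core (NCR), with NCR ⊂ ET ⊂
NET ⊂ ED — painted with modality-dependent mean intensities that mimic the
standard clinical contrasts: edema is bright on FLAIR/T2, the active tumor
core is bright on post-contrast T1 (T1CE).  On top of the piecewise-constant
tissue means the generator applies a smooth multiplicative intensity offset
(bias) field and additive Gaussian noise, the two confounders that intensity
standardization and offset correction address in real MRI.

Everything is driven by a single integer seed: identical config and seed
give bitwise-identical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import CaseRecord, ImageVolume, LabelMap, LabelScheme, Modality

__all__ = ["PhantomConfig", "generate_case", "generate_cohort", "subregion_masks", "REGIONS"]

#: Tumor subregions ordered from innermost to outermost.
REGIONS = ("NCR", "ET", "NET", "ED")

#: BraTS label code painted for each subregion shell (NCR and NET share code 1).
_REGION_CODE = {"NCR": 1, "ET": 4, "NET": 1, "ED": 2}

# Mean intensities in normalized (roughly [0, 1]) units, chosen to mimic the
# standard sequence contrasts: FLAIR/T2-bright edema, T1CE-bright enhancing
# core, dark necrosis on T1/T1CE.
_DEFAULT_MEANS: Dict[Tuple[str, str], float] = {
    ("T1", "background"): 0.50, ("T1", "ED"): 0.35, ("T1", "NET"): 0.45,
    ("T1", "ET"): 0.40, ("T1", "NCR"): 0.25,
    ("T1CE", "background"): 0.45, ("T1CE", "ED"): 0.40, ("T1CE", "NET"): 0.50,
    ("T1CE", "ET"): 0.95, ("T1CE", "NCR"): 0.20,
    ("T2", "background"): 0.35, ("T2", "ED"): 0.80, ("T2", "NET"): 0.65,
    ("T2", "ET"): 0.60, ("T2", "NCR"): 0.75,
    ("FLAIR", "background"): 0.30, ("FLAIR", "ED"): 0.90, ("FLAIR", "NET"): 0.70,
    ("FLAIR", "ET"): 0.65, ("FLAIR", "NCR"): 0.55,
}

_DEFAULT_RADII: Dict[str, Tuple[float, ...]] = {
    "NCR": (3.0, 2.0),
    "ET": (6.0, 4.5),
    "NET": (9.0, 7.0),
    "ED": (12.0, 9.0),
}


@dataclass
class PhantomConfig:
    """All tunables of one synthetic case.

    ``radii`` maps each subregion to ellipse/ellipsoid semi-axes (pixels) and
    must be strictly nested per axis, NCR < ET < NET < ED.  ``noise_sd`` is the
    standard deviation of the additive Gaussian noise in the same normalized
    intensity units as ``tissue_means``; ``bias_amplitude`` is the peak
    relative deviation of the smooth multiplicative offset field.
    """

    shape: Tuple[int, ...] = (64, 64)
    tumor_center: Optional[Tuple[float, ...]] = None
    radii: Dict[str, Tuple[float, ...]] = field(default_factory=lambda: dict(_DEFAULT_RADII))
    tissue_means: Dict[Tuple[str, str], float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    noise_sd: float = 0.4
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        ndim = len(self.shape)
        if ndim not in (2, 3):
            raise ValueError("phantoms are 2-D or 3-D")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must be in [0, 1)")
        missing = [r for r in REGIONS if r not in self.radii]
        if missing:
            raise ValueError(f"radii missing for region(s): {missing}")
        for region in REGIONS:
            if len(self.radii[region]) != ndim:
                raise ValueError(f"radii[{region}] must have {ndim} components")
        for inner, outer in zip(REGIONS, REGIONS[1:]):
            if not all(a < b for a, b in zip(self.radii[inner], self.radii[outer])):
                raise ValueError(
                    f"radii must be strictly nested per axis: {inner} {self.radii[inner]} "
                    f"!< {outer} {self.radii[outer]}"
                )

    @property
    def center(self) -> Tuple[float, ...]:
        if self.tumor_center is not None:
            return tuple(float(c) for c in self.tumor_center)
        return tuple((s - 1) / 2.0 for s in self.shape)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return dist2 <= 1.0


def _brain_mask(shape) -> np.ndarray:
    center = tuple((s - 1) / 2.0 for s in shape)
    semi = tuple(0.47 * s for s in shape)
    return _ellipsoid_mask(shape, center, semi)


def subregion_masks(config: PhantomConfig) -> Dict[str, np.ndarray]:
    """Boolean masks of the four *solid* (filled, nested) subregion ellipses.

    ``masks["NCR"] ⊆ masks["ET"] ⊆ masks["NET"] ⊆ masks["ED"]`` by
    construction; ``masks["ED"]`` is the whole tumor.
    """
    center = config.center
    return {r: _ellipsoid_mask(config.shape, center, config.radii[r]) for r in REGIONS}


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field in [1 - a, 1 + a] (a broad Gaussian bump)."""
    if amplitude == 0:
        return np.ones(shape)
    center = [rng.uniform(0.25 * s, 0.75 * s) for s in shape]
    sigma = [0.6 * s for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    bump = np.exp(-0.5 * sum(((g - c) / sg) ** 2 for g, c, sg in zip(grids, center, sigma)))
    bump = np.broadcast_to(bump, shape)
    lo, hi = bump.min(), bump.max()
    unit = (bump - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return 1.0 + amplitude * (2.0 * unit - 1.0)


def generate_case(config: PhantomConfig, case_id: Optional[str] = None) -> CaseRecord:
    """Generate one multimodal phantom case with BraTS-coded ground truth.

    Outside the brain ellipse all intensities are exactly zero (as in
    skull-stripped MRI); inside, each modality is its piecewise-constant
    tissue means times a shared bias field plus independent Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    brain = _brain_mask(config.shape)
    masks = subregion_masks(config)

    # Region-id grid: background inside brain, then paint outer→inner shells.
    labels = np.zeros(config.shape, dtype=np.int64)
    region_of = np.full(config.shape, "background", dtype=object)
    for region in reversed(REGIONS):  # ED first, NCR last (innermost wins)
        labels[masks[region]] = _REGION_CODE[region]
        region_of[masks[region]] = region
    labels[~brain] = 0
    region_of[~brain] = None

    bias = _bias_field(config.shape, config.bias_amplitude, rng)
    volumes = {}
    for mod in (Modality.T1, Modality.T1CE, Modality.T2, Modality.FLAIR):
        img = np.zeros(config.shape)
        for region in ("background",) + REGIONS:
            sel = region_of == region
            img[sel] = config.tissue_means[(mod.value, region)]
        img *= bias
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=config.shape)
        img[~brain] = 0.0
        volumes[mod] = ImageVolume(data=img, modality=mod)

    truth = LabelMap(data=labels, scheme=LabelScheme.BRATS)
    return CaseRecord(case_id=case_id or f"phantom_{config.seed:08d}", volumes=volumes, truth=truth)


def generate_cohort(n_cases: int, base_config: Optional[PhantomConfig] = None,
                    seed: int = 0) -> List[CaseRecord]:
    """Generate a cohort of phantoms with jittered tumor centers and radii.

    Tumor centers are jittered uniformly by up to ±12% of each axis and the
    subregion radii by ±15% (multiplicative, per region); draws producing
    non-nested radii are resampled so every emitted config is valid.
    Reproducible per (base_config, seed).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        for _ in range(100):
            center = tuple(
                c + rng.uniform(-0.12, 0.12) * s for c, s in zip(base.center, base.shape)
            )
            radii = {
                region: tuple(a * rng.uniform(0.85, 1.15) for a in base.radii[region])
                for region in REGIONS
            }
            nested = all(
                all(a < b for a, b in zip(radii[inner], radii[outer]))
                for inner, outer in zip(REGIONS, REGIONS[1:])
            )
            if nested:
                break
        else:  # pragma: no cover - jitter bounds make this unreachable in practice
            raise RuntimeError("could not draw nested radii")
        cfg = replace(base, tumor_center=center, radii=radii, seed=case_seed)
        cases.append(generate_case(cfg, case_id=f"phantom_{i:03d}"))
    return cases
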