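"""Synthetic B-mode phantoms of superficial colorectal tumors.

The clinical dataset this package is designed for is private, so every
stage of the pipeline is exercised on simulated specimens instead. The
generator is statistical rather than acoustic: it reproduces the features
the losses, metrics and ensembles actually depend on —

* a hypoechoic (dark) lesion whose smooth, radially perturbed boundary sits
  with its top at a sampled *margin depth* below the transducer surface;
* a layered soft-tissue background with depth-dependent attenuation;
* multiplicative, spatially correlated speckle;
* an exact binary lesion mask.

Geometry follows the reported cohort: margin depth 6.4 +/- 3.7 mm and
lesion diameter 41 +/- 19 mm, with 1-3 images per synthetic patient. The
margin distribution is a truncated normal whose pre-truncation parameters
are moment-matched so that the *realized* mean/sd hit the cohort values
despite the finite imaging depth. Two texture domains ("source" standing
in for breast ultrasound, "target" for colorectal) differ in speckle
strength, lesion contrast and boundary roughness, giving transfer learning
a real gap to bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .image import (
    DEFAULT_COL_SPACING_MM,
    DEFAULT_ROW_SPACING_MM,
    RAW_COL_SPACING_MM,
    RAW_ROW_SPACING_MM,
    RAW_SHAPE,
    USImage,
    write_image,
    write_mask,
)

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "tradeoff_probability_maps"]

# Texture statistics per domain: speckle amplitude, lesion contrast
# multiplier (lesion echo = contrast x background echo; closer to 1 is
# subtler), boundary roughness as a fraction of the radius, and the
# Gaussian blur (px) applied to the lesion insertion, which controls how
# diffuse the tumor boundary appears. Tumor boundaries in B-mode are far
# from step edges, and the top boundary competes with speckle — that
# difficulty is what makes margin-aware training matter.
_DOMAIN_TEXTURE = {
    "source": {"speckle": 0.35, "contrast": 0.55, "roughness": 0.05, "edge_sigma": 1.5},
    "target": {"speckle": 0.50, "contrast": 0.65, "roughness": 0.12, "edge_sigma": 2.5},
}


@dataclass
class PhantomSpec:
    """Study conditions for the phantom generator.

    Defaults mirror the reported cohort: 74 patients with 1-3 images each,
    margin depth 6.4 +/- 3.7 mm, lesion diameter 41 +/- 19 mm (truncated to
    the field of view), 128 x 128 images at the post-preprocessing pixel
    spacing. ``split_fractions`` reproduce the 121/28/30 train/val/test
    image proportions, applied patient-wise.
    """

    n_patients: int = 74
    images_per_patient: tuple[int, int] = (1, 3)
    image_shape: tuple[int, int] = (128, 128)
    row_spacing_mm: float = DEFAULT_ROW_SPACING_MM
    col_spacing_mm: float = DEFAULT_COL_SPACING_MM
    margin_mean_mm: float = 6.4
    margin_sd_mm: float = 3.7
    margin_bounds_mm: tuple[float, float] = (0.3, 14.0)
    diameter_mean_mm: float = 41.0
    diameter_sd_mm: float = 19.0
    lesion_aspect: tuple[float, float] = (0.35, 0.65)  # vertical/horizontal axis ratio
    attenuation_per_mm: float = 0.045
    domain: str = "target"
    split_fractions: tuple[float, float, float] = (121 / 179, 28 / 179, 30 / 179)
    seed: int = 0
    _margin_params: tuple[float, float] = field(init=False, repr=False, default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.domain not in _DOMAIN_TEXTURE:
            raise ValueError(f"unknown domain {self.domain!r}")
        for value in (
            self.margin_mean_mm,
            self.margin_sd_mm,
            self.diameter_mean_mm,
            self.diameter_sd_mm,
            self.row_spacing_mm,
            self.col_spacing_mm,
        ):
            if value <= 0:
                raise ValueError("distribution and spacing parameters must be positive")
        lo, hi = self.margin_bounds_mm
        if not 0 < lo < hi:
            raise ValueError("margin bounds must satisfy 0 < lo < hi")
        self._margin_params = _match_truncnorm_moments(
            self.margin_mean_mm, self.margin_sd_mm, lo, hi
        )

    @property
    def texture(self) -> dict:
        return _DOMAIN_TEXTURE[self.domain]

    def sample_margin_mm(self, rng: np.random.Generator) -> float:
        mu, sigma = self._margin_params
        lo, hi = self.margin_bounds_mm
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))


def _match_truncnorm_moments(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose [lo, hi]-truncated moments equal (mean, sd).

    Any distribution on an interval of width W has sd <= W/2, and a
    truncated normal at most W/sqrt(12) (the uniform limit); the requested
    sd must be feasible or the solve fails loudly.
    """
    width = hi - lo
    if sd >= width / np.sqrt(12.0):
        raise ValueError(
            f"sd {sd} not realizable by a truncated normal on [{lo}, {hi}]"
        )

    def residual(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        residual, [mean, np.log(2.0 * sd)], full_output=True
    )
    if ier != 1:
        raise RuntimeError(f"margin-distribution moment matching failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _lesion_mask(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    semi_axes_px: tuple[float, float],
    roughness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Radially perturbed ellipse: smooth low-order boundary noise."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dr = (rr - center_rc[0]) / semi_axes_px[0]
    dc = (cc - center_rc[1]) / semi_axes_px[1]
    radius = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    # Low-order Fourier perturbation of the unit radius keeps the boundary
    # smooth but non-elliptical.
    perturb = np.zeros_like(theta)
    for harmonic in (2, 3, 4):
        amp = roughness * rng.uniform(0.3, 1.0) / harmonic
        phase = rng.uniform(0, 2 * np.pi)
        perturb += amp * np.cos(harmonic * theta + phase)
    return radius <= 1.0 + perturb


def generate_phantom(
    spec: PhantomSpec,
    patient_seed: int,
    patient_id: str = "",
    image_id: str = "",
    geometry: dict | None = None,
) -> tuple[USImage, np.ndarray]:
    """Simulate one B-mode frame and its exact tumor mask.

    ``geometry`` optionally carries a patient-level (margin, diameter,
    center column) tuple so repeated frames of the same synthetic patient
    share anatomy up to a small jitter. The top of the lesion lands at the
    sampled margin depth (+/- the boundary perturbation); the lesion may
    run off the bottom of the field of view, as large tumors do.
    """
    rng = np.random.default_rng(patient_seed)
    rows, cols = spec.image_shape
    tex = spec.texture
    height_mm = rows * spec.row_spacing_mm

    for _attempt in range(20):
        if geometry is None:
            margin_mm = spec.sample_margin_mm(rng)
            diameter_mm = float(
                np.clip(
                    rng.normal(spec.diameter_mean_mm, spec.diameter_sd_mm),
                    6.0,
                    0.9 * cols * spec.col_spacing_mm,
                )
            )
            center_col = rng.uniform(0.3, 0.7) * cols
        else:
            margin_mm = geometry["margin_mm"] + rng.normal(0, 0.15)
            margin_mm = float(np.clip(margin_mm, *spec.margin_bounds_mm))
            diameter_mm = geometry["diameter_mm"] * rng.uniform(0.95, 1.05)
            center_col = geometry["center_col"] + rng.normal(0, 1.5)

        semi_c = 0.5 * diameter_mm / spec.col_spacing_mm
        semi_r = semi_c * rng.uniform(*spec.lesion_aspect) * spec.col_spacing_mm / spec.row_spacing_mm
        target_top = int(np.clip(round(margin_mm / spec.row_spacing_mm), 1, rows - 3))
        center_row = target_top + semi_r
        mask = _lesion_mask(
            (rows, cols), (center_row, center_col), (semi_r, semi_c), tex["roughness"], rng
        )
        if not mask.any():
            continue
        # Pin the realized top row to the sampled margin depth: the radial
        # boundary perturbation would otherwise shift it by several pixels
        # and bias the margin distribution.
        actual_top = int(np.nonzero(mask.any(axis=1))[0][0])
        shift = target_top - actual_top
        shifted = np.zeros_like(mask)
        if shift >= 0:
            if shift < rows:
                shifted[shift:] = mask[: rows - shift]
        else:
            shifted[:shift] = mask[-shift:]
        mask = shifted
        if mask.any() and not mask[0].any():
            break
    else:
        raise RuntimeError("could not place a lesion inside the field of view")

    # Layered background: smooth horizontal strata + depth attenuation.
    depth_mm = np.arange(rows)[:, None] * spec.row_spacing_mm
    strata = ndimage.gaussian_filter1d(rng.normal(0, 1, rows), sigma=6)
    echo = 0.62 + 0.10 * strata[:, None] + np.zeros((rows, cols))
    echo *= np.exp(-spec.attenuation_per_mm * depth_mm)
    # Hypoechoic lesion with a diffuse edge and mild internal heterogeneity.
    lesion_soft = ndimage.gaussian_filter(mask.astype(float), sigma=tex["edge_sigma"])
    heterogeneity = 1.0 + 0.10 * ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), sigma=4)
    echo *= 1.0 - (1.0 - tex["contrast"] * heterogeneity) * lesion_soft
    # Multiplicative correlated speckle (Rayleigh, unit mean).
    rayleigh = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=(rows, cols))
    speckle = ndimage.gaussian_filter(rayleigh, sigma=0.8)
    pixels = echo * (1.0 + tex["speckle"] * (speckle - speckle.mean()))
    pixels = np.clip(pixels, 0.0, None)
    pixels /= max(pixels.max(), 1e-12)

    img = USImage(
        pixels=pixels,
        row_spacing_mm=spec.row_spacing_mm,
        col_spacing_mm=spec.col_spacing_mm,
        patient_id=patient_id,
        image_id=image_id,
        meta={"margin_mm": margin_mm, "diameter_mm": diameter_mm, "domain": spec.domain},
    )
    return img, mask.astype(np.uint8)


def generate_raw_phantom(spec: PhantomSpec, patient_seed: int, **kw) -> tuple[USImage, np.ndarray]:
    """Phantom at the 430 x 344 acquisition geometry (for the crop/resize path)."""
    from dataclasses import replace

    raw_spec = replace(
        spec,
        image_shape=RAW_SHAPE,
        row_spacing_mm=RAW_ROW_SPACING_MM,
        col_spacing_mm=RAW_COL_SPACING_MM,
        margin_bounds_mm=spec.margin_bounds_mm,
    )
    return generate_phantom(raw_spec, patient_seed, **kw)


def generate_dataset(
    spec: PhantomSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[USImage, np.ndarray]], pd.DataFrame]:
    """Generate a patient-wise split dataset and its manifest.

    Patients are assigned whole to train/validation/test in the configured
    proportions (no patient spans splits); each contributes 1-3 frames that
    share lesion geometry up to jitter. Returns the (image, mask) list and
    a manifest DataFrame (image_id, patient_id, split, margin_mm); when
    ``out_dir`` is given, PNGs and ``manifest.csv`` are written there.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_patients < 3:
        raise ValueError("need at least 3 patients to populate all splits")

    order = rng.permutation(spec.n_patients)
    n_val = max(1, round(spec.split_fractions[1] * spec.n_patients))
    n_test = max(1, round(spec.split_fractions[2] * spec.n_patients))
    split_of = {}
    for idx, p in enumerate(order):
        if idx < n_test:
            split_of[p] = "test"
        elif idx < n_test + n_val:
            split_of[p] = "val"
        else:
            split_of[p] = "train"

    samples: list[tuple[USImage, np.ndarray]] = []
    records = []
    lo, hi = spec.images_per_patient
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        n_images = int(rng.integers(lo, hi + 1))
        geometry = None
        for i in range(n_images):
            image_id = f"{patient_id}_I{i}"
            img, mask = generate_phantom(
                spec,
                patient_seed=int(rng.integers(0, 2**31 - 1)),
                patient_id=patient_id,
                image_id=image_id,
                geometry=geometry,
            )
            if geometry is None:
                geometry = {
                    "margin_mm": img.meta["margin_mm"],
                    "diameter_mm": img.meta["diameter_mm"],
                    "center_col": spec.image_shape[1] / 2,
                }
            samples.append((img, mask))
            records.append(
                {
                    "image_id": image_id,
                    "patient_id": patient_id,
                    "split": split_of[p],
                    "margin_mm": img.meta["margin_mm"],
                    "domain": spec.domain,
                }
            )
    manifest = pd.DataFrame.from_records(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, mask in samples:
            write_image(out / f"{img.image_id}.png", img.pixels)
            write_mask(out / f"{img.image_id}_mask.png", mask)
        manifest.to_csv(out / "manifest.csv", index=False)
    return samples, manifest


def tradeoff_probability_maps(
    n_images: int = 8,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Construct (truths, probability maps) with a Dice/margin trade-off.

    Each map assigns high confidence (0.9) to the tumor core but only 0.35
    to the tumor's top rows, and adds a large 0.35-confidence false-positive
    region well below the tumor. Binarizing at a low threshold recovers the
    true top margin at the price of the false positives (good margin, worse
    Dice); a mid threshold drops both (best Dice, margin off by the height
    of the faint cap). The optimal thresholds for the two metrics therefore
    differ — the geometry behind threshold-sweep optimization.
    """
    rng = np.random.default_rng(seed)
    truths, maps = [], []
    rows, cols = shape
    for _ in range(n_images):
        truth = np.zeros(shape, dtype=np.uint8)
        top = int(rng.integers(8, 14))
        bottom = int(rng.integers(30, 38))
        left = int(rng.integers(8, 14))
        right = cols - int(rng.integers(8, 14))
        truth[top:bottom, left:right] = 1

        pmap = np.zeros(shape)
        cap = 3  # faint rows at the tumor top
        pmap[top + cap : bottom, left:right] = 0.9
        pmap[top : top + cap, left:right] = 0.35
        # Distractor blob far below the tumor, sized to dent the Dice score
        # whenever the threshold dips low enough to include the faint cap.
        d_top = min(bottom + 8, rows - 10)
        pmap[d_top : d_top + 8, left:right] = 0.35
        truths.append(truth)
        maps.append(pmap)
    return truths, maps
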