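"""Synthetic phantom cohort: PET/CT volumes, dual-reader masks, outcomes.

No images from the clinical study this pipeline emulates were ever deposited,
so every downstream stage is exercised on phantoms with the statistical
structure the analysis assumes:

* multi-lesion FDG-avid tumor burden over a low background, plus a liver
  reference region for PERCIST-style thresholding;
* per-patient latent lesion-intensity *median* and *skewness*, realized by a
  shifted-gamma sampler whose closed-form skewness (2/sqrt(shape)) makes the
  generator testable against an analytic oracle;
* a logistic link from (skewness, median) to treatment non-response and a
  Weibull proportional-hazards link to progression-free survival, so the
  selection/model/survival stages have a known signal to recover;
* a second reader emulated by random morphological perturbation of the first
  reader's tumor mask, giving controllable inter-reader agreement.

The default cohort composition (44 patients; responder/non-responder 33/11;
TPS groups 21/13/10) mirrors the published NSCLC cohort the defaults emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomPlacementError, UnsupportedParameterError
from .grids import RoiMask, VoxelGrid

# Composition of the reference 44-patient cohort the generator's defaults
# emulate (second follow-up RECIST categories and PD-L1 TPS groups).
REFERENCE_RECIST_COUNTS: dict[str, int] = {"CR": 1, "PR": 17, "SD": 15, "PD": 11}
REFERENCE_TPS_COUNTS: dict[str, int] = {"TPS>=50": 21, "TPS1-49": 13, "TPS<1": 10}

TPS_LEVELS = ("TPS>=50", "TPS1-49", "TPS<1")
RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")

COHORT_COLUMNS = [
    "patient_id", "recist", "responder", "overall_progression",
    "pfs_months", "event", "tps_group",
]

# Threshold below which a skewness target is realized by the normal limit of
# the gamma family (shape -> infinity).
_SKEW_EPS = 1e-3


@dataclass
class SyntheticConfig:
    """All knobs of the phantom-cohort generator.

    SUV parameters are in SUV units, spacing in mm, survival times in months.
    The logistic coefficients act on the latent per-patient lesion skewness
    and median; positive ``beta_skew`` means higher skewness -> higher
    probability of non-response, negative ``beta_median`` means higher median
    -> lower probability, matching the direction reported for the clinical
    cohort. ``gamma_*`` are log-hazard coefficients of the Weibull PH model
    for PFS.
    """

    n_patients: int = 44
    lesions_min: int = 1
    lesions_max: int = 4
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    liver_mean_suv: float = 2.0
    liver_sd_suv: float = 0.25
    background_suv: float = 0.8
    background_noise_suv: float = 0.1
    lesion_median_range: tuple[float, float] = (6.0, 12.0)
    lesion_skew_range: tuple[float, float] = (0.1, 2.5)
    lesion_sigma_suv: float = 0.8
    beta0: float = -3.5
    beta_skew: float = 3.0
    beta_median: float = -0.25
    weibull_shape: float = 1.2
    base_scale: float = 2.8
    gamma_skew: float = 0.7
    gamma_median: float = -0.30
    censor_horizon_months: float = 24.0
    accrual_window_months: tuple[float, float] = (6.0, 57.0)
    reader2_perturb_iters: int = 1
    tps_probs: tuple[float, float, float] = (21 / 44, 13 / 44, 10 / 44)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def implied_percist_threshold(self) -> float:
        return 1.5 * self.liver_mean_suv + 2.0 * self.liver_sd_suv

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not (0 < self.lesions_min <= self.lesions_max):
            raise ValueError("lesion count range invalid")
        if abs(sum(self.tps_probs) - 1.0) > 1e-9:
            raise ValueError("tps_probs must sum to 1")
        for name in ("liver_mean_suv", "liver_sd_suv", "background_suv",
                     "lesion_sigma_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.lesion_median_range
        if not lo <= hi:
            raise ValueError("lesion_median_range inverted")
        # Lesions must live strictly above the PERCIST threshold implied by
        # the liver parameters, with a 3-sigma margin on the intensity spread,
        # so PERCIST segmentation recovers exactly the planted voxels.
        if lo - 3.0 * self.lesion_sigma_suv <= self.implied_percist_threshold:
            raise ValueError(
                "lesion_median_range lower bound too close to the implied "
                f"PERCIST threshold {self.implied_percist_threshold:.2f}"
            )
        if self.weibull_shape <= 0 or self.base_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be positive")
        if self.reader2_perturb_iters < 0:
            raise ValueError("reader2_perturb_iters must be >= 0")

    # --- flat key = value round trip -------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "SyntheticConfig":
        kwargs: dict = {}
        types = {f.name: f for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, tuple):
                parts = [p for p in raw.split(",") if p]
                elem = int if all(isinstance(x, int) for x in default) else float
                kwargs[key] = tuple(elem(p) for p in parts)
            elif isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class SyntheticPatient:
    """One phantom: volumes, masks, latent truth and the outcome row.

    ``lesion_mask`` is the full FDG-avid region (core plus rim) the PERCIST
    threshold recovers; the reader masks are the two manual adjustments of
    it, which differ only at the rim.
    """

    patient_id: str
    pet: VoxelGrid
    ct: VoxelGrid
    liver_mask: RoiMask
    lesion_mask: RoiMask
    tumor_mask_reader1: RoiMask
    tumor_mask_reader2: RoiMask
    true_median: float
    true_skewness: float
    outcome_row: dict


def _gamma_shape_for_skewness(skew: float) -> float:
    """Gamma shape k with skewness 2/sqrt(k); defined for skew > 0 only."""
    if skew <= 0:
        raise UnsupportedParameterError(
            "gamma family supports strictly positive skewness targets"
        )
    return (2.0 / skew) ** 2


def sample_lesion_intensities(median_target: float, skew_target: float,
                              n: int, rng: np.random.Generator,
                              sigma: float = 0.8) -> np.ndarray:
    """Draw ``n`` SUV values with prescribed empirical median and skewness.

    Shifted-gamma family: the skewness target fixes the gamma shape via the
    closed form skew = 2/sqrt(shape); ``sigma`` sets the spread; the sample is
    then shifted so its empirical median equals ``median_target`` exactly.
    Negative targets use the mirrored gamma; |skew| below 1e-3 uses the
    normal limit.
    """
    if n < 10:
        raise ValueError("need n >= 10 voxels for a lesion sample")
    if abs(skew_target) < _SKEW_EPS:
        raw = rng.normal(0.0, sigma, size=n)
    else:
        shape = _gamma_shape_for_skewness(abs(skew_target))
        scale = sigma / math.sqrt(shape)
        raw = rng.gamma(shape, scale, size=n)
        if skew_target < 0:
            raw = -raw
    return raw - np.median(raw) + median_target


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray,
                    semi_axes_vox: np.ndarray) -> np.ndarray:
    lo = np.maximum(np.floor(center - semi_axes_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center + semi_axes_vox).astype(int) + 2,
                    np.asarray(shape))
    out = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                        indexing="ij")
    d = sum(((grids[i] - center[i]) / semi_axes_vox[i]) ** 2 for i in range(3))
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d <= 1.0
    return out


def _liver_mask(config: SyntheticConfig) -> np.ndarray:
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.spacing_mm)
    center = shape * np.array([0.30, 0.35, 0.50])
    semi_axes = np.array([40.0, 34.0, 26.0]) / spacing
    return _ellipsoid_mask(config.grid_shape, center, semi_axes)


def _place_lesions(config: SyntheticConfig, liver: np.ndarray,
                   rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Union mask of ellipsoidal lesions avoiding the (dilated) liver."""
    shape = np.asarray(config.grid_shape)
    forbidden = ndimage.binary_dilation(liver, iterations=2)
    n_lesions = int(rng.integers(config.lesions_min, config.lesions_max + 1))
    union = np.zeros(config.grid_shape, dtype=bool)
    placed = 0
    tries = 0
    while placed < n_lesions:
        if tries >= max_tries:
            raise PhantomPlacementError(
                f"could not place lesion {placed + 1}/{n_lesions} "
                f"after {max_tries} tries"
            )
        tries += 1
        semi = rng.uniform(2.0, 4.5, size=3)
        margin = semi + 2
        center = rng.uniform(margin, shape - margin)
        lesion = _ellipsoid_mask(config.grid_shape, center, semi)
        if np.any(lesion & forbidden):
            continue
        union |= lesion
        placed += 1
    return union


def _perturb_mask(reader1: np.ndarray, core: np.ndarray, halo: np.ndarray,
                  iters: int, rng: np.random.Generator,
                  edit_fraction: float = 0.2) -> np.ndarray:
    """Reader-2 emulation: random dilate/erode rounds restricted to the halo.

    Manual adjustment of a threshold-defined volume differs between readers
    only at the lesion rim, so each round randomly flips membership of halo
    voxels (adding = partial dilation, removing = partial erosion) while the
    lesion core is never touched: agreement degrades gradually with the
    iteration count, the mask never empties, and both readers always overlap.
    """
    out = reader1.copy()
    halo_idx = np.argwhere(halo)
    for _ in range(iters):
        flip = halo_idx[rng.random(len(halo_idx)) < edit_fraction]
        out[tuple(flip.T)] = ~out[tuple(flip.T)]
    assert np.all(out[core])
    return out


def draw_outcomes(config: SyntheticConfig, skew: float, median: float,
                  rng: np.random.Generator, patient_id: str = "") -> dict:
    """Outcome row for one patient given its latent lesion statistics.

    Non-response ~ Bernoulli(logistic(beta0 + beta_skew*skew +
    beta_median*median)); PFS ~ Weibull PH with log hazard gamma_skew*skew +
    gamma_median*median; censoring at min(censor horizon, per-patient
    administrative follow-up); TPS group ~ multinomial(tps_probs).
    """
    eta = config.beta0 + config.beta_skew * skew + config.beta_median * median
    p_nonresponse = 1.0 / (1.0 + math.exp(-eta))
    non_responder = bool(rng.random() < p_nonresponse)
    if non_responder:
        recist = "PD"
    else:
        counts = np.array([REFERENCE_RECIST_COUNTS[c] for c in ("CR", "PR", "SD")],
                          dtype=float)
        recist = str(rng.choice(["CR", "PR", "SD"], p=counts / counts.sum()))

    lp = config.gamma_skew * skew + config.gamma_median * median
    u = rng.random()
    t_event = config.base_scale * (-math.log(u) / math.exp(lp)) ** (1.0 / config.weibull_shape)
    admin = rng.uniform(*config.accrual_window_months)
    t_censor = min(config.censor_horizon_months, admin)
    event = bool(t_event <= t_censor)
    pfs = min(t_event, t_censor)

    tps_group = str(rng.choice(list(TPS_LEVELS), p=np.asarray(config.tps_probs)))
    return {
        "patient_id": patient_id,
        "recist": recist,
        "responder": not non_responder,
        "overall_progression": event,
        "pfs_months": float(pfs),
        "event": event,
        "tps_group": tps_group,
    }


def generate_phantom(config: SyntheticConfig, patient_index: int,
                     rng: np.random.Generator | None = None) -> SyntheticPatient:
    """One phantom patient; deterministic given (config.seed, patient_index).

    The per-patient substream is seeded as ``config.seed + patient_index`` so
    a cohort can be extended without regenerating earlier patients.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + patient_index)
    patient_id = f"P{patient_index:04d}"
    shape, spacing = config.grid_shape, config.spacing_mm

    # Latent lesion-intensity statistics first, then geometry, then outcomes:
    # a fixed draw order is part of the determinism contract.
    true_median = float(rng.uniform(*config.lesion_median_range))
    true_skew = float(rng.uniform(*config.lesion_skew_range))

    liver = _liver_mask(config)
    core = _place_lesions(config, liver, rng)
    struct = ndimage.generate_binary_structure(3, 1)
    halo = ndimage.binary_dilation(core, structure=struct) & ~core & ~liver
    lesion = core | halo

    pet = rng.normal(config.background_suv, config.background_noise_suv,
                     size=shape)
    np.clip(pet, 0.05, None, out=pet)
    pet[liver] = rng.normal(config.liver_mean_suv, config.liver_sd_suv,
                            size=int(liver.sum()))
    lesion_values = sample_lesion_intensities(
        true_median, true_skew, int(lesion.sum()), rng,
        sigma=config.lesion_sigma_suv,
    )
    # Belt over the validated 3-sigma margin: PERCIST must keep every voxel.
    np.clip(lesion_values, config.implied_percist_threshold + 0.2, None,
            out=lesion_values)
    pet[lesion] = lesion_values

    # Low-dose CT: smoothed HU texture, denser soft tissue in liver/tumor,
    # deliberately carrying no outcome signal.
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), 1.5)
    texture /= max(texture.std(), 1e-12)
    ct = -70.0 + 25.0 * texture
    ct[liver] += 130.0
    ct[lesion] += 110.0

    # Reader 1 trims about half the rim of the thresholded volume; reader 2
    # starts from reader 1 and re-edits the rim for the configured rounds.
    halo_idx = np.argwhere(halo)
    reader1 = core.copy()
    keep = halo_idx[rng.random(len(halo_idx)) < 0.5]
    reader1[tuple(keep.T)] = True
    reader2 = _perturb_mask(reader1, core, halo,
                            config.reader2_perturb_iters, rng)

    outcome = draw_outcomes(config, true_skew, true_median, rng, patient_id)

    return SyntheticPatient(
        patient_id=patient_id,
        pet=VoxelGrid(pet, spacing),
        ct=VoxelGrid(ct, spacing),
        liver_mask=RoiMask(liver, spacing, reader="auto", role="liver"),
        lesion_mask=RoiMask(lesion, spacing, role="tumor"),
        tumor_mask_reader1=RoiMask(reader1, spacing, reader="R1", role="tumor"),
        tumor_mask_reader2=RoiMask(reader2, spacing, reader="R2", role="tumor"),
        true_median=true_median,
        true_skewness=true_skew,
        outcome_row=outcome,
    )


def generate_cohort(config: SyntheticConfig) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Full phantom cohort plus its outcome table (one row per patient)."""
    patients = [generate_phantom(config, i) for i in range(config.n_patients)]
    table = pd.DataFrame([p.outcome_row for p in patients], columns=COHORT_COLUMNS)
    return patients, table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("responder", "overall_progression", "event"):
        table[col] = table[col].astype(bool)
    return table


def save_patient_volumes(patient: SyntheticPatient, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = patient.patient_id
    patient.pet.to_nifti(outdir / f"{pid}_pet.nii.gz")
    patient.ct.to_nifti(outdir / f"{pid}_ct.nii.gz")
    patient.liver_mask.to_nifti(outdir / f"{pid}_liver.nii.gz")
    patient.tumor_mask_reader1.to_nifti(outdir / f"{pid}_tumor_r1.nii.gz")
    patient.tumor_mask_reader2.to_nifti(outdir / f"{pid}_tumor_r2.nii.gz")
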