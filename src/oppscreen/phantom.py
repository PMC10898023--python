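"""Synthetic axial vertebral CT phantoms.

Each phantom slice shows an elliptical vertebral body on a soft-tissue
background: a bright cortical rim, a textured trabecular interior whose
mean intensity encodes the trabecular bone mineral density through a
linear calibration (identity by default, so intensity is numerically
BMD in mg/cm3), and optionally a small dark basivertebral vessel void in
the posterior third of the body.  Cohorts reproduce the three-class
structure of an adult health-check population: per-class truncated-normal
BMD distributions, class mix, and paired L1/L2 vertebrae that share a
subject-level BMD up to a small jitter.

The ground-truth mask is the set of pixels strictly inside the inner
edge of the cortical rim — exactly the region a radiologist outlines
for quantitative-CT measurement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .errors import ConfigurationError, ValidationError
from .qct import LABELS, classify_bmd, subject_bmd

__all__ = ["PhantomSpec", "CohortSpec", "PhantomSubject", "generate_subject",
           "generate_cohort", "write_cohort", "load_slice", "save_slice",
           "STUDY_CLASS_COUNTS", "STUDY_CLASS_BMD"]

# Cohort structure of the motivating health-check population:
# (normal, osteopenia, osteoporosis) counts of 1048 subjects and the
# per-class BMD mean, sd and observed range in mg/cm3.
STUDY_CLASS_COUNTS = (621, 296, 131)
STUDY_CLASS_BMD = {
    "normal": (168.33, 23.12, 120.30, 295.10),
    "osteopenia": (99.35, 10.91, 80.00, 120.00),
    "osteoporosis": (60.32, 16.48, 5.70, 79.90),
}
_BMD_RANGE = (5.70, 295.10)
PNG_SCALE = 100.0  # intensity units per uint16 step when writing 16-bit PNG


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and calibration of a single phantom slice."""

    image_size: int = 512
    vertebra_axes: tuple[float, float] = (0.26, 0.20)  # semi-axes / image_size
    cortical_thickness: int = 6                         # pixels
    cortical_intensity: float = 420.0
    trabecular_noise_sd: float = 25.0
    texture_blob_fraction: float = 0.15  # low-freq blob sd as fraction of noise sd
    vessel_probability: float = 0.5
    vessel_radius_fraction: float = 0.12  # of the minor inner semi-axis
    vessel_depth: float = 35.0            # intensity drop inside the void
    background_level: float = 40.0
    background_noise_sd: float = 10.0
    calibration_slope: float = 1.0
    calibration_intercept: float = 0.0
    center_jitter_fraction: float = 0.02
    axis_jitter_fraction: float = 0.05

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        ax, ay = self.vertebra_axes
        max_frac = max(ax * (1 + self.axis_jitter_fraction),
                       ay * (1 + self.axis_jitter_fraction)) \
            + self.center_jitter_fraction
        if max_frac >= 0.5:
            raise ConfigurationError(
                "vertebra ellipse (with jitter) exceeds the image bounds")
        if min(ax, ay) * self.image_size * (1 - self.axis_jitter_fraction) \
                <= self.cortical_thickness + 2:
            raise ConfigurationError("cortical rim leaves no trabecular interior")
        hi_mean = self.calibration_slope * _BMD_RANGE[1] + self.calibration_intercept
        lo_mean = self.calibration_slope * _BMD_RANGE[0] + self.calibration_intercept
        if self.cortical_intensity <= max(hi_mean, lo_mean):
            raise ConfigurationError(
                "cortical rim intensity must exceed the trabecular mean over "
                f"the cohort BMD range {_BMD_RANGE}")

    @classmethod
    def desk(cls, image_size: int = 96, **kw) -> "PhantomSpec":
        """Reduced-size profile for CPU-scale experiments."""
        kw.setdefault("cortical_thickness", max(2, round(6 * image_size / 512)))
        return cls(image_size=image_size, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "vertebra_axes" in d:
            d["vertebra_axes"] = tuple(d["vertebra_axes"])
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic screening cohort.

    ``class_counts`` is (normal, osteopenia, osteoporosis).  Per-class BMD
    is sampled from a normal distribution truncated to the stated bounds;
    bounds must respect the label cut-offs (80/120 mg/cm3).  Each subject
    draws one subject-level BMD; L1/L2 get +/- a half-jitter so their mean
    is exactly the subject value and the label stays consistent.
    """

    n_subjects: int = 1048
    class_counts: tuple[int, int, int] = STUDY_CLASS_COUNTS
    bmd_params: dict = field(default_factory=lambda: dict(STUDY_CLASS_BMD))
    jitter_sd: float = 4.0         # sd of the L1/L2 half-difference, mg/cm3
    sample_demographics: bool = True
    seed: int = 0

    def __post_init__(self):
        if sum(self.class_counts) != self.n_subjects:
            raise ConfigurationError(
                f"class counts {self.class_counts} do not sum to {self.n_subjects}")
        if any(c < 0 for c in self.class_counts):
            raise ConfigurationError("class counts must be non-negative")
        bounds = {"normal": (120.0, np.inf), "osteopenia": (80.0, 120.0),
                  "osteoporosis": (0.0, 80.0)}
        for lab in LABELS:
            mean, sd, lo, hi = self.bmd_params[lab]
            blo, bhi = bounds[lab]
            if lo < blo - 1e-9 or hi > bhi + 1e-9 or lo >= hi or sd <= 0:
                raise ConfigurationError(
                    f"{lab}: truncation [{lo}, {hi}] incompatible with the "
                    f"label bounds [{blo}, {bhi}] or sd <= 0")
            if not (lo <= mean <= hi) and not (blo <= mean <= bhi):
                raise ConfigurationError(
                    f"{lab}: mean {mean} outside the feasible label range")

    @classmethod
    def scaled(cls, n_subjects: int, seed: int = 0, **kw) -> "CohortSpec":
        """Cohort of ``n_subjects`` at the reference cohort's 621:296:131 class mix."""
        w = np.array(STUDY_CLASS_COUNTS, dtype=float)
        w /= w.sum()
        base = np.floor(w * n_subjects).astype(int)
        rem = n_subjects - base.sum()
        order = np.argsort(-(w * n_subjects - base), kind="stable")
        base[order[:rem]] += 1
        return cls(n_subjects=n_subjects, class_counts=tuple(int(c) for c in base),
                   seed=seed, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_counts"] = list(self.class_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["class_counts"] = tuple(d["class_counts"])
        if "bmd_params" in d:
            d["bmd_params"] = {k: tuple(v) for k, v in d["bmd_params"].items()}
        return cls(**d)


@dataclass
class PhantomSubject:
    subject_id: str
    l1_slice: np.ndarray
    l2_slice: np.ndarray
    l1_mask: np.ndarray
    l2_mask: np.ndarray
    true_bmd_l1: float
    true_bmd_l2: float
    true_label: str
    sex: str | None = None
    age: float | None = None

    @property
    def true_bmd_individual(self) -> float:
        return subject_bmd(self.true_bmd_l1, self.true_bmd_l2)


def _render_slice(spec: PhantomSpec, bmd: float, rng: np.random.Generator):
    """One axial slice + ground-truth mask for a given trabecular BMD."""
    n = spec.image_size
    img = np.full((n, n), spec.background_level, dtype=np.float64)
    if spec.background_noise_sd > 0:
        img += rng.normal(0.0, spec.background_noise_sd, size=(n, n))

    jc = spec.center_jitter_fraction * n
    cy = n / 2.0 + rng.uniform(-jc, jc)
    cx = n / 2.0 + rng.uniform(-jc, jc)
    aj = spec.axis_jitter_fraction
    ax = spec.vertebra_axes[0] * n * (1.0 + rng.uniform(-aj, aj))
    ay = spec.vertebra_axes[1] * n * (1.0 + rng.uniform(-aj, aj))

    yy, xx = np.mgrid[0:n, 0:n]
    r_outer = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    ax_in, ay_in = ax - spec.cortical_thickness, ay - spec.cortical_thickness
    r_inner = ((xx - cx) / ax_in) ** 2 + ((yy - cy) / ay_in) ** 2
    outer = r_outer <= 1.0
    mask = r_inner < 1.0          # strictly inside the inner rim edge
    rim = outer & ~mask

    img[rim] = spec.cortical_intensity
    mean_int = spec.calibration_slope * bmd + spec.calibration_intercept
    interior = np.full(mask.sum(), mean_int)
    if spec.trabecular_noise_sd > 0:
        interior = interior + rng.normal(0.0, spec.trabecular_noise_sd,
                                         size=interior.size)
        blob_sd = spec.texture_blob_fraction * spec.trabecular_noise_sd
        if blob_sd > 0:
            low = ndimage.gaussian_filter(
                rng.normal(0.0, 1.0, size=(n, n)), sigma=n / 16.0)
            s = low.std()
            if s > 0:
                interior = interior + blob_sd * (low[mask] - low[mask].mean()) / s
    img[mask] = interior

    if spec.vessel_probability > 0 and rng.uniform() < spec.vessel_probability:
        # basivertebral vessel: small dark disc, posterior third of the body
        vr = max(1.5, spec.vessel_radius_fraction * min(ax_in, ay_in))
        vy = cy + 0.55 * ay_in
        vx = cx + rng.uniform(-0.2, 0.2) * ax_in
        vdisc = ((xx - vx) ** 2 + (yy - vy) ** 2) <= vr ** 2
        img[vdisc & mask] -= spec.vessel_depth

    return img, mask.astype(np.uint8)


def generate_subject(spec: PhantomSpec, bmd_l1: float, bmd_l2: float,
                     seed: int, subject_id: str = "S0",
                     sex: str | None = None, age: float | None = None) -> PhantomSubject:
    """Deterministically generate one subject (two slices + masks)."""
    for v in (bmd_l1, bmd_l2):
        if not (1.0 <= v <= 400.0):
            raise ValidationError(f"BMD {v} outside the supported range [1, 400]")
    rng = np.random.default_rng(seed)
    l1, m1 = _render_slice(spec, bmd_l1, rng)
    l2, m2 = _render_slice(spec, bmd_l2, rng)
    label = classify_bmd(subject_bmd(bmd_l1, bmd_l2))
    return PhantomSubject(subject_id=subject_id, l1_slice=l1, l2_slice=l2,
                          l1_mask=m1, l2_mask=m2, true_bmd_l1=float(bmd_l1),
                          true_bmd_l2=float(bmd_l2), true_label=label,
                          sex=sex, age=age)


from functools import lru_cache


@lru_cache(maxsize=None)
def _matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Parent-normal (mu, sigma) whose [lo, hi]-truncation has the given
    mean and sd.  The printed cohort statistics are moments of the
    truncated data, so sampling with the raw parameters would bias the
    class means; falls back to the raw parameters if the solve fails."""
    from scipy.optimize import fsolve

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, _ = fsolve(moments, [mean, np.log(sd)], full_output=True)
    if ier != 1 or np.abs(info["fvec"]).max() > 1e-6:
        return float(mean), float(sd)
    return float(sol[0]), float(np.exp(sol[1]))


def _truncnorm(mean, sd, lo, hi, size, rng):
    mu, sigma = _matched_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


# Label-feasible BMD interval per class (used to keep jittered L1/L2 in range)
_CLASS_INTERVAL = {"normal": (120.0 + 1e-6, 400.0),
                   "osteopenia": (80.0, 120.0),
                   "osteoporosis": (1.0, 80.0 - 1e-6)}


def generate_cohort(cohort: CohortSpec, spec: PhantomSpec,
                    ) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate a cohort of phantom subjects and its metadata table."""
    rng = np.random.default_rng(cohort.seed)
    ss = np.random.SeedSequence(cohort.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(cohort.n_subjects)]

    labels: list[str] = []
    subject_means: list[float] = []
    for lab, count in zip(LABELS, cohort.class_counts):
        if count == 0:
            continue
        mean, sd, lo, hi = cohort.bmd_params[lab]
        subject_means.extend(_truncnorm(mean, sd, lo, hi, count, rng))
        labels.extend([lab] * count)

    perm = rng.permutation(cohort.n_subjects)
    subjects: list[PhantomSubject] = []
    rows = []
    for i, j in enumerate(perm):
        m, lab = float(subject_means[j]), labels[j]
        lo, hi = max(_CLASS_INTERVAL[lab][0], 1.0), min(_CLASS_INTERVAL[lab][1], 400.0)
        dmax = min(m - lo, hi - m)
        d = rng.normal(0.0, cohort.jitter_sd)
        if abs(d) > dmax:                 # keep both vertebrae inside the class range
            d = np.sign(d) * dmax
        bmd_l1, bmd_l2 = m + d, m - d
        if classify_bmd(subject_bmd(bmd_l1, bmd_l2)) != lab:
            bmd_l1 = bmd_l2 = m   # float rounding at a class boundary
        sex = age = None
        if cohort.sample_demographics:
            sex = "male" if rng.uniform() < 605 / 1048 else "female"
            age = float(np.clip(rng.normal(51.19, 14.35), 20, 92))
        subj = generate_subject(spec, bmd_l1, bmd_l2, child_seeds[i],
                                subject_id=f"S{i:05d}", sex=sex, age=age)
        subjects.append(subj)
        rows.append(dict(subject_id=subj.subject_id, age=age, sex=sex,
                         bmd_l1=bmd_l1, bmd_l2=bmd_l2, label=lab))
    meta = pd.DataFrame(rows)
    return subjects, meta


# ---------------------------------------------------------------------------
# disk formats: 16-bit PNG or single-slice NIfTI, masks as 8-bit PNG {0,255}
# or NIfTI {0,1}; metadata CSV; specs as YAML
# ---------------------------------------------------------------------------

def save_slice(arr: np.ndarray, path: Path, fmt: str = "png") -> Path:
    path = Path(path)
    if fmt == "png":
        from PIL import Image
        scaled = np.clip(np.round(np.asarray(arr) * PNG_SCALE), 0, 65535)
        Image.fromarray(scaled.astype(np.uint16)).save(path.with_suffix(".png"))
        return path.with_suffix(".png")
    if fmt == "nifti":
        import nibabel as nib
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[..., None],
                              affine=np.eye(4))
        nib.save(img, str(path.with_suffix(".nii.gz")))
        return path.with_suffix(".nii.gz")
    raise ValidationError(f"unknown image format {fmt!r}")


def load_slice(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        from PIL import Image
        arr = np.asarray(Image.open(path))
        if arr.dtype == np.uint16:   # 16-bit intensity image
            return arr.astype(np.float64) / PNG_SCALE
        return arr.astype(np.float64)   # 8-bit mask {0,255}
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64).squeeze()


def _save_mask(mask: np.ndarray, path: Path, fmt: str) -> Path:
    if fmt == "png":
        from PIL import Image
        Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(
            path.with_suffix(".png"))
        return path.with_suffix(".png")
    import nibabel as nib
    img = nib.Nifti1Image((np.asarray(mask) > 0).astype(np.uint8)[..., None],
                          affine=np.eye(4))
    nib.save(img, str(path.with_suffix(".nii.gz")))
    return path.with_suffix(".nii.gz")


def load_mask(path: Path) -> np.ndarray:
    arr = load_slice(path)
    return (arr > 0).astype(np.uint8)


def write_cohort(subjects: list[PhantomSubject], meta: pd.DataFrame,
                 out_dir: Path, fmt: str = "png") -> Path:
    """Write slices, masks and the metadata CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    meta = meta.copy()
    paths: dict[str, list[str]] = {k: [] for k in
                                   ("l1_path", "l2_path", "l1_mask_path", "l2_mask_path")}
    for subj in subjects:
        sid = subj.subject_id
        paths["l1_path"].append(str(
            save_slice(subj.l1_slice, img_dir / f"{sid}_l1", fmt).relative_to(out_dir)))
        paths["l2_path"].append(str(
            save_slice(subj.l2_slice, img_dir / f"{sid}_l2", fmt).relative_to(out_dir)))
        paths["l1_mask_path"].append(str(
            _save_mask(subj.l1_mask, img_dir / f"{sid}_l1_mask", fmt).relative_to(out_dir)))
        paths["l2_mask_path"].append(str(
            _save_mask(subj.l2_mask, img_dir / f"{sid}_l2_mask", fmt).relative_to(out_dir)))
    for k, v in paths.items():
        meta[k] = v
    cols = ["subject_id", "age", "sex", "l1_path", "l2_path",
            "l1_mask_path", "l2_mask_path", "bmd_l1", "bmd_l2", "label"]
    csv_path = out_dir / "cohort.csv"
    meta[cols].to_csv(csv_path, index=False)
    return csv_path


def save_specs_yaml(path: Path, phantom: PhantomSpec, cohort: CohortSpec | None = None):
    doc = {"phantom": phantom.to_dict()}
    if cohort is not None:
        doc["cohort"] = cohort.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_specs_yaml(path: Path) -> tuple[PhantomSpec, CohortSpec | None]:
    doc = yaml.safe_load(Path(path).read_text())
    ph = PhantomSpec.from_dict(doc["phantom"])
    co = CohortSpec.from_dict(doc["cohort"]) if "cohort" in doc else None
    return ph, co
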