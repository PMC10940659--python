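"""Desk-scale synthetic cohorts with the statistical structure of clinical
imaging datasets.

Two generators are provided.  ``generate_cxr_like`` emits 2D radiograph-style
images: a smooth random background plus one localized Gaussian bump per
positive finding (left/right findings live in the corresponding image half),
clutter bumps emulating tubes/devices, and subgroup-dependent image quality —
harder subgroups get noisier, more cluttered images with fainter findings.
Severity of a finding (the clinical 5-level vocabulary) increases monotonically
with the rendered bump contrast.  ``generate_ct_like`` emits 3D volumes in a
Hounsfield-like value range where positive records carry a hyperdense
ellipsoidal lesion in a fixed anatomical sub-region.

Label co-occurrence is induced by a Gaussian copula: one latent severity
factor per record couples the per-label positivity draws with correlation
``label_correlation``.

These are statistical stand-ins, not anatomical simulations: prevalences,
subgroup proportions and difficulty gradients are controllable and
recoverable, which is what the downstream privacy/fairness analysis needs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .preprocessing import binarize_labels

__all__ = [
    "SubgroupSpec",
    "DatasetSpec",
    "ImageRecord",
    "LabeledImageSet",
    "generate_cxr_like",
    "generate_ct_like",
    "split_patientwise",
    "cxr_desk_spec",
    "clinical_subgroup_grid",
    "pdac_desk_spec",
    "AGE_BINS",
]

#: Age bins used for subgroup reporting.
AGE_BINS: tuple[str, ...] = ("[0,30)", "[30,60)", "[60,70)", "[70,80)", "[80,100)")

#: Training-cohort age-bin proportions of the emulated radiograph dataset
#: (counts 4279 / 42340 / 36882 / 48864 / 21137 of 153502).
AGE_PROPORTIONS: tuple[float, ...] = (
    4279 / 153502, 42340 / 153502, 36882 / 153502, 48864 / 153502, 21137 / 153502,
)

#: Male share of the emulated radiograph training cohort (100659 / 153502).
MALE_PROPORTION: float = 100659 / 153502

_POSITIVE_SEVERITIES = ("mild", "moderate", "severe")
_POSITIVE_CARDIO = ("borderline", "enlarged", "massively enlarged")
_UNCERTAIN_GIVEN_NEGATIVE = 0.1  # share of negative findings labeled "uncertain"


class SpecValidationError(ValueError):
    """A dataset specification field violates its constraints."""


@dataclass(frozen=True)
class SubgroupSpec:
    """One patient subgroup: its share, label prevalences and image difficulty.

    ``difficulty`` multiplies noise/clutter amplitude and divides finding
    contrast (higher = harder images).  ``clutter_rate`` is the expected count
    of confounding bumps per image.  ``sex``/``age_group`` are the attribute
    values stamped on the subgroup's patients; a ``None`` age_group is drawn
    per patient from the cohort-wide age distribution (recorded attribute with
    no difficulty effect).
    """

    name: str
    proportion: float
    prevalence_per_label: Mapping[str, float]
    difficulty: float = 1.0
    clutter_rate: float = 0.0
    sex: str = "male"
    age_group: str | None = None

    def validate(self, labels: Sequence[str]) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise SpecValidationError(
                f"subgroup {self.name!r}: proportion must be in [0,1], "
                f"got {self.proportion}"
            )
        if not self.difficulty > 0:
            raise SpecValidationError(
                f"subgroup {self.name!r}: difficulty must be > 0, got {self.difficulty}"
            )
        if self.clutter_rate < 0:
            raise SpecValidationError(
                f"subgroup {self.name!r}: clutter_rate must be >= 0"
            )
        for label in labels:
            p = self.prevalence_per_label.get(label, 0.0)
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(
                    f"subgroup {self.name!r}: prevalence for {label!r} must be "
                    f"in [0,1], got {p}"
                )


@dataclass(frozen=True)
class DatasetSpec:
    """Blueprint of a synthetic cohort.

    ``images_per_patient`` is either a fixed integer >= 1 or
    ``("geometric", mean)`` for a shifted-geometric count with the given mean.
    ``label_correlation`` in [0,1] couples findings through one latent
    severity factor per record.  ``label_amplitude`` optionally scales the
    rendered contrast per label (lower = harder finding); default 1.0 each.
    """

    n_patients: int
    image_shape: tuple[int, ...]
    labels: tuple[str, ...]
    subgroups: tuple[SubgroupSpec, ...]
    images_per_patient: int | tuple[str, float] = 1
    label_correlation: float = 0.0
    label_amplitude: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecValidationError("n_patients must be >= 1")
        if len(self.image_shape) not in (2, 3):
            raise SpecValidationError(
                f"image_shape must be 2D or 3D, got {self.image_shape}"
            )
        if any(e < 8 for e in self.image_shape):
            raise SpecValidationError(
                f"image_shape extents must be >= 8, got {self.image_shape}"
            )
        if not self.labels:
            raise SpecValidationError("labels must be non-empty")
        if not self.subgroups:
            raise SpecValidationError("at least one subgroup required")
        if not 0.0 <= self.label_correlation <= 1.0:
            raise SpecValidationError("label_correlation must be in [0,1]")
        total = sum(g.proportion for g in self.subgroups)
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(
                f"subgroup proportions must sum to 1, got {total}"
            )
        for g in self.subgroups:
            g.validate(self.labels)
        if isinstance(self.images_per_patient, tuple):
            kind, mean = self.images_per_patient
            if kind != "geometric" or mean < 1:
                raise SpecValidationError(
                    "images_per_patient descriptor must be an int >= 1 or "
                    "('geometric', mean >= 1)"
                )
        elif self.images_per_patient < 1:
            raise SpecValidationError("images_per_patient must be >= 1")

    def amplitude(self, label: str) -> float:
        if self.label_amplitude is None:
            return 1.0
        return float(self.label_amplitude.get(label, 1.0))


@dataclass
class ImageRecord:
    record_id: str
    patient_id: str
    sex: str
    age_group: str
    image: np.ndarray
    labels: dict[str, str | int]  # severity tokens (2D) or binary ints (3D)


@dataclass
class LabeledImageSet:
    """Generated records plus the spec they came from."""

    records: list[ImageRecord]
    spec: DatasetSpec
    kind: str  # "cxr" | "ct"

    def __len__(self) -> int:
        return len(self.records)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "record_id": r.record_id,
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age_group": r.age_group,
            }
            row.update({label: r.labels[label] for label in self.spec.labels})
            rows.append(row)
        return pd.DataFrame(rows)

    def binary_labels(self) -> np.ndarray:
        """(n_records, n_labels) binary matrix after severity collapse."""
        out = np.empty((len(self.records), len(self.spec.labels)), dtype=int)
        for i, r in enumerate(self.records):
            if self.kind == "ct":
                out[i] = [int(r.labels[l]) for l in self.spec.labels]
            else:
                b = binarize_labels(r.labels, self.spec.labels)
                out[i] = [b[l] for l in self.spec.labels]
        return out

    def images(self) -> np.ndarray:
        return np.stack([r.image for r in self.records])

    def to_hdf5(self, path) -> None:
        import h5py

        meta = self.metadata_frame()
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images())
            f.attrs["kind"] = self.kind
            f.attrs["labels"] = list(self.spec.labels)
            f.attrs["seed"] = self.spec.seed
            grp = f.create_group("metadata")
            for col in meta.columns:
                grp.create_dataset(
                    col, data=np.asarray(meta[col].astype(str), dtype="S")
                )

    def metadata_to_csv(self, path) -> None:
        self.metadata_frame().to_csv(path, index=False)

    def export_png(self, directory) -> None:
        """Write each 2D image as an 8-bit PNG (min-max scaled)."""
        from PIL import Image

        from .preprocessing import normalize_minmax_uint8

        for r in self.records:
            Image.fromarray(normalize_minmax_uint8(r.image)).save(
                f"{directory}/{r.record_id}.png"
            )

    def export_nifti(self, directory) -> None:
        """Write each 3D volume as a NIfTI file."""
        import nibabel as nib

        for r in self.records:
            nib.save(
                nib.Nifti1Image(r.image.astype(np.float32), np.eye(4)),
                f"{directory}/{r.record_id}.nii",
            )


def _spawn_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator keyed by arbitrary string tokens."""
    digest = hashlib.sha256(("|".join(map(str, tokens))).encode()).digest()
    child = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, child]))


def _assign_patients(spec: DatasetSpec, rng: np.random.Generator):
    """Per-patient subgroup, sex, age_group and image count."""
    n = spec.n_patients
    props = np.array([g.proportion for g in spec.subgroups])
    groups = rng.choice(len(spec.subgroups), size=n, p=props / props.sum())
    if isinstance(spec.images_per_patient, tuple):
        mean = spec.images_per_patient[1]
        counts = rng.geometric(1.0 / mean, size=n)  # support {1, 2, ...}
    else:
        counts = np.full(n, int(spec.images_per_patient))
    ages = rng.choice(len(AGE_BINS), size=n, p=np.array(AGE_PROPORTIONS))
    out = []
    for i in range(n):
        g = spec.subgroups[groups[i]]
        age = g.age_group if g.age_group is not None else AGE_BINS[ages[i]]
        out.append((f"p{i:05d}", g, g.sex, age, int(counts[i])))
    return out


def _draw_severities(
    spec: DatasetSpec, group: SubgroupSpec, rng: np.random.Generator
) -> dict[str, tuple[str, float]]:
    """Per-label (severity token, contrast in [0,1]) for one record.

    A latent factor z couples labels (Gaussian copula with loading
    sqrt(label_correlation)); positivity occurs when the per-label uniform
    falls below the prevalence.  Within positives the same uniform, rescaled,
    sets both the contrast and — through equally spaced quantile thresholds —
    the severity level, so severity is monotone in rendered contrast.
    """
    rho = spec.label_correlation
    z = rng.normal()
    out: dict[str, tuple[str, float]] = {}
    for label in spec.labels:
        p = group.prevalence_per_label.get(label, 0.0)
        x = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.normal()
        u = norm.cdf(x)
        cardio = "cardiomegaly" in label.lower()
        positives = _POSITIVE_CARDIO if cardio else _POSITIVE_SEVERITIES
        if p > 0 and u < p:
            v = u / p  # uniform in [0,1) given positive
            level = min(int(v * 3), 2)
            severity = positives[level]
            contrast = 0.5 + 0.5 * v  # mild..severe span [0.5, 1.0)
        else:
            if rng.random() < _UNCERTAIN_GIVEN_NEGATIVE:
                severity = "uncertain"
                contrast = 0.15
            else:
                severity = "normal" if cardio else "negative"
                contrast = 0.0
        out[label] = (severity, contrast)
    return out


def _label_center(spec: DatasetSpec, label: str, rng: np.random.Generator):
    """Deterministic locus per label, jittered; lateral findings stay in
    their image half (columns = last axis)."""
    h, w = spec.image_shape[0], spec.image_shape[1]
    idx = spec.labels.index(label)
    row = (0.25 + 0.5 * ((idx + 0.5) / len(spec.labels))) * h
    name = label.lower()
    if "right" in name:
        col = 0.75 * w
    elif "left" in name:
        col = 0.25 * w
    else:
        col = 0.5 * w
    jitter = rng.normal(scale=0.03 * min(h, w), size=2)
    r = float(np.clip(row + jitter[0], 2, h - 3))
    c_lo, c_hi = (w / 2 + 2, w - 3) if "right" in name else (2, w - 3)
    if "left" in name:
        c_lo, c_hi = 2, w / 2 - 2
    c = float(np.clip(col + jitter[1], c_lo, c_hi))
    return r, c


def _gaussian_bump(shape, center, width, amplitude) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    sq = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-sq / (2.0 * width**2))


def generate_cxr_like(spec: DatasetSpec) -> LabeledImageSet:
    """Generate a 2D radiograph-style multi-label cohort from ``spec``."""
    spec.validate()
    if len(spec.image_shape) != 2:
        raise SpecValidationError(
            f"generate_cxr_like needs a 2D image_shape, got {spec.image_shape}"
        )
    h, w = spec.image_shape
    bump_width = 0.06 * min(h, w)
    records: list[ImageRecord] = []
    patients = _assign_patients(spec, _spawn_rng(spec.seed, "patients"))
    for patient_id, group, sex, age, n_images in patients:
        for j in range(n_images):
            record_id = f"{patient_id}_r{j}"
            rng = _spawn_rng(spec.seed, "record", record_id)
            severities = _draw_severities(spec, group, rng)
            background = gaussian_filter(
                rng.normal(size=(h, w)), sigma=0.12 * min(h, w)
            )
            img = 0.5 + background
            for label in spec.labels:
                severity, contrast = severities[label]
                if contrast > 0:
                    center = _label_center(spec, label, rng)
                    amp = contrast * spec.amplitude(label) / group.difficulty
                    img += _gaussian_bump((h, w), center, bump_width, amp)
            n_clutter = rng.poisson(group.clutter_rate * group.difficulty)
            for _ in range(n_clutter):
                center = rng.uniform([0, 0], [h, w])
                amp = rng.uniform(0.3, 0.8)
                img += _gaussian_bump((h, w), center, bump_width * 0.8, amp)
            img += rng.normal(scale=0.25 * group.difficulty, size=(h, w))
            records.append(
                ImageRecord(
                    record_id, patient_id, sex, age, img.astype(np.float64),
                    {label: severities[label][0] for label in spec.labels},
                )
            )
    return LabeledImageSet(records, spec, "cxr")


def generate_ct_like(spec: DatasetSpec) -> LabeledImageSet:
    """Generate a 3D CT-style binary-task cohort from ``spec``.

    Exactly one label is required; positives receive a hyperdense ellipsoidal
    lesion in a fixed sub-region (the pancreatic bed stand-in around relative
    coordinates (0.5, 0.45, 0.4)).  Voxel values are Hounsfield-like: soft
    tissue around 30 HU, lesion contrast on the order of +100 HU scaled down
    by subgroup difficulty.
    """
    spec.validate()
    if len(spec.image_shape) != 3:
        raise SpecValidationError(
            f"generate_ct_like needs a 3D image_shape, got {spec.image_shape}"
        )
    if len(spec.labels) != 1:
        raise SpecValidationError(
            f"generate_ct_like needs exactly one label, got {spec.labels}"
        )
    label = spec.labels[0]
    shape = spec.image_shape
    records: list[ImageRecord] = []
    patients = _assign_patients(spec, _spawn_rng(spec.seed, "patients"))
    for patient_id, group, sex, age, n_images in patients:
        for j in range(n_images):
            record_id = f"{patient_id}_r{j}"
            rng = _spawn_rng(spec.seed, "record", record_id)
            p = group.prevalence_per_label.get(label, 0.0)
            positive = int(rng.random() < p)
            field = gaussian_filter(rng.normal(size=shape), sigma=0.1 * min(shape))
            field /= max(field.std(), 1e-12)
            vol = 30.0 + 25.0 * field
            vol += rng.normal(scale=12.0 * group.difficulty, size=shape)
            if positive:
                rel = np.array([0.5, 0.45, 0.4])
                center = rel * np.array(shape) + rng.normal(
                    scale=0.03 * min(shape), size=3
                )
                width = rng.uniform(0.08, 0.14) * min(shape)
                contrast = rng.uniform(70.0, 130.0) / group.difficulty
                vol += _gaussian_bump(shape, center, width, contrast)
            records.append(
                ImageRecord(
                    record_id, patient_id, sex, age, vol.astype(np.float64),
                    {label: positive},
                )
            )
    return LabeledImageSet(records, spec, "ct")


def _floor_cumulative_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """Split sizes: floor the validation/test targets, remainder to train."""
    s2 = int(np.floor(n * fractions[1]))
    s3 = int(np.floor(n * fractions[2]))
    return n - s2 - s3, s2, s3


def split_patientwise(
    ds: LabeledImageSet,
    fractions: Sequence[float],
    stratify_on: str | None = None,
    seed: int = 0,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Patient-wise train/validation/test split.

    No patient appears in more than one split.  Fractions apply to patients;
    sizes follow the floor-cumulative rule with the remainder assigned to
    train.  With ``stratify_on`` set (a label name), the positive:negative
    patient ratio of every split is kept within one patient of exact — a
    patient counts positive if any of its records is positive after severity
    collapse.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError(f"need three non-negative fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {sum(fractions)}")
    if stratify_on is not None and stratify_on not in ds.spec.labels:
        raise ValueError(f"stratify label {stratify_on!r} not in {ds.spec.labels}")

    rng = np.random.default_rng(seed)
    patient_ids = sorted({r.patient_id for r in ds.records})
    n = len(patient_ids)
    sizes = _floor_cumulative_sizes(n, fractions)

    if stratify_on is None:
        order = list(rng.permutation(patient_ids))
        assignment = (
            {p: 0 for p in order[: sizes[0]]}
            | {p: 1 for p in order[sizes[0]: sizes[0] + sizes[1]]}
            | {p: 2 for p in order[sizes[0] + sizes[1]:]}
        )
    else:
        binary = ds.binary_labels()[:, ds.spec.labels.index(stratify_on)]
        patient_class: dict[str, int] = {}
        for rec, b in zip(ds.records, binary):
            patient_class[rec.patient_id] = max(
                patient_class.get(rec.patient_id, 0), int(b)
            )
        pos = [p for p in patient_ids if patient_class[p] == 1]
        neg = [p for p in patient_ids if patient_class[p] == 0]
        c1 = int(np.floor(len(pos) * fractions[0]))
        c2 = int(np.floor(len(pos) * (fractions[0] + fractions[1])))
        pos_sizes = (c1, c2 - c1, len(pos) - c2)
        neg_sizes = tuple(s - ps for s, ps in zip(sizes, pos_sizes))
        if any(s < 0 for s in neg_sizes) or sum(neg_sizes) != len(neg):
            raise ValueError("stratified split infeasible for these fractions")
        assignment = {}
        for pool, pool_sizes in ((pos, pos_sizes), (neg, neg_sizes)):
            order = list(rng.permutation(pool))
            bounds = np.cumsum((0,) + pool_sizes)
            for split_idx in range(3):
                for p in order[bounds[split_idx]: bounds[split_idx + 1]]:
                    assignment[p] = split_idx

    buckets: tuple[list, list, list] = ([], [], [])
    for rec in ds.records:
        buckets[assignment[rec.patient_id]].append(rec)
    return tuple(
        LabeledImageSet(list(b), ds.spec, ds.kind) for b in buckets
    )


def clinical_subgroup_grid(
    prevalence: Mapping[str, float],
    base_clutter: float = 1.0,
) -> tuple[SubgroupSpec, ...]:
    """Sex x age-bin subgroup grid emulating the radiograph training cohort.

    Proportions are products of the cohort's sex and age margins; difficulty
    and clutter grow with the age bin, emulating the harder image acquisition
    in older patients.
    """
    difficulties = (1.0, 1.15, 1.3, 1.45, 1.6)
    groups = []
    for sex, sex_p in (("male", MALE_PROPORTION), ("female", 1.0 - MALE_PROPORTION)):
        for age, age_p, diff in zip(AGE_BINS, AGE_PROPORTIONS, difficulties):
            groups.append(
                SubgroupSpec(
                    name=f"{sex}_{age}",
                    proportion=sex_p * age_p,
                    prevalence_per_label=dict(prevalence),
                    difficulty=diff,
                    clutter_rate=base_clutter * diff,
                    sex=sex,
                    age_group=age,
                )
            )
    return tuple(groups)


#: Default per-label prevalences for the desk-scale radiograph-like cohort:
#: the cohort's imbalance pattern (one common finding, several uncommon ones),
#: with the rare tail raised enough that a few-hundred-record test split still
#: contains dozens of positives per label.
DESK_PREVALENCE: Mapping[str, float] = {
    "cardiomegaly": 0.45,
    "congestion": 0.20,
    "pleural_effusion_right": 0.15,
    "pleural_effusion_left": 0.12,
}

#: Per-label rendered contrast scale; congestion is the injected hard finding.
DESK_AMPLITUDE: Mapping[str, float] = {
    "cardiomegaly": 1.0,
    "congestion": 0.45,
    "pleural_effusion_right": 0.9,
    "pleural_effusion_left": 0.9,
}


def cxr_desk_spec(
    n_patients: int = 465,
    image_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    difficulty_gap: float = 2.0,
) -> DatasetSpec:
    """Default desk-scale radiograph-like cohort (~2000 records).

    Two sex subgroups with the cohort's 0.656/0.344 split; the minority
    subgroup's images are ``difficulty_gap`` times harder (noise/clutter up,
    finding contrast down), the injected disparity the fairness audit should
    recover.  Images per patient follow the cohort's shifted-geometric count
    with mean ~4.3.
    """
    subgroups = (
        SubgroupSpec(
            name="male",
            proportion=MALE_PROPORTION,
            prevalence_per_label=dict(DESK_PREVALENCE),
            difficulty=1.0,
            clutter_rate=1.0,
            sex="male",
        ),
        SubgroupSpec(
            name="female",
            proportion=1.0 - MALE_PROPORTION,
            prevalence_per_label=dict(DESK_PREVALENCE),
            difficulty=difficulty_gap,
            clutter_rate=1.0,
            sex="female",
        ),
    )
    return DatasetSpec(
        n_patients=n_patients,
        image_shape=image_shape,
        labels=tuple(DESK_PREVALENCE),
        subgroups=subgroups,
        images_per_patient=("geometric", 193311 / 45016),
        label_correlation=0.3,
        label_amplitude=dict(DESK_AMPLITUDE),
        seed=seed,
    )


def pdac_desk_spec(
    n_patients: int = 1625,
    image_shape: tuple[int, int, int] = (32, 32, 32),
    seed: int = 0,
) -> DatasetSpec:
    """Desk-scale CT-like cohort: 867/1625 tumor prevalence, one image each."""
    prevalence = {"tumor": 867 / 1625}
    subgroups = (
        SubgroupSpec(
            name="male", proportion=0.55, prevalence_per_label=prevalence,
            difficulty=1.0, sex="male",
        ),
        SubgroupSpec(
            name="female", proportion=0.45, prevalence_per_label=prevalence,
            difficulty=1.3, sex="female",
        ),
    )
    return DatasetSpec(
        n_patients=n_patients,
        image_shape=image_shape,
        labels=("tumor",),
        subgroups=subgroups,
        images_per_patient=1,
        seed=seed,
    )
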