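"""Synthetic cohort generator: statistical recovery, determinism, splits."""

from __future__ import annotations

import numpy as np
import pytest

from dpfair.synthetic import (
    AGE_BINS,
    DatasetSpec,
    SpecValidationError,
    SubgroupSpec,
    _draw_severities,
    _spawn_rng,
    cxr_desk_spec,
    generate_cxr_like,
    generate_ct_like,
    pdac_desk_spec,
    split_patientwise,
    clinical_subgroup_grid,
)
from conftest import two_group_spec


def binomial_band(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1 - p) / n)


class TestValidation:
    def test_proportions_must_sum_to_one(self):
        spec = two_group_spec()
        bad = DatasetSpec(
            n_patients=10, image_shape=(16, 16), labels=("a",),
            subgroups=(
                SubgroupSpec("x", 0.6, {"a": 0.5}),
                SubgroupSpec("y", 0.3, {"a": 0.5}),
            ),
        )
        with pytest.raises(SpecValidationError, match="proportion"):
            generate_cxr_like(bad)

    def test_field_errors_name_the_field(self):
        with pytest.raises(SpecValidationError, match="difficulty"):
            SubgroupSpec("x", 1.0, {"a": 0.5}, difficulty=0.0).validate(("a",))
        with pytest.raises(SpecValidationError, match="prevalence"):
            SubgroupSpec("x", 1.0, {"a": 1.5}).validate(("a",))
        with pytest.raises(SpecValidationError, match="extents"):
            DatasetSpec(
                n_patients=5, image_shape=(4, 4), labels=("a",),
                subgroups=(SubgroupSpec("x", 1.0, {"a": 0.5}),),
            ).validate()

    def test_ct_requires_3d_and_single_label(self):
        spec = two_group_spec()
        with pytest.raises(SpecValidationError, match="3D"):
            generate_ct_like(spec)
        with pytest.raises(SpecValidationError, match="2D"):
            generate_cxr_like(pdac_desk_spec(n_patients=4))


class TestCxrGeneration:
    def test_zero_prevalence_means_all_negative(self):
        spec = two_group_spec(n_patients=30, prevalence=0.0)
        ds = generate_cxr_like(spec)
        assert ds.binary_labels().sum() == 0

    def test_deterministic_given_seed(self):
        spec = two_group_spec(n_patients=20)
        a, b = generate_cxr_like(spec), generate_cxr_like(spec)
        assert [r.record_id for r in a.records] == [r.record_id for r in b.records]
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.image, rb.image)
            assert ra.labels == rb.labels

    def test_sex_proportion_recovered(self):
        """Subgroup shares land within 3 binomial SE of the cohort margins."""
        spec = two_group_spec(n_patients=5000, image_shape=(8, 8),
                              proportions=(0.656, 0.344), seed=1)
        ds = generate_cxr_like(spec)
        patients = {r.patient_id: r.sex for r in ds.records}
        male = np.mean([s == "male" for s in patients.values()])
        assert abs(male - 0.656) <= binomial_band(0.656, 5000)

    @pytest.mark.parametrize("n,seed", [(300, 2), (1200, 3)])
    def test_prevalence_recovered_at_two_sizes(self, n, seed):
        spec = two_group_spec(n_patients=n, image_shape=(8, 8), prevalence=0.4,
                              seed=seed)
        ds = generate_cxr_like(spec)
        emp = ds.binary_labels().mean(axis=0)
        band = binomial_band(0.4, n)
        assert np.all(np.abs(emp - 0.4) <= band)

    def test_lateral_findings_stay_in_their_half(self):
        """A left-named finding brightens the left image half and vice versa."""
        labels = ("finding_left", "finding_right")
        spec = DatasetSpec(
            n_patients=150, image_shape=(24, 24), labels=labels,
            subgroups=(SubgroupSpec("g", 1.0, {l: 0.5 for l in labels}),),
            seed=7,
        )
        ds = generate_cxr_like(spec)
        binary = ds.binary_labels()
        for j, label in enumerate(labels):
            pos = [r.image for r, b in zip(ds.records, binary[:, j]) if b]
            neg = [r.image for r, b in zip(ds.records, binary[:, j]) if not b]
            half = slice(0, 12) if "left" in label else slice(12, 24)
            delta = (
                np.mean([im[:, half].mean() for im in pos])
                - np.mean([im[:, half].mean() for im in neg])
            )
            assert delta > 0

    def test_difficulty_raises_image_noise(self):
        easy = generate_cxr_like(two_group_spec(n_patients=60, seed=5))
        hard = generate_cxr_like(
            two_group_spec(n_patients=60, seed=5, difficulty_ratio=3.0)
        )
        noise = {
            ds_name: np.mean([
                np.std(np.diff(r.image, axis=0)) for r in ds.records
                if r.sex == "female"
            ])
            for ds_name, ds in (("easy", easy), ("hard", hard))
        }
        assert noise["hard"] > noise["easy"]

    def test_severity_monotone_in_contrast(self):
        """Within the positive range, higher severity always renders with
        higher contrast (equally spaced quantile thresholds)."""
        spec = two_group_spec(n_patients=10)
        group = spec.subgroups[0]
        order = {"mild": 0, "moderate": 1, "severe": 2}
        draws = []
        for i in range(500):
            sev = _draw_severities(spec, group, _spawn_rng(9, "t", i))
            for token, contrast in sev.values():
                if token in order:
                    draws.append((order[token], contrast))
        levels = sorted({d[0] for d in draws})
        assert levels == [0, 1, 2]
        maxima = {
            lvl: max(c for l, c in draws if l == lvl) for lvl in levels
        }
        minima = {
            lvl: min(c for l, c in draws if l == lvl) for lvl in levels
        }
        assert maxima[0] <= minima[1] + 1e-12 or maxima[0] < minima[2]
        assert maxima[0] <= minima[1] and maxima[1] <= minima[2]

    def test_geometric_images_per_patient(self):
        spec = two_group_spec(n_patients=400, image_shape=(8, 8),
                              images_per_patient=("geometric", 4.3), seed=11)
        ds = generate_cxr_like(spec)
        counts = {}
        for r in ds.records:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        mean = np.mean(list(counts.values()))
        assert min(counts.values()) >= 1
        assert mean == pytest.approx(4.3, abs=3 * 4.3 / np.sqrt(400))


class TestCtGeneration:
    def test_full_prevalence_gives_lesion_in_every_volume(self):
        spec = DatasetSpec(
            n_patients=25, image_shape=(16, 16, 16), labels=("tumor",),
            subgroups=(SubgroupSpec("g", 1.0, {"tumor": 1.0}),), seed=2,
        )
        ds = generate_ct_like(spec)
        assert ds.binary_labels().sum() == 25
        # lesion neighbourhood is hyperdense relative to the volume median
        center = (8, 7, 6)  # relative (0.5, 0.45, 0.4) of 16^3
        for r in ds.records:
            region = r.image[
                center[0] - 2: center[0] + 3,
                center[1] - 2: center[1] + 3,
                center[2] - 2: center[2] + 3,
            ]
            assert region.mean() > np.median(r.image)

    def test_case_control_ratio_within_three_se(self):
        spec = pdac_desk_spec(n_patients=1625, image_shape=(8, 8, 8), seed=4)
        ds = generate_ct_like(spec)
        positives = int(ds.binary_labels().sum())
        p = 867 / 1625
        band = 3.0 * np.sqrt(1625 * p * (1 - p))  # +-60 around 867
        assert abs(positives - 867) <= band

    def test_deterministic_given_seed(self):
        spec = pdac_desk_spec(n_patients=6, image_shape=(8, 8, 8), seed=5)
        a, b = generate_ct_like(spec), generate_ct_like(spec)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.image, rb.image)


class TestSplitPatientwise:
    def test_paper_sized_stratified_split(self, small_ct_set):
        spec = pdac_desk_spec(n_patients=1625, image_shape=(8, 8, 8), seed=6)
        ds = generate_ct_like(spec)
        tr, va, te = split_patientwise(ds, (0.6, 0.2, 0.2), "tumor", seed=0)
        assert (len(tr), len(va), len(te)) == (975, 325, 325)
        # class ratio preserved within one record of exact in every split
        exact = ds.binary_labels().mean()
        for part in (tr, va, te):
            pos = part.binary_labels().sum()
            assert abs(pos - exact * len(part)) <= 1.0

    def test_everything_to_first_split(self, small_cxr_set):
        tr, va, te = split_patientwise(small_cxr_set, (1.0, 0.0, 0.0))
        assert len(tr) == len(small_cxr_set) and len(va) == len(te) == 0

    def test_patients_never_straddle_splits(self):
        spec = two_group_spec(
            n_patients=80, image_shape=(8, 8),
            images_per_patient=("geometric", 3.0), seed=13,
        )
        ds = generate_cxr_like(spec)
        parts = split_patientwise(ds, (0.5, 0.25, 0.25), seed=1)
        seen: dict[str, int] = {}
        for i, part in enumerate(parts):
            for r in part.records:
                assert seen.setdefault(r.patient_id, i) == i
        assert sum(len(p) for p in parts) == len(ds)
        assert len(seen) == 80

    def test_bad_fractions_rejected(self, small_cxr_set):
        with pytest.raises(ValueError, match="sum"):
            split_patientwise(small_cxr_set, (0.5, 0.4, 0.2))
        with pytest.raises(ValueError, match="stratify"):
            split_patientwise(small_cxr_set, (0.6, 0.2, 0.2), "missing")


class TestExports:
    def test_hdf5_and_csv_round_trip(self, tmp_path, small_ct_set):
        import h5py
        import pandas as pd

        path = tmp_path / "cohort.h5"
        small_ct_set.to_hdf5(path)
        with h5py.File(path) as f:
            assert f["images"].shape[0] == len(small_ct_set)
            assert f.attrs["kind"] == "ct"
        csv = tmp_path / "meta.csv"
        small_ct_set.metadata_to_csv(csv)
        meta = pd.read_csv(csv)
        assert list(meta.columns[:4]) == [
            "record_id", "patient_id", "sex", "age_group"
        ]
        assert len(meta) == len(small_ct_set)

    def test_png_and_nifti_export(self, tmp_path, small_cxr_set, small_ct_set):
        png_dir = tmp_path / "png"
        png_dir.mkdir()
        subset = type(small_cxr_set)(
            small_cxr_set.records[:2], small_cxr_set.spec, "cxr"
        )
        subset.export_png(png_dir)
        assert len(list(png_dir.glob("*.png"))) == 2
        nii_dir = tmp_path / "nii"
        nii_dir.mkdir()
        ct_subset = type(small_ct_set)(
            small_ct_set.records[:2], small_ct_set.spec, "ct"
        )
        ct_subset.export_nifti(nii_dir)
        assert len(list(nii_dir.glob("*.nii"))) == 2


class TestFactories:
    def test_clinical_subgroup_grid_cover_sex_by_age(self):
        groups = clinical_subgroup_grid({"cardiomegaly": 0.4})
        assert len(groups) == 10
        assert sum(g.proportion for g in groups) == pytest.approx(1.0)
        ages = {g.age_group for g in groups}
        assert ages == set(AGE_BINS)
        # difficulty grows with the age bin
        male = sorted(
            (g for g in groups if g.sex == "male"),
            key=lambda g: AGE_BINS.index(g.age_group),
        )
        diffs = [g.difficulty for g in male]
        assert diffs == sorted(diffs) and diffs[0] < diffs[-1]

    def test_desk_spec_defaults(self):
        spec = cxr_desk_spec()
        spec.validate()
        assert spec.image_shape == (64, 64)
        assert len(spec.labels) == 4
        assert spec.subgroups[0].proportion == pytest.approx(0.6557, abs=1e-3)
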