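"""Compactness metric: medium extraction, scoring, classification, stats."""

import dataclasses

import numpy as np
import pytest

from orgamri import (
    BinaryMask,
    PhantomSpec,
    VolumeImage,
    classify_cysticity,
    compactness,
    compare_groups_compactness,
    extract_medium_mask,
    find_organoid_planes,
    generate_cohort,
    generate_phantom,
    minmax_normalize,
)
from orgamri.cysticity import CompactnessResult
from orgamri.phantom import label_fields


def _mask_on_planes(planes, shape=(32, 16, 16)):
    data = np.zeros(shape, bool)
    for p in planes:
        data[p, 6:10, 6:10] = True
    return BinaryMask(data)


class TestFindOrganoidPlanes:
    def test_contiguous_range(self):
        assert find_organoid_planes(_mask_on_planes(range(10, 21))) == (10, 20)

    def test_single_plane(self):
        assert find_organoid_planes(_mask_on_planes([5])) == (5, 5)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            find_organoid_planes(BinaryMask(np.zeros((8, 8, 8), bool)))


class TestExtractMediumMask:
    def test_medium_purity_on_phantom(self, noncystic_sample):
        """≥99% of extracted voxels are true medium voxels per the phantom
        ground-truth label fields."""
        v = minmax_normalize(noncystic_sample.volume)
        medium = extract_medium_mask(v, noncystic_sample.organoid_mask)
        truth = label_fields(noncystic_sample.spec)["medium"]
        purity = (medium.data & truth).sum() / medium.count()
        assert purity >= 0.99

    def test_first_and_last_planes_contribute_nothing(self, noncystic_sample):
        v = minmax_normalize(noncystic_sample.volume)
        medium = extract_medium_mask(v, noncystic_sample.organoid_mask)
        first, last = find_organoid_planes(noncystic_sample.organoid_mask)
        assert medium.data[first].sum() == 0
        assert medium.data[last].sum() == 0

    def test_no_organoid_voxels_in_medium(self, cystic_sample):
        v = minmax_normalize(cystic_sample.volume)
        medium = extract_medium_mask(v, cystic_sample.organoid_mask)
        assert not (medium.data & cystic_sample.organoid_mask.data).any()

    def test_fewer_than_three_planes_rejected(self, noncystic_sample):
        thin = np.zeros_like(noncystic_sample.organoid_mask.data)
        thin[10:12] = noncystic_sample.organoid_mask.data[10:12]
        thin[10:12, 0, 0] = True  # ensure nonempty on both planes
        with pytest.raises(ValueError, match="3 coronal planes"):
            extract_medium_mask(
                minmax_normalize(noncystic_sample.volume), BinaryMask(thin)
            )


class TestCompactness:
    def test_noise_free_value_matches_label_set_means(self):
        """With zero noise, compactness equals |mean tissue/cyst mix − mean
        medium| computed directly over the ground-truth label fields."""
        spec = PhantomSpec(
            grid_shape=(32, 32, 32), organoid_radius_vox=8.0, noise_sigma=0.0, seed=3
        )
        s = generate_phantom(spec)
        v = minmax_normalize(s.volume)
        res = compactness(v, s.organoid_mask)
        fields = label_fields(spec)
        # oracle means over ground-truth labels, restricted to interior planes
        first, last = find_organoid_planes(s.organoid_mask)
        interior = np.zeros_like(fields["medium"])
        interior[first + 1 : last] = True
        mu_org = v.data[s.organoid_mask.data].mean()
        mu_medium = v.data[fields["medium"] & interior].mean()
        assert res.compactness == pytest.approx(abs(mu_org - mu_medium), abs=1e-6)
        assert res.mu_org == pytest.approx(mu_org)

    def test_zero_when_means_equal(self):
        res = CompactnessResult(
            mu_org=0.5, mu_medium=0.5, compactness=0.0,
            plane_first=1, plane_last=5, n_medium_voxels=10,
        )
        assert res.compactness == abs(res.mu_org - res.mu_medium) == 0.0

    def test_symmetry_of_absolute_difference(self, noncystic_sample):
        v = minmax_normalize(noncystic_sample.volume)
        res = compactness(v, noncystic_sample.organoid_mask)
        assert res.compactness == pytest.approx(abs(res.mu_medium - res.mu_org))

    def test_shift_invariance_and_scale_equivariance(self, noncystic_sample):
        v = minmax_normalize(noncystic_sample.volume)
        base = compactness(v, noncystic_sample.organoid_mask)
        shifted = VolumeImage(v.data + 0.3, v.spacing_um)
        scaled = VolumeImage(v.data * 2.5, v.spacing_um)
        res_shift = compactness(shifted, noncystic_sample.organoid_mask)
        res_scale = compactness(scaled, noncystic_sample.organoid_mask)
        assert res_shift.compactness == pytest.approx(base.compactness, rel=1e-3)
        assert res_scale.compactness == pytest.approx(2.5 * base.compactness, rel=1e-3)

    def test_cystic_scores_below_noncystic(self, cystic_sample, noncystic_sample):
        c = compactness(minmax_normalize(cystic_sample.volume), cystic_sample.organoid_mask)
        n = compactness(
            minmax_normalize(noncystic_sample.volume), noncystic_sample.organoid_mask
        )
        assert c.compactness < n.compactness

    def test_monotone_decrease_with_cyst_volume_fraction(self):
        """Compactness falls as the cyst takes over more of the organoid."""
        values = []
        for cyst_r in (0.0, 3.0, 5.0, 6.5):
            cysts = [((16.0, 16.0, 16.0), cyst_r)] if cyst_r else []
            spec = PhantomSpec(
                grid_shape=(32, 32, 32), organoid_radius_vox=8.0,
                cysts=cysts, noise_sigma=0.02, seed=4,
            )
            s = generate_phantom(spec)
            values.append(
                compactness(minmax_normalize(s.volume), s.organoid_mask).compactness
            )
        assert all(v2 < v1 for v1, v2 in zip(values, values[1:]))


@pytest.fixture(scope="module")
def cohort_results():
    spec = PhantomSpec(grid_shape=(32, 32, 32), organoid_radius_vox=8.0)
    cohort = generate_cohort(20, [30], 0.5, base_spec=spec, seed=17)
    return [
        (compactness(minmax_normalize(s.volume), s.organoid_mask), s.cystic_label)
        for s in cohort
    ]


class TestClassifyCysticity:
    def test_default_cohort_separates_perfectly(self, cohort_results):
        roc, _ = classify_cysticity(cohort_results)
        assert roc.auc == 1.0

    def test_monotone_transform_invariance(self, cohort_results):
        roc, _ = classify_cysticity(cohort_results)
        transformed = [
            (dataclasses.replace(r, compactness=np.exp(3 * r.compactness)), lbl)
            for r, lbl in cohort_results
        ]
        roc2, _ = classify_cysticity(transformed)
        assert roc2.auc == pytest.approx(roc.auc)

    def test_equal_values_give_half(self):
        res = CompactnessResult(0.5, 0.5, 0.3, 1, 5, 10)
        results = [(res, True), (res, False), (res, True), (res, False)]
        roc, _ = classify_cysticity(results)
        assert roc.auc == pytest.approx(0.5)

    def test_permutation_null_is_centered_at_half(self, cohort_results, rng):
        """Random label shuffles destroy the association: mean AUC ≈ 0.5."""
        scores = np.array([-r.compactness for r, _ in cohort_results])
        labels = np.array([lbl for _, lbl in cohort_results])
        from orgamri import roc_auc

        aucs = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            if perm.all() or not perm.any():
                continue
            aucs.append(roc_auc(scores, perm).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups_compactness([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0 and p == 1.0

    def test_swapping_groups_flips_sign(self):
        a, b = [0.5, 0.6, 0.55], [0.1, 0.2, 0.15]
        t1, p1 = compare_groups_compactness(a, b)
        t2, p2 = compare_groups_compactness(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_separated_phantom_groups_highly_significant(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), organoid_radius_vox=8.0)
        cohort = generate_cohort(20, [30], 0.5, base_spec=spec, seed=23)
        vals = {
            True: [], False: [],
        }
        for s in cohort:
            vals[s.cystic_label].append(
                compactness(minmax_normalize(s.volume), s.organoid_mask).compactness
            )
        t, p = compare_groups_compactness(vals[False], vals[True])
        assert t > 0  # non-cystic organoids are more compact
        assert p < 1e-4

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            compare_groups_compactness([0.1], [0.2, 0.3])
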