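"""Synthetic cohort generator: determinism, planted effects, persistence."""

import numpy as np
import pytest
from scipy import stats

from voxelsurvey import CONTROL, DISEASE, generate_cohort, load_cohort, save_cohort


def _group_mean_diff(cohort):
    """Control-minus-disease mean map (positive where disease lost density)."""
    maps = np.stack([m.data for m in cohort.maps])
    labels = cohort.labels
    return maps[labels == CONTROL].mean(0) - maps[labels == DISEASE].mean(0)


def test_seed_determinism():
    kw = dict(n_disease=10, n_control=10, dims=(6, 7, 6), n_informative=20,
              effect_size=0.3, noise_sd=0.05, seed=7)
    a, b = generate_cohort(**kw), generate_cohort(**kw)
    assert np.array_equal(a.truth_mask, b.truth_mask)
    for ma, mb in zip(a.maps, b.maps):
        assert ma.subject_id == mb.subject_id and ma.group == mb.group
        assert np.array_equal(ma.data, mb.data)


def test_noiseless_construction_plants_exact_shift():
    c = generate_cohort(n_disease=4, n_control=4, dims=(6, 7, 6),
                        n_informative=15, effect_size=0.3, noise_sd=0.0, seed=3)
    diff = _group_mean_diff(c)
    # baseline lives in [0.3, 0.7], so a 0.3 loss never clips below 0
    assert np.allclose(diff[c.truth_mask], 0.3)
    assert np.allclose(diff[~c.truth_mask], 0.0)


def test_zero_effect_is_indistinguishable_across_voxel_classes():
    """With effect 0 the group difference carries no signal at planted voxels."""
    inf_means, other_means = [], []
    for seed in range(50):
        c = generate_cohort(n_disease=5, n_control=5, dims=(5, 5, 5),
                            n_informative=10, effect_size=0.0, noise_sd=0.05,
                            seed=seed)
        diff = _group_mean_diff(c)
        inf_means.append(diff[c.truth_mask].mean())
        other_means.append(diff[~c.truth_mask].mean())
    t = stats.ttest_ind(inf_means, other_means)
    assert t.pvalue > 0.01


@pytest.mark.parametrize("layout", ["blob", "scattered"])
def test_truth_mask_counts_and_clipping(layout):
    c = generate_cohort(n_disease=6, n_control=6, dims=(8, 8, 8),
                        n_informative=30, effect_size=0.4, noise_sd=0.3,
                        seed=1, informative_layout=layout)
    assert c.truth_mask.sum() == 30
    for m in c.maps:
        assert m.data.min() >= 0.0 and m.data.max() <= 1.0


def test_blob_layout_is_contiguous():
    from scipy.ndimage import label

    c = generate_cohort(n_disease=2, n_control=2, dims=(8, 8, 8),
                        n_informative=25, effect_size=0.3, noise_sd=0.0, seed=5)
    _, n_components = label(c.truth_mask)
    assert n_components == 1


def test_effect_monotonicity_on_matched_seeds():
    prev = -np.inf
    for effect in (0.0, 0.1, 0.2, 0.3, 0.5):
        c = generate_cohort(n_disease=8, n_control=8, dims=(6, 6, 6),
                            n_informative=12, effect_size=effect,
                            noise_sd=0.05, seed=11)
        mean_abs = np.abs(_group_mean_diff(c)[c.truth_mask]).mean()
        assert mean_abs >= prev - 1e-12
        prev = mean_abs


@pytest.mark.parametrize(
    "kw, named",
    [
        (dict(dims=(0, 5, 5)), "dims"),
        (dict(n_informative=10_000), "n_informative"),
        (dict(noise_sd=-0.1), "noise_sd"),
        (dict(n_disease=0), "n_disease"),
        (dict(informative_layout="ring"), "informative_layout"),
    ],
)
def test_invalid_parameters_rejected_by_name(kw, named):
    base = dict(n_disease=4, n_control=4, dims=(5, 5, 5), n_informative=5,
                effect_size=0.3, noise_sd=0.05, seed=0)
    base.update(kw)
    with pytest.raises(ValueError, match=named):
        generate_cohort(**base)


def test_save_load_round_trip(tmp_path):
    c = generate_cohort(n_disease=2, n_control=2, dims=(5, 6, 5),
                        n_informative=8, effect_size=0.3, noise_sd=0.05, seed=2)
    save_cohort(c, tmp_path / "cohort")
    loaded = load_cohort(tmp_path / "cohort")
    assert loaded.dims == c.dims
    assert np.array_equal(loaded.truth_mask, c.truth_mask)
    for ma, mb in zip(c.maps, loaded.maps):
        assert ma.subject_id == mb.subject_id and ma.group == mb.group
        assert np.allclose(ma.data, mb.data, atol=1e-12)
    assert loaded.gen_params["seed"] == 2


def test_load_missing_map_file_names_it(tmp_path):
    c = generate_cohort(n_disease=2, n_control=2, dims=(5, 5, 5),
                        n_informative=4, effect_size=0.3, noise_sd=0.05, seed=2)
    save_cohort(c, tmp_path / "cohort")
    victim = next((tmp_path / "cohort").glob("sub-dis*.nii.gz"))
    victim.unlink()
    with pytest.raises(FileNotFoundError, match=victim.name):
        load_cohort(tmp_path / "cohort")


def test_load_without_manifest_fails(tmp_path):
    with pytest.raises(FileNotFoundError, match="manifest"):
        load_cohort(tmp_path)


def test_full_scale_map_has_canonical_voxel_count(tmp_path):
    """A full-resolution 61 x 73 x 61 map holds 271,633 voxels on disk."""
    c = generate_cohort(n_disease=1, n_control=1, dims=(61, 73, 61),
                        n_informative=0, effect_size=0.0, noise_sd=0.0, seed=0)
    save_cohort(c, tmp_path / "full")
    loaded = load_cohort(tmp_path / "full")
    assert all(m.data.size == 271_633 for m in loaded.maps)
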