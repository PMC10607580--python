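"""Generator correctness: determinism, implied correlations, ground truth."""

import numpy as np
import pytest
from scipy import stats

from genecomm.simulate import (
    SyntheticDesign,
    generate_dataset,
    generate_merge_check_dataset,
    generate_nested_dataset,
)


def _mean_offdiag_corr(values: np.ndarray) -> float:
    C = np.corrcoef(values)
    iu = np.triu_indices(C.shape[0], k=1)
    return float(C[iu].mean())


class TestFlatGenerator:
    def test_same_seed_bit_identical(self):
        d = SyntheticDesign(seed=5)
        m1, _ = generate_dataset(d)
        m2, _ = generate_dataset(SyntheticDesign(seed=5))
        assert np.array_equal(m1.values, m2.values)
        assert m1.gene_ids == m2.gene_ids and m1.sample_ids == m2.sample_ids

    def test_within_module_correlation_matches_design(self):
        # lam^2/(lam^2+sigma^2)=0.8; Fisher-z sampling bound at n=200
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 100, "normal": 100},
            module_sizes=[50], discriminative_flags=[False],
            n_noise_genes=0, rho_within=0.8, seed=2,
        )
        m, _ = generate_dataset(d)
        assert 0.74 <= _mean_offdiag_corr(m.values) <= 0.86

    def test_null_effect_t_statistics_calibrated(self):
        # with no class shift, ~5% of per-gene two-sample t-tests at 0.05
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 100, "normal": 100},
            module_sizes=[], n_noise_genes=1000, effect_size=0.0, seed=9,
        )
        m, _ = generate_dataset(d)
        is_tumor = m.label_array() == "tumor"
        _, p = stats.ttest_ind(m.values[:, is_tumor], m.values[:, ~is_tumor],
                               axis=1)
        frac = (p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_ground_truth_partition_conserved(self, flat_dataset):
        m, truth = flat_dataset
        assert set(truth.gene_module) == set(m.gene_ids)
        counts = np.bincount([truth.gene_module[g] for g in m.gene_ids])
        assert counts[1:].tolist() == [60, 50, 40, 30, 20]

    def test_invalid_design_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SyntheticDesign(rho_within=1.5)
        with pytest.raises(ValueError):
            SyntheticDesign(module_sizes=[0, 10])
        with pytest.raises(ValueError):
            SyntheticDesign(n_samples_per_class={"tumor": 0})

    def test_discriminative_module_shifts_between_classes(self):
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 200, "normal": 200},
            module_sizes=[40], discriminative_flags=[True],
            effect_size=2.0, n_noise_genes=0, seed=4,
        )
        m, truth = generate_dataset(d)
        is_tumor = m.label_array() == "tumor"
        gap = m.values[:, is_tumor].mean() - m.values[:, ~is_tumor].mean()
        # per-gene shift = lam * effect = sqrt(0.8)*2 ~ 1.79
        assert abs(gap - np.sqrt(0.8) * 2.0) < 0.2


class TestNestedGenerator:
    def test_between_and_within_child_correlations(self):
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 100, "normal": 100},
            module_sizes=[150], nesting={0: [60, 50, 40]},
            discriminative_flags=[False],
            rho_super=0.3, rho_within=0.8, n_noise_genes=0, seed=6,
        )
        m, truth = generate_nested_dataset(d)
        lab = truth.module_label_array(m.gene_ids)
        within = _mean_offdiag_corr(m.values[lab == 1])
        c1 = m.values[lab == 1]
        c2 = m.values[lab == 2]
        between = float(np.corrcoef(np.vstack([c1, c2]))[: len(c1), len(c1):].mean())
        assert 0.74 <= within <= 0.86
        assert 0.24 <= between <= 0.36

    def test_nesting_absent_redirects_to_flat_generator(self):
        with pytest.raises(ValueError, match="generate_dataset"):
            generate_nested_dataset(SyntheticDesign(nesting=None))

    def test_child_sizes_must_sum_to_super(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticDesign(module_sizes=[100], nesting={0: [60, 50]})

    def test_two_supers_give_two_first_level_blocks(self):
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 30, "normal": 30},
            module_sizes=[150, 150],
            nesting={0: [60, 50, 40], 1: [60, 50, 40]},
            rho_super=0.3, n_noise_genes=10, seed=1,
        )
        m, truth = generate_nested_dataset(d)
        supers = {truth.gene_supermodule[g] for g in m.gene_ids}
        assert supers == {0, 1, 2}  # two supers plus noise id 0
        assert sum(truth.gene_supermodule[g] == 1 for g in m.gene_ids) == 150


class TestMergeCheckGenerator:
    def test_zero_shift_classes_identical_in_law(self):
        d = SyntheticDesign(
            n_samples_per_class={"tumor": 50, "normal": 200, "peritumoral": 200},
            module_sizes=[40], discriminative_flags=[True],
            effect_size=2.0, peritumoral_shift=0.0, n_noise_genes=0, seed=8,
        )
        m, _ = generate_merge_check_dataset(d)
        cls = m.label_array()
        # module genes share one factor, so compare per-sample factor
        # estimates (independent across samples) between the two classes
        z_hat = m.values.mean(axis=0)
        _, p = stats.ttest_ind(z_hat[cls == "normal"], z_hat[cls == "peritumoral"])
        assert p > 0.01

    def test_large_shift_creates_distinguishable_third_group(self):
        from genecomm.preprocess import cluster_diagnostics

        d = SyntheticDesign(
            n_samples_per_class={"tumor": 100, "normal": 100, "peritumoral": 100},
            module_sizes=[60, 50, 40, 30, 20],
            discriminative_flags=[True, True, True, True, False],
            effect_size=8.0, peritumoral_shift=4.0, n_noise_genes=0, seed=1,
        )
        m, _ = generate_merge_check_dataset(d)
        diag = cluster_diagnostics(m, k_max=5, seed=0)
        assert diag.chosen_k == 3

    def test_peritumoral_class_required(self):
        with pytest.raises(ValueError, match="peritumoral"):
            generate_merge_check_dataset(SyntheticDesign())
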