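import numpy as np
import pytest

from genecomm import ExpressionMatrix, SyntheticDesign, generate_dataset


@pytest.fixture(scope="session")
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples toy with hand-checkable values."""
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        np.array([[5.0, 4.0], [2.0, 1.0], [3.0, 6.0]]),
    )


@pytest.fixture(scope="session")
def flat_dataset():
    """Default flat planted design: 5 modules, no noise, 240 samples."""
    design = SyntheticDesign(
        n_samples_per_class={"tumor": 150, "normal": 90},
        module_sizes=[60, 50, 40, 30, 20],
        n_noise_genes=0,
        seed=0,
    )
    return generate_dataset(design)


@pytest.fixture(scope="session")
def discriminative_dataset():
    """One 50-gene module shifted 2 SD between classes plus noise genes."""
    design = SyntheticDesign(
        n_samples_per_class={"tumor": 150, "normal": 90},
        module_sizes=[50],
        discriminative_flags=[True],
        effect_size=2.0,
        n_noise_genes=50,
        seed=3,
    )
    return generate_dataset(design)
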