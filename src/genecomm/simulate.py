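"""Synthetic expression data with planted co-expression modules.

The generator emulates the structure of a two-condition (tumor vs normal)
bulk microarray study: groups of co-expressed genes driven by shared latent
factors, a subset of those factors shifted between classes, optional nesting
(a large super-module containing tighter child modules), an optional third
sample class generated from the normal model ("peritumoral"), and i.i.d.
noise genes.

Each module m carries one latent factor per sample, z_s ~ N(mu_class(m), 1);
gene g in m is lam * z_s + eps with eps ~ N(0, sigma) and
lam^2 / (lam^2 + sigma^2) = rho_within, so the model-implied within-module
correlation is exactly rho_within and can be checked against the sample
correlation analytically.  A discriminative module's factor mean differs by
``effect_size`` (in factor SD units) between tumor and normal.

Discriminative modules alternate the direction of their class shift (first
up-regulated in tumor, next down-regulated, ...), mirroring the mix of up-
and down-regulated programs in real tumors.  Same-direction shifts would
induce genuine positive correlation between otherwise independent modules
through the shared class structure; alternating signs instead yield
negative between-module correlation, exercising the signed (negative-edge)
community objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "generate_dataset",
    "generate_nested_dataset",
    "generate_merge_check_dataset",
]

TUMOR = "tumor"
NORMAL = "normal"
PERITUMORAL = "peritumoral"


@dataclass
class SyntheticDesign:
    """Parameters of a planted-module expression dataset.

    Defaults mirror the scale of the study design the generator emulates:
    ~150 tumor and ~90 normal samples, module sizes of a few tens of genes,
    a within-module correlation of 0.8 (strong co-expression), and a
    two-standard-deviation class shift on discriminative factors.
    """

    n_samples_per_class: dict[str, int] = field(
        default_factory=lambda: {TUMOR: 152, NORMAL: 91}
    )
    module_sizes: list[int] = field(default_factory=lambda: [60, 50, 40, 30, 20])
    nesting: dict[int, list[int]] | None = None
    rho_within: float = 0.8
    rho_super: float = 0.3
    n_noise_genes: int = 100
    discriminative_flags: list[bool] | None = None
    effect_size: float = 2.0
    peritumoral_shift: float = 0.0
    noise_sd: float = 1.0
    global_factor_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.n_samples_per_class:
            raise ValueError("at least one sample class required")
        for cls, n in self.n_samples_per_class.items():
            if n < 1:
                raise ValueError(f"class {cls!r} has non-positive sample count {n}")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (0.0 < self.rho_within < 1.0):
            raise ValueError("rho_within must lie strictly in (0, 1)")
        if self.nesting is not None:
            if not (0.0 < self.rho_super < self.rho_within):
                raise ValueError("rho_super must lie in (0, rho_within)")
            for idx, children in self.nesting.items():
                if idx < 0 or idx >= len(self.module_sizes):
                    raise ValueError(f"nesting refers to unknown module index {idx}")
                if sum(children) != self.module_sizes[idx]:
                    raise ValueError(
                        f"child sizes {children} do not sum to super-module "
                        f"size {self.module_sizes[idx]}"
                    )
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")
        if self.effect_size < 0 or self.peritumoral_shift < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.discriminative_flags is not None and len(
            self.discriminative_flags
        ) != len(self.module_sizes):
            raise ValueError("one discriminative flag per module required")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_noise_genes

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_class.values())

    def flags(self) -> list[bool]:
        if self.discriminative_flags is not None:
            return list(self.discriminative_flags)
        # default: only the first module is discriminative.  Two or more
        # class-shifted modules are mutually correlated through the shared
        # class structure and thus form a genuine super-block rather than
        # independent planted blocks; explicit flags opt into that.
        return [i == 0 for i in range(len(self.module_sizes))]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``gene_module`` maps every gene id to its planted module id (0 for noise
    genes); module ids are dense integers starting at 1.  For nested designs
    ``gene_supermodule`` additionally records the first-level (super-module)
    membership.
    """

    gene_module: dict[str, int]
    module_discriminative: dict[int, bool]
    sample_class: dict[str, str]
    gene_supermodule: dict[str, int] | None = None

    def module_label_array(self, gene_ids: list[str]) -> np.ndarray:
        return np.asarray([self.gene_module[g] for g in gene_ids])

    def to_dict(self) -> dict:
        out = {
            "gene_module": self.gene_module,
            "module_discriminative": {
                str(k): v for k, v in self.module_discriminative.items()
            },
            "sample_class": self.sample_class,
        }
        if self.gene_supermodule is not None:
            out["gene_supermodule"] = self.gene_supermodule
        return out


def _class_factor_means(
    design: SyntheticDesign, discriminative: bool, disc_rank: int
) -> dict[str, float]:
    """Latent factor mean per class for one module.

    ``disc_rank`` is the module's index among discriminative modules; even
    ranks shift up in tumor, odd ranks shift down (alternating direction).
    """
    if not discriminative:
        return {cls: 0.0 for cls in design.n_samples_per_class}
    sign = 1.0 if disc_rank % 2 == 0 else -1.0
    means = {TUMOR: sign * design.effect_size, NORMAL: 0.0}
    if PERITUMORAL in design.n_samples_per_class:
        means[PERITUMORAL] = sign * design.peritumoral_shift
    for cls in design.n_samples_per_class:
        means.setdefault(cls, 0.0)
    return means


def _sample_classes(design: SyntheticDesign) -> tuple[list[str], list[str]]:
    sample_ids: list[str] = []
    classes: list[str] = []
    for cls, n in design.n_samples_per_class.items():
        for i in range(n):
            sample_ids.append(f"{cls}_{i + 1}")
            classes.append(cls)
    return sample_ids, classes


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a flat planted-module dataset.

    Deterministic given ``design.seed``.  Gene ids are ``M<m>_g<i>`` for
    module genes and ``noise_<i>`` for noise genes; sample ids are
    ``<class>_<i>``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    sample_ids, classes = _sample_classes(design)
    n_samples = len(sample_ids)
    flags = design.flags()

    lam = float(np.sqrt(design.rho_within))
    sigma = float(np.sqrt(1.0 - design.rho_within))

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    gene_module: dict[str, int] = {}
    global_factor = rng.normal(size=n_samples)

    disc_rank = 0
    for m_idx, size in enumerate(design.module_sizes):
        module_id = m_idx + 1
        means = _class_factor_means(design, flags[m_idx], disc_rank)
        if flags[m_idx]:
            disc_rank += 1
        mu = np.asarray([means[c] for c in classes])
        z = rng.normal(loc=mu, scale=1.0, size=n_samples)
        eps = rng.normal(scale=sigma, size=(size, n_samples))
        blocks.append(lam * z[None, :] + eps)
        for g in range(size):
            gid = f"M{module_id}_g{g + 1}"
            gene_ids.append(gid)
            gene_module[gid] = module_id

    if design.n_noise_genes:
        noise = rng.normal(
            scale=design.noise_sd, size=(design.n_noise_genes, n_samples)
        )
        if design.global_factor_weight > 0:
            noise = noise + design.global_factor_weight * global_factor[None, :]
        blocks.append(noise)
        for g in range(design.n_noise_genes):
            gid = f"noise_{g + 1}"
            gene_ids.append(gid)
            gene_module[gid] = 0

    values = np.vstack(blocks) if blocks else np.empty((0, n_samples))
    labels = dict(zip(sample_ids, classes))
    matrix = ExpressionMatrix(gene_ids, sample_ids, values, labels)
    truth = GroundTruth(
        gene_module=gene_module,
        module_discriminative={
            m_idx + 1: flags[m_idx] for m_idx in range(len(design.module_sizes))
        },
        sample_class=labels,
    )
    return matrix, truth


def generate_nested_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a dataset with two-level planted hierarchy.

    Modules listed in ``design.nesting`` contribute a shared weak
    super-module factor (between-child correlation ``rho_super``) plus a
    strong per-child factor, so that within-child correlation is
    ``rho_within`` and between-child (same super) correlation is
    ``rho_super``.  Non-nested modules behave as in :func:`generate_dataset`.
    """
    design.validate()
    if design.nesting is None:
        raise ValueError(
            "design.nesting is absent; use generate_dataset for flat designs"
        )
    rng = np.random.default_rng(design.seed)
    sample_ids, classes = _sample_classes(design)
    n_samples = len(sample_ids)
    flags = design.flags()

    a = float(np.sqrt(design.rho_super))  # super-factor loading
    b = float(np.sqrt(design.rho_within - design.rho_super))  # child loading
    sigma = float(np.sqrt(1.0 - design.rho_within))
    lam = float(np.sqrt(design.rho_within))
    sigma_flat = float(np.sqrt(1.0 - design.rho_within))

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    gene_module: dict[str, int] = {}
    gene_super: dict[str, int] = {}
    module_disc: dict[int, bool] = {}
    next_leaf_id = 1

    disc_rank = 0
    for m_idx, size in enumerate(design.module_sizes):
        super_id = m_idx + 1
        means = _class_factor_means(design, flags[m_idx], disc_rank)
        if flags[m_idx]:
            disc_rank += 1
        mu = np.asarray([means[c] for c in classes])
        if m_idx in design.nesting:
            u = rng.normal(loc=mu, scale=1.0, size=n_samples)
            for child_size in design.nesting[m_idx]:
                leaf_id = next_leaf_id
                next_leaf_id += 1
                module_disc[leaf_id] = flags[m_idx]
                v = rng.normal(size=n_samples)
                eps = rng.normal(scale=sigma, size=(child_size, n_samples))
                blocks.append(a * u[None, :] + b * v[None, :] + eps)
                for g in range(child_size):
                    gid = f"S{super_id}_C{leaf_id}_g{g + 1}"
                    gene_ids.append(gid)
                    gene_module[gid] = leaf_id
                    gene_super[gid] = super_id
        else:
            leaf_id = next_leaf_id
            next_leaf_id += 1
            module_disc[leaf_id] = flags[m_idx]
            z = rng.normal(loc=mu, scale=1.0, size=n_samples)
            eps = rng.normal(scale=sigma_flat, size=(size, n_samples))
            blocks.append(lam * z[None, :] + eps)
            for g in range(size):
                gid = f"M{leaf_id}_g{g + 1}"
                gene_ids.append(gid)
                gene_module[gid] = leaf_id
                gene_super[gid] = super_id

    if design.n_noise_genes:
        blocks.append(
            rng.normal(scale=design.noise_sd, size=(design.n_noise_genes, n_samples))
        )
        for g in range(design.n_noise_genes):
            gid = f"noise_{g + 1}"
            gene_ids.append(gid)
            gene_module[gid] = 0
            gene_super[gid] = 0

    values = np.vstack(blocks)
    labels = dict(zip(sample_ids, classes))
    matrix = ExpressionMatrix(gene_ids, sample_ids, values, labels)
    truth = GroundTruth(
        gene_module=gene_module,
        module_discriminative=module_disc,
        sample_class=labels,
        gene_supermodule=gene_super,
    )
    return matrix, truth


def generate_merge_check_dataset(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a three-class dataset for the class-merging check.

    The "peritumoral" class is drawn from the "normal" generative model with
    an additional mean shift of ``peritumoral_shift`` on discriminative
    factors.  With shift 0 the two classes are statistically identical, so a
    two-cluster unsupervised analysis should co-assign them.
    """
    design.validate()
    if PERITUMORAL not in design.n_samples_per_class:
        raise ValueError('design must include a "peritumoral" class')
    return generate_dataset(design)
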