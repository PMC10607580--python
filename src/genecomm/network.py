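"""Signed weighted gene co-expression networks.

A network is the complete graph over genes whose edge weights are pairwise
correlations of expression profiles across samples; weights keep their sign
(co-expression vs anti-expression).  No hard thresholding is applied: the
downstream community objective consumes signed weights directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CoexpressionNetwork", "build_network", "subnetwork"]


@dataclass
class CoexpressionNetwork:
    """Symmetric signed weight matrix over an ordered gene set.

    Invariants (checked on construction): |w_ij| <= 1, w symmetric, zero
    diagonal, gene ids unique and aligned with the matrix order.
    """

    gene_ids: list[str]
    weights: np.ndarray
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids in network")
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{n} genes"
            )
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weight matrix is not symmetric")
        if np.abs(self.weights).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("weights must lie in [-1, 1]")
        if n and np.abs(np.diag(self.weights)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        # exact symmetry/clipping so later code can rely on it
        self.weights = np.clip((self.weights + self.weights.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_edge_list(self, path: str | Path) -> None:
        """Write a (gene_a, gene_b, weight) TSV of the upper triangle."""
        with open(Path(path), "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            iu = np.triu_indices(self.n_genes, k=1)
            for i, j in zip(*iu):
                fh.write(
                    f"{self.gene_ids[i]}\t{self.gene_ids[j]}\t"
                    f"{self.weights[i, j]:.10g}\n"
                )


def build_network(
    m: ExpressionMatrix, method: str = "pearson"
) -> CoexpressionNetwork:
    """Correlation network over genes.

    ``method`` is ``"pearson"`` or ``"spearman"``.  Constant (zero-variance)
    genes cannot be correlated and are dropped with a warning; if every gene
    is constant, or there are fewer than 3 samples, an error is raised.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if m.n_samples < 3:
        raise ValueError("at least 3 samples required to estimate correlations")
    values = m.values
    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.any():
        raise ValueError("all genes are constant; no correlations defined")
    if not keep.all():
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        logger.warning(
            "dropping %d constant gene(s): %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    X = values[keep]
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    W = np.corrcoef(X)
    W = np.clip(W, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return CoexpressionNetwork(gene_ids, W, correlation_method=method)


def subnetwork(
    net: CoexpressionNetwork,
    genes: list[str],
    recompute_from: ExpressionMatrix | None = None,
) -> CoexpressionNetwork:
    """Principal submatrix of the network restricted to ``genes``.

    Edge weights are inherited from the parent network by default; pass
    ``recompute_from`` to re-estimate correlations on the gene subset
    instead (sensitivity analysis).
    """
    index = {g: i for i, g in enumerate(net.gene_ids)}
    unknown = [g for g in genes if g not in index]
    if unknown:
        raise KeyError(f"gene(s) not in network: {unknown[:5]}")
    if recompute_from is not None:
        return build_network(
            recompute_from.subset_genes(list(genes)), net.correlation_method
        )
    rows = np.asarray([index[g] for g in genes], dtype=int)
    W = net.weights[np.ix_(rows, rows)]
    return CoexpressionNetwork(list(genes), W.copy(), net.correlation_method)
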