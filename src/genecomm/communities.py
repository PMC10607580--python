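"""Stability-driven hierarchical Leiden community detection.

The central procedure of the package.  On a signed co-expression network it
repeatedly runs the Leiden algorithm (two-layer signed modularity: positive
weights attract within communities, negative weights repel) from L random
initial configurations per parameter configuration (resolution gamma,
randomness beta), takes the majority partition, and accepts it only if it is
simultaneously

* stable      — mean pairwise normalized mutual information of the L run
                partitions is at least ``nmi_threshold`` (default 0.80),
* nontrivial  — more than one community,
* unfragmented — no community smaller than ``min_fragment_frac`` (default
                5%) of the current (sub)network.

Among accepted configurations the one with the highest mean NMI wins.
Communities of the winning partition with >= ``max_community_size`` genes
(default 100) are recursed on as subnetworks; communities smaller than
``min_community_size`` (default 4) are discarded; the rest are final leaves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .network import CoexpressionNetwork, subnetwork

__all__ = [
    "Partition",
    "LeidenConfig",
    "StabilityConfig",
    "StabilityResult",
    "CommunityTree",
    "TreeNode",
    "signed_quality",
    "leiden_run",
    "nmi",
    "mean_pairwise_nmi",
    "majority_partition",
    "assess_partition",
    "select_config",
    "hierarchical_detect",
    "HierarchicalCommunities",
]


# ---------------------------------------------------------------------------
# partitions


class Partition:
    """Assignment of every gene of a (sub)network to one community.

    Stored in canonical form: labels are renumbered 1..K by first appearance
    in gene order, so two partitions are equal (``==``, hashable via
    ``key``) iff they are identical up to label permutation.
    """

    __slots__ = ("gene_ids", "labels")

    def __init__(self, gene_ids: list[str], labels) -> None:
        labels = np.asarray(labels)
        if len(gene_ids) != labels.shape[0]:
            raise ValueError("one label per gene required")
        self.gene_ids = list(gene_ids)
        self.labels = _canonicalize(labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max(initial=0))

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]

    def communities(self) -> list[list[str]]:
        """Gene lists per community, ordered by canonical label 1..K."""
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for g, lab in zip(self.gene_ids, self.labels):
            out[lab - 1].append(g)
        return out

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Partition)
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.labels, other.labels)
        )

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"Partition({len(self.gene_ids)} genes, {self.n_communities} communities)"


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by first appearance."""
    mapping: dict = {}
    out = np.empty(labels.shape[0], dtype=int)
    nxt = 1
    for i, lab in enumerate(labels):
        lab = lab.item() if hasattr(lab, "item") else lab
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LeidenConfig:
    """Leiden optimizer settings.

    ``gamma`` is the modularity resolution; ``beta`` the nominal
    randomness level of the run ensemble (it parameterizes the per-run
    random initial configurations and seed streams); ``n_iterations`` caps
    the move/refine/aggregate passes (optimization stops early once a pass
    yields no improvement).  ``gamma_grid`` x ``beta_grid`` is the search
    space of :func:`select_config`.
    """

    gamma: float = 1.0
    beta: float = 0.05
    n_iterations: int = 200
    objective: str = "modularity"
    gamma_grid: list[float] = field(
        default_factory=lambda: [0.5, 0.75, 1.0, 1.25, 1.5]
    )
    beta_grid: list[float] = field(default_factory=lambda: [0.05])

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if not self.gamma_grid or not self.beta_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.objective != "modularity":
            raise ValueError("only the modularity objective is supported")


@dataclass
class StabilityConfig:
    """Stability-ensemble settings and acceptance thresholds."""

    L: int = 100
    nmi_threshold: float = 0.80
    min_fragment_frac: float = 0.05
    max_community_size: int = 100
    min_community_size: int = 4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be positive")
        if not (0.0 < self.nmi_threshold <= 1.0):
            raise ValueError("nmi_threshold must lie in (0, 1]")
        if not (0.0 <= self.min_fragment_frac < 1.0):
            raise ValueError("min_fragment_frac must lie in [0, 1)")


@dataclass
class StabilityResult:
    """Outcome of the L-run stability analysis at one (gamma, beta)."""

    gamma: float
    beta: float
    ensemble: list[Partition]
    mean_nmi: float
    majority: Partition
    majority_count: int
    accepted: bool = False
    rejection_reasons: tuple[str, ...] = ()

    def summary(self) -> dict:
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "L": len(self.ensemble),
            "mean_nmi": self.mean_nmi,
            "majority_count": self.majority_count,
            "n_communities": self.majority.n_communities,
            "community_sizes": self.majority.community_sizes().tolist(),
            "accepted": self.accepted,
            "rejection_reasons": list(self.rejection_reasons),
        }


# ---------------------------------------------------------------------------
# signed modularity


def _layer_modularity(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Newman-Girvan modularity at resolution gamma on one non-negative layer."""
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    strength = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        within = W[np.ix_(idx, idx)].sum()
        deg = strength[idx].sum()
        q += within / two_m - gamma * (deg / two_m) ** 2
    return float(q)


def signed_quality(
    net: CoexpressionNetwork, p: Partition, gamma: float = 1.0
) -> float:
    """Two-layer signed modularity Q = Q+ - Q-.

    Q+ is the gamma-resolution modularity of the positive-weight layer and
    Q- that of the absolute negative-weight layer; a good signed partition
    keeps positive weight within communities and negative weight between
    them.
    """
    if p.gene_ids != net.gene_ids:
        missing = set(net.gene_ids) - set(p.gene_ids)
        if missing:
            raise ValueError(f"partition missing gene(s): {sorted(missing)[:5]}")
        order = {g: i for i, g in enumerate(p.gene_ids)}
        labels = np.asarray([p.labels[order[g]] for g in net.gene_ids])
    else:
        labels = p.labels
    W = net.weights
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    return _layer_modularity(Wp, labels, gamma) - _layer_modularity(Wn, labels, gamma)


# ---------------------------------------------------------------------------
# Leiden runs


class _SignedGraph:
    """Positive/negative igraph layers of a signed network, built once so
    many seeded runs can share them."""

    def __init__(self, net: CoexpressionNetwork) -> None:
        self.n = net.n_genes
        W = net.weights
        iu, ju = np.triu_indices(self.n, k=1)
        w = W[iu, ju]
        pos = w > 0
        neg = w < 0
        self.g_pos = ig.Graph(
            self.n, list(zip(iu[pos].tolist(), ju[pos].tolist()))
        )
        self.w_pos = w[pos].tolist()
        self.g_neg = ig.Graph(
            self.n, list(zip(iu[neg].tolist(), ju[neg].tolist()))
        )
        self.w_neg = (-w[neg]).tolist()

    def run(self, gamma: float, seed: int, n_iterations: int) -> np.ndarray:
        """One seeded Leiden optimization of the signed objective.

        The optimizer maximizes gamma-resolution modularity on the
        positive layer minus the total within-community negative weight
        (a null-free penalty layer).  A configuration-model null on the
        negative layer would reward co-clustering nodes of high negative
        degree whenever total negative weight is small — for correlation
        networks with a noise-level negative layer that merges unrelated
        modules at every resolution — so the negative layer enters as a
        pure repulsion term, directly implementing "positive weight within
        communities, negative weight across".
        """
        rng = np.random.default_rng(seed)
        # random initial configuration: an arbitrary number of communities
        # with arbitrary node assignment
        k0 = int(rng.integers(1, self.n + 1))
        init = rng.integers(0, k0, size=self.n).tolist()
        part_pos = la.RBConfigurationVertexPartition(
            self.g_pos,
            initial_membership=init,
            weights=self.w_pos,
            resolution_parameter=gamma,
        )
        part_neg = la.CPMVertexPartition(
            self.g_neg,
            initial_membership=init,
            weights=self.w_neg,
            resolution_parameter=0.0,
        )
        opt = la.Optimiser()
        opt.set_rng_seed(int(seed) % (2**31 - 1))
        for _ in range(max(1, n_iterations)):
            diff = opt.optimise_partition_multiplex(
                [part_pos, part_neg], layer_weights=[1, -1], n_iterations=1
            )
            if diff <= 0:
                break
        return np.asarray(part_pos.membership)


def leiden_run(
    net: CoexpressionNetwork, cfg: LeidenConfig, seed: int
) -> Partition:
    """One Leiden run on a signed network; deterministic given ``seed``.

    Starts from a random initial configuration drawn from ``seed`` and
    optimizes the two-layer signed modularity at ``cfg.gamma``.
    """
    if net.n_genes == 0:
        raise ValueError("empty network")
    sg = _SignedGraph(net)
    membership = sg.run(cfg.gamma, seed, cfg.n_iterations)
    return Partition(net.gene_ids, membership)


def derive_seed(master_seed: int, gamma: float, beta: float, run: int) -> int:
    """Deterministic per-run seed from the master seed and configuration."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(int(round(gamma * 1_000_000)), int(round(beta * 1_000_000)), run),
    )
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# NMI


def _label_arrays(p_a: Partition, p_b: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(p_a.gene_ids) != set(p_b.gene_ids):
        raise ValueError("partitions cover different gene sets")
    if p_a.gene_ids == p_b.gene_ids:
        return p_a.labels, p_b.labels
    order = {g: i for i, g in enumerate(p_b.gene_ids)}
    idx = np.asarray([order[g] for g in p_a.gene_ids])
    return p_a.labels, p_b.labels[idx]


def nmi(p_a: Partition, p_b: Partition) -> float:
    """Normalized mutual information 2 I(a;b) / (H(a) + H(b)).

    Natural-log entropies over the joint label distribution.  Equals 1 iff
    the partitions are identical up to relabeling; by convention returns 1
    when both partitions are trivial (H(a)+H(b)=0).
    """
    la_, lb_ = _label_arrays(p_a, p_b)
    n = la_.shape[0]
    cont = np.zeros((la_.max(), lb_.max()))
    np.add.at(cont, (la_ - 1, lb_ - 1), 1.0)
    pa = cont.sum(axis=1) / n
    pb = cont.sum(axis=0) / n
    pj = cont / n
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha + hb == 0.0:
        return 1.0
    mask = pj > 0
    mi = float(np.sum(pj[mask] * (np.log(pj[mask]) - np.log(np.outer(pa, pb)[mask]))))
    val = 2.0 * mi / (ha + hb)
    return float(min(max(val, 0.0), 1.0))


def mean_pairwise_nmi(ensemble: list[Partition]) -> float:
    """Average NMI over all distinct unordered pairs of the ensemble.

    <NMI> = 2 / (L (L-1)) * sum_{a<b} NMI(p_a, p_b).  Identical partitions
    are grouped first so only distinct canonical forms are compared.
    """
    L = len(ensemble)
    if L < 2:
        raise ValueError("at least two partitions required")
    groups: dict[tuple[int, ...], tuple[Partition, int]] = {}
    for p in ensemble:
        key = p.key
        if key in groups:
            rep, cnt = groups[key]
            groups[key] = (rep, cnt + 1)
        else:
            groups[key] = (p, 1)
    reps = list(groups.values())
    total = 0.0
    for (rep_g, n_g) in reps:
        total += 1.0 * (n_g * (n_g - 1) / 2)  # identical pairs: NMI = 1
    for (rep_g, n_g), (rep_h, n_h) in itertools.combinations(reps, 2):
        total += n_g * n_h * nmi(rep_g, rep_h)
    return float(total / (L * (L - 1) / 2))


def majority_partition(
    ensemble: list[Partition],
    net: CoexpressionNetwork | None = None,
    gamma: float = 1.0,
) -> tuple[Partition, int]:
    """Most recurring partition (up to relabeling) and its multiplicity.

    Ties are broken by signed quality (when ``net`` is given), then by the
    lexicographically smallest canonical label sequence, so the result is
    fully deterministic.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    counts: dict[tuple[int, ...], tuple[Partition, int]] = {}
    for p in ensemble:
        key = p.key
        if key in counts:
            rep, cnt = counts[key]
            counts[key] = (rep, cnt + 1)
        else:
            counts[key] = (p, 1)
    best_count = max(cnt for _, cnt in counts.values())
    tied = [(key, rep) for key, (rep, cnt) in counts.items() if cnt == best_count]
    if len(tied) > 1 and net is not None:
        qualities = {key: signed_quality(net, rep, gamma) for key, rep in tied}
        best_q = max(qualities.values())
        tied = [(k, r) for k, r in tied if qualities[k] >= best_q - 1e-12]
    key, rep = min(tied, key=lambda kr: kr[0])
    return rep, best_count


# ---------------------------------------------------------------------------
# acceptance and configuration selection


def assess_partition(
    sr: StabilityResult, net_size: int, cfg: StabilityConfig
) -> StabilityResult:
    """Fill the accepted flag: stable AND nontrivial AND not fragmented.

    A partition is fragmented if any community has fewer nodes than
    ``min_fragment_frac`` x net_size (strict inequality: a community of
    exactly 5 nodes in a 100-node network is not fragmented at 5%).
    """
    reasons: list[str] = []
    if sr.mean_nmi < cfg.nmi_threshold:
        reasons.append("unstable")
    if sr.majority.n_communities < 2:
        reasons.append("trivial")
    sizes = sr.majority.community_sizes()
    if sizes.size and sizes.min() < cfg.min_fragment_frac * net_size:
        reasons.append("fragmented")
    sr.accepted = not reasons
    sr.rejection_reasons = tuple(reasons)
    return sr


def _stability_run(
    net: CoexpressionNetwork,
    sg: _SignedGraph,
    gamma: float,
    beta: float,
    lcfg: LeidenConfig,
    scfg: StabilityConfig,
) -> StabilityResult:
    seeds = [derive_seed(scfg.master_seed, gamma, beta, r) for r in range(scfg.L)]
    ensemble = [
        Partition(net.gene_ids, sg.run(gamma, s, lcfg.n_iterations)) for s in seeds
    ]
    majority, count = majority_partition(ensemble, net, gamma)
    m_nmi = mean_pairwise_nmi(ensemble) if scfg.L >= 2 else 1.0
    sr = StabilityResult(
        gamma=gamma,
        beta=beta,
        ensemble=ensemble,
        mean_nmi=m_nmi,
        majority=majority,
        majority_count=count,
    )
    return assess_partition(sr, net.n_genes, scfg)


def select_config(
    net: CoexpressionNetwork,
    lcfg: LeidenConfig,
    scfg: StabilityConfig,
    return_all: bool = False,
):
    """Grid search over (gamma, beta): L seeded runs each, keep the accepted
    configuration with the highest mean NMI.

    Exact ties in mean NMI (e.g. several configurations each perfectly
    stable) are broken by resolution-plateau width: the majority partition
    that recurs as majority across the largest number of accepted
    configurations wins, a partition robust to the resolution being the
    more trustworthy structure.  Residual ties fall back on the signed
    quality of the majority partition at the reference resolution gamma=1,
    then on the smaller gamma and the smaller beta.  Returns ``None`` (or
    ``(None, all_results)``) when no configuration is accepted.
    """
    sg = _SignedGraph(net)
    results: list[StabilityResult] = []
    for gamma in lcfg.gamma_grid:
        for beta in lcfg.beta_grid:
            results.append(_stability_run(net, sg, gamma, beta, lcfg, scfg))
    accepted = [r for r in results if r.accepted]
    best = None
    if accepted:
        top_nmi = max(r.mean_nmi for r in accepted)
        tied = [r for r in accepted if r.mean_nmi >= top_nmi - 1e-9]
        if len(tied) > 1:
            plateau: dict[tuple[int, ...], int] = {}
            for r in accepted:
                key = r.majority.key
                plateau[key] = plateau.get(key, 0) + 1
            quality = {id(r): signed_quality(net, r.majority, 1.0) for r in tied}
            best = min(
                tied,
                key=lambda r: (
                    -plateau[r.majority.key],
                    -quality[id(r)],
                    r.gamma,
                    r.beta,
                ),
            )
        else:
            best = tied[0]
    if return_all:
        return best, results
    return best


# ---------------------------------------------------------------------------
# hierarchy


@dataclass
class TreeNode:
    """One node of the community hierarchy."""

    genes: list[str]
    depth: int
    path: tuple[int, ...]  # community index at each ancestor split
    status: str  # internal | leaf | discarded | unresolvable
    stability: StabilityResult | None = None
    children: list["TreeNode"] = field(default_factory=list)
    leaf_id: int = 0

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class CommunityTree:
    """Hierarchy of accepted partitions over a root gene set.

    ``leaves`` are the final communities (between the minimum and maximum
    community size); ``discarded`` are groups below the minimum size;
    ``unresolvable`` are oversized groups where no configuration was
    accepted.  Their gene sets are pairwise disjoint and together equal the
    root gene set (conservation).
    """

    root: TreeNode
    leaves: list[TreeNode] = field(default_factory=list)
    discarded: list[TreeNode] = field(default_factory=list)
    unresolvable: list[TreeNode] = field(default_factory=list)

    def finalize(self) -> None:
        """Assign dense leaf ids 1..K in depth-first order and check
        conservation."""
        for i, leaf in enumerate(self.leaves, start=1):
            leaf.leaf_id = i
        assigned: list[str] = []
        for group in (self.leaves, self.discarded, self.unresolvable):
            for node in group:
                assigned.extend(node.genes)
        if sorted(assigned) != sorted(self.root.genes):
            raise AssertionError("community tree does not conserve the gene set")

    def leaf_assignment(self) -> dict[str, int]:
        """gene -> leaf id (0 for genes of discarded/unresolvable groups)."""
        out = {g: 0 for g in self.root.genes}
        for leaf in self.leaves:
            for g in leaf.genes:
                out[g] = leaf.leaf_id
        return out

    def leaf_partition(self) -> Partition:
        """Partition of the root gene set by final community (0-labelled
        genes grouped as label of their own)."""
        assign = self.leaf_assignment()
        return Partition(self.root.genes, [assign[g] for g in self.root.genes])

    def to_rows(self) -> list[tuple[str, tuple[int, ...], int]]:
        rows: list[tuple[str, tuple[int, ...], int]] = []

        def visit(node: TreeNode) -> None:
            if node.status in ("leaf", "discarded", "unresolvable"):
                for g in node.genes:
                    rows.append((g, node.path, node.leaf_id))
            for child in node.children:
                visit(child)

        visit(self.root)
        order = {g: i for i, g in enumerate(self.root.genes)}
        rows.sort(key=lambda r: order[r[0]])
        return rows

    def report(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {
                "depth": node.depth,
                "path": list(node.path),
                "size": node.size,
                "status": node.status,
            }
            if node.stability is not None:
                d["stability"] = node.stability.summary()
            if node.status == "leaf":
                d["leaf_id"] = node.leaf_id
            if node.children:
                d["children"] = [node_dict(c) for c in node.children]
            return d

        return {
            "n_leaves": len(self.leaves),
            "n_discarded": len(self.discarded),
            "n_unresolvable": len(self.unresolvable),
            "tree": node_dict(self.root),
        }


def hierarchical_detect(
    net: CoexpressionNetwork,
    lcfg: LeidenConfig | None = None,
    scfg: StabilityConfig | None = None,
) -> CommunityTree:
    """Depth-first stability-driven hierarchical community detection.

    Each node's subnetwork undergoes :func:`select_config`; communities of
    the winning majority partition are discarded (< min size), kept as
    leaves (< max size) or recursed on (>= max size).  Oversized nodes with
    no accepted configuration are recorded as unresolvable.
    """
    lcfg = lcfg or LeidenConfig()
    scfg = scfg or StabilityConfig()
    if net.n_genes < scfg.min_community_size:
        raise ValueError(
            f"network of {net.n_genes} genes is smaller than the minimum "
            f"community size {scfg.min_community_size}"
        )
    root = TreeNode(genes=list(net.gene_ids), depth=0, path=(), status="internal")
    tree = CommunityTree(root=root)

    def recurse(node: TreeNode, node_net: CoexpressionNetwork) -> None:
        best = select_config(node_net, lcfg, scfg)
        if best is None:
            node.status = "unresolvable"
            tree.unresolvable.append(node)
            return
        node.status = "internal"
        node.stability = best
        for c_idx, genes in enumerate(best.majority.communities(), start=1):
            child = TreeNode(
                genes=genes,
                depth=node.depth + 1,
                path=node.path + (c_idx,),
                status="pending",
            )
            node.children.append(child)
            if len(genes) < scfg.min_community_size:
                child.status = "discarded"
                tree.discarded.append(child)
            elif len(genes) < scfg.max_community_size:
                child.status = "leaf"
                tree.leaves.append(child)
            else:
                recurse(child, subnetwork(node_net, genes))

    recurse(root, net)
    tree.finalize()
    return tree


# ---------------------------------------------------------------------------
# estimator facade


class HierarchicalCommunities(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer over genes.

    ``fit(X)`` with X of shape (n_genes, n_samples) builds the signed
    correlation network and runs hierarchical stability-driven Leiden
    detection.  ``labels_`` holds the final community id per gene (0 for
    genes not in any retained community).
    """

    def __init__(
        self,
        correlation_method: str = "pearson",
        gamma_grid: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5),
        beta_grid: tuple[float, ...] = (0.05,),
        n_iterations: int = 200,
        L: int = 100,
        nmi_threshold: float = 0.80,
        min_fragment_frac: float = 0.05,
        max_community_size: int = 100,
        min_community_size: int = 4,
        random_state: int = 0,
    ) -> None:
        self.correlation_method = correlation_method
        self.gamma_grid = gamma_grid
        self.beta_grid = beta_grid
        self.n_iterations = n_iterations
        self.L = L
        self.nmi_threshold = nmi_threshold
        self.min_fragment_frac = min_fragment_frac
        self.max_community_size = max_community_size
        self.min_community_size = min_community_size
        self.random_state = random_state

    def fit(self, X, y=None):
        from .io import ExpressionMatrix
        from .network import build_network

        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_genes, n_samples)")
        gene_ids = [f"g{i}" for i in range(X.shape[0])]
        sample_ids = [f"s{j}" for j in range(X.shape[1])]
        m = ExpressionMatrix(gene_ids, sample_ids, X)
        net = build_network(m, self.correlation_method)
        lcfg = LeidenConfig(
            gamma_grid=list(self.gamma_grid),
            beta_grid=list(self.beta_grid),
            n_iterations=self.n_iterations,
        )
        scfg = StabilityConfig(
            L=self.L,
            nmi_threshold=self.nmi_threshold,
            min_fragment_frac=self.min_fragment_frac,
            max_community_size=self.max_community_size,
            min_community_size=self.min_community_size,
            master_seed=self.random_state,
        )
        self.tree_ = hierarchical_detect(net, lcfg, scfg)
        assign = self.tree_.leaf_assignment()
        full = {g: 0 for g in gene_ids}  # genes dropped as constant stay 0
        full.update(assign)
        self.labels_ = np.asarray([full[g] for g in gene_ids])
        self.n_communities_ = len(self.tree_.leaves)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
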