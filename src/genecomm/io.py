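"""Reading and writing of pipeline artifacts.

Expression matrices are plain delimited text, genes in rows, a header row of
sample identifiers and a first column of gene identifiers.  Partitions are
TSV with one row per gene; reports are JSON.  All loaders validate strictly:
duplicate identifiers and non-numeric or missing cells are errors, never
silently repaired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_partition",
    "read_partition",
    "write_json",
    "read_json",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix with identifiers.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, aligned with the rows of ``values``.
    sample_ids : list of str
        Unique sample identifiers, aligned with the columns of ``values``.
    values : ndarray of shape (n_genes, n_samples)
        Expression values (log scale for microarray-like data).
    labels : dict, optional
        Maps every sample id to a class string (e.g. ``"tumor"`` /
        ``"normal"``).  When present it must cover every sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix columns"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise ValueError(f"labels missing for samples: {missing[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def label_array(self) -> np.ndarray:
        """Class label per sample, in sample order."""
        if self.labels is None:
            raise ValueError("expression matrix carries no labels")
        return np.asarray([self.labels[s] for s in self.sample_ids])

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        unknown = [g for g in genes if g not in index]
        if unknown:
            raise KeyError(f"unknown gene(s): {unknown[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows, :], self.labels
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in samples if s not in index]
        if unknown:
            raise KeyError(f"unknown sample(s): {unknown[:5]}")
        cols = [index[s] for s in samples]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in samples}
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols], labels
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    The first column (or first row when ``genes_in_rows=False``) holds gene
    identifiers; the header holds sample identifiers.  Orientation is always
    normalised to genes x samples.  Duplicate identifiers, non-numeric cells
    and missing values raise ``ValueError`` with coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if not genes_in_rows:
        raw = raw.T
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(gene_ids, "gene id")
    _check_unique(sample_ids, "sample id")
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r} "
                    f"(row {i}), sample {sample_ids[j]!r} (column {j})"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    m.to_frame().to_csv(Path(path), sep=delimiter, index_label="gene_id")


def read_labels(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column sample -> class file.

    A sample listed twice with conflicting classes is an error; an empty
    file yields an empty map with a warning.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if lineno == 1 and parts[0] in ("sample_id", "sample"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sample, cls = parts[0].strip(), parts[1].strip()
            if sample in labels and labels[sample] != cls:
                raise ValueError(
                    f"sample {sample!r} listed with conflicting classes "
                    f"{labels[sample]!r} and {cls!r}"
                )
            labels[sample] = cls
    if not labels:
        logger.warning("label file %s is empty", path)
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")


# -- partition files -------------------------------------------------------

UNASSIGNED = 0  # reserved leaf id for genes of discarded / unresolved groups


def write_partition(tree, path: str | Path) -> None:
    """Serialise the leaf assignment of a community tree.

    One row per root gene: gene id, the community label at every hierarchy
    depth (dot-joined path, empty at depths the gene does not reach) and the
    final leaf id.  Genes of discarded (<4 genes) or unresolvable groups get
    the reserved leaf id 0 so that gene accounting is conserved.
    """
    rows = tree.to_rows()
    max_depth = max((len(r[1]) for r in rows), default=0)
    with open(Path(path), "w") as fh:
        header = ["gene_id"] + [f"depth_{d + 1}" for d in range(max_depth)]
        header.append("leaf_id")
        fh.write("\t".join(header) + "\n")
        for gene, path_labels, leaf_id in rows:
            cells = [gene]
            for d in range(max_depth):
                cells.append(str(path_labels[d]) if d < len(path_labels) else "")
            cells.append(str(leaf_id))
            fh.write("\t".join(cells) + "\n")


@dataclass
class PartitionFile:
    """Deserialised partition table: per-gene hierarchy path and leaf id."""

    gene_ids: list[str]
    depth_labels: list[tuple[str, ...]]
    leaf_ids: list[int]

    def leaf_map(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, self.leaf_ids))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, leaf in zip(self.gene_ids, self.leaf_ids):
            out.setdefault(leaf, []).append(g)
        return out


def read_partition(path: str | Path) -> PartitionFile:
    genes: list[str] = []
    paths: list[tuple[str, ...]] = []
    leaves: list[int] = []
    with open(Path(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_depth = len(header) - 2
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            gene = cells[0]
            if gene in genes[-1:] or gene in set(genes):
                raise ValueError(f"gene {gene!r} appears more than once")
            genes.append(gene)
            paths.append(tuple(c for c in cells[1 : 1 + n_depth] if c != ""))
            leaves.append(int(cells[-1]))
    nonzero = sorted({l for l in leaves if l != UNASSIGNED})
    if nonzero and nonzero != list(range(1, len(nonzero) + 1)):
        raise ValueError(f"leaf ids are not dense 1..K: {nonzero}")
    return PartitionFile(genes, paths, leaves)


# -- generic JSON ----------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(Path(path)) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
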