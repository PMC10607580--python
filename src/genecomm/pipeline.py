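"""End-to-end workflow orchestration.

Runs the full analysis on one configuration: (optional) simulation or
loading of an expression matrix, normalization, signed network
construction, stability-driven hierarchical community detection, per-leaf
Boruta selection on the 40% selection split, repeated cross-validated
random-forest classification on the 60% split, community ranking by mean
accuracy, optional external validation, and SHAP explanation of the top
communities.  Every stage writes plain-text artifacts (TSV/JSON) into the
output directory, and a manifest records the configuration echo, derived
seeds, stage timings and library versions so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (
    CVConfig,
    RFConfig,
    external_validate,
    rank_communities,
    repeated_cv,
    train_rf,
)
from .communities import LeidenConfig, StabilityConfig, hierarchical_detect
from .feature_selection import BorutaConfig, SplitConfig, boruta_select, \
    split_selection_classification
from .io import (
    ExpressionMatrix,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    write_json,
    write_labels,
    write_partition,
)
from .network import build_network
from .preprocess import log2_transform, quantile_normalize
from .simulate import SyntheticDesign, generate_dataset
from .xai import approx_shap, plot_shap_summary, shap_summary

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Complete configuration of a pipeline run.

    Every stage seed is derived deterministically from ``master_seed``.
    """

    out_dir: str = "genecomm_run"
    matrix_path: str | None = None
    labels_path: str | None = None
    external_matrix_path: str | None = None
    external_labels_path: str | None = None
    delimiter: str = "\t"

    simulate: dict = field(default_factory=dict)  # SyntheticDesign kwargs

    apply_log2: bool = False
    log2_offset: float = 0.0
    apply_quantile: bool = True

    correlation_method: str = "pearson"

    gamma_grid: list[float] = field(default_factory=lambda: [0.5, 0.75, 1.0, 1.25, 1.5])
    beta_grid: list[float] = field(default_factory=lambda: [0.05])
    leiden_iterations: int = 200
    L: int = 100
    nmi_threshold: float = 0.80
    min_fragment_frac: float = 0.05
    max_community_size: int = 100
    min_community_size: int = 4

    boruta_max_iterations: int = 100
    boruta_alpha: float = 0.05
    boruta_correction: str = "bonferroni"
    boruta_rf_trees: int = 300
    boruta_importance: str = "impurity"

    selection_fraction: float = 0.40
    stratified_split: bool = True

    rf_trees: int = 300
    rf_mtry: str = "all_features"
    cv_folds: int = 5
    cv_repeats: int = 100

    accuracy_cutoff: float = 90.0
    positive_class: str = "tumor"

    shap_max_communities: int = 2
    shap_n_permutations: int = 100
    shap_background_size: int = 50
    shap_n_explain: int = 30
    shap_plots: bool = False

    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_or_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> ExpressionMatrix:
    if cfg.matrix_path:
        path = Path(cfg.matrix_path)
        if not path.exists():
            raise FileNotFoundError(f"input matrix not found: {path}")
        m = read_expression_matrix(path, delimiter=cfg.delimiter)
        manifest["inputs"] = {"matrix": _sha256(path)}
        if cfg.labels_path:
            lpath = Path(cfg.labels_path)
            if not lpath.exists():
                raise FileNotFoundError(f"labels file not found: {lpath}")
            labels = read_labels(lpath)
            m = ExpressionMatrix(m.gene_ids, m.sample_ids, m.values, labels)
            manifest["inputs"]["labels"] = _sha256(lpath)
        return m
    design_kwargs = dict(cfg.simulate)
    design_kwargs.setdefault("seed", _stage_seed(cfg.master_seed, "simulate"))
    design = SyntheticDesign(**design_kwargs)
    m, truth = generate_dataset(design)
    write_expression_matrix(m, out / "expression.tsv")
    write_labels(m.labels or {}, out / "labels.tsv")
    write_json(truth.to_dict(), out / "ground_truth.json")
    manifest["inputs"] = {"simulated": True, "design": asdict(design)}
    return m


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(cfg),
        "master_seed": cfg.master_seed,
        "stages": {},
        "versions": _versions(),
    }
    cfg.to_yaml(out / "config.yaml")

    def stage(name: str):
        manifest["stages"][name] = {"started": time.time()}

        def done(**info) -> None:
            rec = manifest["stages"][name]
            rec["seconds"] = round(time.time() - rec.pop("started"), 3)
            rec.update(info)

        return done

    try:
        done = stage("load")
        m = _load_or_simulate(cfg, out, manifest)
        if m.labels is None:
            raise ValueError("sample labels are required (labels file or simulation)")
        done(n_genes=m.n_genes, n_samples=m.n_samples)

        done = stage("preprocess")
        if cfg.apply_log2:
            m = log2_transform(m, cfg.log2_offset)
        if cfg.apply_quantile:
            m = quantile_normalize(m)
            write_expression_matrix(m, out / "normalized.tsv")
        done(log2=cfg.apply_log2, quantile=cfg.apply_quantile)

        done = stage("network")
        net = build_network(m, cfg.correlation_method)
        done(n_genes=net.n_genes, method=cfg.correlation_method)

        done = stage("communities")
        lcfg = LeidenConfig(
            gamma_grid=list(cfg.gamma_grid),
            beta_grid=list(cfg.beta_grid),
            n_iterations=cfg.leiden_iterations,
        )
        scfg = StabilityConfig(
            L=cfg.L,
            nmi_threshold=cfg.nmi_threshold,
            min_fragment_frac=cfg.min_fragment_frac,
            max_community_size=cfg.max_community_size,
            min_community_size=cfg.min_community_size,
            master_seed=_stage_seed(cfg.master_seed, "communities"),
        )
        tree = hierarchical_detect(net, lcfg, scfg)
        write_partition(tree, out / "partition.tsv")
        write_json(tree.report(), out / "community_report.json")
        done(n_leaves=len(tree.leaves), n_discarded=len(tree.discarded),
             n_unresolvable=len(tree.unresolvable))

        done = stage("split")
        split_cfg = SplitConfig(
            selection_fraction=cfg.selection_fraction,
            stratified=cfg.stratified_split,
            seed=_stage_seed(cfg.master_seed, "split"),
        )
        binary_labels = {
            s: ("tumor" if c == cfg.positive_class else "non_tumor")
            for s, c in (m.labels or {}).items()
        }
        sel_ids, clf_ids = split_selection_classification(
            m.sample_ids, binary_labels, split_cfg
        )
        write_json({"selection": sel_ids, "classification": clf_ids},
                   out / "split.json")
        done(n_selection=len(sel_ids), n_classification=len(clf_ids))

        y_all = (m.label_array() == cfg.positive_class).astype(int)
        sample_index = {s: i for i, s in enumerate(m.sample_ids)}
        sel_idx = np.asarray([sample_index[s] for s in sel_ids])
        clf_idx = np.asarray([sample_index[s] for s in clf_ids])

        done = stage("select_and_classify")
        boruta_dir = out / "boruta"
        boruta_dir.mkdir(exist_ok=True)
        gene_index = {g: i for i, g in enumerate(m.gene_ids)}
        reports: dict[int, object] = {}
        selected_genes: dict[int, list[str]] = {}
        table_rows: list[dict] = []
        for leaf in tree.leaves:
            comm_id = leaf.leaf_id
            rows = np.asarray([gene_index[g] for g in leaf.genes])
            X_sel = m.values[np.ix_(rows, sel_idx)].T
            bcfg = BorutaConfig(
                max_iterations=cfg.boruta_max_iterations,
                alpha=cfg.boruta_alpha,
                correction=cfg.boruta_correction,
                rf_trees=cfg.boruta_rf_trees,
                importance=cfg.boruta_importance,
                seed=_stage_seed(cfg.master_seed, f"boruta:{comm_id}"),
            )
            bres = boruta_select(X_sel, y_all[sel_idx], bcfg)
            write_json(bres.to_dict(leaf.genes), boruta_dir / f"comm_{comm_id}.json")
            genes = [leaf.genes[i] for i in bres.confirmed_indices()]
            selected_genes[comm_id] = genes
            with open(boruta_dir / f"comm_{comm_id}_selected.txt", "w") as fh:
                fh.write("\n".join(genes) + ("\n" if genes else ""))
            if not genes:
                table_rows.append(
                    {"Community": f"Comm_{comm_id}", "Cardinality": leaf.size,
                     "Selected": 0, "Accuracy": "NA", "AUC": "NA", "F1": "NA",
                     "LogLoss": "NA"}
                )
                continue
            g_rows = np.asarray([gene_index[g] for g in genes])
            X_clf = m.values[np.ix_(g_rows, clf_idx)].T
            report = repeated_cv(
                X_clf,
                y_all[clf_idx],
                RFConfig(n_trees=cfg.rf_trees, mtry=cfg.rf_mtry,
                         seed=_stage_seed(cfg.master_seed, f"rf:{comm_id}")),
                CVConfig(k_folds=cfg.cv_folds, repeats=cfg.cv_repeats,
                         seed=_stage_seed(cfg.master_seed, f"cv:{comm_id}")),
            )
            reports[comm_id] = report
            row = {"Community": f"Comm_{comm_id}", "Cardinality": leaf.size,
                   "Selected": len(genes)}
            row.update(report.format_row())
            table_rows.append(row)
        _write_table(table_rows, out / "cv_report.tsv")
        done(n_classified=len(reports))

        done = stage("rank")
        ranked = rank_communities(reports, cfg.accuracy_cutoff)
        write_json(
            [{"community": f"Comm_{c}", "mean_accuracy": a} for c, a in ranked],
            out / "ranked_communities.json",
        )
        done(n_selected=len(ranked))

        if cfg.external_matrix_path:
            done = stage("external_validation")
            ext = read_expression_matrix(cfg.external_matrix_path,
                                         delimiter=cfg.delimiter)
            if cfg.external_labels_path:
                ext_labels = read_labels(cfg.external_labels_path)
                ext = ExpressionMatrix(ext.gene_ids, ext.sample_ids, ext.values,
                                       ext_labels)
            if cfg.apply_quantile:
                ext = quantile_normalize(ext)
            ext_rows: list[dict] = []
            for comm_id, _acc in ranked:
                genes = selected_genes[comm_id]
                g_rows = np.asarray([gene_index[g] for g in genes])
                X_train = m.values[np.ix_(g_rows, clf_idx)].T
                model = train_rf(
                    X_train, y_all[clf_idx],
                    RFConfig(n_trees=cfg.rf_trees, mtry=cfg.rf_mtry,
                             seed=_stage_seed(cfg.master_seed, f"ext:{comm_id}")),
                )
                means = {g: float(X_train[:, j].mean()) for j, g in enumerate(genes)}
                metrics = external_validate(model, genes, ext, means,
                                            positive_class=cfg.positive_class)
                row = {"Community": f"Comm_{comm_id}", "Cardinality": len(genes)}
                row.update({k: f"{v:.2f}" for k, v in metrics.to_dict().items()})
                ext_rows.append(row)
            _write_table(ext_rows, out / "external_validation.tsv")
            done(n_validated=len(ext_rows))

        done = stage("explain")
        shap_dir = out / "shap"
        shap_dir.mkdir(exist_ok=True)
        explained = []
        for comm_id, _acc in ranked[: cfg.shap_max_communities]:
            genes = selected_genes[comm_id]
            g_rows = np.asarray([gene_index[g] for g in genes])
            X_train = m.values[np.ix_(g_rows, clf_idx)].T
            model = train_rf(
                X_train, y_all[clf_idx],
                RFConfig(n_trees=cfg.rf_trees, mtry=cfg.rf_mtry,
                         seed=_stage_seed(cfg.master_seed, f"shap_rf:{comm_id}")),
            )
            rng = np.random.default_rng(_stage_seed(cfg.master_seed,
                                                    f"shap:{comm_id}"))
            bg_pick = rng.choice(
                X_train.shape[0],
                size=min(cfg.shap_background_size, X_train.shape[0]),
                replace=False,
            )
            X_explain_full = m.values[np.ix_(g_rows, sel_idx)].T
            ex_pick = rng.choice(
                X_explain_full.shape[0],
                size=min(cfg.shap_n_explain, X_explain_full.shape[0]),
                replace=False,
            )
            exp = approx_shap(
                model,
                X_explain_full[ex_pick],
                X_train[bg_pick],
                n_permutations=cfg.shap_n_permutations,
                seed=_stage_seed(cfg.master_seed, f"shap_perm:{comm_id}"),
            )
            summary = shap_summary(exp, top_k=20, feature_names=genes)
            write_json(
                {"community": f"Comm_{comm_id}", "base_value": exp.base_value,
                 "summary": summary.to_dict()},
                shap_dir / f"comm_{comm_id}.json",
            )
            if cfg.shap_plots:
                plot_shap_summary(exp, genes, shap_dir / f"comm_{comm_id}.png")
            explained.append(comm_id)
        done(communities=[f"Comm_{c}" for c in explained])
    except Exception as err:  # record the failing stage, then re-raise
        running = [k for k, v in manifest["stages"].items() if "started" in v]
        manifest["error"] = {"stage": running[-1] if running else "unknown",
                            "message": str(err)}
        write_json(manifest, out / "manifest.json")
        raise
    write_json(manifest, out / "manifest.json")
    return manifest


def _write_table(rows: list[dict], path: Path) -> None:
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    cols = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")


def _versions() -> dict:
    import igraph
    import leidenalg
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "python-igraph": igraph.__version__,
        "leidenalg": leidenalg.version,
    }
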