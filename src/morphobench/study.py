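"""Orchestration of the full factorial simulation study.

The design crosses two 32-taxon generating tree shapes (fully symmetric,
fully pectinate) with three matrix sizes (100, 350, 1000 characters) and R
replicate matrices per cell; each replicate is analysed with equal-weights
parsimony, implied-weights parsimony (k = 2), maximum-likelihood Mk+Gamma
and Bayesian Mk+Gamma, and every method's result is summarised as a
majority-rule consensus scored against the generating tree.

Replicate matrices are admitted per cell through the homoplasy
bin-matching sampler, so each cell's CI distribution matches the target
histogram. Every engine is seeded deterministically from the master seed,
the cell and the replicate index, making any replicate reproducible in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .homoplasy import (HomoplasyTarget, bin_match_sampler,
                        ci_matrix_generator, default_homoplasy_target)
from .mcmc import MCMCConfig, run_mcmc
from .metrics import (depth_accuracy_correlation, majority_rule_consensus,
                      per_node_accuracy, resolution, rf_distance)
from .mk import MkConfig, ml_search
from .parsimony import ParsimonyConfig, parsimony_search
from .simulate import CharacterMatrix
from .trees import Tree, make_asymmetric_tree, make_symmetric_tree

__all__ = [
    "StudyDesign",
    "CellResult",
    "StudyResult",
    "generating_tree",
    "run_replicate_method",
    "run_cell",
    "run_study",
    "count_matrices",
    "make_report",
]

METHODS = ("ew", "iw", "ml", "bayes")
SHAPES = ("symmetric", "asymmetric")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design and engine settings for one study run."""

    shapes: tuple[str, ...] = SHAPES
    sizes: tuple[int, ...] = (100, 350, 1000)
    replicates: int = 50
    methods: tuple[str, ...] = METHODS
    master_seed: int = 0
    n_taxa: int = 32
    binary_fraction: float = 0.55
    target: HomoplasyTarget = field(default_factory=default_homoplasy_target)
    parsimony: ParsimonyConfig = field(default_factory=ParsimonyConfig)
    mk: MkConfig = field(default_factory=MkConfig)
    mcmc: MCMCConfig = field(
        default_factory=lambda: MCMCConfig(n_generations=100_000, n_runs=1)
    )
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for s in self.shapes:
            if s not in SHAPES:
                raise ValueError(f"unknown tree shape {s!r}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def desk(cls, master_seed: int = 0, **kw) -> "StudyDesign":
        """Desk-scale preset: 50 replicates/cell, 100k-generation single-run
        MCMC, no Metropolis coupling."""
        return cls(master_seed=master_seed, **kw)

    @classmethod
    def paper(cls, master_seed: int = 0, **kw) -> "StudyDesign":
        """Full-scale preset: 1000 replicates/cell and the printed MCMC
        settings (1M generations, two runs, four coupled chains)."""
        return cls(
            master_seed=master_seed,
            replicates=1000,
            mcmc=MCMCConfig.paper_scale(),
            **kw,
        )


def generating_tree(shape: str, n_taxa: int = 32) -> Tree:
    if shape == "symmetric":
        return make_symmetric_tree(n_taxa)
    if shape == "asymmetric":
        return make_asymmetric_tree(n_taxa)
    raise ValueError(f"unknown tree shape {shape!r}")


def count_matrices(design: StudyDesign) -> int:
    """Dry-run matrix count of the full design (shapes x sizes x replicates)."""
    return len(design.shapes) * len(design.sizes) * design.replicates


def _method_seed(design: StudyDesign, shape: str, size: int, rep: int,
                 method: str) -> int:
    key = (SHAPES.index(shape), size, rep, METHODS.index(method))
    ss = np.random.SeedSequence(design.master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicate_method(
    matrix: CharacterMatrix,
    gen_tree: Tree,
    method: str,
    design: StudyDesign,
    seed: int,
) -> dict:
    """Run one inference method on one matrix; returns consensus + scores."""
    if method == "ew":
        res = parsimony_search(
            matrix, replace(design.parsimony, weighting="equal"), seed=seed
        )
        consensus = majority_rule_consensus(res.best_trees)
        extra = {"score": res.best_score, "n_best_trees": len(res.best_trees)}
    elif method == "iw":
        res = parsimony_search(
            matrix, replace(design.parsimony, weighting="implied"), seed=seed
        )
        consensus = majority_rule_consensus(res.best_trees)
        extra = {"score": res.best_score, "n_best_trees": len(res.best_trees)}
    elif method == "ml":
        res = ml_search(matrix, design.mk, seed=seed)
        consensus = res.tree  # ML yields a single fully resolved tree
        extra = {"loglik": res.loglik, "alpha": res.alpha}
    elif method == "bayes":
        sample = run_mcmc(matrix, design.mcmc, seed=seed)
        consensus = sample.consensus()
        extra = {
            "mean_loglik": float(sample.loglik.mean()),
            "mean_alpha": float(sample.alpha.mean()),
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "consensus": consensus,
        "rf": rf_distance(consensus, gen_tree),
        "resolution": resolution(consensus, gen_tree.n_leaves),
        **extra,
    }


@dataclass
class CellResult:
    shape: str
    n_characters: int
    per_replicate: pd.DataFrame  # replicate x method rows: rf, resolution, ci
    node_accuracy: dict[str, pd.DataFrame]  # method -> per-node table
    spearman: pd.DataFrame  # method rows: rho, p_value
    consensuses: dict[str, list[Tree]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = self.per_replicate.groupby("method")
        out = g.agg(
            mean_rf=("rf", "mean"),
            min_rf=("rf", "min"),
            max_rf=("rf", "max"),
            mean_resolution=("resolution", "mean"),
        ).reset_index()
        out.insert(0, "shape", self.shape)
        out.insert(1, "n_characters", self.n_characters)
        return out


def run_cell(
    shape: str,
    n_characters: int,
    replicates: int,
    methods: tuple[str, ...] = METHODS,
    design: StudyDesign | None = None,
    log_path: str | Path | None = None,
) -> CellResult:
    """Simulate, homoplasy-filter and analyse one design cell."""
    design = design or StudyDesign()
    gen_tree = generating_tree(shape, design.n_taxa)
    cell_seed = _method_seed(design, shape, n_characters, 0, methods[0]) ^ 0x5EED
    generator = ci_matrix_generator(
        gen_tree, n_characters, design.binary_fraction
    )
    matrices = bin_match_sampler(
        generator, design.target, replicates, seed=cell_seed,
        reallocate_after=300 * replicates,
    )
    rows = []
    consensuses: dict[str, list[Tree]] = {m: [] for m in methods}
    log_records = []
    for rep, matrix in enumerate(matrices):
        for method in methods:
            seed = _method_seed(design, shape, n_characters, rep, method)
            try:
                out = run_replicate_method(matrix, gen_tree, method, design, seed)
            except Exception as exc:  # engine failure: flag, keep going
                rows.append(
                    {"replicate": rep, "method": method, "ci": matrix.ci,
                     "rf": np.nan, "resolution": np.nan, "error": str(exc)}
                )
                continue
            consensuses[method].append(out["consensus"])
            row = {
                "replicate": rep,
                "method": method,
                "ci": matrix.ci,
                "rf": out["rf"],
                "resolution": out["resolution"],
                "error": "",
            }
            rows.append(row)
            log_records.append(
                {"shape": shape, "n_characters": n_characters, "replicate": rep,
                 "method": method, "seed": seed, "ci": matrix.ci,
                 "rf": out["rf"], "resolution": out["resolution"]}
            )
    per_replicate = pd.DataFrame(rows)
    node_acc = {}
    spearman_rows = []
    for method in methods:
        if not consensuses[method]:
            continue
        table = per_node_accuracy(gen_tree, consensuses[method])
        node_acc[method] = table
        sp = depth_accuracy_correlation(table)
        spearman_rows.append(
            {"method": method, "rho": sp.rho, "p_value": sp.p_value,
             "defined": sp.defined}
        )
    if log_path is not None:
        with open(log_path, "a") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    return CellResult(
        shape, n_characters, per_replicate, node_acc,
        pd.DataFrame(spearman_rows), consensuses,
    )


@dataclass
class StudyResult:
    design: StudyDesign
    cells: list[CellResult]

    def rf_table(self) -> pd.DataFrame:
        """Mean and range of RF distances per cell and method."""
        return pd.concat([c.summary() for c in self.cells], ignore_index=True)

    def spearman_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            t = c.spearman.copy()
            t.insert(0, "shape", c.shape)
            t.insert(1, "n_characters", c.n_characters)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


def run_study(design: StudyDesign, log_path: str | Path | None = None) -> StudyResult:
    cells = []
    for shape in design.shapes:
        for size in design.sizes:
            cells.append(
                run_cell(shape, size, design.replicates, design.methods,
                         design, log_path)
            )
    return StudyResult(design, cells)


def make_report(result: StudyResult, outdir: str | Path) -> list[Path]:
    """Write CSV tables and diagnostic figures for a finished study."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.cells:
        raise ValueError("no results to report")
    if not result.design.methods:
        raise ValueError("no methods were run")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    rf = result.rf_table()
    p = outdir / "rf_summary.csv"
    rf.to_csv(p, index=False)
    written.append(p)

    sp = result.spearman_table()
    p = outdir / "depth_accuracy_spearman.csv"
    sp.to_csv(p, index=False)
    written.append(p)

    per_rep = pd.concat(
        [c.per_replicate.assign(shape=c.shape, n_characters=c.n_characters)
         for c in result.cells],
        ignore_index=True,
    )
    p = outdir / "per_replicate.csv"
    per_rep.to_csv(p, index=False)
    written.append(p)

    for c in result.cells:
        for method, table in c.node_accuracy.items():
            p = outdir / f"node_accuracy_{c.shape}_{c.n_characters}_{method}.csv"
            table.to_csv(p, index=False)
            written.append(p)

    # RF vs resolution density (one panel per method)
    methods = list(result.design.methods)
    fig, axes = plt.subplots(
        1, len(methods), figsize=(4 * len(methods), 4), squeeze=False
    )
    for ax, method in zip(axes[0], methods):
        sub = per_rep[(per_rep["method"] == method) & per_rep["rf"].notna()]
        ax.hexbin(sub["resolution"], sub["rf"], gridsize=20, cmap="YlOrRd",
                  mincnt=1)
        ax.set_xlabel("resolution")
        ax.set_ylabel("RF distance")
        ax.set_title(method)
    fig.tight_layout()
    p = outdir / "rf_vs_resolution.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # per-node accuracy against depth
    for c in result.cells:
        if not c.node_accuracy:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        for method, table in c.node_accuracy.items():
            ax.scatter(table["depth"], table["accuracy_pct"], label=method,
                       alpha=0.7)
        ax.set_xlabel("node depth (edges from root)")
        ax.set_ylabel("recovery (%)")
        ax.set_title(f"{c.shape}, {c.n_characters} characters")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"node_accuracy_{c.shape}_{c.n_characters}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
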