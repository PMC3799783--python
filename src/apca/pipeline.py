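"""End-to-end run: load -> collapse -> select (a, b) -> decompose -> score
-> call DEGs -> network + ROC -> write tables.

Every convention applied along the way (duplicate collapses, chosen
weights, basis mode, sign rule, threshold, combination rule) is
recorded as machine-parsable ``key=value`` lines in ``run_log.txt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .calling import DEGCallResult, call_degs, score_threshold
from .core import APCAParams, apca, gene_scores, score_table
from .evaluation import DEFAULT_TAU, EvaluationResult, evaluate_degs
from .selection import DEFAULT_A_GRID, DEFAULT_B_GRID, grid_search

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run.

    Either preset weights (``a``, ``b``) or a grid search
    (``use_grid=True``) must be chosen, not both. ``basis`` selects the
    back-projection convention: ``"raw"`` keeps gene scores on the
    intensity scale of the data (where the integer floor threshold is
    meaningful), ``"orthonormal"`` yields unit-norm score vectors.
    """

    expr: str | Path
    labels: str | Path
    out_dir: str | Path
    annotation: str | Path | None = None
    dialect: str = "plain-tsv"
    a: float | None = 0.3
    b: float | None = 20.0
    use_grid: bool = False
    a_grid: tuple[float, ...] = DEFAULT_A_GRID
    b_grid: tuple[float, ...] = DEFAULT_B_GRID
    k: int = 2
    theta: float | None = None
    tau: float = DEFAULT_TAU
    basis: str = "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.use_grid and (self.a is not None or self.b is not None):
            raise ValueError("preset (a, b) and grid search are mutually exclusive")
        if not self.use_grid and (self.a is None or self.b is None):
            raise ValueError("either preset (a, b) or use_grid must be given")


@dataclass
class RunResult:
    """Key outputs of one pipeline run."""

    params: APCAParams
    decomposition_summary: pd.DataFrame
    scores: pd.DataFrame
    degs: DEGCallResult
    evaluation: EvaluationResult | None
    out_files: list[Path] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    """An error wrapped with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; see module docstring for the stages."""
    log: list[str] = [f"seed={config.seed}", f"basis={config.basis}",
                      f"sign_rule=max_abs_positive",
                      f"combination_rule=mean_sign_aligned_zscore"]

    try:
        x = io.read_expression_table(config.expr, dialect=config.dialect)
        x = x.with_labels(io.read_labels(config.labels))
        annotation = (io.read_annotation(config.annotation)
                      if config.annotation else None)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("io_expr", e) from e

    groups = io.find_duplicate_samples(x)
    removed = [s for g in groups for s in g[1:]]
    x = io.collapse_duplicates(x)
    log += [f"n_probes={x.n_probes}",
            f"duplicates_removed={','.join(removed) if removed else 'none'}",
            f"n_samples={x.n_samples}", f"n_controls={x.n_controls}",
            f"n_cases={x.n_cases}"]

    if config.use_grid:
        sel = grid_search(x, config.a_grid, config.b_grid, mode=config.basis)
        log.append(f"selection_status={sel.status}")
        if sel.chosen is None:
            raise StageError("selection",
                             RuntimeError("no (a, b) separates the classes"))
        params = sel.chosen
    else:
        sel = None
        params = APCAParams(a=config.a, b=config.b)
    log += [f"a={params.a}", f"b={params.b}", f"k={config.k}"]

    try:
        dec = apca(x, params, mode=config.basis)
        scores_vec = gene_scores(dec.basis, dec.eigen.eigenvectors, k=config.k)
        scores = score_table(scores_vec, x.probe_ids, annotation)
    except Exception as e:  # noqa: BLE001
        raise StageError("apca_core", e) from e

    theta = config.theta if config.theta is not None else score_threshold(scores)
    degs = call_degs(scores, theta)
    log += [f"theta={theta}",
            f"max_abs_score={scores['score'].abs().max():.6g}",
            f"n_deg_probes={degs.n_probes}", f"n_deg_genes={degs.n_genes}"]

    evaluation = None
    if degs.n_probes >= 1 and x.n_cases >= 3:
        try:
            evaluation = evaluate_degs(x, degs.calls, tau=config.tau)
            log += [f"tau={config.tau}",
                    f"n_edges={len(evaluation.network.edges)}",
                    f"n_subnetworks={len(evaluation.network.subnetworks)}",
                    f"n_pairs={len(evaluation.network.pairs)}",
                    f"n_singletons={len(evaluation.network.singletons)}"]
        except Exception as e:  # noqa: BLE001
            raise StageError("evaluation", e) from e

    out_dir = Path(config.out_dir)
    tables = {
        "decomposition": dec.summary(),
        "scores": scores,
        "degs": degs.calls,
    }
    if sel is not None:
        tables["feasible"] = pd.DataFrame(sel.feasible,
                                          columns=["a", "b", "margin"])
    if evaluation is not None:
        tables["edges"] = evaluation.network.edge_table()
        tables["components"] = pd.DataFrame(
            [(i + 1, len(c), ";".join(c))
             for i, c in enumerate(evaluation.network.components)],
            columns=["component", "size", "members"])
        tables["roc"] = evaluation.roc_table()
    try:
        out_files = io.write_tables(tables, out_dir)
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log) + "\n")
        out_files.append(log_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("io_expr", e) from e

    for line in log:
        logger.info("%s", line)
    return RunResult(params=params, decomposition_summary=dec.summary(),
                     scores=scores, degs=degs, evaluation=evaluation,
                     out_files=out_files, log_lines=log)
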