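"""Synthetic unbalanced two-class expression matrices with known truth.

The generator emulates the structure the method is designed for: many
probes, few samples, unbalanced classes (majority controls, minority
cases). Each matrix combines

* a shared baseline profile per probe (the genome-wide commonality that
  dominates total variance on unnormalised arrays),
* a per-sample multiplicative scale factor (array effect) acting on
  that baseline — this is what makes the leading component of real
  intensity data a "commonality" axis rather than a class contrast,
* planted class-differential probes, either as a case-class mean shift
  (``de_mode="mean"``) or as case-only correlated variance structure
  (``de_mode="case-variance"``, where class means stay exactly equal and
  the signal lives entirely in the minority class's covariance; a
  control-only distractor factor of equal strength is planted on a
  disjoint probe set, emulating the majority-class structure that
  dominates the minor components of sample-fraction-weighted PCA),
* optional correlated probe blocks driven by a shared latent factor,
* i.i.d. Gaussian noise, and
* optional exactly duplicated control columns (technical replicates).

Defaults mirror the study design this package targets: 19 independent
controls plus 10 cases, 30 planted probes at a 3-standard-deviation
effect, out of 2000 probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix, write_expression_table

DE_MODES = ("mean", "case-variance")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``effect`` is the class-mean shift (or case-variance factor scale)
    in units of the noise standard deviation. ``block_rho`` is the
    target within-block Pearson correlation. ``sample_scale_sd`` is the
    standard deviation of the per-sample multiplicative array effect.
    ``duplicate_controls`` appends that many exact copies of the first
    control column.
    """

    m: int = 2000
    n_controls: int = 19
    n_cases: int = 10
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_de: int = 30
    effect: float = 3.0
    de_mode: str = "mean"
    n_blocks: int = 2
    block_size: int = 5
    block_rho: float = 0.9
    noise_sd: float = 1.0
    sample_scale_sd: float = 0.15
    duplicate_controls: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("need m >= 2 and at least one sample per class")
        if self.n_controls + self.n_cases < 4:
            raise ValueError("need at least 4 samples in total")
        if not 0 <= self.n_de <= self.m:
            raise ValueError("n_de must lie in [0, m]")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.de_mode not in DE_MODES:
            raise ValueError(f"de_mode must be one of {DE_MODES}")
        planted = self.n_de * (2 if self.de_mode == "case-variance" else 1)
        if planted + self.n_blocks * self.block_size > self.m:
            raise ValueError("planted probes and blocks exceed the probe count")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.duplicate_controls < 0:
            raise ValueError("duplicate_controls must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted into a generated matrix."""

    de_probes: list[str]
    de_signs: dict[str, int]
    blocks: list[list[str]] = field(default_factory=list)
    distractor_probes: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = [(p, "de", self.de_signs[p]) for p in self.de_probes]
        rows += [(p, "distractor", 0) for p in self.distractor_probes]
        for k, blk in enumerate(self.blocks, start=1):
            rows += [(p, f"block_{k}", 0) for p in blk]
        return pd.DataFrame(rows, columns=["probe_id", "role", "sign"])


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one dataset; identical configs (and seeds) are bit-identical."""
    rng = np.random.default_rng(config.seed)
    m, n, d = config.m, config.n_controls, config.n_cases
    l = n + d
    probe_ids = [f"probe_{i:05d}" for i in range(m)]
    sample_ids = [f"ctrl_{j:02d}" for j in range(n)] + \
                 [f"case_{j:02d}" for j in range(d)]
    labels = [CONTROL] * n + [CASE] * d

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)
    # array effect drawn with equal class means, so class differences come
    # only from the planted signal, not from array-scale sampling noise
    scale = rng.normal(0.0, config.sample_scale_sd, size=l)
    scale[:n] -= scale[:n].mean()
    scale[n:] -= scale[n:].mean()
    values = baseline[:, None] * (1.0 + scale[None, :])

    # planted differential probes, distractor (case-variance mode only),
    # then disjoint correlated blocks
    order = rng.permutation(m)
    de_idx = np.sort(order[:config.n_de])
    pool = order[config.n_de:]
    distractor_idx = np.array([], dtype=int)
    if config.de_mode == "case-variance":
        distractor_idx = np.sort(pool[:config.n_de])
        pool = pool[config.n_de:]
    blocks_idx = [np.sort(pool[k * config.block_size:(k + 1) * config.block_size])
                  for k in range(config.n_blocks)]

    signs = rng.choice([-1, 1], size=config.n_de)
    ctrl_cols = np.arange(0, n)
    case_cols = np.arange(n, l)
    if config.n_de:
        amp = config.effect * config.noise_sd
        if config.de_mode == "mean":
            values[np.ix_(de_idx, case_cols)] += amp * signs[:, None]
        else:
            # case-only latent factor, centred so class means stay equal
            u = rng.normal(0.0, 1.0, size=d)
            u -= u.mean()
            values[np.ix_(de_idx, case_cols)] += amp * signs[:, None] * u[None, :]
            # majority-class structure of matching strength on other probes
            v = rng.normal(0.0, 1.0, size=n)
            v -= v.mean()
            d_signs = rng.choice([-1, 1], size=len(distractor_idx))
            values[np.ix_(distractor_idx, ctrl_cols)] += (
                amp * d_signs[:, None] * v[None, :])

    if config.block_rho > 0:
        c = config.noise_sd * np.sqrt(config.block_rho / (1 - config.block_rho))
        for blk in blocks_idx:
            if len(blk) == 0:
                continue
            f = rng.normal(0.0, 1.0, size=l)
            values[blk, :] += c * f[None, :]

    values += rng.normal(0.0, config.noise_sd, size=(m, l))

    if config.duplicate_controls:
        reps = np.repeat(values[:, [0]], config.duplicate_controls, axis=1)
        values = np.concatenate([values[:, [0]], reps, values[:, 1:]], axis=1)
        rep_ids = [f"ctrl_00_rep{r}" for r in range(1, config.duplicate_controls + 1)]
        sample_ids = sample_ids[:1] + rep_ids + sample_ids[1:]
        labels = [CONTROL] * (1 + config.duplicate_controls) + labels[1:]

    x = ExpressionMatrix(values, probe_ids, sample_ids, labels)
    truth = SyntheticTruth(
        de_probes=[probe_ids[i] for i in de_idx],
        de_signs={probe_ids[i]: int(s) for i, s in zip(de_idx, signs)},
        blocks=[[probe_ids[i] for i in blk] for blk in blocks_idx],
        distractor_probes=[probe_ids[i] for i in distractor_idx],
    )
    return x, truth


def rank_recall(scores: pd.DataFrame, truth_probes: list[str],
                top: int | None = None) -> float:
    """Fraction of planted probes among the top-|truth| probes by |score|."""
    truth = set(truth_probes)
    if not truth:
        raise ValueError("empty truth set")
    top = top if top is not None else len(truth)
    ranked = scores.reindex(scores["score"].abs().sort_values(
        ascending=False, kind="mergesort").index)
    top_probes = set(ranked["probe_id"].head(top))
    return len(top_probes & truth) / len(truth)


def called_recall(calls: pd.DataFrame, truth_probes: list[str]) -> float:
    """Fraction of planted probes present in the called DEG table."""
    truth = set(truth_probes)
    if not truth:
        raise ValueError("empty truth set")
    return len(set(calls["probe_id"]) & truth) / len(truth)


def save_dataset(x: ExpressionMatrix, truth: SyntheticTruth,
                 out_dir: str | Path) -> dict[str, Path]:
    """Serialise matrix, labels and ground truth as plain TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression_table(x, paths["expression"])
    pd.DataFrame({"sample_id": x.sample_ids, "class": x.labels}).to_csv(
        paths["labels"], sep="\t", index=False, header=False)
    truth.frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
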