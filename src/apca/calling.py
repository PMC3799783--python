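"""Turning discriminant-component scores into a DEG list.

The calling rule is deliberately simple: the threshold is the floor of
half the largest absolute score, theta = floor(|S|_max / 2), and a probe
is called when |S| is *strictly* greater than theta. Probe-level calls
are aggregated to gene level on the verbatim gene-symbol string, so a
composite locus such as ``"HBA1 /// HBA2"`` counts as one gene even
when several probes report it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .io import sort_score_table

logger = logging.getLogger(__name__)


@dataclass
class DEGCallResult:
    """Threshold and surviving records of one calling pass."""

    theta: int
    calls: pd.DataFrame  # probe_id, gene_symbol, score; descending |score|
    n_probes: int
    n_genes: int


def score_threshold(scores: pd.DataFrame) -> int:
    """theta = floor(max |score| / 2), an integer on the score scale.

    All-zero scores yield theta = 0 with a warning, since no probe can
    then exceed the threshold under the strict comparison.
    """
    if scores.empty:
        raise ValueError("score table is empty")
    s_max = float(scores["score"].abs().max())
    theta = math.floor(s_max / 2.0)
    if s_max == 0:
        logger.warning("all scores are zero; theta = 0 calls nothing")
    return theta


def call_degs(scores: pd.DataFrame, theta: float) -> DEGCallResult:
    """Call probes with |score| strictly above theta.

    Output rows are sorted by descending |score| (probe_id breaks ties);
    ``n_genes`` collapses called probes sharing a gene symbol, with
    unannotated probes each counting as their own gene.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    called = scores[scores["score"].abs() > theta]
    called = sort_score_table(called)
    keys = [
        sym if isinstance(sym, str) and sym else probe
        for probe, sym in zip(called["probe_id"], called["gene_symbol"])
    ]
    return DEGCallResult(
        theta=theta,
        calls=called,
        n_probes=len(called),
        n_genes=len(set(keys)),
    )
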