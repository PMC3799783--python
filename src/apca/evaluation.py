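"""Discrimination power of called DEGs: correlation networks and ROC/AUC.

Called genes are first organised by their co-expression structure
*within one class* (by default the case group): Pearson correlations
between every DEG pair are thresholded at CC >= tau (tau = 0.9) and the
connected components of the resulting graph partition the DEGs into
subnetworks (>= 3 members), connection pairs (2) and individual genes.

Each gene, and each component-derived combination, is then scored as a
classifier of case vs control samples via the area under the ROC curve.
The AUC is computed as the Mann-Whitney U statistic normalised by
n_pos * n_neg (ties counted half), with a two-sided p-value from the
normal-approximation rank test with tie correction. Cases are the
positive class. The combination score of a component is the mean of its
members' z-scored expression, each sign-aligned with the sign of the
member's discriminant score, so that all members vote in the same
direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .io import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Edge threshold on the within-class Pearson correlation.
DEFAULT_TAU = 0.9

#: Two-sided p-values below this are reported as "< 1e-15", never as 0.
P_FLOOR = 1e-15


@dataclass
class CorrelationNetwork:
    """Thresholded within-class co-expression graph over called DEGs."""

    nodes: list[str]
    cc: pd.DataFrame                      # symmetric correlation matrix
    tau: float
    edges: list[tuple[str, str, float]]   # (probe_a, probe_b, cc), a < b
    components: list[list[str]]           # maximal connected sets, largest first
    dropped: list[str] = field(default_factory=list)  # zero-variance probes

    @property
    def subnetworks(self) -> list[list[str]]:
        return [c for c in self.components if len(c) >= 3]

    @property
    def pairs(self) -> list[list[str]]:
        return [c for c in self.components if len(c) == 2]

    @property
    def singletons(self) -> list[list[str]]:
        return [c for c in self.components if len(c) == 1]

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["probe_a", "probe_b", "cc"])


@dataclass
class ROCResult:
    """AUC with significance for one gene or one gene combination."""

    auc: float
    p_value: float
    fpr: np.ndarray
    tpr: np.ndarray
    members: list[str]
    orientation: list[int] | None = None

    @property
    def p_display(self) -> str:
        return f"< {P_FLOOR:g}" if self.p_value <= P_FLOOR else f"{self.p_value:.3g}"


@dataclass
class EvaluationResult:
    """Network plus per-gene and per-combination ROC results."""

    network: CorrelationNetwork
    single: dict[str, ROCResult]
    combinations: dict[str, ROCResult]

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for probe, r in self.single.items():
            rows.append(("gene", probe, 1, r.auc, r.p_value, r.p_display))
        for name, r in self.combinations.items():
            rows.append(("combination", name, len(r.members), r.auc,
                         r.p_value, r.p_display))
        return pd.DataFrame(
            rows, columns=["unit", "id", "n_probes", "auc", "p_value", "p"])


def within_class_cc(x: ExpressionMatrix, probes: list[str],
                    group: str = CASE) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between probe pairs over one class's samples.

    Returns the correlation matrix over the usable probes plus the list
    of probes excluded because they have zero variance within the group
    (their correlation is undefined).
    """
    x._require_labels()
    cols = [j for j, c in enumerate(x.labels) if c == group]
    if len(cols) < 3:
        raise ValueError(f"need >= 3 samples in group {group!r}, have {len(cols)}")
    index = {p: i for i, p in enumerate(x.probe_ids)}
    missing = [p for p in probes if p not in index]
    if missing:
        raise ValueError(f"probes not in matrix: {missing}")
    sub = x.values[np.ix_([index[p] for p in probes], cols)]
    sd = sub.std(axis=1)
    dropped = [p for p, s in zip(probes, sd) if s == 0]
    if dropped:
        logger.warning("zero variance within %s group, excluded: %s", group, dropped)
    kept = [p for p in probes if p not in set(dropped)]
    sub = sub[[i for i, p in enumerate(probes) if p not in set(dropped)]]
    cc = np.corrcoef(sub)
    cc = np.atleast_2d(cc)
    return pd.DataFrame(cc, index=kept, columns=kept), dropped


def build_network(cc: pd.DataFrame, tau: float = DEFAULT_TAU) -> CorrelationNetwork:
    """Threshold the correlation matrix at cc >= tau and take components.

    The comparison is inclusive. Components are maximal connected sets
    of the edge graph (connectivity is transitive even though high
    correlation itself is not), ordered by decreasing size then by first
    member.
    """
    nodes = list(cc.index)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    vals = cc.to_numpy()
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if vals[i, j] >= tau:
                g.add_edge(a, nodes[j], cc=float(vals[i, j]))
    edges = sorted((min(a, b), max(a, b), d["cc"]) for a, b, d in g.edges(data=True))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return CorrelationNetwork(nodes=nodes, cc=cc, tau=tau, edges=edges,
                              components=comps)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg), ties half."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_single(values: np.ndarray, labels: list[str],
               member: str = "") -> ROCResult:
    """ROC/AUC of one per-sample score against the case/control labels.

    Cases are positives. The p-value is the two-sided Mann-Whitney
    normal approximation with tie correction; with all values tied the
    test is uninformative and p = 1.
    """
    values = np.asarray(values, float)
    lab = np.asarray(labels)
    pos = values[lab == CASE]
    neg = values[lab == CONTROL]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc = _rank_auc(pos, neg)
    if np.ptp(values) == 0:
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # exact-tie corner emits a RuntimeWarning
            res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                     method="asymptotic")
        p = float(res.pvalue)
    p = max(p, P_FLOOR)
    y = (lab == CASE).astype(int)
    fpr, tpr, _ = roc_curve(y, values)
    return ROCResult(auc=auc, p_value=p, fpr=fpr, tpr=tpr,
                     members=[member] if member else [])


def auc_combination(x: ExpressionMatrix, probes: list[str],
                    orientations: list[int], labels: list[str] | None = None) -> ROCResult:
    """ROC/AUC of a gene combination.

    The per-sample combination score is the mean over member probes of
    the probe's z-scored expression multiplied by the sign of its
    discriminant score, so down-regulated members contribute with
    flipped sign. Zero-variance probes cannot be z-scored and are
    excluded with a warning.
    """
    if len(probes) < 2:
        raise ValueError("a combination needs >= 2 probes")
    if len(orientations) != len(probes):
        raise ValueError("one orientation per probe required")
    labels = labels if labels is not None else x.labels
    index = {p: i for i, p in enumerate(x.probe_ids)}
    zs, kept = [], []
    for probe, sign in zip(probes, orientations):
        row = x.values[index[probe]]
        sd = row.std()
        if sd == 0:
            logger.warning("zero-variance probe %s excluded from combination", probe)
            continue
        zs.append((1 if sign >= 0 else -1) * (row - row.mean()) / sd)
        kept.append(probe)
    if not zs:
        raise ValueError("no usable probes in combination")
    combined = np.mean(zs, axis=0)
    res = auc_single(combined, labels)
    res.members = kept
    res.orientation = [1 if s >= 0 else -1 for s in orientations]
    return res


def evaluate_degs(x: ExpressionMatrix, calls: pd.DataFrame,
                  tau: float = DEFAULT_TAU, group: str = CASE) -> EvaluationResult:
    """Network + ROC evaluation of a called DEG table.

    ``calls`` must hold probe_id, gene_symbol and score columns (as
    produced by DEG calling). The co-expression network is built within
    ``group``; single-gene AUCs are computed for every called probe and
    combination AUCs for every network component with >= 2 members.
    """
    probes = list(calls["probe_id"])
    signs = {p: (1 if s >= 0 else -1)
             for p, s in zip(calls["probe_id"], calls["score"])}
    cc, dropped = within_class_cc(x, probes, group=group)
    net = build_network(cc, tau=tau)
    net.dropped = dropped
    single = {p: auc_single(x.values[x.probe_ids.index(p)], x.labels, member=p)
              for p in probes}
    combos: dict[str, ROCResult] = {}
    for i, comp in enumerate(net.components, start=1):
        if len(comp) < 2:
            continue
        combos[f"component_{i}"] = auc_combination(
            x, comp, [signs[p] for p in comp])
    return EvaluationResult(network=net, single=single, combinations=combos)
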