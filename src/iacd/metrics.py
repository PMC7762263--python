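"""Partition-agreement metrics: NMI, ARI and Purity.

All three are computed from the contingency table between a predicted
partition Ω = {ω_1, …, ω_k} and a reference classification C = {c_1, …, c_j}
over the same N nodes:

* ``NMI = 2 I(X;Y) / (H(X) + H(Y))`` — mutual information with
  arithmetic-mean normalisation (the log base cancels in the ratio);
* ``ARI = (RI − E[RI]) / (max RI − E[RI])`` — the Hubert–Arabie
  pair-counting adjusted Rand index;
* ``Purity = (1/N) Σ_i max_j |ω_i ∩ c_j|`` — the fraction of nodes falling
  in their predicted community's plurality class.

NMI and ARI are symmetric in (prediction, reference); Purity is not
(an all-singletons prediction scores 1 against any reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import GroundTruth, Partition

__all__ = [
    "ContingencyTable",
    "MetricReport",
    "contingency_table",
    "nmi",
    "ari",
    "purity",
    "evaluate",
]

PartitionLike = Partition | GroundTruth


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap counts |ω_i ∩ c_j| between predicted and true groups."""

    counts: np.ndarray  # shape (k_pred, k_true)
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _check_same_nodes(p: PartitionLike, t: PartitionLike) -> None:
    if p.nodes != t.nodes:
        only_p = sorted(p.nodes - t.nodes)[:5]
        only_t = sorted(t.nodes - p.nodes)[:5]
        raise ValueError(
            "partitions cover different node sets "
            f"(e.g. only in prediction: {only_p}, only in reference: {only_t})"
        )


def contingency_table(p: PartitionLike, t: PartitionLike) -> ContingencyTable:
    _check_same_nodes(p, t)
    rows = sorted({str(c) for c in p.assignment.values()})
    cols = sorted({str(c) for c in t.assignment.values()})
    ri = {c: i for i, c in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for node, pc in p.assignment.items():
        counts[ri[str(pc)], ci[str(t.assignment[node])]] += 1
    return ContingencyTable(counts=counts, row_labels=tuple(rows), col_labels=tuple(cols))


def _entropy(sizes: np.ndarray, n: int) -> float:
    """Shannon entropy of group proportions, with the 0·log 0 = 0 convention."""
    probs = sizes[sizes > 0] / n
    return float(-(probs * np.log(probs)).sum())


def nmi(p: PartitionLike, t: PartitionLike) -> float:
    """Normalised mutual information, 2·I/(H(X)+H(Y)), in [0, 1].

    When both entropies vanish (each side is a single group over the same
    nodes) the partitions are identical and the score is 1.
    """
    ct = contingency_table(p, t)
    n = ct.n
    a = ct.counts.sum(axis=1)
    b = ct.counts.sum(axis=0)
    hx, hy = _entropy(a, n), _entropy(b, n)
    if hx + hy == 0.0:
        return 1.0
    nz = ct.counts > 0
    nij = ct.counts[nz].astype(float)
    outer = np.outer(a, b)[nz].astype(float)
    mi = float((nij / n * np.log(n * nij / outer)).sum())
    return 2.0 * mi / (hx + hy)


def ari(p: PartitionLike, t: PartitionLike) -> float:
    """Hubert–Arabie adjusted Rand index over all node pairs, in [-1, 1]."""
    ct = contingency_table(p, t)
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = comb2(ct.counts.astype(float)).sum()
    sum_a = comb2(ct.counts.sum(axis=1).astype(float)).sum()
    sum_b = comb2(ct.counts.sum(axis=0).astype(float)).sum()
    total = comb2(float(ct.n))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both sides all-singletons or both a single block: identical by construction
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def purity(p: PartitionLike, t: PartitionLike) -> float:
    """Fraction of nodes in their predicted group's plurality true class."""
    ct = contingency_table(p, t)
    return float(ct.counts.max(axis=1).sum() / ct.n)


@dataclass(frozen=True)
class MetricReport:
    nmi: float
    ari: float
    purity: float

    def to_tsv(self) -> str:
        return (
            f"nmi\t{self.nmi:.4f}\n"
            f"ari\t{self.ari:.4f}\n"
            f"purity\t{self.purity:.4f}\n"
        )


def evaluate(p: PartitionLike, t: PartitionLike) -> MetricReport:
    """All three agreement scores for a prediction against a reference."""
    return MetricReport(nmi=nmi(p, t), ari=ari(p, t), purity=purity(p, t))
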