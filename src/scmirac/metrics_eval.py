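"""Cluster-agreement metrics: cluster consistent ratio (CCR) and adjusted Rand index.

CCR is the fraction of cell pairs co-clustered in a finer candidate
partition that are also co-clustered in a coarse reference partition; it
deliberately does not penalize splitting a reference cluster into
sub-clusters (any refinement of the reference scores 1.0).  ARI is the
chance-corrected Hubert-Arabie pair-counting index, computed through
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = ["AgreementReport", "ccr", "ari", "agreement_report"]


@dataclass
class AgreementReport:
    ccr: float
    ari: float
    n_pairs_evaluated: int


def _labels(x) -> np.ndarray:
    lab = getattr(x, "labels", x)
    return np.asarray(lab).ravel()


def ccr(reference, candidate, per_cluster: bool = False) -> float:
    """Cluster consistent ratio of ``candidate`` against ``reference``.

    Pools all within-cluster pairs of the candidate by default;
    ``per_cluster=True`` instead averages the per-cluster ratios.  A
    candidate with no within-cluster pair (all singletons) scores 1.0
    vacuously.
    """
    r, c = _labels(reference), _labels(candidate)
    if r.size != c.size:
        raise ValueError(f"partition lengths differ: {r.size} vs {c.size}")
    total_hits = 0
    total_pairs = 0
    ratios = []
    for g in np.unique(c):
        members = r[c == g]
        pairs = comb(len(members), 2)
        if pairs == 0:
            continue
        _, counts = np.unique(members, return_counts=True)
        hits = sum(comb(int(x), 2) for x in counts)
        total_hits += hits
        total_pairs += pairs
        ratios.append(hits / pairs)
    if total_pairs == 0:
        return 1.0
    if per_cluster:
        return float(np.mean(ratios))
    return total_hits / total_pairs


def ccr_n_pairs(reference, candidate) -> int:
    """Number of within-cluster candidate pairs entering the CCR."""
    c = _labels(candidate)
    _, counts = np.unique(c, return_counts=True)
    return sum(comb(int(x), 2) for x in counts)


def ari(a, b) -> float:
    """Adjusted Rand index (Hubert-Arabie), symmetric and label-invariant."""
    la, lb = _labels(a), _labels(b)
    if la.size != lb.size:
        raise ValueError(f"partition lengths differ: {la.size} vs {lb.size}")
    return float(adjusted_rand_score(la, lb))


def agreement_report(reference, candidate) -> AgreementReport:
    return AgreementReport(
        ccr=ccr(reference, candidate),
        ari=ari(reference, candidate),
        n_pairs_evaluated=ccr_n_pairs(reference, candidate),
    )
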