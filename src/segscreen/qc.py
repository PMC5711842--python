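"""Replicate reproducibility metrics.

Two experiments are compared on the treatments analyzable in both:
pointwise Pearson correlation of all paired (treatment, parameter) scores,
and the normalized Hamming distance (proportion of paired measurements that
differ at all, in [0, 1]).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .model import PhenotypicVector, ScreenTable

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    correlation_r: float
    correlation_p: float
    n_pairs: int
    hamming: float
    n_compared: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)


def paired_score_matrices(
    table: ScreenTable, exp_a: str, exp_b: str
) -> Tuple[np.ndarray, np.ndarray, list]:
    """Score matrices (treatments x parameters) for the (compound, concentration)
    treatments analyzable in both experiments, aligned row for row.

    Treatments analyzable in only one experiment (lethal or unscored in the
    other) are excluded from the comparison, not imputed.
    """
    by_exp: dict = {exp_a: {}, exp_b: {}}
    n_dropped = 0
    for r in table.records:
        if r.experiment not in by_exp:
            continue
        if r.analyzable:
            by_exp[r.experiment][(r.compound_id, r.concentration)] = r.vector
        else:
            n_dropped += 1
    common = sorted(set(by_exp[exp_a]) & set(by_exp[exp_b]))
    if n_dropped:
        logger.info(
            "replicate comparison %s vs %s: %d non-analyzable treatments ignored",
            exp_a, exp_b, n_dropped,
        )
    a = np.array([by_exp[exp_a][k].scores for k in common], dtype=int)
    b = np.array([by_exp[exp_b][k].scores for k in common], dtype=int)
    return a, b, common


def replicate_correlation(
    table: ScreenTable, exp_a: str, exp_b: str, method: str = "pearson"
) -> Tuple[float, float, int]:
    """Correlation over all paired (treatment, parameter) scores.

    Returns (r, two-sided p, n_pairs).  Pearson by default, as the comparison
    is a linear correlation of identical ordinal scales; Spearman available.
    """
    a, b, _ = paired_score_matrices(table, exp_a, exp_b)
    x, y = a.ravel().astype(float), b.ravel().astype(float)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 paired measurements, got {x.size}"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in one margin"
        )
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), int(x.size)


def hamming_distance(table: ScreenTable, exp_a: str, exp_b: str) -> float:
    """Proportion of paired (treatment, parameter) measurements that differ.

    Any difference counts as one mismatch regardless of magnitude; symmetric
    in its arguments; 0 for identical replicates, 1 for fully differing ones.
    """
    a, b, _ = paired_score_matrices(table, exp_a, exp_b)
    if a.size == 0:
        raise InsufficientDataError("no paired measurements to compare")
    return float(np.mean(a != b))


def vector_distance(v1: PhenotypicVector, v2: PhenotypicVector) -> float:
    """Correlation distance 1 - Pearson(r) between two vectors, in [0, 2]."""
    x = np.asarray(v1.scores, dtype=float)
    y = np.asarray(v2.scores, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError(
            "correlation distance undefined for a constant vector"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def qc_report(table: ScreenTable, exp_a: str, exp_b: str) -> QcReport:
    r, p, n_pairs = replicate_correlation(table, exp_a, exp_b)
    a, _, _ = paired_score_matrices(table, exp_a, exp_b)
    return QcReport(
        correlation_r=r,
        correlation_p=p,
        n_pairs=n_pairs,
        hamming=hamming_distance(table, exp_a, exp_b),
        n_compared=int(a.size),
    )
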