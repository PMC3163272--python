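"""Isoform switching: transcripts of one gene with opposing laminar patterns.

A gene is called as switching when two conditions hold over its classifiable
transcripts:

1. *CI divergence* — some transcript pair has non-overlapping 95% CIs in a
   sample pair, in opposite directions (one transcript higher in sample *s*,
   the other higher in sample *s'*). Interval comparison is strict, so
   touching CIs do not qualify.
2. *Pattern divergence* — some transcript pair's calibrated layer-probability
   vectors (five layer dimensions, no-enrichment excluded) differ by
   Euclidean distance greater than 0.5.

The two conditions need not be met by the same pair; the same-pair reading is
computed and reported as well.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classifier import LayerPrediction
from .expression import LAYERS, QuantRecord


@dataclass
class SwitchCall:
    gene_id: str
    transcript_pair: tuple[str, str]  # maximally distant pair in probability space
    witness_samples: tuple[int, int] | None  # sample indices satisfying condition 1
    distance: float
    stage1: bool  # CI-divergent pair exists
    stage2: bool  # probability distance > threshold
    same_pair_both: bool  # one pair satisfies both conditions simultaneously

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def ci_divergent(t1: QuantRecord, t2: QuantRecord) -> tuple[int, int] | None:
    """First ordered sample pair (s, s') with t1 strictly higher in s and t2
    strictly higher in s', judged by non-overlapping CIs; None if no pair.

    The search is lexicographic over ordered sample-index pairs, so the first
    witness is deterministic.
    """
    if t1.gene_id != t2.gene_id:
        raise ValueError("transcripts must share a gene")
    n = t1.n_samples
    for s in range(n):
        for sp in range(n):
            if s == sp:
                continue
            if t1.ci_lo[s] > t1.ci_hi[sp] and t2.ci_lo[sp] > t2.ci_hi[s]:
                return (s, sp)
    return None


def probability_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two five-layer calibrated probability vectors."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability vectors differ in length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _layer_vector(pred: LayerPrediction) -> np.ndarray:
    return np.array([pred.cal_prob[l] for l in LAYERS])


def call_switching(
    gene_id: str,
    transcripts: Sequence[QuantRecord],
    predictions: Mapping[str, LayerPrediction],
    distance_threshold: float = 0.5,
) -> SwitchCall | None:
    """Evaluate both switching conditions over a gene's classifiable transcripts.

    Returns a :class:`SwitchCall` carrying the stage flags, or None when the
    gene has fewer than two transcripts with predictions. The reported distance
    and pair are the maximally distant transcript pair in calibrated
    layer-probability space.
    """
    txs = [t for t in transcripts if t.feature_id in predictions]
    if len(txs) < 2:
        return None

    # ci_divergent is symmetric up to witness orientation, so unordered pairs suffice
    witness = None
    witness_pair: tuple[int, int] | None = None
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            w = ci_divergent(txs[i], txs[j])
            if w is not None and witness is None:
                witness = w
                witness_pair = (i, j)

    best_dist = -1.0
    best_pair = (0, 1)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            d = probability_distance(
                _layer_vector(predictions[txs[i].feature_id]),
                _layer_vector(predictions[txs[j].feature_id]))
            if d > best_dist:
                best_dist = d
                best_pair = (i, j)

    stage1 = witness is not None
    stage2 = best_dist > distance_threshold
    same_pair = False
    if stage1 and witness_pair is not None:
        i_, j_ = witness_pair
        d_w = probability_distance(
            _layer_vector(predictions[txs[i_].feature_id]),
            _layer_vector(predictions[txs[j_].feature_id]))
        same_pair = d_w > distance_threshold

    return SwitchCall(
        gene_id=gene_id,
        transcript_pair=(txs[best_pair[0]].feature_id, txs[best_pair[1]].feature_id),
        witness_samples=witness,
        distance=best_dist,
        stage1=stage1,
        stage2=stage1 and stage2,
        same_pair_both=same_pair,
    )


def isoform_fraction_correlation(
    factor: QuantRecord,
    target_transcript: QuantRecord,
    target_gene: QuantRecord,
) -> tuple[float, float, float, float]:
    """Correlate a putative regulator's FPKM with a target isoform's usage.

    Returns ``(r_fraction, p_fraction, r_fpkm, p_fpkm)``: Pearson correlations
    of the factor's FPKM profile with the isoform fraction (transcript FPKM /
    gene FPKM) and with the transcript FPKM, each with a one-tailed p-value
    from the t-transform on n - 2 degrees of freedom (positive direction).
    """
    if np.any(target_gene.fpkm <= 0):
        raise ValueError("gene FPKM must be positive in every sample")
    frac = target_transcript.fpkm / target_gene.fpkm
    out = []
    for target in (frac, target_transcript.fpkm):
        x, yv = factor.fpkm, target
        if np.std(x) == 0 or np.std(yv) == 0:
            raise ValueError("zero-variance input: correlation undefined")
        r = float(np.corrcoef(x, yv)[0, 1])
        n = x.size
        t = r * math.sqrt((n - 2) / max(1e-300, 1 - r * r))
        p = float(stats.t.sf(t, df=n - 2))
        out += [r, p]
    return tuple(out)  # type: ignore[return-value]
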