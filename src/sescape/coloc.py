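"""Pairwise factor co-localization enrichment and chromatin-state enrichment.

Enrichment is computed at single-base resolution against a binomial
background: two factor binding sets with coverages cov(a) and cov(b) on a
genome of L bases are expected to share cov(a) * cov(b) / L bases under
independent placement; the score is observed/expected and the tail
probability treats the smaller coverage as the number of binomial trials,
each succeeding with probability max-coverage / L.  Factors are then
clustered hierarchically on the correlation structure of their
log-enrichment profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import IntervalSet, overlap_bp
from .io import SegmentationRecord


@dataclass(frozen=True)
class EnrichmentResult:
    factor_a: str
    factor_b: str
    observed_bp: int
    expected_bp: float
    score: float
    p_value: float


def pairwise_enrichment(
    a: IntervalSet,
    b: IntervalSet,
    genome_bp: int,
    name_a: str = "a",
    name_b: str = "b",
) -> EnrichmentResult:
    """Observed/expected base-pair overlap enrichment under a binomial null.

    expected = cov(a) * cov(b) / L; p = P(X >= observed) for
    X ~ Binomial(n = min coverage, p = max coverage / L).
    """
    cov_a = a.total_covered_bp
    cov_b = b.total_covered_bp
    if cov_a == 0 or cov_b == 0:
        raise ValueError(
            f"enrichment undefined for empty set ({name_a if cov_a == 0 else name_b})"
        )
    if cov_a > genome_bp or cov_b > genome_bp:
        raise ValueError("coverage exceeds genome length")
    observed = overlap_bp(a, b)
    expected = cov_a * cov_b / genome_bp
    n = min(cov_a, cov_b)
    p_success = max(cov_a, cov_b) / genome_bp
    p_value = float(stats.binom.sf(observed - 1, n, p_success))
    return EnrichmentResult(name_a, name_b, observed, expected, observed / expected, p_value)


@dataclass
class EnrichmentMatrix:
    """All pairwise enrichments plus a factor dendrogram.

    The diagonal holds the self-enrichment L/cov(f); it is flagged and
    masked out of the clustering distance, never clustered on.
    """

    factors: list[str]
    scores: pd.DataFrame
    p_values: pd.DataFrame
    linkage: np.ndarray
    order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels from cutting the dendrogram into k groups."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.factors, (int(x) for x in labels)))


def enrichment_matrix(
    factor_sets: Mapping[str, IntervalSet], genome_bp: int
) -> EnrichmentMatrix:
    """Pairwise enrichment scores for every factor pair, hierarchically
    clustered with average linkage on correlation distance between rows of
    the log2(score + 1) matrix (diagonal masked).

    Factor order is sorted by name for a deterministic tie-break.
    """
    factors = sorted(factor_sets)
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    for f in factors:
        if factor_sets[f].total_covered_bp == 0:
            raise ValueError(f"factor {f!r} has an empty binding set")
    n = len(factors)
    scores = np.zeros((n, n))
    pvals = np.ones((n, n))
    for i, fa in enumerate(factors):
        for j, fb in enumerate(factors):
            if j < i:
                continue
            if i == j:
                scores[i, i] = genome_bp / factor_sets[fa].total_covered_bp
                pvals[i, i] = 0.0
                continue
            res = pairwise_enrichment(
                factor_sets[fa], factor_sets[fb], genome_bp, fa, fb
            )
            scores[i, j] = scores[j, i] = res.score
            pvals[i, j] = pvals[j, i] = res.p_value
    log_scores = np.log2(scores + 1.0)
    dist = _masked_correlation_distance(log_scores)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [factors[i] for i in hierarchy.leaves_list(linkage)]
    idx = pd.Index(factors, name="factor")
    return EnrichmentMatrix(
        factors=factors,
        scores=pd.DataFrame(scores, index=idx, columns=factors),
        p_values=pd.DataFrame(pvals, index=idx, columns=factors),
        linkage=linkage,
        order=order,
    )


def _masked_correlation_distance(log_scores: np.ndarray) -> np.ndarray:
    """1 - Pearson r between matrix rows with the self-enrichment diagonal
    masked out: each row's own-column entry is replaced by the mutual pair
    score, so two factors that co-enrich strongly stay close even when the
    rest of their profiles is flat (two-member blocks)."""
    n = log_scores.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi = log_scores[i].copy()
            xj = log_scores[j].copy()
            xi[i] = xj[j] = log_scores[i, j]
            if np.std(xi) == 0.0 or np.std(xj) == 0.0:
                d = 1.0
            else:
                d = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass(frozen=True)
class StateEnrichment:
    state: str
    state_bp: int
    overlap_bp: int
    expected_bp: float
    score: float | None  # None for zero-coverage states


def state_enrichment(
    peaks: IntervalSet,
    segmentation: Sequence[SegmentationRecord],
    genome_bp: int,
    states: Sequence[str] | None = None,
) -> list[StateEnrichment]:
    """Observed/expected overlap of a peak set with each chromatin state.

    score(s) = overlap(peaks, s) / (cov(s) * cov(peaks) / L).  States with
    zero coverage are reported with an undefined (None) score.
    """
    cov_peaks = peaks.total_covered_bp
    if cov_peaks == 0:
        raise ValueError("empty peak set")
    labels = list(states) if states is not None else sorted(
        {seg.state_label for seg in segmentation}
    )
    by_state: dict[str, list] = {lab: [] for lab in labels}
    for seg in segmentation:
        if seg.state_label not in by_state:
            raise ValueError(f"segment with undeclared state {seg.state_label!r}")
        by_state[seg.state_label].append((seg.chrom, seg.start, seg.end))
    out = []
    for lab in labels:
        state_set = IntervalSet(by_state[lab])
        cov_s = state_set.total_covered_bp
        if cov_s == 0:
            out.append(StateEnrichment(lab, 0, 0, 0.0, None))
            continue
        obs = overlap_bp(peaks, state_set)
        expected = cov_s * cov_peaks / genome_bp
        out.append(StateEnrichment(lab, cov_s, obs, expected, obs / expected))
    return out
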