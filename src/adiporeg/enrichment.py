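"""Score-threshold-optimised hypergeometric motif enrichment.

For each motif and conservation mode, every observed promoter score is a
candidate threshold; the proportion of cluster promoters scoring at or
above the threshold is compared with the proportion among all other
promoters with a one-sided hypergeometric test.  The threshold is chosen
to maximise the fold-change in those proportions among candidates whose
Bonferroni-corrected p-value is below alpha, and results with fold-change
below 1.8 are discarded.  Per motif, the conservation mode giving the
strongest over-representation (lowest raw p, ties broken by higher fold)
is reported.

The statistic depends only on score ranks, so any monotone rescaling of
the scores leaves the result unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

__all__ = [
    "hypergeom_upper_tail",
    "optimize_threshold",
    "enrich_clusters",
    "EnrichmentRecord",
    "MotifEnrichment",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentRecord:
    """One motif's optimised enrichment in one cluster."""

    motif_id: str
    tf_family: str
    mode: float | str | None  # conservation level, or "none"
    threshold: float
    k: int  # cluster promoters scoring >= threshold
    n: int  # cluster size
    K: int  # universe promoters scoring >= threshold
    N: int  # universe size
    fold: float
    p_raw: float
    p_bonferroni: float


def _fold_change(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / ((K-k)/(N-n)): cluster rate vs rate among all other promoters."""
    inside = k / n
    rest = K - k
    if N == n:
        return np.nan
    if rest == 0:
        return np.inf if inside > 0 else np.nan
    return inside / (rest / (N - n))


def optimize_threshold(
    cluster_scores: Sequence[float],
    background_scores: Sequence[float],
    alpha: float = 0.01,
    correction_factor: int = 1,
    min_fold: float = 1.8,
) -> EnrichmentRecord | None:
    """Pick the score threshold maximising fold-change under the p filter.

    Candidate thresholds are all distinct observed scores ("scoring over"
    means score >= threshold, so the sweep over observed values is
    exhaustive).  Among candidates whose Bonferroni-corrected p is below
    alpha, the fold-maximising one wins (ties -> larger threshold); if the
    winner's fold is below ``min_fold`` nothing is returned.

    ``background_scores`` are the scores of all promoters *outside* the
    cluster; promoters ineligible under the conservation mode should be
    passed as NaN so they never reach any threshold.
    """
    cl = np.asarray(cluster_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if cl.size == 0 or bg.size == 0:
        raise ValueError("empty cluster or background score set")
    if correction_factor < 1:
        raise ValueError("correction_factor must be >= 1")
    n, N = cl.size, cl.size + bg.size
    candidates = np.unique(np.concatenate([cl[~np.isnan(cl)], bg[~np.isnan(bg)]]))
    best: EnrichmentRecord | None = None
    for t in candidates:
        k = int(np.sum(cl >= t))
        K = k + int(np.sum(bg >= t))
        p_raw = hypergeom_upper_tail(k, K, n, N)
        p_bonf = min(1.0, p_raw * correction_factor)
        if p_bonf >= alpha:
            continue
        fold = _fold_change(k, n, K, N)
        if np.isnan(fold):
            continue
        if (
            best is None
            or fold > best.fold
            or (fold == best.fold and t > best.threshold)
        ):
            best = EnrichmentRecord(
                motif_id="", tf_family="", mode=None, threshold=float(t),
                k=k, n=n, K=K, N=N, fold=float(fold),
                p_raw=p_raw, p_bonferroni=p_bonf,
            )
    if best is None or best.fold < min_fold:
        return None
    return best


def enrich_clusters(
    scores: pd.DataFrame,
    cluster_genes: Iterable[str],
    universe_genes: Iterable[str] | None = None,
    alpha: float = 0.01,
    min_fold: float = 1.8,
    correction_factor: int | None = None,
    tf_families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Run threshold optimisation per motif x mode; keep each motif's best mode.

    ``scores`` is the long-form table from :func:`~adiporeg.motifs.scan_promoters`
    (promoter_id, motif_id, mode, score, eligible).  The default Bonferroni
    correction factor is (number of motifs) x (number of modes).  Returns
    one row per motif that passes both the corrected-p and fold filters,
    sorted by raw p.
    """
    cluster = set(cluster_genes)
    motif_ids = scores["motif_id"].unique()
    modes = scores["mode"].unique()
    if universe_genes is None:
        universe = set(scores["promoter_id"].unique())
    else:
        universe = set(universe_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes not contained in the score universe")
    if correction_factor is None:
        correction_factor = len(motif_ids) * len(modes)
    tf_families = tf_families or {}

    rows = []
    for motif_id, motif_scores in scores.groupby("motif_id", sort=False):
        best: EnrichmentRecord | None = None
        for mode, mode_scores in motif_scores.groupby("mode", sort=False):
            sub = mode_scores[mode_scores["promoter_id"].isin(universe)]
            in_cluster = sub["promoter_id"].isin(cluster)
            # ineligible promoters count as non-scoring at every threshold
            vals = sub["score"].where(sub["eligible"], np.nan)
            rec = optimize_threshold(
                vals[in_cluster], vals[~in_cluster],
                alpha=alpha, correction_factor=correction_factor,
                min_fold=min_fold,
            )
            if rec is None:
                continue
            rec.motif_id = str(motif_id)
            rec.mode = mode
            rec.tf_family = tf_families.get(str(motif_id), "")
            if (
                best is None
                or rec.p_raw < best.p_raw
                or (rec.p_raw == best.p_raw and rec.fold > best.fold)
            ):
                best = rec
        if best is not None:
            rows.append(best)
    rows.sort(key=lambda r: (r.p_raw, -r.fold, r.motif_id))
    return pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "tf_family": r.tf_family,
                "conservation_level": r.mode,
                "n_cluster_promoters_with_motif": r.k,
                "cluster_size": r.n,
                "n_universe_promoters_with_motif": r.K,
                "universe_size": r.N,
                "fold_enrichment": r.fold,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "threshold": r.threshold,
            }
            for r in rows
        ],
        columns=[
            "motif_id", "tf_family", "conservation_level",
            "n_cluster_promoters_with_motif", "cluster_size",
            "n_universe_promoters_with_motif", "universe_size",
            "fold_enrichment", "p_raw", "p_bonferroni", "threshold",
        ],
    )


class MotifEnrichment(BaseEstimator):
    """Estimator wrapper around :func:`enrich_clusters`.

    Parameters mirror the pipeline defaults: alpha 0.01 on the
    Bonferroni-corrected hypergeometric p, minimum fold-change 1.8.

    Attributes (after ``fit``)
    --------------------------
    records_ : DataFrame of enriched motifs (one row per passing motif).
    correction_factor_ : the Bonferroni factor actually applied.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_fold: float = 1.8,
        correction_factor: int | None = None,
    ):
        self.alpha = alpha
        self.min_fold = min_fold
        self.correction_factor = correction_factor

    def fit(self, scores: pd.DataFrame, cluster_genes: Iterable[str]):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_fold < 0:
            raise ValueError("min_fold must be non-negative")
        cf = self.correction_factor
        if cf is None:
            cf = scores["motif_id"].nunique() * scores["mode"].nunique()
        self.correction_factor_ = cf
        self.records_ = enrich_clusters(
            scores, cluster_genes,
            alpha=self.alpha, min_fold=self.min_fold, correction_factor=cf,
        )
        return self
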