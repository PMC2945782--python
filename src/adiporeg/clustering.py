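"""Multi-contrast expression clustering for treatment-specific genes.

The experimental design has nine condition cells (day 3 untreated; days 6
and 11 each under control, CD2314, BIO and CD2314+BIO), three biological
replicates each.  A gene is called "CD2314-specific" at a time point when
it differs significantly, in the same direction, from *every* other
treatment arm at that time point.  Genes are then binned into five
clusters by when (day 6, day 11, or both) they respond to CD2314 and in
which direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

TIME_POINTS = ("d3", "d6", "d11")
TREATMENTS = ("control", "CD2314", "BIO", "CD2314+BIO")
#: time points at which treatment arms exist and contrasts are tested
TESTED_TIME_POINTS = ("d6", "d11")
#: the non-adipogenic arms each CD2314 sample group is compared with
COMPARATORS = ("control", "BIO", "CD2314+BIO")

__all__ = [
    "welch_t_test",
    "bh_fdr",
    "compute_contrasts",
    "assign_clusters",
    "qpcr_relative_expression",
    "CD2314ClusterAssigner",
]


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]):
    """Two-sided unequal-variance t-test between two replicate groups.

    Returns ``(t_statistic, p_value, direction)`` where *direction* is the
    sign of ``mean(group_a) - mean(group_b)``.  Degrees of freedom follow
    Welch-Satterthwaite.  When both groups have zero variance the test is
    degenerate: equal means give ``(0, 1, 0)``, unequal means are treated
    as maximally significant (``p -> 0``) with the observed direction so
    that constant, clearly shifted genes are not silently dropped.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicate values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite expression values")
    direction = int(np.sign(a.mean() - b.mean()))
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if direction == 0:
            return 0.0, 1.0, 0
        return float(np.inf * direction), 0.0, direction
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), direction


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level *q*.

    Rejects all hypotheses with p <= p(k*) where k* is the largest k such
    that p(k) <= k*q/m over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y by Newton iteration."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return y


def _fit_inv_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square variance prior.

    Given per-gene sample variances with ``df`` residual degrees of
    freedom, estimates (d0, s0^2) of the prior by matching the mean and
    variance of log sample variances (the moment method of the standard
    empirical-Bayes moderated-t construction).  Returns ``d0 = inf`` when
    the observed spread is no wider than the sampling noise, i.e. a
    common variance fits.
    """
    from scipy.special import digamma, polygamma

    s2 = np.clip(np.asarray(s2, dtype=float), 1e-300, None)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    n = e.size
    excess = ((e - ebar) ** 2).sum() / max(n - 1, 1)
    excess -= float(polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def _vectorized_moderated(a: np.ndarray, b: np.ndarray):
    """Row-wise moderated t between two genes x replicates blocks.

    Pools the two group variances per gene (n1+n2-2 df), shrinks them
    toward an empirical-Bayes prior fitted across genes, and tests with
    df = d0 + (n1 + n2 - 2).
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((a.var(axis=1, ddof=1) * (n1 - 1)) + (b.var(axis=1, ddof=1) * (n2 - 1))) / df
    d0, s0_2 = _fit_inv_chisq_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    direction = np.sign(diff).astype(int)
    return t, p, direction


def _design_frame(design: Mapping[str, tuple[str, str]] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        df = design.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df = df[["time_point", "treatment"]]
    else:
        df = pd.DataFrame.from_dict(
            dict(design), orient="index", columns=["time_point", "treatment"]
        )
    bad_tp = set(df["time_point"]) - set(TIME_POINTS)
    bad_tr = set(df["treatment"]) - set(TREATMENTS)
    if bad_tp or bad_tr:
        raise ValueError(f"unknown design labels: {bad_tp | bad_tr}")
    return df


def compute_contrasts(
    matrix: pd.DataFrame,
    design: Mapping[str, tuple[str, str]] | pd.DataFrame,
    q: float = 0.05,
    test: Literal["moderated", "welch"] = "moderated",
) -> pd.DataFrame:
    """Test CD2314 against every other arm at each tested time point.

    *matrix* is genes x samples on a log scale; *design* maps sample id to
    ``(time_point, treatment)``.  For each time point in {d6, d11} and each
    comparator arm a per-gene t-test is run and BH correction is applied
    per (time point, comparator) family across genes.

    With ``test="moderated"`` (default) the per-gene pooled variance is
    shrunk toward an empirical-Bayes prior fitted across all genes before
    testing, which stabilises the statistic at three replicates per arm;
    ``test="welch"`` uses the plain unequal-variance t-test.

    Returns a long-form frame with columns ``gene_id, time_point,
    comparator, t_statistic, p_value, direction, fdr_significant``.
    """
    if test not in ("moderated", "welch"):
        raise ValueError(f"unknown test flavour {test!r}")
    des = _design_frame(design)
    missing = set(des.index) - set(matrix.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
    if not np.all(np.isfinite(matrix.to_numpy(dtype=float))):
        raise ValueError("expression matrix contains non-finite values")

    out = []
    for tp in TESTED_TIME_POINTS:
        cd_samples = des.index[(des.time_point == tp) & (des.treatment == "CD2314")]
        if len(cd_samples) < 2:
            raise ValueError(f"need >=2 CD2314 replicates at {tp}")
        a = matrix[cd_samples].to_numpy(dtype=float)
        for comparator in COMPARATORS:
            cmp_samples = des.index[
                (des.time_point == tp) & (des.treatment == comparator)
            ]
            if len(cmp_samples) < 2:
                raise ValueError(f"need >=2 {comparator} replicates at {tp}")
            b = matrix[cmp_samples].to_numpy(dtype=float)
            if test == "moderated":
                t, p, direction = _vectorized_moderated(a, b)
            else:
                t, p, direction = _vectorized_welch(a, b)
            rej = bh_fdr(p, q=q)
            out.append(
                pd.DataFrame(
                    {
                        "gene_id": matrix.index,
                        "time_point": tp,
                        "comparator": comparator,
                        "t_statistic": t,
                        "p_value": p,
                        "direction": direction,
                        "fdr_significant": rej,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def _vectorized_welch(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch test for two genes x replicates blocks."""
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    direction = np.sign(a.mean(axis=1) - b.mean(axis=1)).astype(int)
    # scipy yields nan for zero-variance rows; apply the degenerate rule
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if np.any(degenerate):
        eq = degenerate & (direction == 0)
        ne = degenerate & (direction != 0)
        t = np.where(eq, 0.0, t)
        p = np.where(eq, 1.0, p)
        t = np.where(ne, np.inf * direction, t)
        p = np.where(ne, 0.0, p)
    return t, p, direction


def assign_clusters(
    contrasts: pd.DataFrame,
    cluster5_direction: Literal["same", "any"] = "same",
) -> pd.DataFrame:
    """Bin genes into the five CD2314-response clusters.

    A gene is CD2314-specific at a time point iff all three comparisons at
    that time point are FDR-significant with one common direction.  Labels:
    day-6-only up -> 1, down -> 2; day-11-only up -> 3, down -> 4;
    both days -> 5.  With ``cluster5_direction="same"`` (default) cluster 5
    requires the same direction at both days; genes significant at both
    days with opposite directions then keep the day-6 label.  With
    ``"any"`` any gene specific at both days goes to cluster 5.

    Returns a frame ``gene_id, cluster`` with cluster 0 meaning "none".
    """
    required = {"gene_id", "time_point", "comparator", "direction", "fdr_significant"}
    if not required <= set(contrasts.columns):
        raise ValueError(f"contrast table missing columns {required - set(contrasts.columns)}")

    # per (gene, time point): specific iff 3/3 significant, single direction
    status: dict[str, dict[str, int]] = {}
    for (gene, tp), grp in contrasts.groupby(["gene_id", "time_point"], sort=False):
        if set(grp["comparator"]) != set(COMPARATORS):
            raise ValueError(f"gene {gene} at {tp}: missing comparator results")
        sig = grp["fdr_significant"].to_numpy()
        dirs = grp["direction"].to_numpy()
        if sig.all() and len(set(dirs)) == 1 and dirs[0] != 0:
            status.setdefault(gene, {})[tp] = int(dirs[0])
        else:
            status.setdefault(gene, {})[tp] = 0

    rows = []
    for gene, by_tp in status.items():
        d6 = by_tp.get("d6", 0)
        d11 = by_tp.get("d11", 0)
        if d6 != 0 and d11 != 0:
            if cluster5_direction == "any" or d6 == d11:
                cluster = 5
            else:
                cluster = 1 if d6 > 0 else 2
        elif d6 > 0:
            cluster = 1
        elif d6 < 0:
            cluster = 2
        elif d11 > 0:
            cluster = 3
        elif d11 < 0:
            cluster = 4
        else:
            cluster = 0
        rows.append((gene, cluster))
    return pd.DataFrame(rows, columns=["gene_id", "cluster"])


def qpcr_relative_expression(
    ct_target: float, ct_refs: Iterable[float], n_refs: int = 3
) -> float:
    """Relative expression by the dCT method against reference genes.

    Normalises to the geometric mean of the reference-gene expression
    levels: since each level is 2**(-Ct), the geometric mean equals
    2**(-mean(Ct_refs)), so the result is ``2**-(ct_target - mean(ct_refs))``.
    """
    refs = np.asarray(list(ct_refs), dtype=float)
    if refs.size == 0:
        raise ValueError("empty reference Ct list")
    if refs.size != n_refs:
        raise ValueError(f"expected {n_refs} reference genes, got {refs.size}")
    if not (np.isfinite(ct_target) and np.all(np.isfinite(refs))):
        raise ValueError("non-finite Ct values")
    return float(2.0 ** -(ct_target - refs.mean()))


@dataclass
class _Unset:
    pass


class CD2314ClusterAssigner(BaseEstimator):
    """Estimator wrapper: fit the contrast tests and cluster assignment.

    Parameters
    ----------
    q : float
        BH false-discovery-rate level per contrast family (default 0.05).
    cluster5_direction : {"same", "any"}
        Whether cluster 5 requires the same response direction at both
        time points.
    test : {"moderated", "welch"}
        Per-gene statistic: empirical-Bayes variance-moderated t
        (default) or plain Welch t.

    Attributes (after ``fit``)
    --------------------------
    contrasts_ : DataFrame of per-gene, per-contrast test results.
    labels_ : pandas Series mapping gene_id -> cluster (0 = unassigned).
    """

    def __init__(
        self,
        q: float = 0.05,
        cluster5_direction: str = "same",
        test: str = "moderated",
    ):
        self.q = q
        self.cluster5_direction = cluster5_direction
        self.test = test

    def fit(self, X: pd.DataFrame, design: Mapping[str, tuple[str, str]] | pd.DataFrame):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        self.contrasts_ = compute_contrasts(X, design, q=self.q, test=self.test)
        assignment = assign_clusters(
            self.contrasts_, cluster5_direction=self.cluster5_direction
        )
        self.labels_ = assignment.set_index("gene_id")["cluster"]
        return self

    def cluster_genes(self, cluster: int) -> list[str]:
        """Gene ids assigned to one cluster, in input order."""
        return list(self.labels_.index[self.labels_ == cluster])
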