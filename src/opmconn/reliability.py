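"""Test-retest reliability and neural-fingerprinting statistics.

Connectomes are vectorised using only elements above the leading diagonal.
Group-level reliability is the Pearson correlation between run-1 and run-2
group-average (normalised) connectomes, with a subsample analysis over all
subject subsets. Individual-level analysis builds the n x n matrix of
run-1 vs run-2 correlations: its diagonal holds within-subject values, the
off-diagonal between-subject values; the identifiability difference
(mean within - mean between) is tested against a Monte-Carlo null that
re-draws which n of the n^2 values count as "within", and fingerprinting
declares a subject identified when their within-subject correlation
strictly exceeds every between-subject value in their row (run-1 probe
against the run-2 gallery). Per-band p-values are Benjamini-Hochberg
corrected across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import Connectome

__all__ = [
    "upper_triangle",
    "group_average_connectome",
    "between_run_group_correlation",
    "subsample_consistency",
    "ComparisonMatrix",
    "comparison_matrix",
    "identifiability_difference",
    "permutation_test",
    "fingerprint_identify",
    "bh_correction",
    "ReliabilityAnalysis",
]


def upper_triangle(m: np.ndarray | Connectome) -> np.ndarray:
    """Row-major vector of strictly-above-diagonal elements (length P(P-1)/2)."""
    if isinstance(m, Connectome):
        m = m.values
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def group_average_connectome(connectomes: list[Connectome]) -> Connectome:
    """Element-wise mean of per-subject normalised connectomes.

    Requires every input to be normalised (so no single high-connectivity
    subject dominates); mixing normalised and raw matrices is an error.
    """
    if not connectomes:
        raise ValueError("empty connectome list")
    flags = {c.normalised for c in connectomes}
    if flags != {True}:
        raise ValueError("group averaging requires uniformly normalised connectomes")
    shapes = {c.values.shape for c in connectomes}
    if len(shapes) != 1:
        raise ValueError("connectomes must share one parcellation")
    mean = np.mean([c.values for c in connectomes], axis=0)
    ref = connectomes[0]
    return Connectome(
        values=mean, band=ref.band, subject="group", run=ref.run, normalised=True
    )


def between_run_group_correlation(run1_avg: Connectome, run2_avg: Connectome) -> float:
    """Pearson r between the two group averages' upper-triangle vectors."""
    v1 = upper_triangle(run1_avg)
    v2 = upper_triangle(run2_avg)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero-variance connectome vector: correlation undefined")
    return float(stats.pearsonr(v1, v2).statistic)


def subsample_consistency(
    run1: list[Connectome],
    run2: list[Connectome],
    sizes: list[int] | None = None,
    max_subsets: int = 100_000,
) -> dict[int, tuple[float, float]]:
    """Between-run group correlation over all subject subsets of each size.

    For each N, every C(n, N) subset (the same subjects in both runs) is
    averaged per run and correlated; returns {N: (mean r, sd r)}. Raises if
    the subset count exceeds ``max_subsets`` (enable random subsets
    explicitly for larger groups).
    """
    n = len(run1)
    if len(run2) != n:
        raise ValueError("need matched run lists")
    if n < 3:
        raise ValueError("subsample analysis needs at least 3 subjects")
    if sizes is None:
        sizes = list(range(2, n))
    out: dict[int, tuple[float, float]] = {}
    for N in sizes:
        if not (2 <= N <= n):
            raise ValueError(f"subset size {N} out of range")
        from math import comb

        if comb(n, N) > max_subsets:
            raise ValueError(
                f"C({n},{N}) exceeds max_subsets={max_subsets}; use a random-subset mode"
            )
        rs = []
        for subset in combinations(range(n), N):
            g1 = group_average_connectome([run1[s] for s in subset])
            g2 = group_average_connectome([run2[s] for s in subset])
            rs.append(between_run_group_correlation(g1, g2))
        rs = np.asarray(rs)
        out[N] = (float(rs.mean()), float(rs.std()))
    return out


@dataclass
class ComparisonMatrix:
    """n x n run-1 (rows) vs run-2 (columns) connectome correlations."""

    r: np.ndarray
    band: str = "unknown"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("comparison matrix must be square")

    @property
    def n_subjects(self) -> int:
        return self.r.shape[0]

    @property
    def within(self) -> np.ndarray:
        return np.diag(self.r)

    @property
    def between(self) -> np.ndarray:
        n = self.n_subjects
        return self.r[~np.eye(n, dtype=bool)]


def comparison_matrix(
    run1: list[Connectome], run2: list[Connectome], band: str = "unknown"
) -> ComparisonMatrix:
    """All n^2 run-1 vs run-2 upper-triangle Pearson correlations."""
    n = len(run1)
    if len(run2) != n or n < 2:
        raise ValueError("need matched run lists with at least 2 subjects")
    v1 = np.array([upper_triangle(c) for c in run1])
    v2 = np.array([upper_triangle(c) for c in run2])
    v1 = v1 - v1.mean(axis=1, keepdims=True)
    v2 = v2 - v2.mean(axis=1, keepdims=True)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-variance connectome vector: correlation undefined")
    r = (v1 @ v2.T) / np.outer(n1, n2)
    return ComparisonMatrix(r=r, band=band)


def identifiability_difference(cm: ComparisonMatrix) -> float:
    """Mean within-subject minus mean between-subject correlation."""
    return float(cm.within.mean() - cm.between.mean())


def permutation_test(
    cm: ComparisonMatrix,
    iters: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo p-value for the identifiability difference.

    Null: which n of the n^2 comparison values count as "within" is
    re-drawn uniformly without replacement; the observed difference is
    compared one-sidedly against the resampled differences. Returns
    (1 + #{delta* >= delta_obs}) / (1 + iters), never exactly zero.
    """
    if iters < 1000:
        raise ValueError("need at least 1000 iterations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = cm.r.ravel()
    n = cm.n_subjects
    total = vals.sum()
    n_all = vals.size
    n_between = n_all - n
    delta_obs = identifiability_difference(cm)

    # vectorised draws of n indices without replacement per iteration
    batch = max(1, min(iters, int(2e7 // n_all)))
    count = 0
    done = 0
    while done < iters:
        b = min(batch, iters - done)
        keys = rng.random((b, n_all))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        within_sum = vals[idx].sum(axis=1)
        delta = within_sum / n - (total - within_sum) / n_between
        count += int(np.sum(delta >= delta_obs))
        done += b
    return (1 + count) / (1 + iters)


def fingerprint_identify(cm: ComparisonMatrix) -> tuple[int, np.ndarray]:
    """Row-wise fingerprinting: hits and per-subject identification flags.

    Subject s is identified when their run-1 connectome correlates strictly
    higher with their own run-2 connectome than with any other subject's
    (ties count as unidentified).
    """
    r = cm.r
    n = cm.n_subjects
    flags = np.zeros(n, dtype=bool)
    for s in range(n):
        row = np.delete(r[s], s)
        flags[s] = r[s, s] > row.max()
    return int(flags.sum()), flags


def bh_correction(
    pvalues: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


@dataclass
class BandReliability:
    """Reliability summary for one band."""

    band: str
    group_r: float
    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float
    identifiability: float
    p_value: float
    fingerprint_hits: int
    fingerprint_flags: list[bool]
    p_adjusted: float = float("nan")
    significant: bool = False
    subsample_curve: dict[int, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["subsample_curve"] = {
            str(k): list(v) for k, v in self.subsample_curve.items()
        }
        return d


class ReliabilityAnalysis(BaseEstimator):
    """Estimator computing the full per-band reliability report.

    ``fit`` takes ``{band: (run1_connectomes, run2_connectomes)}`` with one
    normalised connectome per subject per run, and populates
    ``report_`` (band -> BandReliability), applying the Monte-Carlo
    identifiability test per band and BH correction across bands.
    """

    def __init__(
        self,
        permutation_iters: int = 100_000,
        alpha: float = 0.05,
        seed: int = 0,
        subsample: bool = True,
    ):
        self.permutation_iters = permutation_iters
        self.alpha = alpha
        self.seed = seed
        self.subsample = subsample

    def fit(self, connectomes_by_band: dict[str, tuple[list[Connectome], list[Connectome]]]):
        rng = np.random.default_rng(self.seed)
        report: dict[str, BandReliability] = {}
        self.comparison_matrices_: dict[str, ComparisonMatrix] = {}
        for band, (run1, run2) in connectomes_by_band.items():
            g1 = group_average_connectome(run1)
            g2 = group_average_connectome(run2)
            cm = comparison_matrix(run1, run2, band=band)
            self.comparison_matrices_[band] = cm
            p = permutation_test(cm, self.permutation_iters, rng)
            hits, flags = fingerprint_identify(cm)
            curve = (
                subsample_consistency(run1, run2)
                if self.subsample and len(run1) >= 3
                else {}
            )
            report[band] = BandReliability(
                band=band,
                group_r=between_run_group_correlation(g1, g2),
                within_mean=float(cm.within.mean()),
                within_sd=float(cm.within.std()),
                between_mean=float(cm.between.mean()),
                between_sd=float(cm.between.std()),
                identifiability=identifiability_difference(cm),
                p_value=p,
                fingerprint_hits=hits,
                fingerprint_flags=[bool(f) for f in flags],
                subsample_curve=curve,
            )
        bands = list(report)
        if bands:
            p_adj, rej = bh_correction(
                [report[b].p_value for b in bands], self.alpha
            )
            for b, pa, rj in zip(bands, p_adj, rej):
                report[b].p_adjusted = float(pa)
                report[b].significant = bool(rj)
        self.report_ = report
        return self
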