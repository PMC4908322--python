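"""Differential event usage between two sample groups.

Inclusion-junction counts are modelled per event with a negative-binomial
GLM (log link).  An offset of log(size factor) + log(total event evidence)
makes the group contrast target *relative* isoform usage rather than gene
expression.  Overdispersion is estimated per event by method of moments
within replicate groups, stabilised by shrinkage towards a mean-dispersion
trend fitted across events, and significance comes from a likelihood-ratio
test of the group coefficient against chi-square(1), followed by
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DispersionModel",
    "TestResult",
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_nb_glm",
    "lrt_pvalue",
    "bh_adjust",
    "test_counts",
    "test_events",
]

_POISSON_ALPHA = 1e-8  # below this the NB family degenerates to Poisson


@dataclass(slots=True)
class CountMatrix:
    """Event-by-sample count matrix with group labels and size factors."""

    counts: np.ndarray            # shape (n_features, n_samples), integers
    feature_ids: List[str]
    groups: np.ndarray            # 0/1 per sample
    size_factors: Optional[np.ndarray] = None
    offsets: Optional[np.ndarray] = None   # extra per-cell log offsets

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.groups = np.asarray(self.groups)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for g in (0, 1):
            if np.sum(self.groups == g) < 2:
                raise ValueError("need >= 2 samples per group for dispersion "
                                 "estimation")


@dataclass(slots=True)
class DispersionModel:
    """Raw, trend and shrunk NB dispersions per feature."""

    raw: np.ndarray
    trend: np.ndarray
    shrunk: np.ndarray
    weight: float
    trend_fn: Callable[[np.ndarray], np.ndarray] | None = None


@dataclass(slots=True)
class TestResult:
    event_id: str
    lrt_statistic: float
    p_value: float
    q_value: float
    mean_psi_a: Optional[float]
    mean_psi_b: Optional[float]
    tested: bool = True
    event_type: str = ""
    gene_id: str = ""
    strand: str = "+"

    @property
    def delta_psi(self) -> Optional[float]:
        if self.mean_psi_a is None or self.mean_psi_b is None:
            return None
        return self.mean_psi_b - self.mean_psi_a


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors (geometric-mean reference)."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.all(np.isfinite(logc), axis=1)
    if not np.any(usable):
        raise ValueError("no feature with nonzero counts in every sample; "
                         "provide more or deeper samples")
    ref = np.exp(logc[usable].mean(axis=1, keepdims=True))
    factors = np.median(counts[usable] / ref, axis=0)
    return factors


def _group_mom_alpha(counts: np.ndarray, mu: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments dispersion from one replicate group.

    Uses per-sample fitted means ``mu`` (which absorb offsets):
    E[(c - mu)^2] = (1 - 1/n)(mu + alpha mu^2), so the squared residuals get
    a Bessel-style n/(n-1) correction before the shot-noise term mu is
    subtracted.  Returns (numerator, denominator) contributions so groups
    can be pooled.
    """
    n = len(counts)
    if n < 2:
        return 0.0, 0.0
    num = float(((counts - mu) ** 2).sum() * n / (n - 1) - mu.sum())
    den = float((mu ** 2).sum())
    return num, den


def estimate_dispersions(matrix: CountMatrix,
                         weight: Optional[float] = None) -> DispersionModel:
    """Per-feature MoM dispersions with a fitted trend and shrinkage.

    Raw dispersions pool moment equations over the two replicate groups on
    offset-normalised fitted means.  The trend alpha(mu) = a0 + a1/mu is fit
    by least squares over features with positive mean.  The dispersion used
    for testing is the *maximum* of the fitted trend and the per-feature
    estimate: with few replicates the raw estimate is far too noisy to trust
    when it falls below the trend, while an excess above the trend is real
    signal worth keeping — the conservative rule that keeps the chi-square
    LRT honest at small replicate numbers.  ``weight`` (default
    1/(min replicates per group - 1), capped at 1) is retained as metadata
    describing how much per-feature information the design carries.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    n_feat, n_samp = counts.shape
    sf = (matrix.size_factors if matrix.size_factors is not None
          else np.ones(n_samp))
    log_off = np.log(sf)[None, :] + (
        matrix.offsets if matrix.offsets is not None else 0.0)
    # per-cell effective exposure, broadcast to the full matrix shape
    eff = np.broadcast_to(np.exp(log_off), counts.shape)
    raw = np.zeros(n_feat)
    base_mean = np.zeros(n_feat)
    for i in range(n_feat):
        num = den = 0.0
        for g in (0, 1):
            sel = matrix.groups == g
            c, e = counts[i, sel], eff[i, sel]
            rate = c.sum() / e.sum() if e.sum() > 0 else 0.0
            mu = rate * e
            n_, d_ = _group_mom_alpha(c, mu)
            num += n_
            den += d_
        raw[i] = max(0.0, num / den) if den > 0 else 0.0
        base_mean[i] = counts[i].mean()
    ok = base_mean > 0
    if ok.sum() >= 3 and np.ptp(base_mean[ok]) > 0:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = float(np.median(raw[ok]))
        trend_fn = lambda m: a0 + a1 / np.maximum(m, 1e-8)
    else:
        med = float(np.median(raw[ok])) if ok.any() else 0.0
        trend_fn = lambda m: np.full_like(np.asarray(m, dtype=float), med)
    trend = np.asarray(trend_fn(np.maximum(base_mean, 1e-8)), dtype=float)
    if weight is None:
        min_rep = min(int(np.sum(matrix.groups == g)) for g in (0, 1))
        weight = 1.0 if min_rep <= 2 else 1.0 / (min_rep - 1)
    shrunk = np.maximum(trend, raw)
    return DispersionModel(raw, trend, shrunk, weight, trend_fn)


def fit_nb_glm(counts: np.ndarray, design: np.ndarray, offset: np.ndarray,
               alpha: float, maxiter: int = 100):
    """Fit an NB (or, for alpha ~ 0, Poisson) log-link GLM.

    Returns the statsmodels results object; raises on non-convergence so the
    caller can flag the feature untested.
    """
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if alpha < _POISSON_ALPHA:
        family = sm.families.Poisson()
    else:
        family = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(counts, design, family=family, offset=offset)
        res = model.fit(maxiter=maxiter, tol=1e-8)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("GLM fit did not converge")
    return res


def lrt_pvalue(full_deviance: float, reduced_deviance: float,
               df: int = 1, tol: float = 1e-6) -> Tuple[float, float]:
    """Likelihood-ratio p-value from nested-model deviances.

    Returns (statistic, p).  A slightly negative statistic within ``tol`` is
    clamped to zero; a larger one indicates a numerical fitting failure.
    """
    stat = reduced_deviance - full_deviance
    if stat < -tol:
        raise ValueError(f"reduced deviance below full deviance by {-stat:g}")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, max(p, np.finfo(float).tiny)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_counts(matrix: CountMatrix,
                dispersion: Optional[DispersionModel] = None
                ) -> Tuple[List[dict], DispersionModel]:
    """Per-feature NB-GLM LRT of the group effect on a count matrix.

    Returns one record per feature with statistic and raw p-value (q-values
    are attached by :func:`test_events` / the caller after any filtering).
    """
    counts = np.asarray(matrix.counts, dtype=float)
    n_feat, n_samp = counts.shape
    sf = (matrix.size_factors if matrix.size_factors is not None
          else np.ones(n_samp))
    if dispersion is None:
        dispersion = estimate_dispersions(matrix)
    design_full = np.column_stack([np.ones(n_samp), matrix.groups])
    design_red = np.ones((n_samp, 1))
    records = []
    for i in range(n_feat):
        offset = np.log(sf)
        if matrix.offsets is not None:
            offset = offset + matrix.offsets[i]
        rec = {"feature_id": matrix.feature_ids[i], "tested": True,
               "lrt_statistic": 0.0, "p_value": 1.0}
        try:
            full = fit_nb_glm(counts[i], design_full, offset,
                              dispersion.shrunk[i])
            red = fit_nb_glm(counts[i], design_red, offset,
                             dispersion.shrunk[i])
            stat, p = lrt_pvalue(full.deviance, red.deviance)
            rec["lrt_statistic"], rec["p_value"] = stat, p
        except (RuntimeError, ValueError) as exc:
            log.warning("feature %s not tested: %s", matrix.feature_ids[i], exc)
            rec["tested"] = False
        records.append(rec)
    return records, dispersion


def test_events(quantifications: Sequence["EventQuantification"],
                groups: Sequence[int], alpha: float = 0.05,
                min_total_count: float = 10.0) -> List[TestResult]:
    """Differential usage test over quantified events.

    For each event the per-sample inclusion evidence (mean of the inclusion
    diagnostic counts, rounded) is regressed on the group label with an
    offset log(size factor) + log(max(1, inclusion + exclusion mean)), then
    LRT p-values are BH-adjusted across all tested events.  Events whose
    total diagnostic count stays below ``min_total_count`` in either group,
    or whose PSI is undefined throughout a group, are excluded up front.
    """
    groups = np.asarray(groups)
    inc_rows, tot_rows, kept, skipped = [], [], [], []
    for q in quantifications:
        inc = np.array([np.mean(c) for c in q.inclusion_counts])
        exc = np.array([np.mean(c) for c in q.exclusion_counts])
        tot = inc + exc
        ok = True
        for g in (0, 1):
            sel = groups == g
            if tot[sel].sum() < min_total_count:
                ok = False
            if all(q.psi[i] is None for i in np.flatnonzero(sel)):
                ok = False
        if ok:
            inc_rows.append(np.round(inc).astype(int))
            tot_rows.append(tot)
            kept.append(q)
        else:
            skipped.append(q)
            log.info("event %s excluded from testing (insufficient evidence)",
                     q.event.event_id)
    results: List[TestResult] = []
    if kept:
        inc_mat = np.vstack(inc_rows)
        tot_mat = np.vstack(tot_rows)
        try:
            sf = estimate_size_factors(tot_mat)
        except ValueError:
            sf = np.ones(inc_mat.shape[1])
        offsets = np.log(np.maximum(tot_mat, 1.0))
        matrix = CountMatrix(inc_mat,
                             [q.event.event_id for q in kept],
                             groups, size_factors=sf, offsets=offsets)
        records, _ = test_counts(matrix)
        tested_idx = [i for i, r in enumerate(records) if r["tested"]]
        qvals = bh_adjust([records[i]["p_value"] for i in tested_idx])
        qmap = dict(zip(tested_idx, qvals))
        for i, (q, rec) in enumerate(zip(kept, records)):
            sel_a = np.flatnonzero(groups == 0)
            sel_b = np.flatnonzero(groups == 1)
            results.append(TestResult(
                event_id=q.event.event_id,
                lrt_statistic=rec["lrt_statistic"],
                p_value=rec["p_value"],
                q_value=float(qmap.get(i, 1.0)),
                mean_psi_a=q.mean_psi(sel_a),
                mean_psi_b=q.mean_psi(sel_b),
                tested=rec["tested"],
                event_type=q.event.event_type,
                gene_id=q.event.gene_id,
                strand=q.event.strand,
            ))
    for q in skipped:
        sel_a = np.flatnonzero(groups == 0)
        sel_b = np.flatnonzero(groups == 1)
        results.append(TestResult(
            event_id=q.event.event_id, lrt_statistic=0.0, p_value=1.0,
            q_value=1.0, mean_psi_a=q.mean_psi(sel_a),
            mean_psi_b=q.mean_psi(sel_b), tested=False,
            event_type=q.event.event_type, gene_id=q.event.gene_id,
            strand=q.event.strand))
    results.sort(key=lambda r: (not r.tested, r.p_value, r.event_id))
    return results
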