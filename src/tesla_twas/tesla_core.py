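"""Gene-level trans-ancestry TWAS statistics and p-value combinations.

Given eQTL weights w and the projected effects b^ (with standard deviations s^
and covariance Sigma_b) from the ancestry meta-regression, the model-order-L
TWAS statistic is

    U^[L] = sum_j w_j b^_j^[L] / s^_j^[L],
    V^[L] = w' D^-1 Sigma_b^[L] D^-1 w,      D = diag(s^),
    T^[L] = U^[L] / sqrt(V^[L]),  p^[L] = 2 Phi(-|T^[L]|).

The four statistics (L = 0..3 by default) are combined by a minimal-P
approach: P* = min_L p^[L] is calibrated against the joint multivariate-normal
distribution of the T statistics, whose correlation matrix follows from the
cross-model covariance of the projected effects.  Tissue-level p-values are
combined with the Cauchy combination test.  Fixed-effects, DerSimonian–Laird
random-effects, and ancestry-subset TWAS comparators are provided; the L = 0
model is mathematically identical to FE-TWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import chi2, qmc

from .meta_regression import AncestryProjection, ancestry_projection, effect_covariance

__all__ = [
    "TwasStat",
    "TeslaResult",
    "MultiTissueResult",
    "twas_statistic",
    "model_correlation",
    "minp_pvalue",
    "mvn_rectangle",
    "nearest_correlation",
    "cauchy_combine",
    "combine_tissues",
    "analyze_gene",
    "fe_twas",
    "re_twas",
    "subset_twas",
    "dersimonian_laird",
    "genomic_control_lambda",
    "noncentrality",
]

_MINP_SEED = 987654321  # fixed quasi-random seed: P* must be reproducible
_MINP_POINTS = 2**13


@dataclass(frozen=True)
class TwasStat:
    """One gene-level linear-combination statistic."""

    U: float
    V: float
    T: float
    p: float
    testable: bool = True

    @classmethod
    def untestable(cls) -> "TwasStat":
        return cls(np.nan, np.nan, np.nan, np.nan, testable=False)


@dataclass
class TeslaResult:
    """Per-gene, per-tissue TWAS result across model orders."""

    gene_id: str
    tissue: str
    orders: tuple[int, ...]
    stats: dict[int, TwasStat]
    R_T: np.ndarray
    p_star: float
    n_variants_used: int
    model_downgrades: dict[int, dict[int, int]] = field(default_factory=dict)
    p_fe: float = np.nan
    p_re: float = np.nan
    p_subset: float = np.nan

    @property
    def pvalues(self) -> dict[int, float]:
        return {L: st.p for L, st in self.stats.items()}


@dataclass
class MultiTissueResult:
    gene_id: str
    tissue_pvalues: dict[str, float]
    weights: dict[str, float]
    p_combined: float


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def _std_weights(w: np.ndarray, b_hat: np.ndarray, s_hat: np.ndarray) -> np.ndarray:
    """w_j / s^_j with zeros for variants lacking a finite projected effect."""
    w = np.asarray(w, dtype=float)
    valid = np.isfinite(b_hat) & np.isfinite(s_hat) & (s_hat > 0)
    a = np.zeros_like(w)
    a[valid] = w[valid] / s_hat[valid]
    return a


def twas_statistic(
    w: np.ndarray, b_hat: np.ndarray, s_hat: np.ndarray, sigma_b: np.ndarray
) -> TwasStat:
    """Weighted linear-combination TWAS statistic from projected effects.

    Variants without a finite projected effect contribute nothing (their
    weight is zeroed); a gene whose effective weights all vanish, or whose
    variance degenerates to zero (e.g. perfectly anticorrelated cancellation),
    is flagged untestable rather than given a spurious p-value.
    """
    a = _std_weights(w, b_hat, s_hat)
    if not np.any(a != 0):
        return TwasStat.untestable()
    # U = sum_j a_j b^_j  (a already zero where b^ is missing)
    u = float(a @ np.nan_to_num(b_hat, nan=0.0))
    v = float(a @ sigma_b @ a)
    scale = float(np.max(np.abs(a))) ** 2 * float(np.max(np.abs(np.diag(sigma_b))) + 1.0)
    if v <= 1e-12 * max(scale, 1e-300):
        return TwasStat.untestable()
    t = u / np.sqrt(v)
    p = float(2.0 * ndtr(-abs(t)))
    return TwasStat(U=u, V=v, T=t, p=max(p, 5e-324))


def model_correlation(
    w: np.ndarray,
    projections: Mapping[int, AncestryProjection],
    cross_cov: Mapping[tuple[int, int], np.ndarray],
    stats: Mapping[int, TwasStat],
    orders: Sequence[int],
) -> np.ndarray:
    """Correlation matrix of the T statistics across model orders.

    Corr(T^[L], T^[L']) = a_L' Cov(b^[L], b^[L']) a_L' / sqrt(V^[L] V^[L']),
    with a_L = w / s^[L].
    """
    m = len(orders)
    R = np.eye(m)
    a = {
        L: _std_weights(w, projections[L].b_hat, projections[L].s_hat)
        for L in orders
    }
    for i, L1 in enumerate(orders):
        for jj in range(i + 1, m):
            L2 = orders[jj]
            C = cross_cov[(L1, L2)] if (L1, L2) in cross_cov else cross_cov[(L2, L1)].T
            num = float(a[L1] @ C @ a[L2])
            den = np.sqrt(stats[L1].V * stats[L2].V)
            r = num / den if den > 0 else 0.0
            R[i, jj] = R[jj, i] = float(np.clip(r, -1.0, 1.0))
    return R


# ---------------------------------------------------------------------------
# multivariate-normal rectangle (Genz separation-of-variables, fixed QMC seed)
# ---------------------------------------------------------------------------

def nearest_correlation(R: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Repair a near-correlation matrix: clip eigenvalues, renormalize the diagonal."""
    R = (np.asarray(R, dtype=float) + np.asarray(R, dtype=float).T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eig_floor:
        return R
    vals = np.clip(vals, eig_floor, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def mvn_rectangle(
    lower: np.ndarray,
    upper: np.ndarray,
    corr: np.ndarray,
    n_points: int = _MINP_POINTS,
    seed: int = _MINP_SEED,
) -> float:
    """Pr(lower < Z < upper) for Z ~ N(0, corr), by Genz's transform with scrambled Sobol.

    Deterministic for fixed ``seed``; absolute accuracy is typically well below
    1e-5 at the default 8,192 points for the small dimensions used here.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = len(lower)
    if d == 1:
        return float(ndtr(upper[0]) - ndtr(lower[0]))
    corr = np.asarray(corr, dtype=float)
    jitter = 0.0
    for _ in range(6):
        try:
            C = np.linalg.cholesky(corr + jitter * np.eye(d))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
    else:  # pragma: no cover - eigenvalue repair always yields a factorable matrix
        C = np.linalg.cholesky(nearest_correlation(corr, 1e-8))

    pts = qmc.Sobol(d - 1, scramble=True, seed=seed).random(n_points)
    dn = np.full(n_points, ndtr(lower[0] / C[0, 0]))
    en = np.full(n_points, ndtr(upper[0] / C[0, 0]))
    f = en - dn
    y = np.empty((n_points, d - 1))
    for i in range(1, d):
        z = np.clip(dn + pts[:, i - 1] * (en - dn), 1e-16, 1.0 - 1e-16)
        y[:, i - 1] = ndtri(z)
        mu = y[:, :i] @ C[i, :i]
        cii = max(C[i, i], 1e-12)
        dn = ndtr((lower[i] - mu) / cii)
        en = ndtr((upper[i] - mu) / cii)
        f = f * np.clip(en - dn, 0.0, 1.0)
    return float(f.mean())


def minp_pvalue(
    pvalues: Sequence[float],
    R_T: np.ndarray,
    n_points: int = _MINP_POINTS,
    seed: int = _MINP_SEED,
) -> float:
    """Calibrated minimal p-value across the model-order statistics.

    P* = Pr(min_L p^[L] <= p_min) = 1 - Pr(|T^[L]| < t for all L) under the
    zero-mean multivariate normal with correlation ``R_T``, where
    t = Phi^-1(1 - p_min / 2).  The result is clamped to its analytic bounds
    [p_min, m * p_min] (perfect dependence / Bonferroni).  Below p_min = 1e-15
    the rectangle integral is numerically uninformative and the Bonferroni
    bound is returned.
    """
    p = np.asarray([pv for pv in pvalues if np.isfinite(pv)], dtype=float)
    if p.size == 0:
        return np.nan
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    p_min = float(p.min())
    m = p.size
    if m == 1:
        return p_min
    R = nearest_correlation(np.asarray(R_T, dtype=float))
    off = R[~np.eye(m, dtype=bool)]
    if off.size and off.min() > 1.0 - 1e-8:  # effectively one test
        return p_min
    if p_min < 1e-15:
        return float(min(1.0, m * p_min))
    t = -ndtri(p_min / 2.0)
    rect = mvn_rectangle(np.full(m, -t), np.full(m, t), R, n_points=n_points, seed=seed)
    p_star = 1.0 - rect
    return float(np.clip(p_star, p_min, min(1.0, m * p_min)))


# ---------------------------------------------------------------------------
# Cauchy combination across tissues
# ---------------------------------------------------------------------------

def cauchy_combine(pvalues: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Cauchy combination of dependent p-values (equal weights by default).

    S = sum_i w_i tan((0.5 - p_i) pi); combined p = 0.5 - arctan(S)/pi.  Valid
    under arbitrary dependence between the tests.  P-values below 1e-15 use the
    asymptotic substitution tan((0.5 - p) pi) ~ 1/(p pi); a huge positive S is
    converted back with the matching tail expansion 1/(S pi).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    if weights is None:
        wts = np.full(p.size, 1.0 / p.size)
    else:
        wts = np.asarray(weights, dtype=float)
        if wts.shape != p.shape or np.any(wts < 0) or wts.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        wts = wts / wts.sum()
    small = p < 1e-15
    terms = np.empty_like(p)
    terms[small] = 1.0 / (p[small] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    s = float(wts @ terms)
    if s > 1e15:
        return float(1.0 / (s * np.pi))
    return float(0.5 - np.arctan(s) / np.pi)


def combine_tissues(
    gene_id: str,
    tissue_pvalues: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> MultiTissueResult:
    """Cauchy-combine one gene's per-tissue p-values (equal tissue weights by default)."""
    tissues = sorted(tissue_pvalues)
    usable = [t for t in tissues if np.isfinite(tissue_pvalues[t])]
    if weights is None:
        wts = {t: 1.0 for t in usable}
    else:
        wts = {t: float(weights[t]) for t in usable}
    total = sum(wts.values())
    wts = {t: v / total for t, v in wts.items()}
    p = cauchy_combine([tissue_pvalues[t] for t in usable], [wts[t] for t in usable])
    return MultiTissueResult(gene_id, dict(tissue_pvalues), wts, p)


# ---------------------------------------------------------------------------
# comparators: FE, DerSimonian-Laird RE, ancestry subset
# ---------------------------------------------------------------------------

def _fe_hat_and_estimates(
    B: np.ndarray, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-variance fixed-effects meta-analysis per variant (direct formulas)."""
    J, K = B.shape
    hat = np.zeros((J, K))
    b_fe = np.full(J, np.nan)
    s_fe = np.full(J, np.nan)
    for j in range(J):
        ok = np.isfinite(B[j]) & np.isfinite(S[j]) & (S[j] > 0)
        if not ok.any():
            continue
        w = 1.0 / S[j, ok] ** 2
        hat[j, ok] = w / w.sum()
        b_fe[j] = float(hat[j, ok] @ B[j, ok])
        s_fe[j] = float(1.0 / np.sqrt(w.sum()))
    return hat, b_fe, s_fe


def _direct_covariance(
    hat: np.ndarray, S: np.ndarray, ld_by_cohort: Sequence[np.ndarray]
) -> np.ndarray:
    """Plain-loop covariance assembly (kept independent of the meta-regression path)."""
    J, K = hat.shape
    s = np.nan_to_num(np.asarray(S, dtype=float), nan=0.0)
    C = np.zeros((J, J))
    for j1 in range(J):
        for j2 in range(J):
            acc = 0.0
            for k in range(K):
                acc += hat[j1, k] * hat[j2, k] * ld_by_cohort[k][j1, j2] * s[j1, k] * s[j2, k]
            C[j1, j2] = acc
    return C


def fe_twas(
    w: np.ndarray, B: np.ndarray, S: np.ndarray, ld_by_cohort: Sequence[np.ndarray]
) -> TwasStat:
    """Fixed-effects TWAS: inverse-variance meta-analysis per variant, then the
    weighted combination statistic.  Coded directly from the FE formulas (not
    through the meta-regression machinery) so it doubles as an independent
    check of the L = 0 model."""
    hat, b_fe, s_fe = _fe_hat_and_estimates(B, S)
    sigma = _direct_covariance(hat, S, ld_by_cohort)
    return twas_statistic(w, b_fe, s_fe, sigma)


def dersimonian_laird(b: np.ndarray, s: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """DerSimonian-Laird random-effects meta-analysis of one variant.

    Returns (estimate, se, tau2, hat_weights); hat_weights are the normalized
    1/(s^2 + tau2) combination weights.
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)
    w = 1.0 / s**2
    b_fe = float(w @ b / w.sum())
    q = float(w @ (b - b_fe) ** 2)
    df = b.size - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (s**2 + tau2)
    a = wstar / wstar.sum()
    est = float(a @ b)
    se = float(1.0 / np.sqrt(wstar.sum()))
    return est, se, tau2, a


def re_twas(
    w: np.ndarray, B: np.ndarray, S: np.ndarray, ld_by_cohort: Sequence[np.ndarray]
) -> TwasStat:
    """Random-effects (DerSimonian-Laird) TWAS comparator.

    Each variant is meta-analyzed with DL weights; the cross-variant sampling
    covariance is assembled from the DL combination weights and ancestry LD,
    and the between-study variance tau2 enters the diagonal (random effects of
    different variants treated as independent).
    """
    J, K = B.shape
    hat = np.zeros((J, K))
    b_re = np.full(J, np.nan)
    s_re = np.full(J, np.nan)
    tau2 = np.zeros(J)
    for j in range(J):
        ok = np.isfinite(B[j]) & np.isfinite(S[j]) & (S[j] > 0)
        if not ok.any():
            continue
        est, se, t2, a = dersimonian_laird(B[j, ok], S[j, ok])
        b_re[j], s_re[j], tau2[j] = est, se, t2
        hat[j, ok] = a
    sigma = effect_covariance(hat, hat, S, ld_by_cohort)
    sigma = (sigma + sigma.T) / 2.0
    sigma[np.diag_indices(J)] += tau2 * (hat**2).sum(axis=1)
    return twas_statistic(w, b_re, s_re, sigma)


def subset_twas(
    w: np.ndarray,
    B: np.ndarray,
    S: np.ndarray,
    ld_by_cohort: Sequence[np.ndarray],
    ancestry_labels: Sequence[str],
    target_ancestry: str,
) -> TwasStat:
    """FE-TWAS restricted to the cohorts whose ancestry matches the eQTL panel."""
    mask = np.asarray([a == target_ancestry for a in ancestry_labels], dtype=bool)
    if not mask.any():
        raise ValueError(f"no cohorts with ancestry label {target_ancestry!r}")
    idx = np.flatnonzero(mask)
    return fe_twas(w, B[:, idx], S[:, idx], [ld_by_cohort[k] for k in idx])


# ---------------------------------------------------------------------------
# per-gene driver
# ---------------------------------------------------------------------------

def analyze_gene(
    gene_id: str,
    tissue: str,
    w: np.ndarray,
    B: np.ndarray,
    S: np.ndarray,
    design: np.ndarray,
    x_tilde: np.ndarray,
    ld_by_cohort: Sequence[np.ndarray],
    orders: Sequence[int] = (0, 1, 2, 3),
    ancestry_labels: Sequence[str] | None = None,
    panel_ancestry: str | None = None,
    comparators: Sequence[str] = ("fe", "re", "subset"),
    minp_points: int = _MINP_POINTS,
    minp_seed: int = _MINP_SEED,
) -> TeslaResult:
    """Run the full per-gene analysis: meta-regression at each model order,
    per-order statistics, cross-model correlation, minimal-P combination, and
    the requested comparator statistics."""
    w = np.asarray(w, dtype=float)
    orders = tuple(int(L) for L in orders)
    projs = {
        L: ancestry_projection(gene_id, B, S, design, x_tilde, L, ld_by_cohort)
        for L in orders
    }
    stats = {L: twas_statistic(w, projs[L].b_hat, projs[L].s_hat, projs[L].sigma_b) for L in orders}
    usable = [L for L in orders if stats[L].testable]
    n_used = int(np.sum(np.isfinite(projs[orders[0]].b_hat))) if orders else 0

    if usable:
        cross = {}
        for i, L1 in enumerate(usable):
            for L2 in usable[i + 1 :]:
                cross[(L1, L2)] = effect_covariance(
                    projs[L1].hat_map, projs[L2].hat_map, S, ld_by_cohort
                )
        R = model_correlation(w, projs, cross, stats, usable)
        p_star = minp_pvalue(
            [stats[L].p for L in usable], R, n_points=minp_points, seed=minp_seed
        )
    else:
        R = np.empty((0, 0))
        p_star = np.nan

    res = TeslaResult(
        gene_id=gene_id,
        tissue=tissue,
        orders=orders,
        stats=stats,
        R_T=R,
        p_star=p_star,
        n_variants_used=n_used,
        model_downgrades={L: projs[L].downgrades for L in orders if projs[L].downgrades},
    )
    if "fe" in comparators:
        res.p_fe = fe_twas(w, B, S, ld_by_cohort).p
    if "re" in comparators:
        res.p_re = re_twas(w, B, S, ld_by_cohort).p
    if "subset" in comparators and ancestry_labels is not None and panel_ancestry is not None:
        try:
            res.p_subset = subset_twas(w, B, S, ld_by_cohort, ancestry_labels, panel_ancestry).p
        except ValueError:
            res.p_subset = np.nan
    return res


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def genomic_control_lambda(pvalues: Sequence[float]) -> float:
    """Genomic-control lambda: median chi-square of the p-values over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return np.nan
    stats_ = chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(stats_) / chi2.isf(0.5, df=1))


def noncentrality(weights: np.ndarray, mean_z: np.ndarray, corr_z: np.ndarray) -> float:
    """Noncentrality mu^2 = (E[U]/sqrt(V))^2 of the linear statistic U = w'z.

    Used to examine the proportionality condition: by Cauchy-Schwarz the
    maximizer is w proportional to corr_z^-1 mean_z, i.e. to the causal
    effects when the marginal z-score means are LD-convolved causal effects.
    """
    v = np.asarray(weights, dtype=float)
    num = float(v @ np.asarray(mean_z, dtype=float))
    den = float(v @ np.asarray(corr_z, dtype=float) @ v)
    if den <= 0:
        return 0.0
    return num**2 / den
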