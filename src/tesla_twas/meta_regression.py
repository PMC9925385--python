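"""Per-variant meta-regression of cohort effects on ancestry PCs.

For each variant j of a gene, the per-cohort effect estimates b_jk are modeled
as a linear function of the cohorts' allele-frequency PC coordinates,

    M^[L]:  b_jk = sum_{l=0..L} X_kl * gamma_lj + eps_jk,   X_k0 = 1,

with b_jk ~ N(mean, s_jk^2).  The model is fitted by weighted least squares
with inverse-variance weights W = diag(s_jk^-2); the fitted surface evaluated
at the eQTL panel's PC coordinates X~ gives the projected effect

    b^_j^[L] = X~^[L] (X' W X)^-1 X' W b_j. ,

a fixed linear combination ("hat" row) of the per-cohort effects.  L = 0
(intercept only) is exactly the fixed-effects inverse-variance meta-analysis.
Because b^ is linear in the cohort effects, its covariance across variants —
and across model orders, as needed by the minimal-P combination — follows from
the within-cohort sampling covariance Cov(b_j1k, b_j2k) = r_j1j2^(k) s_j1k s_j2k,
with r^(k) taken from the LD panel of cohort k's ancestry and zero covariance
between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AncestryProjection",
    "fit_variant_meta_regression",
    "ancestry_projection",
    "project_effects",
    "effect_covariance",
]

_RANK_RTOL = 1e-8


@dataclass
class AncestryProjection:
    """Fitted meta-regression for one gene at model order L.

    ``hat_map[j, k]`` is the weight of cohort k's effect b_jk in the projected
    effect b^_j (zero when cohort k lacks variant j), so ``b_hat = sum_k
    hat_map[:, k] * B[:, k]`` holds exactly.  ``downgrades`` maps variant index
    to the reduced order actually fitted when fewer cohorts than L + 2 carry
    the variant or the weighted design is rank deficient.
    """

    gene_id: str
    L: int
    gamma_hat: np.ndarray  # (L+1, J), NaN above a downgraded variant's order
    b_hat: np.ndarray  # (J,)
    s_hat: np.ndarray  # (J,)
    sigma_b: np.ndarray  # (J, J)
    hat_map: np.ndarray  # (J, K)
    downgrades: dict[int, int] = field(default_factory=dict)


def fit_variant_meta_regression(
    b: np.ndarray, s: np.ndarray, X: np.ndarray, x_tilde: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """WLS fit of one variant's cohort effects on the PC design.

    Parameters are the per-cohort effects ``b``, their standard errors ``s``
    (all finite, positive) and the design ``X`` (cohorts by L+1, intercept
    first).  Returns ``(gamma_hat, hat_row)`` where ``hat_row`` maps the cohort
    effects to the projected effect at coordinates ``x_tilde`` (defaults to the
    intercept-only point (1, 0, ..., 0)).  Uses a pseudo-inverse so collinear
    designs do not raise; callers should downgrade the order when the weighted
    design is rank deficient (see :func:`ancestry_projection`).
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if x_tilde is None:
        x_tilde = np.eye(X.shape[1])[0]
    w = 1.0 / s**2
    xtw = X.T * w
    m = xtw @ X
    m_inv = np.linalg.pinv(m, rcond=_RANK_RTOL)
    gamma = m_inv @ (xtw @ b)
    hat_row = np.asarray(x_tilde, dtype=float) @ m_inv @ xtw
    return gamma, hat_row


def _weighted_rank(X: np.ndarray, w: np.ndarray) -> int:
    sv = np.linalg.svd(np.sqrt(w)[:, None] * X, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > sv[0] * _RANK_RTOL))


def ancestry_projection(
    gene_id: str,
    B: np.ndarray,
    S: np.ndarray,
    design: np.ndarray,
    x_tilde: np.ndarray,
    L: int,
    ld_by_cohort: Sequence[np.ndarray],
) -> AncestryProjection:
    """Fit M^[L] for every variant of a gene and assemble the projected effects.

    ``B`` and ``S`` are J-by-K effect and standard-error matrices with NaN
    marking cohorts that do not carry a variant (those cohorts are excluded
    from that variant's fit, never zero-imputed).  ``design`` is the full
    K-by-(Lmax+1) PC design and ``x_tilde`` the panel coordinate vector; only
    their first L+1 columns/entries are used.  ``ld_by_cohort[k]`` is the
    J-by-J LD correlation among the gene's variants in cohort k's ancestry.
    """
    B = np.asarray(B, dtype=float)
    S = np.asarray(S, dtype=float)
    J, K = B.shape
    if design.shape[0] != K:
        raise ValueError("design rows must match the number of cohorts")
    gamma = np.full((L + 1, J), np.nan)
    hat = np.zeros((J, K))
    b_hat = np.full(J, np.nan)
    downgrades: dict[int, int] = {}

    for j in range(J):
        ok = np.isfinite(B[j]) & np.isfinite(S[j]) & (S[j] > 0)
        npres = int(ok.sum())
        if npres == 0:
            continue
        # reduce the order until enough cohorts support it and the design has full rank
        Leff = min(L, max(0, npres - 2))
        w = 1.0 / S[j, ok] ** 2
        while Leff > 0 and _weighted_rank(design[ok, : Leff + 1], w) < Leff + 1:
            Leff -= 1
        if Leff < L:
            downgrades[j] = Leff
        g, hrow = fit_variant_meta_regression(
            B[j, ok], S[j, ok], design[ok, : Leff + 1], x_tilde[: Leff + 1]
        )
        gamma[: Leff + 1, j] = g
        hat[j, ok] = hrow
        b_hat[j] = hrow @ B[j, ok]

    sigma = effect_covariance(hat, hat, S, ld_by_cohort)
    sigma = (sigma + sigma.T) / 2.0
    s_hat = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
    return AncestryProjection(
        gene_id=gene_id,
        L=L,
        gamma_hat=gamma,
        b_hat=b_hat,
        s_hat=s_hat,
        sigma_b=sigma,
        hat_map=hat,
        downgrades=downgrades,
    )


def project_effects(gamma_hat: np.ndarray, x_tilde: np.ndarray) -> np.ndarray:
    """Projected effects b^_j = X~ gamma_.j for a fitted coefficient matrix."""
    g = np.nan_to_num(np.asarray(gamma_hat, dtype=float), nan=0.0)
    return np.asarray(x_tilde, dtype=float) @ g


def effect_covariance(
    hat1: np.ndarray,
    hat2: np.ndarray,
    S: np.ndarray,
    ld_by_cohort: Sequence[np.ndarray],
) -> np.ndarray:
    """Covariance between two sets of projected effects sharing the cohort data.

    Entry (j1, j2) is ``sum_k a1[j1,k] a2[j2,k] r^(k)[j1,j2] s[j1,k] s[j2,k]``:
    cohorts are independent, and within cohort k the effect estimates of two
    variants correlate according to that ancestry's LD.  Hat-map zeros make the
    sum run only over cohorts carrying both variants.  With ``hat1 is hat2``
    this is Sigma_b^[L]; with the hat maps of two model orders it is the
    cross-model block needed for the minimal-P combination.
    """
    hat1 = np.asarray(hat1, dtype=float)
    hat2 = np.asarray(hat2, dtype=float)
    s = np.nan_to_num(np.asarray(S, dtype=float), nan=0.0)
    J, K = hat1.shape
    if len(ld_by_cohort) != K:
        raise ValueError("need one LD matrix per cohort")
    C = np.zeros((J, J))
    for k in range(K):
        a1 = hat1[:, k] * s[:, k]
        a2 = hat2[:, k] * s[:, k]
        C += np.outer(a1, a2) * ld_by_cohort[k]
    return C
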