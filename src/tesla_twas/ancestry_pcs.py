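"""Principal components of cohort allele frequencies as continuous ancestry proxies.

Each GWAS cohort contributes a genome-wide allele-frequency vector over a
variant set shared by all cohorts.  The singular value decomposition of the
cohort-by-variant frequency matrix F yields per-cohort PC scores X_kl that
capture systematic frequency differences between ancestries (with column
centering, the leading PC typically separates the most diverged ancestry
groups).  The eQTL reference panel's frequency vector is projected through the
same loadings to obtain its coordinates in the identical space, which anchor
the meta-regression's effect prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrequencyPCs", "compute_frequency_pcs", "project_panel", "design_matrix"]


@dataclass
class FrequencyPCs:
    """SVD of the (optionally column-centered) cohort-by-variant frequency matrix.

    ``scores[k, l]`` is the (l+1)-th PC coordinate of cohort k; ``loadings`` has
    orthonormal columns (variant-by-component); ``mean_freq`` is the per-variant
    mean subtracted before the SVD (zeros when ``centered`` is False).
    """

    cohort_ids: list[str]
    variant_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    mean_freq: np.ndarray
    centered: bool

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def compute_frequency_pcs(
    freqs: np.ndarray,
    n_components: int = 3,
    center: bool = True,
    cohort_ids: list[str] | None = None,
    variant_ids: list[str] | None = None,
) -> FrequencyPCs:
    """SVD-based PCs of the cohort-by-variant frequency matrix.

    Component signs are fixed deterministically by making the largest-magnitude
    loading of each component positive, so repeated runs are bit-identical.
    Requires ``n_components < n_cohorts``.
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("need a 2-D frequency matrix with at least 1 cohort")
    if np.isnan(f).any():
        raise ValueError("frequency matrix has missing entries; exclude those variants upstream")
    k, m = f.shape
    if n_components >= k:
        raise ValueError(
            f"insufficient cohorts for requested PCs: {n_components} components, {k} cohorts"
        )
    mean = f.mean(axis=0) if center else np.zeros(m)
    u, sv, vt = np.linalg.svd(f - mean, full_matrices=False)
    r = min(n_components, len(sv))
    loadings = vt[:r].T.copy()
    scores = u[:, :r] * sv[:r]
    # deterministic sign convention: largest-|loading| entry of each component positive
    for j in range(r):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    if r < n_components:  # rank-deficient matrix: pad with zero components
        loadings = np.hstack([loadings, np.zeros((m, n_components - r))])
        scores = np.hstack([scores, np.zeros((k, n_components - r))])
        sv = np.concatenate([sv[:r], np.zeros(n_components - r)])
    return FrequencyPCs(
        cohort_ids=list(cohort_ids) if cohort_ids is not None else [f"cohort{i}" for i in range(k)],
        variant_ids=list(variant_ids) if variant_ids is not None else [f"v{i}" for i in range(m)],
        scores=scores,
        loadings=loadings,
        singular_values=np.asarray(sv[:n_components], dtype=float),
        mean_freq=mean,
        centered=center,
    )


def design_matrix(pcs: FrequencyPCs, L: int) -> np.ndarray:
    """Meta-regression design X^[L]: intercept column (X_k0 = 1) plus the first L PC scores."""
    if L > pcs.n_components:
        raise ValueError(f"L={L} exceeds the {pcs.n_components} retained components")
    return np.column_stack([np.ones(pcs.scores.shape[0]), pcs.scores[:, :L]])


def project_panel(
    panel_freqs: np.ndarray,
    pcs: FrequencyPCs,
    L: int,
    max_missing: float = 0.05,
) -> np.ndarray:
    """Coordinates of a frequency vector in the cohort PC space.

    Returns the length-(L+1) vector ``(1, x_1, ..., x_L)`` — the leading 1 is
    the intercept coordinate; L = 0 gives the intercept-only (fixed-effects)
    limit.  The panel vector is centered with the cohort means and mapped
    through the cohort loadings.  Missing entries (NaN) are tolerated up to
    ``max_missing`` of the variant set and excluded from the inner products.
    """
    if L > pcs.n_components:
        raise ValueError(f"L={L} exceeds the {pcs.n_components} retained components")
    f = np.asarray(panel_freqs, dtype=float)
    if f.shape != (len(pcs.variant_ids),):
        raise ValueError("panel frequency vector does not match the PC variant set")
    missing = ~np.isfinite(f)
    frac = missing.mean()
    if frac > max_missing:
        ids = [v for v, m in zip(pcs.variant_ids, missing) if m]
        raise ValueError(
            f"panel is missing {frac:.1%} of PC variants (cap {max_missing:.0%}): {ids[:10]}..."
        )
    ok = ~missing
    coords = (f[ok] - pcs.mean_freq[ok]) @ pcs.loadings[ok, :L] if L else np.empty(0)
    return np.concatenate([[1.0], coords])
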