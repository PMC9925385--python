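"""Synthetic multi-ancestry GWAS summary statistics for calibration and power studies.

The generator emulates the structure the trans-ancestry TWAS operates on:
several ancestry clusters with systematically different allele frequencies
(a one-dimensional frequency cline, so the leading frequency PC orders the
ancestries) and ancestry-specific LD (first-order autoregressive correlation
with a per-ancestry decay).  Summary statistics are drawn directly at the
summary level: within cohort k the per-variant effect estimates are

    b_.k ~ MVN(beta_.k, R_ancestry(k) / n_k),   s_jk = 1/sqrt(n_k),

the standardized-genotype convention (z ~ sqrt(n) b).  Three true-effect
architectures are supported, all mediated through the eQTL weights w and a
gene-to-trait effect c:

* ``homogeneous``        beta_jk = w_j * c for every cohort;
* ``pc_heterogeneous``   beta_jk = w_j * (c - slope * d_k), where d_k is the
  cohort's displacement from the eQTL panel along the standardized leading
  frequency PC, oriented so the cohort mass lies at positive d (the PC sign
  itself is an arbitrary convention).  The trend is anchored at the panel
  ancestry: slope > 0 means the effect is c in the panel-matched ancestry and
  decays linearly with PC distance from it.  Still linear in PC1, so the
  one-PC meta-regression model is correctly specified;
* ``single_ancestry``    beta_jk = w_j * c only in the target ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ancestry_pcs import FrequencyPCs, compute_frequency_pcs, design_matrix, project_panel
from .io_summary import CohortSummary, LDPanel, write_frequency_matrix, write_ld_matrix
from . import tesla_core

__all__ = [
    "SimulationScenario",
    "ScenarioData",
    "ar1_correlation",
    "simulate_frequency_panels",
    "prepare_scenario",
    "true_effects",
    "simulate_effect_matrix",
    "simulate_cohort_summaries",
    "run_power_experiment",
    "write_scenario",
]

ARCHITECTURES = ("homogeneous", "pc_heterogeneous", "single_ancestry")


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of one simulated study design.

    Defaults give the desk-scale grid used throughout the test-bench: 3
    ancestries x 4 cohorts of 10,000 samples each, 10 variants per gene,
    ancestry-specific AR(1) LD, and a frequency cline strong enough for the
    leading PC to separate the ancestries.
    """

    n_ancestries: int = 3
    cohorts_per_ancestry: int = 4
    n_per_cohort: int = 10_000
    n_variants: int = 10
    ld_rho: tuple[float, ...] = (0.8, 0.6, 0.4)
    freq_offset: float = 0.15
    within_noise: float = 0.01
    n_pc_variants: int = 500
    weight_sd: float = 1.0
    mediation_c: float = 0.0
    het_slope: float = 0.0
    architecture: str = "homogeneous"
    target_ancestry: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_per_cohort <= 0 or self.cohorts_per_ancestry <= 0:
            raise ValueError("sample sizes and cohort counts must be positive")
        if any(not -1 < r < 1 for r in self.ld_rho):
            raise ValueError("AR(1) rho must lie in (-1, 1)")

    @property
    def n_cohorts(self) -> int:
        return self.n_ancestries * self.cohorts_per_ancestry


@dataclass
class ScenarioData:
    """Realized study structure shared by all gene replicates of a scenario."""

    scenario: SimulationScenario
    cohort_ids: list[str]
    ancestry_of_cohort: np.ndarray  # (K,) int
    ancestry_labels: list[str]  # (K,) strings like "ANC0"
    cohort_freqs: np.ndarray  # (K, M) PC variant frequencies
    panel_freqs: np.ndarray  # (M,)
    gene_freqs: np.ndarray  # (A, J) per-ancestry gene-variant frequencies
    ld: list[np.ndarray]  # per ancestry (J, J)
    ld_chol: list[np.ndarray]
    pcs: FrequencyPCs
    design: np.ndarray  # (K, n_components + 1)
    x_tilde: np.ndarray  # (n_components + 1,)
    u_std: np.ndarray  # (K,) standardized PC1
    u_panel: float
    S: np.ndarray  # (J, K)

    @property
    def ld_by_cohort(self) -> list[np.ndarray]:
        return [self.ld[a] for a in self.ancestry_of_cohort]

    @property
    def panel_ancestry_label(self) -> str:
        return f"ANC{self.scenario.target_ancestry}"


def ar1_correlation(rho: float, size: int) -> np.ndarray:
    """First-order autoregressive correlation matrix r_ij = rho^|i-j|."""
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_frequency_panels(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw PC-variant frequencies for every cohort plus the eQTL panel.

    Ancestry bases sit on a shared per-variant cline (offset scaled by the
    ancestry's position), cohorts add small within-ancestry noise, and the
    panel tracks the target ancestry's base.  Also returns per-ancestry
    frequencies for the gene's variants, drawn by the same scheme.
    """
    sc = scenario
    a_pos = np.arange(sc.n_ancestries) - (sc.n_ancestries - 1) / 2.0

    def _bases(m: int) -> np.ndarray:
        base = rng.uniform(0.1, 0.9, size=m)
        cline = rng.standard_normal(m)
        return np.clip(
            base[None, :] + sc.freq_offset * a_pos[:, None] * cline[None, :], 0.01, 0.99
        )

    pc_bases = _bases(sc.n_pc_variants)  # (A, M)
    gene_freqs = _bases(sc.n_variants)  # (A, J)

    ancestry_of_cohort = np.repeat(np.arange(sc.n_ancestries), sc.cohorts_per_ancestry)
    cohort_freqs = np.clip(
        pc_bases[ancestry_of_cohort]
        + sc.within_noise * rng.standard_normal((sc.n_cohorts, sc.n_pc_variants)),
        0.01,
        0.99,
    )
    panel_freqs = np.clip(
        pc_bases[sc.target_ancestry] + sc.within_noise * rng.standard_normal(sc.n_pc_variants),
        0.01,
        0.99,
    )
    return cohort_freqs, panel_freqs, ancestry_of_cohort, gene_freqs


def prepare_scenario(scenario: SimulationScenario, n_components: int = 3) -> ScenarioData:
    """Realize the study structure (frequencies, PCs, LD) once per scenario.

    All gene replicates of a scenario share this structure, mirroring a real
    study where genome-wide PCs and LD references are fixed while genes vary.
    Deterministic given ``scenario.seed``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    cohort_freqs, panel_freqs, anc, gene_freqs = simulate_frequency_panels(sc, rng)
    cohort_ids = [f"coh{k}" for k in range(sc.n_cohorts)]
    pcs = compute_frequency_pcs(
        cohort_freqs, n_components=n_components, center=True, cohort_ids=cohort_ids
    )
    design = design_matrix(pcs, n_components)
    x_tilde = project_panel(panel_freqs, pcs, n_components)
    pc1 = pcs.scores[:, 0]
    sd = pc1.std()
    u_std = (pc1 - pc1.mean()) / sd if sd > 0 else np.zeros_like(pc1)
    u_panel = float((x_tilde[1] - pc1.mean()) / sd) if sd > 0 else 0.0

    rhos = list(sc.ld_rho)
    if len(rhos) < sc.n_ancestries:
        rhos = (rhos * sc.n_ancestries)[: sc.n_ancestries]
    ld = [ar1_correlation(r, sc.n_variants) for r in rhos[: sc.n_ancestries]]
    ld_chol = [np.linalg.cholesky(m) for m in ld]
    s = 1.0 / np.sqrt(float(sc.n_per_cohort))
    S = np.full((sc.n_variants, sc.n_cohorts), s)
    return ScenarioData(
        scenario=sc,
        cohort_ids=cohort_ids,
        ancestry_of_cohort=anc,
        ancestry_labels=[f"ANC{a}" for a in anc],
        cohort_freqs=cohort_freqs,
        panel_freqs=panel_freqs,
        gene_freqs=gene_freqs,
        ld=ld,
        ld_chol=ld_chol,
        pcs=pcs,
        design=design,
        x_tilde=x_tilde,
        u_std=u_std,
        u_panel=u_panel,
        S=S,
    )


def true_effects(data: ScenarioData, w: np.ndarray) -> np.ndarray:
    """True per-variant, per-cohort phenotypic effects beta_jk for the architecture."""
    sc = data.scenario
    w = np.asarray(w, dtype=float)
    if sc.architecture == "homogeneous":
        mult = np.full(sc.n_cohorts, sc.mediation_c)
    elif sc.architecture == "pc_heterogeneous":
        disp = data.u_std - data.u_panel
        orient = np.sign(disp.mean()) or 1.0  # put the cohort mass at positive d
        mult = sc.mediation_c - sc.het_slope * (orient * disp)
    else:  # single_ancestry
        mult = np.where(
            data.ancestry_of_cohort == sc.target_ancestry, sc.mediation_c, 0.0
        )
    return np.outer(w, mult)


def simulate_effect_matrix(
    data: ScenarioData, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Observed effect estimates B (J x K): beta plus LD-correlated sampling noise."""
    sc = data.scenario
    J, K = sc.n_variants, sc.n_cohorts
    z = rng.standard_normal((J, K))
    B = np.empty((J, K))
    s = 1.0 / np.sqrt(float(sc.n_per_cohort))
    for k in range(K):
        B[:, k] = beta[:, k] + s * (data.ld_chol[data.ancestry_of_cohort[k]] @ z[:, k])
    return B


def _draw_weights(sc: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(0.0, sc.weight_sd, size=sc.n_variants)
    if not np.any(w != 0):  # pragma: no cover - probability zero
        w[0] = sc.weight_sd
    return w


def simulate_cohort_summaries(
    scenario: SimulationScenario,
    weights: np.ndarray | None = None,
    data: ScenarioData | None = None,
    seed: int | None = None,
) -> tuple[list[CohortSummary], dict, ScenarioData]:
    """Emit full CohortSummary objects for one simulated gene.

    Returns (cohorts, truth, data): ``truth`` records the weights, the true
    effect matrix and the architecture for downstream assertions.  Gene
    variants are named ``1:<pos>:A:G`` with A/G alleles (never palindromic) so
    harmonization passes them through unchanged.
    """
    sc = scenario
    if data is None:
        data = prepare_scenario(sc)
    rng = np.random.default_rng(sc.seed + 1 if seed is None else seed)
    w = _draw_weights(sc, rng) if weights is None else np.asarray(weights, dtype=float)
    beta = true_effects(data, w)
    B = simulate_effect_matrix(data, beta, rng)
    s = 1.0 / np.sqrt(float(sc.n_per_cohort))
    positions = [1000 * (j + 1) for j in range(sc.n_variants)]
    variant_ids = [f"1:{p}:A:G" for p in positions]
    cohorts = []
    for k in range(sc.n_cohorts):
        a = int(data.ancestry_of_cohort[k])
        eaf = np.clip(
            data.gene_freqs[a] + sc.within_noise * rng.standard_normal(sc.n_variants),
            0.01,
            0.99,
        )
        table = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chrom": "1",
                "pos": positions,
                "ref": "A",
                "alt": "G",
                "eaf": eaf,
                "b": B[:, k],
                "s": s,
                "n": float(sc.n_per_cohort),
            }
        )
        table["z"] = table["b"] / table["s"]
        cohorts.append(
            CohortSummary(
                cohort_id=data.cohort_ids[k],
                ancestry_label=data.ancestry_labels[k],
                table=table,
            )
        )
    truth = {
        "weights": w,
        "beta": beta,
        "architecture": sc.architecture,
        "mediation_c": sc.mediation_c,
        "het_slope": sc.het_slope,
        "variant_ids": variant_ids,
    }
    return cohorts, truth, data


# ---------------------------------------------------------------------------
# power / type-I-error harness
# ---------------------------------------------------------------------------

_METHOD_COLUMNS = {"tesla": "p_star", "fe": "p_fe", "re": "p_re", "subset": "p_subset"}


def _method_pvalues(
    data: ScenarioData,
    w: np.ndarray,
    B: np.ndarray,
    methods: Sequence[str],
    orders: Sequence[int],
) -> dict[str, float]:
    comparators = tuple(m for m in methods if m in ("fe", "re", "subset"))
    res = tesla_core.analyze_gene(
        "sim",
        "sim",
        w,
        B,
        data.S,
        data.design,
        data.x_tilde,
        data.ld_by_cohort,
        orders=orders,
        ancestry_labels=data.ancestry_labels,
        panel_ancestry=data.panel_ancestry_label,
        comparators=comparators,
    )
    out = {}
    for m in methods:
        out[m] = {
            "tesla": res.p_star,
            "fe": res.p_fe,
            "re": res.p_re,
            "subset": res.p_subset,
        }[m]
    return out


def run_power_experiment(
    scenarios: Sequence[SimulationScenario],
    methods: Sequence[str] = ("tesla", "fe", "re", "subset"),
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    orders: Sequence[int] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Empirical rejection rate of each method under each scenario.

    Every replicate is a fresh gene (new weights and summary statistics) on the
    scenario's fixed study structure.  Returns one row per (scenario, method)
    with the rejection fraction and its binomial standard error.
    """
    unknown = set(methods) - set(_METHOD_COLUMNS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for idx, sc in enumerate(scenarios):
        data = prepare_scenario(sc)
        rng = np.random.default_rng(sc.seed + 7919 * (idx + 1))
        rej = {m: 0 for m in methods}
        n_ok = {m: 0 for m in methods}
        for _ in range(n_replicates):
            w = _draw_weights(sc, rng)
            B = simulate_effect_matrix(data, true_effects(data, w), rng)
            pvals = _method_pvalues(data, w, B, methods, orders)
            for m, p in pvals.items():
                if np.isfinite(p):
                    n_ok[m] += 1
                    rej[m] += p < alpha
        for m in methods:
            n = max(n_ok[m], 1)
            power = rej[m] / n
            rows.append(
                {
                    "architecture": sc.architecture,
                    "mediation_c": sc.mediation_c,
                    "het_slope": sc.het_slope,
                    "method": m,
                    "alpha": alpha,
                    "power": power,
                    "se": float(np.sqrt(power * (1 - power) / n)),
                    "n_replicates": n_ok[m],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artifact output for the CLI
# ---------------------------------------------------------------------------

def write_scenario(out_dir: str | Path, scenario: SimulationScenario) -> ScenarioData:
    """Write one simulated gene's inputs as flat files (summaries, frequencies, LD, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts, truth, data = simulate_cohort_summaries(scenario)
    for c in cohorts:
        c.table.to_csv(out / f"{c.cohort_id}.summary.tsv", sep="\t", index=False)
    write_frequency_matrix(
        out / "frequencies.tsv",
        data.cohort_ids,
        [f"pcv{i}" for i in range(scenario.n_pc_variants)],
        data.cohort_freqs,
    )
    pd.DataFrame(
        {"variant_id": [f"pcv{i}" for i in range(scenario.n_pc_variants)],
         "freq": data.panel_freqs}
    ).to_csv(out / "panel_freqs.tsv", sep="\t", index=False)
    for a in range(scenario.n_ancestries):
        panel = LDPanel(f"ANC{a}", truth["variant_ids"], data.ld[a])
        write_ld_matrix(out / f"ANC{a}.ld", panel)
    pd.DataFrame(
        {
            "variant_id": truth["variant_ids"],
            "weight": truth["weights"],
            **{f"beta_{cid}": truth["beta"][:, k] for k, cid in enumerate(data.cohort_ids)},
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene": "gene1",
            "tissue": "tissue1",
            "variant_id": truth["variant_ids"],
            "ref": "A",
            "alt": "G",
            "weight": truth["weights"],
        }
    ).to_csv(out / "weights.tsv", sep="\t", index=False)
    manifest = pd.DataFrame(
        {
            "cohort_id": data.cohort_ids,
            "path": [f"{cid}.summary.tsv" for cid in data.cohort_ids],
            "ancestry": data.ancestry_labels,
            "n": scenario.n_per_cohort,
        }
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    run_cfg = {
        "cohorts": "manifest.tsv",
        "weights": "weights.tsv",
        "freq_matrix": "frequencies.tsv",
        "panel_freqs": "panel_freqs.tsv",
        "ld": ".",
        "panel_ancestry": f"ANC{scenario.target_ancestry}",
        "n_components": 3,
        "models": [0, 1, 2, 3],
        "seed": scenario.seed,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh)
    return data
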