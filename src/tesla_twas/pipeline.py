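"""Manifest-driven end-to-end runs: inputs -> harmonization -> PCs -> per-gene tests.

A run manifest (YAML or dict) names the per-cohort summary files with their
ancestry/LD assignments, the weight table(s), the cohort frequency matrix and
eQTL-panel frequencies, and the LD references; `run_pipeline` wires the
modules together and writes per-gene result tables with provenance metadata
(package version, seed, config hash) plus a per-tissue genomic-control lambda
diagnostic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry_pcs import compute_frequency_pcs, design_matrix, project_panel
from .io_summary import (
    CohortSummary,
    GeneModel,
    LDPanel,
    harmonize_alleles,
    read_cohort_summary,
    read_frequency_matrix,
    read_ld_matrix,
    read_weight_table,
    write_results,
)
from .tesla_core import analyze_gene, combine_tissues, genomic_control_lambda

log = logging.getLogger("tesla")

__all__ = ["RunManifest", "run_pipeline", "combine_results", "config_hash"]


@dataclass
class RunManifest:
    """Validated description of one pipeline run."""

    cohorts: list[dict]  # id, path, ancestry, optional n
    weights: str
    freq_matrix: str
    panel_freqs: str
    ld: dict[str, str]  # ancestry label -> LD matrix path
    panel_ancestry: str | None = None
    n_components: int = 3
    centered: bool = True
    models: tuple[int, ...] = (0, 1, 2, 3)
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_dict(cls, cfg: Mapping, base_dir: str | Path = ".") -> "RunManifest":
        base = Path(base_dir)
        cohorts = cfg["cohorts"]
        if isinstance(cohorts, str):  # a cohort-registry TSV
            reg = pd.read_csv(base / cohorts, sep="\t")
            cohorts = reg.to_dict("records")
        cohorts = [
            {"id": str(c.get("id", c.get("cohort_id"))), "path": str(c["path"]),
             "ancestry": str(c["ancestry"])}
            for c in cohorts
        ]
        ld = cfg["ld"]
        if isinstance(ld, str):  # a directory of <ancestry>.ld files
            ld = {p.stem: str(p.relative_to(base)) for p in sorted((base / ld).glob("*.ld"))}
        else:
            ld = {str(k): str(v) for k, v in ld.items()}
        m = cls(
            cohorts=cohorts,
            weights=str(cfg["weights"]),
            freq_matrix=str(cfg["freq_matrix"]),
            panel_freqs=str(cfg["panel_freqs"]),
            ld=ld,
            panel_ancestry=cfg.get("panel_ancestry"),
            n_components=int(cfg.get("n_components", 3)),
            centered=bool(cfg.get("centered", True)),
            models=tuple(int(x) for x in cfg.get("models", (0, 1, 2, 3))),
            seed=int(cfg.get("seed", 0)),
            base_dir=base,
        )
        m.validate()
        return m

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, base_dir=path.parent)

    def validate(self) -> None:
        missing = [c["ancestry"] for c in self.cohorts if c["ancestry"] not in self.ld]
        if missing:
            raise ValueError(f"cohort ancestries without an LD panel: {sorted(set(missing))}")
        if any(L > self.n_components for L in self.models):
            raise ValueError("model orders must not exceed n_components")

    def to_config(self) -> dict:
        return {
            "cohorts": self.cohorts,
            "weights": self.weights,
            "freq_matrix": self.freq_matrix,
            "panel_freqs": self.panel_freqs,
            "ld": self.ld,
            "panel_ancestry": self.panel_ancestry,
            "n_components": self.n_components,
            "centered": self.centered,
            "models": list(self.models),
            "seed": self.seed,
        }


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _gene_matrices(
    model: GeneModel, cohorts: list[CohortSummary]
) -> tuple[np.ndarray, np.ndarray]:
    """J x K effect and se matrices for a gene (NaN where a cohort lacks a variant)."""
    J, K = len(model.variant_ids), len(cohorts)
    B = np.full((J, K), np.nan)
    S = np.full((J, K), np.nan)
    for k, cohort in enumerate(cohorts):
        t = cohort.table
        idx = pd.Index(t["variant_id"])
        locs = idx.get_indexer(model.variant_ids)
        for j, loc in enumerate(locs):
            if loc >= 0:
                B[j, k] = t["b"].iat[loc]
                S[j, k] = t["s"].iat[loc]
    return B, S


def run_pipeline(manifest: RunManifest) -> tuple[pd.DataFrame, dict]:
    """Execute a full run; returns (results table, provenance metadata)."""
    base = manifest.base_dir
    cohorts = [
        read_cohort_summary(base / c["path"], cohort_id=c["id"], ancestry_label=c["ancestry"])
        for c in manifest.cohorts
    ]
    models = read_weight_table(base / manifest.weights)
    cohorts, harm_report = harmonize_alleles(cohorts, models)
    log.info("harmonization: %s", {k: v["kept"] for k, v in harm_report.items()})

    cohort_ids, pc_variants, F = read_frequency_matrix(base / manifest.freq_matrix)
    order = {cid: i for i, cid in enumerate(cohort_ids)}
    try:
        perm = [order[c.cohort_id] for c in cohorts]
    except KeyError as e:  # pragma: no cover - config error path
        raise ValueError(f"cohort {e} missing from the frequency matrix") from e
    pcs = compute_frequency_pcs(
        F[perm],
        n_components=manifest.n_components,
        center=manifest.centered,
        cohort_ids=[c.cohort_id for c in cohorts],
        variant_ids=pc_variants,
    )
    panel_df = pd.read_csv(base / manifest.panel_freqs, sep="\t")
    panel = panel_df.set_index("variant_id")["freq"].reindex(pc_variants).to_numpy(dtype=float)
    x_tilde = project_panel(panel, pcs, manifest.n_components)
    design = design_matrix(pcs, manifest.n_components)

    panels = {anc: read_ld_matrix(base / path, anc) for anc, path in manifest.ld.items()}
    ancestry_labels = [c.ancestry_label for c in cohorts]

    rows = []
    for model in models:
        B, S = _gene_matrices(model, cohorts)
        ld_by_cohort = [
            panels[c.ancestry_label].submatrix(model.variant_ids) for c in cohorts
        ]
        res = analyze_gene(
            model.gene_id,
            model.tissue,
            model.weights,
            B,
            S,
            design,
            x_tilde,
            ld_by_cohort,
            orders=manifest.models,
            ancestry_labels=ancestry_labels,
            panel_ancestry=manifest.panel_ancestry,
        )
        row = {"gene": model.gene_id, "tissue": model.tissue}
        for L in manifest.models:
            row[f"p_L{L}"] = res.stats[L].p
        row.update(
            p_tesla=res.p_star,
            p_fe=res.p_fe,
            p_re=res.p_re,
            p_subset=res.p_subset,
            n_variants_used=res.n_variants_used,
        )
        rows.append(row)
        log.debug("gene %s/%s: p*=%.3g", model.gene_id, model.tissue, res.p_star)

    results = pd.DataFrame(rows)
    meta = {
        "tesla_version": __version__,
        "seed": manifest.seed,
        "config_hash": config_hash(manifest.to_config()),
    }
    if len(results):
        for tissue, grp in results.groupby("tissue"):
            lam = genomic_control_lambda(grp["p_tesla"])
            meta[f"gc_lambda_{tissue}"] = f"{lam:.4f}"
            log.info("tissue %s: genomic-control lambda %.3f", tissue, lam)
    return results, meta


def combine_results(results: pd.DataFrame, p_column: str = "p_tesla") -> pd.DataFrame:
    """Cauchy-combine per-tissue gene results into one multi-tissue p per gene."""
    rows = []
    for gene, grp in results.groupby("gene"):
        pvals = {str(t): float(p) for t, p in zip(grp["tissue"], grp[p_column])}
        usable = {t: p for t, p in pvals.items() if np.isfinite(p) and 0 < p < 1}
        if not usable:
            rows.append({"gene": gene, "n_tissues": 0, "p_combined": np.nan})
            continue
        res = combine_tissues(str(gene), usable)
        rows.append({"gene": gene, "n_tissues": len(usable), "p_combined": res.p_combined})
    return pd.DataFrame(rows)


def write_run(results: pd.DataFrame, meta: dict, path: str | Path) -> None:
    write_results(results, path, metadata=meta)
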