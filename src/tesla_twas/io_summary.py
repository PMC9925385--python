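"""Reading, validation and harmonization of GWAS summary statistics and weights.

This module converts the flat-file inputs of a trans-ancestry TWAS — per-cohort
GWAS summary statistics, eQTL weight tables, allele-frequency matrices and LD
reference matrices — into the internal data model, and writes result tables.

Conventions
-----------
* Effects ``b`` and standard errors ``s`` are on the standardized-genotype
  scale (genotypes normalized to mean 0, variance 1), so ``z = b/s ~ sqrt(n)*b``.
* Variant identity is ``(chrom, pos, ref, alt)``; positions are 1-based.
* All effect alleles are harmonized to the orientation of the weight tables
  before any analysis; strand-ambiguous (A/T, C/G) variants are dropped by
  default.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "CohortSummary",
    "GeneModel",
    "LDPanel",
    "read_cohort_summary",
    "read_weight_table",
    "read_frequency_matrix",
    "read_ld_matrix",
    "write_ld_matrix",
    "ld_from_genotypes",
    "harmonize_alleles",
    "write_results",
    "read_results",
    "bonferroni_threshold",
]

#: canonical internal column names -> description
SUMMARY_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "eaf", "b", "s", "n", "z")

#: complementary base pairs used to detect strand-ambiguous variants
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SchemaError(ValueError):
    """Raised when a summary-statistics file lacks mandatory columns."""


@dataclass(frozen=True)
class VariantRecord:
    """A single harmonized variant within one cohort."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect_allele_freq: float
    b: float
    s: float
    n: float

    @property
    def z(self) -> float:
        return self.b / self.s


@dataclass
class CohortSummary:
    """Validated per-cohort GWAS summary statistics.

    ``table`` holds one row per variant with the canonical columns
    ``variant_id, chrom, pos, ref, alt, eaf, b, s, n, z``.  ``load_report``
    counts rows kept and rejected (with reasons) during loading.
    """

    cohort_id: str
    ancestry_label: str
    table: pd.DataFrame
    load_report: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[VariantRecord]:
        return [
            VariantRecord(
                variant_id=r.variant_id,
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref_allele=r.ref,
                alt_allele=r.alt,
                effect_allele_freq=float(r.eaf),
                b=float(r.b),
                s=float(r.s),
                n=float(r.n),
            )
            for r in self.table.itertuples(index=False)
        ]


@dataclass
class GeneModel:
    """eQTL expression-prediction weights for one gene in one tissue.

    ``weights[i]`` is the eQTL effect w_j of ``variant_ids[i]`` on expression,
    oriented to the effect allele ``alt`` of ``alleles[i] = (ref, alt)``.
    """

    gene_id: str
    tissue: str
    variant_ids: list[str]
    weights: np.ndarray
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.variant_ids):
            raise ValueError("weights and variant_ids length mismatch")

    @property
    def is_testable(self) -> bool:
        return bool(np.any(self.weights != 0))


@dataclass
class LDPanel:
    """Ancestry-specific LD reference: a correlation matrix over named variants."""

    ancestry_id: str
    variant_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.matrix, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if r.shape[0] != len(self.variant_ids):
            raise ValueError("LD matrix size does not match variant ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self.matrix = (r + r.T) / 2.0
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def submatrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Correlation submatrix for ``variant_ids``.

        Variants absent from the panel are treated as uncorrelated with
        everything (identity row/column) — the conservative default for
        reference-panel gaps.
        """
        j = len(variant_ids)
        out = np.eye(j)
        idx = [self._index.get(v, -1) for v in variant_ids]
        for a in range(j):
            if idx[a] < 0:
                continue
            for b in range(a + 1, j):
                if idx[b] < 0:
                    continue
                out[a, b] = out[b, a] = self.matrix[idx[a], idx[b]]
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "eaf": "eaf",
    "b": "b",
    "s": "s",
    "n": "n",
    "z": "z",
}


def _parse_variant_id(vid: str) -> tuple[str, int]:
    parts = str(vid).split(":")
    if len(parts) >= 2:
        try:
            return parts[0], int(parts[1])
        except ValueError:
            pass
    return ".", 0


def read_cohort_summary(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    cohort_id: str | None = None,
    ancestry_label: str = "",
) -> CohortSummary:
    """Read one tab-delimited GWAS summary-statistics file.

    ``schema`` maps canonical names (``variant_id, chrom, pos, ref, alt, eaf,
    b, s, n, z``) to the column names used in the file; unmapped canonical
    names default to themselves.  The file must provide variant id, alleles,
    frequency, n, and either (b, s) or (z, n); when only z and n are present
    the standardized-genotype identities ``b = z/sqrt(n)``, ``s = 1/sqrt(n)``
    reconstruct the effect scale.

    Rows with nonpositive standard errors or sample sizes, frequencies outside
    (0, 1), or non-finite effects are dropped and counted in ``load_report``.
    """
    path = Path(path)
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype={colmap["variant_id"]: str})

    present = {k: v for k, v in colmap.items() if v in df.columns}
    mandatory = ["variant_id", "ref", "alt", "eaf", "n"]
    missing = [k for k in mandatory if k not in present]
    has_bs = "b" in present and "s" in present
    has_zn = "z" in present and "n" in present
    if missing or not (has_bs or has_zn):
        need = missing + ([] if (has_bs or has_zn) else ["b+s or z+n"])
        raise SchemaError(f"{path.name}: missing mandatory columns: {need}")

    out = pd.DataFrame(
        {k: df[v] for k, v in present.items() if k in SUMMARY_COLUMNS}
    )
    if "chrom" not in out.columns or "pos" not in out.columns:
        parsed = [_parse_variant_id(v) for v in out["variant_id"]]
        out["chrom"] = [c for c, _ in parsed]
        out["pos"] = [p for _, p in parsed]
    out["chrom"] = out["chrom"].astype(str)

    n = pd.to_numeric(out["n"], errors="coerce")
    if not has_bs:
        z = pd.to_numeric(out["z"], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            out["b"] = z / np.sqrt(n)
            out["s"] = 1.0 / np.sqrt(n)
    for col in ("eaf", "b", "s", "n"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    report: dict[str, int] = {"input_rows": len(out)}
    reasons = {
        "nonpositive se": out["s"] <= 0,
        "nonpositive n": out["n"] <= 0,
        "frequency outside (0,1)": ~out["eaf"].between(0, 1, inclusive="neither"),
        "non-finite effect": ~np.isfinite(out["b"]),
    }
    bad = pd.Series(False, index=out.index)
    for reason, mask in reasons.items():
        mask = mask.fillna(True) & ~bad
        report[f"rejected: {reason}"] = int(mask.sum())
        bad |= mask
    out = out.loc[~bad].reset_index(drop=True)
    out["z"] = out["b"] / out["s"]
    report["kept_rows"] = len(out)
    # multi-allelic sites: each (chrom,pos,ref,alt) is its own record
    dup = out.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        report["rejected: duplicate variant"] = int(dup.sum())
        out = out.loc[~dup].reset_index(drop=True)
        report["kept_rows"] = len(out)

    return CohortSummary(
        cohort_id=cohort_id or path.stem,
        ancestry_label=ancestry_label,
        table=out[list(SUMMARY_COLUMNS)],
        load_report=report,
    )


def read_weight_table(path: str | Path, default_tissue: str = "tissue") -> list[GeneModel]:
    """Read a tab-delimited eQTL weight table (gene, variant_id, ref, alt, weight[, tissue])."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    need = {"gene", "variant_id", "ref", "alt", "weight"}
    if not need.issubset(df.columns):
        raise SchemaError(f"weight table missing columns: {sorted(need - set(df.columns))}")
    if "tissue" not in df.columns:
        df["tissue"] = default_tissue
    models = []
    for (gene, tissue), grp in df.groupby(["gene", "tissue"], sort=True):
        models.append(
            GeneModel(
                gene_id=str(gene),
                tissue=str(tissue),
                variant_ids=[str(v) for v in grp["variant_id"]],
                weights=grp["weight"].to_numpy(dtype=float),
                alleles=list(zip(grp["ref"].astype(str), grp["alt"].astype(str))),
            )
        )
    return models


def read_predictdb(path: str | Path, default_tissue: str | None = None) -> list[GeneModel]:
    """Read a PredictDB-style SQLite weight database (``weights`` table).

    Expects the standard columns ``gene, rsid, ref_allele, eff_allele, weight``;
    the tissue defaults to the database filename stem.
    """
    import sqlite3

    path = Path(path)
    tissue = default_tissue or path.stem
    con = sqlite3.connect(path)
    try:
        rows = con.execute(
            "SELECT gene, rsid, ref_allele, eff_allele, weight FROM weights ORDER BY gene"
        ).fetchall()
    finally:
        con.close()
    models: list[GeneModel] = []
    by_gene: dict[str, list] = {}
    for gene, rsid, ref, alt, weight in rows:
        by_gene.setdefault(str(gene), []).append((str(rsid), str(ref), str(alt), float(weight)))
    for gene, entries in sorted(by_gene.items()):
        models.append(
            GeneModel(
                gene_id=gene,
                tissue=tissue,
                variant_ids=[e[0] for e in entries],
                weights=np.array([e[3] for e in entries]),
                alleles=[(e[1], e[2]) for e in entries],
            )
        )
    return models


def read_frequency_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a cohort-by-variant frequency matrix (rows = cohorts, first column = cohort id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.index], [str(v) for v in df.columns], df.to_numpy(dtype=float)


def write_frequency_matrix(
    path: str | Path, cohort_ids: Sequence[str], variant_ids: Sequence[str], freqs: np.ndarray
) -> None:
    pd.DataFrame(freqs, index=list(cohort_ids), columns=list(variant_ids)).to_csv(path, sep="\t")


def read_ld_matrix(path: str | Path, ancestry_id: str | None = None) -> LDPanel:
    """Read a square whitespace-delimited LD matrix with a header row of variant ids."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        mat = np.loadtxt(io.StringIO(fh.read()))
    mat = np.atleast_2d(mat)
    return LDPanel(ancestry_id or path.stem, [str(v) for v in header], mat)


def write_ld_matrix(path: str | Path, panel: LDPanel) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(panel.variant_ids) + "\n")
        np.savetxt(fh, panel.matrix, fmt="%.10g", delimiter="\t")


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

def ld_from_genotypes(
    genotypes: np.ndarray,
    shrinkage: float = 0.1,
    variant_ids: Sequence[str] | None = None,
    ancestry_id: str = "panel",
) -> LDPanel:
    """Pearson LD from an individuals-by-variants genotype matrix, shrunk toward identity.

    The correlation matrix ``r`` is replaced by ``(1 - shrinkage)*r + shrinkage*I``,
    which guarantees positive definiteness for any ``shrinkage > 0``.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with at least 2 individuals")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    ids = [str(v) for v in (variant_ids or range(g.shape[1]))]
    sd = g.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant genotype column(s): {[ids[i] for i in constant]}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    r = (1.0 - shrinkage) * r + shrinkage * np.eye(r.shape[0])
    np.fill_diagonal(r, 1.0)
    return LDPanel(ancestry_id, ids, r)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ref: str, alt: str) -> bool:
    return frozenset((ref.upper(), alt.upper())) in _PALINDROMIC


def harmonize_alleles(
    cohorts: Sequence[CohortSummary],
    models: Sequence[GeneModel],
    drop_palindromic: bool = True,
    freq_orient_threshold: float = 0.08,
) -> tuple[list[CohortSummary], dict]:
    """Orient every cohort record to the weight tables' effect alleles.

    For each weight-table variant the (ref, alt) pair defines the reference
    orientation.  Matching cohort records are kept; records with swapped
    alleles get ``b`` (and ``z``) negated and frequency replaced by ``1 - f``;
    strand-ambiguous A/T and C/G variants are dropped (unless
    ``drop_palindromic=False``, in which case they are kept only when the
    frequency is informative, ``|f - 0.5| > freq_orient_threshold``);
    incompatible allele pairs are dropped.  Cohort variants absent from every
    weight table pass through unchanged.

    Returns harmonized copies and a per-cohort report with kept / flipped /
    dropped counts.  The operation is idempotent.
    """
    reference: dict[str, tuple[str, str]] = {}
    for m in models:
        alleles = m.alleles or []
        for vid, (ref, alt) in zip(m.variant_ids, alleles):
            reference.setdefault(vid, (ref.upper(), alt.upper()))

    harmonized: list[CohortSummary] = []
    report: dict[str, dict] = {}
    for cohort in cohorts:
        t = cohort.table.copy()
        keep = np.ones(len(t), dtype=bool)
        flip = np.zeros(len(t), dtype=bool)
        drop_reason: dict[str, int] = {}
        for i, row in enumerate(t.itertuples(index=False)):
            pair = reference.get(row.variant_id)
            if pair is None:
                continue
            ref, alt = row.ref.upper(), row.alt.upper()
            if _is_palindromic(ref, alt):
                ambiguous = drop_palindromic or abs(row.eaf - 0.5) <= freq_orient_threshold
                if ambiguous:
                    keep[i] = False
                    drop_reason["strand-ambiguous"] = drop_reason.get("strand-ambiguous", 0) + 1
                    continue
            if (ref, alt) == pair:
                continue
            if (alt, ref) == pair:
                flip[i] = True
            else:
                keep[i] = False
                drop_reason["allele-mismatch"] = drop_reason.get("allele-mismatch", 0) + 1
        if flip.any():
            t.loc[flip, ["ref", "alt"]] = t.loc[flip, ["alt", "ref"]].to_numpy()
            t.loc[flip, "b"] = -t.loc[flip, "b"]
            t.loc[flip, "z"] = -t.loc[flip, "z"]
            t.loc[flip, "eaf"] = 1.0 - t.loc[flip, "eaf"]
        n_flipped = int(flip.sum())
        dropped = int((~keep).sum())
        t = t.loc[keep].reset_index(drop=True)
        harmonized.append(
            CohortSummary(cohort.cohort_id, cohort.ancestry_label, t, dict(cohort.load_report))
        )
        report[cohort.cohort_id] = {
            "input": len(keep),
            "kept": len(t),
            "flipped": n_flipped,
            "dropped": dropped,
            "drop_reasons": drop_reason,
        }
    return harmonized, report


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int = 20_000, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests (0.05 / 20,000 = 2.5e-6)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def write_results(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a results table as TSV, with ``# key=value`` metadata header lines.

    Floats are written with full round-trip precision.
    """
    meta = dict(metadata or {})
    meta.setdefault("significance_threshold", bonferroni_threshold())
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta
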