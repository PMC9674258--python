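"""Gene-level annotation and expression-enrichment statistics.

Brain-expression tiers from GTEx-style TPM values, intolerance-score
comparisons (Wilcoxon rank-sum), trimmed-mean expression summaries,
per-cell-type Kolmogorov-Smirnov gene-set comparisons, and an
expression-weighted bootstrap enrichment of a gene signature against
same-size random gene sets (EWCE-style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_bh

#: The 13 GTEx brain tissues entering the brain-average TPM.
BRAIN_TISSUES = (
    "amygdala", "anterior_cingulate_cortex", "caudate",
    "cerebellar_hemisphere", "cerebellum", "cortex", "frontal_cortex",
    "hippocampus", "hypothalamus", "nucleus_accumbens", "putamen",
    "spinal_cord", "substantia_nigra",
)

#: TPM tier cutoffs (lower bound inclusive): high >= 1000 > medium >= 10 >
#: low >= 0.5 > none.
TIER_CUTOFFS = (("high", 1000.0), ("medium", 10.0), ("low", 0.5))


class ExpressionError(ValueError):
    pass


def expression_tier(mean_tpm: float) -> str:
    """Brain-expression tier of a mean TPM value."""
    if mean_tpm < 0 or not math.isfinite(mean_tpm):
        raise ExpressionError(f"invalid TPM {mean_tpm!r}")
    for tier, cutoff in TIER_CUTOFFS:
        if mean_tpm >= cutoff:
            return tier
    return "none"


def brain_mean_tpm(tissue_tpms: Sequence[float], expected: int = 13) -> float:
    """Arithmetic mean TPM across brain tissues (13 expected)."""
    values = np.asarray(tissue_tpms, dtype=float)
    if np.isnan(values).any():
        raise ExpressionError("missing TPM value")
    if (values < 0).any():
        raise ExpressionError("negative TPM value")
    if expected and len(values) != expected:
        import warnings

        warnings.warn(
            f"expected {expected} brain tissues, got {len(values)}"
        )
    if len(values) == 0:
        raise ExpressionError("no TPM values supplied")
    return float(values.mean())


@dataclass
class GeneAnnotation:
    """Intolerance scores and brain-expression summary for one gene."""

    gene: str
    pli: float
    loeuf: float
    rvis: float
    mis_z: float
    brain_mean: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pli <= 1.0):
            raise ExpressionError(f"{self.gene}: pLI outside [0, 1]")
        if self.loeuf < 0:
            raise ExpressionError(f"{self.gene}: negative LOEUF")

    @property
    def tier(self) -> str:
        return expression_tier(self.brain_mean)


def annotate_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Attach brain mean TPM and expression tier to an annotation TSV frame.

    Expects columns gene, pLI, LOEUF, RVIS, mis_Z plus one TPM column per
    brain tissue (named as in :data:`BRAIN_TISSUES`).
    """
    tissues = [t for t in BRAIN_TISSUES if t in table.columns]
    out = table.copy()
    out["brain_mean_tpm"] = [
        brain_mean_tpm(row, expected=len(tissues))
        for row in out[tissues].to_numpy()
    ]
    out["expression_tier"] = out["brain_mean_tpm"].map(expression_tier)
    return out


def intolerance_compare(
    gene_set_scores: Sequence[float],
    background_scores: Sequence[float],
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing intolerance-score samples.

    Exact for small samples without ties, tie-corrected normal approximation
    otherwise (scipy's automatic policy).
    """
    x = np.asarray(gene_set_scores, dtype=float)
    y = np.asarray(background_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ExpressionError("empty sample in rank-sum comparison")
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
    )


def trimmed_mean(values: Sequence[float], trim_fraction: float = 0.25) -> float:
    """Symmetric trimmed mean: drop floor(trim * n) values off each end."""
    if not (0.0 <= trim_fraction < 0.5):
        raise ExpressionError("trim_fraction must be in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    k = int(math.floor(trim_fraction * len(v)))
    kept = v[k:len(v) - k] if k else v
    if len(kept) == 0:
        raise ExpressionError("no values retained after trimming")
    return float(kept.mean())


def trimmed_mean_expression(
    cpm_values: Sequence[float], trim_fraction: float = 0.25
) -> float:
    """Trimmed mean of log2(CPM + 1)-transformed expression values."""
    cpm = np.asarray(cpm_values, dtype=float)
    if (cpm < 0).any():
        raise ExpressionError("negative CPM value")
    return trimmed_mean(np.log2(cpm + 1.0), trim_fraction)


def _per_celltype_values(
    genes: Sequence[str],
    expression: pd.DataFrame,
    cell_types: pd.Series,
    cell_type: str,
) -> np.ndarray:
    cells = cell_types.index[cell_types == cell_type]
    sub = expression.loc[list(genes), cells]
    return sub.mean(axis=1).to_numpy()


def ks_celltype_enrichment(
    gene_set: Sequence[str],
    control_set: Sequence[str],
    expression: pd.DataFrame,
    cell_types: pd.Series,
) -> pd.DataFrame:
    """Per-cell-type KS comparison of gene-set versus control expression.

    ``expression`` is genes x cells; ``cell_types`` labels each cell.  For
    each cell type the two gene sets' per-gene mean expression distributions
    are compared with a two-sample KS test; p-values are Bonferroni-corrected
    across cell types.
    """
    gene_set, control_set = list(dict.fromkeys(gene_set)), list(
        dict.fromkeys(control_set)
    )
    if len(gene_set) < 2 or len(control_set) < 2:
        raise ExpressionError("gene sets must contain at least 2 genes")
    for name, s in (("gene_set", gene_set), ("control_set", control_set)):
        missing = set(s) - set(expression.index)
        if missing:
            raise ExpressionError(f"{name} gene(s) absent from matrix: "
                                  f"{sorted(missing)[:10]}")
    overlap = set(gene_set) & set(control_set)
    if overlap:
        import logging

        logging.getLogger(__name__).info(
            "gene and control sets overlap on %d gene(s)", len(overlap)
        )
    types = sorted(cell_types.unique())
    rows = []
    for ct in types:
        x = _per_celltype_values(gene_set, expression, cell_types, ct)
        y = _per_celltype_values(control_set, expression, cell_types, ct)
        stat, p = stats.ks_2samp(x, y, method="auto")
        rows.append(dict(cell_type=ct, ks_stat=float(stat), p=float(p)))
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.clip(out["p"] * len(types), None, 1.0)
    return out


def bootstrap_signature_enrichment(
    gene_set: Sequence[str],
    background_set: Sequence[str],
    expression: pd.DataFrame,
    cell_types: pd.Series,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """EWCE-style bootstrap enrichment of a gene signature per cell type.

    For every cell type, the observed mean expression of the gene set is
    compared with ``n_boot`` same-size gene sets drawn without replacement
    from the background; ``z`` is the SD-from-mean of the null and
    ``p = (1 + #{null >= observed}) / (n_boot + 1)`` tests over-expression.
    BH correction runs across cell types.
    """
    if n_boot < 100:
        raise ExpressionError("n_boot must be >= 100")
    gene_set = list(dict.fromkeys(gene_set))
    background = list(dict.fromkeys(background_set))
    if len(gene_set) > len(background):
        raise ExpressionError("gene set larger than background")
    outside = set(gene_set) - set(background)
    if outside:
        import logging

        logging.getLogger(__name__).info(
            "%d signature gene(s) outside the background", len(outside)
        )
    missing = (set(gene_set) | set(background)) - set(expression.index)
    if missing:
        raise ExpressionError(
            f"gene(s) absent from matrix: {sorted(missing)[:10]}"
        )
    rng = np.random.default_rng(seed)
    types = sorted(cell_types.unique())
    k = len(gene_set)
    bg_index = expression.index.get_indexer(background)
    set_index = expression.index.get_indexer(gene_set)
    # Mean expression per gene per cell type, computed once.
    by_type = {
        ct: expression.loc[:, cell_types.index[cell_types == ct]]
        .mean(axis=1).to_numpy()
        for ct in types
    }
    draws = np.empty((n_boot, k), dtype=np.int64)
    bg = np.asarray(bg_index)
    for b in range(n_boot):
        draws[b] = rng.choice(bg, size=k, replace=False)
    rows = []
    for ct in types:
        vals = by_type[ct]
        obs = float(vals[set_index].mean())
        null = vals[draws].mean(axis=1)
        sd = float(null.std(ddof=1))
        z = (obs - float(null.mean())) / sd if sd > 0 else 0.0
        p = float((1 + int((null >= obs - 1e-12).sum())) / (n_boot + 1))
        rows.append(dict(
            cell_type=ct, observed_mean=obs, null_mean=float(null.mean()),
            null_sd=sd, z=z, p=p,
        ))
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out
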