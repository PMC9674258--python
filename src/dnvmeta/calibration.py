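"""End-to-end calibration and power studies on synthetic cohorts.

These workflows wire the simulator, count table, enrichment tests and tier
assignment together to answer two standing questions about the pipeline:

* Null calibration — under a cohort with no risk genes, how often does each
  of the seven enrichment tests call a gene significant at nominal 0.05?
  Because the tests are discrete (Poisson upper tails and permutation
  estimators of the form (r+1)/(n+1)), their null p-values are super-uniform:
  the attainable level at 0.05 is below 0.05 and depends on each gene's
  expectation.  For the five analytic Poisson tests the attainable level is
  computed exactly, so the observed significant fraction can be compared to
  its true expectation rather than to the nominal level.

* Planted-gene recovery — with risk genes planted at known relative risks,
  what fraction is recovered into the LC candidate tier, and how many null
  genes ride along.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import assign_tiers, run_three_models
from .harmonize import count_dnvs
from .mutation_model import expected_count
from .simulate import (
    SimConfig, make_gene_models, plant_architecture, simulate_cohort,
)


def attainable_level(lams, alpha: float = 0.05, k_max: int = 400) -> np.ndarray:
    """Exact null probability that a Poisson upper-tail p falls below alpha.

    For X ~ Poisson(lam) the p-value of observing k is P(X >= k), so
    P(p < alpha) = P(X >= k*) with k* the smallest count whose tail is below
    alpha.  This is the attainable level of the discrete test — at most
    alpha, and far below it when lam is small.
    """
    lam = np.atleast_1d(np.asarray(lams, dtype=float))
    out = np.zeros_like(lam)
    remaining = lam > 0
    for k in range(1, k_max + 1):
        if not remaining.any():
            break
        tail = stats.poisson.sf(k - 1, lam)
        hit = remaining & (tail < alpha)
        out[hit] = tail[hit]
        remaining &= ~hit
    return out


@dataclass
class CalibrationResult:
    """Observed vs expected significance of one test on a null cohort."""

    model: str
    test: str
    n_genes: int
    n_significant: int
    expected_significant: float | None  # analytic, Poisson tests only
    expected_sd: float | None
    fraction: float


def null_calibration(
    seed: int = 0,
    n_genes: int = 2_000,
    n_asd: int = 3_000,
    n_dd: int = 3_000,
    alpha: float = 0.05,
    n_iter: int = 999,
    group: str = "NDD",
) -> list[CalibrationResult]:
    """Simulate a null cohort (no risk genes) and measure each test's
    significant fraction at nominal ``alpha``."""
    cfg = SimConfig(
        n_genes=n_genes, n_asd=n_asd, n_dd=n_dd, n_sibling=0,
        n_risk_genes=0, seed=seed,
    )
    models = make_gene_models(cfg)
    records, manifest = simulate_cohort(models, None, cfg)
    table = count_dnvs(records, manifest, genes=[g.gene for g in models])
    model_map = {g.gene: g for g in models}
    results = run_three_models(
        table, model_map, group, records=records, n_iter=n_iter, seed=seed,
    )
    gs = table.sizes[group]
    out = []
    for (model, test), sub in results.groupby(["model", "test"]):
        n_sig = int((sub["p"] < alpha).sum())
        expected = sd = None
        if model in ("CH", "TRI"):
            lam = np.array([
                expected_count(model_map[g], test, gs.n_male, gs.n_female)
                for g in sub["gene"]
            ])
            probs = attainable_level(lam, alpha)
            expected = float(probs.sum())
            sd = float(np.sqrt((probs * (1 - probs)).sum()))
        out.append(CalibrationResult(
            model=model, test=test, n_genes=len(sub), n_significant=n_sig,
            expected_significant=expected, expected_sd=sd,
            fraction=n_sig / len(sub),
        ))
    return out


@dataclass
class RecoveryResult:
    """LC-tier recovery of planted risk genes on a synthetic cohort."""

    n_planted: int
    n_recovered: int
    n_lc: int
    n_false: int
    recovery: float
    tiers: pd.DataFrame
    planted: list[str]


def planted_recovery(
    seed: int = 0,
    n_genes: int = 10_000,
    n_trios: int = 5_000,
    n_risk_genes: int = 50,
    rr_range: tuple[float, float] = (10.0, 50.0),
    alpha: float = 0.05,
    n_iter: int = 9_999,
) -> RecoveryResult:
    """Plant risk genes, run the full pipeline, and score LC recovery."""
    cfg = SimConfig(
        n_genes=n_genes, n_asd=n_trios // 2, n_dd=n_trios - n_trios // 2,
        n_sibling=0, n_risk_genes=n_risk_genes,
        relative_risk_ranges={"LGD": rr_range, "MIS": rr_range},
        seed=seed,
    )
    models = make_gene_models(cfg)
    arch = plant_architecture(models, cfg)
    records, manifest = simulate_cohort(models, arch, cfg)
    table = count_dnvs(records, manifest, genes=[g.gene for g in models])
    model_map = {g.gene: g for g in models}
    results = run_three_models(
        table, model_map, "NDD", records=records, n_iter=n_iter, seed=seed,
    )
    qualifying = table.counts["NDD"]["LGD"] + table.counts["NDD"]["MIS"]
    tiers = assign_tiers(
        results, None, qualifying, alpha=alpha, model_universe=n_genes,
    )
    lc = set(tiers.loc[tiers["tier"].isin(["LC", "MC", "HC"]), "gene"])
    planted = set(arch.risk_genes)
    recovered = lc & planted
    return RecoveryResult(
        n_planted=len(planted), n_recovered=len(recovered), n_lc=len(lc),
        n_false=len(lc - planted),
        recovery=len(recovered) / len(planted) if planted else float("nan"),
        tiers=tiers, planted=sorted(planted),
    )
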