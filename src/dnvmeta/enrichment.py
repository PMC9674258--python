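"""Per-gene DNV enrichment testing, multiple-testing control and tiering.

Three model flavors are run over the grouped count table:

* ``CH``  — Poisson upper-tail tests of the LGD, MIS and MIS30 counts against
  divergence-calibrated expectations (3 tests);
* ``TRI`` — Poisson upper-tail tests of the LGD and MIS counts against
  trinucleotide-context expectations (2 tests);
* ``WPT`` — a severity-weighted permutation test of all DNVs plus a combined
  missense enrichment / positional-clustering test (2 tests);

seven tests in total.  Gene tiers: LC = union FDR 5% across models, MC =
intersection FDR 5%, HC = intersection exome-wide (Bonferroni) significance,
all with the "more than two qualifying DNVs" requirement and with genes
showing sibling significance excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import CountTable
from .mutation_model import GeneModel, expected_count

MODELS = ("CH", "TRI", "WPT")
MODEL_TESTS = {
    "CH": ("LGD", "MIS", "MIS30"),
    "TRI": ("LGD", "MIS"),
    "WPT": ("allDNV", "MISens"),
}

#: Gene universes over which the FDR of each model is controlled in the
#: full-scale analysis (each model scores a slightly different gene set).
DEFAULT_MODEL_UNIVERSE = {"CH": 18946, "TRI": 19618, "WPT": 18762}

#: Number of genes used for the exome-wide Bonferroni correction (the
#: largest universe among the three models) and the number of tests.
EXOME_WIDE_GENES = 19618
N_TESTS = 7


class EnrichmentError(ValueError):
    pass


def poisson_upper_tail(observed: int, lam: float) -> float:
    """P(X >= observed) for X ~ Poisson(lam); 1 when observed == 0."""
    if observed < 0 or lam < 0:
        raise EnrichmentError("negative input to Poisson tail")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


@dataclass
class WeightScheme:
    """Severity weights per variant class for the weighted test.

    The published weighted framework estimates weights from positive
    predictive values; here the default is a fixed severity ordering
    (LGD > MIS30 > MIS > SYN), overridable per class.
    """

    weights: Mapping[str, float] = field(
        default_factory=lambda: {"LGD": 1.0, "MIS30": 0.8, "MIS": 0.5, "SYN": 0.1}
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise EnrichmentError("weights must be nonnegative")

    def weight(self, cls: str) -> float:
        return float(self.weights.get(cls, 0.0))


def _mc_pvalue(n_exceed: int | np.ndarray, n_iter: int):
    # (r + 1) / (n + 1): valid under resampling, never exactly zero.
    return (1.0 + n_exceed) / (n_iter + 1.0)


def weighted_statistic_test(
    observed_classes: Sequence[str],
    lambdas: Mapping[str, float],
    weights: WeightScheme | None = None,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo p for the severity-weighted DNV statistic of one gene.

    The statistic is the summed weight of the observed DNVs; under the null
    the per-class counts are independent Poissons with the supplied means, so
    each null replicate draws per-class counts and sums their weights.
    """
    if n_iter < 1:
        raise EnrichmentError("n_iter must be >= 1")
    weights = weights or WeightScheme()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    s_obs = sum(weights.weight(c) for c in observed_classes)
    s_null = np.zeros(n_iter)
    for cls, lam in lambdas.items():
        w = weights.weight(cls)
        if lam > 0 and w > 0:
            s_null += w * rng.poisson(lam, n_iter)
    return float(_mc_pvalue(int((s_null >= s_obs - 1e-12).sum()), n_iter))


def missense_clustering_test(
    positions: Sequence[int],
    gene_model: GeneModel | int,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo p for positional clustering of missense DNVs.

    The statistic is the mean pairwise CDS distance of the observed missense
    positions (1-based); the null resamples the same number of positions in
    proportion to the per-site missense rate (uniform when the model carries
    no site-level rates).  Fewer than two missense DNVs yield p = 1.
    """
    if n_iter < 1:
        raise EnrichmentError("n_iter must be >= 1")
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return 1.0
    if isinstance(gene_model, GeneModel):
        length = gene_model.cds_length
        site_rates = gene_model.site_mis_rates
    else:
        length, site_rates = int(gene_model), None
    if length < 1:
        raise EnrichmentError("gene model lacks a CDS length")
    if positions.min() < 1 or positions.max() > length:
        raise EnrichmentError("missense position outside the CDS")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    k = len(positions)

    def mean_pairwise(x: np.ndarray) -> np.ndarray:
        # x: (..., k) -> mean |xi - xj| over the k(k-1)/2 pairs.
        diff = np.abs(x[..., :, None] - x[..., None, :])
        return diff.sum(axis=(-2, -1)) / (k * (k - 1))

    d_obs = float(mean_pairwise(positions))
    if site_rates is not None:
        p = np.asarray(site_rates, dtype=float)
        p = p / p.sum()
        null = rng.choice(length, size=(n_iter, k), p=p) + 1.0
    else:
        null = rng.integers(1, length + 1, size=(n_iter, k)).astype(float)
    d_null = mean_pairwise(null)
    return float(_mc_pvalue(int((d_null <= d_obs + 1e-12).sum()), n_iter))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method for combining independent p-values."""
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * len(p)))


def _records_for_group(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Restrict a DNV record table to the samples of one analysis group."""
    if group == "NDD":
        return records[records["phenotype"].isin(["ASD", "DD"])]
    if group in ("male", "female"):
        return records[
            records["phenotype"].isin(["ASD", "DD"]) & (records["sex"] == group)
        ]
    return records[records["phenotype"] == group]


def _lambda_frame(
    gene_models: Mapping[str, GeneModel],
    genes: Sequence[str],
    sizes_male: int,
    sizes_female: int,
) -> pd.DataFrame:
    missing = [g for g in genes if g not in gene_models]
    if missing:
        raise EnrichmentError(f"missing gene model(s): {missing[:20]}")
    data = {
        cls: [expected_count(gene_models[g], cls, sizes_male, sizes_female)
              for g in genes]
        for cls in ("LGD", "MIS", "MIS30", "SYN")
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def _wpt_pvalues(
    obs: pd.DataFrame,
    lam: pd.DataFrame,
    classes: Sequence[str],
    weights: WeightScheme,
    n_iter: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Vectorised weighted-statistic Monte-Carlo p across genes."""
    w = np.array([weights.weight(c) for c in classes])
    s_obs = obs[list(classes)].to_numpy(dtype=float) @ w
    lam_m = lam[list(classes)].to_numpy(dtype=float)
    out = np.ones(len(obs))
    for lo in range(0, len(obs), chunk):
        hi = min(lo + chunk, len(obs))
        s_null = np.zeros((hi - lo, n_iter))
        for j, wj in enumerate(w):
            if wj > 0:
                col = lam_m[lo:hi, j]
                if col.any():
                    s_null += wj * rng.poisson(
                        col[:, None], size=(hi - lo, n_iter)
                    )
        exceed = (s_null >= s_obs[lo:hi, None] - 1e-12).sum(axis=1)
        out[lo:hi] = _mc_pvalue(exceed, n_iter)
    return out


def run_three_models(
    count_table: CountTable,
    gene_models: Mapping[str, GeneModel] | Iterable[GeneModel],
    group: str,
    weight_scheme: WeightScheme | None = None,
    records: pd.DataFrame | None = None,
    models: Sequence[str] = MODELS,
    rate_models: Mapping[str, Mapping[str, GeneModel]] | None = None,
    n_iter: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the enrichment tests of each model for one analysis group.

    ``gene_models`` supplies the expectations for every model unless
    ``rate_models`` maps a model name to its own per-gene models (the CH and
    trinucleotide flavors differ in real analyses).  ``records`` (classified
    DNV rows for the group's samples) feed the clustering component of the
    weighted model; without them the clustering p is 1.

    Returns a long frame: gene, model, test, observed, expected, p.
    """
    if not isinstance(gene_models, Mapping):
        gene_models = {g.gene: g for g in gene_models}
    weights = weight_scheme or WeightScheme()
    rng = np.random.default_rng(seed)
    if group not in count_table.counts.columns.get_level_values(0):
        raise EnrichmentError(f"group {group!r} absent from count table")
    obs = count_table.counts[group]
    genes = list(obs.index)
    gs = count_table.sizes[group]
    lam_for = {}
    for model in models:
        gm = (rate_models or {}).get(model, gene_models)
        if not isinstance(gm, Mapping):
            gm = {g.gene: g for g in gm}
        lam_for[model] = _lambda_frame(gm, genes, gs.n_male, gs.n_female)

    out = []
    for model in models:
        lam = lam_for[model]
        if model in ("CH", "TRI"):
            for test in MODEL_TESTS[model]:
                o = obs[test].to_numpy()
                l = lam[test].to_numpy()
                p = np.where(o == 0, 1.0, stats.poisson.sf(o - 1, l))
                out.append(pd.DataFrame(dict(
                    gene=genes, model=model, test=test,
                    observed=o, expected=l, p=p,
                )))
        elif model == "WPT":
            all_classes = ("LGD", "MIS", "MIS30", "SYN")
            # MIS column includes MIS30; split into disjoint strata so the
            # per-class Poissons are independent.
            obs_d = obs.copy()
            obs_d["MIS"] = obs["MIS"] - obs["MIS30"]
            lam_d = lam.copy()
            lam_d["MIS"] = (lam["MIS"] - lam["MIS30"]).clip(lower=0.0)
            p_all = _wpt_pvalues(obs_d, lam_d, all_classes, weights, n_iter, rng)
            p_mis = _wpt_pvalues(
                obs_d, lam_d, ("MIS", "MIS30"), weights, n_iter, rng
            )
            p_clust = np.ones(len(genes))
            if records is not None and len(records):
                rec = records
                if "var_class" not in rec.columns:
                    from .harmonize import _classify_frame

                    rec = _classify_frame(rec)
                rec = _records_for_group(rec, group)
                rec = rec[
                    rec["var_class"].isin(["MIS", "MIS30"])
                    & rec["gene"].isin(genes)
                ]
                by_gene = rec.groupby("gene")["pos"]
                gene_ix = {g: i for i, g in enumerate(genes)}
                for gene, positions in by_gene:
                    if len(positions) >= 2 and gene in gene_models:
                        gm = gene_models[gene]
                        if gm.cds_length >= 1:
                            pos = np.clip(positions.to_numpy(), 1, gm.cds_length)
                            p_clust[gene_ix[gene]] = missense_clustering_test(
                                pos, gm, n_iter=n_iter, seed=rng
                            )
            p_misens = np.array([
                fisher_combine([pm, pc]) for pm, pc in zip(p_mis, p_clust)
            ])
            lam_all = lam.drop(columns="MIS30").sum(axis=1).to_numpy()
            obs_all = obs.drop(columns="MIS30").sum(axis=1).to_numpy()
            obs_mis = obs["MIS"].to_numpy()
            out.append(pd.DataFrame(dict(
                gene=genes, model="WPT", test="allDNV",
                observed=obs_all, expected=lam_all, p=p_all,
            )))
            out.append(pd.DataFrame(dict(
                gene=genes, model="WPT", test="MISens",
                observed=obs_mis, expected=lam["MIS"].to_numpy(), p=p_misens,
            )))
        else:
            raise EnrichmentError(f"unknown model {model!r}")
    return pd.concat(out, ignore_index=True)


def adjust_bh(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with denominator ``m``.

    ``m`` may exceed the number of p-values supplied (the model's gene
    universe, which includes untested zero-count genes whose p is 1).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise EnrichmentError("p-values outside [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise EnrichmentError(f"universe m={m} smaller than {n} p-values")
    if n == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, None, 1.0)
    return q


def fwer_threshold(n_genes: int = EXOME_WIDE_GENES, n_tests: int = N_TESTS,
                   alpha: float = 0.05) -> float:
    """Bonferroni exome-wide significance threshold alpha/(genes x tests)."""
    if n_genes < 1 or n_tests < 1 or not (0 < alpha < 1):
        raise EnrichmentError("invalid Bonferroni parameters")
    return alpha / (n_genes * n_tests)


def model_level_significance(
    results: pd.DataFrame,
    model_universe: Mapping[str, int] | int | None = None,
    combine: str = "min_q",
) -> pd.DataFrame:
    """Collapse per-test results to one (min-p, min-q) pair per gene x model.

    ``combine='min_q'`` computes a per-test BH q over the model's gene
    universe and takes the minimum; ``'min_p_then_fdr'`` takes the minimum p
    across tests first and runs BH once on that minimum.
    """
    if combine not in ("min_q", "min_p_then_fdr"):
        raise EnrichmentError(f"unknown combine rule {combine!r}")
    frames = []
    for model, sub in results.groupby("model"):
        if isinstance(model_universe, Mapping):
            m = model_universe.get(model)
        else:
            m = model_universe
        if m is None:
            m = sub["gene"].nunique()
        if combine == "min_q":
            sub = sub.copy()
            sub["q"] = sub.groupby("test")["p"].transform(
                lambda s: adjust_bh(s.to_numpy(), m)
            )
            agg = sub.groupby("gene").agg(p=("p", "min"), q=("q", "min"))
        else:
            agg = sub.groupby("gene").agg(p=("p", "min"))
            agg["q"] = adjust_bh(agg["p"].to_numpy(), m)
        agg["model"] = model
        frames.append(agg.reset_index())
    return pd.concat(frames, ignore_index=True)


def assign_tiers(
    proband_results: pd.DataFrame,
    sibling_results: pd.DataFrame | None,
    counts: Mapping[str, int] | pd.Series,
    alpha: float = 0.05,
    threshold: float | None = None,
    model_universe: Mapping[str, int] | int | None = None,
    combine: str = "min_q",
    min_dnv_count: int = 3,
) -> pd.DataFrame:
    """Assign LC / MC / HC candidate tiers with sibling exclusion.

    ``counts`` maps gene -> qualifying (LGD + MIS) DNV count in the analysed
    group; "DNV count > 2" is enforced as count >= ``min_dnv_count``.  Genes
    FDR-significant in siblings under any sibling model are removed from all
    tiers and flagged.
    """
    if threshold is None:
        threshold = fwer_threshold()
    counts = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    level = model_level_significance(proband_results, model_universe, combine)
    wide_q = level.pivot(index="gene", columns="model", values="q")
    wide_p = level.pivot(index="gene", columns="model", values="p")
    models = list(wide_q.columns)
    genes = wide_q.index
    cnt = counts.reindex(genes).fillna(0).astype(int)
    enough = cnt >= min_dnv_count

    fdr_sig = wide_q < alpha
    fwer_sig = wide_p < threshold
    lc = fdr_sig.any(axis=1) & enough
    mc = fdr_sig.all(axis=1) & enough
    hc = fwer_sig.all(axis=1) & enough

    excluded = pd.Series(False, index=genes)
    if sibling_results is not None and len(sibling_results):
        sib_level = model_level_significance(
            sibling_results, model_universe, combine
        )
        sib_sig = set(sib_level.loc[sib_level["q"] < alpha, "gene"])
        excluded = genes.to_series().isin(sib_sig)

    tier = np.where(hc, "HC", np.where(mc, "MC", np.where(lc, "LC", "none")))
    tier = np.where(excluded, "none", tier)
    supporting = fdr_sig.apply(lambda r: ",".join(m for m in models if r[m]),
                               axis=1)
    return pd.DataFrame(dict(
        gene=genes,
        tier=tier,
        supporting_models=supporting.to_numpy(),
        dnv_count=cnt.to_numpy(),
        sibling_excluded=excluded.to_numpy(),
        min_p=wide_p.min(axis=1).to_numpy(),
        min_q=wide_q.min(axis=1).to_numpy(),
    )).reset_index(drop=True)
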