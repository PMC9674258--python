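"""2x2 contingency burden comparisons.

Covers the four comparison families of the analysis: per-gene DD-versus-ASD
DNV burden, variant-class bias (LGD versus missense) against the rest of the
exome, female-versus-male burden with X-chromosome copy-number denominators,
and one-sided case-control burden of ultra-rare LGD carriers.  All use
Fisher's exact test; odds ratios are sample (cross-product) ratios with exact
conditional confidence intervals, so zero "exposure" cells print as Inf with
a finite one-sided bound, matching the conventions of the published tables.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .harmonize import CountTable
from .enrichment import adjust_bh

#: Denominator of the Benjamini-Hochberg correction in the burden screens
#: ("corrected for 20,000 genes").
BURDEN_FDR_GENES = 20_000


class BurdenError(ValueError):
    pass


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if b * c > 0:
        return (a * d) / (b * c)
    if a * d > 0:
        return math.inf
    return math.nan  # OR undefined when both diagonals contain a zero


def fisher_2x2(
    a: int, b: int, c: int, d: int,
    sided: str = "two",
    ci_method: str = "conditional",
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact test of [[a, b], [c, d]].

    Returns ``(odds_ratio, (ci_low, ci_high), p)``.  The odds ratio is the
    cross-product estimate; the CI is the exact conditional interval by
    default (``ci_method='woolf'`` selects the asymptotic log-OR interval).
    ``sided`` is ``'two'`` or ``'greater'`` (first row enriched).
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise BurdenError(f"cells must be nonnegative integers, got {cells}")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    alternative = {"two": "two-sided", "greater": "greater", "one": "greater"}[sided]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    orr = _sample_or(a, b, c, d)
    if ci_method == "conditional":
        res = _cond_odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(confidence)
        low, high = float(ci.low), float(ci.high)
    elif ci_method == "woolf":
        if min(cells) == 0:
            low, high = 0.0, math.inf
        else:
            log_or = math.log(orr)
            se = math.sqrt(sum(1.0 / x for x in cells))
            z = stats.norm.ppf(0.5 + confidence / 2)
            low, high = math.exp(log_or - z * se), math.exp(log_or + z * se)
    else:
        raise BurdenError(f"unknown ci_method {ci_method!r}")
    return orr, (low, high), p


def _result_row(gene, comparison, a, b, c, d, sided, **extra) -> dict:
    orr, (lo, hi), p = fisher_2x2(a, b, c, d, sided=sided)
    return dict(
        gene=gene, comparison=comparison, a=a, b=b, c=c, d=d,
        OR=orr, ci_low=lo, ci_high=hi, p=p, sided=sided, **extra,
    )


def phenotype_burden(
    count_table: CountTable,
    n_dd: int | None = None,
    n_asd: int | None = None,
    m: int = BURDEN_FDR_GENES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene DD-versus-ASD DNV burden (two-sided, DD in the top row).

    For every gene, 2x2 tables of [DNV carriers' variant count, samples
    minus count] are tested for total DNVs (LGD+MIS), LGD only and MIS only;
    the ``significant_variant`` column lists which categories pass FDR.
    """
    sizes = count_table.sizes
    n_dd = n_dd if n_dd is not None else sizes["DD"].n
    n_asd = n_asd if n_asd is not None else sizes["ASD"].n
    if n_dd <= 0 or n_asd <= 0:
        raise BurdenError("group sizes must be positive")
    dd = count_table.counts["DD"]
    asd = count_table.counts["ASD"]
    rows = []
    for gene in count_table.counts.index:
        cats = {
            "DNV": (int(dd.at[gene, "LGD"] + dd.at[gene, "MIS"]),
                    int(asd.at[gene, "LGD"] + asd.at[gene, "MIS"])),
            "dnLGD": (int(dd.at[gene, "LGD"]), int(asd.at[gene, "LGD"])),
            "dnMIS": (int(dd.at[gene, "MIS"]), int(asd.at[gene, "MIS"])),
        }
        for cat, (x_dd, x_asd) in cats.items():
            rows.append(_result_row(
                gene, "DD_vs_ASD", x_dd, n_dd - x_dd, x_asd, n_asd - x_asd,
                "two", category=cat,
            ))
    out = pd.DataFrame(rows)
    out["q"] = out.groupby("category")["p"].transform(
        lambda s: adjust_bh(s.to_numpy(), m)
    )
    sig = out[out["q"] < alpha].groupby("gene")["category"].agg(
        lambda cats: "&".join(
            c for c in ("DNV", "dnLGD", "dnMIS") if c in set(cats)
        )
    )
    out["significant_variant"] = out["gene"].map(sig).fillna("")
    return out


def class_bias(
    count_table: CountTable,
    group: str = "NDD",
    m: int = BURDEN_FDR_GENES,
) -> pd.DataFrame:
    """Per-gene LGD-versus-missense bias against the exome-wide background.

    Each gene's (LGD, MIS) counts are compared with the summed counts of all
    other genes in the group (two-sided).  Genes whose DNVs are all of one
    class are flagged in ``pattern`` (e.g. LGD-exclusive).
    """
    sub = count_table.counts[group]
    tot_lgd = int(sub["LGD"].sum())
    tot_mis = int(sub["MIS"].sum())
    rows = []
    for gene in sub.index:
        g_lgd, g_mis = int(sub.at[gene, "LGD"]), int(sub.at[gene, "MIS"])
        if g_lgd > tot_lgd or g_mis > tot_mis:
            raise BurdenError("genome totals smaller than gene counts")
        pattern = ""
        if g_lgd + g_mis > 0:
            if g_mis == 0:
                pattern = "LGD-exclusive"
            elif g_lgd == 0:
                pattern = "MIS-exclusive"
        rows.append(_result_row(
            gene, "LGD_vs_MIS",
            g_lgd, g_mis, tot_lgd - g_lgd, tot_mis - g_mis,
            "two", pattern=pattern,
        ))
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy(), m)
    return out


def sex_burden(
    count_table: CountTable | None = None,
    n_male: int | None = None,
    n_female: int | None = None,
    m: int = BURDEN_FDR_GENES,
    counts: pd.DataFrame | None = None,
    gene_chrom: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Female-versus-male DNV burden with chromosome-copy denominators.

    Denominators are chromosome copies, not samples: two per sample on
    autosomes for both sexes; on chromosome X one copy per male and two per
    female.  Females occupy the top row, so OR > 1 flags female excess.
    Either a full :class:`CountTable` (with its male/female groups) or an
    explicit per-gene frame with ``F`` and ``M`` DNV-count columns may be
    supplied.
    """
    if count_table is not None:
        fem = count_table.counts["female"]
        mal = count_table.counts["male"]
        counts = pd.DataFrame({
            "F": fem["LGD"] + fem["MIS"],
            "M": mal["LGD"] + mal["MIS"],
        })
        n_male = n_male if n_male is not None else count_table.sizes["male"].n
        n_female = (n_female if n_female is not None
                    else count_table.sizes["female"].n)
        gene_chrom = count_table.gene_chrom
    if counts is None or n_male is None or n_female is None:
        raise BurdenError("need a count table or explicit counts and sizes")
    gene_chrom = gene_chrom or {}
    rows = []
    for gene, row in counts.iterrows():
        chrom = str(gene_chrom.get(gene, "autosome")).upper()
        if chrom in ("X",):
            copies_f, copies_m = 2 * n_female, n_male
        elif chrom in ("Y", "MT", "M"):
            raise BurdenError(f"unsupported chromosome {chrom!r} for {gene}")
        else:
            copies_f, copies_m = 2 * n_female, 2 * n_male
        f, mm = int(row["F"]), int(row["M"])
        r = _result_row(
            gene, "F_vs_M", f, copies_f - f, mm, copies_m - mm, "two",
            chrom=chrom,
        )
        r["female_excess"] = r["OR"] > 1 if np.isfinite(r["OR"]) else (f > 0)
        rows.append(r)
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy(), m)
    return out


def case_control_burden(
    carriers: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    maf_threshold: float = 1e-4,
) -> pd.DataFrame:
    """One-sided (greater-in-cases) ultra-rare LGD carrier burden per gene.

    ``carriers`` has one row per gene with ``case`` and ``control`` carrier
    counts, already filtered to ultra-rare variants (the MAF threshold is
    recorded as metadata only).  FDR is computed over the genes tested.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise BurdenError("cohort sizes must be positive")
    rows = []
    for gene, row in carriers.iterrows():
        a, c = int(row["case"]), int(row["control"])
        if a > n_cases or c > n_controls:
            raise BurdenError(f"{gene}: carriers exceed cohort size")
        rows.append(_result_row(
            gene, "case_vs_control", a, n_cases - a, c, n_controls - c,
            "greater",
        ))
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy())
    out.attrs["maf_threshold"] = maf_threshold
    return out


def fold_enrichment(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Per-sample frequency ratio (count_a/n_a)/(count_b/n_b), 2 decimals."""
    if n_a <= 0 or n_b <= 0:
        raise BurdenError("sample sizes must be positive")
    if count_b == 0:
        import warnings

        warnings.warn("zero counts in the reference group; ratio is infinite")
        return math.inf
    return round((count_a / n_a) / (count_b / n_b), 2)
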