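"""Per-gene, per-class expected de novo mutation rates.

Two rate flavors are produced from a coding sequence: a transition /
transversion / indel parameterisation calibrated against a genome-wide
divergence target ("CH-style"), and a trinucleotide-context table flavor.
Both reduce to the same substrate: enumeration of all 3L single-base
substitutions of a CDS and their coding consequences.  Rates are per haploid
copy per generation; cohort expectations apply the X-dosage convention of one
copy in males and two in females.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

# Standard codon table; '*' marks stop.
from Bio.Data.CodonTable import standard_dna_table as _STANDARD_TABLE

_CODON = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON[_stop] = "*"

#: Default frameshift-indel rate expressed as a multiple of the gene's
#: nonsense (stop-gain) SNV rate — the usual convention in trinucleotide
#: mutation-rate frameworks.
DEFAULT_INDEL_MULTIPLIER = 1.3

#: Default fraction of the missense rate attributed to severe missense
#: (CADD > 30); roughly the genome-wide share of severe missense DNVs.
DEFAULT_MIS30_FRACTION = 0.18


class RateModelError(ValueError):
    """Invalid input to a mutation-rate computation."""


@dataclass
class GeneModel:
    """Per-gene mutation rates (per haploid copy per generation)."""

    gene: str
    chromosome: str
    cds_length: int
    mu_lgd: float
    mu_mis: float
    mu_mis30: float
    mu_syn: float
    #: optional per-site missense rate vector (length = cds_length) used by
    #: the clustering null; uniform when absent.
    site_mis_rates: np.ndarray | None = None

    def mu(self, cls: str) -> float:
        try:
            return {
                "LGD": self.mu_lgd, "MIS": self.mu_mis,
                "MIS30": self.mu_mis30, "SYN": self.mu_syn,
            }[cls]
        except KeyError:
            raise RateModelError(f"unknown variant class {cls!r}") from None

    def __post_init__(self) -> None:
        for name in ("mu_lgd", "mu_mis", "mu_mis30", "mu_syn"):
            if getattr(self, name) < 0:
                raise RateModelError(f"{self.gene}: negative rate {name}")
        if self.mu_mis30 > self.mu_mis + 1e-12:
            raise RateModelError(f"{self.gene}: mu_mis30 exceeds mu_mis")


def is_transition(ref: str, alt: str) -> bool:
    return (ref in _PURINES) == (alt in _PURINES)


def enumerate_cds_events(cds: str) -> pd.DataFrame:
    """Enumerate all 3L single-base substitutions of a CDS.

    Returns a frame with columns ``pos`` (0-based), ``ref``, ``alt``,
    ``cls`` in {LGD, MIS, SYN, other} (stop-gain is LGD, stop-loss is other)
    and ``transition``.
    """
    cds = str(cds).upper()
    if len(cds) == 0 or len(cds) % 3:
        raise RateModelError(
            f"CDS length {len(cds)} is empty or not a multiple of 3"
        )
    if set(cds) - set(_BASES):
        raise RateModelError(f"non-ACGT character(s) in CDS: {set(cds) - set(_BASES)}")
    rows = []
    for i, ref in enumerate(cds):
        codon_start = 3 * (i // 3)
        codon = cds[codon_start:codon_start + 3]
        offset = i - codon_start
        aa = _CODON[codon]
        for alt in _BASES:
            if alt == ref:
                continue
            new = codon[:offset] + alt + codon[offset + 1:]
            new_aa = _CODON[new]
            if new_aa == aa:
                cls = "SYN"
            elif new_aa == "*":
                cls = "LGD"
            elif aa == "*":
                cls = "other"  # stop-loss
            else:
                cls = "MIS"
            rows.append((i, ref, alt, cls, is_transition(ref, alt)))
    return pd.DataFrame(
        rows, columns=["pos", "ref", "alt", "cls", "transition"]
    )


@dataclass
class ContextRateTable:
    """Trinucleotide-context SNV rates: (64 contexts x 3 alternates).

    ``rates[(context, alt)]`` is the per-site per-generation substitution
    rate for the middle base of ``context`` mutating to ``alt``.
    """

    rates: Mapping[tuple[str, str], float]
    indel_multiplier: float = DEFAULT_INDEL_MULTIPLIER

    def __post_init__(self) -> None:
        for (ctx, alt), r in self.rates.items():
            if r < 0:
                raise RateModelError(f"negative rate for {ctx}>{alt}")

    def validate_complete(self) -> None:
        for ctx in ("".join(t) for t in product(_BASES, repeat=3)):
            for alt in _BASES:
                if alt != ctx[1] and (ctx, alt) not in self.rates:
                    raise RateModelError(f"missing context entry {ctx}>{alt}")

    @classmethod
    def uniform(cls, rate: float, indel_multiplier: float = DEFAULT_INDEL_MULTIPLIER
                ) -> "ContextRateTable":
        rates = {
            ("".join(t), alt): rate
            for t in product(_BASES, repeat=3)
            for alt in _BASES if alt != t[1]
        }
        return cls(rates=rates, indel_multiplier=indel_multiplier)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "ContextRateTable":
        frame = pd.read_csv(path, sep="\t")
        rates = {
            (str(c).upper(), str(a).upper()): float(r)
            for c, a, r in frame[["context", "alt", "rate"]].itertuples(index=False)
        }
        return cls(rates=rates, **kw)


def _class_sums(events: pd.DataFrame, rate_of_event) -> dict[str, float]:
    sums = {"LGD": 0.0, "MIS": 0.0, "SYN": 0.0, "other": 0.0}
    for row in events.itertuples(index=False):
        sums[row.cls] += rate_of_event(row)
    return sums


def context_rates(
    cds: str,
    table: ContextRateTable,
    gene: str = "",
    chromosome: str = "autosome",
    mis30_fraction: float = DEFAULT_MIS30_FRACTION,
    flank5: str = "A",
    flank3: str = "A",
) -> GeneModel:
    """Trinucleotide-context per-gene rates.

    The CDS is padded with one flanking base on each side (supplied or the
    configured default) so terminal sites have a context.  The LGD rate adds
    a frameshift-indel term: ``indel_multiplier`` times the nonsense SNV
    rate.  The severe-missense rate is ``mis30_fraction`` of the missense
    rate (per-site severity scoring is outside this model).
    """
    events = enumerate_cds_events(cds)
    padded = (flank5 + str(cds).upper() + flank3)

    def rate_of(row):
        ctx = padded[row.pos:row.pos + 3]
        key = (ctx, row.alt)
        if key not in table.rates:
            raise RateModelError(f"missing context entry {ctx}>{row.alt}")
        return table.rates[key]

    sums = _class_sums(events, rate_of)
    mu_lgd = sums["LGD"] * (1.0 + table.indel_multiplier)
    mu_mis = sums["MIS"]
    n_sites = len(cds)
    site = np.full(n_sites, mu_mis / n_sites) if mu_mis > 0 else None
    return GeneModel(
        gene=gene, chromosome=chromosome, cds_length=n_sites,
        mu_lgd=mu_lgd, mu_mis=mu_mis, mu_mis30=mis30_fraction * mu_mis,
        mu_syn=sums["SYN"], site_mis_rates=site,
    )


def ch_rates(
    cds: str,
    transition_rate: float,
    transversion_rate: float,
    indel_rate: float = 0.0,
    calibration: float = 1.0,
    gene: str = "",
    chromosome: str = "autosome",
    mis30_fraction: float = DEFAULT_MIS30_FRACTION,
) -> GeneModel:
    """Transition/transversion/indel per-gene rates with divergence scaling.

    Each enumerated substitution contributes the transition or transversion
    per-site rate; the frameshift term is ``indel_rate`` per site times the
    CDS length.  All class rates are multiplied by the divergence calibration
    constant (see :func:`calibrate`).
    """
    for name, value in (
        ("transition_rate", transition_rate),
        ("transversion_rate", transversion_rate),
        ("indel_rate", indel_rate),
    ):
        if value < 0:
            raise RateModelError(f"negative {name}")
    events = enumerate_cds_events(cds)
    sums = _class_sums(
        events,
        lambda row: transition_rate if row.transition else transversion_rate,
    )
    C = calibration
    mu_lgd = C * (sums["LGD"] + indel_rate * len(cds))
    mu_mis = C * sums["MIS"]
    return GeneModel(
        gene=gene, chromosome=chromosome, cds_length=len(cds),
        mu_lgd=mu_lgd, mu_mis=mu_mis, mu_mis30=mis30_fraction * mu_mis,
        mu_syn=C * sums["SYN"],
    )


def calibrate(
    gene_models: Iterable[GeneModel],
    cohort_size: int,
    target_total: float,
    reference_class: str = "SYN",
) -> float:
    """Scaling constant making the genome-wide reference-class expectation
    over a diploid cohort of ``cohort_size`` equal ``target_total`` exactly."""
    denom = sum(2.0 * cohort_size * g.mu(reference_class) for g in gene_models)
    if denom <= 0:
        raise RateModelError("zero genome-wide expectation; cannot calibrate")
    return target_total / denom


def scale_models(gene_models: Iterable[GeneModel], C: float) -> list[GeneModel]:
    """Apply a calibration constant to every class rate of every gene."""
    return [
        GeneModel(
            gene=g.gene, chromosome=g.chromosome, cds_length=g.cds_length,
            mu_lgd=C * g.mu_lgd, mu_mis=C * g.mu_mis,
            mu_mis30=C * g.mu_mis30, mu_syn=C * g.mu_syn,
            site_mis_rates=None if g.site_mis_rates is None
            else C * g.site_mis_rates,
        )
        for g in gene_models
    ]


def expected_count(
    gene_model: GeneModel, cls: str, n_male: int, n_female: int
) -> float:
    """Cohort expectation λ = copies × μ_class.

    Autosomes carry two copies per person; chromosome X carries one copy in
    males and two in females.
    """
    if n_male < 0 or n_female < 0:
        raise RateModelError("negative sample counts")
    mu = gene_model.mu(cls)
    if str(gene_model.chromosome).upper() == "X":
        copies = n_male + 2 * n_female
    else:
        copies = 2 * (n_male + n_female)
    return copies * mu


def models_to_frame(gene_models: Iterable[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene=g.gene, chrom=g.chromosome, cds_length=g.cds_length,
                mu_lgd=g.mu_lgd, mu_mis=g.mu_mis, mu_mis30=g.mu_mis30,
                mu_syn=g.mu_syn,
            )
            for g in gene_models
        ]
    ).set_index("gene")


def frame_to_models(frame: pd.DataFrame) -> list[GeneModel]:
    frame = frame.reset_index() if frame.index.name == "gene" else frame
    return [
        GeneModel(
            gene=str(r.gene), chromosome=str(r.chrom),
            cds_length=int(getattr(r, "cds_length", 0) or 0),
            mu_lgd=float(r.mu_lgd), mu_mis=float(r.mu_mis),
            mu_mis30=float(r.mu_mis30), mu_syn=float(r.mu_syn),
        )
        for r in frame.itertuples(index=False)
    ]


def read_rate_table(path: str | Path) -> list[GeneModel]:
    """Read a precomputed per-gene rate TSV (gene, chrom, mu_* columns)."""
    return frame_to_models(pd.read_csv(path, sep="\t"))


def write_rate_table(gene_models: Iterable[GeneModel], path: str | Path) -> None:
    models_to_frame(gene_models).to_csv(path, sep="\t")


def models_from_fasta(
    path: str | Path,
    table: ContextRateTable | None = None,
    ch_params: Mapping[str, float] | None = None,
    x_genes: Iterable[str] = (),
    **kw,
) -> list[GeneModel]:
    """Build gene models from a CDS FASTA (one record per gene, id = symbol)."""
    from Bio import SeqIO

    if (table is None) == (ch_params is None):
        raise RateModelError("supply exactly one of `table` or `ch_params`")
    x_genes = set(x_genes)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chrom = "X" if rec.id in x_genes else "autosome"
        if table is not None:
            out.append(context_rates(str(rec.seq), table, gene=rec.id,
                                     chromosome=chrom, **kw))
        else:
            out.append(ch_rates(str(rec.seq), gene=rec.id, chromosome=chrom,
                                **dict(ch_params), **kw))
    return out
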