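"""Synthetic trio cohorts and expression matrices.

Generates multi-cohort DNV tables with the statistical structure the
analysis assumes: per-gene per-class mutation rates drawn on a log scale and
normalised to configured per-proband DNV rates, ASD / DD / sibling trio
groups with male and female children, autosomal and X-linked genes with the
one-copy-male / two-copy-female dosage convention, Poisson DNV counts per
(child, gene, class), and a planted set of risk genes with elevated
class-specific relative risks.  Everything is deterministic given the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import DNV_COLUMNS
from .mutation_model import GeneModel

_LGD_TERMS = (
    "frameshift_variant", "stop_gained", "splice_donor_variant",
    "splice_acceptor_variant",
)


class ConfigError(ValueError):
    """A simulation parameter violates its contract."""


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic trio cohort.

    Cohort sizes default to the integrated NDD meta-analysis design (15,560
    ASD and 31,052 DD probands, 5,241 unaffected siblings); per-proband DNV
    rates default to the harmonized genome-wide class rates of that cohort
    (0.148 LGD, 0.703 missense — 18.1% of it severe — and 0.251 synonymous
    DNVs per proband over a diploid exome).
    """

    n_genes: int = 19_618
    n_asd: int = 15_560
    n_dd: int = 31_052
    n_sibling: int = 5_241
    male_fraction: float = 0.6425
    x_linked_fraction: float = 0.04
    #: per-proband (diploid) DNV rate targets per class; MIS includes MIS30.
    target_rates: Mapping[str, float] = field(
        default_factory=lambda: {"LGD": 0.148, "MIS": 0.703, "SYN": 0.251}
    )
    mis30_fraction: float = 0.181
    #: log-scale spread of the per-gene rate distribution.
    rate_log_sigma: float = 1.0
    #: CDS length distribution (log-scale location/spread, bases).
    cds_log_mean: float = 7.3
    cds_log_sigma: float = 0.6
    n_risk_genes: int = 0
    relative_risk_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"LGD": (10.0, 50.0), "MIS": (10.0, 50.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_asd", "n_dd", "n_sibling", "n_risk_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("male_fraction", "x_linked_fraction", "mis30_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if any(r < 0 for r in self.target_rates.values()):
            raise ConfigError("target_rates must be nonnegative")
        for name in ("rate_log_sigma", "cds_log_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_risk_genes > self.n_genes:
            raise ConfigError("n_risk_genes exceeds n_genes")
        for cls, (lo, hi) in self.relative_risk_ranges.items():
            if lo < 1.0 or hi < lo:
                raise ConfigError(
                    f"relative-risk range for {cls} must satisfy 1 <= lo <= hi"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ConfigError("config must specify a seed")
        if "relative_risk_ranges" in raw:
            raw["relative_risk_ranges"] = {
                k: tuple(v) for k, v in raw["relative_risk_ranges"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = asdict(self)
        data["target_rates"] = dict(self.target_rates)
        data["relative_risk_ranges"] = {
            k: list(v) for k, v in self.relative_risk_ranges.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class TrueArchitecture:
    """Ground-truth genetic architecture of a simulated cohort.

    ``relative_risk[gene][cls]`` multiplies the per-copy mutation rate of
    that class in probands; unlisted genes are null (RR exactly 1).
    Optional per-gene sex multipliers scale proband risk by child sex.
    """

    relative_risk: dict[str, dict[str, float]] = field(default_factory=dict)
    sex_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)

    def rr(self, gene: str, cls: str) -> float:
        base = "MIS" if cls == "MIS30" else cls
        return float(self.relative_risk.get(gene, {}).get(base, 1.0))

    def sex_mult(self, gene: str, sex: str) -> float:
        return float(self.sex_multipliers.get(gene, {}).get(sex, 1.0))

    @property
    def risk_genes(self) -> list[str]:
        return sorted(self.relative_risk)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), stream])


def make_gene_models(config: SimConfig) -> list[GeneModel]:
    """Draw per-gene per-class mutation rates and chromosome assignments.

    Per-gene rates are lognormal weights normalised so that the diploid
    genome-wide expectation sums exactly to the configured per-proband class
    rates.  A configured fraction of genes is X-linked; the rest are spread
    over the autosomes.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    if n == 0:
        return []
    names = [f"G{i:05d}" for i in range(n)]
    n_x = int(round(config.x_linked_fraction * n))
    x_idx = set(rng.choice(n, size=n_x, replace=False).tolist())
    chroms = [
        "X" if i in x_idx else str(rng.integers(1, 23)) for i in range(n)
    ]
    lengths = 3 * np.maximum(
        (np.exp(rng.normal(config.cds_log_mean, config.cds_log_sigma, n)) / 3)
        .round().astype(int), 30,
    )
    mu = {}
    for cls in ("LGD", "MIS", "SYN"):
        w = np.exp(rng.normal(0.0, config.rate_log_sigma, n))
        mu[cls] = config.target_rates.get(cls, 0.0) * w / (2.0 * w.sum())
    return [
        GeneModel(
            gene=names[i], chromosome=chroms[i], cds_length=int(lengths[i]),
            mu_lgd=float(mu["LGD"][i]), mu_mis=float(mu["MIS"][i]),
            mu_mis30=float(config.mis30_fraction * mu["MIS"][i]),
            mu_syn=float(mu["SYN"][i]),
        )
        for i in range(n)
    ]


def plant_architecture(
    gene_models: Sequence[GeneModel], config: SimConfig
) -> TrueArchitecture:
    """Select risk genes and draw their class-specific relative risks."""
    if config.n_risk_genes > len(gene_models):
        raise ConfigError("n_risk_genes exceeds the number of genes")
    rng = _rng(config, 1)
    if config.n_risk_genes == 0:
        return TrueArchitecture()
    chosen = rng.choice(
        len(gene_models), size=config.n_risk_genes, replace=False
    )
    rr: dict[str, dict[str, float]] = {}
    for i in sorted(chosen.tolist()):
        gene = gene_models[i].gene
        rr[gene] = {
            cls: float(rng.uniform(lo, hi))
            for cls, (lo, hi) in config.relative_risk_ranges.items()
        }
    return TrueArchitecture(relative_risk=rr)


def _copies(chrom: str, sex: str) -> int:
    if str(chrom).upper() == "X":
        return 1 if sex == "male" else 2
    return 2


# Disjoint simulation strata: MIS is split into severe (CADD > 30) and
# non-severe missense so the two can carry the proper rate split.
_STRATA = ("LGD", "MIS_low", "MIS30", "SYN")


def _stratum_mu(g: GeneModel, stratum: str) -> float:
    return {
        "LGD": g.mu_lgd,
        "MIS_low": max(g.mu_mis - g.mu_mis30, 0.0),
        "MIS30": g.mu_mis30,
        "SYN": g.mu_syn,
    }[stratum]


def simulate_cohort(
    gene_models: Sequence[GeneModel],
    architecture: TrueArchitecture | None,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-group trio DNV table plus its sample manifest.

    Each (child, gene, class) count is Poisson with mean
    ``copies x mu_class x RR`` where copies follow the X-dosage convention;
    group totals are drawn at once and assigned to children uniformly,
    which yields the identical joint law.  Returns ``(records, manifest)``
    in the harmonize module's TSV dialect.
    """
    architecture = architecture or TrueArchitecture()
    rng = _rng(config, 2)
    groups = (
        ("ASD", config.n_asd, True),
        ("DD", config.n_dd, True),
        ("sibling", config.n_sibling, False),
    )
    manifest_rows = []
    record_parts = []
    genes = np.array([g.gene for g in gene_models])
    chroms = np.array([g.chromosome for g in gene_models])
    lengths = np.array([max(g.cds_length, 3) for g in gene_models])

    for phenotype, n, affected in groups:
        n_male = int(round(config.male_fraction * n))
        n_female = n - n_male
        ids = np.array([f"{phenotype}_{i:06d}" for i in range(n)])
        sexes = np.array(["male"] * n_male + ["female"] * n_female)
        for sid, sex in zip(ids, sexes):
            manifest_rows.append(
                dict(sample_id=sid, cohort="sim", phenotype=phenotype,
                     sex=sex, platform="exome")
            )
        for sex, sex_n, sex_lo in (
            ("male", n_male, 0), ("female", n_female, n_male)
        ):
            if sex_n == 0:
                continue
            copies = np.array([_copies(c, sex) for c in chroms])
            for stratum in _STRATA:
                base_cls = {"MIS_low": "MIS", "MIS30": "MIS"}.get(
                    stratum, stratum
                )
                mu = np.array([_stratum_mu(g, stratum) for g in gene_models])
                if affected:
                    rr = np.array([
                        architecture.rr(g, base_cls)
                        * architecture.sex_mult(g, sex)
                        for g in genes
                    ])
                else:
                    rr = 1.0
                lam = sex_n * copies * mu * rr
                counts = rng.poisson(lam)
                total = int(counts.sum())
                if total == 0:
                    continue
                gene_idx = np.repeat(np.arange(len(genes)), counts)
                child = rng.integers(sex_lo, sex_lo + sex_n, total)
                pos = (
                    rng.random(total) * lengths[gene_idx]
                ).astype(np.int64) + 1
                if stratum == "LGD":
                    csq = rng.choice(_LGD_TERMS, total)
                    cadd = rng.uniform(20.0, 60.0, total)
                elif stratum == "MIS_low":
                    csq = np.full(total, "missense_variant")
                    cadd = rng.uniform(0.0, 30.0, total)
                elif stratum == "MIS30":
                    csq = np.full(total, "missense_variant")
                    cadd = rng.uniform(30.5, 60.0, total)
                else:
                    csq = np.full(total, "synonymous_variant")
                    cadd = rng.uniform(0.0, 15.0, total)
                ref = rng.choice(list("ACGT"), total)
                alt_shift = rng.integers(1, 4, total)
                bases = np.array(list("ACGT"))
                base_ix = np.searchsorted(bases, ref)
                alt = bases[(base_ix + alt_shift) % 4]
                record_parts.append(pd.DataFrame(dict(
                    sample_id=ids[child],
                    cohort="sim",
                    phenotype=phenotype,
                    sex=sex,
                    chrom=chroms[gene_idx],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=genes[gene_idx],
                    consequence=csq,
                    cadd=np.round(cadd, 2),
                    platform="exome",
                )))
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "cohort", "phenotype", "sex", "platform"],
    )
    if record_parts:
        records = pd.concat(record_parts, ignore_index=True)
    else:
        records = pd.DataFrame(columns=list(DNV_COLUMNS))
        records["pos"] = records["pos"].astype(np.int64)
        records["cadd"] = records["cadd"].astype(float)
    return records, manifest


def simulate_expression(
    genes: Sequence[str],
    signature_genes: Sequence[str],
    cell_types: Sequence[str] = ("EN", "IN", "OPC", "astro"),
    target_cell_types: Sequence[str] = ("EN",),
    n_cells_per_type: int = 50,
    effect_size_sd: float = 0.0,
    log_mean: float = 2.0,
    log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x cells expression matrix with cell-type labels.

    Baseline expression is lognormal per gene; signature genes are shifted
    upward by ``effect_size_sd`` standard deviations (log scale) in the
    target cell types.  Returns ``(matrix, cell_type_labels)``.
    """
    genes = list(genes)
    unknown = set(signature_genes) - set(genes)
    if unknown:
        raise ConfigError(
            f"signature gene(s) outside the gene set: {sorted(unknown)[:10]}"
        )
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    cells, labels = [], []
    for ct in cell_types:
        for i in range(n_cells_per_type):
            cells.append(f"{ct}_{i:04d}")
            labels.append(ct)
    label_s = pd.Series(labels, index=cells, name="cell_type")
    base = rng.normal(log_mean, log_sd, size=len(genes))
    log_expr = (
        base[:, None] + rng.normal(0.0, log_sd / 2, (len(genes), len(cells)))
    )
    sig_rows = [genes.index(g) for g in signature_genes]
    target_cols = np.array([lb in set(target_cell_types) for lb in labels])
    if sig_rows and target_cols.any() and effect_size_sd:
        log_expr[np.ix_(sig_rows, np.flatnonzero(target_cols))] += (
            effect_size_sd * log_sd
        )
    matrix = pd.DataFrame(
        np.exp(log_expr), index=pd.Index(genes, name="gene"), columns=cells
    )
    return matrix, label_s


def subsample_cohort(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    group: str,
    target_n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Downsample one phenotype group to exactly ``target_n`` samples."""
    members = manifest.loc[manifest["phenotype"] == group, "sample_id"]
    if target_n > len(members):
        raise ConfigError(
            f"target_n={target_n} exceeds group size {len(members)}"
        )
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    keep = set(rng.choice(members.to_numpy(), size=target_n, replace=False))
    man = manifest[
        (manifest["phenotype"] != group) | manifest["sample_id"].isin(keep)
    ].reset_index(drop=True)
    rec = records[
        records["sample_id"].isin(set(man["sample_id"]))
    ].reset_index(drop=True)
    return rec, man


def upsample_cohort(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    group: str,
    target_n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap-upsample one group to ``target_n`` by resampling probands
    with replacement under fresh sample identifiers."""
    members = manifest.loc[manifest["phenotype"] == group]
    if target_n < len(members):
        raise ConfigError("target_n below current size; use subsample_cohort")
    extra = target_n - len(members)
    if extra == 0:
        return records.copy(), manifest.copy()
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    picks = rng.choice(members["sample_id"].to_numpy(), size=extra, replace=True)
    man_ix = manifest.set_index("sample_id")
    new_rows, new_recs = [], []
    for j, src in enumerate(picks):
        new_id = f"{src}_bs{j:05d}"
        row = man_ix.loc[src].to_dict()
        row["sample_id"] = new_id
        new_rows.append(row)
        sub = records[records["sample_id"] == src].copy()
        sub["sample_id"] = new_id
        new_recs.append(sub)
    man = pd.concat([manifest, pd.DataFrame(new_rows)], ignore_index=True)
    rec = pd.concat([records, *new_recs], ignore_index=True)
    return rec, man
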