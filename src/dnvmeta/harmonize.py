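"""Ingest, classify, deduplicate, filter and count de novo variants (DNVs).

Everything downstream of this module consumes either the validated DNV record
table (one row per de novo variant) or the grouped :class:`CountTable` built by
:func:`count_dnvs`.  Coordinates are 1-based inclusive for variants and 0-based
half-open for BED blacklists; the conversion happens in :func:`filter_dnvs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Variant classes used throughout the pipeline.  MIS30 (missense with CADD
#: phred > 30) is a flagged subset of MIS: wherever per-class counts are
#: reported, the MIS column includes the MIS30 variants.
CLASSES = ("LGD", "MIS", "MIS30", "SYN")

PHENOTYPES = ("ASD", "DD", "sibling")
SEXES = ("male", "female", "unknown")
PLATFORMS = ("exome", "genome")

#: Mandatory columns of the DNV TSV dialect.
DNV_COLUMNS = (
    "sample_id", "cohort", "phenotype", "sex", "chrom", "pos",
    "ref", "alt", "gene", "consequence", "cadd", "platform",
)

MANIFEST_COLUMNS = ("sample_id", "cohort", "phenotype", "sex", "platform")

# Heterogeneous annotation dialects are normalised onto a small internal
# vocabulary before severity ranking.
_CONSEQUENCE_SYNONYMS = {
    "frameshift_variant": "frameshift",
    "frameshift": "frameshift",
    "stop_gained": "stop-gain",
    "stop_gain": "stop-gain",
    "stop-gain": "stop-gain",
    "nonsense": "stop-gain",
    "splice_donor_variant": "splice-donor",
    "splice_donor": "splice-donor",
    "splice-donor": "splice-donor",
    "splice_acceptor_variant": "splice-acceptor",
    "splice_acceptor": "splice-acceptor",
    "splice-acceptor": "splice-acceptor",
    "missense_variant": "missense",
    "missense": "missense",
    "synonymous_variant": "synonymous",
    "synonymous": "synonymous",
}

_LGD_TERMS = {"frameshift", "stop-gain", "splice-donor", "splice-acceptor"}

# Severity order for multi-consequence annotations (most deleterious wins).
_SEVERITY = {"LGD": 3, "MIS": 2, "SYN": 1, "other": 0}

#: CADD phred threshold above which (strictly) a missense variant counts as
#: severe missense (MIS30).
CADD_SEVERE_THRESHOLD = 30.0


class ValidationError(ValueError):
    """A DNV or manifest table violates the input contract."""


def classify_variant(consequence: str, cadd: float = 0.0) -> str:
    """Classify one variant into LGD / MIS / MIS30 / SYN / other.

    ``consequence`` may carry several ``&``- or ``,``-joined terms; the most
    severe one is used.  Missense variants with CADD phred strictly greater
    than 30 are classified MIS30 (a subset of MIS for counting purposes).
    """
    if not consequence:
        raise ValidationError("empty consequence term")
    best, best_rank = "other", -1
    for term in str(consequence).replace(",", "&").split("&"):
        norm = _CONSEQUENCE_SYNONYMS.get(term.strip().lower())
        if norm in _LGD_TERMS:
            cls = "LGD"
        elif norm == "missense":
            cls = "MIS"
        elif norm == "synonymous":
            cls = "SYN"
        else:
            cls = "other"
        if _SEVERITY[cls] > best_rank:
            best, best_rank = cls, _SEVERITY[cls]
    if best == "other":
        logger.debug("unclassified consequence %r mapped to 'other'", consequence)
    if best == "MIS" and float(cadd) > CADD_SEVERE_THRESHOLD:
        return "MIS30"
    return best


def _classify_frame(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["var_class"] = [
        classify_variant(c, q) for c, q in zip(out["consequence"], out["cadd"])
    ]
    return out


def _validate_enum(frame: pd.DataFrame, column: str, allowed: Sequence[str]) -> None:
    bad = frame.loc[~frame[column].isin(allowed), column]
    if len(bad):
        lines = ", ".join(
            f"line {i + 2}: {v!r}" for i, v in bad.head(20).items()
        )
        raise ValidationError(
            f"unknown {column} token(s) ({len(bad)} row(s)): {lines}"
        )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a DNV table against the record contract; returns a copy."""
    missing = [c for c in DNV_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    out = records.loc[:, list(DNV_COLUMNS)].copy()
    for col, allowed in (
        ("phenotype", PHENOTYPES), ("sex", SEXES), ("platform", PLATFORMS)
    ):
        out[col] = out[col].astype(str)
        _validate_enum(out, col, allowed)
    out["pos"] = pd.to_numeric(out["pos"], errors="raise").astype(np.int64)
    if (out["pos"] < 1).any():
        bad = out.index[out["pos"] < 1].tolist()[:20]
        raise ValidationError(f"position < 1 at row(s) {bad}")
    out["cadd"] = pd.to_numeric(out["cadd"], errors="raise").astype(float)
    if (out["cadd"] < 0).any():
        raise ValidationError("negative CADD score(s)")
    out["chrom"] = out["chrom"].astype(str).str.removeprefix("chr")
    return out.reset_index(drop=True)


def parse_dnv_input(
    path: str | Path,
    format: str = "tsv",
    manifest: pd.DataFrame | None = None,
    info_keys: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read DNVs from a TSV (the native dialect) or a minimal annotated VCF.

    VCF ingestion expects single-sample records with gene / consequence / CADD
    INFO keys (names configurable through ``info_keys``: ``gene``, ``csq``,
    ``cadd``); phenotype, sex and platform are joined in from ``manifest``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if frame.empty:
            return validate_records(
                pd.DataFrame(columns=list(DNV_COLUMNS))
            ) if set(DNV_COLUMNS) <= set(frame.columns) else _empty_records()
        return validate_records(frame)
    if format == "vcf":
        return _parse_vcf(path, manifest, info_keys or {})
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _empty_records() -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in DNV_COLUMNS})
    frame["pos"] = frame["pos"].astype(np.int64)
    frame["cadd"] = frame["cadd"].astype(float)
    return frame


def _parse_vcf(
    path: Path, manifest: pd.DataFrame | None, info_keys: Mapping[str, str]
) -> pd.DataFrame:
    import pysam

    gene_key = info_keys.get("gene", "GENE")
    csq_key = info_keys.get("csq", "CSQ")
    cadd_key = info_keys.get("cadd", "CADD")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValidationError(
                f"expected a single-sample VCF, found {len(samples)} samples"
            )
        sample = samples[0]
        for rec in vcf:
            info = rec.info
            if gene_key not in info or csq_key not in info:
                raise ValidationError(
                    f"record {rec.chrom}:{rec.pos} lacks INFO/{gene_key} or "
                    f"INFO/{csq_key}"
                )
            gene = info[gene_key]
            csq = info[csq_key]
            gene = gene[0] if isinstance(gene, tuple) else gene
            csq = csq[0] if isinstance(csq, tuple) else csq
            cadd = info.get(cadd_key, 0.0)
            cadd = cadd[0] if isinstance(cadd, tuple) else cadd
            rows.append(
                dict(
                    sample_id=sample, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=rec.alts[0] if rec.alts else ".",
                    gene=str(gene), consequence=str(csq), cadd=float(cadd),
                )
            )
    frame = pd.DataFrame(rows) if rows else _empty_records()
    meta = dict(cohort="vcf", phenotype="ASD", sex="unknown", platform="exome")
    if manifest is not None and len(frame):
        m = manifest.set_index("sample_id")
        sid = frame["sample_id"].iloc[0]
        if sid not in m.index:
            raise ValidationError(f"VCF sample {sid!r} not in manifest")
        meta = {
            k: m.at[sid, k] for k in ("cohort", "phenotype", "sex", "platform")
        }
    for key, value in meta.items():
        frame[key] = value
    return validate_records(frame)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing column(s): {missing}")
    out = manifest.loc[:, list(MANIFEST_COLUMNS)].copy()
    _validate_enum(out, "phenotype", PHENOTYPES)
    _validate_enum(out, "sex", SEXES)
    _validate_enum(out, "platform", PLATFORMS)
    return out.reset_index(drop=True)


def deduplicate_samples(
    records: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Resolve samples present on both platforms, preferring genome data.

    Returns ``(records, manifest, drop_log)``; the drop log lists one row per
    discarded (sample, platform) pair.  A sample carrying conflicting
    phenotype labels across cohorts is a hard error.
    """
    manifest = validate_manifest(manifest)
    pheno = manifest.groupby("sample_id")["phenotype"].nunique()
    conflicts = pheno.index[pheno > 1].tolist()
    if conflicts:
        raise ValidationError(
            f"conflicting phenotype labels for sample(s): {conflicts[:20]}"
        )
    plat = manifest.groupby("sample_id")["platform"].agg(set)
    dual = set(plat.index[plat.apply(lambda s: {"exome", "genome"} <= s)])
    keep_rec = ~(
        records["sample_id"].isin(dual) & (records["platform"] == "exome")
    )
    keep_man = ~(
        manifest["sample_id"].isin(dual) & (manifest["platform"] == "exome")
    )
    drop_log = records.loc[~keep_rec, ["sample_id", "platform"]].assign(
        reason="exome superseded by genome"
    )
    # One manifest row per sample after platform resolution.
    deduped = manifest.loc[keep_man].drop_duplicates(subset="sample_id")
    return records.loc[keep_rec].reset_index(drop=True), deduped.reset_index(
        drop=True
    ), drop_log.reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a blacklist BED (0-based, half-open) into a 3-column frame."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed BED line {lineno}: {line!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValidationError(f"malformed BED line {lineno}: {line!r}") from exc
        if start < 0 or end < start:
            raise ValidationError(f"invalid interval on BED line {lineno}")
        rows.append((parts[0].removeprefix("chr"), start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def filter_dnvs(
    records: pd.DataFrame,
    blacklist: pd.DataFrame | str | Path | None = None,
    per_sample_cap: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Drop DNVs in blacklisted regions and hypermutated samples.

    A variant at 1-based position ``p`` overlaps a half-open BED interval
    ``[start, end)`` iff ``start <= p - 1 < end``.  Samples with more than
    ``per_sample_cap`` remaining DNVs are removed entirely (excess DNV counts
    typically indicate sample-level artifacts).  Idempotent.
    """
    log = {"blacklisted": 0, "capped_samples": [], "capped_records": 0}
    out = records
    if blacklist is not None:
        if not isinstance(blacklist, pd.DataFrame):
            blacklist = read_bed(blacklist)
        if len(blacklist):
            from intervaltree import IntervalTree

            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in blacklist.itertuples(index=False):
                if end > start:
                    trees.setdefault(str(chrom), IntervalTree()).addi(start, end)
            hit = np.array([
                bool(trees[c][p - 1]) if c in trees else False
                for c, p in zip(out["chrom"].astype(str), out["pos"])
            ], dtype=bool) if len(out) else np.zeros(0, dtype=bool)
            log["blacklisted"] = int(hit.sum())
            out = out.loc[~hit]
    if per_sample_cap is not None and len(out):
        counts = out["sample_id"].value_counts()
        over = counts.index[counts > per_sample_cap]
        mask = out["sample_id"].isin(over)
        log["capped_samples"] = sorted(over.tolist())
        log["capped_records"] = int(mask.sum())
        out = out.loc[~mask]
    if log["blacklisted"] or log["capped_records"]:
        logger.info(
            "filter_dnvs removed %d blacklisted DNV(s) and %d DNV(s) from "
            "%d over-cap sample(s)",
            log["blacklisted"], log["capped_records"], len(log["capped_samples"]),
        )
    return out.reset_index(drop=True), log


@dataclass
class GroupSize:
    """Sample-count denominators for one analysis group."""

    n: int
    n_male: int = 0
    n_female: int = 0


@dataclass
class CountTable:
    """Per (gene, group, class) DNV counts plus group denominators.

    ``counts`` is indexed by gene with a (group, class) column MultiIndex;
    the MIS column includes the MIS30 subset.  ``sizes`` holds the manifest
    denominators so genes with zero DNVs still have valid expectations;
    ``gene_chrom`` records each gene's chromosome for X-dosage handling.
    """

    counts: pd.DataFrame
    sizes: dict[str, GroupSize]
    gene_chrom: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def group_counts(self, group: str) -> pd.DataFrame:
        return self.counts[group]

    def get(self, gene: str, group: str, cls: str) -> int:
        try:
            return int(self.counts.at[gene, (group, cls)])
        except KeyError:
            return 0

    def totals(self, group: str) -> pd.Series:
        """Genome-wide class totals for one group."""
        return self.counts[group].sum(axis=0)


#: Analysis groups derived from phenotype and sex labels.  NDD pools ASD and
#: DD probands; male/female pool probands (not siblings) of known sex.
DERIVED_GROUPS = ("NDD", "male", "female")


def count_dnvs(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> CountTable:
    """Aggregate classified DNVs into the grouped count table.

    Groups are the three phenotype labels plus NDD (= ASD + DD) and the
    proband sex groups.  Sample sizes come from the manifest, never from the
    records, so zero-DNV genes keep correct denominators.
    """
    manifest = validate_manifest(manifest)
    if len(records):
        unknown = set(records["sample_id"]) - set(manifest["sample_id"])
        if unknown:
            raise ValidationError(
                f"sample(s) in records but not manifest: {sorted(unknown)[:20]}"
            )
    rec = records if "var_class" in records.columns else _classify_frame(records)
    rec = rec[rec["var_class"].isin(["LGD", "MIS", "MIS30", "SYN"])].copy()

    proband = manifest["phenotype"].isin(["ASD", "DD"])
    group_members = {p: manifest.loc[manifest["phenotype"] == p, "sample_id"]
                     for p in PHENOTYPES}
    group_members["NDD"] = manifest.loc[proband, "sample_id"]
    for sex in ("male", "female"):
        group_members[sex] = manifest.loc[
            proband & (manifest["sex"] == sex), "sample_id"
        ]

    sizes = {}
    sex_of = manifest.set_index("sample_id")["sex"]
    for group, members in group_members.items():
        sx = sex_of.loc[members]
        sizes[group] = GroupSize(
            n=len(members),
            n_male=int((sx == "male").sum()),
            n_female=int((sx == "female").sum()),
        )

    gene_index = pd.Index(
        sorted(set(genes) | set(rec["gene"])) if genes is not None
        else sorted(set(rec["gene"])), name="gene",
    )
    columns = pd.MultiIndex.from_product(
        [list(group_members), list(CLASSES)], names=["group", "class"]
    )
    counts = pd.DataFrame(0, index=gene_index, columns=columns, dtype=np.int64)

    member_sets = {g: set(m) for g, m in group_members.items()}
    for group, members in member_sets.items():
        sub = rec[rec["sample_id"].isin(members)]
        if not len(sub):
            continue
        tab = sub.groupby(["gene", "var_class"]).size().unstack(fill_value=0)
        for cls in ("LGD", "SYN"):
            if cls in tab:
                counts.loc[tab.index, (group, cls)] = tab[cls]
        mis30 = tab["MIS30"] if "MIS30" in tab else 0
        mis = (tab["MIS"] if "MIS" in tab else 0) + mis30
        counts.loc[tab.index, (group, "MIS")] = mis
        counts.loc[tab.index, (group, "MIS30")] = mis30

    gene_chrom = (
        rec.drop_duplicates("gene").set_index("gene")["chrom"].astype(str).to_dict()
    )
    return CountTable(counts=counts, sizes=sizes, gene_chrom=gene_chrom)


def summarize_rates(records: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Nonsynonymous DNVs per person for each phenotype group (2 decimals)."""
    manifest = validate_manifest(manifest)
    rec = records if "var_class" in records.columns else _classify_frame(records)
    nonsyn = rec[rec["var_class"].isin(["LGD", "MIS", "MIS30"])]
    out = {}
    for pheno in PHENOTYPES:
        members = manifest.loc[manifest["phenotype"] == pheno, "sample_id"]
        if not len(members):
            continue
        n_dnv = int(nonsyn["sample_id"].isin(set(members)).sum())
        out[pheno] = round(n_dnv / len(members), 2)
    if not out:
        raise ValidationError("manifest defines no non-empty phenotype group")
    return pd.Series(out, name="nonsyn_dnv_per_person")


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write counts plus a size header as a flat TSV."""
    flat = table.counts.copy()
    flat.columns = [f"{g}:{c}" for g, c in flat.columns]
    with open(path, "w") as fh:
        for group, gs in table.sizes.items():
            fh.write(f"#size\t{group}\t{gs.n}\t{gs.n_male}\t{gs.n_female}\n")
        for gene, chrom in sorted(table.gene_chrom.items()):
            fh.write(f"#chrom\t{gene}\t{chrom}\n")
        flat.to_csv(fh, sep="\t")


def read_count_table(path: str | Path) -> CountTable:
    sizes: dict[str, GroupSize] = {}
    gene_chrom: dict[str, str] = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#size\t"):
            _, group, n, nm, nf = line.split("\t")
            sizes[group] = GroupSize(int(n), int(nm), int(nf))
        elif line.startswith("#chrom\t"):
            _, gene, chrom = line.split("\t")
            gene_chrom[gene] = chrom
        else:
            body.append(line)
    from io import StringIO

    flat = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col=0)
    flat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":")) for c in flat.columns], names=["group", "class"]
    )
    return CountTable(counts=flat, sizes=sizes, gene_chrom=gene_chrom)
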