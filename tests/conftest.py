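import numpy as np
import pandas as pd
import pytest

from dnvmeta.harmonize import CLASSES, CountTable, GroupSize


def make_count_table(group_counts, sizes, gene_chrom=None, genes=None):
    """Build a CountTable from nested dicts.

    ``group_counts``: {group: {gene: {cls: count}}}; MIS is filled to include
    MIS30 automatically when only MIS30 is given.
    ``sizes``: {group: (n, n_male, n_female)} or {group: n}.
    """
    all_genes = set(genes or [])
    for per_gene in group_counts.values():
        all_genes |= set(per_gene)
    index = pd.Index(sorted(all_genes), name="gene")
    columns = pd.MultiIndex.from_product(
        [list(group_counts), list(CLASSES)], names=["group", "class"]
    )
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=np.int64)
    for group, per_gene in group_counts.items():
        for gene, cls_counts in per_gene.items():
            for cls, n in cls_counts.items():
                counts.loc[gene, (group, cls)] = n
            mis30 = cls_counts.get("MIS30", 0)
            mis = cls_counts.get("MIS", 0)
            counts.loc[gene, (group, "MIS")] = max(mis, mis30)
    size_objs = {}
    for group, val in sizes.items():
        if isinstance(val, tuple):
            size_objs[group] = GroupSize(*val)
        else:
            size_objs[group] = GroupSize(n=val)
    return CountTable(counts=counts, sizes=size_objs,
                      gene_chrom=dict(gene_chrom or {}))


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 1,500-gene cohort with 15 planted risk genes, shared across
    tests that only read from it."""
    from dnvmeta import (
        SimConfig, count_dnvs, make_gene_models, plant_architecture,
        simulate_cohort,
    )

    cfg = SimConfig(
        n_genes=1500, n_asd=2000, n_dd=3000, n_sibling=600,
        n_risk_genes=15, seed=11,
    )
    models = make_gene_models(cfg)
    arch = plant_architecture(models, cfg)
    records, manifest = simulate_cohort(models, arch, cfg)
    table = count_dnvs(records, manifest, genes=[g.gene for g in models])
    return dict(
        config=cfg, models=models, model_map={g.gene: g for g in models},
        architecture=arch, records=records, manifest=manifest, table=table,
    )
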