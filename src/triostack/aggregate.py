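"""Stage 1: CpG-site aggregation into methylated-gene features.

On a 450K-style array each gene is covered by one or more CpG probes and a
probe may sit in the regulatory neighbourhood of more than one gene. The
aggregation step collapses the probe-by-sample beta matrix to a
gene-by-sample matrix by taking, per gene and sample, the arithmetic mean of
the beta values of all probes mapped to that gene. The many-to-many relation
is preserved: a shared probe contributes to every gene it maps to. This is
unsupervised (labels never enter), so it can run once, globally, before any
cross-validation split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BETA, CPG_PROBE, METHYLATED_GENE, OmicsMatrix, ProbeGeneMap

logger = logging.getLogger(__name__)


@dataclass
class MethylatedGeneMatrix(OmicsMatrix):
    """Gene-level beta matrix with per-gene probe provenance."""

    provenance: dict[str, list[str]]

    def __init__(self, values, feature_types, data_scale, samples, provenance):
        super().__init__(values, feature_types, data_scale, samples)
        self.provenance = provenance


def aggregate_cpg_to_genes(meth: OmicsMatrix, pmap: ProbeGeneMap) -> MethylatedGeneMatrix:
    """Average probe betas into one methylated-gene feature per mapped gene.

    For gene *g* and sample *s*, ``MG[g, s]`` is the arithmetic mean over the
    probes mapped to *g* of ``beta[probe, s]``, averaging only non-missing
    entries. Probes in the map but absent from the matrix are ignored
    (logged); genes with no present probe are omitted. Raises if no map probe
    is present in the matrix at all.
    """
    if not set(meth.feature_types.unique()) <= {CPG_PROBE}:
        raise ValueError("input matrix must contain cpg_probe features")
    if meth.data_scale != BETA:
        raise ValueError("input matrix must be on the beta scale")
    if len(pmap) == 0:
        raise ValueError("probe-gene map is empty")

    present = set(map(str, meth.feature_ids))
    by_gene = pmap.probes_for_gene()
    provenance = {
        g: [p for p in probes if p in present] for g, probes in by_gene.items()
    }
    n_absent = sum(
        1 for probes in by_gene.values() for p in probes if p not in present
    )
    provenance = {g: probes for g, probes in provenance.items() if probes}
    if not provenance:
        raise ValueError("no probe in the map is present in the matrix")
    if n_absent:
        logger.info("aggregation: %d mapped probe entries absent from matrix", n_absent)

    # long-format join, then a grouped mean per gene (NaN-skipping)
    probe_col = []
    gene_col = []
    for g in sorted(provenance):
        for p in provenance[g]:
            probe_col.append(p)
            gene_col.append(g)
    expanded = meth.values.loc[probe_col].to_numpy(dtype=float)
    frame = pd.DataFrame(expanded, columns=meth.values.columns)
    frame.insert(0, "_gene", gene_col)
    mg = frame.groupby("_gene", sort=True).mean()
    mg.index.name = None

    logger.info(
        "aggregation: %d probes -> %d methylated genes", meth.n_features, mg.shape[0]
    )
    return MethylatedGeneMatrix(
        mg, METHYLATED_GENE, BETA, list(meth.samples), provenance
    )


def write_provenance_tsv(mg: MethylatedGeneMatrix, path: str | Path) -> None:
    """Side-car provenance table: ``gene_id\\tn_probes\\tprobe1;probe2;...``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tn_probes\tprobes\n")
        for g in mg.feature_ids:
            probes = mg.provenance[str(g)]
            fh.write(f"{g}\t{len(probes)}\t{';'.join(probes)}\n")


__all__ = ["MethylatedGeneMatrix", "aggregate_cpg_to_genes", "write_provenance_tsv"]
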