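"""Synthetic triple-omics datasets with known planted ground truth.

The generator emulates a tumor/normal TCGA-style cohort at desk scale:
class-imbalanced samples (more tumors than normals), negative-binomial
HTSeq-style counts for the protein-coding and ncRNA blocks with planted
log2 fold changes in the tumor group, and Beta-distributed 450K-style
probe methylation whose gene-level means are shifted in tumors for planted
genes. Probes are generated around their gene's mean, so averaging probes
back to genes is the correct recovery operator by construction. A
many-to-many probe-gene map (each gene covered by one or more probes, a
configurable fraction of probes shared by a second gene) accompanies the
methylation block.

Counts use a gamma-Poisson mixture parameterized by mean and dispersion;
methylation uses Beta(mu*phi, (1-mu)*phi) with precision phi. Everything is
reproducible from the spec's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BETA,
    COUNTS,
    CPG_PROBE,
    NCRNA,
    PROTEIN_CODING,
    GroundTruth,
    OmicsMatrix,
    ProbeGeneMap,
    SampleMeta,
    TripleDataset,
)
from .io import write_matrix_tsv, write_probe_gene_map

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults are the desk-scale study conditions: 60 tumor / 20 normal
    samples, 2000 protein-coding and 1000 ncRNA features, 500 methylated
    genes, planted |log2FC| = 4 on expression and a 0.3 beta-mean shift on
    methylation.
    """

    n_tumor: int = 60
    n_normal: int = 20
    n_pc: int = 2000
    n_nc: int = 1000
    n_genes_meth: int = 500
    probes_per_gene_mean: float = 3.0
    frac_shared_probes: float = 0.2
    d_pc: int = 40
    d_nc: int = 20
    d_meth: int = 20
    planted_log2fc: float = 4.0
    planted_delta_beta: float = 0.3
    nb_dispersion: float = 0.3
    base_mean: float = 100.0
    beta_precision: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per class")
        if not (0 <= self.frac_shared_probes <= 1):
            raise ValueError("frac_shared_probes must lie in [0, 1]")
        if self.probes_per_gene_mean < 1:
            raise ValueError("probes_per_gene_mean must be >= 1")
        if self.d_pc > self.n_pc or self.d_nc > self.n_nc or self.d_meth > self.n_genes_meth:
            raise ValueError("planted feature counts exceed block sizes")
        if not (0 <= self.planted_delta_beta < 1):
            raise ValueError("planted_delta_beta must lie in [0, 1)")
        for name in ("nb_dispersion", "base_mean", "beta_precision"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,))
    )


def make_probe_gene_map(spec: SyntheticSpec) -> ProbeGeneMap:
    """Draw the many-to-many probe-gene relation for the methylation block.

    Every gene receives ``1 + Poisson(mean - 1)`` primary probes; a
    ``frac_shared_probes`` fraction of all probes is additionally mapped to
    a second, different, random gene. Deterministic under the spec seed.
    """
    spec.validate()
    rng = _rng(spec, 0)
    genes = [f"gene{g:04d}" for g in range(spec.n_genes_meth)]
    pairs: list[tuple[str, str]] = []
    probe_primary: list[tuple[str, str]] = []
    counter = 0
    for g, gene in enumerate(genes):
        n_probes = 1 + int(rng.poisson(spec.probes_per_gene_mean - 1.0))
        for _ in range(n_probes):
            probe = f"cg{counter:06d}"
            counter += 1
            pairs.append((probe, gene))
            probe_primary.append((probe, gene))
    n_shared = int(round(spec.frac_shared_probes * len(probe_primary)))
    shared_idx = rng.choice(len(probe_primary), size=n_shared, replace=False)
    for i in sorted(shared_idx):
        probe, primary = probe_primary[i]
        if spec.n_genes_meth < 2:
            break
        other = primary
        while other == primary:
            other = genes[int(rng.integers(spec.n_genes_meth))]
        pairs.append((probe, other))
    return ProbeGeneMap(pairs)


def _planted(prefix_ids: list[str], d: int) -> list[str]:
    return prefix_ids[:d]


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws with E = mean, Var = mean + dispersion * mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_triple(spec: SyntheticSpec) -> tuple[TripleDataset, GroundTruth]:
    """Generate a sample-aligned synthetic triple dataset plus ground truth.

    Expression counts are NegativeBinomial with feature base means drawn
    lognormally around ``base_mean``; planted features get their tumor mean
    multiplied by ``2**(+/-planted_log2fc)`` (signs alternate so both up-
    and downregulation occur). Methylation probes draw from
    Beta(mu*phi, (1-mu)*phi) around their primary gene's class mean, with
    planted genes shifted by ``+/-planted_delta_beta`` in tumors (direction
    chosen to stay inside (0, 1); degenerate shifts raise before sampling).
    The methylation block is probe-level; downstream aggregation recovers
    gene features via :func:`make_probe_gene_map` (same spec, same map).
    """
    spec.validate()
    pmap = make_probe_gene_map(spec)
    n = spec.n_tumor + spec.n_normal
    tumor = np.zeros(n, dtype=bool)
    tumor[: spec.n_tumor] = True
    y = np.where(tumor, 1, -1)

    samples = []
    for i in range(n):
        code = "01" if tumor[i] else "11"
        barcode = f"TCGA-SY-{i:04d}-{code}A"
        samples.append(
            SampleMeta(barcode, f"TCGA-SY-{i:04d}", code, 1 if tumor[i] else -1)
        )
    sample_ids = [s.sample_id for s in samples]

    def expression_block(n_feat, d, prefix, ftype, stream):
        rng = _rng(spec, stream)
        ids = [f"{prefix}{j:05d}" for j in range(n_feat)]
        base = spec.base_mean * np.exp(rng.normal(0.0, 1.0, size=n_feat))
        means = np.tile(base[:, None], (1, n))
        planted = _planted(ids, d)
        for j in range(d):
            sign = 1.0 if j % 2 == 0 else -1.0
            means[j, tumor] = base[j] * 2.0 ** (sign * spec.planted_log2fc)
        counts = _nb_counts(rng, means, spec.nb_dispersion)
        df = pd.DataFrame(counts, index=ids, columns=[s.barcode for s in samples])
        return OmicsMatrix(df, ftype, COUNTS, list(samples)), planted

    pc, planted_pc = expression_block(spec.n_pc, spec.d_pc, "pcg", PROTEIN_CODING, 1)
    nc, planted_nc = expression_block(spec.n_nc, spec.d_nc, "ncr", NCRNA, 2)

    rng = _rng(spec, 3)
    genes = sorted({g for _, g in pmap.pairs})
    planted_genes = genes[: spec.d_meth]
    # Planted genes alternate hyper-/hypomethylation events: hyper events
    # start from a low baseline and gain planted_delta_beta in tumors, hypo
    # events start high and lose it, mimicking the two canonical directions
    # of aberrant promoter methylation. Null genes draw from the full range.
    gene_mu = {}
    for j, g in enumerate(genes):
        if j < spec.d_meth:
            lo, hi = (0.15, 0.45) if j % 2 == 0 else (0.55, 0.85)
        else:
            lo, hi = 0.2, 0.8
        gene_mu[g] = rng.uniform(lo, hi)
    tumor_mu = dict(gene_mu)
    for j, g in enumerate(planted_genes):
        sign = 1.0 if j % 2 == 0 else -1.0
        shifted = gene_mu[g] + sign * spec.planted_delta_beta
        if not (0.0 < shifted < 1.0):
            raise ValueError(
                f"planted beta shift for {g} leaves (0, 1): mean {gene_mu[g]:.3f}"
            )
        tumor_mu[g] = shifted

    primary_gene = {}
    for p, g in sorted(pmap.pairs):
        primary_gene.setdefault(p, g)  # first (sorted) mapping is the generating gene
    probes = sorted(primary_gene)
    phi = spec.beta_precision
    betas = np.empty((len(probes), n))
    for i, p in enumerate(probes):
        g = primary_gene[p]
        mu = np.where(tumor, tumor_mu[g], gene_mu[g])
        betas[i] = rng.beta(mu * phi, (1.0 - mu) * phi)
    betas = np.clip(betas, 1e-6, 1.0 - 1e-6)
    meth_df = pd.DataFrame(betas, index=probes, columns=[s.barcode for s in samples])
    meth = OmicsMatrix(meth_df, CPG_PROBE, BETA, list(samples))

    dataset = TripleDataset(pc, nc, meth, y, sample_ids)
    truth = GroundTruth(pc=planted_pc, nc=planted_nc, meth=list(planted_genes))
    logger.info(
        "simulated cohort: %d tumor / %d normal; planted %d pc, %d nc, %d meth",
        spec.n_tumor, spec.n_normal, len(planted_pc), len(planted_nc), len(planted_genes),
    )
    return dataset, truth


def inject_missing(
    dataset: TripleDataset, fraction: float, seed: int = 0
) -> TripleDataset:
    """Blank a random fraction of expression cells (simulated missingness)."""
    rng = np.random.default_rng(seed)
    blocks = {}
    for name, block in dataset.blocks.items():
        if block.data_scale == BETA:
            blocks[name] = block
            continue
        values = block.values.copy()
        mask = rng.random(values.shape) < fraction
        arr = values.to_numpy(dtype=float)
        arr[mask] = np.nan
        blocks[name] = OmicsMatrix(
            pd.DataFrame(arr, index=values.index, columns=values.columns),
            block.feature_types,
            block.data_scale,
            list(block.samples),
        )
    return TripleDataset(
        blocks["pc"], blocks["nc"], blocks["meth"], dataset.y, list(dataset.sample_ids)
    )


def write_fixture(
    dataset: TripleDataset,
    pmap: ProbeGeneMap,
    outdir: str | Path,
    truth: GroundTruth | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Emit the TSV fixture set (three matrices, manifest, labels).

    Refuses a non-empty existing directory unless ``overwrite``. The files
    read back (via the I/O module) to an equal dataset.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pc": outdir / "protein_coding.tsv",
        "nc": outdir / "ncrna.tsv",
        "meth": outdir / "methylation_beta.tsv",
        "manifest": outdir / "probe_gene_map.tsv",
        "labels": outdir / "labels.tsv",
    }
    for name, block in dataset.blocks.items():
        write_matrix_tsv(block, paths[name])
    write_probe_gene_map(pmap, paths["manifest"])
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.y):
            fh.write(f"{sid}\t{'tumor' if lab == 1 else 'normal'}\n")
    if truth is not None:
        paths["truth"] = outdir / "ground_truth.json"
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(truth.as_dict(), fh, indent=1)
    return paths


__all__ = [
    "SyntheticSpec",
    "make_probe_gene_map",
    "simulate_triple",
    "inject_missing",
    "write_fixture",
]
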