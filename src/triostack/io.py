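"""Reading, writing and preprocessing of the standard matrix/manifest formats.

Matrix TSV dialect: UTF-8, tab-separated, header ``feature_id\\t<barcode1>...``,
one feature per row, empty cell = missing. Probe manifest dialect (450K
style): ``probe_id\\tgene1;gene2;...``. Label override TSV:
``sample_id\\tlabel`` with label in {tumor, normal}.

Preprocessing follows the usual tumor/normal workflow: keep primary-tumor
("01") and solid-tissue-normal ("11") samples only, collapse duplicate
aliquots per patient, drop duplicate and fully missing features, mean-impute
partial missingness, and quantile-normalize expression matrices across
samples (beta matrices are already bounded ratios and are left as is).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    BETA,
    PRIMARY_TUMOR,
    SOLID_NORMAL,
    OmicsMatrix,
    ProbeGeneMap,
    SampleMeta,
    TripleDataset,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# barcode parsing and sample handling
# ---------------------------------------------------------------------------

def parse_tcga_barcode(barcode: str) -> SampleMeta:
    """Parse a TCGA-style barcode into sample metadata.

    The patient ID is the first three dash-separated fields and the two-digit
    sample type code the first two characters of the fourth field (e.g.
    ``TCGA-BH-A1ES-06A-...`` is a metastatic sample, code "06"). Barcodes
    with fewer than four fields get code "unknown" with a warning.
    """
    fields = barcode.split("-")
    if len(fields) < 4:
        logger.warning("barcode %r has fewer than 4 fields; sample type unknown", barcode)
        return SampleMeta(barcode, barcode, "unknown")
    patient_id = "-".join(fields[:3])
    code = fields[3][:2]
    if len(code) != 2 or not code.isdigit():
        logger.warning("barcode %r has malformed sample-type field; unknown", barcode)
        return SampleMeta(barcode, patient_id, "unknown")
    label = {PRIMARY_TUMOR: 1, SOLID_NORMAL: -1}.get(code)
    return SampleMeta(barcode, patient_id, code, label)


def filter_and_label_samples(m: OmicsMatrix) -> OmicsMatrix:
    """Keep primary tumor and solid tissue normal samples and label them.

    Only sample type codes "01" (labelled +1) and "11" (labelled -1) are
    retained; everything else — metastatic "06" included — is dropped. When a
    patient has several aliquots with the same code, the lexicographically
    smallest full barcode survives (a deterministic tie-break).
    """
    best: dict[str, int] = {}
    for i, s in enumerate(m.samples):
        if s.sample_type_code not in (PRIMARY_TUMOR, SOLID_NORMAL):
            continue
        key = s.sample_id
        if key not in best or s.barcode < m.samples[best[key]].barcode:
            best[key] = i
    keep = sorted(best.values())
    kept = [m.samples[i] for i in keep]
    for cls, code in (("tumor", PRIMARY_TUMOR), ("normal", SOLID_NORMAL)):
        if not any(s.sample_type_code == code for s in kept):
            raise ValueError(f"no {cls} samples after filtering")
    labeled = [
        SampleMeta(
            s.barcode,
            s.patient_id,
            s.sample_type_code,
            1 if s.sample_type_code == PRIMARY_TUMOR else -1,
        )
        for s in kept
    ]
    out = m.select_samples(keep)
    out.samples = labeled
    logger.info(
        "sample filtering: %d -> %d samples (%d tumor, %d normal)",
        m.n_samples,
        len(keep),
        sum(s.label == 1 for s in labeled),
        sum(s.label == -1 for s in labeled),
    )
    return out


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path, feature_type: str, data_scale: str) -> OmicsMatrix:
    """Read a feature-by-sample matrix TSV into an :class:`OmicsMatrix`.

    Empty cells become NaN. Duplicate sample columns are an error; duplicate
    feature rows are retained here and collapsed later by
    :func:`preprocess_features`. A non-numeric cell raises with its row/column
    coordinates.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = [c for c in header if c in seen or seen.add(c)]
    if dups:
        raise ValueError(f"{path}: duplicate sample columns {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index.name = None
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        converted = pd.to_numeric(pd.Series(raw).replace("", np.nan), errors="coerce")
        bad = converted.isna() & (pd.Series(raw) != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell {raw[i]!r} at feature "
                f"{df.index[i]!r} (row {i + 1}), sample {col!r} (column {j + 1})"
            )
        # numpy's parser is correctly rounded, keeping round trips bit-exact
        values[col] = np.where(raw == "", "nan", raw).astype(np.float64)
    samples = [parse_tcga_barcode(str(c)) for c in values.columns]
    m = OmicsMatrix(values, feature_type, data_scale, samples)
    logger.info("read %s: %d features x %d samples", path, m.n_features, m.n_samples)
    return m


def write_matrix_tsv(m: OmicsMatrix, path: str | Path) -> None:
    """Write the matrix TSV dialect; missing values become empty cells."""
    df = m.values.copy()
    df.index.name = "feature_id"
    # %.17g keeps binary64 round trips bit-exact
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def apply_label_overrides(m: OmicsMatrix, path: str | Path) -> OmicsMatrix:
    """Apply a ``sample_id\\tlabel`` table (label in {tumor, normal})."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    mapping = {}
    for _, row in table.iterrows():
        if row["label"] not in ("tumor", "normal"):
            raise ValueError(f"unknown label {row['label']!r} for {row['sample_id']!r}")
        mapping[row["sample_id"]] = 1 if row["label"] == "tumor" else -1
    samples = [
        SampleMeta(s.barcode, s.patient_id, s.sample_type_code, mapping.get(s.sample_id, s.label))
        for s in m.samples
    ]
    out = m.select_samples(list(range(m.n_samples)))
    out.samples = samples
    return out


# ---------------------------------------------------------------------------
# feature preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a complete feature-by-sample array.

    Every column is mapped onto the across-column mean of the sorted values
    (the classic sort/mean/unsort scheme); tied values receive the average of
    the reference values at their tied ranks.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = np.sort(values, axis=0).mean(axis=1)
    grid = np.arange(values.shape[0], dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return out


def preprocess_features(m: OmicsMatrix, normalization: str = "quantile") -> OmicsMatrix:
    """Collapse duplicate features, drop fully missing ones, impute, normalize.

    Duplicate feature IDs keep their first occurrence. A feature missing in
    100% of samples is deleted; partial missingness is imputed with the
    feature's mean over the non-missing samples. Count/expression matrices
    are quantile-normalized across samples when ``normalization='quantile'``
    (``'none'`` disables it); beta matrices are never normalized.
    """
    if normalization not in ("quantile", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    dup = m.values.index.duplicated(keep="first")
    if dup.any():
        logger.info("dropping %d duplicate feature rows", int(dup.sum()))
    values = m.values.loc[~dup]
    ftypes = m.feature_types.loc[~dup]
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d fully missing features", int(all_missing.sum()))
    values = values.loc[~all_missing]
    ftypes = ftypes.loc[~all_missing]
    if values.empty:
        raise ValueError("matrix is empty after feature preprocessing")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        row_means = np.nanmean(arr, axis=1)
        idx = np.where(np.isnan(arr))
        arr[idx] = row_means[idx[0]]
    if m.data_scale != BETA and normalization == "quantile":
        arr = quantile_normalize(arr)
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    logger.info(
        "feature preprocessing: %d -> %d features", m.n_features, out.shape[0]
    )
    return OmicsMatrix(out, ftypes, m.data_scale, list(m.samples))


# ---------------------------------------------------------------------------
# triple-dataset assembly
# ---------------------------------------------------------------------------

def assemble_triple(pc: OmicsMatrix, nc: OmicsMatrix, meth: OmicsMatrix) -> TripleDataset:
    """Align the three blocks on shared sample IDs and bundle the labels.

    The join key is patient ID plus sample type code (aliquot fields differ
    across assays). Blocks are restricted to the three-way intersection,
    ordered by sorted sample ID; conflicting labels for the same sample ID
    across blocks are an error.
    """
    blocks = {"pc": pc, "nc": nc, "meth": meth}
    id_sets = {name: set(b.sample_ids) for name, b in blocks.items()}
    shared = sorted(set.intersection(*id_sets.values()))
    if not shared:
        raise ValueError("no shared samples across the three blocks")
    labels: dict[str, int] = {}
    for name, b in blocks.items():
        for s in b.samples:
            if s.sample_id in labels and s.label != labels[s.sample_id]:
                raise ValueError(
                    f"conflicting labels for sample {s.sample_id!r} (block {name!r})"
                )
            if s.label is not None:
                labels[s.sample_id] = s.label
    missing = [sid for sid in shared if sid not in labels]
    if missing:
        raise ValueError(f"unlabeled shared samples: {missing[:5]}")
    aligned = {}
    for name, b in blocks.items():
        pos = {sid: i for i, sid in enumerate(b.sample_ids)}
        aligned[name] = b.select_samples([pos[sid] for sid in shared])
    y = np.array([labels[sid] for sid in shared], dtype=int)
    ds = TripleDataset(aligned["pc"], aligned["nc"], aligned["meth"], y, shared)
    logger.info(
        "triple dataset: %d shared samples (%d tumor, %d normal)",
        len(shared), int((y == 1).sum()), int((y == -1).sum()),
    )
    return ds


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column probe manifest into a :class:`ProbeGeneMap`.

    Second column is a semicolon-separated gene list; repeated genes within a
    list collapse to one pair. Probes with an empty gene field are dropped
    (count logged). An optional header line starting with ``probe_id`` is
    skipped.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.startswith("probe_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            probe, genes = parts
            genes = genes.strip()
            if not genes:
                dropped += 1
                continue
            for gene in genes.split(";"):
                if gene:
                    pairs.add((probe, gene))
    if dropped:
        logger.info("probe manifest: dropped %d probes with empty gene field", dropped)
    return ProbeGeneMap(pairs)


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    """Write the manifest dialect, one probe per line, genes ';'-joined."""
    by_probe = pmap.genes_for_probe()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tgenes\n")
        for probe in sorted(by_probe):
            fh.write(f"{probe}\t{';'.join(by_probe[probe])}\n")


__all__ = [
    "parse_tcga_barcode",
    "filter_and_label_samples",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "apply_label_overrides",
    "quantile_normalize",
    "preprocess_features",
    "assemble_triple",
    "read_probe_gene_map",
    "write_probe_gene_map",
]
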