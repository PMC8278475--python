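"""In-memory containers shared across the pipeline.

The universal carrier is :class:`OmicsMatrix`, a feature-by-sample numeric
matrix (a pandas DataFrame) tagged with the feature type of each row, the
scale of the stored values, and per-sample metadata parsed from TCGA-style
barcodes. Three sample-aligned matrices plus one binary label vector form a
:class:`TripleDataset`, the input to the diagnosis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# feature type tags
PROTEIN_CODING = "protein_coding"
NCRNA = "ncRNA"
CPG_PROBE = "cpg_probe"
METHYLATED_GENE = "methylated_gene"
FEATURE_TYPES = (PROTEIN_CODING, NCRNA, CPG_PROBE, METHYLATED_GENE)

# data scale tags
COUNTS = "counts"
BETA = "beta"
LOG2_EXPR = "log2_expr"
DATA_SCALES = (COUNTS, BETA, LOG2_EXPR)

#: TCGA sample-type codes of interest. Positive class is the primary tumor,
#: negative class the solid tissue normal; metastatic samples are excluded.
PRIMARY_TUMOR = "01"
SOLID_NORMAL = "11"
METASTATIC = "06"

_VALID_CODES = {f"{i:02d}" for i in range(1, 20)}


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column.

    ``patient_id`` is the first three dash-separated barcode fields
    (characters 1-12 of a TCGA barcode); ``sample_type_code`` the two leading
    digits of the fourth field (positions 14-15). ``label`` is +1 for primary
    tumor ("01"), -1 for solid tissue normal ("11"), ``None`` when unset.
    """

    barcode: str
    patient_id: str
    sample_type_code: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.sample_type_code != "unknown" and self.sample_type_code not in _VALID_CODES:
            raise ValueError(
                f"invalid sample_type_code {self.sample_type_code!r} for {self.barcode!r}"
            )
        if self.label is not None:
            expect = {PRIMARY_TUMOR: 1, SOLID_NORMAL: -1}.get(self.sample_type_code)
            if expect is not None and self.label != expect:
                raise ValueError(
                    f"label {self.label} inconsistent with sample type "
                    f"{self.sample_type_code!r} for {self.barcode!r}"
                )

    @property
    def sample_id(self) -> str:
        """Cross-assay join key: patient plus sample type (aliquot-agnostic)."""
        return f"{self.patient_id}-{self.sample_type_code}"


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with typed rows and annotated columns.

    Parameters
    ----------
    values
        DataFrame, features in rows (index = feature IDs), samples in
        columns (columns = barcodes). Missing entries are NaN.
    feature_types
        Series aligned to ``values.index`` with one of the feature type tags
        per row, or a single tag applied to every row.
    data_scale
        One of ``counts``, ``beta``, ``log2_expr``.
    samples
        One :class:`SampleMeta` per column, index-aligned with the columns.
    """

    values: pd.DataFrame
    feature_types: pd.Series
    data_scale: str
    samples: list[SampleMeta]

    def __init__(
        self,
        values: pd.DataFrame,
        feature_types: pd.Series | str,
        data_scale: str,
        samples: list[SampleMeta],
    ) -> None:
        if isinstance(feature_types, str):
            feature_types = pd.Series(feature_types, index=values.index)
        if data_scale not in DATA_SCALES:
            raise ValueError(f"unknown data_scale {data_scale!r}")
        if len(samples) != values.shape[1]:
            raise ValueError(
                f"{len(samples)} sample records for {values.shape[1]} columns"
            )
        if not feature_types.index.equals(values.index):
            raise ValueError("feature_types index must match values index")
        bad = set(feature_types.unique()) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types {sorted(bad)}")
        if data_scale == BETA:
            arr = values.to_numpy(dtype=float)
            finite = arr[~np.isnan(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta-scale values must lie in [0, 1]")
        self.values = values
        self.feature_types = feature_types
        self.data_scale = data_scale
        self.samples = list(samples)

    # -- convenience ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def labels(self) -> np.ndarray:
        """Label vector in {-1, +1}; raises if any sample is unlabeled."""
        labs = [s.label for s in self.samples]
        if any(lab is None for lab in labs):
            raise ValueError("matrix contains unlabeled samples")
        return np.asarray(labs, dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def select_samples(self, keep: list[int]) -> "OmicsMatrix":
        """Return a copy restricted to the given column positions, in order."""
        return OmicsMatrix(
            self.values.iloc[:, keep].copy(),
            self.feature_types.copy(),
            self.data_scale,
            [self.samples[i] for i in keep],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = ",".join(sorted(self.feature_types.unique()))
        return (
            f"OmicsMatrix({self.n_features} features x {self.n_samples} samples, "
            f"types=[{kinds}], scale={self.data_scale})"
        )


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-many CpG-probe <-> gene relation as a set of (probe, gene) pairs.

    A probe may modify several genes and a gene may be covered by several
    probes; duplicate pairs are not stored.
    """

    pairs: frozenset[tuple[str, str]]

    def __init__(self, pairs) -> None:
        object.__setattr__(self, "pairs", frozenset((str(p), str(g)) for p, g in pairs))

    @property
    def probes(self) -> set[str]:
        return {p for p, _ in self.pairs}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def probes_for_gene(self) -> dict[str, list[str]]:
        """Gene -> sorted list of mapped probes."""
        out: dict[str, list[str]] = {}
        for p, g in self.pairs:
            out.setdefault(g, []).append(p)
        return {g: sorted(ps) for g, ps in out.items()}

    def genes_for_probe(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, g in self.pairs:
            out.setdefault(p, []).append(g)
        return {p: sorted(gs) for p, gs in out.items()}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TripleDataset:
    """Sample-aligned bundle of the three omics blocks plus labels.

    All three blocks carry exactly the shared sample set in identical order;
    ``y`` holds one label in {-1, +1} per shared sample and both classes are
    required to be present.
    """

    pc: OmicsMatrix
    nc: OmicsMatrix
    meth: OmicsMatrix
    y: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name, block in self.blocks.items():
            if block.n_samples != n:
                raise ValueError(f"block {name!r} has {block.n_samples} samples, expected {n}")
            if block.sample_ids != self.sample_ids:
                raise ValueError(f"block {name!r} sample order differs from sample_ids")
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (n,):
            raise ValueError("y length must equal the shared sample count")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be -1 or +1")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def blocks(self) -> dict[str, OmicsMatrix]:
        return {"pc": self.pc, "nc": self.nc, "meth": self.meth}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_meth(self, meth: OmicsMatrix) -> "TripleDataset":
        """Replace the methylation block (e.g. after CpG-to-gene aggregation)."""
        return TripleDataset(self.pc, self.nc, meth, self.y, list(self.sample_ids))


@dataclass
class GroundTruth:
    """Planted differential feature IDs per block of a synthetic dataset."""

    pc: list[str] = field(default_factory=list)
    nc: list[str] = field(default_factory=list)
    meth: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[str]]:
        return {"pc": list(self.pc), "nc": list(self.nc), "meth": list(self.meth)}

    @property
    def all_features(self) -> set[str]:
        return set(self.pc) | set(self.nc) | set(self.meth)


__all__ = [
    "SampleMeta",
    "OmicsMatrix",
    "ProbeGeneMap",
    "TripleDataset",
    "GroundTruth",
    "PROTEIN_CODING",
    "NCRNA",
    "CPG_PROBE",
    "METHYLATED_GENE",
    "COUNTS",
    "BETA",
    "LOG2_EXPR",
    "PRIMARY_TUMOR",
    "SOLID_NORMAL",
    "METASTATIC",
]
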