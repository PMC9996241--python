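"""Data model, file readers/writers and configuration.

All tabular files are tab-separated UTF-8 text with ``NA`` marking missing
values.  Matrices are stored feature-by-sample: the header row carries the
sample identifiers and the first column the feature identifiers.  Protein
coordinates are 1-based and inclusive, following the HGVSp convention.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("protact")

NA_TOKEN = "NA"
LAYERS = ("mrna", "protein", "phospho", "cnv", "activity")
PHOSPHO_RESIDUES = frozenset("STY")
CNV_LEVELS = frozenset({-2.0, -1.0, 0.0, 1.0, 2.0})

#: Mutation classes recognised in mutation tables.
MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "stop_loss",
    "silent",
)

#: Classes that set a cell of the binary mutation matrix to 1.
FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "stop_loss"}
)

#: Loss-of-function classes (expected to disable the protein product).
LOF_CLASSES = frozenset({"frameshift_indel", "nonsense", "splice_site", "stop_loss"})

PRIOR_SOURCES = ("database", "textmining", "invivo", "invitro")

# Mode-of-regulation aliases accepted in regulon files.
MODE_ALIASES = {"1": 1, "+1": 1, "-1": -1, "A": 1, "I": -1}


class DataError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """A feature x sample grid of real values with explicit missingness.

    Parameters
    ----------
    values
        DataFrame with feature ids as index, sample ids as columns.  Missing
        cells are NaN, never zero.
    layer
        One of :data:`LAYERS`; the ``cnv`` layer admits only the discrete
        GISTIC levels -2..2.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DataError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise DataError(f"duplicate feature ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dupes}")
        self.values = self.values.astype(float)
        if self.layer == "cnv":
            observed = set(np.unique(self.values.to_numpy()))
            bad = {v for v in observed if not np.isnan(v)} - CNV_LEVELS
            if bad:
                raise DataError(f"cnv layer admits only -2..2; found {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.layer == other.layer and self.values.equals(other.values)


@dataclass(frozen=True, order=True)
class PhosphositeKey:
    """One phosphorylation site: protein symbol, 1-based position, residue."""

    protein: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise DataError(
                f"residue must be one of S/T/Y, got {self.residue!r} "
                f"({self.protein} {self.position})"
            )

    def __str__(self) -> str:  # e.g. AKT1_S473
        return f"{self.protein}_{self.residue}{self.position}"


@dataclass(frozen=True)
class MutationRecord:
    """One classified somatic mutation call."""

    sample_id: str
    gene: str
    mclass: str
    position: int | None = None
    ref_residue: str | None = None
    alt_residue: str | None = None

    def __post_init__(self) -> None:
        if self.mclass not in MUTATION_CLASSES:
            raise DataError(f"unknown mutation class {self.mclass!r}")
        if self.mclass != "splice_site":
            if self.position is None or self.ref_residue is None:
                raise DataError(
                    f"{self.mclass} record for {self.gene} in {self.sample_id} "
                    "must carry a protein position and reference residue"
                )
            if self.position < 1:
                raise DataError(f"position must be >= 1, got {self.position}")


@dataclass
class PriorNetwork:
    """Regulator -> target priors for kinases and transcription factors.

    ``kinase_targets`` maps each kinase to its substrate phosphosites, each
    tagged with the evidence source; ``regulons`` maps each TF to signed
    transcriptional targets (mode +1 activating, -1 repressing) with a
    confidence grade.
    """

    kinase_targets: dict[str, dict[PhosphositeKey, str]] = field(default_factory=dict)
    regulons: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kin, targets in self.kinase_targets.items():
            if not targets:
                raise DataError(f"kinase {kin!r} has an empty target set")
            for site, source in targets.items():
                if source not in PRIOR_SOURCES:
                    raise DataError(f"unknown source {source!r} for {kin}/{site}")
        for tf, targets in self.regulons.items():
            if not targets:
                raise DataError(f"TF {tf!r} has an empty regulon")
            for gene, mode, conf in targets:
                if mode not in (-1, 1):
                    raise DataError(f"mode must be +/-1, got {mode!r} for {tf}/{gene}")

    def substrate_sets(self) -> dict[str, frozenset[PhosphositeKey]]:
        return {k: frozenset(v) for k, v in self.kinase_targets.items()}


@dataclass
class EdgeList:
    """Undirected confidence-scored protein pairs, stored canonically."""

    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical: dict[tuple[str, str], int] = {}
        for (a, b), score in self.edges.items():
            score = int(score)
            if not 150 <= score <= 999:
                raise DataError(f"combined_score must lie in [150, 999], got {score}")
            key = (a, b) if a <= b else (b, a)
            canonical[key] = max(score, canonical.get(key, 0))
        self.edges = canonical

    def score(self, a: str, b: str) -> int | None:
        return self.edges.get((a, b) if a <= b else (b, a))

    def filtered(self, min_score: int) -> "EdgeList":
        return EdgeList({k: s for k, s in self.edges.items() if s >= min_score})

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.edges


@dataclass(frozen=True)
class GoldStandardPair:
    """A (kinase, condition) combination with known regulation."""

    kinase: str
    condition_id: str
    direction: str | None = None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """All analysis thresholds in one declarative object.

    Defaults match the published workflow: activity cut-off 1.75 for calling
    a regulator "regulated", noise gate 0.15 for group splits, STRING score
    850 for confident edges, mutation filters 20/10/5 for the association
    models, dendrogram heights 0.8/0.85 for substrate-redundancy reduction,
    k = 8 sample clusters, and BMI 37 / age 50 binarisation of clinical
    covariates.
    """

    # activity inference
    min_targets: int = 3
    min_regulon: int = 5
    functional_score_gate: float = 0.4
    regulated_percentile: float = 96.7
    regulated_min_fraction: float = 0.05
    activity_cutoff: float = 1.75
    noise_gate: float = 0.15
    # preprocessing
    outlier_median_threshold: float = 1.0
    log2_pseudocount: float = 1.0
    # associations
    min_gene_mutations: int = 20
    min_activity_samples: int = 10
    min_pair_mutations: int = 5
    string_min_score: int = 850
    fdr_threshold: float = 0.05
    # landscape
    redundancy_height: float = 0.85
    redundancy_height_pairs: float = 0.8
    layer_corr_min_n: int = 10
    specificity_z: float = 2.0
    # benchmark
    n_resamples: int = 100
    # survival
    min_mut_for_genotype: int = 100
    tf_survival_min_deaths: int = 10
    tf_survival_min_group: int = 10
    kinase_survival_min_deaths: int = 5
    kinase_survival_min_group: int = 5
    # clustering
    n_clusters: int = 8
    dereg_threshold: float = 2.0
    min_level_count: int = 5
    bmi_cutoff: float = 37.0
    age_cutoff: float = 50.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, layer: str) -> FeatureMatrix:
    """Read a feature x sample TSV into a :class:`FeatureMatrix`.

    Empty cells and ``NA`` parse as missing, not zero.  Duplicate feature or
    sample ids and non-numeric cells are hard errors naming the offender.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN, ""],
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise DataError(
                f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        numeric[col] = converted
    logger.info("read %s matrix %s: %d features x %d samples",
                layer, path, *numeric.shape)
    return FeatureMatrix(numeric, layer)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips bit-identically for finite values."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_kinase_prior(path: str | Path) -> dict[str, dict[PhosphositeKey, str]]:
    """Read kinase substrate rows: kinase, protein, position, residue, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"kinase", "protein", "position", "residue", "source"}
    if not required.issubset(df.columns):
        raise DataError(f"kinase prior must carry columns {sorted(required)}")
    targets: dict[str, dict[PhosphositeKey, str]] = {}
    for row in df.itertuples(index=False):
        site = PhosphositeKey(row.protein, int(row.position), row.residue)
        if row.source not in PRIOR_SOURCES:
            raise DataError(f"unknown prior source {row.source!r}")
        targets.setdefault(row.kinase, {})[site] = row.source
    return targets


def read_regulons(path: str | Path) -> dict[str, list[tuple[str, int, str]]]:
    """Read regulon rows: tf, target, mode, confidence.

    Mode accepts +/-1 or the activator/inhibitor aliases A and I.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tf", "target", "mode", "confidence"}
    if not required.issubset(df.columns):
        raise DataError(f"regulon table must carry columns {sorted(required)}")
    regulons: dict[str, list[tuple[str, int, str]]] = {}
    for row in df.itertuples(index=False):
        if row.mode not in MODE_ALIASES:
            raise DataError(f"unknown regulon mode {row.mode!r} for {row.tf}")
        if row.confidence not in ("A", "B", "C"):
            raise DataError(f"confidence must be A/B/C, got {row.confidence!r}")
        regulons.setdefault(row.tf, []).append(
            (row.target, MODE_ALIASES[row.mode], row.confidence)
        )
    return regulons


def read_prior(kinase_path: str | Path | None = None,
               regulon_path: str | Path | None = None) -> PriorNetwork:
    """Assemble a :class:`PriorNetwork` from kinase and/or regulon tables."""
    return PriorNetwork(
        kinase_targets=read_kinase_prior(kinase_path) if kinase_path else {},
        regulons=read_regulons(regulon_path) if regulon_path else {},
    )


def write_kinase_prior(targets: Mapping[str, Mapping[PhosphositeKey, str]],
                       path: str | Path) -> None:
    rows = [
        (kin, s.protein, s.position, s.residue, src)
        for kin in sorted(targets)
        for s, src in sorted(targets[kin].items(), key=lambda kv: kv[0])
    ]
    pd.DataFrame(rows, columns=["kinase", "protein", "position", "residue", "source"]
                 ).to_csv(path, sep="\t", index=False)


def write_regulons(regulons: Mapping[str, Sequence[tuple[str, int, str]]],
                   path: str | Path) -> None:
    rows = [
        (tf, gene, mode, conf)
        for tf in sorted(regulons)
        for gene, mode, conf in sorted(regulons[tf])
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode", "confidence"]
                 ).to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a mutation table: sample_id, gene, class, position, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN, ""],
                     keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.position) if pd.notna(row.position) else None
        records.append(MutationRecord(
            sample_id=row.sample_id, gene=row.gene, mclass=row.mclass,
            position=pos,
            ref_residue=row.ref_residue if pd.notna(row.ref_residue) else None,
            alt_residue=row.alt_residue if pd.notna(row.alt_residue) else None,
        ))
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        (r.sample_id, r.gene, r.mclass,
         r.position if r.position is not None else NA_TOKEN,
         r.ref_residue or NA_TOKEN, r.alt_residue or NA_TOKEN)
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene", "mclass", "position",
                                "ref_residue", "alt_residue"]
                 ).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> EdgeList:
    """Read an undirected edge list: protein_a, protein_b, combined_score."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str,
                                            "combined_score": int})
    return EdgeList({(r.protein_a, r.protein_b): r.combined_score
                     for r in df.itertuples(index=False)})


def write_edges(edges: EdgeList, path: str | Path) -> None:
    rows = [(a, b, s) for (a, b), s in sorted(edges.edges.items())]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]
                 ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; the header up to the first whitespace is the id."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DataError(f"duplicate FASTA header {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_gold_standard(path: str | Path) -> list[GoldStandardPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN],
                     keep_default_na=False)
    pairs = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.kinase, row.condition_id)
        if key in seen:
            raise DataError(f"duplicate gold-standard pair {key}")
        seen.add(key)
        direction = getattr(row, "direction", None)
        pairs.append(GoldStandardPair(
            row.kinase, row.condition_id,
            direction if pd.notna(direction) else None))
    return pairs


def write_gold_standard(pairs: Iterable[GoldStandardPair], path: str | Path) -> None:
    rows = [(p.kinase, p.condition_id, p.direction or NA_TOKEN) for p in pairs]
    pd.DataFrame(rows, columns=["kinase", "condition_id", "direction"]
                 ).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table, indexed by sample id.

    Enforces that an overall-survival event flag is only present together
    with a survival time.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN, ""],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    if "os_event" in df.columns and "os_time_days" in df.columns:
        bad = df["os_event"].notna() & df["os_time_days"].isna()
        if bad.any():
            raise DataError(
                f"os_event without os_time_days for samples {list(df.index[bad])}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")
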