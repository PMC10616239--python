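"""Shared domain types for the ceRNA inference pipeline.

The pipeline works on three RNA layers (mRNA, lncRNA, miRNA) measured over a
small two-group design (HIGH vs LOW intramuscular-fat content). Everything
downstream — normalization, differential screening, target prediction and the
ceRNA triplet caller — consumes the containers defined here.

Genomic coordinates are 0-based half-open throughout; conversion from the
1-based inclusive GTF/GFF convention happens once, at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "lncRNA", "miRNA")
UNITS = ("count", "FPKM", "TPM")
GROUPS = ("HIGH", "LOW")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """One RNA layer's features x samples expression values.

    ``data`` is a dense DataFrame (features on the index, samples on the
    columns); ``layer`` is one of mRNA/lncRNA/miRNA and ``unit`` one of
    count/FPKM/TPM. Counts must be integral; all values finite and >= 0.
    Missing values are not permitted — absence must be encoded as 0 upstream.
    """

    data: pd.DataFrame
    layer: str
    unit: str = "count"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.shape[0] == 0:
            raise ValidationError("no features")
        if self.data.shape[1] == 0:
            raise ValidationError("no samples")
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {dup_f}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric values in expression matrix")
        if not np.isfinite(values).all():
            raise ValidationError("non-finite values in expression matrix")
        if (values < 0).any():
            raise ValidationError("negative values in expression matrix")
        if self.unit == "count" and not np.allclose(values, np.round(values)):
            raise ValidationError("unit='count' requires integral values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(ids)], self.layer, self.unit)


@dataclass
class DesignTable:
    """sample -> group (HIGH or LOW) assignment for the two-group contrast."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if g not in self.groups.values():
                raise ValidationError(f"group {g} is empty")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location and biotype of one feature (0-based half-open)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.feature_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.feature_id}: unknown strand {self.strand!r}")
        if self.length_bp < 1:
            raise ValidationError(f"{self.feature_id}: length_bp must be >= 1")


@dataclass(frozen=True)
class TargetRelation:
    """A (regulator, target) edge from one prediction strategy.

    ``mechanism`` is antisense / cis / trans / seed_match / provided; the score
    is mechanism-specific: complementarity fraction, genomic gap in bp,
    correlation r, seed-site count, or 0 for externally provided relations.
    """

    regulator_id: str
    target_id: str
    mechanism: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.regulator_id == self.target_id:
            raise ValidationError(f"self-relation {self.regulator_id}")
        if self.mechanism == "cis" and self.score < 0:
            raise ValidationError("cis score is a genomic distance and must be >= 0")


@dataclass
class DEResult:
    """Per-feature outcome of the two-group differential screen."""

    feature_id: str
    log2fc: float
    p_value: float
    direction: str  # up | down | none
    significant: bool


@dataclass
class MiRNACeRNAEdge:
    """miRNA -> candidate ceRNA edge retained by the Spearman screen."""

    mirna_id: str
    cerna_id: str
    cerna_class: str  # lncRNA | mRNA
    spearman_rho: float


@dataclass
class CeRNAPair:
    """Candidate lncRNA-mRNA pair with its correlation and shared-miRNA test.

    k_shared miRNAs regulate both partners out of K_lnc (lncRNA's regulators)
    and n_mrna (mRNA's regulators) drawn from a universe of N_universe miRNAs.
    """

    lncrna_id: str
    mrna_id: str
    pearson_r: float = float("nan")
    shared_mirnas: frozenset = field(default_factory=frozenset)
    k_shared: int = 0
    K_lnc: int = 0
    n_mrna: int = 0
    N_universe: int = 0
    hypergeom_p: float = float("nan")
    final: bool = False


@dataclass
class CeRNANetwork:
    """Typed ceRNA network: miRNA-target edges plus lncRNA-mRNA ceRNA edges.

    ``nodes`` maps node id -> rna_class; ``edges`` is a list of
    (source, target, edge_type, statistic, p_value) with edge_type in
    {mirna_target, cerna_pair}. statistic is the screening correlation; for
    cerna_pair edges p_value is the shared-miRNA hypergeometric p.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[tuple] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for src, tgt, etype, stat, p in self.edges:
            if src not in self.nodes or tgt not in self.nodes:
                raise ValidationError(f"edge endpoint missing from nodes: {src}->{tgt}")
            if src == tgt:
                raise ValidationError(f"self-edge on {src}")
            if etype not in ("mirna_target", "cerna_pair"):
                raise ValidationError(f"unknown edge type {etype!r}")
            key = (src, tgt, etype)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def edge_keys(self) -> set[tuple]:
        return {(src, tgt, etype) for src, tgt, etype, _, _ in self.edges}


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement."""

    sample_id: str
    gene_id: str
    ct: float
    role: str  # target | reference
    condition: str  # treated | control

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct) and self.ct > 0):
            raise ValidationError(f"Ct must be finite and > 0, got {self.ct}")
        if self.role not in ("target", "reference"):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.condition not in ("treated", "control"):
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe, for over-representation analysis."""

    sets: dict[str, tuple[str, frozenset]]
    universe: frozenset

    def restrict_to_universe(self) -> "GeneSetCollection":
        sets = {}
        for term_id, (name, members) in self.sets.items():
            kept = frozenset(members) & self.universe
            if kept:
                sets[term_id] = (name, kept)
        return GeneSetCollection(sets=sets, universe=self.universe)
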