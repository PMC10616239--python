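"""Readers and writers for every external format the pipeline touches.

Count matrices are TSV (first column feature ids, header row sample ids);
annotations are GTF or GFF3 (converted here, once, to 0-based half-open
coordinates); sequences are FASTA; networks go out as SIF, GraphML or TSV;
gene sets come in as GMT. No alignment-level I/O (BAM/SAM/FASTQ) is handled.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import (
    CeRNANetwork,
    DesignTable,
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSetCollection,
    TargetRelation,
    ValidationError,
)

_ID_ATTRIBUTES = ("gene_id", "ID", "transcript_id", "Name")
_BIOTYPE_ATTRIBUTES = ("gene_biotype", "biotype", "gene_type")


def read_counts(path, layer: str, unit: str = "count") -> ExpressionMatrix:
    """Read a TSV expression matrix (features x samples) for one RNA layer.

    Duplicated feature/sample ids and non-numeric cells are hard errors that
    name the offending id or cell address. ``unit`` defaults to raw counts;
    pass FPKM/TPM to re-load normalized matrices.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no features")
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no samples")
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate feature ids: {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        feature, sample = bad[bad].index[0]
        raise ValidationError(
            f"{path}: non-numeric value at feature {feature!r}, sample {sample!r}"
        )
    return ExpressionMatrix(numeric, layer=layer, unit=unit)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path) -> DesignTable:
    """Read a two-column TSV (sample_id, group) into a DesignTable."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValidationError(f"{path}: expected columns sample_id, group")
    dup = df.sample_id[df.sample_id.duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate samples {dup}")
    return DesignTable(dict(zip(df.sample_id, df.group)))


def write_design(design: DesignTable, path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.groups), "group": list(design.groups.values())}
    ).to_csv(path, sep="\t", index=False)


def _first_attribute(feature, names):
    for name in names:
        if name in feature.attributes:
            values = feature.attributes[name]
            if values:
                return values[0]
    return None


def read_annotation(path, feature_types: tuple = ("gene",)) -> list[FeatureAnnotation]:
    """Parse gene-level records from a GTF or GFF3 file.

    File coordinates are 1-based inclusive; internal ones 0-based half-open,
    so ``start_internal = start_file - 1`` and ``end_internal = end_file``.
    A record with end < start or a strand other than +/- is a hard error.
    An optional ``length`` attribute overrides the genomic span as the
    effective length used for FPKM.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature_types and feature.featuretype not in feature_types:
                continue
            feature_id = _first_attribute(feature, _ID_ATTRIBUTES)
            if feature_id is None:
                raise ValidationError(f"{path}:{lineno}: record without an id attribute")
            if feature.end < feature.start:
                raise ValidationError(
                    f"{path}:{lineno}: end {feature.end} < start {feature.start}"
                )
            if feature.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}:{lineno}: unknown strand {feature.strand!r}"
                )
            biotype = _first_attribute(feature, _BIOTYPE_ATTRIBUTES) or "mRNA"
            length_attr = _first_attribute(feature, ("length",))
            start = feature.start - 1
            end = feature.end
            length = int(length_attr) if length_attr is not None else end - start
            out.append(
                FeatureAnnotation(
                    feature_id=feature_id,
                    chrom=feature.seqid,
                    start=start,
                    end=end,
                    strand=feature.strand,
                    biotype=biotype,
                    length_bp=length,
                )
            )
    return out


def write_annotation_gtf(annotations: list[FeatureAnnotation], path) -> None:
    """Write gene-level GTF records (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for a in annotations:
            attrs = (
                f'gene_id "{a.feature_id}"; gene_biotype "{a.biotype}"; '
                f'length "{a.length_bp}";'
            )
            fh.write(
                f"{a.chrom}\tcernapipe\tgene\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\t{attrs}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_predictions(path, mechanism: str = "provided") -> list[TargetRelation]:
    """Read a predictions TSV (regulator_id, target_id[, mechanism, score])."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator_id": str, "target_id": str})
    if "regulator_id" not in df.columns or "target_id" not in df.columns:
        raise ValidationError(f"{path}: expected columns regulator_id, target_id")
    relations = []
    for row in df.itertuples(index=False):
        relations.append(
            TargetRelation(
                regulator_id=row.regulator_id,
                target_id=row.target_id,
                mechanism=getattr(row, "mechanism", mechanism),
                score=float(getattr(row, "score", 0.0)),
            )
        )
    return relations


def write_predictions(relations: list[TargetRelation], path) -> None:
    pd.DataFrame(
        [
            {
                "regulator_id": r.regulator_id,
                "target_id": r.target_id,
                "mechanism": r.mechanism,
                "score": r.score,
            }
            for r in relations
        ],
        columns=["regulator_id", "target_id", "mechanism", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, members...)."""
    sets: dict[str, tuple[str, frozenset]] = {}
    members_union: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term, name, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
            if not members:
                raise ValidationError(f"{path}: empty gene set {term}")
            sets[term] = (name, members)
            members_union |= members
    uni = frozenset(universe) if universe is not None else frozenset(members_union)
    return GeneSetCollection(sets=sets, universe=uni).restrict_to_universe()


NETWORK_TSV_COLUMNS = ["source", "target", "edge_type", "statistic", "p_value"]


def write_network(network: CeRNANetwork, path, format: str = "TSV") -> None:
    """Export a ceRNA network as SIF, GraphML or TSV.

    SIF uses interaction labels ``targets`` (miRNA -> RNA) and ``ceRNA``
    (lncRNA - mRNA co-regulation). TSV carries source/target/edge_type/
    statistic/p_value and round-trips exactly through
    :func:`read_network_tsv`. GraphML carries the ``rna_class`` node
    attribute.
    """
    network.validate()
    fmt = format.upper()
    path = Path(path)
    if fmt == "SIF":
        with open(path, "w") as fh:
            for src, tgt, etype, _, _ in network.edges:
                label = "targets" if etype == "mirna_target" else "ceRNA"
                fh.write(f"{src}\t{label}\t{tgt}\n")
    elif fmt == "TSV":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(NETWORK_TSV_COLUMNS)
            for src, tgt, etype, stat, p in network.edges:
                writer.writerow([src, tgt, etype, repr(float(stat)), repr(float(p))])
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for node, rna_class in network.nodes.items():
            g.add_node(node, rna_class=rna_class)
        for src, tgt, etype, stat, p in network.edges:
            g.add_edge(src, tgt, edge_type=etype, statistic=float(stat), p_value=float(p))
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network_tsv(path, node_classes: dict[str, str] | None = None) -> CeRNANetwork:
    """Read back a network TSV written by :func:`write_network`.

    Node classes are inferred from edge types (miRNA sources of mirna_target
    edges); ceRNA-pair endpoints default to lncRNA/mRNA by position unless
    ``node_classes`` overrides them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    if list(df.columns) != NETWORK_TSV_COLUMNS:
        raise ValidationError(f"{path}: expected columns {NETWORK_TSV_COLUMNS}")
    network = CeRNANetwork()
    for row in df.itertuples(index=False):
        network.edges.append(
            (row.source, row.target, row.edge_type, float(row.statistic), float(row.p_value))
        )
    classes = dict(node_classes or {})
    for src, tgt, etype, _, _ in network.edges:
        if etype == "mirna_target":
            classes.setdefault(src, "miRNA")
        elif etype == "cerna_pair":
            classes.setdefault(src, "lncRNA")
            classes.setdefault(tgt, "mRNA")
    for src, tgt, _, _, _ in network.edges:
        network.nodes.setdefault(src, classes.get(src, "mRNA"))
        network.nodes.setdefault(tgt, classes.get(tgt, "mRNA"))
    network.validate()
    return network
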