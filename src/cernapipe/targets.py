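"""lncRNA and miRNA target prediction.

lncRNA targets come from three strategies:

* **antisense** — opposite-strand genomic overlap, optionally scored by base
  complementarity (Watson-Crick plus G.U wobble) over the overlapping span;
* **cis** — genes whose locus lies within a fixed radius (default 10 kb) of
  the lncRNA locus on the same chromosome, measured as the inter-interval
  gap (0 for overlapping loci), strand-agnostic, inclusive at the radius;
* **trans** — co-expression: |Pearson r| >= 0.9 across all samples,
  regardless of genomic location.

miRNA targets use a 7-mer seed match (miRNA positions 2-8 from the 5' end,
perfect reverse complement in the target region) as a fully specified
stand-in for sequence/thermodynamics predictors, and the final-target rule —
keep the pairs called by both of two predictors — is implemented exactly.

All operations here are deterministic; there is no randomness in this module.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .models import ExpressionMatrix, FeatureAnnotation, TargetRelation, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CIS_RADIUS_BP = 10_000

_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G", "N": "N"}
# RNA duplex pairing: Watson-Crick plus the G.U wobble
_PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_PAIRS_WOBBLE = _PAIRS_WC | {("G", "U"), ("U", "G")}
_VALID_BASES = set("ACGUTN")


def interval_gap(a: FeatureAnnotation, b: FeatureAnnotation) -> int | None:
    """Bases strictly between two loci; 0 if they overlap; None across chroms."""
    if a.chrom != b.chrom:
        return None
    return max(0, a.start - b.end, b.start - a.end)


def predict_cis(
    lncrnas: list[FeatureAnnotation],
    genes: list[FeatureAnnotation],
    radius_bp: int = DEFAULT_CIS_RADIUS_BP,
) -> list[TargetRelation]:
    """Genes within ``radius_bp`` of a lncRNA locus (inclusive boundary).

    The distance is the inter-interval gap from the lncRNA locus boundaries,
    not TSS-to-TSS; strand is ignored. A gene at a gap of exactly the radius
    is included; one base farther is not. Score = gap in bp.
    """
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for lnc in lncrnas:
        for gene in by_chrom.get(lnc.chrom, ()):
            if gene.feature_id == lnc.feature_id:
                continue
            gap = interval_gap(lnc, gene)
            if gap is not None and gap <= radius_bp:
                out.append(
                    TargetRelation(
                        regulator_id=lnc.feature_id,
                        target_id=gene.feature_id,
                        mechanism="cis",
                        score=float(gap),
                    )
                )
    out.sort(key=lambda r: (r.regulator_id, r.target_id))
    return out


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValidationError(f"invalid base {exc.args[0]!r} in sequence") from exc


def antisense_complementarity(
    plus_span: str, minus_span: str, allow_wobble: bool = True
) -> float:
    """Fraction of paired positions that are complementary in an antisense
    duplex formed by the overlapping spans of a plus- and a minus-strand
    transcript (both given 5'->3'; position i pairs with position -1-i)."""
    if len(plus_span) != len(minus_span):
        raise ValidationError("overlap spans must have equal length")
    pairs = _PAIRS_WOBBLE if allow_wobble else _PAIRS_WC
    p = _rna(plus_span)
    m = _rna(minus_span)
    n = len(p)
    hits = sum((p[i], m[n - 1 - i]) in pairs for i in range(n))
    return hits / n if n else 0.0


def predict_antisense(
    lncrnas: list[FeatureAnnotation],
    genes: list[FeatureAnnotation],
    lnc_seqs: dict[str, str] | None = None,
    gene_seqs: dict[str, str] | None = None,
    min_complementarity: float = 0.5,
    allow_wobble: bool = True,
) -> list[TargetRelation]:
    """Opposite-strand overlapping lncRNA-gene pairs, optionally sequence-scored.

    Candidates overlap by >= 1 bp on opposite strands. With sequences (each
    feature's transcript 5'->3'), the score is the complementary fraction
    over the overlapping span and candidates below ``min_complementarity``
    are dropped; without sequences the score is the overlap length in bp and
    every candidate passes. A provided sequence shorter than the annotated
    span is a hard error.
    """
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for lnc in lncrnas:
        for gene in by_chrom.get(lnc.chrom, ()):
            if gene.feature_id == lnc.feature_id or gene.strand == lnc.strand:
                continue
            lo = max(lnc.start, gene.start)
            hi = min(lnc.end, gene.end)
            if hi - lo < 1:
                continue
            if lnc_seqs is not None and gene_seqs is not None:
                lseq = lnc_seqs.get(lnc.feature_id)
                gseq = gene_seqs.get(gene.feature_id)
                if lseq is None or gseq is None:
                    continue  # sequence not supplied for this pair
                score = _scored_overlap(lnc, gene, lseq, gseq, lo, hi, allow_wobble)
                if score < min_complementarity:
                    continue
            else:
                score = float(hi - lo)
            out.append(
                TargetRelation(
                    regulator_id=lnc.feature_id,
                    target_id=gene.feature_id,
                    mechanism="antisense",
                    score=float(score),
                )
            )
    out.sort(key=lambda r: (r.regulator_id, r.target_id))
    return out


def _transcript_span(feature: FeatureAnnotation, seq: str, lo: int, hi: int) -> str:
    """Slice a transcript sequence down to the genomic window [lo, hi).

    The stored sequence is the transcript 5'->3': the genomic forward strand
    for + features, its reverse complement for - features.
    """
    if len(seq) < feature.end - feature.start:
        raise ValidationError(
            f"{feature.feature_id}: sequence ({len(seq)} nt) shorter than "
            f"annotated span ({feature.end - feature.start} bp)"
        )
    if feature.strand == "+":
        return seq[lo - feature.start : hi - feature.start]
    return seq[feature.end - hi : feature.end - lo]


def _scored_overlap(lnc, gene, lseq, gseq, lo, hi, allow_wobble) -> float:
    plus_feat, plus_seq = (lnc, lseq) if lnc.strand == "+" else (gene, gseq)
    minus_feat, minus_seq = (gene, gseq) if lnc.strand == "+" else (lnc, lseq)
    plus_span = _transcript_span(plus_feat, plus_seq, lo, hi)
    minus_span = _transcript_span(minus_feat, minus_seq, lo, hi)
    return antisense_complementarity(plus_span, minus_span, allow_wobble)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p for every row of x against every row of y."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return r, p


def predict_trans(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    r_threshold: float = 0.9,
    p_threshold: float = 0.05,
) -> list[TargetRelation]:
    """Co-expression targets: |Pearson r| >= r_threshold and test p <= p_threshold.

    Both matrices must cover the same samples (order is aligned here).
    Constant vectors have undefined r and are excluded with a warning.
    """
    if set(lnc_expr.sample_ids) != set(gene_expr.sample_ids):
        raise ValidationError("trans prediction requires identical sample sets")
    x = lnc_expr.data.to_numpy(dtype=float)
    y = gene_expr.data[lnc_expr.sample_ids].to_numpy(dtype=float)
    const_x = x.std(axis=1) == 0
    const_y = y.std(axis=1) == 0
    if const_x.any() or const_y.any():
        logger.warning(
            "excluding %d lncRNA and %d gene constant vectors from trans screen",
            const_x.sum(),
            const_y.sum(),
        )
    r, p = _pairwise_pearson(x, y)
    out = []
    for i, lnc_id in enumerate(lnc_expr.feature_ids):
        if const_x[i]:
            continue
        for j, gene_id in enumerate(gene_expr.feature_ids):
            if const_y[j] or lnc_id == gene_id:
                continue
            if abs(r[i, j]) >= r_threshold and p[i, j] <= p_threshold:
                out.append(
                    TargetRelation(
                        regulator_id=lnc_id,
                        target_id=gene_id,
                        mechanism="trans",
                        score=float(r[i, j]),
                    )
                )
    out.sort(key=lambda rel: (rel.regulator_id, rel.target_id))
    return out


def seed_site(mirna_seq: str) -> str:
    """Reverse complement of the 7-mer seed (miRNA positions 2-8, 1-based)."""
    seq = _rna(mirna_seq)
    if len(seq) < 8:
        raise ValidationError(f"miRNA sequence too short for a seed: {len(seq)} nt")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValidationError(f"invalid base(s) {sorted(bad)} in miRNA sequence")
    seed = seq[1:8]
    return _rna(reverse_complement(seed))


def count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def predict_seed_targets(
    mirnas: dict[str, str], utrs: dict[str, str]
) -> list[TargetRelation]:
    """miRNA targets by perfect 7-mer seed match in the target region.

    A relation is called iff the reverse complement of the miRNA's seed
    (positions 2-8 from the 5' end) occurs at least once in the target
    sequence; the score is the (overlapping) occurrence count. U and T are
    interchangeable; any character outside {A,C,G,U,T,N} is a hard error.
    """
    clean_utrs = {}
    for utr_id, seq in utrs.items():
        rna = _rna(seq)
        bad = set(rna) - _VALID_BASES
        if bad:
            raise ValidationError(f"invalid base(s) {sorted(bad)} in {utr_id}")
        clean_utrs[utr_id] = rna
    out = []
    for mir_id in sorted(mirnas):
        site = seed_site(mirnas[mir_id])
        for utr_id in sorted(clean_utrs):
            if utr_id == mir_id:
                continue
            hits = count_overlapping(clean_utrs[utr_id], site)
            if hits > 0:
                out.append(
                    TargetRelation(
                        regulator_id=mir_id,
                        target_id=utr_id,
                        mechanism="seed_match",
                        score=float(hits),
                    )
                )
    return out


def intersect_predictions(
    pred_a: list[TargetRelation], pred_b: list[TargetRelation]
) -> list[TargetRelation]:
    """Final targets = (regulator, target) pairs called by both predictors.

    Output mechanism is ``provided`` and the order deterministic
    (regulator, then target, lexicographic).
    """
    pairs_a = {(r.regulator_id, r.target_id) for r in pred_a}
    pairs_b = {(r.regulator_id, r.target_id) for r in pred_b}
    return [
        TargetRelation(regulator_id=reg, target_id=tgt, mechanism="provided", score=0.0)
        for reg, tgt in sorted(pairs_a & pairs_b)
    ]
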