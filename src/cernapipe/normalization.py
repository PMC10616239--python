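"""Within-sample normalization: TPM for miRNA, FPKM for mRNA/lncRNA.

miRNA abundance is tags-per-million: ``TPM = T * 1e6 / N`` with T the tags of
one miRNA and N the sample's total tags, so every TPM column sums to 1e6.
mRNA/lncRNA use FPKM, ``count * 1e9 / (length_bp * library_size)``, with the
library size taken as the column sum of the supplied matrix and the effective
length the annotated length in bp (no fragment-length correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ExpressionMatrix, FeatureAnnotation, ValidationError


@dataclass
class NormalizationReport:
    layer: str
    library_sizes: dict[str, float]
    formula: str  # "FPKM" | "TPM"

    def __post_init__(self) -> None:
        bad = [s for s, n in self.library_sizes.items() if not n > 0]
        if bad:
            raise ValidationError(f"non-positive library size for samples {bad}")


def compute_tpm(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Tags-per-million per sample; columns sum to 1e6 by construction."""
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample column(s): {zero}")
    tpm = counts.data * 1e6 / totals
    report = NormalizationReport(
        layer=counts.layer, library_sizes=totals.to_dict(), formula="TPM"
    )
    return ExpressionMatrix(tpm, layer=counts.layer, unit="TPM"), report


def compute_fpkm(
    counts: ExpressionMatrix, annotation: list[FeatureAnnotation]
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Fragments per kilobase of transcript per million mapped reads.

    Every feature in the matrix must have an annotation providing its
    effective length; missing features are a hard error listing the ids.
    """
    lengths = {a.feature_id: a.length_bp for a in annotation}
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise ValidationError(f"features missing from annotation: {missing}")
    length_vec = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample column(s): {zero}")
    fpkm = counts.data * 1e9 / totals
    fpkm = fpkm.div(length_vec, axis=0)
    report = NormalizationReport(
        layer=counts.layer, library_sizes=totals.to_dict(), formula="FPKM"
    )
    return ExpressionMatrix(fpkm, layer=counts.layer, unit="FPKM"), report


def normalize_layer(
    counts: ExpressionMatrix, annotation: list[FeatureAnnotation] | None = None
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Dispatch to the layer's conventional unit (miRNA -> TPM, else FPKM)."""
    if counts.layer == "miRNA":
        return compute_tpm(counts)
    if annotation is None:
        raise ValidationError("FPKM normalization requires an annotation")
    return compute_fpkm(counts, annotation)
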