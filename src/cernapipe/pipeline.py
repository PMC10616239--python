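"""End-to-end ceRNA pipeline: normalize -> DE screen -> screens -> network.

The driver ties the stages together exactly in the published order: the
three layers are normalized (TPM for miRNA, FPKM otherwise), each layer is
screened for differential expression (fold change > 1.5, p <= 0.05), target
relations are restricted to differential features, miRNA-target edges pass
the Spearman screen (rho <= -0.7), candidate lncRNA-mRNA pairs — by default
those sharing at least one retained miRNA — pass the Pearson screen
(r > 0.9) and the shared-miRNA hypergeometric test (p <= 0.05), and the
surviving triplets are assembled into the typed network.

Correlation screens run on log2(x + 1) of the normalized values by default
(``log_scale=False`` switches to the raw normalized scale; Spearman is
unaffected either way, being rank-based).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr
from .cerna import (
    assemble_network,
    hypergeom_shared_test,
    pearson_screen,
    regulator_sets,
    spearman_screen,
)
from .models import (
    CeRNANetwork,
    DesignTable,
    ExpressionMatrix,
    FeatureAnnotation,
    TargetRelation,
    ValidationError,
)
from .normalization import normalize_layer


@dataclass
class PipelineThresholds:
    """All screening thresholds, with the published defaults."""

    fc: float = 1.5
    de_p: float = 0.05
    rho: float = -0.7
    r: float = 0.9
    hypergeom_p: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineThresholds":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class PipelineConfig:
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    de_method: str = "welch_log"
    de_seed: int | None = None
    log_scale: bool = True
    candidate_rule: str = "shared_mirna_first"  # or "all_pairs"
    universe: str = "retained_edges"  # or "expressed"


def _log_view(matrix: ExpressionMatrix, enabled: bool) -> ExpressionMatrix:
    if not enabled:
        return matrix
    return ExpressionMatrix(np.log2(matrix.data + 1.0), matrix.layer, matrix.unit)


def run_cerna_pipeline(
    mrna_counts: ExpressionMatrix,
    lncrna_counts: ExpressionMatrix,
    mirna_counts: ExpressionMatrix,
    design: DesignTable,
    annotation: list[FeatureAnnotation],
    relations: list[TargetRelation],
    config: PipelineConfig | None = None,
) -> tuple[CeRNANetwork, dict]:
    """Run the whole screen and return (network, stage-count report).

    ``relations`` are miRNA -> target (lncRNA or mRNA) predictions; only
    relations among differential features are carried into the Spearman
    screen. The report records the count surviving every stage.
    """
    config = config or PipelineConfig()
    th = config.thresholds
    report: dict = {"thresholds": asdict(th)}

    mrna_norm, _ = normalize_layer(mrna_counts, annotation)
    lncrna_norm, _ = normalize_layer(lncrna_counts, annotation)
    mirna_norm, _ = normalize_layer(mirna_counts)

    de_sets = {}
    for name, norm in (("mRNA", mrna_norm), ("lncRNA", lncrna_norm), ("miRNA", mirna_norm)):
        results = diffexpr.de_screen(
            norm,
            design,
            fc_threshold=th.fc,
            p_threshold=th.de_p,
            method=config.de_method,
            seed=config.de_seed,
        )
        up, down = diffexpr.split_directions(results)
        de_sets[name] = up | down
        report[f"n_de_{name}"] = len(de_sets[name])

    de_all = de_sets["mRNA"] | de_sets["lncRNA"] | de_sets["miRNA"]
    de_relations = [
        rel
        for rel in relations
        if rel.regulator_id in de_sets["miRNA"] and rel.target_id in de_all
    ]
    report["n_relations_in"] = len(relations)
    report["n_relations_de"] = len(de_relations)

    log_mir = _log_view(mirna_norm, config.log_scale)
    log_lnc = _log_view(lncrna_norm, config.log_scale)
    log_mrna = _log_view(mrna_norm, config.log_scale)

    lnc_ids = set(log_lnc.feature_ids)
    mrna_ids = set(log_mrna.feature_ids)
    edges = spearman_screen(
        log_mir,
        log_lnc,
        [r for r in de_relations if r.target_id in lnc_ids],
        rho_threshold=th.rho,
    ) + spearman_screen(
        log_mir,
        log_mrna,
        [r for r in de_relations if r.target_id in mrna_ids],
        rho_threshold=th.rho,
    )
    report["n_edges_spearman"] = len(edges)

    regs = regulator_sets(edges)
    de_lnc = sorted(de_sets["lncRNA"])
    de_mrna = sorted(de_sets["mRNA"])
    if config.candidate_rule == "shared_mirna_first":
        candidates = [
            (l, m)
            for l in de_lnc
            for m in de_mrna
            if regs.get(l, set()) & regs.get(m, set())
        ]
    elif config.candidate_rule == "all_pairs":
        candidates = [(l, m) for l in de_lnc for m in de_mrna]
    else:
        raise ValidationError(f"unknown candidate rule {config.candidate_rule!r}")
    report["n_candidate_pairs"] = len(candidates)

    pairs = pearson_screen(log_lnc, log_mrna, candidates, r_threshold=th.r)
    report["n_pairs_pearson"] = len(pairs)

    if config.universe == "retained_edges":
        universe = None
    elif config.universe == "expressed":
        universe = set(mirna_norm.feature_ids)
    else:
        raise ValidationError(f"unknown universe choice {config.universe!r}")
    tested = (
        [hypergeom_shared_test(p, edges, universe=universe) for p in pairs]
        if edges
        else []
    )

    network = assemble_network(edges, tested, p_threshold=th.hypergeom_p)
    report["n_final_pairs"] = sum(
        1 for _, _, etype, _, _ in network.edges if etype == "cerna_pair"
    )
    report["n_nodes"] = len(network.nodes)
    report["n_edges"] = len(network.edges)
    return network, report


def network_triplets(network: CeRNANetwork) -> set[tuple[str, str, str]]:
    """All (lncRNA, miRNA, mRNA) triplets implied by the network edges."""
    targets_of: dict[str, set[str]] = {}
    for src, tgt, etype, _, _ in network.edges:
        if etype == "mirna_target":
            targets_of.setdefault(src, set()).add(tgt)
    triplets = set()
    for src, tgt, etype, _, _ in network.edges:
        if etype != "cerna_pair":
            continue
        for mir, hit in targets_of.items():
            if src in hit and tgt in hit:
                triplets.add((src, mir, tgt))
    return triplets


def report_to_frame(report: dict) -> pd.DataFrame:
    rows = [(k, v) for k, v in report.items() if not isinstance(v, dict)]
    return pd.DataFrame(rows, columns=["stage", "count"])
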