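"""Construction of the lncRNA-miRNA-mRNA ceRNA network.

A competing-endogenous-RNA (ceRNA) pair is a lncRNA and an mRNA that both
carry response elements for the same miRNAs, so that either can titrate the
shared miRNAs away from the other. The caller screens candidate triplets in
four stages, all with the published default thresholds:

1. **Spearman screen** — for every predicted (miRNA, target) relation, keep
   the edge iff Spearman rho(miRNA, target) <= -0.7 across all samples
   (average ranks for ties), the signature of miRNA-mediated repression.
2. **Pearson screen** — candidate lncRNA-mRNA pairs survive iff
   Pearson r > 0.9, strictly: a pair at exactly 0.9 is rejected.
3. **Shared-miRNA test** — upper-tail hypergeometric P[X >= k] of seeing at
   least k shared retained-miRNA regulators given the pair's regulator set
   sizes K and n in a universe of N miRNAs; pairs with p <= 0.05 are final.
4. **Assembly** — final pairs plus the miRNA-target edges incident to them
   form the typed network (solid miRNA-target edges, dashed ceRNA edges in
   the usual drawing convention).

By default the universe N is the set of miRNAs appearing in the retained
(post-Spearman) edge set; set ``universe`` explicitly for "all expressed
miRNAs" behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import stats

from .hypergeom import hypergeom_upper_tail
from .models import (
    CeRNANetwork,
    CeRNAPair,
    ExpressionMatrix,
    MiRNACeRNAEdge,
    TargetRelation,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_RHO = -0.7
DEFAULT_R = 0.9
DEFAULT_HYPERGEOM_P = 0.05


def _aligned(values: ExpressionMatrix, sample_order: list[str]) -> np.ndarray:
    return values.data[sample_order].to_numpy(dtype=float)


def spearman_screen(
    mirna_expr: ExpressionMatrix,
    cerna_expr: ExpressionMatrix,
    relations: list[TargetRelation],
    rho_threshold: float = DEFAULT_RHO,
) -> list[MiRNACeRNAEdge]:
    """Retain (miRNA, target) relations with Spearman rho <= rho_threshold.

    Only pairs present in ``relations`` are evaluated. rho uses average ranks
    for ties over all samples of both groups; a constant vector on either
    side is skipped with a warning.
    """
    if set(mirna_expr.sample_ids) != set(cerna_expr.sample_ids):
        raise ValidationError("Spearman screen requires identical sample sets")
    samples = mirna_expr.sample_ids
    mir = _aligned(mirna_expr, samples)
    cer = _aligned(cerna_expr, samples)
    mir_ranks = np.apply_along_axis(stats.rankdata, 1, mir)
    cer_ranks = np.apply_along_axis(stats.rankdata, 1, cer)
    mir_idx = {f: i for i, f in enumerate(mirna_expr.feature_ids)}
    cer_idx = {f: i for i, f in enumerate(cerna_expr.feature_ids)}
    cerna_class = cerna_expr.layer
    edges = []
    n_skipped = 0
    for rel in relations:
        i = mir_idx.get(rel.regulator_id)
        j = cer_idx.get(rel.target_id)
        if i is None or j is None:
            continue
        a, b = mir_ranks[i], cer_ranks[j]
        if a.std() == 0 or b.std() == 0:
            n_skipped += 1
            continue
        rho = float(np.corrcoef(a, b)[0, 1])
        if rho <= rho_threshold:
            edges.append(
                MiRNACeRNAEdge(
                    mirna_id=rel.regulator_id,
                    cerna_id=rel.target_id,
                    cerna_class=cerna_class,
                    spearman_rho=rho,
                )
            )
    if n_skipped:
        logger.warning("spearman_screen skipped %d constant pair(s)", n_skipped)
    edges.sort(key=lambda e: (e.mirna_id, e.cerna_id))
    return edges


def pearson_screen(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    candidates: list[tuple[str, str]],
    r_threshold: float = DEFAULT_R,
) -> list[CeRNAPair]:
    """Keep candidate (lncRNA, mRNA) pairs with Pearson r strictly above the cut."""
    if set(lnc_expr.sample_ids) != set(mrna_expr.sample_ids):
        raise ValidationError("Pearson screen requires identical sample sets")
    samples = lnc_expr.sample_ids
    lnc = _aligned(lnc_expr, samples)
    mrna = _aligned(mrna_expr, samples)
    lnc_idx = {f: i for i, f in enumerate(lnc_expr.feature_ids)}
    mrna_idx = {f: i for i, f in enumerate(mrna_expr.feature_ids)}
    pairs = []
    n_skipped = 0
    for lnc_id, mrna_id in candidates:
        i = lnc_idx.get(lnc_id)
        j = mrna_idx.get(mrna_id)
        if i is None or j is None:
            continue
        a, b = lnc[i], mrna[j]
        if a.std() == 0 or b.std() == 0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > r_threshold:
            pairs.append(CeRNAPair(lncrna_id=lnc_id, mrna_id=mrna_id, pearson_r=r))
    if n_skipped:
        logger.warning("pearson_screen skipped %d constant pair(s)", n_skipped)
    pairs.sort(key=lambda p: (p.lncrna_id, p.mrna_id))
    return pairs


def regulator_sets(edges: list[MiRNACeRNAEdge]) -> dict[str, set[str]]:
    """ceRNA id -> set of retained miRNA regulators."""
    out: dict[str, set[str]] = {}
    for e in edges:
        out.setdefault(e.cerna_id, set()).add(e.mirna_id)
    return out


def hypergeom_shared_test(
    pair: CeRNAPair,
    edges: list[MiRNACeRNAEdge],
    universe: set[str] | None = None,
) -> CeRNAPair:
    """Fill in the pair's shared-miRNA hypergeometric upper-tail p.

    K = retained-edge miRNAs of the lncRNA, n = of the mRNA, k = shared;
    the universe N defaults to all miRNAs in the retained edge set.
    """
    regs = regulator_sets(edges)
    if universe is None:
        universe = {e.mirna_id for e in edges}
    universe = set(universe)
    if not universe:
        raise ValidationError("empty miRNA universe")
    lnc_regs = regs.get(pair.lncrna_id, set()) & universe
    mrna_regs = regs.get(pair.mrna_id, set()) & universe
    shared = lnc_regs & mrna_regs
    N = len(universe)
    K, n, k = len(lnc_regs), len(mrna_regs), len(shared)
    if K > N or n > N:
        raise ValidationError(f"regulator sets exceed the universe: K={K}, n={n}, N={N}")
    p = hypergeom_upper_tail(k, N, K, n)
    return replace(
        pair,
        shared_mirnas=frozenset(shared),
        k_shared=k,
        K_lnc=K,
        n_mrna=n,
        N_universe=N,
        hypergeom_p=p,
    )


def assemble_network(
    edges: list[MiRNACeRNAEdge],
    pairs: list[CeRNAPair],
    p_threshold: float = DEFAULT_HYPERGEOM_P,
) -> CeRNANetwork:
    """Assemble the final typed network from tested pairs and retained edges.

    ceRNA edges appear only for final pairs (hypergeometric p <= threshold);
    miRNA-target edges only for miRNAs shared by at least one final pair,
    and only towards members of final pairs — the network is the union of
    the interacting triplets. Ordering is deterministic.
    """
    final_pairs = []
    for pair in pairs:
        final = bool(pair.hypergeom_p <= p_threshold)
        final_pairs.append(replace(pair, final=final))
    network = CeRNANetwork()
    kept = [p for p in final_pairs if p.final]
    edge_rho = {(e.mirna_id, e.cerna_id): (e.spearman_rho, e.cerna_class) for e in edges}
    mirna_edges = []
    for p in kept:
        for mir in sorted(p.shared_mirnas):
            for cerna_id in (p.lncrna_id, p.mrna_id):
                rho, cerna_class = edge_rho[(mir, cerna_id)]
                mirna_edges.append((mir, cerna_id, rho, cerna_class))
    for mir, cerna_id, rho, cerna_class in sorted(mirna_edges):
        if (mir, cerna_id, "mirna_target") in network.edge_keys:
            continue
        network.nodes.setdefault(mir, "miRNA")
        network.nodes.setdefault(cerna_id, cerna_class)
        network.edges.append((mir, cerna_id, "mirna_target", rho, float("nan")))
    for p in sorted(kept, key=lambda q: (q.lncrna_id, q.mrna_id)):
        network.nodes.setdefault(p.lncrna_id, "lncRNA")
        network.nodes.setdefault(p.mrna_id, "mRNA")
        network.edges.append(
            (p.lncrna_id, p.mrna_id, "cerna_pair", p.pearson_r, p.hypergeom_p)
        )
    network.validate()
    return network
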