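"""Two-group differential screen: fold change > 1.5 and p <= 0.05.

The selection rule is the published one; the test behind the p-value is a
documented stand-in for count-model DE tools: Welch's two-sample t on
log2(x + 1) (``welch_log``), or an exact/randomized label-permutation test of
the group mean difference on the same scale (``permutation``). With 3 + 3
samples the permutation null has only C(6,3) = 20 assignments, so permutation
p-values live on the lattice k/20 and the smallest achievable two-sided p is
2/20 = 0.1.

Fold-change direction: HIGH is the numerator, so up-regulated means higher in
the HIGH group. "More than 1.5-fold" is strict: |log2fc| > log2(1.5), and a
feature at exactly 1.5-fold is rejected.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy import stats

from .models import DEResult, DesignTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FC = 1.5
DEFAULT_P = 0.05


def _log2_groups(matrix: ExpressionMatrix, design: DesignTable):
    design.check_covers(matrix)
    high = [s for s in matrix.sample_ids if design.groups[s] == "HIGH"]
    low = [s for s in matrix.sample_ids if design.groups[s] == "LOW"]
    if len(high) < 2 or len(low) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got HIGH={len(high)}, LOW={len(low)}"
        )
    log_all = np.log2(matrix.data.to_numpy(dtype=float) + 1.0)
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    hi = log_all[:, [cols[s] for s in high]]
    lo = log_all[:, [cols[s] for s in low]]
    return hi, lo


def _welch_p(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups gives a nan t; call those
    # features p=1 when means agree, p=0 when they are cleanly separated
    nan = ~np.isfinite(p)
    if nan.any():
        diff = hi.mean(axis=1) - lo.mean(axis=1)
        p[nan & (diff == 0)] = 1.0
        p[nan & (diff != 0)] = 0.0
    return p


def permutation_assignments(n_samples: int, n_high: int, max_exact: int = 50000):
    """All (or None if too many) HIGH-column index sets for the label null."""
    from math import comb

    if comb(n_samples, n_high) <= max_exact:
        return list(combinations(range(n_samples), n_high))
    return None


def _permutation_p(
    hi: np.ndarray, lo: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Two-sided permutation p for the mean log difference, per feature.

    Enumerates all C(n, n_high) label assignments when feasible (exact test;
    the observed assignment is one of them) and falls back to seeded random
    sampling with the observed statistic included in the null otherwise.
    Constant features get p = 1 by convention.
    """
    values = np.concatenate([hi, lo], axis=1)
    n_high = hi.shape[1]
    n = values.shape[1]
    obs = np.abs(hi.mean(axis=1) - lo.mean(axis=1))
    assignments = permutation_assignments(n, n_high)
    if assignments is not None:
        sel = np.zeros((len(assignments), n), dtype=float)
        for i, combo in enumerate(assignments):
            sel[i, list(combo)] = 1.0
        # mean(HIGH) - mean(LOW) for every assignment at once
        weights = sel / n_high - (1.0 - sel) / (n - n_high)
        null = np.abs(values @ weights.T)  # features x assignments
        p = (null >= obs[:, None] - 1e-12).mean(axis=1)
    else:
        n_permutations = max(int(n_permutations), 1000)
        hits = np.ones(values.shape[0])  # the observed assignment counts once
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ph = values[:, perm[:n_high]].mean(axis=1)
            pl = values[:, perm[n_high:]].mean(axis=1)
            hits += np.abs(ph - pl) >= obs - 1e-12
        p = hits / (n_permutations + 1)
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.warning("%d constant feature(s): permutation p set to 1", constant.sum())
        p[constant] = 1.0
    return p


def de_screen(
    matrix: ExpressionMatrix,
    design: DesignTable,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
    method: str = "welch_log",
    n_permutations: int = 1000,
    seed: int | None = None,
    bh_adjust: bool = False,
) -> list[DEResult]:
    """Screen every feature for differential expression between HIGH and LOW.

    log2fc is the difference of group means of log2(x + 1); significance
    requires |log2fc| > log2(fc_threshold) (strict) and p <= p_threshold.
    ``bh_adjust`` switches the p cut to Benjamini-Hochberg adjusted values
    (off by default, matching a raw-p selection rule).
    """
    if fc_threshold <= 0:
        raise ValidationError("fc_threshold must be positive")
    hi, lo = _log2_groups(matrix, design)
    log2fc = hi.mean(axis=1) - lo.mean(axis=1)
    if method == "welch_log":
        p = _welch_p(hi, lo)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        p = _permutation_p(hi, lo, n_permutations, rng)
    else:
        raise ValidationError(f"unknown method {method!r}")
    p_screen = p
    if bh_adjust:
        p_screen = _bh(p)
    log2_cut = np.log2(fc_threshold)
    results = []
    for i, feature_id in enumerate(matrix.feature_ids):
        significant = bool(abs(log2fc[i]) > log2_cut and p_screen[i] <= p_threshold)
        if significant:
            direction = "up" if log2fc[i] > 0 else "down"
        else:
            direction = "none"
        results.append(
            DEResult(
                feature_id=feature_id,
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                direction=direction,
                significant=significant,
            )
        )
    return results


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(p, method="bh")


def split_directions(results: list[DEResult]) -> tuple[set[str], set[str]]:
    """Partition the significant features by sign of log2fc."""
    up = {r.feature_id for r in results if r.significant and r.direction == "up"}
    down = {r.feature_id for r in results if r.significant and r.direction == "down"}
    return up, down


def significant_ids(results: list[DEResult]) -> set[str]:
    return {r.feature_id for r in results if r.significant}
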