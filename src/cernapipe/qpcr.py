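"""Livak 2^-ddCt relative-quantification arithmetic for qPCR validation.

dCt = Ct(target) - Ct(reference) within each condition; ddCt =
dCt(treated) - dCt(control); relative expression = 2^-ddCt. Replicates are
averaged on the Ct scale before differencing. Useful identities: ddCt = 0
gives 1.0; swapping the conditions inverts the result; adding a constant to
every Ct leaves it unchanged.
"""

from __future__ import annotations

import pandas as pd

from .models import CtRecord, ValidationError

_CELLS = [
    ("target", "treated"),
    ("reference", "treated"),
    ("target", "control"),
    ("reference", "control"),
]


def mean_ct_by_cell(records: list[CtRecord]) -> dict[tuple[str, str], float]:
    """Average replicate Ct values within each (role, condition) cell."""
    sums: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        sums.setdefault((rec.role, rec.condition), []).append(rec.ct)
    return {cell: sum(v) / len(v) for cell, v in sums.items()}


def ddct(records: list[CtRecord]) -> float:
    """Relative expression 2^-ddCt of the target in treated vs control."""
    cells = mean_ct_by_cell(records)
    missing = [cell for cell in _CELLS if cell not in cells]
    if missing:
        raise ValidationError(f"missing Ct cell(s): {missing}")
    dct_treated = cells[("target", "treated")] - cells[("reference", "treated")]
    dct_control = cells[("target", "control")] - cells[("reference", "control")]
    ddct_value = dct_treated - dct_control
    return float(2.0 ** (-ddct_value))


def read_ct_table(path) -> list[CtRecord]:
    """TSV with columns sample_id, gene_id, ct, role, condition."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = ["sample_id", "gene_id", "ct", "role", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        CtRecord(
            sample_id=row.sample_id,
            gene_id=row.gene_id,
            ct=float(row.ct),
            role=row.role,
            condition=row.condition,
        )
        for row in df.itertuples(index=False)
    ]


def write_ct_table(records: list[CtRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene_id": r.gene_id,
                "ct": r.ct,
                "role": r.role,
                "condition": r.condition,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
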