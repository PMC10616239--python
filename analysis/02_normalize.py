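"""Normalize the three count layers: FPKM for mRNA/lncRNA, TPM for miRNA.

Reads the counts written by 01_simulate_cohort.py, applies the
within-sample normalizations, verifies the TPM column-sum contract and
writes the normalized matrices under results/normalized/.
"""

import argparse
from pathlib import Path

from cernapipe import io_core
from cernapipe.normalization import compute_fpkm, compute_tpm


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/normalized"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = io_core.read_annotation(args.data / "annotation.gtf")
    for layer, fname, norm in (
        ("mRNA", "mrna", "FPKM"),
        ("lncRNA", "lncrna", "FPKM"),
        ("miRNA", "mirna", "TPM"),
    ):
        counts = io_core.read_counts(args.data / f"{fname}_counts.tsv", layer=layer)
        if norm == "TPM":
            matrix, report = compute_tpm(counts)
            colsums = matrix.data.sum(axis=0)
            print(f"{layer}: TPM column sums (should all be 1e6): "
                  f"min={colsums.min():.3f} max={colsums.max():.3f}")
        else:
            matrix, report = compute_fpkm(counts, annotation)
            print(f"{layer}: FPKM over library sizes "
                  f"{ {s: int(n) for s, n in report.library_sizes.items()} }")
        io_core.write_counts(matrix, args.out / f"{fname}_{norm.lower()}.tsv")
    print(f"wrote normalized matrices to {args.out}")


if __name__ == "__main__":
    main()
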