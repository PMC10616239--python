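"""Two-group differential screen on each RNA layer.

Applies the selection rule (fold change > 1.5, p <= 0.05, Welch's t on
log2(x+1)) to the normalized matrices, reports up/down counts per layer
and writes per-feature result tables under results/de/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernapipe import io_core
from cernapipe.diffexpr import de_screen, split_directions


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--normalized", type=Path, default=Path("results/normalized"))
    parser.add_argument("--out", type=Path, default=Path("results/de"))
    parser.add_argument("--fc", type=float, default=1.5)
    parser.add_argument("--p", type=float, default=0.05)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = io_core.read_design(args.data / "design.tsv")
    for layer, fname, unit in (
        ("mRNA", "mrna_fpkm", "FPKM"),
        ("lncRNA", "lncrna_fpkm", "FPKM"),
        ("miRNA", "mirna_tpm", "TPM"),
    ):
        matrix = io_core.read_counts(args.normalized / f"{fname}.tsv", layer, unit)
        results = de_screen(matrix, design, fc_threshold=args.fc, p_threshold=args.p)
        up, down = split_directions(results)
        print(f"{layer}: {len(up) + len(down)} differential "
              f"({len(up)} up, {len(down)} down in HIGH)")
        pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "direction": r.direction,
                    "significant": r.significant,
                }
                for r in results
            ]
        ).to_csv(args.out / f"{layer.lower()}_de.tsv", sep="\t", index=False)
    print(f"wrote DE tables to {args.out}")


if __name__ == "__main__":
    main()
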