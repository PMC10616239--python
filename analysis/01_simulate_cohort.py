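"""Generate the synthetic study cohort.

Emulates the two-group design the pipeline targets: 3 HIGH- vs 3 LOW-fat
samples, three RNA layers of negative-binomial counts with 20 planted
ceRNA triplets, planted differential features, miRNA-target predictions,
and a genomic annotation with designated cis and antisense pairs. Writes
all standard-format inputs plus the ground truth under results/data/.
"""

import argparse
from pathlib import Path

from cernapipe import SimConfig, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240901)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    result = simulate(config)
    result.write_dir(args.out)

    truth = result.truth
    print(f"wrote cohort to {args.out}")
    print(f"  samples: {result.design.groups}")
    for layer, mat in (("mRNA", result.mrna), ("lncRNA", result.lncrna), ("miRNA", result.mirna)):
        print(f"  {layer}: {mat.data.shape[0]} features x {mat.data.shape[1]} samples")
    print(f"  planted triplets: {len(truth.triplets)} "
          f"({config.n_triplets} ceRNA pairs x {config.shared_targets_per_triplet} shared miRNAs)")
    print(f"  planted DE features per layer: "
          f"{ {k: len(v) for k, v in truth.de_features.items()} }")
    print(f"  designated cis pairs (gap, expected_in): "
          f"{[(g, e) for _, _, g, e in truth.cis_pairs]}")
    print(f"  designated antisense pairs (complementarity, expected_in): "
          f"{[(c, e) for _, _, c, e in truth.antisense_pairs]}")


if __name__ == "__main__":
    main()
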