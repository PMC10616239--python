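"""Score the inferred network against the planted ground truth.

Loads the network from 05 and the truth table from 01, reports recall of
planted (lncRNA, miRNA, mRNA) triplets and the false-discovery proportion,
and repeats the whole simulate+infer cycle across seeds to report mean
operating characteristics alongside a pure-noise control.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cernapipe import SimConfig, evaluate_recovery, io_core, run_cerna_pipeline, simulate
from cernapipe.simulate import TruthTable


def run_once(config: SimConfig):
    res = simulate(config)
    network, _ = run_cerna_pipeline(
        res.mrna, res.lncrna, res.mirna, res.design, res.annotation, res.relations
    )
    return network, res.truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--network", type=Path, default=Path("results/network"))
    parser.add_argument("--out", type=Path, default=Path("results/recovery"))
    parser.add_argument("--seed", type=int, default=20240901)
    parser.add_argument("--n-seeds", type=int, default=10)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    network = io_core.read_network_tsv(args.network / "network.tsv")
    truth = TruthTable.from_json(args.data / "truth.json")
    recall, fdp, counts = evaluate_recovery(network, truth)
    print(f"this cohort: recall {recall:.3f}, FDP {fdp:.3f}, {counts}")

    recalls, fdps = [], []
    for i in range(args.n_seeds):
        net, tr = run_once(SimConfig(seed=args.seed + i))
        r, f, _ = evaluate_recovery(net, tr)
        recalls.append(r)
        fdps.append(f)
    print(f"across {args.n_seeds} seeds: mean recall {np.mean(recalls):.3f}, "
          f"mean FDP {np.mean(fdps):.3f}")

    empty = 0
    n_null = 20
    for i in range(n_null):
        net, _ = run_once(
            SimConfig(seed=args.seed + 1000 + i, n_triplets=0, n_de_per_layer=0)
        )
        empty += not net.edges
    print(f"pure-noise control: empty final network in {empty}/{n_null} runs")

    summary = {
        "cohort_recall": recall,
        "cohort_fdp": fdp,
        "mean_recall": float(np.mean(recalls)),
        "mean_fdp": float(np.mean(fdps)),
        "null_empty_fraction": empty / n_null,
    }
    (args.out / "recovery.json").write_text(json.dumps(summary, indent=1))
    print(f"wrote {args.out / 'recovery.json'}")


if __name__ == "__main__":
    main()
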