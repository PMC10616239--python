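"""Build the ceRNA network from counts, design, annotation and predictions.

Runs the full screen — DE per layer, Spearman miRNA-target screen
(rho <= -0.7), Pearson ceRNA-pair screen (r > 0.9), shared-miRNA
hypergeometric test (p <= 0.05) — and exports the final network as
TSV, SIF and GraphML plus the stage-count report.
"""

import argparse
import json
from pathlib import Path

from cernapipe import io_core, run_cerna_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/network"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    network, report = run_cerna_pipeline(
        mrna_counts=io_core.read_counts(args.data / "mrna_counts.tsv", "mRNA"),
        lncrna_counts=io_core.read_counts(args.data / "lncrna_counts.tsv", "lncRNA"),
        mirna_counts=io_core.read_counts(args.data / "mirna_counts.tsv", "miRNA"),
        design=io_core.read_design(args.data / "design.tsv"),
        annotation=io_core.read_annotation(args.data / "annotation.gtf"),
        relations=io_core.read_predictions(args.data / "mirna_targets.tsv"),
    )

    for stage, count in report.items():
        if not isinstance(count, dict):
            print(f"  {stage}: {count}")
    classes = list(network.nodes.values())
    print(f"final network: {len(network.nodes)} nodes "
          f"({classes.count('lncRNA')} lncRNA, {classes.count('miRNA')} miRNA, "
          f"{classes.count('mRNA')} mRNA), {len(network.edges)} edges")

    io_core.write_network(network, args.out / "network.tsv", "TSV")
    io_core.write_network(network, args.out / "network.sif", "SIF")
    io_core.write_network(network, args.out / "network.graphml", "GraphML")
    (args.out / "report.json").write_text(json.dumps(report, indent=1))
    print(f"wrote network + report to {args.out}")


if __name__ == "__main__":
    main()
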