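"""Target prediction: lncRNA strategies and miRNA seed matching.

Runs the three lncRNA target strategies (cis within 10 kb, antisense
opposite-strand overlap with sequence complementarity, trans
co-expression), the miRNA 7-mer seed-match predictor, and the
two-predictor intersection rule on the externally supplied tables.
Writes one predictions TSV per strategy under results/targets/.
"""

import argparse
from pathlib import Path

from cernapipe import io_core
from cernapipe.targets import (
    intersect_predictions,
    predict_antisense,
    predict_cis,
    predict_seed_targets,
    predict_trans,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--normalized", type=Path, default=Path("results/normalized"))
    parser.add_argument("--out", type=Path, default=Path("results/targets"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = io_core.read_annotation(args.data / "annotation.gtf")
    lncrnas = [a for a in annotation if a.biotype == "lncRNA"]
    genes = [a for a in annotation if a.biotype == "mRNA"]

    cis = predict_cis(lncrnas, genes)
    print(f"cis (gap <= 10 kb): {len(cis)} lncRNA-gene pairs")

    anti = predict_antisense(
        lncrnas,
        genes,
        lnc_seqs=io_core.read_fasta(args.data / "antisense_lnc.fasta"),
        gene_seqs=io_core.read_fasta(args.data / "antisense_gene.fasta"),
    )
    print(f"antisense (opposite-strand overlap, complementarity >= 0.5): {len(anti)}")

    lnc_expr = io_core.read_counts(args.normalized / "lncrna_fpkm.tsv", "lncRNA", "FPKM")
    gene_expr = io_core.read_counts(args.normalized / "mrna_fpkm.tsv", "mRNA", "FPKM")
    trans = predict_trans(lnc_expr, gene_expr)
    print(f"trans (|Pearson r| >= 0.9, p <= 0.05): {len(trans)}")

    seed = predict_seed_targets(
        io_core.read_fasta(args.data / "mirna_mature.fasta"),
        {
            **io_core.read_fasta(args.data / "mrna_utr.fasta"),
            **io_core.read_fasta(args.data / "lncrna_seq.fasta"),
        },
    )
    print(f"seed-match (7-mer, miRNA positions 2-8): {len(seed)} miRNA-target relations")

    final = intersect_predictions(
        io_core.read_predictions(args.data / "predictor_a.tsv"),
        io_core.read_predictions(args.data / "predictor_b.tsv"),
    )
    print(f"intersection of the two external predictors: {len(final)} final targets")

    for name, rels in (
        ("cis", cis),
        ("antisense", anti),
        ("trans", trans),
        ("seed_match", seed),
        ("intersection", final),
    ):
        io_core.write_predictions(rels, args.out / f"{name}.tsv")
    print(f"wrote prediction tables to {args.out}")


if __name__ == "__main__":
    main()
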