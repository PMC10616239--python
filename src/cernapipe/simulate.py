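"""Synthetic multi-layer RNA-seq generator with planted ceRNA structure.

Emulates the study design every stage of the pipeline assumes: two groups of
``n_per_group`` samples (default 3 + 3), three RNA layers (mRNA, lncRNA,
miRNA) of negative-binomial counts, planted differential features at a
stated fold change, planted lncRNA-miRNA-mRNA triplets with strong negative
miRNA-ceRNA rank correlation and strong positive lncRNA-mRNA correlation,
planted miRNA-target relations giving small shared-miRNA hypergeometric p,
and a genomic architecture with designated cis neighbours straddling the
10 kb boundary and antisense opposite-strand overlaps. Everything is
deterministic given the seed, and the ground truth is returned alongside
the data.

Planting strategy
-----------------
Each triplet is driven by a per-sample latent vector ``z`` whose group means
are separated (so every triplet member is differentially expressed) and
whose within-group spread keeps sample ranks informative. The lncRNA and
mRNA log-means move with two deterministic rotations of ``z`` whose sample
correlation equals the Pearson target after discounting the count noise;
the miRNA moves against a rank-permuted copy of ``z`` whose rank correlation
with ``z`` is the closest achievable n=6 Spearman lattice value to the
requested target. Count noise (the negative-binomial dispersion) is then
the only stochastic degradation, so realized correlations concentrate near
their targets instead of showing the full sampling spread of an n=6
correlation coefficient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path

import numpy as np

from . import io_core
from .models import (
    CeRNANetwork,
    DesignTable,
    ExpressionMatrix,
    FeatureAnnotation,
    TargetRelation,
    ValidationError,
)
from .pipeline import network_triplets
from .targets import reverse_complement, seed_site

import pandas as pd


@dataclass
class GenomeConfig:
    """Chromosome lengths and placement rules for designated pairs."""

    n_random_chroms: int = 4
    chrom_length: int = 3_000_000
    designated_chrom: str = "chr_designated"
    cis_gaps: tuple = (9_999, 10_000, 10_001)
    cis_radius_bp: int = 10_000
    antisense_overlap_bp: int = 200
    block_spacing_bp: int = 100_000


@dataclass
class SimConfig:
    """All knobs of the generator; defaults mirror the emulated study design."""

    seed: int = 0
    n_per_group: int = 3
    n_mrna: int = 300
    n_lncrna: int = 150
    n_mirna: int = 100
    n_de_per_layer: int = 10  # planted DE features beyond the triplet members
    planted_log2fc: float = 1.64
    nb_dispersion: float = 0.05
    n_triplets: int = 20
    triplet_rho: float = -0.85  # target Spearman(miRNA, ceRNA)
    triplet_r: float = 0.95  # target Pearson(lncRNA, mRNA)
    mirna_universe: int | None = None  # defaults to n_mirna
    shared_targets_per_triplet: int = 2
    n_background_relations: int = 100
    genome: GenomeConfig = field(default_factory=GenomeConfig)

    # internal planting constants (see docs): latent group mean, within-group
    # half-spread, and log2 amplitude of the planted effect
    latent_group_mean: float = 1.3
    latent_spread: float = 0.45
    amplitude_log2: float = 2.2

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not -1.0 <= self.triplet_rho < 0.0:
            raise ValidationError("triplet_rho must lie in [-1, 0)")
        if not 0.0 < self.triplet_r <= 1.0:
            raise ValidationError("triplet_r must lie in (0, 1]")
        if self.n_triplets > 0:
            if self.triplet_rho > -0.55:
                raise ValidationError(
                    "infeasible triplet_rho: anti-correlation weaker than -0.55 "
                    "cannot coexist with group-separated (differential) triplet "
                    "members at n=3+3"
                )
            # Pearson target must survive the count-noise attenuation
            noise_var = self._noise_log2_var()
            signal_var = self.amplitude_log2**2 * self._latent_var()
            attenuation = signal_var / (signal_var + noise_var)
            if self.triplet_r > attenuation:
                raise ValidationError(
                    "infeasible triplet_r: count noise at this dispersion exceeds "
                    "the correlation budget; lower nb_dispersion or triplet_r"
                )
        need_mir = self.n_triplets * self.shared_targets_per_triplet + self.n_de_per_layer
        if need_mir > self.n_mirna:
            raise ValidationError("n_mirna too small for the planted structure")
        if self.n_triplets + self.n_de_per_layer + 10 > self.n_lncrna:
            raise ValidationError("n_lncrna too small for the planted structure")
        if self.n_triplets + self.n_de_per_layer + 10 > self.n_mrna:
            raise ValidationError("n_mrna too small for the planted structure")

    def _latent_var(self) -> float:
        return self.latent_group_mean**2 + (2.0 / 3.0) * self.latent_spread**2

    def _noise_log2_var(self) -> float:
        # log-scale variance of NB counts: Var[log X] ~ dispersion + 1/mu
        mu_ref = 450.0  # geometric mid of the triplet base-mean range
        return (self.nb_dispersion + 1.0 / mu_ref) / math.log(2.0) ** 2


@dataclass
class TruthTable:
    """Ground truth of one simulation run."""

    de_features: dict[str, dict[str, int]]  # layer -> {feature_id: +1/-1}
    triplets: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    target_relations: list[TargetRelation]  # planted miRNA -> ceRNA relations
    cis_pairs: list[tuple[str, str, int, bool]]  # (lnc, gene, gap, expected_in)
    antisense_pairs: list[tuple[str, str, float, bool]]  # (lnc, gene, comp, in)

    def to_json(self, path) -> None:
        payload = {
            "de_features": self.de_features,
            "triplets": [list(t) for t in self.triplets],
            "target_relations": [
                [r.regulator_id, r.target_id, r.mechanism, r.score]
                for r in self.target_relations
            ],
            "cis_pairs": [list(t) for t in self.cis_pairs],
            "antisense_pairs": [list(t) for t in self.antisense_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_features=payload["de_features"],
            triplets=[tuple(t) for t in payload["triplets"]],
            target_relations=[
                TargetRelation(regulator_id=a, target_id=b, mechanism=m, score=s)
                for a, b, m, s in payload["target_relations"]
            ],
            cis_pairs=[tuple(t) for t in payload["cis_pairs"]],
            antisense_pairs=[tuple(t) for t in payload["antisense_pairs"]],
        )


@dataclass
class SimResult:
    """Everything one simulation run produces."""

    config: SimConfig
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    design: DesignTable
    annotation: list[FeatureAnnotation]
    fastas: dict[str, dict[str, str]]
    predictor_a: list[TargetRelation]
    predictor_b: list[TargetRelation]
    relations: list[TargetRelation]  # planted + background (pipeline input)
    truth: TruthTable

    def write_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_core.write_counts(self.mrna, out / "mrna_counts.tsv")
        io_core.write_counts(self.lncrna, out / "lncrna_counts.tsv")
        io_core.write_counts(self.mirna, out / "mirna_counts.tsv")
        io_core.write_design(self.design, out / "design.tsv")
        io_core.write_annotation_gtf(self.annotation, out / "annotation.gtf")
        for name, seqs in self.fastas.items():
            if seqs:
                io_core.write_fasta(seqs, out / f"{name}.fasta")
        io_core.write_predictions(self.predictor_a, out / "predictor_a.tsv")
        io_core.write_predictions(self.predictor_b, out / "predictor_b.tsv")
        io_core.write_predictions(self.relations, out / "mirna_targets.tsv")
        self.truth.to_json(out / "truth.json")


@lru_cache(maxsize=None)
def _closest_rank_offset(target_rho: float, n: int, n_high: int) -> tuple[int, ...]:
    """Within-group position permutation planting the Spearman target.

    Order the samples by descending latent value; a permutation pi that maps
    position k to value-slot pi(k) of the ascending negated latent realizes
    Spearman(z, z_mir) = -corr(k, pi(k)). Only within-group re-orderings are
    considered so group separation (hence differential expression of the
    miRNA) is preserved; the achievable values form the n-sample Spearman
    lattice and the closest one to ``target_rho`` is chosen (ties -> more
    negative, then lexicographic for determinism).
    """
    k = np.arange(n, dtype=float)
    candidates = []
    for perm_hi in permutations(range(n_high)):
        for perm_lo in permutations(range(n_high, n)):
            perm = perm_hi + perm_lo
            rho = -float(np.corrcoef(k, np.array(perm, dtype=float))[0, 1])
            candidates.append((perm, rho))
    # count noise only weakens the realized rank correlation, so plant the
    # closest lattice value that is at least as strong as the target
    at_least = [(p, r) for p, r in candidates if r <= target_rho + 1e-12]
    pool = at_least if at_least else candidates
    best_perm, _ = min(pool, key=lambda pr: (abs(pr[1] - target_rho), pr[1], pr[0]))
    return best_perm


@lru_cache(maxsize=None)
def _pearson_pair_permutation(
    design_target: float,
    mir_perm: tuple[int, ...],
    target_rho: float,
    mu: float,
    spread: float,
    n: int,
    n_high: int,
) -> tuple[int, ...]:
    """Within-group position permutation planting the Pearson target.

    The mRNA latent re-uses the lncRNA latent's values, re-ordered within
    groups by sigma; the resulting Pearson correlation between the two
    latents sits on a deterministic lattice. Pick the lattice value closest
    to the (noise-inflated) design target, among permutations that keep the
    composed miRNA-mRNA rank correlation strong (<= -0.75), so the Pearson
    planting cannot silently break the Spearman edge to the mRNA.
    """
    offsets = spread * np.linspace(-1.0, 1.0, n_high)
    v = np.concatenate([mu + offsets[::-1], -mu + offsets[::-1]])  # descending
    vc = v - v.mean()
    pi = np.array(mir_perm, dtype=float)
    best_key, best_perm = None, None
    for perm_hi in permutations(range(n_high)):
        for perm_lo in permutations(range(n_high, n)):
            sigma = perm_hi + perm_lo
            sig_arr = np.array(sigma, dtype=float)
            c = float((vc @ vc[list(sigma)]) / (vc @ vc))
            mir_mrna_rho = -float(np.corrcoef(pi, sig_arr)[0, 1])
            feasible = mir_mrna_rho <= -0.75
            key = (
                not feasible,
                round(abs(c - design_target), 9),
                round(abs(mir_mrna_rho - target_rho), 9),
                -c,
                sigma,
            )
            if best_key is None or key < best_key:
                best_key, best_perm = key, sigma
    return best_perm


def _latent_vectors(config: SimConfig, rng: np.random.Generator, n: int, n_high: int):
    """Per-triplet latent vectors (z_lnc, z_mrna, z_mir) over samples.

    z is group-separated with a fixed within-group spread, randomly ordered
    within groups per triplet. The lncRNA latent is z itself; the mRNA
    latent re-orders z's values within groups so their correlation matches
    the Pearson target after count-noise attenuation; the miRNA latent is
    the negated copy of z re-ordered within groups to sit on the Spearman
    lattice value at least as strong as the target. All planted structure
    is deterministic, so count noise is the only stochastic degradation.
    """
    mu, spread, a = config.latent_group_mean, config.latent_spread, config.amplitude_log2
    offsets = spread * np.linspace(-1.0, 1.0, n_high)
    z = np.empty(n)
    z[:n_high] = mu + rng.permutation(offsets)
    z[n_high:] = -mu + rng.permutation(offsets)

    signal_var = a**2 * config._latent_var()
    noise_var = config._noise_log2_var()
    attenuation = signal_var / (signal_var + noise_var)
    design_target = min(config.triplet_r / attenuation, 1.0)

    order = np.argsort(-z)  # samples by descending z (HIGH precede LOW)
    values_desc = z[order]
    values_asc = np.sort(-z)  # negated, ascending: HIGH-destined first

    perm = _closest_rank_offset(config.triplet_rho, n, n_high)
    z_mir = np.empty(n)
    for pos, sample in enumerate(order):
        z_mir[sample] = values_asc[perm[pos]]

    sigma = _pearson_pair_permutation(
        design_target, perm, config.triplet_rho, mu, spread, n, n_high
    )
    z_mrna = np.empty(n)
    for pos, sample in enumerate(order):
        z_mrna[sample] = values_desc[sigma[pos]]

    z_lnc = z.copy()
    return z_lnc, z_mrna, z_mir


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


_NONPAIRING = {"A": "C", "G": "A", "C": "A", "T": "C", "U": "C"}


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic dataset plus its truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_high = config.n_per_group
    n = 2 * n_high
    samples = [f"H{i + 1}" for i in range(n_high)] + [f"L{i + 1}" for i in range(n_high)]
    design = DesignTable({s: ("HIGH" if s.startswith("H") else "LOW") for s in samples})
    group_sign = np.array([1.0] * n_high + [-1.0] * n_high)

    mrna_ids = [f"gene{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"lnc{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"mir{i + 1:03d}" for i in range(config.n_mirna)]

    s = config.shared_targets_per_triplet
    triplet_lnc = lnc_ids[: config.n_triplets]
    triplet_mrna = mrna_ids[: config.n_triplets]
    triplet_mirs = [
        mir_ids[t * s : (t + 1) * s] for t in range(config.n_triplets)
    ]
    n_tm = config.n_triplets * s
    extra_de = {
        "mRNA": mrna_ids[config.n_triplets : config.n_triplets + config.n_de_per_layer],
        "lncRNA": lnc_ids[config.n_triplets : config.n_triplets + config.n_de_per_layer],
        "miRNA": mir_ids[n_tm : n_tm + config.n_de_per_layer],
    }

    # log2 base means: log-uniform [20, 2000]; triplet members in [100, 2000]
    def base_means(ids, planted):
        lo, hi = np.log2(20.0), np.log2(2000.0)
        means = rng.uniform(lo, hi, size=len(ids))
        for i, fid in enumerate(ids):
            if fid in planted:
                means[i] = rng.uniform(np.log2(100.0), hi)
        return means

    planted_ids = set(triplet_lnc) | set(triplet_mrna) | {m for ms in triplet_mirs for m in ms}
    log_mu = {
        "mRNA": base_means(mrna_ids, planted_ids),
        "lncRNA": base_means(lnc_ids, planted_ids),
        "miRNA": base_means(mir_ids, planted_ids),
    }

    # per-feature per-sample log2 effects
    effects = {
        "mRNA": np.zeros((config.n_mrna, n)),
        "lncRNA": np.zeros((config.n_lncrna, n)),
        "miRNA": np.zeros((config.n_mirna, n)),
    }
    de_truth: dict[str, dict[str, int]] = {"mRNA": {}, "lncRNA": {}, "miRNA": {}}
    a = config.amplitude_log2
    triplets: list[tuple[str, str, str]] = []
    for t in range(config.n_triplets):
        z_lnc, z_mrna, z_mir = _latent_vectors(config, rng, n, n_high)
        orient = 1.0 if t % 2 == 0 else -1.0  # balance up/down across triplets
        effects["lncRNA"][t] = orient * a * z_lnc
        effects["mRNA"][t] = orient * a * z_mrna
        for m_id in triplet_mirs[t]:
            mi = mir_ids.index(m_id)
            effects["miRNA"][mi] = orient * a * z_mir
            triplets.append((triplet_lnc[t], m_id, triplet_mrna[t]))
        sign = int(orient)
        de_truth["lncRNA"][triplet_lnc[t]] = sign
        de_truth["mRNA"][triplet_mrna[t]] = sign
        for m_id in triplet_mirs[t]:
            de_truth["miRNA"][m_id] = -sign

    for layer, ids in (("mRNA", mrna_ids), ("lncRNA", lnc_ids), ("miRNA", mir_ids)):
        for j, fid in enumerate(extra_de[layer]):
            sign = 1 if j % 2 == 0 else -1
            idx = ids.index(fid)
            effects[layer][idx] += sign * config.planted_log2fc * group_sign / 2.0
            de_truth[layer][fid] = sign

    matrices = {}
    for layer, ids in (("mRNA", mrna_ids), ("lncRNA", lnc_ids), ("miRNA", mir_ids)):
        mean = 2.0 ** (log_mu[layer][:, None] + effects[layer])
        counts = _nb_counts(rng, mean, config.nb_dispersion)
        matrices[layer] = ExpressionMatrix(
            pd.DataFrame(counts, index=ids, columns=samples), layer=layer, unit="count"
        )

    annotation, cis_truth, antisense_truth, antisense_seqs = _build_annotation(
        config, rng, mrna_ids, lnc_ids, mir_ids
    )

    # sequences: miRNAs 22 nt; target regions 300 nt with planted seed sites
    bases = np.array(list("ACGU"))
    mir_seqs = {
        m: "".join(rng.choice(bases, size=22)) for m in mir_ids
    }
    planted_relations = []
    for lnc, mir, gene in triplets:
        planted_relations.append(
            TargetRelation(regulator_id=mir, target_id=lnc, mechanism="provided", score=0.0)
        )
        planted_relations.append(
            TargetRelation(regulator_id=mir, target_id=gene, mechanism="provided", score=0.0)
        )
    utr_seqs = {g: "".join(rng.choice(bases, size=300)) for g in mrna_ids}
    lnc_seqs = {l: "".join(rng.choice(bases, size=300)) for l in lnc_ids}
    for rel in planted_relations:
        site = seed_site(mir_seqs[rel.regulator_id])
        pool = utr_seqs if rel.target_id in utr_seqs else lnc_seqs
        seq = pool[rel.target_id]
        pos = int(rng.integers(0, len(seq) - len(site)))
        pool[rel.target_id] = seq[:pos] + site + seq[pos + len(site) :]

    # two predictor tables whose intersection is exactly the planted set
    all_targets = lnc_ids + mrna_ids
    planted_pairs = {(r.regulator_id, r.target_id) for r in planted_relations}

    def extra_relations(k, taken):
        out = []
        while len(out) < k:
            mir = mir_ids[int(rng.integers(0, len(mir_ids)))]
            tgt = all_targets[int(rng.integers(0, len(all_targets)))]
            if (mir, tgt) in planted_pairs or (mir, tgt) in taken:
                continue
            taken.add((mir, tgt))
            out.append(
                TargetRelation(regulator_id=mir, target_id=tgt, mechanism="provided")
            )
        return out

    used: set = set()
    predictor_a = planted_relations + extra_relations(40, used)
    predictor_b = planted_relations + extra_relations(40, used)
    background = extra_relations(config.n_background_relations, used)
    relations = planted_relations + background

    truth = TruthTable(
        de_features=de_truth,
        triplets=triplets,
        target_relations=planted_relations,
        cis_pairs=cis_truth,
        antisense_pairs=antisense_truth,
    )
    fastas = {
        "mirna_mature": mir_seqs,
        "mrna_utr": utr_seqs,
        "lncrna_seq": lnc_seqs,
        "antisense_lnc": antisense_seqs[0],
        "antisense_gene": antisense_seqs[1],
    }
    return SimResult(
        config=config,
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        design=design,
        annotation=annotation,
        fastas=fastas,
        predictor_a=predictor_a,
        predictor_b=predictor_b,
        relations=relations,
        truth=truth,
    )


def _build_annotation(config, rng, mrna_ids, lnc_ids, mir_ids):
    """Place features on the genome; designated cis/antisense pairs on a
    dedicated chromosome in well-separated blocks."""
    g = config.genome
    annotation: list[FeatureAnnotation] = []
    lengths = {"mRNA": (1000, 3000), "lncRNA": (500, 2000), "miRNA": (60, 120)}

    n_cis = len(g.cis_gaps)
    cis_lnc = lnc_ids[-n_cis:]
    cis_gene = mrna_ids[-n_cis:]
    anti_lnc = lnc_ids[-n_cis - 4 : -n_cis]
    anti_gene = mrna_ids[-n_cis - 4 : -n_cis]
    designated = set(cis_lnc + cis_gene + anti_lnc + anti_gene)

    for layer, ids in (("mRNA", mrna_ids), ("lncRNA", lnc_ids), ("miRNA", mir_ids)):
        lo, hi = lengths[layer]
        for fid in ids:
            if fid in designated:
                continue
            length = int(rng.integers(lo, hi))
            chrom = f"chr{int(rng.integers(1, g.n_random_chroms + 1))}"
            start = int(rng.integers(0, g.chrom_length - length))
            strand = "+" if rng.random() < 0.5 else "-"
            annotation.append(
                FeatureAnnotation(fid, chrom, start, start + length, strand, layer, length)
            )

    cis_truth = []
    block = 0
    for gap, lnc, gene in zip(g.cis_gaps, cis_lnc, cis_gene):
        base = block * g.block_spacing_bp
        lnc_iv = (base, base + 1000)
        gene_iv = (base + 1000 + gap, base + 1000 + gap + 800)
        annotation.append(
            FeatureAnnotation(lnc, g.designated_chrom, *lnc_iv, "+", "lncRNA", 1000)
        )
        annotation.append(
            FeatureAnnotation(gene, g.designated_chrom, *gene_iv, "+", "mRNA", 800)
        )
        cis_truth.append((lnc, gene, gap, gap <= g.cis_radius_bp))
        block += 1

    antisense_truth = []
    lnc_fa: dict[str, str] = {}
    gene_fa: dict[str, str] = {}
    bases = np.array(list("ACGU"))
    # (non-complementary fraction over the overlap, gene strand,
    #  expected to pass at the default 0.5 complementarity threshold)
    plans = [(0.02, "-", True), (0.20, "-", True), (0.60, "-", False), (0.02, "+", False)]
    ov = g.antisense_overlap_bp
    for (mut, gene_strand, expected), lnc, gene in zip(plans, anti_lnc, anti_gene):
        base = block * g.block_spacing_bp
        # plus-strand genomic segment [base, base+600); lnc covers [0, 200+ov)
        # of it on '+', the gene covers [200, 600) so the overlap is
        # [200, 200+ov) with ov = 200
        genomic = "".join(rng.choice(bases, size=600))
        lnc_fa[lnc] = genomic[: 200 + ov]
        if gene_strand == "-":
            gene_list = list(reverse_complement(genomic[200:600]).replace("T", "U"))
            n_mut = int(round(mut * ov))
            mut_pos = sorted(int(p) for p in rng.choice(ov, size=n_mut, replace=False))
            for p in mut_pos:
                x = 200 + p  # genomic segment position inside the overlap
                # '-'-strand transcript index facing genomic position x
                idx = (600 - x) - 1
                gene_list[idx] = _NONPAIRING[genomic[x].replace("T", "U")]
            gene_fa[gene] = "".join(gene_list)
            comp = 1.0 - n_mut / ov
        else:
            gene_fa[gene] = genomic[200:600]
            comp = 0.0
        annotation.append(
            FeatureAnnotation(
                lnc, g.designated_chrom, base, base + 200 + ov, "+", "lncRNA", 200 + ov
            )
        )
        annotation.append(
            FeatureAnnotation(
                gene, g.designated_chrom, base + 200, base + 600, gene_strand, "mRNA", 400
            )
        )
        antisense_truth.append((lnc, gene, comp, expected))
        block += 1

    return annotation, cis_truth, antisense_truth, (lnc_fa, gene_fa)


def evaluate_recovery(
    network: CeRNANetwork, truth: TruthTable
) -> tuple[float, float, dict]:
    """Recall and false-discovery proportion of planted triplets.

    A planted (lncRNA, miRNA, mRNA) triplet is recovered when the final
    network contains its ceRNA pair and miRNA-target edges from that miRNA
    to both partners. FDP counts final-network triplets that were not
    planted (0 when the network implies no triplets).
    """
    final = network_triplets(network)
    planted = {(l, m, g) for l, m, g in truth.triplets}
    recovered = planted & final
    recall = len(recovered) / len(planted) if planted else 1.0
    fdp = len(final - planted) / len(final) if final else 0.0
    counts = {
        "planted": len(planted),
        "final": len(final),
        "recovered": len(recovered),
        "false": len(final - planted),
    }
    return recall, fdp, counts
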