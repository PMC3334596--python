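"""Randomization controls and the synthetic-data generator.

The controls operate on real input: synonymous-codon resampling that
preserves each protein sequence and the genome-wide codon bias, slow-codon
permutation within genes, and per-gene density permutation.

The synthetic generator emulates the statistical structure the analysis
assumes: a genome whose first ~R codons are enriched for low-adaptiveness
codons, positively charged residues and folding-prone composition (the
"ramp"), a weak-folding first few codons, protein abundance increasing with
gene tAI up to multiplicative noise, and ribosome densities produced by the
package's own traffic model at known parameters plus noise.  The ground
truth (parameters, ramp length, slow set) is recorded for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .seq_core import (
    CHARGE,
    CodingSequence,
    ExpressionTable,
    Genome,
    SENSE_CODONS,
    STANDARD_CODE,
)
from . import tai as tai_mod
from .tai import CodonWeights, TRNAPool, codon_weights


def codon_usage(genome: Genome) -> Dict[str, int]:
    counts: Dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for g in genome:
        for c in g.codons:
            counts[c] += 1
    return counts


def randomize_genome(genome: Genome, seed: int = 0) -> Genome:
    """Resample every codon synonymously from the genome-wide usage.

    Each codon is replaced by a codon of the same amino acid, drawn from the
    genome's synonymous-frequency distribution, preserving every protein
    sequence exactly and the codon bias in expectation.
    """
    rng = np.random.default_rng(seed)
    usage = codon_usage(genome)
    by_aa: Dict[str, Tuple[List[str], np.ndarray]] = {}
    for aa in set(STANDARD_CODE.values()):
        syn = sorted(c for c, a in STANDARD_CODE.items() if a == aa)
        freqs = np.array([usage[c] for c in syn], dtype=float)
        if freqs.sum() == 0:
            freqs = np.ones(len(syn))
        by_aa[aa] = (syn, freqs / freqs.sum())
    genes = []
    for g in genome:
        new_codons = []
        for c in g.codons:
            syn, p = by_aa[STANDARD_CODE[c]]
            new_codons.append(syn[rng.choice(len(syn), p=p)])
        genes.append(
            CodingSequence(g.gene_id, "".join(new_codons), utr5=g.utr5, utr3=g.utr3)
        )
    return Genome(genes, organism=genome.organism)


def permute_slow_codons(
    gene: CodingSequence,
    weights: CodonWeights,
    slow_fraction: float = 0.10,
    seed: int = 0,
    slow_set: Optional[Set[str]] = None,
) -> CodingSequence:
    """Shuffle the gene's slow codons among the positions they occupy.

    Positions holding slow codons exchange their codons uniformly at
    random; fast codons are untouched, so the codon multiset and the set of
    slow positions are both preserved.
    """
    from .profiles import slow_codon_set

    slow = slow_set if slow_set is not None else slow_codon_set(weights, slow_fraction)
    codons = gene.codons
    idx = [i for i, c in enumerate(codons) if c in slow]
    if len(idx) < 2:
        return CodingSequence(gene.gene_id, gene.cds, utr5=gene.utr5, utr3=gene.utr3)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(idx))
    new = list(codons)
    for slot, src in zip(idx, perm):
        new[slot] = codons[idx[src]]
    return CodingSequence(gene.gene_id, "".join(new), utr5=gene.utr5, utr3=gene.utr3)


def permute_density(
    table: Dict[str, np.ndarray], seed: int = 0
) -> Dict[str, np.ndarray]:
    """Independently permute each gene's density vector (multiset kept)."""
    rng = np.random.default_rng(seed)
    return {
        gid: np.asarray(v)[rng.permutation(len(v))] for gid, v in table.items()
    }


@dataclass
class SynthSpec:
    """Study conditions for the synthetic genome.

    Defaults: 200 genes of 300 codons, a 40-codon 5' ramp of strength 1
    (low-adaptiveness codons and positively charged residues boosted, the
    first 5 codons AT-rich / weak-folding), densities from the traffic
    model at a* = (1.0, 0.4, 0.2) with multiplicative lognormal noise
    sigma = 0.3 and per-codon dropout 0.2, protein abundance monotone in
    gene tAI with lognormal noise 0.3.
    """

    n_genes: int = 200
    length_mean: int = 300
    length_sd: int = 0
    ramp_length: int = 40
    ramp_strength: float = 1.0
    weak_fold_start: int = 5
    optimality_exponent: float = 1.0  # mean bias toward high-w codons
    optimality_spread: float = 1.0  # gene-to-gene half-range of the bias
    positive_charge_bias: float = 1.3  # mild genome-wide excess of +residues
    n_anticodons: int = 40
    abundance_noise: float = 0.3
    abundance_slope: float = 4.0
    density_a: Tuple[float, float, float] = (1.0, 0.4, 0.2)
    density_noise: float = 0.3
    density_dropout: float = 0.2
    utr3_len: int = 60
    tunnel_len: int = 31
    seed: int = 0
    #: generate densities (requires folding the whole genome); sequence-only
    #: studies (e.g. ramp detection on tAI/charge) can skip it
    with_density: bool = True

    def __post_init__(self) -> None:
        if self.ramp_length < 0 or self.ramp_strength < 0:
            raise ValueError("ramp parameters must be >= 0")
        if self.density_noise < 0 or self.abundance_noise < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class SynthResult:
    genome: Genome
    pool: TRNAPool
    weights: CodonWeights
    expression: ExpressionTable
    densities: Dict[str, np.ndarray]
    truth: dict


def _sample_pool(rng: np.random.Generator, spec: SynthSpec) -> TRNAPool:
    """Heavy-tailed tRNA gene copy numbers over a subset of anticodons.

    Every amino acid keeps at least one Watson-Crick decoder so all sense
    codons stay usable.
    """
    wc_anticodon = {c: tai_mod._revcomp(c) for c in SENSE_CODONS}
    by_aa: Dict[str, List[str]] = {}
    for c in SENSE_CODONS:
        by_aa.setdefault(STANDARD_CODE[c], []).append(c)
    chosen: Set[str] = set()
    for aa, codons in sorted(by_aa.items()):
        pick = codons[rng.integers(len(codons))]
        chosen.add(wc_anticodon[pick])
    all_acs = sorted({wc_anticodon[c] for c in SENSE_CODONS} - chosen)
    extra = rng.permutation(len(all_acs))[: max(0, spec.n_anticodons - len(chosen))]
    chosen.update(all_acs[i] for i in extra)
    copies = {
        ac: int(min(rng.zipf(1.8), 25)) for ac in sorted(chosen)
    }
    return TRNAPool(copies)


def _position_weights(
    spec: SynthSpec, weights: CodonWeights, in_ramp: bool, weak_fold: bool
) -> np.ndarray:
    """Sampling weight per sense codon for one position class.

    Background codons follow an optimality bias (probability proportional
    to w ** exponent); inside the ramp the lowest-decile-w codons get a
    bounded multiplicative boost of (1 + 9 * strength), positive residues a
    (1 + strength) boost, and GC-rich codons a folding-prone tilt.
    """
    from .profiles import slow_codon_set

    w = np.array([weights.w[c] for c in SENSE_CODONS])
    charge = np.array(
        [CHARGE[STANDARD_CODE[c]] for c in SENSE_CODONS], dtype=float
    )
    gc = np.array([sum(nt in "GC" for nt in c) / 3.0 for c in SENSE_CODONS])
    slow = np.array(
        [c in slow_codon_set(weights) for c in SENSE_CODONS], dtype=float
    )
    logp = spec.optimality_exponent * np.log(w)
    logp += np.log(spec.positive_charge_bias) * (charge > 0)
    if in_ramp:
        s = spec.ramp_strength
        logp += np.log1p(9.0 * s) * slow  # boost low-adaptiveness codons
        logp += np.log1p(s) * (charge > 0)  # boost positive residues
        logp += 1.0 * s * gc  # folding-prone composition
    if weak_fold:
        logp -= 2.0 * gc  # AT-rich, weak folding right after the start
    p = np.exp(logp - logp.max())
    return p / p.sum()


def synth_genome(spec: Optional[SynthSpec] = None) -> SynthResult:
    """Generate a full synthetic data set with recorded ground truth."""
    from .folding import ToyBackend, genome_fe_vectors
    from .profiles import slow_codon_set
    from .simulate import genome_norms, nominal_times
    from .tai import gene_tai

    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    pool = _sample_pool(rng, spec)
    weights = codon_weights(pool)

    genes = []
    n_codon = len(SENSE_CODONS)
    for k in range(spec.n_genes):
        # gene-to-gene variation in codon-optimality bias: the synthetic
        # analogue of expression-driven codon bias, and what makes gene tAI
        # (and hence protein abundance) vary across genes
        gene_spec = replace(
            spec,
            optimality_exponent=float(
                rng.uniform(
                    max(0.0, spec.optimality_exponent - spec.optimality_spread),
                    spec.optimality_exponent + spec.optimality_spread,
                )
            ),
        )
        p_bg = _position_weights(gene_spec, weights, in_ramp=False, weak_fold=False)
        p_ramp = _position_weights(gene_spec, weights, in_ramp=True, weak_fold=False)
        p_weak = _position_weights(gene_spec, weights, in_ramp=True, weak_fold=True)
        if spec.length_sd > 0:
            length = max(60, int(rng.normal(spec.length_mean, spec.length_sd)))
        else:
            length = spec.length_mean
        n_weak = min(spec.weak_fold_start, spec.ramp_length, length) - 1
        n_weak = max(n_weak, 0)
        n_ramp = max(min(spec.ramp_length, length) - 1 - n_weak, 0)
        n_bg = length - 1 - n_weak - n_ramp
        draws = np.concatenate(
            [
                rng.choice(n_codon, n_weak, p=p_weak),
                rng.choice(n_codon, n_ramp, p=p_ramp),
                rng.choice(n_codon, n_bg, p=p_bg),
            ]
        )
        codons = ["ATG"] + [SENSE_CODONS[i] for i in draws]
        utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, spec.utr3_len))
        genes.append(
            CodingSequence(f"g{k:04d}", "".join(codons), utr3=utr3)
        )
    genome = Genome(genes, organism="synthetic")

    tai_by_gene = {g.gene_id: gene_tai(g.codons, weights) for g in genome}
    noise = rng.normal(0.0, spec.abundance_noise, spec.n_genes)
    abundance = {
        g.gene_id: float(
            np.exp(spec.abundance_slope * tai_by_gene[g.gene_id] + noise[i])
        )
        for i, g in enumerate(genome)
    }
    mrna = {
        gid: float(v ** 0.5 * np.exp(rng.normal(0.0, spec.abundance_noise)))
        for gid, v in abundance.items()
    }
    expression = ExpressionTable(mrna_level=mrna, protein_abundance=abundance)

    densities: Dict[str, np.ndarray] = {}
    times = {}
    fe_vectors: Dict[str, np.ndarray] = {}
    norms = None
    if not spec.with_density:
        truth = {
            "a": spec.density_a,
            "ramp_length": spec.ramp_length,
            "slow_codons": sorted(slow_codon_set(weights)),
            "gene_tai": tai_by_gene,
        }
        return SynthResult(genome, pool, weights, expression, densities, truth)
    backend = ToyBackend()
    fe_vectors = genome_fe_vectors(genome, backend)
    norms = genome_norms(genome, weights, fe_vectors, spec.tunnel_len)
    for g in genome:
        nt = nominal_times(
            g, weights, fe_vectors[g.gene_id], norms,
            a=spec.density_a, tunnel_len=spec.tunnel_len,
        )
        times[g.gene_id] = nt
        d = nt.t.copy()
        if spec.density_noise > 0:
            d *= np.exp(rng.normal(0.0, spec.density_noise, len(d)))
        if spec.density_dropout > 0:
            drop = rng.random(len(d)) < spec.density_dropout
            d[drop] = np.nan
        densities[g.gene_id] = d

    truth = {
        "a": spec.density_a,
        "ramp_length": spec.ramp_length,
        "slow_codons": sorted(slow_codon_set(weights)),
        "gene_tai": tai_by_gene,
        "norms": norms,
        "nominal_times": times,
        "fe_vectors": fe_vectors,
    }
    return SynthResult(genome, pool, weights, expression, densities, truth)


def write_synth(result: SynthResult, outdir) -> None:
    """Write the synthetic data set in the formats the loaders read."""
    import json
    from pathlib import Path

    import pandas as pd

    from .profiles import write_density_table
    from .seq_core import write_expression, write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(result.genome, outdir / "genome.fasta")
    pd.DataFrame(
        sorted(result.pool.copies.items()), columns=["anticodon", "copies"]
    ).to_csv(outdir / "trna_pool.tsv", sep="\t", index=False)
    write_expression(result.expression, outdir / "expression.tsv")
    write_density_table(result.densities, outdir / "density.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "a": list(result.truth["a"]),
                "ramp_length": result.truth["ramp_length"],
                "slow_codons": result.truth["slow_codons"],
            },
            fh,
            indent=2,
        )
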