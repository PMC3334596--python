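# ribotraffic

Quantifying how three coding-sequence determinants shape the speed and
density of translating ribosomes:

* **tRNA-pool adaptation** — how well each codon is served by the cellular
  tRNA pool, measured by the tRNA adaptation index (tAI);
* **amino-acid charge** — positively charged residues (Arg, His, Lys) in the
  negatively charged ribosomal exit tunnel (~31 residues) slow elongation;
* **local mRNA folding** — the minimum free energy of the 40-nt window
  downstream of each codon, which the ribosome's helicase must unwind.

The package is aimed at researchers studying translation-elongation
regulation: it builds metagene profiles of these determinants and of
ribosome densities, detects the 5' "ramp" of slow codons, scans coding
sequences for robustness to single-nucleotide transcription errors, and
turns the determinants into per-codon translation times that drive both a
deterministic and a stochastic ribosome-traffic model (a TASEP with
extended particles). A synthetic-genome generator with recorded ground
truth makes every stage testable end-to-end.

## The model

For codon *i* of a gene, the relative adaptiveness is
`w_i = W_i / max_j W_j` with `W_i = Σ_j (1 − S_ij) · tCGN_ij`, summing over
the anticodons that decode codon *i* (`tCGN_ij` = tRNA gene copy number,
`S_ij` = wobble-pairing penalty). The tAI of a gene is the geometric mean
of its codons' `w`. The nominal translation time of codon *i* combines the
three determinants, each normalized to genome mean 1:

```
t_i = a1 · Ntai(i) · exp(a2 · Nch(i) + a3 · Nfe(i))
```

where `Ntai ∝ 1/w_i`, `Nch` is the summed charge of the ≤31 residues
upstream (the exit-tunnel load), and `Nfe` the folding energy of the 40-nt
window starting at the codon. `a1, a2, a3 ∈ [0, 1]` are fitted by grid
search against observed ribosome-density profiles. Ribosome traffic is
simulated either by a deterministic max-plus recurrence (a ribosome is
delayed until the one downstream clears its footprint of *l* = 13 codons)
or by an event-driven stochastic exclusion process with initiation rate λ
and hopping rates `λ_i ∝ 1/t_i`.

The 5' ramp of a positional profile is detected by sliding 13-codon
windows over the first 200 codons, testing each (one-sided KS) against the
rest; a run of consecutive significant windows starting within the first
five codons defines the ramp, of length (number of windows + 12).

## Worked example

```python
import numpy as np
from ribotraffic import (
    SynthSpec, detect_ramp, feature_vectors, fit_abc, synth_genome,
)

# a synthetic genome: 100 genes x 300 codons with a planted 40-codon ramp,
# densities from the traffic model at a* = (1.0, 0.4, 0.2) plus noise
data = synth_genome(SynthSpec(n_genes=100, length_mean=300, seed=1))

tai = feature_vectors(data.genome, "tai", weights=data.weights)
ramp = detect_ramp(list(tai.values()), direction="lower")
print(f"ramp present: {ramp.present}, start: {ramp.start}, "
      f"length: {ramp.length} codons")

(a1, a2, a3), rho = fit_abc(
    data.truth["nominal_times"], data.densities, max_positions=None
)
print(f"fitted (a1, a2, a3) = ({a1}, {a2}, {a3}); "
      f"profile Spearman = {rho:.3f}")
```

prints

```
ramp present: True, start: 1, length: 47 codons
fitted (a1, a2, a3) = (1.0, 0.3, 0.15); profile Spearman = 0.891
```

The planted 40-codon ramp is recovered at length 47 (window resolution is
±13 codons), and the translation-time parameters are recovered within two
grid steps of the generating values despite 30% multiplicative density
noise and 20% per-codon dropout; on noiseless densities the recovery is
exact.

The same pipelines are available from the shell:

```
ribotraffic synth --out data --seed 1
ribotraffic ramp  --genome data/genome.fasta --pool data/trna_pool.tsv \
                  --feature tai --out ramp.json
ribotraffic fit   --genome data/genome.fasta --pool data/trna_pool.tsv \
                  --density data/density.tsv --out fit.json
```

## Layout

| module | contents |
| --- | --- |
| `seq_core` | coding-sequence data model, genetic code, charge, FASTA/TSV I/O |
| `tai` | codon adaptiveness from tRNA copy numbers, wobble penalties, S-vector refitting |
| `folding` | folding backends, 40-nt window energy vectors, base-pair-set distances |
| `profiles` | start/end-aligned metagene profiles, smoothing, group and PARS profiles |
| `stats` | KS tests, (partial) Spearman correlations, density regressor, cross-validation |
| `ramp` | 5' ramp detection and its two profile-level P-values |
| `robustness` | single-nucleotide mutational scans of folding/charge/tAI |
| `simulate` | nominal times, deterministic and stochastic traffic, parameter fitting, bottlenecks |
| `generators` | randomization controls and the synthetic-genome generator |
| `cli` | `ribotraffic` command-line interface |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
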