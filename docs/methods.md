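# Methods

## Scope and data model

The package analyses protein-coding genes as codon sequences. Sequences
are stored in the DNA alphabet (`U` converted to `T` on input), trailing
stop codons are stripped at load time, and genes with internal stops or
lengths not divisible by 3 are skipped with a logged warning. Codon
indices are 0-based internally and 1-based in all reports. No minimum gene
length is imposed: short genes simply contribute to fewer profile
positions (per-position denominators vary). An optional
`min_length_codons` filter exists for callers who want length-restricted
gene sets.

## tRNA adaptation index

Absolute adaptiveness of codon *i* is `W_i = Σ_j (1 − S_ij) · tCGN_ij`
over the anticodons that decode it; relative adaptiveness `w_i` divides by
the maximum `W`. The codon:anticodon relations follow the standard
wobble scheme, shipped as an inspectable data file
(`data/wobble_scheme.tsv`): each codon is reached by its Watson–Crick
anticodon (penalty classes I:U, G:C, U:A, C:G, starting at 0) and by one
wobble anticodon determined by its third position — G34 reads NNU (G:U,
0.41), inosine reads NNC (I:C, 0.28) and NNA (I:A, 0.9999), U34 reads NNG
(U:G, 0.68). The rule is applied uniformly to all 61 sense codons;
anticodons whose Watson–Crick codon is a stop are never counted as
decoders (which removes the spurious U34 decoder of Trp). Organism-
specific tRNA modifications (e.g. lysidine for bacterial Ile-AUA) are not
modelled.

Codons with `w = 0` (no decoder in the pool) receive the geometric mean of
the non-zero `w` values, so a single undecodable codon does not zero a
gene's tAI. Gene tAI is the geometric mean of codon `w` over sense codons.

The wobble penalties can be refitted to expression data by hill-climbing
the Spearman correlation between gene tAI and protein abundance:
coordinate-wise ±0.05 proposals clamped to [0, 1], strictly improving
steps only, optional random restarts, all seeded. The trace is monotone
and the result deterministic for fixed inputs and seed.

## Folding

A folding backend is a pure map `sequence → (energy, dot-bracket)`. The
production backend is ViennaRNA MFE folding at default parameters (37 °C).
The built-in default ("toy") backend is a Nussinov maximum-base-pairing
model — WC + GU pairs, minimum hairpin loop 3, energy −1 kcal/mol per
pair — whose traceback returns the unique maximum-pairing structure with
the lexicographically smallest pair list. It exists so the whole pipeline
(including the 120-mutant folding scans) runs deterministically and
quickly with no external dependency; it is validated against exhaustive
enumeration for all sequences up to 12 nt. Energies are cached per
backend instance.

Per-codon folding vectors use 40-nt windows starting at the codon's first
nucleotide, extending into the 3'UTR where one is provided. Windows that
cannot reach 40 nt are recorded as missing rather than folded short,
because profiles average fixed-width windows (`fold_short_tails` flips
this). Windows for the first codons use CDS sequence only; 5'UTR-anchored
windows are available separately with negative codon offsets.

## Profiles

Positional profiles line genes up at the start codon or at the last sense
codon and average any per-codon quantity position-wise; missing entries
drop out of numerator and denominator, and per-position gene counts are
reported. The mean is the default aggregator (a median option exists).
Start-aligned determinant vectors drop the initiator codon by default:
position 1 is constitutionally ATG, and including it plants an artificial
fixed value at the first profile position that the ramp test would flag in
any genome. Profiles default to the first 200 codons (600 nt for
per-nucleotide pairing-score profiles); end-aligned offsets are negative
integers counted from the last sense codon.

Smoothing is a centred five-point moving average whose window shrinks at
the edges. Gene groups (e.g. top/bottom 10% by expression × density) are
selected by ranked key with deterministic gene-id tie-breaking. The
identical-slow-codon pair profile scores adjacent identical slow codons
(lowest-decile `w`); a same-window co-occurrence variant is available.

## Ramp detection

Sliding 13-codon windows over the first 200 codons are each compared by a
one-sided two-sample KS test against all values outside the window
(within the region). Windows may carry one observation per position (a
mean profile) or the pooled per-gene values (the default for genome-scale
data, which gives the KS test real sample sizes). A maximal run of
consecutive significant windows (P ≤ 0.05) whose first window starts
within the first five codons defines the ramp; its length is the run
length plus 12. Detection is invariant under strictly monotone transforms
of the values and never shrinks as alpha grows. Because adjacent windows
overlap, the false-detection rate on ramp-free genomes exceeds the nominal
alpha; it is measured (≈0.1 at alpha 0.05) by the acceptance script.
Directions per feature: tAI lower, folding energy lower, charge higher —
slower in each case. Two profile-level P-values accompany a detected
ramp: pooled in-ramp values vs the rest of the region, and in-ramp values
of the real vs a synonymously randomized genome.

## Robustness scans

Folding robustness enumerates all 40 × 3 single-nucleotide substitutions
of each 40-nt window, folds every mutant, and aggregates |ΔFE|, the
base-pair-set symmetric difference, and structure-changed/preserved
counts. Charge and tAI robustness enumerate the 13 × 9 substitutions of
13-codon windows, scoring |Δcharge| and |Δw| of the mutated codon.
Mutants that create stop codons are excluded from the codon-level scans (a
premature stop is neither a charge nor a decoding change;
`count_stops_as_changes` flips this); nucleotide-level folding scans keep
all 120 mutants. Mutations are weighted by a transition:transversion
ratio (default 1:1, with 2:1 as the biologically motivated variant) and by
per-codon-position weights (default uniform; 1, 0.1, 1 emulates the rarity
of second-position translation errors). All aggregates are exactly
reproduced by an independent brute-force enumeration in the test suite.
Windows slide at one-codon stride so all robustness profiles share codon
coordinates; binned control profiles recompute the profile within five
equal-size quantile bins of the windows' own values to decouple robustness
from value extremity. The expected number of windows per transcription
error is `1 / (3 · window_codons · rate)` — ≈67 windows of 50 codons at a
rate of 10⁻⁴ per nucleotide.

## Traffic models

Nominal per-codon times combine the three determinants,
`t_i = a1·Ntai·exp(a2·Nch + a3·Nfe)`, each feature normalized to genome
mean 1 (an error is raised if a feature's mean is numerically zero). The
charge window covers the 31 residues strictly upstream (the exit-tunnel
length; the literature also quotes 32 — `tunnel_len` is configurable),
truncated at the gene start. Codons whose folding window is undefined (no
3'UTR) fall back to the gene-mean `Nfe` rather than dropping lattice
sites.

The deterministic model is a max-plus recurrence: ribosome *r* finishes
codon *i* at `f_r(i) = max(f_r(i−1), f_{r−1}(i+l)) + t_i` with footprint
*l* = 13 codons (odd, mid-codon convention) and a termination slot
appended after the last codon. Ribosomes enter at a fixed interval
(default `2·l·mean(t)`; infinite interval gives the single-ribosome
regime, where dwell equals `t` exactly). Binding waits until the previous
ribosome clears the entry footprint, and pre-binding queueing is not
counted as dwell — without this convention the codon-1 dwell grows without
bound in jammed regimes and the steady-state iteration cannot converge.
Iteration stops when consecutive ribosomes' dwell vectors agree to a
relative 10⁻⁶ (cap 10,000 ribosomes, then an error with diagnostics).

The stochastic model is an event-driven exclusion process with extended
particles: initiation at rate λ when the first (l+1)/2 codons are
uncovered, hops from codon *i* at rate `λ_i = 1/t_i` when codon
*i* + (l+1)/2 is uncovered (always allowed when that site is beyond the
lattice), termination as the hop off the last codon. Events — including
failed attempts — advance an exponential clock at the summed active rate;
the event identity is sampled proportionally to rates. After a burn-in of
250,000 events, occupancies are time-averaged and the production rate is
terminations per unit time over 1,000,000 measured events (both
configurable; tests use smaller counts). With pointlike particles and
uniform rates the measured current reproduces the known open-boundary
behavior: α(1−α) at low initiation, saturation near 1/4 at strong
initiation. The event loop is compiled with numba.

## Parameter fitting

`fit_abc` grid-searches `a2, a3` on [0, 1] (step 0.05), maximizing the
Spearman correlation between the five-point-smoothed predicted and
observed density profiles, with ties broken toward smaller values. In the
default (non-interacting) fit regime predicted density is proportional to
`t_i`, so `a1` only scales the prediction and a rank objective cannot see
it; `a1` is therefore selected on the same grid by least-squares magnitude
matching of the two profiles. On noiseless synthetic densities this
recovers the generating parameters exactly; identifiability of `a1` from
profile shape alone would require the interacting regime. A
cross-validated variant trains on half the genes via the split-half
machinery.

The linear regressor explains the density profile by `1/tAI`, folding
energy and charge profiles (OLS with intercept, statsmodels), by default
on five-point-smoothed profiles (raw fits also reported). Split-half
cross-validation draws seeded 50/50 gene splits; model comparisons use an
absolute-difference significance margin of 0.004, and the empirical
P-value is the fraction of repeats in which the reduced model beats the
full one. Partial Spearman correlations use the recursive first-order
formula on ranks (verified against matrix inversion to machine precision);
permutation P-values permute the two uncontrolled variables independently
with controls fixed, counting ties conservatively. No multiple-testing
correction is applied (stated in output metadata). Per-gene bottlenecks
are the most extreme 10-codon window means; predicted-vs-observed
bottleneck distances are compared against a per-gene density-permutation
null by mean and KS test.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with all randomness driven by one master seed:

* a tRNA pool with heavy-tailed (zipf, capped) copy numbers over a subset
  of anticodons, every amino acid keeping at least one Watson–Crick
  decoder;
* genes sampled codon-by-codon with probability ∝ `w^e`, the exponent *e*
  drawn per gene (uniform on mean ± 1) — the synthetic analogue of
  expression-driven codon bias, and what makes gene tAI vary across genes;
* a planted 5' ramp (default 40 codons): lowest-decile-`w` codons boosted
  ×(1+9s), positively charged residues ×(1+s), GC-rich codons tilted
  upward, with an AT-rich (weak-folding) first five codons; a mild
  genome-wide positive-charge excess keeps the charge normalization away
  from zero;
* protein abundance `exp(4·tAI)` with lognormal noise (σ = 0.3), mRNA
  levels correlated with it;
* densities equal to the model's per-codon times at a* = (1.0, 0.4, 0.2)
  with multiplicative lognormal noise (σ = 0.3) and per-codon dropout
  (p = 0.2) to mimic measurement sparsity.

Ground truth (a*, ramp length, slow set, per-gene tAI and nominal times)
is recorded for recovery tests. What the generator does **not** emulate:
organism-specific codon usage, UTR biology beyond random 3' tails,
sequencing-level read noise, initiation-rate variation across genes, and
selection at the amino-acid level. Passing tests therefore demonstrate
that the machinery recovers planted structure of the assumed form, not
that real genomes contain it.

## Numerical and design notes

* Degenerate inputs raise rather than return silently: constant vectors in
  correlations, all-zero adaptiveness, unbalanced dot-brackets, rank-
  deficient regression designs, stop codons inside scan windows.
* Ties are broken deterministically everywhere (gene-id order in group
  selection, smallest start in bottlenecks, smaller (a2, a3) in fitting,
  5'-most pairs in the toy fold).
* The problem sizes used by the test suite and acceptance script — 200
  genes × 300 codons for recovery studies, 10–20 seeds for rate estimates,
  1.25 M events per stochastic run — were chosen to give stable estimates
  at desk scale; all are configurable upward.
* Real-genome inputs (FASTA CDS, tRNA copy-number TSV, expression TSV,
  per-nucleotide density TSV) are supported by the loaders, but
  reproducing published organism-level values requires those datasets and
  is outside the test suite's scope.
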