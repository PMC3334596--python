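"""Robustness of coding-sequence determinants to single-nucleotide errors.

Each scanner enumerates every single-nucleotide substitution of a window and
measures how much the determinant changes:

* folding: all 40 x 3 = 120 mutants of a 40-nt window are folded and
  compared to the wild type by |delta energy|, base-pair-set distance, and a
  structure-changed indicator;
* charge: all substitutions of a 13-codon window, scored by the change in
  amino-acid charge;
* tAI: all substitutions of a 13-codon window, scored by the change in the
  codon's relative adaptiveness w.

Mutations are weighted by a transition:transversion ratio and per-codon-
position weights (e.g. down-weighting second positions for translation
errors).  Mutants that create stop codons are excluded from the charge and
tAI scans by default (a premature stop is neither a charge nor a decoding
change); nucleotide-level folding scans always keep all 120 mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .folding import bp_distance
from .profiles import PositionalProfile, mean_profile
from .seq_core import CHARGE, STANDARD_CODE, STOP_CODONS

_NTS = "ACGT"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class ScanWeights:
    """Mutation weights: transition:transversion ratio and per-codon-position
    weights (position 0/1/2 within the codon)."""

    ts_tv_ratio: float = 1.0
    position_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.ts_tv_ratio < 0 or any(w < 0 for w in self.position_weights):
            raise ValueError("weights must be >= 0")
        if self.ts_tv_ratio == 0 and not any(self.position_weights):
            raise ValueError("all weights zero")

    def weight(self, ref: str, alt: str, codon_pos: int) -> float:
        ts = (ref, alt) in _TRANSITION
        return (self.ts_tv_ratio if ts else 1.0) * self.position_weights[
            codon_pos % 3
        ]


@dataclass
class WindowRobustness:
    start: int  # 0-based codon index of the window start
    n_mutants: float = 0.0  # weighted total in the denominator
    # folding-energy scan fields (40-nt windows)
    mean_abs_dfe: Optional[float] = None
    structure_changing: Optional[float] = None  # weighted count
    mean_bp_distance: Optional[float] = None
    structure_preserving: Optional[float] = None
    # charge / tAI scan fields (13-codon windows)
    mean_abs_dcharge: Optional[float] = None
    charge_changing: Optional[float] = None
    mean_abs_dw: Optional[float] = None
    tai_preserving: Optional[float] = None


def _mutations(seq: str) -> Iterator[Tuple[int, str, str]]:
    """All (position, ref, alt) single-nucleotide substitutions."""
    for pos, ref in enumerate(seq):
        for alt in _NTS:
            if alt != ref:
                yield pos, ref, alt


def fe_robustness(
    window: str, backend, weights: Optional[ScanWeights] = None, start: int = 0
) -> WindowRobustness:
    """Mutational scan of a 40-nt window's folding energy and structure."""
    weights = weights or ScanWeights()
    if len(window) != 40:
        raise ValueError(f"folding scan window must be 40 nt, got {len(window)}")
    wt = backend(window)
    total_w = 0.0
    sum_dfe = 0.0
    sum_bp = 0.0
    changing = 0.0
    preserving = 0.0
    for pos, ref, alt in _mutations(window):
        wgt = weights.weight(ref, alt, pos)
        mut = backend(window[:pos] + alt + window[pos + 1 :])
        dist = bp_distance(wt.structure, mut.structure)
        total_w += wgt
        sum_dfe += wgt * abs(mut.energy - wt.energy)
        sum_bp += wgt * dist
        if dist > 0:
            changing += wgt
        else:
            preserving += wgt
    return WindowRobustness(
        start=start,
        n_mutants=total_w,
        mean_abs_dfe=sum_dfe / total_w,
        structure_changing=changing,
        mean_bp_distance=sum_bp / total_w,
        structure_preserving=preserving,
    )


def _codon_scan(
    codons: Sequence[str],
    value_of,
    weights: ScanWeights,
    count_stops_as_changes: bool,
) -> Tuple[float, float, float, float]:
    """Shared enumeration for charge/tAI scans.

    Returns (weighted mutant total, weighted mean |delta|, weighted count of
    value-changing mutants, weighted count of value-preserving mutants).
    """
    total_w = 0.0
    sum_abs = 0.0
    changing = 0.0
    preserving = 0.0
    for ci, codon in enumerate(codons):
        base = value_of(codon)
        for pos, ref, alt in _mutations(codon):
            mut_codon = codon[:pos] + alt + codon[pos + 1 :]
            wgt = weights.weight(ref, alt, pos)
            if mut_codon in STOP_CODONS:
                if not count_stops_as_changes:
                    continue
                delta = abs(base)  # stop treated as losing the residue
            else:
                delta = abs(value_of(mut_codon) - base)
            total_w += wgt
            sum_abs += wgt * delta
            if delta > 0:
                changing += wgt
            else:
                preserving += wgt
    mean_abs = sum_abs / total_w if total_w else 0.0
    return total_w, mean_abs, changing, preserving


def charge_robustness(
    codons: Sequence[str],
    weights: Optional[ScanWeights] = None,
    start: int = 0,
    count_stops_as_changes: bool = False,
) -> WindowRobustness:
    """Mutational scan of a 13-codon window's amino-acid charge."""
    weights = weights or ScanWeights()
    if len(codons) != 13:
        raise ValueError(f"charge scan window must be 13 codons, got {len(codons)}")
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("stop codon inside scan window")
    total, mean_abs, changing, preserving = _codon_scan(
        codons,
        lambda c: float(CHARGE[STANDARD_CODE[c]]),
        weights,
        count_stops_as_changes,
    )
    return WindowRobustness(
        start=start,
        n_mutants=total,
        mean_abs_dcharge=mean_abs,
        charge_changing=changing,
    )


def tai_robustness(
    codons: Sequence[str],
    codon_weights,
    scan_weights: Optional[ScanWeights] = None,
    start: int = 0,
    count_stops_as_changes: bool = False,
) -> WindowRobustness:
    """Mutational scan of a 13-codon window's relative adaptiveness w."""
    scan_weights = scan_weights or ScanWeights()
    if len(codons) != 13:
        raise ValueError(f"tAI scan window must be 13 codons, got {len(codons)}")
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("stop codon inside scan window")
    total, mean_abs, changing, preserving = _codon_scan(
        codons,
        lambda c: float(codon_weights.w[c]),
        scan_weights,
        count_stops_as_changes,
    )
    return WindowRobustness(
        start=start,
        n_mutants=total,
        mean_abs_dw=mean_abs,
        tai_preserving=preserving,
    )


_FIELDS = [
    "mean_abs_dfe",
    "structure_changing",
    "mean_bp_distance",
    "structure_preserving",
    "mean_abs_dcharge",
    "charge_changing",
    "mean_abs_dw",
    "tai_preserving",
]


def scan_gene(
    gene,
    scanner: Literal["fe", "charge", "tai"],
    backend=None,
    codon_weights=None,
    scan_weights: Optional[ScanWeights] = None,
    fe_window_nt: int = 40,
    codon_window: int = 13,
) -> List[WindowRobustness]:
    """All sliding-window scans of a gene (stride one codon)."""
    out: List[WindowRobustness] = []
    if scanner == "fe":
        seq = gene.cds + (gene.utr3 or "")
        for c in range(gene.n_codons):
            lo = 3 * c
            if lo + fe_window_nt > len(seq):
                break
            out.append(
                fe_robustness(seq[lo : lo + fe_window_nt], backend, scan_weights, start=c)
            )
    else:
        codons = gene.codons
        for c in range(len(codons) - codon_window + 1):
            win = codons[c : c + codon_window]
            if scanner == "charge":
                out.append(charge_robustness(win, scan_weights, start=c))
            else:
                out.append(
                    tai_robustness(win, codon_weights, scan_weights, start=c)
                )
    return out


def robustness_profile(
    genome,
    scanner: Literal["fe", "charge", "tai"],
    backend=None,
    codon_weights=None,
    scan_weights: Optional[ScanWeights] = None,
    max_positions: Optional[int] = 200,
) -> Dict[str, PositionalProfile]:
    """Genome-wide positional profiles, one per robustness metric."""
    per_gene: Dict[str, List[WindowRobustness]] = {
        g.gene_id: scan_gene(
            g, scanner, backend=backend, codon_weights=codon_weights,
            scan_weights=scan_weights,
        )
        for g in genome
    }
    return profiles_from_scans(per_gene, max_positions)


def profiles_from_scans(
    per_gene: Dict[str, List[WindowRobustness]],
    max_positions: Optional[int] = 200,
) -> Dict[str, PositionalProfile]:
    out: Dict[str, PositionalProfile] = {}
    for name in _FIELDS:
        vectors = []
        any_defined = False
        for scans in per_gene.values():
            if not scans:
                continue
            n = max(s.start for s in scans) + 1
            vec = np.full(n, np.nan)
            for s in scans:
                v = getattr(s, name)
                if v is not None:
                    vec[s.start] = v
                    any_defined = True
            vectors.append(vec)
        if any_defined and vectors:
            out[name] = mean_profile(
                vectors, "start", max_positions, feature=name
            )
    return out


def binned_control_profiles(
    per_gene_scans: Dict[str, List[WindowRobustness]],
    window_values: Dict[str, Sequence[float]],
    metric: str,
    n_bins: int = 5,
    max_positions: Optional[int] = 200,
):
    """Robustness profiles within quantile bins of the windows' own values.

    ``window_values[gene][k]`` is the binning key (e.g. the window's folding
    energy) for the k-th scan of that gene.  Windows are split into
    ``n_bins`` equal-size groups; within each group the profile of
    ``metric`` is recomputed.  Returns (list of per-bin profiles, bin
    boundaries).  Degenerate value distributions collapse to one bin.
    """
    flat = []
    for gid, scans in per_gene_scans.items():
        vals = window_values[gid]
        for k, s in enumerate(scans):
            flat.append((float(vals[k]), gid, s))
    if len(flat) < n_bins:
        raise ValueError("fewer windows than bins")
    values = np.array([f[0] for f in flat])
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    if len(np.unique(qs)) < n_bins + 1:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate window values: collapsing to a single bin"
        )
        qs = np.array([values.min(), values.max()])
    # equal-size bins by rank, boundaries reported from the quantiles
    order = np.argsort(values, kind="stable")
    n_eff = len(qs) - 1
    bin_of = np.empty(len(flat), dtype=int)
    for rank, idx in enumerate(order):
        bin_of[idx] = min(rank * n_eff // len(flat), n_eff - 1)
    profiles = []
    for b in range(n_eff):
        per_gene: Dict[str, List[WindowRobustness]] = {}
        for (val, gid, s), bb in zip(flat, bin_of):
            if bb == b:
                per_gene.setdefault(gid, []).append(s)
        prof = profiles_from_scans(per_gene, max_positions).get(metric)
        profiles.append(prof)
    return profiles, qs


def expected_windows_per_error(
    error_rate_per_nt: float, window_codons: int
) -> Tuple[float, int]:
    """How many windows of ``window_codons`` codons per transcription error.

    With an error rate of r per nucleotide, one error is expected per
    1 / (3 * window_codons * r) windows.  Returns the exact value and its
    nearest-integer presentation.
    """
    if not 0 < error_rate_per_nt < 1:
        raise ValueError("error rate must be in (0, 1)")
    if window_codons < 1:
        raise ValueError("window must be >= 1 codon")
    exact = 1.0 / (3 * window_codons * error_rate_per_nt)
    return exact, int(round(exact))
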