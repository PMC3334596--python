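"""tRNA adaptation index (tAI).

Codon adaptiveness is derived from tRNA gene copy numbers discounted by
wobble-pairing penalties.  For codon *i* decoded by isoacceptors *j* with
copy numbers ``tCGN_ij`` and selective constraints ``S_ij``::

    W_i = sum_j (1 - S_ij) * tCGN_ij
    w_i = W_i / max_k W_k

and the tAI of a gene is the geometric mean of the ``w`` values of its sense
codons.  Codons with ``w == 0`` receive the geometric mean of the non-zero
``w`` values so that a single undecodable codon does not zero out a gene.

The codon:anticodon pairing scheme (which anticodons reach which codons, and
the penalty class of each pairing) ships as a data file and follows the
standard scheme: each codon is reached by its Watson-Crick anticodon and by
one wobble anticodon determined by its third position (G34 reads NNU, inosine
reads NNC/NNA/NNU, U34 reads NNG).

The wobble penalties themselves can be re-fitted to expression data by
hill-climbing on the Spearman correlation between gene tAI and protein
abundance (:func:`optimize_s_vector`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import spearmanr

from .seq_core import (
    ExpressionTable,
    Genome,
    SENSE_CODONS,
    STOP_CODONS,
    normalize_nt,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _load_scheme() -> List[Tuple[str, str, str, str, float]]:
    rows = []
    text = (
        resources.files("ribotraffic.data")
        .joinpath("wobble_scheme.tsv")
        .read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("codon3"):
            continue
        codon3, ac34, label, kind, s0 = line.split("\t")
        rows.append((codon3, ac34, label, kind, float(s0)))
    return rows


_SCHEME = _load_scheme()

#: Wobble-pairing labels in scheme order (I:U, G:U, G:C, I:C, U:A, I:A, ...).
S_LABELS: List[str] = [r[2] for r in _SCHEME]

#: Published starting penalties for each label.
INITIAL_S: Dict[str, float] = {r[2]: r[4] for r in _SCHEME}


@dataclass
class SVector:
    """Selective-constraint penalty per wobble-pairing label, each in [0,1]."""

    s: Dict[str, float] = field(default_factory=lambda: dict(INITIAL_S))

    def __post_init__(self) -> None:
        for label, v in self.s.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"S[{label}] = {v} outside [0, 1]")

    def __getitem__(self, label: str) -> float:
        return self.s[label]


@dataclass
class TRNAPool:
    """tRNA gene copy number per anticodon (stored in the DNA alphabet)."""

    copies: Dict[str, int]

    def __post_init__(self) -> None:
        norm = {}
        for ac, n in self.copies.items():
            if n < 0:
                raise ValueError(f"negative copy number for {ac}")
            norm[normalize_nt(ac)] = int(n)
        self.copies = norm
        if not any(self.copies.values()):
            raise ValueError("tRNA pool has no anticodon with copies > 0")

    def get(self, anticodon: str, default: int = 0) -> int:
        return self.copies.get(anticodon, default)


def load_trna_pool(path) -> TRNAPool:
    """Read a tab-separated pool with columns ``anticodon``, ``copies``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    col = "copies" if "copies" in df.columns else "copy_number"
    return TRNAPool(dict(zip(df["anticodon"].astype(str), df[col].astype(int))))


def codon_anticodon_pairs() -> Dict[str, List[Tuple[str, str]]]:
    """For each sense codon, the decoding anticodons and their pairing label.

    Anticodons whose Watson-Crick codon is a stop codon are excluded as
    decoders (they are release-factor territory, not tRNAs).
    """
    table: Dict[str, List[Tuple[str, str]]] = {}
    for codon in SENSE_CODONS:
        entries = []
        for codon3, ac34, label, _kind, _s0 in _SCHEME:
            if codon[2] != codon3:
                continue
            anticodon = ac34 + _revcomp(codon[:2])
            if _revcomp(anticodon) in STOP_CODONS:
                continue
            entries.append((anticodon, label))
        table[codon] = entries
    return table


_PAIRS = codon_anticodon_pairs()


@dataclass
class CodonWeights:
    """Absolute (W) and relative (w) adaptiveness per sense codon."""

    W: Dict[str, float]
    w: Dict[str, float] = field(default_factory=dict)
    n_isoacceptors: Dict[str, int] = field(default_factory=dict)


def absolute_adaptiveness(pool: TRNAPool, s: Optional[SVector] = None) -> CodonWeights:
    """W_i = sum over recognizing anticodons of (1 - S_ij) * copy number."""
    s = s or SVector()
    W: Dict[str, float] = {}
    n_iso: Dict[str, int] = {}
    for codon in SENSE_CODONS:
        total = 0.0
        n = 0
        for anticodon, label in _PAIRS[codon]:
            copies = pool.get(anticodon)
            if copies > 0:
                total += (1.0 - s[label]) * copies
                n += 1
        W[codon] = total
        n_iso[codon] = n
    return CodonWeights(W=W, n_isoacceptors=n_iso)


def relative_adaptiveness(weights: CodonWeights) -> CodonWeights:
    """Normalize by the maximum W; zero-w codons get the geometric mean of
    the non-zero w values."""
    wmax = max(weights.W.values())
    if wmax <= 0:
        raise ValueError("all absolute adaptiveness values are zero")
    w = {c: Wi / wmax for c, Wi in weights.W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    weights.w = {c: (v if v > 0 else gm) for c, v in w.items()}
    return weights


def codon_weights(pool: TRNAPool, s: Optional[SVector] = None) -> CodonWeights:
    """Convenience: absolute then relative adaptiveness in one call."""
    return relative_adaptiveness(absolute_adaptiveness(pool, s))


def gene_tai(cds_or_codons, weights: CodonWeights) -> float:
    """Geometric mean of per-codon relative adaptiveness (stops excluded)."""
    if isinstance(cds_or_codons, str):
        from .seq_core import CodingSequence

        codons = CodingSequence("_", cds_or_codons).codons
    else:
        codons = list(cds_or_codons)
    if not codons:
        raise ValueError("gene has no sense codons")
    logsum = sum(math.log(weights.w[c]) for c in codons)
    return math.exp(logsum / len(codons))


def genome_tai(genome: Genome, weights: CodonWeights) -> Dict[str, float]:
    return {g.gene_id: gene_tai(g.codons, weights) for g in genome}


def write_codon_weights(weights: CodonWeights, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "codon": SENSE_CODONS,
            "W": [weights.W[c] for c in SENSE_CODONS],
            "w": [weights.w.get(c, float("nan")) for c in SENSE_CODONS],
        }
    ).to_csv(path, sep="\t", index=False)


def optimize_s_vector(
    genome: Genome,
    pool: TRNAPool,
    expression: ExpressionTable,
    *,
    step: float = 0.05,
    max_iter: int = 200,
    n_restarts: int = 0,
    seed: int = 0,
    min_genes: int = 20,
    initial: Optional[SVector] = None,
) -> Tuple[SVector, float]:
    """Hill-climb the wobble penalties against protein abundance.

    Maximizes Spearman(gene tAI, protein abundance) over the S-vector by
    coordinate-wise +/-``step`` proposals clamped to [0, 1], accepting only
    strictly improving steps, starting from the published penalties.
    Returns the best vector and its objective value.
    """
    gene_ids = [g.gene_id for g in genome if g.gene_id in expression.protein_abundance]
    if len(gene_ids) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with protein abundance, have {len(gene_ids)}"
        )
    abundance = np.array([expression.protein_abundance[g] for g in gene_ids])
    if np.all(abundance == abundance[0]):
        raise ValueError("protein abundance is constant; correlation undefined")
    genes = [genome[g].codons for g in gene_ids]

    def objective(svec: SVector) -> float:
        weights = codon_weights(pool, svec)
        tai = np.array([gene_tai(c, weights) for c in genes])
        if np.all(tai == tai[0]):
            return -np.inf
        return float(spearmanr(tai, abundance).statistic)

    rng = np.random.default_rng(seed)
    start = dict((initial or SVector()).s)
    best_s, best_obj = dict(start), objective(SVector(dict(start)))

    starts = [dict(start)]
    for _ in range(n_restarts):
        starts.append({k: float(rng.uniform(0, 1)) for k in start})

    for s0 in starts:
        cur, cur_obj = dict(s0), objective(SVector(dict(s0)))
        for _ in range(max_iter):
            improved = False
            for label in S_LABELS:
                for delta in (step, -step):
                    cand = dict(cur)
                    cand[label] = min(1.0, max(0.0, cand[label] + delta))
                    if cand[label] == cur[label]:
                        continue
                    obj = objective(SVector(cand))
                    if obj > cur_obj:
                        cur, cur_obj = cand, obj
                        improved = True
            if not improved:
                break
        if cur_obj > best_obj:
            best_s, best_obj = cur, cur_obj
    return SVector(best_s), best_obj
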