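"""Local mRNA secondary-structure folding.

A folding *backend* is a pure function ``sequence -> FoldResult`` (minimum
free energy plus dot-bracket structure).  Two backends are provided:

``toy``
    Nussinov-style maximum base pairing over Watson-Crick + GU pairs with a
    minimum hairpin loop of 3 unpaired nucleotides; energy is -1.0 kcal/mol
    per pair.  Among maximum-pairing structures the traceback returns the one
    whose sorted pair list is lexicographically smallest (5'-most pairs
    preferred), which makes the backend fully deterministic and cheap enough
    for exhaustive mutational scans.

``vienna``
    ViennaRNA MFE folding at its default temperature (37 degrees C), used
    when the RNA python bindings are importable.

Per-codon local folding-energy vectors use 40-nt windows starting at each
codon's first nucleotide; windows overrunning the CDS extend into the 3'UTR
when one is provided and are otherwise recorded as missing (NaN).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .seq_core import CodingSequence, normalize_nt

try:  # numba accelerates the toy backend; plain python otherwise
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


MIN_HAIRPIN = 3  # unpaired nucleotides required inside a hairpin loop

# pairability matrix over A=0, C=1, G=2, T=3 (WC + GU wobble)
_PAIRABLE = np.zeros((4, 4), dtype=np.uint8)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = 1

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FoldResult:
    """MFE in kcal/mol (<= 0; 0 means unstructured) and its dot-bracket."""

    energy: float
    structure: str

    def __post_init__(self) -> None:
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")


def bp_set(structure: str) -> Set[Tuple[int, int]]:
    """Base pairs (i, j), i < j, 0-based, of a dot-bracket string."""
    stack: List[int] = []
    pairs: Set[Tuple[int, int]] = set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' remaining")
    return pairs


def bp_distance(structure_a: str, structure_b: str) -> int:
    """Size of the symmetric difference between two base-pair sets."""
    return len(bp_set(structure_a) ^ bp_set(structure_b))


@njit(cache=True)
def _nussinov_tables(seq: np.ndarray, pairable: np.ndarray) -> np.ndarray:
    n = seq.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if pairable[seq[i], seq[k]]:
                    inner = M[i + 1, k - 1] if k - 1 > i else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


@njit(cache=True)
def _nussinov_traceback(
    seq: np.ndarray, pairable: np.ndarray, M: np.ndarray
) -> np.ndarray:
    """Lexicographically-smallest maximum-pairing structure.

    At every interval the 5'-most nucleotide is paired whenever some optimum
    pairs it, to the smallest admissible partner; this greedy rule yields the
    sorted-pair-list lexicographic minimum among all maximum structures.
    """
    n = seq.shape[0]
    pair_of = np.full(n, -1, dtype=np.int32)
    stack = np.empty((n + 1, 2), dtype=np.int32)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i, j = stack[top, 0], stack[top, 1]
        while i < j:
            if M[i, j] == 0:
                break
            paired = False
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if pairable[seq[i], seq[k]]:
                    inner = M[i + 1, k - 1] if k - 1 > i else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    if 1 + inner + right == M[i, j]:
                        pair_of[i] = k
                        pair_of[k] = i
                        if k + 1 <= j:
                            stack[top, 0] = k + 1
                            stack[top, 1] = j
                            top += 1
                        j = k - 1
                        i = i + 1
                        paired = True
                        break
            if not paired:
                i += 1
    return pair_of


def _encode(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX[c] for c in seq], dtype=np.int8)


class ToyBackend:
    """Deterministic maximum-base-pairing fold; -1 kcal/mol per pair."""

    name = "toy"

    def __init__(self, cache_size: int = 200_000) -> None:
        self._fold = functools.lru_cache(maxsize=cache_size)(self._fold_impl)

    def __call__(self, seq: str) -> FoldResult:
        return self._fold(normalize_nt(seq))

    @staticmethod
    def _fold_impl(seq: str) -> FoldResult:
        n = len(seq)
        if n == 0:
            raise ValueError("cannot fold an empty sequence")
        enc = _encode(seq)
        if n <= MIN_HAIRPIN + 1:
            return FoldResult(0.0, "." * n)
        M = _nussinov_tables(enc, _PAIRABLE)
        if M[0, n - 1] == 0:
            return FoldResult(0.0, "." * n)
        pair_of = _nussinov_traceback(enc, _PAIRABLE, M)
        chars = ["."] * n
        for i in range(n):
            if pair_of[i] > i:
                chars[i] = "("
                chars[pair_of[i]] = ")"
        n_pairs = int(M[0, n - 1])
        return FoldResult(-1.0 * n_pairs, "".join(chars))


class ViennaBackend:
    """ViennaRNA MFE folding (default parameters, 37 degrees C)."""

    name = "vienna"

    def __init__(self, cache_size: int = 200_000) -> None:
        import RNA  # deferred: conda-provided bindings

        self._RNA = RNA
        self._fold = functools.lru_cache(maxsize=cache_size)(self._fold_impl)

    def __call__(self, seq: str) -> FoldResult:
        return self._fold(normalize_nt(seq))

    def _fold_impl(self, seq: str) -> FoldResult:
        structure, energy = self._RNA.fold(seq.replace("T", "U"))
        return FoldResult(float(min(energy, 0.0)), structure)


def get_backend(name: str = "toy"):
    if name == "toy":
        return ToyBackend()
    if name == "vienna":
        return ViennaBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def local_fe_vector(
    gene: CodingSequence,
    backend,
    window_nt: int = 40,
    fold_short_tails: bool = False,
) -> np.ndarray:
    """Folding energy of the ``window_nt``-nt window starting at each codon.

    Entry *i* (0-based) is the energy of the window beginning at the first
    nucleotide of codon *i*.  Windows that overrun the CDS use the 3'UTR when
    available; otherwise the entry is NaN unless ``fold_short_tails``.
    """
    seq = gene.cds + (gene.utr3 or "")
    n_codons = gene.n_codons
    out = np.full(n_codons, np.nan)
    for i in range(n_codons):
        start = 3 * i
        window = seq[start : start + window_nt]
        if len(window) == window_nt or (fold_short_tails and window):
            out[i] = backend(window).energy
    return out


def upstream_fe_vector(
    gene: CodingSequence, backend, window_nt: int = 40
) -> Dict[int, float]:
    """Energies of windows starting at codon-aligned positions in the 5'UTR.

    Keys are negative codon offsets relative to the start codon (-1 is the
    codon-width slot immediately upstream of A of ATG); windows run across
    the UTR/CDS junction over the concatenated sequence.
    """
    if not gene.utr5:
        return {}
    seq = gene.utr5 + gene.cds + (gene.utr3 or "")
    n_utr_codons = len(gene.utr5) // 3
    out: Dict[int, float] = {}
    for k in range(1, n_utr_codons + 1):
        start = len(gene.utr5) - 3 * k
        window = seq[start : start + window_nt]
        if len(window) == window_nt:
            out[-k] = backend(window).energy
    return out


def genome_fe_vectors(
    genome, backend, window_nt: int = 40, fold_short_tails: bool = False
) -> Dict[str, np.ndarray]:
    return {
        g.gene_id: local_fe_vector(g, backend, window_nt, fold_short_tails)
        for g in genome
    }
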