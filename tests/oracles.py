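"""Independent brute-force oracles used to cross-check the implementation.

Everything here re-derives results from first principles (exhaustive
enumeration, direct definitions) without reusing the package's aggregation
code paths.
"""

from __future__ import annotations

import functools
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_HAIRPIN = 3
STOPS = {"TAA", "TAG", "TGA"}

CODE = {}
_B = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, codon in enumerate(a + b + c for a in _B for b in _B for c in _B):
    if _AAS[_i] != "*":
        CODE[codon] = _AAS[_i]
CHARGE = {aa: 0 for aa in set(CODE.values())}
CHARGE.update({"R": 1, "H": 1, "K": 1, "D": -1, "E": -1})


@functools.lru_cache(maxsize=None)
def _best_structures(seq: str) -> Tuple[int, Tuple[Tuple[int, int], ...]]:
    """(max pairs, lexicographically smallest sorted pair list) by full
    enumeration of nested structures with minimum hairpin 3."""
    n = len(seq)
    if n <= MIN_HAIRPIN + 1:
        return 0, ()
    # option: position 0 unpaired
    cnt, pairs = _best_structures(seq[1:])
    best = (cnt, tuple((i + 1, j + 1) for i, j in pairs))
    for k in range(MIN_HAIRPIN + 1, n):
        if (seq[0], seq[k]) in _PAIRS:
            c_in, p_in = _best_structures(seq[1:k])
            c_out, p_out = _best_structures(seq[k + 1 :])
            cand_pairs = (
                ((0, k),)
                + tuple((i + 1, j + 1) for i, j in p_in)
                + tuple((i + k + 1, j + k + 1) for i, j in p_out)
            )
            cand = (1 + c_in + c_out, tuple(sorted(cand_pairs)))
            if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    return best


def brute_fold(seq: str) -> Tuple[float, str]:
    """Maximum-pairing fold by exhaustive enumeration (for short sequences)."""
    cnt, pairs = _best_structures(seq)
    chars = ["."] * len(seq)
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return -1.0 * cnt, "".join(chars)


def parse_pairs(structure: str) -> Set[Tuple[int, int]]:
    stack, out = [], set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            out.add((stack.pop(), i))
    return out


def mutation_weight(ref: str, alt: str, pos: int, ts_tv: float, pos_w) -> float:
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    w = ts_tv if (ref, alt) in transitions else 1.0
    return w * pos_w[pos % 3]


def brute_fe_scan(
    window: str, backend, ts_tv: float = 1.0, pos_w=(1.0, 1.0, 1.0)
) -> dict:
    wt = backend(window)
    wt_pairs = parse_pairs(wt.structure)
    tot = dfe = bp = chg = pres = 0.0
    for p in range(len(window)):
        for alt in "ACGT":
            if alt == window[p]:
                continue
            w = mutation_weight(window[p], alt, p, ts_tv, pos_w)
            mut = backend(window[:p] + alt + window[p + 1 :])
            d = len(wt_pairs ^ parse_pairs(mut.structure))
            tot += w
            dfe += w * abs(mut.energy - wt.energy)
            bp += w * d
            if d:
                chg += w
            else:
                pres += w
    return {
        "n_mutants": tot,
        "mean_abs_dfe": dfe / tot,
        "structure_changing": chg,
        "mean_bp_distance": bp / tot,
        "structure_preserving": pres,
    }


def brute_codon_scan(
    codons: Sequence[str],
    value,
    ts_tv: float = 1.0,
    pos_w=(1.0, 1.0, 1.0),
) -> dict:
    tot = dsum = chg = pres = 0.0
    for codon in codons:
        for p in range(3):
            for alt in "ACGT":
                if alt == codon[p]:
                    continue
                mut = codon[:p] + alt + codon[p + 1 :]
                if mut in STOPS:
                    continue
                w = mutation_weight(codon[p], alt, p, ts_tv, pos_w)
                d = abs(value(mut) - value(codon))
                tot += w
                dsum += w * d
                if d > 0:
                    chg += w
                else:
                    pres += w
    return {
        "n_mutants": tot,
        "mean_abs": dsum / tot if tot else 0.0,
        "changing": chg,
        "preserving": pres,
    }


def brute_charge_scan(codons, ts_tv=1.0, pos_w=(1.0, 1.0, 1.0)) -> dict:
    return brute_codon_scan(
        codons, lambda c: float(CHARGE[CODE[c]]), ts_tv, pos_w
    )


def brute_tai_scan(codons, w_table: Dict[str, float], ts_tv=1.0, pos_w=(1.0, 1.0, 1.0)) -> dict:
    return brute_codon_scan(codons, lambda c: float(w_table[c]), ts_tv, pos_w)


def ks_statistic_brute(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample KS D as the maximum ECDF gap, scanned directly."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    grid = np.concatenate([a, b])
    best = 0.0
    for x in grid:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def residual_partial_spearman(x, y, controls) -> float:
    """Partial rank correlation via regressing ranks on the controls and
    correlating the residuals (independent of the recursive formula)."""
    from scipy.stats import pearsonr, rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    Z = np.column_stack([np.ones(len(rx))] + [rankdata(c) for c in controls])
    bx, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    by, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    return float(pearsonr(rx - Z @ bx, ry - Z @ by).statistic)
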