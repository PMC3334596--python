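"""Metagene positional profiles.

A positional profile lines genes up at the start codon (positions 1, 2, ...
in codons) or at the last sense codon (positions -1, -2, ... walking
upstream) and averages any per-codon quantity position-wise over the genes
that reach that position.  Missing entries (NaN) drop out of both the
numerator and the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Set

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Alignment = Literal["start", "end"]


@dataclass
class PositionalProfile:
    feature: str
    alignment: Alignment
    positions: np.ndarray  # codon offsets: 1.. for start, -1.. for end
    mean: np.ndarray
    count: np.ndarray  # contributing genes per position

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.mean) == len(self.count) == n):
            raise ValueError("profile arrays must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "n_genes": self.count,
                "feature": self.feature,
                "alignment": self.alignment,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _stack(vectors: Sequence[np.ndarray], align_end: bool) -> np.ndarray:
    max_len = max(len(v) for v in vectors)
    mat = np.full((len(vectors), max_len), np.nan)
    for r, v in enumerate(vectors):
        v = np.asarray(v, dtype=float)
        if align_end:
            mat[r, : len(v)] = v[::-1]
        else:
            mat[r, : len(v)] = v
    return mat


def mean_profile(
    vectors: Dict[str, np.ndarray] | Sequence[np.ndarray],
    alignment: Alignment = "start",
    max_positions: Optional[int] = None,
    feature: str = "",
    aggregator: Literal["mean", "median"] = "mean",
) -> PositionalProfile:
    """Position-wise mean (or median) of per-gene vectors."""
    if isinstance(vectors, dict):
        vectors = list(vectors.values())
    vectors = [np.asarray(v, dtype=float) for v in vectors if len(v)]
    if not vectors:
        raise ValueError("no vectors to profile")
    mat = _stack(vectors, align_end=(alignment == "end"))
    if max_positions is not None:
        mat = mat[:, :max_positions]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        if aggregator == "median":
            agg = np.nanmedian(mat, axis=0)
        else:
            agg = np.nanmean(mat, axis=0)
    count = np.sum(~np.isnan(mat), axis=0)
    keep = count > 0
    idx = np.arange(1, mat.shape[1] + 1)[keep]
    if alignment == "end":
        positions = -idx
    else:
        positions = idx
    return PositionalProfile(
        feature=feature,
        alignment=alignment,
        positions=positions,
        mean=agg[keep],
        count=count[keep],
    )


def smooth(profile: PositionalProfile, span: int = 5) -> PositionalProfile:
    """Centered moving average with a window that shrinks at the edges."""
    return PositionalProfile(
        feature=profile.feature,
        alignment=profile.alignment,
        positions=profile.positions.copy(),
        mean=smooth_vector(profile.mean, span),
        count=profile.count.copy(),
    )


def smooth_vector(values: np.ndarray, span: int = 5) -> np.ndarray:
    if span % 2 == 0 or span < 1:
        raise ValueError("smoothing span must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    half = span // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        window = v[lo:hi]
        good = ~np.isnan(window)
        out[i] = window[good].mean() if good.any() else np.nan
    return out


def density_per_codon(nt_values: Sequence[float]) -> np.ndarray:
    """Average per-nucleotide ribosome densities over each codon's 3 nt."""
    v = np.asarray(nt_values, dtype=float)
    rem = len(v) % 3
    if rem:
        logger.warning("dropping %d trailing nucleotide(s) (partial codon)", rem)
        v = v[: len(v) - rem]
    return v.reshape(-1, 3).mean(axis=1)


def load_density_table(path, units: str = "nt") -> Dict[str, np.ndarray]:
    """Read a long-format density TSV (gene_id, position, value).

    Positions are 1-based; ``units`` is ``nt`` (averaged per codon) or
    ``codon`` (used as is).
    """
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, np.ndarray] = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("position")
        n = int(sub["position"].max())
        vec = np.full(n, np.nan)
        vec[sub["position"].astype(int).to_numpy() - 1] = sub["value"].to_numpy()
        out[str(gid)] = density_per_codon(vec) if units == "nt" else vec
    return out


def write_density_table(table: Dict[str, np.ndarray], path, units: str = "codon") -> None:
    rows = []
    for gid, vec in table.items():
        for i, v in enumerate(np.asarray(vec, dtype=float), start=1):
            if not np.isnan(v):
                rows.append((gid, i, v))
    pd.DataFrame(rows, columns=["gene_id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


def select_group(
    keys: Dict[str, float],
    fraction: float = 0.10,
    side: Literal["top", "bottom"] = "top",
) -> Set[str]:
    """Gene ids in the top/bottom ``fraction`` by key value.

    Ties are broken by gene id order (deterministic); requires the key to be
    defined for at least 10 genes and fraction in (0, 0.5].
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    items = [(gid, v) for gid, v in keys.items() if v == v]
    if len(items) < 10:
        raise ValueError("key defined for fewer than 10 genes")
    n_take = int(np.ceil(fraction * len(items)))
    reverse = side == "top"
    ranked = sorted(items, key=lambda kv: (kv[1], kv[0]), reverse=reverse)
    return {gid for gid, _ in ranked[:n_take]}


def expression_density_key(
    mrna: Dict[str, float], density: Dict[str, np.ndarray]
) -> Dict[str, float]:
    """(mRNA level) x (mean ribosomal density) ranking key per gene."""
    out = {}
    for gid, level in mrna.items():
        vec = density.get(gid)
        if vec is not None and len(vec):
            with np.errstate(invalid="ignore"):
                m = np.nanmean(vec)
            if m == m:
                out[gid] = level * float(m)
    return out


def pars_profiles(
    scores: Dict[str, np.ndarray],
    sequences: Dict[str, str],
    max_positions: int = 600,
):
    """Per-nucleotide pairing-score profiles: simple and hydrogen-bond weighted.

    The weighted mean weights each gene's score at a position by the number
    of hydrogen bonds its nucleotide can form (3 for G/C, 2 for A/T).
    """
    simple = mean_profile(scores, "start", max_positions, feature="pars")
    max_len = max(len(v) for v in scores.values())
    L = min(max_len, max_positions)
    num = np.zeros(L)
    den = np.zeros(L)
    cnt = np.zeros(L, dtype=int)
    for gid, vec in scores.items():
        seq = sequences[gid]
        if len(seq) < len(vec):
            raise ValueError(f"{gid}: scores longer than sequence")
        v = np.asarray(vec, dtype=float)[:L]
        for i, s in enumerate(v):
            if s != s:
                continue
            wgt = 3.0 if seq[i] in "GC" else 2.0
            num[i] += wgt * s
            den[i] += wgt
            cnt[i] += 1
    keep = cnt > 0
    weighted = PositionalProfile(
        feature="pars_weighted",
        alignment="start",
        positions=np.arange(1, L + 1)[keep],
        mean=(num[keep] / den[keep]),
        count=cnt[keep],
    )
    return simple, weighted


def intra_window_pair_counts(
    structures: Dict[str, str], window_nt: int = 40
) -> Dict[str, np.ndarray]:
    """Per codon-start window, pairs with both partners inside the window.

    Consumes dot-bracket structures of full transcripts; entry *i* counts the
    base pairs (i, j) of the structure wholly contained in the 40-nt window
    beginning at codon *i*.
    """
    from .folding import bp_set

    out: Dict[str, np.ndarray] = {}
    for gid, struct in structures.items():
        pairs = sorted(bp_set(struct))
        n_codons = len(struct) // 3
        vec = np.full(n_codons, np.nan)
        for c in range(n_codons):
            lo = 3 * c
            hi = lo + window_nt
            if hi > len(struct):
                break
            vec[c] = sum(1 for i, j in pairs if lo <= i and j < hi)
        out[gid] = vec
    return out


def slow_codon_pair_profile(
    genome,
    weights,
    slow_fraction: float = 0.10,
    mode: Literal["adjacent", "window"] = "adjacent",
    window: int = 13,
    max_positions: Optional[int] = None,
) -> PositionalProfile:
    """Positional mean of identical-slow-codon pair indicators.

    Slow codons are the lowest ``slow_fraction`` of sense codons by relative
    adaptiveness w.  In ``adjacent`` mode position *i* scores 1 when codons
    *i* and *i+1* are identical and both slow; in ``window`` mode it counts
    identical slow-codon pairs co-occurring in the window starting at *i*.
    """
    slow = slow_codon_set(weights, slow_fraction)
    vectors = []
    for g in genome:
        codons = g.codons
        n = len(codons)
        if mode == "adjacent":
            vec = np.zeros(max(n - 1, 0))
            for i in range(n - 1):
                if codons[i] in slow and codons[i] == codons[i + 1]:
                    vec[i] = 1.0
        else:
            vec = np.full(n, np.nan)
            for i in range(n - window + 1):
                win = codons[i : i + window]
                count = 0
                for a in range(window):
                    for b in range(a + 1, window):
                        if win[a] in slow and win[a] == win[b]:
                            count += 1
                vec[i] = count
        vectors.append(vec)
    return mean_profile(
        vectors, "start", max_positions, feature="slow_codon_pairs"
    )


def feature_vectors(
    genome,
    feature: Literal["tai", "charge", "fe"],
    weights=None,
    fe_vectors: Optional[Dict[str, np.ndarray]] = None,
    skip_initiator: bool = True,
) -> Dict[str, np.ndarray]:
    """Per-gene determinant vectors for profile and ramp analyses.

    The initiator codon is dropped by default: it is constitutionally ATG,
    so including it plants a spurious fixed value at position 1 of every
    start-aligned profile (start-aligned profiles conventionally begin at
    the second position).  Entry *i* then corresponds to codon *i* + 2.
    """
    out: Dict[str, np.ndarray] = {}
    lo = 1 if skip_initiator else 0
    for g in genome:
        if feature == "tai":
            v = np.array([weights.w[c] for c in g.codons], dtype=float)
        elif feature == "charge":
            v = np.array(g.charge_vector(), dtype=float)
        else:
            v = np.asarray(fe_vectors[g.gene_id], dtype=float)
        out[g.gene_id] = v[lo:]
    return out


def slow_codon_set(weights, slow_fraction: float = 0.10) -> Set[str]:
    """Lowest-``slow_fraction`` sense codons by relative adaptiveness."""
    items = sorted(weights.w.items(), key=lambda kv: (kv[1], kv[0]))
    n_slow = max(1, int(np.ceil(slow_fraction * len(items))))
    return {codon for codon, _ in items[:n_slow]}
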