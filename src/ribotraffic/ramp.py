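"""Detection of the 5' "ramp" in a positional profile.

Sliding 13-codon windows over the first 200 codons are each compared (KS
test, one-sided) against all remaining positions of the region.  A run of
consecutive significant windows whose first window starts within the first
five codons defines the ramp; its length is the number of significant
consecutive windows plus 12 (the window width minus one), so a single
significant window already spans 13 codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np

from .stats import ks_test

Direction = Literal["lower", "higher"]

#: One-sided KS alternative testing that the window values are shifted in
#: ``direction`` relative to the rest.  "lower" (window stochastically
#: smaller) means the window ECDF lies above the rest, scipy's "greater".
_ALTERNATIVE = {"lower": "greater", "higher": "less"}


def _per_position(values) -> List[np.ndarray]:
    """Normalize input to a list of per-position observation arrays.

    Accepts a 1-D profile (one observation per position), a list of
    per-gene vectors (pooled by position), or an explicit list of arrays.
    """
    if isinstance(values, dict):
        values = list(values.values())
    first = np.asarray(values[0] if len(values) else [], dtype=float)
    if first.ndim == 0:  # a flat 1-D profile
        flat = np.asarray(values, dtype=float)
        return [flat[i : i + 1] for i in range(len(flat))]
    # list of per-gene vectors: pool by position
    n_pos = max(len(np.atleast_1d(v)) for v in values)
    pools: List[List[float]] = [[] for _ in range(n_pos)]
    for v in values:
        v = np.asarray(v, dtype=float)
        for i, x in enumerate(v):
            if x == x:
                pools[i].append(x)
    return [np.asarray(p) for p in pools]


@dataclass
class RampResult:
    present: bool
    start: Optional[int]  # 1-based codon position of the first window
    length: Optional[int]  # codons
    window_p: np.ndarray = field(repr=False)
    n_windows: int = 0
    alpha: float = 0.05
    summary_p: Optional[float] = None  # ramp values vs rest
    control_p: Optional[float] = None  # real vs randomized genome

    def to_dict(self) -> dict:
        return {
            "present": self.present,
            "start": self.start,
            "length": self.length,
            "alpha": self.alpha,
            "summary_p": self.summary_p,
            "control_p": self.control_p,
            "window_p": [float(p) for p in self.window_p],
        }


def detect_ramp(
    values,
    direction: Direction = "lower",
    window: int = 13,
    region: int = 200,
    alpha: float = 0.05,
    max_start: int = 5,
) -> RampResult:
    """Locate the 5' ramp of a per-position value collection.

    ``values`` may be a mean profile (one value per position) or per-gene
    vectors (pooled per position, the default mode for genome-scale data).
    """
    pools = _per_position(values)[:region]
    if len(pools) < 2 * window:
        raise ValueError(
            f"profile covers {len(pools)} positions; need >= {2 * window}"
        )
    region = len(pools)
    n_windows = region - window + 1
    alt = _ALTERNATIVE[direction]
    pvals = np.ones(n_windows)
    for s in range(n_windows):
        inside = np.concatenate(pools[s : s + window])
        outside = np.concatenate(pools[:s] + pools[s + window :])
        if len(inside) < 2 or len(outside) < 2:
            continue
        _, pvals[s] = ks_test(inside, outside, alternative=alt)
    significant = pvals <= alpha

    best_run = 0
    best_start = None
    s = 0
    while s < n_windows:
        if significant[s]:
            run = 1
            while s + run < n_windows and significant[s + run]:
                run += 1
            if s < max_start and run > best_run:
                best_run, best_start = run, s
            s += run
        else:
            s += 1
    if best_start is None:
        return RampResult(False, None, None, pvals, n_windows, alpha)
    return RampResult(
        present=True,
        start=best_start + 1,
        length=best_run + window - 1,
        window_p=pvals,
        n_windows=n_windows,
        alpha=alpha,
    )


def ramp_p_vs_rest(values, ramp: RampResult, region: int = 200) -> float:
    """KS P-value of pooled in-ramp values against the rest of the region."""
    if not ramp.present:
        raise ValueError("no ramp detected; nothing to test")
    pools = _per_position(values)[:region]
    lo, hi = ramp.start - 1, ramp.start - 1 + ramp.length
    inside = np.concatenate(pools[lo:hi])
    outside = np.concatenate(pools[:lo] + pools[hi:])
    _, p = ks_test(inside, outside)
    return p


def ramp_p_vs_randomized(
    real_values, randomized_values, ramp: RampResult, region: int = 200
) -> float:
    """KS P-value comparing in-ramp values of the real genome with the same
    positions of a randomized genome."""
    if not ramp.present:
        raise ValueError("no ramp detected; nothing to test")
    lo, hi = ramp.start - 1, ramp.start - 1 + ramp.length
    real = np.concatenate(_per_position(real_values)[:region][lo:hi])
    rand = np.concatenate(_per_position(randomized_values)[:region][lo:hi])
    _, p = ks_test(real, rand)
    return p
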