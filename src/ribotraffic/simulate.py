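"""Ribosome traffic models and per-codon translation times.

The nominal translation time of codon *i* combines the three coding-sequence
determinants, each normalized to genome mean 1::

    t_i = a1 * Ntai(i) * exp(a2 * Nch(i) + a3 * Nfe(i))

where ``Ntai`` is the normalized tRNA-adaptation time (1 / w_i), ``Nch`` the
normalized sum of amino-acid charges over the exit-tunnel window upstream of
the codon (default 31 residues, truncated at the gene start), and ``Nfe``
the normalized folding energy of the 40-nt window downstream of the codon.

Two traffic models turn nominal times into densities:

* a deterministic max-plus recurrence where a ribosome is delayed whenever
  the one downstream has not cleared its footprint, iterated to steady
  state; and
* an event-driven stochastic exclusion process (a TASEP with extended
  particles) with initiation rate ``lam`` and per-codon hopping rates
  ``1 / t_i``, whose time-averaged codon occupancies and termination rate
  are measured after a burn-in.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .profiles import PositionalProfile, mean_profile, smooth_vector
from .seq_core import CodingSequence, Genome
from .stats import ks_test

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class FeatureNorms:
    """Genome-wide means used to normalize the three determinant times."""

    mean_inv_w: float
    mean_charge_sum: float
    mean_fe: float

    def __post_init__(self) -> None:
        for name in ("mean_inv_w", "mean_charge_sum", "mean_fe"):
            if abs(getattr(self, name)) < 1e-9:
                raise ValueError(f"{name} ~ 0: normalization undefined")


def charge_window_sums(
    charges: Sequence[int], tunnel_len: int = 31
) -> np.ndarray:
    """Sum of charges of the ``tunnel_len`` residues strictly before each
    codon (truncated near the start; codon 1 sees an empty window)."""
    c = np.asarray(charges, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(c)])
    n = len(c)
    idx = np.arange(n)
    lo = np.maximum(idx - tunnel_len, 0)
    return cum[idx] - cum[lo]


def genome_norms(
    genome: Genome,
    weights,
    fe_vectors: Dict[str, np.ndarray],
    tunnel_len: int = 31,
) -> FeatureNorms:
    """Means of 1/w, upstream charge sums, and folding energies over all
    codons of all genes (undefined folding windows excluded)."""
    inv_w, ch, fe = [], [], []
    for g in genome:
        inv_w.extend(1.0 / weights.w[c] for c in g.codons)
        ch.append(charge_window_sums(g.charge_vector(), tunnel_len))
        v = np.asarray(fe_vectors[g.gene_id], dtype=float)
        fe.append(v[~np.isnan(v)])
    return FeatureNorms(
        mean_inv_w=float(np.mean(inv_w)),
        mean_charge_sum=float(np.mean(np.concatenate(ch))),
        mean_fe=float(np.mean(np.concatenate(fe))),
    )


@dataclass
class NominalTimes:
    """Per-codon normalized feature times and the combined time t_i."""

    gene_id: str
    ntai: np.ndarray
    nch: np.ndarray
    nfe: np.ndarray
    a: Tuple[float, float, float]
    t: np.ndarray = field(init=False)
    n_fe_filled: int = 0  # tail codons whose Nfe fell back to the gene mean

    def __post_init__(self) -> None:
        self.t = self.combined(self.a)
        if np.any(self.t <= 0):
            raise ValueError("non-positive translation time")

    def combined(self, a: Tuple[float, float, float]) -> np.ndarray:
        a1, a2, a3 = a
        return a1 * self.ntai * np.exp(a2 * self.nch + a3 * self.nfe)


def nominal_times(
    gene: CodingSequence,
    weights,
    fe_vector: Sequence[float],
    norms: FeatureNorms,
    a: Tuple[float, float, float] = (1.0, 0.4, 0.2),
    tunnel_len: int = 31,
) -> NominalTimes:
    inv_w = np.array([1.0 / weights.w[c] for c in gene.codons])
    ntai = inv_w / norms.mean_inv_w
    nch = charge_window_sums(gene.charge_vector(), tunnel_len) / norms.mean_charge_sum
    fe = np.asarray(fe_vector, dtype=float)
    nfe = fe / norms.mean_fe
    missing = np.isnan(nfe)
    n_filled = int(missing.sum())
    if n_filled:
        fill = float(np.nanmean(nfe)) if n_filled < len(nfe) else 1.0
        nfe = np.where(missing, fill, nfe)
    return NominalTimes(
        gene_id=gene.gene_id, ntai=ntai, nch=nch, nfe=nfe, a=a,
        n_fe_filled=n_filled,
    )


@dataclass
class TrafficConfig:
    footprint: int = 13  # codons covered by one ribosome; odd
    lam: float = 0.1  # stochastic initiation rate
    #: deterministic entry spacing; None = 2 * footprint * mean(t) (a sparse
    #: but interacting regime), math.inf = single ribosome
    init_interval: Optional[float] = None
    binding_time: float = 0.0
    termination_time: float = 1.0
    burn_in: int = 250_000  # events discarded
    measure: int = 1_000_000  # events measured
    seed: int = 0
    tol: float = 1e-6
    max_ribosomes: int = 10_000

    def __post_init__(self) -> None:
        if self.footprint < 1 or self.footprint % 2 == 0:
            raise ValueError("footprint must be odd and >= 1")
        if self.lam <= 0:
            raise ValueError("initiation rate must be > 0")
        if self.burn_in < 0 or self.measure < 1:
            raise ValueError("need measure >= 1 events")


@dataclass
class SimResult:
    gene_id: str
    mode: str
    dwell: Optional[np.ndarray] = None  # deterministic per-codon dwell times
    occupancy: Optional[np.ndarray] = None  # stochastic <n_i>, in [0, 1]
    production_rate: float = 0.0
    mean_ribosomes: float = 0.0
    n_ribosomes_to_converge: Optional[int] = None

    @property
    def density(self) -> np.ndarray:
        """Predicted per-codon ribosome density (dwell or occupancy)."""
        return self.dwell if self.dwell is not None else self.occupancy


def simulate_deterministic(
    times: NominalTimes, cfg: Optional[TrafficConfig] = None
) -> SimResult:
    """Steady-state dwell times of the deterministic traffic model.

    Ribosome r finishes codon i at ``f_r(i) = max(f_r(i-1), f_{r-1}(i+l))
    + t_i``: it cannot advance past a downstream ribosome closer than the
    footprint l.  Ribosomes enter at fixed intervals (plus binding time) and
    the recurrence is iterated until consecutive ribosomes' dwell vectors
    agree to within the tolerance.  With ``init_interval=math.inf`` (single
    ribosome) the dwell times equal the nominal times exactly; ``None``
    defaults to twice the footprint transit time, 2 * l * mean(t).
    """
    cfg = cfg or TrafficConfig()
    t = times.t
    N = len(t)
    if N < cfg.footprint:
        raise ValueError("gene shorter than the ribosome footprint")
    interval = (
        cfg.init_interval
        if cfg.init_interval is not None
        else 2.0 * cfg.footprint * float(np.mean(t))
    )
    if math.isinf(interval):
        return SimResult(
            gene_id=times.gene_id,
            mode="deterministic",
            dwell=t.copy(),
            production_rate=1.0 / (t.sum() + cfg.termination_time),
            mean_ribosomes=1.0,
            n_ribosomes_to_converge=1,
        )
    l = cfg.footprint
    prev_f = np.full(N + 2, -np.inf)  # finish times of the previous ribosome
    prev_dwell = None
    prev_finish_last = None
    production = 0.0
    for r in range(cfg.max_ribosomes):
        f = np.empty(N + 1)
        # binding waits for the previous ribosome to clear the entry
        # footprint; queueing before binding is not part of any dwell
        entry_free = prev_f[l + 1] if l + 1 <= N + 1 else -np.inf
        f[0] = max(r * interval + cfg.binding_time, entry_free)
        for i in range(1, N + 1):
            k = i + l  # codon the previous ribosome must have cleared
            block = prev_f[k] if k <= N + 1 else -np.inf
            f[i] = max(f[i - 1], block) + t[i - 1]
        dwell = np.diff(f)
        if prev_dwell is not None:
            rel = np.max(np.abs(dwell - prev_dwell) / np.maximum(prev_dwell, 1e-300))
            if rel < cfg.tol and r >= 1:
                production = (
                    1.0 / (f[N] - prev_finish_last) if prev_finish_last else 0.0
                )
                return SimResult(
                    gene_id=times.gene_id,
                    mode="deterministic",
                    dwell=dwell,
                    production_rate=production,
                    n_ribosomes_to_converge=r + 1,
                )
        prev_dwell = dwell
        prev_finish_last = f[N]
        prev_f[1 : N + 1] = f[1:]
        prev_f[N + 1] = f[N] + cfg.termination_time
    raise RuntimeError(
        f"{times.gene_id}: no steady state within {cfg.max_ribosomes} ribosomes "
        f"(last max relative dwell change {rel:.3g})"
    )


@njit(cache=True)
def _tasep_events(
    rates: np.ndarray,
    l: int,
    lam: float,
    n_burn: int,
    n_meas: int,
    seed: int,
) -> Tuple[np.ndarray, float, int, float]:
    np.random.seed(seed)
    N = rates.shape[0]
    half = (l + 1) // 2
    occ = np.zeros(N, dtype=np.uint8)
    occ_time = np.zeros(N)
    active = 0.0  # sum of rates of translating ribosomes
    t_meas = 0.0
    n_term = 0
    rib_time = 0.0
    n_rib = 0
    for step in range(n_burn + n_meas):
        mu = lam + active
        dt = np.random.exponential(1.0 / mu)
        if step >= n_burn:
            t_meas += dt
            rib_time += n_rib * dt
            for i in range(N):
                if occ[i]:
                    occ_time[i] += dt
        u = np.random.random() * mu
        if u < lam:
            # initiation attempt: first (l+1)/2 codons must be uncovered,
            # i.e. no translating ribosome within the first l codons
            free = True
            for j in range(min(l, N)):
                if occ[j]:
                    free = False
                    break
            if free:
                occ[0] = 1
                active += rates[0]
                n_rib += 1
        else:
            acc = lam
            chosen = -1
            for i in range(N):
                if occ[i]:
                    acc += rates[i]
                    if u < acc:
                        chosen = i
                        break
            if chosen >= 0:
                i = chosen
                if i == N - 1:  # termination
                    occ[i] = 0
                    active -= rates[i]
                    n_rib -= 1
                    if step >= n_burn:
                        n_term += 1
                else:
                    target = i + half  # codon that must be uncovered
                    free = True
                    if target <= N - 1:
                        hi = i + l if i + l < N else N - 1
                        for j in range(i + 1, hi + 1):
                            if occ[j]:
                                free = False
                                break
                    if free:
                        occ[i] = 0
                        occ[i + 1] = 1
                        active += rates[i + 1] - rates[i]
    return occ_time, t_meas, n_term, rib_time


def simulate_stochastic(
    times_or_rates,
    cfg: Optional[TrafficConfig] = None,
    gene_id: str = "",
) -> SimResult:
    """Event-driven stochastic exclusion-process simulation.

    Accepts a :class:`NominalTimes` (rates 1/t_i) or an explicit rate
    vector.  Events (initiation / jump / termination attempts, including
    failed ones) advance an exponential clock with the summed active rate;
    occupancies are time-averaged over the measurement phase and the
    production rate is terminations per unit measured time.  Identical seed
    and configuration give identical results.
    """
    cfg = cfg or TrafficConfig()
    if isinstance(times_or_rates, NominalTimes):
        rates = 1.0 / times_or_rates.t
        gene_id = gene_id or times_or_rates.gene_id
    else:
        rates = np.asarray(times_or_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("all hopping rates must be > 0")
    occ_time, t_meas, n_term, rib_time = _tasep_events(
        rates.astype(np.float64),
        cfg.footprint,
        float(cfg.lam),
        int(cfg.burn_in),
        int(cfg.measure),
        int(cfg.seed) & 0x7FFFFFFF,
    )
    return SimResult(
        gene_id=gene_id,
        mode="stochastic",
        occupancy=occ_time / t_meas,
        production_rate=n_term / t_meas,
        mean_ribosomes=rib_time / t_meas,
    )


def predict_density_profile(
    times: Dict[str, NominalTimes],
    cfg: Optional[TrafficConfig] = None,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
    max_positions: Optional[int] = None,
    span: int = 5,
) -> Tuple[PositionalProfile, PositionalProfile]:
    """Positional mean of per-gene predicted densities (raw and smoothed)."""
    vectors = {}
    for gid, nt in times.items():
        if mode == "deterministic":
            sim = simulate_deterministic(nt, cfg)
        else:
            sim = simulate_stochastic(nt, cfg)
        vectors[gid] = sim.density
    prof = mean_profile(vectors, "start", max_positions, feature=f"predicted_density_{mode}")
    from .profiles import smooth as _smooth

    return prof, _smooth(prof, span)


def fit_abc(
    times: Dict[str, NominalTimes],
    densities: Dict[str, np.ndarray],
    grid_step: float = 0.05,
    max_positions: Optional[int] = 200,
    span: int = 5,
    a1_min: float = 0.05,
) -> Tuple[Tuple[float, float, float], float]:
    """Fit the translation-time parameters (a1, a2, a3) on [0, 1].

    a2 and a3 are selected by grid search maximizing the Spearman
    correlation between the smoothed predicted and observed density
    profiles (ties broken toward smaller values); a1, to which a rank
    objective is blind because it scales all times uniformly, is then
    selected on the same grid by least-squares magnitude matching of the
    two profiles.  Returns ((a1, a2, a3), best Spearman).
    """
    from scipy.stats import spearmanr

    gids = [g for g in times if g in densities]
    if not gids:
        raise ValueError("no genes shared between times and densities")
    obs_prof = mean_profile(
        {g: densities[g] for g in gids}, "start", max_positions
    )
    obs_sm = smooth_vector(obs_prof.mean, span)

    def profile_for(a2: float, a3: float) -> np.ndarray:
        vecs = {g: times[g].combined((1.0, a2, a3)) for g in gids}
        prof = mean_profile(vecs, "start", max_positions)
        n = min(len(prof.mean), len(obs_sm))
        return smooth_vector(prof.mean, span)[:n]

    n_steps = int(round(1.0 / grid_step))
    grid = [round(k * grid_step, 10) for k in range(n_steps + 1)]
    best = (-np.inf, None, None)
    for a2, a3 in itertools.product(grid, grid):
        pred = profile_for(a2, a3)
        o = obs_sm[: len(pred)]
        if np.all(pred == pred[0]):
            continue
        rho = spearmanr(pred, o).statistic
        if rho > best[0]:
            best = (rho, a2, a3)
    if best[1] is None:
        raise ValueError("objective degenerate at every grid point")
    rho_best, a2, a3 = best
    base = profile_for(a2, a3)  # prediction at a1 = 1
    o = obs_sm[: len(base)]
    a1_grid = [g for g in grid if g >= a1_min]
    sse = [float(np.sum((a1 * base - o) ** 2)) for a1 in a1_grid]
    a1 = a1_grid[int(np.argmin(sse))]
    return (a1, a2, a3), float(rho_best)


def feature_bottleneck(
    values: Sequence[float],
    window: int = 10,
    region: int = 200,
    direction: Literal["min", "max"] = "min",
) -> int:
    """1-based start of the most extreme ``window``-codon mean in a gene.

    ``direction='min'`` finds the slowest region for features where low
    means slow (tAI, folding energy); ``'max'`` for charge, predicted time
    or observed density.  Ties go to the smallest start.
    """
    v = np.asarray(values, dtype=float)[:region]
    if len(v) < window:
        raise ValueError(f"gene covers {len(v)} positions; window is {window}")
    means = np.array(
        [np.nanmean(v[i : i + window]) for i in range(len(v) - window + 1)]
    )
    if direction == "min":
        return int(np.nanargmin(means)) + 1
    return int(np.nanargmax(means)) + 1


def bottleneck_distance_analysis(
    predictions: Dict[str, np.ndarray],
    densities: Dict[str, np.ndarray],
    window: int = 10,
    region: int = 200,
    n_permutations: int = 1,
    seed: int = 0,
) -> dict:
    """Distances between predicted and observed highest-density windows.

    For each gene, the |start difference| between the window with the
    highest observed density and the window with the highest predicted
    density, compared against a null where each gene's density vector is
    randomly permuted.  Reports the two distance samples, their means and a
    one-sided KS P-value for the real distances being smaller.
    """
    rng = np.random.default_rng(seed)
    real, null = [], []
    for gid, pred in predictions.items():
        obs = densities.get(gid)
        if obs is None:
            continue
        n = min(len(pred), len(obs))
        if n < window:
            continue
        p_start = feature_bottleneck(pred[:n], window, region, "max")
        o_start = feature_bottleneck(obs[:n], window, region, "max")
        real.append(abs(p_start - o_start))
        for _ in range(n_permutations):
            perm = np.asarray(obs[:n])[rng.permutation(n)]
            null.append(
                abs(p_start - feature_bottleneck(perm, window, region, "max"))
            )
    if not real:
        raise ValueError("no genes with both predictions and densities")
    _, p = ks_test(real, null, alternative="greater")
    return {
        "distances": real,
        "null_distances": null,
        "mean_real": float(np.mean(real)),
        "mean_null": float(np.mean(null)),
        "ks_p": float(p),
    }
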