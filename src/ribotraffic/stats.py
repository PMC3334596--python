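"""Statistical machinery: KS tests, (partial) Spearman correlations with
permutation P-values, the density regressor, and split-half cross-validation.

The recursive partial correlation controls for two covariates by applying
the first-order formula twice::

    r_xy.z  = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
    r_xy.zw = (r_xy.z - r_xw.z r_yw.z) / sqrt((1 - r_xw.z^2)(1 - r_yw.z^2))

On rank-transformed data this is the partial Spearman correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .profiles import smooth_vector


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    empirical_p: Optional[float] = None

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError(f"|coefficient| = {abs(self.coefficient)} > 1")


def ks_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    One-sided alternatives follow scipy's ECDF convention:
    ``'greater'`` tests whether the ECDF of ``sample_a`` lies above that of
    ``sample_b`` (i.e. ``sample_a`` stochastically smaller), ``'less'`` the
    reverse.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    res = sps.ks_2samp(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _check_pair(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    good = ~(np.isnan(x) | np.isnan(y))
    x, y = x[good], y[good]
    if len(x) < 3:
        raise ValueError("need n >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks)."""
    x, y = _check_pair(x, y)
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def partial_corr_1(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation from the three pairwise coefficients."""
    if abs(rxz) >= 1.0 or abs(ryz) >= 1.0:
        raise ValueError("control correlation with |r| >= 1: undefined")
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))


def _corr_matrix(vectors: List[np.ndarray], method: str) -> np.ndarray:
    mat = np.vstack(vectors)
    if method == "spearman":
        mat = np.vstack([sps.rankdata(v) for v in mat])
    return np.corrcoef(mat)


def partial_corr_2(
    x,
    y,
    z,
    w,
    method: Literal["spearman", "pearson"] = "spearman",
) -> CorrelationResult:
    """Correlation of x and y controlling for z and w (recursive formula)."""
    vecs = [np.asarray(v, dtype=float) for v in (x, y, z, w)]
    n = len(vecs[0])
    if any(len(v) != n for v in vecs):
        raise ValueError("all four vectors must have equal length")
    good = ~np.any([np.isnan(v) for v in vecs], axis=0)
    vecs = [v[good] for v in vecs]
    n = int(good.sum())
    if n < 4:
        raise ValueError("need n >= 4 complete quadruples")
    R = _corr_matrix(vecs, method)
    ix, iy, iz, iw = range(4)
    rxy_z = partial_corr_1(R[ix, iy], R[ix, iz], R[iy, iz])
    rxw_z = partial_corr_1(R[ix, iw], R[ix, iz], R[iw, iz])
    ryw_z = partial_corr_1(R[iy, iw], R[iy, iz], R[iw, iz])
    coef = partial_corr_1(rxy_z, rxw_z, ryw_z)
    coef = float(np.clip(coef, -1.0, 1.0))
    # large-sample t approximation with 2 controls
    df = n - 4
    if df > 0 and abs(coef) < 1:
        t = coef * math.sqrt(df / (1 - coef**2))
        p = 2 * sps.t.sf(abs(t), df)
    else:
        p = float("nan")
    return CorrelationResult(coef, float(p), n)


def partial_corr_matrix(
    x, y, controls: Sequence[Sequence[float]], method: str = "spearman"
) -> float:
    """Partial correlation via inversion of the full correlation matrix.

    Independent route used to cross-check the recursive formula.
    """
    vecs = [np.asarray(v, dtype=float) for v in (x, y, *controls)]
    R = _corr_matrix(vecs, method)
    P = np.linalg.inv(R)
    return float(-P[0, 1] / math.sqrt(P[0, 0] * P[1, 1]))


def empirical_p(
    x,
    y,
    controls: Sequence[Sequence[float]],
    stat: Optional[Callable[..., float]] = None,
    B: int = 100,
    seed: int = 0,
) -> float:
    """Permutation P-value for a partial correlation.

    ``x`` and ``y`` (the uncontrolled variables) are independently permuted
    ``B`` times with the controls held fixed; the P-value is the fraction of
    permutations whose statistic is >= the observed one (ties count against
    significance).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if stat is None:
        if len(controls) != 2:
            raise ValueError("default statistic expects exactly 2 controls")

        def stat(xx, yy, z, w):
            return partial_corr_2(xx, yy, z, w).coefficient

    observed = stat(x, y, *controls)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        xp = x[rng.permutation(len(x))]
        yp = y[rng.permutation(len(y))]
        if stat(xp, yp, *controls) >= observed:
            hits += 1
    return hits / B


@dataclass
class RegressorFit:
    """OLS fit of ribosomal density on (1/tAI, folding energy, charge)."""

    coefficients: Dict[str, float]
    intercept: float
    p_values: Dict[str, float]
    spearman_fit: float
    n_positions: int
    smoothing: Optional[int]
    fitted: np.ndarray = field(repr=False, default=None)

    def predict(self, features: Dict[str, np.ndarray]) -> np.ndarray:
        out = np.full_like(next(iter(features.values())), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            out = out + coef * np.asarray(features[name], dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "p_values": self.p_values,
            "spearman_fit": self.spearman_fit,
            "n_positions": self.n_positions,
            "smoothing": self.smoothing,
            "multiple_testing_correction": "none",
        }


def fit_regressor(
    inv_tai: Sequence[float],
    fe: Sequence[float],
    charge: Sequence[float],
    density: Sequence[float],
    smooth: bool = True,
    span: int = 5,
) -> RegressorFit:
    """OLS of the (optionally smoothed) density profile on the three
    determinant profiles: density ~ a*(1/tAI) + b*FE + c*charge + d."""
    import statsmodels.api as sm

    arrays = [np.asarray(v, dtype=float) for v in (inv_tai, fe, charge, density)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("profiles must cover the same positions")
    if smooth:
        arrays = [smooth_vector(a, span) for a in arrays]
    good = ~np.any([np.isnan(a) for a in arrays], axis=0)
    Xcols = np.column_stack([a[good] for a in arrays[:3]])
    yv = arrays[3][good]
    X = sm.add_constant(Xcols, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    model = sm.OLS(yv, X).fit()
    names = ["inv_tai", "fe", "charge"]
    fitted = model.fittedvalues
    rho = float(sps.spearmanr(fitted, yv).statistic)
    return RegressorFit(
        coefficients=dict(zip(names, map(float, model.params[1:]))),
        intercept=float(model.params[0]),
        p_values=dict(zip(names, map(float, model.pvalues[1:]))),
        spearman_fit=rho,
        n_positions=int(good.sum()),
        smoothing=span if smooth else None,
        fitted=fitted,
    )


@dataclass
class SplitHalfResult:
    """Per-repeat test-set correlations for two model variants."""

    full: np.ndarray
    reduced: np.ndarray
    significance_margin: float = 0.004

    @property
    def differences(self) -> np.ndarray:
        return self.full - self.reduced

    @property
    def empirical_p(self) -> float:
        """Fraction of repeats where the reduced model beats the full one
        by more than the significance margin."""
        return float(
            np.mean(self.reduced - self.full > self.significance_margin)
        )

    @property
    def verdicts(self) -> List[str]:
        out = []
        for d in self.differences:
            if abs(d) <= self.significance_margin:
                out.append("not significant")
            elif d > 0:
                out.append("full better")
            else:
                out.append("reduced better")
        return out


def split_half_validation(
    gene_ids: Sequence[str],
    fit_full: Callable[[List[str]], Callable[[List[str]], float]],
    fit_reduced: Optional[Callable[[List[str]], Callable[[List[str]], float]]] = None,
    repeats: int = 20,
    seed: int = 0,
    margin: float = 0.004,
) -> SplitHalfResult:
    """Seeded 50/50 split-half cross-validation.

    ``fit_full(train_ids)`` must return an evaluator ``eval(test_ids) ->
    test correlation``; likewise for the reduced variant (defaults to the
    full model, giving all-zero differences).
    """
    ids = list(gene_ids)
    if len(ids) < 4:
        raise ValueError("need >= 4 genes for split-half validation")
    fit_reduced = fit_reduced or fit_full
    rng = np.random.default_rng(seed)
    full_scores, reduced_scores = [], []
    for _ in range(repeats):
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        train = [ids[i] for i in perm[:half]]
        test = [ids[i] for i in perm[half:]]
        full_scores.append(fit_full(train)(test))
        reduced_scores.append(fit_reduced(train)(test))
    return SplitHalfResult(
        np.asarray(full_scores), np.asarray(reduced_scores), margin
    )
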