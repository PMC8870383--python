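"""Feature-relevance scoring: normalized mutual information and Spearman.

Mutual information I(X, Y) = sum_xy p(x,y) log2( p(x,y) / (f(x) g(y)) ) is
estimated by the plug-in (histogram) method: continuous variables are
quantile-binned (default 10 bins), discrete variables used as-is, and the
score is normalized to [0, 1] by sqrt(H(X) H(Y)).  Because quantile
binning depends only on ranks, the normalized score is invariant under
strictly monotone transforms of either variable.

Spearman's correlation is the Pearson correlation of mid-ranks; the
p-value uses the t approximation t = rho sqrt((n-2)/(1-rho^2)) and the
statistical power the Fisher z normal approximation at the observed rho.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError


@dataclass(frozen=True)
class JointDistribution:
    """A discrete joint probability table with consistent marginals."""

    p: np.ndarray  # shape (nx, ny)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2:
            raise ValueError("joint table must be 2-D")
        if (p < 0).any():
            raise ValueError("joint table has negative entries")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"joint table sums to {p.sum()}, not 1")

    @property
    def f(self) -> np.ndarray:  # marginal of X (rows)
        return np.asarray(self.p).sum(axis=1)

    @property
    def g(self) -> np.ndarray:  # marginal of Y (columns)
        return np.asarray(self.p).sum(axis=0)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(joint: JointDistribution) -> float:
    """I(X, Y) in bits; zero-probability cells contribute nothing."""
    p = np.asarray(joint.p, dtype=float)
    outer = np.outer(joint.f, joint.g)
    mask = p > 0
    terms = p[mask] * np.log2(p[mask] / outer[mask])
    return float(max(terms.sum(), 0.0))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Quantile-bin a variable; small discrete supports pass through."""
    values = np.unique(x)
    if len(values) <= bins:
        return np.searchsorted(values, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def joint_from_samples(x: np.ndarray, y: np.ndarray, bins: int = 10) -> JointDistribution:
    xd = _discretize(np.asarray(x, dtype=float), bins)
    yd = _discretize(np.asarray(y, dtype=float), bins)
    table = pd.crosstab(xd, yd).to_numpy(dtype=float)
    return JointDistribution(table / table.sum())


def normalized_mi(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """I(X, Y) / sqrt(H(X) H(Y)), clipped to [0, 1]; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    joint = joint_from_samples(x, y, bins)
    hx = _entropy_bits(joint.f)
    hy = _entropy_bits(joint.g)
    if hx == 0.0 or hy == 0.0:
        warnings.warn("constant variable: normalized MI defined as 0")
        return 0.0
    return float(np.clip(mutual_information(joint) / np.sqrt(hx * hy), 0.0, 1.0))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    power: float


def spearman_with_power(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> SpearmanResult:
    """Spearman rho with t-approximation p-value and Fisher-z power."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input")
    rho, p_value = stats.spearmanr(x, y)
    power = _fisher_z_power(rho, n, alpha)
    return SpearmanResult(float(rho), float(p_value), float(power))


def _fisher_z_power(rho: float, n: int, alpha: float) -> float:
    """Two-sided power to detect the observed rho at sample size n."""
    if abs(rho) >= 1.0:
        return 1.0
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    shift = abs(z) / se
    return float(stats.norm.cdf(shift - crit) + stats.norm.cdf(-shift - crit))


def relevance_report(
    features: pd.DataFrame,
    mmse: np.ndarray,
    labels: np.ndarray,
    bins: int = 10,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, SpearmanResult]:
    """Score every feature column against MMSE and the binary label.

    Returns a table (feature, nmi_mmse, nmi_label, rank — rank 1 is the
    feature sharing most information with MMSE) and the Spearman block for
    MMSE against the label (AD coded 1, so an informative MMSE is strongly
    negative).
    """
    label01 = np.asarray([1 if l == "AD" else 0 for l in labels], dtype=float)
    mmse = np.asarray(mmse, dtype=float)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        rows.append(
            {
                "feature": name,
                "nmi_mmse": normalized_mi(x, mmse, bins),
                "nmi_label": normalized_mi(x, label01, bins),
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table["nmi_mmse"].rank(ascending=False, method="first").astype(int)
    )
    spearman = spearman_with_power(mmse, label01, alpha)
    return table, spearman
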