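"""Multilocus HKA test with varying per-locus sample sizes.

Under neutrality, polymorphism within a species and divergence from an
outgroup are both proportional to the neutral mutation rate, so their ratio
should be homogeneous across loci.  For locus i with ingroup sample size
n_i, L_i silent sites and a single outgroup sequence:

    E[S_i] = theta_i * L_i * a_{n_i},          a_n = sum_{k<n} 1/k
    E[D_i] = theta_i * L_i * (T + 1)

where theta_i is the per-site population mutation parameter, T the species
divergence time in units of 2N generations, and the ``+ 1`` the expected
extra coalescence time of an ingroup/outgroup lineage pair in an ancestral
population of the same size (the mean of the sample-vs-one-sequence mean
pairwise divergence does not depend on n_i).  Divergence D_i is the mean
(multiple-hit corrected) difference count between each ingroup sequence and
the outgroup, hence generally fractional.  The moment system is closed by
the conservation equations sum E[S] = sum S and sum E[D] = sum D; the
goodness-of-fit statistic sums the standardised squared residuals with the
variances  Var(S) = E[S] + b_n (theta L)^2  and  Var(D) = E[D] + (theta L)^2,
and is referred to chi-square with (loci - 1) degrees of freedom, or to a
coalescent simulation of the fitted null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import _kernels
from .diversity import harmonic, harmonic2

__all__ = [
    "HKALocusDatum",
    "HKAResult",
    "fit_hka",
    "hka_pvalue_sim",
    "hka_locus_datum",
]

logger = logging.getLogger(__name__)


@dataclass
class HKALocusDatum:
    """Observed polymorphism and divergence for one locus."""

    locus: str
    S_obs: int
    D_obs: float
    n: int
    L: float

    def __post_init__(self) -> None:
        if self.S_obs < 0 or self.D_obs < 0:
            raise ValueError(f"{self.locus}: S_obs and D_obs must be >= 0")
        if self.n < 2:
            raise ValueError(f"{self.locus}: ingroup sample size must be >= 2")
        if self.L <= 0:
            raise ValueError(f"{self.locus}: L must be positive")


@dataclass
class HKAResult:
    """Fitted HKA parameters, expectations and goodness-of-fit."""

    loci: list[str]
    theta_hat: dict[str, float]  # per site
    T_hat: float
    expected_S: dict[str, float]
    expected_D: dict[str, float]
    var_S: dict[str, float]
    var_D: dict[str, float]
    statistic: float
    df: int
    p_chisq: float
    p_sim: float | None = None
    n_sim: int = 0

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")


def fit_hka(data: Sequence[HKALocusDatum]) -> HKAResult:
    """Fit the HKA moment system and compute the goodness-of-fit statistic.

    The per-locus conservation S_i + D_i = theta_i L_i (a_{n_i} + T + 1)
    expresses each theta_i in terms of T; T is then the root of the total
    divergence equation sum theta_i L_i (T+1) = sum D_i, which is strictly
    increasing in T, so the solution is unique (clamped at T=0 when even a
    zero divergence time over-predicts divergence).  At the root the sums of
    expected S and D automatically match the observed sums.
    """
    data = list(data)
    if len(data) < 2:
        raise ValueError("the HKA test needs at least two loci")
    if all(d.S_obs == 0 for d in data):
        raise ValueError("all loci have S = 0; theta is unidentifiable")
    a = np.array([harmonic(d.n) for d in data])
    b = np.array([harmonic2(d.n) for d in data])
    S = np.array([float(d.S_obs) for d in data])
    D = np.array([float(d.D_obs) for d in data])
    tot = S + D

    def theta_L(T: float) -> np.ndarray:
        return tot / (a + T + 1.0)

    def excess_divergence(T: float) -> float:
        return float((theta_L(T) * (T + 1.0)).sum() - D.sum())

    if excess_divergence(0.0) >= 0.0:
        T_hat = 0.0
    else:
        hi = 1.0
        while excess_divergence(hi) < 0.0:
            hi *= 2.0
            if hi > 1e12:
                raise RuntimeError("HKA divergence equation failed to bracket")
        T_hat = float(optimize.brentq(excess_divergence, 0.0, hi, xtol=1e-12))

    tl = theta_L(T_hat)
    ES = tl * a
    ED = tl * (T_hat + 1.0)
    var_S = ES + b * tl**2
    var_D = ED + tl**2
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(var_S > 0, (S - ES) ** 2 / var_S, 0.0) + np.where(
            var_D > 0, (D - ED) ** 2 / var_D, 0.0
        )
    statistic = float(contrib.sum())
    df = len(data) - 1
    loci = [d.locus for d in data]
    return HKAResult(
        loci=loci,
        theta_hat={d.locus: float(t / d.L) for d, t in zip(data, tl)},
        T_hat=T_hat,
        expected_S=dict(zip(loci, ES.tolist())),
        expected_D=dict(zip(loci, ED.tolist())),
        var_S=dict(zip(loci, var_S.tolist())),
        var_D=dict(zip(loci, var_D.tolist())),
        statistic=statistic,
        df=df,
        p_chisq=float(stats.chi2.sf(statistic, df)),
    )


def hka_locus_datum(alignment, subset=None, silent_only: bool = True) -> HKALocusDatum:
    """Observed (S, D, n, L) for one locus from an alignment with an outgroup.

    Both polymorphism and divergence are restricted to silent columns at
    which the outgroup base is unambiguous, so S and D share the same
    surveyed-site denominator L.  D is the mean over ingroup sequences of
    the Jukes-Cantor-corrected difference count to the single outgroup
    sequence (hence generally fractional).
    """
    from .diversity import _is_synonymous_column, silent_sites

    og = alignment.outgroup_array()
    if og is None:
        raise ValueError(f"{alignment.locus_name}: no outgroup sequence")
    ss = silent_sites(alignment)
    og_valid = np.isin(og, [b"A", b"C", b"G", b"T"])
    eligible = (ss.fraction > 0) & og_valid
    L = float(ss.fraction[eligible].sum())
    if L <= 0:
        raise ValueError(f"{alignment.locus_name}: no surveyed silent sites")
    idx = alignment.subset_indices(subset)
    sub = alignment.matrix()[idx]
    cols = np.nonzero(eligible)[0]
    S = 0
    for col in cols:
        col_vals = sub[:, col]
        if not (col_vals != col_vals[0]).any():
            continue
        if silent_only and ss.coding[col]:
            if not _is_synonymous_column(
                alignment, ss, col, np.unique(col_vals)
            ):
                continue
        S += 1
    diffs = (sub[:, cols] != og[cols]).sum(axis=1)
    p = diffs / L
    if (p >= 0.75).any():
        raise ValueError(
            f"{alignment.locus_name}: divergence saturates the Jukes-Cantor correction"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return HKALocusDatum(
        locus=alignment.locus_name,
        S_obs=S,
        D_obs=float(d.mean() * L),
        n=len(idx),
        L=L,
    )


def _simulate_locus(n: int, theta_locus: float, T: float, rng) -> tuple[int, float]:
    """One neutral two-species replicate: (S, mean ingroup-outgroup D)."""
    exp_draws = rng.exponential(size=n + 2)
    pair_draws = rng.random(size=2 * (n + 2))
    parent = np.empty(2 * n + 1, dtype=np.int64)
    node_time = np.empty(2 * n + 1)
    _kernels.two_species_tree(n, T, exp_draws, pair_draws, parent, node_time)
    blen = node_time[parent] - node_time
    blen[-1] = 0.0
    tip_class = np.zeros(n + 1, dtype=np.int64)
    tip_class[n] = 1  # the outgroup
    cnt = _kernels.class_counts(parent, tip_class, n + 1, 2)
    s_b = rng.poisson(0.5 * theta_locus * blen)
    c_in = cnt[:, 0]
    c_out = cnt[:, 1]
    seg = (c_in > 0) & (c_in < n)
    S = int(s_b[seg].sum())
    w = np.where(c_out == 0, c_in / n, (n - c_in) / n)
    D = float((s_b * w).sum())
    return S, D


def hka_pvalue_sim(
    data: Sequence[HKALocusDatum],
    fitted: HKAResult,
    n_sim: int,
    rng=None,
) -> float:
    """Simulation P value: fraction of null replicates with a statistic >= observed.

    Each replicate simulates every locus under the fitted (theta, T) with a
    neutral constant-size coalescent (no inversion events) at the observed
    sample sizes, refits the moment system, and compares statistics.  A
    replicate whose refit is degenerate (no polymorphism anywhere) is
    counted as at least as extreme, which can only be conservative.
    """
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} < 100 gives an unstable simulation P value")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    data = list(data)
    exceed = 0
    for _ in range(n_sim):
        sim = []
        for d in data:
            theta_locus = fitted.theta_hat[d.locus] * d.L
            S, D = _simulate_locus(d.n, theta_locus, fitted.T_hat, rng)
            sim.append(HKALocusDatum(d.locus, S, D, d.n, d.L))
        try:
            stat = fit_hka(sim).statistic
        except ValueError:
            exceed += 1
            continue
        if stat >= fitted.statistic:
            exceed += 1
    return exceed / n_sim
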