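"""Classification of polymorphisms across gene arrangements.

A segregating site is *unique* when it is polymorphic within exactly one
arrangement and *shared* when it segregates in two or more; the outgroup
sequence polarizes each biallelic site, the allele not matching the outgroup
being the derived mutation, and arrangements in which the derived allele has
fixed are tallied separately.  The null hypothesis that polymorphism occurs
independently across the K arrangements assigns every site a presence/absence
configuration in {0,1}^K with expected count N * prod_j p_j^c_j (1-p_j)^(1-c_j)
from the marginal polymorphism probabilities p_j; a Pearson chi-square over
all 2^K configurations (df = 2^K - 1) tests the independence null, and a
K-category chi-square tests whether unique polymorphisms are distributed
proportionally to each arrangement's share of segregating sites.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ld import SiteTable

__all__ = [
    "SiteClassification",
    "polarize_site",
    "classify_sites",
    "IndependenceResult",
    "independence_null_test",
    "unique_excess_test",
    "category_chisq",
]

logger = logging.getLogger(__name__)


def polarize_site(
    alleles: Sequence[str], outgroup_allele: str | None
) -> str | None:
    """Infer the derived allele of a biallelic site from the outgroup base.

    The allele that does not match the outgroup base is derived.  When the
    outgroup base matches neither allele, or is a gap/N/absent, the site is
    unpolarizable and None is returned.
    """
    a, b = alleles
    if not outgroup_allele or outgroup_allele not in "ACGT":
        return None
    if outgroup_allele == a:
        return b
    if outgroup_allele == b:
        return a
    return None


@dataclass
class SiteClassification:
    """Per-site polymorphism configuration over the analyzed arrangements."""

    locus: str
    position: int
    configuration: tuple[int, ...]  # presence of polymorphism per arrangement
    derived_allele: str | None
    fixed_in: tuple[str, ...]  # arrangements where the derived allele is fixed
    site_class: str  # "unique" | "shared" | "monomorphic"

    def __post_init__(self) -> None:
        n_poly = sum(self.configuration)
        expect = (
            "unique" if n_poly == 1 else "shared" if n_poly >= 2 else "monomorphic"
        )
        if self.site_class != expect:
            raise ValueError("site_class inconsistent with configuration")


def classify_sites(
    site_table: SiteTable,
    arrangements: Sequence[str] | None = None,
) -> tuple[list[SiteClassification], dict[tuple[int, ...], int], list[str]]:
    """Classify every site and tally the 2^K presence/absence configurations.

    Arrangements with fewer than two strains cannot harbour polymorphism and
    are excluded from the configurations (logged).  Returns the per-site
    classifications, the configuration counts over all 2^K patterns, and the
    list of analyzed arrangements (in the order used by the configurations).
    A site is "monomorphic" when it segregates in the pooled panel but within
    no single arrangement (different alleles fixed in different
    arrangements).
    """
    labels = site_table.arrangement_labels
    if arrangements is None:
        arrangements = sorted(set(labels))
    usable = []
    for arr in arrangements:
        if (labels == arr).sum() < 2:
            logger.info("arrangement %s has n < 2; excluded from configurations", arr)
            continue
        usable.append(arr)
    if not usable:
        raise ValueError("no arrangement has two or more strains")
    K = len(usable)
    masks = {arr: labels == arr for arr in usable}
    counts: dict[tuple[int, ...], int] = {
        cfg: 0 for cfg in itertools.product((0, 1), repeat=K)
    }
    out: list[SiteClassification] = []
    for s in range(site_table.n_sites):
        row = site_table.alleles[s]
        cfg = []
        for arr in usable:
            sub = row[masks[arr]]
            sub = sub[sub >= 0]
            cfg.append(int(sub.size >= 2 and (sub != sub[0]).any()))
        cfg = tuple(cfg)
        counts[cfg] += 1
        og = (
            site_table.outgroup_allele[s]
            if site_table.outgroup_allele is not None
            else None
        )
        derived = polarize_site((site_table.major[s], site_table.minor[s]), og)
        fixed_in = []
        if derived is not None:
            derived_code = 0 if derived == site_table.major[s] else 1
            for arr in usable:
                sub = row[masks[arr]]
                sub = sub[sub >= 0]
                if sub.size and (sub == derived_code).all():
                    fixed_in.append(arr)
        n_poly = sum(cfg)
        out.append(
            SiteClassification(
                locus=str(site_table.loci[s]),
                position=int(site_table.positions[s]),
                configuration=cfg,
                derived_allele=derived,
                fixed_in=tuple(fixed_in),
                site_class=(
                    "unique" if n_poly == 1 else "shared" if n_poly >= 2
                    else "monomorphic"
                ),
            )
        )
    return out, counts, usable


@dataclass
class IndependenceResult:
    """Pearson chi-square of configuration counts against independence."""

    chi2: float
    df: int
    p: float
    expected: dict[tuple[int, ...], float]
    marginal_probs: np.ndarray
    chi2_pooled: float | None = None
    df_pooled: int | None = None
    p_pooled: float | None = None
    pooled_bin: list[tuple[int, ...]] | None = None


def independence_null_test(
    configuration_counts: Mapping[tuple[int, ...], int],
    K: int,
    marginal_probs: Sequence[float] | None = None,
) -> IndependenceResult:
    """Test whether polymorphism occurs independently across arrangements.

    Expected configuration counts are products of the per-arrangement
    marginal polymorphism probabilities (estimated from the counts unless
    supplied), scaled by the total site count; the Pearson chi-square runs
    over all 2^K configurations with df = 2^K - 1.  The df is exact when the
    margins are supplied externally; with margins estimated from the same
    counts it matches the conventional report but is mildly conservative.
    When any expected count falls below 1, the rarest-expectation cells are
    additionally pooled into one bin and the pooled statistic reported
    alongside the raw one.
    """
    configs = list(itertools.product((0, 1), repeat=K))
    obs = np.array([configuration_counts.get(cfg, 0) for cfg in configs], dtype=float)
    N = obs.sum()
    if N <= 0:
        raise ValueError("no classified sites")
    if marginal_probs is None:
        marg = np.array(
            [
                sum(c for cfg, c in configuration_counts.items() if cfg[j] == 1) / N
                for j in range(K)
            ]
        )
    else:
        marg = np.asarray(marginal_probs, dtype=float)
        if marg.shape != (K,) or (marg < 0).any() or (marg > 1).any():
            raise ValueError("marginal_probs must be K probabilities")
    cfg_mat = np.array(configs, dtype=float)
    probs = np.prod(
        np.where(cfg_mat == 1, marg, 1.0 - marg), axis=1
    )
    expected = N * probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, np.where(obs > 0, np.inf, 0.0))
    chi2 = float(terms.sum())
    df = 2**K - 1
    p = float(stats.chi2.sf(chi2, df))
    result = IndependenceResult(
        chi2=chi2,
        df=df,
        p=p,
        expected=dict(zip(configs, expected.tolist())),
        marginal_probs=marg,
    )
    if (expected < 1.0).any():
        order = np.argsort(expected)
        pooled_idx = []
        pooled_exp = 0.0
        pos = 0
        while pos < len(order) and (pooled_exp < 1.0 or expected[order[pos]] < 1.0):
            pooled_idx.append(order[pos])
            pooled_exp += expected[order[pos]]
            pos += 1
        keep = [i for i in range(len(configs)) if i not in set(pooled_idx)]
        obs_p = np.append(obs[keep], obs[pooled_idx].sum())
        exp_p = np.append(expected[keep], pooled_exp)
        chi2_p = float((((obs_p - exp_p) ** 2) / exp_p).sum())
        df_p = len(obs_p) - 1
        result.chi2_pooled = chi2_p
        result.df_pooled = df_p
        result.p_pooled = float(stats.chi2.sf(chi2_p, df_p))
        result.pooled_bin = [configs[i] for i in pooled_idx]
        logger.info(
            "independence test: %d low-expectation configurations pooled", len(pooled_idx)
        )
    return result


def unique_excess_test(
    unique_counts_by_arrangement: Mapping[str, int],
    segregating_site_totals: Mapping[str, int],
) -> tuple[float, int, float]:
    """Chi-square for an excess of unique polymorphisms in some arrangement.

    Expected unique counts are proportional to each arrangement's share of
    the total segregating sites; df = K - 1.
    """
    arrs = list(unique_counts_by_arrangement)
    if len(arrs) < 2:
        raise ValueError("need at least two arrangements")
    obs = np.array([float(unique_counts_by_arrangement[a]) for a in arrs])
    seg = np.array([float(segregating_site_totals[a]) for a in arrs])
    if (seg <= 0).any():
        raise ValueError("every arrangement needs a positive segregating-site total")
    expected = obs.sum() * seg / seg.sum()
    if (expected == 0).any():
        raise ValueError("zero expected category")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(arrs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def category_chisq(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, int, float]:
    """Generic goodness-of-fit chi-square over user-defined categories.

    ``expected`` is rescaled to the observed total; df = categories - 1.
    Exposed for category schemes defined by the caller (for example a
    three-way split of fixed derived differences).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected must be equal-length vectors")
    if (exp <= 0).any():
        raise ValueError("expected categories must be positive")
    exp = exp * obs.sum() / exp.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
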