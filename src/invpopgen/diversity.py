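"""Nucleotide diversity and frequency-spectrum statistics.

Estimates of the population mutation parameter 4Nu per silent site from a
locus alignment: Watterson's theta (from the number of segregating sites S,
with its no-recombination variance), pairwise nucleotide heterozygosity pi
(optionally Jukes-Cantor corrected), and Tajima's D, computed for the full
sample or for any subset of gene arrangements, plus per-region summaries
(proximal / inverted / distal relative to an arrangement's breakpoints).

Silent sites are all noncoding positions plus synonymous positions within
annotated coding intervals; potential synonymous sites are counted by the
Nei-Gojobori fractional method, so ``sites_surveyed`` is generally
fractional.  Columns containing a gap or ``N`` in any ingroup sequence are
excluded everywhere (complete deletion), which keeps site counts comparable
across arrangement subsets of a locus.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ArrangementModel, LocusAlignment, RegionClass, classify_region

__all__ = [
    "harmonic",
    "harmonic2",
    "DiversityEstimate",
    "SilentSites",
    "silent_sites",
    "segregating_sites",
    "watterson_theta",
    "pairwise_pi",
    "mean_pairwise_differences",
    "tajimas_d",
    "tajima_d_pvalue",
    "diversity_estimate",
    "region_summary",
    "estimates_to_frame",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = ("A", "C", "G", "T")


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n)))


# ---------------------------------------------------------------------------
# Silent-site bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SilentSites:
    """Per-position silent-site weights for one alignment.

    ``fraction[j]`` is the number of potential silent sites contributed by
    alignment column ``j``: 1 for surveyed noncoding columns, the
    Nei-Gojobori synonymous fraction for surveyed coding columns inside a
    complete codon, 0 for masked columns and for coding columns without a
    complete, stop-free codon context.  ``codon_context[j]`` holds
    ``(codon_start, offset)`` for coding columns with usable context.
    """

    fraction: np.ndarray
    coding: np.ndarray          # bool: inside an annotated coding interval
    surveyed: np.ndarray        # bool: complete-deletion mask
    codon_context: dict[int, tuple[int, int]]
    majority: np.ndarray        # bytes: majority ingroup base per column

    @property
    def total(self) -> float:
        return float(self.fraction.sum())


def _majority_bases(matrix: np.ndarray) -> np.ndarray:
    out = np.empty(matrix.shape[1], dtype="S1")
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        vals, counts = np.unique(col, return_counts=True)
        keep = np.isin(vals, [b"A", b"C", b"G", b"T"])
        if keep.any():
            vals, counts = vals[keep], counts[keep]
            out[j] = vals[np.argmax(counts)]
        else:
            out[j] = b"N"
    return out


def _synonymous_fraction(codon: str, offset: int) -> float:
    aa = _CODON_TABLE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[offset]:
            continue
        mutant = codon[:offset] + b + codon[offset + 1:]
        if _CODON_TABLE[mutant] == aa:
            syn += 1
    return syn / 3.0


def silent_sites(alignment: LocusAlignment) -> SilentSites:
    """Classify every alignment column and count potential silent sites."""
    m = alignment.matrix()
    L = alignment.length
    surveyed = alignment.surveyed_mask()
    coding = np.zeros(L, dtype=bool)
    for start, end, frame in alignment.coding_intervals:
        coding[start:end] = True
    majority = _majority_bases(m)
    fraction = np.zeros(L)
    fraction[surveyed & ~coding] = 1.0
    codon_context: dict[int, tuple[int, int]] = {}
    for start, end, frame in alignment.coding_intervals:
        first = start + frame
        for cstart in range(first, end - 2, 3):
            cols = (cstart, cstart + 1, cstart + 2)
            if not all(surveyed[c] for c in cols):
                continue
            codon = b"".join(majority[list(cols)]).decode()
            if any(ch not in "ACGT" for ch in codon):
                continue
            if _CODON_TABLE[codon] == "*":
                continue  # majority codon is a stop; no synonymous convention
            for off, c in enumerate(cols):
                fraction[c] = _synonymous_fraction(codon, off)
                codon_context[c] = (cstart, off)
    return SilentSites(
        fraction=fraction,
        coding=coding,
        surveyed=surveyed,
        codon_context=codon_context,
        majority=majority,
    )


def _is_synonymous_column(
    alignment: LocusAlignment, ss: SilentSites, col: int, alleles: Iterable[bytes]
) -> bool:
    """True when every observed allele at a coding column is synonymous."""
    if col not in ss.codon_context:
        return False
    cstart, off = ss.codon_context[col]
    codon = [chr(ss.majority[cstart + k][0]) for k in range(3)]
    aas = set()
    for a in alleles:
        codon[off] = a.decode()
        aas.add(_CODON_TABLE["".join(codon)])
    return len(aas) == 1 and "*" not in aas


def _scan_columns(
    alignment: LocusAlignment,
    subset: Sequence[str] | None,
    silent_only: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared column scan.

    Returns ``(positions, sub_matrix_at_positions, sites_surveyed)`` where
    positions are the segregating columns eligible under the site filter and
    ``sites_surveyed`` is the (possibly fractional) denominator.
    """
    idx = alignment.subset_indices(subset)
    if len(idx) == 0:
        raise ValueError(f"{alignment.locus_name}: empty arrangement subset {subset}")
    m = alignment.matrix()[idx]
    ss = silent_sites(alignment)
    if silent_only:
        candidate = ss.fraction > 0
        denom = ss.total
    else:
        candidate = ss.surveyed
        denom = float(ss.surveyed.sum())
    variable = (m != m[0]).any(axis=0) & candidate
    positions = []
    for col in np.nonzero(variable)[0]:
        if silent_only and ss.coding[col]:
            alleles = np.unique(m[:, col])
            if not _is_synonymous_column(alignment, ss, col, alleles):
                continue
        positions.append(int(col))
    positions = np.array(positions, dtype=int)
    return positions, m[:, positions] if len(positions) else m[:, :0], denom


def segregating_sites(
    alignment: LocusAlignment,
    subset: Sequence[str] | None = None,
    silent_only: bool = False,
) -> tuple[list[int], int]:
    """Segregating-site positions and count S within an arrangement subset.

    A column segregates when it carries at least two distinct alleles among
    the subset sequences at a surveyed column; with ``silent_only`` the
    column must additionally be noncoding or a synonymous variant.
    """
    positions, _, _ = _scan_columns(alignment, subset, silent_only)
    return list(positions), len(positions)


def watterson_theta(S: int, n: int, sites_surveyed: float) -> tuple[float, float]:
    """Watterson's per-site theta and its no-recombination variance.

    theta_w = S / (a_n * L).  The variance uses Var(S) = a_n*theta_L +
    b_n*theta_L**2 evaluated at the estimate theta_L = S/a_n (per-locus
    scale), then rescales to per-site units.
    """
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if sites_surveyed <= 0:
        raise ValueError("sites_surveyed must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    a_n = harmonic(n)
    b_n = harmonic2(n)
    theta = S / (a_n * sites_surveyed)
    theta_locus = S / a_n
    var_S = a_n * theta_locus + b_n * theta_locus**2
    var = var_S / (a_n * sites_surveyed) ** 2
    return theta, var


def mean_pairwise_differences(
    alignment: LocusAlignment,
    subset: Sequence[str] | None = None,
    silent_only: bool = True,
) -> tuple[float, float]:
    """Mean number of pairwise differences and the surveyed-site denominator."""
    positions, sub, denom = _scan_columns(alignment, subset, silent_only)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("need at least two sequences for pairwise differences")
    total = 0
    npairs = 0
    for i, j in itertools.combinations(range(k), 2):
        total += int((sub[i] != sub[j]).sum())
        npairs += 1
    return total / npairs, denom


def pairwise_pi(
    alignment: LocusAlignment,
    subset: Sequence[str] | None = None,
    silent_only: bool = True,
    jc_correct: bool = True,
) -> float:
    """Per-site pairwise heterozygosity pi, Jukes-Cantor corrected by default.

    Each unordered pair's per-site difference proportion p is transformed as
    d = -(3/4) ln(1 - 4p/3) when ``jc_correct`` and the transformed values
    are averaged over pairs.  A pair with p >= 0.75 makes the correction
    undefined and raises.
    """
    positions, sub, denom = _scan_columns(alignment, subset, silent_only)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("need at least two sequences for pi")
    vals = []
    for i, j in itertools.combinations(range(k), 2):
        p = int((sub[i] != sub[j]).sum()) / denom
        if jc_correct:
            if p >= 0.75:
                raise ValueError(
                    f"{alignment.locus_name}: pairwise difference {p:.3f} >= 0.75; "
                    "Jukes-Cantor correction undefined"
                )
            vals.append(-0.75 * math.log1p(-4.0 * p / 3.0))
        else:
            vals.append(p)
    return float(np.mean(vals))


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from S and the mean number of pairwise differences.

    Returns NaN when S = 0 (the statistic is undefined without variation).
    ``pi_total`` is on the per-locus (count) scale, not per site.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if n < 2:
        raise ValueError("tajimas_d requires n >= 2")
    if S == 0:
        return float("nan")
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / math.sqrt(var)


def tajima_d_pvalue(D: float, n: int) -> float:
    """Two-tailed significance of Tajima's D via the beta approximation.

    D is treated as a scaled beta variate with zero mean and unit variance on
    its theoretical support [Dmin, Dmax] (large-S limits of the fully
    singleton and fully intermediate-frequency configurations).
    """
    if math.isnan(D):
        return float("nan")
    a1 = harmonic(n)
    _, _, _, _, _, _, _, e2 = _tajima_constants(n)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / a1) / math.sqrt(e2)
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


# ---------------------------------------------------------------------------
# Per-locus estimates and region summaries
# ---------------------------------------------------------------------------

@dataclass
class DiversityEstimate:
    """Diversity statistics for one locus within one arrangement subset."""

    locus: str
    subset: tuple[str, ...] | None
    n: int
    sites_surveyed: float
    S: int
    theta_w: float
    var_theta_w: float
    pi: float
    tajima_d: float  # NaN when S = 0

    def __post_init__(self) -> None:
        if (self.S == 0) != (self.theta_w == 0):
            raise ValueError("theta_w must be zero exactly when S is zero")


def diversity_estimate(
    alignment: LocusAlignment,
    subset: Sequence[str] | None = None,
    silent_only: bool = True,
    jc_correct: bool = True,
) -> DiversityEstimate:
    """All core statistics for one (locus, arrangement-subset) pair."""
    idx = alignment.subset_indices(subset)
    n = len(idx)
    positions, _, denom = _scan_columns(alignment, subset, silent_only)
    S = len(positions)
    theta, var = watterson_theta(S, n, denom)
    if S:
        pi_count, _ = mean_pairwise_differences(alignment, subset, silent_only)
        pi = pairwise_pi(alignment, subset, silent_only, jc_correct)
        d = tajimas_d(S, n, pi_count)
    else:
        pi, d = 0.0, float("nan")
    return DiversityEstimate(
        locus=alignment.locus_name,
        subset=tuple(subset) if subset is not None else None,
        n=n,
        sites_surveyed=denom,
        S=S,
        theta_w=theta,
        var_theta_w=var,
        pi=pi,
        tajima_d=d,
    )


def _youngest(subset: tuple[str, ...], model: ArrangementModel) -> str:
    order = {name: i for i, name in enumerate(model.names)}
    return min(subset, key=lambda a: order.get(a, len(order)))


def region_summary(
    estimates: Iterable[DiversityEstimate],
    model: ArrangementModel,
) -> pd.DataFrame:
    """Mean +/- SD of pi per region class per arrangement subset.

    Loci are grouped by the region (proximal / inverted / distal) of the
    marker relative to the youngest (derived) arrangement of the subset; the
    mean and SD are unweighted across loci (SD 0 for a single locus), and
    ``bp`` totals pool the per-locus surveyed site counts.  Regions with no
    loci are omitted with a warning.
    """
    rows = []
    groups: dict[tuple[tuple[str, ...], RegionClass], list[DiversityEstimate]] = {}
    for est in estimates:
        if est.subset is None:
            raise ValueError("region_summary needs estimates with explicit subsets")
        region = classify_region(est.locus, _youngest(est.subset, model), model)
        groups.setdefault((est.subset, region), []).append(est)
    seen_subsets = {key[0] for key in groups}
    for subset in seen_subsets:
        for region in RegionClass:
            key = (subset, region)
            if key not in groups:
                warnings.warn(
                    f"no loci in region {region.value!r} for subset {subset}; omitted"
                )
                continue
            vals = np.array([e.pi for e in groups[key]])
            rows.append(
                {
                    "subset": "-".join(subset),
                    "region": region.value,
                    "n_loci": len(vals),
                    "mean_pi": float(vals.mean()),
                    "sd_pi": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "bp": float(sum(e.sites_surveyed for e in groups[key])),
                }
            )
    return pd.DataFrame(rows)


def estimates_to_frame(
    estimates: Iterable[DiversityEstimate],
    model: ArrangementModel | None = None,
) -> pd.DataFrame:
    """One row per (locus, subset): the machine-readable per-locus table."""
    rows = []
    for e in estimates:
        row = {
            "locus": e.locus,
            "subset": "-".join(e.subset) if e.subset else "all",
            "n": e.n,
            "bp": e.sites_surveyed,
            "S": e.S,
            "theta_w": e.theta_w,
            "var_theta_w": e.var_theta_w,
            "pi": e.pi,
            "tajima_d": e.tajima_d,
        }
        if model is not None and e.subset is not None:
            try:
                row["region"] = classify_region(
                    e.locus, _youngest(e.subset, model), model
                ).value
            except KeyError:
                row["region"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
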