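"""Linkage-disequilibrium scan over pairs of segregating sites.

Each strain is an isochromosomal line contributing one haplotype, so a pair
of biallelic sites cross-tabulates directly into a 2x2 table tested with
Fisher's exact test (two-tailed, probability-mass definition).  Because most
site pairs cannot reach significance for any allele configuration with their
margins, pairs are pre-filtered by the minimum attainable two-tailed P over
the corner tables; only "valid" pairs enter the multiple-testing correction,
which uses Storey q-values at a chosen false-discovery rate.  Locus-pair
heat-map summaries, site-by-arrangement association scans, a homogeneity
chi-square over the significant-count matrix, and combined-subset scans with
a shared significance cutoff complete the toolkit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LocusAlignment

__all__ = [
    "SiteTable",
    "build_site_table",
    "fisher_exact_2x2",
    "min_attainable_p",
    "qvalue_fdr",
    "LDScanResult",
    "ld_scan",
    "AssociationResult",
    "arrangement_association",
    "HomogeneityResult",
    "homogeneity_chisq",
    "subset_combined_scan",
]

logger = logging.getLogger(__name__)

#: Relative tolerance for probability-mass ties in the two-tailed test.
TIE_TOLERANCE = 1e-7


# ---------------------------------------------------------------------------
# Fisher exact machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=2_000_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    r1, c1, n = a + b, a + c, a + b + c + d
    if min(r1, n - r1, c1, n - c1) == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1.0 + TIE_TOLERANCE)].sum()
    return float(min(1.0, p))


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-tailed Fisher exact P of a 2x2 table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table (with a small
    relative tolerance for floating-point ties).  A table with a zero margin
    carries no information and returns P = 1 by convention; such pairs are
    flagged invalid upstream by the attainability filter.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    return _fisher_p(int(a), int(b), int(c), int(d))


@lru_cache(maxsize=2_000_000)
def _min_attainable(r1: int, r2: int, c1: int, c2: int) -> float:
    n = r1 + r2
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    p_lo = _fisher_p(lo, r1 - lo, c1 - lo, c2 - (r1 - lo))
    p_hi = _fisher_p(hi, r1 - hi, c1 - hi, c2 - (r1 - hi))
    return min(p_lo, p_hi)


def min_attainable_p(margins: Sequence[int]) -> float:
    """Smallest two-tailed Fisher P achievable with the given margins.

    Evaluates the two extreme corner tables permitted by the margins
    ``(r1, r2, c1, c2)``.  A pair of sites is worth testing only when this
    minimum is at or below the validity threshold; a monomorphic margin
    yields 1 (no signal possible).
    """
    r1, r2, c1, c2 = (int(x) for x in margins)
    if min(r1, r2, c1, c2) < 0 or r1 + r2 != c1 + c2:
        raise ValueError("margins must be non-negative with equal totals")
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    return _min_attainable(r1, r2, c1, c2)


def qvalue_fdr(
    p_values: Sequence[float],
    fdr: float = 0.01,
    pi0: float | None = None,
) -> tuple[np.ndarray, float | None, float]:
    """Storey q-values and the largest P significant at the given FDR.

    pi0 (the null proportion) is estimated on a lambda grid 0.05..0.95 with
    a cubic-polynomial smoother extrapolated to lambda = 1 and clamped to
    (0, 1]; with fewer than 20 tests pi0 is fixed at 1 (plain
    Benjamini-Hochberg) with a warning.  Returns ``(q, cutoff, pi0)`` with q
    in the input order; ``cutoff`` is None when nothing is significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 20:
            warnings.warn("fewer than 20 tests: pi0 fixed at 1 (plain BH)")
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
            coeffs = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coeffs, 1.0))
            pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    sig = p[q <= fdr]
    cutoff = float(sig.max()) if sig.size else None
    return q, cutoff, pi0


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Biallelic segregating sites across one or more loci.

    ``alleles`` is an ``(n_sites, n_strains)`` int8 matrix: 0 the major
    allele, 1 the minor allele, -1 missing (gap or N in that strain).  Only
    sites with exactly two observed alleles among the included strains are
    retained.
    """

    loci: np.ndarray
    positions: np.ndarray
    alleles: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    strain_ids: list[str]
    arrangement_labels: np.ndarray
    outgroup_allele: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def subset_strains(self, arrangements: Sequence[str]) -> "SiteTable":
        """Restrict to strains of the given arrangements, re-filtering sites
        so every retained site is still biallelic within the subset."""
        wanted = set(arrangements)
        keep = np.array([a in wanted for a in self.arrangement_labels])
        if not keep.any():
            raise ValueError(f"no strains carry arrangements {sorted(wanted)}")
        alleles = self.alleles[:, keep]
        counts0 = (alleles == 0).sum(axis=1)
        counts1 = (alleles == 1).sum(axis=1)
        biallelic = (counts0 > 0) & (counts1 > 0)
        return SiteTable(
            loci=self.loci[biallelic],
            positions=self.positions[biallelic],
            alleles=alleles[biallelic],
            major=self.major[biallelic],
            minor=self.minor[biallelic],
            strain_ids=[s for s, k in zip(self.strain_ids, keep) if k],
            arrangement_labels=self.arrangement_labels[keep],
            outgroup_allele=(
                self.outgroup_allele[biallelic]
                if self.outgroup_allele is not None
                else None
            ),
        )


def build_site_table(
    alignments: Sequence[LocusAlignment],
    strains: Sequence[str] | None = None,
) -> SiteTable:
    """Concatenate loci into a biallelic site table over shared strains.

    ``strains`` defaults to the strains common to all alignments (the study
    concatenated the loci sequenced in every strain).  Gaps and Ns are
    per-strain missing data; sites with more than two observed alleles are
    dropped (logged).
    """
    if not alignments:
        raise ValueError("no alignments")
    if strains is None:
        common = set(alignments[0].strain_ids)
        for aln in alignments[1:]:
            common &= set(aln.strain_ids)
        strains = [s for s in alignments[0].strain_ids if s in common]
    strains = list(strains)
    if not strains:
        raise ValueError("no strains shared across loci")
    label_of: dict[str, str] = {}
    for aln in alignments:
        for sid, lab in zip(aln.strain_ids, aln.arrangement_labels):
            label_of.setdefault(sid, lab)
    loci, positions, rows, major, minor, out_alleles = [], [], [], [], [], []
    n_multiallelic = 0
    for aln in alignments:
        sid_index = {s: i for i, s in enumerate(aln.strain_ids)}
        idx = np.array([sid_index[s] for s in strains])
        m = aln.matrix()[idx]
        og = aln.outgroup_array()
        missing = (m == b"-") | (m == b"N")
        for col in range(aln.length):
            obs = m[~missing[:, col], col]
            if obs.size < 2:
                continue
            vals, counts = np.unique(obs, return_counts=True)
            if len(vals) < 2:
                continue
            if len(vals) > 2:
                n_multiallelic += 1
                continue
            order = np.argsort(-counts, kind="stable")
            maj, mnr = vals[order[0]], vals[order[1]]
            row = np.full(len(strains), -1, dtype=np.int8)
            row[m[:, col] == maj] = 0
            row[m[:, col] == mnr] = 1
            loci.append(aln.locus_name)
            positions.append(col)
            rows.append(row)
            major.append(maj.decode())
            minor.append(mnr.decode())
            if og is not None:
                ch = og[col].decode()
                out_alleles.append(ch if ch in "ACGT" else "")
            else:
                out_alleles.append("")
    if n_multiallelic:
        logger.info("dropped %d sites with >2 alleles", n_multiallelic)
    if not rows:
        raise ValueError("no biallelic segregating sites found")
    return SiteTable(
        loci=np.array(loci),
        positions=np.array(positions, dtype=int),
        alleles=np.vstack(rows),
        major=np.array(major),
        minor=np.array(minor),
        strain_ids=strains,
        arrangement_labels=np.array([label_of[s] for s in strains]),
        outgroup_allele=np.array(out_alleles),
    )


# ---------------------------------------------------------------------------
# Pairwise LD scan
# ---------------------------------------------------------------------------

@dataclass
class LDScanResult:
    """Outcome of a pairwise LD scan."""

    pairs: pd.DataFrame  # locus_a, pos_a, locus_b, pos_b, p, q, significant
    total_pairs: int
    valid_pairs: int
    q_cutoff_p: float | None
    fdr: float
    validity_alpha: float
    pi0: float | None = None

    @property
    def n_significant(self) -> int:
        return int(self.pairs["significant"].sum()) if len(self.pairs) else 0

    def locus_pair_matrix(self) -> pd.DataFrame:
        """Per locus-pair (significant, valid, fraction) heat-map summary."""
        if not len(self.pairs):
            return pd.DataFrame(
                columns=["locus_a", "locus_b", "significant", "valid", "fraction"]
            )
        df = self.pairs.copy()
        key = [tuple(sorted(k)) for k in zip(df.locus_a, df.locus_b)]
        df["pair_key"] = key
        grouped = df.groupby("pair_key").agg(
            significant=("significant", "sum"), valid=("p", "size")
        )
        grouped["fraction"] = grouped.significant / grouped.valid
        grouped = grouped.reset_index()
        grouped["locus_a"] = [k[0] for k in grouped.pair_key]
        grouped["locus_b"] = [k[1] for k in grouped.pair_key]
        return grouped[["locus_a", "locus_b", "significant", "valid", "fraction"]]

    def aggregate_fractions(self) -> dict[str, float]:
        """Within-locus and between-locus significant fractions."""
        out = {}
        if not len(self.pairs):
            return {"within": float("nan"), "between": float("nan")}
        within = self.pairs.locus_a == self.pairs.locus_b
        for name, mask in (("within", within), ("between", ~within)):
            n_valid = int(mask.sum())
            n_sig = int(self.pairs.significant[mask].sum())
            out[name] = n_sig / n_valid if n_valid else float("nan")
        return out


def _pair_tables(alleles: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cross-tabulations for all site pairs via indicator matrix products."""
    m1 = (alleles == 1).astype(np.float64)
    m0 = (alleles == 0).astype(np.float64)
    n11 = m1 @ m1.T
    n10 = m1 @ m0.T
    n01 = m0 @ m1.T
    n00 = m0 @ m0.T
    return (
        n11.astype(np.int64),
        n10.astype(np.int64),
        n01.astype(np.int64),
        n00.astype(np.int64),
    )


def ld_scan(
    site_table: SiteTable,
    strain_subset: Sequence[str] | None = None,
    fdr: float = 0.01,
    validity_alpha: float = 0.05,
    compute_q: bool = True,
) -> LDScanResult:
    """All-pairs Fisher-exact LD scan with validity filter and q-value FDR.

    Strains missing at either site of a pair are excluded pairwise from that
    table.  A pair is valid when its margins could attain a two-tailed P <=
    ``validity_alpha`` for some table; only valid pairs are tested and enter
    the q-value analysis.  ``strain_subset`` optionally restricts to the
    strains of the named arrangements.
    """
    table = (
        site_table.subset_strains(strain_subset)
        if strain_subset is not None
        else site_table
    )
    ns = table.n_sites
    if ns < 2:
        raise ValueError("need at least two segregating sites in the subset")
    n11, n10, n01, n00 = _pair_tables(table.alleles)
    records = []
    total_pairs = ns * (ns - 1) // 2
    for i, j in itertools.combinations(range(ns), 2):
        a, b, c, d = n11[i, j], n10[i, j], n01[i, j], n00[i, j]
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if min(r1, r2, c1, c2) == 0:
            continue
        if _min_attainable(r1, r2, c1, c2) > validity_alpha:
            continue
        records.append(
            (
                table.loci[i], table.positions[i],
                table.loci[j], table.positions[j],
                _fisher_p(a, b, c, d),
            )
        )
    pairs = pd.DataFrame(
        records, columns=["locus_a", "pos_a", "locus_b", "pos_b", "p"]
    )
    pi0 = None
    cutoff = None
    if compute_q and len(pairs):
        q, cutoff, pi0 = qvalue_fdr(pairs["p"].to_numpy(), fdr)
        pairs["q"] = q
        pairs["significant"] = q <= fdr
    else:
        pairs["q"] = np.nan
        pairs["significant"] = False
    logger.info(
        "LD scan: %d sites, %d/%d valid pairs, %d significant at FDR %.3g",
        ns, len(pairs), total_pairs, int(pairs["significant"].sum()), fdr,
    )
    return LDScanResult(
        pairs=pairs,
        total_pairs=total_pairs,
        valid_pairs=len(pairs),
        q_cutoff_p=cutoff,
        fdr=fdr,
        validity_alpha=validity_alpha,
        pi0=pi0,
    )


# ---------------------------------------------------------------------------
# Site-by-arrangement association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Site-by-arrangement Fisher association scan with its own Q analysis."""

    table: pd.DataFrame  # locus, position, arrangement, p, q, significant
    n_enumerated: int
    valid_tests: int
    q_cutoff_p: float | None
    fdr: float


def arrangement_association(
    site_table: SiteTable,
    arrangements: Sequence[str] | None = None,
    fdr: float = 0.01,
    validity_alpha: float = 0.05,
) -> AssociationResult:
    """Test every site for association with each gene arrangement.

    For each site and arrangement X, a 2x2 Fisher test of allele (major or
    minor) against membership (arrangement X vs all others), with the same
    attainability filter as the pair scan and a separate q-value analysis.
    The enumerated test count is n_sites x n_arrangements.
    """
    if arrangements is None:
        arrangements = sorted(set(site_table.arrangement_labels))
    arrangements = list(arrangements)
    present = set(site_table.arrangement_labels)
    absent = [a for a in arrangements if a not in present]
    if absent:
        raise ValueError(f"arrangements {absent} absent from the site table")
    if len(arrangements) < 2:
        raise ValueError("need at least two arrangements")
    n_enumerated = site_table.n_sites * len(arrangements)
    rows = []
    labels = site_table.arrangement_labels
    for arr in arrangements:
        in_arr = labels == arr
        for s in range(site_table.n_sites):
            alleles = site_table.alleles[s]
            typed = alleles >= 0
            a = int(((alleles == 1) & in_arr & typed).sum())
            b = int(((alleles == 1) & ~in_arr & typed).sum())
            c = int(((alleles == 0) & in_arr & typed).sum())
            d = int(((alleles == 0) & ~in_arr & typed).sum())
            r1, r2, c1, c2 = a + b, c + d, a + c, b + d
            if min(r1, r2, c1, c2) == 0:
                continue
            if _min_attainable(r1, r2, c1, c2) > validity_alpha:
                continue
            rows.append(
                (
                    site_table.loci[s], site_table.positions[s], arr,
                    _fisher_p(a, b, c, d),
                )
            )
    df = pd.DataFrame(rows, columns=["locus", "position", "arrangement", "p"])
    cutoff = None
    if len(df):
        q, cutoff, _ = qvalue_fdr(df["p"].to_numpy(), fdr)
        df["q"] = q
        df["significant"] = q <= fdr
    else:
        df["q"] = np.nan
        df["significant"] = False
    return AssociationResult(
        table=df,
        n_enumerated=n_enumerated,
        valid_tests=len(df),
        q_cutoff_p=cutoff,
        fdr=fdr,
    )


# ---------------------------------------------------------------------------
# Homogeneity of significant counts
# ---------------------------------------------------------------------------

@dataclass
class HomogeneityResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    flags: list[str]  # per cell: "above" / "below" / ""
    pooled_cells: int


def homogeneity_chisq(
    significant_counts: Sequence[int],
    valid_counts: Sequence[int],
) -> HomogeneityResult:
    """Chi-square homogeneity test of significant counts across cells.

    Expected counts are proportional to the number of valid tests per cell.
    Cells with zero valid tests carry no information and are removed (logged
    as pooled), reducing the degrees of freedom.  Each cell is additionally
    flagged above/below when a two-sided binomial test against the overall
    significant fraction is at P < 0.05 (the heat-map dots).
    """
    obs = np.asarray(significant_counts, dtype=float)
    valid = np.asarray(valid_counts, dtype=float)
    if obs.shape != valid.shape:
        raise ValueError("counts and valid-test vectors must align")
    if (obs > valid).any():
        raise ValueError("significant counts cannot exceed valid counts")
    keep = valid > 0
    pooled = int((~keep).sum())
    if pooled:
        logger.info("homogeneity test: %d zero-valid cells pooled out", pooled)
    obs_k = obs[keep]
    valid_k = valid[keep]
    total_sig = obs_k.sum()
    rate = total_sig / valid_k.sum()
    expected = total_sig * valid_k / valid_k.sum()
    if (expected == 0).any():
        # no significant tests at all: homogeneous by definition
        chi2 = 0.0
    else:
        chi2 = float(((obs_k - expected) ** 2 / expected).sum())
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    flags_kept = []
    for o, v in zip(obs_k, valid_k):
        res = stats.binomtest(int(o), int(v), rate)
        if res.pvalue < 0.05:
            flags_kept.append("above" if o / v > rate else "below")
        else:
            flags_kept.append("")
    flags = []
    it = iter(flags_kept)
    for k in keep:
        flags.append(next(it) if k else "")
    full_expected = np.zeros_like(obs)
    full_expected[keep] = expected
    return HomogeneityResult(
        chi2=chi2, df=df, p=p, expected=full_expected, flags=flags,
        pooled_cells=pooled,
    )


def subset_combined_scan(
    site_table: SiteTable,
    subsets: Sequence[Sequence[str]],
    fdr: float = 0.01,
    validity_alpha: float = 0.05,
) -> list[LDScanResult]:
    """LD scans per arrangement subset with one pooled significance cutoff.

    Each subset is scanned separately; all valid-pair P values are pooled
    into a single q-value analysis whose cutoff then re-flags every subset's
    pairs, giving the scans a common false-discovery rate.
    """
    if len(subsets) < 2:
        raise ValueError("need at least two subsets to combine")
    results = []
    for subset in subsets:
        if not subset:
            raise ValueError("empty arrangement subset")
        results.append(
            ld_scan(site_table, subset, fdr, validity_alpha, compute_q=False)
        )
    pooled_p = np.concatenate([r.pairs["p"].to_numpy() for r in results])
    q, cutoff, pi0 = qvalue_fdr(pooled_p, fdr)
    start = 0
    for r in results:
        n = len(r.pairs)
        r.pairs["q"] = q[start:start + n]
        r.pairs["significant"] = (
            r.pairs["p"] <= cutoff if cutoff is not None else False
        )
        r.q_cutoff_p = cutoff
        r.pi0 = pi0
        start += n
    return results
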