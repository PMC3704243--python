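"""Coalescent neutrality test for arrangement-structured samples.

The test asks whether observed within- and among-arrangement heterozygosity
is compatible with a neutral genealogy that carries both nucleotide and
inversion mutations.  Genealogies for ``n_tips`` individuals are simulated
under a constant-size or exponentially growing coalescent; inversion events
are placed uniformly on the total branch length, labelling every tip with an
arrangement class (the most recent event on its root path, or the ancestral
class).  A genealogy is accepted when the number of distinct classes equals
the number of arrangements observed and the ascending-sorted simulated class
frequencies are componentwise >= the observed sample counts ordered youngest
to oldest -- under neutrality allele age and frequency are positively
related, so the youngest arrangement is matched to the least frequent class.
Nucleotide mutations (infinite sites) are then dropped on the accepted
genealogy, alleles are subsampled within each class to exactly the observed
counts, and per-arrangement and overall pi and Watterson's theta are
accumulated over accepted replicates into 95% envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .diversity import harmonic

__all__ = [
    "Genealogy",
    "CoalescentConfig",
    "EnvelopeResult",
    "simulate_genealogy",
    "place_inversions",
    "accept_genealogy",
    "drop_mutations",
    "nested_subsample",
    "neutrality_envelope",
    "accepted_genealogies",
]

logger = logging.getLogger(__name__)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class Genealogy:
    """A coalescent genealogy with optional inversion-class labels.

    ``parent[i]`` is the parent index of node ``i`` (-1 at the root); tips
    are nodes ``0..n_tips-1`` at time 0 and internal-node times strictly
    increase root-ward.  After :func:`place_inversions`, ``class_labels``
    holds an arrangement class per tip (0 = ancestral class) and
    ``class_birth_time`` the age of each class's founding inversion event
    (+inf for the ancestral class).
    """

    n_tips: int
    parent: np.ndarray
    node_time: np.ndarray
    class_labels: np.ndarray | None = None
    class_birth_time: np.ndarray | None = None
    events: tuple[np.ndarray, np.ndarray] | None = None  # (branch, time) per event

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Branch length above each node (0 at the root)."""
        out = self.node_time[self.parent] - self.node_time
        out[-1] = 0.0
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def class_frequencies(self) -> np.ndarray:
        """Tip counts of the non-empty classes (ascending class id)."""
        if self.class_labels is None:
            raise ValueError("place_inversions has not been run")
        counts = np.bincount(self.class_labels)
        return counts[counts > 0]


def simulate_genealogy(
    n_tips: int, growth_alpha: float = 0.0, rng=None
) -> Genealogy:
    """Simulate a neutral genealogy (constant size or exponential growth).

    Times are in coalescent units of 2N generations.  ``growth_alpha`` is
    the exponential growth-rate parameter on that timescale (0 = constant
    population size); backward in time the population shrinks as
    N(t) = N0 * exp(-growth_alpha * t), so coalescence accelerates with
    depth and the TMRCA shrinks as growth strengthens.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if growth_alpha < 0:
        raise ValueError("growth_alpha must be >= 0")
    rng = _as_rng(rng)
    exp_draws = rng.exponential(size=n_tips - 1)
    pair_draws = rng.random(size=2 * (n_tips - 1))
    parent = np.empty(2 * n_tips - 1, dtype=np.int64)
    node_time = np.empty(2 * n_tips - 1)
    _kernels.simulate_topology(
        n_tips, float(growth_alpha), exp_draws, pair_draws, parent, node_time
    )
    return Genealogy(n_tips=n_tips, parent=parent, node_time=node_time)


def place_inversions(genealogy: Genealogy, k_events: int, rng=None) -> np.ndarray:
    """Place inversion events uniformly on the tree and label every tip.

    Each event founds a new arrangement class; a tip's class is the most
    recent event on its path to the root (class 0 if none).  Events landing
    below a more recent event are shadowed for the tips concerned, so the
    number of realised classes can be smaller than ``k_events + 1``.
    Returns the per-tip labels and stores them on the genealogy together
    with each class's birth time.
    """
    if k_events < 0:
        raise ValueError("k_events must be >= 0")
    rng = _as_rng(rng)
    n = genealogy.n_tips
    m = genealogy.n_nodes
    blen = genealogy.branch_lengths()
    labels_all = np.zeros(m, dtype=np.int64)
    if k_events == 0:
        genealogy.class_labels = labels_all[:n]
        genealogy.class_birth_time = np.array([np.inf])
        genealogy.events = (np.empty(0, dtype=np.int64), np.empty(0))
        return genealogy.class_labels
    cum = np.cumsum(blen)
    total = cum[-1]
    pos = rng.uniform(0.0, total, size=k_events)
    branch = np.searchsorted(cum, pos, side="right").astype(np.int64)
    frac = rng.random(size=k_events)
    ev_time = genealogy.node_time[branch] + frac * blen[branch]
    _kernels.label_tips(genealogy.parent, n, branch, ev_time, labels_all)
    birth = np.concatenate([[np.inf], ev_time])
    genealogy.class_labels = labels_all[:n]
    genealogy.class_birth_time = birth
    genealogy.events = (branch, ev_time)
    return genealogy.class_labels


def accept_genealogy(
    class_labels: np.ndarray | Sequence[int],
    observed_counts_by_age: Sequence[int],
    n_arrangements: int | None = None,
) -> bool:
    """Acceptance rule of the nested-subsampling neutrality test.

    True iff the simulated tips fall into exactly ``n_arrangements`` distinct
    classes and the ascending-sorted class frequencies are componentwise >=
    the observed counts ordered youngest to oldest (least frequent simulated
    class matched to the youngest arrangement).
    """
    observed = np.asarray(observed_counts_by_age, dtype=np.int64)
    if n_arrangements is None:
        n_arrangements = len(observed)
    counts = np.bincount(np.asarray(class_labels, dtype=np.int64))
    counts = counts[counts > 0]
    if len(counts) != n_arrangements:
        return False
    return bool(np.all(np.sort(counts) >= observed))


def drop_mutations(genealogy: Genealogy, theta: float, rng=None) -> np.ndarray:
    """Drop infinite-sites mutations; returns an (n_tips, S) 0/1 matrix.

    Mutation counts per branch are Poisson with mean (theta/2) * branch
    length, ``theta`` on the per-locus scale (4N times the locus mutation
    rate); each mutation is a new segregating column carried by the branch's
    descendant tips.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = _as_rng(rng)
    blen = genealogy.branch_lengths()
    counts = rng.poisson(0.5 * theta * blen)
    counts[-1] = 0  # no branch above the root
    mutated = np.nonzero(counts)[0]
    if len(mutated) == 0:
        return np.zeros((genealogy.n_tips, 0), dtype=np.int8)
    branches = np.repeat(mutated, counts[mutated]).astype(np.int64)
    mask = _kernels.descendant_mask(genealogy.parent, genealogy.n_tips, branches)
    return mask.T.astype(np.int8)


def nested_subsample(
    haplotypes: np.ndarray,
    class_labels: np.ndarray,
    observed_counts_by_age: Sequence[int],
    rng=None,
    class_birth_time: np.ndarray | None = None,
    arrangement_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Subsample alleles within each class to the observed sample sizes.

    Simulated classes sorted by ascending frequency are identified with the
    arrangements sorted youngest to oldest (frequency rank matches age rank
    under neutrality); ties in frequency are broken by class birth time, the
    older event taking the older arrangement.  From each class exactly the
    observed number of tips is drawn uniformly without replacement.

    Returns ``(sub_haplotypes, labels, tip_indices)``.
    """
    rng = _as_rng(rng)
    observed = list(observed_counts_by_age)
    if arrangement_names is None:
        arrangement_names = [f"class{i}" for i in range(len(observed))]
    labels = np.asarray(class_labels)
    class_ids = np.unique(labels)
    if len(class_ids) != len(observed):
        raise ValueError(
            f"{len(class_ids)} simulated classes != {len(observed)} arrangements; "
            "subsampling requires an accepted genealogy"
        )
    freqs = np.array([(labels == c).sum() for c in class_ids])
    if class_birth_time is not None:
        births = class_birth_time[class_ids]
    else:
        births = np.zeros(len(class_ids))
    # ascending frequency; equal frequencies: younger event (smaller birth
    # time) first, i.e. matched to the younger arrangement
    order = np.lexsort((births, freqs))
    chosen: list[np.ndarray] = []
    out_labels: list[str] = []
    for rank, k_obs in enumerate(observed):
        cid = class_ids[order[rank]]
        members = np.nonzero(labels == cid)[0]
        assert len(members) >= k_obs, "acceptance rule violated"
        take = rng.choice(members, size=k_obs, replace=False)
        chosen.append(np.sort(take))
        out_labels.extend([arrangement_names[rank]] * k_obs)
    idx = np.concatenate(chosen)
    return haplotypes[idx], out_labels, idx


# ---------------------------------------------------------------------------
# Neutrality envelope
# ---------------------------------------------------------------------------

@dataclass
class CoalescentConfig:
    """Study conditions for the neutrality envelope.

    ``observed_counts_by_age`` gives, per locus, the sample counts of each
    arrangement ordered youngest to oldest; ``theta_per_locus`` the per-site
    mutation parameter used to drop mutations (conventionally the locus's
    own all-arrangement Watterson estimate); ``sites_per_locus`` the number
    of silent sites, which scales per-site statistics.
    """

    arrangement_names: tuple[str, ...]
    observed_counts_by_age: Mapping[str, tuple[int, ...]]
    theta_per_locus: Mapping[str, float]
    sites_per_locus: Mapping[str, float]
    n_tips: int = 5000
    growth_alpha: float = 0.0
    n_inversion_events: int | None = None
    n_accepted: int = 1000
    seed: int = 0
    acceptance_floor: float = 1e-4
    acceptance_floor_window: int = 20000  # attempts before the floor applies

    def __post_init__(self) -> None:
        k = len(self.arrangement_names)
        if self.n_inversion_events is None:
            self.n_inversion_events = k - 1
        if self.n_inversion_events != k - 1:
            raise ValueError(
                "n_inversion_events must equal number of arrangements - 1"
            )
        for locus, counts in self.observed_counts_by_age.items():
            if len(counts) != k:
                raise ValueError(f"{locus}: need one count per arrangement")
            if self.n_tips < sum(counts):
                raise ValueError(f"{locus}: n_tips < total observed count")
            if min(counts) < 1:
                raise ValueError(f"{locus}: all counts must be >= 1")


@dataclass
class EnvelopeResult:
    """Percentile envelopes per (locus, arrangement-or-all, statistic)."""

    table: pd.DataFrame
    n_accepted: int
    attempts: int
    config: CoalescentConfig

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.attempts if self.attempts else 0.0

    def flag(self, locus: str, arrangement: str, statistic: str) -> str:
        row = self.table[
            (self.table.locus == locus)
            & (self.table.arrangement == arrangement)
            & (self.table.statistic == statistic)
        ].iloc[0]
        return row["flag"]


def _flag(value: float, lo: float, hi: float) -> str:
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "inside"


def accepted_genealogies(config: CoalescentConfig, counts: tuple[int, ...], rng):
    """Yield ``(genealogy, cumulative_attempts)`` for one observed-count vector.

    Each yielded genealogy satisfies the acceptance rule for ``counts``.
    Aborts with a diagnostic when the running acceptance rate falls below
    the configured floor after ``acceptance_floor_window`` attempts.
    """
    n_checked = 0
    n_ok = 0
    min_attempts_for_floor = config.acceptance_floor_window
    while True:
        gen = simulate_genealogy(config.n_tips, config.growth_alpha, rng)
        place_inversions(gen, config.n_inversion_events, rng)
        n_checked += 1
        if accept_genealogy(gen.class_labels, counts):
            n_ok += 1
            yield gen, n_checked
        elif (
            n_checked >= min_attempts_for_floor
            and n_ok / n_checked < config.acceptance_floor
        ):
            raise RuntimeError(
                f"acceptance rate {n_ok}/{n_checked} below floor "
                f"{config.acceptance_floor}; observed counts {counts} are too "
                f"restrictive for n_tips={config.n_tips}"
            )


def neutrality_envelope(
    config: CoalescentConfig,
    observed: Mapping[tuple[str, str, str], float] | None = None,
) -> EnvelopeResult:
    """Run the accept-reject loop and build 95% envelopes for pi and theta_w.

    For each accepted genealogy the observed sample counts are subsampled
    within classes, locus-specific mutations are dropped, and per-site pi
    and Watterson's theta are computed within each arrangement and over all
    arrangements (no multiple-hit correction: simulated data are infinite
    sites).  Reports the 2.5/50/97.5 percentiles per (locus, arrangement,
    statistic) cell, flagging any supplied observed value as inside, below
    or above the envelope.

    Loci with identical observed counts share the accepted-genealogy stream
    (acceptance depends only on the counts); mutations are still dropped
    independently per locus.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.arrangement_names)
    K = len(names)
    loci = list(config.observed_counts_by_age)
    groups: dict[tuple[int, ...], list[str]] = {}
    for locus in loci:
        groups.setdefault(tuple(config.observed_counts_by_age[locus]), []).append(locus)

    sums: dict[tuple[str, str, str], list[float]] = {
        (locus, arr, stat): []
        for locus in loci
        for arr in names + ["all"]
        for stat in ("pi", "theta_w")
    }
    a_n = {k: harmonic(k) for k in set(
        list(np.concatenate([list(c) for c in groups]).astype(int))
        + [sum(c) for c in groups]
    ) if k >= 2}

    total_attempts = 0
    for counts, group_loci in groups.items():
        counts_arr = np.array(counts)
        n_total = int(counts_arr.sum())
        pair_tot = n_total * (n_total - 1) / 2.0
        pair_c = counts_arr * (counts_arr - 1) / 2.0
        stream = accepted_genealogies(config, counts, rng)
        for _ in range(config.n_accepted):
            gen, attempts = next(stream)
            _, sub_labels, idx = nested_subsample(
                np.zeros((config.n_tips, 0), dtype=np.int8),
                gen.class_labels,
                counts,
                rng,
                gen.class_birth_time,
                names,
            )
            tip_class = np.full(config.n_tips, -1, dtype=np.int64)
            name_index = {a: i for i, a in enumerate(names)}
            for tip, lab in zip(idx, sub_labels):
                tip_class[tip] = name_index[lab]
            cnt = _kernels.class_counts(gen.parent, tip_class, config.n_tips, K)
            blen = gen.branch_lengths()
            tot = cnt.sum(axis=1)
            rel = np.nonzero((tot > 0) & (tot < n_total))[0]
            rel = rel[rel != gen.n_nodes - 1]
            cnt_rel = cnt[rel]
            tot_rel = tot[rel]
            blen_rel = blen[rel]
            for locus in group_loci:
                theta_locus = (
                    config.theta_per_locus[locus] * config.sites_per_locus[locus]
                )
                L = config.sites_per_locus[locus]
                s_b = rng.poisson(0.5 * theta_locus * blen_rel)
                S_all = int(s_b.sum())  # every relevant branch segregates overall
                pi_all = float((s_b * tot_rel * (n_total - tot_rel)).sum() / pair_tot)
                sums[(locus, "all", "theta_w")].append(S_all / (a_n[n_total] * L))
                sums[(locus, "all", "pi")].append(pi_all / L)
                for ci, arr in enumerate(names):
                    k_c = counts_arr[ci]
                    c_b = cnt_rel[:, ci]
                    seg = (c_b > 0) & (c_b < k_c)
                    S_c = int(s_b[seg].sum())
                    if k_c >= 2:
                        pi_c = float(
                            (s_b * c_b * (k_c - c_b)).sum() / pair_c[ci]
                        )
                        sums[(locus, arr, "theta_w")].append(S_c / (a_n[k_c] * L))
                        sums[(locus, arr, "pi")].append(pi_c / L)
                    else:
                        sums[(locus, arr, "theta_w")].append(float("nan"))
                        sums[(locus, arr, "pi")].append(float("nan"))
        total_attempts += attempts
        logger.info(
            "envelope counts=%s: %d accepted in %d attempts (rate %.4f)",
            counts, config.n_accepted, attempts, config.n_accepted / attempts,
        )

    rows = []
    for (locus, arr, stat), vals in sums.items():
        vals = np.asarray(vals)
        if np.isnan(vals).all():
            continue
        lo, med, hi = np.nanpercentile(vals, [2.5, 50.0, 97.5])
        row = {
            "locus": locus,
            "arrangement": arr,
            "statistic": stat,
            "p025": lo,
            "p500": med,
            "p975": hi,
            "mean": float(np.nanmean(vals)),
        }
        if observed is not None and (locus, arr, stat) in observed:
            obs = observed[(locus, arr, stat)]
            row["observed"] = obs
            row["flag"] = _flag(obs, lo, hi)
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        bad = table[(table.p025 > table.p500) | (table.p500 > table.p975)]
        assert bad.empty, "envelope percentiles must be monotone"
    return EnvelopeResult(
        table=table,
        n_accepted=config.n_accepted * len(groups),
        attempts=total_attempts,
        config=config,
    )
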