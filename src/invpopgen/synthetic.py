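"""Study-shaped synthetic datasets.

Generates per-locus alignments whose statistical structure mirrors a
multi-arrangement inversion-polymorphism survey: each locus receives an
independent neutral genealogy carrying inversion events (module
:mod:`invpopgen.coalescent`), the observed number of chromosomes per
arrangement is drawn by nested subsampling from the accepted genealogy,
infinite-sites mutations are mapped to concrete alignment positions and
bases, and a single outgroup sequence diverges at a configurable coalescent
time T.  Optional gene-conversion events copy short tracts (300-400 bp by
default) from a donor arrangement into a recipient strain, so analyses can
be re-run with conversion-carrying strains removed.

Defaults echo the study conditions: 18 loci, per-locus sample counts
(CH 16, AR 19, PP 20, ST 18, TL 4), locus lengths spanning 355-3293 bp,
per-site theta spanning 0.006-0.017 (the silent-site heterozygosity range),
and outgroup divergence T = 2.17.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import _kernels
from .coalescent import (
    accept_genealogy,
    nested_subsample,
    place_inversions,
    simulate_genealogy,
)
from .io import (
    ArrangementModel,
    LocusAlignment,
    write_locus_alignment,
    write_locus_metadata,
    write_strain_metadata,
)

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "default_arrangement_model",
    "generate_dataset",
    "inject_gene_conversion",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Arrangement ages in years (point estimate, 95% CI), youngest to oldest;
# the two oldest have overlapping CIs and the stated order is assumed.
_AGES = {
    "CH": (510_000.0, 450_000.0, 570_000.0),
    "AR": (580_000.0, 510_000.0, 650_000.0),
    "PP": (990_000.0, 880_000.0, 1_100_000.0),
    "ST": (1_380_000.0, 1_190_000.0, 1_420_000.0),
    "TL": (1_220_000.0, 1_090_000.0, 1_340_000.0),
}
_PARENT = {"CH": "SC", "AR": "ST", "PP": "ST", "ST": "HY", "TL": "SC"}
_BREAKPOINTS = {
    "CH": (22.1, 77.3),
    "AR": (30.4, 70.2),
    "PP": (15.6, 84.8),
    "ST": (25.3, 75.1),
    "TL": (33.7, 66.9),
}


@dataclass
class SynthConfig:
    """Conditions of the emulated survey (defaults are the study's)."""

    n_loci: int = 18
    arrangements: tuple[str, ...] = ("CH", "AR", "PP", "ST", "TL")
    counts: tuple[int, ...] = (16, 19, 20, 18, 4)
    locus_lengths: tuple[int, ...] | None = None
    theta_site: tuple[float, ...] | None = None
    divergence_T: float = 2.17
    conversion_rate: float = 0.0  # expected conversion events per locus
    tract_bounds: tuple[int, int] = (300, 400)
    growth_alpha: float = 0.0
    n_tips: int = 1000
    add_coding_intervals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.arrangements):
            raise ValueError("one sample count per arrangement required")
        if min(self.counts) < 1:
            raise ValueError("all sample counts must be >= 1")
        if self.locus_lengths is None:
            self.locus_lengths = tuple(
                int(x) for x in np.linspace(355, 3293, self.n_loci)
            )
        if self.theta_site is None:
            self.theta_site = tuple(np.linspace(0.006, 0.017, self.n_loci))
        if len(self.locus_lengths) != self.n_loci or len(self.theta_site) != self.n_loci:
            raise ValueError("per-locus lengths and theta must match n_loci")
        if min(self.locus_lengths) <= 0 or min(self.theta_site) <= 0:
            raise ValueError("lengths and theta must be positive")
        if self.n_tips < sum(self.counts):
            raise ValueError("n_tips must be at least the total sample count")

    @property
    def locus_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    @property
    def strain_ids(self) -> list[str]:
        out = []
        for arr, k in zip(self.arrangements, self.counts):
            out.extend(f"{arr}_{i + 1:02d}" for i in range(k))
        return out


def default_arrangement_model(config: SynthConfig) -> ArrangementModel:
    """Arrangement model matching the synthetic panel's geometry."""
    positions = np.linspace(2.5, 97.5, config.n_loci)
    return ArrangementModel(
        names=list(config.arrangements),
        ages={a: _AGES[a] for a in config.arrangements if a in _AGES},
        parent={a: _PARENT.get(a) for a in config.arrangements},
        breakpoints={
            a: _BREAKPOINTS.get(a, (25.0, 75.0)) for a in config.arrangements
        },
        marker_positions=dict(zip(config.locus_names, positions.tolist())),
    )


@dataclass
class SyntheticDataset:
    """A generated panel: alignments, metadata, model and the truth log."""

    alignments: list[LocusAlignment]
    strain_metadata: pd.DataFrame
    locus_metadata: pd.DataFrame
    model: ArrangementModel
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_locus_alignment(aln, out / f"{aln.locus_name}.fasta", "outgroup")
        write_strain_metadata(self.strain_metadata, out / "strain_metadata.tsv")
        write_locus_metadata(self.locus_metadata, out / "locus_metadata.tsv")
        self.model.to_json(out / "arrangement_model.json")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def _attach_outgroup(gen, T: float, rng) -> tuple[int, float]:
    """Sample where the outgroup lineage joins the ingroup genealogy.

    The outgroup diverged T coalescent units ago; looking backward from T it
    coalesces with the ingroup's ancestral lineages at pairwise rate 1 (same
    ancestral population size), i.e. at total rate k while k ingroup
    lineages remain.  Returns ``(node, time)``: the join splits the branch
    above ``node`` at ``time`` (the root when the join is older than the
    TMRCA).  Subsampling consistency of the coalescent makes this the exact
    marginal law for the sample plus one outgroup lineage.
    """
    n = gen.n_tips
    internal_times = gen.node_time[n:]
    t = T
    pos = int(np.searchsorted(internal_times, t, side="right"))
    k = n - pos
    while k > 1:
        w = rng.exponential(1.0 / k)
        if t + w < internal_times[pos]:
            t = t + w
            break
        t = internal_times[pos]
        pos += 1
        k -= 1
    else:
        t = max(t, gen.tmrca) + rng.exponential()
        return gen.n_nodes - 1, t
    active = [
        v
        for v in range(gen.n_nodes)
        if gen.node_time[v] <= t
        and (gen.parent[v] == -1 or gen.node_time[gen.parent[v]] > t)
    ]
    return int(active[rng.integers(len(active))]), t


def _extended_tree(gen, join_node: int, join_time: float):
    """Ingroup genealogy plus the outgroup as tip ``n_tips``.

    Internal nodes are renumbered in time order so parent indices again
    exceed child indices (the invariant the kernels rely on).
    """
    n = gen.n_tips
    m = gen.n_nodes
    n2 = n + 1
    m2 = 2 * n2 - 1
    items = sorted(
        [(gen.node_time[v], v) for v in range(n, m)] + [(join_time, -99)]
    )
    new_index = {v: n2 + i for i, (_, v) in enumerate(items)}
    remap = lambda v: v if v < n else new_index[v]
    parent2 = np.full(m2, -1, dtype=np.int64)
    time2 = np.zeros(m2)
    for v in range(m):
        nv = remap(v)
        time2[nv] = gen.node_time[v]
        if v == join_node:
            parent2[nv] = new_index[-99]
        elif gen.parent[v] != -1:
            parent2[nv] = remap(gen.parent[v])
    j = new_index[-99]
    time2[j] = join_time
    parent2[n] = j  # the outgroup tip
    p = gen.parent[join_node]
    parent2[j] = remap(p) if p != -1 else -1
    return parent2, time2


def _coding_interval(L: int) -> tuple[int, int, int]:
    start = L // 3
    length = 3 * (max(L // 3, 3) // 3)
    return (start, min(start + length, L), 0)


def generate_dataset(
    config: SynthConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full synthetic panel under the configured conditions.

    Per locus: an accepted arrangement-structured genealogy (acceptance on
    the configured sample counts), nested subsampling to those counts,
    infinite-sites mutations at per-locus theta mapped to uniform positions
    with uniformly drawn derived bases, an outgroup lineage joining the
    genealogy's root at max(T, TMRCA) + Exp(1), and optional gene-conversion
    tract copies.  The same strains are sampled at every locus, so the panel
    supports concatenated LD scans.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.arrangements)
    counts = tuple(config.counts)
    k_events = len(names) - 1
    n_sample = sum(counts)
    model = default_arrangement_model(config)
    strain_ids = config.strain_ids
    strain_labels = []
    for arr, k in zip(names, counts):
        strain_labels.extend([arr] * k)

    alignments: list[LocusAlignment] = []
    truth_loci = {}
    conversion_events = []
    for li, locus in enumerate(config.locus_names):
        L = config.locus_lengths[li]
        theta_locus = config.theta_site[li] * L
        attempts = 0
        while True:
            attempts += 1
            gen = simulate_genealogy(config.n_tips, config.growth_alpha, rng)
            place_inversions(gen, k_events, rng)
            if accept_genealogy(gen.class_labels, counts):
                break
            if attempts > 500_000:
                raise RuntimeError(
                    f"{locus}: observed counts {counts} unsatisfiable at "
                    f"n_tips={config.n_tips}"
                )
        _, sub_labels, idx = nested_subsample(
            np.zeros((config.n_tips, 0), dtype=np.int8),
            gen.class_labels,
            counts,
            rng,
            gen.class_birth_time,
            names,
        )
        # extended genealogy with the outgroup as one extra tip
        join_node, t_join = _attach_outgroup(gen, config.divergence_T, rng)
        parent2, time2 = _extended_tree(gen, join_node, t_join)
        n2 = config.n_tips + 1
        tip_class = np.full(n2, -1, dtype=np.int64)
        tip_class[idx] = 0
        tip_class[config.n_tips] = 1  # the outgroup tip
        cnt = _kernels.class_counts(parent2, tip_class, n2, 2)
        blen = time2[parent2] - time2
        blen[-1] = 0.0
        # branches invisible to the sample and the outgroup carry no signal
        visible = np.nonzero(cnt.sum(axis=1) > 0)[0][:-1]
        s_b = rng.poisson(0.5 * theta_locus * blen[visible])
        M = int(s_b.sum())
        if M > L:
            raise ValueError(
                f"{locus}: {M} mutations exceed {L} sites; lower theta or "
                "lengthen the locus (infinite-sites mapping)"
            )
        positions = rng.choice(L, size=M, replace=False)
        ancestral = _BASES[rng.integers(0, 4, size=L)]
        matrix = np.tile(ancestral, (n_sample + 1, 1))  # last row = outgroup
        shift = rng.integers(1, 4, size=M)
        base_idx = np.searchsorted(_BASES, ancestral[positions])
        derived = _BASES[(base_idx + shift) % 4]
        mut_branches = np.repeat(visible, s_b).astype(np.int64)
        if len(mut_branches):
            carrier = _kernels.descendant_mask(parent2, n2, mut_branches)
            in_carrier = carrier[:, idx]
            out_carrier = carrier[:, config.n_tips]
            for r in range(len(mut_branches)):
                col = positions[r]
                matrix[:-1][in_carrier[r], col] = derived[r]
                if out_carrier[r]:
                    matrix[-1, col] = derived[r]
        coding = (
            [_coding_interval(L)]
            if config.add_coding_intervals and li % 4 == 0
            else []
        )
        aln = LocusAlignment(
            locus_name=locus,
            sequences=[row.tobytes().decode() for row in matrix[:-1]],
            strain_ids=list(strain_ids),
            arrangement_labels=list(strain_labels),
            coding_intervals=coding,
            outgroup_sequence=matrix[-1].tobytes().decode(),
        )
        if config.conversion_rate > 0:
            for _ in range(rng.poisson(config.conversion_rate)):
                donor = names[rng.integers(len(names))]
                others = [s for s, a in zip(strain_ids, strain_labels) if a != donor]
                recipient = others[rng.integers(len(others))]
                tlen = int(rng.integers(config.tract_bounds[0], config.tract_bounds[1] + 1))
                tlen = min(tlen, L)
                start = int(rng.integers(0, L - tlen + 1))
                aln, record = inject_gene_conversion(
                    aln, donor, recipient, (start, start + tlen), rng
                )
                conversion_events.append(record)
        alignments.append(aln)
        truth_loci[locus] = {
            "theta_site": config.theta_site[li],
            "length": L,
            "t_join": t_join,
            "tmrca": gen.tmrca,
            "acceptance_attempts": attempts,
            "n_mutations": M,
        }
        logger.info("%s: accepted after %d attempts, %d mutations", locus, attempts, M)

    strain_metadata = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "arrangement": strain_labels,
            "population": ["synthetic"] * n_sample,
        }
    )
    locus_metadata = pd.DataFrame(
        {
            "locus": config.locus_names,
            "position": [model.marker_positions[l] for l in config.locus_names],
            "coding_intervals": [a.coding_intervals for a in alignments],
        }
    )
    truth = {
        "seed": config.seed,
        "divergence_T": config.divergence_T,
        "growth_alpha": config.growth_alpha,
        "n_tips": config.n_tips,
        "arrangements": names,
        "counts": list(counts),
        "loci": truth_loci,
        "conversion_events": conversion_events,
    }
    ds = SyntheticDataset(
        alignments=alignments,
        strain_metadata=strain_metadata,
        locus_metadata=locus_metadata,
        model=model,
        truth=truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def shuffle_sites(site_table, rng=None):
    """Free-recombination null: permute each site's alleles independently.

    Destroys all between-site association while preserving every site's
    allele frequencies and missingness pattern, so an LD scan on the result
    should flag no more than the nominal false-discovery fraction.
    """
    from .ld import SiteTable

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    alleles = site_table.alleles.copy()
    for s in range(alleles.shape[0]):
        rng.shuffle(alleles[s])
    return SiteTable(
        loci=site_table.loci.copy(),
        positions=site_table.positions.copy(),
        alleles=alleles,
        major=site_table.major.copy(),
        minor=site_table.minor.copy(),
        strain_ids=list(site_table.strain_ids),
        arrangement_labels=site_table.arrangement_labels.copy(),
        outgroup_allele=(
            site_table.outgroup_allele.copy()
            if site_table.outgroup_allele is not None
            else None
        ),
    )


def inject_gene_conversion(
    alignment: LocusAlignment,
    donor_class: str,
    recipient_strain: str,
    tract: tuple[int, int],
    rng=None,
) -> tuple[LocusAlignment, dict]:
    """Copy a donor-arrangement consensus tract into a recipient strain.

    The recipient's bases in ``[start, end)`` are replaced by the
    majority-rule consensus of the donor class, emulating a nonreciprocal
    gene-conversion event; the returned record lets analyses be re-run with
    the converted strain removed.
    """
    start, end = tract
    if not (0 <= start < end <= alignment.length):
        raise ValueError(f"tract {tract} outside [0, {alignment.length})")
    donor_rows = [
        i for i, a in enumerate(alignment.arrangement_labels) if a == donor_class
    ]
    if not donor_rows:
        raise ValueError(f"donor class {donor_class!r} is empty")
    if recipient_strain not in alignment.strain_ids:
        raise ValueError(f"recipient {recipient_strain!r} not in alignment")
    r = alignment.strain_ids.index(recipient_strain)
    m = alignment.matrix()
    consensus = []
    for col in range(start, end):
        col_vals = m[donor_rows, col]
        vals, cnts = np.unique(col_vals, return_counts=True)
        consensus.append(vals[np.argmax(cnts)])
    consensus = b"".join(consensus).decode()
    seqs = list(alignment.sequences)
    changed = sum(
        1 for k, ch in enumerate(consensus) if seqs[r][start + k] != ch
    )
    seqs[r] = seqs[r][:start] + consensus + seqs[r][end:]
    record = {
        "locus": alignment.locus_name,
        "donor_class": donor_class,
        "recipient": recipient_strain,
        "tract": [start, end],
        "sites_changed": changed,
    }
    return (
        LocusAlignment(
            locus_name=alignment.locus_name,
            sequences=seqs,
            strain_ids=list(alignment.strain_ids),
            arrangement_labels=list(alignment.arrangement_labels),
            coding_intervals=list(alignment.coding_intervals),
            outgroup_sequence=alignment.outgroup_sequence,
        ),
        record,
    )
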