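"""Shared domain types and readers/writers for the standard file formats.

The analyses in this package consume per-locus multiple sequence alignments
(FASTA, one file per locus) together with a strain metadata table mapping
each strain to its gene-arrangement label, a locus metadata table giving
chromosomal positions and coding annotation, and an arrangement model that
records the age order, inversion phylogeny and breakpoint intervals of the
gene arrangements under study.

Coordinates are 0-based and half-open throughout.  Metadata tables are
tab-separated with a header row; the arrangement model is a single JSON
document (schema documented on :class:`ArrangementModel`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "LocusAlignment",
    "ArrangementModel",
    "RegionClass",
    "read_locus_alignment",
    "write_locus_alignment",
    "read_strain_metadata",
    "write_strain_metadata",
    "read_locus_metadata",
    "write_locus_metadata",
    "classify_region",
]

#: Characters permitted in an aligned sequence.
ALPHABET = frozenset("ACGTN-")


class RegionClass(str, Enum):
    """Position of a marker relative to an arrangement's breakpoints.

    Proximal markers lie between the centromere and the proximal breakpoint,
    inverted markers between the two breakpoints, and distal markers between
    the distal breakpoint and the telomere.
    """

    PROXIMAL = "proximal"
    INVERTED = "inverted"
    DISTAL = "distal"


@dataclass
class LocusAlignment:
    """An aligned sample of haplotypes at one locus, with arrangement labels.

    Parameters
    ----------
    locus_name
        Identifier of the locus (marker).
    sequences
        Equal-length aligned sequences over ``ACGTN-`` (uppercase).
    strain_ids
        Unique strain identifiers, aligned to ``sequences``.
    arrangement_labels
        Gene-arrangement label per strain, aligned to ``sequences``.
    coding_intervals
        ``(start, end, frame)`` triples in alignment coordinates
        (0-based, half-open); ``frame`` is the offset of the first complete
        codon within the interval (0, 1 or 2).
    outgroup_sequence
        Optional single aligned outgroup sequence (same length).
    """

    locus_name: str
    sequences: list[str]
    strain_ids: list[str]
    arrangement_labels: list[str]
    coding_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    outgroup_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.locus_name}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if self.outgroup_sequence is not None:
            lengths.add(len(self.outgroup_sequence))
        if len(lengths) != 1:
            raise ValueError(
                f"{self.locus_name}: unequal alignment lengths {sorted(lengths)}"
            )
        if len(self.strain_ids) != len(self.sequences):
            raise ValueError(f"{self.locus_name}: strain_ids/sequences length mismatch")
        if len(self.arrangement_labels) != len(self.sequences):
            raise ValueError(f"{self.locus_name}: one arrangement label per sequence required")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = {s for s in self.strain_ids if self.strain_ids.count(s) > 1}
            raise ValueError(f"{self.locus_name}: duplicate strain IDs {sorted(dupes)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.outgroup_sequence is not None:
            self.outgroup_sequence = self.outgroup_sequence.upper()
        bad = set("".join(self.sequences)) - ALPHABET
        if bad:
            raise ValueError(f"{self.locus_name}: invalid characters {sorted(bad)}")
        L = self.length
        for start, end, frame in self.coding_intervals:
            if not (0 <= start < end <= L):
                raise ValueError(
                    f"{self.locus_name}: coding interval ({start}, {end}) outside [0, {L})"
                )
            if frame not in (0, 1, 2):
                raise ValueError(f"{self.locus_name}: frame must be 0, 1 or 2")
        self._matrix: np.ndarray | None = None

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def arrangements(self) -> list[str]:
        """Distinct arrangement labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for a in self.arrangement_labels:
            seen.setdefault(a)
        return list(seen)

    # -- array views -------------------------------------------------------
    def matrix(self) -> np.ndarray:
        """Ingroup alignment as a ``(n, L)`` byte matrix (cached)."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self.sequences).encode(), dtype="S1"
            ).reshape(self.n_sequences, self.length)
        return self._matrix

    def outgroup_array(self) -> np.ndarray | None:
        if self.outgroup_sequence is None:
            return None
        return np.frombuffer(self.outgroup_sequence.encode(), dtype="S1")

    def subset_indices(self, arrangements: Sequence[str] | None) -> np.ndarray:
        """Row indices of strains carrying one of ``arrangements`` (None = all)."""
        if arrangements is None:
            return np.arange(self.n_sequences)
        wanted = set(arrangements)
        unknown = wanted - set(self.arrangement_labels)
        if unknown:
            raise ValueError(
                f"{self.locus_name}: arrangements {sorted(unknown)} not present"
            )
        idx = np.array(
            [i for i, a in enumerate(self.arrangement_labels) if a in wanted],
            dtype=np.intp,
        )
        return idx

    def surveyed_mask(self) -> np.ndarray:
        """Complete-deletion mask: True at columns free of gaps and Ns.

        Any column containing ``-`` or ``N`` in *any* ingroup sequence is
        excluded from every downstream statistic, so site counts are
        comparable across arrangement subsets of the same locus.
        """
        m = self.matrix()
        return ~((m == b"-") | (m == b"N")).any(axis=0)


@dataclass
class ArrangementModel:
    """Ages, phylogeny and breakpoint intervals of the gene arrangements.

    Attributes
    ----------
    names
        Arrangement names ordered youngest to oldest.
    ages
        ``name -> (age, lower, upper)`` in years (point estimate with a 95%
        confidence interval).
    parent
        ``name -> ancestral arrangement`` (the arrangement each inversion
        arose on); the root ancestor maps to ``None``.
    breakpoints
        ``name -> (proximal, distal)`` positions of the inversion breakpoints
        on a common reference coordinate (half-open interval).
    marker_positions
        ``locus -> position`` on the same reference coordinate.
    """

    names: list[str]
    ages: dict[str, tuple[float, float, float]]
    parent: dict[str, str | None]
    breakpoints: dict[str, tuple[float, float]]
    marker_positions: dict[str, float]

    def __post_init__(self) -> None:
        for name, (prox, dist) in self.breakpoints.items():
            if not prox < dist:
                raise ValueError(f"{name}: proximal breakpoint must precede distal")
        prev: tuple[float, float, float] | None = None
        for name in self.names:
            if name not in self.ages:
                continue
            cur = self.ages[name]
            if prev is not None and cur[0] < prev[0] and cur[2] < prev[1]:
                # Strictly younger with non-overlapping CIs: order violated.
                raise ValueError(
                    f"age order violated at {name}: {cur} after {prev} "
                    "(ages must weakly increase along the stated order)"
                )
            prev = cur

    def to_json(self, path: str | Path) -> None:
        doc = {
            "names": self.names,
            "ages": {k: list(v) for k, v in self.ages.items()},
            "parent": self.parent,
            "breakpoints": {k: list(v) for k, v in self.breakpoints.items()},
            "marker_positions": self.marker_positions,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ArrangementModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            names=list(doc["names"]),
            ages={k: tuple(v) for k, v in doc["ages"].items()},
            parent=dict(doc["parent"]),
            breakpoints={k: tuple(v) for k, v in doc["breakpoints"].items()},
            marker_positions=dict(doc["marker_positions"]),
        )


def classify_region(
    locus: str, arrangement: str, model: ArrangementModel
) -> RegionClass:
    """Classify a marker as proximal, inverted or distal for an arrangement.

    A marker between the centromere and the proximal breakpoint is proximal,
    between the two breakpoints inverted, and beyond the distal breakpoint
    distal.  A position exactly equal to a breakpoint coordinate is refused:
    the caller must resolve it through its own coordinate convention.
    """
    if locus not in model.marker_positions:
        raise KeyError(f"locus {locus!r} has no position in the arrangement model")
    if arrangement not in model.breakpoints:
        raise KeyError(f"arrangement {arrangement!r} has no breakpoints in the model")
    pos = model.marker_positions[locus]
    prox, dist = model.breakpoints[arrangement]
    if pos == prox or pos == dist:
        raise ValueError(
            f"{locus} at {pos} coincides with a {arrangement} breakpoint; "
            "resolve with an explicit coordinate convention"
        )
    if pos < prox:
        return RegionClass.PROXIMAL
    if pos < dist:
        return RegionClass.INVERTED
    return RegionClass.DISTAL


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_strain_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV (columns: strain_id, arrangement, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "arrangement"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strain metadata missing columns {sorted(missing)}")
    if df["strain_id"].duplicated().any():
        dupes = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
        raise ValueError(f"duplicate strain IDs in metadata: {dupes}")
    return df


def write_strain_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _format_intervals(intervals: Sequence[tuple[int, int, int]]) -> str:
    return ";".join(f"{s}:{e}:{f}" for s, e, f in intervals)


def _parse_intervals(text: str) -> list[tuple[int, int, int]]:
    if not text or text in (".", "nan"):
        return []
    out = []
    for chunk in text.split(";"):
        s, e, f = chunk.split(":")
        out.append((int(s), int(e), int(f)))
    return out


def read_locus_metadata(path: str | Path) -> pd.DataFrame:
    """Read the locus metadata TSV (locus, position, coding_intervals).

    ``coding_intervals`` is a ``;``-separated list of ``start:end:frame``
    triples (0-based, half-open) or ``.`` for none.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    missing = {"locus", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"locus metadata missing columns {sorted(missing)}")
    if "coding_intervals" in df.columns:
        df["coding_intervals"] = (
            df["coding_intervals"].fillna(".").astype(str).map(_parse_intervals)
        )
    else:
        df["coding_intervals"] = [[] for _ in range(len(df))]
    return df


def write_locus_metadata(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "coding_intervals" in out.columns:
        out["coding_intervals"] = out["coding_intervals"].map(
            lambda v: _format_intervals(v) if isinstance(v, (list, tuple)) and v else "."
        )
    out.to_csv(path, sep="\t", index=False)


def read_locus_alignment(
    fasta_path: str | Path,
    strain_metadata: pd.DataFrame | str | Path,
    locus_name: str | None = None,
    coding_intervals: Sequence[tuple[int, int, int]] | None = None,
    outgroup_id: str | None = None,
) -> LocusAlignment:
    """Read one locus alignment from FASTA, validated against strain metadata.

    Every FASTA record ID must appear in the metadata (or equal
    ``outgroup_id``, in which case it becomes the outgroup sequence).
    """
    if not isinstance(strain_metadata, pd.DataFrame):
        strain_metadata = read_strain_metadata(strain_metadata)
    arrangement_of = dict(
        zip(strain_metadata["strain_id"], strain_metadata["arrangement"])
    )
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    sequences, strain_ids, labels = [], [], []
    outgroup = None
    for rec in records:
        if outgroup_id is not None and rec.id == outgroup_id:
            outgroup = str(rec.seq)
            continue
        if rec.id not in arrangement_of:
            raise ValueError(
                f"{fasta_path}: strain {rec.id!r} absent from the strain metadata"
            )
        sequences.append(str(rec.seq))
        strain_ids.append(rec.id)
        labels.append(arrangement_of[rec.id])
    return LocusAlignment(
        locus_name=locus_name or fasta_path.stem,
        sequences=sequences,
        strain_ids=strain_ids,
        arrangement_labels=labels,
        coding_intervals=list(coding_intervals or []),
        outgroup_sequence=outgroup,
    )


@dataclass
class Dataset:
    """A loaded analysis directory: alignments plus metadata and model."""

    alignments: list[LocusAlignment]
    strain_metadata: pd.DataFrame
    locus_metadata: pd.DataFrame
    model: ArrangementModel


def read_dataset(directory: str | Path, outgroup_id: str = "outgroup") -> Dataset:
    """Load a directory of one-FASTA-per-locus data with its metadata tables.

    Expects ``<locus>.fasta`` per locus listed in ``locus_metadata.tsv``,
    plus ``strain_metadata.tsv`` and ``arrangement_model.json`` (the layout
    written by :meth:`invpopgen.synthetic.SyntheticDataset.write`).
    """
    directory = Path(directory)
    strain_meta = read_strain_metadata(directory / "strain_metadata.tsv")
    locus_meta = read_locus_metadata(directory / "locus_metadata.tsv")
    model = ArrangementModel.from_json(directory / "arrangement_model.json")
    alignments = []
    for _, row in locus_meta.iterrows():
        alignments.append(
            read_locus_alignment(
                directory / f"{row.locus}.fasta",
                strain_meta,
                locus_name=row.locus,
                coding_intervals=row.coding_intervals,
                outgroup_id=outgroup_id,
            )
        )
    return Dataset(alignments, strain_meta, locus_meta, model)


def write_locus_alignment(
    alignment: LocusAlignment,
    fasta_path: str | Path,
    outgroup_id: str | None = None,
) -> None:
    """Write an alignment back to FASTA (outgroup last, under ``outgroup_id``)."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for s, sid in zip(alignment.sequences, alignment.strain_ids)
    ]
    if alignment.outgroup_sequence is not None:
        records.append(
            SeqRecord(
                Seq(alignment.outgroup_sequence),
                id=outgroup_id or "outgroup",
                description="",
            )
        )
    SeqIO.write(records, str(fasta_path), "fasta")
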