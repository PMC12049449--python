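"""Strand-resolved cut calling and circular cleavage profiles.

Ligation capture tags the free 3'-OH terminus of the *incised* strand, but
sequencing proceeds along the intact complement, so the read maps to the
strand opposite the cut: a read aligned to the top (plus) strand reports a
bottom-strand incision and vice versa.  This module inverts alignment
strands into cut strands, aggregates calls into a per-position per-strand
histogram over the circle, and exports polar-plot and hotspot summaries.

Ambiguous (multi-mapping) reads are excluded by default; a fractional mode
spreads each ambiguous read as weight 1/k over its k co-optimal placements.
The hotspot report (count > mean + k.SD of the pooled per-site counts) is
a simple operationalisation of "some sites are cleaved more efficiently
than others" — a descriptive filter, not a calibrated peak caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .circular import AMBIGUOUS, UNIQUE, ReadAlignment
from .synthetic import BOTTOM, TOP

__all__ = [
    "CutEvent",
    "CutProfile",
    "call_cut",
    "call_cuts",
    "aggregate_profile",
    "export_polar",
    "hotspots",
    "write_profile_bedgraph",
    "write_profile_tsv",
    "read_profile_tsv",
]

#: alignment strand -> strand carrying the inferred 3'-OH
STRAND_INVERSION = {"plus": BOTTOM, "minus": TOP}


class CutEvent(NamedTuple):
    position: int
    strand: str


@dataclass
class CutProfile:
    """Per-position, per-strand cut counts over the full circle.

    Counts are floats so that fractional multi-mapper weights are exact;
    with unique-only calling every entry is integral.
    """

    L: int
    counts_top: np.ndarray
    counts_bottom: np.ndarray

    @property
    def total(self) -> float:
        return float(self.counts_top.sum() + self.counts_bottom.sum())

    def counts(self, strand: str) -> np.ndarray:
        if strand == TOP:
            return self.counts_top
        if strand == BOTTOM:
            return self.counts_bottom
        raise ValueError(f"unknown strand {strand!r}")


def call_cut(aln: ReadAlignment) -> CutEvent:
    """Infer the cut behind one uniquely mapped read.

    The cut position equals the alignment's 5'-base coordinate (the
    registration convention) and the cut strand is the opposite of the
    alignment strand.
    """
    if aln.status != UNIQUE:
        raise ValueError(
            f"read {aln.read_id!r} is {aln.status}; no single cut can be called"
        )
    return CutEvent(aln.start, STRAND_INVERSION[aln.strand])


def call_cuts(
    alignments: Iterable[ReadAlignment],
    ambiguous: str = "drop",
) -> tuple[list[CutEvent], list[float]]:
    """Convert alignments to weighted cut events.

    ``ambiguous='drop'`` (default) keeps unique alignments only;
    ``'fractional'`` also spreads each ambiguous read as 1/k over its k
    placements.  Unmapped reads never contribute.  Returns parallel lists
    of events and weights; with ``'drop'`` every weight is 1.0.
    """
    if ambiguous not in ("drop", "fractional"):
        raise ValueError("ambiguous must be 'drop' or 'fractional'")
    events: list[CutEvent] = []
    weights: list[float] = []
    for aln in alignments:
        if aln.status == UNIQUE:
            events.append(call_cut(aln))
            weights.append(1.0)
        elif aln.status == AMBIGUOUS and ambiguous == "fractional":
            k = len(aln.placements)
            for strand, start in aln.placements:
                events.append(CutEvent(start, STRAND_INVERSION[strand]))
                weights.append(1.0 / k)
    return events, weights


def aggregate_profile(
    cuts: Sequence[CutEvent],
    L: int,
    weights: Sequence[float] | None = None,
) -> CutProfile:
    """Exact per-position per-strand histogram; order-independent."""
    top = np.zeros(L)
    bottom = np.zeros(L)
    if weights is None:
        weights = np.ones(len(cuts))
    if len(weights) != len(cuts):
        raise ValueError("weights and cuts must have equal length")
    for (pos, strand), w in zip(cuts, weights):
        if not 0 <= pos < L:
            raise ValueError(f"cut position {pos} outside [0, {L})")
        if strand == TOP:
            top[pos] += w
        elif strand == BOTTOM:
            bottom[pos] += w
        else:
            raise ValueError(f"unknown strand {strand!r}")
    return CutProfile(L, top, bottom)


def export_polar(profile: CutProfile, normalized: bool = False) -> pd.DataFrame:
    """Polar-plot table: theta = 2*pi*position/L, radius = count.

    One row per nonzero (position, strand).  In normalized mode radii are
    divided by the grand total so they sum to 1 across both strands.
    """
    if profile.L <= 0:
        raise ValueError("profile must cover a positive-length circle")
    total = profile.total
    rows = []
    for strand in (TOP, BOTTOM):
        counts = profile.counts(strand)
        for pos in np.flatnonzero(counts):
            radius = counts[pos] / total if normalized else counts[pos]
            rows.append(
                {
                    "theta": 2.0 * np.pi * pos / profile.L,
                    "radius": float(radius),
                    "strand": strand,
                    "position": int(pos),
                }
            )
    return pd.DataFrame(rows, columns=["theta", "radius", "strand", "position"])


def hotspots(profile: CutProfile, k: float = 3.0) -> pd.DataFrame:
    """Sites cleaved more efficiently than the bulk of the circle.

    Reports (position, strand, count) for every site whose count exceeds
    mean + k*SD of the pooled per-position counts of both strands, sorted
    by descending count.  An all-zero profile yields an empty table.
    """
    pooled = np.concatenate([profile.counts_top, profile.counts_bottom])
    if pooled.sum() == 0:
        return pd.DataFrame(columns=["position", "strand", "count"])
    threshold = pooled.mean() + k * pooled.std()
    rows = []
    for strand in (TOP, BOTTOM):
        counts = profile.counts(strand)
        for pos in np.flatnonzero(counts > threshold):
            rows.append(
                {"position": int(pos), "strand": strand, "count": float(counts[pos])}
            )
    df = pd.DataFrame(rows, columns=["position", "strand", "count"])
    return df.sort_values(
        ["count", "position", "strand"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# exports


def write_profile_bedgraph(profile: CutProfile, chrom: str, prefix: str) -> None:
    """Two bedGraph tracks (<prefix>.top.bedgraph / .bottom.bedgraph)."""
    for strand in (TOP, BOTTOM):
        counts = profile.counts(strand)
        with open(f"{prefix}.{strand}.bedgraph", "w") as fh:
            fh.write(f'track type=bedGraph name="cuts_{strand}"\n')
            for pos in np.flatnonzero(counts):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{counts[pos]:g}\n")


def write_profile_tsv(profile: CutProfile, chrom: str, path) -> None:
    """Combined BED-like TSV, 0-based half-open, '+' = top strand."""
    rows = []
    for strand, symbol in ((TOP, "+"), (BOTTOM, "-")):
        counts = profile.counts(strand)
        for pos in np.flatnonzero(counts):
            rows.append((chrom, int(pos), int(pos) + 1, "cut", float(counts[pos]), symbol))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "count", "strand"]
    ).sort_values(["start", "strand"])
    df.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, L: int) -> CutProfile:
    """Inverse of :func:`write_profile_tsv`."""
    df = pd.read_csv(path, sep="\t")
    top = np.zeros(L)
    bottom = np.zeros(L)
    for start, strand, count in zip(df["start"], df["strand"], df["count"]):
        target = top if strand == "+" else bottom
        target[int(start)] += float(count)
    return CutProfile(L, top, bottom)
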