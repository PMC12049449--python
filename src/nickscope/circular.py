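"""Circular read mapping via a triplicated linear reference.

Short reads from a circular plasmid can span the arbitrary origin of the
written sequence.  Rather than aligning against a circular structure
directly, the reference top strand is concatenated three times and reads
are aligned to this linear triplication; any circular placement of a read
no longer than the circle then appears as an ordinary linear placement,
and its coordinate folds back onto the circle by reduction modulo L.

The mapper is an exhaustive mismatch-count scan (no gaps): every circular
start position is evaluated on both strands and the minimal-mismatch
placement wins.  Placements identical modulo L are the same placement and
are collapsed before ambiguity assessment.  ``strand='plus'`` means the
read as given matches the top strand; ``'minus'`` means its reverse
complement does.  The reported ``start`` is always the folded top-strand
coordinate of the read's **5'-terminal** aligned base — for a minus-strand
placement that is the highest top-strand coordinate the read touches —
because that base marks the captured 3'-OH terminus downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import CircularSequence, GloeRead, revcomp

__all__ = [
    "TripledReference",
    "ReadAlignment",
    "build_index",
    "fold_coordinate",
    "align_read",
    "align_reads",
    "write_alignments_tsv",
    "read_alignments_tsv",
]

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

DEFAULT_MAX_MISMATCHES = 3

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class TripledReference:
    """Three tandem copies of the circular top strand, plus scan caches."""

    source: CircularSequence
    sequence: str = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.source.sequence * 3
        self._encoded = _encode(self.sequence)
        self._window_cache: dict[int, np.ndarray] = {}

    @property
    def L(self) -> int:
        return self.source.length

    def windows(self, R: int) -> np.ndarray:
        """(L, R) uint8 view: row s is the circular window starting at s."""
        if R not in self._window_cache:
            view = np.lib.stride_tricks.sliding_window_view(
                self._encoded[: self.L + R - 1], R
            )
            self._window_cache[R] = view
        return self._window_cache[R]


@dataclass(frozen=True)
class ReadAlignment:
    """Placement of a read on the circle.

    ``start`` is the folded coordinate in [0, L) of the read's 5'-terminal
    aligned base; it is ``None`` for unmapped reads.  ``placements`` lists
    every (strand, start) tied at the minimal mismatch count — a single
    entry for unique alignments, all co-optimal placements for ambiguous
    ones.
    """

    read_id: str
    strand: str | None
    start: int | None
    mismatches: int | None
    status: str
    placements: tuple[tuple[str, int], ...] = ()


def build_index(reference: CircularSequence) -> TripledReference:
    """Triplicate the top strand; no other transformation is applied."""
    if reference.length == 0:
        raise ValueError("cannot index an empty reference")
    return TripledReference(reference)


def fold_coordinate(pos_concat: int, L: int) -> int:
    """Fold a triplicated-reference coordinate back onto the circle."""
    if not 0 <= pos_concat < 3 * L:
        raise ValueError(f"coordinate {pos_concat} outside [0, {3 * L})")
    return pos_concat % L


def align_read(
    read: GloeRead,
    index: TripledReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> ReadAlignment:
    """Best mismatch-only placement of one read on the circle."""
    return align_reads([read], index, max_mismatches)[0]


def align_reads(
    reads: Sequence[GloeRead],
    index: TripledReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[ReadAlignment]:
    """Vectorised scan of many reads against both strands of the circle.

    Reads are grouped by length so each group shares one window matrix.
    """
    L = index.L
    out: list[ReadAlignment | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        if len(r.bases) > L:
            raise ValueError(
                f"read {r.read_id!r} ({len(r.bases)} nt) longer than circle ({L} bp)"
            )
        by_len.setdefault(len(r.bases), []).append(i)

    for R, idxs in by_len.items():
        win = index.windows(R)  # (L, R)
        fwd = np.stack([_encode(reads[i].bases) for i in idxs])
        rev = np.stack([_encode(revcomp(reads[i].bases)) for i in idxs])
        chunk = max(1, int(4e6 // (L * R)) or 1)
        for c0 in range(0, len(idxs), chunk):
            sel = slice(c0, c0 + chunk)
            # (n, L) mismatch counts for each circular start
            mm_plus = (win[None, :, :] != fwd[sel, None, :]).sum(axis=2)
            mm_minus = (win[None, :, :] != rev[sel, None, :]).sum(axis=2)
            for j, i in enumerate(idxs[sel]):
                out[i] = _resolve(
                    reads[i].read_id, mm_plus[j], mm_minus[j], L, R, max_mismatches
                )
    return out  # type: ignore[return-value]


def _resolve(
    read_id: str,
    mm_plus: np.ndarray,
    mm_minus: np.ndarray,
    L: int,
    R: int,
    max_mismatches: int,
) -> ReadAlignment:
    best = int(min(mm_plus.min(), mm_minus.min()))
    if best > max_mismatches:
        return ReadAlignment(read_id, None, None, None, UNMAPPED)
    placements: list[tuple[str, int]] = []
    for s in np.flatnonzero(mm_plus == best):
        placements.append(("plus", int(s)))
    for s in np.flatnonzero(mm_minus == best):
        # minus placement over window [s, s+R): the read's 5' base sits at
        # the window's right edge on top-strand coordinates
        placements.append(("minus", (int(s) + R - 1) % L))
    placements = sorted(set(placements))
    status = UNIQUE if len(placements) == 1 else AMBIGUOUS
    strand, start = placements[0]
    if status == AMBIGUOUS:
        return ReadAlignment(read_id, strand, start, best, status, tuple(placements))
    return ReadAlignment(read_id, strand, start, best, status, tuple(placements))


# ---------------------------------------------------------------------------
# TSV round-trip of alignment tables


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "strand": a.strand if a.strand is not None else ".",
            "start": a.start if a.start is not None else -1,
            "mismatches": a.mismatches if a.mismatches is not None else -1,
            "status": a.status,
            "placements": ";".join(f"{s}:{p}" for s, p in a.placements),
        }
        for a in alignments
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "strand", "start", "mismatches", "status", "placements"],
    ).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "placements": str})
    out = []
    for row in df.itertuples(index=False):
        unmapped = row.status == UNMAPPED
        placements = tuple(
            (s, int(p))
            for s, p in (
                tok.split(":") for tok in str(row.placements).split(";") if ":" in tok
            )
        )
        out.append(
            ReadAlignment(
                row.read_id,
                None if unmapped else row.strand,
                None if unmapped else int(row.start),
                None if unmapped else int(row.mismatches),
                row.status,
                placements,
            )
        )
    return out
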