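"""Synthetic substrates, nicks, and ligation-capture sequencing reads.

This module generates the inputs the rest of the pipeline consumes:
circular plasmid references, ground-truth single-strand nick events with
hotspot structure, GLOE-seq-style single-end reads, and band-intensity
tables mimicking agarose-gel densitometry of nicking assays.

The read model follows the chemistry of ligation-mediated 3'-OH capture:
a nick leaves a free 3'-OH terminus; the sequencing read starts at that
terminus and extends along the *intact complement* of the incised strand,
so the read maps to the strand opposite the cut. Concretely, with the
reference top strand written 5'->3':

* a **top**-strand nick at top-strand coordinate ``p`` yields a read equal
  to the reverse complement of the circular top-strand window *ending* at
  ``p`` (the read aligns to the bottom strand, its 5'-terminal base at top
  coordinate ``p``);
* a **bottom**-strand nick at ``p`` yields the circular top-strand window
  *starting* at ``p`` (the read aligns to the top strand, 5' base at ``p``).

The registration convention — the read's 5' mapped base coincides exactly
with the 3'-OH coordinate — is a documented convention of this package,
not a claim about the ligation chemistry; the cut caller applies the same
convention so simulated nicks round-trip exactly.

Coordinates are 0-based throughout; exported intervals are 0-based
half-open.  Only substitution errors are simulated (no indels), each nick
yields exactly one read (no fragmentation or duplicate model), and quality
strings are a constant Q30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircularSequence",
    "NickEvent",
    "NickModel",
    "GloeRead",
    "make_plasmid",
    "uniform_nick_model",
    "hotspot_nick_model",
    "sample_nicks",
    "simulate_gloeseq_reads",
    "simulate_band_table",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_truth_bed",
]

TOP = "top"
BOTTOM = "bottom"
STRANDS = (TOP, BOTTOM)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: constant Phred+33 quality symbol (Q30) used for all simulated bases
Q30 = "?"

MIN_PLASMID_LENGTH = 200


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A circular DNA reference with an explicit top-strand orientation.

    ``sequence`` is the top strand written 5'->3'; position 0 is an
    arbitrary origin on the circle.
    """

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("circular reference must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet restricted to A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def window(self, start: int, length: int) -> str:
        """Circular top-strand window of ``length`` bases starting at ``start``."""
        L = self.length
        if length > L:
            raise ValueError(f"window length {length} exceeds circle length {L}")
        start %= L
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def rotate(self, r: int) -> "CircularSequence":
        """Same circle with the origin moved to old coordinate ``r``."""
        r %= self.length
        return CircularSequence(self.identifier, self.sequence[r:] + self.sequence[:r])


class NickEvent(NamedTuple):
    """A single-strand incision: the 3'-OH of the cut strand sits at the
    base whose top-strand coordinate is ``position``."""

    position: int
    strand: str


@dataclass(frozen=True)
class GloeRead:
    """A single-end read captured at a 3'-OH terminus."""

    read_id: str
    bases: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")


@dataclass
class NickModel:
    """Relative cleavage propensities per (strand, position).

    ``site_weights`` has shape ``(2, L)``: row 0 is the top strand, row 1
    the bottom strand.  Weights are relative — only their ratios matter.
    Non-uniform weights encode the observation that some sites on a
    plasmid are cleaved far more efficiently than others.
    """

    site_weights: np.ndarray
    total_events: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.site_weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 2:
            raise ValueError("site_weights must have shape (2, L)")
        if (w < 0).any():
            raise ValueError("site_weights must be non-negative")
        if self.total_events < 0:
            raise ValueError("total_events must be non-negative")
        self.site_weights = w


def make_plasmid(length: int, seed: int, gc_fraction: float = 0.5) -> CircularSequence:
    """Generate a reproducible pseudorandom circular plasmid sequence.

    Parameters
    ----------
    length
        Circle length in bp; must be at least 200 (anything shorter is not
        a plausible plasmid substrate and breaks read-length preconditions
        downstream).
    seed
        RNG seed; identical seeds give byte-identical sequences.
    gc_fraction
        Expected G+C content; G/C and A/T are drawn symmetrically.
    """
    if length < MIN_PLASMID_LENGTH:
        raise ValueError(
            f"plasmid length must be >= {MIN_PLASMID_LENGTH} bp, got {length}"
        )
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    idx = rng.choice(4, size=length, p=p)
    seq = _BASES[idx].tobytes().decode("ascii")
    return CircularSequence(f"plasmid_L{length}_s{seed}", seq)


def uniform_nick_model(L: int, total_events: int, seed: int = 0) -> NickModel:
    """Every (strand, position) equally cleavable."""
    return NickModel(np.ones((2, L)), total_events, seed)


def hotspot_nick_model(
    L: int,
    total_events: int,
    n_hotspots: int = 20,
    enrichment: float = 50.0,
    background: float = 1.0,
    seed: int = 0,
) -> NickModel:
    """Uniform background plus ``n_hotspots`` strongly preferred sites.

    Hotspot positions and strands are drawn without replacement from the
    2L (strand, position) sites; each hotspot's weight is ``enrichment``
    times the background.  This emulates the observed non-uniform site
    preference of the plasmid cleavage profile.
    """
    if n_hotspots > 2 * L:
        raise ValueError("more hotspots than available sites")
    rng = np.random.default_rng(seed)
    w = np.full((2, L), float(background))
    flat = rng.choice(2 * L, size=n_hotspots, replace=False)
    w[np.unravel_index(flat, (2, L))] = background * enrichment
    return NickModel(w, total_events, seed)


def sample_nicks(model: NickModel, reference: CircularSequence) -> list[NickEvent]:
    """Draw ``model.total_events`` nick events ~ multinomial(site_weights).

    Events are returned in a reproducible shuffled order (seeded by the
    model).  All-zero weights are rejected.
    """
    L = reference.length
    if model.site_weights.shape != (2, L):
        raise ValueError(
            f"site_weights shape {model.site_weights.shape} does not match (2, {L})"
        )
    total_w = model.site_weights.sum()
    if total_w <= 0:
        raise ValueError("site_weights must sum to a positive value")
    if model.total_events == 0:
        return []
    rng = np.random.default_rng(model.seed)
    probs = model.site_weights.ravel() / total_w
    counts = rng.multinomial(model.total_events, probs)
    sites = np.repeat(np.arange(2 * L), counts)
    rng.shuffle(sites)
    strands, positions = np.unravel_index(sites, (2, L))
    return [
        NickEvent(int(p), STRANDS[s]) for p, s in zip(positions, strands)
    ]


def _inject_errors(bases: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        # substitute with one of the three *other* bases
        code = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_gloeseq_reads(
    reference: CircularSequence,
    nicks: Sequence[NickEvent],
    read_length: int = 120,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[GloeRead]:
    """One read per nick, per the 3'-OH capture convention (module docstring).

    Reads wrap the origin transparently (the reference is circular).
    Substitution errors are injected per base at ``error_rate``; read ids
    encode a serial number only, never the truth coordinates.
    """
    L = reference.length
    R = read_length
    if R > L:
        raise ValueError(f"read length {R} exceeds circle length {L}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    quals = Q30 * R
    reads: list[GloeRead] = []
    for i, nick in enumerate(nicks):
        p = nick.position % L
        if nick.strand == TOP:
            # window ending at p, read = its reverse complement (maps minus)
            bases = revcomp(reference.window(p - R + 1, R))
        elif nick.strand == BOTTOM:
            bases = reference.window(p, R)
        else:
            raise ValueError(f"unknown strand {nick.strand!r}")
        bases = _inject_errors(bases, error_rate, rng)
        reads.append(GloeRead(f"read_{i:06d}", bases, quals))
    return reads


# ---------------------------------------------------------------------------
# gel band-intensity tables


def simulate_band_table(
    fractions: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    control_lane: str | None = None,
    total_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Synthetic densitometry table for a plasmid nicking assay.

    Each lane is split between a supercoiled and a nicked band so that
    nicked/(supercoiled+nicked+linear) equals the lane's true fraction
    before noise; the linear band is zero.  Gaussian noise with standard
    deviation ``noise_sd`` (arbitrary units) is then added and clipped at
    zero.  Exactly one lane is flagged as the no-protein control
    (``control_lane``; defaults to the first lane).

    Returns a DataFrame with columns
    ``lane, supercoiled, nicked, linear, is_control``.
    """
    if not fractions:
        raise ValueError("at least one lane is required")
    lanes = list(fractions)
    for lane, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"lane {lane!r}: fraction {f} outside [0, 1]")
    if control_lane is None:
        control_lane = lanes[0]
    if control_lane not in fractions:
        raise ValueError(f"control lane {control_lane!r} not among lanes")
    rng = np.random.default_rng(seed)
    rows = []
    for lane in lanes:
        f = fractions[lane]
        nicked = f * total_intensity
        sc = (1.0 - f) * total_intensity
        linear = 0.0
        if noise_sd > 0:
            nicked, sc, linear = np.clip(
                np.array([nicked, sc, linear]) + rng.normal(0, noise_sd, 3), 0, None
            )
        rows.append(
            {
                "lane": lane,
                "supercoiled": sc,
                "nicked": nicked,
                "linear": linear,
                "is_control": lane == control_lane,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file I/O — FASTA / FASTQ / BED-like truth


def write_fasta(reference: CircularSequence, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(reference.sequence), id=reference.identifier, description="")
    SeqIO.write([rec], path, "fasta")


def read_fasta(path) -> CircularSequence:
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return CircularSequence(rec.id, str(rec.seq).upper())


def write_fastq(reads: Iterable[GloeRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.qualities}\n")


def read_fastq(path) -> list[GloeRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(GloeRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_truth_bed(
    nicks: Sequence[NickEvent], reference: CircularSequence, path
) -> None:
    """Ground-truth nicks as BED-like TSV (0-based half-open; + = top)."""
    counts: dict[NickEvent, int] = {}
    for n in nicks:
        counts[n] = counts.get(n, 0) + 1
    with open(path, "w") as fh:
        for (p, strand), c in sorted(counts.items()):
            bed_strand = "+" if strand == TOP else "-"
            fh.write(
                f"{reference.identifier}\t{p}\t{p + 1}\tnick\t{c}\t{bed_strand}\n"
            )
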