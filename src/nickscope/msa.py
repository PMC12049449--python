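"""Species-paired MSA construction for protein-complex interface modeling.

Coevolution-based structure predictors need, for a heterodimer, a single
alignment whose rows concatenate homologs of both chains *from the same
species*, so that inter-chain covariation is carried by genuinely
co-occurring sequence pairs.  This module implements the preprocessing
around that pairing for pre-aligned homolog sets:

1. per-hit identity/coverage statistics against the query;
2. threshold filtering (defaults: identity >= 25%, coverage >= 50%;
   boundary values are kept);
3. one-per-species selection keeping the highest-identity homolog
   (identity ties broken by lexicographically smallest hit id);
4. column delimitation of each chain alignment to a query-residue range;
5. row-wise concatenation where shared species are paired and
   species unique to one chain are padded with gaps in the other block.

Identity is computed over mutually aligned (both non-gap) columns;
coverage is the fraction of the query's residues aligned to a hit
residue.  Both denominators are conventions of this package — the
thresholds they feed are only meaningful together with them.

Homology search and realignment (e.g. mmseqs2, mafft) are out of scope:
inputs are aligned FASTA or A3M (lowercase insertion columns are dropped
on reading).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HomologHit",
    "ChainMSA",
    "PairedMSA",
    "pairwise_stats",
    "filter_homologs",
    "best_per_species",
    "delimit",
    "concat_paired",
    "species_from_header",
    "read_msa_fasta",
    "write_msa_fasta",
    "write_paired_a3m",
    "write_pairing_manifest",
    "read_hit_table",
    "write_hit_table",
]

GAP_CHARS = set("-.")


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


@dataclass(frozen=True)
class HomologHit:
    """One aligned homolog of a query chain.

    ``query_aln`` and ``hit_aln`` are the gapped query/hit rows of equal
    length; ``identity`` and ``coverage`` are filled from
    :func:`pairwise_stats` when not given.
    """

    hit_id: str
    species: str | None
    query_aln: str
    hit_aln: str
    identity: float = field(default=-1.0)
    coverage: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.hit_aln):
            raise ValueError(f"hit {self.hit_id!r}: gapped rows differ in length")
        if self.identity < 0 or self.coverage < 0:
            ident, cov = pairwise_stats(self.query_aln, self.hit_aln)
            object.__setattr__(self, "identity", ident)
            object.__setattr__(self, "coverage", cov)


def pairwise_stats(query_row: str, hit_row: str) -> tuple[float, float]:
    """(identity, coverage) of a gapped hit row against its gapped query row.

    identity = identical columns / columns where both rows are non-gap
    (0.0 when no column is mutually aligned); coverage = query residues
    aligned to a hit residue / total query residues.
    """
    if len(query_row) != len(hit_row):
        raise ValueError("gapped rows must have equal length")
    aligned = matched = covered = qlen = 0
    for q, h in zip(query_row.upper(), hit_row.upper()):
        qgap, hgap = _is_gap(q), _is_gap(h)
        if not qgap:
            qlen += 1
            if not hgap:
                covered += 1
        if not qgap and not hgap:
            aligned += 1
            if q == h:
                matched += 1
    if qlen == 0:
        raise ValueError("query row contains no residues")
    identity = matched / aligned if aligned else 0.0
    return identity, covered / qlen


def filter_homologs(
    hits: Iterable[HomologHit],
    min_identity: float = 0.25,
    min_coverage: float = 0.50,
) -> list[HomologHit]:
    """Keep hits with identity >= min_identity and coverage >= min_coverage.

    Hits exactly at a threshold are kept (the filter removes those *below*
    it).
    """
    return [
        h
        for h in hits
        if h.identity >= min_identity and h.coverage >= min_coverage
    ]


def best_per_species(hits: Sequence[HomologHit]) -> list[HomologHit]:
    """One hit per species: the highest identity, ties to smallest hit id.

    Hits without a species tag are passed through untouched (they can
    never pair anyway).  Output order follows first appearance of each
    species.
    """
    best: dict[str, HomologHit] = {}
    order: list[str] = []
    untagged: list[HomologHit] = []
    for h in hits:
        if h.species is None:
            untagged.append(h)
            continue
        cur = best.get(h.species)
        if cur is None:
            best[h.species] = h
            order.append(h.species)
        elif (h.identity, _neg_id(h.hit_id)) > (cur.identity, _neg_id(cur.hit_id)):
            best[h.species] = h
    return [best[s] for s in order] + untagged


class _neg_id(str):
    """Reverses string comparison so max() prefers the smallest hit id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class ChainMSA:
    """Alignment of one chain: query first, one row per homolog.

    ``rows`` are (species tag or None, aligned sequence) pairs, all of
    equal length; ``region`` is the 1-based inclusive query-residue range
    the columns cover after delimitation.
    """

    query_id: str
    rows: tuple[tuple[str | None, str], ...]
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("an MSA needs at least the query row")
        width = len(self.rows[0][1])
        for sp, seq in self.rows:
            if len(seq) != width:
                raise ValueError("all MSA rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def query_row(self) -> str:
        return self.rows[0][1]

    @property
    def query_length(self) -> int:
        return sum(1 for c in self.query_row if not _is_gap(c))

    def species(self) -> list[str | None]:
        return [sp for sp, _ in self.rows[1:]]


def delimit(msa: ChainMSA, start: int, end: int) -> ChainMSA:
    """Restrict to columns whose query residue index lies in [start, end].

    Indices are 1-based inclusive over the query's residues (gap columns
    in the query carry no residue index and are dropped with the region
    outside the bounds).  Row count is unchanged; homolog rows that become
    all-gap are retained.
    """
    qlen = msa.query_length
    if not 1 <= start <= end <= qlen:
        raise ValueError(
            f"bounds ({start}, {end}) invalid for query of {qlen} residues"
        )
    keep = []
    residue = 0
    for col, c in enumerate(msa.query_row):
        if _is_gap(c):
            continue
        residue += 1
        if start <= residue <= end:
            keep.append(col)
    rows = tuple(
        (sp, "".join(seq[c] for c in keep)) for sp, seq in msa.rows
    )
    return ChainMSA(msa.query_id, rows, region=(start, end))


@dataclass(frozen=True)
class PairedMSA:
    """Row-wise concatenation of two chain MSAs with species-aware pairing."""

    msa_a: ChainMSA
    msa_b: ChainMSA
    rows: tuple[tuple[str, str, bool], ...]  # (label, sequence, paired)
    n_paired: int
    n_unpaired_a: int
    n_unpaired_b: int

    @property
    def width(self) -> int:
        return self.msa_a.width + self.msa_b.width


def concat_paired(msa_a: ChainMSA, msa_b: ChainMSA) -> PairedMSA:
    """Concatenate two chain alignments, pairing rows of shared species.

    Both inputs must carry at most one row per species (run
    :func:`best_per_species` upstream).  The concatenated queries come
    first; each species present in both chains contributes one paired row
    (A block ++ B block); a species present in only one chain contributes
    a row whose partner block is all gaps.  Untagged homolog rows are kept
    unpaired.
    """
    for name, msa in (("A", msa_a), ("B", msa_b)):
        tags = [sp for sp in msa.species() if sp is not None]
        if len(tags) != len(set(tags)):
            raise ValueError(f"MSA {name} has several rows for one species")

    gap_a = "-" * msa_a.width
    gap_b = "-" * msa_b.width
    by_species_b = {sp: seq for sp, seq in msa_b.rows[1:] if sp is not None}

    rows: list[tuple[str, str, bool]] = [
        (
            f"{msa_a.query_id}+{msa_b.query_id}",
            msa_a.query_row + msa_b.query_row,
            True,
        )
    ]
    paired_species = set()
    n_paired = n_up_a = n_up_b = 0
    for sp, seq in msa_a.rows[1:]:
        if sp is not None and sp in by_species_b:
            rows.append((sp, seq + by_species_b[sp], True))
            paired_species.add(sp)
            n_paired += 1
        else:
            rows.append((sp or "unknown", seq + gap_b, False))
            n_up_a += 1
    for sp, seq in msa_b.rows[1:]:
        if sp is None or sp not in paired_species:
            rows.append((sp or "unknown", gap_a + seq, False))
            n_up_b += 1
    return PairedMSA(msa_a, msa_b, tuple(rows), n_paired, n_up_a, n_up_b)


# ---------------------------------------------------------------------------
# headers, hit tables and file formats

# taxon token grammar tried in order: "OX=<taxid>", "TaxID=<taxid>",
# then the UniProt-style mnemonic suffix of the first header token
# (e.g. "MLH1_HUMAN" -> "HUMAN").
_OX_RE = re.compile(r"\bOX=(\d+)")
_TAXID_RE = re.compile(r"\bTaxID=(\w+)", re.IGNORECASE)
_MNEMONIC_RE = re.compile(r"^\S*_([A-Z0-9]{2,10})$")


def species_from_header(header: str) -> str | None:
    """Extract a species tag from a FASTA/A3M header, or None."""
    m = _OX_RE.search(header) or _TAXID_RE.search(header)
    if m:
        return m.group(1)
    first = header.split()[0] if header.split() else ""
    m = _MNEMONIC_RE.match(first)
    if m:
        return m.group(1)
    return None


def read_msa_fasta(path, query_id: str | None = None) -> ChainMSA:
    """Read an aligned FASTA or A3M file into a ChainMSA.

    Lowercase characters (A3M insertion states) are removed, reducing the
    file to query-column space.  The first record is taken as the query
    unless ``query_id`` names another record to promote.  Species tags are
    parsed from headers via :func:`species_from_header`; the query row
    keeps tag None.
    """
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line and not line.startswith("#"):
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise ValueError(f"no sequences in {path}")

    def strip_insertions(seq: str) -> str:
        return "".join(c for c in seq if not c.islower())

    records = [(h, strip_insertions(s)) for h, s in records]
    if query_id is not None:
        idx = next(
            (i for i, (h, _) in enumerate(records) if h.split()[0] == query_id), 0
        )
        records.insert(0, records.pop(idx))
    qheader, qseq = records[0]
    rows: list[tuple[str | None, str]] = [(None, qseq)]
    rows += [(species_from_header(h), s) for h, s in records[1:]]
    return ChainMSA(qheader.split()[0], tuple(rows))


def write_msa_fasta(msa: ChainMSA, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{msa.query_id}\n{msa.query_row}\n")
        for i, (sp, seq) in enumerate(msa.rows[1:]):
            tag = f" TaxID={sp}" if sp else ""
            fh.write(f">hit_{i:04d}{tag}\n{seq}\n")


def write_paired_a3m(paired: PairedMSA, path) -> None:
    """Paired alignment as A3M/aligned-FASTA (match states only)."""
    with open(path, "w") as fh:
        for label, seq, flag in paired.rows:
            fh.write(f">{label} paired={'yes' if flag else 'no'}\n{seq}\n")


def write_pairing_manifest(paired: PairedMSA, path) -> None:
    pd.DataFrame(
        [(label, flag) for label, _, flag in paired.rows[1:]],
        columns=["species", "paired"],
    ).to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> pd.DataFrame:
    """Hit table TSV: id, species, identity, coverage."""
    return pd.read_csv(path, sep="\t")


def write_hit_table(hits: Sequence[HomologHit], path) -> None:
    pd.DataFrame(
        [(h.hit_id, h.species or "", h.identity, h.coverage) for h in hits],
        columns=["id", "species", "identity", "coverage"],
    ).to_csv(path, sep="\t", index=False)
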