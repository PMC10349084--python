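"""Protein sequence records, FASTA I/O, pairwise identity and active-site
cysteine context detection.

The DMSP lyase (Alma1 family) carries two catalytic cysteines whose
four-residue neighbourhoods are diagnostic: an N-terminal ``[D/N]CGF`` site
and a downstream ``ECT[E/Q]`` site (C108 and C265 in the *E. huxleyi*
enzyme).  This module locates those contexts in ungapped sequences and
decides whether a sequence carries the canonical pair in the expected order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X", "-"}

N_SITE_PATTERN = re.compile(r"(?=([DN]CGF))")
C_SITE_PATTERN = re.compile(r"(?=(ECT[EQ]))")


class SequenceError(ValueError):
    """Invalid sequence content or inconsistent alignment shape."""


class EmptyInputError(SequenceError):
    """An input file or collection contained no records."""


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with optional taxon metadata.

    ``residues`` is over the 20 standard amino acids plus ``X`` (unknown)
    and, for aligned records, ``-`` (gap).
    """

    id: str
    residues: str
    description: str = ""
    taxon: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be nonempty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: residues must be nonempty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _VALID
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def without_gaps(self) -> "ProteinRecord":
        return ProteinRecord(self.id, self.ungapped, self.description, self.taxon)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple alignment: records of equal aligned length."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SequenceError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SequenceError(f"unequal aligned lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


class Site(Enum):
    N_SITE = "N_SITE"
    C_SITE = "C_SITE"


@dataclass(frozen=True)
class CysteineContextHit:
    """One occurrence of a canonical cysteine context.

    ``c_position`` is the 1-based index of the cysteine itself in the
    ungapped sequence; the cysteine sits at the second position of the
    4-residue ``context`` window.
    """

    site: Site
    c_position: int
    context: str


_TAXON_RE = re.compile(r"taxon=(\S+)")


def _parse_taxon(description: str) -> str:
    m = _TAXON_RE.search(description)
    return m.group(1) if m else "unknown"


def read_fasta(path: str | Path, aligned: bool = False) -> list[ProteinRecord] | Alignment:
    """Read FASTA into records (or an :class:`Alignment` if ``aligned``).

    Ids are taken from the header up to the first whitespace; a
    ``taxon=<label>`` token in the description sets the taxon.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            ProteinRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=desc,
                taxon=_parse_taxon(desc),
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    if aligned:
        return Alignment(records)
    for r in records:
        if "-" in r.residues:
            raise SequenceError(
                f"record {r.id!r} contains gaps; pass aligned=True for alignments"
            )
    return records


def write_fasta(records: Iterable[ProteinRecord] | Alignment, path: str | Path) -> None:
    recs = records.records if isinstance(records, Alignment) else list(records)
    seqio_recs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in recs
    ]
    SeqIO.write(seqio_recs, str(path), "fasta")


def pairwise_identity(
    a: ProteinRecord, b: ProteinRecord, scope: str = "aligned_columns"
) -> float:
    """Percent identity between two aligned sequences, in [0, 100].

    ``aligned_columns``: matches / columns where at least one member has a
    residue (columns gapped in both are ignored).  ``shorter_sequence``:
    the denominator is the shorter ungapped length.  ``X`` never matches,
    not even another ``X``.
    """
    if len(a) != len(b):
        raise SequenceError("sequences must be aligned to equal length")
    if scope not in ("aligned_columns", "shorter_sequence"):
        raise ValueError(f"unknown scope {scope!r}")
    matches = 0
    scored = 0
    for x, y in zip(a.residues, b.residues):
        if x == "-" and y == "-":
            continue
        scored += 1
        if x == y and x not in ("-", "X"):
            matches += 1
    if scope == "shorter_sequence":
        scored = min(len(a.ungapped), len(b.ungapped))
    if scored == 0:
        return 0.0
    return 100.0 * matches / scored


def find_cysteine_contexts(rec: ProteinRecord) -> list[CysteineContextHit]:
    """All canonical cysteine contexts in an ungapped sequence, sorted by
    position; overlapping occurrences are all reported."""
    seq = rec.residues
    if "-" in seq:
        raise SequenceError("remove gaps before context scanning")
    hits: list[CysteineContextHit] = []
    for m in N_SITE_PATTERN.finditer(seq):
        hits.append(CysteineContextHit(Site.N_SITE, m.start() + 2, m.group(1)))
    for m in C_SITE_PATTERN.finditer(seq):
        hits.append(CysteineContextHit(Site.C_SITE, m.start() + 2, m.group(1)))
    hits.sort(key=lambda h: (h.c_position, h.site.value))
    return hits


def has_canonical_pair(
    hits: Sequence[CysteineContextHit], require_order: bool = True
) -> bool:
    """True iff the sequence carries both canonical sites.

    With ``require_order`` (default) some C-site must lie strictly
    downstream of some N-site, mirroring the C108 < C265 arrangement of the
    reference enzyme.
    """
    n_positions = [h.c_position for h in hits if h.site is Site.N_SITE]
    c_positions = [h.c_position for h in hits if h.site is Site.C_SITE]
    if not n_positions or not c_positions:
        return False
    if not require_order:
        return True
    return max(c_positions) > min(n_positions)
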