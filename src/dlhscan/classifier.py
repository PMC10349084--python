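"""Putative DMSP-lyase homolog (DLH) classification.

A candidate protein is called a DLH when three independent lines of
evidence agree, mirroring the published decision rule:

* a hit to a racemase-family domain profile (a position-specific scoring
  stand-in for the Asp/Glu/Hydantoin racemase superfamily, CDD cl00518),
* the canonical active-site cysteine pair ([D/N]CGF upstream, ECT[E/Q]
  downstream),
* matches to at least ``min_motifs`` of the diagnostic sequence motifs.

Domain duplication (two or more non-overlapping profile hits) is flagged,
as it is a notable feature of this family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import (
    AA_INDEX,
    MotifModel,
    _log_odds,
    _pad,
    _window_scores,
    scan_motifs,
)
from .seq_core import (
    AMINO_ACIDS,
    Alignment,
    CysteineContextHit,
    ProteinRecord,
    find_cysteine_contexts,
    has_canonical_pair,
)


class ClassifierError(ValueError):
    pass


@dataclass
class DomainProfile:
    """Ungapped position-specific scoring profile for the racemase domain.

    ``threshold`` is calibrated so that a configurable fraction ``fpr`` of
    unrelated decoy sequences score above it; ``gap_penalty`` (bits per
    skipped profile column) applies only when a query is shorter than the
    profile.
    """

    name: str
    length: int
    log_odds: np.ndarray  # (length, 20)
    gap_penalty: float
    threshold: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.length < 50:
            raise ClassifierError("profile length must be >= 50")
        if self.log_odds.shape != (self.length, 20):
            raise ClassifierError("log_odds must be length x 20")

    def log_odds_extended(self) -> np.ndarray:
        return np.hstack([self.log_odds, np.zeros((self.length, 1))])

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    start: int  # 1-based inclusive, ungapped coordinates
    end: int
    score: float


@dataclass
class ClassificationResult:
    record_id: str
    is_dlh: bool
    domain_hits: list[DomainHit]
    cys_hits: list[CysteineContextHit]
    motif_ids_matched: set[int]
    duplication: bool

    @property
    def n_motifs_matched(self) -> int:
        return len(self.motif_ids_matched)


def build_domain_profile(
    seed_alignment: Alignment,
    decoy_set: Sequence[ProteinRecord],
    gap_penalty: float = -2.0,
    fpr: float = 0.01,
    name: str = "Asp/Glu/Hydantoin racemase, cl00518 stand-in",
) -> DomainProfile:
    """Build a profile from a seed alignment and calibrate its threshold on
    decoys.

    Profile columns are the alignment columns with >= 50% residue occupancy;
    per-column log-odds use gap-excluded counts with pseudocount 0.1 over a
    uniform background.  The threshold is the (1 - fpr) quantile of
    best-hit scores over ``decoy_set``, so at most ~fpr of unrelated
    sequences exceed it.
    """
    if len(seed_alignment) < 5:
        raise ClassifierError("seed alignment needs at least 5 sequences")
    if not decoy_set:
        raise ClassifierError("decoy_set must be nonempty")
    n = len(seed_alignment)
    kept_counts = []
    for j in range(seed_alignment.length):
        col = seed_alignment.column(j)
        residues = [c for c in col if c not in ("-", "X")]
        if len(residues) < 0.5 * n:
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[AA_INDEX[c]] += 1
        kept_counts.append(counts)
    if not kept_counts:
        raise ClassifierError("no alignment column reaches 50% occupancy")
    counts = np.vstack(kept_counts)
    log_odds = _log_odds(counts, np.full(20, 1 / 20))
    profile = DomainProfile(
        name=name,
        length=counts.shape[0],
        log_odds=log_odds,
        gap_penalty=gap_penalty,
        threshold=-np.inf,
    )
    decoy_scores = np.array([_best_domain_score(r, profile) for r in decoy_set])
    # floor at 0 bits: a hit must at least beat the background model, even
    # when the decoy quantile sits far below it
    profile.threshold = max(
        float(np.quantile(decoy_scores, 1 - fpr, method="higher")), 0.0
    )
    return profile


def _raw_window_scores(rec: ProteinRecord, profile: DomainProfile) -> np.ndarray:
    seq = rec.ungapped
    mat, lengths = _pad([seq])
    return _window_scores(mat, lengths, profile.log_odds_extended())[0]


def _best_domain_score(rec: ProteinRecord, profile: DomainProfile) -> float:
    seq = rec.ungapped
    if len(seq) >= profile.length:
        return float(_raw_window_scores(rec, profile).max())
    # query shorter than profile: best contiguous placement, uncovered
    # profile columns pay the gap penalty
    enc = np.array([AA_INDEX.get(c, 20) for c in seq])
    lo = profile.log_odds_extended()
    best = -np.inf
    uncovered = profile.length - len(seq)
    for off in range(uncovered + 1):
        s = float(lo[np.arange(len(seq)) + off, enc].sum())
        best = max(best, s + profile.gap_penalty * uncovered)
    return best


def scan_domain(rec: ProteinRecord, profile: DomainProfile) -> list[DomainHit]:
    """Above-threshold profile placements, merged so overlapping hits keep
    only the higher-scoring one; coordinates are 1-based inclusive."""
    seq = rec.ungapped
    if len(seq) < profile.length:
        score = _best_domain_score(rec, profile)
        if score >= profile.threshold:
            return [DomainHit(1, len(seq), score)]
        return []
    scores = _raw_window_scores(rec, profile)
    above = np.nonzero(scores >= profile.threshold)[0]
    if above.size == 0:
        return []
    order = above[np.argsort(-scores[above], kind="stable")]
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= profile.length for q in kept):
            kept.append(int(p))
    hits = [
        DomainHit(p + 1, p + profile.length, float(scores[p])) for p in sorted(kept)
    ]
    return hits


def classify_dlh(
    rec: ProteinRecord,
    profile: DomainProfile,
    motifs: Sequence[MotifModel],
    min_motifs: int = 5,
    require_order: bool = True,
) -> ClassificationResult:
    """Combine domain, cysteine-pair and motif evidence into a verdict.

    All evidence is retained in the result regardless of the verdict, so a
    near-miss can be inspected.
    """
    clean = rec.without_gaps()
    domain_hits = scan_domain(clean, profile)
    cys_hits = find_cysteine_contexts(clean)
    motif_ids = {h.motif_id for h in scan_motifs(clean, motifs)}
    is_dlh = (
        len(domain_hits) >= 1
        and has_canonical_pair(cys_hits, require_order=require_order)
        and len(motif_ids) >= min_motifs
    )
    return ClassificationResult(
        record_id=rec.id,
        is_dlh=is_dlh,
        domain_hits=domain_hits,
        cys_hits=cys_hits,
        motif_ids_matched=motif_ids,
        duplication=len(domain_hits) >= 2,
    )


def classify_batch(
    records: Sequence[ProteinRecord],
    profile: DomainProfile,
    motifs: Sequence[MotifModel],
    min_motifs: int = 5,
    require_order: bool = True,
) -> tuple[list[ClassificationResult], dict]:
    """Classify a collection and summarize: input/DLH counts, counts per
    taxon among DLHs, and the domain-duplication fraction (None when no
    DLH was found, not 0)."""
    if not records:
        raise ClassifierError("empty record collection")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise ClassifierError(f"duplicate record ids: {dupes}")
    results = [
        classify_dlh(r, profile, motifs, min_motifs, require_order) for r in records
    ]
    dlh = [res for res in results if res.is_dlh]
    taxa = Counter(r.taxon for r, res in zip(records, results) if res.is_dlh)
    summary = {
        "n_input": len(records),
        "n_dlh": len(dlh),
        "per_taxon": dict(taxa),
        "duplication_fraction": (
            sum(res.duplication for res in dlh) / len(dlh) if dlh else None
        ),
    }
    return results, summary


# ---------------------------------------------------------------------------
# Profile I/O: plain TSV with commented header metadata.

def write_profile(profile: DomainProfile, path: str | Path) -> None:
    lines = [
        f"# name= {profile.name}",
        f"# gap_penalty= {profile.gap_penalty:.6f}",
        f"# threshold= {profile.threshold:.6f}",
        "pos\t" + "\t".join(AMINO_ACIDS),
    ]
    for j, row in enumerate(profile.log_odds, start=1):
        lines.append(f"{j}\t" + "\t".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> DomainProfile:
    name, gap_penalty, threshold = "profile", -2.0, 0.0
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# name="):
            name = line.split("=", 1)[1].strip()
        elif line.startswith("# gap_penalty="):
            gap_penalty = float(line.split("=", 1)[1])
        elif line.startswith("# threshold="):
            threshold = float(line.split("=", 1)[1])
        elif line and not line.startswith(("#", "pos\t")):
            rows.append([float(x) for x in line.split("\t")[1:]])
    log_odds = np.array(rows)
    return DomainProfile(
        name=name,
        length=log_odds.shape[0],
        log_odds=log_odds,
        gap_penalty=gap_penalty,
        threshold=threshold,
    )
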