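"""Discriminative amino-acid motif discovery, scanning and logo matrices.

Finds short ungapped motifs (widths 4–15) that separate a positive protein
family from a control family, the way the ten diagnostic DMSP-lyase motifs
separate eukaryotic lyase domains from bacterial racemases.  The algorithm
is a seeded, deterministic enumerate-and-refine scheme:

1. positives and controls are split into train/hold-out halves by a seeded
   shuffle;
2. every w-mer present in at least ``min_seed_frac`` of training positives
   is a seed;
3. each seed is refined into a PWM from its best match per training
   positive (zero-or-one occurrence per sequence), with pseudocount 0.1 and
   the background taken from pooled control residue frequencies;
4. the match threshold maximizes training-set discrimination (true-positive
   rate minus false-positive rate over per-sequence best scores);
5. significance is a one-sided Fisher exact test on the hold-out halves
   (sequences with/without a match, positives vs. controls), Bonferroni
   scaled by the number of seeds tested — an E-value;
6. the best motif is accepted if its E-value passes ``alpha``, its
   occurrences are masked with ``X`` in all positives, and the search
   repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .seq_core import AMINO_ACIDS, ProteinRecord

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_X = 20  # index for unknown residue; scores 0 against any column

PSEUDOCOUNT = 0.1


class MotifError(ValueError):
    """Invalid motif parameters or inputs."""


@dataclass
class MotifModel:
    """A width-w position weight matrix with a calibrated match threshold.

    ``counts`` rows hold the contributing sites; ``log_odds`` is
    log2(position frequency / background frequency) with pseudocount
    :data:`PSEUDOCOUNT`.  ``significance`` is an E-value-like score (Fisher
    hold-out p times the number of seeds tested); banks built directly from
    consensus strings carry the uninformative default 1.0.
    """

    id: int
    width: int
    counts: np.ndarray  # (w, 20)
    log_odds: np.ndarray  # (w, 20)
    significance: float
    consensus: str
    threshold: float
    background: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.counts.shape != (self.width, 20):
            raise MotifError("counts must be width x 20")
        if self.log_odds.shape != (self.width, 20):
            raise MotifError("log_odds must be width x 20")
        if not self.significance > 0:
            raise MotifError("significance must be positive")

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def log_odds_extended(self) -> np.ndarray:
        """(w, 21) log-odds with a zero column for unknown residues."""
        return np.hstack([self.log_odds, np.zeros((self.width, 1))])


@dataclass(frozen=True)
class MotifHit:
    motif_id: int
    position: int  # 1-based start in the ungapped sequence
    score: float


def encode(seq: str) -> np.ndarray:
    """Encode residues as integers 0..19, with X (or any non-standard
    letter) as 20."""
    return np.fromiter((AA_INDEX.get(c, _X) for c in seq), dtype=np.int64, count=len(seq))


def _pad(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded sequences into one padded matrix (pad index = X)."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.full((len(seqs), int(lengths.max(initial=1))), _X, dtype=np.int64)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    return mat, lengths


def _window_scores(mat: np.ndarray, lengths: np.ndarray, lo_ext: np.ndarray) -> np.ndarray:
    """Score every width-w window of every row; windows running past a
    sequence end score -inf."""
    w = lo_ext.shape[0]
    n, L = mat.shape
    n_win = L - w + 1
    if n_win <= 0:
        return np.full((n, 0), -np.inf)
    scores = np.zeros((n, n_win))
    for j in range(w):
        scores += lo_ext[j, mat[:, j : j + n_win]]
    pos = np.arange(n_win)[None, :]
    scores[pos > (lengths - w)[:, None]] = -np.inf
    return scores


def _best_scores(mat, lengths, lo_ext) -> tuple[np.ndarray, np.ndarray]:
    scores = _window_scores(mat, lengths, lo_ext)
    if scores.shape[1] == 0:
        n = mat.shape[0]
        return np.full(n, -np.inf), np.full(n, -1, dtype=np.int64)
    return scores.max(axis=1), scores.argmax(axis=1)


def background_frequencies(records: Iterable[ProteinRecord] | Sequence[str]) -> np.ndarray:
    """Pooled residue frequencies over a set of sequences, lightly
    regularized so every residue has positive probability."""
    counts = np.full(20, PSEUDOCOUNT)
    for rec in records:
        seq = rec.ungapped if isinstance(rec, ProteinRecord) else seq_str(rec)
        for c in seq:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def seq_str(s: str) -> str:
    return s.replace("-", "")


def motif_significance(
    k_pos: int, n_pos: int, k_neg: int, n_neg: int, n_tested: int
) -> float:
    """E-value: one-sided Fisher exact p for enrichment of matching
    sequences among positives, Bonferroni-scaled by ``n_tested``."""
    if not (0 <= k_pos <= n_pos and 0 <= k_neg <= n_neg):
        raise MotifError("counts must satisfy 0 <= k <= n")
    if n_tested < 1:
        raise MotifError("n_tested must be >= 1")
    table = [[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]]
    p = stats.fisher_exact(table, alternative="greater")[1]
    p = max(float(p), np.finfo(float).tiny)
    return p * n_tested


def _pwm_from_sites(sites: Sequence[str], width: int) -> np.ndarray:
    counts = np.zeros((width, 20))
    for site in sites:
        for j, c in enumerate(site):
            i = AA_INDEX.get(c)
            if i is not None:
                counts[j, i] += 1
    return counts


def _log_odds(counts: np.ndarray, background: np.ndarray) -> np.ndarray:
    padded = counts + PSEUDOCOUNT
    freqs = padded / padded.sum(axis=1, keepdims=True)
    return np.log2(freqs / background[None, :])


def _consensus(counts: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in counts.argmax(axis=1))


def _discrimination_threshold(pos_best: np.ndarray, ctrl_best: np.ndarray) -> float:
    """Threshold maximizing TPR - FPR over per-sequence best scores.

    The largest threshold whose objective lies within one sequence's worth
    of the maximum is returned, so a single noisy training sequence cannot
    drag the threshold deep into the background score range.
    """
    candidates = np.unique(np.concatenate([pos_best, ctrl_best]))
    candidates = candidates[np.isfinite(candidates)]
    if candidates.size == 0:
        return np.inf
    objs = np.array([
        float(np.mean(pos_best >= t)) - float(np.mean(ctrl_best >= t))
        for t in candidates
    ])
    tol = 1.0 / min(len(pos_best), len(ctrl_best))
    ok = objs >= objs.max() - tol
    return float(candidates[ok].max())


def _enumerate_seeds(
    train_pos: Sequence[str], width: int, min_seed_frac: float
) -> dict[str, int]:
    """All w-mers (no X, no gap) present in at least ``min_seed_frac`` of
    the training positives, with their sequence presence counts."""
    presence: dict[str, int] = {}
    for seq in train_pos:
        seen = set()
        for p in range(len(seq) - width + 1):
            kmer = seq[p : p + width]
            if "X" in kmer or "-" in kmer:
                continue
            seen.add(kmer)
        for kmer in seen:
            presence[kmer] = presence.get(kmer, 0) + 1
    need = min_seed_frac * len(train_pos)
    return {k: c for k, c in sorted(presence.items()) if c >= need}


def discover_motifs(
    positives: Sequence[ProteinRecord],
    controls: Sequence[ProteinRecord],
    width_min: int = 4,
    width_max: int = 15,
    n_motifs: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    min_seed_frac: float = 0.2,
) -> list[MotifModel]:
    """Discover up to ``n_motifs`` discriminative motifs, ordered by
    significance (most significant first)."""
    if not positives or not controls:
        raise MotifError("positives and controls must be nonempty")
    if len(positives) < 5 or len(controls) < 5:
        raise MotifError("need at least 5 positives and 5 controls")
    if width_min > width_max:
        raise MotifError("width_min must be <= width_max")
    if width_min < 4 or width_max > 15:
        raise MotifError("widths must lie within [4, 15]")

    rng = np.random.default_rng(seed)
    pos_seqs = [r.ungapped for r in positives]
    ctrl_seqs = [r.ungapped for r in controls]
    pos_order = rng.permutation(len(pos_seqs))
    ctrl_order = rng.permutation(len(ctrl_seqs))
    n_pos_train = (len(pos_seqs) + 1) // 2
    n_ctrl_train = (len(ctrl_seqs) + 1) // 2
    pos_train_idx = pos_order[:n_pos_train]
    pos_hold_idx = pos_order[n_pos_train:]
    ctrl_train_idx = ctrl_order[:n_ctrl_train]
    ctrl_hold_idx = ctrl_order[n_ctrl_train:]

    background = background_frequencies(controls)
    masked = list(pos_seqs)  # masking applies to every positive

    ctrl_train = [ctrl_seqs[i] for i in ctrl_train_idx]
    ctrl_hold = [ctrl_seqs[i] for i in ctrl_hold_idx]
    ctrl_train_mat = _pad(ctrl_train)
    ctrl_hold_mat = _pad(ctrl_hold)

    accepted: list[MotifModel] = []
    while len(accepted) < n_motifs:
        train_pos = [masked[i] for i in pos_train_idx]
        hold_pos = [masked[i] for i in pos_hold_idx]
        pos_train_mat = _pad(train_pos)
        pos_hold_mat = _pad(hold_pos)

        seeds_by_width = {
            w: _enumerate_seeds(train_pos, w, min_seed_frac)
            for w in range(width_min, width_max + 1)
        }
        # keep only maximal seeds: when a superstring seed occurs in (nearly)
        # the same set of sequences, the substring carries no independent
        # evidence, and evaluating it lets sampling noise promote truncated
        # motifs; a substring with substantial occurrences of its own (a
        # shared core of two motifs, say) is kept, and masking re-exposes
        # independent sub-motifs on later iterations anyway
        all_counts = {
            s: c for seeds in seeds_by_width.values() for s, c in seeds.items()
        }
        for w in seeds_by_width:
            seeds_by_width[w] = [
                s
                for s, c in seeds_by_width[w].items()
                if not any(
                    s != t and s in t and ct >= 0.9 * c
                    for t, ct in all_counts.items()
                )
            ]
        n_tested = sum(len(s) for s in seeds_by_width.values())
        if n_tested == 0:
            break

        best = None  # (evalue, -k_pos_hold, consensus, model fields)
        for w, seeds in seeds_by_width.items():
            for kmer in seeds:
                seed_counts = _pwm_from_sites([kmer], w)
                lo0 = np.hstack([_log_odds(seed_counts, background), np.zeros((w, 1))])
                best0, best_pos = _best_scores(*pos_train_mat, lo0)
                # zero-or-one: a sequence contributes its best window only
                # when it scores at least half the seed's consensus score,
                # so motif-free sequences contribute nothing
                site_floor = 0.5 * float(lo0[:, :20].max(axis=1).sum())
                sites = [
                    s[p : p + w]
                    for s, p, sc in zip(train_pos, best_pos, best0)
                    if p >= 0 and sc >= site_floor
                ]
                if not sites:
                    continue
                counts = _pwm_from_sites(sites, w)
                lo = _log_odds(counts, background)
                lo_ext = np.hstack([lo, np.zeros((w, 1))])

                pos_best, _ = _best_scores(*pos_train_mat, lo_ext)
                ctl_best, _ = _best_scores(*ctrl_train_mat, lo_ext)
                threshold = _discrimination_threshold(pos_best, ctl_best)

                k_pos = int(np.sum(_best_scores(*pos_hold_mat, lo_ext)[0] >= threshold))
                k_neg = int(np.sum(_best_scores(*ctrl_hold_mat, lo_ext)[0] >= threshold))
                evalue = motif_significance(
                    k_pos, len(hold_pos), k_neg, len(ctrl_hold), n_tested
                )
                # ties: more hold-out positives, then the wider (more
                # informative) motif, then lexicographic consensus
                key = (evalue, -k_pos, -w, _consensus(counts))
                if best is None or key < best[0]:
                    best = (key, w, counts, lo, threshold, evalue)

        key, w, counts, lo, threshold, evalue = best
        if evalue >= alpha:
            break
        model = MotifModel(
            id=len(accepted) + 1,
            width=w,
            counts=counts,
            log_odds=lo,
            significance=evalue,
            consensus=_consensus(counts),
            threshold=threshold,
            background=background,
        )
        accepted.append(model)

        # mask every above-threshold occurrence in all positives with X
        lo_ext = model.log_odds_extended()
        mat, lengths = _pad(masked)
        scores = _window_scores(mat, lengths, lo_ext)
        for i, seq in enumerate(masked):
            hit_pos = np.nonzero(scores[i] >= threshold)[0] if scores.shape[1] else []
            if len(hit_pos):
                chars = list(seq)
                for p in hit_pos:
                    chars[p : p + w] = "X" * w
                masked[i] = "".join(chars)

    accepted.sort(key=lambda m: (m.significance, m.id))
    for rank, m in enumerate(accepted, start=1):
        m.id = rank
    return accepted


def scan_motifs(rec: ProteinRecord, motifs: Sequence[MotifModel]) -> list[MotifHit]:
    """Every window of ``rec`` scoring at or above a motif's threshold.

    Unknown residues (X) contribute the background log-odds of zero.
    """
    seq = rec.ungapped
    hits: list[MotifHit] = []
    if not seq:
        return hits
    mat, lengths = _pad([seq])
    for m in motifs:
        scores = _window_scores(mat, lengths, m.log_odds_extended())
        if scores.shape[1] == 0:
            continue
        for p in np.nonzero(scores[0] >= m.threshold)[0]:
            hits.append(MotifHit(m.id, int(p) + 1, float(scores[0, p])))
    hits.sort(key=lambda h: (h.position, h.motif_id))
    return hits


def logo_matrix(motif: MotifModel) -> np.ndarray:
    """Per-position letter heights in bits: height = frequency x IC, where
    IC = log2(20) - H(column) with no small-sample correction."""
    row_sums = motif.counts.sum(axis=1)
    if np.any(row_sums <= 0):
        raise MotifError("every counts row must be nonzero")
    freqs = motif.counts / row_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(20) - entropy
    return freqs * ic[:, None]


def bank_from_consensus(
    consensus_list: Sequence[str],
    background: np.ndarray | None = None,
    site_weight: float = 9.0,
    threshold_frac: float = 0.75,
) -> list[MotifModel]:
    """Build a motif bank directly from consensus strings (e.g. a truth
    manifest or a published motif table), one motif per string.

    The match threshold is ``threshold_frac`` of the consensus score, so an
    exact consensus occurrence always matches while random windows do not.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    models = []
    for i, cons in enumerate(consensus_list, start=1):
        w = len(cons)
        if not 4 <= w <= 15:
            raise MotifError(f"consensus {cons!r}: width must be in [4, 15]")
        counts = _pwm_from_sites([cons], w) * site_weight
        lo = _log_odds(counts, background)
        threshold = threshold_frac * float(lo.max(axis=1).sum())
        models.append(
            MotifModel(
                id=i,
                width=w,
                counts=counts,
                log_odds=lo,
                significance=1.0,
                consensus=cons,
                threshold=threshold,
                background=background,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Motif bank I/O: a MEME-like minimal plain-text format.

def write_motif_bank(motifs: Sequence[MotifModel], path: str | Path) -> None:
    lines = ["MEME version 4 (minimal, dlhscan dialect)", ""]
    lines += [f"ALPHABET= {AMINO_ACIDS}", ""]
    bg = motifs[0].background if motifs else np.full(20, 1 / 20)
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{a} {f:.6f}" for a, f in zip(AMINO_ACIDS, bg)))
    lines.append("")
    for m in motifs:
        nsites = m.counts.sum(axis=1).max()
        lines.append(f"MOTIF {m.id} {m.consensus}")
        lines.append(
            f"letter-probability matrix: alength= 20 w= {m.width} "
            f"nsites= {nsites:.2f} E= {m.significance:.6g}"
        )
        freqs = m.counts / np.maximum(m.counts.sum(axis=1, keepdims=True), 1e-12)
        for row in freqs:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append(f"threshold= {m.threshold:.6f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_motif_bank(path: str | Path) -> list[MotifModel]:
    text = Path(path).read_text().splitlines()
    bg = np.full(20, 1 / 20)
    motifs: list[MotifModel] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = text[i + 1].split()
            bg = np.array([float(parts[j * 2 + 1]) for j in range(20)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            fields = line.split()
            motif_id = int(fields[1])
            consensus = fields[2] if len(fields) > 2 else ""
            header = text[i + 1]
            tokens = header.replace("=", "= ").split()
            w = int(tokens[tokens.index("w=") + 1])
            nsites = float(tokens[tokens.index("nsites=") + 1])
            evalue = float(tokens[tokens.index("E=") + 1])
            freqs = np.array(
                [[float(x) for x in text[i + 2 + j].split()] for j in range(w)]
            )
            thr_line = text[i + 2 + w].strip()
            threshold = float(thr_line.split("=")[1])
            counts = freqs * nsites
            motifs.append(
                MotifModel(
                    id=motif_id,
                    width=w,
                    counts=counts,
                    log_odds=_log_odds(counts, bg),
                    significance=max(evalue, np.finfo(float).tiny),
                    consensus=consensus or _consensus(counts),
                    threshold=threshold,
                    background=bg,
                )
            )
            i += 3 + w
            continue
        i += 1
    return motifs


def write_logo_tsv(motif: MotifModel, path: str | Path) -> None:
    """Export the letter-height matrix as TSV (positions x residues)."""
    heights = logo_matrix(motif)
    lines = ["pos\t" + "\t".join(AMINO_ACIDS)]
    for j, row in enumerate(heights, start=1):
        lines.append(f"{j}\t" + "\t".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
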