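"""Domain trimming, alignment column filtering, protein distances,
Neighbor-Joining trees and bootstrap support.

The tree pipeline mirrors common practice for divergent protein families:
sequences are cut to the conserved domain, sparse alignment columns
(fewer than ``min_occupancy`` residues) are dropped, pairwise distances are
computed under a selectable model (p-distance, Poisson correction, or the
Kimura protein correction d = -ln(1 - p - 0.2 p^2)), and an unrooted
Saitou–Nei Neighbor-Joining tree is built with column-resampling bootstrap
support.  Trees are scikit-bio ``TreeNode`` objects and serialize to
Newick with integer support values as internal node labels.
"""

from __future__ import annotations

import io
import logging
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .classifier import DomainHit
from .seq_core import Alignment, ProteinRecord, SequenceError

logger = logging.getLogger(__name__)

DISTANCE_MODELS = ("p_distance", "poisson", "kimura_protein")


class PhylogenyError(ValueError):
    pass


def extract_domain_region(rec: ProteinRecord, hit: DomainHit) -> ProteinRecord:
    """Cut an ungapped record to a domain hit (1-based inclusive); the id
    is suffixed with the coordinates so duplicated domains stay distinct."""
    seq = rec.ungapped
    if not (1 <= hit.start <= hit.end <= len(seq)):
        raise PhylogenyError(
            f"hit {hit.start}-{hit.end} outside sequence {rec.id!r} (len {len(seq)})"
        )
    return ProteinRecord(
        id=f"{rec.id}/{hit.start}-{hit.end}",
        residues=seq[hit.start - 1 : hit.end],
        description=rec.description,
        taxon=rec.taxon,
    )


def filter_columns(aln: Alignment, min_occupancy: int = 10) -> Alignment:
    """Keep exactly the columns with at least ``min_occupancy`` non-gap
    residues; row order is unchanged."""
    keep = [
        j
        for j in range(aln.length)
        if sum(c != "-" for c in aln.column(j)) >= min_occupancy
    ]
    if not keep:
        raise PhylogenyError("no column satisfies the occupancy threshold")
    records = [
        ProteinRecord(
            id=r.id,
            residues="".join(r.residues[j] for j in keep),
            description=r.description,
            taxon=r.taxon,
        )
        for r in aln.records
    ]
    return Alignment(records)


def distance_matrix(
    aln: Alignment, model: str = "kimura_protein", max_distance: float = 10.0
) -> DistanceMatrix:
    """Pairwise distances with pairwise gap exclusion.

    p = mismatches / scored columns over columns where both sequences have
    a residue; X matches nothing.  Saturated pairs (log argument <= 0) are
    capped at ``max_distance``.
    """
    if model not in DISTANCE_MODELS:
        raise PhylogenyError(f"unknown model {model!r}")
    if len(aln) < 3:
        raise PhylogenyError("need at least 3 sequences")
    n = len(aln)
    rows = [r.residues for r in aln.records]
    labels = [r.id for r in aln.records]
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(n, aln.length)
    gap = arr == b"-"
    unknown = arr == b"X"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scored = ~(gap[i] | gap[j])
            n_scored = int(scored.sum())
            if n_scored == 0:
                raise PhylogenyError(
                    f"no shared residue columns for pair ({labels[i]!r}, {labels[j]!r})"
                )
            match = scored & (arr[i] == arr[j]) & ~unknown[i]
            p = 1.0 - match.sum() / n_scored
            d[i, j] = d[j, i] = _corrected_distance(p, model, max_distance)
    return DistanceMatrix(d, ids=labels)


def _corrected_distance(p: float, model: str, max_distance: float) -> float:
    if model == "p_distance":
        return min(p, max_distance)
    arg = 1.0 - p if model == "poisson" else 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return max_distance
    return min(-np.log(arg), max_distance)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei Neighbor-Joining.

    At each step the pair minimizing the Q criterion is joined (ties broken
    by smallest (i, j) in current label order); negative branch lengths are
    clamped to zero with the deficit transferred to the sister branch.
    Returns an unrooted tree (trifurcating root) over ``dm``'s ids.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-9):
        raise PhylogenyError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.ids]
    if len(nodes) < 3:
        raise PhylogenyError("need at least 3 taxa")
    d = d.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # row-major: smallest (i, j)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        du = np.maximum(np.delete(du, [i, j]), 0.0)
        d = np.delete(np.delete(d, [i, j], axis=0), [i, j], axis=1)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = du
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = dab - la
    lc = dac - la
    la, lb = _clamp_pair(la, lb)
    lc = max(lc, 0.0)
    root = TreeNode()
    a.length, b.length, c.length = la, lb, lc
    root.extend([a, b, c])
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        y += x
        x = 0.0
    if y < 0:
        x += y
        y = 0.0
    return max(x, 0.0), max(y, 0.0)


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf names (the
    side not containing the lexicographically smallest leaf)."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(frozenset(side))
    return parts


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = 1000,
    model: str = "kimura_protein",
    seed: int = 0,
    max_distance: float = 10.0,
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap support.

    Columns are resampled with replacement per replicate; each internal
    edge of the full-data tree gets the percentage of successful replicates
    whose NJ tree contains the same bipartition (as an integer node label).
    Replicates with degenerate distances are skipped with a warning and do
    not count toward the denominator.
    """
    if n_replicates < 1:
        raise PhylogenyError("n_replicates must be >= 1")
    full_tree = neighbor_joining(distance_matrix(aln, model, max_distance))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {p: 0 for p in tree_bipartitions(full_tree)}
    n_ok = 0
    n_skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        records = [
            ProteinRecord(
                id=r.id,
                residues="".join(r.residues[j] for j in cols),
                taxon=r.taxon,
            )
            for r in aln.records
        ]
        try:
            rep_tree = neighbor_joining(
                distance_matrix(Alignment(records), model, max_distance)
            )
        except PhylogenyError as exc:
            n_skipped += 1
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        n_ok += 1
        rep_parts = tree_bipartitions(rep_tree)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    if n_ok == 0:
        raise PhylogenyError("all bootstrap replicates degenerate")
    leaves = {t.name for t in full_tree.tips()}
    ref = min(leaves)
    for node in full_tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = leaves - side
        if frozenset(side) in counts:
            node.name = str(int(round(100 * counts[frozenset(side)] / n_ok)))
    return full_tree


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    try:
        return TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises format-specific errors
        raise PhylogenyError(f"newick parse error: {exc}") from exc


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    lines = ["\t" + "\t".join(dm.ids)]
    for label, row in zip(dm.ids, dm.data):
        lines.append(label + "\t" + "\t".join(f"{x:.6f}" for x in row))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
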