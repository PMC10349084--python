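"""Synthetic data with known ground truth for every pipeline stage.

Real inputs to this kind of survey are external databases (culture
transcriptomes, genome portals, ocean metatranscriptome atlases).  This
module emulates their relevant structure offline:

* positive proteins carrying a racemase-like domain, both canonical
  cysteine contexts inside it, and a set of planted motifs at configurable
  penetrance; bacterial-style decoys carrying the (noised) domain but no
  canonical contexts;
* protein families evolved along a known tree, for phylogeny tests;
* station x depth abundance/expression tables with a Gaussian-copula link
  between a taxon's abundance and an environmental variable at a target
  Spearman correlation, and negative-binomial counts with planted
  euphotic/mesopelagic fold changes.

Every generator is a pure function of its seed, and each returns a truth
manifest sufficient to score recall and precision of the consuming stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .ecology import AbundanceTable
from .seq_core import AMINO_ACIDS, Alignment, ProteinRecord

# Typical amino-acid composition used for backbones, flanks and decoys.
BACKGROUND_FREQS = np.array(
    [0.083083, 0.014014, 0.055055, 0.067067, 0.039039, 0.071071, 0.023023,
     0.059059, 0.058058, 0.097097, 0.024024, 0.040040, 0.047047, 0.039039,
     0.055055, 0.066066, 0.053053, 0.069069, 0.011011, 0.029029]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

# Fixed 120-residue consensus standing in for the racemase-domain core.
DEFAULT_DOMAIN_CONSENSUS = (
    "VDTVIAYVPIFLALDLLSDKPADKVGVGCKTTVVLEEGELQVPDWVDGEHALYGEWIFIELTIRVGTKAFDD"
    "LYHMFRALKTDVNPKYVRAAALIDYEGHSLKINSIFACRSGAYTKANR"
)

# Default ten-motif bank (widths 4-15), free of the cysteine context
# patterns so motif and context evidence stay independent.
DEFAULT_MOTIFS = (
    "QEPV", "MDQQR", "FRGEPR", "KFALIKY", "KSKAKLGK", "GGVKSQLDF",
    "LSSAAIITEL", "MVDVISGKALL", "EHIVNKEMLPED", "LFTWADPCLESQLAA",
)

N_CONTEXTS = ("DCGF", "NCGF")
C_CONTEXTS = ("ECTE", "ECTQ")
_AA = np.array(list(AMINO_ACIDS))


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Study conditions for the protein-set generator.

    ``context_spacing`` is the (min, max) gap between the N-site and
    C-site cysteines inside the domain; ``domain_noise`` is the per-site
    substitution probability applied to each planted domain copy;
    ``duplication_fraction`` of positives receive a second domain copy.
    """

    seed: int = 0
    n_pos: int = 100
    n_neg: int = 1000
    sequence_length: int = 400
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS
    motif_penetrance: float = 1.0
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS
    context_spacing: tuple[int, int] = (60, 100)
    domain_noise: float = 0.05
    duplication_fraction: float = 0.33
    plant_domain: bool = True
    plant_contexts: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.motif_penetrance <= 1:
            raise GeneratorError("motif_penetrance must be in (0, 1]")
        for m in self.motif_set:
            if len(m) > self.sequence_length:
                raise GeneratorError(f"motif {m!r} longer than sequence_length")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n, p=BACKGROUND_FREQS))


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: set[int] = frozenset()
) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if i in protected or rng.random() >= rate:
            continue
        options = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def _domain_copy(
    rng: np.random.Generator, spec: GeneratorSpec, with_contexts: bool
) -> tuple[str, dict]:
    """A noised domain copy, optionally with the cysteine pair planted at
    offsets drawn from the configured spacing (0-based offsets returned)."""
    dom = list(spec.domain_consensus)
    info: dict = {}
    protected: set[int] = set()
    if with_contexts:
        lo, hi = spec.context_spacing
        n_off = int(rng.integers(4, 13))
        spacing = int(rng.integers(lo, hi + 1))
        c_off = min(n_off + spacing, len(dom) - 6)
        dom[n_off : n_off + 4] = N_CONTEXTS[int(rng.integers(2))]
        dom[c_off : c_off + 4] = C_CONTEXTS[int(rng.integers(2))]
        protected = set(range(n_off, n_off + 4)) | set(range(c_off, c_off + 4))
        info = {"n_offset": n_off, "c_offset": c_off}
    noised = _mutate(rng, "".join(dom), spec.domain_noise, protected)
    return noised, info


def _scrub_contexts(rng: np.random.Generator, seq: str) -> str:
    """Destroy every canonical context by mutating its cysteine."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for pat in N_CONTEXTS + C_CONTEXTS:
            p = s.find(pat)
            while p != -1:
                options = [a for a in AMINO_ACIDS if a not in ("C", "T")]
                chars[p + 1] = options[int(rng.integers(len(options)))]
                changed = True
                s = "".join(chars)
                p = s.find(pat, p + 1)
    return "".join(chars)


def _assemble(
    rng: np.random.Generator, segments: list[tuple[str, str, dict]], total_length: int
) -> tuple[str, list[dict]]:
    """Join labelled segments with random spacers; returns the sequence and
    per-segment placements with 1-based start positions."""
    seg_len = sum(len(s) for _, s, _ in segments)
    n_gaps = len(segments) + 1
    min_spacer = 2
    needed = seg_len + min_spacer * n_gaps
    budget = max(total_length, needed) - seg_len - min_spacer * n_gaps
    extra = rng.multinomial(budget, np.full(n_gaps, 1 / n_gaps)) if budget > 0 else np.zeros(n_gaps, dtype=int)
    parts: list[str] = []
    placements: list[dict] = []
    pos = 0
    for k, (kind, seg, info) in enumerate(segments):
        spacer = _random_seq(rng, min_spacer + int(extra[k]))
        parts.append(spacer)
        pos += len(spacer)
        placements.append({"kind": kind, "start": pos + 1, "end": pos + len(seg), **info})
        parts.append(seg)
        pos += len(seg)
    parts.append(_random_seq(rng, min_spacer + int(extra[-1])))
    return "".join(parts), placements


def generate_protein_sets(
    spec: GeneratorSpec,
) -> tuple[list[ProteinRecord], list[ProteinRecord], dict]:
    """Positives, decoys and a truth manifest of every planted coordinate."""
    rng = np.random.default_rng(spec.seed)
    positives: list[ProteinRecord] = []
    manifest: dict = {"positives": {}, "decoys": {}, "spec": spec}
    n_dup = int(round(spec.duplication_fraction * spec.n_pos)) if spec.plant_domain else 0
    for i in range(spec.n_pos):
        segments: list[tuple[str, str, dict]] = []
        planted_motifs = [
            (k, m)
            for k, m in enumerate(spec.motif_set, start=1)
            if rng.random() < spec.motif_penetrance
        ]
        for k, m in planted_motifs:
            segments.append(("motif", m, {"motif_id": k}))
        order = rng.permutation(len(segments)).tolist()
        segments = [segments[j] for j in order]
        if spec.plant_domain:
            dom, info = _domain_copy(rng, spec, spec.plant_contexts)
            insert_at = int(rng.integers(len(segments) + 1))
            segments.insert(insert_at, ("domain", dom, info))
            if i < n_dup:
                dom2, _ = _domain_copy(rng, spec, with_contexts=False)
                segments.append(("domain", dom2, {"duplicate": True}))
        elif spec.plant_contexts:
            spacing = int(rng.integers(*spec.context_spacing))
            ncon = N_CONTEXTS[int(rng.integers(2))]
            ccon = C_CONTEXTS[int(rng.integers(2))]
            block = ncon + _random_seq(rng, spacing - 4) + ccon
            segments.insert(int(rng.integers(len(segments) + 1)), ("contexts", block, {}))
        seq, placements = _assemble(rng, segments, spec.sequence_length)
        rec_id = f"pos_{i:04d}"
        positives.append(ProteinRecord(id=rec_id, residues=seq, taxon="synthetic_positive"))
        manifest["positives"][rec_id] = {
            "placements": placements,
            "motif_ids": sorted(k for k, _ in planted_motifs),
            "duplicated": i < n_dup,
        }

    decoys: list[ProteinRecord] = []
    for i in range(spec.n_neg):
        segments = []
        if spec.plant_domain:
            dom, _ = _domain_copy(rng, spec, with_contexts=False)
            segments.append(("domain", dom, {}))
        seq, placements = _assemble(rng, segments, spec.sequence_length)
        seq = _scrub_contexts(rng, seq)
        rec_id = f"neg_{i:04d}"
        decoys.append(ProteinRecord(id=rec_id, residues=seq, taxon="synthetic_decoy"))
        manifest["decoys"][rec_id] = {"placements": placements}
    return positives, decoys, manifest


def generate_random_proteins(
    n: int, length: int, seed: int = 0, prefix: str = "rand"
) -> list[ProteinRecord]:
    """Plain background-composition sequences (threshold calibration)."""
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(id=f"{prefix}_{i:04d}", residues=_random_seq(rng, length))
        for i in range(n)
    ]


def generate_domain_seed_alignment(
    spec: GeneratorSpec, n_seqs: int = 30
) -> Alignment:
    """Ungapped alignment of noised domain copies, for profile building."""
    rng = np.random.default_rng(spec.seed + 104729)
    records = [
        ProteinRecord(
            id=f"seed_{i:03d}",
            residues=_mutate(rng, spec.domain_consensus, spec.domain_noise),
        )
        for i in range(n_seqs)
    ]
    return Alignment(records)


# ---------------------------------------------------------------------------
# Phylogeny generators

def random_additive_tree(n_leaves: int, seed: int = 0):
    """Random binary unrooted tree with uniform(0.1, 1.0) branch lengths
    and its exactly additive leaf-leaf distance matrix."""
    if n_leaves < 4:
        raise GeneratorError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.extend([b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(0.1, 1.0))
    root.extend(nodes)
    dm = root.tip_tip_distances()
    return root, dm


def generate_family_alignment(
    n_leaves: int = 8,
    length: int = 200,
    seed: int = 0,
    branch_length_range: tuple[float, float] = (0.02, 0.3),
) -> tuple[Alignment, TreeNode]:
    """Sequences evolved along a random tree by per-branch substitutions.

    Each site substitutes along a branch of length b with probability
    1 - exp(-b) to a uniformly random different residue; returns the
    (trivially aligned, ungapped) alignment and the generating tree.
    """
    rng = np.random.default_rng(seed)
    tree, _ = random_additive_tree(max(n_leaves, 4), seed + 1)
    lo, hi = branch_length_range
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    root_seq = _random_seq(rng, length)

    def evolve(seq: str, b: float) -> str:
        p = 1.0 - np.exp(-b)
        return _mutate(rng, seq, p)

    seqs: dict[int, str] = {id(tree): root_seq}
    records = []
    for node in tree.preorder(include_self=False):
        seq = evolve(seqs[id(node.parent)], node.length)
        seqs[id(node)] = seq
        if node.is_tip():
            records.append(ProteinRecord(id=node.name, residues=seq))
    records.sort(key=lambda r: r.id)
    return Alignment(records), tree


def generate_two_clade_alignment(
    n_per_clade: int = 2,
    n_fixed_differences: int = 100,
    length: int = 150,
    seed: int = 0,
) -> Alignment:
    """Two clades separated by a block of fixed differences — a
    strong-signal case where the clade split should bootstrap at ~100%."""
    if n_fixed_differences > length:
        raise GeneratorError("more fixed differences than columns")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)
    other = list(base)
    cols = rng.choice(length, size=n_fixed_differences, replace=False)
    for j in cols:
        options = [a for a in AMINO_ACIDS if a != base[j]]
        other[j] = options[int(rng.integers(len(options)))]
    other = "".join(other)
    records = []
    for k in range(n_per_clade):
        records.append(ProteinRecord(id=f"cladeA_{k}", residues=_mutate(rng, base, 0.01)))
    for k in range(n_per_clade):
        records.append(ProteinRecord(id=f"cladeB_{k}", residues=_mutate(rng, other, 0.01)))
    return Alignment(records)


# ---------------------------------------------------------------------------
# Abundance / expression generators

DEFAULT_REGIONS = ("South Pacific",)
DEFAULT_TAXA = ("Dinophyceae", "Haptophyceae", "Diatoms")


@dataclass
class AbundanceSpec:
    """Study conditions for the station x depth abundance generator.

    ``rho_targets`` maps taxon -> (environmental variable, target Spearman
    rho), applied within every region.  ``fold_changes`` maps gene id ->
    mesopelagic/euphotic fold change for the count matrix (genes absent
    from the map are null).  Depths <= 200 m are euphotic.
    """

    seed: int = 0
    n_stations: int = 10
    depths: tuple[float, ...] = (5, 40, 80, 150, 300, 500)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    taxa: tuple[str, ...] = DEFAULT_TAXA
    genes_per_taxon: int = 4
    rho_targets: dict = field(
        default_factory=lambda: {"Haptophyceae": ("NO3", 0.7)}
    )
    fold_changes: dict = field(default_factory=dict)
    base_mean: float = 100.0
    dispersion: float = 10.0  # NB size parameter; larger = less overdispersed
    size_fraction: str = "0.8-2000"


def _spearman_to_pearson(rho_s: float) -> float:
    # Gaussian copula: rho_s = (6/pi) asin(r/2)  =>  r = 2 sin(pi rho_s / 6)
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_abundance_dataset(
    spec: AbundanceSpec,
) -> tuple[AbundanceTable, pd.DataFrame, dict]:
    """AbundanceTable (percent of mapped reads), a count matrix with
    planted depth fold-changes, and the truth manifest."""
    for taxon, (_, rho) in spec.rho_targets.items():
        if abs(rho) > 1:
            raise GeneratorError(f"target rho for {taxon!r} must be in [-1, 1]")
    rng = np.random.default_rng(spec.seed)
    sample_ids, stations, depths, regions = [], [], [], []
    for s in range(spec.n_stations):
        region = spec.regions[s % len(spec.regions)]
        for dep in spec.depths:
            sample_ids.append(f"st{s:02d}_d{int(dep):04d}")
            stations.append(f"st{s:02d}")
            depths.append(float(dep))
            regions.append(region)
    n_samples = len(sample_ids)

    # environmental fields from latent standard normals
    latent = {v: rng.standard_normal(n_samples) for v in ("temperature", "NO3", "PO4", "Fe")}
    meta = pd.DataFrame(
        {
            "station": stations,
            "depth": depths,
            "region": regions,
            "size_fraction": spec.size_fraction,
            "temperature": 15.0 + 6.0 * latent["temperature"],
            "NO3": np.exp(1.0 + 0.8 * latent["NO3"]),
            "PO4": np.exp(-1.0 + 0.5 * latent["PO4"]),
            "Fe": np.exp(-3.0 + 0.6 * latent["Fe"]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    genes, gene_taxa = [], []
    for taxon in spec.taxa:
        for g in range(spec.genes_per_taxon):
            genes.append(f"{taxon}_g{g}")
            gene_taxa.append(taxon)
    gene_taxa = pd.Series(gene_taxa, index=pd.Index(genes, name="gene_id"), name="taxon")

    total_mapped = 1_000_000.0
    values = np.zeros((len(genes), n_samples))
    for taxon in spec.taxa:
        var, rho_s = spec.rho_targets.get(taxon, (None, 0.0))
        eps = rng.standard_normal(n_samples)
        if var is None:
            t = eps
        else:
            r = _spearman_to_pearson(rho_s)
            t = r * latent[var] + np.sqrt(1 - r * r) * eps
        taxon_total = np.exp(np.log(2000.0) + 0.8 * t)  # reads for the taxon
        idx = [k for k, g in enumerate(genes) if gene_taxa[g] == taxon]
        weights = rng.dirichlet(np.full(len(idx), 5.0), size=n_samples).T
        values[idx, :] = taxon_total[None, :] * weights
    percent = pd.DataFrame(
        100.0 * values / total_mapped, index=gene_taxa.index, columns=sample_ids
    )
    table = AbundanceTable(values=percent, gene_taxa=gene_taxa, meta=meta)

    # count matrix with planted euphotic/mesopelagic fold changes
    euphotic = np.array(depths) <= 200.0
    means = np.full((len(genes), n_samples), spec.base_mean)
    for gene, fold in spec.fold_changes.items():
        gi = genes.index(gene)
        means[gi, ~euphotic] = spec.base_mean * fold
    k = spec.dispersion
    counts = rng.negative_binomial(k, k / (k + means))
    counts_df = pd.DataFrame(counts, index=gene_taxa.index, columns=sample_ids)

    manifest = {
        "rho_targets": dict(spec.rho_targets),
        "fold_changes": dict(spec.fold_changes),
        "euphotic_samples": [s for s, e in zip(sample_ids, euphotic) if e],
        "mesopelagic_samples": [s for s, e in zip(sample_ids, euphotic) if not e],
        "total_mapped": total_mapped,
    }
    return table, counts_df, manifest
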