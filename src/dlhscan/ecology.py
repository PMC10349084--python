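"""Abundance, environmental correlation and depth-differential expression.

Gene/taxon abundance in metatranscriptomes is expressed as percent of
mapped reads.  Per-taxon, per-region associations with environmental
drivers (temperature, NO3, PO4, Fe) use Spearman rank correlation with
pairwise deletion of missing values and Benjamini–Hochberg correction
across the correlation grid.  Expression counts are normalized with
median-of-ratios size factors, and euphotic (<= 200 m) versus mesopelagic
(> 200 m) differential expression is tested with a seeded permutation test
on the difference of mean log2 normalized values, again BH-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EUPHOTIC_BOUNDARY_M = 200.0

META_COLUMNS = ("station", "depth", "region", "size_fraction")
ENV_VARIABLES = ("temperature", "NO3", "PO4", "Fe")


class EcologyError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Gene/taxon x sample percent-of-mapped-reads with sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``gene_taxa``: Series mapping gene id -> taxon label.
    ``meta``: DataFrame indexed by sample id with station, depth, region,
    size_fraction and environmental variables (possibly NaN).
    """

    values: pd.DataFrame
    gene_taxa: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            missing = set(self.values.columns) ^ set(self.meta.index)
            raise EcologyError(f"sample mismatch between values and meta: {missing}")
        if (self.values.fillna(0) < 0).any().any():
            raise EcologyError("abundance values must be non-negative")
        for col in ("station", "depth", "region"):
            if col not in self.meta.columns:
                raise EcologyError(f"metadata missing required column {col!r}")

    def write(self, values_path: str | Path, meta_path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "taxon", self.gene_taxa.reindex(out.index))
        out.to_csv(values_path, sep="\t", index_label="gene_id")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, values_path: str | Path, meta_path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        if "taxon" in df.columns:
            taxa = df["taxon"]
            values = df.drop(columns="taxon").astype(float)
        else:  # plain gene x sample matrix (e.g. raw counts)
            values = df.astype(float)
            taxa = pd.Series("unknown", index=df.index, name="taxon")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        meta = meta.reindex(values.columns)
        if meta["depth"].isna().any():
            missing = meta.index[meta["depth"].isna()].tolist()
            raise EcologyError(f"metadata missing for samples: {missing}")
        return cls(values=values, gene_taxa=taxa, meta=meta)


def percent_mapped_reads(
    counts: pd.DataFrame, total_mapped: pd.Series
) -> pd.DataFrame:
    """100 x count / total mapped reads, per cell; a zero total yields an
    all-NA column with a warning."""
    total = total_mapped.reindex(counts.columns)
    if total.isna().any():
        raise EcologyError("total_mapped missing for some samples")
    if (counts.sum(axis=0) > total + 1e-9).any():
        raise EcologyError("column sums exceed total mapped reads")
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"samples with zero mapped reads set to NA: {list(total.index[zero])}"
        )
    safe = total.replace(0, np.nan)
    return 100.0 * counts.div(safe, axis=1)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho and two-sided p (t approximation, n-2 df) with
    pairwise deletion of missing values.

    Average ranks are used for ties.  Returns (nan, nan) when either
    vector is constant after deletion; fewer than 3 complete pairs is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EcologyError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise EcologyError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class CorrelationResult:
    taxon: str
    region: str
    variable: str
    rho: float
    p: float
    p_adj: float
    n: int


def taxon_region_correlations(
    table: AbundanceTable,
    taxa: Sequence[str],
    variables: Sequence[str] = ENV_VARIABLES,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of summed per-taxon abundance against each
    environmental variable, within each oceanic region.

    Cells with fewer than ``min_samples`` usable samples (or a constant
    vector) are NA; BH adjustment runs across all non-NA cells of the
    grid.  Returns a tidy DataFrame of :class:`CorrelationResult` fields.
    """
    rows = []
    regions = sorted(table.meta["region"].dropna().unique())
    for taxon in taxa:
        genes = table.gene_taxa.index[table.gene_taxa == taxon]
        taxon_abund = table.values.loc[genes].sum(axis=0)
        for region in regions:
            samples = table.meta.index[table.meta["region"] == region]
            for var in variables:
                if var not in table.meta.columns:
                    raise EcologyError(f"metadata missing variable {var!r}")
                x = taxon_abund.reindex(samples).to_numpy(dtype=float)
                y = table.meta.loc[samples, var].to_numpy(dtype=float)
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < min_samples:
                    rows.append((taxon, region, var, np.nan, np.nan, ok.sum()))
                    continue
                rho, p = spearman(x[ok], y[ok])
                rows.append((taxon, region, var, rho, p, int(ok.sum())))
    df = pd.DataFrame(rows, columns=["taxon", "region", "variable", "rho", "p", "n"])
    df["p_adj"] = np.nan
    mask = df["p"].notna()
    if mask.any():
        df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors.

    The reference is the per-gene geometric mean across samples (genes
    with any zero are excluded); each sample's factor is the median over
    genes of count / reference.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise EcologyError(
            "no gene has nonzero counts in every sample; consider a pseudo-reference"
        )
    sub = arr[nonzero]
    reference = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / reference[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fold_change(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene ratio of mean normalized counts (A over B), with a
    pseudocount added to both means."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise EcologyError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise EcologyError("groups must be disjoint")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    return (mean_a + pseudocount) / (mean_b + pseudocount)


def depth_differential(
    values: pd.DataFrame,
    depths: pd.Series,
    boundary_m: float = EUPHOTIC_BOUNDARY_M,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    normalize: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Euphotic (depth <= boundary) vs. mesopelagic (> boundary)
    differential expression per gene.

    Statistic: difference of mean log2(value + pseudocount), euphotic
    minus mesopelagic, on size-factor-normalized counts when
    ``normalize`` is set (raw counts in, e.g. an ExpressionMatrix) or on
    the values as given (e.g. percent of mapped reads).  Two-sided p by
    seeded permutation of zone labels, BH-corrected across genes; a gene
    is called enriched in its higher-mean zone when the adjusted p falls
    below ``alpha``.
    """
    depths = depths.reindex(values.columns)
    if depths.isna().any():
        raise EcologyError("depth missing for some samples")
    euphotic = (depths <= boundary_m).to_numpy()
    if euphotic.all() or (~euphotic).all():
        raise EcologyError(
            f"all samples fall on one side of the {boundary_m} m boundary"
        )
    data = values
    if normalize:
        data = values.div(size_factors(values), axis=1)
    logged = np.log2(data.to_numpy(dtype=float) + pseudocount)
    n_eu = int(euphotic.sum())
    n_me = int((~euphotic).sum())
    obs = logged[:, euphotic].mean(axis=1) - logged[:, ~euphotic].mean(axis=1)

    rng = np.random.default_rng(seed)
    n_samples = logged.shape[1]
    exceed = np.zeros(logged.shape[0], dtype=np.int64)
    col_sum = logged.sum(axis=1)
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)[:n_eu]
        mean_eu = logged[:, perm].mean(axis=1)
        mean_me = (col_sum - logged[:, perm].sum(axis=1)) / n_me
        exceed += np.abs(mean_eu - mean_me) >= np.abs(obs) - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    p_adj = multipletests(p, method="fdr_bh")[1]
    zone = np.where(obs > 0, "euphotic", "mesopelagic")
    called = p_adj < alpha
    return pd.DataFrame(
        {
            "statistic": obs,
            "p": p,
            "p_adj": p_adj,
            "zone": np.where(called, zone, "ns"),
        },
        index=values.index,
    )
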