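"""Cross-dataset sample similarity from mutation, copy-number and
expression profiles.

Binary mutation profiles are compared with the Jaccard index; continuous
gene-wise profiles (CNA log2 ratios, expression) with Pearson or Spearman
correlation over the genes shared by both sources, excluding missing values
pairwise. A matched-versus-unmatched summary quantifies whether each cell
line is most similar to its namesake in the other resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .harmonize import GeneMatrix

#: Minimum shared non-missing features for a correlation to be reported.
MIN_SHARED_FEATURES = 3


@dataclass
class BinaryMutationProfile:
    """Per-sample set of mutated genes (after filtering)."""

    sample_id: str
    mutated_genes: frozenset[str]
    gene_universe: frozenset[str] = field(repr=False, default=frozenset())

    def __post_init__(self) -> None:
        if self.gene_universe and not self.mutated_genes <= self.gene_universe:
            extra = sorted(self.mutated_genes - self.gene_universe)[:5]
            raise InvalidArgumentError(f"mutated genes outside universe: {extra}")


def binarize_mutations(records: pd.DataFrame,
                       gene_universe: set[str] | frozenset[str]) -> dict[str, BinaryMutationProfile]:
    """Collapse filtered mutation records to per-sample mutated-gene sets.

    A gene is included for a sample iff at least one surviving record exists,
    regardless of variant class.
    """
    universe = frozenset(gene_universe)
    out: dict[str, BinaryMutationProfile] = {}
    for sample, grp in records.groupby("sample", sort=False):
        genes = frozenset(grp["gene"]) & universe
        out[str(sample)] = BinaryMutationProfile(str(sample), genes, universe)
    return out


def jaccard(a: BinaryMutationProfile | frozenset | set,
            b: BinaryMutationProfile | frozenset | set) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty sets score 0 (no evidence)."""
    set_a = a.mutated_genes if isinstance(a, BinaryMutationProfile) else frozenset(a)
    set_b = b.mutated_genes if isinstance(b, BinaryMutationProfile) else frozenset(b)
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def jaccard_matrix(profiles_a: dict[str, BinaryMutationProfile],
                   profiles_b: dict[str, BinaryMutationProfile]) -> pd.DataFrame:
    """All-pairs Jaccard similarity (rows: A samples, columns: B samples)."""
    return pd.DataFrame(
        {sb: [jaccard(pa, pb) for pa in profiles_a.values()]
         for sb, pb in profiles_b.items()},
        index=list(profiles_a),
    )


def profile_correlation(matrix_a: GeneMatrix, matrix_b: GeneMatrix,
                        method: str = "pearson") -> pd.DataFrame:
    """Sample-by-sample correlation between two gene matrices.

    Each cell correlates one column of ``matrix_a`` with one column of
    ``matrix_b`` over their shared genes, excluding missing values pairwise.
    Pairs with fewer than three shared non-missing genes, or with a
    zero-variance vector, are reported as NaN (flagged missing).
    """
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown correlation method {method!r}")
    shared = matrix_a.values.index.intersection(matrix_b.values.index)
    if len(shared) < MIN_SHARED_FEATURES:
        raise InvalidArgumentError(
            f"only {len(shared)} shared genes; need >= {MIN_SHARED_FEATURES}")
    va = matrix_a.values.loc[shared].to_numpy(dtype=float)
    vb = matrix_b.values.loc[shared].to_numpy(dtype=float)
    out = np.full((va.shape[1], vb.shape[1]), np.nan)
    clean = not (np.isnan(va).any() or np.isnan(vb).any())
    if clean:
        xa, xb = va, vb
        if method == "spearman":
            xa = np.apply_along_axis(stats.rankdata, 0, va)
            xb = np.apply_along_axis(stats.rankdata, 0, vb)
        sa = xa.std(axis=0)
        sb = xb.std(axis=0)
        za = (xa - xa.mean(axis=0)) / np.where(sa > 0, sa, np.nan)
        zb = (xb - xb.mean(axis=0)) / np.where(sb > 0, sb, np.nan)
        out = za.T @ zb / len(shared)
        out = np.clip(out, -1.0, 1.0)
    else:
        for i in range(va.shape[1]):
            for j in range(vb.shape[1]):
                mask = ~(np.isnan(va[:, i]) | np.isnan(vb[:, j]))
                if mask.sum() < MIN_SHARED_FEATURES:
                    continue
                x, y = va[mask, i], vb[mask, j]
                if x.std() == 0 or y.std() == 0:
                    continue
                if method == "pearson":
                    out[i, j] = stats.pearsonr(x, y).statistic
                else:
                    out[i, j] = stats.spearmanr(x, y).statistic
    return pd.DataFrame(out, index=matrix_a.values.columns, columns=matrix_b.values.columns)


def matched_vs_unmatched(sim_matrix: pd.DataFrame,
                         pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Summarize matched-pair similarity against the unmatched background.

    For every matched ``(row, column)`` pair: the matched similarity, the
    mean similarity of that row to all other columns, and the matched
    entry's rank within its row (1 = most similar; ties as mid-ranks). The
    result carries the fraction of matched pairs ranked first in
    ``result.attrs["fraction_ranked_first"]``.
    """
    rows = []
    for row_id, col_id in pairs:
        if row_id not in sim_matrix.index or col_id not in sim_matrix.columns:
            raise InvalidArgumentError(f"pair ({row_id}, {col_id}) absent from matrix")
        row = sim_matrix.loc[row_id]
        matched = float(row[col_id])
        others = row.drop(labels=[col_id])
        # descending mid-ranks: rank 1 = highest similarity
        ranks = row.rank(ascending=False, method="average")
        rows.append((row_id, col_id, matched, float(others.mean()), float(ranks[col_id])))
    out = pd.DataFrame(rows, columns=["row", "column", "matched_similarity",
                                      "mean_unmatched_similarity", "matched_rank"])
    out.attrs["fraction_ranked_first"] = float((out["matched_rank"] == 1.0).mean())
    return out


def plot_similarity_heatmap(sim_matrix: pd.DataFrame, path: str,
                            title: str = "") -> None:
    """Render a similarity matrix as a raster heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim_matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(sim_matrix.shape[1]))
    ax.set_xticklabels(sim_matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(sim_matrix.shape[0]))
    ax.set_yticklabels(sim_matrix.index, fontsize=5)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
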