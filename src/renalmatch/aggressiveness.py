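"""Do tumours that resemble cell lines look more aggressive?

Tumours are split into a group that co-clusters with cell lines and a group
that does not (or, as a clustering-parameter-free variant, into top and
bottom quartiles by mean copy-number correlation with the cell lines). The
groups are then compared on clinical stage (1-2 vs 3-4), grade (G1-G2 vs
G3-G4), fraction genome altered, and per-gene mutation frequency over a
gene panel, with two-sided Fisher exact tests on the 2x2 tables.

The Fisher test is computed exactly: two-sided p as the sum of
hypergeometric probabilities no larger than the observed table's, evaluated
in rational arithmetic for moderate tables. The reported odds ratio is the
simple cross-product ratio ``(a·d)/(b·c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .subtyping import ClusterResult, FgaResult

#: Largest table total for which the exact rational path is used.
_EXACT_N_LIMIT = 2000


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    Returns ``(odds_ratio, p_two_sided)`` where the odds ratio is the
    cross-product ratio (inf when ``b·c = 0`` and ``a·d > 0``). The p-value
    sums, over all tables with the observed margins, the hypergeometric
    probabilities that do not exceed the observed table's probability;
    comparisons are done in exact rational arithmetic, so ties at the
    observed probability are included exactly. A table with a zero margin
    carries no information: p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidArgumentError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise InvalidArgumentError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        odds = math.nan
        return odds, 1.0
    odds = math.inf if b * c == 0 else (a * d) / (b * c)

    if n > _EXACT_N_LIMIT:  # huge tables: delegate to the scipy implementation
        from scipy import stats
        return odds, float(stats.fisher_exact(t.reshape(2, 2))[1])

    denom = math.comb(n, col1)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    probs = {x: Fraction(math.comb(row1, x) * math.comb(n - row1, col1 - x), denom)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    p = sum(pr for pr in probs.values() if pr <= p_obs)
    return odds, float(p)


def split_by_coclustering(result: ClusterResult, tumour_ids: list[str],
                          cell_line_ids: list[str]) -> tuple[list[str], list[str]]:
    """Split tumours by whether they share the dominant cell-line cluster.

    The focal cluster is the one holding the most cell lines; tumours inside
    it form the with-group, the remaining listed tumours the away-group.
    When no cluster mixes tumours and cell lines the split is undefined and
    the quartile variant should be used instead.
    """
    labels = result.labels
    cl_clusters = labels.reindex([c for c in cell_line_ids if c in labels.index])
    if cl_clusters.empty:
        raise InvalidArgumentError("no cell line present in the clustering")
    tumour_set = set(tumour_ids)
    mixed = [int(c) for c in cl_clusters.unique()
             if any(s in tumour_set for s in labels.index[labels == c])]
    if not mixed:
        raise InvalidArgumentError(
            "no cluster contains both tumours and cell lines; "
            "use the quartile-based split instead")
    counts = cl_clusters.value_counts()
    focal = int(counts[counts.index.isin(mixed)].idxmax())
    members = set(labels.index[labels == focal])
    with_group = [s for s in tumour_ids if s in members]
    away_group = [s for s in tumour_ids if s not in members]
    return with_group, away_group


def split_by_quartile(similarity: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Top and bottom quartiles of tumours by mean similarity to cell lines.

    Rows are tumours, columns cell lines. Quartile size is ``floor(n/4)``;
    ties keep the stable input order. Requires at least 8 tumours.
    """
    n = similarity.shape[0]
    if n < 8:
        raise InvalidArgumentError(f"quartile split needs >= 8 tumours, got {n}")
    means = similarity.mean(axis=1)
    order = means.sort_values(ascending=False, kind="stable").index
    k = n // 4
    return list(order[:k]), list(order[-k:])


@dataclass
class GroupComparison:
    """Side-by-side comparison of two tumour groups."""

    group_a: list[str]
    group_b: list[str]
    stage_table: pd.DataFrame
    grade_table: pd.DataFrame
    stage_test: tuple[float, float]       # (odds ratio, p)
    grade_test: tuple[float, float]
    fga_summary: pd.DataFrame             # group x {mean, median, n}
    gene_tests: pd.DataFrame              # gene, freq_a, freq_b, odds, p, significant
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_group_a": len(self.group_a),
            "n_group_b": len(self.group_b),
            "stage_table": self.stage_table.to_dict(),
            "grade_table": self.grade_table.to_dict(),
            "stage_p": self.stage_test[1],
            "grade_p": self.grade_test[1],
            "fga_summary": self.fga_summary.to_dict(),
            "gene_tests": self.gene_tests.to_dict(orient="records"),
            "notes": self.notes,
        }


def _two_by_two(flag_a: pd.Series, flag_b: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {"high": [int(flag_a.sum()), int(flag_b.sum())],
         "low": [int((~flag_a).sum()), int((~flag_b).sum())]},
        index=["group_a", "group_b"])


def compare_groups(
    group_a: list[str],
    group_b: list[str],
    clinical: pd.DataFrame,
    mutated_genes: dict[str, set[str]],
    fga_results: dict[str, FgaResult],
    gene_panel: list[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare two tumour groups on stage, grade, FGA and panel mutations.

    Stage dichotomized 1-2 vs 3-4, grade G1-G2 vs G3-G4; per-gene tables
    count mutated vs not. All Fisher p-values are two-sided and unadjusted
    for multiplicity (flagged in the notes). Samples missing a covariate are
    excluded from that test with a warning note.
    """
    clin = clinical.set_index("sample_id")
    missing = [s for s in [*group_a, *group_b]
               if s not in clin.index or s not in fga_results]
    if missing:
        import warnings
        warnings.warn(f"excluding {len(missing)} samples missing covariates", stacklevel=2)
    ga = [s for s in group_a if s not in missing]
    gb = [s for s in group_b if s not in missing]

    stage_a = clin.loc[ga, "stage"].astype(int) >= 3
    stage_b = clin.loc[gb, "stage"].astype(int) >= 3
    grade_a = clin.loc[ga, "grade"].astype(str).str.lstrip("G").astype(int) >= 3
    grade_b = clin.loc[gb, "grade"].astype(str).str.lstrip("G").astype(int) >= 3
    stage_table = _two_by_two(stage_a, stage_b)
    grade_table = _two_by_two(grade_a, grade_b)
    stage_test = fisher_exact_2x2(stage_table.to_numpy())
    grade_test = fisher_exact_2x2(grade_table.to_numpy())

    fga_a = np.array([fga_results[s].fga for s in ga])
    fga_b = np.array([fga_results[s].fga for s in gb])
    fga_summary = pd.DataFrame(
        {"mean": [fga_a.mean(), fga_b.mean()],
         "median": [float(np.median(fga_a)), float(np.median(fga_b))],
         "n": [len(ga), len(gb)]},
        index=["group_a", "group_b"])

    rows = []
    for gene in gene_panel:
        mut_a = pd.Series([gene in mutated_genes.get(s, set()) for s in ga], index=ga)
        mut_b = pd.Series([gene in mutated_genes.get(s, set()) for s in gb], index=gb)
        table = _two_by_two(mut_a, mut_b)
        odds, p = fisher_exact_2x2(table.to_numpy())
        rows.append({"gene": gene,
                     "freq_a": float(mut_a.mean()), "freq_b": float(mut_b.mean()),
                     "odds_ratio": odds, "p_value": p, "significant": p < alpha})
    gene_tests = pd.DataFrame(rows)

    return GroupComparison(
        ga, gb, stage_table, grade_table, stage_test, grade_test,
        fga_summary, gene_tests,
        notes={"p_values": "two-sided Fisher exact, unadjusted for multiplicity",
               "odds_ratio": "cross-product ratio (a*d)/(b*c)",
               "excluded_missing_covariates": missing},
    )
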