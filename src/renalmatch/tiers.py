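"""Three-tier cross-database concordance for mutations and copy-number calls.

Two resources profiling the same cell lines rarely agree perfectly. For each
(gene, cell line) pair and data kind the observed pair of calls is placed in
exactly one category:

* **Tier 1** — identical calls in both sources;
* **Tier 2** — both sources report an alteration of the same nature but
  differ in detail (different variant in the same gene; same copy-number
  direction, different extent);
* **Tier 3** — an alteration reported in one source only, or copy-number
  calls of opposite direction;
* **concordant_null** — neither source reports anything (agreement, but not
  evidence of an alteration).

Variant identity is protein-level: the (normalized protein-change string,
variant class) pair, with case/whitespace normalized and the ``p.`` prefix
stripped — tolerant of alignment-induced genomic-coordinate shifts.
Cell lines are ranked by discordance count; a line whose panel calls are all
Tier 1 / concordant_null in a data kind is flagged as fully confirmed there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .harmonize import GeneMatrix

TIER1, TIER2, TIER3, NULL = "tier1", "tier2", "tier3", "concordant_null"


def normalize_variant(protein_change: str, variant_class: str) -> tuple[str, str]:
    """Canonical form of a variant for identity comparison."""
    pc = "".join(str(protein_change).split()).lower()
    if pc.startswith("p."):
        pc = pc[2:]
    return pc, str(variant_class).strip().lower()


def mutation_tier(calls_a: Iterable[tuple[str, str]],
                  calls_b: Iterable[tuple[str, str]]) -> str:
    """Tier for one (gene, cell line) given each source's set of
    (protein_change, variant_class) calls. Sets are compared after
    normalization; any asymmetric difference with both sides non-empty is
    Tier 2."""
    set_a = {normalize_variant(pc, vc) for pc, vc in calls_a}
    set_b = {normalize_variant(pc, vc) for pc, vc in calls_b}
    if not set_a and not set_b:
        return NULL
    if not set_a or not set_b:
        return TIER3
    return TIER1 if set_a == set_b else TIER2


def cna_tier(score_a: float, score_b: float) -> str:
    """Tier for a pair of 5-valued GISTIC-like scores.

    Equal nonzero scores are Tier 1; same sign but different magnitude is
    Tier 2; a call against silence, or opposite directions, is Tier 3;
    (0, 0) is concordant_null.
    """
    for s in (score_a, score_b):
        if s not in (-2, -1, 0, 1, 2):
            raise InvalidArgumentError(f"GISTIC-like score out of range: {s!r}")
    if score_a == 0 and score_b == 0:
        return NULL
    if score_a == score_b:
        return TIER1
    if score_a * score_b > 0:
        return TIER2
    return TIER3


def build_tier_calls(
    mutations_a: pd.DataFrame,
    mutations_b: pd.DataFrame,
    gistic_a: GeneMatrix,
    gistic_b: GeneMatrix,
    panel: list[str],
    cell_lines: list[str],
) -> pd.DataFrame:
    """Tier every (cell line, gene) pair of the panel for both data kinds.

    Returns a long table ``cell_line, gene, data_kind, tier, detail``.
    Genes absent from a GISTIC matrix are skipped for the cna kind (no
    observation is not the same as a zero score).
    """
    if not panel:
        raise InvalidArgumentError("empty panel")
    rows = []

    def variant_sets(df: pd.DataFrame) -> dict[tuple[str, str], set]:
        out: dict[tuple[str, str], set] = {}
        for r in df.itertuples(index=False):
            out.setdefault((r.sample, r.gene), set()).add((r.protein_change, r.variant_class))
        return out

    va, vb = variant_sets(mutations_a), variant_sets(mutations_b)
    for cl in cell_lines:
        for gene in panel:
            a = va.get((cl, gene), set())
            b = vb.get((cl, gene), set())
            tier = mutation_tier(a, b)
            detail = f"{sorted(pc for pc, _ in a)}|{sorted(pc for pc, _ in b)}"
            rows.append((cl, gene, "mutation", tier, detail))

    ga, gb = gistic_a.values, gistic_b.values
    for cl in cell_lines:
        for gene in panel:
            if gene not in ga.index or gene not in gb.index \
                    or cl not in ga.columns or cl not in gb.columns:
                continue
            sa, sb = ga.at[gene, cl], gb.at[gene, cl]
            if np.isnan(sa) or np.isnan(sb):
                continue
            rows.append((cl, gene, "cna", cna_tier(int(sa), int(sb)), f"{int(sa)}|{int(sb)}"))
    return pd.DataFrame(rows, columns=["cell_line", "gene", "data_kind", "tier", "detail"])


@dataclass
class ReliabilityReport:
    """Per-cell-line tier counts, perfect-agreement flags and ranking."""

    counts: pd.DataFrame       # index cell_line; columns (data_kind, tier)
    flags: pd.DataFrame        # all_tier1_mutations, all_tier1_cna
    ranking: pd.DataFrame      # cell_line, discordant, tier1, rank


def reliability_report(tier_calls: pd.DataFrame, panel: list[str],
                       cell_lines: list[str] | None = None) -> ReliabilityReport:
    """Summarize tier calls into a per-cell-line reliability ranking.

    A cell line is flagged fully confirmed for a data kind iff it has no
    Tier 2 or Tier 3 call there. Ranking orders by total discordant calls
    (Tier 2 + Tier 3, both kinds) ascending, ties broken by Tier 1 count
    descending, then by name.
    """
    if cell_lines is None:
        cell_lines = sorted(tier_calls["cell_line"].unique())
    mut_calls = tier_calls[tier_calls["data_kind"] == "mutation"]
    missing = [(cl, g) for cl in cell_lines for g in panel
               if not ((mut_calls["cell_line"] == cl) & (mut_calls["gene"] == g)).any()]
    if missing:
        raise InvalidArgumentError(
            f"tier calls do not cover the panel; missing pairs e.g. {missing[:5]}")

    counts = (tier_calls.groupby(["cell_line", "data_kind", "tier"]).size()
              .unstack(["data_kind", "tier"], fill_value=0)
              .reindex(cell_lines, fill_value=0))
    for kind in ("mutation", "cna"):
        for tier in (TIER1, TIER2, TIER3, NULL):
            if (kind, tier) not in counts.columns:
                counts[(kind, tier)] = 0
    counts = counts.sort_index(axis=1)

    def kind_discordant(kind: str) -> pd.Series:
        return counts[(kind, TIER2)] + counts[(kind, TIER3)]

    flags = pd.DataFrame({
        "all_tier1_mutations": kind_discordant("mutation") == 0,
        "all_tier1_cna": kind_discordant("cna") == 0,
    })
    tier1_total = counts[("mutation", TIER1)] + counts[("cna", TIER1)]
    discordant = kind_discordant("mutation") + kind_discordant("cna")
    ranking = pd.DataFrame({"cell_line": counts.index,
                            "discordant": discordant.to_numpy(),
                            "tier1": tier1_total.to_numpy()})
    ranking = ranking.sort_values(["discordant", "tier1", "cell_line"],
                                  ascending=[True, False, True], kind="stable")
    ranking["rank"] = range(1, len(ranking) + 1)
    return ReliabilityReport(counts, flags, ranking.reset_index(drop=True))
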