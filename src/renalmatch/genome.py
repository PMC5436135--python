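"""Miniature genome model with chromosome-arm semantics.

The analyses in this package reason about whole chromosome arms ("3p loss",
"7/17 gains") and about genes placed on those arms. A :class:`GenomeModel`
holds an ordered set of chromosomes, a centromere per chromosome splitting it
into a p and a q arm, and a non-overlapping gene annotation. Coordinates are
1-based and inclusive throughout the package.

The default synthetic genome mirrors the human karyotype at roughly 1/1000
scale (22 autosomes, loosely decreasing lengths, ~25 genes per arm). A small
panel of kidney-cancer genes (VHL, PBRM1, SETD2, BAP1 on 3p; MET on 7q;
TP53 and FLCN on 17p; ...) is pinned to its canonical arm so that mutation
and concordance analyses read naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

# Approximate human autosome lengths in Mb, used as the length skeleton.
_HUMAN_MB = [249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
             135, 134, 115, 107, 102, 90, 81, 78, 59, 63, 48, 51]

# Kidney-cancer panel genes pinned to their canonical arm. Index is the
# ordinal of the gene slot on that arm that gets renamed.
KIDNEY_PANEL_PLACEMENT: dict[str, str] = {
    "ARID1A": "1p", "MTOR": "1p", "FH": "1q",
    "NFE2L2": "2q",
    "VHL": "3p", "PBRM1": "3p", "SETD2": "3p", "BAP1": "3p", "PIK3CA": "3q",
    "SLC1A3": "5p",
    "CDKN1A": "6p",
    "MET": "7q", "MLL3": "7q",
    "TCEB1": "8q",
    "TSC1": "9q",
    "PTEN": "10q",
    "MICALCL": "11p",
    "TSC2": "16p",
    "TP53": "17p", "FLCN": "17p",
    "KDM5C": "21p", "STAG2": "21q",
    "NF2": "22q", "SMARCB1": "22q",
}

#: The 24 kidney-cancer genes used as the default concordance panel.
KIDNEY_PANEL: tuple[str, ...] = tuple(sorted(KIDNEY_PANEL_PLACEMENT))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosomes, centromeres and a gene annotation.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Chromosome name -> centromere position. The p arm is
        ``[1, centromere]``, the q arm ``[centromere + 1, length]``.
    genes
        DataFrame with columns ``gene_id, chromosome, start, end``
        (1-based inclusive, non-overlapping within a chromosome).
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int] = field(hash=False)
    genes: pd.DataFrame = field(hash=False, compare=False)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, cent in self.centromeres.items():
            if name not in lengths:
                raise InvalidArgumentError(f"centromere for unknown chromosome {name!r}")
            if not (1 <= cent < lengths[name]):
                raise InvalidArgumentError(
                    f"centromere of {name} at {cent} not strictly inside [1, {lengths[name]})"
                )
        g = self.genes
        required = {"gene_id", "chromosome", "start", "end"}
        if not required.issubset(g.columns):
            raise InvalidArgumentError(f"gene table must have columns {sorted(required)}")
        if g["gene_id"].duplicated().any():
            raise InvalidArgumentError("duplicate gene ids in annotation")
        if (g["start"] > g["end"]).any():
            raise InvalidArgumentError("gene with start > end")
        for _, row in g.iterrows():
            if row["chromosome"] not in lengths:
                raise InvalidArgumentError(f"gene {row['gene_id']} on unknown chromosome")
            if row["end"] > lengths[row["chromosome"]] or row["start"] < 1:
                raise InvalidArgumentError(f"gene {row['gene_id']} outside its chromosome")

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chromosome_length(self, name: str) -> int:
        for n, length in self.chromosomes:
            if n == name:
                return length
        raise InvalidArgumentError(f"unknown chromosome {name!r}")

    @property
    def arms(self) -> list[str]:
        out = []
        for name, _ in self.chromosomes:
            out.extend([f"{name}p", f"{name}q"])
        return out

    def arm_bounds(self, arm: str) -> tuple[str, int, int]:
        """Return ``(chromosome, start, end)`` of an arm such as ``"3p"``.

        A bare chromosome name is accepted and denotes the whole chromosome.
        """
        if arm.endswith(("p", "q")) and arm[:-1] in dict(self.chromosomes):
            chrom, which = arm[:-1], arm[-1]
            cent = self.centromeres[chrom]
            if which == "p":
                return chrom, 1, cent
            return chrom, cent + 1, self.chromosome_length(chrom)
        if arm in dict(self.chromosomes):
            return arm, 1, self.chromosome_length(arm)
        raise InvalidArgumentError(f"unknown arm or chromosome {arm!r}")

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def make_genome(
    n_chromosomes: int = 22,
    genes_per_arm: int = 25,
    scale: float = 1e-3,
    seed: int = 0,
    kidney_panel: bool = True,
) -> GenomeModel:
    """Build a deterministic miniature genome.

    Chromosome lengths follow the human autosome skeleton (loosely
    decreasing) scaled by ``scale``, with a small seeded jitter. Each arm is
    tiled by ``genes_per_arm`` equally spaced non-overlapping genes. With
    ``kidney_panel=True`` the kidney-cancer panel genes are pinned to their
    canonical arms by renaming the corresponding gene slots.

    The result is a pure function of the arguments: the same seed yields a
    byte-identical model.
    """
    if n_chromosomes < 3:
        raise InvalidArgumentError("need at least 3 chromosomes (chromosome '3' must exist)")
    if genes_per_arm < 1:
        raise InvalidArgumentError("genes_per_arm must be >= 1")
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    rng = np.random.default_rng(seed)
    chroms: list[tuple[str, int]] = []
    centromeres: dict[str, int] = {}
    for i in range(n_chromosomes):
        mb = _HUMAN_MB[i % len(_HUMAN_MB)]
        if i >= len(_HUMAN_MB):  # beyond 22: keep shrinking
            mb = max(20, _HUMAN_MB[-1] - 2 * (i - len(_HUMAN_MB) + 1))
        length = int(round(mb * 1e6 * scale * rng.uniform(0.97, 1.03)))
        length = max(length, 4 * genes_per_arm + 4)
        name = str(i + 1)
        chroms.append((name, length))
        centromeres[name] = int(round(length * rng.uniform(0.35, 0.5)))

    rows = []
    for name, length in chroms:
        cent = centromeres[name]
        for arm_start, arm_end, arm_tag in ((1, cent, "p"), (cent + 1, length, "q")):
            arm_len = arm_end - arm_start + 1
            slot = arm_len // genes_per_arm
            gene_len = max(1, slot // 2)
            for k in range(genes_per_arm):
                start = arm_start + k * slot
                end = min(start + gene_len - 1, arm_end)
                rows.append(
                    (f"chr{name}{arm_tag}_g{k + 1:02d}", name, start, end)
                )
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])

    if kidney_panel:
        counters: dict[str, int] = {}
        rename: dict[str, str] = {}
        for gene, arm in KIDNEY_PANEL_PLACEMENT.items():
            chrom, tag = arm[:-1], arm[-1]
            if chrom not in dict(chroms):
                continue
            k = counters.get(arm, 0)
            if k >= genes_per_arm:
                continue
            rename[f"chr{chrom}{tag}_g{k + 1:02d}"] = gene
            counters[arm] = k + 1
        genes["gene_id"] = genes["gene_id"].map(lambda g: rename.get(g, g))

    return GenomeModel(tuple(chroms), centromeres, genes)
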