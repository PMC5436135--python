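"""Seeded synthetic cohorts with the structure the downstream analyses assume.

The generator emulates three renal-cancer subtypes through arm-level
copy-number archetypes:

* ccRCC — chromosome 3p loss (the hallmark), 5q and 8q gains, chromosome 14
  loss, and frequent mutations in VHL/PBRM1/SETD2/BAP1;
* pRCC — gains of chromosomes 7, 16 and 17, occasional 9p loss, MET
  mutations;
* chRCC — single-copy losses of chromosomes 1, 2, 6, 10, 13 and 17, TP53
  mutations.

Cell-line samples carry an elevated alteration burden (doubled penetrance of
the non-hallmark events and doubled focal-event rate), so that their
fraction-genome-altered distribution stochastically dominates the tumours'.
Every generator is a pure function of its arguments and a seed; random
streams are split per sample so output does not depend on group ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .genome import GenomeModel, make_genome
from .harmonize import ALLELE, LOG2, GeneMatrix, SegmentProfile

AMINO = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class ArmEvent:
    """A recurrent arm- or chromosome-level copy-number event."""

    region: str                 # "3p", "5q" or a bare chromosome name "14"
    direction: str              # "gain" | "loss"
    penetrance: float = 0.9
    magnitude: float = 0.5      # log2 units, > 0; sign comes from direction

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise InvalidArgumentError(f"direction must be gain/loss, got {self.direction!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise InvalidArgumentError("penetrance must lie in [0, 1]")
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise InvalidArgumentError("magnitude must be finite and non-negative")

    @property
    def signed_magnitude(self) -> float:
        return self.magnitude if self.direction == "gain" else -self.magnitude


@dataclass(frozen=True)
class SubtypeArchetype:
    """Copy-number and mutation signature of one tumour subtype."""

    name: str
    events: tuple[ArmEvent, ...]
    focal_event_rate: float = 1.0
    mutation_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.focal_event_rate < 0:
            raise InvalidArgumentError("focal_event_rate must be >= 0")
        for gene, p in self.mutation_rates.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"mutation rate for {gene} outside [0, 1]")


@dataclass
class CohortTruth:
    """Ground-truth ledger for a generated cohort.

    ``samples`` columns: ``sample_id, group, is_cell_line``. Optional slots
    are filled by the generator that produced them.
    """

    samples: pd.DataFrame
    arm_events: pd.DataFrame | None = None      # sample_id, region, direction, magnitude
    mutated_genes: dict[str, set[str]] = field(default_factory=dict)
    mutation_records: pd.DataFrame | None = None
    expression_class: pd.Series | None = None   # sample -> ccA | ccB | intermediate
    batch: pd.Series | None = None
    clinical: pd.DataFrame | None = None        # sample_id, stage, grade

    def __post_init__(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            raise InvalidArgumentError("duplicate sample ids in truth ledger")

    @property
    def tumour_ids(self) -> list[str]:
        s = self.samples
        return s.loc[~s["is_cell_line"], "sample_id"].tolist()

    @property
    def cell_line_ids(self) -> list[str]:
        s = self.samples
        return s.loc[s["is_cell_line"], "sample_id"].tolist()

    def group_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "samples": self.samples.to_dict(orient="list"),
            "arm_events": None if self.arm_events is None else self.arm_events.to_dict(orient="list"),
            "mutated_genes": {k: sorted(v) for k, v in self.mutated_genes.items()},
            "expression_class": None if self.expression_class is None
            else self.expression_class.to_dict(),
            "clinical": None if self.clinical is None else self.clinical.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            samples=pd.DataFrame(obj["samples"]),
            arm_events=None if obj["arm_events"] is None else pd.DataFrame(obj["arm_events"]),
            mutated_genes={k: set(v) for k, v in obj["mutated_genes"].items()},
            expression_class=None if obj["expression_class"] is None
            else pd.Series(obj["expression_class"]),
            clinical=None if obj["clinical"] is None else pd.DataFrame(obj["clinical"]),
        )


def default_archetypes() -> tuple[SubtypeArchetype, ...]:
    """The three renal-cancer subtype archetypes at default penetrances.

    The first event of each archetype is its hallmark; cell lines double the
    penetrance of the remaining (secondary) events. Penetrances follow the
    arm-event frequencies reported for the three subtypes in large tumour
    cohorts (3p loss in ~90% of clear-cell tumours, 5q gain in about two
    thirds; chromosome 7/17 gains in most papillary tumours; the chromophobe
    monosomies in ~85-90%). Arm-event magnitudes (0.5 log2 units) are
    calibration choices for the synthetic scale.
    """
    ccrcc = SubtypeArchetype(
        name="ccRCC",
        events=(
            ArmEvent("3p", "loss", 0.9, 0.5),
            ArmEvent("5q", "gain", 0.67, 0.5),
            ArmEvent("8q", "gain", 0.35, 0.5),
            ArmEvent("14", "loss", 0.45, 0.5),
        ),
        focal_event_rate=1.0,
        mutation_rates={"VHL": 0.7, "PBRM1": 0.4, "SETD2": 0.13, "BAP1": 0.1,
                        "KDM5C": 0.07, "MTOR": 0.06, "TP53": 0.05},
    )
    prcc = SubtypeArchetype(
        name="pRCC",
        events=(
            ArmEvent("7", "gain", 0.9, 0.5),
            ArmEvent("17", "gain", 0.8, 0.5),
            ArmEvent("16", "gain", 0.55, 0.5),
            ArmEvent("9p", "loss", 0.2, 0.5),
        ),
        focal_event_rate=1.0,
        mutation_rates={"MET": 0.15, "SETD2": 0.08, "NF2": 0.05, "FH": 0.04},
    )
    chrcc = SubtypeArchetype(
        name="chRCC",
        events=(
            ArmEvent("1", "loss", 0.9, 0.5),
            ArmEvent("2", "loss", 0.88, 0.5),
            ArmEvent("6", "loss", 0.88, 0.5),
            ArmEvent("10", "loss", 0.88, 0.5),
            ArmEvent("13", "loss", 0.85, 0.5),
            ArmEvent("17", "loss", 0.85, 0.5),
        ),
        focal_event_rate=0.7,
        mutation_rates={"TP53": 0.3, "PTEN": 0.09},
    )
    return (ccrcc, prcc, chrcc)


# ---------------------------------------------------------------------------
# Copy-number cohort


def _sample_rng(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng([seed, *indices])


def _arm_intervals(genome: GenomeModel, region: str) -> list[tuple[str, int, int]]:
    """Arms covered by a region spec ('3p' -> one arm, '14' -> both arms)."""
    if region in dict(genome.chromosomes):
        cent = genome.centromeres[region]
        return [(region, 1, cent), (region, cent + 1, genome.chromosome_length(region))]
    chrom, start, end = genome.arm_bounds(region)
    return [(chrom, start, end)]


def _subtype_background(genome: GenomeModel, seed: int, group_idx: int,
                        sd: float) -> dict[str, float]:
    """Low-amplitude recurrent arm-dosage pattern shared within a subtype.

    Tumours of one subtype share subtle dosage tendencies across the genome
    beyond the discrete hallmark arm events; this per-arm pattern (drawn
    once per archetype) is applied to every sample of the group, scaled by a
    per-sample intensity.
    """
    rng = np.random.default_rng([seed, 313, group_idx])
    out = {}
    for name, _ in genome.chromosomes:
        out[f"{name}p"] = float(rng.normal(0.0, sd))
        out[f"{name}q"] = float(rng.normal(0.0, sd))
    return out


def _simulate_sample_segments(
    genome: GenomeModel,
    archetype: SubtypeArchetype,
    is_cell_line: bool,
    segment_noise_sd: float,
    rng: np.random.Generator,
    background: dict[str, float] | None = None,
    segments_per_arm: int = 6,
) -> tuple[pd.DataFrame, list[ArmEvent]]:
    # choose which archetype events fire; cell lines double secondary penetrance
    applied: list[ArmEvent] = []
    for i, ev in enumerate(archetype.events):
        pen = ev.penetrance
        if is_cell_line and i > 0:
            pen = min(1.0, 2.0 * pen)
        if rng.random() < pen:
            applied.append(ev)

    # arm-level base value per (chrom, arm_start, arm_end)
    base: dict[tuple[str, int, int], float] = {}
    bg_scale = rng.uniform(0.5, 1.5)
    for name, length in genome.chromosomes:
        cent = genome.centromeres[name]
        for key, arm in (((name, 1, cent), f"{name}p"),
                         ((name, cent + 1, length), f"{name}q")):
            base[key] = bg_scale * background[arm] if background else 0.0
    for ev in applied:
        for key in _arm_intervals(genome, ev.region):
            base[key] += ev.signed_magnitude

    # culture-acquired aneuploidy: cell lines gain/lose extra random arms
    if is_cell_line:
        arm_keys = list(base)
        for _ in range(rng.poisson(2.0)):
            key = arm_keys[rng.integers(len(arm_keys))]
            base[key] += float(rng.choice([-0.5, 0.5]))

    # focal events: pick an arm (length-weighted), exponential length
    rate = archetype.focal_event_rate * (2.0 if is_cell_line else 1.0)
    n_focal = rng.poisson(rate)
    arms = list(base)
    arm_lengths = np.array([e - s + 1 for _, s, e in arms], dtype=float)
    focal: dict[tuple[str, int, int], list[tuple[int, int, float]]] = {k: [] for k in arms}
    for _ in range(n_focal):
        idx = rng.choice(len(arms), p=arm_lengths / arm_lengths.sum())
        chrom, a_start, a_end = arms[idx]
        arm_len = a_end - a_start + 1
        length = int(np.clip(rng.exponential(arm_len / 8.0), 1, arm_len))
        start = int(rng.integers(a_start, a_end - length + 2))
        mag = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.0))
        focal[arms[idx]].append((start, start + length - 1, mag))

    rows = []
    for (chrom, a_start, a_end), base_val in base.items():
        # breakpoints partition the arm exactly once; arms are split into
        # several base segments so noise is not arm-block correlated, as in
        # real segmented profiles
        points = {a_start, a_end + 1}
        arm_len = a_end - a_start + 1
        for k in range(1, segments_per_arm):
            cut = a_start + (k * arm_len) // segments_per_arm
            if a_start < cut <= a_end:
                points.add(cut)
        for f_start, f_end, _ in focal[(chrom, a_start, a_end)]:
            points.add(f_start)
            points.add(f_end + 1)
        cuts = sorted(points)
        for s, e_next in zip(cuts[:-1], cuts[1:]):
            e = e_next - 1
            value = base_val
            for f_start, f_end, mag in focal[(chrom, a_start, a_end)]:
                if f_start <= s and e <= f_end:
                    value += mag
            value += rng.normal(0.0, segment_noise_sd) if segment_noise_sd > 0 else 0.0
            rows.append((chrom, s, e, value))
    seg = pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])
    return seg, applied


def _one_mutation(sample_id: str, gene: str, rng: np.random.Generator) -> tuple:
    pos = int(rng.integers(1, 600))
    ref, alt = rng.choice(list(AMINO), 2, replace=False)
    cls = str(rng.choice(["missense", "nonsense", "frameshift", "splice"],
                         p=[0.6, 0.15, 0.15, 0.1]))
    change = f"p.{ref}{pos}fs" if cls == "frameshift" else f"p.{ref}{pos}{alt}"
    depth = int(rng.integers(30, 200))
    vaf = float(rng.uniform(0.2, 0.9))
    return (sample_id, gene, cls, change, depth, vaf)


def _simulate_sample_mutations(
    sample_id: str,
    archetype: SubtypeArchetype,
    all_genes: np.ndarray,
    passenger_rate: float,
    rng: np.random.Generator,
) -> list[tuple]:
    rows = []
    for gene, p in archetype.mutation_rates.items():
        if rng.random() < p:
            rows.append(_one_mutation(sample_id, gene, rng))
    # passenger variants scattered over the rest of the gene universe
    if passenger_rate > 0:
        n_pass = rng.binomial(len(all_genes), passenger_rate)
        taken = {r[1] for r in rows}
        for gene in rng.choice(all_genes, size=n_pass, replace=False):
            if gene not in taken:
                rows.append(_one_mutation(sample_id, str(gene), rng))
    return rows


def simulate_cna_cohort(
    genome: GenomeModel,
    archetypes: Sequence[SubtypeArchetype] | None = None,
    n_per_group: int = 100,
    n_cell_lines_per_group: int = 10,
    segment_noise_sd: float = 0.1,
    seed: int = 0,
    background_ratio: float = 0.8,
    passenger_rate: float = 0.008,
) -> tuple[list[SegmentProfile], CohortTruth]:
    """Simulate tumour and cell-line copy-number profiles for each subtype.

    Per sample, each archetype event fires independently with its penetrance
    (cell lines: doubled penetrance for secondary events and doubled focal
    rate), focal events are layered on top, and Gaussian noise with sd
    ``segment_noise_sd`` is added per segment. Each archetype additionally
    carries a shared low-amplitude arm-dosage background (per-arm sd
    ``background_ratio * segment_noise_sd``, per-sample intensity), so
    samples of one subtype correlate beyond their discrete events — with
    noiseless settings both the noise and the background vanish and segment
    values are exact. Segments partition every chromosome exactly once.
    Somatic mutations combine the archetype's per-driver Bernoulli rates
    with a uniform passenger rate over the whole gene universe (default
    0.008/gene, ~9 passengers per sample on the default genome — of the
    order observed in exome-panel cell-line profiles); all are recorded in
    the truth ledger.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise InvalidArgumentError("need at least one archetype")
    if n_per_group < 1:
        raise InvalidArgumentError("n_per_group must be >= 1")
    if segment_noise_sd < 0:
        raise InvalidArgumentError("segment_noise_sd must be >= 0")
    for arch in archetypes:
        for ev in arch.events:
            genome.arm_bounds(ev.region)  # raises on unknown region

    profiles: list[SegmentProfile] = []
    sample_rows, event_rows, mut_rows = [], [], []
    mutated: dict[str, set[str]] = {}
    all_genes = genome.genes["gene_id"].to_numpy()
    for g_idx, arch in enumerate(archetypes):
        bg_sd = background_ratio * segment_noise_sd
        background = (_subtype_background(genome, seed, g_idx, bg_sd)
                      if bg_sd > 0 and arch.events else None)
        n_total = n_per_group + n_cell_lines_per_group
        for m_idx in range(n_total):
            is_cl = m_idx >= n_per_group
            tag = "CL" if is_cl else "T"
            sample_id = f"{arch.name}_{tag}{(m_idx - n_per_group if is_cl else m_idx) + 1:03d}"
            rng = _sample_rng(seed, g_idx, m_idx)
            seg, applied = _simulate_sample_segments(
                genome, arch, is_cl, segment_noise_sd, rng, background)
            profiles.append(SegmentProfile(sample_id, seg, LOG2))
            sample_rows.append((sample_id, arch.name, is_cl))
            for ev in applied:
                event_rows.append((sample_id, ev.region, ev.direction, ev.magnitude))
            rows = _simulate_sample_mutations(
                sample_id, arch, all_genes, passenger_rate, rng)
            mut_rows.extend(rows)
            mutated[sample_id] = {r[1] for r in rows}

    truth = CohortTruth(
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "group", "is_cell_line"]),
        arm_events=pd.DataFrame(event_rows,
                                columns=["sample_id", "region", "direction", "magnitude"]),
        mutated_genes=mutated,
        mutation_records=pd.DataFrame(
            mut_rows, columns=["sample", "gene", "variant_class",
                               "protein_change", "depth", "vaf"]),
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# Allele-specific scenarios


def balanced_diploid_scenario() -> dict:
    """Minor 1 / total 2 everywhere."""
    return {"default": (2, 1), "arms": {}}


def masked_loss_scenario(arm: str = "3p") -> dict:
    """Minor allele lost but total copy number kept at 3 by major-allele
    amplification, so a log2 total-copy view shows nothing on the arm."""
    return {"default": (2, 1), "arms": {arm: (3, 0)}}


def ploidy_relative_scenario(arm: str = "3p") -> dict:
    """Arm retains two balanced copies while the rest of the genome sits at
    3-4 copies: a loss relative to the sample's average copy number."""
    return {"default": (3, 1), "arms": {arm: (2, 1)}, "alt_default": (4, 2)}


def simulate_allele_specific(
    genome: GenomeModel,
    scenarios: Mapping[str, dict],
    seed: int = 0,
) -> list[SegmentProfile]:
    """Build allele-specific integral profiles from per-sample scenarios.

    A scenario maps arms to ``(total, minor)`` pairs with a ``default`` pair
    for unlisted arms; an optional ``alt_default`` is applied to every other
    chromosome (alternating by chromosome order) to raise average ploidy.
    The output is noise-free — integral calls carry no residual noise.
    """
    del seed  # deterministic by construction; kept for interface symmetry
    profiles = []
    for sample_id, scen in scenarios.items():
        default = tuple(scen.get("default", (2, 1)))
        alt = scen.get("alt_default")
        arm_map = {k: tuple(v) for k, v in scen.get("arms", {}).items()}
        for total, minor in [default, *(() if alt is None else (tuple(alt),)), *arm_map.values()]:
            if minor > total or minor < 0 or total < 0:
                raise InvalidArgumentError(
                    f"{sample_id}: invalid (total={total}, minor={minor})")
        rows = []
        for c_idx, (name, length) in enumerate(genome.chromosomes):
            cent = genome.centromeres[name]
            for arm_tag, (start, end) in (("p", (1, cent)), ("q", (cent + 1, length))):
                arm = f"{name}{arm_tag}"
                if arm in arm_map:
                    total, minor = arm_map[arm]
                elif name in arm_map:
                    total, minor = arm_map[name]
                elif alt is not None and c_idx % 2 == 1:
                    total, minor = tuple(alt)
                else:
                    total, minor = default
                rows.append((name, start, end, int(total), int(minor)))
        seg = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                          "total_cn", "minor_cn"])
        profiles.append(SegmentProfile(sample_id, seg, ALLELE))
    return profiles


# ---------------------------------------------------------------------------
# Two-source views with injected discrepancies


@dataclass
class TwoSourceViews:
    """Paired mutation tables and GISTIC-like matrices with an injection ledger.

    ``ledger`` columns: ``kind`` (mutation|cna), ``sample``, ``gene``,
    ``action`` (drop|alter|extent_shift), ``view`` (A|B).
    """

    mutations_a: pd.DataFrame
    mutations_b: pd.DataFrame
    gistic_a: GeneMatrix
    gistic_b: GeneMatrix
    ledger: pd.DataFrame


def simulate_two_source_views(
    truth_mutations: pd.DataFrame,
    truth_gistic: GeneMatrix,
    drop: float = 0.0,
    alter: float = 0.0,
    extent_shift: float = 0.0,
    seed: int = 0,
) -> TwoSourceViews:
    """Duplicate truth into two source views and inject discrepancies.

    ``drop`` removes a mutation call from one randomly chosen view (a
    present-in-one-only case); ``alter`` perturbs the protein change in one
    view (same gene, different variant); ``extent_shift`` moves a nonzero
    GISTIC-like score between magnitudes 1 and 2 in one view (same
    direction, different extent). With all rates zero the views are
    identical. Each truth call receives at most one injection.
    """
    for name, rate in (("drop", drop), ("alter", alter), ("extent_shift", extent_shift)):
        if not 0.0 <= rate <= 1.0:
            raise InvalidArgumentError(f"{name} rate outside [0, 1]")
    rng = np.random.default_rng([seed, 9151])
    led = []

    mut = truth_mutations.reset_index(drop=True)
    keep_a = np.ones(len(mut), dtype=bool)
    keep_b = np.ones(len(mut), dtype=bool)
    mut_a = mut.copy()
    mut_b = mut.copy()
    for i in range(len(mut)):
        view = "A" if rng.random() < 0.5 else "B"
        u = rng.random()
        if u < drop:
            (keep_a if view == "A" else keep_b)[i] = False
            led.append(("mutation", mut.at[i, "sample"], mut.at[i, "gene"], "drop", view))
        elif u < drop + alter:
            target = mut_a if view == "A" else mut_b
            change = mut.at[i, "protein_change"]
            target.at[i, "protein_change"] = _perturb_protein_change(change, rng)
            led.append(("mutation", mut.at[i, "sample"], mut.at[i, "gene"], "alter", view))
    mut_a = mut_a[keep_a].reset_index(drop=True)
    mut_b = mut_b[keep_b].reset_index(drop=True)

    va = truth_gistic.values.copy()
    vb = truth_gistic.values.copy()
    genes, samples = va.index, va.columns
    arr = truth_gistic.values.to_numpy(dtype=float)
    nz_gene, nz_sample = np.nonzero(np.nan_to_num(arr) != 0)
    for gi, si in zip(nz_gene, nz_sample):
        if rng.random() < extent_shift:
            view = "A" if rng.random() < 0.5 else "B"
            target = va if view == "A" else vb
            old = arr[gi, si]
            new = np.sign(old) * (1.0 if abs(old) == 2 else 2.0)
            target.iat[gi, si] = new
            led.append(("cna", samples[si], genes[gi], "extent_shift", view))

    ledger = pd.DataFrame(led, columns=["kind", "sample", "gene", "action", "view"])
    return TwoSourceViews(mut_a, mut_b, GeneMatrix(va, "gistic5"),
                          GeneMatrix(vb, "gistic5"), ledger)


def _perturb_protein_change(change: str, rng: np.random.Generator) -> str:
    """Produce a different variant string in the same gene (shifted residue)."""
    digits = "".join(ch for ch in change if ch.isdigit())
    if digits:
        pos = int(digits)
        return change.replace(digits, str(pos + 1), 1)
    return change + "alt"


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    gene_list: Sequence[str],
    n_per_class: int = 100,
    n_intermediate: int = 20,
    class_effect_size: float = 2.0,
    n_marker_genes: int = 200,
    batch_assignment: int | Sequence[str] = 2,
    batch_shift: float = 1.0,
    batch_scale: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[GeneMatrix, CohortTruth]:
    """Two-class expression with marker genes, intermediates and batch effects.

    The first ``n_marker_genes`` genes differ between the two classes by
    ``±class_effect_size`` around a common per-gene baseline (balanced signs:
    half the markers are up in ccA and down in ccB, half the reverse, with a
    small seeded spread of magnitudes — subtype signatures mix up- and
    down-regulated genes, which is what rank-based centroid calling relies
    on); intermediate samples sit at the midpoint. Batch effects follow the location/scale
    model used by empirical-Bayes batch correction: per-batch per-gene
    additive shifts drawn from N(0, ``batch_shift``²) and multiplicative
    noise-scale factors log-normal around ``batch_scale`` (exactly 1 when
    ``batch_scale`` is 1).
    """
    if not gene_list:
        raise InvalidArgumentError("empty gene list")
    if n_marker_genes > len(gene_list):
        raise InvalidArgumentError("n_marker_genes exceeds gene list size")
    if noise_sd < 0 or batch_scale <= 0 or batch_shift < 0:
        raise InvalidArgumentError("scales must be non-negative (batch_scale > 0)")
    genes = list(gene_list)
    n_genes = len(genes)
    rng = np.random.default_rng([seed, 771])
    baseline = rng.normal(7.0, 1.0, size=n_genes)

    classes = (["ccA"] * n_per_class + ["ccB"] * n_per_class
               + ["intermediate"] * n_intermediate)
    sample_ids = [f"{cls}_{i + 1:03d}" for cls in ("ccA", "ccB")
                  for i in range(n_per_class)]
    sample_ids += [f"int_{i + 1:03d}" for i in range(n_intermediate)]
    n_samples = len(sample_ids)

    if isinstance(batch_assignment, int):
        if batch_assignment < 1:
            raise InvalidArgumentError("need at least one batch")
        batches = [f"batch{(i % batch_assignment) + 1}" for i in range(n_samples)]
    else:
        batches = list(batch_assignment)
        if len(batches) != n_samples:
            raise InvalidArgumentError("batch_assignment length != number of samples")
    batch_names = sorted(set(batches))
    gamma = {b: rng.normal(0.0, batch_shift, size=n_genes) if batch_shift > 0
             else np.zeros(n_genes) for b in batch_names}
    log_scale_sd = 0.25 * abs(np.log(batch_scale))
    delta = {b: np.exp(rng.normal(np.log(batch_scale), log_scale_sd, size=n_genes))
             for b in batch_names}

    effect = np.zeros(n_genes)
    marker_sign = np.where(np.arange(n_marker_genes) % 2 == 0, 1.0, -1.0)
    marker_mag = rng.uniform(0.75, 1.25, size=n_marker_genes)
    effect[:n_marker_genes] = marker_sign * marker_mag * class_effect_size / 2.0
    sign = {"ccA": 1.0, "ccB": -1.0, "intermediate": 0.0}

    data = np.empty((n_genes, n_samples))
    for j, (sid, cls, b) in enumerate(zip(sample_ids, classes, batches)):
        srng = np.random.default_rng([seed, 772, j])
        eps = srng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
        data[:, j] = baseline + sign[cls] * effect + gamma[b] + delta[b] * eps

    matrix = GeneMatrix(pd.DataFrame(data, index=genes, columns=sample_ids),
                        kind="expression")
    truth = CohortTruth(
        samples=pd.DataFrame({"sample_id": sample_ids, "group": classes,
                              "is_cell_line": False}),
        expression_class=pd.Series(classes, index=sample_ids, name="expression_class"),
        batch=pd.Series(batches, index=sample_ids, name="batch"),
    )
    truth.marker_genes = genes[:n_marker_genes]  # type: ignore[attr-defined]
    return matrix, truth


# ---------------------------------------------------------------------------
# Clinical covariates


def simulate_clinical(
    truth: CohortTruth,
    fga_values: Mapping[str, float],
    stage_logit_slope: float = 8.0,
    grade_logit_slope: float = 8.0,
    fga_center: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Stage and grade covariates tied to copy-number burden.

    P(stage 3/4) and P(grade G3/G4) follow a logistic link in the sample's
    fraction genome altered, centred at ``fga_center``; within the high and
    low halves the specific stage/grade is uniform. Returns a table with
    columns ``sample_id, stage, grade`` for tumour samples.
    """
    tumours = truth.tumour_ids
    missing = [s for s in tumours if s not in fga_values]
    if missing:
        raise InvalidArgumentError(f"missing FGA for samples {missing[:5]}"
                                   + ("..." if len(missing) > 5 else ""))
    rows = []
    for i, sid in enumerate(tumours):
        rng = np.random.default_rng([seed, 4242, i])
        fga = float(fga_values[sid])
        p_high_stage = 1.0 / (1.0 + np.exp(-stage_logit_slope * (fga - fga_center)))
        p_high_grade = 1.0 / (1.0 + np.exp(-grade_logit_slope * (fga - fga_center)))
        stage = int(rng.choice([3, 4]) if rng.random() < p_high_stage else rng.choice([1, 2]))
        grade = f"G{int(rng.choice([3, 4]) if rng.random() < p_high_grade else rng.choice([1, 2]))}"
        rows.append((sid, stage, grade))
    return pd.DataFrame(rows, columns=["sample_id", "stage", "grade"])


def make_default_genome(seed: int = 0) -> GenomeModel:
    """The package's default miniature genome (22 chromosomes, 25 genes/arm)."""
    return make_genome(n_chromosomes=22, genes_per_arm=25, scale=1e-3, seed=seed)
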