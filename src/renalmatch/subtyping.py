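"""Copy-number statistics and co-clustering subtype assignment.

Three per-sample statistics quantify copy-number alteration:

* **FGA** (fraction genome altered): the length-weighted fraction of the
  profiled genome whose segment log2 ratio exceeds a threshold T in
  absolute value, ``FGA = Σ L(i)·1[|CN_i| ≥ T] / Σ L(i)``.
* **Arm-loss fraction**: the fraction of one chromosome arm (by covered
  length, segments clipped to the arm) with log2 ratio at or below a loss
  threshold — the total-copy view of arm loss.
* **Arm LOH fraction**: from allele-specific integral calls, the fraction
  of the arm with minor-allele copy number 0, plus a ploidy-relative
  variant (total copy number at least 0.5 below the sample's length-weighted
  mean). The minor-allele view exposes losses that major-allele
  amplification masks in the total-copy view.

Samples are assigned to subtypes by co-clustering tumours and cell lines:
average-linkage hierarchical clustering with distance 1 − Spearman
correlation on gene-wise copy number, a dendrogram cut at a fixed height,
and majority vote of tumour subtypes within each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, InvalidArgumentError
from .genome import GenomeModel
from .harmonize import ALLELE, LOG2, GeneMatrix, SegmentProfile
from .similarity import profile_correlation

logger = logging.getLogger(__name__)


@dataclass
class FgaResult:
    sample_id: str
    fga: float
    threshold: float
    total_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fga <= 1.0:
            raise InvalidArgumentError("FGA outside [0, 1]")


@dataclass
class ArmLossResult:
    """Arm-level loss evidence from up to two estimators."""

    sample_id: str
    arm: str
    log2_loss_fraction: float | None = None
    zero_minor_fraction: float | None = None
    relative_loss_fraction: float | None = None
    sample_mean_total_cn: float | None = None
    combined_call: str = "indeterminate"  # lost | negligible | indeterminate


@dataclass
class ClusterResult:
    """A cut dendrogram with cluster composition and cell-line subtype calls."""

    linkage: np.ndarray
    sample_ids: list[str]
    cut_height: float
    labels: pd.Series                    # sample -> cluster id (1..k)
    composition: pd.DataFrame            # cluster x group counts
    cell_line_calls: pd.Series | None = None


def fraction_genome_altered(profile: SegmentProfile, threshold: float = 0.2) -> FgaResult:
    """Length-weighted fraction of segments altered beyond ``threshold``.

    Inclusive comparison: a segment counts as altered iff |value| >= T.
    """
    if profile.value_kind != LOG2:
        raise InvalidArgumentError("FGA requires a log2-ratio profile")
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    seg = profile.segments
    if len(seg) == 0:
        raise DegenerateInputError(f"{profile.sample_id}: empty profile")
    lengths = profile.lengths
    altered = np.abs(seg["value"].to_numpy()) >= threshold
    total = int(lengths.sum())
    return FgaResult(profile.sample_id, float(lengths[altered].sum() / total),
                     threshold, total)


def _clip_to_arm(seg: pd.DataFrame, chrom: str, a_start: int, a_end: int) -> pd.DataFrame:
    on = seg[(seg["chromosome"].astype(str) == chrom)
             & (seg["end"] >= a_start) & (seg["start"] <= a_end)].copy()
    on["start"] = on["start"].clip(lower=a_start)
    on["end"] = on["end"].clip(upper=a_end)
    return on


def arm_loss_fraction(profile: SegmentProfile, genome: GenomeModel,
                      arm: str = "3p", loss_thresh: float = -0.2) -> float | None:
    """Fraction of an arm's covered length with log2 ratio <= ``loss_thresh``.

    Segments are clipped to the arm; the denominator is the covered arm
    length, so uncovered regions carry no evidence. Returns None
    (indeterminate) when no segment overlaps the arm.
    """
    if profile.value_kind != LOG2:
        raise InvalidArgumentError("arm_loss_fraction requires a log2-ratio profile")
    chrom, a_start, a_end = genome.arm_bounds(arm)
    on = _clip_to_arm(profile.segments, chrom, a_start, a_end)
    if len(on) == 0:
        logger.warning("%s: no segment overlaps arm %s", profile.sample_id, arm)
        return None
    lengths = (on["end"] - on["start"] + 1).to_numpy()
    lost = on["value"].to_numpy() <= loss_thresh
    return float(lengths[lost].sum() / lengths.sum())


def arm_loh_fraction(profile: SegmentProfile, genome: GenomeModel, arm: str = "3p",
                     relative_margin: float = 0.5) -> tuple[float | None, float | None, float]:
    """Minor-allele and ploidy-relative loss fractions for one arm.

    Returns ``(zero_minor_fraction, relative_loss_fraction,
    sample_mean_total_cn)`` where the relative rule counts arm length with
    total copy number <= sample mean − ``relative_margin`` (the mean is the
    length-weighted genome-wide average). Fractions are None when the arm
    is uncovered.
    """
    if profile.value_kind != ALLELE:
        raise InvalidArgumentError("arm_loh_fraction requires an allele-specific profile")
    seg = profile.segments
    if len(seg) == 0:
        raise DegenerateInputError(f"{profile.sample_id}: empty profile")
    lengths_all = profile.lengths.astype(float)
    mean_total = float(np.average(seg["total_cn"].to_numpy(dtype=float), weights=lengths_all))
    chrom, a_start, a_end = genome.arm_bounds(arm)
    on = _clip_to_arm(seg, chrom, a_start, a_end)
    if len(on) == 0:
        logger.warning("%s: no allele-specific segment overlaps arm %s", profile.sample_id, arm)
        return None, None, mean_total
    lengths = (on["end"] - on["start"] + 1).to_numpy(dtype=float)
    covered = lengths.sum()
    zero_minor = float(lengths[on["minor_cn"].to_numpy() == 0].sum() / covered)
    rel_lost = on["total_cn"].to_numpy(dtype=float) <= mean_total - relative_margin
    relative = float(lengths[rel_lost].sum() / covered)
    return zero_minor, relative, mean_total


def combined_3p_call(log2_fraction: float | None, zero_minor_fraction: float | None,
                     lost_cutoff: float = 0.8) -> str:
    """Either-method arm-loss call: lost if any available estimator reports a
    loss fraction >= ``lost_cutoff``; negligible if all available estimators
    fall below; indeterminate when neither is available."""
    available = [f for f in (log2_fraction, zero_minor_fraction) if f is not None]
    if not available:
        return "indeterminate"
    return "lost" if max(available) >= lost_cutoff else "negligible"


def arm_loss_report(
    log2_profiles: dict[str, SegmentProfile],
    allele_profiles: dict[str, SegmentProfile],
    genome: GenomeModel,
    arm: str = "3p",
    loss_thresh: float = -0.2,
    lost_cutoff: float = 0.8,
) -> list[ArmLossResult]:
    """Combine both arm-loss estimators for every sample seen in either view."""
    out = []
    for sid in sorted(set(log2_profiles) | set(allele_profiles)):
        res = ArmLossResult(sid, arm)
        if sid in log2_profiles:
            res.log2_loss_fraction = arm_loss_fraction(
                log2_profiles[sid], genome, arm, loss_thresh)
        if sid in allele_profiles:
            zm, rel, mean_total = arm_loh_fraction(allele_profiles[sid], genome, arm)
            res.zero_minor_fraction = zm
            res.relative_loss_fraction = rel
            res.sample_mean_total_cn = mean_total
        res.combined_call = combined_3p_call(
            res.log2_loss_fraction, res.zero_minor_fraction, lost_cutoff)
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Clustering


def cluster_profiles(gene_matrix: GeneMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering with 1 − Spearman distance.

    Correlations use pairwise-complete genes. Samples whose genes are all
    missing are excluded with a warning. Returns the SciPy linkage matrix
    and the clustered sample ids (in input order).
    """
    values = gene_matrix.values
    all_missing = values.isna().all(axis=0)
    if all_missing.any():
        logger.warning("excluding %d all-missing samples from clustering",
                       int(all_missing.sum()))
        values = values.loc[:, ~all_missing]
    if values.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 samples to cluster")
    gm = GeneMatrix(values, kind=gene_matrix.kind)
    rho = profile_correlation(gm, gm, method="spearman")
    dist = 1.0 - rho.to_numpy()
    if np.isnan(dist).any():
        raise InvalidArgumentError("sample pair with fewer than 3 shared genes")
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)  # symmetrize fp jitter
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return linkage, list(values.columns)


def cut_and_summarize(linkage: np.ndarray, sample_ids: list[str],
                      group_labels: pd.Series, cut_height: float = 0.9) -> ClusterResult:
    """Cut the dendrogram at ``cut_height`` and cross-tabulate composition.

    Clusters are the connected components joined by merges at height
    <= ``cut_height``. Cluster ids are renumbered 1..k in order of first
    appearance among the samples.
    """
    if cut_height < 0:
        raise InvalidArgumentError("cut height must be >= 0")
    flat = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    # renumber in order of first appearance for stable reporting
    remap: dict[int, int] = {}
    for c in flat:
        if c not in remap:
            remap[c] = len(remap) + 1
    labels = pd.Series([remap[c] for c in flat], index=sample_ids, name="cluster")
    groups = group_labels.reindex(sample_ids)
    composition = pd.crosstab(labels, groups)
    composition.index.name = "cluster"
    return ClusterResult(linkage, sample_ids, cut_height, labels, composition)


def assign_cell_line_subtype(result: ClusterResult, tumour_subtypes: pd.Series,
                             cell_line_ids: list[str], min_tumours: int = 5) -> pd.Series:
    """Call each cell line by the majority tumour subtype of its cluster.

    A cell line in a cluster with fewer than ``min_tumours`` tumours — or a
    tied majority — is an ``outlier`` (cell lines clustering on their own
    do not inherit a subtype). The calls are also stored on ``result``.
    """
    calls = {}
    for cl in cell_line_ids:
        if cl not in result.labels.index:
            calls[cl] = "outlier"
            continue
        members = result.labels.index[result.labels == result.labels[cl]]
        tumours = tumour_subtypes.reindex(members).dropna()
        if len(tumours) < min_tumours:
            calls[cl] = "outlier"
            continue
        counts = tumours.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            calls[cl] = "outlier"
        else:
            calls[cl] = f"{counts.index[0]}-like"
    series = pd.Series(calls, name="subtype_call")
    result.cell_line_calls = series
    return series


def linkage_to_newick(linkage: np.ndarray, sample_ids: list[str]) -> str:
    """Export a SciPy linkage matrix as a Newick string with branch heights."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, sample_ids)
    return str(tree)
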