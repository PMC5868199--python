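"""Downstream ChIP-seq analysis for validating predicted TF-target modules.

Consumes called peaks (narrowPeak-like tables with per-sample read counts),
filters them by FDR and read support, maps them to genes by summit-to-TSS
distance, ranks genes by peak count, and tests concordance between ChIP
target genes and network-predicted modules.  Differential occupancy between
genotype groups reuses the negative-binomial count test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrich import _fisher_one_sided, _odds_ratios
from .nbglm import nb_lrt_two_group
from .priors import GeneAnnotation

__all__ = [
    "PeakTable",
    "PeakGeneMap",
    "filter_peaks",
    "distance_to_nearest_tss",
    "map_peaks_to_genes",
    "qualitative_overlap",
    "OverlapSummary",
    "occupancy_correlation",
    "module_chip_concordance",
    "differential_occupancy",
]

PEAK_COLS = ["chrom", "start", "end", "summit", "fdr"]


@dataclass
class PeakTable:
    """Peak intervals with summits, FDR and per-sample read counts.

    ``frame`` holds chrom/start/end/summit/fdr plus one column per sample;
    ``groups`` maps sample column -> group label (e.g. mutant / wildtype).
    """

    frame: pd.DataFrame
    sample_columns: tuple[str, ...]
    groups: dict[str, str]

    def __post_init__(self):
        missing = set(PEAK_COLS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        bad = ~(
            (self.frame["summit"] >= self.frame["start"])
            & (self.frame["summit"] < self.frame["end"])
        )
        if bad.any():
            raise ValueError("peak summits must lie within their intervals")
        if ((self.frame["fdr"] < 0) | (self.frame["fdr"] > 1)).any():
            raise ValueError("peak FDR values must lie in [0, 1]")

    def __len__(self):
        return len(self.frame)

    def counts(self) -> np.ndarray:
        return self.frame[list(self.sample_columns)].to_numpy(dtype=float)


@dataclass
class PeakGeneMap:
    """Peaks assigned to genes by TSS distance, with per-gene counts/ranks."""

    gene_stats: pd.DataFrame   # index gene: n_peaks, rank, top_target
    peak_distances: pd.Series  # per peak: distance to nearest TSS (NaN if none)
    window_bp: int
    mean_count: float
    sd_count: float

    def top_targets(self) -> set[str]:
        return set(self.gene_stats.index[self.gene_stats["top_target"]])

    def peak_positive_genes(self) -> set[str]:
        return set(self.gene_stats.index[self.gene_stats["n_peaks"] > 0])


def filter_peaks(
    peaks: PeakTable,
    fdr_threshold: float = 0.01,
    min_count: int = 10,
    min_samples: int = 2,
) -> PeakTable:
    """Retain peaks with FDR strictly below threshold and read support.

    Read support requires a count of at least ``min_count`` in at least
    ``min_samples`` individual samples.
    """
    if len(peaks.sample_columns) < min_samples:
        raise ValueError("fewer sample columns than min_samples")
    counts = peaks.counts()
    support = (counts >= min_count).sum(axis=1) >= min_samples
    keep = (peaks.frame["fdr"].to_numpy() < fdr_threshold) & support
    return PeakTable(
        frame=peaks.frame[keep].reset_index(drop=True),
        sample_columns=peaks.sample_columns,
        groups=dict(peaks.groups),
    )


def _tss_arrays(annotations: list[GeneAnnotation]):
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in annotations:
        for tss in g.tss_positions:
            by_chrom.setdefault(g.chrom, []).append((tss, g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs], dtype=object),
        )
    return out


def distance_to_nearest_tss(
    peaks: PeakTable, annotations: list[GeneAnnotation]
) -> pd.Series:
    """Per-peak distance |summit - tss| to the nearest annotated TSS.

    Peaks on chromosomes without annotated genes get NaN.
    """
    tss = _tss_arrays(annotations)
    dist = np.full(len(peaks), np.nan)
    for chrom, grp in peaks.frame.groupby("chrom"):
        if chrom not in tss:
            continue
        positions, _ = tss[chrom]
        summits = grp["summit"].to_numpy()
        idx = np.searchsorted(positions, summits)
        left = np.abs(summits - positions[np.clip(idx - 1, 0, len(positions) - 1)])
        right = np.abs(summits - positions[np.clip(idx, 0, len(positions) - 1)])
        dist[grp.index.to_numpy()] = np.minimum(left, right)
    return pd.Series(dist, index=peaks.frame.index, name="tss_distance")


def map_peaks_to_genes(
    peaks: PeakTable,
    annotations: list[GeneAnnotation],
    window_bp: int = 10_000,
    *,
    use_summit: bool = True,
    sd_multiplier: float = 2.0,
) -> PeakGeneMap:
    """Assign peaks to genes within a TSS window and rank genes by peak count.

    A peak assigns to a gene when its summit lies within ``window_bp``
    (inclusive) of any TSS of the gene; with ``use_summit=False`` the
    distance is measured from the nearest peak edge instead.  One peak may
    assign to several genes.  Genes are ranked by peak count (dense ranking,
    ties share a rank) and flagged as top targets when their count exceeds
    mean + ``sd_multiplier`` * SD over all annotated genes (population SD,
    zero-count genes included).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    annotations = [g for g in annotations if g.tss_positions]
    gene_ids = [g.gene_id for g in annotations]
    n_peaks = {g: 0 for g in gene_ids}
    tss = _tss_arrays(annotations)
    for row in peaks.frame.itertuples():
        if row.chrom not in tss:
            continue
        positions, ids = tss[row.chrom]
        if use_summit:
            d = np.abs(positions - row.summit)
        else:
            d = np.maximum(
                0, np.maximum(row.start - positions, positions - (row.end - 1))
            )
        hit_genes = set(ids[d <= window_bp])
        for g in hit_genes:
            n_peaks[g] += 1
    stats_df = pd.DataFrame(
        {"n_peaks": pd.Series(n_peaks)}, index=pd.Index(gene_ids, name="gene")
    )
    counts = stats_df["n_peaks"].to_numpy(dtype=float)
    mean, sd = float(counts.mean()), float(counts.std(ddof=0))
    stats_df["rank"] = stats_df["n_peaks"].rank(method="dense", ascending=False).astype(int)
    stats_df["top_target"] = stats_df["n_peaks"] > mean + sd_multiplier * sd
    return PeakGeneMap(
        gene_stats=stats_df,
        peak_distances=distance_to_nearest_tss(peaks, annotations),
        window_bp=window_bp,
        mean_count=mean,
        sd_count=sd,
    )


@dataclass
class OverlapSummary:
    """Qualitative peak overlap between two peak sets (by >= 1 bp).

    Multi-overlaps make the tally asymmetric: an A peak spanning two B peaks
    counts once on the A side while both B peaks count as shared, so the
    shared counts are reported per side rather than as one number.
    """

    a_shared: int
    a_only: int
    b_shared: int
    b_only: int

    @property
    def n_a(self):
        return self.a_shared + self.a_only

    @property
    def n_b(self):
        return self.b_shared + self.b_only


def _overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(query), dtype=bool)
    for chrom, grp in query.groupby("chrom"):
        sub = subject[subject["chrom"] == chrom].sort_values("start")
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        max_end = np.maximum.accumulate(ends)
        for i, (s, e) in zip(grp.index, zip(grp["start"], grp["end"])):
            j = np.searchsorted(starts, e, side="left")
            mask[i] = bool(j > 0 and (max_end[:j] > s).any())
    return mask


def qualitative_overlap(peaks_a: PeakTable, peaks_b: PeakTable) -> OverlapSummary:
    """Counts of shared and exclusive peaks between two sets (>= 1 bp)."""
    fa = peaks_a.frame.reset_index(drop=True)
    fb = peaks_b.frame.reset_index(drop=True)
    a_shared = int(_overlap_mask(fa, fb).sum())
    b_shared = int(_overlap_mask(fb, fa).sum())
    return OverlapSummary(
        a_shared=a_shared,
        a_only=len(fa) - a_shared,
        b_shared=b_shared,
        b_only=len(fb) - b_shared,
    )


def occupancy_correlation(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    restrict: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two occupancy signals over genomic regions."""
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if restrict is not None:
        a, b = a[restrict], b[restrict]
    if len(a) < 3:
        raise ValueError("need at least 3 regions")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("signals must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance signal")
    return float(stats.pearsonr(a, b)[0])


def module_chip_concordance(
    module_targets: set[str],
    peak_gene_map: PeakGeneMap,
    universe: set[str] | None = None,
):
    """Fisher test: module membership vs having >= 1 peak within the window.

    Returns ``(overlap, odds_ratio, p)``; the universe defaults to all
    annotated genes in the map.
    """
    if universe is None:
        universe = set(peak_gene_map.gene_stats.index)
    universe = set(universe)
    module = set(module_targets) & universe
    if not module:
        raise ValueError("module empty after universe intersection")
    positive = peak_gene_map.peak_positive_genes() & universe
    a = len(module & positive)
    b = len(module) - a
    c = len(positive) - a
    d = len(universe) - a - b - c
    raw, _ = _odds_ratios(a, b, c, d)
    return a, raw, _fisher_one_sided(a, b, c, d)


def differential_occupancy(peaks: PeakTable, case_group: str) -> pd.DataFrame:
    """Per-peak NB test of differential occupancy between genotype groups.

    ``case_group`` names the group treated as the case (e.g. the mutant).
    Returns per-peak log2 fold change, P, and BH FDR; the fraction of peaks
    with weaker occupancy in the case group is in ``.attrs['frac_weaker']``.
    """
    group_of = peaks.groups
    is_case = np.array([group_of[s] == case_group for s in peaks.sample_columns])
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    res = nb_lrt_two_group(peaks.counts(), is_case)
    out = pd.DataFrame(
        {
            "log2_fc": res["log2_fc"],
            "pvalue": res["pvalue"],
        },
        index=peaks.frame.index,
    )
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out.attrs["frac_weaker"] = float((out["log2_fc"] < 0).mean())
    return out
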