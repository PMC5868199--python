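"""Construction of the TF -> gene candidate-regulator prior.

A transcription factor is a *candidate* regulator of a gene when at least one
instance of a motif recognized by that TF falls inside a DNase-I genomic
footprint located within a fixed window (default +/- 5 kb) of one of the
gene's transcription start sites.  Footprint calling and motif scanning are
upstream tools; this module consumes their interval output.

Coordinates follow the BED dialect: 0-based, half-open ``[start, end)``.  The
TSS window is ``[tss - w, tss + w + 1)`` so that positions exactly w bases up-
or downstream of the TSS are included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneAnnotation",
    "PriorMatrix",
    "merge_intervals",
    "intersect_footprints_motifs",
    "map_sites_to_genes",
    "evaluate_prior_against_reference",
]

FOOTPRINT_COLS = ["chrom", "start", "end"]
MOTIF_HIT_COLS = ["chrom", "start", "end", "motif_id"]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with one TSS per annotated transcript."""

    gene_id: str
    chrom: str
    strand: str
    tss_positions: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class PriorMatrix:
    """Binary TF x gene incidence with per-pair supporting-site counts.

    ``site_counts`` maps (tf, gene) -> number of distinct genomic sites
    supporting the pair; incidence is exactly ``site_count > 0``.
    """

    tfs: tuple[str, ...]
    genes: tuple[str, ...]
    site_counts: dict[tuple[str, str], int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tfs = tuple(self.tfs)
        self.genes = tuple(self.genes)
        self._by_gene: dict[str, list[str]] = {}
        for (tf, gene), n in self.site_counts.items():
            if n <= 0:
                raise ValueError("site counts must be positive")
            self._by_gene.setdefault(gene, []).append(tf)
        for tf_list in self._by_gene.values():
            tf_list.sort()

    @property
    def n_edges(self) -> int:
        return len(self.site_counts)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.site_counts)

    def tfs_for_gene(self, gene: str) -> list[str]:
        return list(self._by_gene.get(gene, []))

    def targets_of(self, tf: str) -> set[str]:
        return {g for (t, g) in self.site_counts if t == tf}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.site_counts.items())
        return pd.DataFrame(
            [(tf, gene, n) for (tf, gene), n in rows],
            columns=["tf", "gene", "n_sites"],
        )

    @classmethod
    def from_edges(cls, edges, tfs=None, genes=None, metadata=None) -> "PriorMatrix":
        """Build from an iterable of (tf, gene) or (tf, gene, n_sites)."""
        counts: dict[tuple[str, str], int] = {}
        for e in edges:
            tf, gene = e[0], e[1]
            n = int(e[2]) if len(e) > 2 else 1
            counts[(tf, gene)] = counts.get((tf, gene), 0) + n
        tfs = tuple(tfs) if tfs is not None else tuple(sorted({t for t, _ in counts}))
        genes = tuple(genes) if genes is not None else tuple(sorted({g for _, g in counts}))
        return cls(tfs, genes, counts, metadata or {})


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union possibly-overlapping intervals into disjoint ones, per chromosome."""
    pieces = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": merged_s, "end": merged_e}))
    if not pieces:
        return pd.DataFrame(columns=FOOTPRINT_COLS)
    return pd.concat(pieces, ignore_index=True)


def _validate_intervals(df: pd.DataFrame, what: str):
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValueError(f"{what}: intervals must satisfy start < end")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{what}: negative coordinates")


def intersect_footprints_motifs(
    footprints: pd.DataFrame, motif_hits: pd.DataFrame
) -> pd.DataFrame:
    """Retain motif hits overlapping a footprint by at least 1 bp.

    Footprints (possibly pooled from many tissues) are unioned before the
    intersection, so a hit is kept if it overlaps occupied sequence anywhere.
    An empty footprint set yields an empty result with a warning.
    """
    _validate_intervals(footprints, "footprints")
    _validate_intervals(motif_hits, "motif hits")
    if len(footprints) == 0:
        warnings.warn("empty footprint set: no motif hits retained", stacklevel=2)
        return motif_hits.iloc[0:0].copy()
    merged = merge_intervals(footprints)
    keep = np.zeros(len(motif_hits), dtype=bool)
    hit_idx = np.arange(len(motif_hits))
    for chrom, grp in motif_hits.groupby("chrom", sort=False):
        fp = merged[merged["chrom"] == chrom]
        if len(fp) == 0:
            continue
        fp_starts = fp["start"].to_numpy()
        fp_ends = fp["end"].to_numpy()
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # merged intervals are disjoint & sorted: the first interval whose end
        # exceeds the hit start is the only candidate for overlap
        cand = np.searchsorted(fp_ends, s, side="right")
        ok = cand < len(fp_starts)
        ok[ok] &= fp_starts[cand[ok]] < e[ok]
        keep[hit_idx[motif_hits["chrom"] == chrom]] = ok
    return motif_hits[keep].copy()


def map_sites_to_genes(
    tfbs: pd.DataFrame,
    genes: list[GeneAnnotation],
    motif_map: dict[str, set[str]],
    window_bp: int = 5000,
    *,
    allow_self: bool = False,
) -> PriorMatrix:
    """Assign footprint-supported motif hits to genes by TSS proximity.

    A site supports (tf, gene) when its interval overlaps
    ``[tss - window_bp, tss + window_bp + 1)`` for *any* TSS of the gene, and
    the motif is recognized by the TF.  A motif recognized by several family
    members yields one supporting site for each.  Each genomic site counts at
    most once per (tf, gene) pair even when several TSSs of the gene match.
    Self-pairs (a TF within its own gene's window) are dropped unless
    ``allow_self``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    _validate_intervals(tfbs, "TFBS")
    trees: dict[str, IntervalTree] = {}
    all_gene_ids = []
    for g in genes:
        all_gene_ids.append(g.gene_id)
        if len(g.tss_positions) == 0:
            raise ValueError(f"gene {g.gene_id} has no annotated TSS")
        tree = trees.setdefault(g.chrom, IntervalTree())
        for tss in g.tss_positions:
            tree.addi(max(0, tss - window_bp), tss + window_bp + 1, g.gene_id)

    counts: dict[tuple[str, str], int] = {}
    n_unmapped = 0
    for chrom, s, e, motif in zip(
        tfbs["chrom"], tfbs["start"], tfbs["end"], tfbs["motif_id"]
    ):
        tf_set = motif_map.get(motif)
        if not tf_set:
            n_unmapped += 1
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        matched_genes = {iv.data for iv in tree.overlap(s, e)}
        for gene_id in matched_genes:
            for tf in tf_set:
                if tf == gene_id and not allow_self:
                    continue
                counts[(tf, gene_id)] = counts.get((tf, gene_id), 0) + 1

    tf_universe = tuple(sorted(set().union(*motif_map.values()))) if motif_map else ()
    return PriorMatrix(
        tfs=tf_universe,
        genes=tuple(sorted(all_gene_ids)),
        site_counts=counts,
        metadata={"window_bp": window_bp, "n_unmapped_motif_hits": n_unmapped},
    )


def evaluate_prior_against_reference(
    prior: PriorMatrix,
    reference_targets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Benchmark predicted target sets against reference (e.g. ChIP) targets.

    For each TF present in both the prior and the reference, computes recall,
    precision, the odds ratio, and a one-sided Fisher P-value on the 2x2 table
    over the stated gene universe, then BH-adjusts across TFs.  TFs with an
    empty reference set (after universe intersection) are skipped.
    """
    universe = set(universe)
    rows = []
    for tf in sorted(reference_targets):
        ref = set(reference_targets[tf]) & universe
        if not ref:
            warnings.warn(f"TF {tf}: empty reference target set, skipped", stacklevel=2)
            continue
        if tf not in prior.tfs:
            warnings.warn(f"TF {tf}: not in prior, skipped", stacklevel=2)
            continue
        pred = prior.targets_of(tf) & universe
        a = len(pred & ref)
        b = len(pred) - a
        c = len(ref) - a
        d = len(universe) - a - b - c
        recall = a / len(ref)
        precision = a / len(pred) if pred else np.nan
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan
        )
        # one-sided (enrichment) Fisher P == hypergeometric upper tail
        p = float(stats.hypergeom.sf(a - 1, len(universe), len(ref), len(pred)))
        rows.append(
            dict(tf=tf, n_pred=len(pred), n_ref=len(ref), overlap=a,
                 recall=recall, precision=precision, odds_ratio=odds, p=p)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
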