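"""Readers and writers for the plain-text formats the pipeline consumes.

Counts/design/prior/peak tables are TSV; intervals are BED; modules and
generic gene sets are GMT; the ground-truth network serializes to JSON.
All formats are round-trippable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import PeakTable
from .priors import GeneAnnotation, PriorMatrix
from .simulate import GroundTruthNetwork, SyntheticStudy
from .trn import TFModule, TRNModel

__all__ = [
    "read_counts", "write_counts",
    "read_design", "write_design",
    "read_bed", "write_bed",
    "read_motif_hits", "write_motif_hits",
    "read_motif_map", "write_motif_map",
    "read_gene_annotations_bed", "write_gene_annotations_bed",
    "read_gene_annotations_gtf",
    "read_prior", "write_prior",
    "read_gmt", "write_gmt", "modules_to_gmt",
    "read_peaks", "write_peaks",
    "read_truth", "write_truth",
    "write_trn", "write_study",
]


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path):
    counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path):
    design.to_csv(path, sep="\t", index_label="sample")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df


def write_bed(intervals: pd.DataFrame, path):
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_motif_hits(path) -> pd.DataFrame:
    df = read_bed(path)
    return df.rename(columns={"name": "motif_id"})


def write_motif_hits(hits: pd.DataFrame, path):
    out = hits.rename(columns={"motif_id": "name"})
    write_bed(out, path)


def read_motif_map(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.motif_id: set(str(row.tfs).split(","))
        for row in df.itertuples()
    }


def write_motif_map(motif_map: dict[str, set[str]], path):
    rows = [(m, ",".join(sorted(tfs))) for m, tfs in sorted(motif_map.items())]
    pd.DataFrame(rows, columns=["motif_id", "tfs"]).to_csv(path, sep="\t", index=False)


def write_gene_annotations_bed(annotations: list[GeneAnnotation], path):
    """One BED6 row per TSS: chrom, tss, tss+1, gene_id, 0, strand."""
    rows = []
    for g in annotations:
        for tss in g.tss_positions:
            rows.append((g.chrom, tss, tss + 1, g.gene_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotations_bed(path) -> list[GeneAnnotation]:
    df = read_bed(path)
    out = []
    for (gene, chrom, strand), grp in df.groupby(
        ["name", "chrom", "strand"], sort=True
    ):
        out.append(GeneAnnotation(gene, chrom, strand, tuple(sorted(grp["start"]))))
    return out


def read_gene_annotations_gtf(path) -> list[GeneAnnotation]:
    """Reduce GTF transcript records to per-gene TSS lists.

    The TSS is the transcript start on '+' strands and (end - 1) on '-'
    strands (GTF is 1-based inclusive; positions are converted to 0-based).
    """
    by_gene: dict[tuple[str, str, str], set[int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for piece in attrs.split(";"):
                piece = piece.strip()
                if piece.startswith("gene_id"):
                    gene_id = piece.split()[1].strip('"')
                    break
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1
            by_gene.setdefault((gene_id, chrom, strand), set()).add(tss)
    return [
        GeneAnnotation(g, c, s, tuple(sorted(tss)))
        for (g, c, s), tss in sorted(by_gene.items())
    ]


def read_prior(path) -> PriorMatrix:
    df = pd.read_csv(path, sep="\t")
    return PriorMatrix.from_edges(
        list(df[["tf", "gene", "n_sites"]].itertuples(index=False, name=None))
    )


def write_prior(prior: PriorMatrix, path):
    prior.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "."):
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def modules_to_gmt(modules: dict[str, TFModule], path):
    write_gmt({tf: set(m.targets) for tf, m in modules.items()}, path,
              description="TF-target module")


def read_peaks(path, sample_columns: list[str], groups: dict[str, str]) -> PeakTable:
    frame = pd.read_csv(path, sep="\t")
    return PeakTable(frame=frame, sample_columns=tuple(sample_columns), groups=groups)


def write_peaks(peaks: PeakTable, path):
    peaks.frame.to_csv(path, sep="\t", index=False)


def write_truth(truth: GroundTruthNetwork, path):
    payload = {
        "tf_ids": list(truth.tf_ids),
        "gene_ids": list(truth.gene_ids),
        "edges": [[t, g, w] for (t, g), w in sorted(truth.edges.items())],
        "tf_base_activity": truth.tf_base_activity,
        "perturbation": [
            [t, a, age, s] for (t, a, age), s in sorted(truth.perturbation.items())
        ],
        "core_tf_ids": list(truth.core_tf_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> GroundTruthNetwork:
    payload = json.loads(Path(path).read_text())
    return GroundTruthNetwork(
        tf_ids=tuple(payload["tf_ids"]),
        gene_ids=tuple(payload["gene_ids"]),
        edges={(t, g): w for t, g, w in payload["edges"]},
        tf_base_activity=payload["tf_base_activity"],
        perturbation={(t, a, age): s for t, a, age, s in payload["perturbation"]},
        core_tf_ids=tuple(payload["core_tf_ids"]),
    )


def write_trn(model: TRNModel, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    model.fits.to_csv(outdir / "gene_fits.tsv", sep="\t", index=False)


def write_study(study: SyntheticStudy, outdir):
    """Write every synthetic artifact as plain text under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, outdir / "counts.tsv")
    write_design(study.design, outdir / "design.tsv")
    write_prior(study.prior, outdir / "prior.tsv")
    write_bed(study.intervals.footprints, outdir / "footprints.bed")
    write_motif_hits(study.intervals.motif_hits, outdir / "motif_hits.bed")
    write_motif_map(study.intervals.motif_map, outdir / "motif_map.tsv")
    write_gene_annotations_bed(study.intervals.annotations, outdir / "genes.bed")
    write_peaks(study.intervals.peaks, outdir / "peaks.tsv")
    write_truth(study.truth, outdir / "truth.json")
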