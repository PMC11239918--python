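"""Copy-number segment signatures and 4-cluster nearest-centroid assignment.

Segmented copy-number profiles (SEG format, mean log2-ratio per segment)
are mapped to gene-level signals by maximal overlap, averaged within a
set of named genomic segments (519 in the full model), scored against a
linear signature model (one coefficient vector per signature over the
segments), and finally assigned to one of four clusters by Euclidean
distance to cluster centroids in signature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class CNModelError(ValueError):
    pass


class CNQualityError(ValueError):
    """Raised when too many segments are missing to score a sample reliably."""


@dataclass(frozen=True)
class SegmentRecord:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    cn_signal: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment start must be < end, got [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class SegmentProfile:
    sample_id: str
    records: tuple[SegmentRecord, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[SegmentRecord]] = {}
        for r in self.records:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for chrom, recs in by_chrom.items():
            recs = sorted(recs, key=lambda r: r.start)
            for a, b in zip(recs, recs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene id -> (chromosome, start, end), 1-based inclusive."""

    table: pd.DataFrame  # index: gene id; columns: chromosome, start, end

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicated gene ids in annotation")
        bad = self.table[self.table["start"] >= self.table["end"]]
        if len(bad):
            raise ValueError(f"gene with start >= end: {bad.index[0]!r}")


@dataclass(frozen=True)
class CNSignatureModel:
    """Linear CN signature model plus cluster centroids.

    coefficients: signatures x segments; centroids: clusters x signatures.
    Optional per-signature standardization (means/sds) is applied to
    scores before computing Euclidean distances when provided.
    """

    coefficients: pd.DataFrame
    centroids: pd.DataFrame
    standardize_means: pd.Series | None = None
    standardize_sds: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.coefficients.index.equals(self.centroids.columns):
            if set(self.coefficients.index) != set(self.centroids.columns):
                raise CNModelError(
                    "centroid signature names do not match coefficient rows"
                )
            object.__setattr__(
                self, "centroids", self.centroids[self.coefficients.index]
            )
        if self.standardize_means is not None or self.standardize_sds is not None:
            if self.standardize_means is None or self.standardize_sds is None:
                raise CNModelError("standardization needs both means and sds")
            if (self.standardize_sds <= 0).any():
                raise CNModelError("standardization sds must be positive")

    @property
    def segments(self) -> pd.Index:
        return self.coefficients.columns

    @property
    def signatures(self) -> pd.Index:
        return self.coefficients.index


def map_segments_to_genes(
    profile: SegmentProfile, annotation: GeneAnnotation
) -> pd.Series:
    """Gene-level CN signal: each gene takes the signal of the segment
    with maximal base-pair overlap; genes overlapping nothing are absent."""
    seg_by_chrom: dict[str, list[SegmentRecord]] = {}
    for r in profile.records:
        seg_by_chrom.setdefault(r.chromosome, []).append(r)

    genes_out: list[str] = []
    signals_out: list[np.ndarray] = []
    for chrom, genes in annotation.table.groupby("chromosome", sort=False):
        segs = seg_by_chrom.get(chrom)
        if not segs:
            continue
        seg_start = np.array([s.start for s in segs])
        seg_end = np.array([s.end for s in segs])
        seg_signal = np.array([s.cn_signal for s in segs])
        g_start = genes["start"].to_numpy()[:, None]
        g_end = genes["end"].to_numpy()[:, None]
        overlap = np.minimum(g_end, seg_end) - np.maximum(g_start, seg_start) + 1
        best = overlap.argmax(axis=1)
        best_overlap = overlap[np.arange(len(genes)), best]
        hit = best_overlap > 0
        genes_out.extend(genes.index[hit])
        signals_out.append(seg_signal[best[hit]])
    values = np.concatenate(signals_out) if signals_out else np.array([])
    return pd.Series(values, index=genes_out, dtype=float, name=profile.sample_id)


def segment_signal(
    gene_cn: pd.Series, segment_genes: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Per-segment signal: arithmetic mean of member genes present in gene_cn.

    Segments with no present member gene come back NaN; a warning lists
    them.  All-missing input is an error.
    """
    for seg, genes in segment_genes.items():
        if not genes:
            raise CNModelError(f"segment {seg!r} has no member genes")
    member_genes = [g for genes in segment_genes.values() for g in genes]
    member_segs = [s for s, genes in segment_genes.items() for _ in genes]
    vals = gene_cn.reindex(member_genes).to_numpy()
    means = (
        pd.Series(vals, index=member_segs)
        .groupby(level=0, sort=False)
        .mean()  # NaN-skipping; all-NaN group stays NaN
    )
    result = means.reindex(list(segment_genes)).rename(gene_cn.name)
    missing = list(result.index[result.isna()])
    if len(missing) == len(segment_genes):
        raise CNQualityError("no segment has any gene-level signal")
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(segment_genes)} segments have no signal "
            f"(first: {missing[0]!r})",
            stacklevel=2,
        )
    return result


def score_signatures(
    segvec: pd.Series,
    model: CNSignatureModel,
    max_missing_fraction: float = 0.2,
) -> pd.Series:
    """Linear signature scores: dot product of coefficients with segment signals.

    Missing segments contribute 0 (no silent renormalization of a linear
    model); if the missing fraction exceeds ``max_missing_fraction`` the
    sample fails with :class:`CNQualityError`.
    """
    aligned = segvec.reindex(model.segments)
    n_missing = int(aligned.isna().sum())
    frac = n_missing / len(model.segments)
    if frac > max_missing_fraction:
        raise CNQualityError(
            f"{n_missing}/{len(model.segments)} segments missing "
            f"({frac:.0%} > allowed {max_missing_fraction:.0%})"
        )
    x = aligned.fillna(0.0).to_numpy(dtype=float)
    scores = model.coefficients.to_numpy(dtype=float) @ x
    return pd.Series(scores, index=model.signatures, name=segvec.name)


@dataclass(frozen=True)
class ClusterCall:
    cluster: str
    distances: Mapping[str, float]
    tie: bool


def assign_cluster(scores: pd.Series, model: CNSignatureModel) -> ClusterCall:
    """Nearest cluster centroid by Euclidean distance in signature space.

    If the model carries standardization means/sds they are applied to
    the scores first.  Exact distance ties break to the lowest cluster
    label and are flagged.
    """
    aligned = scores.reindex(model.signatures)
    if aligned.isna().any():
        missing = aligned.index[aligned.isna()][0]
        raise CNModelError(f"missing signature score: {missing!r}")
    x = aligned.to_numpy(dtype=float)
    if model.standardize_means is not None:
        mu = model.standardize_means.reindex(model.signatures).to_numpy(dtype=float)
        sd = model.standardize_sds.reindex(model.signatures).to_numpy(dtype=float)
        x = (x - mu) / sd
    dists = {}
    for name, row in model.centroids.iterrows():
        c = row.to_numpy(dtype=float)
        dists[name] = float(np.sqrt(np.sum((x - c) ** 2)))
    best = min(dists.values())
    winners = sorted(n for n, d in dists.items() if abs(d - best) <= 1e-12)
    return ClusterCall(cluster=winners[0], distances=dists, tie=len(winners) > 1)


def score_cohort(
    profiles: Sequence[SegmentProfile],
    annotation: GeneAnnotation,
    segment_genes: Mapping[str, Sequence[str]],
    model: CNSignatureModel,
    max_missing_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Full CN pipeline over a cohort.

    Returns (segment signals samples x segments, signature scores
    samples x signatures, cluster calls per sample).
    """
    seg_rows, score_rows, clusters = {}, {}, {}
    for p in profiles:
        gene_cn = map_segments_to_genes(p, annotation)
        segvec = segment_signal(gene_cn, segment_genes)
        scores = score_signatures(segvec, model, max_missing_fraction)
        seg_rows[p.sample_id] = segvec
        score_rows[p.sample_id] = scores
        clusters[p.sample_id] = assign_cluster(scores, model).cluster
    return (
        pd.DataFrame(seg_rows).T,
        pd.DataFrame(score_rows).T,
        pd.Series(clusters, name="cluster"),
    )
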