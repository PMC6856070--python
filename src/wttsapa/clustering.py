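"""Cluster polyadenylation-adjacent sites into predicted APA sites.

Positions on the same chromosome and strand are grouped by positional
single-linkage: two positions belong to the same cluster iff they are
connected by a chain of gaps each no larger than the window (24 nt by
default, boundary inclusive).  An alternative ``anchor`` mode iteratively
absorbs positions within +/- window of the most abundant remaining
position.  Each cluster reports a representative coordinate — the
highest-count member position, ties broken toward the 3' end of the
cluster's strand — per-sample counts, and the mean mapping quality of its
supporting reads.  The expression filter keeps clusters whose read total
across all samples reaches ``min_total_reads`` (16 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPAN_WARN_NT = 200


@dataclass(frozen=True)
class ClusterParams:
    window: int = 24
    min_total_reads: int = 16
    mode: str = "chain"  # "chain" (single linkage) or "anchor"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_total_reads < 1:
            raise ValueError("min_total_reads must be >= 1")
        if self.mode not in ("chain", "anchor"):
            raise ValueError("mode must be 'chain' or 'anchor'")


@dataclass
class APACluster:
    """A predicted APA site: clustered positions with per-sample counts."""

    cluster_id: str
    chrom: str
    strand: str
    positions_with_counts: dict[int, dict[str, int]]
    representative: int
    mean_mapq: float

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.positions_with_counts), max(self.positions_with_counts))

    @property
    def total_count(self) -> int:
        return sum(
            n for per in self.positions_with_counts.values() for n in per.values()
        )

    def per_sample_counts(self, sample_ids: Sequence[str]) -> np.ndarray:
        out = np.zeros(len(sample_ids), dtype=int)
        for per in self.positions_with_counts.values():
            for j, s in enumerate(sample_ids):
                out[j] += per.get(s, 0)
        return out


def pick_representative(
    positions_with_counts: dict[int, dict[str, int]], strand: str
) -> int:
    """Modal position; ties broken by the 3'-most coordinate on the strand."""
    totals = {p: sum(per.values()) for p, per in positions_with_counts.items()}
    best_count = max(totals.values())
    tied = [p for p, n in totals.items() if n == best_count]
    return max(tied) if strand == "+" else min(tied)


def _chain_partition(positions: Sequence[int], window: int) -> list[list[int]]:
    """Single-linkage partition of sorted unique positions by gap <= window."""
    pos = sorted(set(positions))
    groups: list[list[int]] = []
    for p in pos:
        if groups and p - groups[-1][-1] <= window:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def _anchor_partition(
    counts: dict[int, int], window: int, strand: str
) -> list[list[int]]:
    """Iteratively seed on the modal position and absorb within +/- window."""
    remaining = dict(counts)
    groups = []
    while remaining:
        anchor = pick_representative(
            {p: {"_": n} for p, n in remaining.items()}, strand
        )
        members = [p for p in remaining if abs(p - anchor) <= window]
        groups.append(sorted(members))
        for p in members:
            del remaining[p]
    groups.sort(key=lambda g: g[0])
    return groups


def cluster_sites(
    sites: pd.DataFrame, params: Optional[ClusterParams] = None
) -> list[APACluster]:
    """Cluster a site table into predicted APA sites.

    ``sites`` requires columns chrom, position, strand, sample_id, mapq.
    Output order is deterministic: (chrom, strand, min member position).
    """
    params = params or ClusterParams()
    required = {"chrom", "position", "strand", "sample_id", "mapq"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    clusters: list[APACluster] = []
    if len(sites):
        grouped = sites.groupby(["chrom", "strand"], sort=True)
        for (chrom, strand), sub in grouped:
            pos_counts = sub.groupby("position").size().to_dict()
            if params.mode == "chain":
                groups = _chain_partition(list(pos_counts), params.window)
            else:
                groups = _anchor_partition(pos_counts, params.window, strand)
            by_pos_sample = (
                sub.groupby(["position", "sample_id"]).size().unstack(fill_value=0)
            )
            mapq_by_pos = sub.groupby("position")["mapq"].agg(["sum", "count"])
            for members in groups:
                pwc = {
                    int(p): {
                        s: int(n)
                        for s, n in by_pos_sample.loc[p].items()
                        if n > 0
                    }
                    for p in members
                }
                mq = mapq_by_pos.loc[members]
                mean_mapq = float(mq["sum"].sum() / mq["count"].sum())
                rep = pick_representative(pwc, strand)
                span = max(members) - min(members)
                if span > SPAN_WARN_NT:
                    logger.warning(
                        "cluster at %s:%d spans %d nt (> %d)",
                        chrom, min(members), span, SPAN_WARN_NT,
                    )
                clusters.append(
                    APACluster(
                        cluster_id="",
                        chrom=chrom,
                        strand=strand,
                        positions_with_counts=pwc,
                        representative=rep,
                        mean_mapq=mean_mapq,
                    )
                )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.span[0]))
    for i, c in enumerate(clusters, 1):
        c.cluster_id = f"APA{i:05d}"
    return clusters


def expression_filter(
    clusters: Sequence[APACluster], params: Optional[ClusterParams] = None
) -> tuple[list[APACluster], dict[str, int]]:
    """Keep clusters with total reads >= min_total_reads (inclusive)."""
    params = params or ClusterParams()
    kept = [c for c in clusters if c.total_count >= params.min_total_reads]
    report = {"n_input": len(clusters), "n_kept": len(kept),
              "n_dropped": len(clusters) - len(kept)}
    return kept, report


def clusters_to_frame(
    clusters: Sequence[APACluster], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Cluster table: one row per predicted APA site, one count column per sample."""
    rows = []
    for c in clusters:
        lo, hi = c.span
        row = {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "representative": c.representative,
            "span_start": lo,
            "span_end": hi,
            "total": c.total_count,
            "mean_mapq": c.mean_mapq,
        }
        per = c.per_sample_counts(sample_ids)
        for s, n in zip(sample_ids, per):
            row[s] = int(n)
        rows.append(row)
    cols = [
        "cluster_id", "chrom", "strand", "representative",
        "span_start", "span_end", "total", "mean_mapq", *sample_ids,
    ]
    return pd.DataFrame(rows, columns=cols)
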