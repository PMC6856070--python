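"""End-to-end orchestration: FASTQ -> sites -> clusters -> classes -> DE.

Glues the stage modules together for the common case of a simulated or
on-disk dataset processed with the built-in exact mapper.  Each stage
remains usable on its own; this module only sequences them and carries
the intermediate tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotate, clustering, differential, mapping, preprocess
from .annotate import AnnotParams, GeneModel
from .clustering import ClusterParams
from .differential import DEParams
from .preprocess import PreprocessParams


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    clusters: list
    cluster_table: pd.DataFrame
    classified: list
    class_tally: dict
    preprocess_reports: dict
    map_stats: dict
    de_results: Optional[pd.DataFrame] = None
    de_summary: Optional[dict] = None


def run_pipeline(
    genome: dict[str, str],
    genes: list[GeneModel],
    fastq_by_sample: dict[str, os.PathLike],
    design: pd.DataFrame,
    pre_params: Optional[PreprocessParams] = None,
    cluster_params: Optional[ClusterParams] = None,
    annot_params: Optional[AnnotParams] = None,
    de_params: Optional[DEParams] = None,
    run_differential: bool = True,
    orientation: str = "antisense",
) -> PipelineResult:
    """Process per-sample FASTQ files through the whole pipeline.

    The built-in mapper reports MAPQ 60 for every unique alignment, so
    the default DE parameters here disable the MAPQ>=70 gate
    (``mapq_min=0``); pass explicit ``de_params`` to restore it for
    externally aligned data.
    """
    pre_params = pre_params or PreprocessParams()
    cluster_params = cluster_params or ClusterParams()
    annot_params = annot_params or AnnotParams()
    index = mapping.GenomeIndex(genome)
    all_sites = []
    reports = {}
    stats = {}
    for sample, path in fastq_by_sample.items():
        report = preprocess.PreprocessReport()
        reads = preprocess.preprocess_reads(
            preprocess.iter_fastq(path), pre_params, report
        )
        sites, mstats = mapping.sites_from_reads(reads, index, sample, orientation)
        all_sites.extend(sites)
        reports[sample] = report
        stats[sample] = mstats
    site_table = mapping.sites_to_frame(all_sites)
    clusters = clustering.cluster_sites(site_table, cluster_params)
    kept, _ = clustering.expression_filter(clusters, cluster_params)
    sample_ids = list(design["sample_id"])
    cluster_table = clustering.clusters_to_frame(kept, sample_ids)
    classified, tally = annotate.classify_all(kept, genes, annot_params)
    result = PipelineResult(
        sites=site_table,
        clusters=kept,
        cluster_table=cluster_table,
        classified=classified,
        class_tally=tally,
        preprocess_reports=reports,
        map_stats=stats,
    )
    if run_differential and len(cluster_table):
        de_params = de_params or DEParams(mapq_min=0.0)
        result.de_results, result.de_summary = differential.run_de(
            cluster_table, design, de_params
        )
    return result
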