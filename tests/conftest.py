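import pandas as pd
import pytest

from wttsapa import SimParams, run_pipeline, simulate_dataset
from wttsapa.clustering import APACluster


@pytest.fixture(scope="session")
def sim_params():
    """Default study conditions: 60 sites, 10 per class, 8+8 samples."""
    return SimParams(seed=7)


@pytest.fixture(scope="session")
def sim_dataset(sim_params, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(sim_params, outdir)


@pytest.fixture(scope="session")
def design(sim_dataset):
    return pd.read_csv(sim_dataset["design_tsv"], sep="\t")


@pytest.fixture(scope="session")
def pipeline_result(sim_dataset, design):
    return run_pipeline(
        sim_dataset["genome"], sim_dataset["genes"], sim_dataset["fastq"], design
    )


def make_cluster(chrom, strand, positions, mapq=60.0, cluster_id="c1"):
    """Cluster with given {position: total count} member map, one sample."""
    pwc = {int(p): {"s1": int(n)} for p, n in positions.items()}
    from wttsapa.clustering import pick_representative

    return APACluster(
        cluster_id=cluster_id,
        chrom=chrom,
        strand=strand,
        positions_with_counts=pwc,
        representative=pick_representative(pwc, strand),
        mean_mapq=mapq,
    )


@pytest.fixture
def mk_cluster():
    return make_cluster
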