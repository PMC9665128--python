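import numpy as np
import pandas as pd
import pytest

from epicpipe import synth
from epicpipe.io_formats import BetaMatrix


@pytest.fixture(scope="session")
def toy_config():
    return synth.SimConfig(
        seed=7,
        genome={"chr1": 30_000, "chr2": 20_000, "chrX": 10_000},
        n_probes=400,
        n_transcripts=60,
        n_cell_lines=3,
        n_islands=15,
    )


@pytest.fixture(scope="session")
def toy_fixtures(toy_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return synth.gen_genome_fixtures(toy_config, outdir)


def make_matrix(values: dict, probe_ids=None, detp=None, meta=None) -> BetaMatrix:
    df = pd.DataFrame(values)
    if probe_ids is not None:
        df.index = pd.Index(probe_ids, name="probe_id")
    else:
        df.index = pd.Index([f"cg{i:06d}" for i in range(len(df))], name="probe_id")
    p = None
    if detp is not None:
        p = pd.DataFrame(detp)
        p.index = df.index
        p.columns = df.columns
    return BetaMatrix(df, p, meta)


@pytest.fixture()
def simple_probes():
    return pd.DataFrame(
        {
            "probe_id": ["cg000001", "cg000002", "cg000003", "cg000004"],
            "chrom": ["chr1", "chr1", "chrX", "chr2"],
            "position": [151, 251, 51, 1001],
            "pos0": [150, 250, 50, 1000],
            "design_type": ["I", "II", "II", "I"],
            "platform": "850k",
            "cross_reactive": [False, True, False, False],
            "snp_overlap": [False, False, False, True],
        }
    )
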