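import logging

import numpy as np
import pandas as pd
import pytest

from epitwin.qc import filter_probes
from epitwin.simulate import SimulationConfig, generate_cohort
from epitwin.types import MethylationMatrix, ProbeRecord, SampleSheet

logging.getLogger("epitwin").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_cohort():
    """One 20k-probe, 5-pair cohort under default study conditions."""
    return generate_cohort(SimulationConfig(seed=1, n_probes=20_000, n_pairs=5))


@pytest.fixture(scope="session")
def default_kept(default_cohort):
    kept, _ = filter_probes(default_cohort.manifest)
    return kept


@pytest.fixture()
def tiny_manifest():
    """Ten hand-built probes on two chromosomes."""
    return [
        ProbeRecord(f"cg{i:02d}", "chr1", 100 + 150 * i, feature_class="promoter")
        for i in range(6)
    ] + [
        ProbeRecord(f"cg{i:02d}", "chr2", 500 + 200 * (i - 6))
        for i in range(6, 10)
    ]


@pytest.fixture()
def paper_design_sheet():
    """Two complete MZ pairs plus one singleton co-twin (5 individuals)."""
    rows = [
        ("s31", "31", "MZ3"),
        ("s32", "32", "MZ3"),
        ("s21", "21", "MZ2"),
        ("s22", "22", "MZ2"),
        ("s11", "11", "MZ1"),
    ]
    return SampleSheet(
        pd.DataFrame(
            [
                {
                    "sample_id": s,
                    "individual_id": i,
                    "pair_id": p,
                    "replicate_id": "r1",
                    "time_point": 2,
                    "platform": "dense",
                }
                for s, i, p in rows
            ]
        )
    )


def make_matrix(probe_ids, data):
    """Beta matrix from a {sample: values} dict."""
    return MethylationMatrix(pd.DataFrame(data, index=probe_ids, dtype=float))
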