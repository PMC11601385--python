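"""Shared fixtures: a small fast benchmark for unit tests and the full
desk-scale benchmark (assembled once per session) for the end-to-end
property tests."""

import numpy as np
import pandas as pd
import pytest

from drugsens.dataset import assemble
from drugsens.signatures import build_tcs_table, filter_level4, rescale_unit
from drugsens.simulate import SimConfig, make_benchmark


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_cell_lines=12, n_tissues=3, n_compounds=6, n_genes=60,
                     n_assay_cell_lines=3, seed=1234)


@pytest.fixture(scope="session")
def small_bench(small_cfg):
    return make_benchmark(small_cfg)


def assemble_benchmark(bench):
    """Standard assembly: TCS + expression, unit-scaled, truth labels."""
    tcs = rescale_unit(build_tcs_table(filter_level4(
        bench.perturbations, timepoint_h=bench.cfg.timepoint_hours)))
    cells = rescale_unit(bench.expression)
    records = bench.truth.pairs.rename(columns={"dss3_true": "score"})[
        ["cell_line_id", "compound_id", "score", "label"]].copy()
    records["metric"] = "DSS3"
    inputs, report = assemble(records, tcs, cells, tissues=bench.tissues)
    return inputs, report


@pytest.fixture(scope="session")
def small_inputs(small_bench):
    inputs, _ = assemble_benchmark(small_bench)
    return inputs


@pytest.fixture(scope="session")
def benchmark_inputs():
    """The default ~20,000-record planted-signal benchmark, assembled."""
    bench = make_benchmark(SimConfig())
    inputs, report = assemble_benchmark(bench)
    assert report["n_assembled"] == 20000
    return inputs
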