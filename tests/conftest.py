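import numpy as np
import pandas as pd
import pytest

import methsplice as ms


@pytest.fixture(scope="session")
def small_config():
    return ms.SimulationConfig(
        seed=11,
        n_genes=120,
        n_chromosomes=2,
        chromosome_length=600_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One small simulated dataset shared by read-only tests."""
    models, truth = ms.generate_annotation(small_config)
    calls, site_truth = ms.generate_methylation(models, truth, small_config)
    expr = ms.generate_expression(models, truth, small_config)
    cons, cons_truth = ms.generate_conservation(truth, small_config)
    truth.sites = site_truth
    truth.conservation = cons_truth
    return {
        "config": small_config,
        "models": models,
        "truth": truth,
        "calls": calls,
        "sites": ms.CpGSites(calls),
        "expression": expr,
        "conservation": cons,
    }


@pytest.fixture()
def tiny_sites():
    """Hand-built site table: chr1 has mCG {0.5, 1.0, 0.0} in [0, 200)."""
    frame = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [10, 50, 120, 30],
            "meth_reads": [2, 5, 0, 3],
            "unmeth_reads": [2, 0, 4, 1],
        }
    )
    return ms.CpGSites(frame)


def brute_force_region(frame: pd.DataFrame, chrom: str, start: int, end: int):
    """Naive full-scan oracle for region methylation sums."""
    total = frame["meth_reads"] + frame["unmeth_reads"]
    mcg = frame["meth_reads"] / total
    mask = (frame["chrom"] == chrom) & (frame["pos"] >= start) & (frame["pos"] < end)
    return int(mask.sum()), float(mcg[mask].sum())
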