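import numpy as np
import pandas as pd
import pytest

from ecdyatlas.config import SimulationConfig
from ecdyatlas.catalog import call_responsive, fisher_combine, summarize_catalog
from ecdyatlas.diffexpr import (estimate_size_factors, fit_dispersions,
                                run_de_all_lines)
from ecdyatlas.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A compact configuration exercising every planted structure."""
    return SimulationConfig(
        n_lines=12, n_genes=700, n_tfs=12, n_widespread=60, n_restricted=120,
        n_weak=30, operon_pair_count=10, divergent_pair_count=10,
        tss_switch_count=2, isoform_coupled_count=3, bidirectional_count=4,
        timecourse_lines=("CL01", "CL02"), frac_replicated_lines=0.2,
        seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """DE tables, Fisher records, and the summarized catalog for the small run."""
    cm = small_dataset.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    tables = run_de_all_lines(cm, sf, disp)
    fi = fisher_combine(tables, "induction")
    fr = fisher_combine(tables, "repression")
    calls = call_responsive(tables, fi, fr)
    catalog = summarize_catalog(calls, fi, fr)
    return {"cm": cm, "sf": sf, "dispersions": disp, "de_tables": tables,
            "fisher_induction": fi, "fisher_repression": fr,
            "calls": calls, "catalog": catalog}


def make_de_table(genes, log2fc, p_raw, p_adj=None, line="L1"):
    """Hand-build a DE table for catalog-level unit tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    if p_adj is None:
        p_adj = np.minimum(p_raw * len(genes), 1.0)
    return pd.DataFrame({
        "cell_line": line,
        "baseMean": 100.0,
        "mean_0h": 100.0,
        "mean_5h": 100.0 * 2.0**log2fc,
        "log2FC": log2fc,
        "p_raw": p_raw,
        "p_adj": np.asarray(p_adj, dtype=float),
        "direction": np.sign(log2fc).astype(int),
    }, index=pd.Index(genes, name="gene_id"))
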