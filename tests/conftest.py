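"""Shared simulated cohorts (session-scoped: the HMM fits are reused widely)."""

import numpy as np
import pytest

import contactzone as cz


@pytest.fixture(scope="session")
def f1_cohort():
    """50 true F1 individuals at 2.7x depth with informative panels, fitted."""
    cfg = cz.SimConfig(
        n_sites=1000, n_chromosomes=2, map_length=0.5,
        n_outcrosser=50, n_selfer=0, pedigree_class="F1",
        cohort_taxon="outcrosser", depth_mean=2.7, seed=101,
    )
    panels = cz.simulate_panels(cfg)
    records, truth = cz.simulate_zone(cfg, panels)
    reads = cz.simulate_reads(truth, panels, cfg)
    fits = cz.fit_group(reads, panels, "outcrosser")
    return cfg, panels, truth, reads, fits


@pytest.fixture(scope="session")
def admixed_cohort():
    """100 old-admixed individuals, true alpha ~ U(0, 0.25), fitted."""
    cfg = cz.SimConfig(
        n_sites=2000, n_chromosomes=2, map_length=1.0,
        n_outcrosser=100, n_selfer=0, pedigree_class="old_admixed",
        alpha_range=(0.0, 0.25), depth_mean=2.7, seed=202,
    )
    panels = cz.simulate_panels(cfg)
    records, truth = cz.simulate_zone(cfg, panels)
    reads = cz.simulate_reads(truth, panels, cfg)
    fits = cz.fit_group(reads, panels, "outcrosser")
    return cfg, panels, truth, reads, fits


@pytest.fixture(scope="session")
def tiny_panels():
    """Six informative sites on one chromosome for oracle-scale HMM checks."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(6)],
            "chrom": ["chr1"] * 6,
            "pos": [1000, 1400, 2100, 5000, 9000, 15000],
            "morgan": [0.001, 0.0014, 0.0021, 0.005, 0.009, 0.015],
            "ac_out": [27.0, 3.0, 24.0, 28.5, 1.5, 21.0],
            "an_out": [30.0] * 6,
            "ac_self": [3.0, 27.0, 6.0, 1.5, 28.5, 9.0],
            "an_self": [30.0] * 6,
        }
    )
    return cz.SnpPanelTable(df)
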