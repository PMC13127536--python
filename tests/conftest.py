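"""Shared fixtures: small simulated panels and summary-statistics files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps


@pytest.fixture(scope="session")
def null_panel():
    """Pure-noise panel: 3 disorders + 6 regions (region block r=0.3), M=5000."""
    cfg = ps.preset_brain_disorder(
        R=6, D=3, M=5000, pi_region=0.0, pi_disorder=0.0, seed=11
    )
    panel, truth = ps.simulate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def independent_null_panel():
    """Pure-noise panel with identity residual covariance, M=20000, m=6."""
    cfg = ps.preset_brain_disorder(
        R=4, D=2, M=20_000, pi_region=0.0, pi_disorder=0.0, region_r=0.0, seed=5
    )
    panel, truth = ps.simulate_panel(cfg)
    return panel


def make_sumstats_frame(M: int = 20, seed: int = 0) -> pd.DataFrame:
    """A valid random summary-statistics table in the standard layout."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=M, replace=False))
    beta = rng.normal(0, 0.02, M)
    se = np.full(M, 0.01)
    from scipy import stats

    alleles = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    a1, a2 = zip(*[alleles[i % len(alleles)] for i in range(M)])
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(M)],
            "CHR": rng.integers(1, 23, M),
            "POS": pos,
            "A1": a1,
            "A2": a2,
            "BETA": beta,
            "SE": se,
            "P": 2 * stats.norm.sf(np.abs(beta / se)),
            "N": 10_000,
        }
    )


@pytest.fixture()
def sumstats_file(tmp_path):
    def write(df: pd.DataFrame, name: str = "trait.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return write
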