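"""Shared fixtures: synthetic runs are expensive, so the reference bundles
(noiseless and default-noise) are built once per session and reused."""

from __future__ import annotations

import pytest

from gecxms.pipeline import RunConfig, run_search
from gecxms.synthetic_data import (
    SimConfig,
    default_ncaa_residue_mass,
    noiseless_config,
    simulate_run,
)


def make_run_config(bundle, **overrides) -> RunConfig:
    params = dict(ncaa_site=bundle.ncaa_site,
                  ncaa_mass=default_ncaa_residue_mass())
    params.update(overrides)
    return RunConfig(**params)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Seed-7 ideal-spectrum run: 200 proteins, 150 implanted links."""
    return simulate_run(noiseless_config(seed=7))


@pytest.fixture(scope="session")
def noiseless_search(noiseless_bundle):
    return run_search(noiseless_bundle.proteins, noiseless_bundle.bait,
                      noiseless_bundle.spectra, make_run_config(noiseless_bundle))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-noise run (dropout, ppm error, noise peaks, background scans)."""
    return simulate_run(SimConfig(seed=42))


@pytest.fixture(scope="session")
def noisy_search(noisy_bundle):
    return run_search(noisy_bundle.proteins, noisy_bundle.bait,
                      noisy_bundle.spectra, make_run_config(noisy_bundle))
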