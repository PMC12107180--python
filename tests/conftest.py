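import numpy as np
import pytest

from llpskit import qpi, synthetic as syn


@pytest.fixture(scope="session")
def default_model() -> syn.BinodalModel:
    """Curved binodal with tie lines, MEX-5 sites at the measured Kd."""
    return syn.BinodalModel(k_tie=0.02)


@pytest.fixture(scope="session")
def phase_records(default_model):
    """A broad phase-diagram dataset without MEX-5 (shared, read-only)."""
    df, truth = syn.gen_phase_diagram(
        default_model,
        6000,
        {"pgl3_uM": (0.05, 2.5), "rna_ng_per_uL": (1.0, 150.0),
         "mex5_uM": (0.0, 0.0)},
        seed=11,
    )
    return df, truth


@pytest.fixture()
def sessile_cap() -> qpi.DropletFit:
    """An identifiable truncated-cap geometry (Zeq < R)."""
    return qpi.DropletFit(dn=0.0184, radius_um=2.0, xc_um=6.4, yc_um=6.4,
                          zeq_um=1.5, phi0=0.3)


@pytest.fixture(scope="session")
def render_cap():
    """Callable rendering a single-cap phase image at 0.1 um/px."""

    def _render(fit, noise_sd=0.0, seed=0, shape=(96, 96)):
        return syn.gen_phase_image([fit], noise_sd=noise_sd, shape=shape,
                                   pixel_size_um=0.1, phi0=fit.phi0, seed=seed)

    return _render
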