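"""Shared fixtures: small seeded WE runs reused across test modules."""

import pytest

import permweight as pw


@pytest.fixture(scope="session")
def scaled_fentanyl():
    return pw.make_scaled_presets()["fentanyl"]


@pytest.fixture(scope="session")
def small_run(scaled_fentanyl):
    """A short steady-state WE run on the low-barrier preset (with observables)."""
    return pw.run_weighted_ensemble(
        scaled_fentanyl,
        n_iterations=150,
        tau=100.0,
        pH=7.5,
        seed=42,
        dt=10.0,
    )


@pytest.fixture(scope="session")
def flat_landscape():
    """Free diffusion: no barrier, no wells, no titration coupling."""
    return pw.ToyLandscape(
        barrier_height=0.0,
        interface_well_depth=0.0,
        charged_penalty=0.0,
        pKa_shift_scale=0.0,
        diffusion_coeff=0.05,
        attempt_rate=1e-9,
        name="flat",
    )
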