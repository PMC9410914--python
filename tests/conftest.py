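import numpy as np
import pytest

from ribokin.datamodel import (
    AcquisitionParams,
    Dwell,
    DwellSet,
    KineticScheme,
    PhotophysicsParams,
)


@pytest.fixture(scope="session")
def wt_scheme() -> KineticScheme:
    """Ligand-free wild-type two-pathway scheme (slow rates as published)."""
    return KineticScheme(
        k_on_fast=3.3e6, k_on_slow=0.33e6, a_on_slow=0.89,
        k_off_fast=0.5, k_off_slow=0.002, a_off_slow=0.58,
    )


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams(frame_time=0.1, n_frames=10_000)


@pytest.fixture
def clean_photophysics() -> PhotophysicsParams:
    """No noise, no bleaching: rendering is a deterministic two-level map."""
    return PhotophysicsParams(
        k_bleach_acceptor=0.0, k_bleach_donor=0.0, noise_sd=0.0
    )


def make_dwells(
    durations,
    state: str = "bound",
    censored=None,
    frame_time: float = 0.1,
    n_molecules: int = 20,
) -> DwellSet:
    """DwellSet from raw durations, molecules assigned round-robin."""
    durations = np.asarray(durations, dtype=float)
    censored = (
        np.zeros(durations.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    dwells = [
        Dwell(
            state=state,
            duration=float(t),
            left_censored=False,
            right_censored=bool(c),
            molecule_id=f"m{i % n_molecules:03d}",
        )
        for i, (t, c) in enumerate(zip(durations, censored))
    ]
    return DwellSet(dwells, frame_time)
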