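"""Core domain types shared by every pipeline stage.

The pipeline analyses two-colour (donor = surface-tethered mRNA, acceptor =
labelled 30S ribosomal subunit) single-molecule colocalization traces.  A
molecule cycles between an unbound and a bound state; each state carries a
two-pathway (fast/slow) exponential dwell-time mixture.  All concentrations
are stored in molar, all times in seconds, all energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

GAS_CONSTANT_KCAL = 1.987e-3
"""Gas constant R in kcal/(mol*K)."""

State = Literal["bound", "unbound"]
OccupancyClass = Literal["L", "M", "H"]


@dataclass
class AcquisitionParams:
    """Camera/movie settings.

    frame_time is the integration time per frame in seconds (0.1 s default;
    0.15 s for the slow-binding mutant constructs), n_frames the movie length.
    """

    frame_time: float = 0.1
    n_frames: int = 10_000
    illumination: str = "continuous"

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.illumination not in ("continuous", "shuttered"):
            raise ValueError("illumination must be 'continuous' or 'shuttered'")

    @property
    def duration(self) -> float:
        return self.frame_time * self.n_frames


@dataclass
class KineticScheme:
    """Two-pathway binding/dissociation scheme.

    Association rate constants are second order (per molar per second) and
    act pseudo-first-order at the stated ribosome concentration; dissociation
    rate constants are first order.  ``a_on_slow`` / ``a_off_slow`` are the
    fractions of unbound / bound dwells drawn from the slow pathway.
    """

    k_on_fast: float
    k_on_slow: float
    a_on_slow: float
    k_off_fast: float
    k_off_slow: float
    a_off_slow: float
    ribosome_conc: float = 20e-9

    def __post_init__(self) -> None:
        for name in ("k_on_fast", "k_on_slow", "k_off_fast", "k_off_slow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_on_fast < self.k_on_slow:
            raise ValueError("k_on_fast must be >= k_on_slow")
        if self.k_off_fast < self.k_off_slow:
            raise ValueError("k_off_fast must be >= k_off_slow")
        for name in ("a_on_slow", "a_off_slow"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ribosome_conc <= 0:
            raise ValueError("ribosome_conc must be > 0")

    @property
    def k_unbind_pseudo_fast(self) -> float:
        """Pseudo-first-order fast binding rate at the scheme concentration."""
        return self.k_on_fast * self.ribosome_conc

    @property
    def k_unbind_pseudo_slow(self) -> float:
        return self.k_on_slow * self.ribosome_conc


@dataclass
class PhotophysicsParams:
    """Fluorophore and camera-noise settings for trace rendering.

    The labelled ribosome carries ``n_acceptor_labels`` acceptor fluorophores
    (dual labelling mitigates bleach-truncation of long bound events); each
    bleaches independently at ``k_bleach_acceptor``.  The surface-tethered
    donor bleaches at ``k_bleach_donor`` and terminates the analyzable window.
    """

    k_bleach_acceptor: float = 2e-4
    n_acceptor_labels: int = 2
    k_bleach_donor: float = 1e-4
    intensity_unbound: float = 100.0
    intensity_bound: float = 600.0
    noise_sd: float = 50.0

    def __post_init__(self) -> None:
        if self.k_bleach_acceptor < 0 or self.k_bleach_donor < 0:
            raise ValueError("bleach rates must be >= 0")
        if self.n_acceptor_labels < 1:
            raise ValueError("n_acceptor_labels must be >= 1")
        if self.intensity_bound <= self.intensity_unbound:
            raise ValueError("intensity_bound must exceed intensity_unbound")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Trace:
    """Per-molecule two-channel intensity time series on a uniform grid."""

    molecule_id: str
    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    condition: str = ""
    ligand_conc: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = len(self.times)
        if n < 1:
            raise ValueError("empty trace")
        if len(self.donor) != n or len(self.acceptor) != n:
            raise ValueError("times, donor, acceptor must have equal length")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(steps - steps[0])) > 1e-6:
                raise ValueError("time grid must be uniform (1e-6 s tolerance)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_time(self) -> float:
        if len(self.times) < 2:
            raise ValueError("frame_time undefined for single-frame trace")
        return float(self.times[1] - self.times[0])


@dataclass
class Idealization:
    """Binary bound/unbound path aligned to the frames of a trace.

    ``valid_until`` is the index of the first frame that is no longer
    analyzable (donor bleached); dwell extraction stops there.
    """

    molecule_id: str
    states: np.ndarray
    valid_until: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary (0 = unbound, 1 = bound)")
        if not 0 <= self.valid_until <= len(self.states):
            raise ValueError("valid_until out of range")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class Dwell:
    """One maximal bound or unbound interval from an idealized trace."""

    state: State
    duration: float
    left_censored: bool
    right_censored: bool
    molecule_id: str
    preceding_event_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.state not in ("bound", "unbound"):
            raise ValueError("state must be 'bound' or 'unbound'")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class DwellSet:
    """Censoring-annotated dwells pooled per condition, in per-molecule order."""

    dwells: list[Dwell]
    frame_time: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")

    def __len__(self) -> int:
        return len(self.dwells)

    def select(self, state: State, complete_only: bool = False) -> "DwellSet":
        keep = [
            d
            for d in self.dwells
            if d.state == state and not (complete_only and d.censored)
        ]
        return DwellSet(keep, self.frame_time, self.condition)

    def durations(self) -> np.ndarray:
        return np.array([d.duration for d in self.dwells], dtype=float)

    def censored_flags(self) -> np.ndarray:
        """Right-censoring flags (left-censored dwells are also uncertain in
        length only on the right of their observation window, so any censoring
        enters the likelihood as a survival term)."""
        return np.array([d.censored for d in self.dwells], dtype=bool)

    def molecule_ids(self) -> list[str]:
        return sorted({d.molecule_id for d in self.dwells})

    def extend(self, other: "DwellSet") -> None:
        if abs(other.frame_time - self.frame_time) > 1e-9:
            raise ValueError("cannot pool dwells across different frame times")
        self.dwells.extend(other.dwells)


@dataclass
class ExpMixtureFit:
    """Maximum-likelihood exponential-mixture fit of one dwell class."""

    n_components: int
    rates: np.ndarray
    amplitudes: np.ndarray
    log_likelihood: float
    bic: float
    n_dwells: int = 0
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if len(self.rates) != self.n_components:
            raise ValueError("rates length must equal n_components")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be > 0")
        if np.any(np.diff(self.rates) > 0):
            raise ValueError("rates must be sorted descending (fast first)")
        if abs(self.amplitudes.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if np.any(self.amplitudes <= 0) or np.any(self.amplitudes > 1):
            raise ValueError("amplitudes must lie in (0, 1]")

    @property
    def k_fast(self) -> float:
        return float(self.rates[0])

    @property
    def k_slow(self) -> float:
        return float(self.rates[-1])

    @property
    def a_fast(self) -> float:
        return float(self.amplitudes[0])

    @property
    def a_slow(self) -> float:
        return float(self.amplitudes[-1])


@dataclass
class ClassThresholds:
    """Fractional-bound-time boundaries separating L/M/H occupancy."""

    low_high_boundaries: tuple[float, float] = (0.10, 0.20)
    source: str = "fixed"

    def __post_init__(self) -> None:
        t1, t2 = self.low_high_boundaries
        if not 0.0 < t1 < t2 < 1.0:
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < 1")
        if self.source not in ("fixed", "gaussian_crossover"):
            raise ValueError("source must be 'fixed' or 'gaussian_crossover'")


@dataclass
class OccupancyProfile:
    """Per-molecule fractional bound time and L/M/H occupancy class."""

    molecule_id: str
    fractional_bound_time: float
    occupancy_class: OccupancyClass
    n_events_short: int = 0
    n_events_long: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fractional_bound_time <= 1.0:
            raise ValueError("fractional_bound_time must be in [0, 1]")
        if self.occupancy_class not in ("L", "M", "H"):
            raise ValueError("occupancy_class must be L, M or H")
        if self.n_events_short < 0 or self.n_events_long < 0:
            raise ValueError("event counts must be >= 0")

    @property
    def n_events(self) -> int:
        return self.n_events_short + self.n_events_long


@dataclass
class HillFit:
    """Non-cooperative (|n| = 1) Hill titration fit of one rate constant."""

    K_half: float
    k_at_zero: float
    k_at_sat: float
    coefficient: int
    shared_K: bool = False
    K_stderr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.K_half <= 0:
            raise ValueError("K_half must be > 0")
        if self.coefficient not in (-1, 1):
            raise ValueError("coefficient must be -1 or +1")

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        frac = conc / (self.K_half + conc)
        return self.k_at_zero + (self.k_at_sat - self.k_at_zero) * frac


@dataclass
class FreeEnergyDiagram:
    """Kinetically derived free-energy levels of the initiation pathway.

    ``dG_standby`` is the binding free energy of the transient standby-site
    complex (fast pathway) at the reference concentration; the accommodation
    values are the additional free-energy change of the standby -> cleft-
    accommodated step without and with saturating ligand; ``net_penalty`` is
    their difference (the non-equilibrium unfolding penalty the ligand adds).
    """

    dG_standby: float
    dG_accommodation_minus_ligand: float
    dG_accommodation_plus_ligand: float
    net_penalty: float
    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL
    reference_conc: float = 20e-9

    def __post_init__(self) -> None:
        expected = (
            self.dG_accommodation_plus_ligand - self.dG_accommodation_minus_ligand
        )
        if abs(self.net_penalty - expected) > 1e-12:
            raise ValueError("net_penalty must equal plus - minus exactly")


_CLASS_ORDER = {"inaccessible": 0, "L": 1, "M": 2, "H": 3}


@dataclass
class JumpRecord:
    """Occupancy class of one molecule before/after a ligand jump."""

    molecule_id: str
    class_before: str
    class_after: str
    response: str = field(init=False)

    def __post_init__(self) -> None:
        for c in (self.class_before, self.class_after):
            if c not in _CLASS_ORDER:
                raise ValueError(f"unknown occupancy class {c!r}")
        before, after = _CLASS_ORDER[self.class_before], _CLASS_ORDER[self.class_after]
        self.response = (
            "same" if after == before else "decreased" if after < before else "increased"
        )


def events_tile(events: Sequence[tuple[str, float, float]], duration: float,
                tol: float = 1e-9) -> bool:
    """Check that (state, start, end) events tile [0, duration] gaplessly."""
    if not events:
        return False
    if abs(events[0][1]) > tol or abs(events[-1][2] - duration) > tol:
        return False
    for (_, _, end), (_, start, _) in zip(events[:-1], events[1:]):
        if abs(end - start) > tol:
            return False
    return all(e[2] > e[1] for e in events)
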