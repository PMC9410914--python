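"""Synthetic cohort generator for ribosome-binding colocalization movies.

Emulates the single-molecule experiment: surface-tethered mRNA molecules are
visited by labelled 30S subunits, producing alternating unbound/bound dwells.
Each dwell class follows a two-component (fast/slow pathway) exponential
mixture; the fast/slow choice is made independently per dwell with the
mixture amplitude, which reproduces exactly the double-exponential dwell
likelihood reported by the analysis stage.  Long-term per-molecule
heterogeneity is injected through molecule classes, each with its own
kinetic scheme.

Rendering converts the event list into camera frames: the acceptor channel
sits at the bound level while at least one of the (fresh-per-event) acceptor
labels is unbleached on a bound ribosome, frames straddling a transition
carry duty-cycle-weighted intensity, the donor channel collapses to zero at
donor bleach (ending the analyzable window), and i.i.d. Gaussian camera
noise is added per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    AcquisitionParams,
    KineticScheme,
    PhotophysicsParams,
    Trace,
    events_tile,
)

Event = tuple[str, float, float]  # (state, start_s, end_s)

#: Default fast-pathway rate constants.  The analysis's headline numbers are
#: the slow-pathway constants; these fast-pathway defaults are generator
#: knobs chosen to keep standby events ~2 s long and clearly separated from
#: accommodated events.
DEFAULT_K_ON_FAST = 3.3e6
DEFAULT_K_OFF_FAST = 0.5

#: Half-saturation of the riboswitch used when generating titrations (molar).
K_HALF_PREQ1 = 48e-9


@dataclass
class MoleculeClassSpec:
    """One molecule subpopulation: a sampling weight and its kinetic scheme."""

    weight: float
    scheme: KineticScheme
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth for one molecule."""

    molecule_id: str
    events: list[Event]
    class_label: str
    acceptor_bleach_times: list[float] = field(default_factory=list)
    donor_bleach_time: float = np.inf

    def frame_states(self, acquisition: AcquisitionParams) -> np.ndarray:
        """True kinetic state per frame (bound if >50% of the frame is bound)."""
        frac = _frame_fractions(
            [(s, e) for st, s, e in self.events if st == "bound"], acquisition
        )
        return (frac > 0.5).astype(np.int8)


@dataclass
class Cohort:
    """A simulated condition: traces, per-molecule truth, manifest records."""

    traces: list[Trace]
    ground_truths: dict[str, GroundTruth]
    acquisition: AcquisitionParams
    photophysics: PhotophysicsParams
    condition: str = ""
    ligand_conc: float = 0.0

    def manifest_records(self) -> list[dict]:
        return [
            {
                "molecule_id": t.molecule_id,
                "path": f"{t.molecule_id}.tsv",
                "condition": self.condition,
                "ligand_conc": self.ligand_conc,
                "frame_time": self.acquisition.frame_time,
            }
            for t in self.traces
        ]


def simulate_events(
    scheme: KineticScheme, duration: float, seed: int | np.random.Generator
) -> list[Event]:
    """Draw an alternating unbound/bound event list covering [0, duration].

    Each unbound dwell is exponential with pseudo-first-order rate
    ``k_on * [30S]`` from the slow pathway with probability ``a_on_slow``
    (fast otherwise); bound dwells analogously with ``a_off_slow``.  The final
    event is truncated (right-censored) at ``duration``; durations tile the
    window exactly.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k_on = (scheme.k_unbind_pseudo_fast, scheme.k_unbind_pseudo_slow)
    k_off = (scheme.k_off_fast, scheme.k_off_slow)
    events: list[Event] = []
    t = 0.0
    state = "unbound"
    while t < duration:
        if state == "unbound":
            k = k_on[int(rng.random() < scheme.a_on_slow)]
        else:
            k = k_off[int(rng.random() < scheme.a_off_slow)]
        dwell = rng.exponential(1.0 / k) if k > 0 else np.inf
        end = min(t + dwell, duration)
        events.append((state, t, end))
        t = end
        state = "bound" if state == "unbound" else "unbound"
    assert events_tile(events, duration)
    return events


def _frame_fractions(
    intervals: Sequence[tuple[float, float]], acquisition: AcquisitionParams
) -> np.ndarray:
    """Fraction of each frame covered by the union of disjoint intervals."""
    dt = acquisition.frame_time
    n = acquisition.n_frames
    frac = np.zeros(n)
    for start, end in intervals:
        start, end = max(0.0, start), min(end, n * dt)
        if end <= start:
            continue
        i0 = int(start // dt)
        i1 = min(int(np.ceil(end / dt)), n)
        idx = np.arange(i0, i1)
        lo = np.maximum(start, idx * dt)
        hi = np.minimum(end, (idx + 1) * dt)
        frac[idx] += (hi - lo) / dt
    return np.clip(frac, 0.0, 1.0)


def render_trace(
    events: Sequence[Event],
    acquisition: AcquisitionParams,
    photophysics: PhotophysicsParams,
    seed: int | np.random.Generator,
    molecule_id: str = "mol",
    class_label: str = "",
    condition: str = "",
    ligand_conc: float = 0.0,
) -> tuple[Trace, GroundTruth]:
    """Render an event list into a noisy two-channel trace.

    Acceptor labels are drawn fresh for every binding event (each event is a
    new ribosome from solution); the event's signal survives until the last
    of the ``n_acceptor_labels`` labels bleaches.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration = acquisition.duration
    total = events[-1][2]
    if total < duration - 1e-9:
        import warnings

        warnings.warn(
            "event list shorter than the movie; trailing frames rendered unbound",
            stacklevel=2,
        )

    visible: list[tuple[float, float]] = []
    bleach_times: list[float] = []
    for state, start, end in events:
        if state != "bound":
            continue
        if photophysics.k_bleach_acceptor > 0:
            per_label = rng.exponential(
                1.0 / photophysics.k_bleach_acceptor,
                size=photophysics.n_acceptor_labels,
            )
            loss = float(per_label.max())
        else:
            loss = np.inf
        bleach_times.append(loss)
        visible.append((start, min(end, start + loss)))

    frac = _frame_fractions(visible, acquisition)
    span = photophysics.intensity_bound - photophysics.intensity_unbound
    acceptor = photophysics.intensity_unbound + frac * span

    if photophysics.k_bleach_donor > 0:
        donor_bleach = float(rng.exponential(1.0 / photophysics.k_bleach_donor))
    else:
        donor_bleach = np.inf
    donor_frac = _frame_fractions([(0.0, min(donor_bleach, duration))], acquisition)
    donor = donor_frac * photophysics.intensity_bound

    if photophysics.noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, photophysics.noise_sd, acquisition.n_frames)
        donor = donor + rng.normal(0.0, photophysics.noise_sd, acquisition.n_frames)

    times = np.arange(acquisition.n_frames) * acquisition.frame_time
    trace = Trace(
        molecule_id=molecule_id,
        times=times,
        donor=donor,
        acceptor=acceptor,
        condition=condition,
        ligand_conc=ligand_conc,
    )
    truth = GroundTruth(
        molecule_id=molecule_id,
        events=list(events),
        class_label=class_label,
        acceptor_bleach_times=bleach_times,
        donor_bleach_time=donor_bleach,
    )
    return trace, truth


def generate_cohort(
    classes: Sequence[MoleculeClassSpec],
    n_molecules: int,
    acquisition: AcquisitionParams,
    photophysics: PhotophysicsParams,
    ligand_conc: float = 0.0,
    seed: int = 0,
    condition: str = "",
    id_prefix: str = "mol",
) -> Cohort:
    """Simulate ``n_molecules`` traces, sampling each molecule's class.

    Reproducible under ``seed``: a single root seed is split per molecule
    with a counter, so cohorts are bit-identical across runs.
    """
    if not classes:
        raise ValueError("empty class list")
    weights = np.array([c.weight for c in classes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("class weights must sum to 1")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")

    seeds = np.random.SeedSequence(seed).spawn(n_molecules + 1)
    class_rng = np.random.default_rng(seeds[0])
    class_idx = class_rng.choice(len(classes), size=n_molecules, p=weights)

    width = max(4, len(str(n_molecules)))
    traces: list[Trace] = []
    truths: dict[str, GroundTruth] = {}
    for i in range(n_molecules):
        spec = classes[class_idx[i]]
        rng = np.random.default_rng(seeds[i + 1])
        mol_id = f"{id_prefix}{i:0{width}d}"
        events = simulate_events(spec.scheme, acquisition.duration, rng)
        trace, truth = render_trace(
            events,
            acquisition,
            photophysics,
            rng,
            molecule_id=mol_id,
            class_label=spec.label,
            condition=condition,
            ligand_conc=ligand_conc,
        )
        traces.append(trace)
        truths[mol_id] = truth
    return Cohort(
        traces=traces,
        ground_truths=truths,
        acquisition=acquisition,
        photophysics=photophysics,
        condition=condition,
        ligand_conc=ligand_conc,
    )


def generate_jump_cohort(
    scheme_before: KineticScheme,
    scheme_after: KineticScheme,
    n_molecules: int,
    acquisition: AcquisitionParams,
    photophysics: PhotophysicsParams,
    seed: int = 0,
    ligand_conc_after: float = 1e-6,
) -> tuple[Cohort, Cohort]:
    """Paired before/after segments of the same molecules (ligand jump).

    The same molecule IDs appear in both cohorts; kinetics switch from
    ``scheme_before`` to ``scheme_after`` across the (unmodelled) dark gap.
    """
    before = generate_cohort(
        [MoleculeClassSpec(1.0, scheme_before, "before")],
        n_molecules,
        acquisition,
        photophysics,
        ligand_conc=0.0,
        seed=seed,
        condition="jump_before",
    )
    after = generate_cohort(
        [MoleculeClassSpec(1.0, scheme_after, "after")],
        n_molecules,
        acquisition,
        photophysics,
        ligand_conc=ligand_conc_after,
        seed=seed + 1,
        condition="jump_after",
    )
    return before, after


def sample_occupancy_mixture(
    weights: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    n_molecules: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-molecule fractional bound times from a Gaussian mixture.

    Returns ``(fractions, component_index)``; fractions are clipped to [0, 1].
    Used to emulate cohorts whose molecule subpopulations differ in overall
    occupancy rather than to render full traces.
    """
    weights = np.asarray(weights, float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    comp = rng.choice(len(weights), size=n_molecules, p=weights)
    fractions = rng.normal(np.asarray(means, float)[comp], np.asarray(sds, float)[comp])
    return np.clip(fractions, 0.0, 1.0), comp


def simulate_titration(
    concs: Sequence[float],
    kon_zero: float,
    kon_sat: float,
    koff_zero: float,
    koff_sat: float,
    K_half: float = K_HALF_PREQ1,
    noise_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Generate kon/koff series over a ligand titration from the Hill model.

    kon decreases (Hill coefficient -1) and koff increases (+1) towards their
    saturating values with shared half-saturation ``K_half``; multiplicative
    Gaussian noise of fractional SD ``noise_frac`` is applied to each point.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    conc = np.asarray(concs, dtype=float)
    frac = conc / (K_half + conc)
    kon = kon_zero + (kon_sat - kon_zero) * frac
    koff = koff_zero + (koff_sat - koff_zero) * frac
    kon = kon * (1.0 + noise_frac * rng.standard_normal(conc.size))
    koff = koff * (1.0 + noise_frac * rng.standard_normal(conc.size))
    return {"conc": conc, "kon": kon, "koff": koff}


def generate_bleach_control(
    n_molecules: int,
    photophysics: PhotophysicsParams,
    seed: int = 0,
    acquisition: AcquisitionParams | None = None,
) -> Cohort:
    """Locked-on control cohort for estimating the effective bleach rate.

    Every molecule is bound for the whole movie, so each apparent signal
    loss is photobleaching of the last acceptor label.  The default movie is
    long (1 s frames, 8x the expected mean loss time) so essentially all
    molecules bleach on camera and truncation bias is negligible; donor
    bleaching is disabled because the control observes the acceptor channel.
    """
    if acquisition is None:
        k = photophysics.k_bleach_acceptor
        if k <= 0:
            raise ValueError("bleach control requires k_bleach_acceptor > 0")
        harmonic = sum(1.0 / i for i in range(1, photophysics.n_acceptor_labels + 1))
        n_frames = int(np.ceil(8.0 * harmonic / k))
        acquisition = AcquisitionParams(frame_time=1.0, n_frames=n_frames)
    control_phot = PhotophysicsParams(
        k_bleach_acceptor=photophysics.k_bleach_acceptor,
        n_acceptor_labels=photophysics.n_acceptor_labels,
        k_bleach_donor=0.0,
        intensity_unbound=photophysics.intensity_unbound,
        intensity_bound=photophysics.intensity_bound,
        noise_sd=photophysics.noise_sd,
    )
    seeds = np.random.SeedSequence(seed).spawn(n_molecules)
    traces, truths = [], {}
    duration = acquisition.duration
    width = max(4, len(str(n_molecules)))
    for i in range(n_molecules):
        mol_id = f"ctrl{i:0{width}d}"
        events: list[Event] = [("bound", 0.0, duration)]
        trace, truth = render_trace(
            events,
            acquisition,
            control_phot,
            np.random.default_rng(seeds[i]),
            molecule_id=mol_id,
            class_label="control",
            condition="bleach_control",
        )
        traces.append(trace)
        truths[mol_id] = truth
    return Cohort(
        traces=traces,
        ground_truths=truths,
        acquisition=acquisition,
        photophysics=control_phot,
        condition="bleach_control",
    )


# --- condition presets -----------------------------------------------------

@dataclass
class Preset:
    """Generator settings for one experimental condition."""

    name: str
    classes: list[MoleculeClassSpec]
    acquisition: AcquisitionParams
    photophysics: PhotophysicsParams
    ligand_conc: float

    @property
    def scheme(self) -> KineticScheme:
        """Scheme of the (single) dominant class."""
        return self.classes[0].scheme


def _scheme(k_on_slow: float, a_on_slow: float, k_off_slow: float,
            a_off_slow: float) -> KineticScheme:
    return KineticScheme(
        k_on_fast=DEFAULT_K_ON_FAST,
        k_on_slow=k_on_slow,
        a_on_slow=a_on_slow,
        k_off_fast=DEFAULT_K_OFF_FAST,
        k_off_slow=k_off_slow,
        a_off_slow=a_off_slow,
    )


# Slow-pathway rate constants are the published per-condition estimates;
# amplitudes are the published relative amplitudes where available and the
# wild-type values otherwise.  Mutant (I/S-series) movies use 150 ms frames.
_PRESET_TABLE: dict[str, dict] = {
    "wt_minus": dict(scheme=_scheme(0.33e6, 0.89, 0.002, 0.58), ligand=0.0),
    "wt_plus": dict(scheme=_scheme(0.24e6, 0.96, 0.006, 0.41), ligand=1e-6),
    "i1s8": dict(scheme=_scheme(0.25e6, 0.89, 0.006, 0.58), ligand=0.0, frame=0.15),
    "i2s8": dict(scheme=_scheme(0.29e6, 0.89, 0.006, 0.58), ligand=0.0, frame=0.15),
    "i4s8": dict(scheme=_scheme(0.36e6, 0.89, 0.006, 0.58), ligand=0.0, frame=0.15),
    "i6s8": dict(scheme=_scheme(0.34e6, 0.89, 0.006, 0.58), ligand=0.0, frame=0.15),
    "i4s0": dict(scheme=_scheme(0.26e6, 0.89, 0.006, 0.58), ligand=0.0, frame=0.15),
    "ds1": dict(scheme=_scheme(0.24e6, 0.89, 0.01, 0.58), ligand=0.0),
    "ifs": dict(scheme=_scheme(0.39e6, 0.89, 0.002, 0.58), ligand=0.0),
    "ifs_plus": dict(scheme=_scheme(0.27e6, 0.96, 0.006, 0.41), ligand=1e-6),
    "jump_before": dict(scheme=_scheme(0.33e6, 0.89, 0.002, 0.58), ligand=0.0,
                        n_frames=8000),
    "jump_after": dict(scheme=_scheme(0.24e6, 0.96, 0.006, 0.41), ligand=1e-6,
                       n_frames=8000),
}


def preset(name: str) -> Preset:
    """Return generator settings for a named experimental condition."""
    key = name.lower()
    if key not in _PRESET_TABLE:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESET_TABLE))}"
        )
    entry = _PRESET_TABLE[key]
    acquisition = AcquisitionParams(
        frame_time=entry.get("frame", 0.1), n_frames=entry.get("n_frames", 10_000)
    )
    return Preset(
        name=key,
        classes=[MoleculeClassSpec(1.0, entry["scheme"], key)],
        acquisition=acquisition,
        photophysics=PhotophysicsParams(),
        ligand_conc=entry["ligand"],
    )


def preset_names() -> list[str]:
    return sorted(_PRESET_TABLE)
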