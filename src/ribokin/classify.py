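"""Event-level (standby vs cleft-accommodated) and molecule-level (L/M/H)
classification, rastergrams, conditional dwell analysis, and ligand-jump
pairing.

Short bound events are transient standby-site contacts; long events are
cleft-accommodated complexes.  The short/long boundary is the point where
the two weighted components of the fitted dissociation mixture have equal
density — the Bayes-optimal decision boundary for the mixture.  Molecules
are ranked by the fraction of analyzable time they spend bound and binned
as low/mid/high occupancy, with boundaries either fixed (0.10/0.20) or
derived from the crossovers of a three-Gaussian fit to the occupancy
histogram.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .datamodel import (
    ClassThresholds,
    DwellSet,
    ExpMixtureFit,
    Idealization,
    JumpRecord,
    OccupancyProfile,
)

logger = logging.getLogger(__name__)


def event_threshold(fit: ExpMixtureFit) -> float:
    """Short/long bound-time boundary from the dissociation mixture.

    Equal-weighted-density point of the two components:
    t* = ln[(a_f k_f) / (a_s k_s)] / (k_f - k_s).  Events longer than t*
    are more likely to come from the slow (cleft-accommodated) pathway.
    """
    if fit.n_components != 2:
        raise ValueError("event threshold requires a 2-component fit")
    k_f, k_s = fit.k_fast, fit.k_slow
    a_f, a_s = fit.a_fast, fit.a_slow
    if k_f == k_s:
        raise ValueError("equal rates: no short/long separation exists")
    if a_f == 0.0:
        return 0.0
    # a vanishing fast amplitude drives the formula negative: every event
    # is then more likely slow, so the boundary clamps to zero (all long)
    return max(0.0, float(np.log((a_f * k_f) / (a_s * k_s)) / (k_f - k_s)))


def classify_events(
    dwells: DwellSet, t_star: float
) -> tuple[list[str], dict[str, int]]:
    """Label each bound dwell 'short' or 'long' against the threshold.

    Censored dwells are only classifiable when already longer than t*
    (their true duration can only be larger); otherwise they are
    'indeterminate' and excluded from the counts.
    """
    if t_star <= 0:
        raise ValueError("t_star must be > 0")
    labels: list[str] = []
    counts = {"short": 0, "long": 0, "indeterminate": 0}
    for d in dwells.dwells:
        if d.state != "bound":
            raise ValueError("classify_events expects bound dwells only")
        if d.duration > t_star:
            label = "long"
        elif d.censored:
            label = "indeterminate"
        else:
            label = "short"
        labels.append(label)
        counts[label] += 1
    return labels, counts


def fractional_bound_time(ideal: Idealization) -> float:
    """Bound frames / analyzable frames (before donor bleach), in [0, 1]."""
    states = ideal.states[: ideal.valid_until]
    if states.size == 0:
        raise ValueError(f"{ideal.molecule_id}: zero analyzable frames")
    return float(np.mean(states))


def build_rastergram(
    ideals: Sequence[Idealization],
    frame_time: float,
    t_star: float | None = None,
    max_rows: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format event matrix (molecule, row, start_s, end_s, label).

    Rows (molecules) are sorted by fractional bound time, most accessible
    first; an optional reproducible random subsample of ``max_rows``
    molecules is taken before sorting.  Bound events are labelled short or
    long when a threshold is supplied.
    """
    if not ideals:
        raise ValueError("need at least one molecule")
    chosen = list(ideals)
    if max_rows is not None and max_rows < len(chosen):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(chosen), size=max_rows, replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    occ = [fractional_bound_time(i) for i in chosen]
    order = np.argsort(-np.asarray(occ), kind="stable")
    rows = []
    for row, i in enumerate(order):
        ideal = chosen[i]
        states = ideal.states[: ideal.valid_until]
        if states.size == 0:
            continue
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [states.size]))
        for i0, i1 in zip(starts, ends):
            if states[i0] != 1:
                continue
            duration = (i1 - i0) * frame_time
            label = "bound"
            if t_star is not None:
                label = "long" if duration > t_star else "short"
            rows.append(
                {
                    "molecule": ideal.molecule_id,
                    "row": row,
                    "start_s": i0 * frame_time,
                    "end_s": i1 * frame_time,
                    "label": label,
                }
            )
    return pd.DataFrame(rows, columns=["molecule", "row", "start_s", "end_s", "label"])


def plot_rastergram(raster: pd.DataFrame, ax=None):
    """Render a rastergram DataFrame (red = short/standby, blue = long)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    colors = {"short": "tab:red", "long": "tab:blue", "bound": "tab:gray"}
    for _, r in raster.iterrows():
        ax.plot(
            [r["start_s"], r["end_s"]],
            [r["row"], r["row"]],
            color=colors.get(r["label"], "k"),
            lw=2,
            solid_capstyle="butt",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("molecule (sorted by occupancy)")
    ax.invert_yaxis()
    return ax


class OccupancyMixture(BaseEstimator):
    """Three-Gaussian occupancy histogram resolver with crossover thresholds.

    Fits a 3-component Gaussian mixture to the per-molecule fractional bound
    times and sets the L/M and M/H boundaries at the points between adjacent
    component means where the weighted densities are equal.  When components
    collapse (adjacent means closer than ``collapse_tol``) or no crossover
    exists between a pair of means, the fixed working boundaries are used
    instead.
    """

    def __init__(
        self,
        fallback: tuple[float, float] = (0.10, 0.20),
        collapse_tol: float = 0.02,
        n_init: int = 5,
        random_state: int = 0,
    ):
        self.fallback = fallback
        self.collapse_tol = collapse_tol
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, fractions, y=None):
        f = np.asarray(fractions, dtype=float).reshape(-1, 1)
        if f.size < 50:
            raise ValueError("need >= 50 molecules to resolve three Gaussians")
        gmm = GaussianMixture(
            n_components=3,
            n_init=self.n_init,
            random_state=self.random_state,
            reg_covar=1e-6,
        ).fit(f)
        order = np.argsort(gmm.means_.ravel())
        self.means_ = gmm.means_.ravel()[order]
        self.sds_ = np.sqrt(gmm.covariances_.ravel()[order])
        self.weights_ = gmm.weights_[order]
        if np.any(np.diff(self.means_) < self.collapse_tol):
            import warnings

            warnings.warn(
                "occupancy components collapsed; using fixed thresholds"
            )
            self.thresholds_ = ClassThresholds(self.fallback, source="fixed")
            return self
        crossovers = []
        for i in (0, 1):
            w1, m1, s1 = self.weights_[i], self.means_[i], self.sds_[i]
            w2, m2, s2 = self.weights_[i + 1], self.means_[i + 1], self.sds_[i + 1]

            def diff(x):
                return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

            if diff(m1) * diff(m2) >= 0:
                import warnings

                warnings.warn(
                    "no density crossover between adjacent components; "
                    "using fixed thresholds"
                )
                self.thresholds_ = ClassThresholds(self.fallback, source="fixed")
                return self
            crossovers.append(float(brentq(diff, m1, m2, xtol=1e-10)))
        self.thresholds_ = ClassThresholds(
            tuple(sorted(crossovers)), source="gaussian_crossover"
        )
        return self

    def predict(self, fractions) -> np.ndarray:
        t1, t2 = self.thresholds_.low_high_boundaries
        f = np.asarray(fractions, dtype=float).ravel()
        return np.where(f < t1, "L", np.where(f > t2, "H", "M"))


def fit_occupancy_gaussians(fractions: Sequence[float],
                            random_state: int = 0) -> OccupancyMixture:
    """Fit the three-Gaussian occupancy mixture; thresholds via crossovers."""
    return OccupancyMixture(random_state=random_state).fit(fractions)


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def classify_molecules(
    fractions: Sequence[float],
    thresholds: ClassThresholds | None = None,
    molecule_ids: Sequence[str] | None = None,
    event_counts: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[OccupancyProfile], dict]:
    """Assign L/M/H occupancy classes and summarize population fractions.

    L if f < t1, M if t1 <= f <= t2 (boundaries belong to M, matching the
    "0.1 to 0.2" mid-class convention), H if f > t2.  The summary carries
    binomial (Wilson 95%) intervals per class; fractions sum to 1.
    """
    thresholds = thresholds or ClassThresholds()
    t1, t2 = thresholds.low_high_boundaries
    f = np.asarray(fractions, dtype=float)
    ids = (
        list(molecule_ids)
        if molecule_ids is not None
        else [f"mol{i:04d}" for i in range(f.size)]
    )
    profiles = []
    for i, (mol, frac) in enumerate(zip(ids, f)):
        cls = "L" if frac < t1 else ("H" if frac > t2 else "M")
        n_short, n_long = event_counts[i] if event_counts is not None else (0, 0)
        profiles.append(
            OccupancyProfile(
                molecule_id=mol,
                fractional_bound_time=float(frac),
                occupancy_class=cls,
                n_events_short=n_short,
                n_events_long=n_long,
            )
        )
    n = len(profiles)
    summary: dict = {"n_molecules": n, "thresholds": thresholds}
    for cls in ("L", "M", "H"):
        k = sum(p.occupancy_class == cls for p in profiles)
        summary[cls] = {
            "count": k,
            "fraction": k / n if n else 0.0,
            "ci95": _wilson_ci(k, n),
        }
    return profiles, summary


def conditional_unbound_dwells(
    dwells: DwellSet,
    bound_labels: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Unbound dwells split by the class of the immediately following event.

    Tests whether standby and cleft-accommodated events are preceded by
    systematically different waiting times (a ratio of means whose CI
    includes 1 indicates sequential standby -> accommodation kinetics with
    no separate entry pathway).  ``bound_labels`` must align with the bound
    dwells of ``dwells`` in order.
    """
    bound = [d for d in dwells.dwells if d.state == "bound"]
    if len(bound) != len(bound_labels):
        raise ValueError("bound_labels must align with the bound dwells")
    label_of = dict(zip(map(id, bound), bound_labels))
    groups: dict[str, list[float]] = {"short": [], "long": []}
    prev = None
    for d in dwells.dwells:
        if (
            prev is not None
            and prev.state == "unbound"
            and not prev.censored
            and d.state == "bound"
            and d.molecule_id == prev.molecule_id
        ):
            label = label_of[id(d)]
            if label in groups:
                groups[label].append(prev.duration)
                prev.preceding_event_class = label
        prev = d
    short = np.asarray(groups["short"])
    long_ = np.asarray(groups["long"])
    out: dict = {"short": short, "long": long_}
    if short.size and long_.size:
        out["ratio_of_means"] = float(np.mean(long_) / np.mean(short))
        if short.size >= 10 and long_.size >= 10:
            rng = np.random.default_rng(seed)
            ratios = [
                np.mean(rng.choice(long_, long_.size)) /
                np.mean(rng.choice(short, short.size))
                for _ in range(n_boot)
            ]
            out["ratio_ci95"] = (
                float(np.percentile(ratios, 2.5)),
                float(np.percentile(ratios, 97.5)),
            )
    return out


def pair_jump_segments(
    before: Sequence[OccupancyProfile],
    after: Sequence[OccupancyProfile],
) -> tuple[list[JumpRecord], dict]:
    """Pair per-molecule occupancy classes across a ligand jump.

    A molecule with zero detected binding events in a segment is classed
    'inaccessible' (below L in the ordering).  Unmatched molecule IDs are
    excluded with a log entry.  The summary reports the decreased / same /
    increased response fractions and the inaccessible-after fraction.
    """
    before_by_id = {p.molecule_id: p for p in before}
    after_by_id = {p.molecule_id: p for p in after}
    records = []
    for mol in sorted(before_by_id):
        if mol not in after_by_id:
            logger.info("molecule %s missing in after-segment; excluded", mol)
            continue
        b, a = before_by_id[mol], after_by_id[mol]
        cls_b = "inaccessible" if b.n_events == 0 else b.occupancy_class
        cls_a = "inaccessible" if a.n_events == 0 else a.occupancy_class
        records.append(JumpRecord(mol, cls_b, cls_a))
    for mol in sorted(set(after_by_id) - set(before_by_id)):
        logger.info("molecule %s missing in before-segment; excluded", mol)
    n = len(records)
    summary = {"n_molecules": n}
    for response in ("decreased", "same", "increased"):
        k = sum(r.response == response for r in records)
        summary[response] = k / n if n else 0.0
    summary["inaccessible_after"] = (
        sum(r.class_after == "inaccessible" for r in records) / n if n else 0.0
    )
    return records, summary
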