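"""Rate-constant estimation from pooled dwell times.

The dwell-time model is a one- or two-component exponential mixture,
left-truncated at one camera frame (events shorter than a frame are not
observable, so the density is renormalized on [frame_time, inf)) and with
right-censored dwells entering the likelihood through survival terms —
censoring is non-ignorable here because the slow dissociation pathway
(~0.002 1/s) is of the same order as the inverse observation window.

Fits pool the complete and censored dwells of all molecules within a
condition ("global" fitting); bootstrap errors resample molecules, not
dwells, to respect per-molecule correlation.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .datamodel import DwellSet, ExpMixtureFit, HillFit

logger = logging.getLogger(__name__)

_LOG_RATE_BOUNDS = (np.log(1e-9), np.log(1e9))


class InsufficientDataError(ValueError):
    """Fewer complete dwells than the fit requires."""


class BoundaryFitError(RuntimeError):
    """The optimizer pinned a rate at the search boundary."""


def _mixture_nll(theta: np.ndarray, t: np.ndarray, cens: np.ndarray,
                 t_min: float, gamma_ab: tuple[float, float] = (1.0, 0.0)
                 ) -> float:
    """Negative log-(posterior) of a 2-exponential mixture.

    theta = (log k1, log k2, logit a1); truncation at t_min renormalizes
    by S(t_min); censored observations contribute S(t)/S(t_min).

    ``gamma_ab`` = (alpha, beta) of a weak Gamma prior on each rate, added
    as (alpha-1)*ln k - beta*k.  Right-censored mixtures have a boundary
    degeneracy — an arbitrarily slow, small-amplitude component can absorb
    the censored tail (k -> 0), and an empty component can run away
    (k -> inf).  A weak prior removes both while perturbing identified
    rates by only O(1/n).
    """
    k = np.exp(theta[:2])
    a1 = expit(theta[2])
    log_a = np.log(np.array([a1, 1.0 - a1]) + 1e-300)
    log_k = theta[:2]
    tc = t[~cens]
    ll = 0.0
    if tc.size:
        ll += logsumexp(log_a + log_k - np.outer(tc, k), axis=1).sum()
    tx = t[cens]
    if tx.size:
        ll += logsumexp(log_a - np.outer(tx, k), axis=1).sum()
    log_s_min = logsumexp(log_a - k * t_min)
    ll -= t.size * log_s_min
    alpha, beta = gamma_ab
    ll += float(np.sum((alpha - 1.0) * log_k - beta * k))
    return -ll


class ExponentialMixtureMLE(BaseEstimator):
    """Maximum-likelihood exponential-mixture fit of dwell durations.

    Parameters
    ----------
    n_components : 1 or 2.
    t_min : left-truncation point in seconds (one camera frame).
    n_starts : number of multistart optimizations for the 2-component fit
        (rates in log space, amplitude in logit space, so the search is
        unconstrained and mixture local optima are escaped).
    random_state : seeds the multistart jitter.

    Attributes (after :meth:`fit`)
    ------------------------------
    rates_ : descending (fast first), 1/s.
    amplitudes_ : untruncated mixture weights, fast first, summing to 1.
    log_likelihood_, bic_, n_dwells_ (complete count), n_total_.
    """

    def __init__(self, n_components: int = 2, t_min: float = 0.0,
                 n_starts: int = 5, max_iter: int = 1000,
                 prior_alpha: float = 1.0, random_state: int = 0):
        self.n_components = n_components
        self.t_min = t_min
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.prior_alpha = prior_alpha
        self.random_state = random_state

    def fit(self, durations, censored=None):
        t = np.asarray(durations, dtype=float)
        cens = (
            np.zeros(t.size, dtype=bool)
            if censored is None
            else np.asarray(censored, dtype=bool)
        )
        if t.size != cens.size:
            raise ValueError("durations and censored must have equal length")
        if np.any(t < self.t_min - 1e-12):
            raise ValueError("durations below the truncation point t_min")
        n_complete = int((~cens).sum())
        if n_complete < 20:
            raise InsufficientDataError(
                f"need >= 20 complete dwells, got {n_complete}"
            )
        n_params = 1 if self.n_components == 1 else 3
        if n_complete < 10 * n_params:
            warnings.warn(
                f"only {n_complete} complete dwells for {n_params} parameters"
            )

        if self.n_components == 1:
            # closed form: shifted-exponential MLE with censoring
            total = float(np.sum(t - self.t_min))
            k = n_complete / total
            ll = n_complete * np.log(k) - k * total
            self.rates_ = np.array([k])
            self.amplitudes_ = np.array([1.0])
            self.log_likelihood_ = float(ll)
        elif self.n_components == 2:
            theta, _ = self._fit_two(t, cens)
            k = np.exp(theta[:2])
            a = np.array([expit(theta[2]), 1.0 - expit(theta[2])])
            order = np.argsort(-k)
            self.rates_ = k[order]
            self.amplitudes_ = a[order]
            # report the unpenalized likelihood at the MAP point
            self.log_likelihood_ = -float(
                _mixture_nll(theta, t, cens, self.t_min)
            )
            if np.any(np.abs(np.log(self.rates_)[None, :]
                             - np.array(_LOG_RATE_BOUNDS)[:, None]) < 1e-3):
                raise BoundaryFitError("fitted rate pinned at search boundary")
        else:
            raise ValueError("n_components must be 1 or 2")
        self.n_dwells_ = n_complete
        self.n_total_ = int(t.size)
        self.bic_ = float(n_params * np.log(t.size) - 2.0 * self.log_likelihood_)
        return self

    def _starts(self, t: np.ndarray, cens: np.ndarray) -> list[np.ndarray]:
        tc = t[~cens] - self.t_min
        mean = max(float(np.mean(tc)), 1e-9)
        longest = max(float(np.max(t)), mean)
        rng = np.random.default_rng(self.random_state)
        base = [
            (2.0 / mean, 0.2 / mean, 0.5),
            (5.0 / mean, 0.5 / mean, 0.3),
            (10.0 / mean, 1.0 / longest, 0.7),
            (1.0 / mean, 0.1 / longest, 0.5),
            (20.0 / mean, 2.0 / longest, 0.6),
        ]
        starts = []
        for i in range(self.n_starts):
            k1, k2, a = base[i % len(base)]
            if i >= len(base):
                jitter = rng.normal(0, 0.3, size=2)
                k1, k2 = k1 * np.exp(jitter[0]), k2 * np.exp(jitter[1])
            starts.append(np.array([np.log(k1), np.log(k2),
                                    np.log(a / (1 - a))]))
        return starts

    def _fit_two(self, t: np.ndarray, cens: np.ndarray) -> tuple[np.ndarray, float]:
        bounds = [_LOG_RATE_BOUNDS, _LOG_RATE_BOUNDS, (-15.0, 15.0)]
        # weak Gamma prior scaled to the data (prior mode = 1/mean(t));
        # alpha = 1 makes it flat (pure maximum likelihood)
        mean_c = max(float(np.mean(t[~cens] - self.t_min)), 1e-12)
        gamma_ab = (self.prior_alpha, (self.prior_alpha - 1.0) * mean_c)
        best_theta, best_nll = None, np.inf
        for theta0 in self._starts(t, cens):
            res = minimize(
                _mixture_nll,
                theta0,
                args=(t, cens, self.t_min, gamma_ab),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter},
            )
            if res.fun < best_nll:
                best_theta, best_nll = res.x, float(res.fun)
        if best_theta is None:
            raise RuntimeError("all optimizer starts failed")
        return best_theta, best_nll

    def to_fit(self) -> ExpMixtureFit:
        return ExpMixtureFit(
            n_components=self.n_components,
            rates=self.rates_,
            amplitudes=self.amplitudes_,
            log_likelihood=self.log_likelihood_,
            bic=self.bic_,
            n_dwells=self.n_dwells_,
        )


def fit_exponential_mixture(
    dwells: DwellSet, n_components: int, frame_time: float | None = None,
    random_state: int = 0,
) -> ExpMixtureFit:
    """Fit the dwell durations of one state class, pooled across molecules.

    ``dwells`` must contain a single state class (use ``DwellSet.select``).
    Complete dwells contribute the truncated density and right-censored
    dwells survival terms.  Left-censored dwells (first run of a trace) are
    excluded: their observed length is exactly the quantity that defines
    them, so folding them in as survival bounds is informatively coarsened
    and biases rates downward.  Truncation is at one frame (``frame_time``
    defaults to the dwell set's own).
    """
    states = {d.state for d in dwells.dwells}
    if len(states) > 1:
        raise ValueError("dwell set mixes bound and unbound dwells")
    t_min = frame_time if frame_time is not None else dwells.frame_time
    usable = [d for d in dwells.dwells if not d.left_censored]
    est = ExponentialMixtureMLE(
        n_components=n_components, t_min=t_min, random_state=random_state
    )
    est.fit(
        np.array([d.duration for d in usable], dtype=float),
        np.array([d.right_censored for d in usable], dtype=bool),
    )
    return est.to_fit()


def _two_component_is_degenerate(fit: ExpMixtureFit, max_duration: float) -> bool:
    """A 2-component fit whose minority pathway is not interpretable.

    Either component amplitude below 3% (no pathway support) or a slow
    rate whose mean dwell exceeds the longest observation (unidentifiable
    against censoring; such a component only mimics the censored tail).
    Closely spaced rates are deliberately not flagged: an under-resolved
    pair still brackets the dominant rate.
    """
    return bool(
        fit.amplitudes.min() < 0.03 or fit.k_slow * max_duration < 1.0
    )


def select_and_fit(dwells: DwellSet, frame_time: float | None = None,
                   random_state: int = 0) -> ExpMixtureFit:
    """BIC-selected exponential-mixture fit (1 or 2 components).

    Conditions near saturation are effectively single-pathway (published
    slow amplitudes up to 96%), where a forced 2-component fit leaves a
    near-empty component free to wander; BIC plus a degeneracy guard
    reports the model the dwells actually support.
    """
    fit1 = fit_exponential_mixture(dwells, 1, frame_time, random_state)
    try:
        fit2 = fit_exponential_mixture(dwells, 2, frame_time, random_state)
    except (BoundaryFitError, RuntimeError):
        return fit1
    max_duration = float(np.max([d.duration for d in dwells.dwells]))
    if _two_component_is_degenerate(fit2, max_duration):
        return fit1
    return fit2 if fit2.bic < fit1.bic else fit1


def select_model(dwells: DwellSet, frame_time: float | None = None) -> int:
    """Number of mixture components (1 or 2) preferred by BIC; ties -> 1."""
    return select_and_fit(dwells, frame_time).n_components


def robust_two_component_fit(
    dwells: DwellSet, frame_time: float | None = None, random_state: int = 0
) -> ExpMixtureFit:
    """Two-pathway fit with a single-exponential fallback on degeneracy.

    The two-pathway model is the working model of the analysis; the
    fallback only engages when the fitted minority component is
    uninterpretable (see :func:`_two_component_is_degenerate`), which
    happens when a condition is effectively single-pathway in the sampled
    window.  The slow rate of a (healthy) 1-component fit is a good proxy
    for the slow pathway whenever the slow amplitude dominates, since the
    fast pathway then contributes little observation time.
    """
    fit1 = fit_exponential_mixture(dwells, 1, frame_time, random_state)
    try:
        fit2 = fit_exponential_mixture(dwells, 2, frame_time, random_state)
    except (BoundaryFitError, RuntimeError):
        return fit1
    max_duration = float(np.max([d.duration for d in dwells.dwells]))
    if _two_component_is_degenerate(fit2, max_duration):
        return fit1
    return fit2


def correct_photobleaching(k_obs: float, k_bleach_eff: float) -> float:
    """Remove the effective photobleach rate from an observed decay rate.

    Apparent signal loss is the first of dissociation or bleach, so the
    observed rate is (approximately) the sum of the two; the corrected
    dissociation rate is their difference.  Raises when bleaching dominates
    (the rate is then not identifiable).
    """
    if k_bleach_eff < 0:
        raise ValueError("k_bleach_eff must be >= 0")
    if k_obs <= k_bleach_eff:
        raise ValueError(
            f"k_obs ({k_obs:g}) <= k_bleach_eff ({k_bleach_eff:g}): "
            "bleaching dominates; dissociation rate not identifiable"
        )
    return k_obs - k_bleach_eff


def bleach_effective_rate(k_per_label: float, n_labels: int) -> float:
    """Effective signal-loss rate for n labels bleaching independently.

    Signal survives until the last label bleaches; the mean loss time is
    H_n / k (harmonic number), e.g. 3/(2k) for the dual-label case, and the
    effective rate is defined as 1/mean.
    """
    if k_per_label < 0 or n_labels < 1:
        raise ValueError("invalid bleach parameters")
    if k_per_label == 0:
        return 0.0
    harmonic = sum(1.0 / i for i in range(1, n_labels + 1))
    return k_per_label / harmonic


def estimate_bleach_rate(loss_times: Sequence[float] | np.ndarray,
                         n_labels: int = 2) -> float:
    """Effective bleach rate from signal-loss times of locked-on molecules.

    ``loss_times`` are the apparent bound durations of a control cohort in
    which binding never ends, so every loss event is photobleaching of the
    last acceptor label.  The effective rate is 1/mean by construction
    (mean = H_n / k_per_label for n independent labels).
    """
    loss = np.asarray(loss_times, dtype=float)
    if loss.size < 20:
        raise InsufficientDataError(
            f"need >= 20 bleach loss events, got {loss.size}"
        )
    return float(1.0 / np.mean(loss))


def compute_kon(k_pseudo: float, ribosome_conc: float) -> float:
    """Second-order binding rate constant from a pseudo-first-order rate."""
    if k_pseudo <= 0 or ribosome_conc <= 0:
        raise ValueError("k_pseudo and ribosome_conc must be > 0")
    return k_pseudo / ribosome_conc


def bootstrap_rates(
    dwells: DwellSet,
    n_components: int = 2,
    n_boot: int = 200,
    seed: int = 0,
    frame_time: float | None = None,
) -> dict:
    """Molecule-level bootstrap of the exponential-mixture parameters.

    Molecules (not dwells) are resampled with replacement; replicates whose
    resample yields too few complete dwells are skipped with a log entry.
    Returns point estimates with percentile 68% and 95% intervals; fully
    deterministic under ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    point = fit_exponential_mixture(dwells, n_components, frame_time)
    by_mol: dict[str, list] = {}
    for d in dwells.dwells:
        by_mol.setdefault(d.molecule_id, []).append(d)
    mol_ids = sorted(by_mol)
    rng = np.random.default_rng(seed)
    names = (
        ["k"] if n_components == 1 else ["k_fast", "k_slow", "a_fast", "a_slow"]
    )
    samples: list[np.ndarray] = []
    skipped = 0
    for _ in range(n_boot):
        picked = rng.choice(len(mol_ids), size=len(mol_ids), replace=True)
        pooled = [d for i in picked for d in by_mol[mol_ids[i]]]
        rep = DwellSet(pooled, dwells.frame_time, dwells.condition)
        try:
            fit = fit_exponential_mixture(rep, n_components, frame_time)
        except (InsufficientDataError, BoundaryFitError):
            skipped += 1
            logger.info("bootstrap replicate skipped (insufficient dwells)")
            continue
        if n_components == 1:
            samples.append(np.array([fit.k_fast]))
        else:
            samples.append(
                np.array([fit.k_fast, fit.k_slow, fit.a_fast, fit.a_slow])
            )
    arr = np.array(samples)
    out: dict = {"n_replicates": len(samples), "n_skipped": skipped}
    if n_components == 1:
        estimates = {"k": point.k_fast}
    else:
        estimates = {
            "k_fast": point.k_fast,
            "k_slow": point.k_slow,
            "a_fast": point.a_fast,
            "a_slow": point.a_slow,
        }
    for j, name in enumerate(names):
        col = arr[:, j]
        out[name] = {
            "estimate": estimates[name],
            "ci68": (float(np.percentile(col, 16)), float(np.percentile(col, 84))),
            "ci95": (float(np.percentile(col, 2.5)), float(np.percentile(col, 97.5))),
            "sd": float(np.std(col)),
        }
    return out


def fit_hill_global(
    conc_series: Sequence[float],
    kon_series: Sequence[float],
    koff_series: Sequence[float],
    kon_err: Sequence[float] | None = None,
    koff_err: Sequence[float] | None = None,
) -> tuple[HillFit, HillFit]:
    """Global non-cooperative Hill fit of kon (n = -1) and koff (n = +1).

    kon(c) = kon0 - (kon0 - kon_inf) * c / (K + c)   (decreasing)
    koff(c) = koff0 + (koff_inf - koff0) * c / (K + c)  (increasing)

    The half-saturation K is shared between both series via weighted least
    squares (inverse-variance weights when errors are supplied, otherwise
    each series is weighted by its own scale).
    """
    import lmfit

    conc = np.asarray(conc_series, dtype=float)
    kon = np.asarray(kon_series, dtype=float)
    koff = np.asarray(koff_series, dtype=float)
    if conc.size < 4 or not np.any(conc == 0):
        raise ValueError("need >= 4 concentrations including 0")
    if conc.size != kon.size or conc.size != koff.size:
        raise ValueError("series lengths must match")
    w_on = (
        1.0 / np.asarray(kon_err, float)
        if kon_err is not None
        else np.full(conc.size, 1.0 / np.mean(np.abs(kon)))
    )
    w_off = (
        1.0 / np.asarray(koff_err, float)
        if koff_err is not None
        else np.full(conc.size, 1.0 / np.mean(np.abs(koff)))
    )

    order = np.argsort(conc)
    if kon[order][-1] > kon[order][0] or koff[order][-1] < koff[order][0]:
        warnings.warn("titration series trend opposes the Hill model direction")

    span = conc.max()
    params = lmfit.Parameters()
    params.add("K", value=span / 10 if span > 0 else 1e-9, min=1e-15, max=span * 100)
    params.add("kon0", value=float(kon[np.argmin(conc)]))
    params.add("kon_inf", value=float(kon[np.argmax(conc)]))
    params.add("koff0", value=float(koff[np.argmin(conc)]))
    params.add("koff_inf", value=float(koff[np.argmax(conc)]))

    def residual(p):
        frac = conc / (p["K"] + conc)
        r_on = (p["kon0"] + (p["kon_inf"] - p["kon0"]) * frac - kon) * w_on
        r_off = (p["koff0"] + (p["koff_inf"] - p["koff0"]) * frac - koff) * w_off
        return np.concatenate([r_on, r_off])

    result = lmfit.minimize(residual, params, method="leastsq")
    K = float(result.params["K"].value)
    if K <= 2e-15 or K >= span * 99:
        raise RuntimeError("shared K hit its search bound; fit not usable")
    K_err = result.params["K"].stderr
    fit_on = HillFit(
        K_half=K,
        k_at_zero=float(result.params["kon0"].value),
        k_at_sat=float(result.params["kon_inf"].value),
        coefficient=-1,
        shared_K=True,
        K_stderr=float(K_err) if K_err else None,
    )
    fit_off = HillFit(
        K_half=K,
        k_at_zero=float(result.params["koff0"].value),
        k_at_sat=float(result.params["koff_inf"].value),
        coefficient=+1,
        shared_K=True,
        K_stderr=float(K_err) if K_err else None,
    )
    return fit_on, fit_off


def fold_changes(rates_a: dict, rates_b: dict) -> pd.DataFrame:
    """Ratios b/a and percent changes for matching rate-constant names."""
    if set(rates_a) != set(rates_b):
        raise ValueError("parameter sets do not match")
    rows = []
    for name in rates_a:
        a, b = float(rates_a[name]), float(rates_b[name])
        rows.append(
            {
                "parameter": name,
                "a": a,
                "b": b,
                "fold_change": b / a,
                "percent_change": 100.0 * (b / a - 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
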