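"""Two-state HMM idealization of binding traces and dwell extraction.

Each acceptor-channel trace is fitted with its own two-state hidden Markov
model with Gaussian emissions (intensity levels vary molecule to molecule,
so no global fit is attempted).  The trace is standardized before fitting,
making the idealization exactly invariant to affine intensity rescaling.
Frames after donor photobleach — detected as a sustained collapse of the
donor channel — are excluded from analysis via ``valid_until``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.base import BaseEstimator

from .datamodel import AcquisitionParams, Dwell, DwellSet, Idealization, Trace

# hmmlearn logs rounding-level "not converging" deltas; convergence is
# checked explicitly below
logging.getLogger("hmmlearn").setLevel(logging.ERROR)


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget (strict mode)."""

    def __init__(self, message: str, log_likelihood: float):
        super().__init__(message)
        self.log_likelihood = log_likelihood


class TwoStateIdealizer(BaseEstimator):
    """Per-trace two-state Gaussian-emission HMM, decoded by Viterbi.

    Parameters
    ----------
    max_iter : int
        EM iteration cap (50 is ample for bimodal traces).
    tol : float
        EM log-likelihood convergence tolerance.
    min_separation : float
        Minimum distance between fitted state means, in units of the mean
        within-state SD, below which the trace is treated as single-state
        (guards against splitting pure noise into two spurious states).
    strict_convergence : bool
        If True, raise :class:`ConvergenceError` when EM does not converge;
        otherwise warn and keep the last iterate.

    Attributes (after :meth:`fit`)
    ------------------------------
    means_, variances_ : state emission parameters in original intensity
        units, ordered (unbound, bound) = (low, high).
    transmat_ : frame-to-frame transition matrix in the same order.
    single_state_ : True when the trace was degenerate or unimodal.
    log_likelihood_ : final EM log-likelihood.
    """

    def __init__(
        self,
        max_iter: int = 50,
        tol: float = 1e-6,
        min_separation: float = 2.0,
        init_quantiles: tuple[float, float] = (0.20, 0.80),
        strict_convergence: bool = False,
        random_state: int = 0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.min_separation = min_separation
        self.init_quantiles = init_quantiles
        self.strict_convergence = strict_convergence
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10:
            raise ValueError("trace must have at least 10 frames")
        self._loc = float(np.mean(x))
        self._scale = float(np.std(x))
        if self._scale < 1e-12 * max(1.0, abs(self._loc)):
            warnings.warn("degenerate (zero-variance) trace; single-state fallback")
            self.single_state_ = True
            self.means_ = np.array([self._loc, self._loc])
            self.variances_ = np.zeros(2)
            self.transmat_ = np.eye(2)
            self.log_likelihood_ = 0.0
            return self

        z = ((x - self._loc) / self._scale).reshape(-1, 1)
        q_lo, q_hi = np.quantile(z, self.init_quantiles)
        # rare-event traces: both default quantiles sit in the majority
        # state, so seed the second mean from the extreme tail instead
        noise_z = 1.4826 * float(np.median(np.abs(np.diff(z.ravel())))) / np.sqrt(2)
        q50, q999 = np.quantile(z, (0.50, 0.999))
        if (q_hi - q_lo) < max(2.0 * noise_z, 1e-6) and (
            (q999 - q50) > 5.0 * max(noise_z, 1e-6)
        ):
            q_hi = q999
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=self.max_iter,
            tol=self.tol,
            init_params="",
            params="stmc",
            random_state=self.random_state,
        )
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
        model.means_ = np.array([[q_lo], [q_hi]])
        var0 = max(float(np.var(z)) / 4.0, 1e-4)
        model.covars_ = np.full((2, 1), var0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(z)
        self.log_likelihood_ = float(model.monitor_.history[-1])
        if not model.monitor_.converged:
            msg = (
                f"EM did not converge in {self.max_iter} iterations "
                f"(last log-likelihood {self.log_likelihood_:.6g})"
            )
            if self.strict_convergence:
                raise ConvergenceError(msg, self.log_likelihood_)
            warnings.warn(msg)

        order = np.argsort(model.means_.ravel())  # low (unbound) first
        means_z = model.means_.ravel()[order]
        vars_z = model.covars_.reshape(2)[order] if model.covars_.ndim > 1 else (
            np.asarray(model.covars_).reshape(-1)[order]
        )
        sds_z = np.sqrt(vars_z)
        self.single_state_ = bool(
            (means_z[1] - means_z[0]) < self.min_separation * sds_z.mean()
        )
        self.means_ = means_z * self._scale + self._loc
        self.variances_ = vars_z * self._scale**2
        self.transmat_ = model.transmat_[np.ix_(order, order)]
        self._model = model
        self._order = order
        return self

    def predict(self, X) -> np.ndarray:
        """Most-probable state path; 1 = bound (high mean), 0 = unbound."""
        x = np.asarray(X, dtype=float).ravel()
        if self.single_state_:
            return np.zeros(x.size, dtype=np.int8)
        z = ((x - self._loc) / self._scale).reshape(-1, 1)
        raw = self._model.predict(z)
        # relabel so that index 1 is the higher-mean state
        relabel = np.empty(2, dtype=np.int8)
        relabel[self._order] = np.arange(2, dtype=np.int8)
        return relabel[raw]

    def fit_predict(self, X) -> np.ndarray:
        return self.fit(X).predict(X)


def detect_donor_bleach(
    donor: np.ndarray, window: int = 50, sigma: float = 3.0
) -> int:
    """Index of the first frame past which the donor has bleached.

    The donor channel is rendered near zero after bleaching; the criterion
    is a trailing ``window``-frame median falling below ``sigma`` times a
    robust noise estimate.  Returns ``len(donor)`` when no bleach is seen.
    """
    donor = np.asarray(donor, dtype=float)
    n = donor.size
    if n < window:
        return n
    diffs = np.abs(np.diff(donor))
    noise = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
    threshold = max(sigma * noise, 1e-9)
    med = pd.Series(donor).rolling(window).median().to_numpy()
    below = np.flatnonzero(med < threshold)
    if below.size == 0:
        return n
    # trailing median first dips after ~half the window has bleached frames
    return max(0, int(below[0]) - window // 2)


def idealize_hmm(
    trace: Trace, settings: TwoStateIdealizer | None = None
) -> Idealization:
    """Idealize one trace into a binary bound/unbound path."""
    if len(trace) < 10:
        raise ValueError("trace must have at least 10 frames")
    est = settings if settings is not None else TwoStateIdealizer()
    states = est.fit_predict(trace.acceptor)
    valid_until = detect_donor_bleach(trace.donor)
    return Idealization(
        molecule_id=trace.molecule_id, states=states, valid_until=valid_until
    )


def extract_dwells(
    ideal: Idealization, acquisition: AcquisitionParams
) -> DwellSet:
    """Convert maximal state runs into censoring-annotated dwells.

    Only frames before ``valid_until`` are analyzable.  The first run is
    left-censored (its start precedes the movie); the last analyzable run is
    right-censored (it abuts the movie end or the donor-bleach cutoff).
    """
    dt = acquisition.frame_time
    states = ideal.states[: ideal.valid_until]
    dwells: list[Dwell] = []
    if states.size == 0:
        return DwellSet(dwells, dt)
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    for j, (i0, i1) in enumerate(zip(starts, ends)):
        dwells.append(
            Dwell(
                state="bound" if states[i0] == 1 else "unbound",
                duration=(i1 - i0) * dt,
                left_censored=(j == 0),
                right_censored=(j == len(starts) - 1),
                molecule_id=ideal.molecule_id,
            )
        )
    return DwellSet(dwells, dt)
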