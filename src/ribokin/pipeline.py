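"""End-to-end orchestration: traces -> idealizations -> dwells -> rates ->
classes, shared by the CLI, the test suite and the reproduction script."""

from __future__ import annotations

import logging

import numpy as np

from . import classify, kinetics
from .datamodel import AcquisitionParams, DwellSet, Idealization, Trace
from .idealize import TwoStateIdealizer, extract_dwells, idealize_hmm
from .simulate import Cohort

logger = logging.getLogger(__name__)


def idealize_cohort(
    traces: list[Trace], settings: TwoStateIdealizer | None = None
) -> list[Idealization]:
    ideals = []
    for trace in traces:
        ideals.append(idealize_hmm(trace, settings))
    logger.info("idealized %d traces", len(ideals))
    return ideals


def pool_dwells(
    ideals: list[Idealization], acquisition: AcquisitionParams, condition: str = ""
) -> DwellSet:
    """Pool per-molecule dwells (kept in per-molecule chronological order)."""
    pooled = DwellSet([], acquisition.frame_time, condition)
    for ideal in ideals:
        pooled.extend(extract_dwells(ideal, acquisition))
    logger.info(
        "pooled %d dwells from %d molecules (%s)",
        len(pooled),
        len(ideals),
        condition or "unnamed",
    )
    return pooled


def analyze_condition(
    cohort: Cohort,
    k_bleach_eff: float = 0.0,
    ribosome_conc: float = 20e-9,
    settings: TwoStateIdealizer | None = None,
    random_state: int = 0,
) -> dict:
    """Run the full per-condition analysis on one cohort of traces.

    Returns a dict with the unbound/bound mixture fits, second-order binding
    and bleach-corrected dissociation rate constants, the short/long event
    threshold, per-molecule occupancy profiles and the L/M/H summary.
    Dissociation (bound-dwell) rates are corrected by subtracting
    ``k_bleach_eff``; binding rates are corrected for donor-bleach
    truncation only, through the valid-window handling upstream.
    """
    acq = cohort.acquisition
    ideals = idealize_cohort(cohort.traces, settings)
    dwells = pool_dwells(ideals, acq, cohort.condition)

    unbound = dwells.select("unbound")
    unbound_fit = kinetics.robust_two_component_fit(
        unbound, acq.frame_time, random_state=random_state
    )
    rates: dict = {
        "kon_slow": kinetics.compute_kon(unbound_fit.k_slow, ribosome_conc),
        "a_on_slow": unbound_fit.a_slow,
    }
    if unbound_fit.n_components == 2:
        rates["kon_fast"] = kinetics.compute_kon(unbound_fit.k_fast, ribosome_conc)

    bound = dwells.select("bound")
    bound_fit = None
    t_star = None
    labels: list[str] | None = None
    event_counts: dict = {}
    try:
        bound_fit = kinetics.robust_two_component_fit(
            bound, acq.frame_time, random_state=random_state
        )
        rates["koff_slow"] = kinetics.correct_photobleaching(
            bound_fit.k_slow, k_bleach_eff
        )
        rates["a_off_slow"] = bound_fit.a_slow
        if bound_fit.n_components == 2:
            rates["koff_fast"] = kinetics.correct_photobleaching(
                bound_fit.k_fast, k_bleach_eff
            )
            corrected = bound_fit.__class__(
                n_components=2,
                rates=np.array([rates["koff_fast"], rates["koff_slow"]]),
                amplitudes=bound_fit.amplitudes,
                log_likelihood=bound_fit.log_likelihood,
                bic=bound_fit.bic,
                n_dwells=bound_fit.n_dwells,
            )
            t_star = classify.event_threshold(corrected)
            labels, event_counts = classify.classify_events(bound, t_star)
    except (kinetics.InsufficientDataError, kinetics.BoundaryFitError,
            ValueError) as exc:
        logger.warning("bound-dwell analysis unavailable: %s", exc)

    per_mol_counts = {}
    if labels is not None:
        for dwell, label in zip(bound.dwells, labels):
            c = per_mol_counts.setdefault(dwell.molecule_id, [0, 0])
            if label == "short":
                c[0] += 1
            elif label == "long":
                c[1] += 1

    fractions, mol_ids = [], []
    for ideal in ideals:
        if ideal.valid_until == 0:
            logger.warning("%s: no analyzable frames; skipped", ideal.molecule_id)
            continue
        fractions.append(classify.fractional_bound_time(ideal))
        mol_ids.append(ideal.molecule_id)
    counts = [tuple(per_mol_counts.get(m, (0, 0))) for m in mol_ids]
    profiles, occupancy_summary = classify.classify_molecules(
        fractions, None, molecule_ids=mol_ids, event_counts=counts
    )

    return {
        "condition": cohort.condition,
        "n_molecules": len(cohort.traces),
        "ideals": ideals,
        "dwells": dwells,
        "unbound_fit": unbound_fit,
        "bound_fit": bound_fit,
        "rates": rates,
        "t_star": t_star,
        "event_counts": event_counts,
        "profiles": profiles,
        "occupancy_summary": occupancy_summary,
    }


def estimate_bleach_from_control(control: Cohort,
                                 settings: TwoStateIdealizer | None = None
                                 ) -> float:
    """Effective acceptor-bleach rate from a locked-on control cohort.

    Each control molecule is bound for the whole movie, so its first bound
    run ends at photobleach of the last acceptor label; runs cut off by the
    movie end (right-censored) are discarded.
    """
    ideals = idealize_cohort(control.traces, settings)
    loss_times = []
    for ideal in ideals:
        ds = extract_dwells(ideal, control.acquisition)
        for d in ds.dwells:
            if d.state == "bound" and not d.right_censored:
                loss_times.append(d.duration)
                break
    return kinetics.estimate_bleach_rate(loss_times,
                                         control.photophysics.n_acceptor_labels)


def run_jump_analysis(
    before: Cohort,
    after: Cohort,
    k_bleach_eff: float = 0.0,
    ribosome_conc: float = 20e-9,
    random_state: int = 0,
) -> dict:
    """Paired before/after (ligand-jump) analysis of the same molecules."""
    res_before = analyze_condition(
        before, k_bleach_eff, ribosome_conc, random_state=random_state
    )
    res_after = analyze_condition(
        after, k_bleach_eff, ribosome_conc, random_state=random_state
    )
    records, transitions = classify.pair_jump_segments(
        res_before["profiles"], res_after["profiles"]
    )
    kon_b = res_before["rates"]["kon_slow"]
    kon_a = res_after["rates"]["kon_slow"]
    out = {
        "before": res_before,
        "after": res_after,
        "records": records,
        "transitions": transitions,
        "kon_slow_percent_decrease": 100.0 * (1.0 - kon_a / kon_b),
    }
    if "koff_slow" in res_before["rates"] and "koff_slow" in res_after["rates"]:
        out["koff_slow_fold_increase"] = (
            res_after["rates"]["koff_slow"] / res_before["rates"]["koff_slow"]
        )
    return out


def rates_to_jsonable(result: dict) -> dict:
    """Strip a condition result down to JSON-serializable numbers."""
    out = {
        "condition": result["condition"],
        "n_molecules": result["n_molecules"],
        "rates": {k: float(v) for k, v in result["rates"].items()},
        "t_star": None if result["t_star"] is None else float(result["t_star"]),
        "event_counts": dict(result["event_counts"]),
        "occupancy": {
            cls: {
                "count": result["occupancy_summary"][cls]["count"],
                "fraction": result["occupancy_summary"][cls]["fraction"],
                "ci95": list(result["occupancy_summary"][cls]["ci95"]),
            }
            for cls in ("L", "M", "H")
        },
    }
    return out
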