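"""Headline observables of the normalized potential response.

Reduces trajectories to the quantities the model is judged on: the peak of
the normalized response, the return time below 20% of the wild-type peak,
the delay Δt relative to wild-type, the terminal level, a
homeostatic/delayed/sustained classification, the miRNA-yield switch scan,
and steady-state fold changes per genotype (the bridge from model species
to RT-qPCR observables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypePerturbation, apply_perturbation, builtin_genotypes
from .kinetics import ReactionNetwork, SPECIES, ValidationError, steady_state
from .simulate import NormalizedResponse

__all__ = [
    "ResponseMetrics",
    "SwitchSummary",
    "compute_delta_t",
    "response_metrics_table",
    "classify_switch",
    "switch_scan",
    "steady_state_fold_changes",
    "OBSERVABLE_MAP",
    "DegenerateReferenceError",
    "ConfigurationError",
]

#: model species -> RT-qPCR observable
OBSERVABLE_MAP = {
    "R": "nAcRb2_mRNA",
    "St": "SKIP_transcript",
    "K": "Shal",
    "M": "miR-1010",
}

HOMEOSTATIC = "homeostatic"
DELAYED = "delayed"
SUSTAINED = "sustained"


class DegenerateReferenceError(ZeroDivisionError):
    pass


class ConfigurationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResponseMetrics:
    genotype: str
    peak: float
    time_of_peak: float
    t_return: float | None      # first time after the peak staying < threshold
    delta_t: float | None       # t_return - t_return(wild-type)
    terminal_level: float
    classification: str
    threshold: float


def _t_return(times: np.ndarray, v: np.ndarray, threshold: float) -> tuple[float | None, int]:
    """First grid time at/after the peak from which v stays < threshold.

    "Stays below" scans the entire remaining grid (deterministic ODE output
    cannot chatter, so no debounce window is used).  A curve whose peak is
    already below threshold returns at its own peak time.
    """
    ipk = int(np.argmax(v))
    below = v < threshold
    # suffix scan: ok[i] == True iff below[i:] all True
    ok = np.logical_and.accumulate(below[::-1])[::-1]
    for i in range(ipk, len(times)):
        if ok[i]:
            return float(times[i]), ipk
    return None, ipk


def compute_delta_t(
    resp: NormalizedResponse,
    wt: NormalizedResponse,
    threshold: float = 0.2,
) -> ResponseMetrics:
    """Return time and delay of ``resp`` relative to the wild-type.

    The threshold is a fraction of the wild-type peak, which is 1 on the
    normalized scale.  If ``resp`` never falls and stays below the
    threshold within the horizon, ``t_return`` is absent and the response
    is classified ``sustained``.  A wild-type that itself never returns
    indicates an inconsistent default configuration and raises.
    """
    if len(resp.times) != len(wt.times) or not np.allclose(resp.times, wt.times):
        raise ValidationError("response and wild-type must share the same time base")
    wt_ret, _ = _t_return(wt.times, wt.v_norm, threshold)
    if wt_ret is None:
        raise ConfigurationError(
            "wild-type response never returns below threshold within the "
            "horizon; defaults must be re-examined"
        )
    t_ret, ipk = _t_return(resp.times, resp.v_norm, threshold)
    peak = float(resp.v_norm[ipk])
    if t_ret is None:
        cls, delta = SUSTAINED, None
    else:
        delta = t_ret - wt_ret
        cls = DELAYED if delta > 1e-9 else HOMEOSTATIC
    return ResponseMetrics(
        genotype=resp.genotype,
        peak=peak,
        time_of_peak=float(resp.times[ipk]),
        t_return=t_ret,
        delta_t=delta,
        terminal_level=float(resp.v_norm[-1]),
        classification=cls,
        threshold=threshold,
    )


def response_metrics_table(
    responses: dict[str, NormalizedResponse],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Metrics for every genotype in ``responses`` (must include wild-type)."""
    wt = responses["wild-type"]
    rows = []
    for name, resp in responses.items():
        m = compute_delta_t(resp, wt, threshold)
        rows.append({
            "genotype": name, "peak": m.peak, "time_of_peak": m.time_of_peak,
            "t_return": m.t_return, "delta_t": m.delta_t,
            "terminal_level": m.terminal_level, "classification": m.classification,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SwitchSummary:
    """Result of scanning the mirtron yield eta over a grid.

    ``eta_star`` is the smallest grid eta whose response returns below
    threshold (i.e. is not sustained); ``monotone`` records whether the
    grid is cleanly split (sustained below eta_star, returning above) —
    non-monotone scans are reported as such, never silently fixed.
    """

    eta_grid: tuple[float, ...]
    classifications: tuple[str, ...]
    eta_star: float | None
    monotone: bool


def classify_switch(metrics_by_eta: dict[float, ResponseMetrics]) -> SwitchSummary:
    """Summarise switch behaviour from per-eta response metrics."""
    etas = tuple(sorted(metrics_by_eta))
    if len(etas) < 11:
        raise ValidationError("eta grid must contain at least 11 points")
    cls = tuple(metrics_by_eta[e].classification for e in etas)
    returning = [c != SUSTAINED for c in cls]
    eta_star = next((e for e, r in zip(etas, returning) if r), None)
    if eta_star is None:
        monotone = True
    else:
        i = etas.index(eta_star)
        monotone = (not any(returning[:i])) and all(returning[i:])
    return SwitchSummary(eta_grid=etas, classifications=cls,
                         eta_star=eta_star, monotone=monotone)


def switch_scan(
    network: ReactionNetwork,
    eta_grid=None,
    threshold: float = 0.2,
    horizon: float = 50.0,
    settings=None,
) -> SwitchSummary:
    """Simulate across an eta grid and classify each response.

    Implements the observation that the mirtron expression level acts as a
    switch between high and low receptor expression regimes.
    """
    from .simulate import normalize_to_wildtype, simulate_timecourse

    eta_grid = np.linspace(0.0, 1.0, 11) if eta_grid is None else np.asarray(eta_grid, float)
    wt_tc = simulate_timecourse(network, None, None, horizon, settings)
    wt = normalize_to_wildtype(wt_tc, wt_tc)
    metrics: dict[float, ResponseMetrics] = {}
    base_eta = network.parameters.eta
    for e in eta_grid:
        scale = e / base_eta if base_eta > 0 else 0.0
        g = GenotypePerturbation(name=f"eta={e:g}", eta_scale=scale)
        tc = simulate_timecourse(network, g, None, horizon, settings)
        resp = normalize_to_wildtype(tc, wt_tc)
        metrics[float(e)] = compute_delta_t(resp, wt, threshold)
    return classify_switch(metrics)


def steady_state_fold_changes(
    network: ReactionNetwork,
    genotypes: list[GenotypePerturbation] | None = None,
    stimulus_amplitude: float = 1.0,
) -> pd.DataFrame:
    """Steady-state fold change of each qPCR observable vs wild-type.

    Fold change = genotype steady state / wild-type steady state at the
    same constant stimulus, for R→nAcRb2_mRNA, St→SKIP_transcript, K→Shal
    and M→miR-1010.  Wild-type rows are exactly 1.
    """
    genotypes = genotypes if genotypes is not None else builtin_genotypes()
    wt_ss = steady_state(network, stimulus_amplitude).state
    rows = []
    for g in genotypes:
        net = apply_perturbation(network, g)
        ss = steady_state(net, stimulus_amplitude).state
        for sp, obs in OBSERVABLE_MAP.items():
            ref = wt_ss[SPECIES.index(sp)]
            val = ss[SPECIES.index(sp)]
            if g.name == "wild-type":
                fc = 1.0
            else:
                if ref < 1e-12:
                    raise DegenerateReferenceError(
                        f"wild-type steady state of {obs} is ~0; fold change undefined"
                    )
                fc = float(val / ref)
            rows.append({"observable": obs, "condition": g.name, "fold_change": fc})
    return pd.DataFrame(rows)
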