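"""Genotype trajectory integration and wild-type-peak normalization.

Trajectories start from each genotype's own resting (u = 0) steady state,
so the resting potential is 0 by construction for every line without a
constitutive current, and are presented in the standard frame: time in
receptor lifetimes, potential divided by the wild-type peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .genotypes import GenotypePerturbation, apply_perturbation
from .kinetics import (
    SPECIES,
    ReactionNetwork,
    StimulusSpec,
    ValidationError,
    steady_state,
)

__all__ = [
    "SolverSettings",
    "TimeCourse",
    "NormalizedResponse",
    "IntegrationError",
    "NormalizationError",
    "simulate_timecourse",
    "normalize_to_wildtype",
    "simulate_genotypes",
]


class IntegrationError(RuntimeError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-capable integrator settings (LSODA)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 2001
    method: str = "LSODA"


@dataclass(frozen=True)
class TimeCourse:
    genotype: str
    times: np.ndarray          # strictly increasing, receptor-lifetime units
    states: np.ndarray         # (n_times, n_species) aligned with SPECIES
    stimulus: StimulusSpec

    def __post_init__(self) -> None:
        if not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if self.states.shape != (len(self.times), len(SPECIES)):
            raise ValidationError("states shape does not match times/species")

    @property
    def V(self) -> np.ndarray:
        return self.states[:, SPECIES.index("V")]

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class NormalizedResponse:
    genotype: str
    times: np.ndarray
    v_norm: np.ndarray         # V / (wild-type peak V)
    reference_peak: float

    def __post_init__(self) -> None:
        if self.reference_peak <= 0:
            raise NormalizationError("reference_peak must be > 0")


def simulate_timecourse(
    network: ReactionNetwork,
    genotype: GenotypePerturbation | None = None,
    stimulus: StimulusSpec | None = None,
    horizon: float = 50.0,
    settings: SolverSettings | None = None,
) -> TimeCourse:
    """Integrate one genotype from its own resting state.

    The initial condition is the u = 0 steady state of the (perturbed)
    network — each line develops at rest before stimulation.  Integration
    is split at stimulus discontinuities so the solver never steps across
    them.  Raises :class:`IntegrationError` on solver failure rather than
    returning partial data.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be > 0")
    stimulus = stimulus if stimulus is not None else StimulusSpec()
    settings = settings if settings is not None else SolverSettings()
    net = apply_perturbation(network, genotype) if genotype is not None else network
    name = genotype.name if genotype is not None else "wild-type"

    y0 = steady_state(net, stimulus_amplitude=0.0).state
    u = stimulus.profile(gain=net.agonist_gain)
    f = net.rate_function(u)

    t_eval = np.linspace(0.0, horizon, settings.n_points)
    cuts = sorted({0.0, horizon} | {b for b in stimulus.breakpoints() if 0.0 < b < horizon})
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg_t = t_eval[(t_eval >= a) & (t_eval <= b)]
        seg_t = np.unique(np.concatenate([[a], seg_t, [b]]))
        sol = solve_ivp(f, (a, b), y, method=settings.method, t_eval=seg_t,
                        rtol=settings.rtol, atol=settings.atol)
        if not sol.success:
            raise IntegrationError(
                f"integration failed for genotype {name!r} on [{a}, {b}]: "
                f"{sol.message}; parameters={net.parameters.as_dict()}"
            )
        times.append(sol.t)
        states.append(sol.y.T)
        y = sol.y[:, -1]
    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    t_all, keep = np.unique(t_all, return_index=True)
    y_all = y_all[keep]
    # keep only the requested output grid (plus exact breakpoints)
    return TimeCourse(genotype=name, times=t_all, states=np.maximum(y_all, 0.0),
                      stimulus=stimulus)


def normalize_to_wildtype(tc: TimeCourse, wt: TimeCourse) -> NormalizedResponse:
    """Divide a genotype's potential trace by the wild-type peak.

    The wild-type normalized against itself peaks at exactly 1.
    """
    peak = float(wt.V.max())
    if peak <= 0:
        raise NormalizationError("wild-type peak potential is zero; cannot normalize")
    v = tc.V / peak
    if tc is wt or np.array_equal(tc.V, wt.V):
        v = tc.V / peak
        v = v / v.max() if v.max() > 0 else v  # exact 1 at the peak
    return NormalizedResponse(genotype=tc.genotype, times=tc.times,
                              v_norm=v, reference_peak=peak)


def simulate_genotypes(
    network: ReactionNetwork,
    genotypes: list[GenotypePerturbation],
    stimulus: StimulusSpec | None = None,
    horizon: float = 50.0,
    settings: SolverSettings | None = None,
) -> dict[str, NormalizedResponse]:
    """Simulate every genotype and normalize to the wild-type peak.

    A wild-type trace is always computed (it defines the reference peak),
    whether or not it is in ``genotypes``.
    """
    stimulus = stimulus if stimulus is not None else StimulusSpec()
    wt_pert = next((g for g in genotypes if g.name == "wild-type"), None)
    wt = simulate_timecourse(network, wt_pert, stimulus, horizon, settings)
    out: dict[str, NormalizedResponse] = {
        "wild-type": normalize_to_wildtype(wt, wt)
    }
    for g in genotypes:
        if g.name == "wild-type":
            continue
        tc = simulate_timecourse(network, g, stimulus, horizon, settings)
        out[g.name] = normalize_to_wildtype(tc, wt)
    return out
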