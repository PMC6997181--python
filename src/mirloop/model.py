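"""Model / Results interface tying the kinetic network to the data.

:class:`SynapticHomeostasisModel` is constructed from a table of
fold-change observations (by default the published ones) and a wild-type
parameter set.  ``fit()`` calibrates selected rate constants — and,
optionally, perturbation magnitudes such as the nicotine agonist gain —
against the observed steady-state fold changes by seeded multistart
Nelder–Mead on log-parameters, and returns a :class:`CalibrationResults`
carrying the estimates, per-observation residuals and a ``summary()``
table.  Simulation and metrics hang off both objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotypes import (
    GenotypePerturbation,
    apply_perturbation,
    builtin_genotypes,
    genotype_registry,
    get_genotype,
)
from .kinetics import (
    RateParameters,
    ReactionNetwork,
    SPECIES,
    StimulusSpec,
    SteadyStateError,
    ValidationError,
    build_default_network,
    steady_state,
)
from .metrics import OBSERVABLE_MAP, response_metrics_table, steady_state_fold_changes
from .observations import (
    FoldChangeObservation,
    QPCR_ONLY_CONDITIONS,
    builtin_observation_table,
    observations_from_frame,
    validate_observations,
)
from .simulate import SolverSettings, simulate_genotypes, simulate_timecourse

__all__ = ["SynapticHomeostasisModel", "CalibrationResults", "CalibrationError"]

_SPECIES_FOR = {v: k for k, v in OBSERVABLE_MAP.items()}

#: perturbation fields that may be treated as free calibration parameters,
#: addressed as "<genotype>.<field>"
_PERT_FIELDS = ("agonist_gain", "leak_scale", "extra_depolarization",
                "eta_scale", "krep_scale")


class CalibrationError(RuntimeError):
    pass


#: qualitative sign requirements every acceptable fit must preserve,
#: as (observable, condition, cmp, bound-fold-change); "ge"/"le" compare
#: the predicted steady-state fold change against the bound
DIRECTION_CONSTRAINTS: tuple[tuple[str, str, str, float], ...] = (
    ("nAcRb2_mRNA", "miR-1010-null", "ge", 2.0),
    ("SKIP_transcript", "miR-1010-null", "ge", 1.0),
    ("Shal", "miR-1010-null", "ge", 1.0),
    ("nAcRb2_mRNA", "NaChBac", "le", 1.0),
    ("nAcRb2_mRNA", "Kir2.1", "ge", 1.0),
    ("miR-1010", "nAcRb2-delta1010", "ge", 1.0),
)


class SynapticHomeostasisModel:
    """Kinetic homeostasis model bound to fold-change observations.

    Parameters
    ----------
    observations:
        Fold-change data to calibrate against; defaults to the published
        table.  Rows with weight 0 or qPCR-only conditions are carried but
        never enter the loss.
    params:
        Wild-type rate constants (defaults are the shipped, unfitted set).
    genotypes:
        Genotype registry; defaults to the built-in lines.
    stimulus_amplitude:
        Constant agonist drive at which steady-state fold changes are
        evaluated (1 = baseline activity).
    """

    def __init__(
        self,
        observations: list[FoldChangeObservation] | None = None,
        params: RateParameters | None = None,
        genotypes: dict[str, GenotypePerturbation] | None = None,
        stimulus_amplitude: float = 1.0,
    ):
        self.observations = list(observations) if observations is not None \
            else builtin_observation_table()
        validate_observations(self.observations)
        self.params = params if params is not None else RateParameters()
        self.registry = dict(genotypes) if genotypes is not None else genotype_registry()
        self.stimulus_amplitude = float(stimulus_amplitude)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SynapticHomeostasisModel":
        """Build from an observations table (observable, condition, value,
        weight, source)."""
        return cls(observations=observations_from_frame(df), **kwargs)

    # -- structure -------------------------------------------------------

    def network(self, params: RateParameters | None = None) -> ReactionNetwork:
        return build_default_network(params if params is not None else self.params)

    def _fittable(self) -> list[FoldChangeObservation]:
        return [o for o in self.observations
                if o.weight > 0 and o.condition not in QPCR_ONLY_CONDITIONS]

    # -- prediction and loss --------------------------------------------

    def predict_fold_changes(
        self,
        params: RateParameters | None = None,
        registry: dict[str, GenotypePerturbation] | None = None,
        observations: list[FoldChangeObservation] | None = None,
    ) -> pd.DataFrame:
        """Predicted steady-state fold change for each fittable observation."""
        params = params if params is not None else self.params
        registry = registry if registry is not None else self.registry
        obs = observations if observations is not None else self._fittable()
        net = self.network(params)
        wt = steady_state(net, self.stimulus_amplitude).state
        ss_cache: dict[str, np.ndarray] = {}
        rows = []
        for o in obs:
            if o.condition not in ss_cache:
                g = get_genotype(o.condition, registry)
                pnet = apply_perturbation(net, g)
                # warm start from the wild-type fixed point
                try:
                    ss_cache[o.condition] = steady_state(
                        pnet, self.stimulus_amplitude, init=wt).state
                except SteadyStateError:
                    ss_cache[o.condition] = steady_state(
                        pnet, self.stimulus_amplitude).state
            ss = ss_cache[o.condition]
            i = SPECIES.index(_SPECIES_FOR[o.observable])
            ref = wt[i]
            if ref < 1e-12:
                raise ValidationError(
                    f"wild-type steady state of {o.observable} is ~0")
            rows.append({
                "observable": o.observable, "condition": o.condition,
                "observed": o.value, "predicted": float(ss[i] / ref),
                "weight": o.weight,
            })
        return pd.DataFrame(rows)

    def loss(
        self,
        params: RateParameters | None = None,
        registry: dict[str, GenotypePerturbation] | None = None,
    ) -> float:
        """Weighted sum of squared log2 fold-change residuals."""
        pred = self.predict_fold_changes(params, registry)
        if pred.empty:
            return 0.0
        r = np.log2(pred["predicted"]) - np.log2(pred["observed"])
        return float(np.sum(pred["weight"] * r ** 2))

    # -- fitting ---------------------------------------------------------

    def _split_free(self, free: tuple[str, ...]) -> tuple[list[str], list[tuple[str, str]]]:
        rate_names, pert_names = [], []
        valid_rates = set(self.params.as_dict())
        for name in free:
            if "." in name:
                gname, fname = name.rsplit(".", 1)
                if gname not in self.registry:
                    raise CalibrationError(f"free parameter {name!r}: unknown genotype")
                if fname not in _PERT_FIELDS:
                    raise CalibrationError(
                        f"free parameter {name!r}: field must be one of {_PERT_FIELDS}")
                pert_names.append((gname, fname))
            elif name in valid_rates:
                rate_names.append(name)
            else:
                raise CalibrationError(f"unknown free parameter {name!r}")
        return rate_names, pert_names

    def _apply_vector(self, x: np.ndarray, rate_names, pert_names):
        vals = np.exp(x)
        changes = dict(zip(rate_names, vals[: len(rate_names)]))
        if "eta" in changes:
            changes["eta"] = min(changes["eta"], 1.0)
        params = self.params.replace(**changes)
        registry = dict(self.registry)
        for (gname, fname), v in zip(pert_names, vals[len(rate_names):]):
            registry[gname] = registry[gname].replace(**{fname: float(v)})
        return params, registry

    def _direction_penalty(self, params: RateParameters,
                           registry: dict[str, GenotypePerturbation],
                           weight: float = 10.0) -> float:
        """Soft barrier keeping the search inside the sign-correct region.

        Each published direction (repression of the receptor under boosted
        activity, its rise under silencing or loss of the miRNA, ...) adds
        a squared log2 violation when the prediction crosses its bound.
        """
        obs = [FoldChangeObservation(o, c, b) for o, c, _cmp, b in DIRECTION_CONSTRAINTS]
        pred = self.predict_fold_changes(params, registry, observations=obs)
        pen = 0.0
        for (_, _, cmp_, bound), p in zip(DIRECTION_CONSTRAINTS,
                                          pred["predicted"].to_numpy()):
            v = math.log2(max(p, 1e-12) / bound)
            if (cmp_ == "ge" and v < 0) or (cmp_ == "le" and v > 0):
                pen += v * v
        return weight * pen

    def fit(
        self,
        free: tuple[str, ...] = ("a_R", "k_rep", "g_K", "alpha",
                                 "nicotine-low.agonist_gain",
                                 "Kir2.1.leak_scale"),
        bounds: dict[str, tuple[float, float]] | None = None,
        seed: int = 0,
        n_starts: int = 5,
        maxiter: int = 300,
        xatol: float = 1e-6,
        fatol: float = 1e-10,
        direction_constraints: bool = True,
    ) -> "CalibrationResults":
        """Calibrate ``free`` parameters to the observation table.

        Derivative-free (Nelder–Mead) local search in log-parameter space
        from ``n_starts`` seeded multistarts: the current values plus
        log-normally perturbed copies.  Deterministic given ``seed``.
        ``bounds`` (per-name, positive) are enforced by clipping the start
        points and by a box penalty during the search.  With
        ``direction_constraints`` (default) the search objective adds a
        soft barrier so the fit cannot invert a published qPCR sign even
        if that would lower the least-squares loss; the reported
        ``loss_value`` is always the pure weighted sum of squared log2
        residuals.
        """
        if not self.observations:
            raise CalibrationError("no observations to fit")
        rate_names, pert_names = self._split_free(tuple(free))
        names = list(rate_names) + [f"{g}.{f}" for g, f in pert_names]
        p0 = self.params.as_dict()
        x0 = []
        for n in rate_names:
            x0.append(math.log(max(p0[n], 1e-6)))
        for gname, fname in pert_names:
            x0.append(math.log(max(getattr(self.registry[gname], fname), 1e-6)))
        x0 = np.array(x0)

        if not names:
            # no search: evaluate the loss at the current parameters
            res_df = self.predict_fold_changes()
            loss0 = self.loss()
            return CalibrationResults(
                model=self, params=self.params, registry=dict(self.registry),
                loss_value=loss0, converged=True,
                residuals=_with_residuals(res_df), free_names=[],
                trace={"n_starts": 0, "nfev": 0, "best_start": None}, seed=seed,
            )

        bounds = bounds or {}
        lo = np.array([math.log(bounds.get(n, (1e-2, 1e2))[0]) for n in names])
        hi = np.array([math.log(bounds.get(n, (1e-2, 1e2))[1]) for n in names])

        def objective(x: np.ndarray) -> float:
            penalty = float(np.sum(np.maximum(x - hi, 0) ** 2 +
                                   np.maximum(lo - x, 0) ** 2)) * 1e3
            xc = np.clip(x, lo, hi)
            try:
                params, registry = self._apply_vector(xc, rate_names, pert_names)
                value = self.loss(params, registry) + penalty
                if direction_constraints:
                    value += self._direction_penalty(params, registry)
                return value
            except Exception:
                return 1e6 + penalty

        rng = np.random.default_rng(seed)
        starts = [np.clip(x0, lo, hi)]
        for _ in range(max(n_starts, 1) - 1):
            starts.append(np.clip(x0 + rng.normal(0, 0.5, size=len(x0)), lo, hi))

        best = None
        nfev = 0
        first_error: Exception | None = None
        for i, s in enumerate(starts):
            try:
                sol = minimize(objective, s, method="Nelder-Mead",
                               options={"maxiter": maxiter, "xatol": xatol,
                                        "fatol": fatol})
            except Exception as exc:  # pragma: no cover - defensive
                first_error = first_error or exc
                continue
            nfev += sol.nfev
            if best is None or sol.fun < best[1]:
                best = (np.clip(sol.x, lo, hi), float(sol.fun), bool(sol.success), i)
        if best is None:
            raise CalibrationError(f"all calibration starts failed: {first_error}")

        xbest, fbest, converged, istart = best
        params, registry = self._apply_vector(xbest, rate_names, pert_names)
        res_df = self.predict_fold_changes(params, registry)
        return CalibrationResults(
            model=self, params=params, registry=registry,
            loss_value=self.loss(params, registry), converged=converged,
            residuals=_with_residuals(res_df), free_names=names,
            trace={"n_starts": len(starts), "nfev": nfev, "best_start": istart},
            seed=seed,
        )

    # -- simulation convenience ------------------------------------------

    def simulate(self, genotype: str = "wild-type",
                 stimulus: StimulusSpec | None = None, horizon: float = 50.0,
                 settings: SolverSettings | None = None):
        g = get_genotype(genotype, self.registry)
        return simulate_timecourse(self.network(), g, stimulus, horizon, settings)

    def response_metrics(self, genotype_names: list[str] | None = None,
                         horizon: float = 50.0, threshold: float = 0.2,
                         settings: SolverSettings | None = None) -> pd.DataFrame:
        gs = [self.registry[n] for n in genotype_names] if genotype_names \
            else list(self.registry.values())
        responses = simulate_genotypes(self.network(), gs, horizon=horizon,
                                       settings=settings)
        return response_metrics_table(responses, threshold)

    def plot_responses(self, genotype_names: list[str] | None = None,
                       horizon: float = 50.0, path=None, ax=None):
        """Quick-look PNG/axes of the normalized genotype responses."""
        from .plotting import plot_normalized_responses
        gs = [self.registry[n] for n in genotype_names] if genotype_names \
            else list(self.registry.values())
        responses = simulate_genotypes(self.network(), gs, horizon=horizon)
        return plot_normalized_responses(responses, path=path, ax=ax)


def _with_residuals(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["log2_residual"] = np.log2(df["predicted"]) - np.log2(df["observed"])
    return df


@dataclass
class CalibrationResults:
    """Fit results: estimates, residuals, diagnostics and a summary table.

    ``loss_value`` is the weighted sum of squared log2 residuals and is
    recomputable from the residuals column to numerical precision.
    """

    model: SynapticHomeostasisModel
    params: RateParameters
    registry: dict[str, GenotypePerturbation]
    loss_value: float
    converged: bool
    residuals: pd.DataFrame
    free_names: list[str]
    trace: dict
    seed: int

    def recomputed_loss(self) -> float:
        return float(np.sum(self.residuals["weight"] *
                            self.residuals["log2_residual"] ** 2))

    def fitted_network(self) -> ReactionNetwork:
        return build_default_network(self.params)

    def fold_change_table(self, genotype_names: list[str] | None = None) -> pd.DataFrame:
        gs = [self.registry[n] for n in genotype_names] if genotype_names \
            else list(self.registry.values())
        return steady_state_fold_changes(self.fitted_network(), gs,
                                         self.model.stimulus_amplitude)

    def simulate(self, genotype: str = "wild-type",
                 stimulus: StimulusSpec | None = None, horizon: float = 50.0,
                 settings: SolverSettings | None = None):
        g = get_genotype(genotype, self.registry)
        return simulate_timecourse(self.fitted_network(), g, stimulus,
                                   horizon, settings)

    def response_metrics(self, genotype_names: list[str] | None = None,
                         horizon: float = 50.0, threshold: float = 0.2) -> pd.DataFrame:
        gs = [self.registry[n] for n in genotype_names] if genotype_names \
            else list(self.registry.values())
        responses = simulate_genotypes(self.fitted_network(), gs, horizon=horizon)
        return response_metrics_table(responses, threshold)

    def plot_responses(self, genotype_names: list[str] | None = None,
                       horizon: float = 50.0, path=None, ax=None):
        """Quick-look PNG/axes of the fitted-model genotype responses."""
        from .plotting import plot_normalized_responses
        gs = [self.registry[n] for n in genotype_names] if genotype_names \
            else list(self.registry.values())
        responses = simulate_genotypes(self.fitted_network(), gs, horizon=horizon)
        return plot_normalized_responses(responses, path=path, ax=ax)

    def as_dict(self) -> dict:
        return {
            "parameters": self.params.as_dict(),
            "genotypes": {n: g.as_dict() for n, g in self.registry.items()},
            "loss": self.loss_value,
            "converged": self.converged,
            "free_names": list(self.free_names),
            "residuals": self.residuals.to_dict(orient="records"),
            "trace": dict(self.trace),
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            "Synaptic homeostasis model — calibration results",
            "=" * 56,
            f"loss (weighted sum sq. log2 residuals): {self.loss_value:.6g}",
            f"converged: {self.converged}   seed: {self.seed}   "
            f"starts: {self.trace.get('n_starts')}   nfev: {self.trace.get('nfev')}",
            "",
            "Fitted parameters",
            "-" * 56,
        ]
        p = self.params.as_dict()
        for name in self.free_names:
            if "." in name:
                g, f = name.rsplit(".", 1)
                lines.append(f"  {name:28s} {getattr(self.registry[g], f):12.6g}")
            else:
                lines.append(f"  {name:28s} {p[name]:12.6g}")
        if not self.free_names:
            lines.append("  (no free parameters; loss evaluated at current values)")
        lines += ["", "Observations", "-" * 56]
        hdr = f"  {'observable':16s}{'condition':18s}{'obs':>7s}{'pred':>9s}{'log2 res':>10s}"
        lines.append(hdr)
        for r in self.residuals.itertuples():
            lines.append(f"  {r.observable:16s}{r.condition:18s}"
                         f"{r.observed:7.3g}{r.predicted:9.3g}{r.log2_residual:10.3f}")
        return "\n".join(lines)
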