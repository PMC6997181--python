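"""Fly lines and treatments as parameter-level edits of the wild-type model.

Each genotype or pharmacological condition is a :class:`GenotypePerturbation`
— a named bundle of multiplicative/flag edits applied to the wild-type
network.  Perturbations never touch species abundances directly, only
parameters, so every condition is simulated as a variant of one model:

* ``miR-1010-null`` / ``miR-1010-het`` — mirtron yield ``eta`` scaled by
  0 / 0.5 (the heterozygote is modelled as 50% miRNA dosage).
* ``SKIP-MiMIC`` — a truncating cassette that leaves transcription (and
  hence mirtron production) intact but abolishes functional protein:
  only the translation rate ``k_Sp`` is zeroed.
* ``nAcRb2-delta1010`` — the miRNA binding site in the nAcRβ2 3'UTR is
  mutated; repression ``k_rep`` is zeroed while the mirtron itself is intact.
* ``NaChBac`` — a constitutively open bacterial sodium channel: additive
  depolarizing current in dV/dt.
* ``Kir2.1`` — an inward-rectifier potassium channel: increased leak.
* ``nicotine-low`` / ``nicotine-high`` — agonist exposure: the stimulus
  amplitude is multiplied by the dose-dependent gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .kinetics import ReactionNetwork, ValidationError

__all__ = [
    "GenotypePerturbation",
    "apply_perturbation",
    "builtin_genotypes",
    "genotype_registry",
    "get_genotype",
    "UnknownGenotypeError",
]


@dataclass(frozen=True)
class GenotypePerturbation:
    name: str
    eta_scale: float = 1.0
    krep_scale: float = 1.0
    skip_protein_functional: bool = True
    extra_depolarization: float = 0.0
    leak_scale: float = 1.0
    agonist_gain: float = 1.0

    def __post_init__(self) -> None:
        for f in ("eta_scale", "krep_scale", "extra_depolarization",
                  "leak_scale", "agonist_gain"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{self.name}: {f} must be >= 0")

    @property
    def is_identity(self) -> bool:
        return self == GenotypePerturbation(name=self.name)

    def replace(self, **changes) -> "GenotypePerturbation":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class UnknownGenotypeError(KeyError):
    pass


def apply_perturbation(network: ReactionNetwork, g: GenotypePerturbation) -> ReactionNetwork:
    """Return a new network with ``g``'s parameter edits applied.

    The input network is never modified; the identity perturbation returns
    an equivalent network.
    """
    p = network.parameters
    changes: dict[str, float] = {}
    if g.eta_scale != 1.0:
        changes["eta"] = min(p.eta * g.eta_scale, 1.0)
    if g.krep_scale != 1.0:
        changes["k_rep"] = p.k_rep * g.krep_scale
    if not g.skip_protein_functional:
        changes["k_Sp"] = 0.0
    if g.leak_scale != 1.0:
        changes["k_leak"] = p.k_leak * g.leak_scale
    new_params = p.replace(**changes) if changes else p
    return network.with_parameters(
        new_params,
        extra_depolarization=network.extra_depolarization + g.extra_depolarization,
        agonist_gain=network.agonist_gain * g.agonist_gain,
    )


def builtin_genotypes() -> list[GenotypePerturbation]:
    """All fly lines and treatments shipped with the package.

    The NaChBac / Kir2.1 / nicotine magnitudes are unconstrained by direct
    measurements and are exposed in config; calibration may refit them.
    """
    G = GenotypePerturbation
    return [
        G("wild-type"),
        G("miR-1010-null", eta_scale=0.0),
        G("miR-1010-het", eta_scale=0.5),
        G("SKIP-MiMIC", skip_protein_functional=False),
        G("nAcRb2-delta1010", krep_scale=0.0),
        G("NaChBac", extra_depolarization=1.0),
        G("Kir2.1", leak_scale=3.0),
        G("nicotine-low", agonist_gain=2.0),
        G("nicotine-high", agonist_gain=4.0),
    ]


def genotype_registry() -> dict[str, GenotypePerturbation]:
    return {g.name: g for g in builtin_genotypes()}


def get_genotype(name: str, registry: dict[str, GenotypePerturbation] | None = None) -> GenotypePerturbation:
    reg = registry if registry is not None else genotype_registry()
    try:
        return reg[name]
    except KeyError:
        raise UnknownGenotypeError(
            f"unknown genotype {name!r}; registered: {sorted(reg)}"
        ) from None
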