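"""Well-mixed mass-action reaction networks with rate-constant scaling.

A :class:`ReactionNetwork` is an ordered list of species and mass-action
:class:`Reaction` channels, optionally partitioned into *fast* and *slow*
channels.  Fast reversible pairs may be marked *downscalable*, meaning their
rate constants can be divided by a common factor during a simulation without
breaking detailed balance (both members of a pair scale together, so the
pair's equilibrium constant is preserved).

Rate constants are stored in concentration units (nM-based for bimolecular
channels); the ``conversion`` factor (molecules per nM) maps them to
copy-number propensities.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "NetworkValidationError",
    "build_benchmark_network",
    "propensity",
    "apply_reaction",
    "scale_rate_constants",
    "read_network_config",
    "write_network_config",
]

ZEROTH = "zeroth"
UNIMOLECULAR = "unimolecular"
BIMOLECULAR_DISTINCT = "bimolecular-distinct"
BIMOLECULAR_IDENTICAL = "bimolecular-identical"
KINDS = (ZEROTH, UNIMOLECULAR, BIMOLECULAR_DISTINCT, BIMOLECULAR_IDENTICAL)


class NetworkValidationError(ValueError):
    """A reaction network or its text config violates a structural invariant."""


@dataclass
class Reaction:
    """One mass-action reaction channel.

    Channel ids are 1-based and frozen to the construction order so that log
    messages such as "channels 3-6 are fast" can be read against the network
    definition directly.
    """

    id: int
    reactant_stoich: dict[str, int]
    product_stoich: dict[str, int]
    rate_constant: float
    kind: str
    downscalable: bool = False
    reverse_partner: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise NetworkValidationError(
                f"reaction {self.id}: unknown kind {self.kind!r}"
            )
        if self.rate_constant < 0:
            raise NetworkValidationError(
                f"reaction {self.id}: negative rate constant"
            )
        for stoich in (self.reactant_stoich, self.product_stoich):
            for sp, cnt in stoich.items():
                if not (isinstance(cnt, (int, np.integer)) and cnt >= 0):
                    raise NetworkValidationError(
                        f"reaction {self.id}: stoichiometric count for {sp} "
                        f"must be a nonnegative integer, got {cnt!r}"
                    )
        if self.downscalable and self.reverse_partner is None:
            raise NetworkValidationError(
                f"reaction {self.id}: downscalable channel lacks a reverse partner"
            )
        order = sum(self.reactant_stoich.values())
        expected = {
            ZEROTH: 0,
            UNIMOLECULAR: 1,
            BIMOLECULAR_DISTINCT: 2,
            BIMOLECULAR_IDENTICAL: 2,
        }[self.kind]
        if order != expected:
            raise NetworkValidationError(
                f"reaction {self.id}: kind {self.kind} expects reactant order "
                f"{expected}, got {order}"
            )
        if self.kind == BIMOLECULAR_IDENTICAL and len(self.reactant_stoich) != 1:
            raise NetworkValidationError(
                f"reaction {self.id}: bimolecular-identical requires a single "
                "species with stoichiometry 2"
            )
        if self.kind == BIMOLECULAR_DISTINCT and len(self.reactant_stoich) != 2:
            raise NetworkValidationError(
                f"reaction {self.id}: bimolecular-distinct requires two distinct "
                "reactant species"
            )


@dataclass
class ReactionNetwork:
    species: list[str]
    reactions: list[Reaction]
    conservation_laws: list[tuple[list[str], int]] = field(default_factory=list)
    fast_set: frozenset[int] = frozenset()
    slow_set: frozenset[int] = frozenset()
    expected_frequency_ranking: list[int] = field(default_factory=list)
    initial_state: dict[str, int] = field(default_factory=dict)
    conversion: float = 1.0

    def __post_init__(self) -> None:
        self.fast_set = frozenset(self.fast_set)
        self.slow_set = frozenset(self.slow_set)
        ids = [r.id for r in self.reactions]
        if ids != list(range(1, len(ids) + 1)):
            raise NetworkValidationError(
                f"channel ids must be 1..{len(ids)} in order, got {ids}"
            )
        known = set(self.species)
        for r in self.reactions:
            for sp in {**r.reactant_stoich, **r.product_stoich}:
                if sp not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id}: unknown species {sp!r}"
                    )
        all_ids = set(ids)
        if self.fast_set | self.slow_set != all_ids:
            raise NetworkValidationError(
                "fast and slow sets must cover all channels"
            )
        if self.fast_set & self.slow_set:
            raise NetworkValidationError(
                f"channels in both fast and slow sets: "
                f"{sorted(self.fast_set & self.slow_set)}"
            )
        by_id = {r.id: r for r in self.reactions}
        for r in self.reactions:
            if r.downscalable:
                if r.id not in self.fast_set:
                    raise NetworkValidationError(
                        f"downscalable channel {r.id} is not in the fast set"
                    )
                partner = by_id.get(r.reverse_partner)
                if partner is None or not partner.downscalable \
                        or partner.reverse_partner != r.id:
                    raise NetworkValidationError(
                        f"downscalable channel {r.id}: pairing with "
                        f"{r.reverse_partner} is not symmetric"
                    )
        if self.initial_state:
            pops = self.populations_array(self.initial_state)
            self.check_conservation(pops)

    # -- helpers -----------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def downscalable_pairs(self) -> list[tuple[int, int]]:
        """Forward/reverse downscalable pairs, each listed once (low id first)."""
        pairs = []
        for r in self.reactions:
            if r.downscalable and r.id < r.reverse_partner:
                pairs.append((r.id, r.reverse_partner))
        return pairs

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def populations_array(self, pops: dict[str, int]) -> np.ndarray:
        arr = np.zeros(self.n_species, dtype=np.int64)
        for sp, cnt in pops.items():
            arr[self.species_index(sp)] = cnt
        return arr

    def populations_dict(self, arr: np.ndarray) -> dict[str, int]:
        return {sp: int(arr[i]) for i, sp in enumerate(self.species)}

    def check_conservation(self, populations: np.ndarray) -> None:
        for subset, total in self.conservation_laws:
            s = sum(int(populations[self.species_index(sp)]) for sp in subset)
            if s != total:
                raise NetworkValidationError(
                    f"conservation law {'+'.join(subset)} = {total} violated "
                    f"(found {s})"
                )

    def copy(self) -> "ReactionNetwork":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters of the benchmark oscillator.

    ``zeta`` multiplies the fast association constants (phi = 9.77*zeta,
    chi = 3.91*zeta, both nM^-1 min^-1) and thereby controls the time-scale
    separation (stiffness) of the system.  ``conversion`` is the
    molecules-per-nM factor used to turn concentration-based constants into
    copy-number propensities.
    """

    O_total: int = 10
    Y_total: int = 1035
    k0: float = 0.15          # min^-1, basal production of X from free operator
    k1: float = 50.0          # min^-1, production of X from the bound operator
    k2: float = 1.88e-3       # nM^-1 min^-1, X2-catalyzed activation of Yi
    phi: float = 977.0        # nM^-1 min^-1, operator-dimer association
    chi: float = 391.0        # nM^-1 min^-1, dimerization
    a: float = 159.37         # nM, operator-dimer dissociation constant
    b: float = 5.31           # nM, dimer dissociation constant
    lambda1: float = 9.38e-3  # nM^-1 min^-1, degradation of X by active Y
    lambda2: float = 0.01     # min^-1, deactivation of Y
    zeta: float = 100.0       # dimensionless stiffness control
    conversion: float = 1.0   # molecules per nM

    @classmethod
    def from_zeta(cls, zeta: float, conversion: float = 1.0) -> "ParameterSet":
        if zeta <= 0:
            raise ValueError(f"zeta must be positive, got {zeta}")
        if conversion <= 0:
            raise ValueError(f"conversion must be positive, got {conversion}")
        return cls(phi=9.77 * zeta, chi=3.91 * zeta, zeta=zeta,
                   conversion=conversion)

    def __post_init__(self) -> None:
        for name in ("O_total", "Y_total", "k0", "k1", "k2", "phi", "chi",
                     "a", "b", "lambda1", "lambda2", "zeta", "conversion"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")


def build_benchmark_network(zeta: float, conversion: float = 1.0,
                            params: ParameterSet | None = None) -> ReactionNetwork:
    """Build the six-species, nine-reaction benchmark oscillator.

    The system mimics a cell cycle: protein X is produced from an operator O
    (basal rate) or much faster from the dimer-bound operator OX2 (positive
    feedback through the dimer X2), while the active form Y of a regulator
    degrades X (negative feedback).  Channels 3-6 (dimerization and operator
    binding, both reversible) are fast and quasi-equilibrated; they carry the
    stiffness and are the downscalable pairs, controlled by the parameters
    chi and phi only.

    The stored rate constant of channel 3 is ``2*chi`` so that, with the
    ``c * n(n-1)/2`` identical-pair propensity, the macroscopic rate of dimer
    formation is ``chi * x**2``.

    Initial state: all operator dimer-bound (OX2 = O_total) and all regulator
    inactive (Yi = Y_total); every other species at zero.
    """
    p = params if params is not None else ParameterSet.from_zeta(zeta, conversion)
    species = ["O", "X", "X2", "OX2", "Yi", "Y"]
    mk = Reaction
    reactions = [
        mk(1, {"O": 1}, {"O": 1, "X": 1}, p.k0, UNIMOLECULAR),
        mk(2, {"OX2": 1}, {"OX2": 1, "X": 1}, p.k1, UNIMOLECULAR),
        mk(3, {"X": 2}, {"X2": 1}, 2.0 * p.chi, BIMOLECULAR_IDENTICAL,
           downscalable=True, reverse_partner=4),
        mk(4, {"X2": 1}, {"X": 2}, p.chi * p.b, UNIMOLECULAR,
           downscalable=True, reverse_partner=3),
        mk(5, {"O": 1, "X2": 1}, {"OX2": 1}, p.phi, BIMOLECULAR_DISTINCT,
           downscalable=True, reverse_partner=6),
        mk(6, {"OX2": 1}, {"O": 1, "X2": 1}, p.phi * p.a, UNIMOLECULAR,
           downscalable=True, reverse_partner=5),
        mk(7, {"X2": 1, "Yi": 1}, {"X2": 1, "Y": 1}, p.k2, BIMOLECULAR_DISTINCT),
        mk(8, {"X": 1, "Y": 1}, {"Y": 1}, p.lambda1, BIMOLECULAR_DISTINCT),
        mk(9, {"Y": 1}, {"Yi": 1}, p.lambda2, UNIMOLECULAR),
    ]
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        conservation_laws=[(["O", "OX2"], p.O_total), (["Y", "Yi"], p.Y_total)],
        fast_set=frozenset({3, 4, 5, 6}),
        slow_set=frozenset({1, 2, 7, 8, 9}),
        expected_frequency_ranking=[5, 6, 3, 4, 2, 8, 7, 9, 1],
        initial_state={"OX2": p.O_total, "Yi": p.Y_total},
        conversion=p.conversion,
    )


def copy_number_constant(reaction: Reaction, conversion: float) -> float:
    """Copy-number-space rate constant: bimolecular constants are divided by
    the molecules-per-nM conversion; zeroth/unimolecular pass through."""
    if reaction.kind in (BIMOLECULAR_DISTINCT, BIMOLECULAR_IDENTICAL):
        return reaction.rate_constant / conversion
    return reaction.rate_constant


def propensity(reaction: Reaction, populations: dict[str, int] | np.ndarray,
               conversion: float = 1.0,
               species: list[str] | None = None) -> float:
    """Mass-action propensity of ``reaction`` in the given state.

    ``populations`` may be a species->count dict or an array indexed
    consistently with ``species``.
    """
    if isinstance(populations, dict):
        get = populations.get
    else:
        idx = {sp: i for i, sp in enumerate(species)}
        get = lambda sp, d=0: int(populations[idx[sp]])  # noqa: E731
    for sp in reaction.reactant_stoich:
        if get(sp, 0) < 0:
            raise ValueError(f"negative population for species {sp!r}")
    c = copy_number_constant(reaction, conversion)
    if reaction.kind == ZEROTH:
        return c
    if reaction.kind == UNIMOLECULAR:
        (sp,) = reaction.reactant_stoich
        return c * get(sp, 0)
    if reaction.kind == BIMOLECULAR_DISTINCT:
        sp1, sp2 = reaction.reactant_stoich
        return c * get(sp1, 0) * get(sp2, 0)
    (sp,) = reaction.reactant_stoich
    n = get(sp, 0)
    return c * n * (n - 1) / 2.0


def apply_reaction(populations: dict[str, int], reaction: Reaction) -> dict[str, int]:
    """Return the state after firing ``reaction`` once (product minus reactant
    stoichiometry).  A would-be negative count signals a propensity bug."""
    out = dict(populations)
    for sp, cnt in reaction.reactant_stoich.items():
        out[sp] = out.get(sp, 0) - cnt
    for sp, cnt in reaction.product_stoich.items():
        out[sp] = out.get(sp, 0) + cnt
    negative = [sp for sp, cnt in out.items() if cnt < 0]
    if negative:
        raise RuntimeError(
            f"firing reaction {reaction.id} drove species {negative} negative; "
            "this indicates an inconsistent propensity"
        )
    return out


def scale_rate_constants(network: ReactionNetwork, factor: float) -> ReactionNetwork:
    """Return a copy of ``network`` with every downscalable channel's rate
    constant divided by ``factor`` (>= 1).  Other channels are untouched."""
    if factor < 1:
        raise ValueError(f"downscale factor must be >= 1, got {factor}")
    out = network.copy()
    for r in out.reactions:
        if r.downscalable:
            r.rate_constant /= factor
    return out


# -- structured-text config (YAML) ----------------------------------------


def _network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "species": list(network.species),
        "conversion": float(network.conversion),
        "reactions": [
            {
                "id": r.id,
                "reactants": dict(r.reactant_stoich),
                "products": dict(r.product_stoich),
                "rate_constant": float(r.rate_constant),
                "kind": r.kind,
            }
            for r in network.reactions
        ],
        "fast": sorted(network.fast_set),
        "slow": sorted(network.slow_set),
        "downscalable_pairs": [list(p) for p in network.downscalable_pairs],
        "conservation": [
            {"species": list(subset), "total": int(total)}
            for subset, total in network.conservation_laws
        ],
        "initial_state": {k: int(v) for k, v in network.initial_state.items()},
        "expected_frequency_ranking": list(network.expected_frequency_ranking),
    }


def write_network_config(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_network_to_dict(network), fh, sort_keys=False)


def read_network_config(path) -> ReactionNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        pair_of = {}
        for pair in doc.get("downscalable_pairs", []):
            fwd, rev = pair
            pair_of[fwd] = rev
            pair_of[rev] = fwd
        reactions = [
            Reaction(
                id=rd["id"],
                reactant_stoich=dict(rd.get("reactants", {})),
                product_stoich=dict(rd.get("products", {})),
                rate_constant=float(rd["rate_constant"]),
                kind=rd["kind"],
                downscalable=rd["id"] in pair_of,
                reverse_partner=pair_of.get(rd["id"]),
            )
            for rd in doc["reactions"]
        ]
        return ReactionNetwork(
            species=list(doc["species"]),
            reactions=reactions,
            conservation_laws=[
                (list(c["species"]), int(c["total"]))
                for c in doc.get("conservation", [])
            ],
            fast_set=frozenset(doc.get("fast", [])),
            slow_set=frozenset(doc.get("slow", [])),
            expected_frequency_ranking=list(
                doc.get("expected_frequency_ranking", [])
            ),
            initial_state=dict(doc.get("initial_state", {})),
            conversion=float(doc.get("conversion", 1.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, NetworkValidationError):
            raise
        raise NetworkValidationError(f"malformed network config {path}: {exc}")
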