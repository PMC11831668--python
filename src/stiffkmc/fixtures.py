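"""Programmatic toy networks and synthetic cost/error point sets.

These generators provide self-describing test substrates: each returns its
ground-truth parameters (stationary laws, power-law exponents) alongside the
object, so recovery tests can close the loop without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import CostPoint, ErrorPoint
from .network import UNIMOLECULAR, ZEROTH, Reaction, ReactionNetwork

__all__ = ["ToyNetworkSpec", "ToyNetwork", "make_toy_network",
           "make_cost_error_points"]

TEMPLATES = ("birth", "birth-death", "fast-pair-slow-sink",
             "two-slow-channels")


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Template name plus rate parameters for a toy network."""

    template: str
    rates: dict[str, float] = field(default_factory=dict)


@dataclass
class ToyNetwork:
    network: ReactionNetwork
    reference: dict
    """Analytic reference quantities (stationary law, relaxation rates ...)."""


def make_toy_network(spec: ToyNetworkSpec | str, **rates) -> ToyNetwork:
    """Build a toy network from a template.

    Templates:

    * ``birth``: 0 -> A at rate lam; Poisson-process counting reference.
    * ``birth-death``: 0 -> A (lam), A -> 0 (mu per molecule); stationary law
      Poisson(lam/mu).
    * ``fast-pair-slow-sink``: A <-> B fast downscalable pair (kf, kr) with
      B -> C slow (ks) — the minimal fast/slow separable structure whose slow
      dynamics (first C-production time) are invariant to downscaling the
      fast pair at high separation.
    * ``two-slow-channels``: birth-death with an empty fast set; downscaling
      attempts on it always fail the separation gate.
    """
    if isinstance(spec, str):
        spec = ToyNetworkSpec(template=spec, rates=rates)
    r = dict(spec.rates)
    r.update(rates)
    t = spec.template
    if t == "birth":
        lam = r.get("lam", 1.0)
        net = ReactionNetwork(
            species=["A"],
            reactions=[Reaction(1, {}, {"A": 1}, lam, ZEROTH)],
            fast_set=frozenset(), slow_set=frozenset({1}),
            initial_state={"A": 0})
        return ToyNetwork(net, {"counting_rate": lam})
    if t == "birth-death":
        lam, mu = r.get("lam", 10.0), r.get("mu", 1.0)
        net = ReactionNetwork(
            species=["A"],
            reactions=[Reaction(1, {}, {"A": 1}, lam, ZEROTH),
                       Reaction(2, {"A": 1}, {}, mu, UNIMOLECULAR)],
            fast_set=frozenset(), slow_set=frozenset({1, 2}),
            initial_state={"A": 0})
        return ToyNetwork(net, {"stationary_mean": lam / mu,
                                "stationary_law": "poisson",
                                "relaxation_rate": mu})
    if t == "fast-pair-slow-sink":
        kf = r.get("kf", 1e3)
        kr = r.get("kr", 1e3)
        ks = r.get("ks", 1.0)
        n0 = int(r.get("n0", 20))
        net = ReactionNetwork(
            species=["A", "B", "C"],
            reactions=[
                Reaction(1, {"A": 1}, {"B": 1}, kf, UNIMOLECULAR,
                         downscalable=True, reverse_partner=2),
                Reaction(2, {"B": 1}, {"A": 1}, kr, UNIMOLECULAR,
                         downscalable=True, reverse_partner=1),
                Reaction(3, {"B": 1}, {"C": 1}, ks, UNIMOLECULAR),
            ],
            conservation_laws=[(["A", "B", "C"], n0)],
            fast_set=frozenset({1, 2}), slow_set=frozenset({3}),
            expected_frequency_ranking=[1, 2, 3],
            initial_state={"A": n0})
        # at quasi-equilibrium a fraction kf/(kf+kr) of unconverted mass is
        # in B, so C is produced at effective per-molecule rate ks*kf/(kf+kr)
        return ToyNetwork(net, {"qe_fraction_b": kf / (kf + kr),
                                "effective_sink_rate": ks * kf / (kf + kr),
                                "n0": n0})
    if t == "two-slow-channels":
        lam, mu = r.get("lam", 5.0), r.get("mu", 1.0)
        net = ReactionNetwork(
            species=["A"],
            reactions=[Reaction(1, {}, {"A": 1}, lam, ZEROTH),
                       Reaction(2, {"A": 1}, {}, mu, UNIMOLECULAR)],
            fast_set=frozenset(), slow_set=frozenset({1, 2}),
            initial_state={"A": 0})
        return ToyNetwork(net, {"stationary_mean": lam / mu})
    raise ValueError(f"unknown toy-network template {t!r}; "
                     f"choose from {TEMPLATES}")


def make_cost_error_points(slope: float, p: float, q: float,
                           df_grid: np.ndarray, noise_sd: float, seed: int,
                           n_channels: int = 1,
                           ) -> tuple[list[CostPoint], list[ErrorPoint]]:
    """Synthetic cost and error points following exact power laws with
    optional log-normal scatter: c = df**slope * 10**eps and
    ||d|| = p * df**q * 10**eps', eps ~ Normal(0, noise_sd).

    ``df_grid`` must be uniform in log (e.g. powers of a base factor).
    Reproducible via ``seed``.
    """
    df_grid = np.asarray(df_grid, dtype=float)
    rng = np.random.default_rng(seed)
    cost = [CostPoint(df=float(df),
                      c=float(df ** slope
                              * 10.0 ** rng.normal(0.0, noise_sd)))
            for df in df_grid]
    error = [ErrorPoint(df=float(df), channel=ch,
                        norm=float(p * df ** q
                                   * 10.0 ** rng.normal(0.0, noise_sd)))
             for ch in range(1, n_channels + 1) for df in df_grid]
    return cost, error
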