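"""Independent direct-method SSA (Gillespie) oracle.

Deliberately coded without any stiffkmc.engine machinery (plain numpy RNG,
cumulative-sum channel selection) so that it can serve as an independent
check of the Mod-NRM engine's distributional correctness on small networks.
"""

from __future__ import annotations

import numpy as np

from stiffkmc.network import (
    BIMOLECULAR_DISTINCT,
    BIMOLECULAR_IDENTICAL,
    UNIMOLECULAR,
    ZEROTH,
    copy_number_constant,
)


def _propensities(network, pops):
    a = np.zeros(network.n_reactions)
    for j, r in enumerate(network.reactions):
        c = copy_number_constant(r, network.conversion)
        if r.kind == ZEROTH:
            a[j] = c
        elif r.kind == UNIMOLECULAR:
            (sp,) = r.reactant_stoich
            a[j] = c * pops[network.species_index(sp)]
        elif r.kind == BIMOLECULAR_DISTINCT:
            s1, s2 = r.reactant_stoich
            a[j] = (c * pops[network.species_index(s1)]
                    * pops[network.species_index(s2)])
        elif r.kind == BIMOLECULAR_IDENTICAL:
            (sp,) = r.reactant_stoich
            n = pops[network.species_index(sp)]
            a[j] = c * n * (n - 1) / 2.0
    return a


def direct_ssa(network, t_end, seed, sample_interval=0.1, initial=None):
    """Direct-method SSA run; returns (sample_times, samples, counts)."""
    rng = np.random.default_rng(seed)
    pops = network.populations_array(
        initial if initial is not None else network.initial_state)
    net_change = np.zeros((network.n_reactions, network.n_species), np.int64)
    for j, r in enumerate(network.reactions):
        for sp, cnt in r.reactant_stoich.items():
            net_change[j, network.species_index(sp)] -= cnt
        for sp, cnt in r.product_stoich.items():
            net_change[j, network.species_index(sp)] += cnt

    n_samp = int(np.floor(t_end / sample_interval))
    sample_times = (np.arange(n_samp) + 1) * sample_interval
    samples = np.zeros((n_samp, network.n_species), np.int64)
    counts = np.zeros(network.n_reactions, np.int64)
    t = 0.0
    isamp = 0
    while True:
        a = _propensities(network, pops)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a0)
        while isamp < n_samp and sample_times[isamp] < t_next:
            samples[isamp] = pops
            isamp += 1
        if t_next > t_end:
            break
        t = t_next
        mu = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0),
                                 side="right"))
        mu = min(mu, network.n_reactions - 1)
        pops = pops + net_change[mu]
        counts[mu] += 1
    while isamp < n_samp:
        samples[isamp] = pops
        isamp += 1
    return sample_times, samples, counts
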