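"""Modified Next Reaction Method (Mod-NRM) propagation engine.

Every reaction channel j owns an internal clock: T_j is the internal time
consumed so far and P_j the internal time of its next firing, with P_j - T_j
exponentially distributed.  A step computes Delta_j = (P_j - T_j)/a_j for
channels with positive propensity a_j, fires the channel with the smallest
Delta (ties break to the lowest channel id), advances every internal clock by
a_j * Delta, and replenishes P of the fired channel with a fresh
unit-exponential from that channel's random stream.

Streams follow the random-time-change discipline used for common-random-number
(CRN) replication: each *slow* channel draws from its own stream, all *fast*
channels share one stream.  A :class:`Snapshot` captures populations, rate
constants and the slow-channel clocks and stream states only; restoring it
replays the slow reaction path exactly while the fast dynamics re-randomize.

The inner loop is numba-compiled; a 500-KMC-minute benchmark trajectory
(~2e7 steps) takes a few seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._rng import make_streams, next_exponential
from .network import (
    BIMOLECULAR_DISTINCT,
    BIMOLECULAR_IDENTICAL,
    UNIMOLECULAR,
    ZEROTH,
    ReactionNetwork,
    copy_number_constant,
)

__all__ = ["Engine", "Snapshot", "TrajectoryChunk", "ExhaustedError",
           "initialize_engine", "execution_frequencies"]

_KIND_CODE = {ZEROTH: 0, UNIMOLECULAR: 1,
              BIMOLECULAR_DISTINCT: 2, BIMOLECULAR_IDENTICAL: 3}

STATUS_DONE = 0
STATUS_BUFFER_FULL = 1
STATUS_EXHAUSTED = 2
STATUS_MAX_STEPS = 3

_UNLIMITED = 2 ** 62


class ExhaustedError(RuntimeError):
    """All propensities are zero: no channel can fire."""


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _update_propensities(kind, r1, r2, c, pops, a):
    for j in range(kind.shape[0]):
        k = kind[j]
        if k == 0:
            a[j] = c[j]
        elif k == 1:
            a[j] = c[j] * pops[r1[j]]
        elif k == 2:
            a[j] = c[j] * pops[r1[j]] * pops[r2[j]]
        else:
            n = pops[r1[j]]
            a[j] = c[j] * n * (n - 1) * 0.5


@njit(cache=True)
def _init_clocks(kind, r1, r2, c, pops, a, T, P, states, stream_of):
    _update_propensities(kind, r1, r2, c, pops, a)
    for j in range(kind.shape[0]):
        T[j] = 0.0
        P[j] = next_exponential(states, stream_of[j])


@njit(cache=True)
def _one_step(kind, r1, r2, net, c, pops, T, P, a, t, states, stream_of):
    """Advance a single Mod-NRM step.  Returns (mu, t_new); mu = -1 on
    exhaustion (state untouched)."""
    m = kind.shape[0]
    best = np.inf
    mu = -1
    for j in range(m):
        if a[j] > 0.0:
            d = (P[j] - T[j]) / a[j]
            if d < best:
                best = d
                mu = j
    if mu < 0:
        return -1, t
    t_new = t + best
    for j in range(m):
        T[j] += a[j] * best
    for s in range(net.shape[1]):
        pops[s] += net[mu, s]
    P[mu] += next_exponential(states, stream_of[mu])
    _update_propensities(kind, r1, r2, c, pops, a)
    return mu, t_new


@njit(cache=True)
def _run_chunk(kind, r1, r2, net, c, pops, T, P, a, tbox, t_f,
               states, stream_of, sample_times, pbox, samples,
               record, ev_ch, ev_t, ebox, counts, max_steps):
    """Propagate to t_f (or for max_steps), recording samples (zero-order
    hold) and slow events.

    Returns STATUS_DONE, STATUS_BUFFER_FULL (caller grows the event buffer
    and re-enters), STATUS_EXHAUSTED (no channel can fire; clocks frozen,
    flat tail recorded) or STATUS_MAX_STEPS.
    """
    m = kind.shape[0]
    nsp = net.shape[1]
    t = tbox[0]
    sp = pbox[0]
    ep = ebox[0]
    n_samp = sample_times.shape[0]
    cap = ev_t.shape[0]
    steps = 0
    status = STATUS_DONE
    while True:
        best = np.inf
        mu = -1
        for j in range(m):
            if a[j] > 0.0:
                d = (P[j] - T[j]) / a[j]
                if d < best:
                    best = d
                    mu = j
        if mu < 0:
            while sp < n_samp and sample_times[sp] <= t_f:
                for s in range(nsp):
                    samples[sp, s] = pops[s]
                sp += 1
            t = t_f
            status = STATUS_EXHAUSTED
            break
        t_new = t + best
        if t_new > t_f:
            dt = t_f - t
            for j in range(m):
                T[j] += a[j] * dt
            while sp < n_samp and sample_times[sp] <= t_f:
                for s in range(nsp):
                    samples[sp, s] = pops[s]
                sp += 1
            t = t_f
            break
        while sp < n_samp and sample_times[sp] < t_new:
            for s in range(nsp):
                samples[sp, s] = pops[s]
            sp += 1
        for j in range(m):
            T[j] += a[j] * best
        for s in range(nsp):
            pops[s] += net[mu, s]
        counts[mu] += 1
        P[mu] += next_exponential(states, stream_of[mu])
        _update_propensities(kind, r1, r2, c, pops, a)
        t = t_new
        steps += 1
        if record[mu]:
            ev_ch[ep] = mu
            ev_t[ep] = t_new
            ep += 1
            if ep == cap:
                status = STATUS_BUFFER_FULL
                break
        if steps >= max_steps:
            status = STATUS_MAX_STEPS
            break
    tbox[0] = t
    pbox[0] = sp
    ebox[0] = ep
    return status


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class TrajectoryChunk:
    """Samples and slow-event record over one KMC window (t_start, t_end]."""

    t_start: float
    t_end: float
    sample_times: np.ndarray                 # uniform grid within the window
    samples: np.ndarray                      # (n_samples, n_species), counts
    species: list[str]
    events: dict[int, np.ndarray]            # channel id -> firing times
    counts: np.ndarray                       # per-channel firings (id order)
    total_steps: int = 0
    exhausted: bool = False

    @property
    def width(self) -> float:
        return self.t_end - self.t_start

    def series(self, species: str) -> np.ndarray:
        return self.samples[:, self.species.index(species)]


@dataclass
class Snapshot:
    """Slow-stream snapshot taken at the start of a downscaling window."""

    t: float
    populations: np.ndarray
    rate_constants: np.ndarray               # copy-number constants, all channels
    downscale_factor: float
    slow_T: np.ndarray
    slow_P: np.ndarray
    slow_stream_states: np.ndarray           # (n_slow, 4) uint64
    n_channels: int
    step_count: int = 0


def _concatenate_events(parts: list[tuple[np.ndarray, np.ndarray]],
                        record_ids: np.ndarray) -> dict[int, np.ndarray]:
    if parts:
        ch = np.concatenate([p[0] for p in parts])
        tt = np.concatenate([p[1] for p in parts])
    else:
        ch = np.empty(0, dtype=np.int64)
        tt = np.empty(0, dtype=np.float64)
    return {int(cid): tt[ch == cid - 1] for cid in record_ids}


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------

class Engine:
    """Mod-NRM engine bound to a :class:`ReactionNetwork`.

    Use :func:`initialize_engine` (or the constructor) to set up internal
    clocks and streams from a master seed, then :meth:`simulate_chunk` /
    :meth:`advance_one_step` to propagate.
    """

    def __init__(self, network: ReactionNetwork,
                 initial_populations: dict[str, int] | None = None,
                 master_seed: int = 0):
        self.network = network
        pops = network.populations_array(
            initial_populations if initial_populations is not None
            else network.initial_state)
        network.check_conservation(pops)

        m = network.n_reactions
        self.kind = np.array([_KIND_CODE[r.kind] for r in network.reactions],
                             dtype=np.int64)
        self.r1 = np.full(m, -1, dtype=np.int64)
        self.r2 = np.full(m, -1, dtype=np.int64)
        self.net = np.zeros((m, network.n_species), dtype=np.int64)
        for j, r in enumerate(network.reactions):
            reac = list(r.reactant_stoich.items())
            if r.kind == UNIMOLECULAR or r.kind == BIMOLECULAR_IDENTICAL:
                self.r1[j] = network.species_index(reac[0][0])
            elif r.kind == BIMOLECULAR_DISTINCT:
                self.r1[j] = network.species_index(reac[0][0])
                self.r2[j] = network.species_index(reac[1][0])
            for sp, cnt in r.reactant_stoich.items():
                self.net[j, network.species_index(sp)] -= cnt
            for sp, cnt in r.product_stoich.items():
                self.net[j, network.species_index(sp)] += cnt

        self.base_c = np.array(
            [copy_number_constant(r, network.conversion)
             for r in network.reactions])
        self.downscalable = np.array(
            [r.downscalable for r in network.reactions])
        self.c = self.base_c.copy()
        self.downscale_factor = 1.0

        self.slow_ids = sorted(network.slow_set)
        self._slow_idx = np.array([cid - 1 for cid in self.slow_ids],
                                  dtype=np.int64)
        # stream 0 is shared by all fast channels; slow channel cid uses the
        # stream keyed by its own id
        self.master_seed = master_seed
        self.streams = make_streams(master_seed, [0] + list(self.slow_ids))
        self.stream_of = np.zeros(m, dtype=np.int64)
        for rank, cid in enumerate(self.slow_ids):
            self.stream_of[cid - 1] = 1 + rank

        self.pops = pops
        self.t = 0.0
        self.T = np.zeros(m)
        self.P = np.zeros(m)
        self.a = np.zeros(m)
        self.step_count = 0
        _init_clocks(self.kind, self.r1, self.r2, self.c, self.pops,
                     self.a, self.T, self.P, self.streams, self.stream_of)

    # -- propensities & rate constants ------------------------------------

    def _refresh_propensities(self) -> None:
        _update_propensities(self.kind, self.r1, self.r2, self.c,
                             self.pops, self.a)

    def set_downscale_factor(self, factor: float) -> None:
        """Set the *absolute* downscale factor applied to downscalable
        channels (their constants become base/factor)."""
        if factor < 1:
            raise ValueError(f"downscale factor must be >= 1, got {factor}")
        self.downscale_factor = float(factor)
        self.c = self.base_c.copy()
        self.c[self.downscalable] /= factor
        self._refresh_propensities()

    # -- stepping ---------------------------------------------------------

    def advance_one_step(self) -> tuple[int, float]:
        """Fire one reaction; returns (channel id, new time)."""
        mu, t_new = _one_step(self.kind, self.r1, self.r2, self.net, self.c,
                              self.pops, self.T, self.P, self.a, self.t,
                              self.streams, self.stream_of)
        if mu < 0:
            raise ExhaustedError("all propensities are zero")
        self.t = t_new
        self.step_count += 1
        return mu + 1, t_new

    def advance_steps(self, n: int) -> int:
        """Advance exactly n steps (or fewer on exhaustion); returns the
        number executed."""
        done = 0
        try:
            for _ in range(n):
                self.advance_one_step()
                done += 1
        except ExhaustedError:
            pass
        return done

    def simulate_chunk(self, t_f: float, record_slow_events: bool = False,
                       sample_interval: float = 0.1) -> TrajectoryChunk:
        """Propagate to exactly ``t_f``; the trailing partial step is paused,
        not fired (internal clocks advance by a_j*(t_f - t), pending draws
        are retained), so stopping is statistically neutral.

        Samples are taken on the global uniform grid (multiples of
        ``sample_interval`` inside the window) by carrying the pre-step state
        across sample points.
        """
        return self._simulate(t_f, record_slow_events, sample_interval,
                              _UNLIMITED)

    def simulate_chunk_steps(self, max_steps: int, t_f: float,
                             record_slow_events: bool = False,
                             sample_interval: float = 0.1) -> TrajectoryChunk:
        """Propagate until ``max_steps`` reactions have fired or ``t_f`` is
        reached, whichever comes first."""
        return self._simulate(t_f, record_slow_events, sample_interval,
                              int(max_steps))

    _SAMPLE_BLOCK = 1 << 20

    def _simulate(self, t_f: float, record_slow_events: bool,
                  sample_interval: float, max_steps: int) -> TrajectoryChunk:
        if t_f < self.t:
            raise ValueError(f"t_f={t_f} is before current time {self.t}")
        t_s = self.t
        step_limited = max_steps < _UNLIMITED
        eps = 1e-9 * max(1.0, abs(t_s))
        k0 = int(np.ceil((t_s + eps) / sample_interval))
        k_last = int(np.floor(t_f / sample_interval))
        counts = np.zeros(self.network.n_reactions, dtype=np.int64)
        record = np.zeros(self.network.n_reactions, dtype=np.bool_)
        record_ids = np.array(self.slow_ids, dtype=np.int64)
        if record_slow_events:
            record[self._slow_idx] = True

        tbox = np.array([self.t])
        pbox = np.zeros(1, dtype=np.int64)
        ebox = np.zeros(1, dtype=np.int64)
        slow_rate = float(self.a[self._slow_idx].sum()) if self._slow_idx.size \
            else 0.0
        cap = max(4096, int(3 * slow_rate * (t_f - t_s)) + 64) \
            if not step_limited else 4096
        parts: list[tuple[np.ndarray, np.ndarray]] = []
        sample_parts: list[tuple[np.ndarray, np.ndarray]] = []
        exhausted = False
        k_block = k0
        done = False
        while not done:
            # sample grid allocated block-wise so that an (effectively)
            # unbounded t_f with a step limit does not allocate the world
            k_hi = min(k_last, k_block + self._SAMPLE_BLOCK - 1)
            sample_times = np.arange(k_block, k_hi + 1) * sample_interval
            samples = np.zeros((sample_times.size, self.network.n_species),
                               dtype=np.int64)
            t_f_block = min(t_f, (k_hi + 1) * sample_interval) \
                if k_hi < k_last else t_f
            pbox[0] = 0
            while True:
                ev_ch = np.empty(cap, dtype=np.int64)
                ev_t = np.empty(cap, dtype=np.float64)
                ebox[0] = 0
                remaining = max_steps - int(counts.sum())
                status = _run_chunk(self.kind, self.r1, self.r2, self.net,
                                    self.c, self.pops, self.T, self.P, self.a,
                                    tbox, t_f_block, self.streams,
                                    self.stream_of, sample_times, pbox,
                                    samples, record, ev_ch, ev_t, ebox,
                                    counts, remaining)
                ne = int(ebox[0])
                if ne:
                    parts.append((ev_ch[:ne].copy(), ev_t[:ne].copy()))
                if status == STATUS_BUFFER_FULL:
                    if int(counts.sum()) >= max_steps:
                        done = True
                        break
                    cap *= 2
                    continue
                if status == STATUS_MAX_STEPS:
                    done = True
                elif status == STATUS_EXHAUSTED:
                    exhausted = True
                    # step-limited: stop where we are; otherwise keep going
                    # so later blocks record the flat tail up to t_f
                    done = step_limited
                break
            n_filled = int(pbox[0])
            sample_parts.append((sample_times[:n_filled],
                                 samples[:n_filled]))
            k_block = k_hi + 1
            if k_block > k_last:
                done = True
        self.t = float(tbox[0])
        self.step_count += int(counts.sum())
        events = (_concatenate_events(parts, record_ids)
                  if record_slow_events else {})
        all_times = np.concatenate([p[0] for p in sample_parts]) \
            if sample_parts else np.empty(0)
        all_samples = np.concatenate([p[1] for p in sample_parts]) \
            if sample_parts else np.empty((0, self.network.n_species),
                                          dtype=np.int64)
        return TrajectoryChunk(
            t_start=t_s, t_end=self.t, sample_times=all_times,
            samples=all_samples, species=list(self.network.species),
            events=events, counts=counts, total_steps=int(counts.sum()),
            exhausted=exhausted)

    # -- snapshots --------------------------------------------------------

    def save_snapshot(self) -> Snapshot:
        """Capture the state needed for CRN replicate generation: populations,
        rate constants, and the slow channels' clocks and stream states.  Fast
        clocks and the fast stream are deliberately left out."""
        return Snapshot(
            t=self.t,
            populations=self.pops.copy(),
            rate_constants=self.c.copy(),
            downscale_factor=self.downscale_factor,
            slow_T=self.T[self._slow_idx].copy(),
            slow_P=self.P[self._slow_idx].copy(),
            slow_stream_states=self.streams[1:].copy(),
            n_channels=self.network.n_reactions,
            step_count=self.step_count,
        )

    def restore_snapshot(self, snapshot: Snapshot) -> None:
        """Rewind to the snapshot.  Slow channels resume their exact clocks
        and stream states; fast channels are re-initialized with fresh draws
        from the (never restored) shared fast stream."""
        if snapshot.n_channels != self.network.n_reactions:
            raise ValueError("snapshot belongs to a different network topology")
        self.t = snapshot.t
        self.pops = snapshot.populations.copy()
        self.c = snapshot.rate_constants.copy()
        self.downscale_factor = snapshot.downscale_factor
        self.step_count = snapshot.step_count
        self.T[:] = 0.0
        self.T[self._slow_idx] = snapshot.slow_T
        self.P[self._slow_idx] = snapshot.slow_P
        self.streams[1:] = snapshot.slow_stream_states
        self._refresh_propensities()
        for j in range(self.network.n_reactions):
            if j not in self._slow_idx:
                self.P[j] = self.T[j] + next_exponential(
                    self.streams, self.stream_of[j])

    # -- full state (internal; exact pause/resume for the controller) -----

    def capture_full_state(self) -> dict:
        return {
            "t": self.t, "pops": self.pops.copy(), "T": self.T.copy(),
            "P": self.P.copy(), "a": self.a.copy(), "c": self.c.copy(),
            "factor": self.downscale_factor, "streams": self.streams.copy(),
            "step_count": self.step_count,
        }

    def restore_full_state(self, state: dict) -> None:
        self.t = state["t"]
        self.pops = state["pops"].copy()
        self.T = state["T"].copy()
        self.P = state["P"].copy()
        self.a = state["a"].copy()
        self.c = state["c"].copy()
        self.downscale_factor = state["factor"]
        self.streams = state["streams"].copy()
        self.step_count = state["step_count"]


def initialize_engine(network: ReactionNetwork,
                      initial_populations: dict[str, int] | None = None,
                      master_seed: int = 0) -> Engine:
    """Construct an engine with internal clocks T_j = 0 and first firing
    times P_j drawn from each channel's stream."""
    return Engine(network, initial_populations, master_seed)


def execution_frequencies(chunk: TrajectoryChunk) -> dict[int, float]:
    """Events per KMC minute for every channel over the chunk's window."""
    if chunk.width <= 0:
        raise ValueError("chunk window has zero width")
    return {j + 1: float(chunk.counts[j]) / chunk.width
            for j in range(chunk.counts.size)}
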