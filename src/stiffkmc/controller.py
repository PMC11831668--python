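"""On-the-fly rate-constant downscaling controller.

Every ``N`` KMC steps the controller opens a window (t_s, t_f), saves a
snapshot, generates a reference ("unscaled") chunk, and — if the
quasi-equilibrium, frequency-ordering and time-scale-separation gates pass —
replays the window n times from the snapshot with the downscalable rate
constants divided by exponentially increasing factors (CRN replicates: slow
channels reuse their exact random streams, fast channels re-randomize).
The replicates yield cost points (KMC steps, normalized by the reference
chunk) and error points (per-slow-channel interarrival-time error norms),
power laws are fitted to both, and the weighted objective

    F(df) = alpha * C(df) + beta * E(df)

is minimized over [df_current, df_max] to select df_opt.  If the predicted
error at df_opt passes the absolute and relative caps, the window is
regenerated at df_opt and registered as official and the reduction becomes
permanent; otherwise the reference chunk is registered and the run continues
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .engine import Engine, TrajectoryChunk, execution_frequencies, \
    initialize_engine
from .network import ReactionNetwork

__all__ = [
    "DownscaleConfig", "CostPoint", "CostModel", "ErrorPoint", "ErrorModel",
    "AttemptRecord", "RunResult", "choose_window", "qe_check",
    "ordering_check", "compute_tss", "generate_replicates", "detect_df_max",
    "fit_cost_model", "iat_error_norm", "fit_error_model",
    "minimize_objective", "evaluate_acceptance", "run_with_downscaling",
]


@dataclass(frozen=True)
class DownscaleConfig:
    """User-tunable parameters of the downscaling algorithm.

    Defaults are the benchmark values: invoke every N=1e5 steps, window width
    in [10, 15] KMC min, base factor 5 with n=9 replicates (relative factors
    5^0..5^8), at least 2 orders of magnitude of time-scale separation,
    cost/error weights (1, 2), error caps e_max=0.05 and e_inc=2 orders.
    """

    N: int = 100_000
    w_min: float = 10.0
    w_max: float = 15.0
    df_b: float = 5.0
    n: int = 9
    TSS_min: float = 2.0
    alpha: float = 1.0
    beta: float = 2.0
    e_max: float = 0.05
    e_inc: float = 2.0
    delta: float = 0.05          # quasi-equilibrium imbalance threshold
    q_min: float = 0.2           # error-saturation bound on per-channel q
    slope_thresh: float = -0.9   # cost-law slope detector
    curv_thresh: float = 0.05    # cost-law curvature detector
    fit_window: int = 4          # sliding-window size for the slope detector
    min_slow_firings: int = 5    # window-extension forecast target
    sample_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (self.w_max >= self.w_min > 0):
            raise ValueError("need w_max >= w_min > 0")
        if self.df_b <= 1:
            raise ValueError("df_b must be > 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not (0 < self.delta < 1):
            raise ValueError("delta must be in (0, 1)")
        if not (0 < self.e_max < 1):
            raise ValueError("e_max must be in (0, 1)")


@dataclass(frozen=True)
class CostPoint:
    df: float      # absolute downscale factor
    c: float       # KMC steps on the absolute scale: 1 = original-rate window


@dataclass(frozen=True)
class CostModel:
    """Log-log line: C(df) = 10**intercept * df**slope, valid on [1, df_max]."""

    slope: float
    intercept: float

    def __call__(self, df):
        return 10.0 ** self.intercept * np.asarray(df, dtype=float) ** self.slope


@dataclass(frozen=True)
class ErrorPoint:
    df: float
    channel: int
    norm: float    # interarrival-time error norm, KMC min


@dataclass(frozen=True)
class ErrorModel:
    """Aggregated power law E(df) = p * df**q, with the per-channel fits
    retained for the saturation check."""

    p: float
    q: float
    per_channel: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __call__(self, df):
        return self.p * np.asarray(df, dtype=float) ** self.q


@dataclass
class AttemptRecord:
    index: int
    t_s: float
    t_f: float
    tss: float = math.nan
    gates: dict[str, bool] = field(default_factory=dict)
    cost_points: list[CostPoint] = field(default_factory=list)
    error_points: list[ErrorPoint] = field(default_factory=list)
    excluded_channels: list[int] = field(default_factory=list)
    df_max: float = math.nan
    cost_model: CostModel | None = None
    error_model: ErrorModel | None = None
    baseline_norm: float = math.nan
    df_opt: float = math.nan
    error_at_opt: float = math.nan
    unscaled_steps: int = 0
    accepted: bool = False
    abort_reason: str | None = None
    df_cumulative: float = 1.0

    def to_dict(self) -> dict:
        d = {
            "attempt": self.index, "t_s": self.t_s, "t_f": self.t_f,
            "tss": self.tss, "gates": dict(self.gates),
            "cost_points": [[p.df, p.c] for p in self.cost_points],
            "error_points": [[p.df, p.channel, p.norm]
                             for p in self.error_points],
            "excluded_channels": list(self.excluded_channels),
            "df_max": self.df_max,
            "unscaled_steps": self.unscaled_steps,
            "baseline_norm": self.baseline_norm,
            "df_opt": self.df_opt, "error_at_opt": self.error_at_opt,
            "accepted": self.accepted, "abort_reason": self.abort_reason,
            "df_cumulative": self.df_cumulative,
        }
        if self.cost_model is not None:
            d["cost_model"] = {"slope": self.cost_model.slope,
                               "intercept": self.cost_model.intercept}
        if self.error_model is not None:
            d["error_model"] = {"p": self.error_model.p,
                                "q": self.error_model.q,
                                "per_channel": {
                                    k: list(v) for k, v in
                                    self.error_model.per_channel.items()}}
        return d


@dataclass
class RunResult:
    """Official trajectory (concatenated chunks) plus the attempt ledger."""

    chunks: list[TrajectoryChunk]
    attempts: list[AttemptRecord]
    final_downscale_factor: float
    total_steps: int
    sample_interval: float

    def series(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Uniformly sampled (times, counts) for one species across the run."""
        times = np.concatenate([c.sample_times for c in self.chunks])
        values = np.concatenate([c.series(species) for c in self.chunks])
        return times, values


# --------------------------------------------------------------------------
# gates
# --------------------------------------------------------------------------

def choose_window(engine: Engine, config: DownscaleConfig) -> tuple[float, float]:
    """Window (t_s, t_f) starting now.  The width starts at w_min and grows
    in steps of w_min/2 (capped at w_max) while a propensity-based forecast
    predicts fewer than ``min_slow_firings`` slow firings in total — without
    any slow events the error cannot be quantified at all.  Per-channel
    sufficiency is deliberately not required: channels that happen not to
    fire are excluded by the common-length truncation of the error norm."""
    t_s = engine.t
    slow_idx = engine._slow_idx
    w = config.w_min
    if slow_idx.size:
        total_rate = float(engine.a[slow_idx].sum())
        while w < config.w_max and total_rate * w < config.min_slow_firings:
            w = min(w + config.w_min / 2.0, config.w_max)
    return t_s, t_s + w


def qe_check(n_forward: int, n_reverse: int, delta: float) -> bool:
    """Quasi-equilibrium criterion: execution counts of a reversible pair are
    balanced, |Nf - Nr| / (Nf + Nr) <= delta.  Zero total counts fail (the
    pair was not sampled)."""
    total = n_forward + n_reverse
    if total <= 0:
        return False
    return abs(n_forward - n_reverse) / total <= delta


def ordering_check(frequencies: dict[int, float],
                   fast_set, slow_set) -> bool:
    """True iff the anticipated fast channels were all strictly faster than
    every anticipated slow channel in the observed window."""
    if not fast_set or not slow_set:
        return False
    min_fast = min(frequencies[j] for j in fast_set)
    max_slow = max(frequencies[j] for j in slow_set)
    return min_fast > max_slow


def compute_tss(frequencies: dict[int, float], fast_set, slow_set) -> float:
    """Time-scale separation in orders of magnitude:
    log10(min fast frequency / max slow frequency).  Returns +inf when no
    slow channel fired (insufficient sampling; the attempt must abort)."""
    if not fast_set or not slow_set:
        return -math.inf
    min_fast = min(frequencies[j] for j in fast_set)
    max_slow = max(frequencies[j] for j in slow_set)
    if max_slow == 0:
        return math.inf
    if min_fast == 0:
        return -math.inf
    return math.log10(min_fast / max_slow)


# --------------------------------------------------------------------------
# replicates, cost and error quantification
# --------------------------------------------------------------------------

def generate_replicates(snapshot, engine: Engine, config: DownscaleConfig,
                        t_f: float) -> list[TrajectoryChunk]:
    """Generate the n CRN replicates of the window (t_s = snapshot.t, t_f).

    Replicate k (1-based) runs with the current constants divided by
    df_b**(k-1); k=1 keeps them unchanged and differs from the reference
    chunk only through the re-randomized fast dynamics, providing the error
    baseline.  Slow-channel streams and clocks are restored from the snapshot
    before every replicate, so all replicates share the slow reaction path.
    """
    replicates = []
    for k in range(1, config.n + 1):
        engine.restore_snapshot(snapshot)
        engine.set_downscale_factor(
            snapshot.downscale_factor * config.df_b ** (k - 1))
        replicates.append(engine.simulate_chunk(
            t_f, record_slow_events=True,
            sample_interval=config.sample_interval))
    return replicates


def detect_df_max(cost_points: list[CostPoint],
                  config: DownscaleConfig) -> float:
    """Largest downscale factor for which the inverse-proportionality cost
    law holds, from two detectors on the log-log cost data:

    * sliding 4-point linear fits — the first window whose slope exceeds
      ``slope_thresh`` (default -0.9) flags its second-to-last point;
    * central-difference second derivative on the uniform log-df grid — the
      point *preceding* the first exceedance of ``curv_thresh`` is flagged.

    The smaller of the two flags wins; with neither firing, the largest df is
    returned.  Points beyond df_max are to be discarded by the caller.
    """
    pts = sorted(cost_points, key=lambda p: p.df)
    if len(pts) < config.fit_window:
        raise ValueError(
            f"need at least {config.fit_window} cost points, got {len(pts)}")
    x = np.log10([p.df for p in pts])
    y = np.log10([p.c for p in pts])
    n = len(pts)
    w = config.fit_window

    df_max_1 = pts[-1].df
    for i in range(n - w + 1):
        slope = np.polyfit(x[i:i + w], y[i:i + w], 1)[0]
        if slope > config.slope_thresh:
            df_max_1 = pts[i + w - 2].df
            break

    # central second differences of log10(c) with respect to the natural-log
    # df coordinate; the 0.05 threshold is calibrated to this convention (a
    # curvature per decade^2 would trip on the gentle bend of the slow-step
    # cost floor long before the cost law actually breaks)
    df_max_2 = pts[-1].df
    h_ln = float(np.diff(np.log([p.df for p in pts])).mean())
    for i in range(1, n - 1):
        d2 = (y[i + 1] - 2.0 * y[i] + y[i - 1]) / h_ln ** 2
        if abs(d2) > config.curv_thresh:
            df_max_2 = pts[i - 1].df
            break

    return min(df_max_1, df_max_2)


def fit_cost_model(cost_points: list[CostPoint]) -> CostModel:
    """Least-squares line through (log10 df, log10 c)."""
    if len(cost_points) < 2:
        raise ValueError("need at least 2 valid cost points")
    x = np.log10([p.df for p in cost_points])
    y = np.log10([p.c for p in cost_points])
    slope, intercept = np.polyfit(x, y, 1)
    return CostModel(slope=float(slope), intercept=float(intercept))


def iat_error_norm(reference_events: np.ndarray,
                   replicate_events: np.ndarray,
                   t_start: float) -> float | None:
    """Euclidean norm of the interarrival-time difference vector for one slow
    channel.  The first interarrival time is measured from the window start;
    the two IAT vectors are truncated to their common length.  Returns None
    when either list is empty (channel must be excluded from the fit)."""
    if len(reference_events) == 0 or len(replicate_events) == 0:
        return None
    ref = np.diff(reference_events, prepend=t_start)
    rep = np.diff(replicate_events, prepend=t_start)
    m = min(ref.size, rep.size)
    return float(np.linalg.norm(rep[:m] - ref[:m]))


def fit_error_model(error_points: list[ErrorPoint], df_max: float,
                    config: DownscaleConfig) -> tuple[ErrorModel, bool]:
    """Aggregated power-law fit E(df) = p*df**q over all channels' points
    with df <= df_max, plus per-channel fits for the saturation check
    (saturation_ok is False when any per-channel exponent q_j < q_min,
    meaning that channel's error no longer grows with df)."""
    pts = [p for p in error_points if p.df <= df_max and p.norm > 0]
    dfs = sorted({p.df for p in pts})
    if len(dfs) < 2:
        raise ValueError("need points at >= 2 distinct downscale factors")
    x = np.log10([p.df for p in pts])
    y = np.log10([p.norm for p in pts])
    q, logp = np.polyfit(x, y, 1)

    per_channel: dict[int, tuple[float, float]] = {}
    saturation_ok = True
    for ch in sorted({p.channel for p in pts}):
        cp = [p for p in pts if p.channel == ch]
        if len({p.df for p in cp}) < 2:
            continue
        qj, logpj = np.polyfit(np.log10([p.df for p in cp]),
                               np.log10([p.norm for p in cp]), 1)
        per_channel[ch] = (float(10.0 ** logpj), float(qj))
        if qj < config.q_min:
            saturation_ok = False
    return ErrorModel(p=float(10.0 ** logp), q=float(q),
                      per_channel=per_channel), saturation_ok


def minimize_objective(cost_model: CostModel, error_model: ErrorModel,
                       alpha: float, beta: float,
                       df_lo: float, df_max: float) -> float:
    """Minimize F(df) = alpha*C(df) + beta*E(df) over [df_lo, df_max].  A
    dense log-grid scan brackets the minimum, then bounded scalar refinement
    polishes it; df_opt need not be a power of the base factor.

    The models are used exactly as fitted.  The cost points behind C carry
    the absolute normalization (cost 1 = an original-rate window), so from
    the second attempt onward the marginal speed gain of further downscaling
    is correctly tiny and the error term stops the optimizer early.
    """
    if not (df_max >= df_lo >= 1):
        raise ValueError(f"need df_max >= df_lo >= 1, got [{df_lo}, {df_max}]")

    def objective(log_df):
        df = 10.0 ** log_df
        return alpha * float(cost_model(df)) + beta * float(error_model(df))

    lo, hi = math.log10(df_lo), math.log10(df_max)
    if hi == lo:
        return df_lo
    grid = np.linspace(lo, hi, 2000)
    vals = np.array([objective(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise ValueError("objective is not finite on the search interval")
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    if a == b:
        return float(10.0 ** grid[k])
    res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-8})
    best = res.x if res.fun <= vals[k] else grid[k]
    return float(10.0 ** best)


@dataclass(frozen=True)
class AcceptanceDecision:
    accepted: bool
    error_at_opt: float
    absolute_ok: bool
    relative_ok: bool
    relative_checked: bool


def evaluate_acceptance(df_opt: float, error_model: ErrorModel,
                        baseline_norm: float,
                        config: DownscaleConfig) -> AcceptanceDecision:
    """Error gates on the candidate df_opt: the fitted error must not exceed
    e_max, nor exceed the df=1 baseline by more than e_inc orders of
    magnitude.  A zero baseline skips the relative criterion."""
    e_opt = float(error_model(df_opt))
    absolute_ok = e_opt <= config.e_max
    if baseline_norm > 0:
        relative_checked = True
        relative_ok = math.log10(e_opt / baseline_norm) <= config.e_inc
    else:
        relative_checked = False
        relative_ok = True
    return AcceptanceDecision(
        accepted=absolute_ok and relative_ok,
        error_at_opt=e_opt, absolute_ok=absolute_ok,
        relative_ok=relative_ok, relative_checked=relative_checked)


# --------------------------------------------------------------------------
# the full loop
# --------------------------------------------------------------------------

def _attempt_downscaling(engine: Engine, config: DownscaleConfig,
                         record: AttemptRecord) -> TrajectoryChunk:
    """Run one downscaling attempt starting at the current engine time.
    Returns the chunk to register as official; ``record`` is filled in
    place.  On any abort the engine is left exactly at the end state of the
    reference chunk."""
    network = engine.network
    df_cum = engine.downscale_factor
    record.df_cumulative = df_cum

    t_s, t_f = choose_window(engine, config)
    record.t_s, record.t_f = t_s, t_f
    snapshot = engine.save_snapshot()
    unscaled = engine.simulate_chunk(
        t_f, record_slow_events=True, sample_interval=config.sample_interval)
    record.unscaled_steps = unscaled.total_steps
    end_state = engine.capture_full_state()

    def abort(reason: str) -> TrajectoryChunk:
        record.abort_reason = reason
        engine.restore_full_state(end_state)
        return unscaled

    freq = execution_frequencies(unscaled)
    counts = unscaled.counts

    qe_ok = all(
        qe_check(int(counts[f - 1]), int(counts[r - 1]), config.delta)
        for f, r in network.downscalable_pairs)
    record.gates["qe"] = qe_ok
    order_ok = ordering_check(freq, network.fast_set, network.slow_set)
    record.gates["ordering"] = order_ok
    tss = compute_tss(freq, network.fast_set, network.slow_set)
    record.tss = tss
    tss_ok = math.isfinite(tss) and tss >= config.TSS_min
    record.gates["tss"] = tss_ok
    if not (qe_ok and order_ok and tss_ok):
        return abort("gate failure (qe/ordering/tss)")

    replicates = generate_replicates(snapshot, engine, config, t_f)

    valid = [(k, rep) for k, rep in enumerate(replicates, start=1)
             if not rep.exhausted]
    # absolute anchoring: the reference chunk ran at df_cum, so its absolute
    # cost is 1/df_cum of an original-rate window; this propagates previous
    # accepted speed gains into the cost model of later attempts
    record.cost_points = [
        CostPoint(df=df_cum * config.df_b ** (k - 1),
                  c=rep.total_steps / unscaled.total_steps / df_cum)
        for k, rep in valid]
    if len(record.cost_points) < config.fit_window:
        return abort("insufficient cost points")

    df_max = detect_df_max(record.cost_points, config)
    record.df_max = df_max
    if df_max < df_cum:
        return abort("df_max below current downscale factor")

    error_points: list[ErrorPoint] = []
    excluded: set[int] = set()
    baseline_norms: list[float] = []
    for k, rep in valid:
        df_abs = df_cum * config.df_b ** (k - 1)
        for cid in engine.slow_ids:
            norm = iat_error_norm(unscaled.events[cid], rep.events[cid], t_s)
            if norm is None:
                excluded.add(cid)
                continue
            error_points.append(ErrorPoint(df=df_abs, channel=cid, norm=norm))
            if k == 1:
                baseline_norms.append(norm)
    record.error_points = error_points
    record.excluded_channels = sorted(excluded)
    if not baseline_norms:
        return abort("no slow channel with common firings at df=1")
    record.baseline_norm = float(np.mean(baseline_norms))

    try:
        error_model, saturation_ok = fit_error_model(
            error_points, df_max, config)
    except ValueError as exc:
        return abort(f"error fit failed: {exc}")
    record.error_model = error_model
    record.gates["saturation"] = saturation_ok
    if not saturation_ok:
        return abort("error norm saturated for at least one slow channel")

    cost_model = fit_cost_model(
        [p for p in record.cost_points if p.df <= df_max])
    record.cost_model = cost_model

    try:
        df_opt = minimize_objective(cost_model, error_model, config.alpha,
                                    config.beta, df_cum, df_max)
    except ValueError as exc:
        return abort(f"optimization failed: {exc}")
    record.df_opt = df_opt

    decision = evaluate_acceptance(df_opt, error_model,
                                   record.baseline_norm, config)
    record.error_at_opt = decision.error_at_opt
    record.gates["e_max"] = decision.absolute_ok
    record.gates["e_inc"] = decision.relative_ok
    if not decision.accepted:
        return abort("error caps exceeded at df_opt")

    # regenerate the window at df_opt and make the reduction permanent
    engine.restore_snapshot(snapshot)
    engine.set_downscale_factor(df_opt)
    official = engine.simulate_chunk(
        t_f, record_slow_events=False, sample_interval=config.sample_interval)
    record.accepted = True
    record.df_cumulative = df_opt
    return official


def run_with_downscaling(network: ReactionNetwork,
                         initial_state: dict[str, int] | None,
                         config: DownscaleConfig,
                         master_seed: int,
                         t_end: float) -> RunResult:
    """Full simulation loop: propagate N steps, attempt a downscaling, repeat
    until t_end.  Aborted attempts register the reference chunk (negligible
    extra cost); accepted attempts register the regenerated chunk and reduce
    the downscalable rate constants permanently."""
    engine = initialize_engine(network, initial_state, master_seed)
    chunks: list[TrajectoryChunk] = []
    attempts: list[AttemptRecord] = []
    m = 0
    while engine.t < t_end:
        filler = engine.simulate_chunk_steps(
            config.N, t_end, sample_interval=config.sample_interval)
        chunks.append(filler)
        if engine.t >= t_end or filler.exhausted:
            break
        m += 1
        record = AttemptRecord(index=m, t_s=engine.t, t_f=engine.t)
        official = _attempt_downscaling(engine, config, record)
        attempts.append(record)
        chunks.append(official)
        if official.exhausted:
            break
    return RunResult(chunks=chunks, attempts=attempts,
                     final_downscale_factor=engine.downscale_factor,
                     total_steps=engine.step_count,
                     sample_interval=config.sample_interval)
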