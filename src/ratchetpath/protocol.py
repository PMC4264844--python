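"""The three-step search for a binding intermediate.

Step 1 runs ratchet-biased unbinding from each bound-state start structure
at the strong initial bias (300 pN/A, chosen so the ligand unbinds within
the run limit).  Metastable segments with lifetime above 150 ps go straight
into the candidate pool; shorter stable stretches yield restart structures.
Step 2 re-runs each restart at a bias lowered in steps of 25 pN/A within
50-250 pN/A to extend the lifetime, with branch logic: a long plateau is
pooled (2b); a ligand that returns to the bound state means the bias was
too low (discard); a fast unbinding with no plateau means it was too high
(retry at the next lower alpha); an exhausted schedule discards the
restart.  Step 3 clusters the pooled segments on their structural feature
vector (per-moiety pocket COM distances and per-moiety RMSDs) and applies
four acceptance criteria: within-run stability, protein integrity, tight
clustering across runs, and proximity to the bound state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .bmd import (ALPHA_INITIAL, BiasState, BMDResult, ScheduleExhausted,
                  next_alpha, run_bmd)
from .geometry import com_distance, superpose, apply_transform
from .metastable import MetastableSegment, detect_plateaus
from .toysim import LangevinParams, ToyComplex, run_langevin

__all__ = [
    "DetectorParams",
    "ProtocolConfig",
    "PooledSegment",
    "CandidatePool",
    "ClusterReport",
    "MonitorSeries",
    "compute_monitor_series",
    "step1_unbind",
    "step2_extend",
    "step2_schedule",
    "step3_cluster",
    "run_protocol",
    "ProtocolResult",
]

#: Channel layout of the monitor series.
MONITOR_CHANNELS = (
    "d_RC", "d_CM_core", "d_CM_iBu", "d_CM_Tol", "d_CM_Ethe",
    "rmsd_nonloop_A1",
    "rmsd_core_A1", "rmsd_iBu_A1", "rmsd_Tol_A1", "rmsd_Ethe_A1",
)
#: Channels used as the clustering feature vector (step 3).
FEATURE_CHANNELS = (
    "d_CM_core", "d_CM_iBu", "d_CM_Tol", "d_CM_Ethe",
    "rmsd_core_A1", "rmsd_iBu_A1", "rmsd_Tol_A1", "rmsd_Ethe_A1",
)
MOIETIES = ("core", "iBu", "Tol", "Ethe")


@dataclass
class DetectorParams:
    window: float = 50.0       # ps
    drift_tol: float = 0.5     # Angstrom
    fluct_tol: float = 1.0     # Angstrom
    min_lifetime: float = 150.0  # ps (pooling requires strictly more)
    short_lifetime: float = 25.0  # ps, restart-candidate stretches


@dataclass
class ProtocolConfig:
    alpha1: float = ALPHA_INITIAL       # pN/Angstrom
    time_limit: float = 2000.0          # ps per biased run
    step2_time_limit: float = 600.0     # ps per extension run
    unbound_offset: float = 8.0         # unbound_rho = bound rho + offset
    n_starts: int = 6
    start_spacing: float = 10.0         # ps between bound-state snapshots
    temperature: float = 300.0
    friction: float = 60.0              # ps^-1
    dt: float = 0.02                    # ps
    frame_interval: float = 0.5         # ps between analyzed frames
    detector: DetectorParams = field(default_factory=DetectorParams)
    rebound_tol: float = 1.0            # Angstrom around the bound rho
    rebound_time: float = 50.0          # ps within tolerance => rebound
    integrity_threshold: float = 2.0    # Angstrom, non-loop protein RMSD
    tight_threshold: float = 1.0        # Angstrom, per-feature ensemble SD
    proximity_offset: float = 5.0       # Angstrom above bound d_CM(core)
    max_restarts: int = 6               # step-2 restarts processed per seed


@dataclass
class MonitorSeries:
    names: tuple[str, ...]
    values: np.ndarray  # (n_frames, n_channels)
    dt: float  # ps per frame


def compute_monitor_series(frames: np.ndarray, system: ToyComplex,
                           reference: np.ndarray, dt: float) -> MonitorSeries:
    """Monitor channels per frame: d_RC, four d_CM, non-loop protein RMSD
    (A1), and per-moiety heavy-atom RMSDs after the same A1 superposition."""
    topo = system.topology
    masses = system.masses
    rc_i, rc_j = system.rc_pair
    pocket = topo.group("pocket")
    calpha = list(topo.group("calpha"))
    nonloop = list(topo.group("nonloop"))
    moiety_idx = [list(topo.group(m)) for m in MOIETIES]
    vals = np.empty((len(frames), len(MONITOR_CHANNELS)))
    for fi, x in enumerate(frames):
        vals[fi, 0] = float(np.linalg.norm(x[rc_i] - x[rc_j]))
        for mi, idx in enumerate(moiety_idx):
            vals[fi, 1 + mi] = com_distance(x, pocket, idx, masses)
        R, t, _ = superpose(x, reference, calpha)
        moved = apply_transform(x, R, t)
        dev = moved - reference
        vals[fi, 5] = float(np.sqrt(np.mean(np.sum(dev[nonloop] ** 2, axis=1))))
        for mi, idx in enumerate(moiety_idx):
            vals[fi, 6 + mi] = float(
                np.sqrt(np.mean(np.sum(dev[idx] ** 2, axis=1))))
    return MonitorSeries(names=MONITOR_CHANNELS, values=vals, dt=dt)


@dataclass
class PooledSegment:
    segment: MetastableSegment
    run_id: str
    alpha: float
    channel_means: dict[str, float]
    channel_fluctuations: dict[str, float]

    @property
    def mean_rho(self) -> float:
        return self.channel_means["d_RC"]

    @property
    def features(self) -> np.ndarray:
        return np.array([self.channel_means[c] for c in FEATURE_CHANNELS])


@dataclass
class CandidatePool:
    segments: list[PooledSegment] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def add(self, entry: PooledSegment) -> None:
        if entry.segment.lifetime <= 150.0:
            raise ValueError("pooled segments must have lifetime > 150 ps")
        self.segments.append(entry)


@dataclass
class RestartCandidate:
    coords: np.ndarray
    run_id: str
    alpha: float
    mean_rho: float


def _segments_of(monitors: MonitorSeries, det: DetectorParams,
                 min_lifetime: float) -> list[MetastableSegment]:
    if monitors.values.shape[0] <= int(round(det.window / monitors.dt)) + 1:
        return []
    return detect_plateaus(monitors.values, monitors.dt, window=det.window,
                           drift_tol=det.drift_tol, fluct_tol=det.fluct_tol,
                           min_lifetime=min_lifetime)


def _entry(seg: MetastableSegment, run_id: str, alpha: float) -> PooledSegment:
    means = dict(zip(MONITOR_CHANNELS, seg.channel_means))
    flucts = dict(zip(MONITOR_CHANNELS, seg.channel_fluctuations))
    return PooledSegment(segment=seg, run_id=run_id, alpha=alpha,
                         channel_means=means, channel_fluctuations=flucts)


def _still_bound(mean_rho: float, bound_rho: float, tol: float) -> bool:
    return mean_rho <= bound_rho + tol


def _detect_rebound(rho: np.ndarray, dt: float, bound_rho: float,
                    tol: float, min_time: float) -> bool:
    """True if rho stays within tol of the bound value for >= min_time,
    after first having left the bound vicinity."""
    inside = rho <= bound_rho + tol
    left_once = False
    run_start = None
    for k, flag in enumerate(inside):
        if not flag:
            left_once = True
            run_start = None
        elif left_once:
            if run_start is None:
                run_start = k
            if (k - run_start) * dt >= min_time:
                return True
    return False


def _run_and_monitor(system: ToyComplex, config: ProtocolConfig,
                     alpha: float, coords0: np.ndarray, time_limit: float,
                     unbound_rho: float, rng: np.random.Generator
                     ) -> tuple[BMDResult, MonitorSeries]:
    params = LangevinParams(temperature=config.temperature,
                            friction=config.friction, dt=config.dt)
    record_every = max(1, int(round(config.frame_interval / config.dt)))
    bias = BiasState(rc_atoms=system.rc_pair, rho_max=0.0, alpha=alpha)
    result = run_bmd(system, params, bias, time_limit=time_limit,
                     unbound_rho=unbound_rho, coords0=coords0,
                     record_every=record_every, rng=rng)
    monitors = compute_monitor_series(result.trajectory.frames, system,
                                      system.coords, result.trajectory.dt)
    return result, monitors


def step1_unbind(system: ToyComplex, start_structures: list[np.ndarray],
                 config: ProtocolConfig, rng: np.random.Generator,
                 bound_rho: float
                 ) -> tuple[CandidatePool, list[RestartCandidate]]:
    """Biased unbinding of every start structure at the initial alpha.

    Long-lived (> 150 ps) off-bound segments are pooled; shorter stable
    stretches yield restart structures for step 2.  Failed runs are logged,
    never fatal.
    """
    pool = CandidatePool()
    restarts: list[RestartCandidate] = []
    unbound_rho = bound_rho + config.unbound_offset
    for si, coords0 in enumerate(start_structures):
        run_id = f"step1/start{si}"
        child = np.random.default_rng(rng.integers(2**31 - 1))
        try:
            result, monitors = _run_and_monitor(
                system, config, config.alpha1, coords0,
                config.time_limit, unbound_rho, child)
        except Exception as exc:  # failed runs are logged, not fatal
            pool.log.append(f"step=1 run={run_id} status=failed error={exc}")
            continue
        segs = _segments_of(monitors, config.detector,
                            config.detector.short_lifetime)
        pooled = 0
        for seg in segs:
            entry = _entry(seg, run_id, config.alpha1)
            if _still_bound(entry.mean_rho, bound_rho, config.rebound_tol):
                continue  # the reactant state is not an intermediate candidate
            if seg.lifetime > config.detector.min_lifetime:
                pool.add(entry)
                pooled += 1
            else:
                idx = min(seg.last_frame_index,
                          result.trajectory.n_frames - 1)
                restarts.append(RestartCandidate(
                    coords=result.trajectory.frames[idx].copy(),
                    run_id=run_id, alpha=config.alpha1,
                    mean_rho=entry.mean_rho))
        pool.log.append(
            f"step=1 run={run_id} alpha={config.alpha1:g} "
            f"unbound={result.stopped_unbound} segments={len(segs)} "
            f"pooled={pooled}")
    return pool, restarts


@dataclass
class Step2Outcome:
    kind: str  # 'pooled' | 'retry' | 'rebound' | 'exhausted'
    entry: PooledSegment | None = None
    next_alpha: float | None = None
    restart_coords: np.ndarray | None = None


def step2_extend(system: ToyComplex, restart: np.ndarray, alpha: float,
                 config: ProtocolConfig, rng: np.random.Generator,
                 bound_rho: float, run_id: str = "step2") -> Step2Outcome:
    """One lifetime-extension run at a lowered alpha, with branch logic.

    A plateau longer than 150 ps away from the bound state is pooled (2b).
    A return to the bound-state vicinity means alpha was too low: the
    simulation is discarded as a rebound (2c).  Unbinding with no plateau
    means alpha was too high: retry at the next lower alpha (2c -> 2a),
    until the schedule is exhausted at 50 pN/A.
    """
    unbound_rho = bound_rho + config.unbound_offset
    result, monitors = _run_and_monitor(system, config, alpha, restart,
                                        config.step2_time_limit,
                                        unbound_rho, rng)
    segs = _segments_of(monitors, config.detector,
                        config.detector.short_lifetime)
    off_bound = [s for s in segs
                 if not _still_bound(_entry(s, run_id, alpha).mean_rho,
                                     bound_rho, config.rebound_tol)]
    long_segs = [s for s in off_bound
                 if s.lifetime > config.detector.min_lifetime]
    if long_segs:
        best = max(long_segs, key=lambda s: s.lifetime)
        return Step2Outcome(kind="pooled", entry=_entry(best, run_id, alpha))
    if _detect_rebound(result.rho, config.dt, bound_rho,
                       config.rebound_tol, config.rebound_time):
        return Step2Outcome(kind="rebound")
    # too high: no metastable state; restart lower, from the latest stable
    # stretch when one exists
    new_restart = restart
    if off_bound:
        last = max(off_bound, key=lambda s: s.last_frame_index)
        idx = min(last.last_frame_index, result.trajectory.n_frames - 1)
        new_restart = result.trajectory.frames[idx].copy()
    try:
        lowered = next_alpha(alpha)
    except ScheduleExhausted:
        return Step2Outcome(kind="exhausted")
    return Step2Outcome(kind="retry", next_alpha=lowered,
                        restart_coords=new_restart)


def step2_schedule(system: ToyComplex, restart: RestartCandidate,
                   config: ProtocolConfig, rng: np.random.Generator,
                   bound_rho: float, pool: CandidatePool) -> str:
    """Walk the alpha schedule for one restart until pooled/discarded."""
    try:
        alpha = next_alpha(restart.alpha)
    except ScheduleExhausted:
        return "exhausted"
    coords = restart.coords
    while True:
        child = np.random.default_rng(rng.integers(2**31 - 1))
        outcome = step2_extend(system, coords, alpha, config, child,
                               bound_rho, run_id=f"{restart.run_id}/a{alpha:g}")
        pool.log.append(
            f"step=2 restart={restart.run_id} alpha={alpha:g} "
            f"outcome={outcome.kind}")
        if outcome.kind == "pooled":
            pool.add(outcome.entry)
            return "pooled"
        if outcome.kind in ("rebound", "exhausted"):
            return outcome.kind
        alpha = outcome.next_alpha
        coords = outcome.restart_coords


@dataclass
class ClusterReport:
    clusters: list[list[int]]                 # pool indices per cluster
    feature_means: list[np.ndarray]
    feature_ensemble_sds: list[np.ndarray]
    criteria: list[dict[str, bool]]
    accepted_cluster: int | None
    feature_names: tuple[str, ...] = FEATURE_CHANNELS

    @property
    def n_accepted(self) -> int:
        return sum(all(c.values()) for c in self.criteria)


def step3_cluster(pool: CandidatePool, config: ProtocolConfig,
                  bound_dcm_core: float) -> ClusterReport:
    """Cluster the pooled segments and apply the four acceptance criteria.

    (i) every member's within-run fluctuations pass the detector tolerance;
    (ii) the non-loop protein RMSD stays below the integrity threshold;
    (iii) every feature's ensemble SD is below the tight-cluster threshold;
    (iv) the cluster-mean pocket-to-core distance lies within the proximity
    window of the bound-state value.
    """
    if not pool.segments:
        raise ValueError("candidate pool is empty")
    feats = np.array([s.features for s in pool.segments])
    n = len(pool.segments)
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(feats), method="average")
        cutoff = config.tight_threshold * np.sqrt(feats.shape[1])
        labels = fcluster(z, t=cutoff, criterion="distance")

    clusters, means, sds, criteria = [], [], [], []
    for cl in sorted(set(labels)):
        idx = [i for i in range(n) if labels[i] == cl]
        members = [pool.segments[i] for i in idx]
        f = feats[idx]
        mean = f.mean(axis=0)
        sd = f.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(f.shape[1])
        stable = all(
            all(v <= config.detector.fluct_tol
                for v in m.channel_fluctuations.values())
            for m in members)
        integrity = float(np.mean(
            [m.channel_means["rmsd_nonloop_A1"] for m in members])
        ) <= config.integrity_threshold
        tight = bool(np.all(sd <= config.tight_threshold))
        core_mean = float(np.mean([m.channel_means["d_CM_core"]
                                   for m in members]))
        proximal = core_mean <= bound_dcm_core + config.proximity_offset
        clusters.append(idx)
        means.append(mean)
        sds.append(sd)
        criteria.append({"stable": stable, "integrity": integrity,
                         "tight": tight, "proximal": proximal})

    passing = [k for k, c in enumerate(criteria) if all(c.values())]
    accepted = None
    if passing:
        # prefer the best-populated passing cluster
        accepted = max(passing, key=lambda k: len(clusters[k]))
    return ClusterReport(clusters=clusters, feature_means=means,
                         feature_ensemble_sds=sds, criteria=criteria,
                         accepted_cluster=accepted)


@dataclass
class ProtocolResult:
    found: bool
    pool: CandidatePool
    report: ClusterReport | None
    bound_rho: float
    bound_dcm_core: float
    accepted_mean_rho: float | None
    accepted_segments: list[PooledSegment]
    log: list[str]


def sample_bound_starts(system: ToyComplex, config: ProtocolConfig,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Unbiased bound-state sampling; snapshots become unbinding starts."""
    from .toysim import run_toy

    params = LangevinParams(temperature=config.temperature,
                            friction=config.friction, dt=config.dt)
    spacing_steps = int(round(config.start_spacing / config.dt))
    n_steps = spacing_steps * config.n_starts
    child = np.random.default_rng(rng.integers(2**31 - 1))
    result = run_toy(system, params, system.coords, n_steps, child,
                     record_every=spacing_steps)
    frames = result.positions[1:]  # skip the un-equilibrated frame 0
    return [f.copy() for f in frames[:config.n_starts]]


def run_protocol(system: ToyComplex, config: ProtocolConfig | None = None,
                 master_seed: int = 0) -> ProtocolResult:
    """Full search: bound sampling -> step 1 -> step 2 -> step 3.

    Deterministic for a given master seed.  ``found`` is True iff step 3
    accepts a cluster.
    """
    config = config if config is not None else ProtocolConfig()
    rng = np.random.default_rng(master_seed)
    i, j = system.rc_pair
    bound_rho = float(np.linalg.norm(system.coords[i] - system.coords[j]))
    topo = system.topology
    bound_dcm_core = com_distance(system.coords, topo.group("pocket"),
                                  topo.group("core"), system.masses)

    starts = sample_bound_starts(system, config, rng)
    pool, restarts = step1_unbind(system, starts, config, rng, bound_rho)
    for restart in restarts[:config.max_restarts]:
        status = step2_schedule(system, restart, config, rng, bound_rho, pool)
        pool.log.append(f"step=2 restart={restart.run_id} final={status}")

    if not pool.segments:
        pool.log.append("step=3 status=empty-pool outcome=none-found")
        return ProtocolResult(found=False, pool=pool, report=None,
                              bound_rho=bound_rho,
                              bound_dcm_core=bound_dcm_core,
                              accepted_mean_rho=None, accepted_segments=[],
                              log=pool.log)
    report = step3_cluster(pool, config, bound_dcm_core)
    accepted_segments: list[PooledSegment] = []
    accepted_rho = None
    if report.accepted_cluster is not None:
        idx = report.clusters[report.accepted_cluster]
        accepted_segments = [pool.segments[k] for k in idx]
        accepted_rho = float(np.mean([s.mean_rho for s in accepted_segments]))
        pool.log.append(
            f"step=3 clusters={len(report.clusters)} accepted="
            f"{report.accepted_cluster} mean_rho={accepted_rho:.3f}")
    else:
        pool.log.append(f"step=3 clusters={len(report.clusters)} accepted=none")
    return ProtocolResult(found=report.accepted_cluster is not None,
                          pool=pool, report=report, bound_rho=bound_rho,
                          bound_dcm_core=bound_dcm_core,
                          accepted_mean_rho=accepted_rho,
                          accepted_segments=accepted_segments, log=pool.log)
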