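"""Metropolis-Hastings sampling of conformations from the posterior.

Chains start from points placed uniformly in a cube whose side is ten
times the mean inferred pairwise distance, and evolve by single-point
proposals drawn volume-uniformly from a ball of radius ``r``.  Two (or
more) parallel chains are run; at geometrically growing milestones ``k``
the 11 snapshots at iterations ``k/2 + i*k/20`` of each chain are
compared: mixing is declared when the mean within-chain structure
distance and the mean cross-chain structure distance agree within 10%.
Samples are then collected every ``delta = k/20`` iterations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .core import (Conformation, FragmentMap, InteractionDataset, ModelParams,
                   PosteriorCache, TECH_5C, if_to_distance)

__all__ = [
    "SamplerConfig",
    "ChainState",
    "Ensemble",
    "MixingCheck",
    "MixingReport",
    "MixingError",
    "init_structure",
    "initial_cube_side",
    "propose_move",
    "accept",
    "mh_step",
    "advance",
    "assess_mixing",
    "sample_ensemble",
    "max_posterior_index",
    "max_posterior_structure",
]


@dataclasses.dataclass
class SamplerConfig:
    """Tuning knobs for :func:`sample_ensemble`.

    ``perturbation_radius`` is in model units (nm).  Mixing is checked at
    milestones ``check_interval_base * 2**j``; once mixed at milestone k,
    thinning is ``delta = k // thin_divisor``.  ``ensemble_size`` is the
    number of samples collected per chain.
    """

    perturbation_radius: float = 0.25
    max_iterations: int = 200_000_000
    mixing_threshold: float = 0.10
    check_interval_base: int = 100_000
    thin_divisor: int = 20
    ensemble_size: int = 100
    n_chains: int = 2
    seed: int = 0
    block_size: int = 1 << 18
    engine: str = "numba"

    def __post_init__(self) -> None:
        if not self.perturbation_radius > 0:
            raise ValueError("perturbation_radius must be > 0")
        if not 0 < self.mixing_threshold < 1:
            raise ValueError("mixing_threshold must be in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.n_chains < 2:
            raise ValueError("at least two parallel chains are required")
        if self.check_interval_base < 20:
            raise ValueError("check_interval_base must be >= 20")
        if self.engine not in ("numba", "python"):
            raise ValueError("engine must be 'numba' or 'python'")


@dataclasses.dataclass
class ChainState:
    """Mutable state of one chain."""

    conf: Conformation
    cache: PosteriorCache
    rng: np.random.Generator
    chain_id: int = 0
    t: int = 0
    accepted: int = 0
    snapshots: Dict[int, np.ndarray] = dataclasses.field(default_factory=dict)

    @property
    def log_posterior(self) -> float:
        return self.cache.total


def initial_cube_side(data: InteractionDataset, params: ModelParams) -> float:
    """Side length of the initialization cube: 10 x mean inferred distance.

    Pairs with non-positive values (possible after noise truncation, or
    zero Hi-C counts) carry no usable distance and are skipped.
    """
    vals = data.values[data.values > 0]
    if len(vals) == 0:
        raise ValueError("no measured pairs with positive value")
    return 10.0 * float(np.mean(if_to_distance(vals, params)))


def init_structure(data: InteractionDataset, params: ModelParams,
                   rng: np.random.Generator) -> Conformation:
    """Random start: each point uniform in the initialization cube."""
    side = initial_cube_side(data, params)
    return Conformation(rng.random((data.n_fragments, 3)) * side)


def _ball_displacement(normals: np.ndarray, u: np.ndarray,
                       radius: float) -> np.ndarray:
    """Volume-uniform points in the ball of ``radius`` (vectorized).

    Direction from normalized Gaussian triples, length ``r * U**(1/3)``.
    """
    norms = np.sqrt(np.einsum("ij,ij->i", normals, normals))
    norms[norms == 0] = 1.0
    return normals * (radius * np.cbrt(u) / norms)[:, None]


def propose_move(conf: Conformation, radius: float,
                 rng: np.random.Generator) -> Tuple[int, np.ndarray]:
    """Pick a fragment uniformly and displace it within a ball of ``radius``."""
    if not radius > 0:
        raise ValueError("radius must be > 0")
    i = int(rng.integers(conf.n))
    disp = _ball_displacement(rng.standard_normal((1, 3)), rng.random(1),
                              radius)[0]
    return i, conf.points[i] + disp


def accept(delta_log_posterior: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always keep improvements, else keep with prob e^delta."""
    if delta_log_posterior >= 0:
        return True
    return bool(rng.random() < math.exp(delta_log_posterior))


def mh_step(state: ChainState, data: InteractionDataset, params: ModelParams,
            config: SamplerConfig) -> ChainState:
    """One Metropolis-Hastings step, updating the cache incrementally."""
    i, new_point = propose_move(state.conf, config.perturbation_radius,
                                state.rng)
    new_total, stash = state.cache.evaluate_move(state.conf, i, new_point)
    delta = new_total - state.cache.total
    if not math.isinf(delta) and accept(delta, state.rng):
        state.cache.apply_move(state.conf, i, new_point, stash, new_total)
        state.accepted += 1
    elif math.isinf(delta) and delta > 0:  # pragma: no cover - defensive
        raise RuntimeError("non-finite positive delta")
    state.t += 1
    return state


def _draw_block(rng: np.random.Generator, n: int, size: int, radius: float):
    """One block of proposal randomness; the python and numba engines
    consume identical arrays, so their trajectories are bit-identical."""
    idx = rng.integers(0, n, size=size)
    normals = rng.standard_normal((size, 3))
    u_rad = rng.random(size)
    u_acc = rng.random(size)
    return idx, _ball_displacement(normals, u_rad, radius), u_acc


def _python_leg(points, cache: PosteriorCache, idx, disp, uacc,
                t_start, snap_iters, snap_out, greedy: bool):
    """Reference implementation of the kernel contract (same trajectory)."""
    conf_view = Conformation.__new__(Conformation)
    conf_view.points = points
    sp = 0
    accepted = 0
    for s in range(len(idx)):
        i = int(idx[s])
        new_point = points[i] + disp[s]
        new_total, stash = cache.evaluate_move(conf_view, i, new_point)
        delta = new_total - cache.total
        if greedy:
            acc = delta > 0.0
        else:
            acc = delta >= 0.0 or uacc[s] < math.exp(delta)
        if acc:
            cache.apply_move(conf_view, i, new_point, stash, new_total)
            accepted += 1
        t = t_start + s + 1
        if sp < len(snap_iters) and t == snap_iters[sp]:
            snap_out[sp] = points
            sp += 1
    return cache.total, accepted, sp


def advance(conf: Conformation, cache: PosteriorCache,
            rng: np.random.Generator, n_steps: int, radius: float, *,
            greedy: bool = False, engine: str = "numba",
            block_size: int = 1 << 18, t0: int = 0,
            snapshot_iters: Sequence[int] = ()) -> Tuple[int, Dict[int, np.ndarray]]:
    """Advance a chain ``n_steps`` proposals from global iteration ``t0``.

    Returns ``(accepted, snapshots)`` where snapshots maps iteration
    numbers (from ``snapshot_iters``, which must lie in ``(t0, t0+n_steps]``)
    to copies of the conformation at that iteration.  Mutates ``conf``
    and ``cache`` in place.
    """
    data, params = cache.data, cache.params
    snaps = np.asarray(sorted(set(int(s) for s in snapshot_iters)),
                       dtype=np.int64)
    if len(snaps) and (snaps[0] <= t0 or snaps[-1] > t0 + n_steps):
        raise ValueError("snapshot iterations outside the leg")
    out: Dict[int, np.ndarray] = {}
    accepted = 0
    t = t0
    done = 0
    si = 0
    while done < n_steps:
        b = min(block_size, n_steps - done)
        idx, disp, uacc = _draw_block(rng, conf.n, b, radius)
        in_block = snaps[(snaps > t) & (snaps <= t + b)]
        snap_out = np.empty((len(in_block), conf.n, 3))
        if engine == "numba":
            from . import _kernels
            if data.technology == TECH_5C:
                total, acc, _ = _kernels.run_leg_5c(
                    conf.points, cache.logterms, cache.total,
                    data.values, data.sigmas,
                    cache.ptr, cache.nbr_pair, cache.nbr_other,
                    float(params.alpha), float(params.psi),
                    idx, disp, uacc, t, in_block, snap_out, greedy)
            else:
                total, sum_dpow, acc, _ = _kernels.run_leg_hic(
                    conf.points, cache.dpow, cache.sum_dpow, cache.total,
                    data.values, cache.total_reads, float(params.kappa),
                    cache.ptr, cache.nbr_pair, cache.nbr_other,
                    float(params.alpha),
                    idx, disp, uacc, t, in_block, snap_out, greedy)
                cache.sum_dpow = float(sum_dpow)
            cache.total = float(total)
        else:
            total, acc, _ = _python_leg(conf.points, cache, idx, disp, uacc,
                                        t, in_block, snap_out, greedy)
        accepted += acc
        for k, it in enumerate(in_block):
            out[int(it)] = snap_out[k].copy()
        t += b
        done += b
        si += len(in_block)
    return accepted, out


@dataclasses.dataclass
class MixingCheck:
    mixed: bool
    within_mean: float
    cross_mean: float
    ratio: float


def _snapshot_list(chain) -> List[np.ndarray]:
    if hasattr(chain, "snapshots"):
        return [chain.snapshots[k] for k in sorted(chain.snapshots)]
    return [np.asarray(c.points if isinstance(c, Conformation) else c, float)
            for c in chain]


def assess_mixing(chain_a, chain_b, threshold: float = 0.10) -> MixingCheck:
    """Compare within-chain vs cross-chain mean structure distances.

    Accepts :class:`ChainState` objects (uses their stored snapshots) or
    plain sequences of conformations/point arrays.  The within-chain mean
    is over unordered snapshot pairs of chain A; the cross mean is over
    the full A x B product.  Mixed iff ``|within - cross| / within`` is
    at or below the threshold.
    """
    snaps_a = _snapshot_list(chain_a)
    snaps_b = _snapshot_list(chain_b)
    if len(snaps_a) < 2 or len(snaps_b) < 2:
        raise ValueError("need at least 2 snapshots per chain to assess mixing")
    va = np.stack([pdist(s) for s in snaps_a])
    vb = np.stack([pdist(s) for s in snaps_b])
    within = float(pdist(va).mean())
    cross = float(cdist(va, vb).mean())
    if within == 0.0:
        ratio = 0.0 if cross == 0.0 else np.inf
    else:
        ratio = abs(within - cross) / within
    return MixingCheck(bool(ratio <= threshold), within, cross, float(ratio))


@dataclasses.dataclass
class MixingRecord:
    iteration: int
    within_mean: float
    cross_mean: float
    ratio: float
    mixed: bool


@dataclasses.dataclass
class MixingReport:
    records: List[MixingRecord] = dataclasses.field(default_factory=list)
    threshold: float = 0.10
    mixed_at: Optional[int] = None
    thinning: Optional[int] = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.iteration, r.within_mean, r.cross_mean, r.ratio, r.mixed)
             for r in self.records],
            columns=["iteration", "within_mean", "cross_mean", "ratio",
                     "mixed"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class MixingError(RuntimeError):
    """Mixing was not achieved within the iteration budget."""

    def __init__(self, message: str, report: MixingReport):
        super().__init__(message)
        self.report = report


@dataclasses.dataclass
class Ensemble:
    """Thinned posterior samples with provenance.

    Samples are stored chain-major and iteration-sorted within a chain,
    so lexicographic (chain, iteration) order equals storage order.
    """

    conformations: np.ndarray  # (N, n, 3)
    log_posteriors: np.ndarray  # (N,)
    chain_ids: np.ndarray  # (N,)
    iterations: np.ndarray  # (N,)
    fragment_map: Optional[FragmentMap] = None

    def __post_init__(self) -> None:
        self.conformations = np.asarray(self.conformations, float)
        self.log_posteriors = np.asarray(self.log_posteriors, float)
        self.chain_ids = np.asarray(self.chain_ids, np.int64)
        self.iterations = np.asarray(self.iterations, np.int64)
        if self.conformations.ndim != 3 or self.conformations.shape[2] != 3:
            raise ValueError("conformations must have shape (N, n, 3)")
        m = len(self.conformations)
        if not (len(self.log_posteriors) == len(self.chain_ids)
                == len(self.iterations) == m):
            raise ValueError("ensemble field lengths disagree")
        for c in np.unique(self.chain_ids):
            its = self.iterations[self.chain_ids == c]
            if np.any(np.diff(its) <= 0):
                raise ValueError("iterations must strictly increase per chain")

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def n_points(self) -> int:
        return self.conformations.shape[1]

    def member(self, i: int) -> Conformation:
        return Conformation(self.conformations[i])

    def distance_vectors(self) -> np.ndarray:
        """(N, n*(n-1)/2) condensed intra-structure distance matrix rows."""
        return np.stack([pdist(c) for c in self.conformations])


def _milestone_snapshot_positions(k: int) -> List[int]:
    """The 11 snapshot iterations k/2 + i*k/20, i = 0..10 (rounded)."""
    return sorted({int(round(k * (10 + i) / 20.0)) for i in range(11)})


def sample_ensemble(data: InteractionDataset, params: ModelParams,
                    config: SamplerConfig) -> Tuple[Ensemble, MixingReport]:
    """Run parallel chains to mixing, then collect a thinned ensemble.

    Raises :class:`MixingError` (carrying the diagnostic trace) if the
    chains are still unmixed at ``config.max_iterations``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    states: List[ChainState] = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(children[c])
        conf = init_structure(data, params, rng)
        states.append(ChainState(conf, PosteriorCache(data, params, conf),
                                 rng, chain_id=c))

    report = MixingReport(threshold=config.mixing_threshold)
    k = config.check_interval_base
    mixed_k: Optional[int] = None
    while k <= config.max_iterations:
        positions = _milestone_snapshot_positions(k)
        for st in states:
            st.snapshots = {}
            if positions[0] == st.t:
                st.snapshots[st.t] = st.conf.points.copy()
                leg_positions = positions[1:]
            else:
                leg_positions = positions
            acc, snaps = advance(st.conf, st.cache, st.rng, k - st.t,
                                 config.perturbation_radius,
                                 engine=config.engine,
                                 block_size=config.block_size, t0=st.t,
                                 snapshot_iters=leg_positions)
            st.snapshots.update(snaps)
            st.accepted += acc
            st.t = k
            st.cache.resync(st.conf)  # kill float drift between milestones
        checks = [assess_mixing(states[a], states[b], config.mixing_threshold)
                  for a in range(len(states)) for b in range(a + 1, len(states))]
        first = checks[0]
        all_mixed = all(c.mixed for c in checks)
        report.records.append(MixingRecord(k, first.within_mean,
                                           first.cross_mean, first.ratio,
                                           all_mixed))
        if all_mixed:
            mixed_k = k
            break
        k *= 2
    if mixed_k is None:
        raise MixingError(
            f"mixing not achieved within {config.max_iterations} iterations "
            f"(threshold {config.mixing_threshold}); see the attached report",
            report)

    delta = max(1, mixed_k // config.thin_divisor)
    report.mixed_at = mixed_k
    report.thinning = delta
    confs, lps, cids, its = [], [], [], []
    for st in states:
        for m in range(config.ensemble_size):
            if m > 0:
                st.accepted += advance(st.conf, st.cache, st.rng, delta,
                                       config.perturbation_radius,
                                       engine=config.engine,
                                       block_size=config.block_size,
                                       t0=st.t)[0]
                st.t += delta
            confs.append(st.conf.points.copy())
            lps.append(st.cache.total)
            cids.append(st.chain_id)
            its.append(st.t)
    ens = Ensemble(np.stack(confs), np.array(lps), np.array(cids),
                   np.array(its), fragment_map=data.fragment_map)
    return ens, report


def max_posterior_index(ens: Ensemble) -> int:
    """Index of the max-log-posterior sample; ties break to the earliest
    (chain id, iteration), which is storage order."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    return int(np.argmax(ens.log_posteriors))


def max_posterior_structure(ens: Ensemble) -> Tuple[Conformation, float]:
    i = max_posterior_index(ens)
    return ens.member(i), float(ens.log_posteriors[i])
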