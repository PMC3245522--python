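"""Probabilistic model linking pairwise interaction frequencies to 3D distances.

A chromatin region is represented as an ordered set of 3D points, one per
restriction site (5C) or genomic bin (Hi-C).  The expected interaction
frequency between two sites decays as a power law of their Euclidean
distance, ``IF = psi * d**(-alpha)``.  Observed 5C frequencies are modelled
as Gaussian around that expectation with per-pair standard deviations;
Hi-C read counts are modelled as Gaussian with variance equal to the mean
plus a small constant, with the count scale tied to the sequencing total.

All likelihoods are evaluated in log space and are defined up to an
additive constant (the posterior normalizer is never computed).  A
per-pair term cache supports O(degree) re-evaluation after single-point
moves, which is what makes long Metropolis-Hastings chains affordable.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Conformation",
    "FragmentMap",
    "InteractionDataset",
    "ModelParams",
    "PosteriorCache",
    "CacheConsistencyError",
    "pairwise_distances",
    "expected_if",
    "if_to_distance",
    "log_likelihood_5c",
    "log_likelihood_hic",
    "log_posterior",
    "delta_log_posterior",
]

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: relative floor applied to 5C standard deviations (fraction of max |IF|)
SIGMA_FLOOR_REL = 1e-6

TECH_5C = "5C"
TECH_HIC = "HiC"


class CacheConsistencyError(RuntimeError):
    """Raised when a posterior cache disagrees with a full recomputation."""


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameters of the distance-to-frequency transform.

    Attributes
    ----------
    alpha : float
        Power-law exponent (> 0).  The expected frequency at distance
        ``d`` is ``psi * d**(-alpha)``.
    psi : float
        Scale of the power law (> 0), in IF units times ``nm**alpha``.
        After calibration it plays the role of a physical scale constant.
    kappa : float
        Additive variance constant for the Hi-C noise model (>= 0);
        keeps small expected counts from being assigned a near-zero
        variance.  Default 10.
    technology : str, optional
        Informational flag, ``"5C"`` or ``"HiC"``.
    """

    alpha: float = 2.0
    psi: float = 1.0
    kappa: float = 10.0
    technology: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.psi > 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.technology not in (None, TECH_5C, TECH_HIC):
            raise ValueError(f"unknown technology {self.technology!r}")


class Conformation:
    """An ordered set of n 3D points, one per restriction site or bin.

    Points are stored as an ``(n, 3)`` float64 array in model units
    (nominally nanometres).  Order matches genomic order.
    """

    __slots__ = ("points",)

    def __init__(self, points) -> None:
        pts = np.array(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a conformation needs at least one point")
        if not np.isfinite(pts).all():
            raise ValueError("conformation coordinates must be finite")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    def copy(self) -> "Conformation":
        return Conformation(self.points)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Conformation(n={self.n})"


@dataclasses.dataclass
class FragmentMap:
    """Genomic metadata for the modelled fragments/bins.

    Intervals are 0-based half-open, sorted by start and non-overlapping.
    Fragment ids are implicit 1-based indices (genomic order).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if len(self.starts) == 0:
            raise ValueError("fragment map must contain at least one fragment")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragment intervals must satisfy end > start")
        if np.any(np.diff(self.starts) < 0):
            raise ValueError("fragments must be sorted by start")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("fragment intervals must not overlap")

    @classmethod
    def uniform(cls, n: int, fragment_length: int = 1000,
                chrom: str = "chr7", start: int = 0) -> "FragmentMap":
        """Contiguous equal-length fragments; handy for synthetic data."""
        starts = start + fragment_length * np.arange(n, dtype=np.int64)
        return cls(np.array([chrom] * n, dtype=object), starts,
                   starts + fragment_length)

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


@dataclasses.dataclass
class InteractionDataset:
    """Measured pairwise interactions plus fragment metadata.

    ``pair_i``/``pair_j`` are 0-based fragment indices with ``i < j``; the
    set of pairs present IS the measurable-pair mask -- pairs absent from
    the arrays contribute nothing to any likelihood.  For 5C, ``values``
    are interaction frequencies and ``sigmas`` per-pair standard
    deviations (floored at ``SIGMA_FLOOR_REL * max|IF|``).  For Hi-C,
    ``values`` are non-negative read counts and ``sigmas`` is None.
    """

    fragment_map: FragmentMap
    technology: str
    pair_i: np.ndarray
    pair_j: np.ndarray
    values: np.ndarray
    sigmas: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.technology not in (TECH_5C, TECH_HIC):
            raise ValueError(f"unknown technology {self.technology!r}")
        self.pair_i = np.asarray(self.pair_i, dtype=np.int64)
        self.pair_j = np.asarray(self.pair_j, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.fragment_map.n
        if not (len(self.pair_i) == len(self.pair_j) == len(self.values)):
            raise ValueError("pair arrays must have equal length")
        if len(self.pair_i) == 0:
            raise ValueError("dataset must contain at least one measured pair")
        if np.any(self.pair_i >= self.pair_j):
            raise ValueError("pairs must satisfy i < j")
        if np.any(self.pair_i < 0) or np.any(self.pair_j >= n):
            raise ValueError("pair indices out of range of the fragment map")
        keys = self.pair_i * n + self.pair_j
        if len(np.unique(keys)) != len(keys):
            raise ValueError("duplicate pairs in dataset")
        if not np.isfinite(self.values).all():
            raise ValueError("interaction values must be finite")
        if self.technology == TECH_5C:
            if self.sigmas is None:
                raise ValueError("5C datasets require per-pair sigmas")
            self.sigmas = np.asarray(self.sigmas, dtype=np.float64)
            if len(self.sigmas) != len(self.values):
                raise ValueError("sigmas length mismatch")
            if np.any(self.sigmas < 0) or not np.isfinite(self.sigmas).all():
                raise ValueError("sigmas must be finite and non-negative")
            floor = SIGMA_FLOOR_REL * max(np.abs(self.values).max(), 1e-300)
            self.sigmas = np.maximum(self.sigmas, floor)
        else:
            if np.any(self.values < 0):
                raise ValueError("Hi-C counts must be non-negative")
            if self.values.sum() <= 0:
                raise ValueError("Hi-C count matrix is all zero")
            self.sigmas = None
        self._csr = None

    @property
    def n_fragments(self) -> int:
        return self.fragment_map.n

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def degrees(self) -> np.ndarray:
        """Number of measured pairs touching each fragment."""
        deg = np.zeros(self.n_fragments, dtype=np.int64)
        np.add.at(deg, self.pair_i, 1)
        np.add.at(deg, self.pair_j, 1)
        return deg

    def neighbor_csr(self):
        """CSR adjacency: for fragment f, the measured pairs involving f.

        Returns ``(ptr, pair_idx, other)`` where for fragment ``f`` the
        slice ``ptr[f]:ptr[f+1]`` indexes into ``pair_idx`` (row in the
        pair arrays) and ``other`` (the partner fragment).
        """
        if self._csr is None:
            p = self.n_pairs
            frag = np.concatenate([self.pair_i, self.pair_j])
            other = np.concatenate([self.pair_j, self.pair_i])
            pidx = np.concatenate([np.arange(p), np.arange(p)])
            order = np.argsort(frag, kind="stable")
            frag = frag[order]
            ptr = np.searchsorted(frag, np.arange(self.n_fragments + 1))
            self._csr = (ptr.astype(np.int64), pidx[order].astype(np.int64),
                         other[order].astype(np.int64))
        return self._csr

    def subset(self, keep: np.ndarray) -> "InteractionDataset":
        """Dataset restricted to pairs where ``keep`` is True (LOOCV folds)."""
        keep = np.asarray(keep, dtype=bool)
        sig = None if self.sigmas is None else self.sigmas[keep]
        return InteractionDataset(self.fragment_map, self.technology,
                                  self.pair_i[keep], self.pair_j[keep],
                                  self.values[keep], sig)


def _as_points(conf) -> np.ndarray:
    pts = conf.points if isinstance(conf, Conformation) else np.asarray(conf, float)
    if not np.isfinite(pts).all():
        raise ValueError("conformation coordinates must be finite")
    return pts


def pairwise_distances(conf) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix of a conformation."""
    pts = _as_points(conf)
    if pts.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def expected_if(d, params: ModelParams):
    """Expected interaction frequency at distance ``d``: ``psi * d**(-alpha)``."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("distances must be strictly positive")
    out = params.psi * d ** (-params.alpha)
    return float(out) if out.ndim == 0 else out


def if_to_distance(f, params: ModelParams):
    """Inverse of :func:`expected_if`: ``d = (psi / IF) ** (1 / alpha)``."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("interaction frequencies must be strictly positive")
    out = (params.psi / f) ** (1.0 / params.alpha)
    return float(out) if out.ndim == 0 else out


def _pair_dists(pts: np.ndarray, data: InteractionDataset) -> np.ndarray:
    diff = pts[data.pair_i] - pts[data.pair_j]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def log_likelihood_5c(conf, data: InteractionDataset,
                      params: ModelParams) -> float:
    """Gaussian 5C log-likelihood summed over measured pairs.

    Returns ``-inf`` (never raises) if any measured pair has coincident
    points, where the power law is undefined.
    """
    if data.technology != TECH_5C:
        raise ValueError("log_likelihood_5c requires a 5C dataset")
    pts = _as_points(conf)
    d = _pair_dists(pts, data)
    if np.any(d == 0):
        return -np.inf
    mu = params.psi * d ** (-params.alpha)
    z = (data.values - mu) / data.sigmas
    return float(np.sum(-0.5 * z * z - np.log(data.sigmas) - LOG_SQRT_2PI))


def hic_beta(pts: np.ndarray, data: InteractionDataset,
             params: ModelParams) -> float:
    """Count scale making model totals match the observed sequencing total."""
    d = _pair_dists(pts, data)
    if np.any(d == 0):
        return np.nan
    return float(data.values.sum() / np.sum(d ** (-params.alpha)))


def log_likelihood_hic(conf, data: InteractionDataset,
                       params: ModelParams) -> float:
    """Hi-C log-likelihood: Gaussian with variance = mean + kappa.

    Expected counts are ``beta * d**(-alpha)`` with ``beta`` chosen so
    model totals equal the observed read total over measured pairs (the
    counts are proportions of a sequencing total).
    """
    if data.technology != TECH_HIC:
        raise ValueError("log_likelihood_hic requires a Hi-C dataset")
    pts = _as_points(conf)
    d = _pair_dists(pts, data)
    if np.any(d == 0):
        return -np.inf
    dpow = d ** (-params.alpha)
    beta = data.values.sum() / dpow.sum()
    m = beta * dpow
    var = m + params.kappa
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * var)
                        - 0.5 * (data.values - m) ** 2 / var))


def log_posterior(conf, data: InteractionDataset, params: ModelParams) -> float:
    """Log-posterior up to an additive constant (flat structure prior)."""
    if data.technology == TECH_5C:
        return log_likelihood_5c(conf, data, params)
    return log_likelihood_hic(conf, data, params)


class PosteriorCache:
    """Per-pair log-likelihood terms for incremental move evaluation.

    For 5C the cache stores one Gaussian log-density per measured pair, so
    moving fragment ``i`` only touches the terms of pairs involving ``i``.
    For Hi-C the count scale couples all pairs through its normalization,
    so a move updates the cached ``d**(-alpha)`` of the touched pairs and
    re-sums the full (vectorized) likelihood.
    """

    def __init__(self, data: InteractionDataset, params: ModelParams, conf):
        self.data = data
        self.params = params
        self.ptr, self.nbr_pair, self.nbr_other = data.neighbor_csr()
        pts = _as_points(conf)
        d = _pair_dists(pts, data)
        if np.any(d == 0):
            raise ValueError("cannot build cache on coincident points")
        if data.technology == TECH_5C:
            mu = params.psi * d ** (-params.alpha)
            z = (data.values - mu) / data.sigmas
            self.logterms = -0.5 * z * z - np.log(data.sigmas) - LOG_SQRT_2PI
            self.total = float(self.logterms.sum())
        else:
            self.dpow = d ** (-params.alpha)
            self.sum_dpow = float(self.dpow.sum())
            self.total_reads = float(data.values.sum())
            self.total = self._hic_total(self.dpow, self.sum_dpow)

    def _hic_total(self, dpow: np.ndarray, sum_dpow: float) -> float:
        beta = self.total_reads / sum_dpow
        m = beta * dpow
        var = m + self.params.kappa
        return float(np.sum(-0.5 * np.log(2.0 * np.pi * var)
                            - 0.5 * (self.data.values - m) ** 2 / var))

    @property
    def log_posterior(self) -> float:
        return self.total

    def _neighbors(self, i: int):
        sl = slice(self.ptr[i], self.ptr[i + 1])
        return self.nbr_pair[sl], self.nbr_other[sl]

    def evaluate_move(self, conf, i: int, new_point: np.ndarray):
        """Log-posterior if fragment ``i`` moved to ``new_point``.

        Returns ``(new_total, stash)``; pass the stash to
        :meth:`apply_move` to commit without recomputation.
        """
        pts = _as_points(conf)
        pairs, others = self._neighbors(i)
        diff = pts[others] - np.asarray(new_point, float)
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        data, params = self.data, self.params
        if data.technology == TECH_5C:
            with np.errstate(divide="ignore"):
                mu = params.psi * d ** (-params.alpha)
            sig = data.sigmas[pairs]
            new_terms = np.where(
                d > 0,
                -0.5 * ((data.values[pairs] - mu) / sig) ** 2
                - np.log(sig) - LOG_SQRT_2PI,
                -np.inf,
            )
            delta = new_terms.sum() - self.logterms[pairs].sum()
            return self.total + delta, (pairs, new_terms)
        if np.any(d == 0):
            return -np.inf, (pairs, None, None)
        new_dpow = d ** (-params.alpha)
        sum_new = self.sum_dpow - self.dpow[pairs].sum() + new_dpow.sum()
        dpow_vec = self.dpow.copy()
        dpow_vec[pairs] = new_dpow
        new_total = self._hic_total(dpow_vec, sum_new)
        return new_total, (pairs, new_dpow, sum_new)

    def apply_move(self, conf, i: int, new_point, stash=None,
                   new_total: Optional[float] = None) -> float:
        """Commit a move evaluated by :meth:`evaluate_move`."""
        if stash is None or new_total is None:
            new_total, stash = self.evaluate_move(conf, i, new_point)
        if self.data.technology == TECH_5C:
            pairs, new_terms = stash
            self.logterms[pairs] = new_terms
        else:
            pairs, new_dpow, sum_new = stash
            if new_dpow is None:
                raise ValueError("cannot commit a coincident-point move (Hi-C)")
            self.dpow[pairs] = new_dpow
            self.sum_dpow = sum_new
        self.total = float(new_total)
        conf.points[i] = np.asarray(new_point, float)
        return self.total

    def resync(self, conf) -> float:
        """Recompute everything from the conformation; returns the drift."""
        old = self.total
        self.__init__(self.data, self.params, conf)
        return self.total - old

    def validate(self, conf, rtol: float = 1e-8) -> None:
        """Debug check: cached total must match a full recomputation."""
        full = log_posterior(conf, self.data, self.params)
        scale = max(abs(full), 1.0)
        if not np.isclose(self.total, full, rtol=rtol, atol=rtol * scale):
            raise CacheConsistencyError(
                f"cached log-posterior {self.total!r} != full {full!r}")


def delta_log_posterior(conf, cache: PosteriorCache, moved_index: int,
                        new_point, data=None, params=None):
    """Move one point, updating the cache incrementally.

    Returns ``(new_log_posterior, cache)``.  ``data``/``params`` are
    accepted for signature symmetry but the cache is already bound to
    them.  The conformation is updated in place.
    """
    new_total, stash = cache.evaluate_move(conf, moved_index, new_point)
    cache.apply_move(conf, moved_index, new_point, stash, new_total)
    return new_total, cache
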