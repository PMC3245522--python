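"""Gold-standard conformations and simulated 5C/Hi-C datasets.

These generators serve both as test fixtures and as the validation
protocol: simulate interaction data from a known structure, run the
sampler, and compare what comes back against the generator.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Tuple

import numpy as np

from .core import (Conformation, FragmentMap, InteractionDataset, ModelParams,
                   TECH_5C, TECH_HIC, expected_if, pairwise_distances)

__all__ = [
    "NoiseSpec",
    "make_structure",
    "make_fragment_map",
    "even_odd_pairs",
    "all_pairs",
    "simulate_5c",
    "simulate_hic",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """5C noise model: ``sigma(i,j) = cv * IF(i,j) + sigma0``.

    With ``mode="none"`` values are exact and a small constant sigma
    (1% of the mean expected IF) is recorded so the likelihood stays
    well-defined.  ``sigma0=None`` defaults to 1% of the mean expected IF.
    """

    mode: str = "per_pair_sigma"
    cv: float = 0.1
    sigma0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "per_pair_sigma"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.sigma0 is not None and self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    return v / norms[:, None]


def make_structure(kind: str, n: int, seed: int = 0, *, step: float = 1.0,
                   radius: float = 1.0, pitch: float = 0.5,
                   turn: float = 0.6, separation: float = 1.0,
                   domain_gap: float = 10.0,
                   domain_scale: float = 1.0) -> Conformation:
    """Deterministic parameterized gold-standard conformations.

    Kinds: ``random_walk`` (fixed step length), ``helix``, ``two_domain``
    (two compact clusters joined across a gap), ``hairpin`` (two
    antiparallel strands ``separation`` apart, re-entrant geometry).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "random_walk":
        steps = _unit_vectors(rng, n - 1) * step
        pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    elif kind == "helix":
        t = turn * np.arange(n)
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                               pitch * np.arange(n)])
    elif kind == "two_domain":
        half = n // 2
        a = rng.standard_normal((half, 3)) * domain_scale
        b = rng.standard_normal((n - half, 3)) * domain_scale
        b[:, 0] += domain_gap
        pts = np.vstack([a, b])
    elif kind == "hairpin":
        half = (n + 1) // 2
        fwd = np.column_stack([step * np.arange(half),
                               np.zeros(half), np.zeros(half)])
        back_len = n - half
        back = np.column_stack([step * (half - 1 - np.arange(back_len)),
                                np.full(back_len, separation),
                                np.zeros(back_len)])
        pts = np.vstack([fwd, back])
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    return Conformation(pts)


def make_fragment_map(n: int, fragment_length: int = 1000,
                      chrom: str = "chr7", start: int = 0) -> FragmentMap:
    return FragmentMap.uniform(n, fragment_length, chrom, start)


def even_odd_pairs(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Measurable 5C pairs: one even- and one odd-numbered fragment
    (1-based numbering, as on the detection array)."""
    iu, ju = np.triu_indices(n, k=1)
    # 1-based parities differ <=> 0-based parities differ
    keep = (iu + ju) % 2 == 1
    return iu[keep], ju[keep]


def all_pairs(n: int) -> Tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def simulate_5c(conf: Conformation, fmap: FragmentMap, params: ModelParams,
                noise: NoiseSpec = NoiseSpec(), even_odd_mask: bool = True,
                rng: Optional[np.random.Generator] = None,
                seed: int = 0) -> InteractionDataset:
    """Simulate a 5C dataset from a gold-standard conformation.

    For each measurable pair the observed IF is drawn from a Gaussian
    around the model expectation with sd ``cv * IF + sigma0``, truncated
    at zero (negative frequencies are not observable; the truncation
    rate is logged).
    """
    if fmap.n != conf.n:
        raise ValueError("fragment map size must match the conformation")
    if rng is None:
        rng = np.random.default_rng(seed)
    pi, pj = even_odd_pairs(conf.n) if even_odd_mask else all_pairs(conf.n)
    d = pairwise_distances(conf)[pi, pj]
    mu = expected_if(d, params)
    floor = 0.01 * float(mu.mean())
    if noise.mode == "none":
        values = mu.copy()
        sigmas = np.full_like(mu, floor)
    else:
        sigma0 = floor if noise.sigma0 is None else noise.sigma0
        sigmas = noise.cv * mu + sigma0
        raw = rng.normal(mu, sigmas)
        n_trunc = int(np.count_nonzero(raw < 0))
        if n_trunc:
            logger.info("simulate_5c: truncated %d/%d negative draws at 0",
                        n_trunc, len(raw))
        values = np.clip(raw, 0.0, None)
    return InteractionDataset(fmap, TECH_5C, pi, pj, values, sigmas)


def simulate_hic(conf: Conformation, params: ModelParams, total_reads: int,
                 rng: Optional[np.random.Generator] = None, seed: int = 0,
                 fmap: Optional[FragmentMap] = None,
                 bin_size: int = 1_000_000) -> InteractionDataset:
    """Simulate Hi-C counts: reads distributed multinomially over pairs
    with probabilities proportional to ``d**(-alpha)``."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if fmap is None:
        fmap = FragmentMap.uniform(conf.n, bin_size, chrom="chr14")
    elif fmap.n != conf.n:
        raise ValueError("fragment map size must match the conformation")
    pi, pj = all_pairs(conf.n)
    d = pairwise_distances(conf)[pi, pj]
    if np.any(d == 0):
        raise ValueError("gold structure has coincident points")
    w = d ** (-params.alpha)
    counts = rng.multinomial(total_reads, w / w.sum()).astype(float)
    return InteractionDataset(fmap, TECH_HIC, pi, pj, counts)
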