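"""Base-resolution structural statistics along the chromatin curve.

A conformation is interpreted as a piecewise-linear curve through its
site coordinates; DNA bases are placed at unit genomic spacing along the
segments.  Three per-base counts are measured inside a closed ball of
radius ``r`` centred at a base: density (all bases inside), compaction
(the contiguous run through the centre) and looping (re-entrant bases,
i.e. density minus compaction).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Conformation, FragmentMap
from .sampler import Ensemble

__all__ = [
    "BaseCurve",
    "interpolate_bases",
    "base_density",
    "base_compaction",
    "base_looping",
    "PropertyProfile",
    "property_profile",
]


@dataclasses.dataclass
class BaseCurve:
    """Per-base 3D positions along the piecewise-linear curve.

    Base ``b`` sits at genomic coordinate ``genomic_start + b``; the
    total base count equals the genomic span between the first and last
    sites (no extrapolation beyond them).
    """

    positions: np.ndarray  # (B, 3)
    genomic_start: float

    @property
    def n_bases(self) -> int:
        return len(self.positions)

    def genomic_positions(self) -> np.ndarray:
        return self.genomic_start + np.arange(self.n_bases)


def _site_positions(sites) -> np.ndarray:
    if isinstance(sites, FragmentMap):
        return sites.midpoints.astype(float)
    return np.asarray(sites, float)


def interpolate_bases(conf, sites) -> BaseCurve:
    """Place one base per bp by linear interpolation between sites.

    ``sites`` is either a :class:`FragmentMap` (its midpoints are used)
    or an explicit increasing sequence of genomic positions, one per
    conformation point.
    """
    pts = conf.points if isinstance(conf, Conformation) else np.asarray(conf, float)
    g = _site_positions(sites)
    if len(g) != len(pts):
        raise ValueError("one genomic position per conformation point required")
    if len(pts) < 2:
        raise ValueError("need at least two sites to build a curve")
    if np.any(np.diff(g) <= 0):
        raise ValueError("zero-length genomic segment between sites")
    span = int(round(g[-1] - g[0]))
    offsets = g[0] + np.arange(span)
    curve = np.column_stack([np.interp(offsets, g, pts[:, k])
                             for k in range(3)])
    return BaseCurve(curve, float(g[0]))


def _check_index(curve: BaseCurve, i: int, r: float) -> None:
    if not 0 <= i < curve.n_bases:
        raise ValueError(f"base index {i} out of range [0, {curve.n_bases})")
    if not r > 0:
        raise ValueError("radius must be > 0")


def _inside(curve: BaseCurve, i: int, r: float) -> np.ndarray:
    d2 = np.sum((curve.positions - curve.positions[i]) ** 2, axis=1)
    return d2 <= r * r


def base_density(curve: BaseCurve, i: int, r: float) -> int:
    """Number of bases (including ``i``) within the closed ball of radius
    ``r`` around base ``i``."""
    _check_index(curve, i, r)
    return int(np.count_nonzero(_inside(curve, i, r)))


def _run_length(inside: np.ndarray, i: int) -> int:
    # contiguous run through i: stop at the first base outside the ball
    # in each direction; re-entrant bases beyond the stop never count
    right = inside[i:]
    out_r = np.flatnonzero(~right)
    len_r = int(out_r[0]) if len(out_r) else len(right)
    left = inside[:i + 1][::-1]
    out_l = np.flatnonzero(~left)
    len_l = int(out_l[0]) if len(out_l) else len(left)
    return len_r + len_l - 1  # base i counted once


def base_compaction(curve: BaseCurve, i: int, r: float) -> int:
    """Length of the maximal contiguous base run through ``i`` that stays
    inside the ball."""
    _check_index(curve, i, r)
    return _run_length(_inside(curve, i, r), i)


def base_looping(curve: BaseCurve, i: int, r: float) -> int:
    """Bases inside the ball on re-entrant segments: density - compaction."""
    _check_index(curve, i, r)
    inside = _inside(curve, i, r)
    return int(np.count_nonzero(inside)) - _run_length(inside, i)


@dataclasses.dataclass
class PropertyProfile:
    """Ensemble mean +/- sd of the three measures at evaluation positions."""

    genomic_positions: np.ndarray
    base_offsets: np.ndarray
    radius: float
    step: int
    density_mean: np.ndarray
    density_sd: np.ndarray
    compaction_mean: np.ndarray
    compaction_sd: np.ndarray
    looping_mean: np.ndarray
    looping_sd: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position_bp": self.genomic_positions,
            "density_mean": self.density_mean,
            "density_sd": self.density_sd,
            "compaction_mean": self.compaction_mean,
            "compaction_sd": self.compaction_sd,
            "looping_mean": self.looping_mean,
            "looping_sd": self.looping_sd,
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _member_counts(curve: BaseCurve, offsets: np.ndarray, r: float):
    dens = np.empty(len(offsets), dtype=np.int64)
    comp = np.empty(len(offsets), dtype=np.int64)
    for k, i in enumerate(offsets):
        inside = _inside(curve, int(i), r)
        dens[k] = int(np.count_nonzero(inside))
        comp[k] = _run_length(inside, int(i))
    return dens, comp


def property_profile(ens: Ensemble, sites=None, r: float = 1.0,
                     step: int = 10,
                     members: Optional[Sequence[int]] = None) -> PropertyProfile:
    """Mean and standard deviation of density/compaction/looping across an
    ensemble, evaluated every ``step``-th base with sphere radius ``r``.

    ``sites`` defaults to the ensemble's fragment map.  ``members``
    optionally restricts the computation to a subsample of the ensemble.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    if sites is None:
        if ens.fragment_map is None:
            raise ValueError("no fragment map available; pass sites")
        sites = ens.fragment_map
    if step < 1:
        raise ValueError("step must be >= 1")
    idx = range(len(ens)) if members is None else members
    dens_all, comp_all = [], []
    offsets = None
    g0 = None
    for m in idx:
        curve = interpolate_bases(ens.conformations[m], sites)
        if offsets is None:
            offsets = np.arange(0, curve.n_bases, step)
            g0 = curve.genomic_start
        d, c = _member_counts(curve, offsets, r)
        dens_all.append(d)
        comp_all.append(c)
    dens = np.stack(dens_all)
    comp = np.stack(comp_all)
    loop = dens - comp
    return PropertyProfile(
        genomic_positions=g0 + offsets,
        base_offsets=offsets,
        radius=r,
        step=step,
        density_mean=dens.mean(0), density_sd=dens.std(0, ddof=0),
        compaction_mean=comp.mean(0), compaction_sd=comp.std(0, ddof=0),
        looping_mean=loop.mean(0), looping_sd=loop.std(0, ddof=0),
    )
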