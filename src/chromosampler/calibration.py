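"""Exponent selection by leave-one-out cross-validation and scale estimation.

The exponent of the distance-to-frequency power law is chosen as the
value best able to predict held-out interaction frequencies: for each
candidate exponent and each held-out pair, a maximum-posterior structure
is fitted on the remaining pairs (short MCMC run plus a greedy
accept-only-improvement polish) and the held-out IF is predicted from
the fitted distance.  The physical scale is anchored on short-range
pairs via a chromatin packing density (bp per nm).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (Conformation, InteractionDataset, ModelParams,
                   PosteriorCache, log_posterior)
from .sampler import advance, init_structure, initial_cube_side

__all__ = [
    "FitConfig",
    "fit_structure",
    "LoocvResult",
    "loocv_mse",
    "select_alpha",
    "ScaleEstimate",
    "estimate_scale",
]


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Budget for one maximum-posterior structure fit.

    Each of ``n_starts`` restarts runs a short MCMC exploration phase
    (tracking the best structure seen), a deterministic gradient polish
    of the log-likelihood (5C only; random single-point hill climbing
    cannot reach the sharp optimum of near-noise-free data at desk
    budgets), and a final greedy accept-only-improvement pass.  The best
    restart by final log-posterior wins.  ``radius=None`` scales the
    proposal radius to 2% of the initialization cube side.
    """

    n_iterations: int = 10_000
    n_greedy: int = 2_000
    n_starts: int = 2
    polish_maxiter: int = 2_000
    radius: Optional[float] = None
    track_every: int = 2_500
    seed: int = 0
    engine: str = "numba"


def _negll_grad_5c(x: np.ndarray, data: InteractionDataset,
                   params: ModelParams):
    """Residual part of -log L and its gradient wrt flattened coordinates."""
    n = data.n_fragments
    pts = x.reshape(n, 3)
    diff = pts[data.pair_i] - pts[data.pair_j]
    d2 = np.maximum(np.einsum("ij,ij->i", diff, diff), 1e-12)
    d = np.sqrt(d2)
    mu = params.psi * d ** (-params.alpha)
    w = (data.values - mu) / data.sigmas ** 2
    f = 0.5 * float(np.sum((data.values - mu) ** 2 / data.sigmas ** 2))
    coef = w * params.alpha * params.psi * d ** (-params.alpha - 2.0)
    g = np.zeros((n, 3))
    gv = coef[:, None] * diff
    np.add.at(g, data.pair_i, gv)
    np.add.at(g, data.pair_j, -gv)
    return f, g.ravel()


def _one_fit(data: InteractionDataset, params: ModelParams,
             config: FitConfig, rng: np.random.Generator
             ) -> Tuple[Conformation, float]:
    conf = init_structure(data, params, rng)
    cache = PosteriorCache(data, params, conf)
    r = config.radius
    if r is None:
        r = 0.02 * initial_cube_side(data, params)
    best_pts, best_lp = conf.points.copy(), cache.total
    done = 0
    while done < config.n_iterations:
        chunk = min(config.track_every, config.n_iterations - done)
        advance(conf, cache, rng, chunk, r, engine=config.engine)
        done += chunk
        if cache.total > best_lp:
            best_pts, best_lp = conf.points.copy(), cache.total
    if data.technology == "5C" and config.polish_maxiter > 0:
        from scipy.optimize import minimize

        res = minimize(_negll_grad_5c, best_pts.ravel(),
                       args=(data, params), jac=True, method="L-BFGS-B",
                       options={"maxiter": config.polish_maxiter})
        best_pts = res.x.reshape(-1, 3)
    conf = Conformation(best_pts)
    cache = PosteriorCache(data, params, conf)
    half = config.n_greedy // 2
    advance(conf, cache, rng, half, r / 10.0, greedy=True,
            engine=config.engine)
    advance(conf, cache, rng, config.n_greedy - half, r / 100.0, greedy=True,
            engine=config.engine)
    cache.resync(conf)
    return conf, cache.total


def fit_structure(data: InteractionDataset, params: ModelParams,
                  config: FitConfig = FitConfig(),
                  rng: Optional[np.random.Generator] = None
                  ) -> Tuple[Conformation, float]:
    """Maximum-posterior structure fit (multistart MCMC + gradient polish).

    Returns the fitted conformation and its log-posterior.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    best: Optional[Tuple[Conformation, float]] = None
    for _ in range(max(1, config.n_starts)):
        conf, lp = _one_fit(data, params, config, rng)
        if best is None or lp > best[1]:
            best = (conf, lp)
    return best


@dataclasses.dataclass
class LoocvResult:
    """MSE(alpha) over a grid, with per-fold records."""

    alphas: np.ndarray
    mses: np.ndarray
    n_folds: np.ndarray  # folds actually evaluated per alpha
    records: pd.DataFrame  # alpha, pair_i, pair_j, observed, predicted
    subsampled: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alphas, "mse": self.mses,
                             "n_folds": self.n_folds})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def loocv_mse(data: InteractionDataset, alpha_grid: Sequence[float],
              fit_config: FitConfig = FitConfig(), psi: float = 1.0,
              max_folds: Optional[int] = None, seed: int = 0) -> LoocvResult:
    """Leave-one-out cross-validation of the power-law exponent.

    For each alpha and held-out pair, a structure is fitted on the
    remaining pairs; the fold's scale is re-fit so model totals match the
    training totals, and the held-out IF is predicted from the fitted
    distance.  Folds that would leave a fragment with fewer than two
    measured pairs are skipped with a warning.  With ``max_folds`` set,
    a seeded random subset of folds is used (recorded in the result).
    """
    alphas = np.sort(np.asarray(alpha_grid, float))
    if len(alphas) == 0:
        raise ValueError("alpha grid must be non-empty")
    p = data.n_pairs
    if p < 10:
        warnings.warn(f"only {p} measured pairs; LOOCV will be unstable")
    rng = np.random.default_rng(seed)
    if max_folds is not None and p > max_folds:
        folds = np.sort(rng.choice(p, size=max_folds, replace=False))
        subsampled = True
    else:
        folds = np.arange(p)
        subsampled = False

    mses = np.empty(len(alphas))
    n_folds = np.zeros(len(alphas), dtype=np.int64)
    rec: List[tuple] = []
    for ai, alpha in enumerate(alphas):
        params = ModelParams(alpha=float(alpha), psi=psi,
                             technology=data.technology)
        errs = []
        for f in folds:
            keep = np.ones(p, dtype=bool)
            keep[f] = False
            train = data.subset(keep)
            if train.degrees().min() < 2:
                warnings.warn(
                    f"fold {f}: a fragment has < 2 measured pairs after "
                    "hold-out; fold skipped")
                continue
            fold_rng = np.random.default_rng(
                np.random.SeedSequence([fit_config.seed, ai, int(f)]))
            conf, _ = fit_structure(train, params, fit_config, rng=fold_rng)
            # re-fit the scale on the training pairs (totals matched)
            diff = conf.points[train.pair_i] - conf.points[train.pair_j]
            dpow = np.sum(diff * diff, axis=1) ** (-alpha / 2.0)
            psi_fold = train.values.sum() / dpow.sum()
            i, j = int(data.pair_i[f]), int(data.pair_j[f])
            d_held = float(np.linalg.norm(conf.points[i] - conf.points[j]))
            pred = psi_fold * d_held ** (-alpha)
            errs.append((pred - data.values[f]) ** 2)
            rec.append((float(alpha), i, j, float(data.values[f]),
                        float(pred)))
        if not errs:
            raise ValueError("all LOOCV folds were skipped; dataset degenerate")
        mses[ai] = float(np.mean(errs))
        n_folds[ai] = len(errs)
    records = pd.DataFrame(rec, columns=["alpha", "pair_i", "pair_j",
                                         "observed", "predicted"])
    return LoocvResult(alphas, mses, n_folds, records, subsampled)


def select_alpha(result: LoocvResult) -> float:
    """Grid value minimizing the LOOCV MSE; ties go to the smaller alpha."""
    if len(result.alphas) == 0:
        raise ValueError("empty LOOCV result")
    return float(result.alphas[int(np.argmin(result.mses))])


@dataclasses.dataclass
class ScaleEstimate:
    psi: float  # power-law scale: IF = psi * d**(-alpha)
    c_nm: float  # distance (nm) at unit interaction frequency
    physical_length_nm: float  # inferred distance of short-range pairs
    mean_short_if: float
    mean_short_sep_bp: float
    n_short_pairs: int


def estimate_scale(data: InteractionDataset, params: ModelParams,
                   packing_bp_per_nm: float = 130.0,
                   max_separation_bp: float = 5000.0) -> ScaleEstimate:
    """Anchor the power-law scale on short-range pairs.

    Pairs closer than ``max_separation_bp`` along the genome are assumed
    to sit at the packed-chromatin distance implied by
    ``packing_bp_per_nm`` (110-150 bp/nm for packed chromatin; default
    130).  ``psi`` is set so the mean short-range IF maps to that
    physical distance.
    """
    if not 0 < packing_bp_per_nm:
        raise ValueError("packing_bp_per_nm must be > 0")
    mids = data.fragment_map.midpoints
    sep = np.abs(mids[data.pair_j] - mids[data.pair_i])
    short = sep < max_separation_bp
    if not short.any():
        raise ValueError(
            f"no measured pairs closer than {max_separation_bp} bp; "
            "set the scale psi manually")
    mean_if = float(data.values[short].mean())
    if mean_if <= 0:
        raise ValueError("mean short-range IF is non-positive")
    mean_sep = float(sep[short].mean())
    l_phys = mean_sep / packing_bp_per_nm
    psi = mean_if * l_phys ** params.alpha
    return ScaleEstimate(psi=psi, c_nm=psi ** (1.0 / params.alpha),
                         physical_length_nm=l_phys, mean_short_if=mean_if,
                         mean_short_sep_bp=mean_sep,
                         n_short_pairs=int(short.sum()))
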