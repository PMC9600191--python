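"""Data-driven GI/GS cutoff on the score distribution.

Cohort score distributions are bimodal: a tight genome-stable cluster near
zero and a broad genome-unstable cluster well above it.  The default method
fits a two-component Gaussian mixture by EM (multiple restarts, seeded) and
places the threshold where posterior membership flips between the two
components — the "valley" between the modes.  A degenerate fit (vanishing
component weight or near-coincident means) falls back to the Otsu
criterion, which minimises within-class variance over a fixed grid.  A
constant threshold (e.g. 0.07) is available as ``method="fixed"``.

Tie rule: a score exactly at the cutoff is classified GI (the boundary is
assigned to the unstable class).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .models import ConfigError, CutoffModel, GIResult

logger = logging.getLogger(__name__)

DEFAULT_FIXED_CUTOFF = 0.07
_GRID_POINTS = 1000


def _otsu_threshold(scores: np.ndarray) -> float:
    """Threshold minimising the weighted within-class variance on a grid."""
    lo, hi = float(scores.min()), float(scores.max())
    if hi <= lo:
        return lo
    grid = np.linspace(lo, hi, _GRID_POINTS)[1:-1]
    best_t, best_v = grid[0], np.inf
    for t in grid:
        left = scores[scores < t]
        right = scores[scores >= t]
        if len(left) == 0 or len(right) == 0:
            continue
        v = len(left) * left.var() + len(right) * right.var()
        if v < best_v:
            best_t, best_v = t, v
    return float(best_t)


def fit_cutoff(
    scores: Sequence[float],
    method: str = "mixture",
    rng_seed: int = 0,
    fixed_value: float = DEFAULT_FIXED_CUTOFF,
    n_restarts: int = 50,
) -> CutoffModel:
    """Fit a GI/GS score threshold on a cohort's scores.

    Parameters
    ----------
    scores
        Finite GI scores in [0, 1]; at least 10 are required for the
        data-driven methods.
    method
        "mixture" (two-component Gaussian mixture, posterior-flip
        threshold), "otsu", or "fixed".
    rng_seed
        Seed for the EM restarts; the fit is deterministic given the seed.
    fixed_value
        The constant returned by ``method="fixed"``.
    """
    if method == "fixed":
        return CutoffModel(method="fixed", cutoff=float(fixed_value), rng_seed=rng_seed)

    x = np.asarray([s for s in scores if s is not None], dtype=float)
    if not np.isfinite(x).all() or ((x < 0) | (x > 1)).any():
        raise ConfigError("scores must be finite and within [0, 1]")
    if len(x) < 10:
        raise ConfigError(
            f"only {len(x)} scores; too few for a data-driven cutoff — "
            "use method='fixed'"
        )

    if method == "otsu":
        return CutoffModel(method="otsu", cutoff=_otsu_threshold(x), rng_seed=rng_seed)
    if method != "mixture":
        raise ConfigError(f"unknown cutoff method {method!r}")

    gm = GaussianMixture(
        n_components=2,
        n_init=n_restarts,
        random_state=rng_seed,
        reg_covar=1e-6,
    ).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(v)) for v in gm.covariances_.ravel()[order])
    weights = tuple(float(w) for w in gm.weights_[order])

    degenerate = min(weights) < 0.05 or abs(means[1] - means[0]) < 0.02
    if degenerate:
        logger.warning(
            "degenerate mixture fit (weights=%s, means=%s); falling back to Otsu",
            weights, means,
        )
        return CutoffModel(
            method="otsu",
            cutoff=_otsu_threshold(x),
            means=means,
            sds=sds,
            weights=weights,
            rng_seed=rng_seed,
            fallback=True,
        )

    # threshold = first point between the component means where posterior
    # membership flips to the upper component
    grid = np.linspace(means[0], means[1], _GRID_POINTS)
    post = gm.predict_proba(grid[:, None])[:, order[1]]
    flips = np.nonzero(post >= 0.5)[0]
    if len(flips) == 0:  # pathological posterior; use the midpoint
        cutoff = float(0.5 * (means[0] + means[1]))
    else:
        cutoff = float(grid[flips[0]])
    return CutoffModel(
        method="mixture",
        cutoff=cutoff,
        means=means,
        sds=sds,
        weights=weights,
        rng_seed=rng_seed,
    )


def classify_status(result: GIResult, model: CutoffModel) -> GIResult:
    """Assign GI/GS by the fitted cutoff; score >= cutoff is GI.

    Indeterminate results pass through unchanged.
    """
    if result.status == "indeterminate" or result.score is None:
        return result
    status = "GI" if result.score >= model.cutoff else "GS"
    return replace(result, status=status, cutoff_used=model.cutoff)


def classify_all(results: Iterable[GIResult], model: CutoffModel) -> list[GIResult]:
    return [classify_status(r, model) for r in results]
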