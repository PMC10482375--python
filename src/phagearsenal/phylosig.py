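"""Pagel's lambda: maximum-likelihood phylogenetic signal for leaf traits.

Under Brownian motion on a tree, the trait vector y over the n leaves is
multivariate normal with mean z0 * 1 and covariance sigma^2 * C, where
C[i, j] is the root-to-MRCA shared path length of leaves i and j.  Pagel's
lambda rescales the off-diagonal of C:

    C(lambda) = lambda * C + (1 - lambda) * diag(C)

so lambda = 0 removes all phylogenetic covariance and lambda = 1 recovers
plain Brownian motion.  For a candidate lambda the root state and rate are
profiled analytically (GLS mean, mean residual quadratic form), leaving a
one-dimensional profile log-likelihood

    logL(lambda) = -1/2 [ n log(2 pi sigma^2) + log|C(lambda)| + n ]

maximized by a bounded search.  Significance of the signal is the upper
chi-square(1df) tail of the likelihood-ratio statistic against lambda = 0
(a conservative choice at the boundary, where the 1/2-1/2 mixture would be
less so).

Presence/absence traits are treated as continuous 0/1 values under this
Gaussian model — the same approximation made when a continuous-trait
signal statistic is applied to binary data; see ``docs/methods.md`` for
the caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import ValidationError

#: coarse grid step used to bracket the profile-likelihood maximum
_GRID_STEP = 0.01
#: convergence tolerance of the bounded lambda search
_XTOL = 1e-8


@dataclass
class PhyloSignalResult:
    system_type: str
    lambda_hat: float
    sigma2_hat: float
    root_hat: float
    logL_hat: float
    logL_lambda0: float
    lr_stat: float
    p_value: float
    n_leaves: int


def tree_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    Returns a leaves-by-leaves DataFrame with C[i, i] the depth of leaf i.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels")
    depths = np.array([leaf.root_distance for leaf in leaves])
    if np.max(depths) <= 0:
        raise ValidationError("degenerate zero-depth tree")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = depths[i]
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            shared = 0.5 * (depths[i] + depths[j] - dist)
            cov[i, j] = cov[j, i] = shared
    return pd.DataFrame(cov, index=labels, columns=labels)


def lambda_transform(cov: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of a covariance matrix by ``lam``."""
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    diag = np.diag(np.diag(cov))
    return lam * cov + (1.0 - lam) * diag


def _profile_loglik(
    cov: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, float, float]:
    """Profile log-likelihood at ``lam``; returns (logL, sigma2_hat, root_hat)."""
    n = y.size
    v = lambda_transform(cov, lam)
    # trees with near-zero pendant or internal edges make C(lambda) singular
    # to machine precision near lambda = 1; a graded ridge keeps the
    # likelihood finite without measurably moving it elsewhere
    cho = None
    scale = float(np.trace(v)) / n
    for ridge in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            cho = linalg.cho_factor(v + ridge * scale * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            continue
    if cho is None:
        raise ValidationError(f"C(lambda) not positive definite at lambda={lam}")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ones = np.ones(n)
    vinv_one = linalg.cho_solve(cho, ones)
    vinv_y = linalg.cho_solve(cho, y)
    root = float(ones @ vinv_y) / float(ones @ vinv_one)
    resid = y - root
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    if sigma2 <= 0:
        raise ValidationError("zero residual variance: trait is constant")
    logl = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return logl, sigma2, root


def fit_lambda(
    trait: pd.Series,
    tree: dendropy.Tree,
    bounds: tuple[float, float] = (0.0, 1.0),
    system_type: str = "",
    cov: Optional[pd.DataFrame] = None,
) -> PhyloSignalResult:
    """Maximum-likelihood Pagel's lambda for one leaf trait.

    The profile likelihood is evaluated on a coarse grid over ``bounds``
    and refined around the best point with a bounded scalar search; when
    the likelihood is flat in lambda (e.g. a star tree) the tie breaks to
    lambda = 0.  ``cov`` may carry a precomputed :func:`tree_covariance`
    of the same tree to avoid recomputing it in repeated fits.
    """
    cov_df = tree_covariance(tree) if cov is None else cov
    labels = list(cov_df.index)
    missing = set(labels) - set(trait.index)
    if missing:
        raise ValidationError(f"trait is missing leaves: {sorted(missing)[:5]} ...")
    if len(labels) < 4:
        raise ValidationError("fit_lambda needs >= 4 leaves")
    y = trait.loc[labels].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValidationError("constant trait: phylogenetic signal is undefined")
    cov = cov_df.to_numpy()
    lo, hi = bounds
    if not 0.0 <= lo < hi:
        raise ValidationError(f"invalid bounds {bounds}")

    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    grid_logl = np.array([_profile_loglik(cov, y, lam)[0] for lam in grid])
    best = int(np.argmax(grid_logl))
    win_lo = grid[max(best - 1, 0)]
    win_hi = grid[min(best + 1, grid.size - 1)]
    if win_hi > win_lo:
        opt = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(cov, y, lam)[0],
            bounds=(win_lo, win_hi),
            method="bounded",
            options={"xatol": _XTOL},
        )
        candidates = [float(opt.x), float(grid[best]), lo, hi]
    else:
        candidates = [float(grid[best]), lo, hi]
    scored = [(lam, _profile_loglik(cov, y, lam)[0]) for lam in candidates]
    lam_hat, logl_hat = max(scored, key=lambda t: t[1])

    logl0, sigma2_0, root_0 = _profile_loglik(cov, y, 0.0)
    if logl0 >= logl_hat - 1e-9:  # flat (or maximal at 0): tie-break to 0
        lam_hat, logl_hat = 0.0, max(logl_hat, logl0)
        sigma2_hat, root_hat = sigma2_0, root_0
    else:
        _, sigma2_hat, root_hat = _profile_loglik(cov, y, lam_hat)
    lr_stat = max(0.0, 2.0 * (logl_hat - logl0))
    p_value = float(stats.chi2.sf(lr_stat, df=1)) if lr_stat > 0 else 1.0
    return PhyloSignalResult(
        system_type=system_type,
        lambda_hat=float(lam_hat),
        sigma2_hat=float(sigma2_hat),
        root_hat=float(root_hat),
        logL_hat=float(logl_hat),
        logL_lambda0=float(logl0),
        lr_stat=float(lr_stat),
        p_value=p_value,
        n_leaves=len(labels),
    )


def signal_screen(
    presence: pd.DataFrame,
    tree: dendropy.Tree,
    p_cutoff: float = 0.05,
    max_frequency: Optional[float] = None,
) -> pd.DataFrame:
    """Fit Pagel's lambda for every presence/absence column of a trait matrix.

    ``presence`` is genomes x system_types (0/1); its index must cover the
    tree's leaves.  Types with fewer than two presences or two absences
    among the leaves are reported as skipped (constant or near-constant
    traits carry no signal information).  ``max_frequency`` optionally
    restricts the screen to types at or below that leaf frequency, the
    regime where patchiness is the question of interest.  The ``patchy``
    label marks types whose signal is *not* significant at ``p_cutoff``.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(labels) - set(presence.index)
    if missing:
        raise ValidationError(
            f"presence matrix is missing tree leaves: {sorted(missing)[:5]} ..."
        )
    sub = presence.loc[labels]
    cov = tree_covariance(tree)
    rows = []
    for system_type in sorted(sub.columns):
        trait = sub[system_type].astype(float)
        n_present = int((trait > 0).sum())
        n_absent = int((trait == 0).sum())
        freq = n_present / len(labels)
        if max_frequency is not None and freq > max_frequency:
            rows.append(_skip_row(system_type, freq, "above frequency filter"))
            continue
        if n_present < 2 or n_absent < 2:
            rows.append(_skip_row(system_type, freq, "constant or near-constant"))
            continue
        res = fit_lambda(trait, tree, system_type=system_type, cov=cov)
        rows.append(
            {
                "system_type": system_type,
                "frequency": freq,
                "status": "tested",
                "reason": "",
                "lambda_hat": res.lambda_hat,
                "logL_hat": res.logL_hat,
                "logL_lambda0": res.logL_lambda0,
                "p_value": res.p_value,
                "patchy": res.p_value > p_cutoff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "system_type",
            "frequency",
            "status",
            "reason",
            "lambda_hat",
            "logL_hat",
            "logL_lambda0",
            "p_value",
            "patchy",
        ],
    )


def _skip_row(system_type: str, freq: float, reason: str) -> dict:
    return {
        "system_type": system_type,
        "frequency": freq,
        "status": "skipped",
        "reason": reason,
        "lambda_hat": float("nan"),
        "logL_hat": float("nan"),
        "logL_lambda0": float("nan"),
        "p_value": float("nan"),
        "patchy": float("nan"),
    }
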