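"""Pairwise correlations from compositional abundance data.

Relative abundances carry only relative information: per-sample closure to a
constant sum induces spurious negative correlation under naive estimators.
The SparCC approach estimates correlations between the latent (basis)
abundances from log-ratio variances under a sparsity assumption:

    t_ij = Var_s[ log(x_i / x_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

where ``w_i`` is the basis variance of component i on the log scale. Summing
``t_ij`` over j and treating most correlations as negligible yields a linear
system for the basis variances; correlations then follow as

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption, so the most
correlated pair is iteratively excluded from the row sums and the system
re-solved. Robustness to sampling noise comes from repeating the estimate on
Dirichlet-resampled compositions and taking the elementwise median.

A naive Pearson/Spearman backend is provided as a baseline, and permutation
p-values can be attached to either backend's output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from vitnet.io import AbundanceTable, CorrelationMatrix

logger = logging.getLogger("vitnet")

_VARIANCE_FLOOR = 1e-12


@dataclass
class SparccParams:
    """Tuning knobs of the basis-correlation estimator.

    n_iterations
        Estimation rounds; round 0 uses the observed compositions, later
        rounds Dirichlet-resample them, and the elementwise median is taken.
    exclusion_threshold
        Correlation magnitude above which the most-correlated pair is
        excluded from basis-variance estimation.
    pseudocount
        Small positive fraction added before the log transform so zeros do
        not blow up the log ratios.
    n_exclusion_rounds
        Maximum number of pair exclusions per estimation round.
    resample_depth
        Concentration scale of the Dirichlet resampling (acts like an
        effective count depth).
    """

    n_iterations: int = 20
    exclusion_threshold: float = 0.1
    pseudocount: float = 1e-6
    n_exclusion_rounds: int = 10
    resample_depth: float = 5000.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.exclusion_threshold < 1.0):
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.n_exclusion_rounds < 0:
            raise ValueError("n_exclusion_rounds must be >= 0")
        if self.resample_depth <= 0:
            raise ValueError("resample_depth must be > 0")


class SparCC:
    """Sparse basis-correlation estimator for compositional data.

    Follows the scikit-learn estimator protocol: construct with
    hyperparameters, call :meth:`fit` on a (samples x components) fraction
    matrix, read the result off ``correlation_``.

    Parameters mirror :class:`SparccParams`; ``random_state`` seeds the
    Dirichlet resampling, making the fit fully deterministic.

    Attributes
    ----------
    correlation_ : ndarray of shape (n_components, n_components)
        Estimated basis correlations, clamped to [-1, 1], unit diagonal.
    basis_variance_ : ndarray of shape (n_components,)
        Median estimated log-scale basis variances.
    n_features_in_ : int
    """

    def __init__(
        self,
        n_iterations: int = 20,
        exclusion_threshold: float = 0.1,
        pseudocount: float = 1e-6,
        n_exclusion_rounds: int = 10,
        resample_depth: float = 5000.0,
        random_state: int | None = 0,
    ) -> None:
        self.n_iterations = n_iterations
        self.exclusion_threshold = exclusion_threshold
        self.pseudocount = pseudocount
        self.n_exclusion_rounds = n_exclusion_rounds
        self.resample_depth = resample_depth
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "exclusion_threshold": self.exclusion_threshold,
            "pseudocount": self.pseudocount,
            "n_exclusion_rounds": self.n_exclusion_rounds,
            "resample_depth": self.resample_depth,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SparCC":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for SparCC")
            setattr(self, key, value)
        return self

    # -- core ---------------------------------------------------------------

    def fit(self, X, y=None, feature_keys=None) -> "SparCC":
        params = SparccParams(
            self.n_iterations,
            self.exclusion_threshold,
            self.pseudocount,
            self.n_exclusion_rounds,
            self.resample_depth,
        )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x components)")
        n_samples, n_comp = X.shape
        if n_comp < 4:
            raise ValueError(
                "SparCC needs at least 4 components: the basis-variance "
                f"system is underdetermined for {n_comp}"
            )
        if n_samples < 3:
            raise ValueError("SparCC needs at least 3 samples")
        if (X < 0).any() or not np.isfinite(X).all():
            raise ValueError("abundances must be finite and non-negative")

        # closure removes per-sample scale before anything stochastic
        row_sums = X.sum(axis=1, keepdims=True)
        if (row_sums == 0).any():
            raise ValueError("a sample has zero total abundance")
        fracs = X / row_sums

        constant = np.ptp(fracs, axis=0) < 1e-15

        # Per-component random streams are keyed by feature identity (not
        # column position) so that relabeling/permuting components commutes
        # exactly with the estimate.
        if feature_keys is None:
            keys = np.arange(n_comp, dtype=np.uint32)
        else:
            if len(feature_keys) != n_comp:
                raise ValueError("feature_keys length mismatch")
            keys = np.array(
                [zlib.crc32(str(k).encode()) for k in feature_keys],
                dtype=np.uint32,
            )

        estimates = []
        variances = []
        alpha = fracs * params.resample_depth + 1.0
        base = 0 if self.random_state is None else int(self.random_state)
        for it in range(params.n_iterations):
            if it == 0:
                f = fracs
            else:
                u = np.empty_like(fracs)
                for c in range(n_comp):
                    rng_c = np.random.default_rng([base, it, int(keys[c])])
                    u[:, c] = rng_c.random(n_samples)
                gam = stats.gamma.ppf(u, alpha)
                f = gam / gam.sum(axis=1, keepdims=True)
            rho, w = _basis_correlations(f, params)
            estimates.append(rho)
            variances.append(w)

        r = np.median(estimates, axis=0)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)

        if constant.any():
            idx = np.nonzero(constant)[0]
            logger.warning(
                "ZERO_VARIANCE_GENOME\t%d constant component(s); their "
                "correlations set to 0",
                len(idx),
            )
            r[idx, :] = 0.0
            r[:, idx] = 0.0
            np.fill_diagonal(r, 1.0)

        self.correlation_ = r
        self.basis_variance_ = np.median(variances, axis=0)
        self.n_features_in_ = n_comp
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).correlation_


def _basis_correlations(
    fracs: np.ndarray, params: SparccParams
) -> tuple[np.ndarray, np.ndarray]:
    """One estimation round: variation matrix, basis solve, pair exclusion."""
    f = fracs + params.pseudocount
    f = f / f.sum(axis=1, keepdims=True)
    log_f = np.log(f)
    # t_ij = Var(log x_i) + Var(log x_j) - 2 Cov(log x_i, log x_j)
    cov = np.cov(log_f, rowvar=False, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)

    d = t.shape[0]
    m_diag = np.full(d, float(d - 1))
    t_sums = t.sum(axis=1)
    included = np.ones((d, d), dtype=bool)
    np.fill_diagonal(included, False)

    def solve() -> np.ndarray:
        m = np.where(included, 1.0, 0.0)
        np.fill_diagonal(m, m_diag)
        w = np.linalg.solve(m, t_sums)
        return np.clip(w, _VARIANCE_FLOOR, None)

    def correlations(w: np.ndarray) -> np.ndarray:
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        return np.clip(rho, -1.0, 1.0)

    w = solve()
    rho = correlations(w)
    for _ in range(params.n_exclusion_rounds):
        masked = np.where(included, np.abs(rho), -np.inf)
        np.fill_diagonal(masked, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < params.exclusion_threshold:
            break
        # keep each component in at least 3 pair equations
        if m_diag[i] <= 3 or m_diag[j] <= 3:
            included[i, j] = included[j, i] = False
            continue
        included[i, j] = included[j, i] = False
        m_diag[i] -= 1.0
        m_diag[j] -= 1.0
        t_sums[i] -= t[i, j]
        t_sums[j] -= t[i, j]
        w = solve()
        rho = correlations(w)
    np.fill_diagonal(rho, 1.0)
    return rho, w


def sparcc_correlations(
    tab: AbundanceTable, params: SparccParams | None = None, seed: int = 0
) -> CorrelationMatrix:
    """Estimate SparCC basis correlations for an abundance table.

    Requires at least 4 genomes and 3 samples. Deterministic given ``seed``.
    """
    params = params or SparccParams()
    est = SparCC(
        n_iterations=params.n_iterations,
        exclusion_threshold=params.exclusion_threshold,
        pseudocount=params.pseudocount,
        n_exclusion_rounds=params.n_exclusion_rounds,
        resample_depth=params.resample_depth,
        random_state=seed,
    )
    est.fit(tab.values.to_numpy().T, feature_keys=tab.genome_ids)
    return CorrelationMatrix(tab.genome_ids, est.correlation_)


def naive_correlations(tab: AbundanceTable, method: str = "pearson") -> CorrelationMatrix:
    """Plain Pearson or Spearman correlations between genome abundance
    profiles, as a baseline that ignores compositionality."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if tab.n_samples < 2:
        raise ValueError("need at least 2 samples for correlation")
    df = tab.values.T  # samples x genomes
    r = df.corr(method=method).to_numpy()
    nan_rows = np.isnan(r).all(axis=1) | (np.ptp(df.to_numpy(), axis=0) == 0)
    if nan_rows.any():
        logger.warning(
            "ZERO_VARIANCE_GENOME\t%d genome(s) with zero variance; their "
            "correlations set to 0",
            int(nan_rows.sum()),
        )
    r = np.nan_to_num(r, nan=0.0)
    r[nan_rows, :] = 0.0
    r[:, nan_rows] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tab.genome_ids, r)


def permutation_pvalues(
    tab: AbundanceTable,
    obs: CorrelationMatrix,
    n_perm: int,
    seed: int = 0,
    backend: Callable[[AbundanceTable], CorrelationMatrix] | None = None,
) -> CorrelationMatrix:
    """Attach two-sided permutation p-values to an observed correlation matrix.

    Each permutation independently shuffles every genome's sample order,
    destroying all pairwise association while preserving marginals, then
    recomputes correlations with ``backend`` (default: Pearson). The add-one
    estimator p = (1 + #{|rho*| >= |rho_obs|}) / (1 + n_perm) never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if backend is None:
        backend = lambda t: naive_correlations(t, "pearson")
    if list(obs.genome_ids) != tab.genome_ids:
        raise ValueError("observed matrix and table genome ids disagree")
    rng = np.random.default_rng(seed)
    arr = tab.values.to_numpy()
    abs_obs = np.abs(obs.r)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_perm):
        perm = np.empty_like(arr)
        for i in range(arr.shape[0]):
            perm[i] = arr[i, rng.permutation(arr.shape[1])]
        ptab = AbundanceTable(
            pd.DataFrame(perm, index=tab.genome_ids, columns=tab.sample_ids),
            check_sums=False,
        )
        rstar = backend(ptab).r
        exceed += np.abs(rstar) >= abs_obs - 1e-15
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.minimum(p, p.T)
    return CorrelationMatrix(obs.genome_ids, obs.r, p)
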