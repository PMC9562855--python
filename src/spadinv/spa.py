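"""Successive projections algorithm (SPA) for characteristic-band selection.

SPA builds, from each candidate starting band, a greedy forward chain in
which step j+1 picks the band with the largest residual norm after
orthogonal projection onto the span of the bands already chosen — the
band least collinear with the current subset.  Chains are scored by the
holdout (or cross-validated) RMSE of a multiple linear regression of the
response on the subset; the winning subset size is, by default, the smallest k whose RMSE is not
significantly worse than the curve minimum (F-ratio criterion at
alpha = 0.25, the classical SPA parsimony rule), so that band count is
minimized at (near-)minimal error; a strict argmin rule is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, train_test_split

from .synthetic import WavelengthGrid

__all__ = [
    "SPAConfig",
    "SPAResult",
    "SPAEarlyStopError",
    "project_orthogonal",
    "spa_chain",
    "score_subset",
    "spa_select",
]

_RANK_TOL = 1e-10


class SPAEarlyStopError(RuntimeError):
    """All remaining candidates lie in the span of the selected bands."""


@dataclass(frozen=True)
class SPAConfig:
    max_k: int = 10
    init_strategy: str = "each-band-best"   # or "fixed-index"
    start_band: int = 0                     # used by fixed-index
    scorer: str = "mlr-holdout"             # or "mlr-cv"
    holdout_fraction: float = 0.3
    folds: int = 5
    seed: int = 0
    selection_rule: str = "f-test"          # or "argmin"
    f_alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        if self.init_strategy not in ("each-band-best", "fixed-index"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.scorer not in ("mlr-holdout", "mlr-cv"):
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.selection_rule not in ("f-test", "argmin"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        if not 0 < self.f_alpha < 1:
            raise ValueError("f_alpha must be in (0, 1)")


@dataclass
class SPAResult:
    chains: dict[int, list[int]]         # start band -> ordered selected indices
    rmse_curve: np.ndarray               # best RMSE per subset size 1..max_k
    best_k: int
    selected: list[int]                  # indices of the winning subset
    selected_wavelengths_nm: np.ndarray | None = None
    n_bands: int | None = None
    best_subsets: dict[int, list[int]] | None = None  # best-scoring subset per k

    @property
    def reduction_percent(self) -> float:
        """Share of the spectral bands discarded by the winning subset."""
        if self.n_bands is None:
            raise ValueError("result carries no total band count")
        return band_reduction_percent(self.n_bands, self.best_k)

    def to_dict(self) -> dict:
        return {
            "best_k": self.best_k,
            "selected": list(map(int, self.selected)),
            "selected_wavelengths_nm": (
                None if self.selected_wavelengths_nm is None
                else [float(w) for w in self.selected_wavelengths_nm]
            ),
            "rmse_curve": [float(v) for v in self.rmse_curve],
            "chains": {int(k): list(map(int, v)) for k, v in self.chains.items()},
        }


def band_reduction_percent(n_bands: int, n_selected: int) -> float:
    """Percentage of the spectral bands discarded: 100 * (1 - k / n)."""
    if not 0 < n_selected <= n_bands:
        raise ValueError("need 0 < n_selected <= n_bands")
    return 100.0 * (1.0 - n_selected / n_bands)


def project_orthogonal(candidates: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Residual norms of candidate columns after projection onto the span of
    the selected columns.

    Candidates already inside the span get (numerically) zero norm.  A
    rank-deficient selected set raises, since its span is ill-defined as a
    projection basis.
    """
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    S = np.atleast_2d(np.asarray(selected, dtype=float))
    if C.shape[0] != S.shape[0]:
        raise ValueError("candidates and selected must share the sample dimension")
    q, r = np.linalg.qr(S)
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    if np.any(diag < _RANK_TOL * scale):
        raise np.linalg.LinAlgError("selected band set is rank-deficient")
    resid = C - q @ (q.T @ C)
    return np.linalg.norm(resid, axis=0)


def spa_chain(X: np.ndarray, start_band: int, k: int, center: bool = True) -> list[int]:
    """Greedy SPA forward chain of ``k`` distinct band indices.

    Columns are mean-centred by default.  Residual-norm ties break toward
    the lowest band index; if every remaining candidate is numerically in
    the span of the chain before ``k`` bands are found, a
    ``SPAEarlyStopError`` reports how far the chain got.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 0 <= start_band < m:
        raise ValueError(f"start_band {start_band} out of range for {m} bands")
    if not 1 <= k <= m:
        raise ValueError(f"need 1 <= k <= n_bands, got k={k}")
    Xc = X - X.mean(axis=0) if center else X
    scale = np.linalg.norm(Xc, axis=0).max()
    if scale == 0:
        raise SPAEarlyStopError("design has no variance; chain stopped at 0 bands")

    chain = [start_band]
    basis = Xc[:, [start_band]]
    while len(chain) < k:
        norms = project_orthogonal(Xc, basis)
        norms[chain] = -np.inf
        best = norms.max()
        if best < _RANK_TOL * scale:
            raise SPAEarlyStopError(
                f"all residual norms ~ 0 after {len(chain)} bands "
                f"(chain so far: {chain}); design rank exhausted"
            )
        nxt = int(np.flatnonzero(norms >= best * (1.0 - 1e-12)).min())
        chain.append(nxt)
        basis = Xc[:, chain]
    return chain


def score_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    scorer: str = "mlr-holdout",
    holdout_fraction: float = 0.3,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """RMSE of a multiple linear regression of ``y`` on the chosen bands.

    ``mlr-holdout`` fits on a seeded train split and scores on the held-out
    fraction; ``mlr-cv`` averages squared error over seeded K-fold splits.
    A singular design triggers a tiny ridge fallback with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    subset = list(subset)
    if len(subset) >= X.shape[0]:
        raise ValueError("subset size must be smaller than the sample count")
    Xs = X[:, subset]

    def _fit_predict(Xtr, ytr, Xte):
        A = np.column_stack([Xtr, np.ones(len(Xtr))])
        B = np.column_stack([Xte, np.ones(len(Xte))])
        gram = A.T @ A
        try:
            cond = np.linalg.cond(gram)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            warnings.warn("singular MLR design; falling back to ridge(1e-8)",
                          RuntimeWarning, stacklevel=2)
            gram = gram + 1e-8 * np.eye(gram.shape[0])
        coef = np.linalg.solve(gram, A.T @ ytr)
        return B @ coef

    if scorer == "mlr-holdout":
        Xtr, Xte, ytr, yte = train_test_split(
            Xs, y, test_size=holdout_fraction, random_state=seed
        )
        pred = _fit_predict(Xtr, ytr, Xte)
        return float(np.sqrt(np.mean((yte - pred) ** 2)))
    if scorer == "mlr-cv":
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        sq = []
        for tr, te in kf.split(Xs):
            pred = _fit_predict(Xs[tr], y[tr], Xs[te])
            sq.append((y[te] - pred) ** 2)
        return float(np.sqrt(np.mean(np.concatenate(sq))))
    raise ValueError(f"unknown scorer {scorer!r}")


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SPAConfig | None = None,
    grid: WavelengthGrid | None = None,
) -> SPAResult:
    """Full SPA selection: chains from every configured start, RMSE per
    subset size, and the parsimonious best subset.

    ``rmse_curve[k-1]`` is the best score among all chains' length-k
    prefixes.  Under the default ``f-test`` rule ``best_k`` is the smallest
    k whose RMSE does not exceed the curve minimum by more than the F-ratio
    criterion allows (alpha = ``cfg.f_alpha``); under ``argmin`` it is the
    strict minimizer, ties going to smaller k.
    """
    cfg = cfg or SPAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    max_k = min(cfg.max_k, m, n - 1)
    if max_k < 1:
        raise ValueError("no feasible subset size; need more samples/bands")

    starts = range(m) if cfg.init_strategy == "each-band-best" else [cfg.start_band]
    chains: dict[int, list[int]] = {}
    best_rmse = np.full(max_k, np.inf)
    best_subset: dict[int, list[int]] = {}
    for s in starts:
        try:
            chain = spa_chain(X, s, max_k)
        except SPAEarlyStopError:
            chain = _longest_chain(X, s, max_k)
        chains[s] = chain
        for k in range(1, len(chain) + 1):
            rmse = score_subset(
                X, y, chain[:k], scorer=cfg.scorer,
                holdout_fraction=cfg.holdout_fraction, folds=cfg.folds, seed=cfg.seed,
            )
            if rmse < best_rmse[k - 1]:
                best_rmse[k - 1] = rmse
                best_subset[k] = chain[:k]

    feasible = np.flatnonzero(np.isfinite(best_rmse))
    if feasible.size == 0:
        raise SPAEarlyStopError("no scoreable subset found")
    k_min = int(feasible[np.argmin(best_rmse[feasible])]) + 1  # smallest k on ties
    if cfg.selection_rule == "argmin":
        best_k = k_min
    else:
        rmse_min = best_rmse[k_min - 1]
        n_eval = (
            max(1, int(round(cfg.holdout_fraction * n)))
            if cfg.scorer == "mlr-holdout" else n
        )
        crit = stats.f.ppf(1.0 - cfg.f_alpha, n_eval, n_eval)
        thresh = rmse_min * np.sqrt(crit) if rmse_min > 0 else 0.0
        ok = feasible[best_rmse[feasible] <= max(thresh, rmse_min)]
        best_k = int(ok.min()) + 1
    selected = best_subset[best_k]
    wl = None if grid is None else grid.wavelengths_nm[selected]
    return SPAResult(
        chains=chains,
        rmse_curve=best_rmse,
        best_k=best_k,
        selected=selected,
        selected_wavelengths_nm=wl,
        n_bands=m,
        best_subsets=best_subset,
    )


def _longest_chain(X: np.ndarray, start: int, max_k: int) -> list[int]:
    """Longest chain obtainable from ``start`` before rank exhaustion."""
    lo, hi, best = 1, max_k, [start]
    while lo <= hi:
        mid = (lo + hi) // 2
        try:
            best = spa_chain(X, start, mid)
            lo = mid + 1
        except SPAEarlyStopError:
            hi = mid - 1
    return best
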