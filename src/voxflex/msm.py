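"""Minimal kinetics stack: tICA, k-means microstates, Markov-state models.

The chain is the standard one for analysing loop dynamics: project torsion
features onto their slowest linear coordinates (tICA at lag τ), discretize the
projection into microstates by k-means, count microstate transitions at lag τ
into a row-stochastic transition matrix, and read off stationary populations
π and implied timescales t_i = −τ/ln λ_i.  Macrostates come from a crisp
spectral (PCCA-style) lumping of the dominant right eigenvectors; model
validity is checked with implied-timescale convergence and the
Chapman–Kolmogorov test.

Reversible estimation symmetrizes the count matrix, (C + Cᵀ)/2, before row
normalization — an approximation to the full reversible maximum-likelihood
estimator that is exact in the well-sampled limit and satisfies detailed
balance by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class TicaModel:
    """Time-lagged independent component decomposition of a feature trajectory."""

    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray       # descending
    components: np.ndarray        # (d, k) eigenvectors, one component per column
    projected: np.ndarray         # (F, k)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features) - self.mean) @ self.components


@dataclass(frozen=True)
class MarkovModel:
    """Microstate transition model at lag τ (in frames)."""

    lag: int
    counts: np.ndarray            # (k, k) raw sliding-window counts, active set
    transition: np.ndarray        # (k, k) row-stochastic
    stationary: np.ndarray        # (k,) π, sums to 1
    timescales: np.ndarray        # implied timescales for i >= 2, descending
    active_set: np.ndarray        # original microstate ids in the model
    frame_fraction: float         # fraction of counted transitions retained
    reversible: bool
    macro_assignment: np.ndarray | None = None   # per-active-microstate macro id
    macro_populations: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

def tica(features: np.ndarray, lag: int, epsilon: float = 1e-10) -> TicaModel:
    """Time-lagged independent component analysis with a symmetrized estimator.

    Solves the generalized eigenproblem C_0τ v = λ C_00 v where C_00 is the
    instantaneous covariance and C_0τ the symmetrized time-lagged covariance
    ((C + Cᵀ)/2) of the mean-free features.  ``epsilon`` regularizes C_00.
    Eigenvalues are sorted descending; with the symmetrized estimator they are
    real and (up to sampling noise) bounded by 1 in magnitude.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    F, d = X.shape
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if F <= lag:
        raise ValueError(f"need more frames ({F}) than the lag ({lag})")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    mean = X.mean(axis=0)
    Xc = X - mean
    A, B = Xc[:-lag], Xc[lag:]
    n = F - lag
    C00 = (A.T @ A + B.T @ B) / (2 * n)
    C0t = A.T @ B / n
    C0t = 0.5 * (C0t + C0t.T)
    C00_reg = C00 + epsilon * np.eye(d)

    eigvals, eigvecs = linalg.eigh(C0t, C00_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # eigh of the generalized problem returns B-orthonormal vectors: vᵀ C00 v = I
    return TicaModel(
        lag=lag, mean=mean, eigenvalues=eigvals,
        components=eigvecs, projected=Xc @ eigvecs,
    )


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------

def kmeans_microstates(
    projected: np.ndarray,
    n_states: int = 150,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Discretize projected coordinates into microstates with seeded k-means++."""
    X = np.asarray(projected, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_states > X.shape[0]:
        raise ValueError(f"n_states ({n_states}) exceeds number of frames ({X.shape[0]})")
    km = KMeans(
        n_clusters=n_states, init="k-means++", n_init=1,
        max_iter=max_iter, tol=tol, random_state=seed,
    )
    return km.fit_predict(X)


# ---------------------------------------------------------------------------
# Markov-state model estimation
# ---------------------------------------------------------------------------

def _count_matrix(dtrajs: list[np.ndarray], lag: int, n_states: int) -> np.ndarray:
    C = np.zeros((n_states, n_states), dtype=float)
    for traj in dtrajs:
        a, b = traj[:-lag], traj[lag:]
        np.add.at(C, (a, b), 1.0)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph,
    the most-visited component winning ties."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = C.shape[0]
    _, labels = connected_components(csr_matrix(C > 0), directed=True, connection="strong")
    weights = C.sum(axis=1) + C.sum(axis=0)
    best, best_w, best_size = None, -1.0, 0
    for comp in np.unique(labels):
        members = np.flatnonzero(labels == comp)
        w = float(weights[members].sum())
        if (len(members), w) > (best_size, best_w):
            best, best_w, best_size = members, w, len(members)
    return best


def estimate_msm(
    dtrajs: np.ndarray | list[np.ndarray],
    lag: int,
    reversible: bool = True,
) -> MarkovModel:
    """Estimate a Markov-state model from discrete trajectories at lag τ.

    Sliding-window transition counts are restricted to the largest strongly
    connected component (the model's active set); the retained count fraction
    is reported.  Reversible mode symmetrizes counts before row normalization,
    which enforces detailed balance.  π is the leading left eigenvector of T.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(t, dtype=int) for t in dtrajs]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    for t in dtrajs:
        if len(t) <= lag:
            raise ValueError(f"trajectory of length {len(t)} too short for lag {lag}")
    n_states = int(max(t.max() for t in dtrajs)) + 1
    C_full = _count_matrix(dtrajs, lag, n_states)

    active = _largest_scc(C_full)
    if active is None or active.size == 0:
        raise ValueError("count matrix has no connected component")
    C = C_full[np.ix_(active, active)]
    frame_fraction = float(C.sum() / C_full.sum()) if C_full.sum() > 0 else 0.0

    C_eff = 0.5 * (C + C.T) if reversible else C
    rows = C_eff.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("active set contains a state with no outgoing counts")
    T = C_eff / rows[:, None]

    if reversible:
        # detailed balance: π ∝ row sums of the symmetrized counts
        pi = rows / rows.sum()
        # symmetric similarity transform gives real spectrum
        sqrt_pi = np.sqrt(pi)
        Ts = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
        eigvals = np.sort(linalg.eigvalsh(0.5 * (Ts + Ts.T)))[::-1]
    else:
        ev, left = linalg.eig(T, left=True, right=False)
        # the stationary eigenvector belongs to the eigenvalue closest to 1
        # (magnitude alone is ambiguous, e.g. for a deterministic cycle)
        top = int(np.argmin(np.abs(ev - 1.0)))
        pi = np.real(left[:, top])
        pi = pi / pi.sum()
        order = np.argsort(-np.abs(ev))
        eigvals = np.real(ev[order])

    with np.errstate(divide="ignore", invalid="ignore"):
        lam = eigvals[1:]
        ts = np.where((lam > 0) & (lam < 1), -lag / np.log(np.clip(lam, 1e-300, 1 - 1e-16)), np.nan)
    return MarkovModel(
        lag=lag, counts=C, transition=T, stationary=pi,
        timescales=ts, active_set=active, frame_fraction=frame_fraction,
        reversible=reversible,
    )


def implied_timescales(
    dtrajs: np.ndarray | list[np.ndarray],
    lags: list[int],
    n_timescales: int = 5,
    reversible: bool = True,
) -> pd.DataFrame:
    """Implied timescales t_i(τ) = −τ/ln λ_i(τ) over a grid of lags.

    Flat curves indicate Markovianity at that lag; undefined timescales
    (λ ≤ 0) are reported as NaN.
    """
    rows = []
    for lag in lags:
        model = estimate_msm(dtrajs, lag, reversible=reversible)
        row = {"lag": lag}
        for i in range(n_timescales):
            row[f"t{i + 2}"] = model.timescales[i] if i < len(model.timescales) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Macrostates (crisp PCCA-style spectral lumping) and validation
# ---------------------------------------------------------------------------

def pcca_macrostates(model: MarkovModel, n_macro: int, seed: int = 0) -> MarkovModel:
    """Lump microstates into ``n_macro`` metastable macrostates.

    Crisp spectral assignment: k-means (fixed seed) on each microstate's
    coordinates in the first ``n_macro`` right eigenvectors of T.  Macrostate
    populations are sums of π over members.  This reproduces block structure
    exactly for nearly decomposable chains; it is a simplification of the
    fuzzy-membership PCCA+ optimization.
    """
    k = model.n_states
    if n_macro > k:
        raise ValueError(f"n_macro ({n_macro}) exceeds number of microstates ({k})")
    if not model.reversible:
        raise ValueError("macrostate lumping requires a reversible model")

    pi = model.stationary
    sqrt_pi = np.sqrt(pi)
    Ts = (sqrt_pi[:, None] * model.transition) / sqrt_pi[None, :]
    eigvals, vecs = linalg.eigh(0.5 * (Ts + Ts.T))
    order = np.argsort(eigvals)[::-1]
    # right eigenvectors of T from the symmetric problem: r = v / sqrt(pi)
    R = vecs[:, order[:n_macro]] / sqrt_pi[:, None]

    if n_macro == k:
        assignment = np.arange(k)
    else:
        km = KMeans(n_clusters=n_macro, n_init=10, random_state=seed)
        assignment = km.fit_predict(R)

    macro_pop = np.array([pi[assignment == m].sum() for m in range(n_macro)])
    # relabel by decreasing population for determinism
    order_m = np.argsort(-macro_pop, kind="stable")
    relabel = np.empty(n_macro, dtype=int)
    relabel[order_m] = np.arange(n_macro)
    assignment = relabel[assignment]
    macro_pop = macro_pop[order_m]

    return MarkovModel(
        lag=model.lag, counts=model.counts, transition=model.transition,
        stationary=model.stationary, timescales=model.timescales,
        active_set=model.active_set, frame_fraction=model.frame_fraction,
        reversible=model.reversible,
        macro_assignment=assignment, macro_populations=macro_pop,
    )


def macro_transition_matrix(model: MarkovModel) -> np.ndarray:
    """π-weighted coarse-graining of the microstate transition matrix."""
    if model.macro_assignment is None:
        raise ValueError("run pcca_macrostates first")
    n_macro = int(model.macro_assignment.max()) + 1
    pi = model.stationary
    T = model.transition
    M = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        ia = model.macro_assignment == a
        wa = pi[ia] / pi[ia].sum()
        for b in range(n_macro):
            ib = model.macro_assignment == b
            M[a, b] = float(wa @ T[np.ix_(ia, ib)].sum(axis=1))
    return M


@dataclass(frozen=True)
class CKResult:
    """Chapman–Kolmogorov comparison at one lag multiple."""

    factor: int
    predicted: np.ndarray   # T(τ)^k
    estimated: np.ndarray   # T(kτ) on the common active set
    max_deviation: float


def ck_test(
    dtrajs: np.ndarray | list[np.ndarray],
    lag: int,
    factors: list[int],
    reversible: bool = True,
) -> list[CKResult]:
    """Chapman–Kolmogorov test: does T(τ)^k predict the model estimated at kτ?

    For a Markovian process the deviation shrinks with sampling; persistent
    large deviations flag non-Markovian dynamics or a bad discretization.
    """
    base = estimate_msm(dtrajs, lag, reversible=reversible)
    results = []
    for k in factors:
        if k < 1:
            raise ValueError("factors must be positive integers")
        if k == 1:
            results.append(CKResult(1, base.transition, base.transition, 0.0))
            continue
        longer = estimate_msm(dtrajs, lag * k, reversible=reversible)
        common = np.intersect1d(base.active_set, longer.active_set)
        if common.size == 0:
            raise ValueError(f"no common active states between lag {lag} and {lag * k}")
        pred_full = np.linalg.matrix_power(base.transition, k)
        idx_b = np.searchsorted(base.active_set, common)
        idx_l = np.searchsorted(longer.active_set, common)
        pred = pred_full[np.ix_(idx_b, idx_b)]
        est = longer.transition[np.ix_(idx_l, idx_l)]
        results.append(CKResult(k, pred, est, float(np.abs(pred - est).max())))
    return results


def simulate_markov_chain(
    transition: np.ndarray, n_steps: int, seed: int = 0, start: int = 0
) -> np.ndarray:
    """Sample a discrete trajectory from a row-stochastic transition matrix."""
    T = np.asarray(transition, dtype=float)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    traj = np.empty(n_steps, dtype=int)
    state = start
    u = rng.random(n_steps)
    for t in range(n_steps):
        traj[t] = state
        state = int(np.searchsorted(cum[state], u[t]))
    return traj
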