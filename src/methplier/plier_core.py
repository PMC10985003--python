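"""Knowledge-constrained non-negative matrix factorization (PLIER-style).

Given a compressed data matrix D (features x samples) and a binary knowledge
matrix C (features x gene sets), the solver searches for

    min_{Z >= 0, U >= 0, B}  ||D - Z B||_F^2 + lambda1 ||Z - C U||_F^2
                             + lambda2 ||B||_F^2 + lambda3 ||U||_1

where Z (features x k) holds the latent variables (LVs), B (k x samples) the
per-sample loadings, and U (sets x k) couples each LV sparsely to the prior
gene sets. In practice the U penalty is an elastic net with L1 fraction
``l1_fraction`` (default 0.9), with the pure L1 form recovered at 1.0.

The solver alternates exact ridge updates for B and Z (the latter clipped to
the non-negative orthant) with a non-negative coordinate-descent elastic-net
update for each column of U, and adapts lambda3 until a target fraction of
LVs carries at least one prior association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .knowledge import KnowledgeMatrix
from .probe_compression import GeneWiseMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class PlierConfig:
    """Hyperparameters of the constrained factorization.

    k            latent dimension (no automatic selection).
    lambda1/2/3  penalty weights; "auto" derives lambda2 from the k-th
                 singular value of D, lambda1 = lambda2 / 2, and searches
                 lambda3 for the prior-association target.
    l1_fraction  elastic-net mixing for the U penalty (1.0 = pure L1).
    frac         target fraction of LVs with >= 1 prior gene set.
    max_path     maximum gene sets per LV (hard support cap on U columns).
    """

    k: int
    lambda1: float | str = "auto"
    lambda2: float | str = "auto"
    lambda3: float | str = "auto"
    l1_fraction: float = 0.9
    frac: float = 0.7
    max_iter: int = 350
    tol: float = 1e-6
    max_path: int = 10
    seed: int = 0
    standardize_rows: bool = True

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 < self.frac <= 1.0):
            raise ValueError("frac must be in (0, 1]")
        if not (0.0 < self.l1_fraction <= 1.0):
            raise ValueError("l1_fraction must be in (0, 1]")
        if self.max_path < 1:
            raise ValueError("max_path must be >= 1")


@dataclass
class PlierModel:
    """Fitted factorization with label registries and the optimization trace."""

    Z: pd.DataFrame              # features x k, non-negative
    U: pd.DataFrame              # gene sets x k, non-negative
    B: pd.DataFrame              # k x samples
    config: PlierConfig
    lambdas: dict[str, float]
    trace: list[float]           # internal penalized objective per iteration
    converged: bool
    n_iter: int
    row_means: pd.Series | None = None   # training standardization stats
    row_sds: pd.Series | None = None
    version: str = "methplier-model-1"

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    @property
    def lv_names(self) -> pd.Index:
        return self.Z.columns

    def prior_associated_fraction(self) -> float:
        """Fraction of LVs with at least one nonzero U entry."""
        return float((self.U.to_numpy() > 0).any(axis=0).mean())


def standardize_rows(D: GeneWiseMatrix) -> GeneWiseMatrix:
    """Z-score each feature row across samples (population SD).

    Zero-variance rows are set to all zeros and flagged via the returned
    matrix's ``values.attrs['zero_variance_rows']``.
    """
    vals = D.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("row standardization requires >= 2 samples")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    flat = sd[:, 0] <= 0
    sd[flat] = 1.0
    out = (vals - mu) / sd
    out[flat] = 0.0
    df = pd.DataFrame(out, index=D.values.index, columns=D.values.columns)
    df.attrs["zero_variance_rows"] = list(D.values.index[flat])
    return GeneWiseMatrix(df, D.feature_gene, D.n_imputed_probes)


def _check_shapes(D, C, Z, U, B) -> None:
    pairs = [
        ("D rows vs Z rows", D.shape[0], Z.shape[0]),
        ("D rows vs C rows", D.shape[0], C.shape[0]),
        ("Z cols vs B rows", Z.shape[1], B.shape[0]),
        ("C cols vs U rows", C.shape[1], U.shape[0]),
        ("U cols vs Z cols", U.shape[1], Z.shape[1]),
        ("D cols vs B cols", D.shape[1], B.shape[1]),
    ]
    for name, a, b in pairs:
        if a != b:
            raise ValueError(f"shape mismatch: {name} ({a} != {b})")


def objective(
    D: np.ndarray,
    C: np.ndarray,
    Z: np.ndarray,
    U: np.ndarray,
    B: np.ndarray,
    lambda1: float,
    lambda2: float,
    lambda3: float,
) -> tuple[float, dict[str, float]]:
    """Four-term objective with a pure L1 penalty on U; returns (total, terms)."""
    _check_shapes(D, C, Z, U, B)
    terms = {
        "reconstruction": float(np.sum((D - Z @ B) ** 2)),
        "prior": lambda1 * float(np.sum((Z - C @ U) ** 2)),
        "b_ridge": lambda2 * float(np.sum(B ** 2)),
        "u_l1": lambda3 * float(np.sum(np.abs(U))),
    }
    return sum(terms.values()), terms


def _penalized_objective(D, C, Z, U, B, lambda1, lambda2, lambda3, l1_fraction) -> float:
    """Objective actually minimized: elastic-net penalty on U.

    lambda3 * (a * ||U||_1 + (1 - a)/2 * ||U||_2^2); identical to
    :func:`objective` at l1_fraction = 1.
    """
    a = l1_fraction
    pen = lambda3 * (a * np.sum(np.abs(U)) + 0.5 * (1 - a) * np.sum(U ** 2))
    return (
        float(np.sum((D - Z @ B) ** 2))
        + lambda1 * float(np.sum((Z - C @ U) ** 2))
        + lambda2 * float(np.sum(B ** 2))
        + float(pen)
    )


def init_model(
    D: np.ndarray, C: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based deterministic initialization.

    Z0 = positive part of the first k left singular vectors scaled by their
    singular values; B0 = the matching right factor; U0 = 0. Columns whose
    positive part vanishes are re-seeded from the absolute values so every
    LV starts non-degenerate.
    """
    if k > min(D.shape):
        raise ValueError(f"k={k} exceeds min(D.shape)={min(D.shape)}")
    u, s, vt = np.linalg.svd(D, full_matrices=False)
    # deterministic sign: largest-|.| entry of each left vector positive
    for j in range(k):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]
    Z0 = np.clip(u[:, :k] * s[:k], 0.0, None)
    dead = ~(Z0 > 0).any(axis=0)
    if dead.any():
        Z0[:, dead] = np.abs(u[:, :k][:, dead] * s[:k][dead])
    B0 = vt[:k].copy()
    U0 = np.zeros((C.shape[1], k))
    _ = np.random.default_rng(seed)  # seed reserved; the init itself is closed-form
    return Z0, B0, U0


def update_B(D: np.ndarray, Z: np.ndarray, lambda2: float) -> np.ndarray:
    """Exact ridge minimizer B = (Z'Z + lambda2 I)^-1 Z' D."""
    k = Z.shape[1]
    gram = Z.T @ Z + lambda2 * np.eye(k)
    rhs = Z.T @ D
    if lambda2 <= 0:
        if np.linalg.matrix_rank(Z) < k:
            logger.warning("lambda2=0 with rank-deficient Z: minimum-norm solution")
            return np.linalg.lstsq(Z, D, rcond=None)[0]
    return np.linalg.solve(gram, rhs)


def update_Z(
    D: np.ndarray, B: np.ndarray, C: np.ndarray, U: np.ndarray, lambda1: float
) -> np.ndarray:
    """Ridge minimizer of the Z-dependent terms, clipped to Z >= 0.

    The pre-clipping matrix (D B' + lambda1 C U)(B B' + lambda1 I)^-1 is the
    unconstrained minimizer; clipping enforces the non-negativity constraint.
    """
    k = B.shape[0]
    gram = B @ B.T + lambda1 * np.eye(k)
    if lambda1 <= 0 and np.linalg.matrix_rank(B) < k:
        raise np.linalg.LinAlgError(
            "B B' is singular with lambda1=0; use lambda1 > 0"
        )
    raw = np.linalg.solve(gram.T, (D @ B.T + lambda1 * (C @ U)).T).T
    return np.clip(raw, 0.0, None)


def _cd_column(
    w: np.ndarray,
    G: np.ndarray,
    lam: float,
    alpha: float,
    u0: np.ndarray,
    support: np.ndarray | None = None,
    max_sweeps: int = 2000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Non-negative elastic-net coordinate descent for one U column.

    Minimizes  ||z - C u||^2 + lam * (alpha ||u||_1 + (1-alpha)/2 ||u||_2^2)
    over u >= 0, given w = C'z and G = C'C. ``support`` restricts the active
    coordinates (others pinned at zero).
    """
    m = len(w)
    u = u0.copy()
    idx = np.arange(m) if support is None else support
    if support is not None:
        mask = np.zeros(m, dtype=bool)
        mask[support] = True
        u[~mask] = 0.0
    Gu = G @ u
    thresh = 0.5 * lam * alpha
    for _ in range(max_sweeps):
        delta = 0.0
        for s in idx:
            # minimize over u_s with others fixed; factor 2 from the squared loss
            rho = w[s] - Gu[s] + G[s, s] * u[s]
            new = max(0.0, (rho - thresh) / (G[s, s] + 0.5 * lam * (1 - alpha)))
            d = new - u[s]
            if d != 0.0:
                Gu += G[:, s] * d
                u[s] = new
                delta = max(delta, abs(d))
        if delta < tol:
            break
    else:
        logger.warning("coordinate descent hit the sweep cap without converging")
    return u


def _cd_objective(z, C, u, lam, alpha) -> float:
    r = z - C @ u
    return float(r @ r + lam * (alpha * np.abs(u).sum() + 0.5 * (1 - alpha) * u @ u))


def update_U(
    Z: np.ndarray,
    C: np.ndarray,
    lambda3: float,
    l1_fraction: float = 0.9,
    max_path: int = 10,
    U0: np.ndarray | None = None,
) -> np.ndarray:
    """Columnwise non-negative elastic-net regression of Z on C.

    Each LV column z_j solves
    min_{u>=0} ||z_j - C u||^2 + lambda3 (a ||u||_1 + (1-a)/2 ||u||_2^2).
    If a column's support exceeds ``max_path``, the ``max_path`` largest
    coefficients are kept and re-fitted on that support. When a warm start
    ``U0`` is supplied, a candidate that scores worse than its (feasible)
    warm-start column is discarded, so the U step never degrades the
    penalized objective.
    """
    vals = np.unique(C)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("knowledge matrix C must be binary")
    if lambda3 <= 0:
        raise ValueError("lambda3 must be positive")
    m, k = C.shape[1], Z.shape[1]
    G = C.T @ C.astype(float)
    # guard empty sets (zero diagonal) against division by zero
    G[np.diag_indices_from(G)] = np.maximum(np.diag(G), _EPS)
    W = C.T @ Z
    U = np.zeros((m, k))
    for j in range(k):
        u_start = U0[:, j] if U0 is not None else np.zeros(m)
        u = _cd_column(W[:, j], G, lambda3, l1_fraction, u_start)
        nz = np.flatnonzero(u > 0)
        if len(nz) > max_path:
            keep = nz[np.argsort(u[nz])[::-1][:max_path]]
            u = _cd_column(W[:, j], G, lambda3, l1_fraction, u, support=np.sort(keep))
        if U0 is not None and np.count_nonzero(u_start) <= max_path:
            if _cd_objective(Z[:, j], C, u, lambda3, l1_fraction) > _cd_objective(
                Z[:, j], C, u_start, lambda3, l1_fraction
            ):
                u = u_start.copy()
        U[:, j] = u
    return U


def _auto_lambdas(D: np.ndarray, k: int) -> tuple[float, float]:
    """Scale-equivariant defaults tied to the k-th singular value of D."""
    s = np.linalg.svd(D, compute_uv=False)
    sk = float(s[min(k, len(s)) - 1])
    lam2 = max(sk, _EPS)
    return lam2 / 2.0, lam2


def _assoc_fraction(U: np.ndarray) -> float:
    return float((U > 0).any(axis=0).mean())


def fit(
    D: GeneWiseMatrix | pd.DataFrame,
    C: KnowledgeMatrix | pd.DataFrame,
    config: PlierConfig,
) -> PlierModel:
    """Fit the knowledge-constrained factorization by alternating updates.

    Each iteration runs the exact B ridge step, the clipped Z ridge step and
    the sparse U step. While lambda3 is "auto" it is adapted by a geometric
    search (factor 2, at most 12 rounds of a few iterations each) until the
    fraction of LVs with at least one prior association reaches
    ``config.frac``, then frozen; convergence is declared when the relative
    change of the penalized objective drops below ``config.tol``.
    """
    config.validate()
    D_df = D.values if isinstance(D, GeneWiseMatrix) else D
    C_df = C.C if isinstance(C, KnowledgeMatrix) else C
    if not D_df.index.equals(C_df.index):
        bad = D_df.index.symmetric_difference(C_df.index)
        raise ValueError(
            f"D and C feature rows are not aligned; first offenders: {list(bad[:5])}"
        )
    if config.k > min(D_df.shape):
        raise ValueError(f"k={config.k} exceeds data dimensions {D_df.shape}")

    row_means = row_sds = None
    if config.standardize_rows:
        gwm = D if isinstance(D, GeneWiseMatrix) else GeneWiseMatrix(
            D_df, pd.Series(D_df.index, index=D_df.index)
        )
        vals = D_df.to_numpy(dtype=float)
        row_means = pd.Series(vals.mean(axis=1), index=D_df.index)
        sd = vals.std(axis=1)
        row_sds = pd.Series(np.where(sd > 0, sd, 1.0), index=D_df.index)
        Dm = standardize_rows(gwm).values.to_numpy(dtype=float)
    else:
        Dm = D_df.to_numpy(dtype=float)
    Cm = C_df.to_numpy(dtype=float)

    lam1, lam2 = config.lambda1, config.lambda2
    if lam1 == "auto" or lam2 == "auto":
        a1, a2 = _auto_lambdas(Dm, config.k)
        lam1 = a1 if lam1 == "auto" else float(lam1)
        lam2 = a2 if lam2 == "auto" else float(lam2)
    lam1, lam2 = float(lam1), float(lam2)
    if lam1 <= 0:
        raise ValueError("lambda1 must be positive")

    Z, B, U = init_model(Dm, Cm, config.k, config.seed)

    # lambda3 handling: the U subproblem uses the unscaled penalty
    # lam3_u = lambda3 / lambda1 (the prior term carries the lambda1 weight).
    auto3 = config.lambda3 == "auto"
    if auto3:
        # start at the median column kill-threshold so roughly half the LVs
        # begin with a prior association, then search geometrically
        W = Cm.T @ Z
        col_norm = np.maximum(np.diag(Cm.T @ Cm), 1.0)
        kill = 2.0 * np.max(W / col_norm[:, None], axis=0) / config.l1_fraction
        lam3_u = float(np.median(np.maximum(kill, _EPS)))
        lam3_u = max(lam3_u, _EPS)
    else:
        lam3_u = float(config.lambda3) / lam1

    trace: list[float] = []
    converged = False
    it = 0
    nan_msg = "non-finite objective at iteration %d (lambda1=%g lambda2=%g lambda3=%g)"

    def one_iteration() -> None:
        nonlocal Z, B, U
        B = update_B(Dm, Z, lam2)
        Z = update_Z(Dm, B, Cm, U, lam1)
        U = update_U(Z, Cm, lam3_u, config.l1_fraction, config.max_path, U0=U)
        obj = _penalized_objective(
            Dm, Cm, Z, U, B, lam1, lam2, lam1 * lam3_u, config.l1_fraction
        )
        if not np.isfinite(obj):
            raise FloatingPointError(nan_msg % (it, lam1, lam2, lam1 * lam3_u))
        trace.append(obj)

    if auto3:
        # geometric search starting at the median column kill-threshold and
        # halving (<= 12 rounds of a few iterations) until the target
        # fraction of prior-associated LVs is met; only lowering lambda3
        # keeps the recorded objective trace monotone across the switch
        burn = 6
        for _ in range(12):
            for _ in range(burn):
                if it >= config.max_iter:
                    break
                one_iteration()
                it += 1
            if _assoc_fraction(U) >= config.frac or it >= config.max_iter:
                break
            lam3_u /= 2.0
        logger.info(
            "lambda3 search frozen at %g (prior-associated fraction %.2f)",
            lam1 * lam3_u, _assoc_fraction(U),
        )

    while it < config.max_iter:
        one_iteration()
        it += 1
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) / max(prev, _EPS) < config.tol:
                converged = True
                break

    lv_names = pd.Index([f"LV{j + 1}" for j in range(config.k)], name="LV")
    model = PlierModel(
        Z=pd.DataFrame(Z, index=D_df.index, columns=lv_names),
        U=pd.DataFrame(U, index=C_df.columns, columns=lv_names),
        B=pd.DataFrame(B, index=lv_names, columns=D_df.columns),
        config=config,
        lambdas={"lambda1": lam1, "lambda2": lam2, "lambda3": lam1 * lam3_u},
        trace=trace,
        converged=converged,
        n_iter=it,
        row_means=row_means,
        row_sds=row_sds,
    )
    if not converged:
        logger.warning("factorization hit max_iter=%d without converging", config.max_iter)
    return model
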