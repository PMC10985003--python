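"""Transfer decomposition and downstream loading-matrix analyses.

A large training cohort yields a frozen latent matrix Z. A new cohort,
compressed into the same feature space, is decomposed against that Z with a
ridge solve to obtain its loading matrix B; all cross-cohort comparisons
(clustering, embedding, differential LVs, survival, differential
methylation) then operate on B or on probe betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .plier_core import PlierModel, update_B
from .probe_compression import GeneWiseMatrix

logger = logging.getLogger(__name__)


@dataclass
class LoadingResult:
    """k x samples loading matrix for a new cohort, with provenance."""

    B: pd.DataFrame
    lambda2: float
    provenance: dict

    @property
    def sample_ids(self) -> pd.Index:
        return self.B.columns

    @property
    def lv_names(self) -> pd.Index:
        return self.B.index


def transfer_loadings(
    D_new: GeneWiseMatrix | pd.DataFrame,
    model: PlierModel | pd.DataFrame,
    lambda2: float | None = None,
    apply_standardization: bool = True,
) -> LoadingResult:
    """Decompose a new cohort against a frozen latent matrix.

    Solves B_new = (Z'Z + lambda2 I)^-1 Z' D_new — the same ridge minimizer
    as the B step of the training loop, with Z fixed. When a fitted
    :class:`PlierModel` is given, its training row means/SDs are applied to
    D_new first (so new samples are scored on the training scale) and its
    lambda2 is the default.
    """
    D_df = D_new.values if isinstance(D_new, GeneWiseMatrix) else D_new
    if isinstance(model, PlierModel):
        Z = model.Z
        if lambda2 is None:
            lambda2 = model.lambdas["lambda2"]
        provenance = {"model_version": model.version, "k": model.k}
        if apply_standardization and model.row_means is not None:
            D_df = D_df.sub(model.row_means, axis=0).div(model.row_sds, axis=0)
    else:
        Z = model
        provenance = {"model_version": None, "k": Z.shape[1]}
    if lambda2 is None or lambda2 <= 0:
        raise ValueError("lambda2 must be positive for the transfer solve")
    if not D_df.index.equals(Z.index):
        bad = D_df.index.symmetric_difference(Z.index)
        raise ValueError(
            f"feature rows of the new data do not match Z; first offenders: "
            f"{list(bad[:5])}"
        )
    B = update_B(D_df.to_numpy(dtype=float), Z.to_numpy(dtype=float), float(lambda2))
    return LoadingResult(
        pd.DataFrame(B, index=Z.columns, columns=D_df.columns), float(lambda2), provenance
    )


def hca_clusters(
    X: pd.DataFrame, n_clusters: int
) -> tuple[pd.Series, np.ndarray]:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    ``X`` is samples x dims. Returns integer labels (0..n_clusters-1) and
    the scipy linkage matrix.
    """
    if not X.index.is_unique:
        raise ValueError("duplicate sample labels")
    if not (2 <= n_clusters <= X.shape[0]):
        raise ValueError("n_clusters must be in [2, n_samples]")
    link = sch.linkage(X.to_numpy(dtype=float), method="ward")
    labels = sch.fcluster(link, t=n_clusters, criterion="maxclust") - 1
    return pd.Series(labels, index=X.index, name="cluster"), link


def _within_ss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    ss = 0.0
    for c in range(k):
        pts = X[labels == c]
        if len(pts):
            ss += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return ss


def _hartigan_wong_once(X: np.ndarray, k: int, rng: np.random.Generator,
                        max_iter: int) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    counts = np.bincount(labels, minlength=k).astype(float)
    # re-seed any empty cluster with the point farthest from its centre
    for c in range(k):
        if counts[c] == 0:
            logger.info("empty cluster after init: re-seeding centroid %d", c)
            far = int(np.argmax(d2[np.arange(n), labels]))
            labels[far] = c
            counts = np.bincount(labels, minlength=k).astype(float)
    for c in range(k):
        centers[c] = X[labels == c].mean(axis=0)
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            src = labels[i]
            if counts[src] <= 1:
                continue
            x = X[i]
            # Hartigan-Wong transfer costs with n/(n +- 1) size corrections
            loss_src = counts[src] / (counts[src] - 1) * float(((x - centers[src]) ** 2).sum())
            gains = counts / (counts + 1) * ((x - centers) ** 2).sum(axis=1)
            gains[src] = np.inf
            dst = int(np.argmin(gains))
            if gains[dst] < loss_src - 1e-12:
                centers[src] = (centers[src] * counts[src] - x) / (counts[src] - 1)
                centers[dst] = (centers[dst] * counts[dst] + x) / (counts[dst] + 1)
                counts[src] -= 1
                counts[dst] += 1
                labels[i] = dst
                moved = True
        if not moved:
            break
    return labels, _within_ss(X, labels, k)


def kmeans_clusters(
    X: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 10,
) -> pd.Series:
    """Hartigan-Wong k-means with restarts; the lowest within-SS run wins."""
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    vals = X.to_numpy(dtype=float)
    if k == 1:
        return pd.Series(np.zeros(len(X), dtype=int), index=X.index, name="cluster")
    rng = np.random.default_rng(seed)
    best_labels, best_ss = None, np.inf
    for _ in range(n_init):
        labels, ss = _hartigan_wong_once(vals, k, rng, max_iter)
        if ss < best_ss - 1e-12:
            best_labels, best_ss = labels, ss
    return pd.Series(best_labels, index=X.index, name="cluster")


def umap_embed(
    X: pd.DataFrame,
    n_neighbors: int = 15,
    n_components: int = 2,
    n_epochs: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Euclidean UMAP embedding of samples (rows of X)."""
    if X.shape[0] <= n_neighbors:
        raise ValueError(
            f"need > {n_neighbors} samples for n_neighbors={n_neighbors}; "
            "lower n_neighbors"
        )
    import umap  # deferred: numba compilation is slow

    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        n_components=n_components,
        n_epochs=n_epochs,
        metric="euclidean",
        random_state=seed,
    )
    emb = reducer.fit_transform(X.to_numpy(dtype=float))
    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("UMAP produced non-finite coordinates")
    cols = [f"UMAP{i + 1}" for i in range(n_components)]
    return pd.DataFrame(emb, index=X.index, columns=cols)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _welch_rows(
    X: np.ndarray, g1: np.ndarray, g2: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t test with a guard for zero-variance rows."""
    a, b = X[:, g1], X[:, g2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d test(s) hit a zero-variance guard", int(bad.sum()))
        same = np.isclose(np.nanmean(a, axis=1), np.nanmean(b, axis=1))
        t[bad & same] = 0.0
        p[bad & same] = 1.0
        t[bad & ~same] = np.sign(np.nanmean(a, axis=1) - np.nanmean(b, axis=1))[bad & ~same] * np.inf
        p[bad & ~same] = 0.0
    return t, p


def differential_lv(
    B: LoadingResult | pd.DataFrame,
    groups: pd.Series,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-LV two-sample t test (Welch by default) with BH adjustment.

    ``groups`` maps sample id -> one of exactly two labels. Returns a frame
    indexed by LV with group means, t, p and q, ordered by q then |t|
    descending.
    """
    B_df = B.B if isinstance(B, LoadingResult) else B
    groups = groups.loc[B_df.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    g1 = (groups == levels[0]).to_numpy()
    g2 = (groups == levels[1]).to_numpy()
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    X = B_df.to_numpy(dtype=float)
    t, p = _welch_rows(X, g1, g2, equal_var)
    out = pd.DataFrame(
        {
            f"mean_{levels[0]}": X[:, g1].mean(axis=1),
            f"mean_{levels[1]}": X[:, g2].mean(axis=1),
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=B_df.index,
    )
    out = out.sort_values(["q", "t"], key=lambda s: -s.abs() if s.name == "t" else s)
    return out


def logrank_test(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p, df=1).

    At each distinct event time the observed events in one group are
    compared with their hypergeometric expectation given the risk sets;
    the statistic is (sum O - sum E)^2 / sum V.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {list(levels)}")
    if events.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    m1 = groups == levels[0]
    res = _lifelines_logrank(
        times[m1], times[~m1], event_observed_A=events[m1], event_observed_B=events[~m1]
    )
    return float(res.test_statistic), float(res.p_value)


def dmp_test(
    beta: pd.DataFrame,
    probe_subset: list[str] | pd.Index,
    groups: pd.Series,
    reference_group: str,
    nearest_gene: pd.Series | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe differential methylation between two groups.

    Welch t test on beta values per probe in ``probe_subset``, BH adjusted
    across all tested probes; ``direction`` is ``hypo``/``hyper`` for the
    comparison group relative to ``reference_group`` (``none`` on exactly
    equal means). Probes entirely missing in a group are excluded and
    counted in ``result.attrs['n_excluded']``.
    """
    probe_subset = pd.Index(probe_subset)
    if probe_subset.empty:
        raise ValueError("probe_subset is empty")
    groups = groups.loc[beta.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2 or reference_group not in levels:
        raise ValueError(
            f"groups must have 2 levels including reference {reference_group!r}"
        )
    comparison = [g for g in levels if g != reference_group][0]
    sub = beta.loc[probe_subset.intersection(beta.index)]
    ref_mask = (groups == reference_group).to_numpy()
    cmp_mask = ~ref_mask

    vals = sub.to_numpy(dtype=float)
    ok = (
        np.isfinite(vals[:, ref_mask]).sum(axis=1) >= 2
    ) & (np.isfinite(vals[:, cmp_mask]).sum(axis=1) >= 2)
    n_excluded = int((~ok).sum()) + len(probe_subset.difference(beta.index))
    sub = sub.loc[ok]
    vals = vals[ok]

    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(
            vals[:, cmp_mask], vals[:, ref_mask], axis=1,
            equal_var=equal_var, nan_policy="omit",
        )
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_ref = np.nanmean(vals[:, ref_mask], axis=1)
    mean_cmp = np.nanmean(vals[:, cmp_mask], axis=1)
    equal = mean_cmp == mean_ref
    t[~np.isfinite(t)] = 0.0
    p[~np.isfinite(p)] = 1.0
    direction = np.where(equal, "none", np.where(mean_cmp < mean_ref, "hypo", "hyper"))
    out = pd.DataFrame(
        {
            f"mean_{reference_group}": mean_ref,
            f"mean_{comparison}": mean_cmp,
            "mean_diff": mean_cmp - mean_ref,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "direction": direction,
        },
        index=sub.index,
    )
    if nearest_gene is not None:
        out["nearest_gene"] = nearest_gene.reindex(out.index)
    out = out.sort_values("q", kind="stable")
    out.attrs["n_excluded"] = n_excluded
    return out
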