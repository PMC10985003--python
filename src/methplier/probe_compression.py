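"""Probe-to-transcript compression of methylation beta matrices.

HM450-style arrays report a beta value (fraction methylated, in [0, 1]) per
CpG probe, and several probes annotate the promoter of each transcript.
Knowledge-constrained factorization needs one block of features per
gene/transcript, so this module

1. selects the probes in a window around each transcript's TSS (or,
   alternatively, the probes annotated to the first exon),
2. runs a per-transcript PCA across samples and keeps the leading principal
   component scores up to a cumulative explained-variance threshold
   (default 0.8), and
3. re-projects new cohorts with the stored eigenvectors and training means,
   so different datasets land in the same feature space.

The compressed matrix has one row per retained (transcript, component) pair;
rows may be negative because they are PC scores, not betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "strand", "transcript_id", "tss_pos")

#: separator used to build feature labels "<transcript_id>::PC<i>"
FEATURE_SEP = "::"


def feature_label(transcript_id: str, component: int) -> str:
    """Label for the ``component``-th (1-based) PC score of a transcript."""
    return f"{transcript_id}{FEATURE_SEP}PC{component}"


def split_feature_label(label: str) -> tuple[str, int]:
    tx, pc = label.rsplit(FEATURE_SEP, 1)
    return tx, int(pc[2:])


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check required manifest columns and basic invariants.

    The manifest is transcript-scoped: a probe annotating several transcripts
    has one row per transcript. Coordinates are 1-based.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    if manifest.empty:
        raise ValueError("manifest is empty")
    if (manifest["pos"] < 1).any():
        raise ValueError("manifest contains positions < 1 (coordinates are 1-based)")
    dup = manifest.duplicated(subset=["probe_id", "transcript_id"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicated (probe_id, transcript_id) manifest rows"
        )
    return manifest


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples beta matrix: values in [0,1] or NaN, unique labels."""
    if not beta.index.is_unique:
        raise ValueError("beta matrix has duplicated probe ids")
    if not beta.columns.is_unique:
        raise ValueError("beta matrix has duplicated sample ids")
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    return beta


def select_region_probes(
    manifest: pd.DataFrame,
    mode: str = "tss_window",
    window_bp: int = 1500,
    upstream_only: bool = False,
) -> dict[str, list[str]]:
    """Map each transcript to its ordered list of promoter-region probes.

    Parameters
    ----------
    manifest
        Transcript-scoped probe manifest (see :data:`MANIFEST_COLUMNS`).
    mode
        ``"tss_window"`` keeps probes within ``window_bp`` of the TSS;
        ``"first_exon"`` keeps probes whose ``region_tag`` is ``1stExon``.
    window_bp
        Half-width of the TSS window in base pairs.
    upstream_only
        With ``tss_window``, restrict to the strand-aware upstream side
        (the array's TSS1500 convention) instead of the symmetric window.

    Returns
    -------
    dict mapping transcript_id -> probe ids sorted by genomic position.
    Transcripts with no qualifying probe are omitted.
    """
    validate_manifest(manifest)
    if mode == "tss_window":
        if window_bp <= 0:
            raise ValueError("window_bp must be positive")
        rows = manifest.copy()
        no_tss = rows["tss_pos"].isna()
        if no_tss.any():
            skipped = rows.loc[no_tss, "transcript_id"].unique()
            logger.warning(
                "skipping %d transcript(s) with missing tss_pos: %s",
                len(skipped), ", ".join(map(str, skipped[:5])),
            )
            rows = rows.loc[~no_tss]
        delta = rows["pos"].to_numpy(dtype=float) - rows["tss_pos"].to_numpy(dtype=float)
        if upstream_only:
            minus = rows["strand"].astype(str).isin(["-", "−"]).to_numpy()
            up = np.where(minus, delta, -delta)  # bp upstream of the TSS
            keep = (up >= 0) & (up <= window_bp)
        else:
            keep = np.abs(delta) <= window_bp
        rows = rows.loc[keep]
    elif mode == "first_exon":
        if "region_tag" not in manifest.columns:
            raise ValueError("first_exon mode requires a region_tag manifest column")
        rows = manifest.loc[manifest["region_tag"] == "1stExon"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out: dict[str, list[str]] = {}
    for tx, grp in rows.groupby("transcript_id", sort=True):
        out[str(tx)] = grp.sort_values("pos")["probe_id"].astype(str).tolist()
    return out


@dataclass
class TranscriptComponents:
    """Per-transcript PCA block: probe order, centering means, eigenvectors."""

    probe_ids: list[str]
    means: np.ndarray            # (p,) training mean beta per probe
    eigvecs: np.ndarray          # (p, q) orthonormal columns
    explained_var: np.ndarray    # (q,) per-component explained-variance fraction
    cum_var: float               # cumulative fraction of the retained set
    zero_variance: bool = False

    @property
    def q(self) -> int:
        return self.eigvecs.shape[1]


@dataclass
class CompressionModel:
    """Reusable probe-to-transcript compression: eigenvectors + training means."""

    transcripts: dict[str, TranscriptComponents]
    mode: str
    window_bp: int
    cum_threshold: float
    feature_gene: pd.Series = field(repr=False)  # feature label -> gene symbol

    @property
    def feature_index(self) -> pd.Index:
        labels = [
            feature_label(tx, i + 1)
            for tx, tc in self.transcripts.items()
            for i in range(tc.q)
        ]
        return pd.Index(labels, name="feature")

    @property
    def n_features(self) -> int:
        return sum(tc.q for tc in self.transcripts.values())


@dataclass
class GeneWiseMatrix:
    """Compressed features x samples matrix of per-transcript PC scores."""

    values: pd.DataFrame                 # features x samples, real-valued
    feature_gene: pd.Series              # feature label -> gene symbol
    n_imputed_probes: int = 0            # probes filled at the training mean

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _transcript_gene(manifest_or_map, transcript_id: str) -> str:
    if manifest_or_map is None:
        return transcript_id
    return str(manifest_or_map.get(transcript_id, transcript_id))


def _fix_sign(vec: np.ndarray) -> int:
    """Sign convention: the largest-magnitude eigenvector element is positive."""
    idx = int(np.argmax(np.abs(vec)))
    return -1 if vec[idx] < 0 else 1


def _clean_block(block: np.ndarray, max_missing_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop probes with too many missing samples; mean-impute the rest.

    Returns (kept-row boolean mask, imputed block). PCA needs a complete
    block, so probes with > max_missing_frac missing entries are removed and
    the remaining gaps are filled with the probe's observed mean.
    """
    miss = ~np.isfinite(block)
    keep = miss.mean(axis=1) <= max_missing_frac
    block = block[keep].copy()
    miss = miss[keep]
    if miss.any():
        row_mean = np.nanmean(np.where(miss, np.nan, block), axis=1)
        row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
        block[miss] = np.broadcast_to(row_mean[:, None], block.shape)[miss]
    return keep, block


def fit_compression(
    beta: pd.DataFrame,
    probe_map: dict[str, list[str]],
    cum_threshold: float = 0.8,
    transcript_gene_map: dict[str, str] | pd.Series | None = None,
    max_missing_frac: float = 0.2,
    mode: str = "tss_window",
    window_bp: int = 1500,
) -> tuple[CompressionModel, GeneWiseMatrix]:
    """Fit per-transcript PCA compression on a training beta matrix.

    For every transcript in ``probe_map`` the probe rows are mean-centered
    per probe (across samples) and decomposed by SVD with samples as
    observations; the smallest leading set of components whose cumulative
    explained-variance fraction reaches ``cum_threshold`` is retained. A
    transcript whose probes are all constant keeps a single zero-variance
    component (explained variance defined as 1).

    Returns the fitted :class:`CompressionModel` and the training
    :class:`GeneWiseMatrix` of PC scores.
    """
    validate_beta(beta)
    if beta.shape[1] < 2:
        raise ValueError("compression requires at least 2 samples")
    if not (0.0 < cum_threshold <= 1.0):
        raise ValueError("cum_threshold must be in (0, 1]")

    transcripts: dict[str, TranscriptComponents] = {}
    score_rows: list[np.ndarray] = []
    labels: list[str] = []
    genes: list[str] = []
    n_samples = beta.shape[1]

    for tx in sorted(probe_map):
        probes = [p for p in probe_map[tx] if p in beta.index]
        if not probes:
            continue
        block = beta.loc[probes].to_numpy(dtype=float)
        keep, block = _clean_block(block, max_missing_frac)
        probes = [p for p, k in zip(probes, keep) if k]
        if not probes:
            logger.warning("transcript %s dropped: all probes too sparse", tx)
            continue
        mu = block.mean(axis=1)
        xc = block - mu[:, None]
        p = len(probes)

        total_var = float(np.sum(xc ** 2))
        if total_var <= 1e-24:
            # constant block: keep one zero-variance feature so the transcript
            # survives into the feature space
            v = np.full((p, 1), 1.0 / np.sqrt(p))
            tc = TranscriptComponents(
                probes, mu, v, np.array([1.0]), 1.0, zero_variance=True
            )
            scores = np.zeros((1, n_samples))
        else:
            u, s, _ = np.linalg.svd(xc, full_matrices=False)
            var = s ** 2
            evr = var / var.sum()
            cum = np.cumsum(evr)
            q = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
            q = min(q, len(evr))
            v = u[:, :q].copy()
            for j in range(q):
                v[:, j] *= _fix_sign(v[:, j])
            tc = TranscriptComponents(probes, mu, v, evr[:q].copy(), float(cum[q - 1]))
            scores = v.T @ xc
        transcripts[tx] = tc
        score_rows.append(scores)
        gene = _transcript_gene(transcript_gene_map, tx)
        for i in range(tc.q):
            labels.append(feature_label(tx, i + 1))
            genes.append(gene)

    if not transcripts:
        raise ValueError("no transcript had usable probes in the beta matrix")

    values = pd.DataFrame(
        np.vstack(score_rows), index=pd.Index(labels, name="feature"), columns=beta.columns
    )
    feature_gene = pd.Series(genes, index=values.index, name="gene")
    model = CompressionModel(transcripts, mode, window_bp, cum_threshold, feature_gene)
    return model, GeneWiseMatrix(values, feature_gene)


def project(beta_new: pd.DataFrame, model: CompressionModel) -> GeneWiseMatrix:
    """Project a new beta matrix into the trained compressed feature space.

    New-data probe rows are centered with the TRAINING means and multiplied by
    the stored eigenvectors. Probes absent from the new data are imputed at
    the training mean (zero contribution after centering);
    :attr:`GeneWiseMatrix.n_imputed_probes` counts them. Transcripts with all
    probes absent produce missing (NaN) feature rows.
    """
    validate_beta(beta_new)
    if beta_new.shape[1] < 1:
        raise ValueError("need at least one sample to project")
    n_samples = beta_new.shape[1]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    genes: list[str] = []
    n_imputed = 0

    for tx, tc in model.transcripts.items():
        present = [p in beta_new.index for p in tc.probe_ids]
        gene = str(model.feature_gene.get(feature_label(tx, 1), tx))
        if not any(present):
            logger.warning("transcript %s: all probes missing in new data", tx)
            block_scores = np.full((tc.q, n_samples), np.nan)
        else:
            xc = np.zeros((len(tc.probe_ids), n_samples))
            for i, (p, ok) in enumerate(zip(tc.probe_ids, present)):
                if ok:
                    row = beta_new.loc[p].to_numpy(dtype=float)
                    row = np.where(np.isfinite(row), row, tc.means[i])
                    xc[i] = row - tc.means[i]
                else:
                    n_imputed += 1  # stays 0 after centering
            block_scores = tc.eigvecs.T @ xc
        rows.append(block_scores)
        for i in range(tc.q):
            labels.append(feature_label(tx, i + 1))
            genes.append(gene)

    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(labels, name="feature"), columns=beta_new.columns
    )
    feature_gene = pd.Series(genes, index=values.index, name="gene")
    if n_imputed:
        logger.info("projection imputed %d probe(s) at the training mean", n_imputed)
    return GeneWiseMatrix(values, feature_gene, n_imputed_probes=n_imputed)
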