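"""Synthetic manifests, beta matrices, gene sets and planted factorizations.

Everything the pipeline consumes can be generated here with a known ground
truth, by inverting the analysis pipeline: draw a sparse non-negative
set-coupling matrix U, build gene-level latent directions Z = C U plus
half-normal noise, draw group-structured sample loadings B, form gene
signal G = Z B + Gaussian noise, and emit correlated probe betas through an
inverse-logit link with per-probe offsets. Probe-level compression then
recovers G up to an affine transform, and the factorization can be scored
against the planted truth.

Default fixture conditions: 120 genes, 12 gene sets, k = 6 latent
variables, 80 samples, gene-level noise SD 0.3, seed 17.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import expit

from .knowledge import GeneSetCollection
from .plier_core import PlierModel, standardize_rows
from .probe_compression import GeneWiseMatrix

#: inverse-logit slope, per-probe offset SD and logit-scale measurement
#: noise SD; chosen so most betas fall in [0.05, 0.95] with realistic
#: spread and probe-level scatter (fixture conventions, not data claims)
LOGIT_SLOPE = 1.5
PROBE_OFFSET_SD = 0.5


def simulate_manifest(
    n_genes: int,
    transcripts_per_gene: int = 1,
    probes_per_transcript: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic transcript-scoped probe manifest.

    Genes are laid out 1 Mb apart across chromosomes 1-22; each transcript
    gets ``probes_per_transcript`` probes placed uniformly within +-1500 bp
    of its TSS, on alternating strands. Probes at or downstream of the TSS
    (within 200 bp) are tagged ``1stExon``, the rest ``TSS1500``.
    """
    if min(n_genes, transcripts_per_gene, probes_per_transcript) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    probe_no = 0
    for g in range(n_genes):
        gene = f"G{g + 1:04d}"
        chrom = f"chr{(g % 22) + 1}"
        for t in range(transcripts_per_gene):
            tx = f"{gene}.T{t + 1}"
            tss = 1_000_000 * (g + 1) + 10_000 * t
            strand = "+" if (g + t) % 2 == 0 else "-"
            offsets = rng.integers(-1500, 1501, size=probes_per_transcript)
            for off in sorted(offsets):
                probe_no += 1
                pos = max(1, tss + int(off))
                tag = "1stExon" if 0 <= int(off) <= 200 else "TSS1500"
                rows.append(
                    (f"cg{probe_no:08d}", chrom, pos, strand, tx, tss, tag, gene)
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "chrom", "pos", "strand",
            "transcript_id", "tss_pos", "region_tag", "gene",
        ],
    )
    return df


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset, reproducible from its seed."""

    Z: pd.DataFrame              # genes x k, non-negative
    U: pd.DataFrame              # sets x k, sparse non-negative
    B: pd.DataFrame              # k x samples
    C: pd.DataFrame              # genes x sets binary membership
    groups: pd.Series            # sample -> group label
    group_effects: pd.DataFrame = field(repr=False)  # k x groups mean shifts
    noise_sd: float = 0.3
    seed: int = 17

    @property
    def k(self) -> int:
        return self.Z.shape[1]


def simulate_plier_dataset(
    manifest: pd.DataFrame,
    n_sets: int = 12,
    k: int = 6,
    n_samples: int = 80,
    noise_sd: float = 0.3,
    u_density: float = 0.25,
    seed: int = 17,
    group_effect: float = 2.0,
    probe_noise_sd: float | None = None,
) -> tuple[pd.DataFrame, GeneSetCollection, PlantedTruth]:
    """Generate a probe beta matrix with a planted factorization.

    Each gene set samples ~n_genes/6 member genes; each latent variable
    loads ``round(u_density * n_sets)`` sets with Uniform(0.5, 1.5)
    weights. Sample loadings are standard normal around group-specific
    means (two groups, half the LVs shifted by +-``group_effect``). The
    gene signal is standardized before the inverse-logit link so betas stay
    inside (0, 1) without saturating. ``probe_noise_sd`` is logit-scale
    measurement noise per probe and defaults to ``noise_sd``, so a noiseless
    simulation yields perfectly rank-correlated probes within a gene.
    """
    if k > n_sets:
        raise ValueError("k must not exceed n_sets")
    if not (0.0 < u_density <= 1.0):
        raise ValueError("u_density must be in (0, 1]")
    if probe_noise_sd is None:
        probe_noise_sd = noise_sd
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(manifest["gene"])) if "gene" in manifest.columns else \
        sorted({tx.split(".")[0] for tx in manifest["transcript_id"]})
    n_genes = len(genes)

    set_names = [f"SET{s + 1:03d}" for s in range(n_sets)]
    set_size = max(5, n_genes // 6)
    members = {
        name: sorted(rng.choice(genes, size=set_size, replace=False))
        for name in set_names
    }
    collection = GeneSetCollection(
        {name: list(m) for name, m in members.items()},
        {name: "synthetic" for name in set_names},
    )
    C = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                     columns=pd.Index(set_names, name="gene_set"), dtype=float)
    for name, m in members.items():
        C.loc[m, name] = 1.0

    # each LV owns a distinct primary set and supports overlap by at most one
    # set, so the planted factors are mutually distinguishable
    nnz = max(1, round(u_density * n_sets))
    U = np.zeros((n_sets, k))
    supports: list[set[int]] = []
    for j in range(k):
        primary = j % n_sets
        for _ in range(200):
            extra = rng.choice(
                [s for s in range(n_sets) if s != primary],
                size=nnz - 1, replace=False,
            ) if nnz > 1 else np.array([], dtype=int)
            cand = {primary, *extra.tolist()}
            if all(len(cand & prev) <= 1 for prev in supports):
                break
        supports.append(cand)
        idx = sorted(cand)
        U[idx, j] = rng.uniform(0.5, 1.5, size=len(idx))
    Z = C.to_numpy() @ U + np.abs(rng.normal(0.0, 0.1, size=(n_genes, k)))
    Z /= np.maximum(np.linalg.norm(Z, axis=0, keepdims=True), 1e-12) / np.sqrt(n_genes)

    half = n_samples // 2
    groups = pd.Series(
        ["A"] * half + ["B"] * (n_samples - half),
        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample"),
        name="group",
    )
    shifted = rng.choice(k, size=max(1, k // 2), replace=False)
    effects = np.zeros((k, 2))
    effects[shifted, 1] = rng.choice([-group_effect, group_effect], size=len(shifted))
    B = rng.normal(0.0, 1.0, size=(k, n_samples))
    B[:, half:] += effects[:, [1]]

    G = Z @ B + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    Gs = (G - G.mean()) / max(G.std(), 1e-12)
    gene_signal = pd.DataFrame(Gs, index=genes, columns=groups.index)

    probe_rows: dict[str, np.ndarray] = {}
    beta_rows = []
    probe_index = []
    for row in manifest.itertuples(index=False):
        gene = getattr(row, "gene", row.transcript_id.split(".")[0])
        if row.probe_id not in probe_rows:
            off = rng.normal(0.0, PROBE_OFFSET_SD)
            noise = (
                rng.normal(0.0, probe_noise_sd, size=n_samples)
                if probe_noise_sd > 0 else 0.0
            )
            probe_rows[row.probe_id] = expit(
                LOGIT_SLOPE * gene_signal.loc[gene].to_numpy() + off + noise
            )
        beta_rows.append(probe_rows[row.probe_id])
        probe_index.append(row.probe_id)
    beta = pd.DataFrame(
        np.vstack(beta_rows), index=pd.Index(probe_index, name="probe_id"),
        columns=groups.index,
    ).groupby(level=0).first()
    beta = beta.loc[list(dict.fromkeys(probe_index))]

    lv_names = pd.Index([f"LV{j + 1}" for j in range(k)], name="LV")
    truth = PlantedTruth(
        Z=pd.DataFrame(Z, index=pd.Index(genes, name="gene"), columns=lv_names),
        U=pd.DataFrame(U, index=C.columns, columns=lv_names),
        B=pd.DataFrame(B, index=lv_names, columns=groups.index),
        C=C,
        groups=groups,
        group_effects=pd.DataFrame(effects, index=lv_names, columns=["A", "B"]),
        noise_sd=noise_sd,
        seed=seed,
    )
    return beta, collection, truth


def simulate_survival(
    groups,
    hazard_ratio: float = 1.0,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival with independent exponential censoring.

    ``groups`` is either a sequence of group labels or an (nA, nB) pair.
    The second group's event hazard is ``hazard_ratio`` times the first's;
    the censoring hazard is set so a fraction ``censor_rate`` of subjects is
    censored in expectation (0 disables censoring).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if isinstance(groups, tuple) and len(groups) == 2 and all(
        isinstance(g, (int, np.integer)) for g in groups
    ):
        labels = ["A"] * int(groups[0]) + ["B"] * int(groups[1])
    else:
        labels = [str(g) for g in groups]
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    rng = np.random.default_rng(seed)
    base_rate = 1.0
    rates = {levels[0]: base_rate, levels[1]: base_rate * hazard_ratio}
    rows = []
    for i, g in enumerate(labels):
        event_t = rng.exponential(1.0 / rates[g])
        if censor_rate > 0:
            censor_hazard = rates[g] * censor_rate / (1.0 - censor_rate)
            censor_t = rng.exponential(1.0 / censor_hazard)
        else:
            censor_t = np.inf
        t = min(event_t, censor_t)
        rows.append((f"S{i + 1:03d}", t, int(event_t <= censor_t), g))
    return pd.DataFrame(rows, columns=["sample_id", "time", "event", "group"])


def latent_space_truth(
    D: GeneWiseMatrix | pd.DataFrame, truth: PlantedTruth, standardized: bool = True
) -> pd.DataFrame:
    """Planted latent directions expressed in the compressed feature space.

    The planted Z lives at the gene level, while a fitted model's Z lives on
    (transcript, PC) features; the comparable target is the least-squares
    image of the planted loadings: Zstar = D B_true' (B_true B_true')^-1.
    """
    D_df = D.values if isinstance(D, GeneWiseMatrix) else D
    if standardized:
        gwm = D if isinstance(D, GeneWiseMatrix) else GeneWiseMatrix(
            D_df, pd.Series(D_df.index, index=D_df.index)
        )
        D_df = standardize_rows(gwm).values
    Bt = truth.B[D_df.columns].to_numpy()
    Dm = D_df.to_numpy(dtype=float)
    Zstar = np.linalg.solve(Bt @ Bt.T, Bt @ Dm.T).T
    return pd.DataFrame(Zstar, index=D_df.index, columns=truth.B.index)


def factor_recovery(
    model: PlierModel, D: GeneWiseMatrix | pd.DataFrame, truth: PlantedTruth
) -> pd.Series:
    """Hungarian-matched |correlation| between fitted and planted LVs.

    Fitted Z columns are matched one-to-one to the planted latent directions
    (mapped into feature space by :func:`latent_space_truth`) by maximizing
    total absolute Pearson correlation; returns the matched |r| per planted
    LV.
    """
    Zstar = latent_space_truth(D, truth, standardized=model.config.standardize_rows)
    Zhat = model.Z.loc[Zstar.index].to_numpy()
    Zs = Zstar.to_numpy()
    k_hat, k_true = Zhat.shape[1], Zs.shape[1]
    corr = np.zeros((k_true, k_hat))
    for a in range(k_true):
        for b in range(k_hat):
            x, y = Zs[:, a], Zhat[:, b]
            if x.std() == 0 or y.std() == 0:
                continue
            corr[a, b] = abs(np.corrcoef(x, y)[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    out = pd.Series(0.0, index=truth.B.index, name="abs_corr")
    for a, b in zip(rows, cols):
        out.iloc[a] = corr[a, b]
    return out
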