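"""Readers and writers for manifests, beta matrices and model archives.

Model archives are directories of text matrices plus a JSON metadata block,
so they stay inspectable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge import KnowledgeMatrix
from .plier_core import PlierConfig, PlierModel
from .probe_compression import (
    CompressionModel,
    TranscriptComponents,
    feature_label,
    validate_beta,
    validate_manifest,
)

FORMAT_VERSION = "methplier-archive-1"


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest TSV/CSV (probe_id, chrom, pos, strand,
    transcript_id, tss_pos[, region_tag, gene])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    return validate_manifest(df)


def read_beta(path: str | Path) -> pd.DataFrame:
    """Read a beta matrix TSV/CSV: first column probe ids, NA for missing."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index.name = "probe_id"
    return validate_beta(df)


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    beta.to_csv(path, sep=_sep(path))


def save_compression_model(model: CompressionModel, outdir: str | Path) -> None:
    """Write a compression model as text matrices + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": FORMAT_VERSION,
        "kind": "compression",
        "mode": model.mode,
        "window_bp": model.window_bp,
        "cum_threshold": model.cum_threshold,
        "transcripts": {
            tx: {
                "probe_ids": tc.probe_ids,
                "q": tc.q,
                "cum_var": tc.cum_var,
                "zero_variance": tc.zero_variance,
            }
            for tx, tc in model.transcripts.items()
        },
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    model.feature_gene.rename("gene").to_csv(outdir / "feature_gene.tsv", sep="\t")

    rows = []
    for tx, tc in model.transcripts.items():
        for i, probe in enumerate(tc.probe_ids):
            rec = {"transcript_id": tx, "probe_id": probe, "mean": tc.means[i]}
            for j in range(tc.q):
                rec[f"ev{j + 1}"] = tc.eigvecs[i, j]
            rows.append(rec)
    pd.DataFrame(rows).to_csv(outdir / "eigenvectors.tsv", sep="\t", index=False)
    evr = [
        {"transcript_id": tx, "component": j + 1, "explained_var": tc.explained_var[j]}
        for tx, tc in model.transcripts.items()
        for j in range(tc.q)
    ]
    pd.DataFrame(evr).to_csv(outdir / "explained_variance.tsv", sep="\t", index=False)


def load_compression_model(indir: str | Path) -> CompressionModel:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    if meta.get("kind") != "compression":
        raise ValueError(f"{indir} is not a compression-model archive")
    ev = pd.read_csv(indir / "eigenvectors.tsv", sep="\t")
    evr = pd.read_csv(indir / "explained_variance.tsv", sep="\t")
    feature_gene = pd.read_csv(indir / "feature_gene.tsv", sep="\t", index_col=0)["gene"]

    transcripts: dict[str, TranscriptComponents] = {}
    for tx, info in meta["transcripts"].items():
        block = ev.loc[ev["transcript_id"] == tx].set_index("probe_id")
        block = block.loc[info["probe_ids"]]
        q = int(info["q"])
        eigvecs = block[[f"ev{j + 1}" for j in range(q)]].to_numpy(dtype=float)
        exp = evr.loc[evr["transcript_id"] == tx, "explained_var"].to_numpy(dtype=float)
        transcripts[tx] = TranscriptComponents(
            probe_ids=list(info["probe_ids"]),
            means=block["mean"].to_numpy(dtype=float),
            eigvecs=eigvecs,
            explained_var=exp,
            cum_var=float(info["cum_var"]),
            zero_variance=bool(info.get("zero_variance", False)),
        )
    return CompressionModel(
        transcripts,
        meta["mode"],
        int(meta["window_bp"]),
        float(meta["cum_threshold"]),
        feature_gene,
    )


def save_plier_model(model: PlierModel, outdir: str | Path) -> None:
    """Write a fitted factorization (Z, U, B, config, trace) as text + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": FORMAT_VERSION,
        "kind": "plier",
        "version": model.version,
        "config": asdict(model.config),
        "lambdas": model.lambdas,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "trace": model.trace,
        "standardized": model.row_means is not None,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    model.Z.to_csv(outdir / "Z.tsv", sep="\t")
    model.U.to_csv(outdir / "U.tsv", sep="\t")
    model.B.to_csv(outdir / "B.tsv", sep="\t")
    if model.row_means is not None:
        pd.DataFrame(
            {"mean": model.row_means, "sd": model.row_sds}
        ).to_csv(outdir / "row_stats.tsv", sep="\t")


def load_plier_model(indir: str | Path) -> PlierModel:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    if meta.get("kind") != "plier":
        raise ValueError(f"{indir} is not a factorization archive")
    Z = pd.read_csv(indir / "Z.tsv", sep="\t", index_col=0)
    U = pd.read_csv(indir / "U.tsv", sep="\t", index_col=0)
    B = pd.read_csv(indir / "B.tsv", sep="\t", index_col=0)
    row_means = row_sds = None
    if (indir / "row_stats.tsv").exists():
        stats = pd.read_csv(indir / "row_stats.tsv", sep="\t", index_col=0)
        row_means, row_sds = stats["mean"], stats["sd"]
    return PlierModel(
        Z=Z,
        U=U,
        B=B,
        config=PlierConfig(**meta["config"]),
        lambdas=meta["lambdas"],
        trace=list(meta["trace"]),
        converged=bool(meta["converged"]),
        n_iter=int(meta["n_iter"]),
        row_means=row_means,
        row_sds=row_sds,
        version=meta["version"],
    )


def save_knowledge_matrix(K: KnowledgeMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K.C.to_csv(outdir / "C.tsv", sep="\t")
    K.overlap_genes.rename("overlap_genes").to_csv(outdir / "set_index.tsv", sep="\t")


def load_knowledge_matrix(indir: str | Path) -> KnowledgeMatrix:
    indir = Path(indir)
    C = pd.read_csv(indir / "C.tsv", sep="\t", index_col=0)
    overlap = pd.read_csv(indir / "set_index.tsv", sep="\t", index_col=0)["overlap_genes"]
    return KnowledgeMatrix(C.astype(np.int8), overlap)
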