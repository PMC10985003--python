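"""Conversion of per-CpG bisulfite calls (WGBS/RRBS) to array probe betas.

Sequencing platforms report methylation per CpG cytosine; arrays report per
designed probe. This module joins bisulfite calls onto a probe manifest by
exact genomic coordinate: a probe matches the cytosine of its CpG on either
strand (the probe position itself, or position + 1 for the reverse-strand
cytosine of the dinucleotide). Opposite-strand calls for one CpG are
combined by a coverage-weighted mean, low-coverage sites are set missing,
and a coverage report records how much of the manifest was matched —
typically high for WGBS and low (~10%) for RRBS.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = ("chrom", "pos")  # plus strand and beta or (methylated, total)


def read_cpg_calls(
    path: str | Path,
    dialect: str = "tsv",
    assembly: str | None = None,
) -> pd.DataFrame:
    """Read bisulfite calls from a 1-based TSV or a BED-like 0-based file.

    The TSV dialect expects header columns chrom, pos (1-based), strand and
    either beta or methylated/total. The BED dialect expects chrom, start
    (0-based), end, then the same value columns; coordinates are normalized
    to the 1-based cytosine position.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "bed":
        df = df.rename(columns={"start": "pos"})
        df["pos"] = df["pos"].astype(int) + 1
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    if assembly is not None:
        df.attrs["assembly"] = assembly
    return validate_calls(df)


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check call-table invariants: counts ordered, betas bounded."""
    for col in CALL_COLUMNS:
        if col not in calls.columns:
            raise ValueError(f"call table is missing column {col!r}")
    has_counts = {"methylated", "total"}.issubset(calls.columns)
    has_beta = "beta" in calls.columns
    if not (has_counts or has_beta):
        raise ValueError("call table needs either beta or methylated/total columns")
    if has_counts:
        m = calls["methylated"].to_numpy(dtype=float)
        t = calls["total"].to_numpy(dtype=float)
        if np.any(m < 0) or np.any(t < m):
            raise ValueError("counts must satisfy 0 <= methylated <= total")
    if has_beta:
        b = calls["beta"].to_numpy(dtype=float)
        b = b[np.isfinite(b)]
        if b.size and (b.min() < 0 or b.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
    return calls


def _merge_duplicates(calls: pd.DataFrame, has_counts: bool) -> pd.DataFrame:
    dup = calls.duplicated(subset=["chrom", "pos"], keep=False)
    if not dup.any():
        return calls
    logger.warning(
        "merging %d duplicated (chrom, pos) call rows", int(dup.sum())
    )
    if has_counts:
        agg = calls.groupby(["chrom", "pos"], as_index=False).agg(
            methylated=("methylated", "sum"), total=("total", "sum")
        )
    else:
        agg = calls.groupby(["chrom", "pos"], as_index=False).agg(beta=("beta", "mean"))
    return agg


def liftover_to_probes(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    min_total: int = 5,
    sample_id: str = "sample",
    force: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Map CpG calls onto manifest probes by exact coordinate.

    For each unique probe, candidate calls are the ones at the probe's
    position (forward-strand cytosine) and at position + 1 (reverse-strand
    cytosine of the CpG dinucleotide); when both report, their betas are
    combined by a coverage-weighted mean. Count-based sites with summed
    coverage below ``min_total`` are set missing (``min_total`` is ignored
    when only betas are supplied).

    Returns a single-column beta matrix over all unique manifest probes and
    a coverage report with the matched fraction and per-chromosome counts.
    """
    calls = validate_calls(calls)
    m_asm = manifest.attrs.get("assembly")
    c_asm = calls.attrs.get("assembly")
    if m_asm and c_asm and m_asm != c_asm and not force:
        raise ValueError(
            f"assembly mismatch: calls={c_asm!r} manifest={m_asm!r} (use force=True)"
        )
    has_counts = {"methylated", "total"}.issubset(calls.columns)
    calls = _merge_duplicates(calls, has_counts)
    if has_counts:
        with np.errstate(invalid="ignore", divide="ignore"):
            calls = calls.assign(
                beta=calls["methylated"] / calls["total"],
                weight=calls["total"].astype(float),
            )
    else:
        calls = calls.assign(weight=1.0)
    lookup = {
        (c, p): (b, w)
        for c, p, b, w in zip(calls["chrom"], calls["pos"], calls["beta"], calls["weight"])
    }

    probes = manifest.drop_duplicates(subset="probe_id")[["probe_id", "chrom", "pos"]]
    values: list[float] = []
    matched_rows: list[tuple[str, str]] = []
    for pid, chrom, pos in probes.itertuples(index=False):
        hits = [lookup[key] for key in ((chrom, pos), (chrom, pos + 1)) if key in lookup]
        hits = [(b, w) for b, w in hits if np.isfinite(b)]
        total_w = sum(w for _, w in hits)
        if not hits or (has_counts and total_w < min_total):
            values.append(np.nan)
            continue
        values.append(sum(b * w for b, w in hits) / total_w)
        matched_rows.append((str(pid), str(chrom)))

    beta = pd.DataFrame(
        {sample_id: values}, index=pd.Index(probes["probe_id"], name="probe_id")
    )
    per_chrom: dict[str, int] = {}
    for _, chrom in matched_rows:
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    report = {
        "n_probes": int(len(probes)),
        "n_matched": len(matched_rows),
        "matched_fraction": len(matched_rows) / len(probes) if len(probes) else 0.0,
        "per_chromosome": dict(sorted(per_chrom.items())),
    }
    return beta, report
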