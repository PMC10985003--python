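"""Gene-set ingestion and construction of the binary knowledge matrix C.

The factorization constrains the latent feature matrix Z to lie close to
C @ U, where C is a one-hot features x gene-sets membership matrix. Gene
sets come in as standard GMT files (set name, description, gene symbols);
membership is defined at the gene level and expanded to every PC feature of
every transcript of that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .probe_compression import GeneWiseMatrix


@dataclass
class GeneSetCollection:
    """Ordered set-name -> gene-list mapping with per-set source labels."""

    sets: dict[str, list[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def load_gmt(paths: Iterable[str | Path]) -> GeneSetCollection:
    """Load one or more tab-delimited GMT files into a single collection.

    Gene symbols are uppercased and deduplicated within a set. A set name
    defined in more than one file is disambiguated by prefixing every
    colliding definition with its file stem (``"f1:SETA"``, ``"f2:SETA"``).
    """
    paths = [Path(p) for p in paths]
    raw: list[tuple[str, str, list[str]]] = []  # (stem, name, genes)
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: malformed GMT line (<3 tab-separated fields)"
                    )
                name = fields[0].strip()
                genes: list[str] = []
                seen: set[str] = set()
                for g in fields[2:]:
                    g = g.strip().upper()
                    if g and g not in seen:
                        seen.add(g)
                        genes.append(g)
                if not genes:
                    raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
                raw.append((path.stem, name, genes))

    counts: dict[str, int] = {}
    for _, name, _ in raw:
        counts[name] = counts.get(name, 0) + 1

    sets: dict[str, list[str]] = {}
    sources: dict[str, str] = {}
    for stem, name, genes in raw:
        key = f"{stem}:{name}" if counts[name] > 1 else name
        if key in sets:
            raise ValueError(f"duplicate gene set name {key!r} within one file")
        sets[key] = genes
        sources[key] = stem
    return GeneSetCollection(sets, sources)


@dataclass
class KnowledgeMatrix:
    """Binary features x gene-sets membership matrix aligned to the data rows."""

    C: pd.DataFrame                    # features x sets, entries {0, 1}
    overlap_genes: pd.Series           # set -> count of DISTINCT overlapping genes

    @property
    def set_names(self) -> pd.Index:
        return self.C.columns

    @property
    def feature_ids(self) -> pd.Index:
        return self.C.index


def build_feature_knowledge(
    collection: GeneSetCollection,
    feature_gene_map: Mapping[str, str] | pd.Series,
    min_genes: int = 10,
    keep_orphan_features: bool = False,
) -> KnowledgeMatrix:
    """Expand gene-level set membership to the compressed feature space.

    ``C[f, s] = 1`` iff the gene of feature ``f`` belongs to set ``s``; every
    PC feature of every transcript of a gene inherits the gene's
    memberships. Sets whose distinct-gene overlap with the feature space is
    below ``min_genes`` are dropped. By default, features whose gene appears
    in no retained set are dropped too (the data matrix must then be
    filtered identically, see :func:`align_to_knowledge`).
    """
    fg = pd.Series(feature_gene_map)
    fg = fg.astype(str).str.upper()
    set_names = list(collection.sets)
    gene_sets = {name: set(collection.sets[name]) for name in set_names}

    genes_in_space = set(fg.unique())
    overlap = {
        name: len(gene_sets[name] & genes_in_space) for name in set_names
    }
    retained = [name for name in set_names if overlap[name] >= min_genes]
    if not retained:
        raise ValueError("knowledge matrix empty after filtering")

    mat = np.zeros((len(fg), len(retained)), dtype=np.int8)
    for j, name in enumerate(retained):
        member = fg.isin(gene_sets[name]).to_numpy()
        mat[member, j] = 1
    C = pd.DataFrame(mat, index=fg.index, columns=pd.Index(retained, name="gene_set"))

    if not keep_orphan_features:
        C = C.loc[C.to_numpy().any(axis=1)]
    overlap_genes = pd.Series({n: overlap[n] for n in retained}, name="overlap_genes")
    return KnowledgeMatrix(C, overlap_genes)


def align_to_knowledge(data: GeneWiseMatrix, knowledge: KnowledgeMatrix) -> GeneWiseMatrix:
    """Filter a compressed data matrix to the knowledge matrix's feature rows."""
    missing = knowledge.feature_ids.difference(data.feature_ids)
    if len(missing):
        raise ValueError(
            f"{len(missing)} knowledge features absent from the data matrix, "
            f"e.g. {list(missing[:5])}"
        )
    values = data.values.loc[knowledge.feature_ids]
    return GeneWiseMatrix(
        values, data.feature_gene.loc[knowledge.feature_ids], data.n_imputed_probes
    )
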