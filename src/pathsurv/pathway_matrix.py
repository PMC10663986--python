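"""Binary metabolite-to-pathway incidence matrices and their ablation variants.

The incidence matrix masks a network's first layer so a connection exists
only where a metabolite belongs to a pathway. Two ablation constructors
degrade the biological structure while conserving sparsity: ``randomize``
keeps only the total edge count, ``shuffle_rows`` permutes whole
metabolite-to-pathway membership profiles and therefore keeps every
pathway's in-degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pathsurv")


@dataclass
class PathwayMatrix:
    matrix: np.ndarray  # (P, Q) in {0, 1}
    metabolite_names: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        p, q = self.matrix.shape
        if len(self.metabolite_names) != p or len(self.pathway_names) != q:
            raise ValueError("name registries must match matrix shape")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0 or 1")

    @property
    def edge_count(self) -> int:
        return int(self.matrix.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def load_mapping(mapping_path: str | Path, metabolite_order: list[str]) -> PathwayMatrix:
    """Build an incidence matrix from a two-column or GMT-style mapping file.

    Two-column dialect: ``metabolite<TAB>pathway``, one edge per line. GMT
    dialect: ``pathway<TAB>description<TAB>member...``. Rows follow
    ``metabolite_order``; pathways are sorted lexicographically so the result
    is deterministic. Metabolites without any pathway get an all-zero row
    (warned); mapping entries outside ``metabolite_order`` are ignored
    (warned).
    """
    edges: set[tuple[str, str]] = set()
    lines = [
        ln.rstrip("\n") for ln in Path(mapping_path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise ValueError(f"empty mapping file: {mapping_path}")
    is_gmt = any(len(ln.split("\t")) > 2 for ln in lines)
    for ln in lines:
        parts = ln.split("\t")
        if is_gmt:
            pathway, members = parts[0], parts[2:]
            edges.update((m, pathway) for m in members if m)
        else:
            if len(parts) != 2:
                raise ValueError(f"malformed mapping line: {ln!r}")
            edges.add((parts[0], parts[1]))
    known = set(metabolite_order)
    stray = sorted({m for m, _ in edges} - known)
    if stray:
        logger.warning("ignoring %d mapped metabolites not in feature order: %s",
                       len(stray), stray[:5])
    edges = {(m, p) for m, p in edges if m in known}
    if not edges:
        raise ValueError("mapping contains no edges for the given metabolite order")
    pathways = sorted({p for _, p in edges})
    col = {p: j for j, p in enumerate(pathways)}
    row = {m: i for i, m in enumerate(metabolite_order)}
    mat = np.zeros((len(metabolite_order), len(pathways)))
    for m, p in edges:
        mat[row[m], col[p]] = 1.0
    orphan = [m for m in metabolite_order if mat[row[m]].sum() == 0]
    if orphan:
        logger.warning("%d metabolites have no pathway membership: %s",
                       len(orphan), orphan[:5])
    return PathwayMatrix(mat, list(metabolite_order), pathways)


def write_matrix(pm: PathwayMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(pm.matrix.astype(int), index=pm.metabolite_names,
                      columns=pm.pathway_names)
    df.index.name = "metabolite"
    df.to_csv(path, sep=sep)


def randomize(pm: PathwayMatrix, seed: int) -> PathwayMatrix:
    """Edge-count-matched random mask: the same number of ones placed
    uniformly without replacement over the P x Q cells."""
    rng = np.random.default_rng(seed)
    p, q = pm.shape
    flat = np.zeros(p * q)
    flat[rng.choice(p * q, size=pm.edge_count, replace=False)] = 1.0
    return PathwayMatrix(flat.reshape(p, q), list(pm.metabolite_names),
                         list(pm.pathway_names))


def shuffle_rows(pm: PathwayMatrix, seed: int) -> PathwayMatrix:
    """Row-permuted mask: membership profiles are reassigned to metabolites,
    preserving each pathway's in-degree and the multiset of profiles."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pm.shape[0])
    return PathwayMatrix(pm.matrix[perm], list(pm.metabolite_names),
                         list(pm.pathway_names))
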