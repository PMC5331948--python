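"""Presence/absence reduction and the TE beta-diversity (beta) matrix.

The emergent property of TE flow on an HTT network is compositional: which
TE families each genome ends up carrying.  Pairwise differentiation is
measured with the Jaccard distance over family presence/absence sets —
``beta(i,j) = 1 - |F_i & F_j| / |F_i | F_j|`` — the community-ecology
beta-diversity applied to TE content.  ``beta = 0`` means identical TE
content, ``beta = 1`` no shared family.

Hierarchical clustering of the beta matrix orders species so that blocks of
similar TE content (which mirror connected groups in the generating
network) appear as contiguous blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dynamics import SimResult


@dataclass
class PresenceMatrix:
    """Species x family boolean incidence."""

    values: np.ndarray
    species_ids: list[int] = field(default_factory=list)
    family_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not self.species_ids:
            self.species_ids = list(range(1, self.values.shape[0] + 1))
        if not self.family_ids:
            self.family_ids = list(range(1, self.values.shape[1] + 1))
        if self.values.shape != (len(self.species_ids), len(self.family_ids)):
            raise ValueError("presence matrix shape does not match id lists")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.species_ids, columns=self.family_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(dtype=bool),
            [int(i) for i in df.index],
            [int(c) for c in df.columns],
        )


@dataclass
class BetaMatrix:
    """Species x species Jaccard beta-diversity distance matrix."""

    values: np.ndarray
    species_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("beta matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("beta matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("beta matrix must have a zero diagonal")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("beta values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        if not self.species_ids:
            self.species_ids = list(range(1, v.shape[0] + 1))
        if len(self.species_ids) != v.shape[0]:
            raise ValueError("species id list does not match matrix size")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def similarity(self) -> np.ndarray:
        """Jaccard similarity matrix (1 - beta), unit diagonal."""
        s = 1.0 - self.values
        np.fill_diagonal(s, 1.0)
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [int(i) for i in df.index])

    def to_phylip(self, path) -> None:
        """Square phylip-style distance matrix (interoperability export)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_species}\n")
            for i, sid in enumerate(self.species_ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"sp{sid} {row}\n")


def presence_matrix(result: SimResult | np.ndarray, min_copies: int = 1) -> PresenceMatrix:
    """Reduce copy counts to presence/absence at a copy-number threshold."""
    copies = result.copies if isinstance(result, SimResult) else np.asarray(result)
    return PresenceMatrix(copies >= min_copies)


def beta_matrix(p: PresenceMatrix) -> BetaMatrix:
    """Jaccard beta-diversity distance between all species pairs.

    Two genomes with no TE families at all are defined as identical
    (beta 0); an empty genome against a non-empty one is maximally
    differentiated (beta 1).
    """
    if p.n_species < 2:
        raise ValueError("need at least 2 species")
    x = p.values.astype(np.int64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(beta, 0.0)
    return BetaMatrix(beta, list(p.species_ids))


def cluster_order(
    b: BetaMatrix,
    n_blocks: int | None = None,
    *,
    linkage_method: str = "average",
) -> dict:
    """Hierarchically cluster species by TE beta-diversity.

    Agglomerative clustering (average linkage by default) on beta as a
    distance.  Returns the dendrogram leaf order, the block labels obtained
    by cutting into ``n_blocks`` clusters (or, if ``n_blocks`` is None, at
    the largest gap in merge heights), and the linkage matrix.
    """
    n = b.n_species
    d = b.condensed()
    if np.allclose(d, d[0] if d.size else 0.0):
        warnings.warn("degenerate beta matrix (all pairs equal); single block", stacklevel=2)
        return {
            "order": list(b.species_ids),
            "blocks": {sid: 1 for sid in b.species_ids},
            "linkage": None,
        }
    Z = hierarchy.linkage(d, method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    if n_blocks is None:
        heights = Z[:, 2]
        gaps = np.diff(heights)
        # cut just above the merge that precedes the largest height jump
        n_blocks = n - (int(np.argmax(gaps)) + 1) if gaps.size else 1
    labels = hierarchy.fcluster(Z, t=n_blocks, criterion="maxclust")
    return {
        "order": [b.species_ids[i] for i in leaves],
        "blocks": {b.species_ids[i]: int(labels[i]) for i in range(n)},
        "linkage": Z,
    }
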