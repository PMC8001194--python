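"""Microbial relationship matrix.

M = XX'/N, where X is the n x N matrix of standardized, log-transformed OTU
relative abundances and N is the number of OTUs. M plays the role a kinship
matrix plays in quantitative genetics: it is the covariance kernel of the
random microbial animal effect, and because every column of X has sum of
squares n, trace(M) = n exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu_preprocess import ProcessedAbundanceMatrix


@dataclass
class MicrobialRelationshipMatrix:
    """Symmetric n x n sample similarity kernel built from OTU abundances."""

    matrix: np.ndarray
    sample_ids: list[str]
    n_otus_used: int

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def reorder(self, sample_ids: list[str]) -> "MicrobialRelationshipMatrix":
        """Return a copy with rows/columns in the given sample order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MicrobialRelationshipMatrix(
            self.matrix[np.ix_(idx, idx)], list(sample_ids), self.n_otus_used
        )

    def write_tsv(self, path) -> None:
        """Serialize with samples sorted by id; 17 significant digits round-trip."""
        order = np.argsort(self.sample_ids)
        ids = [self.sample_ids[i] for i in order]
        df = pd.DataFrame(self.matrix[np.ix_(order, order)], index=ids, columns=ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, n_otus_used: int = 0) -> "MicrobialRelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(dtype=float), list(df.columns), n_otus_used)


def build_relationship_matrix(
    X: ProcessedAbundanceMatrix,
) -> MicrobialRelationshipMatrix:
    """Compute M = XX'/N from a processed abundance matrix."""
    if X.n_otus < 1:
        raise ValueError("need at least one OTU column")
    M = X.X @ X.X.T / X.n_otus
    M = (M + M.T) / 2.0  # enforce exact symmetry against rounding
    return MicrobialRelationshipMatrix(M, list(X.sample_ids), X.n_otus)
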