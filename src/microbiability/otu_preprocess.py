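"""OTU table containers, filtering, and model-matrix construction.

The analysis consumes an OTU count table (features x samples). Before it can
enter the mixed model, the table is filtered on mean relative abundance,
total-sum scaled, log-transformed with a pseudocount, and column-standardized
so that each OTU column of the model matrix has mean zero and sum of squares
equal to the number of samples. That standardization makes the microbial
relationship matrix M = XX'/N have trace exactly n, which keeps the microbial
variance component on the phenotypic scale.

Trait counts (feather pecks, aggressive pecks, threats delivered) are
Box-Cox transformed toward normality before model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from skbio.diversity import alpha as _alpha


class OtuTableError(ValueError):
    """Invalid OTU table input (empty samples, bad dimensions, duplicates)."""


@dataclass
class OtuTable:
    """Feature-by-sample count table.

    Parameters
    ----------
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative counts (or abundances).
    otu_ids : list of str
        Unique feature identifiers, one per row.
    sample_ids : list of str
        Unique sample (animal) identifiers, one per column.
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.otu_ids = list(map(str, self.otu_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (OTUs x samples)")
        n_otus, n_samples = self.counts.shape
        if n_otus != len(self.otu_ids) or n_samples != len(self.sample_ids):
            raise OtuTableError("identifier lists do not match matrix shape")
        if n_otus < 2 or n_samples < 2:
            raise OtuTableError("need at least 2 OTUs and 2 samples")
        if len(set(self.otu_ids)) != n_otus:
            raise OtuTableError("duplicate OTU identifiers")
        if len(set(self.sample_ids)) != n_samples:
            raise OtuTableError("duplicate sample identifiers")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise OtuTableError("counts must be finite and non-negative")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """Per-sample proportions (total-sum scaling). Errors on empty samples."""
        totals = self.sample_totals()
        if np.any(totals <= 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t <= 0]
            raise OtuTableError(f"samples with zero total count: {bad}")
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(df)

    @classmethod
    def read_biom(cls, path) -> "OtuTable":
        """Read a BIOM feature table (2.x HDF5 or 1.0 JSON dialect)."""
        import json

        import h5py
        from skbio.table import Table

        try:
            with h5py.File(path, "r") as fh:
                t = Table.from_hdf5(fh)
        except OSError:
            with open(path) as fh:
                t = Table.from_json(json.load(fh))
        counts = np.asarray(t.matrix_data.todense())  # observations x samples
        return cls(counts, list(t.ids("observation")), list(t.ids("sample")))


@dataclass
class ProcessedAbundanceMatrix:
    """Standardized log relative abundances, samples x OTUs.

    Each column is centered and scaled with the population (÷n) standard
    deviation so its sum of squares equals the number of samples.
    """

    X: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    transform_log: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_otus(self) -> int:
        return self.X.shape[1]


def filter_otus(table: OtuTable, min_mean_rel_abund: float = 1e-6) -> OtuTable:
    """Keep OTUs whose mean relative abundance strictly exceeds a threshold.

    The mean is taken over per-sample proportions. The default threshold of
    1e-6 corresponds to a mean abundance of 0.0001%.
    """
    if not (0 <= min_mean_rel_abund < 1):
        raise ValueError("min_mean_rel_abund must lie in [0, 1)")
    mean_rel = table.relative_abundances().mean(axis=1)
    keep = mean_rel > min_mean_rel_abund
    if not keep.any():
        raise OtuTableError("filter removed every OTU")
    return OtuTable(
        table.counts[keep],
        [o for o, k in zip(table.otu_ids, keep) if k],
        list(table.sample_ids),
    )


def default_pseudocount(table: OtuTable) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    rel = table.relative_abundances()
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise OtuTableError("table has no nonzero counts")
    return float(nonzero.min() / 2.0)


def to_model_matrix(
    table: OtuTable, pseudocount: float | str = "auto"
) -> ProcessedAbundanceMatrix:
    """Build the n x N model matrix X of standardized log relative abundances.

    Steps: total-sum scale each sample to proportions; add a pseudocount and
    take natural logs; center each OTU column and divide by its population
    standard deviation so the column sum of squares is exactly n. Columns
    that are constant across samples carry no information and are dropped
    with a warning.
    """
    if pseudocount == "auto":
        pseudocount = default_pseudocount(table)
    pseudocount = float(pseudocount)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rel = table.relative_abundances()            # (N_otus, n)
    logged = np.log(rel + pseudocount).T         # (n, N_otus)
    n = logged.shape[0]
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)                      # population (÷n) denominator
    informative = sd > 0
    if not informative.all():
        dropped = [o for o, k in zip(table.otu_ids, informative) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant-abundance OTU column(s): "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if not informative.any():
        raise OtuTableError("no informative OTU columns after standardization")
    X = (logged[:, informative] - mean[informative]) / sd[informative]
    return ProcessedAbundanceMatrix(
        X=X,
        otu_ids=[o for o, k in zip(table.otu_ids, informative) if k],
        sample_ids=list(table.sample_ids),
        transform_log={
            "pseudocount": pseudocount,
            "log_base": "e",
            "standardization": "population_sd",
            "n_dropped_constant": int((~informative).sum()),
        },
    )


def boxcox_transform(values, lam: float | str = "mle"):
    """Box-Cox transform a positive vector.

    y(λ) = (y**λ - 1)/λ for λ != 0, log(y) at λ = 0. With ``lam="mle"`` the
    exponent maximizing the Box-Cox profile log-likelihood is estimated.

    Returns
    -------
    (transformed, lambda_used)
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("Box-Cox requires strictly positive finite values")
    if isinstance(lam, str):
        if lam != "mle":
            raise ValueError(f"unknown lambda spec {lam!r}")
        transformed, lam_used = scipy.stats.boxcox(values)
        return transformed, float(lam_used)
    return scipy.special.boxcox(values, float(lam)), float(lam)


def transform_traits(
    traits: pd.DataFrame,
    trait_names: list[str] | None = None,
    shift: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Box-Cox transform trait count columns after adding a shift.

    Behavioural traits are counts with zeros, so a shift (default +1) is
    applied before the transform. Returns the transformed table and the
    fitted lambda per trait.
    """
    if trait_names is None:
        trait_names = [c for c in traits.columns if c != "animal_id"]
    out = traits.copy()
    lambdas: dict[str, float] = {}
    for name in trait_names:
        raw = traits[name].to_numpy(dtype=float)
        if np.any(raw < 0):
            raise ValueError(f"trait {name!r} has negative values")
        out[name], lambdas[name] = boxcox_transform(raw + shift, "mle")
    return out, lambdas


def diversity_indices(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon diversity (natural log), Pielou evenness, richness.

    Pielou's J = H/ln(S) is undefined when only one OTU is observed and is
    reported as NaN in that case.
    """
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise OtuTableError(f"empty samples: {bad}")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        counts = table.counts[:, j]
        s = int((counts > 0).sum())
        h = float(_alpha.shannon(counts, base=np.e))
        j_even = h / np.log(s) if s > 1 else np.nan
        rows.append({"sample_id": sid, "shannon": h, "pielou": j_even, "richness": s})
    return pd.DataFrame(rows).set_index("sample_id")
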