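"""Synthetic hen gut-microbiome datasets with known ground truth.

Emulates the statistical structure the microbiability analysis assumes: two
selection lines (high / low feather pecking) whose gut communities diverge in
composition, overdispersed compositional OTU counts per animal, and
behavioural traits generated as y = Xb + m + e where the microbial effect m
is drawn with covariance sigma2_m * M and M is built from the simulated OTU
table itself — so the ground-truth microbiability sigma2_m/(sigma2_m +
sigma2_e_l) is identifiable by construction.

OTU base compositions come from a log-normal on log relative abundance
(heavy-tailed rank-abundance curve); line divergence is an additive shift on
a random subset of OTU log-means; per-sample compositions are Dirichlet
draws around the line composition and counts are multinomial with a Poisson
library size (Dirichlet-multinomial overdispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .otu_preprocess import OtuTable, filter_otus, to_model_matrix
from .mrm import build_relationship_matrix, MicrobialRelationshipMatrix

TRAITS = ("FPD", "APD", "TD")
_STREAM_COUNTS = 1
_STREAM_TRAITS = 2


class SimulationError(ValueError):
    """Invalid simulation configuration."""


class FactorizationError(RuntimeError):
    """M could not be factorized even after the jitter cap."""


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic dataset.

    Defaults mirror the study conditions: lines HFP and LFP with 96 and 73
    animals (ileum mucosa subset), two experimental runs, library size equal
    to the mean reads per sample (44240), variance components on the scale of
    the reported trait analyses.
    """

    n_animals_per_line: tuple[int, int] = (96, 73)
    lines: tuple[str, str] = ("HFP", "LFP")
    n_otus: int = 200
    n_runs: int = 2
    n_pens: int = 6
    sigma2_m: float = 0.1
    sigma2_e_by_line: dict[str, float] = field(
        default_factory=lambda: {"HFP": 0.8, "LFP": 0.4}
    )
    line_effect: float = 1.0
    pen_effect_sd: float = 0.0
    library_size: float = 44240.0
    composition_divergence: float = 1.0
    divergent_otu_fraction: float = 0.2
    dispersion: float = 50.0
    base_log_abundance_sd: float = 1.5
    section: str = "ileum"
    sample_type: str = "mucosa"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2:
            raise SimulationError("need at least 2 OTUs")
        if any(n < 1 for n in self.n_animals_per_line):
            raise SimulationError("each line needs at least one animal")
        if self.sigma2_m < 0:
            raise SimulationError("sigma2_m must be >= 0")
        for l in self.lines:
            if self.sigma2_e_by_line.get(l, -1) <= 0:
                raise SimulationError(f"sigma2_e for line {l!r} must be > 0")
        if self.library_size < 1:
            raise SimulationError("library_size must be >= 1")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if not (0 <= self.divergent_otu_fraction <= 1):
            raise SimulationError("divergent_otu_fraction must lie in [0, 1]")
        if self.composition_divergence < 0:
            raise SimulationError("composition_divergence must be >= 0")

    def ground_truth_microbiability(self) -> dict[str, float]:
        """True m2 per line implied by the variance components."""
        return {
            l: self.sigma2_m / (self.sigma2_m + self.sigma2_e_by_line[l])
            for l in self.lines
        }

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    otu_table: OtuTable
    metadata: pd.DataFrame
    traits: pd.DataFrame
    true_params: SimulationConfig
    true_m: np.ndarray
    mrm: MicrobialRelationshipMatrix | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Animal ids, line labels, round-robin run and pen assignment."""
    rows = []
    idx = 0
    for line, n in zip(config.lines, config.n_animals_per_line):
        for i in range(n):
            rows.append(
                {
                    "animal_id": f"A{idx:04d}",
                    "line": line,
                    "run": f"run{(i % config.n_runs) + 1}",
                    "pen": f"pen{((i // config.n_runs) % config.n_pens) + 1}",
                    "section": config.section,
                    "sample_type": config.sample_type,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _line_compositions(config: SimulationConfig, rng) -> dict[str, np.ndarray]:
    """Base composition per line: log-normal log-means, shifted subset."""
    mu = rng.normal(0.0, config.base_log_abundance_sd, size=config.n_otus)
    n_div = int(round(config.divergent_otu_fraction * config.n_otus))
    shifted = mu.copy()
    if n_div > 0 and config.composition_divergence > 0:
        which = rng.choice(config.n_otus, size=n_div, replace=False)
        shifted[which] = shifted[which] + config.composition_divergence
    comps = {}
    for line, m in zip(config.lines, (mu, shifted)):
        p = np.exp(m - m.max())
        comps[line] = p / p.sum()
    return comps


def simulate_otu_counts(
    config: SimulationConfig, metadata: pd.DataFrame | None = None
) -> OtuTable:
    """Dirichlet-multinomial OTU counts, one column per animal.

    Per-sample composition ~ Dirichlet(dispersion * p_line); counts are
    multinomial with a Poisson(library_size) total. Deterministic given the
    config seed.
    """
    if metadata is None:
        metadata = simulate_metadata(config)
    rng = _rng(config, _STREAM_COUNTS)
    comps = _line_compositions(config, rng)
    otu_ids = [f"OTU{j + 1}" for j in range(config.n_otus)]
    cols = []
    for line in metadata["line"]:
        alpha = config.dispersion * comps[line]
        # numpy dirichlet degenerates for very small alphas; floor for stability
        alpha = np.maximum(alpha, 1e-10)
        p = rng.dirichlet(alpha)
        p = np.maximum(p, 0)
        p = p / p.sum()
        total = max(int(rng.poisson(config.library_size)), 1)
        cols.append(rng.multinomial(total, p))
    counts = np.column_stack(cols).astype(float)
    return OtuTable(counts, otu_ids, list(metadata["animal_id"].astype(str)))


def factor_relationship_matrix(
    M: np.ndarray, max_doublings: int = 10
) -> np.ndarray:
    """Cholesky factor of M, jittering the diagonal when M is only PSD.

    Starts at delta = 1e-8 * mean(diag M) and doubles at most
    ``max_doublings`` times before raising.
    """
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        pass
    delta = 1e-8 * float(np.mean(np.diag(M)))
    for _ in range(max_doublings + 1):
        try:
            return np.linalg.cholesky(M + delta * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            delta *= 2.0
    raise FactorizationError(
        f"relationship matrix not PSD after jitter up to {delta:g}"
    )


def simulate_traits(
    otu_table: OtuTable,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    min_mean_rel_abund: float = 1e-6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Traits y = Xb + m + e on the model scale, plus the realized m.

    m is drawn once with covariance sigma2_m * M, where M is built from the
    *simulated* table through the same preprocessing the analysis uses; each
    trait receives independent line-heteroscedastic residuals. The line fixed
    effect raises the first (high feather pecking) line by ``line_effect``.
    """
    rng = _rng(config, _STREAM_TRAITS)
    filtered = filter_otus(otu_table, min_mean_rel_abund)
    M = build_relationship_matrix(to_model_matrix(filtered))
    L = factor_relationship_matrix(M.matrix)
    n = len(metadata)
    m = np.sqrt(config.sigma2_m) * (L @ rng.standard_normal(n))

    lines = metadata["line"].to_numpy()
    xb = np.where(lines == config.lines[0], config.line_effect, 0.0)
    if config.pen_effect_sd > 0:
        combo = (metadata["run"].astype(str) + ":" + metadata["pen"].astype(str))
        levels = sorted(combo.unique())
        effects = rng.normal(0.0, config.pen_effect_sd, size=len(levels))
        lookup = dict(zip(levels, effects))
        xb = xb + combo.map(lookup).to_numpy()

    sd_e = np.array([np.sqrt(config.sigma2_e_by_line[l]) for l in lines])
    data = {"animal_id": metadata["animal_id"].astype(str)}
    for trait in TRAITS:
        e = sd_e * rng.standard_normal(n)
        data[trait] = xb + m + e
    return pd.DataFrame(data), m


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: OTU table, metadata, traits, ground truth."""
    metadata = simulate_metadata(config)
    otu_table = simulate_otu_counts(config, metadata)
    traits, m = simulate_traits(otu_table, metadata, config)
    return SyntheticDataset(
        otu_table=otu_table,
        metadata=metadata,
        traits=traits,
        true_params=replace(config),
        true_m=m,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write OTU table, metadata, and traits as TSV; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": str(out / "otu_table.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "traits": str(out / "traits.tsv"),
    }
    dataset.otu_table.write_tsv(paths["otu_table"])
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.traits.to_csv(paths["traits"], sep="\t", index=False)
    return paths
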