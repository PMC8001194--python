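"""End-to-end pipeline: simulate/load -> preprocess -> fit -> community stats.

A run is driven by a single config (YAML-friendly dict). Each gut-section x
sample-type subset is analyzed independently: the OTU table is filtered and
transformed within the subset, the microbial relationship matrix is built,
the microbial mixed model is fitted per trait, and the community statistics
(diversity, PERMANOVA on line, NMDS, SIMPER) are computed. A failure in one
subset x trait cell is recorded and does not abort the other cells.

The report JSON is deterministic for a fixed seed: the provenance block
carries the config hash, seed, and package version; wall-clock timestamps go
to the run log instead so that repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community_ecology import bray_curtis, nmds, permanova, simper
from .microbial_lmm import fit_microbiability
from .mrm import build_relationship_matrix
from .otu_preprocess import (
    OtuTable,
    diversity_indices,
    filter_otus,
    to_model_matrix,
    transform_traits,
)
from .synthetic_data import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger("microbiability.pipeline")

TRAIT_NAMES = ["FPD", "APD", "TD"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: dict | None = None
    otu_table: str | None = None
    metadata: str | None = None
    traits_file: str | None = None
    traits: list[str] = field(default_factory=lambda: list(TRAIT_NAMES))
    subsets: list[dict] | None = None  # [{"section": ..., "sample_type": ...}]
    min_mean_rel_abund: float = 1e-6
    pseudocount: float | str = "auto"
    boxcox: bool = False
    run_pen_alpha: float = 0.05
    n_permutations: int = 999
    nmds_dims: int = 2
    nmds_restarts: int = 20
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def as_dict(self) -> dict:
        return {
            "simulation": self.simulation,
            "otu_table": self.otu_table,
            "metadata": self.metadata,
            "traits_file": self.traits_file,
            "traits": list(self.traits),
            "subsets": self.subsets,
            "min_mean_rel_abund": self.min_mean_rel_abund,
            "pseudocount": self.pseudocount,
            "boxcox": self.boxcox,
            "run_pen_alpha": self.run_pen_alpha,
            "n_permutations": self.n_permutations,
            "nmds_dims": self.nmds_dims,
            "nmds_restarts": self.nmds_restarts,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sub_seed(seed: int, *key: int) -> int:
    """Derived sub-seed so stage order does not perturb other stages."""
    ss = np.random.SeedSequence([int(seed), *key])
    return int(ss.generate_state(1)[0] % (2**31))


def load_inputs(config: RunConfig):
    """Load or simulate (otu_table, metadata, traits)."""
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        ds = simulate_dataset(sim)
        return ds.otu_table, ds.metadata, ds.traits
    if not (config.otu_table and config.metadata and config.traits_file):
        raise ValueError("config needs either a simulation block or input paths")
    for path in (config.otu_table, config.metadata, config.traits_file):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    otu = OtuTable.read_tsv(config.otu_table)
    metadata = pd.read_csv(config.metadata, sep="\t", dtype=str)
    traits = pd.read_csv(config.traits_file, sep="\t")
    missing = {"animal_id", "line"} - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return otu, metadata, traits


def _subset_mask(metadata: pd.DataFrame, subset: dict) -> np.ndarray:
    mask = np.ones(len(metadata), dtype=bool)
    for col, val in subset.items():
        mask &= (metadata[col].astype(str) == str(val)).to_numpy()
    return mask


def analyze_subset(
    otu: OtuTable,
    metadata: pd.DataFrame,
    traits: pd.DataFrame,
    config: RunConfig,
    subset_key: int = 0,
) -> dict:
    """Run model fits and community statistics on one sample subset."""
    result: dict = {"n_animals": otu.n_samples}
    filtered = filter_otus(otu, config.min_mean_rel_abund)
    result["n_otus_after_filter"] = filtered.n_otus
    X = to_model_matrix(filtered, config.pseudocount)
    M = build_relationship_matrix(X)
    result["n_otus_in_model"] = M.n_otus_used

    traits = traits.set_index("animal_id").loc[
        metadata["animal_id"].astype(str)
    ].reset_index()
    if config.boxcox:
        traits, lambdas = transform_traits(traits, config.traits)
        result["boxcox_lambda"] = lambdas

    result["traits"] = {}
    for t_idx, trait in enumerate(config.traits):
        try:
            fit = fit_microbiability(
                traits[trait].to_numpy(float),
                metadata,
                M,
                trait=trait,
                include_run_pen="auto",
                alpha=config.run_pen_alpha,
            )
            result["traits"][trait] = fit.as_dict()
        except Exception as exc:  # keep other cells alive
            logger.exception("fit failed for trait %s", trait)
            result["traits"][trait] = {"error": f"{type(exc).__name__}: {exc}"}

    try:
        div = diversity_indices(filtered)
        result["diversity"] = {
            "mean_shannon": float(div["shannon"].mean()),
            "mean_pielou": float(div["pielou"].mean()),
            "mean_richness": float(div["richness"].mean()),
        }
        D = bray_curtis(filtered)
        perm = permanova(
            D,
            metadata[["line"]],
            terms=["line"],
            n_perm=config.n_permutations,
            seed=_sub_seed(config.seed, 10, subset_key),
        )
        result["permanova"] = {
            "line": {
                "pseudo_F": float(perm.table.loc["line", "pseudo_F"]),
                "p_value": float(perm.table.loc["line", "p_value"]),
                "n_permutations": perm.n_permutations,
            }
        }
        ord_res = nmds(
            D,
            k=config.nmds_dims,
            n_restarts=config.nmds_restarts,
            seed=_sub_seed(config.seed, 11, subset_key),
        )
        result["nmds_stress"] = ord_res.stress
        simp = simper(filtered, metadata["line"].to_numpy())
        result["simper_top5"] = simp.table.head(5)[
            ["otu_id", "contribution", "pct"]
        ].to_dict(orient="records")
        result["simper_overall_dissimilarity"] = simp.overall_dissimilarity
    except Exception as exc:
        logger.exception("community statistics failed")
        result["community_error"] = f"{type(exc).__name__}: {exc}"
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s seed %d", config.config_hash(), config.seed)
        otu, metadata, traits = load_inputs(config)
        if config.simulation is not None:
            from .synthetic_data import SyntheticDataset

            write_dataset(
                SyntheticDataset(otu, metadata, traits, None, np.empty(0)),
                out / "simulated",
            )
        missing_ids = set(metadata["animal_id"].astype(str)) - set(
            traits["animal_id"].astype(str)
        )
        if missing_ids:
            raise ValueError(f"traits missing animals: {sorted(missing_ids)[:5]}")

        subsets = config.subsets
        if subsets is None:
            subsets = [
                {"section": s, "sample_type": t}
                for s in sorted(metadata["section"].unique())
                for t in sorted(metadata["sample_type"].unique())
            ]
        report: dict = {
            "provenance": {
                "package_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "config": config.as_dict(),
            },
            "subsets": {},
        }
        for s_idx, subset in enumerate(subsets):
            key = ", ".join(f"{k}={v}" for k, v in sorted(subset.items()))
            mask = _subset_mask(metadata, subset)
            if mask.sum() < 4:
                report["subsets"][key] = {"error": "fewer than 4 samples"}
                continue
            ids = metadata.loc[mask, "animal_id"].astype(str).tolist()
            sub_otu = OtuTable(
                otu.counts[:, mask], otu.otu_ids, ids
            )
            logger.info("subset %s: %d animals", key, mask.sum())
            report["subsets"][key] = analyze_subset(
                sub_otu,
                metadata.loc[mask].reset_index(drop=True),
                traits,
                config,
                subset_key=s_idx,
            )
        _write_report(report, out)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    # flat TSV mirroring the variance-component table layout
    rows = []
    for subset, res in report["subsets"].items():
        for trait, r in (res.get("traits") or {}).items():
            if "error" in r:
                rows.append({"subset": subset, "trait": trait, "error": r["error"]})
                continue
            full = r["full"]
            lines = sorted(full["sigma2_e"])
            row = {
                "subset": subset,
                "trait": trait,
                "sigma2_m": full["sigma2_m"],
                "se_m": full["se_m"],
            }
            for l in lines:
                row[f"sigma2_e[{l}]"] = full["sigma2_e"][l]
                row[f"se_e[{l}]"] = full["se_e"][l]
                row[f"m2[{l}]"] = r["m2"][l]
            row["D"] = r["D"]
            row["p_value"] = r["p_value"]
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "microbiability_table.tsv", sep="\t", index=False)
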