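"""End-to-end orchestration: simulate -> metrics -> stability -> mixed
models -> piecewise SEM -> cascades.

Every stage boundary is a plain CSV so field data can be substituted for
any stage input.  A run is fully determined by its config and seed; the
config hash and seed are stamped into every output file header line
(lines starting with ``#``, which ``pandas.read_csv(comment="#")``
skips).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascades import bootstrap_cascades, chain_table
from .lmm import fit_response_suite
from .metrics import read_group_map, summarise_tiles, write_group_map
from .psem import SemFit, SemSpec, default_sem_spec, fit_psem, multigroup
from .stability import stability_table, FORMULAE
from .synth import (
    SynthParams,
    counteracting_params,
    generate_design,
    null_params,
    read_covers,
    read_design,
    simulate_covers,
)

logger = logging.getLogger(__name__)

SCENARIOS = {"counteracting": counteracting_params, "null": null_params}

#: analysis-table column -> source column produced by the metric stages
NODE_SOURCES = {
    "richness": "mean_richness",
    "evenness": "mean_evenness",
    "dominant": "mean_dominant_nonnative",
    "consumers": "mean_consumer",
    "native": "mean_native_barnacle",
    "ephemeral": "mean_ephemeral_alga",
    "total_cover": "mean_total_cover",
}

STABILITY_NODES = ["temp_stability", "comp_stability", "pop_stability", "asynchrony", "stat_averaging"]

LMM_RESPONSES = [
    "richness", "evenness", "dominant", "consumers", "native", "ephemeral",
    "temp_stability", "comp_stability", "pop_stability", "asynchrony", "stat_averaging",
]

CASCADE_TARGETS = ["pop_stability", "asynchrony", "comp_stability", "temp_stability"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "csv"
    scenario: str = "counteracting"
    synth: dict = field(default_factory=dict)
    csv: dict = field(default_factory=dict)
    sem: str | None = None  # path to a SemSpec YAML; None = packaged default
    alpha: float = 0.05
    n_boot: int = 300
    seed: int = 0
    multigroup: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def validate(self) -> "RunConfig":
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "synthetic" and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {sorted(SCENARIOS)}")
        if self.mode == "csv" and not {"design", "covers"} <= set(self.csv):
            raise ValueError("csv mode needs csv.design and csv.covers paths")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        return self

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: RunConfig
    design: pd.DataFrame
    covers: pd.DataFrame
    tile_table: pd.DataFrame
    lmm_table: pd.DataFrame
    semfit: SemFit
    chains: pd.DataFrame
    cascades: pd.DataFrame
    outdir: Path
    warnings: list[str]


def _stamp(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hetstab {__version__} config={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def build_tile_table(design: pd.DataFrame, covers: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Merge tile design, time-averaged community metrics and stability
    profiles into the tile-level analysis table (one row per tile)."""
    summaries = summarise_tiles(covers, group_map)
    stab = stability_table(covers)
    table = design.merge(summaries, on="tile_id").merge(stab, on="tile_id")
    table["emersion"] = table["emersion_ratio"]
    for node, src in NODE_SOURCES.items():
        if src in table:
            table[node] = table[src]
    return table


def run(config: RunConfig, outdir, seed: int | None = None) -> RunReport:
    """Execute the full pipeline; all intermediate tables are persisted."""
    config = config.validate()
    if seed is not None:
        config.seed = int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    states = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    sim_seed, boot_seed = int(states[0]), int(states[1])

    # --- stage 1: obtain design + covers -----------------------------------
    if config.mode == "synthetic":
        params = SCENARIOS[config.scenario](seed=sim_seed, **config.synth)
        design = generate_design(
            params.n_transects, params.stations_per_transect, params.emersion_range, seed=sim_seed
        )
        covers = simulate_covers(design, params)
        group_map = params.group_map
    else:
        design = read_design(config.csv["design"])
        covers = read_covers(config.csv["covers"])
        if "group_map" in config.csv:
            group_map = read_group_map(config.csv["group_map"])
        else:
            group_map = dict(SynthParams().taxa)
    _stamp(out / "design.csv", design, config)
    _stamp(out / "covers.csv", covers, config)
    write_group_map(group_map, out / "group_map.csv")

    # --- stage 2: tile-level metrics ---------------------------------------
    table = build_tile_table(design, covers, group_map)
    n_degenerate = int(table[[f"{m}_degenerate" for m in FORMULAE]].any(axis=1).sum())
    if n_degenerate:
        warnings.append(f"{n_degenerate} tiles with degenerate stability metrics excluded from models")
    _stamp(out / "analysis_table.csv", table, config)

    # --- stage 3: heterogeneity x emersion mixed models --------------------
    model_table = table.dropna(subset=[c for c in LMM_RESPONSES if c in table])
    lmm_table = fit_response_suite(model_table, [r for r in LMM_RESPONSES if r in table])
    _stamp(out / "lmm_coefficients.csv", lmm_table, config)

    # --- stage 4: piecewise SEM --------------------------------------------
    spec = SemSpec.from_yaml(Path(config.sem).read_text()) if config.sem else default_sem_spec()
    sem_data = table.dropna(subset=[n for n in spec.nodes if n in table])
    if config.multigroup and spec.group and spec.group in sem_data:
        semfit = multigroup(spec, sem_data, alpha=config.alpha)
    else:
        semfit = fit_psem(spec, sem_data)
    warnings.extend(semfit.warnings)
    _stamp(out / "sem_edges.csv", semfit.edges, config)
    _stamp(out / "sem_claims.csv", semfit.claims, config)
    _stamp(out / "sem_r2.csv", semfit.r2, config)

    # --- stage 5: cascading effects ----------------------------------------
    chains = chain_table(spec, semfit, "heterogeneity", CASCADE_TARGETS, alpha=config.alpha)
    _stamp(out / "chains.csv", chains, config)
    casc = bootstrap_cascades(
        spec, sem_data, "heterogeneity", CASCADE_TARGETS,
        n_boot=config.n_boot, seed=boot_seed, alpha=config.alpha,
    )
    _stamp(out / "cascades.csv", casc, config)

    # --- summary ------------------------------------------------------------
    het_sig = chains[(chains["target"] == "temp_stability") & chains["significant"]]
    net = casc[casc["target"] == "temp_stability"]
    lines = [
        f"hetstab {__version__} run",
        f"config hash: {config.hash()}   seed: {config.seed}",
        f"tiles: {len(design)}   censuses: {covers['census_index'].nunique()}   taxa: {covers['taxon_id'].nunique()}",
        f"Fisher's C = {semfit.fisher_c:.2f}  df = {semfit.fisher_df}  p = {semfit.fisher_p:.4f}",
        f"significant heterogeneity -> temporal-stability chains: {len(het_sig)}",
    ]
    for r in net.itertuples():
        lines.append(
            f"net heterogeneity -> temporal stability ({r.group}): {r.net:+.3f} [{r.lo95:+.3f}, {r.hi95:+.3f}]"
        )
    for w in warnings:
        lines.append(f"warning: {w}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        logger.info(line)

    return RunReport(
        config=config, design=design, covers=covers, tile_table=table,
        lmm_table=lmm_table, semfit=semfit, chains=chains, cascades=casc,
        outdir=out, warnings=warnings,
    )
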