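"""Synthetic rocky-shore community generator.

Emulates the field design this package analyses: paired limestone tiles
(one pitted/"heterogeneous", one flat) at stations spread along an
emersion-stress gradient on several transects, surveyed seasonally by
point-count image subsampling.  Cover dynamics come from a latent Gaussian
state per taxon (logistic emersion response + seasonal sinusoid + AR(1)
noise) pushed through a logistic link to expected percent cover, with
binomial point-count sampling on top.  Ground-truth causal pathways
(refugia, richness-mediated asynchrony, dominant suppression, consumer
suppression) are injected as named, signed dials so that every downstream
stage of the pipeline can be tested against a known causal structure.

Richness is emergent: a taxon whose station-level suitability falls below
the presence threshold records zero cover on that tile, so the
heterogeneity->richness dial acts by lifting marginal taxa above the
threshold, mirroring pit colonisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("dominant_nonnative", "native_barnacle", "consumer", "ephemeral_alga", "other")

#: functional group -> SEM node name
GROUP_NODES = {
    "dominant_nonnative": "dominant",
    "native_barnacle": "native",
    "consumer": "consumers",
    "ephemeral_alga": "ephemeral",
}

ZONES = ("low", "mid", "high")

_DAYS_PER_CENSUS = 91  # seasonal (quarterly) sampling
_CENSUSES_PER_YEAR = 4
_CONSUMER_REF_COVER = 20.0  # % cover at which the consumer dial acts at full strength
_DOMINANT_REF_COVER = 50.0  # % dominant cover at which crowding acts at full strength

#: groups whose suitability the heterogeneity->richness dial lifts
RICHNESS_LIFT_GROUPS = ("native_barnacle", "ephemeral_alga", "other")


@dataclass(frozen=True)
class GroupProfile:
    """Latent-scale response profile of one functional group.

    ``cmax`` is the maximum expected cover (%), reached as the latent state
    grows large.  The emersion response is ``amp * (sigmoid(slope * (e -
    center)) - 1/2)``: positive ``slope`` means the group does better at
    high emersion (barnacles), negative means low-shore taxa (algae,
    consumers).  ``season_phase`` is in years; ephemeral algae peak roughly
    opposite to barnacle recruitment.  ``noise_scale`` multiplies the
    AR(1) innovation SD, making e.g. ephemeral algae intrinsically more
    volatile than the dominant barnacle.
    """

    cmax: float
    center: float
    slope: float
    amp: float
    season_phase: float
    season_scale: float
    noise_scale: float
    offset: float


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "dominant_nonnative": GroupProfile(85.0, 0.55, 5.0, 1.6, 0.60, 0.8, 0.35, 1.0),
    "native_barnacle": GroupProfile(40.0, 0.50, 4.0, 1.4, 0.60, 0.6, 0.8, 0.6),
    "consumer": GroupProfile(25.0, 0.40, -4.0, 1.4, 0.10, 0.5, 0.9, 0.5),
    "ephemeral_alga": GroupProfile(50.0, 0.35, -6.0, 2.0, 0.10, 1.8, 2.0, 0.3),
    "other": GroupProfile(25.0, 0.35, -3.0, 1.2, 0.35, 0.8, 1.0, -0.2),
}

DEFAULT_TAXA: tuple[tuple[str, str], ...] = (
    ("Austrominius_modestus", "dominant_nonnative"),
    ("Semibalanus_balanoides", "native_barnacle"),
    ("Chthamalus_montagui", "native_barnacle"),
    ("Balanus_spp", "native_barnacle"),
    ("Perforatus_perforatus", "native_barnacle"),
    ("Patella_spp", "consumer"),
    ("Nucella_lapillus", "consumer"),
    ("Littorina_spp", "consumer"),
    ("Ulva_spp", "ephemeral_alga"),
    ("Cladophora_sp", "ephemeral_alga"),
    ("Porphyra_dioica", "ephemeral_alga"),
    ("Mytilus_edulis", "other"),
    ("Fucus_juv", "other"),
    ("Sabellaria_alveolata", "other"),
    ("Spirobranchus_spp", "other"),
    ("Actinia_equina", "other"),
    ("Lithothamnion_sp", "other"),
    ("Corallina_officinalis", "other"),
    ("Halichondria_sp", "other"),
    ("Dynamena_sp", "other"),
)

#: default ground-truth pathway dials (latent-scale standardised effects).
#: The counteracting-pathways scenario: positive refugia and
#: richness-mediated links balanced against dominant and consumer
#: suppression.  The heterogeneity->richness dial weakens from low to high
#: shore, the study system's hallmark zone-varying link.
DEFAULT_PATHS: dict[str, float | dict[str, float]] = {
    "heterogeneity->richness": {"low": 0.8, "mid": 0.4, "high": 0.0},
    "heterogeneity->pop_stability": 0.35,
    "heterogeneity->dominant": -1.1,
    "heterogeneity->consumers": -0.9,
    "consumers->ephemeral": -0.8,
    "dominant->pop_stability": 0.65,
}


@dataclass
class SynthParams:
    """Parameters of the synthetic community experiment."""

    n_transects: int = 5
    stations_per_transect: int = 7
    n_censuses: int = 11
    taxa: tuple[tuple[str, str], ...] = DEFAULT_TAXA
    path_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_PATHS))
    seasonal_amplitude: float = 1.0
    ar1_rho: float = 0.45
    noise_sd: float = 0.6
    n_points: int = 500
    seed: int = 0
    emersion_range: tuple[float, float] = (0.1, 0.9)
    profiles: dict[str, GroupProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    suitability_sd: float = 0.7
    presence_threshold: float = 0.0
    taxon_offset_step: float = 0.35

    def validate(self) -> "SynthParams":
        if not abs(self.ar1_rho) < 1:
            raise ValueError("ar1_rho must lie strictly inside (-1, 1)")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.n_censuses < 1 or self.n_transects < 1 or self.stations_per_transect < 1:
            raise ValueError("design counts must be positive")
        groups = {g for _, g in self.taxa}
        unknown = groups - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown functional groups: {sorted(unknown)}")
        for key, val in self.path_coefficients.items():
            vals = val.values() if isinstance(val, dict) else [val]
            if not all(np.isfinite(list(vals))):
                raise ValueError(f"non-finite path coefficient for {key!r}")
        return self

    @property
    def group_map(self) -> dict[str, str]:
        return {t: g for t, g in self.taxa}


def null_params(seed: int = 0, **overrides) -> SynthParams:
    """All treatment pathways switched off (the null scenario)."""
    return replace(SynthParams(seed=seed, path_coefficients={}), **overrides)


def counteracting_params(seed: int = 0, **overrides) -> SynthParams:
    """The default counteracting-pathways scenario."""
    return replace(SynthParams(seed=seed), **overrides)


def generate_design(
    n_transects: int,
    stations_per_transect: int,
    emersion_range=(0.1, 0.9),
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out paired tiles at stations along transects.

    Each station holds exactly two tiles sharing an emersion ratio, one per
    heterogeneity level.  Station emersion spans ``emersion_range`` within
    every transect (evenly spaced plus a small seeded jitter), and stations
    are cut into low/mid/high zone terciles of equal size (+-1).
    """
    lo, hi = float(emersion_range[0]), float(emersion_range[1])
    if not (0 < lo <= hi < 1):
        raise ValueError("emersion_range must be a nonempty interval inside (0, 1)")
    if n_transects < 1 or stations_per_transect < 1:
        raise ValueError("need at least one transect and one station")
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_transects):
        if stations_per_transect == 1:
            base = np.array([(lo + hi) / 2.0])
            jitter = np.zeros(1)
        else:
            base = np.linspace(lo, hi, stations_per_transect)
            spacing = (hi - lo) / (stations_per_transect - 1)
            jitter = rng.uniform(-0.3, 0.3, stations_per_transect) * spacing
        emersion = np.clip(base + jitter, max(lo, 1e-6), min(hi, 1 - 1e-6))
        for s in range(stations_per_transect):
            station = f"t{t + 1:02d}s{s + 1:02d}"
            for het, tag in ((1, "h"), (0, "f")):
                rows.append(
                    dict(
                        tile_id=f"{station}{tag}",
                        station_id=station,
                        transect_id=f"t{t + 1:02d}",
                        heterogeneity=het,
                        emersion_ratio=float(emersion[s]),
                    )
                )
    design = pd.DataFrame(rows)
    stations = (
        design.drop_duplicates("station_id")
        .sort_values(["emersion_ratio", "station_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    chunks = np.array_split(np.arange(len(stations)), 3)
    zone_of = {}
    for zone, idx in zip(ZONES, chunks):
        for i in idx:
            zone_of[stations.loc[i, "station_id"]] = zone
    design["zone"] = design["station_id"].map(zone_of)
    return design.sort_values(["transect_id", "station_id", "heterogeneity"], ascending=[True, True, False]).reset_index(drop=True)


def _resolve(value, zone: str) -> float:
    if isinstance(value, dict):
        return float(value.get(zone, 0.0))
    return float(value)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_covers(design: pd.DataFrame, params: SynthParams) -> pd.DataFrame:
    """Simulate a dense long-format cover table for the given tile design.

    Deterministic for identical (design, params): all randomness flows from
    a single generator keyed by ``params.seed``.
    """
    params = params.validate()
    if len(design) == 0:
        raise ValueError("design is empty")
    rng = np.random.default_rng(params.seed)

    taxa = list(params.taxa)
    n_taxa = len(taxa)
    tiles = design.reset_index(drop=True)
    n_tiles = len(tiles)
    T = params.n_censuses
    paths = params.path_coefficients

    e = tiles["emersion_ratio"].to_numpy(float)
    het = tiles["heterogeneity"].to_numpy(float)
    zone = tiles["zone"].to_numpy(str)
    e_sd = e.std(ddof=1)
    e_std = (e - e.mean()) / e_sd if e_sd > 0 else np.zeros_like(e)

    # per-(taxon, station) suitability noise, shared by the paired tiles
    stations = tiles["station_id"].to_numpy(str)
    ustations, st_idx = np.unique(stations, return_inverse=True)
    delta = rng.normal(0.0, params.suitability_sd, size=(n_taxa, len(ustations)))

    # within-group offset ladder makes some taxa marginal -> emergent richness
    group_rank: dict[str, int] = {}
    suit = np.zeros((n_taxa, n_tiles))
    prof_of = []
    for i, (taxon, group) in enumerate(taxa):
        prof = params.profiles[group]
        prof_of.append(prof)
        rank = group_rank.get(group, 0)
        group_rank[group] = rank + 1
        offset_i = prof.offset - params.taxon_offset_step * rank
        resp = prof.amp * (_sigmoid(prof.slope * (e - prof.center)) - 0.5)
        suit[i] = offset_i + resp + delta[i, st_idx]

    # ground-truth pathway dials acting on the latent scale
    def path_vec(key: str) -> np.ndarray:
        if key not in paths:
            return np.zeros(n_tiles)
        return np.array([_resolve(paths[key], z) for z in zone])

    # the richness dial lifts the suitability of refuge-colonising groups
    # (mussels, polychaetes, non-ephemeral algae, native barnacles) --
    # groups with their own heterogeneity dial are excluded so the knobs
    # stay independent
    lift_idx = [i for i, (_, g) in enumerate(taxa) if g in RICHNESS_LIFT_GROUPS]
    lift = (
        path_vec("heterogeneity->richness") * params.suitability_sd * het
        + path_vec("heterogeneity:emersion->richness") * params.suitability_sd * het * e_std
    )
    suit[lift_idx] += lift[None, :]

    # presence is decided before the group-level heterogeneity dials act:
    # pits change how much cover the dominant and the consumers hold, not
    # whether they occur at all, so the suppression dials do not leak into
    # richness
    present = suit > params.presence_threshold

    for group, node in GROUP_NODES.items():
        shift = (
            path_vec(f"heterogeneity->{node}") * het
            + path_vec(f"emersion->{node}") * e_std
            + path_vec(f"heterogeneity:emersion->{node}") * het * e_std
        )
        gi = [i for i, (_, g) in enumerate(taxa) if g == group]
        suit[gi] += shift[None, :]

    # refugia dial: heterogeneity damps temporal innovations
    refugia = np.exp(-path_vec("heterogeneity->pop_stability") * het)  # (tiles,)

    t_years = np.arange(T) / _CENSUSES_PER_YEAR
    season = np.stack(
        [
            params.seasonal_amplitude
            * p.season_scale
            * np.sin(2 * np.pi * (t_years + p.season_phase))
            for p in prof_of
        ]
    )  # (taxa, T)

    rho = params.ar1_rho
    inn_sd = params.noise_sd * np.array([p.noise_scale for p in prof_of])[:, None]
    u = np.zeros((n_taxa, n_tiles, T))
    stat_sd = inn_sd / np.sqrt(1.0 - rho**2) if abs(rho) > 0 else inn_sd
    u[:, :, 0] = rng.normal(0.0, 1.0, (n_taxa, n_tiles)) * stat_sd
    for t in range(1, T):
        u[:, :, t] = rho * u[:, :, t - 1] + rng.normal(0.0, 1.0, (n_taxa, n_tiles)) * inn_sd

    # the refugia dial damps the whole temporal deviation (seasonal forcing
    # and stochastic noise alike): pits buffer desiccation and thermal
    # extremes, so populations in them track the environment less
    temporal = season[:, None, :] + u  # (taxa, tiles, T)
    cmax = np.array([p.cmax for p in prof_of])[:, None, None]
    dom_idx = [i for i, (_, g) in enumerate(taxa) if g == "dominant_nonnative"]

    eta_dom = suit[dom_idx, :, None] + refugia[None, :, None] * temporal[dom_idx]
    dom_expected = np.where(
        present[dom_idx, :, None], cmax[dom_idx] * _sigmoid(eta_dom), 0.0
    )

    # crowding stabilisation: a space-monopolising dominant damps the
    # fluctuations of everything else on the tile, so dominant-rich tiles
    # have steadier populations
    damp = np.tile(refugia[None, :], (n_taxa, 1))
    crowd_c = path_vec("dominant->pop_stability")
    if np.any(crowd_c != 0) and dom_idx:
        dom_mean = dom_expected.sum(axis=0).mean(axis=1)  # (tiles,)
        crowd = np.exp(-crowd_c * dom_mean / _DOMINANT_REF_COVER)
        others = [i for i in range(n_taxa) if i not in dom_idx]
        damp[others] *= crowd[None, :]

    eta = suit[:, :, None] + damp[:, :, None] * temporal
    expected = np.where(present[:, :, None], cmax * _sigmoid(eta), 0.0)
    if dom_idx:
        expected[dom_idx] = dom_expected

    # consumer grazing suppresses ephemeral algae: it reduces both their
    # expected cover and their temporal volatility (grazing keeps the
    # understorey composition constant), so consumer-rich tiles are
    # compositionally calmer as well as ephemeral-poor
    kappa = np.array([_resolve(paths.get("consumers->ephemeral", 0.0), z) for z in zone])
    if np.any(kappa != 0):
        cons_idx = [i for i, (_, g) in enumerate(taxa) if g == "consumer"]
        eph_idx = [i for i, (_, g) in enumerate(taxa) if g == "ephemeral_alga"]
        if cons_idx and eph_idx:
            cons_total = expected[cons_idx].sum(axis=0)  # (tiles, T)
            factor = np.exp(kappa[:, None] * cons_total / _CONSUMER_REF_COVER)
            graze_damp = np.exp(kappa * cons_total.mean(axis=1) / _CONSUMER_REF_COVER)
            mean_eph = expected[eph_idx].mean(axis=2, keepdims=True)
            expected[eph_idx] = mean_eph + (expected[eph_idx] - mean_eph) * graze_damp[None, :, None]
            expected[eph_idx] *= factor[None, :, :]
    expected = np.clip(expected, 0.0, 100.0)

    counts = rng.binomial(params.n_points, expected / 100.0)
    cover = counts / params.n_points * 100.0

    tile_ids = tiles["tile_id"].to_numpy(str)
    taxon_ids = np.array([t for t, _ in taxa])
    out = pd.DataFrame(
        {
            "tile_id": np.repeat(tile_ids, n_taxa * T),
            "census_index": np.tile(np.arange(T), n_tiles * n_taxa),
            "taxon_id": np.tile(np.repeat(taxon_ids, T), n_tiles),
            "cover": cover.transpose(1, 0, 2).reshape(-1),
        }
    )
    out["census_date"] = out["census_index"] * _DAYS_PER_CENSUS
    out = out[["tile_id", "census_index", "census_date", "taxon_id", "cover"]]
    return out.sort_values(["tile_id", "census_index", "taxon_id"], kind="mergesort").reset_index(drop=True)


def ground_truth(params: SynthParams) -> dict:
    """The signed standardised pathway dials the generator was given.

    Values are returned as declared (scalars, or per-zone maps for
    zone-varying links); downstream parameter-recovery tests compare
    estimated standardised path coefficients against these.
    """
    params.validate()
    return dict(params.path_coefficients)


def implied_indirect(params: SynthParams, source: str, target: str) -> float:
    """Indirect effect of ``source`` on ``target`` implied by the dials:
    the sum over causal chains of the product of chain coefficients.
    Per-zone dials enter as their across-zone mean."""
    import networkx as nx

    g = nx.DiGraph()
    weights = {}
    for key, val in params.path_coefficients.items():
        if ":" in key.split("->")[0]:
            continue  # interaction dials have no single-edge interpretation
        u, v = key.split("->")
        scalar = float(np.mean(list(val.values()))) if isinstance(val, dict) else float(val)
        g.add_edge(u, v)
        weights[(u, v)] = scalar
    if source not in g or target not in g:
        return 0.0
    total = 0.0
    for path in nx.all_simple_paths(g, source, target):
        if len(path) < 3:
            continue  # indirect = chains with at least one intermediate node
        prod = 1.0
        for uu, vv in zip(path[:-1], path[1:]):
            prod *= weights[(uu, vv)]
        total += prod
    return total


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def write_covers(covers: pd.DataFrame, path) -> None:
    covers.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_covers(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"tile_id", "census_index", "taxon_id", "cover"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cover table missing columns: {sorted(missing)}")
    return df
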