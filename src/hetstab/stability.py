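"""Per-tile temporal stability decomposition.

Five related metrics are computed from each tile's taxon x census cover
matrix, all after removing a linear trend in census index from every
taxon's series (and consequently from the total, since ordinary
least-squares detrending is additive):

- temporal stability   TS  = mu_T / sd(total residuals)   (inverse CV)
- population stability PS  = sum_i mu_i / sum_i sigma_i
- synchrony            phi = sd(total residuals)^2 / (sum_i sigma_i)^2,
  asynchrony = 1 - phi   (Loreau & de Mazancourt variance ratio)
- statistical averaging SA = sum_i sigma_i / sqrt(sum_i sigma_i^2)
- compositional stability CS = 1 - mean Bray-Curtis dissimilarity between
  consecutive censuses, on raw covers.

Means use the raw series; SDs use detrended residuals with the n-1
denominator.  The algebraic identity TS = PS * phi^(-1/2) holds exactly
because the same residuals enter every term.  Tiles where a metric is
undefined (zero variance, empty censuses) are reported as NaN with a flag
rather than as infinities.

Each metric is looked up through the FORMULAE registry so an alternative
operationalisation can be swapped in without touching callers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

logger = logging.getLogger(__name__)

METRICS = ("temp_stability", "comp_stability", "pop_stability", "synchrony", "asynchrony", "stat_averaging")

#: a residual SD below this fraction of the series scale counts as zero
#: (detrending a constant series leaves float-noise residuals)
_SD_EPS = 1e-10


def _effective_sd(sd, scale):
    """Zero out SDs that are pure floating-point residue."""
    return np.where(sd <= _SD_EPS * np.maximum(1.0, np.abs(scale)), 0.0, sd)


def detrend(series) -> tuple[np.ndarray, tuple[float, float]]:
    """OLS-detrend a per-census series; returns (residuals, (intercept, slope))."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("detrending needs a 1-d series with at least 3 censuses")
    t = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    return resid, (float(intercept), float(slope))


def _residual_matrix(matrix: np.ndarray) -> np.ndarray:
    """Per-taxon detrended residuals; rows = censuses, cols = taxa."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a census x taxon matrix")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 censuses")
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        out[:, j] = detrend(m[:, j])[0]
    return out


def temporal_stability(series) -> float:
    """Inverse CV of the series: raw mean over detrended residual SD."""
    y = np.asarray(series, dtype=float)
    resid, _ = detrend(y)
    mu = y.mean()
    sd = float(_effective_sd(resid.std(ddof=1), mu))
    if mu <= 0:
        raise ValueError("temporal stability needs a positive mean")
    if sd == 0:
        return float("nan")
    return float(mu / sd)


def population_stability(matrix) -> float:
    """Aggregate species-level stability: sum of means over sum of SDs."""
    m = np.asarray(matrix, dtype=float)
    resid = _residual_matrix(m)
    mus = m.mean(axis=0)
    if not np.any(mus > 0):
        raise ValueError("population stability needs at least one taxon with positive mean")
    sigmas = _effective_sd(resid.std(axis=0, ddof=1), mus)
    denom = sigmas.sum()
    if denom == 0:
        return float("nan")
    return float(mus.sum() / denom)


def synchrony_phi(matrix) -> tuple[float, float]:
    """Variance-ratio synchrony phi and asynchrony = 1 - phi."""
    m = np.asarray(matrix, dtype=float)
    resid = _residual_matrix(m)
    sigmas = _effective_sd(resid.std(axis=0, ddof=1), m.mean(axis=0))
    if np.count_nonzero(sigmas > 0) < 1:
        return float("nan"), float("nan")
    total_sd = float(_effective_sd(resid.sum(axis=1).std(ddof=1), m.sum(axis=1).mean()))
    denom = sigmas.sum() ** 2
    phi = float(total_sd**2 / denom)
    phi = min(max(phi, 0.0), 1.0)
    return phi, 1.0 - phi


def statistical_averaging(matrix) -> float:
    """Portfolio effect: sum sigma_i / sqrt(sum sigma_i^2); in [1, sqrt(S)]."""
    m = np.asarray(matrix, dtype=float)
    resid = _residual_matrix(m)
    sigmas = _effective_sd(resid.std(axis=0, ddof=1), m.mean(axis=0))
    ssq = np.sum(sigmas**2)
    if ssq == 0:
        return float("nan")
    return float(sigmas.sum() / np.sqrt(ssq))


def compositional_stability(matrix) -> float:
    """1 - mean Bray-Curtis dissimilarity between consecutive censuses."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("compositional stability needs at least 2 censuses")
    dis = []
    for a, b in zip(m[:-1], m[1:]):
        if a.sum() == 0 and b.sum() == 0:
            continue  # nothing present in either census
        dis.append(braycurtis(a, b))
    if not dis:
        return float("nan")
    return float(1.0 - np.mean(dis))


FORMULAE = {
    "temp_stability": temporal_stability,
    "pop_stability": population_stability,
    "synchrony": synchrony_phi,
    "stat_averaging": statistical_averaging,
    "comp_stability": compositional_stability,
}


def stability_profile(matrix) -> dict[str, float]:
    """All five metrics for one tile's census x taxon cover matrix.

    Degenerate metrics come back as NaN with a matching ``*_degenerate``
    flag; the tile itself is never rejected.  The identity
    TS = PS * phi^(-1/2) is asserted internally on non-degenerate tiles.
    """
    m = np.asarray(matrix, dtype=float)
    out: dict[str, float] = {}

    def guard(name, func, *a):
        try:
            return func(*a)
        except ValueError:
            logger.info("degenerate %s", name)
            return float("nan")

    total = m.sum(axis=1)
    out["temp_stability"] = guard("temp_stability", FORMULAE["temp_stability"], total)
    out["pop_stability"] = guard("pop_stability", FORMULAE["pop_stability"], m)
    try:
        phi, asyn = FORMULAE["synchrony"](m)
    except ValueError:
        logger.info("degenerate synchrony")
        phi, asyn = float("nan"), float("nan")
    out["synchrony"], out["asynchrony"] = phi, asyn
    out["stat_averaging"] = guard("stat_averaging", FORMULAE["stat_averaging"], m)
    out["comp_stability"] = guard("comp_stability", FORMULAE["comp_stability"], m)
    for k in list(out):
        out[f"{k}_degenerate"] = bool(np.isnan(out[k]))

    ts, ps = out["temp_stability"], out["pop_stability"]
    if not any(np.isnan([ts, ps, phi])) and phi > 0:
        assert abs(ts - ps / np.sqrt(phi)) <= 1e-8 * max(1.0, abs(ts)), (
            "stability decomposition identity violated"
        )
    return out


def stability_table(cover_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tile stability profiles from a dense long-format cover table."""
    rows = []
    for tile_id, sub in cover_table.groupby("tile_id", sort=True):
        wide = sub.pivot_table(index="census_index", columns="taxon_id", values="cover", aggfunc="sum")
        prof = stability_profile(wide.to_numpy(float))
        prof["tile_id"] = tile_id
        rows.append(prof)
    table = pd.DataFrame(rows)
    n_deg = int(table[[f"{m}_degenerate" for m in FORMULAE]].any(axis=1).sum())
    if n_deg:
        logger.warning("%d tiles have at least one degenerate stability metric", n_deg)
    cols = ["tile_id"] + [c for c in table.columns if c != "tile_id"]
    return table[cols]
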