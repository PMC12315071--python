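"""Time-averaged per-tile community descriptors.

Richness, Pielou evenness and functional-group covers are computed per
census and then averaged with equal census weights, which is the
mean-over-time-then-model convention used throughout the pipeline.
Evenness is undefined on censuses with fewer than two taxa present; such
censuses are excluded from the average rather than substituted, because
either substitution (0 or 1) would bias sparse high-shore tiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def richness(cover_vector) -> int:
    """Number of taxa with strictly positive cover."""
    v = np.asarray(cover_vector, dtype=float)
    if np.any(v < 0):
        raise ValueError("covers must be nonnegative")
    return int(np.count_nonzero(v > 0))


def pielou_evenness(cover_vector) -> float:
    """Pielou J = H' / ln(S) on the taxa present; NaN when S <= 1."""
    v = np.asarray(cover_vector, dtype=float)
    if np.any(v < 0):
        raise ValueError("covers must be nonnegative")
    present = v[v > 0]
    s = len(present)
    if s <= 1:
        return float("nan")
    h = stats.entropy(present / present.sum())
    return float(h / np.log(s))


def group_cover(cover_vector, taxa, group_map: dict[str, str]) -> dict[str, float]:
    """Sum covers within functional groups; unmapped taxa are an error."""
    v = np.asarray(cover_vector, dtype=float)
    out: dict[str, float] = {g: 0.0 for g in set(group_map.values())}
    for taxon, cov in zip(taxa, v):
        if taxon not in group_map:
            raise KeyError(f"taxon {taxon!r} has no functional group assignment")
        out[group_map[taxon]] += float(cov)
    return out


def _census_pivot(sub: pd.DataFrame) -> pd.DataFrame:
    return sub.pivot_table(index="census_index", columns="taxon_id", values="cover", aggfunc="sum")


def summarise_tiles(cover_table: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Per-tile time averages of richness, evenness and group covers.

    Expects a dense long-format cover table (explicit zeros).  Returns one
    row per tile with ``mean_richness``, ``mean_evenness`` (NaN if no
    census had two or more taxa), one ``mean_<group>`` column per group in
    ``group_map`` and ``mean_total_cover``.
    """
    unmapped = set(cover_table["taxon_id"].unique()) - set(group_map)
    if unmapped:
        raise KeyError(f"taxa without functional group assignment: {sorted(unmapped)}")
    groups = sorted(set(group_map.values()))
    rows = []
    for tile_id, sub in cover_table.groupby("tile_id", sort=True):
        wide = _census_pivot(sub)
        if wide.shape[0] == 0:
            raise ValueError(f"tile {tile_id!r} has no censuses")
        mat = wide.to_numpy(float)
        taxa = list(wide.columns)
        rich = [richness(row) for row in mat]
        even = [pielou_evenness(row) for row in mat]
        gsum = {g: 0.0 for g in groups}
        for row in mat:
            for g, val in group_cover(row, taxa, group_map).items():
                gsum[g] += val
        n_cens = mat.shape[0]
        rec = {
            "tile_id": tile_id,
            "mean_richness": float(np.mean(rich)),
            "mean_evenness": float(np.nanmean(even)) if not np.all(np.isnan(even)) else float("nan"),
            "mean_total_cover": float(mat.sum(axis=1).mean()),
            "n_censuses": n_cens,
        }
        for g in groups:
            rec[f"mean_{g}"] = gsum[g] / n_cens
        rows.append(rec)
    return pd.DataFrame(rows)


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"taxon_id", "group"} <= set(df.columns):
        raise ValueError("group map CSV needs columns taxon_id, group")
    return dict(zip(df["taxon_id"], df["group"]))


def write_group_map(group_map: dict[str, str], path) -> None:
    pd.DataFrame(sorted(group_map.items()), columns=["taxon_id", "group"]).to_csv(path, index=False)
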