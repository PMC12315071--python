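"""Cascading (indirect) effects along causal chains.

The net effect of a source variable (substrate heterogeneity) on a target
(a stability metric) is the sum over all directed chains of the product of
standardised path coefficients, with a chain contributing only when every
edge on it is significant at ``alpha``.  ``alpha = 1`` disables the
masking, in which case the net effect equals the path-tracing geometric
series of the SPC matrix.  Uncertainty comes from a cluster bootstrap that
resamples stations (keeping tile pairs intact) and refits the SEM's
component models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .psem import SemFit, SemSpec, fit_psem, multigroup, validate_spec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathChain:
    nodes: tuple[str, ...]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))

    def __len__(self) -> int:
        return len(self.nodes) - 1


@dataclass
class CascadeEffect:
    source: str
    target: str
    group: str
    direct: float
    indirect: float
    net: float
    n_chains: int
    n_contributing: int
    lo95: float = field(default=float("nan"))
    hi95: float = field(default=float("nan"))


def enumerate_chains(spec: SemSpec, source: str, target: str) -> list[PathChain]:
    """All simple directed chains source -> ... -> target, in deterministic
    lexicographic order."""
    validate_spec(spec)
    if source == target:
        raise ValueError("source and target must differ")
    for n in (source, target):
        if n not in spec.nodes:
            raise ValueError(f"unknown node {n!r}")
    g = spec.graph()
    paths = sorted(tuple(p) for p in nx.all_simple_paths(g, source, target))
    return [PathChain(nodes=p) for p in paths]


def cascade_effect(
    chains: list[PathChain],
    semfit: SemFit,
    alpha: float = 0.05,
    group: str = "all",
) -> CascadeEffect:
    """Sum of products of significant SPCs over the chains.

    A chain contributes its SPC product only if every edge on it has
    p < alpha; the single-edge chain (if present) is the direct effect and
    multi-edge chains sum into the indirect effect.
    """
    stats = semfit.edge_stats(group)
    direct = indirect = 0.0
    n_contrib = 0
    source = target = None
    for chain in chains:
        source, target = chain.nodes[0], chain.nodes[-1]
        prod, significant = 1.0, True
        for edge in chain.edges:
            if edge not in stats:
                raise KeyError(f"no fitted statistics for edge {edge[0]}->{edge[1]}")
            st = stats[edge]
            prod *= st["spc"]
            if not (np.isfinite(st["p"]) and st["p"] < alpha):
                significant = False
        if not significant:
            continue
        n_contrib += 1
        if len(chain) == 1:
            direct += prod
        else:
            indirect += prod
    return CascadeEffect(
        source=source or "", target=target or "", group=group,
        direct=direct, indirect=indirect, net=direct + indirect,
        n_chains=len(chains), n_contributing=n_contrib,
    )


def chain_table(spec: SemSpec, semfit: SemFit, source: str, targets: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Per-chain report: nodes, SPC product, and whether every edge is
    significant, for each (group, target)."""
    rows = []
    for target in targets:
        chains = enumerate_chains(spec, source, target)
        for grp in semfit.groups:
            stats = semfit.edge_stats(grp)
            for chain in chains:
                prod, significant = 1.0, True
                for edge in chain.edges:
                    st = stats[edge]
                    prod *= st["spc"]
                    significant &= bool(np.isfinite(st["p"]) and st["p"] < alpha)
                rows.append(
                    dict(
                        group=grp, target=target, chain=" -> ".join(chain.nodes),
                        length=len(chain), product=prod, significant=significant,
                    )
                )
    return pd.DataFrame(rows)


def _resample_stations(data: pd.DataFrame, rng: np.random.Generator, stratify: str | None) -> pd.DataFrame:
    """Cluster bootstrap over stations; paired tiles travel together.
    Resampled stations are relabelled so repeats count as distinct
    clusters."""
    parts = []
    if stratify and stratify in data:
        strata = [sub for _, sub in data.groupby(data[stratify].astype(str), sort=True)]
    else:
        strata = [data]
    for sub in strata:
        stations = np.sort(sub["station_id"].astype(str).unique())
        picks = rng.choice(stations, size=len(stations), replace=True)
        for k, st in enumerate(picks):
            block = sub[sub["station_id"].astype(str) == st].copy()
            block["station_id"] = f"{st}_b{k}"
            parts.append(block)
    return pd.concat(parts, ignore_index=True)


def bootstrap_cascades(
    spec: SemSpec,
    data: pd.DataFrame,
    source: str,
    targets: list[str],
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    group: str | None = "auto",
    df_method: str = "residual",
) -> pd.DataFrame:
    """Net cascading effects with percentile 95% bootstrap intervals.

    Resamples stations (within zone when a grouping variable is active),
    refits the component models (d-separation tests are not needed for
    path tracing) and recomputes every net effect.  Replicate fits use
    residual-df p values for the significance mask (the cheap
    approximation is immaterial to the percentile interval); failed
    replicates are skipped and counted, and more than 20% failures raises
    a warning flag in the output.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if group == "auto":
        group = spec.group
    grouped = bool(group and group in data)
    if grouped:
        base = multigroup(spec, data, group=group, alpha=alpha, dsep=False, df_method=df_method)
        freed = {
            (r.source, r.target) for r in base.edges[base.edges["free"]].itertuples()
        }
        fit_once = lambda d: multigroup(  # noqa: E731
            spec, d, group=group, alpha=alpha, dsep=False,
            df_method=df_method, freed_edges=freed,
        )
    else:
        fit_once = lambda d: fit_psem(spec, d, dsep=False, df_method=df_method)  # noqa: E731
        base = fit_once(data)
    chains = {t: enumerate_chains(spec, source, t) for t in targets}
    groups = base.groups

    rows = []
    for target in targets:
        for grp in groups:
            eff = cascade_effect(chains[target], base, alpha=alpha, group=grp)
            eff.source, eff.target = source, target
            rows.append(eff)

    rng = np.random.default_rng(seed)
    draws: dict[tuple[str, str], list[float]] = {(e.target, e.group): [] for e in rows}
    n_fail = 0
    for _ in range(n_boot):
        sample = _resample_stations(data, rng, stratify=group)
        try:
            bfit = fit_once(sample)
            for target in targets:
                for grp in groups:
                    use = grp if grp in bfit.groups else "all"
                    eff = cascade_effect(chains[target], bfit, alpha=alpha, group=use)
                    draws[(target, grp)].append(eff.net)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_fail += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if n_fail > 0.2 * n_boot:
        logger.warning("%d of %d bootstrap replicates failed", n_fail, n_boot)

    out = []
    for eff in rows:
        vals = np.asarray(draws[(eff.target, eff.group)])
        if vals.size:
            eff.lo95, eff.hi95 = np.percentile(vals, [2.5, 97.5])
        out.append(
            dict(
                group=eff.group, source=eff.source or source, target=eff.target,
                direct=eff.direct, indirect=eff.indirect, net=eff.net,
                lo95=eff.lo95, hi95=eff.hi95,
                n_chains=eff.n_chains, n_contributing=eff.n_contributing,
                n_boot_ok=int(n_boot - n_fail), n_boot_failed=n_fail,
            )
        )
    return pd.DataFrame(out)
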