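"""Pathway activation scores and greedy correlation clustering.

A pathway activation score is the per-sample sum of HC-scaled adjusted
analyte values over the pathway's members, each multiplied by a +/-1
directionality inferred from the data itself: the sign of the member's
Spearman correlation with an anchor outcome (e.g. global MS disability),
or the sign of its median group difference for two-group anchors.  Summing
direction-aligned z-scaled members amplifies a shared signal relative to
any single member's noise.

Somamers that are significant but belong to no known pathway are grouped by
a greedy complete-linkage-style clustering on absolute Spearman
correlation: the strongest-correlated unassigned pair (|rho| >= 0.7) seeds
a cluster, which then accretes, one at a time, the candidate with the
highest minimum |rho| to all current members while that minimum stays
>= 0.5.  Accretion order is made deterministic by (|rho| descending,
somamer ID ascending) tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PathwayDefinition:
    name: str
    members: list[str]
    directionality: dict[str, int] = field(default_factory=dict)
    anchor: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class ClusterDefinition:
    cluster_id: str
    members: list[str]            # accretion order; first two are the seed
    seed_pair: tuple[str, str]
    seed_rho: float


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one pathway per line, tab-separated name, description, members."""
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        out[parts[0]] = [p for p in parts[2:] if p]
    return out


def write_gmt(path: str | Path, pathways: dict[str, list[str]],
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in pathways.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc] + list(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def infer_directionality(adjusted: pd.DataFrame, members: list[str],
                         anchor: pd.Series,
                         anchor_kind: str = "outcome") -> dict[str, int]:
    """Per-member +/-1 direction from the anchor.

    ``anchor_kind="outcome"``: sign of Spearman rho with a continuous
    outcome.  ``anchor_kind="groups"``: sign of the median difference
    between the two group levels (second minus first in sorted order).
    Zero correlations or constant members default to +1 with a warning.
    """
    directions: dict[str, int] = {}
    common = adjusted.index.intersection(anchor.dropna().index)
    for m in members:
        if m not in adjusted.columns:
            continue
        v = adjusted.loc[common, m].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"member {m!r} is constant; direction set to +1")
            directions[m] = 1
            continue
        if anchor_kind == "outcome":
            rho = stats.spearmanr(v, anchor.loc[common].to_numpy()).statistic
            val = rho
        elif anchor_kind == "groups":
            g = anchor.loc[common]
            levels = sorted(pd.unique(g))
            if len(levels) != 2:
                raise ValueError("group anchor must have exactly 2 levels")
            val = (np.median(v[(g == levels[1]).to_numpy()])
                   - np.median(v[(g == levels[0]).to_numpy()]))
        else:
            raise ValueError(f"unknown anchor kind {anchor_kind!r}")
        if val == 0 or not np.isfinite(val):
            warnings.warn(f"member {m!r} has zero/undefined association; "
                          "direction set to +1")
            directions[m] = 1
        else:
            directions[m] = 1 if val > 0 else -1
    return directions


def score_pathways(adjusted: pd.DataFrame,
                   definitions: list[PathwayDefinition]) -> pd.DataFrame:
    """Sample x pathway score matrix: sum of direction-weighted members."""
    scores = {}
    for d in definitions:
        present = [m for m in d.members if m in adjusted.columns]
        absent = set(d.members) - set(present)
        if absent:
            warnings.warn(f"pathway {d.name!r}: {len(absent)} members "
                          "missing from the matrix; skipped")
        if not present:
            continue
        dirs = np.array([d.directionality.get(m, 1) for m in present],
                        dtype=float)
        scores[d.name] = adjusted[present].to_numpy(dtype=float) @ dirs
    return pd.DataFrame(scores, index=adjusted.index)


def _abs_spearman(adjusted: pd.DataFrame,
                  candidates: list[str]) -> pd.DataFrame:
    vals = adjusted[candidates].to_numpy(dtype=float)
    if vals.shape[1] == 2:
        rho = stats.spearmanr(vals[:, 0], vals[:, 1]).statistic
        mat = np.array([[1.0, rho], [rho, 1.0]])
    else:
        mat = stats.spearmanr(vals).statistic
    return pd.DataFrame(np.abs(mat), index=candidates, columns=candidates)


def greedy_cluster(adjusted: pd.DataFrame, candidates: list[str],
                   seed_thresh: float = 0.7,
                   member_thresh: float = 0.5) -> list[ClusterDefinition]:
    """Greedy correlation clusters among pathway-orphaned somamers.

    Candidates are processed in sorted-ID order so the output is invariant
    to input ordering; each somamer joins at most one cluster.
    """
    pool = sorted(c for c in set(candidates) if c in adjusted.columns)
    if len(pool) < 2:
        return []
    rho = _abs_spearman(adjusted, pool)
    clusters: list[ClusterDefinition] = []
    while len(pool) >= 2:
        # strongest remaining pair; ties broken by ID pair
        best_pair, best_val = None, -1.0
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                v = rho.at[a, b]
                if v > best_val + 1e-15:
                    best_pair, best_val = (a, b), v
        if best_val < seed_thresh:
            break
        members = list(best_pair)
        remaining = [c for c in pool if c not in members]
        while remaining:
            best_c, best_min = None, -1.0
            for c in remaining:
                mn = min(rho.at[c, m] for m in members)
                if mn > best_min + 1e-15:
                    best_c, best_min = c, mn
            if best_min < member_thresh:
                break
            members.append(best_c)
            remaining.remove(best_c)
        clusters.append(ClusterDefinition(
            cluster_id=f"CLUSTER_{len(clusters) + 1:02d}",
            members=members, seed_pair=best_pair,
            seed_rho=float(rho.at[best_pair[0], best_pair[1]])))
        pool = [c for c in pool if c not in set(members)]
    return clusters


def clusters_to_definitions(clusters: list[ClusterDefinition],
                            adjusted: pd.DataFrame, anchor: pd.Series,
                            anchor_kind: str = "outcome"
                            ) -> list[PathwayDefinition]:
    """Attach anchor-inferred directionality so clusters score like pathways."""
    defs = []
    for c in clusters:
        dirs = infer_directionality(adjusted, c.members, anchor, anchor_kind)
        defs.append(PathwayDefinition(name=c.cluster_id, members=c.members,
                                      directionality=dirs,
                                      anchor=str(anchor.name or "")))
    return defs
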