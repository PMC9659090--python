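"""Co-migrating / co-isolated peptide groups and their drift-time resolution.

Two peptides that leave the capillary within the co-migration tolerance
AND fall inside the same quadrupole isolation window (co-isolation
tolerance on precursor m/z) produce chimeric fragmentation spectra
unless a further dimension separates them. This module finds such
groups — connected components of the graph whose edges join record
pairs within both tolerances — and counts which member pairs the drift
tube resolves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class CoClusterConfig:
    """Tolerances: co-migration (min), co-isolation (Th), resolution (ms).

    Comparisons are inclusive ("not more than" reads as <=). A member
    pair counts as resolved when its drift times differ by at least
    ``dt_resolution``.
    """

    mt_tol: float = 0.1
    mz_tol: float = 0.001
    dt_resolution: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mt_tol", "mz_tol", "dt_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CoCluster:
    """One transitive-closure group of co-migrating + co-isolated records."""

    indices: list[int]
    members: pd.DataFrame
    pairwise_dt_gaps: list[float] = field(default_factory=list)
    pairs_total: int = 0
    pairs_resolved: int = 0
    pairs_unassessable: int = 0
    n_species: int = 0
    fully_resolved: bool = False

    @property
    def size(self) -> int:
        return len(self.indices)


def _within(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol


def find_coclusters(records: pd.DataFrame, cfg: CoClusterConfig | None = None) -> list[CoCluster]:
    """Connected components under joint mt/mz tolerance; singletons dropped.

    Candidate pairs are pre-filtered with a sort on m/z, so only the
    sliding window within ``mz_tol`` is tested pairwise.
    """
    cfg = cfg or CoClusterConfig()
    for col in ("mt", "mz"):
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    mz = records["mz"].to_numpy(dtype=float)
    mt = records["mt"].to_numpy(dtype=float)
    order = sorted(range(n), key=lambda i: mz[i])
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if mz[j] - mz[i] > cfg.mz_tol:
                break
            if _within(mt[i], mt[j], cfg.mt_tol):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        CoCluster(indices=sorted(g), members=records.iloc[sorted(g)])
        for g in groups.values()
        if len(g) >= 2
    ]
    clusters.sort(key=lambda c: c.indices[0])
    return clusters


def _count_species(dts: list[float], threshold: float) -> int:
    """Distinct resolvable species: single-linkage components on the dt axis."""
    if not dts:
        return 0
    dts = sorted(dts)
    species = 1
    for prev, cur in zip(dts, dts[1:]):
        if cur - prev >= threshold:
            species += 1
    return species


def assess_resolution(
    clusters: list[CoCluster], cfg: CoClusterConfig | None = None
) -> pd.DataFrame:
    """Count drift-resolved member pairs per cluster (mutates the clusters).

    A pair with a missing drift time is reported unassessable, never
    resolved. Returns a per-cluster summary table.
    """
    cfg = cfg or CoClusterConfig()
    rows = []
    for ci, cluster in enumerate(clusters):
        dts = cluster.members["dt"].tolist() if "dt" in cluster.members else []
        gaps: list[float] = []
        resolved = unassessable = 0
        total = cluster.size * (cluster.size - 1) // 2
        for a in range(cluster.size):
            for b in range(a + 1, cluster.size):
                da, db = dts[a], dts[b]
                if da is None or db is None or math.isnan(da) or math.isnan(db):
                    unassessable += 1
                    continue
                gap = abs(da - db)
                gaps.append(gap)
                if gap >= cfg.dt_resolution:
                    resolved += 1
        valid_dts = [d for d in dts if d is not None and not math.isnan(d)]
        cluster.pairwise_dt_gaps = gaps
        cluster.pairs_total = total
        cluster.pairs_resolved = resolved
        cluster.pairs_unassessable = unassessable
        cluster.n_species = _count_species(valid_dts, cfg.dt_resolution)
        cluster.fully_resolved = resolved == total
        rows.append(
            {
                "cluster": ci,
                "size": cluster.size,
                "pairs_total": total,
                "pairs_resolved": resolved,
                "pairs_unassessable": unassessable,
                "n_species": cluster.n_species,
                "fully_resolved": cluster.fully_resolved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "size", "pairs_total", "pairs_resolved",
            "pairs_unassessable", "n_species", "fully_resolved",
        ],
    )


def resolution_summary(report: pd.DataFrame) -> dict[str, int]:
    """Global counts over a per-cluster report (both pair conventions).

    ``pairs_total`` counts every member pair combinatorially inside
    larger clusters; ``n_clusters_fully_resolved`` gives the
    cluster-level view.
    """
    if report.empty:
        return {
            "n_clusters": 0,
            "pairs_total": 0,
            "pairs_resolved": 0,
            "pairs_unassessable": 0,
            "n_clusters_fully_resolved": 0,
        }
    return {
        "n_clusters": int(len(report)),
        "pairs_total": int(report["pairs_total"].sum()),
        "pairs_resolved": int(report["pairs_resolved"].sum()),
        "pairs_unassessable": int(report["pairs_unassessable"].sum()),
        "n_clusters_fully_resolved": int(report["fully_resolved"].sum()),
    }
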