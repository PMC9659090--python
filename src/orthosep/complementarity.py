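"""Platform complementarity: overlap accounting, quality filtering and
physicochemical comparison of the peptide populations two platforms detect.

The descriptor comparison follows standard practice for this kind of
study: a two-sided Mann-Whitney rank-sum test per descriptor (p <= 0.05
significant) and a PCA of the pooled, standardized descriptor matrix so
that descriptors with incommensurate units (Da, residues, pH units)
contribute comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DESCRIPTORS = ["length", "mass", "mz", "gravy", "pi", "mass_length_ratio"]


@dataclass(frozen=True)
class OverlapResult:
    shared: int
    unique_a: int
    unique_b: int
    total: int
    unique_fraction_a: float
    unique_fraction_b: float


@dataclass
class PropertyComparison:
    tests: pd.DataFrame  # descriptor, statistic, p_value, significant
    explained_variance_pct: np.ndarray
    loadings: pd.DataFrame  # descriptor x component
    scores: pd.DataFrame  # per-record PC scores with platform label
    excluded: list[str]


@dataclass(frozen=True)
class FilterReport:
    kept: pd.DataFrame
    n_in: int
    n_kept: int
    n_failed_score: int
    n_failed_spi: int
    n_missing: int


def overlap(ids_a: set, ids_b: set) -> OverlapResult:
    """Set-algebra overlap between two identifier collections.

    Works at protein level (accessions) or peptide level (modified
    sequence strings); the caller chooses the identity.
    """
    ids_a, ids_b = set(ids_a), set(ids_b)
    shared = len(ids_a & ids_b)
    unique_a = len(ids_a - ids_b)
    unique_b = len(ids_b - ids_a)
    return OverlapResult(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        total=len(ids_a | ids_b),
        unique_fraction_a=100.0 * unique_a / len(ids_a) if ids_a else 0.0,
        unique_fraction_b=100.0 * unique_b / len(ids_b) if ids_b else 0.0,
    )


def filter_identifications(
    records: pd.DataFrame, score_min: float = 5.0, spi_min: float = 50.0
) -> FilterReport:
    """Identification acceptance filter: score > score_min AND spi > spi_min.

    Both thresholds are strict. Records with missing score or SPI are
    rejected and counted separately. Row order is preserved.
    """
    for col in ("score", "spi"):
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    score = pd.to_numeric(records["score"], errors="coerce")
    spi = pd.to_numeric(records["spi"], errors="coerce")
    missing = score.isna() | spi.isna()
    pass_score = score > score_min
    pass_spi = spi > spi_min
    keep = ~missing & pass_score & pass_spi
    return FilterReport(
        kept=records[keep].copy(),
        n_in=len(records),
        n_kept=int(keep.sum()),
        n_failed_score=int((~missing & ~pass_score).sum()),
        n_failed_spi=int((~missing & pass_score & ~pass_spi).sum()),
        n_missing=int(missing.sum()),
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small samples, normal
    approximation with tie correction otherwise."""
    method = "exact" if min(len(a), len(b)) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties; fall back
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_properties(
    props_a: pd.DataFrame,
    props_b: pd.DataFrame,
    descriptors: list[str] | None = None,
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
) -> PropertyComparison:
    """Rank-sum tests per descriptor plus PCA of the pooled matrix.

    PCA runs on standardized (centred, unit-variance) descriptors, i.e.
    on the correlation structure. Constant descriptor columns cannot be
    standardized and are excluded with a warning.
    """
    descriptors = descriptors or DESCRIPTORS
    if len(props_a) < 3 or len(props_b) < 3:
        raise ValueError("need at least 3 records per group")

    rows = []
    for d in descriptors:
        stat, p = rank_sum_test(
            props_a[d].to_numpy(dtype=float), props_b[d].to_numpy(dtype=float)
        )
        rows.append(
            {"descriptor": d, "statistic": stat, "p_value": p, "significant": p <= alpha}
        )
    tests = pd.DataFrame(rows)

    pooled = pd.concat([props_a[descriptors], props_b[descriptors]], ignore_index=True)
    excluded = [d for d in descriptors if pooled[d].nunique() <= 1]
    if excluded:
        logger.warning("excluding constant descriptor(s) from PCA: %s", excluded)
    retained = [d for d in descriptors if d not in excluded]
    if len(retained) < 2:
        raise ValueError("fewer than 2 non-constant descriptors; PCA undefined")

    X = StandardScaler().fit_transform(pooled[retained].to_numpy(dtype=float))
    pca = PCA(n_components=len(retained))
    pcs = pca.fit_transform(X)
    explained = 100.0 * pca.explained_variance_ratio_
    comp_names = [f"PC{i + 1}" for i in range(len(retained))]
    loadings = pd.DataFrame(pca.components_.T, index=retained, columns=comp_names)
    scores = pd.DataFrame(pcs, columns=comp_names)
    scores["platform"] = [label_a] * len(props_a) + [label_b] * len(props_b)
    return PropertyComparison(
        tests=tests,
        explained_variance_pct=explained,
        loadings=loadings,
        scores=scores,
        excluded=excluded,
    )
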