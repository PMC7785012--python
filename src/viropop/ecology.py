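"""Community ecology of viral populations.

Evenness (Pielou's J), second-order jackknife richness, permutation
accumulation curves, Bray–Curtis dissimilarity, average-linkage
dendrograms on Manhattan distances, and habitat-exclusivity / endemism
classification.

Shannon entropy is taken in natural log throughout (required for the
J = H'/ln S normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from viropop.recruitment_abundance import AbundanceMatrix

__all__ = [
    "DiversityReport",
    "DistributionClass",
    "pielou_evenness",
    "shannon",
    "jackknife2_richness",
    "accumulation_curve",
    "bray_curtis",
    "hierarchical_cluster",
    "classify_distribution",
    "diversity_report",
]

_ZONE_CLASSES = {
    frozenset({"euxinic"}): "euxinic_only",
    frozenset({"redoxcline"}): "redoxcline_only",
    frozenset({"redoxcline", "euxinic"}): "redoxcline_and_euxinic",
}


@dataclass(frozen=True)
class DiversityReport:
    sample_id: str
    observed_richness: int
    shannon: float
    pielou_j: float | None  # None when S < 2
    jackknife2: float


@dataclass(frozen=True)
class DistributionClass:
    population_id: str
    endemic: bool
    exclusivity: str


def shannon(rel_abundances) -> float:
    """Shannon entropy H' = -sum p ln p over positive entries."""
    p = np.asarray(rel_abundances, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(rel_abundances) -> float | None:
    """Pielou's J = H'/ln(S); ``None`` (undefined) when fewer than two
    populations are present."""
    p = np.asarray(rel_abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be >= 0")
    if p.sum() <= 0:
        raise ValueError("relative abundances must have positive sum")
    s = int((p > 0).sum())
    if s < 2:
        return None
    return shannon(p) / np.log(s)


def jackknife2_richness(incidence) -> float:
    """Burnham–Overton second-order jackknife richness estimator.

    ``incidence`` is a populations x samples boolean array.  With Q1/Q2
    the number of populations occurring in exactly one/two samples and n
    the number of samples:

        S_j2 = S_obs + Q1 (2n - 3)/n - Q2 (n - 2)^2 / (n (n - 1))
    """
    inc = np.asarray(incidence, dtype=bool)
    if inc.ndim != 2:
        raise ValueError("incidence must be 2-D (populations x samples)")
    n = inc.shape[1]
    if n < 2:
        raise ValueError("jackknife2 requires at least 2 samples")
    occ = inc.sum(axis=1)
    s_obs = int((occ > 0).sum())
    q1 = int((occ == 1).sum())
    q2 = int((occ == 2).sum())
    return s_obs + q1 * (2 * n - 3) / n - q2 * (n - 2) ** 2 / (n * (n - 1))


def accumulation_curve(
    incidence, permutations: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Species-accumulation curve over random sample orderings.

    Returns ``(mean, sd, final_detection_rate)`` where ``mean[k-1]`` /
    ``sd[k-1]`` are the across-permutation mean and standard deviation of
    cumulative richness after k samples, and ``final_detection_rate`` is
    the mean fraction of the observed populations first detected when the
    last sample is added — the "new population detection rate in the final
    random subsampling".
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    inc = np.asarray(incidence, dtype=bool)
    n_pop, n = inc.shape
    rng = np.random.default_rng(seed)
    richness = np.empty((permutations, n))
    new_at_final = np.empty(permutations)
    s_obs = int(inc.any(axis=1).sum())
    for p in range(permutations):
        order = rng.permutation(n)
        seen = np.zeros(n_pop, dtype=bool)
        prev = 0
        for k, j in enumerate(order):
            seen |= inc[:, j]
            cur = int(seen.sum())
            richness[p, k] = cur
            if k == n - 1:
                new_at_final[p] = (cur - prev) / s_obs if s_obs else 0.0
            prev = cur
    return richness.mean(axis=0), richness.std(axis=0), float(new_at_final.mean())


def bray_curtis(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Sample x sample Bray–Curtis dissimilarity on abundance columns.

    BC(x, y) = sum|x-y| / sum(x+y).  Pairs of all-zero columns are
    undefined and flagged as NaN.
    """
    cols = matrix.values.to_numpy(dtype=float).T  # samples x populations
    names = matrix.samples
    d = squareform(pdist(cols, metric="braycurtis"))
    zero = cols.sum(axis=1) == 0
    for i in range(len(names)):
        for j in range(len(names)):
            if i != j and zero[i] and zero[j]:
                d[i, j] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=names, columns=names)


def _manhattan(cols: np.ndarray) -> np.ndarray:
    return squareform(pdist(cols, metric="cityblock"))


def hierarchical_cluster(
    matrix: AbundanceMatrix, metric: str = "manhattan", linkage: str = "average"
) -> str:
    """Agglomerative clustering of sample columns; returns a Newick string.

    Supported: Manhattan distance with average (UPGMA), single or complete
    linkage.  Tie-break: among equal merge heights, the pair with the
    lowest cluster indices (creation order) merges first, making output
    deterministic.  Branch lengths are parent height minus child height.
    """
    if metric != "manhattan":
        raise ValueError(f"unsupported metric {metric!r}")
    reducers = {"average": None, "single": min, "complete": max}
    if linkage not in reducers:
        raise ValueError(f"unsupported linkage {linkage!r}")
    names = matrix.samples
    if len(names) < 2:
        raise ValueError("need at least 2 samples")
    cols = matrix.values.to_numpy(dtype=float).T
    dist = _manhattan(cols)

    # active clusters: id -> (newick, height, size, list of leaf indices)
    clusters: dict[int, tuple[str, float, int]] = {
        i: (name, 0.0, 1) for i, name in enumerate(names)
    }
    # pairwise distances between active cluster ids
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(len(names)) for j in range(i + 1, len(names))
    }
    next_id = len(names)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, hi, si = clusters.pop(i)
        nj, hj, sj = clusters.pop(j)
        merged = f"({ni}:{h / 2 - hi:.12g},{nj}:{h / 2 - hj:.12g})"
        new_height = h / 2
        # distances from the new cluster to the others
        new_d: dict[tuple[int, int], float] = {}
        for k in clusters:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            if linkage == "average":
                val = (si * dik + sj * djk) / (si + sj)
            else:
                val = reducers[linkage](dik, djk)
            new_d[(k, next_id)] = val
        del d[(i, j)]
        clusters[next_id] = (merged, new_height, si + sj)
        d.update(new_d)
        next_id += 1
    (newick, _, _), = clusters.values()
    return newick + ";"


def classify_distribution(
    matrix: AbundanceMatrix,
    zone_of_sample: dict[str, str],
    reference_detected: dict[str, bool] | None = None,
    epsilon: float = 0.0,
) -> list[DistributionClass]:
    """Endemism and habitat-exclusivity class per population.

    A population is *endemic* when absent from the reference (global)
    virome set.  Its exclusivity label comes from the set of zones where
    its abundance exceeds ``epsilon``: euxinic only, redoxcline only, both
    anoxic zones, any oxic-containing set (``cosmopolitan`` when also
    reference-detected, else ``oxygenated_only``), or ``indeterminate``
    when it never exceeds ``epsilon`` anywhere (near-undetectable).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    reference_detected = reference_detected or {}
    for s in matrix.samples:
        if s not in zone_of_sample:
            raise ValueError(f"sample {s!r} has no zone")
        if zone_of_sample[s] not in ("oxic", "redoxcline", "euxinic"):
            raise ValueError(f"sample {s!r}: unknown zone {zone_of_sample[s]!r}")
    out: list[DistributionClass] = []
    for pop in matrix.populations:
        row = matrix.values.loc[pop]
        zones = frozenset(
            zone_of_sample[s] for s in matrix.samples if row[s] > epsilon
        )
        in_reference = bool(reference_detected.get(pop, False))
        if not zones:
            label = "indeterminate"
        elif "oxic" in zones:
            label = "cosmopolitan" if in_reference else "oxygenated_only"
        else:
            label = _ZONE_CLASSES[zones]
        out.append(DistributionClass(pop, endemic=not in_reference, exclusivity=label))
    return out


def diversity_report(
    matrix: AbundanceMatrix, permutations: int = 100, seed: int = 0
) -> list[DiversityReport]:
    """Per-sample diversity: observed richness, Shannon H', Pielou's J,
    and the (whole-dataset) jackknife-2 estimate repeated per row for
    convenience."""
    rel = matrix.relative()
    incidence = (matrix.values.to_numpy() > 0)
    j2 = jackknife2_richness(incidence) if incidence.shape[1] >= 2 else float("nan")
    reports = []
    for s in matrix.samples:
        p = rel[s].to_numpy()
        s_obs = int((p > 0).sum())
        reports.append(
            DiversityReport(
                sample_id=s,
                observed_richness=s_obs,
                shannon=shannon(p),
                pielou_j=pielou_evenness(p) if s_obs >= 1 and p.sum() > 0 else None,
                jackknife2=j2,
            )
        )
    return reports
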