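"""Cluster-normalized distributions and significance testing.

Each protein-ligand cluster contributes total mass 1 to its set's histogram
(every member weighted 1/cluster-size), so a target with 5,000 near-duplicate
ligands counts no more than a singleton.  On these normalized distributions
the module provides:

* weighted medians/means read off the histogram;
* a design-based weighted Wilcoxon rank-sum test between the two sets;
* bootstrap 95% confidence intervals of the median (or mean), resampling
  bins with probabilities corrected for cluster size;
* the dual significance criterion (p < 1e-4 AND disjoint median CIs) and the
  four-level robustness verdict;
* the center-of-cluster alternative analysis (one center per cluster, unit
  weights, classical rank-sum) and single-level (chemistry-only) clustering.

Weighted Wilcoxon construction
------------------------------
Pooled observations are assigned mid-ranks on the weighted empirical CDF,
``R_i = (cum mass below x_i + mass at x_i / 2) / W`` in [0, 1].  The statistic
is the contrast of weighted mean ranks ``U = mean_A(R) − mean_B(R)``.  Its
null variance is permutation-style with a design-effect sample size computed
from *cluster total* weights (Kish effective count; every cluster totals
weight 1, so the effective count is the number of clusters m_g):

    Var(U) = sigma²_R · M/(M−1) · (1/m_A + 1/m_B),

where sigma²_R is the weighted pooled variance of the mid-ranks and M the
pooled effective cluster count.  With all-singleton clusters and equal
weights this is algebraically the classical tie-corrected large-sample
Wilcoxon rank-sum test; replicating a cluster's members k-fold changes
neither ranks, masses, nor effective counts, so the p-value is invariant.
Two-sided p from the normal approximation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chemspace import Fingerprint, similarity_matrix
from .descriptors import CONTINUOUS_CODES, DISCRETE_CODES
from .redundancy import LigandCluster, cluster_center, max_dissimilarity_cluster

__all__ = [
    "WeightedDistribution",
    "ComparisonResult",
    "RobustVerdict",
    "SetVectors",
    "bin_width",
    "cluster_weights",
    "weighted_histogram",
    "weighted_median",
    "weighted_mean",
    "weighted_wilcoxon",
    "bootstrap_ci",
    "set_vectors",
    "compare_descriptor",
    "robust_verdict",
    "single_level_analysis",
    "P_THRESHOLD",
    "DEFAULT_BOOTSTRAP_SAMPLES",
]

#: strict significance threshold for the rank test
P_THRESHOLD = 1e-4

#: default number of bootstrap replicates for the 95% CIs
DEFAULT_BOOTSTRAP_SAMPLES = 100_000


def bin_width(descriptor_code: str) -> float:
    """Histogram bin width: 1 for discrete codes, 0.001 for continuous ones."""
    if descriptor_code in DISCRETE_CODES:
        return 1.0
    if descriptor_code in CONTINUOUS_CODES:
        return 0.001
    raise KeyError(f"unknown descriptor code {descriptor_code!r}")


def _bin_indices(values: np.ndarray, width: float) -> np.ndarray:
    # round-before-floor stabilizes values like 0.136/0.001 = 135.99999...
    return np.floor(np.round(values / width, 9)).astype(np.int64)


@dataclass
class WeightedDistribution:
    """Per-cluster-normalized histogram of one descriptor over one set.

    Each contributing cluster adds total mass exactly 1, so the combined total
    mass equals ``n_clusters``; the display form (``normalized``) divides by
    it so the histogram sums to 1.
    """

    descriptor_code: str
    bin_width: float
    bins: dict[int, float]
    n_clusters: int

    @property
    def total_mass(self) -> float:
        return float(sum(self.bins.values()))

    def edges_and_masses(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted bin lower edges and their masses."""
        idx = np.array(sorted(self.bins), dtype=np.int64)
        masses = np.array([self.bins[i] for i in idx])
        return idx * self.bin_width, masses

    def normalized(self) -> dict[int, float]:
        return {k: v / self.n_clusters for k, v in self.bins.items()}


def cluster_weights(
    clusters: Sequence[LigandCluster],
) -> dict[tuple[str, str], float]:
    """Weight 1/|cluster| for every ligand instance, keyed (cluster, ligand).

    Weights within each cluster sum to 1, so every cluster contributes one
    unit of mass regardless of how many near-duplicates it holds.
    """
    weights: dict[tuple[str, str], float] = {}
    for cl in clusters:
        if cl.size == 0:
            raise ValueError(f"empty cluster {cl.cluster_id}")
        w = 1.0 / cl.size
        for lid in cl.member_ligand_ids:
            weights[(cl.cluster_id, lid)] = w
    return weights


def weighted_histogram(
    values: Sequence[float],
    weights: Sequence[float],
    descriptor_code: str,
    n_clusters: int,
) -> WeightedDistribution:
    """Accumulate cluster-normalized mass into fixed-width bins.

    Bin k covers [k·w, (k+1)·w); non-finite values are excluded.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must be aligned")
    finite = np.isfinite(v)
    v, w = v[finite], w[finite]
    width = bin_width(descriptor_code)
    idx = _bin_indices(v, width)
    bins: dict[int, float] = {}
    for i, mass in zip(idx, w):
        bins[int(i)] = bins.get(int(i), 0.0) + float(mass)
    return WeightedDistribution(descriptor_code, width, bins, n_clusters)


def weighted_median(dist: WeightedDistribution) -> float:
    """Lower edge of the first bin where cumulative mass reaches half the total."""
    if not dist.bins:
        raise ValueError("empty distribution")
    edges, masses = dist.edges_and_masses()
    cum = np.cumsum(masses)
    half = cum[-1] / 2.0
    return float(edges[int(np.searchsorted(cum, half, side="left"))])


def weighted_mean(dist: WeightedDistribution) -> float:
    """Mass-weighted mean of the bin lower edges."""
    if not dist.bins:
        raise ValueError("empty distribution")
    edges, masses = dist.edges_and_masses()
    return float(np.average(edges, weights=masses))


# --------------------------------------------------------------------------
# weighted Wilcoxon rank-sum
# --------------------------------------------------------------------------

def _effective_count(cluster_totals: np.ndarray) -> float:
    """Kish effective sample size of a set of cluster total weights."""
    s1 = cluster_totals.sum()
    s2 = (cluster_totals**2).sum()
    return float(s1 * s1 / s2)


def weighted_wilcoxon(
    values_a: Sequence[float],
    weights_a: Sequence[float],
    values_b: Sequence[float],
    weights_b: Sequence[float],
    clusters_a: Sequence | None = None,
    clusters_b: Sequence | None = None,
) -> float:
    """Two-sided design-based weighted rank-sum p-value.

    ``clusters_a``/``clusters_b`` give the cluster id of each observation;
    omitted, every observation is its own cluster, in which case equal weights
    reproduce the classical large-sample (tie-corrected, no continuity
    correction) Wilcoxon rank-sum test exactly.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(wa <= 0) or np.any(wb <= 0):
        raise ValueError("weights must be > 0")

    x = np.concatenate([va, vb])
    w = np.concatenate([wa, wb])
    W = w.sum()

    # weighted mid-ranks on the pooled empirical CDF
    uniq, inv = np.unique(x, return_inverse=True)
    mass = np.bincount(inv, weights=w)
    cum_before = np.concatenate([[0.0], np.cumsum(mass)[:-1]])
    rank_of_value = (cum_before + 0.5 * mass) / W
    r = rank_of_value[inv]

    ra, rb = r[: va.size], r[va.size :]
    wa_sum, wb_sum = wa.sum(), wb.sum()
    u = float(np.sum(wa * ra) / wa_sum - np.sum(wb * rb) / wb_sum)

    rbar = float(np.sum(w * r) / W)
    sigma2 = float(np.sum(w * (r - rbar) ** 2) / W)
    if sigma2 <= 0.0:
        return 1.0

    def totals(weights: np.ndarray, clusters) -> np.ndarray:
        if clusters is None:
            return weights
        codes = pd.factorize(np.asarray(clusters))[0]
        return np.bincount(codes, weights=weights)

    ta = totals(wa, clusters_a)
    tb = totals(wb, clusters_b)
    m_a = _effective_count(ta)
    m_b = _effective_count(tb)
    m_all = _effective_count(np.concatenate([ta, tb]))
    if m_all <= 1.0:
        return 1.0

    var = sigma2 * (m_all / (m_all - 1.0)) * (1.0 / m_a + 1.0 / m_b)
    z = u / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# --------------------------------------------------------------------------
# bootstrap confidence intervals
# --------------------------------------------------------------------------

def bootstrap_ci(
    dist: WeightedDistribution,
    statistic: str = "median",
    n_samples: int = DEFAULT_BOOTSTRAP_SAMPLES,
    sample_size: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """95% CI of the median (or mean) by histogram bootstrap.

    Each replicate draws ``sample_size`` bin values (default: the number of
    clusters, the natural unit of the weighting) with probability proportional
    to bin mass and computes the statistic; the interval is the 2.5th-97.5th
    percentile of the replicate statistics.  Deterministic given ``seed``.

    The replicate *median* (lower-middle order statistic, rank (n+1)//2) is
    drawn exactly via the order-statistic identity — the k-th order statistic
    of n i.i.d. draws is the inverse CDF at a Beta(k, n−k+1) variate — which
    makes 100,000 replicates cheap.  The mean path resamples bin counts
    multinomially in chunks.
    """
    if dist.total_mass <= 0:
        raise ValueError("distribution has no mass")
    edges, masses = dist.edges_and_masses()
    probs = masses / masses.sum()
    n = int(sample_size) if sample_size is not None else int(dist.n_clusters)
    if n < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)

    if statistic == "median":
        k = (n + 1) // 2
        q = rng.beta(k, n - k + 1, size=n_samples)
        cum = np.cumsum(probs)
        idx = np.searchsorted(cum, q, side="left")
        reps = edges[np.clip(idx, 0, edges.size - 1)]
    elif statistic == "mean":
        chunks = []
        chunk = max(1, min(n_samples, 20_000_000 // max(1, probs.size)))
        done = 0
        while done < n_samples:
            take = min(chunk, n_samples - done)
            counts = rng.multinomial(n, probs, size=take)
            chunks.append(counts @ edges / n)
            done += take
        reps = np.concatenate(chunks)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    return float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))


# --------------------------------------------------------------------------
# per-descriptor comparison and the robustness verdict
# --------------------------------------------------------------------------

@dataclass
class SetVectors:
    """One set's descriptor values with their cluster structure."""

    values: np.ndarray
    cluster_codes: np.ndarray  # integer cluster index per instance
    is_center: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_codes.max()) + 1 if self.cluster_codes.size else 0

    @property
    def weights(self) -> np.ndarray:
        sizes = np.bincount(self.cluster_codes)
        return 1.0 / sizes[self.cluster_codes]


def set_vectors(
    clusters: Sequence[LigandCluster], values_by_ligand: Mapping[str, float]
) -> SetVectors:
    """Flatten clusters into aligned (value, cluster, is-center) arrays."""
    values, codes, centers = [], [], []
    for ci, cl in enumerate(clusters):
        for lid in cl.member_ligand_ids:
            values.append(values_by_ligand[lid])
            codes.append(ci)
            centers.append(lid == cl.center_ligand_id)
    return SetVectors(
        values=np.asarray(values, dtype=float),
        cluster_codes=np.asarray(codes, dtype=int),
        is_center=np.asarray(centers, dtype=bool),
    )


@dataclass
class ComparisonResult:
    """Outcome of one descriptor comparison at one clustering level."""

    descriptor_code: str
    level_label: str
    scheme: str
    median_allo: float
    median_comp: float
    ci95_allo: tuple[float, float] | None
    ci95_comp: tuple[float, float] | None
    p_value: float
    significant_at_level: bool
    direction: str  # allo_higher | comp_higher | none


def _intervals_disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def _seed_seq(seed: int, *tokens) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(seed) % (2**31)] + [zlib.crc32(str(t).encode()) for t in tokens]
    )


def compare_descriptor(
    code: str,
    allo: SetVectors,
    comp: SetVectors,
    level_label: str = "",
    scheme: str = "weighted",
    n_boot: int = DEFAULT_BOOTSTRAP_SAMPLES,
    sample_size: int | None = None,
    seed: int = 0,
    ci_mode: str = "always",
) -> ComparisonResult:
    """Compare one descriptor between the two sets at one clustering level.

    ``scheme='weighted'`` uses all ligands with 1/cluster-size weights and the
    weighted rank test; ``scheme='centers'`` uses one center per cluster with
    unit weights and the classical rank test (straight random bootstrap).

    ``ci_mode='lazy'`` skips the bootstrap when the rank test alone already
    fails the strict threshold; since significance is the conjunction of both
    criteria this cannot change any verdict, only omit CI values (set to
    ``None``).
    """
    if scheme == "weighted":
        va, wa, ca = allo.values, allo.weights, allo.cluster_codes
        vb, wb, cb = comp.values, comp.weights, comp.cluster_codes
        na, nb = allo.n_clusters, comp.n_clusters
    elif scheme == "centers":
        ma, mb = allo.is_center, comp.is_center
        va, vb = allo.values[ma], comp.values[mb]
        wa = np.ones(va.size)
        wb = np.ones(vb.size)
        ca = np.arange(va.size)
        cb = np.arange(vb.size)
        na, nb = va.size, vb.size
    else:
        raise ValueError("scheme must be 'weighted' or 'centers'")

    dist_a = weighted_histogram(va, wa, code, na)
    dist_b = weighted_histogram(vb, wb, code, nb)
    med_a = weighted_median(dist_a)
    med_b = weighted_median(dist_b)
    p = weighted_wilcoxon(va, wa, vb, wb, clusters_a=ca, clusters_b=cb)

    ci_a = ci_b = None
    significant = False
    if p < P_THRESHOLD or ci_mode == "always":
        ci_a = bootstrap_ci(
            dist_a, "median", n_boot, sample_size,
            seed=_seed_seq(seed, code, level_label, scheme, "allo"),
        )
        ci_b = bootstrap_ci(
            dist_b, "median", n_boot, sample_size,
            seed=_seed_seq(seed, code, level_label, scheme, "comp"),
        )
        significant = p < P_THRESHOLD and _intervals_disjoint(ci_a, ci_b)

    if med_a > med_b:
        direction = "allo_higher"
    elif med_a < med_b:
        direction = "comp_higher"
    else:
        direction = "none"
    return ComparisonResult(
        descriptor_code=code,
        level_label=level_label,
        scheme=scheme,
        median_allo=med_a,
        median_comp=med_b,
        ci95_allo=ci_a,
        ci95_comp=ci_b,
        p_value=p,
        significant_at_level=significant,
        direction=direction,
    )


@dataclass
class RobustVerdict:
    """Whether one descriptor differs significantly at all four levels."""

    descriptor_code: str
    significant_all_levels: bool
    direction: str


def robust_verdict(results: Sequence[ComparisonResult]) -> RobustVerdict:
    """Combine the four per-level comparisons of one descriptor.

    Robust iff every level is individually significant and all levels agree on
    the direction.
    """
    if len(results) != 4 or len({r.level_label for r in results}) != 4:
        raise ValueError("robust_verdict requires results at exactly four distinct levels")
    codes = {r.descriptor_code for r in results}
    if len(codes) != 1:
        raise ValueError("results mix descriptor codes")
    all_sig = all(r.significant_at_level for r in results)
    directions = {r.direction for r in results}
    consistent = len(directions) == 1 and directions != {"none"}
    ok = all_sig and consistent
    return RobustVerdict(
        descriptor_code=results[0].descriptor_code,
        significant_all_levels=ok,
        direction=results[0].direction if ok else "none",
    )


# --------------------------------------------------------------------------
# single-level (chemistry-only) clustering
# --------------------------------------------------------------------------

def _global_clusters(
    fps: Sequence[Fingerprint],
    heavy_atoms: Mapping[str, int],
    tc: float,
    prefix: str,
) -> list[LigandCluster]:
    order = sorted(range(len(fps)), key=lambda i: (-heavy_atoms[fps[i].ligand_id], fps[i].ligand_id))
    ordered = [fps[i] for i in order]
    sims = similarity_matrix(ordered)
    clusters = []
    for j, member_idx in enumerate(max_dissimilarity_cluster(ordered, tc, sims=sims)):
        center = cluster_center(member_idx, sims)
        clusters.append(
            LigandCluster(
                cluster_id=f"{prefix}_C{j:05d}",
                family_id=prefix,
                member_ligand_ids=tuple(ordered[i].ligand_id for i in member_idx),
                center_ligand_id=ordered[center].ligand_id,
            )
        )
    return clusters


def single_level_analysis(
    fps_allo: Sequence[Fingerprint],
    desc_allo: pd.DataFrame,
    fps_comp: Sequence[Fingerprint],
    desc_comp: pd.DataFrame,
    tc_thresholds: Iterable[float] = (0.6, 0.75, 0.9, 1.0),
    codes: Sequence[str] | None = None,
    scheme: str = "weighted",
    n_boot: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
    ci_mode: str = "always",
) -> dict[float, dict[str, ComparisonResult]]:
    """Chemistry-only sanity check: cluster each set globally, ignoring protein
    families, at each Tc threshold and compare every descriptor.

    ``desc_*`` are descriptor tables indexed by ligand id (must contain
    ``a_heavy`` for the canonical ordering).
    """
    codes = list(codes) if codes is not None else [c for c in desc_allo.columns]
    ha_a = desc_allo["a_heavy"].astype(int).to_dict()
    ha_b = desc_comp["a_heavy"].astype(int).to_dict()
    out: dict[float, dict[str, ComparisonResult]] = {}
    for tc in tc_thresholds:
        label = f"tc{tc:g}"
        cl_a = _global_clusters(fps_allo, ha_a, tc, f"ALLO_{label}")
        cl_b = _global_clusters(fps_comp, ha_b, tc, f"COMP_{label}")
        per_code: dict[str, ComparisonResult] = {}
        for code in codes:
            sv_a = set_vectors(cl_a, desc_allo[code].to_dict())
            sv_b = set_vectors(cl_b, desc_comp[code].to_dict())
            per_code[code] = compare_descriptor(
                code, sv_a, sv_b, level_label=label, scheme=scheme,
                n_boot=n_boot, seed=seed, ci_mode=ci_mode,
            )
        out[tc] = per_code
    return out
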