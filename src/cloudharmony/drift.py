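"""Point Cloud Semantic Drift (PCSD): a rank-based shape-invariance statistic.

A patient is a cloud of lesion points (rows of a feature table or of an
embedding matrix). A transformation of the feature space — harmonization,
dimensionality reduction — should not reorder each lesion's neighbors: that
ordering encodes intra-tumor heterogeneity. For every anchor lesion we rank
the patient's other lesions by ascending Euclidean distance, in the original
and in the transformed space, and measure the weighted change in rank with a
Spearman-footrule-style statistic:

* footrule:  S = sum_t |r_transf(t) - r_orig(t)|, ranks capped at k+1 outside
  the top k;
* per-anchor drift (PSD): the same sum with each term weighted by the change
  in the neighbor's max-normalized distance to the anchor,
  |M_transf(t) - M_orig(t)|, so swaps between close and far neighbors weigh
  more than local shuffles;
* per-patient drift (PCSD): the mean PSD over the cloud's anchors.

Significance is judged against an empirical null: repeatedly add Gaussian
noise (variance 3 on standardized data) to a random half of each cloud's
lesions, recompute the population mean PCSD, and report the left-tail
empirical p — the fraction of null draws below the observed statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_data import LesionTable

#: clouds with fewer than this many lesions have PCSD identically 0 under
#: max-normalization and are excluded from population statistics
MIN_CLOUD_SIZE = 3


@dataclass
class PointCloud:
    """One patient's lesions as points in feature or embedding space."""

    patient_id: str
    lesion_ids: list[str]
    points: np.ndarray  # (K, dim)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[0] != len(self.lesion_ids):
            raise ValueError("points must be (K, dim) aligned with lesion_ids")
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            raise ValueError(f"duplicate lesion ids in cloud {self.patient_id!r}")
        if self.K < 2:
            raise ValueError(f"cloud {self.patient_id!r} needs K >= 2 lesions")

    @property
    def K(self) -> int:
        return self.points.shape[0]


def clouds_from_table(table: LesionTable) -> list[PointCloud]:
    """Group a lesion table into per-patient clouds (patients with >= 2 lesions)."""
    return clouds_from_arrays(table.lesion_ids, table.patient_ids, table.features)


def clouds_from_arrays(
    lesion_ids: np.ndarray, patient_ids: np.ndarray, matrix: np.ndarray
) -> list[PointCloud]:
    matrix = np.asarray(matrix, float)
    clouds = []
    order = {}
    for i, p in enumerate(patient_ids):
        order.setdefault(p, []).append(i)
    for p, idx in order.items():
        if len(idx) < 2:
            continue
        clouds.append(
            PointCloud(str(p), [str(lesion_ids[i]) for i in idx], matrix[idx])
        )
    return clouds


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

@dataclass
class NeighborRanking:
    """Neighbors of one anchor lesion, ranked by ascending distance.

    ``ranked_ids[0]`` is the nearest neighbor (rank 1). ``scores[id]`` is the
    neighbor's distance to the anchor divided by the maximum such distance,
    so the farthest neighbor always scores 1.
    """

    anchor: str
    ranked_ids: list[str]
    scores: dict[str, float]

    def rank(self, lesion_id: str, k: int | None = None) -> int:
        """1-based rank, capped at k+1 when outside the top k."""
        r = self.ranked_ids.index(lesion_id) + 1
        if k is not None and r > k:
            return k + 1
        return r


def neighbor_ranking(cloud: PointCloud, anchor: str) -> NeighborRanking:
    """Rank the anchor's K-1 peer lesions by ascending Euclidean distance.

    Distances are max-normalized into scores M in (0, 1]; ties in distance are
    broken by lesion-id lexicographic order, deterministically.
    """
    if anchor not in cloud.lesion_ids:
        raise ValueError(f"anchor {anchor!r} not in cloud {cloud.patient_id!r}")
    ai = cloud.lesion_ids.index(anchor)
    others = [(lid, j) for j, lid in enumerate(cloud.lesion_ids) if j != ai]
    dists = {lid: float(np.linalg.norm(cloud.points[j] - cloud.points[ai])) for lid, j in others}
    dmax = max(dists.values())
    if dmax == 0.0:  # all peers coincide with the anchor
        scores = {lid: 1.0 for lid in dists}
    else:
        scores = {lid: d / dmax for lid, d in dists.items()}
    ranked = sorted(dists, key=lambda lid: (dists[lid], lid))
    return NeighborRanking(anchor=anchor, ranked_ids=ranked, scores=scores)


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def footrule(list_a: list[str], list_b: list[str], k: int) -> int:
    """Spearman footrule with top-k truncation: sum over the union of ids of
    the absolute rank difference, ranks capped at k+1 outside the top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate ids in {name}")
    ra = {t: i + 1 for i, t in enumerate(list_a)}
    rb = {t: i + 1 for i, t in enumerate(list_b)}
    total = 0
    for t in set(list_a) | set(list_b):
        total += abs(min(rb.get(t, k + 1), k + 1) - min(ra.get(t, k + 1), k + 1))
    return total


def point_semantic_drift(
    orig: NeighborRanking, transf: NeighborRanking, k: int | None = None
) -> float:
    """Weighted footrule between one anchor's original and transformed
    neighbor rankings: sum_t |M_transf(t) - M_orig(t)| * |r_transf(t) - r_orig(t)|
    with ranks capped at k+1 (default k = K-1, i.e. no truncation).
    """
    if orig.anchor != transf.anchor:
        raise ValueError(f"anchors differ: {orig.anchor!r} vs {transf.anchor!r}")
    if set(orig.ranked_ids) != set(transf.ranked_ids):
        raise ValueError("rankings cover different lesion-id sets")
    if k is None:
        k = len(orig.ranked_ids)
    total = 0.0
    for t in orig.ranked_ids:
        dm = abs(transf.scores[t] - orig.scores[t])
        dr = abs(transf.rank(t, k) - orig.rank(t, k))
        total += dm * dr
    return total


def pcsd(orig: PointCloud, transf: PointCloud, k: int | None = None) -> float:
    """Point Cloud Semantic Drift: mean per-anchor PSD over the cloud.

    Identically 0 for K < 3 (with a single neighbor, rank and normalized
    distance are both fixed); such clouds are flagged degenerate by
    :func:`drift_test` and excluded from population statistics.
    """
    if orig.patient_id != transf.patient_id:
        raise ValueError("clouds belong to different patients")
    if set(orig.lesion_ids) != set(transf.lesion_ids):
        raise ValueError("clouds cover different lesion-id sets")
    vals = [
        point_semantic_drift(
            neighbor_ranking(orig, a), neighbor_ranking(transf, a), k
        )
        for a in orig.lesion_ids
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Null distribution and test
# ---------------------------------------------------------------------------

def _mean_pcsd(pairs: list[tuple[PointCloud, PointCloud]], k: int | None) -> float:
    vals = [pcsd(o, t, k) for o, t in pairs if o.K >= MIN_CLOUD_SIZE]
    if not vals:
        raise ValueError("no cloud with K >= 3; population PCSD undefined")
    return float(np.mean(vals))


def null_pcsd(
    orig_clouds: list[PointCloud],
    n_iter: int = 100,
    noise_variance: float = 3.0,
    subset_fraction: float = 0.5,
    seed: int = 0,
    k: int | None = None,
    perturb_clouds: list[PointCloud] | None = None,
) -> np.ndarray:
    """Empirical null of the population mean PCSD under random transformation.

    Per iteration, for each cloud: pick a uniformly random subset of
    ceil(subset_fraction * K) lesions (at least 1), add i.i.d. Gaussian noise
    with mean 0 and the given variance to their vectors, and compute the
    population mean PCSD of the perturbed clouds against the originals.
    Noise is injected into ``perturb_clouds`` when given (e.g. the
    transformed/embedding clouds), else into the originals.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    targets = orig_clouds if perturb_clouds is None else perturb_clouds
    if perturb_clouds is not None and len(perturb_clouds) != len(orig_clouds):
        raise ValueError("perturb_clouds must pair 1:1 with orig_clouds")
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(noise_variance))
    draws = np.empty(n_iter)
    for it in range(n_iter):
        pairs = []
        for orig, target in zip(orig_clouds, targets):
            n_pick = max(int(np.ceil(subset_fraction * target.K)), 1)
            pick = rng.choice(target.K, size=n_pick, replace=False)
            pts = target.points.copy()
            pts[pick] += sd * rng.standard_normal((n_pick, pts.shape[1]))
            noisy = PointCloud(target.patient_id, list(target.lesion_ids), pts)
            pairs.append((orig, noisy))
        draws[it] = _mean_pcsd(pairs, k)
    return draws


def pcsd_empirical_p(observed_mean: float, null_draws: np.ndarray) -> float:
    """Left-tail empirical p: fraction of null draws strictly below the
    observed statistic."""
    null_draws = np.asarray(null_draws, float)
    if null_draws.size == 0:
        raise ValueError("null_draws must be non-empty")
    return float(np.sum(null_draws < observed_mean) / null_draws.size)


@dataclass
class DriftResult:
    """Population drift-test output: per-patient PCSD, null draws, empirical p."""

    per_patient_pcsd: dict[str, float]
    excluded_patients: list[str]
    observed_mean: float
    null_draws: np.ndarray
    empirical_p: float
    k: int | None = None
    noise_variance: float = 3.0
    n_iter: int = 100
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "per_patient_pcsd": {p: float(v) for p, v in sorted(self.per_patient_pcsd.items())},
            "excluded_patients": sorted(self.excluded_patients),
            "observed_mean_pcsd": float(self.observed_mean),
            "null_draws": np.asarray(self.null_draws, float).tolist(),
            "empirical_p": float(self.empirical_p),
            "k": self.k,
            "noise_variance": self.noise_variance,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def drift_test(
    orig_clouds: list[PointCloud],
    transf_clouds: list[PointCloud],
    k: int | None = None,
    n_iter: int = 100,
    noise_variance: float = 3.0,
    subset_fraction: float = 0.5,
    seed: int = 0,
    perturb: str = "original",
) -> DriftResult:
    """Full shape-invariance test: observed population mean PCSD of a
    transformation vs the Gaussian-noise null, with left-tail empirical p.

    ``perturb`` chooses which space the null noise is injected into:
    ``"original"`` (default) or ``"transformed"``.
    """
    if perturb not in ("original", "transformed"):
        raise ValueError(f"perturb must be 'original' or 'transformed', got {perturb!r}")
    by_id = {c.patient_id: c for c in transf_clouds}
    missing = [c.patient_id for c in orig_clouds if c.patient_id not in by_id]
    if missing:
        raise ValueError(f"transformed clouds missing for patients {missing[:5]}")
    ordered_transf = [by_id[c.patient_id] for c in orig_clouds]

    per_patient, excluded = {}, []
    for o, t in zip(orig_clouds, ordered_transf):
        if o.K < MIN_CLOUD_SIZE:
            excluded.append(o.patient_id)
            continue
        per_patient[o.patient_id] = pcsd(o, t, k)
    if not per_patient:
        raise ValueError("no cloud with K >= 3; population PCSD undefined")
    observed = float(np.mean(list(per_patient.values())))

    keep = [c for c in orig_clouds if c.patient_id in per_patient]
    keep_t = [by_id[c.patient_id] for c in keep]
    draws = null_pcsd(
        keep,
        n_iter=n_iter,
        noise_variance=noise_variance,
        subset_fraction=subset_fraction,
        seed=seed,
        k=k,
        perturb_clouds=keep_t if perturb == "transformed" else None,
    )
    return DriftResult(
        per_patient_pcsd=per_patient,
        excluded_patients=excluded,
        observed_mean=observed,
        null_draws=draws,
        empirical_p=pcsd_empirical_p(observed, draws),
        k=k,
        noise_variance=noise_variance,
        n_iter=n_iter,
        seed=seed,
    )
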