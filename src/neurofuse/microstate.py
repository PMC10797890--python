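"""EEG microstate segmentation.

Global field power (GFP) peak extraction, polarity-invariant topographic
atomize-and-agglomerate hierarchical clustering (TAAHC) with four
cluster-number selection criteria (global explained variance, the
cross-validation criterion, within-cluster dispersion and the Krzanowski-Lai
index), global-map-dissimilarity (GMD) backfitting of the prototypes to the
continuous record, temporal smoothing that dissolves runs shorter than 30 ms,
and per-state statistics (duration, occurrence, coverage, mean GFP and the
run-level transition matrix).

Spatial similarity is everywhere polarity-invariant: a topography and its
sign-flipped copy belong to the same microstate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment

from .datatypes import EEGRecording
from .errors import NeurofuseError

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# GFP and peak maps


@dataclass
class GFPSeries:
    """Per-sample spatial standard deviation across channels (uV)."""

    values: np.ndarray
    fs: float


def compute_gfp(rec: EEGRecording | np.ndarray, fs: float | None = None) -> GFPSeries:
    """GFP_t = population standard deviation across channels at sample t."""
    if isinstance(rec, EEGRecording):
        data, fs = rec.data, rec.fs
    else:
        data = np.asarray(rec, dtype=float)
        if fs is None:
            raise NeurofuseError("fs required when passing a bare array")
    if data.shape[0] < 2:
        raise NeurofuseError("GFP needs at least two channels")
    return GFPSeries(values=data.std(axis=0, ddof=0), fs=fs)


def extract_gfp_peaks(gfp: GFPSeries, rec: EEGRecording, n_peaks: int = 1000,
                      min_dist_ms: float = 10.0):
    """Topographies at GFP local maxima.

    Enforces a minimum peak separation (larger peak wins); if more maxima
    survive than ``n_peaks``, the highest are kept.  Returns
    (peak sample indices, maps matrix n_kept x channels).
    """
    distance = max(1, int(round(min_dist_ms / 1000.0 * gfp.fs)))
    idx, _ = signal.find_peaks(gfp.values, distance=distance)
    if idx.size == 0:
        raise NeurofuseError("no GFP peaks (constant series?)")
    if idx.size > n_peaks:
        keep = np.argsort(gfp.values[idx])[::-1][:n_peaks]
        idx = np.sort(idx[keep])
    return idx, rec.data[:, idx].T.copy()


# ---------------------------------------------------------------------------
# TAAHC clustering


@dataclass
class PrototypeSet:
    """K prototype topographies, zero-mean and unit-norm per map."""

    maps: np.ndarray  # (K, n_channels)

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    labels: np.ndarray  # per-sample state index, UNASSIGNED allowed
    gev: float
    fs: float
    k: int


def _normalize_maps(maps: np.ndarray):
    """Zero-mean each map across channels and scale to unit L2 norm.

    Returns (unit maps, original norms after demeaning)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return m / norms[:, None], norms


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two demeaned topographies (Pearson over channels)."""
    uu, _ = _normalize_maps(u[None, :])
    vv, _ = _normalize_maps(v[None, :])
    return float(uu[0] @ vv[0])


def gmd(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True) -> float:
    """Global map dissimilarity between two topographies.

    GMD = sqrt(mean_c (u/GFP_u - v/GFP_v)^2), minimized over the sign of v
    when polarity-invariant.  Identical maps give 0, uncorrelated unit maps
    sqrt(2), anti-correlated maps 2 (or 0 when polarity-invariant).
    """
    c = len(u)
    uh = (u - u.mean()) / max(np.std(u, ddof=0), 1e-300)
    vh = (v - v.mean()) / max(np.std(v, ddof=0), 1e-300)
    d_plus = np.sqrt(np.mean((uh - vh) ** 2))
    if not polarity_invariant:
        return float(d_plus)
    d_minus = np.sqrt(np.mean((uh + vh) ** 2))
    return float(min(d_plus, d_minus))


class _Cluster:
    __slots__ = ("members", "prototype", "quality")

    def __init__(self, members, prototype, quality):
        self.members = members  # list[int]
        self.prototype = prototype  # unit vector
        self.quality = quality  # sum of |corr| of members to prototype


def _aligned_mean_prototype(U: np.ndarray, members: list[int], ref: np.ndarray):
    """Unit prototype = normalized mean of members, each sign-aligned to ref."""
    sub = U[members]
    signs = np.sign(sub @ ref)
    signs[signs == 0] = 1.0
    m = (sub * signs[:, None]).mean(axis=0)
    n = np.linalg.norm(m)
    if n == 0:
        return ref.copy()
    return m / n


@dataclass
class TAAHCResult:
    prototypes: dict[int, PrototypeSet]
    assignments: dict[int, np.ndarray]
    criteria: pd.DataFrame  # index K: gev, cv, dispersion, kl
    k_selected: int


def taahc_cluster(peak_maps: np.ndarray, k_min: int = 2, k_max: int = 8,
                  select: str = "kl") -> TAAHCResult:
    """Atomize-and-agglomerate clustering of GFP-peak topographies.

    Starts from singleton clusters and repeatedly dissolves the worst
    cluster — the one with the lowest quality, defined as the sum of its
    members' absolute spatial correlation with the cluster prototype —
    reassigning each orphan to the best-correlated remaining cluster.
    Prototypes are the normalized polarity-aligned member means.  Prototype
    sets and selection criteria are recorded at every K from k_max down to
    k_min; the returned ``k_selected`` maximizes the chosen criterion
    (default Krzanowski-Lai).
    """
    maps = np.asarray(peak_maps, dtype=float)
    n, n_ch = maps.shape
    if k_max > n:
        raise NeurofuseError(f"k_max={k_max} exceeds {n} peak maps")
    if not 1 <= k_min <= k_max:
        raise NeurofuseError("need 1 <= k_min <= k_max")
    U, norms = _normalize_maps(maps)

    clusters: dict[int, _Cluster] = {
        i: _Cluster([i], U[i].copy(), 1.0) for i in range(n)
    }
    prototypes: dict[int, PrototypeSet] = {}
    assignments: dict[int, np.ndarray] = {}
    # within-cluster dispersion W_K for K = 1 .. k_max+1 (the KL index at K
    # needs W at K-1 and K+1)
    dispersion: dict[int, float] = {}

    def record(k_now: int) -> None:
        ids = list(clusters)
        P = np.array([clusters[c].prototype for c in ids])
        lab = np.empty(n, dtype=int)
        for pos, c in enumerate(ids):
            lab[clusters[c].members] = pos
        corr = np.abs(np.einsum("ij,ij->i", U, P[lab]))
        dispersion[k_now] = float(np.sum(1.0 - corr**2))
        if k_min <= k_now <= k_max:
            prototypes[k_now] = PrototypeSet(maps=P.copy())
            assignments[k_now] = lab.copy()

    # agglomerate all the way to one cluster: W_1 feeds the KL index at K=2
    while len(clusters) > 1:
        k_now = len(clusters)
        if k_now <= k_max + 1:
            record(k_now)
        # dissolve worst cluster (lowest quality; ties -> lowest id)
        worst = min(clusters, key=lambda c: (clusters[c].quality, c))
        orphans = clusters.pop(worst).members
        ids = list(clusters)
        P = np.array([clusters[c].prototype for c in ids])
        best = np.argmax(np.abs(U[orphans] @ P.T), axis=1)
        touched = set()
        for o, b in zip(orphans, best):
            clusters[ids[b]].members.append(o)
            touched.add(ids[b])
        for c in touched:
            cl = clusters[c]
            cl.prototype = _aligned_mean_prototype(U, cl.members, cl.prototype)
            cl.quality = float(np.sum(np.abs(U[cl.members] @ cl.prototype)))
    if len(clusters) >= 1 and len(clusters) not in dispersion:
        record(len(clusters))

    criteria = _selection_criteria(maps, U, norms, prototypes, assignments,
                                   dispersion, n_ch, k_min, k_max)
    if select not in criteria.columns:
        raise NeurofuseError(f"unknown selection criterion {select!r}")
    if select in ("cv", "dispersion"):
        k_sel = int(criteria[select].idxmin())
    else:
        k_sel = int(criteria[select].idxmax())
    return TAAHCResult(prototypes=prototypes, assignments=assignments,
                       criteria=criteria, k_selected=k_sel)


def _selection_criteria(maps, U, norms, prototypes, assignments, dispersion,
                        n_ch, k_min, k_max) -> pd.DataFrame:
    rows = {}
    total_ss = float(np.sum(norms**2))
    for k in sorted(prototypes):
        P = prototypes[k].maps
        lab = assignments[k]
        corr = np.abs(np.einsum("ij,ij->i", U, P[lab]))
        gev = float(np.sum((norms * corr) ** 2) / total_ss)
        # Pascual-Marqui cross-validation criterion
        resid = np.sum(norms**2 * (1.0 - corr**2))
        sigma2 = resid / (len(lab) * (n_ch - 1))
        cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2 if n_ch - 1 > k else np.inf
        rows[k] = {"gev": gev, "cv": cv, "dispersion": dispersion.get(k, np.nan)}
    tab = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    # Krzanowski-Lai: DIFF(k) = (k-1)^(2/m) W_{k-1} - k^(2/m) W_k
    m = n_ch - 1  # average reference removes one dimension

    def diff(k):
        wa, wb = dispersion.get(k - 1), dispersion.get(k)
        if wa is None or wb is None:
            return np.nan
        return (k - 1) ** (2 / m) * wa - k ** (2 / m) * wb

    kl = {}
    for k in tab.index:
        d1, d2 = diff(k), diff(k + 1)
        kl[k] = abs(d1) / abs(d2) if d2 not in (None, 0) and np.isfinite(d1) and np.isfinite(d2) and d2 != 0 else np.nan
    tab["kl"] = pd.Series(kl)
    return tab


# ---------------------------------------------------------------------------
# backfitting, smoothing, metrics


def backfit(rec: EEGRecording, protos: PrototypeSet,
            gfp_floor: float = 1e-6) -> Segmentation:
    """Label every sample with the prototype of minimal polarity-invariant GMD.

    Minimizing GMD over sign equals maximizing |spatial correlation|.  Samples
    whose GFP falls below ``gfp_floor`` are left unassigned.  The reported GEV
    is the fraction of GFP-weighted variance the labeling explains.
    """
    P = protos.maps
    if P.shape[1] != rec.n_channels:
        raise NeurofuseError(
            f"prototype channels ({P.shape[1]}) != record channels ({rec.n_channels})")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    gfp = data.std(axis=0, ddof=0)
    Pu, _ = _normalize_maps(P)
    Xu, xnorm = _normalize_maps(data.T)
    corr = np.abs(Xu @ Pu.T)  # (samples, K)
    labels = np.argmax(corr, axis=1)
    best = corr[np.arange(len(labels)), labels]
    labels[gfp < gfp_floor] = UNASSIGNED
    ok = labels != UNASSIGNED
    denom = float(np.sum(gfp[ok] ** 2))
    gev = float(np.sum((gfp[ok] * best[ok]) ** 2) / denom) if denom > 0 else 0.0
    return Segmentation(labels=labels, gev=gev, fs=rec.fs, k=protos.k)


def _runs(labels: np.ndarray):
    """Run-length encode: list of (label, start, length)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i - start))
            start = i
    return runs


def smooth_labels(seg: Segmentation, min_dur_ms: float = 30.0) -> Segmentation:
    """Dissolve label runs shorter than ``min_dur_ms``.

    Every sample of a short run is reassigned to the temporally nearest run
    whose duration meets the threshold (ties go to the preceding run);
    repeated until no short run remains or a pass changes nothing.  If no run
    meets the threshold the longest run (first on ties) absorbs everything.
    Unassigned samples are never relabeled.
    """
    labels = seg.labels.copy()
    n = len(labels)
    if n == 0:
        return Segmentation(labels=labels, gev=seg.gev, fs=seg.fs, k=seg.k)
    min_len = int(np.ceil(min_dur_ms / 1000.0 * seg.fs))
    for _ in range(n):  # convergence guaranteed well before n passes
        runs = [r for r in _runs(labels) if r[0] != UNASSIGNED]
        if not runs:
            break
        long_runs = [r for r in runs if r[2] >= min_len]
        if len(long_runs) == len(runs):
            break
        if not long_runs:
            best = max(runs, key=lambda r: (r[2], -r[1]))
            long_runs = [best]
        new = labels.copy()
        # reassign samples of short runs to the nearest long run
        starts = np.array([r[1] for r in long_runs])
        ends = np.array([r[1] + r[2] - 1 for r in long_runs])
        labs = np.array([r[0] for r in long_runs])
        long_set = set((r[1], r[2]) for r in long_runs)
        for lab, start, length in runs:
            if (start, length) in long_set:
                continue
            for i in range(start, start + length):
                # distance to each long run (0 if inside)
                d_before = np.where(i > ends, i - ends, 0)
                d_after = np.where(i < starts, starts - i, 0)
                dist = d_before + d_after
                # ties -> preceding run: among minimal distances prefer the
                # run that ends before i (largest end <= i), else first
                min_d = dist.min()
                cand = np.flatnonzero(dist == min_d)
                preceding = [c for c in cand if ends[c] < i]
                chosen = preceding[-1] if preceding else cand[0]
                new[i] = labs[chosen]
        if np.array_equal(new, labels):
            break
        labels = new
    return Segmentation(labels=labels, gev=seg.gev, fs=seg.fs, k=seg.k)


@dataclass
class MicrostateMetrics:
    per_state: pd.DataFrame  # duration_ms, occurrence, coverage, mean_gfp
    transitions: pd.DataFrame  # K x K row-stochastic, zero diagonal
    unassigned_fraction: float


def microstate_metrics(seg: Segmentation, gfp: GFPSeries) -> MicrostateMetrics:
    """Per-state temporal statistics of a (smoothed) segmentation.

    duration = mean run length (ms); occurrence = runs per second of record;
    coverage = fraction of all samples; mean GFP over the state's samples;
    transitions counted between consecutive distinct runs and normalized per
    source state (self-transitions are impossible at run level).
    """
    labels = seg.labels
    n = len(labels)
    if n == 0 or (labels == UNASSIGNED).all():
        raise NeurofuseError("no assigned samples")
    if len(gfp.values) != n:
        raise NeurofuseError("GFP length mismatch")
    duration_s = n / seg.fs
    runs = [r for r in _runs(labels) if r[0] != UNASSIGNED]
    k = seg.k
    stats = {}
    for s in range(k):
        s_runs = [r for r in runs if r[0] == s]
        n_samples = int(sum(r[2] for r in s_runs))
        stats[s] = {
            "duration_ms": (np.mean([r[2] for r in s_runs]) / seg.fs * 1000.0
                            if s_runs else 0.0),
            "occurrence": len(s_runs) / duration_s,
            "coverage": n_samples / n,
            "mean_gfp": (float(np.mean(gfp.values[labels == s]))
                         if n_samples else 0.0),
        }
    trans = np.zeros((k, k))
    for (a, _, _), (b, _, _) in zip(runs[:-1], runs[1:]):
        if a != b:
            trans[a, b] += 1
    row_sums = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        trans = np.where(row_sums > 0, trans / row_sums, 0.0)
    per_state = pd.DataFrame.from_dict(stats, orient="index")
    return MicrostateMetrics(
        per_state=per_state,
        transitions=pd.DataFrame(trans),
        unassigned_fraction=float((labels == UNASSIGNED).mean()),
    )


# ---------------------------------------------------------------------------
# sklearn-style wrapper and state alignment


class MicrostateSegmenter:
    """TAAHC fit + GMD backfit as a fit/transform estimator.

    ``fit`` extracts GFP peaks from one or more records, clusters them and
    picks K; ``transform`` backfits the prototypes to a record, smooths, and
    returns the segmentation.
    """

    def __init__(self, k_min: int = 2, k_max: int = 8, n_peaks: int = 1000,
                 min_dist_ms: float = 10.0, min_dur_ms: float = 30.0,
                 select: str = "kl", k_fixed: int | None = None):
        self.k_min = k_min
        self.k_max = k_max
        self.n_peaks = n_peaks
        self.min_dist_ms = min_dist_ms
        self.min_dur_ms = min_dur_ms
        self.select = select
        self.k_fixed = k_fixed

    def fit(self, recs: EEGRecording | list[EEGRecording]):
        if isinstance(recs, EEGRecording):
            recs = [recs]
        all_maps = []
        for rec in recs:
            g = compute_gfp(rec)
            _, maps = extract_gfp_peaks(g, rec, n_peaks=self.n_peaks,
                                        min_dist_ms=self.min_dist_ms)
            all_maps.append(maps)
        maps = np.vstack(all_maps)
        self.result_ = taahc_cluster(maps, self.k_min, self.k_max, self.select)
        self.k_ = self.k_fixed or self.result_.k_selected
        self.prototypes_ = self.result_.prototypes[self.k_]
        self.criteria_ = self.result_.criteria
        return self

    def transform(self, rec: EEGRecording) -> Segmentation:
        if not hasattr(self, "prototypes_"):
            raise NeurofuseError("fit before transform")
        seg = backfit(rec, self.prototypes_)
        return smooth_labels(seg, self.min_dur_ms)

    def metrics(self, rec: EEGRecording) -> MicrostateMetrics:
        seg = self.transform(rec)
        return microstate_metrics(seg, compute_gfp(rec))


def align_states(protos_true: np.ndarray, protos_est: np.ndarray) -> np.ndarray:
    """Optimal (Hungarian) matching of estimated states to true states.

    Returns ``perm`` with ``perm[est_state] = true_state``, maximizing total
    absolute spatial correlation.
    """
    A, _ = _normalize_maps(np.asarray(protos_true, float))
    B, _ = _normalize_maps(np.asarray(protos_est, float))
    cost = -np.abs(B @ A.T)  # (est, true)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm
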