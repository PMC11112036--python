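"""PCA spike sorting: waveform-window features, clustering, unit statistics.

Detected cutouts are projected by PCA fitted on the 1.4-2.4 ms segment of
the 5 ms cutout (samples 42..71 at 30 kHz, half-open).  That window covers
the repolarization tail, where waveforms of different neurons on the same
electrode differ most, and yields the familiar two-dimensional point-cloud
plot (one point per spike, one color per cluster).

Cluster count is selected per electrode by BIC over a Gaussian mixture with
full covariances, bounded by ``max_units`` (1-3 units per electrode is
typical for these preparations); k-means with a fixed k is available as a
fallback.  Every spike is assigned to a unit by default; optional
Mahalanobis outlier flagging can divert far-out events to a ``noise`` label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from . import bursts as _bursts
from .errors import ConfigurationError

__all__ = [
    "SortingParams",
    "UnitAssignment",
    "extract_features",
    "realign_cutouts",
    "cluster_units",
    "sort_electrode",
    "summarize_units",
    "match_units_across_sessions",
]

NOISE_LABEL = "noise"


def realign_cutouts(cutouts: np.ndarray, target_index: int | None = None) -> np.ndarray:
    """Shift each cutout so its absolute extremum sits at a common sample.

    Detection timestamps events at the first threshold crossing, which
    jitters by a few samples with noise; that jitter moves the PCA window
    over the waveform and splits one unit into several sub-clusters.
    Re-aligning on the extremum (default target: the median extremum index
    across events) removes the jitter before feature extraction.  Samples
    shifted in from beyond an edge take the edge value.
    """
    cutouts = np.asarray(cutouts, dtype=np.float64)
    if cutouts.size == 0:
        return cutouts
    n = cutouts.shape[1]
    peaks = np.argmax(np.abs(cutouts), axis=1)
    if target_index is None:
        target_index = int(np.median(peaks))
    grid = np.arange(n, dtype=np.float64)
    out = np.empty_like(cutouts)
    for i, (c, p) in enumerate(zip(cutouts, peaks)):
        # sub-sample peak position by parabolic interpolation through the
        # extremum and its neighbours; residual fractional jitter otherwise
        # smears events along the waveform-derivative direction in PCA space
        frac = 0.0
        if 0 < p < n - 1:
            y0, y1, y2 = np.abs(c[p - 1 : p + 2])
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        shift = target_index - (p + frac)
        out[i] = np.interp(grid - shift, grid, c)
    return out


@dataclass(frozen=True)
class SortingParams:
    window_start_ms: float = 1.4
    window_end_ms: float = 2.4
    n_components: int = 2
    max_units: int = 3
    min_cluster_fraction: float = 0.02
    cluster_selection: str = "bic"  # or "fixed_k"
    fixed_k: int = 1
    align: str = "extremum"  # re-align cutouts on the waveform extremum; or "none"
    outlier_mahalanobis: float | None = None  # e.g. 4.0 to flag noise events
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.window_start_ms < self.window_end_ms:
            raise ConfigurationError("need 0 <= window_start_ms < window_end_ms")
        if self.max_units < 1 or self.n_components < 1:
            raise ConfigurationError("max_units and n_components must be >= 1")
        if self.cluster_selection not in ("bic", "fixed_k"):
            raise ConfigurationError(
                f"unknown cluster_selection {self.cluster_selection!r}"
            )
        if self.align not in ("extremum", "none"):
            raise ConfigurationError(f"unknown align mode {self.align!r}")

    def window_indices(self, fs: float) -> tuple[int, int]:
        """Half-open sample window on the cutout; 1.4-2.4 ms at 30 kHz = [42, 72)."""
        lo = round(self.window_start_ms / 1000.0 * fs)
        hi = round(self.window_end_ms / 1000.0 * fs)
        return lo, hi


@dataclass
class UnitAssignment:
    """Sorting result for one electrode."""

    electrode_id: str
    unit_labels: list[str]  # per event: 'U1'..'Uk' or 'noise'
    pca_scores: np.ndarray  # (n_events, n_components)
    templates: dict[str, np.ndarray]  # mean cutout per unit
    sortable: bool = True

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.templates, key=lambda u: int(u[1:]))

    @property
    def n_units(self) -> int:
        return len(self.templates)


def extract_features(
    cutouts: np.ndarray,
    params: SortingParams | None = None,
    sampling_rate: float = 30000.0,
) -> tuple[np.ndarray, bool]:
    """PCA scores of the cutout window; returns (scores, sortable).

    PCA is fitted on the windowed samples only.  Electrodes with fewer than
    ``max(10, n_components + 1)`` cutouts are unsortable: the caller labels
    every event U1 and the returned scores are zeros.
    """
    params = params or SortingParams()
    cutouts = np.asarray(cutouts, dtype=np.float64)
    n_events = cutouts.shape[0]
    min_events = max(10, params.n_components + 1)
    if n_events < min_events:
        return np.zeros((n_events, params.n_components)), False
    lo, hi = params.window_indices(sampling_rate)
    window = cutouts[:, lo:hi]
    n_comp = min(params.n_components, window.shape[1])
    if np.allclose(window, window[0]):  # identical cutouts: all scores at origin
        return np.zeros((n_events, n_comp)), True
    pca = PCA(n_components=n_comp, random_state=params.seed)
    scores = pca.fit_transform(window)
    return scores, True


def _select_k_bic(scores: np.ndarray, params: SortingParams) -> tuple[int, np.ndarray]:
    best_k, best_bic, best_labels = 1, np.inf, np.zeros(len(scores), dtype=int)
    for k in range(1, params.max_units + 1):
        if k > len(scores):
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=params.seed,
            n_init=3,
            reg_covar=1e-6,
        ).fit(scores)
        bic = gm.bic(scores)
        if bic < best_bic:
            best_k, best_bic, best_labels = k, bic, gm.predict(scores)
    return best_k, best_labels


def _merge_small_clusters(scores: np.ndarray, labels: np.ndarray, min_frac: float) -> np.ndarray:
    """Fold clusters below the minimum fraction into the nearest big cluster."""
    labels = labels.copy()
    n = len(labels)
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[counts < min_frac * n]
        if small.size == 0:
            break
        big = [i for i in ids if i not in small]
        if not big:
            break
        centroids = {i: scores[labels == i].mean(axis=0) for i in big}
        lab = small[0]
        for idx in np.flatnonzero(labels == lab):
            d = {i: np.linalg.norm(scores[idx] - c) for i, c in centroids.items()}
            labels[idx] = min(d, key=d.get)
    return labels


def cluster_units(pca_scores: np.ndarray, params: SortingParams | None = None) -> np.ndarray:
    """Cluster PCA scores into k in 1..max_units; returns integer labels.

    'bic': Gaussian mixture, k minimizing BIC.  'fixed_k': k-means at
    ``fixed_k``.  Clusters smaller than ``min_cluster_fraction`` of events
    are merged into their nearest neighbour.  Deterministic given seed.
    """
    params = params or SortingParams()
    scores = np.asarray(pca_scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ConfigurationError("pca_scores must be finite")
    n = scores.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    if np.allclose(scores, scores[0]):
        return np.zeros(n, dtype=int)
    if params.cluster_selection == "fixed_k":
        k = min(params.fixed_k, n)
        labels = KMeans(n_clusters=k, random_state=params.seed, n_init=10).fit_predict(scores)
    else:
        _, labels = _select_k_bic(scores, params)
    labels = _merge_small_clusters(scores, labels, params.min_cluster_fraction)
    # renumber 0..k-1 in first-appearance order (stable across label permutation)
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _mahalanobis_outliers(scores: np.ndarray, labels: np.ndarray, cut: float) -> np.ndarray:
    """True where an event sits more than ``cut`` SDs from its cluster centre."""
    out = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        if len(pts) < scores.shape[1] + 2:
            continue
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T) + 1e-9 * np.eye(scores.shape[1])
        inv = np.linalg.inv(cov)
        d = np.sqrt(np.einsum("ij,jk,ik->i", scores - mu, inv, scores - mu))
        out[labels == lab] = d > cut
    return out


def sort_electrode(
    events,
    params: SortingParams | None = None,
    sampling_rate: float = 30000.0,
    electrode_id: str = "",
) -> UnitAssignment:
    """Full per-electrode sorting: features, clustering, unit naming, templates.

    Units are named U1..Uk in order of descending spike count.  Unsortable
    electrodes (too few events) put every event in U1.
    """
    params = params or SortingParams()
    events = list(events)
    if not events:
        return UnitAssignment(electrode_id, [], np.zeros((0, params.n_components)), {})
    cutouts = np.stack([e.cutout for e in events])
    if params.align == "extremum":
        cutouts = realign_cutouts(cutouts)
    scores, sortable = extract_features(cutouts, params, sampling_rate)
    if not sortable:
        labels = np.zeros(len(events), dtype=int)
    else:
        labels = cluster_units(scores, params)
    str_labels = np.empty(len(events), dtype=object)
    noise_mask = np.zeros(len(events), dtype=bool)
    if params.outlier_mahalanobis is not None and sortable and scores.size:
        noise_mask = _mahalanobis_outliers(scores, labels, params.outlier_mahalanobis)
    # order units by descending spike count (ties: lower original label first)
    kept = labels[~noise_mask]
    order = sorted(np.unique(kept), key=lambda lab: (-(kept == lab).sum(), lab))
    rename = {lab: f"U{r + 1}" for r, lab in enumerate(order)}
    templates: dict[str, np.ndarray] = {}
    for i in range(len(events)):
        str_labels[i] = NOISE_LABEL if noise_mask[i] else rename[labels[i]]
    for lab, name in rename.items():
        sel = (labels == lab) & ~noise_mask
        templates[name] = cutouts[sel].mean(axis=0)
    return UnitAssignment(
        electrode_id=electrode_id,
        unit_labels=list(str_labels),
        pca_scores=scores,
        templates=templates,
        sortable=sortable,
    )


def summarize_units(
    events,
    unit_labels: list[str],
    recording_duration: float,
    burst_params: _bursts.BurstParams | None = None,
) -> pd.DataFrame:
    """Per-unit statistics: spike count, mean frequency, firing-pattern label.

    Noise-labelled events are excluded; units with zero spikes do not appear.
    Mean frequency is count / recording_duration; the pattern label applies
    the burst-based classifier to the unit's own spike train.
    """
    if recording_duration <= 0:
        raise ConfigurationError("recording_duration must be > 0")
    events = list(events)
    rows = []
    labels = np.asarray(unit_labels, dtype=object)
    times = np.array([e.time for e in events], dtype=float)
    for name in sorted(set(labels) - {NOISE_LABEL}, key=lambda u: int(str(u)[1:])):
        t = np.sort(times[labels == name])
        if t.size == 0:
            continue
        rows.append(
            {
                "unit_label": name,
                "n_spikes": int(t.size),
                "mean_frequency_hz": t.size / recording_duration,
                "pattern": _bursts.classify_pattern(
                    t, frame_duration=recording_duration, params=burst_params
                ),
            }
        )
    return pd.DataFrame(rows, columns=["unit_label", "n_spikes", "mean_frequency_hz", "pattern"])


def match_units_across_sessions(
    templates_day_a: dict[str, np.ndarray],
    templates_day_b: dict[str, np.ndarray],
    correlation_floor: float = 0.8,
) -> tuple[list[tuple[str, str, float]], list[str], list[str]]:
    """Pair units across two sessions by greedy maximum template correlation.

    Pearson correlation of templates is scale-invariant, so amplitude drift
    between sessions does not break the pairing.  Pairs below
    ``correlation_floor`` stay unmatched.  Returns (pairs, unmatched_a,
    unmatched_b) with pairs as (unit_a, unit_b, correlation).
    """
    names_a, names_b = list(templates_day_a), list(templates_day_b)
    pairs: list[tuple[str, str, float]] = []
    if names_a and names_b:
        corr = np.full((len(names_a), len(names_b)), -np.inf)
        for i, a in enumerate(names_a):
            for j, b in enumerate(names_b):
                ta, tb = templates_day_a[a], templates_day_b[b]
                if np.std(ta) == 0 or np.std(tb) == 0:
                    continue
                corr[i, j] = np.corrcoef(ta, tb)[0, 1]
        free_a, free_b = set(range(len(names_a))), set(range(len(names_b)))
        while free_a and free_b:
            best = max(
                ((i, j) for i in free_a for j in free_b), key=lambda ij: corr[ij]
            )
            if corr[best] < correlation_floor:
                break
            i, j = best
            pairs.append((names_a[i], names_b[j], float(corr[i, j])))
            free_a.discard(i)
            free_b.discard(j)
    matched_a = {a for a, _, _ in pairs}
    matched_b = {b for _, b, _ in pairs}
    return (
        pairs,
        [a for a in names_a if a not in matched_a],
        [b for b in names_b if b not in matched_b],
    )
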