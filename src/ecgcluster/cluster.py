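"""K-means clustering of ECG feature vectors and label-association metrics.

The clustering is plain Lloyd iteration under Euclidean distance
D(X_i, X_j) = sqrt(sum_k (x_ik - x_jk)^2), initialized with k data points
drawn at random (seeded), and monitored through the square-error criterion

    E = sum_i sum_{p in C_i} |p - m_i|^2

which is non-increasing across iterations. Cluster-label association is
summarized two ways: the *ratio* of condition-positive subjects within a
group (> 50% read as a significant association), and the *concentricity* of
a condition — the largest single-group share of all its positive subjects,
which remains informative when positives are too few for any ratio to clear
50%. Subjects whose flag for a condition is unknown are clustered normally
but excluded from that condition's numerators and denominators.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import cohort as cohort_mod
from .io import CONDITIONS, ECGSignal, MedicalRecord, read_records_csv, read_signal_csv
from .preprocess import FilterSpec, denoise, detect_qrs
from .rbp import subject_rbp_feature
from .waveform import subject_waveform_feature
from .wavelet import subject_wavelet_feature

log = logging.getLogger(__name__)


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclasses.dataclass
class FeatureMatrix:
    """Rows of equal-dimension feature vectors keyed by subject id."""

    ids: list[str]
    X: np.ndarray
    tag: str = ""
    column_mean: Optional[np.ndarray] = None
    column_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("feature matrix must be 2-D with one row per id")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")

    def standardized(self) -> "FeatureMatrix":
        """Z-score each column (constant columns map to zero)."""
        mean = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
        return FeatureMatrix(
            ids=list(self.ids),
            X=(self.X - mean) / safe,
            tag=self.tag,
            column_mean=mean,
            column_sd=sd,
        )


@dataclasses.dataclass
class ClusterModel:
    """Fitted k-means state: centers, 0-based labels, square error E."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    sse: float
    n_iter: int
    seed: int
    sse_history: list[float]


def _sse(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((X - centers[labels]) ** 2))


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)  # ties -> lowest group index
        # recompute centers as means; re-seed empty clusters at the point
        # farthest from its nearest center
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
        empty = [j for j in range(k) if not np.any(new_labels == j)]
        if empty:
            d2 = cdist(X, centers, metric="sqeuclidean")
            nearest = d2.min(axis=1)
            for j in empty:
                far = int(np.argmax(nearest))
                centers[j] = X[far]
                nearest[far] = -np.inf
            d2 = cdist(X, centers, metric="sqeuclidean")
            new_labels = np.argmin(d2, axis=1)
            for j in range(k):
                mask = new_labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
        e = _sse(X, centers, new_labels)
        converged = bool(np.array_equal(new_labels, labels)) or (
            len(history) > 0 and abs(history[-1] - e) < tol
        )
        labels = new_labels
        history.append(e)
        if converged:
            break
    return centers, labels, history[-1], len(history), history


def kmeans(
    features: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    n_init: int = 1,
) -> ClusterModel:
    """Lloyd's k-means with random data-point initialization.

    ``n_init`` > 1 restarts from fresh random initializations and keeps the
    lowest-E fit (the single-start default matches initializing once from k
    random samples). Deterministic given ``seed``.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, labels, e, it, hist = _lloyd(X, k, rng, max_iter, tol)
        if best is None or e < best[2]:
            best = (centers, labels, e, it, hist)
    centers, labels, e, it, hist = best
    return ClusterModel(
        k=k, centers=centers, labels=labels, sse=e, n_iter=it, seed=seed, sse_history=hist
    )


# ---------------------------------------------------------------------------
# crosstab + association metrics


@dataclasses.dataclass
class CrossTab:
    """Per-group sizes and condition counts among subjects with known flags."""

    k: int
    group_sizes: np.ndarray  # total members per group
    positives: dict[str, np.ndarray]  # known positives per group
    known: dict[str, np.ndarray]  # known-flag members per group
    total_positives: dict[str, int]

    @classmethod
    def from_counts(
        cls,
        group_sizes: Sequence[int],
        positives: dict[str, Sequence[int]],
        known: Optional[dict[str, Sequence[int]]] = None,
    ) -> "CrossTab":
        """Build a crosstab directly from printed per-group counts (all flags
        assumed known unless ``known`` is given)."""
        sizes = np.asarray(group_sizes, dtype=int)
        pos = {c: np.asarray(v, dtype=int) for c, v in positives.items()}
        kn = (
            {c: np.asarray(v, dtype=int) for c, v in known.items()}
            if known
            else {c: sizes.copy() for c in pos}
        )
        totals = {c: int(v.sum()) for c, v in pos.items()}
        return cls(len(sizes), sizes, pos, kn, totals)


def crosstab(model: ClusterModel, ids: Sequence[str], records: Sequence[MedicalRecord]) -> CrossTab:
    """Tabulate group sizes and per-condition positive counts.

    Unknown flags are excluded from both the condition's counts and its
    denominators. A clustered subject without a record is an error.
    """
    by_id = {r.subject_id: r for r in records}
    missing = [sid for sid in ids if sid not in by_id]
    if missing:
        raise KeyError(f"no medical record for subject(s) {missing}")
    k = model.k
    sizes = np.bincount(model.labels, minlength=k)
    positives = {c: np.zeros(k, dtype=int) for c in CONDITIONS}
    known = {c: np.zeros(k, dtype=int) for c in CONDITIONS}
    for sid, g in zip(ids, model.labels):
        rec = by_id[sid]
        for c in CONDITIONS:
            flag = rec.flag(c)
            if flag is None:
                continue
            known[c][g] += 1
            if flag:
                positives[c][g] += 1
    totals = {c: int(positives[c].sum()) for c in CONDITIONS}
    return CrossTab(k, sizes, positives, known, totals)


def ratio(tab: CrossTab, condition: str, group: int) -> Optional[float]:
    """Fraction of group ``group`` (1-based, as printed in reports) positive
    for ``condition``, among members with a known flag. ``None`` when the
    group has no known-flag members. A value > 0.5 is read as a significant
    association."""
    if condition not in tab.positives:
        raise KeyError(f"unknown condition {condition!r}")
    if not 1 <= group <= tab.k:
        raise IndexError(f"group {group} outside 1..{tab.k}")
    denom = int(tab.known[condition][group - 1])
    if denom == 0:
        return None
    return tab.positives[condition][group - 1] / denom


def concentricity(tab: CrossTab, condition: str) -> Optional[tuple[float, int]]:
    """Largest single-group share of all known positives for ``condition``,
    with the achieving group (1-based). ``None`` when the cohort has no known
    positives."""
    if condition not in tab.positives:
        raise KeyError(f"unknown condition {condition!r}")
    total = tab.total_positives[condition]
    if total == 0:
        return None
    counts = tab.positives[condition]
    g = int(np.argmax(counts))
    return counts[g] / total, g + 1


def render_crosstab(tab: CrossTab, title: str = "") -> str:
    """Aligned text table: one row per group, condition counts as columns."""
    header = ["Category", "Number", *[c.capitalize() for c in CONDITIONS]]
    rows = [header]
    for g in range(tab.k):
        rows.append(
            [
                f"Group {g + 1}",
                str(int(tab.group_sizes[g])),
                *[str(int(tab.positives[c][g])) for c in CONDITIONS],
            ]
        )
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
    if title:
        lines.insert(0, title)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclasses.dataclass
class PipelineConfig:
    """Full-run configuration: cohort source, feature sets, k values, seeds."""

    cohort: Optional[cohort_mod.CohortConfig] = None
    cohort_dir: Optional[str] = None
    feature_sets: tuple[str, ...] = ("rbp", "waveform", "wavelet")
    ks: tuple[int, ...] = (2, 4, 8)
    cluster_seed: int = 0
    n_init: int = 1
    rbp_m: int = 8
    wavelet_level: int = 6
    wavelet_family: str = "db4"
    filter_spec: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    refractory_ms: float = 200.0
    min_amplitude_fraction: float = 0.3
    standardize: str = "auto"  # auto | always | never

    def __post_init__(self) -> None:
        known = {"rbp", "waveform", "wavelet"}
        bad = set(self.feature_sets) - known
        if bad:
            raise ValueError(f"unknown feature set(s) {sorted(bad)}")
        if self.cohort is None and self.cohort_dir is None:
            self.cohort = cohort_mod.CohortConfig()


def _load_inputs(config: PipelineConfig) -> tuple[list[ECGSignal], list[MedicalRecord]]:
    if config.cohort_dir is not None:
        d = Path(config.cohort_dir)
        records = read_records_csv(d / "records.csv")
        signals = [read_signal_csv(d / f"{r.subject_id}.csv", subject_id=r.subject_id) for r in records]
        return signals, records
    return cohort_mod.generate_cohort(config.cohort)


def _standardize_for(config: PipelineConfig, tag: str) -> bool:
    if config.standardize == "always":
        return True
    if config.standardize == "never":
        return False
    # waveform mixes ms, mV, mV/ms and mV*ms; RBP is already a normalized
    # histogram and wavelet coefficients share units
    return tag == "waveform"


def extract_features(
    config: PipelineConfig,
    signals: Sequence[ECGSignal],
    tag: str,
) -> tuple[FeatureMatrix, list[str]]:
    """Denoise, detect QRS, and build the per-subject feature matrix for one
    feature set; returns the matrix and the ids of excluded subjects."""
    ids, rows, excluded = [], [], []
    for sig in signals:
        clean = denoise(sig, config.filter_spec)
        peaks = detect_qrs(clean, config.refractory_ms, config.min_amplitude_fraction)
        if tag == "rbp":
            vec = subject_rbp_feature(clean, config.rbp_m) if len(peaks) >= 2 else None
        elif tag == "waveform":
            vec = subject_waveform_feature(clean, peaks) if len(peaks) >= 3 else None
        else:
            vec = (
                subject_wavelet_feature(clean, peaks, config.wavelet_level, config.wavelet_family)
                if len(peaks) >= 3
                else None
            )
        if vec is None:
            excluded.append(sig.subject_id)
        else:
            ids.append(sig.subject_id)
            rows.append(vec)
    if not rows:
        raise ValueError(f"no usable subjects for feature set {tag!r}")
    return FeatureMatrix(ids=ids, X=np.stack(rows), tag=tag), excluded


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate/load the cohort, extract each feature set, cluster at each k,
    and report crosstabs plus ratio/concentricity metrics as a JSON-ready
    dict (deterministic given the config)."""
    signals, records = _load_inputs(config)
    report: dict = {
        "n_subjects": len(signals),
        "feature_sets": {},
        "conditions": list(CONDITIONS),
    }
    if config.cohort is not None and config.cohort_dir is None:
        report["cohort_seed"] = config.cohort.seed
    for fi, tag in enumerate(config.feature_sets):
        matrix, excluded = extract_features(config, signals, tag)
        fitted = matrix.standardized() if _standardize_for(config, tag) else matrix
        entry: dict = {
            "n_clustered": len(matrix.ids),
            "excluded": excluded,
            "standardized": _standardize_for(config, tag),
            "dimension": int(matrix.X.shape[1]),
            "k": {},
        }
        for ki, k in enumerate(config.ks):
            seed = (config.cluster_seed * 1_000_003 + 101 * fi + ki) % 2**31
            model = kmeans(fitted, k, seed=seed, n_init=config.n_init)
            tab = crosstab(model, matrix.ids, records)
            metrics: dict = {"ratio": {}, "concentricity": {}}
            for cond in CONDITIONS:
                ratios = [ratio(tab, cond, g) for g in range(1, k + 1)]
                metrics["ratio"][cond] = ratios
                metrics["significant"] = metrics.get("significant", {})
                metrics["significant"][cond] = [
                    bool(r is not None and r > 0.5) for r in ratios
                ]
                conc = concentricity(tab, cond)
                metrics["concentricity"][cond] = (
                    None if conc is None else {"value": conc[0], "group": conc[1]}
                )
            entry["k"][str(k)] = {
                "sse": model.sse,
                "iterations": model.n_iter,
                "seed": seed,
                "group_sizes": np.bincount(model.labels, minlength=k).tolist(),
                "crosstab": {
                    "sizes": tab.group_sizes.tolist(),
                    **{c: tab.positives[c].tolist() for c in CONDITIONS},
                },
                "metrics": metrics,
                "table": render_crosstab(tab, title=f"{tag} feature, k={k}"),
            }
        report["feature_sets"][tag] = entry
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
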