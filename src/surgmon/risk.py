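"""Temporal risk scoring from the two classifier probability streams.

Per second t, the phase network emits P(important phase) and the problem
network P(problem). Both streams are smoothed with a trailing 10-second
moving average (undefined for the first window-1 seconds — no padding is
invented), and the risk level is their product

    D_t = PA_t(important) * TA_t(problem),

which rises exactly when a problem occurs during a critical phase. The
first second with D_t >= threshold is the estimated problem time; a
video's score is its maximum defined D_t, and per-video detection is
evaluated with an ROC curve, its AUC, and the Youden-J operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

DEFAULT_WINDOW = 10

#: class order of the two probability streams
PHASE_CLASSES = ("other", "important")
PROBLEM_CLASSES = ("without", "with")


@dataclass
class ProbabilitySeries:
    """Per-second class-probability vectors of one classifier over a video."""

    video_id: str
    probs: np.ndarray    # (T, n_classes), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a nonempty (T, n_classes) array")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def moving_average(series: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Trailing moving average over the time axis.

    Output t is the mean of entries t-window+1 .. t and is NaN (undefined)
    for t < window-1. Accepts (T,) or (T, C) arrays.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.shape[0] < 1:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    out = np.full_like(x, np.nan, dtype=np.float64)
    if x.shape[0] >= window:
        c = np.cumsum(x, axis=0)
        head = c[window - 1]
        tail = c[window:] - c[:-window]
        out[window - 1] = head / window
        out[window:] = tail / window
    return out


def risk_level(phase_avg: np.ndarray, problem_avg: np.ndarray) -> np.ndarray:
    """Elementwise product of the two smoothed streams (NaN where undefined)."""
    pa = np.asarray(phase_avg, dtype=np.float64)
    ta = np.asarray(problem_avg, dtype=np.float64)
    if pa.shape != ta.shape:
        raise ValueError("the two streams must share one time index")
    return pa * ta


def estimate_problem_time(dt: np.ndarray, threshold: float) -> int | None:
    """First second with D_t >= threshold, or None if never reached.

    The crossing uses >= so a perfect score still fires at threshold 1.0;
    undefined (NaN) warm-up entries never fire.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    dt = np.asarray(dt, dtype=np.float64)
    hits = np.flatnonzero(~np.isnan(dt) & (dt >= threshold))
    return int(hits[0]) if hits.size else None


def video_score(dt: np.ndarray) -> float:
    """Per-video risk score: the maximum defined D_t."""
    dt = np.asarray(dt, dtype=np.float64)
    if np.isnan(dt).all():
        raise ValueError("risk series has no defined entries")
    return float(np.nanmax(dt))


@dataclass
class RiskSeries:
    """Risk trace of one video plus its detection threshold and estimate."""

    video_id: str
    phase_avg: np.ndarray
    problem_avg: np.ndarray
    dt: np.ndarray
    threshold: float
    estimated_time: int | None
    score: float


def compute_risk(phase_probs: ProbabilitySeries, problem_probs: ProbabilitySeries,
                 threshold: float = 0.5, window: int = DEFAULT_WINDOW) -> RiskSeries:
    """Full fusion of one video's two streams into a RiskSeries.

    Uses the "important phase" column of the phase stream and the "with
    problem" column of the problem stream (the only pairing under which
    D_t rises exactly when a problem occurs during a critical phase).
    """
    if phase_probs.probs.shape[0] != problem_probs.probs.shape[0]:
        raise ValueError("streams must cover the same seconds")
    pa = moving_average(phase_probs.probs[:, 1], window)
    ta = moving_average(problem_probs.probs[:, 1], window)
    dt = risk_level(pa, ta)
    return RiskSeries(phase_probs.video_id, pa, ta, dt, threshold,
                      estimate_problem_time(dt, threshold), video_score(dt))


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, float, float]:
    """ROC points, trapezoid AUC and the Youden-J operating threshold.

    Returns (roc_points, auc, threshold) where roc_points has rows
    (fpr, tpr, threshold).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to draw an ROC curve")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    j = tpr - fpr
    op = float(thr[int(np.argmax(j))])
    return np.column_stack([fpr, tpr, thr]), auc, op


def frame_confusion(predictions: np.ndarray, labels: np.ndarray,
                    class_names: tuple[str, str] = PHASE_CLASSES) -> dict:
    """Row-normalized 2x2 confusion table with per-class correct-response
    rates (percent) and their class-frequency-weighted mean."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    counts = np.zeros((2, 2), dtype=np.int64)
    for true_c in (0, 1):
        sel = labels == true_c
        counts[true_c, 0] = int(((predictions == 0) & sel).sum())
        counts[true_c, 1] = int(((predictions == 1) & sel).sum())
    totals = counts.sum(axis=1)
    rates = np.where(totals[:, None] > 0, 100.0 * counts / np.maximum(totals[:, None], 1), np.nan)
    per_class = {class_names[c]: float(rates[c, c]) for c in (0, 1)}
    mean = 100.0 * counts.trace() / max(counts.sum(), 1)
    return {"counts": counts, "rates_percent": rates,
            "per_class_percent": per_class, "mean_percent": float(mean)}


def lead_time_histogram(estimated: list[float], annotated: list[float],
                        bin_width: float = 30.0) -> dict:
    """Lead times (estimated - annotated, seconds) of true-positive videos.

    Negative values mean the detector fired earlier than the annotation.
    """
    if len(estimated) != len(annotated):
        raise ValueError("estimated and annotated time lists must pair up")
    diffs = np.asarray(estimated, dtype=np.float64) - np.asarray(annotated, dtype=np.float64)
    if diffs.size:
        lo = np.floor(diffs.min() / bin_width) * bin_width
        hi = np.ceil(diffs.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        hist, edges = np.histogram(diffs, bins=edges)
    else:
        hist, edges = np.array([], dtype=int), np.array([0.0])
    return {"differences": diffs, "hist": hist, "bin_edges": edges}


@dataclass
class DetectionReport:
    """Per-frame and per-video detection summary of one evaluation run."""

    frame_phase: dict
    frame_problem: dict
    roc_points: np.ndarray
    auc: float
    operating_threshold: float
    lead_times: dict

    def to_dict(self) -> dict:
        return {
            "frame_phase": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in self.frame_phase.items()},
            "frame_problem": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                              for k, v in self.frame_problem.items()},
            "roc_points": self.roc_points.tolist(),
            "auc": self.auc,
            "operating_threshold": self.operating_threshold,
            "lead_times": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in self.lead_times.items()},
        }


def detection_report(phase_preds, phase_labels, problem_preds, problem_labels,
                     video_scores, video_labels, estimated_times, annotated_times
                     ) -> DetectionReport:
    """Assemble the full evaluation: per-frame confusion tables for both
    classifiers, the per-video ROC/AUC with its Youden threshold, and the
    lead-time histogram of the true-positive videos."""
    roc, auc, op = roc_auc(video_scores, video_labels)
    return DetectionReport(
        frame_confusion(phase_preds, phase_labels, PHASE_CLASSES),
        frame_confusion(problem_preds, problem_labels, PROBLEM_CLASSES),
        roc, auc, op,
        lead_time_histogram(estimated_times, annotated_times))


def plot_roc(roc_points: np.ndarray, auc: float, path) -> None:
    """Write the per-video ROC curve to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_points[:, 0], roc_points[:, 1], "-o", ms=3)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"problem detection per video (AUC {auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lead_times(lead: dict, path) -> None:
    """Write the lead-time histogram (negative = earlier than annotation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3))
    edges = lead["bin_edges"]
    if len(edges) > 1:
        ax.bar(edges[:-1], lead["hist"], width=np.diff(edges), align="edge",
               edgecolor="black")
    ax.set_xlabel("estimated - annotated time [s]")
    ax.set_ylabel("videos")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def simulate_streams(n_videos: int = 40, duration: int = 240,
                     problem_fraction: float = 0.5, onset_range=(60, 180),
                     p_low: float = 0.1, p_high: float = 0.9,
                     noise: float = 0.05, seed: int = 0) -> list[dict]:
    """Synthetic per-video probability streams for end-to-end evaluation.

    Each video's problem stream sits at ``p_low`` and jumps to ``p_high``
    at a random onset (problem videos only); the phase stream is high for
    the middle half of the video. Gaussian noise of the given std is added
    and probabilities are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    n_problem = int(round(problem_fraction * n_videos))
    out = []
    for i in range(n_videos):
        has_problem = i < n_problem
        onset = int(rng.integers(*onset_range)) if has_problem else None
        p_problem = np.full(duration, p_low)
        if has_problem:
            p_problem[onset:] = p_high
        p_phase = np.full(duration, 0.05)
        p_phase[duration // 4: 3 * duration // 4] = 0.95
        p_problem = np.clip(p_problem + rng.normal(0, noise, duration), 0, 1)
        p_phase = np.clip(p_phase + rng.normal(0, noise, duration), 0, 1)
        out.append({
            "video_id": f"sim_{i:03d}", "label": int(has_problem), "onset": onset,
            "phase": ProbabilitySeries(f"sim_{i:03d}",
                                       np.column_stack([1 - p_phase, p_phase])),
            "problem": ProbabilitySeries(f"sim_{i:03d}",
                                         np.column_stack([1 - p_problem, p_problem])),
        })
    return out
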