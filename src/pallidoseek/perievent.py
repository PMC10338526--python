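"""Peri-event alignment of ΔF/F, class averages, trial-progression
trends, and pointwise group comparisons.

Snippets are aligned on behavioral events with a half-open window
[t - pre_s, t + post_s): ``pre_s * fps`` pre-event frames followed by
``post_s * fps`` post-event frames, the event frame being the first
frame of the post window (index 60 at the 2 s / 2 s / 30 fps defaults,
120 frames total).  Events whose window leaves the defined (non-NaN)
part of the trace are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .photometry import DffTrace
from .synthetic import BehavioralEvent, EventType

logger = logging.getLogger(__name__)

#: the six behavioral event classes used throughout the analyses
EVENT_CLASSES = ("NP R+", "NP R-", "M_entry R+", "M_entry R-",
                 "M_exit R+", "M_exit R-")

_CLASS_OF = {
    (EventType.NOSE_POKE_ACTIVE, True): "NP R+",
    (EventType.NOSE_POKE_ACTIVE, False): "NP R-",
    (EventType.MAGAZINE_ENTRY, True): "M_entry R+",
    (EventType.MAGAZINE_ENTRY, False): "M_entry R-",
    (EventType.MAGAZINE_EXIT, True): "M_exit R+",
    (EventType.MAGAZINE_EXIT, False): "M_exit R-",
}

#: selectable per-event "degree of change" metrics for the trend analysis
TREND_METRICS = ("post_minus_pre_mean", "peak_minus_pre_mean", "post_auc")


@dataclass
class PeriEventMatrix:
    """events × frames ΔF/F snippets with per-row class labels."""

    snippets: np.ndarray          # (n_events, n_frames)
    event_class: np.ndarray       # per-row label from EVENT_CLASSES
    event_time_s: np.ndarray      # session time of each aligned event
    event_index_within_class: np.ndarray
    fps: float
    pre_s: float
    post_s: float
    n_excluded: int = 0

    @property
    def n_events(self) -> int:
        return self.snippets.shape[0]

    @property
    def n_frames(self) -> int:
        return self.snippets.shape[1]

    @property
    def event_frame(self) -> int:
        """Index of the first post-event frame."""
        return int(round(self.pre_s * self.fps))

    def frame_times_s(self) -> np.ndarray:
        """Frame times relative to the event (event frame at 0)."""
        return (np.arange(self.n_frames) - self.event_frame) / self.fps

    def subset(self, event_class: str) -> "PeriEventMatrix":
        """Rows of one class, or of a class family ('NP', 'M_entry', ...)."""
        mask = _class_mask(self.event_class, event_class)
        return PeriEventMatrix(
            snippets=self.snippets[mask],
            event_class=self.event_class[mask],
            event_time_s=self.event_time_s[mask],
            event_index_within_class=self.event_index_within_class[mask],
            fps=self.fps, pre_s=self.pre_s, post_s=self.post_s,
            n_excluded=self.n_excluded)


@dataclass
class ClassAverage:
    event_class: str
    mean: np.ndarray
    sem: np.ndarray  # NaN for a single event
    n_events: int


@dataclass
class BlockSummary:
    """Decile-block trend of a per-event change metric.

    Events of the class are ordered by time and split into ``n_blocks``
    contiguous blocks (block k covers ordinals floor(k*n/B) ..
    floor((k+1)*n/B)-1); the block-mean metric is regressed on the block
    index 1..B by ordinary least squares.
    """

    event_class: str
    metric: str
    n_blocks: int
    block_means: np.ndarray
    block_counts: np.ndarray
    slope: float
    intercept: float
    slope_p: float


@dataclass(frozen=True)
class SignificantRange:
    """Maximal run of significant frames, [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    start_s: float  # relative to the event
    end_s: float


def _class_mask(labels: np.ndarray, event_class: str) -> np.ndarray:
    if event_class in EVENT_CLASSES:
        return labels == event_class
    family = [c for c in EVENT_CLASSES if c.rsplit(" ", 1)[0] == event_class]
    if not family:
        raise ValueError(f"unknown event class {event_class!r}")
    return np.isin(labels, family)


def extract_perievent(dff: DffTrace, events: Sequence[BehavioralEvent],
                      pre_s: float = 2.0,
                      post_s: float = 2.0) -> PeriEventMatrix:
    """Align ΔF/F snippets to the six behavioral event classes.

    Inactive pokes and reward-delivery timestamps carry no class of
    their own and are ignored.  Events whose window exits the defined
    trace (bounds or NaN warm-up) are excluded; the count is logged and
    recorded on the returned matrix.
    """
    if not (pre_s > 0 and post_s > 0):
        raise ValueError("pre_s and post_s must be > 0")
    x = dff.dff
    fps = dff.fps
    n_pre = int(round(pre_s * fps))
    n_post = int(round(post_s * fps))

    rows, classes, times = [], [], []
    n_excluded = 0
    for ev in events:
        label = _CLASS_OF.get((ev.event_type, ev.rewarded))
        if label is None:
            continue
        e = int(round(ev.time_s * fps))
        lo, hi = e - n_pre, e + n_post
        if lo < 0 or hi > len(x) or not np.all(np.isfinite(x[lo:hi])):
            n_excluded += 1
            continue
        rows.append(x[lo:hi])
        classes.append(label)
        times.append(ev.time_s)
    if not rows:
        raise ValueError("no alignable events")
    if n_excluded:
        logger.info("extract_perievent: excluded %d events with incomplete "
                    "windows", n_excluded)

    classes_arr = np.asarray(classes)
    ordinal = np.zeros(len(classes), dtype=np.int64)
    seen: dict[str, int] = {}
    for i, c in enumerate(classes):
        ordinal[i] = seen.get(c, 0)
        seen[c] = ordinal[i] + 1
    return PeriEventMatrix(
        snippets=np.vstack(rows), event_class=classes_arr,
        event_time_s=np.asarray(times, dtype=float),
        event_index_within_class=ordinal,
        fps=fps, pre_s=pre_s, post_s=post_s, n_excluded=n_excluded)


def concat_perievent(mats: Sequence[PeriEventMatrix]) -> PeriEventMatrix:
    """Pool matrices (e.g. sessions of one condition); geometry must match."""
    if not mats:
        raise ValueError("nothing to concatenate")
    first = mats[0]
    for m in mats[1:]:
        if (m.fps, m.pre_s, m.post_s) != (first.fps, first.pre_s, first.post_s):
            raise ValueError("peri-event geometries differ")
    return PeriEventMatrix(
        snippets=np.vstack([m.snippets for m in mats]),
        event_class=np.concatenate([m.event_class for m in mats]),
        event_time_s=np.concatenate([m.event_time_s for m in mats]),
        event_index_within_class=np.concatenate(
            [m.event_index_within_class for m in mats]),
        fps=first.fps, pre_s=first.pre_s, post_s=first.post_s,
        n_excluded=sum(m.n_excluded for m in mats))


def class_average(pem: PeriEventMatrix, event_class: str) -> ClassAverage:
    """Framewise mean ± SEM over all events of one class."""
    mask = _class_mask(pem.event_class, event_class)
    snips = pem.snippets[mask]
    if snips.shape[0] == 0:
        raise ValueError(f"no events of class {event_class!r}")
    mean = snips.mean(axis=0)
    if snips.shape[0] > 1:
        sem = snips.std(axis=0, ddof=1) / np.sqrt(snips.shape[0])
    else:
        sem = np.full(pem.n_frames, np.nan)
    return ClassAverage(event_class=event_class, mean=mean, sem=sem,
                        n_events=int(snips.shape[0]))


def _event_metric(pem: PeriEventMatrix, snips: np.ndarray,
                  metric: str) -> np.ndarray:
    e = pem.event_frame
    pre = snips[:, :e].mean(axis=1)
    if metric == "post_minus_pre_mean":
        return snips[:, e:].mean(axis=1) - pre
    if metric == "peak_minus_pre_mean":
        return snips[:, e:].max(axis=1) - pre
    if metric == "post_auc":
        return (snips[:, e:] - pre[:, None]).sum(axis=1) / pem.fps
    raise ValueError(f"unknown metric {metric!r}; choose from {TREND_METRICS}")


def block_partition(n_events: int, n_blocks: int) -> list[slice]:
    """Floor partition of ordinals 0..n-1 into n_blocks contiguous blocks."""
    starts = [(k * n_events) // n_blocks for k in range(n_blocks + 1)]
    return [slice(starts[k], starts[k + 1]) for k in range(n_blocks)]


def blockwise_trend(pem: PeriEventMatrix, event_class: str,
                    n_blocks: int = 10,
                    metric: str = "post_minus_pre_mean") -> BlockSummary:
    """Regress the block-mean change metric on trial-progression deciles.

    Each session's events of a class are split into 10% increments by
    ordinal position; the default change metric is the mean ΔF/F over
    the post window minus the mean over the pre window.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    mask = _class_mask(pem.event_class, event_class)
    snips = pem.snippets[mask]
    order = np.argsort(pem.event_time_s[mask], kind="stable")
    snips = snips[order]
    n = snips.shape[0]
    if n < n_blocks:
        raise ValueError(
            f"need >= {n_blocks} events of class {event_class!r}, got {n}")
    values = _event_metric(pem, snips, metric)
    blocks = block_partition(n, n_blocks)
    means = np.array([values[b].mean() for b in blocks])
    counts = np.array([b.stop - b.start for b in blocks])
    res = stats.linregress(np.arange(1, n_blocks + 1), means)
    return BlockSummary(event_class=event_class, metric=metric,
                        n_blocks=n_blocks, block_means=means,
                        block_counts=counts, slope=float(res.slope),
                        intercept=float(res.intercept),
                        slope_p=float(res.pvalue))


def pointwise_group_compare(pem_a: PeriEventMatrix, pem_b: PeriEventMatrix,
                            alpha: float = 0.05) -> list[SignificantRange]:
    """Frame-by-frame Welch comparison of two peri-event groups.

    Per-frame two-sample Welch t tests with Benjamini-Hochberg
    correction across frames; returns maximal runs of significant
    frames as time ranges relative to the event.  This is a pointwise
    screen for where two condition traces separate, not a
    repeated-measures model.
    """
    if (pem_a.fps, pem_a.pre_s, pem_a.post_s) != \
            (pem_b.fps, pem_b.pre_s, pem_b.post_s):
        raise ValueError("peri-event geometries differ")
    a, b = pem_a.snippets, pem_b.snippets
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 events")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance frames: not significant
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    padded = np.concatenate([[False], reject, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    e = pem_a.event_frame
    fps = pem_a.fps
    return [SignificantRange(start_frame=int(s), end_frame=int(t),
                             start_s=float((s - e) / fps),
                             end_s=float((t - e) / fps))
            for s, t in zip(starts, ends)]
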