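"""Hybrid-correction library merging.

Per read, the pre- or post-correction version with the higher percent identity
(PID) is retained in the merged library (ties keep the post-correction
version, which has higher base accuracy).  Reads are tallied into five
mutually exclusive comparison categories, and merged reads are classified by
mapping quality against a configurable low-PID threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import FLNCRead

logger = logging.getLogger(__name__)

PID_CATEGORIES = (
    "only_pre_mapped",
    "only_post_mapped",
    "pre_gt_post",
    "pre_eq_post",
    "pre_lt_post",
)

MAPPING_CLASSES = ("unmapped", "multiple_best_mapped", "low_pid", "high_quality")

DEFAULT_LOW_PID_THRESHOLD = 90.0


def compute_pid(matches: int, aligned_columns: int) -> float:
    """Percent identity of an alignment: 100 * matches / aligned_columns."""
    if aligned_columns <= 0:
        raise ValueError("aligned_columns must be > 0")
    if matches > aligned_columns:
        raise ValueError("matches cannot exceed aligned_columns")
    if matches < 0:
        raise ValueError("matches must be >= 0")
    return 100.0 * matches / aligned_columns


@dataclass
class MergedRead:
    read_id: str
    pid: Optional[float]  # None = unmapped in both libraries' merge (excluded)
    source: str  # "pre" | "post"
    category: str


@dataclass
class PidComparisonReport:
    """Five-way pre/post PID comparison with per-category counts and means."""

    counts: Dict[str, int]
    mean_pid_pre: Dict[str, Optional[float]]
    mean_pid_post: Dict[str, Optional[float]]
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in PID_CATEGORIES:
            rows.append(
                {
                    "category": cat,
                    "n_reads": self.counts[cat],
                    "mean_pid_pre": self.mean_pid_pre[cat],
                    "mean_pid_post": self.mean_pid_post[cat],
                }
            )
        rows.append(
            {
                "category": "total",
                "n_reads": self.total,
                "mean_pid_pre": None,
                "mean_pid_post": None,
            }
        )
        return pd.DataFrame(rows)


def categorize_pid(pid_pre: Optional[float], pid_post: Optional[float]) -> Optional[str]:
    """Assign one read to its PID comparison category (None if unmapped twice)."""
    if pid_pre is None and pid_post is None:
        return None
    if pid_post is None:
        return "only_pre_mapped"
    if pid_pre is None:
        return "only_post_mapped"
    if pid_pre > pid_post:
        return "pre_gt_post"
    if pid_pre < pid_post:
        return "pre_lt_post"
    return "pre_eq_post"


def merge_libraries(
    reads: Sequence[FLNCRead],
) -> Tuple[List[MergedRead], PidComparisonReport]:
    """Keep the higher-PID version of each read; report the five-way comparison.

    Reads mapped in neither library are excluded from the merged library and
    counted in ``report.n_excluded``.
    """
    counts = {c: 0 for c in PID_CATEGORIES}
    sum_pre = {c: 0.0 for c in PID_CATEGORIES}
    n_pre = {c: 0 for c in PID_CATEGORIES}
    sum_post = {c: 0.0 for c in PID_CATEGORIES}
    n_post = {c: 0 for c in PID_CATEGORIES}
    merged: List[MergedRead] = []
    n_excluded = 0
    for read in reads:
        cat = categorize_pid(read.pid_pre, read.pid_post)
        if cat is None:
            n_excluded += 1
            logger.warning("read %s mapped in neither library; excluded", read.id)
            continue
        counts[cat] += 1
        if read.pid_pre is not None:
            sum_pre[cat] += read.pid_pre
            n_pre[cat] += 1
        if read.pid_post is not None:
            sum_post[cat] += read.pid_post
            n_post[cat] += 1
        if cat in ("only_pre_mapped", "pre_gt_post"):
            merged.append(MergedRead(read.id, read.pid_pre, "pre", cat))
        else:  # ties keep the post-correction version
            merged.append(MergedRead(read.id, read.pid_post, "post", cat))
    report = PidComparisonReport(
        counts=counts,
        mean_pid_pre={
            c: (sum_pre[c] / n_pre[c] if n_pre[c] else None) for c in PID_CATEGORIES
        },
        mean_pid_post={
            c: (sum_post[c] / n_post[c] if n_post[c] else None) for c in PID_CATEGORIES
        },
        n_excluded=n_excluded,
    )
    return merged, report


@dataclass
class MappingReport:
    """Four-way mapping classification over an explicit denominator."""

    counts: Dict[str, int]
    denominator: int
    low_pid_threshold: float = DEFAULT_LOW_PID_THRESHOLD

    def fraction(self, cls: str) -> float:
        return self.counts[cls] / self.denominator if self.denominator else 0.0

    def to_frame(self) -> pd.DataFrame:
        from .report import ratio

        return pd.DataFrame(
            [
                {
                    "class": cls,
                    "n_reads": self.counts[cls],
                    "percent": ratio(self.counts[cls], self.denominator)
                    if self.denominator
                    else 0.0,
                }
                for cls in MAPPING_CLASSES
            ]
        )


def classify_mapping(
    merged: Sequence[MergedRead],
    low_pid_threshold: float = DEFAULT_LOW_PID_THRESHOLD,
    multimap_ids: Optional[Set[str]] = None,
    n_unmapped: int = 0,
    denominator: Optional[int] = None,
) -> MappingReport:
    """Classify merged reads into unmapped / multimapped / low-PID / high-quality.

    ``n_unmapped`` counts reads absent from the merged library (mapped in
    neither input); ``denominator`` defaults to the total over all four
    classes.
    """
    if not 0.0 < low_pid_threshold < 100.0:
        raise ValueError("low_pid_threshold must be in (0, 100)")
    multimap_ids = multimap_ids or set()
    counts = {c: 0 for c in MAPPING_CLASSES}
    counts["unmapped"] = n_unmapped
    for read in merged:
        if read.pid is None:
            counts["unmapped"] += 1
        elif read.read_id in multimap_ids:
            counts["multiple_best_mapped"] += 1
        elif read.pid < low_pid_threshold:
            counts["low_pid"] += 1
        else:
            counts["high_quality"] += 1
    if denominator is None:
        denominator = sum(counts.values())
    return MappingReport(
        counts=counts, denominator=denominator, low_pid_threshold=low_pid_threshold
    )
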