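"""Standardized vascular lumen profiles and the group-level statistics.

A diameter-versus-arc-length trace is reduced to a fixed number of
equidistant segments (nine by default, numbered 1 at the aortic-arch end to
9 at the bifurcation): arc length is normalized to [0, 1], diameters falling
in each ninth are averaged arithmetically, and the segment lumen area follows
from the circular cross-section assumption, area = pi d^2 / 4.  Normalizing
length makes profiles comparable across animals with different carotid
lengths and aligns CT segments with 500-um-spaced histology sections.

Group statistics mirror the study design: per-segment mean +/- SEM over
animals, one-way ANOVA with Bonferroni-corrected pairwise comparisons on
per-animal mean areas across time points, and unadjusted per-segment
two-sample t-tests between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LumenProfile",
    "GroupProfile",
    "bin_profile",
    "group_profile",
    "timepoint_anova",
    "segment_ttest",
]


@dataclass
class LumenProfile:
    """Per-segment mean diameter and circular lumen area for one vessel."""

    mean_diameter: np.ndarray        # (n_segments,) mm
    area: np.ndarray                 # (n_segments,) mm^2; pi d^2 / 4
    vessel_id: str = "v0"
    side: str = "LCCA"
    timepoint_days: int | None = None
    n_segments: int = field(default=9)

    def __post_init__(self) -> None:
        self.mean_diameter = np.asarray(self.mean_diameter, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if len(self.mean_diameter) != self.n_segments or len(self.area) != self.n_segments:
            raise ValueError(
                f"profile must have exactly {self.n_segments} segments, got "
                f"{len(self.mean_diameter)} diameters / {len(self.area)} areas"
            )
        expected = np.pi * self.mean_diameter**2 / 4.0
        finite = np.isfinite(self.mean_diameter)
        if not np.allclose(self.area[finite], expected[finite], rtol=1e-12, atol=0.0):
            raise ValueError("area must equal pi d^2/4 per segment")

    @property
    def segment_index(self) -> np.ndarray:
        """1-based segment numbers, arch (1) to bifurcation (n_segments)."""
        return np.arange(1, self.n_segments + 1)

    def mean_area(self) -> float:
        """Average lumen area over all segments (one number per animal)."""
        return float(np.nanmean(self.area))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vessel_id": self.vessel_id,
                "side": self.side,
                "timepoint_days": self.timepoint_days,
                "segment": self.segment_index,
                "mean_diameter_mm": self.mean_diameter,
                "area_mm2": self.area,
            }
        )


@dataclass
class GroupProfile:
    """Per-segment mean and SEM of lumen area over a group of animals."""

    mean_area: np.ndarray
    sem_area: np.ndarray
    n: int
    side: str = "LCCA"
    timepoint_days: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": np.arange(1, len(self.mean_area) + 1),
                "mean_area_mm2": self.mean_area,
                "sem_area_mm2": self.sem_area,
                "n": self.n,
                "side": self.side,
                "timepoint_days": self.timepoint_days,
            }
        )


def bin_profile(
    arc_mm,
    diameter_mm,
    n_segments: int = 9,
    *,
    vessel_id: str = "v0",
    side: str = "LCCA",
    timepoint_days: int | None = None,
) -> LumenProfile:
    """Bin a diameter-vs-arc-length trace into equidistant segments.

    Segment i (1-based) covers normalized positions [(i-1)/n, i/n), the last
    closed at 1.  Diameters are averaged arithmetically within each bin and
    converted to area under the circular assumption.  An empty bin means the
    trace was sampled too sparsely and raises a ``ValueError``.
    """
    arc = np.asarray(arc_mm, dtype=float)
    diam = np.asarray(diameter_mm, dtype=float)
    if arc.shape != diam.shape or arc.ndim != 1:
        raise ValueError("arc and diameter must be matching 1-D arrays")
    if len(arc) < n_segments:
        raise ValueError(f"need at least {n_segments} samples, got {len(arc)}")
    if np.any(np.diff(arc) <= 0):
        raise ValueError("arc length must be strictly increasing")
    t = (arc - arc[0]) / (arc[-1] - arc[0])
    idx = np.minimum((t * n_segments).astype(int), n_segments - 1)
    means = np.empty(n_segments)
    for i in range(n_segments):
        sel = diam[idx == i]
        if sel.size == 0:
            raise ValueError(
                f"segment {i + 1} of {n_segments} received no samples; "
                "resample the trace more densely"
            )
        means[i] = sel.mean()
    return LumenProfile(
        mean_diameter=means,
        area=np.pi * means**2 / 4.0,
        vessel_id=vessel_id,
        side=side,
        timepoint_days=timepoint_days,
        n_segments=n_segments,
    )


def group_profile(profiles: list) -> GroupProfile:
    """Per-segment mean and SEM (SD/sqrt(n), ddof=1) over animals.

    All profiles must share side and timepoint.  With a single animal the
    SEM is reported as 0 with a warning.
    """
    if not profiles:
        raise ValueError("no profiles given")
    sides = {p.side for p in profiles}
    tps = {p.timepoint_days for p in profiles}
    if len(sides) > 1 or len(tps) > 1:
        raise ValueError(f"profiles mix sides {sides} or timepoints {tps}")
    areas = np.vstack([p.area for p in profiles])
    n = len(profiles)
    mean = areas.mean(axis=0)
    if n == 1:
        warnings.warn("single profile: SEM reported as 0", UserWarning, stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = areas.std(axis=0, ddof=1) / np.sqrt(n)
    return GroupProfile(
        mean_area=mean,
        sem_area=sem,
        n=n,
        side=profiles[0].side,
        timepoint_days=profiles[0].timepoint_days,
    )


def timepoint_anova(groups: dict) -> pd.DataFrame:
    """One-way ANOVA over per-animal mean areas, Bonferroni-adjusted pairs.

    ``groups`` maps a label (e.g. timepoint in days) to a 1-D array of
    per-animal mean lumen areas (sections 1-9 averaged per animal).  Returns
    a table with the omnibus row (F, raw p) followed by all pairwise
    two-sample t-test rows whose p-values are multiplied by the number of
    comparisons and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.ndim != 1 or len(v) < 2:
            raise ValueError(f"group {k!r} needs at least two animals")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group: F is degenerate")

    f_stat, p_omnibus = stats.f_oneway(*arrays.values())
    if all(np.ptp(v) == 0 for v in arrays.values()) or not np.isfinite(f_stat):
        # identical values within every group but equal means across groups
        f_stat, p_omnibus = 0.0, 1.0
    rows = [
        {
            "comparison": "omnibus",
            "statistic": float(f_stat),
            "p_raw": float(p_omnibus),
            "p_adjusted": float(p_omnibus),
        }
    ]
    pairs = list(combinations(arrays.keys(), 2))
    for a, b in pairs:
        if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0:
            t_val = 0.0 if arrays[a].mean() == arrays[b].mean() else np.inf
            p_raw = 1.0 if t_val == 0.0 else 0.0
        else:
            t_val, p_raw = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "statistic": float(t_val),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, p_raw * len(pairs))),
            }
        )
    return pd.DataFrame(rows)


def segment_ttest(areas_a, areas_b) -> pd.DataFrame:
    """Unadjusted equal-variance two-sample t-test per segment.

    ``areas_a`` and ``areas_b`` are (n_animals, n_segments) arrays of lumen
    (or plaque) areas for the two groups.  Returns one row per segment with
    the raw two-sided p-value, mirroring per-section comparison tables.
    """
    a = np.atleast_2d(np.asarray(areas_a, dtype=float))
    b = np.atleast_2d(np.asarray(areas_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have the same number of segments")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two animals per group")
    rows = []
    for i in range(a.shape[1]):
        xa, xb = a[:, i], b[:, i]
        pooled = ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1))
        if pooled == 0:
            raise ValueError(f"zero pooled variance in segment {i + 1}")
        t_val, p_val = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append({"segment": i + 1, "t": float(t_val), "p": float(p_val)})
    return pd.DataFrame(rows)
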