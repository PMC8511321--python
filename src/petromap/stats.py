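"""Percentile tables, distribution exports, map aggregation, and the
thread-length recommendation.

The headline product is the per-region percentile table of cortical layer
thickness (CLT) and distance to dura/venous sinuses (DDVS): the 1st, 5th,
50th and 95th percentiles per anatomical region plus a pooled "All" row
over every region-of-interest sample.  Percentiles use linear
interpolation between order statistics (inclusive endpoints, the numpy
default).  "All" pools samples rather than averaging region rows.

From such a table the maximal safe screw thread length follows directly:
to seat a screw in ``coverage`` % of an area without touching the dura or
a venous sinus, the thread may be at most the DDVS value at the
(100 − coverage)th percentile, minimised over the allowed regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .thickness import ThicknessMap

__all__ = [
    "PERCENTILES",
    "METRICS",
    "TABLE_REGION_ORDER",
    "PercentileTable",
    "SubjectMeta",
    "GroupMapSet",
    "percentile",
    "build_percentile_table",
    "thread_length_recommendation",
    "aggregate_group_maps",
    "distribution_export",
    "reference_percentile_table",
]

PERCENTILES = (1, 5, 50, 95)
METRICS = ("CLT", "DDVS")

# canonical row order of the published table
TABLE_REGION_ORDER = (
    "All",
    "middle_fossa",
    "superior_temporal_surface",
    "mastoid",
    "petrous_pyramid",
    "parietal",
    "mastoid_tip",
    "retrosigmoid",
)

DISPLAY_NAMES = {
    "All": "All",
    "middle_fossa": "Approx. middle fossa",
    "superior_temporal_surface": "Superior temporal surface",
    "mastoid": "Mastoid region",
    "petrous_pyramid": "Petrous pyramid",
    "parietal": "Parietal region",
    "mastoid_tip": "Mastoid tip",
    "retrosigmoid": "Retrosigmoid region",
}


def percentile(values: Sequence[float], p: float) -> float:
    """Linear-interpolation percentile of a non-empty value list.

    Inclusive-endpoint convention: the sorted values sit at probabilities
    0 … 100 and intermediate p interpolates linearly (numpy ``linear``).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("percentile of an empty value list")
    if not (0.0 < p < 100.0):
        raise ValueError("p must lie in (0, 100)")
    return float(np.percentile(v, p, method="linear"))


@dataclass
class PercentileTable:
    """Region × metric × percentile summary (mm).

    ``values[region][metric]`` maps to a dict percentile → mm.  Regions
    with fewer than two contributing samples are flagged insufficient.
    """

    values: dict[str, dict[str, dict[int, float]]]
    insufficient: set[str] = field(default_factory=set)
    percentiles: tuple[int, ...] = PERCENTILES
    metrics: tuple[str, ...] = METRICS

    def get(self, region: str, metric: str, p: int) -> float:
        return self.values[region][metric][p]

    @property
    def regions(self) -> list[str]:
        ordered = [r for r in TABLE_REGION_ORDER if r in self.values]
        extra = [r for r in self.values if r not in ordered]
        return ordered + sorted(extra)

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product([self.metrics, self.percentiles],
                                          names=["metric", "percentile"])
        rows = []
        for region in self.regions:
            rows.append([self.values[region].get(m, {}).get(p, np.nan)
                         for m in self.metrics for p in self.percentiles])
        index = [DISPLAY_NAMES.get(r, r) for r in self.regions]
        return pd.DataFrame(rows, index=index, columns=cols)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass(frozen=True)
class SubjectMeta:
    """One analysed side of one subject."""

    subject_id: str
    side: str
    age_months: int
    group: str

    _AGE_BANDS = {"G1": (8, 10), "G2": (12, 14), "G3": (24, 24), "G4": (48, 48)}

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.group not in self._AGE_BANDS:
            raise ValueError(f"unknown age group {self.group!r}")
        lo, hi = self._AGE_BANDS[self.group]
        if not (lo <= self.age_months <= hi):
            raise ValueError(
                f"age {self.age_months} months inconsistent with group "
                f"{self.group} ({lo}-{hi} months)"
            )


def build_percentile_table(samples: Sequence, metrics: Sequence[str] = METRICS,
                           percentiles: Sequence[int] = PERCENTILES) -> PercentileTable:
    """Per-region percentile table plus a pooled "All" row.

    Samples must carry ``region``, ``clt`` and ``ddvs`` attributes (see
    :func:`petromap.regions.region_masks`); missing metric values are
    excluded per metric.  "All" pools every ROI sample, including any that
    fall in no named region.
    """
    groups: dict[str, list] = {r: [] for r in TABLE_REGION_ORDER if r != "All"}
    pooled: list = []
    for s in samples:
        if not getattr(s, "valid", True):
            continue
        region = getattr(s, "region", None)
        if region is None or region == "outside_roi":
            continue
        pooled.append(s)
        groups.setdefault(region, []).append(s)

    values: dict[str, dict[str, dict[int, float]]] = {}
    insufficient: set[str] = set()

    def summarise(region: str, members: list) -> None:
        entry: dict[str, dict[int, float]] = {}
        for metric in metrics:
            vals = np.array([getattr(s, metric.lower()) for s in members], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                entry[metric] = {p: np.nan for p in percentiles}
                continue
            entry[metric] = {p: percentile(vals, p) for p in percentiles}
        values[region] = entry
        if len(members) < 2:
            insufficient.add(region)

    summarise("All", pooled)
    for region, members in groups.items():
        summarise(region, members)
    return PercentileTable(values=values, insufficient=insufficient,
                           percentiles=tuple(percentiles), metrics=tuple(metrics))


def thread_length_recommendation(table: PercentileTable,
                                 regions: str | Iterable[str] = "All",
                                 coverage: float = 99.0) -> float:
    """Maximal screw thread length (mm) that avoids the dura/sinus over
    ``coverage`` % of the selected area.

    Reads the DDVS value at the (100 − coverage)th percentile from each
    selected region row and returns the minimum: a thread no longer than
    this stays clear of the deep structures over at least ``coverage`` %
    of the selected area under the table's distributions.
    """
    p = 100.0 - float(coverage)
    p_int = int(round(p))
    if p_int not in table.percentiles or abs(p - p_int) > 1e-9:
        raise ValueError(
            f"coverage {coverage}% needs the {p:g}th percentile, which the "
            f"table does not provide (has {table.percentiles})"
        )
    if isinstance(regions, str):
        region_list = [regions]
    else:
        region_list = list(regions)
    missing = [r for r in region_list if r not in table.values]
    if missing:
        raise KeyError(f"regions not in table: {missing}")
    return min(table.get(r, "DDVS", p_int) for r in region_list)


@dataclass
class GroupMapSet:
    """Cellwise mean and minimum over subject maps plus the per-cell count."""

    mean_map: ThicknessMap
    min_map: ThicknessMap
    n_contributing: np.ndarray
    group: str = "all"


def aggregate_group_maps(maps: Sequence[ThicknessMap],
                         metas: Optional[Sequence[SubjectMeta]] = None,
                         grouping: str = "all") -> dict[str, GroupMapSet]:
    """Cellwise mean/min aggregation of subject maps on a shared grid.

    ``grouping='all'`` pools every map into one set (key ``'all'``);
    ``'by_group'`` emits one set per age group present in ``metas``.
    Cells covered by no subject are missing; maps with mismatched grids
    or metrics are rejected.
    """
    if len(maps) == 0:
        raise ValueError("no maps to aggregate")
    ref = maps[0]
    for m in maps[1:]:
        if m.spacing != ref.spacing or tuple(m.extent) != tuple(ref.extent):
            raise ValueError("maps must share one GridSpec; re-run with a shared grid")
        if m.metric != ref.metric:
            raise ValueError("maps must share one metric")
    if grouping == "all":
        partitions = {"all": list(range(len(maps)))}
    elif grouping == "by_group":
        if metas is None or len(metas) != len(maps):
            raise ValueError("by_group aggregation needs one SubjectMeta per map")
        partitions = {}
        for i, meta in enumerate(metas):
            partitions.setdefault(meta.group, []).append(i)
    else:
        raise ValueError("grouping must be 'all' or 'by_group'")

    out: dict[str, GroupMapSet] = {}
    for key in sorted(partitions):
        stack = np.stack([maps[i].grid for i in partitions[key]])
        with np.errstate(invalid="ignore"):
            n = np.isfinite(stack).sum(axis=0)
            mean = np.where(n > 0, np.nansum(np.where(np.isfinite(stack), stack, 0.0),
                                             axis=0) / np.maximum(n, 1), np.nan)
            mn = np.where(n > 0, np.nanmin(np.where(np.isfinite(stack), stack, np.inf),
                                           axis=0), np.nan)
        out[key] = GroupMapSet(
            mean_map=ThicknessMap(ref.metric, mean, ref.spacing, ref.extent,
                                  subject_id=f"mean:{key}"),
            min_map=ThicknessMap(ref.metric, mn, ref.spacing, ref.extent,
                                 subject_id=f"min:{key}"),
            n_contributing=n,
            group=key,
        )
    return out


def distribution_export(samples, by: str = "region", metric: str = "CLT",
                        bin_width: float = 0.1) -> list[dict]:
    """Histogram + quartile records per group, enough to redraw the
    violin/histogram distribution figures in any plotting tool.

    ``by='region'`` groups a flat sample sequence by region label;
    ``by='subject'`` expects a mapping subject_id → sample sequence.
    Frequencies are relative (sum to 1 per group).
    """
    key = metric.lower()
    if by == "region":
        grouped: dict[str, np.ndarray] = {}
        for s in samples:
            if not getattr(s, "valid", True):
                continue
            region = getattr(s, "region", None)
            if region is None or region == "outside_roi":
                continue
            grouped.setdefault(region, []).append(getattr(s, key))
    elif by == "subject":
        if not isinstance(samples, Mapping):
            raise ValueError("by='subject' expects a mapping subject_id -> samples")
        grouped = {
            sid: [getattr(s, key) for s in seq if getattr(s, "valid", True)]
            for sid, seq in samples.items()
        }
    else:
        raise ValueError("by must be 'region' or 'subject'")

    records = []
    for name in sorted(grouped):
        vals = np.asarray(grouped[name], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        lo = np.floor(vals.min() / bin_width) * bin_width
        hi = np.ceil(vals.max() / bin_width) * bin_width
        n_bins = max(1, int(round((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(vals, bins=edges)
        freqs = counts / counts.sum()
        records.append({
            "group": name,
            "metric": metric,
            "n": int(vals.size),
            "bin_edges": edges.tolist(),
            "freq": freqs.tolist(),
            "q25": percentile(vals, 25),
            "median": percentile(vals, 50),
            "q75": percentile(vals, 75),
        })
    return records


def distributions_to_csv(records: Sequence[dict], path: str | Path) -> None:
    """Long-format CSV: group, metric, bin_lo, bin_hi, freq."""
    rows = []
    for rec in records:
        edges = rec["bin_edges"]
        for lo, hi, f in zip(edges[:-1], edges[1:], rec["freq"]):
            rows.append({"group": rec["group"], "metric": rec["metric"],
                         "bin_lo": lo, "bin_hi": hi, "freq": f})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# published pediatric reference table (20 temporal-bone sides, 8-48 months)

_REFERENCE_ROWS = {
    #                      CLT 1/5/50/95          DDVS 1/5/50/95
    "All":                       ((0.3, 0.7, 1.5, 3.3), (0.8, 1.1, 3.2, 9.3)),
    "middle_fossa":              ((0.5, 0.8, 1.4, 2.4), (0.9, 1.2, 3.1, 7.0)),
    "superior_temporal_surface": ((0.5, 0.8, 1.4, 2.6), (0.5, 0.9, 1.6, 3.3)),
    "mastoid":                   ((0.2, 0.6, 1.3, 2.9), (2.0, 3.1, 7.3, 11.1)),
    "petrous_pyramid":           ((0.6, 0.9, 1.9, 4.3), (1.0, 1.7, 3.9, 7.1)),
    "parietal":                  ((0.4, 1.0, 2.3, 3.9), (1.0, 1.4, 2.6, 4.5)),
    "mastoid_tip":               ((0.1, 0.3, 1.2, 2.2), (0.9, 1.5, 5.6, 10.3)),
    "retrosigmoid":              ((0.3, 0.7, 1.7, 3.3), (0.7, 1.1, 2.5, 5.5)),
}


def reference_percentile_table() -> PercentileTable:
    """The published pediatric per-region percentile table (mm).

    Select percentiles of CLT and DDVS pooled over 20 temporal-bone sides
    of subjects aged 8–48 months; input data for thread-length
    recommendations when no subject-level samples are at hand.
    """
    values = {
        region: {
            "CLT": dict(zip(PERCENTILES, clt)),
            "DDVS": dict(zip(PERCENTILES, ddvs)),
        }
        for region, (clt, ddvs) in _REFERENCE_ROWS.items()
    }
    return PercentileTable(values=values)
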