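"""Tiling-array ChIP signal normalisation and CGI-class comparison.

Probe intensities (perfect-match probes only) are median-scaled per chip to
a common target, quantile-normalised across chips, and replicate-averaged to
one value per probe and condition.  Probes are then partitioned by the CGI
class containing their midpoint and treated-vs-input distributions are
compared with Wilcoxon-Mann-Whitney rank tests, per class and pairwise
between classes on the per-probe treated/input ratios.

The pipeline order is fixed: median scale -> quantile normalise -> average
replicates -> partition -> test; rerunning is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cgiscape.cgi import CgiClass, CpGIsland

__all__ = [
    "REGION_CLASSES",
    "filter_pm",
    "median_scale",
    "quantile_normalize",
    "average_replicates",
    "partition_probes",
    "class_tests",
    "pairwise_ratio_tests",
    "chip_pipeline",
    "read_probe_table",
    "intensity_columns",
]

REGION_CLASSES = (
    "five_prime",
    "intragenic",
    "three_prime",
    "intergenic",
    "non_cgi",
)

_META_COLUMNS = {"probe_id", "chrom", "pos", "kind"}


def intensity_columns(table: pd.DataFrame) -> list[str]:
    """Intensity columns, named ``condition.sample.rep``."""
    return [c for c in table.columns if c not in _META_COLUMNS]


def read_probe_table(path) -> pd.DataFrame:
    """Read a tab-separated probe table.

    Header: probe_id, chrom, pos, kind, then intensity columns named
    ``condition.sample.rep`` (e.g. ``treated.1.2``, ``input.2.3``).
    """
    df = pd.read_csv(path, sep="\t")
    missing = _META_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    return df


def filter_pm(table: pd.DataFrame) -> pd.DataFrame:
    """Drop mismatch (MM) probes; only perfect-match probes are analysed."""
    return table[table["kind"] == "PM"].reset_index(drop=True)


def median_scale(values: np.ndarray, target: float = 500.0) -> np.ndarray:
    """Scale one chip's intensities so the median equals ``target`` exactly."""
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    if med == 0:
        raise ValueError("zero median; cannot scale")
    return values * (target / med)


def quantile_normalize(chips: np.ndarray) -> np.ndarray:
    """Quantile normalisation across chips (columns = chips).

    Each chip's sorted values are replaced by the across-chip mean of order
    statistics; tied values receive the mean of the quantile values they
    would jointly occupy.
    """
    chips = np.asarray(chips, dtype=float)
    if chips.ndim != 2:
        raise ValueError("expected a (n_probes, n_chips) array")
    n, _ = chips.shape
    reference = np.sort(chips, axis=0).mean(axis=1)
    out = np.empty_like(chips)
    for j in range(chips.shape[1]):
        ranks = stats.rankdata(chips[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return out


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average samples x technical replicates to one value per condition.

    Missing values are averaged over the replicates present; the number of
    affected probes is reported in a warning.
    """
    cols = intensity_columns(table)
    conditions = sorted({c.split(".")[0] for c in cols})
    out = table[[c for c in ("probe_id", "chrom", "pos", "kind") if c in table.columns]].copy()
    n_partial = 0
    for cond in conditions:
        sub = table[[c for c in cols if c.split(".")[0] == cond]]
        n_partial += int((sub.isna().any(axis=1) & sub.notna().any(axis=1)).sum())
        out[cond] = sub.mean(axis=1, skipna=True)
    if n_partial:
        warnings.warn(
            f"{n_partial} probes averaged over incomplete replicates",
            stacklevel=2,
        )
    return out


def partition_probes(
    table: pd.DataFrame, cgis: Sequence[CpGIsland]
) -> pd.DataFrame:
    """Assign each probe the class of the CGI containing its midpoint.

    Probes outside all CGIs get ``non_cgi``; probes on chromosomes absent
    from the CGI annotation are ``non_cgi`` with a warning.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in cgis:
        if c.cgi_class is None:
            raise ValueError("CGIs must be classified before partitioning")
        by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end, c.cgi_class.value)
        )
    index = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items], dtype=np.int64)
        ends = np.array([e for _, e, _ in items], dtype=np.int64)
        labels = np.array([l for _, _, l in items])
        index[chrom] = (starts, ends, labels)

    out = table.copy()
    region = np.full(len(table), "non_cgi", dtype=object)
    unknown = 0
    for chrom, sub in table.groupby("chrom"):
        if chrom not in index:
            unknown += len(sub)
            continue
        starts, ends, labels = index[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = (i >= 0) & (pos < ends[np.maximum(i, 0)])
        rows = sub.index.to_numpy()[ok]
        region[table.index.get_indexer(rows)] = labels[i[ok]]
    if unknown:
        warnings.warn(
            f"{unknown} probes on chromosomes without CGI annotation -> non_cgi",
            stacklevel=2,
        )
    out["region_class"] = region
    return out


@dataclass(frozen=True)
class RegionSignalStats:
    """Per-class treated/input comparison."""

    region_class: str
    n_probes: int
    mean_treated: float
    mean_input: float
    median_treated: float
    median_input: float
    ratio_median: float
    p_value: float


def _rank_test(x: np.ndarray, y: np.ndarray, *, exact_below: int = 30) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p; exact for small samples."""
    method = "exact" if min(len(x), len(y)) < exact_below else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # e.g. all values tied under exact method
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def class_tests(partitioned: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-input statistics and rank-test p-value per region class.

    Requires replicate-averaged columns ``treated`` and ``input`` plus
    ``region_class``.  Classes with fewer than 2 probes yield NA rows.
    """
    rows = []
    for cls in REGION_CLASSES:
        sub = partitioned[partitioned["region_class"] == cls]
        n = len(sub)
        if n < 2:
            rows.append(
                {
                    "region_class": cls,
                    "n_probes": n,
                    "mean_treated": float("nan"),
                    "mean_input": float("nan"),
                    "median_treated": float("nan"),
                    "median_input": float("nan"),
                    "ratio_median": float("nan"),
                    "p_value": float("nan"),
                }
            )
            continue
        t = sub["treated"].to_numpy(dtype=float)
        i = sub["input"].to_numpy(dtype=float)
        rows.append(
            {
                "region_class": cls,
                "n_probes": n,
                "mean_treated": float(t.mean()),
                "mean_input": float(i.mean()),
                "median_treated": float(np.median(t)),
                "median_input": float(np.median(i)),
                "ratio_median": float(np.median(t / i)),
                "p_value": _rank_test(t, i),
            }
        )
    return pd.DataFrame(rows).set_index("region_class")


def pairwise_ratio_tests(
    partitioned: pd.DataFrame, *, on: str = "ratio"
) -> pd.DataFrame:
    """Pairwise between-class rank tests (upper triangle), default on ratios.

    ``on="raw"`` compares treated signal distributions instead of
    treated/input ratios.
    """
    values: dict[str, np.ndarray] = {}
    for cls in REGION_CLASSES:
        sub = partitioned[partitioned["region_class"] == cls]
        if len(sub) < 2:
            continue
        if on == "ratio":
            values[cls] = (sub["treated"] / sub["input"]).to_numpy(dtype=float)
        elif on == "raw":
            values[cls] = sub["treated"].to_numpy(dtype=float)
        else:
            raise ValueError("on must be 'ratio' or 'raw'")
    mat = pd.DataFrame(
        np.nan, index=list(REGION_CLASSES), columns=list(REGION_CLASSES)
    )
    for a_i, a in enumerate(REGION_CLASSES):
        for b in REGION_CLASSES[a_i + 1 :]:
            if a in values and b in values:
                mat.loc[a, b] = _rank_test(values[a], values[b])
    return mat


def chip_pipeline(
    probe_table: pd.DataFrame,
    cgis: Sequence[CpGIsland],
    *,
    target: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the fixed normalisation/testing pipeline.

    Returns (per-class stats, pairwise ratio p-value matrix, the
    partitioned replicate-averaged table).
    """
    pm = filter_pm(probe_table)
    cols = intensity_columns(pm)
    mat = pm[cols].to_numpy(dtype=float)
    for j in range(mat.shape[1]):
        mat[:, j] = median_scale(mat[:, j], target=target)
    mat = quantile_normalize(mat)
    scaled = pm.copy()
    scaled[cols] = mat
    averaged = average_replicates(scaled)
    partitioned = partition_probes(averaged, cgis)
    return class_tests(partitioned), pairwise_ratio_tests(partitioned), partitioned
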