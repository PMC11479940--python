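"""Aggregate per-site methylation calls over elements and compare conditions.

Nanopore methylation callers emit one log-likelihood ratio (LLR) per read
per CpG site; positive LLRs favor 5mC.  Calls are binarized with a symmetric
dead zone (|LLR| below the threshold is discarded as ambiguous), aggregated
per element as the fraction of methylated calls — read-level averaging, i.e.
every retained read-site observation counts once — and summarized both over
the full element and over four strand-aware quarters ordered from the
element's transcription start (on minus-strand elements the first quarter
from the TSS is the genomically *last* quarter).  Two groups of element
summaries are compared with a two-sided Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BedRecord

#: required columns of a per-read, per-site methylation call table
CALL_COLUMNS = ("chromosome", "position", "read_id", "log_lik_ratio")

_ALIASES = {
    "chromosome": ("chromosome", "chrom"),
    "position": ("position", "start", "pos"),
    "read_id": ("read_id", "read_name", "read"),
    "log_lik_ratio": ("log_lik_ratio", "llr"),
    "strand": ("strand",),
    "sample": ("sample", "sample_id"),
    "condition": ("condition", "group"),
}


def read_call_table(path) -> pd.DataFrame:
    """Read a nanopolish-style tab-separated methylation call file."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, names in _ALIASES.items():
        for name in names:
            if name in df.columns and canonical not in df.columns:
                rename[name] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table is missing columns: {missing}")
    return df


@dataclass
class BinarizedCalls:
    """Calls surviving binarization, plus the ambiguous-call count."""

    calls: pd.DataFrame  # original columns + boolean 'methylated'
    n_discarded: int


def binarize_calls(calls: pd.DataFrame, llr_threshold: float = 2.0) -> BinarizedCalls:
    """Binarize per-call LLRs with a symmetric dead zone.

    Methylated iff LLR >= threshold, unmethylated iff LLR <= -threshold;
    calls with |LLR| < threshold are discarded and counted.
    """
    if llr_threshold <= 0:
        raise ValueError("llr_threshold must be > 0")
    llr = calls["log_lik_ratio"].to_numpy(dtype=float)
    keep = np.abs(llr) >= llr_threshold
    out = calls.loc[keep].copy()
    out["methylated"] = llr[keep] >= llr_threshold
    return BinarizedCalls(calls=out, n_discarded=int((~keep).sum()))


@dataclass
class ElementMethylation:
    """Per-element methylation summary (full element + strand-aware quarters)."""

    element_id: str
    n_sites: int
    n_calls: int
    mean_methylation: float  # NaN when no calls retained
    quarter_means: np.ndarray  # 4 values, 5'->3' of the element; NaN where empty
    quarter_calls: np.ndarray  # call counts per quarter


def element_methylation(
    binarized: pd.DataFrame, element: BedRecord, site_level: bool = False
) -> ElementMethylation:
    """Summarize binarized calls over one stranded element.

    ``site_level=True`` first averages calls within each CpG site and then
    averages sites; the default counts every read-site call once.
    """
    if element.strand not in {"+", "-"}:
        raise ValueError(f"element {element.name!r} must be stranded (+/-)")
    sel = binarized[
        (binarized["chromosome"] == element.chrom)
        & (binarized["position"] >= element.start)
        & (binarized["position"] < element.end)
    ]
    n_sites = int(sel["position"].nunique())
    n_calls = int(len(sel))

    pos = sel["position"].to_numpy(dtype=int)
    meth = sel["methylated"].to_numpy(dtype=float)
    quarters = np.clip((pos - element.start) * 4 // element.length, 0, 3)
    if element.strand == "-":
        quarters = 3 - quarters

    q_means = np.full(4, np.nan)
    q_calls = np.zeros(4, dtype=int)
    if site_level:
        site_means = sel.assign(q=quarters).groupby(["q", "position"])["methylated"].mean()
        overall = (
            float(sel.groupby("position")["methylated"].mean().mean()) if n_calls else float("nan")
        )
        for q in range(4):
            if q in site_means.index.get_level_values(0):
                vals = site_means.loc[q]
                q_means[q] = float(vals.mean())
                q_calls[q] = len(vals)
    else:
        overall = float(meth.mean()) if n_calls else float("nan")
        for q in range(4):
            mask = quarters == q
            q_calls[q] = int(mask.sum())
            if q_calls[q]:
                q_means[q] = float(meth[mask].mean())

    return ElementMethylation(
        element_id=element.name,
        n_sites=n_sites,
        n_calls=n_calls,
        mean_methylation=overall,
        quarter_means=q_means,
        quarter_calls=q_calls,
    )


def elements_methylation(
    binarized: pd.DataFrame, elements: list[BedRecord], site_level: bool = False
) -> list[ElementMethylation]:
    return [element_methylation(binarized, el, site_level=site_level) for el in elements]


def summaries_to_frame(summaries: list[ElementMethylation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [s.element_id for s in summaries],
            "n_sites": [s.n_sites for s in summaries],
            "n_calls": [s.n_calls for s in summaries],
            "mean_methylation": [s.mean_methylation for s in summaries],
            **{
                f"quarter{q + 1}_mean": [s.quarter_means[q] for s in summaries]
                for q in range(4)
            },
        }
    )


@dataclass
class MethylationComparison:
    """Two-group comparison of element methylation summaries."""

    region: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    t_statistic: float
    p_value: float
    applicable: bool  # False when either group has < 2 usable elements


def _region_values(summaries: list[ElementMethylation], region: str) -> np.ndarray:
    if region == "full":
        vals = [s.mean_methylation for s in summaries]
    elif region == "first_quarter":
        vals = [s.quarter_means[0] for s in summaries]
    else:
        raise ValueError(f"unknown region {region!r}")
    arr = np.asarray(vals, dtype=float)
    return arr[np.isfinite(arr)]


def compare_methylation(
    group_a: list[ElementMethylation],
    group_b: list[ElementMethylation],
    region: str = "full",
) -> MethylationComparison:
    """Two-sided Student's t-test between two groups of element summaries.

    ``region`` selects the full-element mean or the first quarter from the
    TSS.  With fewer than two usable elements in either group the difference
    is still reported but the test is marked not applicable.
    """
    a = _region_values(group_a, region)
    b = _region_values(group_b, region)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain at least one usable element")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if len(a) < 2 or len(b) < 2:
        return MethylationComparison(region, len(a), len(b), mean_a, mean_b,
                                     mean_a - mean_b, float("nan"), float("nan"), False)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return MethylationComparison(region, len(a), len(b), mean_a, mean_b,
                                 mean_a - mean_b, float(t), float(p), True)
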