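"""Tissue/stage specificity (Tau) and differential splicing (LRT).

Specificity of an AS event's isoform side (EII or EEI) across n groups is
measured with the Tau index over normalized abundances x_i:

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

tau = 0 for uniform expression, 1 for expression confined to one group.
With the default threshold of 1, the specificity call reduces to the
literal rule "nonzero in exactly one group".

Differential splicing between two conditions with replicates is tested with
a binomial logistic likelihood-ratio test: the null fits one common
inclusion probability to the pooled (inclusion, exclusion) counts, the
alternative one probability per condition; 2*(l_alt - l_null) ~ chi2(1).
P-values across events are adjusted by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpecificityProfile",
    "DifferentialResult",
    "aggregate_groups",
    "coverage_filter",
    "tau",
    "specificity_profiles",
    "call_specific",
    "differential_lrt",
    "bh_fdr",
    "differential_table",
]

log = logging.getLogger(__name__)


@dataclass
class SpecificityProfile:
    """Per-group normalized abundances of one isoform side of one event."""

    event_key: str
    isoform_side: str  # "EII" | "EEI"
    groups: tuple[str, ...]
    x: np.ndarray  # normalized abundances (CPM), >= 0
    raw: np.ndarray  # raw group counts (for the coverage rule)
    tau: float = field(init=False)
    specific_group: str | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        self.tau = tau(self.x) if self.x.max() > 0 and len(self.x) >= 2 else math.nan


@dataclass
class DifferentialResult:
    """Likelihood-ratio test result for one event and one comparison."""

    event_key: str
    comparison: tuple[str, str]
    lr_statistic: float
    df: int
    p_value: float
    q_value: float | None = None
    significant: bool | None = None
    boundary: bool = False  # separation: a fitted proportion hit 0 or 1


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------


def aggregate_groups(
    quants: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    mode: str = "tissue",
    tissue: str | None = None,
    library_sizes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Sum event counts within groups and normalize to counts per million.

    ``quants`` is the long-format quantification table (event_key,
    sample_id, counts_eii, counts_eei); ``sample_sheet`` maps sample_id to
    tissue, stage and replicate. ``mode="tissue"`` pools all stages and
    replicates per tissue; ``mode="stage"`` pools replicates per stage
    within the given ``tissue``. ``library_sizes`` gives per-sample junction
    library sizes for CPM; by default each sample's total event counts are
    used. Returns a long table (event_key, side, group, raw_count, cpm).
    """
    sheet = sample_sheet.set_index("sample_id")
    unknown = set(quants["sample_id"]) - set(sheet.index)
    if unknown:
        raise ValueError(f"samples missing from sample sheet: {sorted(unknown)}")
    if mode == "tissue":
        group_of = sheet["tissue"].to_dict()
    elif mode == "stage":
        if tissue is None:
            raise ValueError("mode='stage' requires a tissue")
        sheet = sheet[sheet["tissue"] == tissue]
        group_of = sheet["stage"].to_dict()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = quants[quants["sample_id"].isin(group_of)].copy()
    df["group"] = df["sample_id"].map(group_of)

    if library_sizes is None:
        lib = df.groupby("sample_id")[["counts_eii", "counts_eei"]].sum().sum(axis=1)
        library_sizes = lib.to_dict()
    group_lib = {}
    for sample_id, group in group_of.items():
        group_lib[group] = group_lib.get(group, 0.0) + float(
            library_sizes.get(sample_id, 0.0)
        )
    empty = [g for g, size in group_lib.items() if size <= 0]
    if empty:
        log.warning("dropping empty groups (zero library size): %s", empty)
        group_lib = {g: s for g, s in group_lib.items() if s > 0}
        df = df[df["group"].isin(group_lib)]

    agg = (
        df.groupby(["event_key", "group"], as_index=False)[["counts_eii", "counts_eei"]]
        .sum()
        .melt(
            id_vars=["event_key", "group"],
            value_vars=["counts_eii", "counts_eei"],
            var_name="side",
            value_name="raw_count",
        )
    )
    agg["side"] = agg["side"].map({"counts_eii": "EII", "counts_eei": "EEI"})
    agg["cpm"] = agg.apply(
        lambda r: 1e6 * r["raw_count"] / group_lib[r["group"]], axis=1
    )
    return agg.sort_values(["event_key", "side", "group"]).reset_index(drop=True)


def coverage_filter(agg: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Keep isoform sides whose maximum per-group raw count is >= min_count."""
    max_raw = agg.groupby(["event_key", "side"])["raw_count"].transform("max")
    return agg[max_raw >= min_count].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tau
# ---------------------------------------------------------------------------


def tau(x: Sequence[float]) -> float:
    """Specificity index over group abundances; scale-invariant, in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("tau requires at least 2 groups")
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    m = arr.max()
    if m == 0:
        return math.nan
    x_hat = arr / m
    return float((1.0 - x_hat).sum() / (len(arr) - 1))


def specificity_profiles(agg: pd.DataFrame) -> list[SpecificityProfile]:
    """Build per-(event, side) specificity profiles from aggregated counts."""
    profiles = []
    for (event_key, side), sub in agg.groupby(["event_key", "side"], sort=True):
        sub = sub.sort_values("group")
        profiles.append(
            SpecificityProfile(
                event_key=event_key,
                isoform_side=side,
                groups=tuple(sub["group"]),
                x=sub["cpm"].to_numpy(),
                raw=sub["raw_count"].to_numpy(),
            )
        )
    return profiles


def call_specific(
    profiles: Sequence[SpecificityProfile], tau_threshold: float = 1.0
) -> pd.DataFrame:
    """Call group-specific isoform sides.

    With the default threshold of 1.0 a side is specific iff it is expressed
    in exactly one group; with a lower threshold, iff tau >= threshold. The
    specific group is the abundance argmax. Returns one row per profile with
    tau and the call.
    """
    rows = []
    for p in profiles:
        specific = False
        group = None
        if not math.isnan(p.tau):
            if tau_threshold >= 1.0:
                specific = int((p.x > 0).sum()) == 1
            else:
                specific = p.tau >= tau_threshold
            if specific:
                group = p.groups[int(np.argmax(p.x))]
        p.specific_group = group
        rows.append(
            {
                "event_key": p.event_key,
                "side": p.isoform_side,
                "tau": p.tau,
                "specific": specific,
                "specific_group": group,
            }
        )
    return pd.DataFrame(
        rows, columns=["event_key", "side", "tau", "specific", "specific_group"]
    )


# ---------------------------------------------------------------------------
# Differential splicing LRT
# ---------------------------------------------------------------------------


def _binom_loglik(inc: float, exc: float, p: float) -> float:
    # Binomial log-likelihood kernel with the 0*log(0) = 0 convention.
    ll = 0.0
    if inc > 0:
        ll += inc * math.log(p)
    if exc > 0:
        ll += exc * math.log(1.0 - p)
    return ll


def differential_lrt(
    counts_a: Sequence[tuple[int, int]],
    counts_b: Sequence[tuple[int, int]],
    event_key: str = "",
    comparison: tuple[str, str] = ("A", "B"),
) -> DifferentialResult | None:
    """Binomial logistic LRT of condition-specific inclusion odds.

    ``counts_a`` / ``counts_b`` are per-replicate (inclusion, exclusion)
    count pairs. Returns None when either condition has zero total count
    (the event is untestable there). Complete separation (a condition MLE of
    0 or 1) is handled by the boundary log-likelihood and flagged.
    """
    ia = float(sum(i for i, _ in counts_a))
    ea = float(sum(e for _, e in counts_a))
    ib = float(sum(i for i, _ in counts_b))
    eb = float(sum(e for _, e in counts_b))
    ta, tb = ia + ea, ib + eb
    if ta == 0 or tb == 0:
        return None
    pa, pb = ia / ta, ib / tb
    p0 = (ia + ib) / (ta + tb)
    ll_alt = _binom_loglik(ia, ea, pa) + _binom_loglik(ib, eb, pb)
    ll_null = _binom_loglik(ia, ea, p0) + _binom_loglik(ib, eb, p0)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    p_value = float(stats.chi2.sf(lr, df=1))
    return DifferentialResult(
        event_key=event_key,
        comparison=comparison,
        lr_statistic=lr,
        df=1,
        p_value=max(p_value, np.finfo(float).tiny),
        boundary=pa in (0.0, 1.0) or pb in (0.0, 1.0),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    quants: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_column: str = "tissue",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-event LRT between two groups with BH-FDR control.

    Replicate structure comes from the sample sheet: every sample mapped to
    ``group_a`` or ``group_b`` in ``group_column`` contributes one
    (inclusion, exclusion) pair. Events untestable in either group (zero
    total count) are skipped.
    """
    sheet = sample_sheet.set_index("sample_id")
    samples_a = sheet.index[sheet[group_column] == group_a]
    samples_b = sheet.index[sheet[group_column] == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least 2 replicates per condition")

    results: list[DifferentialResult] = []
    for event_key, sub in quants.groupby("event_key", sort=True):
        sub = sub.set_index("sample_id")
        ca = [
            (int(sub.loc[s, "counts_eii"]), int(sub.loc[s, "counts_eei"]))
            for s in samples_a
            if s in sub.index
        ]
        cb = [
            (int(sub.loc[s, "counts_eii"]), int(sub.loc[s, "counts_eei"]))
            for s in samples_b
            if s in sub.index
        ]
        res = differential_lrt(ca, cb, event_key, (group_a, group_b))
        if res is not None:
            results.append(res)

    if not results:
        return pd.DataFrame(
            columns=[
                "event_key", "group_a", "group_b", "lr_statistic", "df",
                "p_value", "q_value", "significant", "boundary",
            ]
        )
    q = bh_fdr([r.p_value for r in results])
    rows = []
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < alpha)
        rows.append(
            {
                "event_key": r.event_key,
                "group_a": group_a,
                "group_b": group_b,
                "lr_statistic": r.lr_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "boundary": r.boundary,
            }
        )
    return pd.DataFrame(rows)
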