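"""Family-level inheritance-rate analysis for single-generation outcrosses.

Each family is one transgenic parent outcrossed to wild-type; its offspring
are scored for the fluorescent marker linked to the drive.  Rates are
computed per family, families with fewer offspring than a scoring minimum
(20 larvae by convention) are excluded, and group summaries use the
inclusive linear-interpolation quantile convention so box-plot statistics
are reproducible across implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import TransHetAssay

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyRecord",
    "GroupSummary",
    "inheritance_rates",
    "mendelian_chisq",
    "activity_rates",
    "compare_groups",
    "read_family_records",
]

DEFAULT_MIN_OFFSPRING = 20


@dataclass(frozen=True)
class FamilyRecord:
    """Offspring counts for one family (one transgenic parent's cross)."""

    line: str
    generation: str  # "OX1" or "OX2"
    parent_sex: str
    n_offspring: int
    n_marker_positive: int
    marker: str = "mCherry"
    grandparent_sex: str | None = None
    pool_label: str | None = None

    def __post_init__(self) -> None:
        if self.n_marker_positive > self.n_offspring:
            raise ValueError("n_marker_positive cannot exceed n_offspring")
        if self.n_offspring < 0:
            raise ValueError("n_offspring must be non-negative")

    @property
    def rate(self) -> float:
        return self.n_marker_positive / self.n_offspring if self.n_offspring else 0.0


@dataclass(frozen=True)
class GroupSummary:
    """Five-number summary of per-family inheritance rates for one group."""

    group_key: tuple
    n_families: int
    median_rate: float
    q1: float
    q3: float
    min: float
    max: float


_DEFAULT_GROUPING = ("line", "generation", "parent_sex")


def inheritance_rates(
    records: Sequence[FamilyRecord],
    min_n: int = DEFAULT_MIN_OFFSPRING,
    group_by: Sequence[str] = _DEFAULT_GROUPING,
) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Per-family marker-inheritance rates plus per-group summaries.

    Families with fewer than ``min_n`` scored offspring are excluded from
    the summaries (and flagged in the returned frame and the log).  If every
    family is filtered the summary list is empty and a warning is logged —
    not an exception.
    """
    if not records:
        raise ValueError("no family records given")
    df = pd.DataFrame(
        {
            "line": r.line,
            "generation": r.generation,
            "parent_sex": r.parent_sex,
            "grandparent_sex": r.grandparent_sex,
            "pool_label": r.pool_label,
            "marker": r.marker,
            "n_offspring": r.n_offspring,
            "n_marker_positive": r.n_marker_positive,
            "rate": r.rate,
            "retained": r.n_offspring >= min_n,
        }
        for r in records
    )
    n_dropped = int((~df["retained"]).sum())
    if n_dropped:
        logger.info("excluded %d families with fewer than %d offspring", n_dropped, min_n)
    kept = df[df["retained"]]
    if kept.empty:
        logger.warning("all %d families fell below the %d-offspring minimum", len(df), min_n)
        return df, []
    summaries = []
    for key, grp in kept.groupby(list(group_by), dropna=False, sort=True):
        rates = grp["rate"].to_numpy()
        q1, med, q3 = np.percentile(rates, [25, 50, 75])  # linear interpolation
        summaries.append(
            GroupSummary(
                group_key=key if isinstance(key, tuple) else (key,),
                n_families=len(rates),
                median_rate=float(med),
                q1=float(q1),
                q3=float(q3),
                min=float(rates.min()),
                max=float(rates.max()),
            )
        )
    return df, summaries


def mendelian_chisq(n_positive: int, n_total: int) -> dict[str, float]:
    """1-df chi-square test of a 1:1 marker ratio (Mendelian expectation)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_positive > n_total or n_positive < 0:
        raise ValueError("n_positive must lie in [0, n_total]")
    chi2, p = stats.chisquare([n_positive, n_total - n_positive])
    return {"chi2": float(chi2), "p": float(p)}


def activity_rates(assay: TransHetAssay) -> pd.DataFrame:
    """Mean +/- SEM activity fraction per marker class and locus.

    Per-replicate activity fractions are averaged within each marker class;
    the SEM uses the sample standard deviation over replicates.  Replicates
    with zero larvae are excluded with a warning.
    """
    rows = []
    for rep in assay.replicates:
        if rep.n_larvae == 0:
            logger.warning("%s: excluding zero-larva replicate", assay.line)
            continue
        rows.append(
            {
                "marker_class": rep.marker_class,
                "carb109": rep.n_active_carb109 / rep.n_larvae,
                "timp4": rep.n_active_timp4 / rep.n_larvae,
            }
        )
    if not rows:
        raise ValueError(f"{assay.line}: no usable replicates")
    df = pd.DataFrame(rows)
    out = []
    for cls, grp in df.groupby("marker_class"):
        for locus in ("carb109", "timp4"):
            vals = grp[locus].to_numpy()
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            out.append(
                {
                    "line": assay.line,
                    "marker_class": cls,
                    "locus": locus,
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(out)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal–Wallis across groups plus Bonferroni-corrected pairwise tests.

    Convenience wrapper around standard routines (scipy Kruskal–Wallis;
    pairwise two-sided Mann–Whitney U with Bonferroni correction via
    statsmodels) for comparing per-family rate distributions between
    crossing groups.
    """
    from statsmodels.stats.multitest import multipletests

    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    kw_stat, kw_p = stats.kruskal(*arrays)
    pairs, raw_p = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            _, p = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            pairs.append((labels[i], labels[j]))
            raw_p.append(p)
    adj = multipletests(raw_p, method="bonferroni")[1] if raw_p else []
    return {
        "kruskal": {"statistic": float(kw_stat), "p": float(kw_p)},
        "pairwise": [
            {"groups": pair, "p_raw": float(p), "p_adjusted": float(q)}
            for pair, p, q in zip(pairs, raw_p, adj)
        ],
    }


def read_family_records(path) -> list[FamilyRecord]:
    """Read family records from CSV (one row per family)."""
    df = pd.read_csv(path)
    required = {"line", "generation", "parent_sex", "n_offspring", "n_marker_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"family CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            FamilyRecord(
                line=row["line"],
                generation=row["generation"],
                parent_sex=row["parent_sex"],
                n_offspring=int(row["n_offspring"]),
                n_marker_positive=int(row["n_marker_positive"]),
                marker=row.get("marker", "mCherry"),
                grandparent_sex=row.get("grandparent_sex"),
                pool_label=row.get("pool_label"),
            )
        )
    return records
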