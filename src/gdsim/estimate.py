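"""Drive-parameter and lifecycle-parameter estimation from assay counts.

Converts the observed single-generation cross data into the rates that
parameterize the inheritance cube and the population model:

* ``estimate_cut_params`` — germline cutting / homing / resistance rates
  (c, ch, cr) per transgenic-parent sex from pooled OX-1 cross counts.
* ``estimate_deposition`` — the maternal Cas9-RNP deposition rate dF from
  the trans-heterozygous (drive / blocked-drive balancer) assay.
* ``derive_lifecycle`` — demographic quantities (betaK, tLarva, xi,
  fertility multiplier) from a life-parameter table.

Two estimators are offered for the cutting rates.  ``method="table"``
reproduces the count arithmetic used to derive the published simulation
parameters: marker-positive offspring from the low and high pools are summed
(P), drive-blocking indels among the marker-negative offspring are estimated
from the per-pool assay fractions (G), and

    c = (P + G) / N,   ch = P / (P + G),   cr = 1 - ch.

That arithmetic treats *every* marker-positive offspring as a homing event,
so it is not consistent with the inheritance-cube model, under which a
hemizygous parent transmits the marker at rate (1 + c*ch)/2 even without any
cutting; plugged into the cube it therefore yields a stronger drive than the
raw marker rates imply.  ``method="cube"`` inverts the cube expectations
(marker rate m = (1+c*ch)/2, resistance rate r = c*cr/2):

    c = 2*(P + G)/N - 1,   ch = (2*P/N - 1) / c,

which is the consistent (method-of-moments) estimator and is the one that
recovers the generating parameters of synthetic crosses.  The default is
``method="table"`` so that table reproduction and simulation
parameterization match the published pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EstimationError",
    "PoolObservation",
    "PooledCrossCounts",
    "TransHetReplicate",
    "TransHetAssay",
    "CutRateEstimate",
    "DepositionEstimate",
    "estimate_cut_params",
    "estimate_deposition",
    "derive_lifecycle",
    "read_pool_counts",
    "pooled_counts_from_table",
]


class EstimationError(ValueError):
    """Raised when counts are insufficient or inconsistent for estimation."""


@dataclass(frozen=True)
class PoolObservation:
    """One OX-1 offspring pool ("low" or "high" drive).

    ``marker_positive`` may be given as a raw count; otherwise it is
    reconstructed as ``round(marker_rate * n_assessed)`` (the tables print
    percentages, and rounding reproduces them at the printed precision).
    """

    pool_label: str
    n_assessed: int
    marker_rate: float | None = None
    marker_positive: int | None = None
    gdbi_tested: int = 0
    gdbi_positive: int = 0

    def __post_init__(self) -> None:
        if self.n_assessed < 0 or self.gdbi_tested < 0 or self.gdbi_positive < 0:
            raise EstimationError("pool counts must be non-negative")
        if self.gdbi_positive > self.gdbi_tested:
            raise EstimationError("gdbi_positive cannot exceed gdbi_tested")
        if self.marker_positive is None and self.marker_rate is None:
            raise EstimationError("pool needs marker_positive or marker_rate")
        if self.marker_rate is not None and not 0.0 <= self.marker_rate <= 1.0:
            raise EstimationError("marker_rate must lie in [0, 1]")
        if self.marker_positive is not None and self.marker_positive > self.n_assessed:
            raise EstimationError("marker_positive cannot exceed n_assessed")

    @property
    def positives(self) -> int:
        if self.marker_positive is not None:
            return int(self.marker_positive)
        return int(round(self.marker_rate * self.n_assessed))


@dataclass(frozen=True)
class PooledCrossCounts:
    """Pooled OX-1 cross observations for one line and transgenic-parent sex."""

    line: str
    parent_sex: str
    pools: tuple[PoolObservation, ...]

    def __post_init__(self) -> None:
        if self.parent_sex not in ("F", "M"):
            raise EstimationError(f"parent_sex must be 'F' or 'M', got {self.parent_sex!r}")
        object.__setattr__(self, "pools", tuple(self.pools))


@dataclass(frozen=True)
class TransHetReplicate:
    """One replicate of the trans-heterozygous deposition assay."""

    marker_class: str  # "eCFP" (balancer-inheriting) or "mCherry" (drive-inheriting)
    n_larvae: int
    n_active_carb109: int = 0
    n_active_timp4: int = 0

    def __post_init__(self) -> None:
        if self.marker_class not in ("eCFP", "mCherry"):
            raise EstimationError(f"unknown marker class {self.marker_class!r}")
        if not (0 <= self.n_active_carb109 <= self.n_larvae >= self.n_active_timp4 >= 0):
            raise EstimationError("activity counts must lie within [0, n_larvae]")


@dataclass(frozen=True)
class TransHetAssay:
    line: str
    replicates: tuple[TransHetReplicate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(self.replicates))


@dataclass(frozen=True)
class CutRateEstimate:
    """Estimated germline cutting parameters for one parent sex."""

    line: str
    parent_sex: str
    c: float
    ch: float
    cr: float
    n_total: int
    n_marker_positive: int
    gdbi_estimate: float
    method: str


@dataclass(frozen=True)
class DepositionEstimate:
    line: str
    dF: float
    dhF: float
    drF: float
    n_replicates: int


def estimate_cut_params(
    counts: PooledCrossCounts, method: str = "table"
) -> CutRateEstimate:
    """Estimate (c, ch, cr) for one parent sex from pooled cross counts.

    See the module docstring for the two methods.  GDBI fractions are
    applied per pool when that pool was assayed; a pool with untested
    marker-negatives falls back to the fraction pooled across the tested
    pools.  Returns ``ch = 1, cr = 0`` when no indels were observed.
    """
    if method not in ("table", "cube"):
        raise EstimationError(f"unknown method {method!r}")
    pools = [p for p in counts.pools if p.n_assessed > 0]
    if not pools:
        raise EstimationError(f"{counts.line}/{counts.parent_sex}: no assessed offspring")

    n_total = sum(p.n_assessed for p in pools)
    positives = sum(p.positives for p in pools)

    tested_pos = sum(p.gdbi_positive for p in pools if p.gdbi_tested > 0)
    tested_n = sum(p.gdbi_tested for p in pools if p.gdbi_tested > 0)
    pooled_frac = tested_pos / tested_n if tested_n > 0 else 0.0

    gdbi = 0.0
    for p in pools:
        negatives = p.n_assessed - p.positives
        if negatives <= 0:
            continue
        frac = p.gdbi_positive / p.gdbi_tested if p.gdbi_tested > 0 else pooled_frac
        gdbi += negatives * frac

    if positives == 0 and gdbi == 0.0 and tested_n == 0:
        raise EstimationError(
            f"{counts.line}/{counts.parent_sex}: all counts are zero; nothing to estimate"
        )

    if method == "table":
        c = (positives + gdbi) / n_total
        ch = positives / (positives + gdbi) if positives + gdbi > 0 else 1.0
    else:  # cube-consistent method of moments
        c = 2.0 * (positives + gdbi) / n_total - 1.0
        c = min(max(c, 0.0), 1.0)
        ch = (2.0 * positives / n_total - 1.0) / c if c > 0 else 1.0
        ch = min(max(ch, 0.0), 1.0)
    c = min(max(c, 0.0), 1.0)
    return CutRateEstimate(
        line=counts.line,
        parent_sex=counts.parent_sex,
        c=c,
        ch=ch,
        cr=1.0 - ch,
        n_total=n_total,
        n_marker_positive=positives,
        gdbi_estimate=gdbi,
        method=method,
    )


def estimate_deposition(assay: TransHetAssay) -> DepositionEstimate:
    """Maternal deposition rate dF from the trans-heterozygous assay.

    dF is the mean over replicates of the per-replicate fraction of
    balancer (eCFP)-inheriting larvae showing Cas9 activity at the drive
    locus.  Those larvae inherited an uncleavable balancer allele from the
    mother, so any edit of the paternal wild-type allele must come from
    deposited Cas9-RNP.  With no homology template in the embryo the
    resolution split is fixed to ``dhF = 0``, ``drF = 1``.
    """
    fracs = [
        r.n_active_carb109 / r.n_larvae
        for r in assay.replicates
        if r.marker_class == "eCFP" and r.n_larvae > 0
    ]
    if not fracs:
        raise EstimationError(f"{assay.line}: no eCFP-class replicates with larvae")
    return DepositionEstimate(
        line=assay.line,
        dF=float(np.mean(fracs)),
        dhF=0.0,
        drF=1.0,
        n_replicates=len(fracs),
    )


def derive_lifecycle(
    fitness: pd.DataFrame,
    line: str,
    reference_line: str = "HWE",
    viability_significant: bool | None = None,
) -> dict[str, float]:
    """Demographic parameters for one drive line from a life-parameter table.

    * ``betaK`` = reference fecundity x 4 (blood meals per lifetime) / 11
      (average adult female lifespan in days) — eggs/female/day.
    * ``tLarva`` = reference larva-to-pupa development time, rounded to days.
    * ``xiF = xiM`` = 1 + (viability(line) - viability(reference)) when the
      drive line's larval viability is *lower* and the difference is flagged
      significant; 1 otherwise (no modifier).  Significance gating is an
      input flag (column ``viability_significant`` or the keyword), not an
      internal hypothesis test.
    * ``fertility_mult`` = 0.9 for drive-carrying genotypes.

    The table needs one row per line with columns ``line``,
    ``fecundity_mean``, ``larval_viability``, ``larva_to_pupa_days`` and
    optionally ``viability_significant``.
    """
    idx = fitness.set_index("line")
    for name in (line, reference_line):
        if name not in idx.index:
            raise EstimationError(f"fitness table has no row for line {name!r}")
    gd = idx.loc[line]
    ref = idx.loc[reference_line]

    if viability_significant is None:
        viability_significant = bool(gd.get("viability_significant", False))

    delta = float(gd["larval_viability"]) - float(ref["larval_viability"])
    xi = 1.0 + delta if (delta < 0 and viability_significant) else 1.0
    return {
        "betaK": float(ref["fecundity_mean"]) * 4.0 / 11.0,
        "tLarva": int(round(float(ref["larva_to_pupa_days"]))),
        "xiF": xi,
        "xiM": xi,
        "fertility_mult": 0.9,
    }


# ---------------------------------------------------------------------------
# tabular I/O


_POOL_COLUMNS = ("line", "parent_sex", "pool", "n_assessed", "gdbi_tested", "gdbi_positive")


def pooled_counts_from_table(
    table: pd.DataFrame, line: str, parent_sex: str
) -> PooledCrossCounts:
    """Build :class:`PooledCrossCounts` from a long-format pool table.

    Accepts either a raw-count column ``marker_positive`` or a percentage
    column ``marker_pct`` (or fractional ``marker_rate``).
    """
    for col in _POOL_COLUMNS:
        if col not in table.columns:
            raise EstimationError(f"pool table missing column {col!r}")
    sub = table[(table["line"] == line) & (table["parent_sex"] == parent_sex)]
    if sub.empty:
        raise EstimationError(f"no pool rows for line={line!r} parent_sex={parent_sex!r}")
    pools = []
    for _, row in sub.iterrows():
        positive = None
        rate = None
        if "marker_positive" in sub.columns and not pd.isna(row.get("marker_positive")):
            positive = int(row["marker_positive"])
        elif "marker_rate" in sub.columns and not pd.isna(row.get("marker_rate")):
            rate = float(row["marker_rate"])
        elif "marker_pct" in sub.columns and not pd.isna(row.get("marker_pct")):
            rate = float(row["marker_pct"]) / 100.0
        else:
            raise EstimationError(
                "pool table needs marker_positive, marker_rate or marker_pct"
            )
        pools.append(
            PoolObservation(
                pool_label=str(row["pool"]),
                n_assessed=int(row["n_assessed"]),
                marker_rate=rate,
                marker_positive=positive,
                gdbi_tested=int(row["gdbi_tested"]),
                gdbi_positive=int(row["gdbi_positive"]),
            )
        )
    return PooledCrossCounts(line=line, parent_sex=parent_sex, pools=tuple(pools))


def read_pool_counts(path, line: str, parent_sex: str) -> PooledCrossCounts:
    """Read a pool-count CSV and extract one line/sex group."""
    return pooled_counts_from_table(pd.read_csv(path), line, parent_sex)
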