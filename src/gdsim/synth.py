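"""Synthetic cross datasets, deposition assays, and amplicon tables.

Generates data with the statistical structure the analysis modules assume,
so the whole pipeline is testable without external data:

* ``synth_cross_dataset`` — hemizygous x wild-type families whose offspring
  genotypes are drawn multinomially from the inheritance cube
  (female-parental crosses include maternal deposition; male-parental
  crosses cannot, since the mother is wild-type), scored for the marker,
  assayed for drive-blocking indels among marker-negative offspring, and
  aggregated into "low"/"high" pools.
* ``synth_transhet`` — the trans-heterozygous (drive / blocked-drive
  balancer) maternal-deposition assay: offspring inherit the balancer or
  the drive with probability 1/2, and balancer-inheriting larvae show
  drive-locus activity with probability ``dF``.
* ``synth_amplicons`` — per-read amplicon edit classifications with an
  optional PCR-chimera artifact that inflates the apparent indel proportion
  above its true value.

Family sizes follow a truncated negative binomial matched to the observed
ranges (female-parental crosses: 20-142 offspring, mean 59; male-parental:
21-415, mean 91); the exact distribution of real family sizes is unknown,
so an overdispersed count distribution fit to those summaries is used.

A marker-negative larva is indel-positive exactly when it carries at least
one resistance (R) allele: sequence-level drive-blocking indels are
identified one-to-one with R alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cube import GENOTYPES, GENOTYPE_INDEX, H_COPIES, R_COPIES, DriveParams, build_cube
from .crosses import FamilyRecord
from .estimate import (
    PoolObservation,
    PooledCrossCounts,
    TransHetAssay,
    TransHetReplicate,
)
from .amplicons import AmpliconClassCounts, IndelEvent

__all__ = [
    "FamilySizeDist",
    "SynthCrossSpec",
    "synth_cross_dataset",
    "synth_transhet",
    "synth_amplicons",
]

_H_MASK = H_COPIES > 0
_R_MASK = R_COPIES > 0


@dataclass(frozen=True)
class FamilySizeDist:
    """Truncated negative binomial family-size distribution."""

    mean: float
    min: int
    max: int
    dispersion: float = 5.0  # negative-binomial shape k; larger = closer to Poisson

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError("need min <= mean <= max")
        if self.min < 1:
            raise ValueError("family sizes must be >= 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.min == self.max:  # degenerate: fixed family size
            return np.full(n, self.min, dtype=np.int64)
        k, m = self.dispersion, self.mean
        p = k / (k + m)
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.negative_binomial(k, p, size=2 * (n - filled) + 8)
            draw = draw[(draw >= self.min) & (draw <= self.max)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out


FEMALE_PARENTAL_SIZES = FamilySizeDist(mean=59, min=20, max=142)
MALE_PARENTAL_SIZES = FamilySizeDist(mean=91, min=21, max=415)


@dataclass(frozen=True)
class SynthCrossSpec:
    """Conditions for a synthetic hemizygous x wild-type cross dataset."""

    params: DriveParams
    n_families_f: int = 12
    n_families_m: int = 12
    sizes_f: FamilySizeDist = FEMALE_PARENTAL_SIZES
    sizes_m: FamilySizeDist = MALE_PARENTAL_SIZES
    gdbi_test_fraction: float = 0.5
    line: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families_f < 0 or self.n_families_m < 0:
            raise ValueError("family counts must be non-negative")
        if not 0.0 <= self.gdbi_test_fraction <= 1.0:
            raise ValueError("gdbi_test_fraction must lie in [0, 1]")


def synth_cross_dataset(
    spec: SynthCrossSpec,
) -> tuple[list[FamilyRecord], dict[str, PooledCrossCounts]]:
    """Generate family records and pooled counts for both parent sexes.

    Families are split into a "low" and a "high" pool at the within-sex
    median family marker rate, mirroring how low- and high-drive pools were
    constituted in the source crosses.
    """
    rng = np.random.default_rng(spec.seed)
    cube = build_cube(spec.params)
    wh, ww = GENOTYPE_INDEX["WH"], GENOTYPE_INDEX["WW"]
    records: list[FamilyRecord] = []
    pooled: dict[str, PooledCrossCounts] = {}

    for parent_sex, n_fam, sizes in (
        ("F", spec.n_families_f, spec.sizes_f),
        ("M", spec.n_families_m, spec.sizes_m),
    ):
        if n_fam == 0:
            continue
        row = cube.probs[wh, ww] if parent_sex == "F" else cube.probs[ww, wh]
        fam_sizes = sizes.sample(n_fam, rng)
        fam_data = []
        for size in fam_sizes:
            counts = rng.multinomial(size, row)
            n_pos = int(counts[_H_MASK].sum())
            neg_r = int(counts[_R_MASK & ~_H_MASK].sum())  # marker-negative R carriers
            n_neg = int(size) - n_pos
            tested = int(rng.binomial(n_neg, spec.gdbi_test_fraction))
            positive = (
                int(rng.hypergeometric(neg_r, n_neg - neg_r, tested)) if tested else 0
            )
            fam_data.append((int(size), n_pos, tested, positive))
            records.append(
                FamilyRecord(
                    line=spec.line,
                    generation="OX1",
                    parent_sex=parent_sex,
                    n_offspring=int(size),
                    n_marker_positive=n_pos,
                )
            )
        rates = np.array([pos / size for size, pos, _, _ in fam_data])
        cut = np.median(rates)
        pools = []
        for label, mask in (("low", rates <= cut), ("high", rates > cut)):
            if not mask.any():
                continue
            sel = [fam_data[i] for i in np.flatnonzero(mask)]
            pools.append(
                PoolObservation(
                    pool_label=label,
                    n_assessed=sum(s for s, *_ in sel),
                    marker_positive=sum(p for _, p, _, _ in sel),
                    gdbi_tested=sum(t for *_, t, _ in sel),
                    gdbi_positive=sum(g for *_, g in sel),
                )
            )
        pooled[parent_sex] = PooledCrossCounts(
            line=spec.line, parent_sex=parent_sex, pools=tuple(pools)
        )
    return records, pooled


def synth_transhet(
    params: DriveParams,
    n_per_rep: int | Sequence[int],
    reps: int = 3,
    seed: int = 0,
    line: str = "synthetic",
    timp4_rate: float | None = None,
) -> TransHetAssay:
    """Synthetic trans-heterozygous deposition assay.

    Mothers carry the drive balanced over the uncleavable eCFP allele, so
    each surviving larva inherits the balancer (eCFP class) or the drive
    (mCherry class) with probability 1/2.  The paternal wild-type allele of
    a balancer-class larva is edited only by maternally deposited Cas9-RNP,
    i.e. with probability ``dF``; drive-class larvae are modelled with the
    same embryonic rate.  ``timp4_rate`` (activity at a secondary locus
    targeted by injected sgRNA) defaults to ``dF``.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(n_per_rep)] * reps if np.isscalar(n_per_rep) else [int(x) for x in n_per_rep]
    t4 = params.dF if timp4_rate is None else timp4_rate
    replicates = []
    for n in sizes:
        n_ecfp = int(rng.binomial(n, 0.5))
        for cls, n_cls in (("eCFP", n_ecfp), ("mCherry", n - n_ecfp)):
            replicates.append(
                TransHetReplicate(
                    marker_class=cls,
                    n_larvae=n_cls,
                    n_active_carb109=int(rng.binomial(n_cls, params.dF)),
                    n_active_timp4=int(rng.binomial(n_cls, t4)),
                )
            )
    return TransHetAssay(line=line, replicates=tuple(replicates))


_DEFAULT_SPECTRUM = {
    "deletion_share": 0.94,   # deletions dominate the indel spectrum
    "insertion_share": 0.04,
    "substitution_share": 0.02,
    "max_deletion_bp": 82,
    "max_insertion_bp": 60,
    "offset_sd_bp": 12.0,     # events concentrate within ~50 bp of the cut
}


def synth_amplicons(
    true_indel_fraction: float,
    n_reads: int,
    chimera_rate: float = 0.0,
    size_spectrum_spec: dict | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> AmpliconClassCounts:
    """Synthetic per-read amplicon classifications with optional chimera.

    Each read carries a true indel with probability ``true_indel_fraction``;
    of the remaining unmodified reads, a fraction ``chimera_rate`` is
    misclassified as edited by template-switching artifacts, so the apparent
    indel proportion is ``f + (1 - f) * chimera_rate`` in expectation —
    above the 50% hemizygous ceiling whenever truth sits at the ceiling and
    any chimerism is present.
    """
    if not 0.0 <= true_indel_fraction <= 1.0 or not 0.0 <= chimera_rate <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    spec = dict(_DEFAULT_SPECTRUM, **(size_spectrum_spec or {}))
    rng = np.random.default_rng(seed)

    true_indel = int(rng.binomial(n_reads, true_indel_fraction))
    chimeric = int(rng.binomial(n_reads - true_indel, chimera_rate))
    n_indel = true_indel + chimeric
    shares = np.array(
        [spec["deletion_share"], spec["insertion_share"], spec["substitution_share"]]
    )
    n_del, n_ins, n_sub = rng.multinomial(n_indel, shares / shares.sum())

    events: list[IndelEvent] = []
    caps = {"deletion": spec["max_deletion_bp"], "insertion": spec["max_insertion_bp"],
            "substitution": 3}
    for etype, count in (("deletion", n_del), ("insertion", n_ins), ("substitution", n_sub)):
        if count == 0:
            continue
        sizes = np.minimum(1 + rng.geometric(0.15, size=count), caps[etype])
        offsets = np.rint(rng.normal(0.0, spec["offset_sd_bp"], size=count)).astype(int)
        agg: dict[tuple[int, int], int] = {}
        for s, o in zip(sizes, offsets):
            agg[(int(s), int(o))] = agg.get((int(s), int(o)), 0) + 1
        for (s, o), n in sorted(agg.items()):
            events.append(IndelEvent(type=etype, size_bp=s, offset_from_cut_bp=o, read_count=n))

    classes = {
        "unmodified": n_reads - n_indel,
        "deletion": int(n_del),
        "insertion": int(n_ins),
        "substitution": int(n_sub),
    }
    return AmpliconClassCounts(
        sample_id=sample_id, n_reads=n_reads, classes=classes, events=tuple(events) or None
    )
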