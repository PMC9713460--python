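"""Amplicon edit-classification summaries for drive-blocking indels (GDBI).

Consumes per-read edit classifications of amplicons spanning the CRISPR
target site (as produced by amplicon-editing quantifiers such as CRISPResso)
and summarizes them into indel proportions, size/position spectra, and a
PCR-chimera diagnostic.

Substitution calls at the cut site are counted toward the indel total by
default: in this assay they are interpreted as composite deletion/insertion
events, not sequencing noise.  Pass ``include_substitutions=False`` to
``indel_proportion`` for a sensitivity analysis without them.

The chimera diagnostic rests on a simple hemizygosity argument: amplicons
from pooled *marker-negative* offspring of a hemizygous-by-wild-type cross
can carry an indel on at most one of the two inherited alleles, so the true
indel proportion cannot exceed 50%; observed proportions above that ceiling
indicate a template-switching (PCR chimera) artifact inflating the count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndelEvent",
    "AmpliconClassCounts",
    "indel_proportion",
    "chimera_flag",
    "size_spectrum",
    "sample_summary",
    "read_class_tsv",
    "write_class_tsv",
    "from_crispresso",
]

CLASSES = ("unmodified", "insertion", "deletion", "substitution")
INDEL_CLASSES = ("insertion", "deletion", "substitution")


@dataclass(frozen=True)
class IndelEvent:
    """One distinct edit event observed in one or more reads."""

    type: str  # insertion | deletion | substitution
    size_bp: int
    offset_from_cut_bp: int
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.type not in INDEL_CLASSES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.size_bp <= 0:
            raise ValueError("event size must be positive")
        if self.read_count <= 0:
            raise ValueError("read_count must be positive")


@dataclass(frozen=True)
class AmpliconClassCounts:
    """Per-read edit classifications for one amplicon sample."""

    sample_id: str
    n_reads: int
    classes: dict[str, int]
    events: tuple[IndelEvent, ...] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        if any(v < 0 for v in self.classes.values()):
            raise ValueError("class counts must be non-negative")
        total = sum(self.classes.values())
        if total != self.n_reads:
            raise ValueError(f"class counts sum to {total}, expected n_reads={self.n_reads}")
        if self.events is not None:
            object.__setattr__(self, "events", tuple(self.events))

    def class_count(self, name: str) -> int:
        return self.classes.get(name, 0)


def indel_proportion(
    counts: AmpliconClassCounts, include_substitutions: bool = True
) -> float:
    """Fraction of reads carrying an edit (insertions + deletions [+ substitutions])."""
    if counts.n_reads <= 0:
        raise ValueError("sample has zero reads")
    keep = INDEL_CLASSES if include_substitutions else ("insertion", "deletion")
    return sum(counts.class_count(c) for c in keep) / counts.n_reads


def chimera_flag(proportion: float, ceiling: float = 0.5) -> tuple[bool, str]:
    """Flag indel proportions above the hemizygous theoretical maximum.

    ``ceiling`` defaults to 0.5 (marker-negative pools from hemizygous
    crosses); it is exposed as a parameter so pools with a different
    expected maximum can be screened too.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if proportion > ceiling:
        return True, (
            f"indel proportion {proportion:.3f} exceeds the theoretical maximum "
            f"{ceiling:.0%} for marker-negative pools; likely PCR-chimera artifact "
            "inflating the apparent GDBI count"
        )
    return False, f"indel proportion {proportion:.3f} within the {ceiling:.0%} ceiling"


def size_spectrum(counts: AmpliconClassCounts, window_bp: int = 50) -> dict:
    """Per-type size histograms and cut-site proximity of the observed events.

    Returns per-type ``{size: reads}`` histograms, the read-weighted fraction
    of events lying within ``window_bp`` of the cut site, and the largest
    deletion/insertion sizes.  Raises if the sample carries no event-level
    detail (class proportions remain computable without it).
    """
    if not counts.events:
        raise ValueError(f"{counts.sample_id}: no event-level data; spectrum unavailable")
    hist: dict[str, dict[int, int]] = {t: {} for t in INDEL_CLASSES}
    total = within = 0
    max_del = max_ins = 0
    for ev in counts.events:
        hist[ev.type][ev.size_bp] = hist[ev.type].get(ev.size_bp, 0) + ev.read_count
        total += ev.read_count
        if abs(ev.offset_from_cut_bp) <= window_bp:
            within += ev.read_count
        if ev.type == "deletion":
            max_del = max(max_del, ev.size_bp)
        elif ev.type == "insertion":
            max_ins = max(max_ins, ev.size_bp)
    return {
        "histograms": hist,
        "fraction_within_window": within / total,
        "window_bp": window_bp,
        "max_deletion_bp": max_del,
        "max_insertion_bp": max_ins,
    }


def sample_summary(counts: AmpliconClassCounts, window_bp: int = 50,
                   ceiling: float = 0.5) -> dict:
    """JSON-ready per-sample summary: proportion, chimera flag, spectrum."""
    prop = indel_proportion(counts)
    flag, note = chimera_flag(prop, ceiling=ceiling)
    out = {
        "sample_id": counts.sample_id,
        "n_reads": counts.n_reads,
        "indel_proportion": prop,
        "chimera_flag": flag,
        "chimera_note": note,
        "classes": dict(counts.classes),
    }
    if counts.events:
        spec = size_spectrum(counts, window_bp=window_bp)
        out["fraction_within_window"] = spec["fraction_within_window"]
        out["max_deletion_bp"] = spec["max_deletion_bp"]
        out["max_insertion_bp"] = spec["max_insertion_bp"]
    return out


# ---------------------------------------------------------------------------
# TSV interchange: sample_id, class, size, offset, read_count
# "unmodified" rows use size=0, offset=0.


def write_class_tsv(samples: Sequence[AmpliconClassCounts], path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "class": "unmodified",
                "size": 0,
                "offset": 0,
                "read_count": s.class_count("unmodified"),
            }
        )
        if s.events:
            for ev in s.events:
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "class": ev.type,
                        "size": ev.size_bp,
                        "offset": ev.offset_from_cut_bp,
                        "read_count": ev.read_count,
                    }
                )
        else:
            for cls in INDEL_CLASSES:
                n = s.class_count(cls)
                if n:
                    rows.append(
                        {"sample_id": s.sample_id, "class": cls, "size": 1,
                         "offset": 0, "read_count": n}
                    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_class_tsv(path) -> list[AmpliconClassCounts]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "class", "size", "offset", "read_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"class TSV missing columns: {sorted(missing)}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        classes = {c: 0 for c in CLASSES}
        events = []
        for cls, size, offset, n in zip(
            grp["class"], grp["size"], grp["offset"], grp["read_count"]
        ):
            n = int(n)
            if cls not in CLASSES:
                raise ValueError(f"sample {sid}: unknown class {cls!r}")
            classes[cls] += n
            if cls != "unmodified":
                events.append(
                    IndelEvent(
                        type=cls,
                        size_bp=int(size),
                        offset_from_cut_bp=int(offset),
                        read_count=n,
                    )
                )
        samples.append(
            AmpliconClassCounts(
                sample_id=str(sid),
                n_reads=sum(classes.values()),
                classes=classes,
                events=tuple(events) or None,
            )
        )
    return samples


def from_crispresso(path) -> AmpliconClassCounts:  # pragma: no cover - stub
    """Converter stub for native amplicon-quantifier output.

    Mapping (not implemented; supplied for users preparing the minimal TSV
    by hand): from the quantifier's per-allele frequency table, take
    ``n_deleted > 0`` rows as ``deletion`` events with ``size = n_deleted``,
    ``n_inserted > 0`` rows as ``insertion`` events with ``size =
    n_inserted``, remaining ``n_mutated > 0`` rows as ``substitution``
    events, and unmodified-reference rows as ``unmodified``; ``offset`` is
    the distance from the predicted cut site to the nearest edited base and
    ``read_count`` the ``#Reads`` column.
    """
    raise NotImplementedError("convert the quantifier output to the minimal TSV instead")
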