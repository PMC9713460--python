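"""Alleles, genotypes, drive parameters, and the homing inheritance cube.

The locus carries one of three alleles that matter for population dynamics:

``W``
    Unedited wild-type allele (cleavable protospacer present).
``H``
    The homing gene-drive allele: the integrated cassette carrying Cas9, the
    U6-driven sgRNA, and the fluorescent marker.  Because Cas9 and its guide
    travel with the construct, cleavage can only happen in individuals that
    carry at least one ``H``.
``R``
    A drive-blocking resistance allele: an end-joining indel at the target
    site that destroys the protospacer.  Resistance alleles formed in an
    intergenic locus are treated as cost free, so fitness-costly and
    cost-free repair products are merged into this single allele class.

A fourth code, ``E``, denotes the eCFP "blocked drive" balancer used in the
trans-heterozygous assays: an uncleavable marker-only insertion at the same
locus.  ``E`` exists only in the cross-synthesis/analysis layer and never
appears on any axis of the population inheritance cube.

The inheritance cube is the mother-genotype x father-genotype x
offspring-genotype probability tensor that drives offspring sampling in the
population model.  Two processes bias it away from Mendelian expectation:

* **Germline homing** — in a ``WH`` germline the ``W`` allele is cut with
  sex-specific probability ``c``; a cut resolves by homology-directed repair
  into a second ``H`` with probability ``ch`` or into an ``R`` indel with
  probability ``cr`` (= 1 - ``ch``).
* **Maternal deposition** — Cas9 ribonucleoprotein carried over in the egg
  from an ``H``-bearing mother cleaves each zygotic ``W`` allele with
  probability ``dF``; with no repair template available the cut resolves to
  ``H`` with probability ``dhF`` (fixed to 0 here) or to ``R`` with ``drF``.
  Deposition is applied to every ``W`` allele of the zygote, including a
  maternally inherited ``W`` that escaped germline cutting (the deposited
  RNP acts in the embryo regardless of the allele's origin).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ALLELES",
    "GENOTYPES",
    "DriveParams",
    "InheritanceCube",
    "ParameterError",
    "gamete_distribution",
    "zygote_distribution",
    "build_cube",
    "mendelian_cube",
]

#: Population-cube alleles in canonical order (W < H < R).
ALLELES: tuple[str, ...] = ("W", "H", "R")

#: Blocked-drive balancer allele; valid only in cross synthesis/analysis.
BALANCER_ALLELE = "E"

_ALLELE_ORDER = {"W": 0, "H": 1, "R": 2, "E": 3}

#: Canonical unordered genotypes over {W, H, R}, in fixed cube order.
GENOTYPES: tuple[str, ...] = ("WW", "WH", "WR", "HH", "HR", "RR")

GENOTYPE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GENOTYPES)}

#: Number of H alleles per canonical genotype (cube order).
H_COPIES = np.array([g.count("H") for g in GENOTYPES])
W_COPIES = np.array([g.count("W") for g in GENOTYPES])
R_COPIES = np.array([g.count("R") for g in GENOTYPES])

#: Boolean mask of genotypes carrying at least one drive allele.
H_CARRIER = H_COPIES > 0


class ParameterError(ValueError):
    """Invalid drive parameters or genotype labels."""


def canonical_genotype(a: str, b: str) -> str:
    """Return the unordered genotype label for an allele pair."""
    if a not in _ALLELE_ORDER or b not in _ALLELE_ORDER:
        raise ParameterError(f"unknown allele in pair ({a!r}, {b!r})")
    return a + b if _ALLELE_ORDER[a] <= _ALLELE_ORDER[b] else b + a


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name}={value!r} is not a probability in [0, 1]")


@dataclass(frozen=True)
class DriveParams:
    """Cube-level rates of drive activity and fitness modifiers.

    Parameters
    ----------
    cF, cM
        Probability that a ``W`` allele in an ``H``-carrying germline is cut
        (female / male parent).
    chF, chM
        Probability that a germline cut resolves by homing (-> ``H``).
    crF, crM
        Probability that a germline cut resolves as resistance (-> ``R``);
        must satisfy ``ch + cr = 1`` per sex.
    dF
        Probability that a zygotic ``W`` allele from an ``H``-carrying mother
        is cleaved by maternally deposited Cas9-RNP.
    dhF, drF
        Resolution split for deposition cuts (``dhF + drF = 1``).  With no
        homology template in the embryo the modelled configuration is
        ``dhF = 0``, ``drF = 1``.
    fertility_mult
        Fecundity multiplier applied to ``H``-carrying genotypes
        (dimensionless; 0.9 models a 10% overall fertility reduction).
    xiF, xiM
        Per-sex pupation-success multiplier applied to ``H``-carrying
        genotypes (dimensionless; 1.0 means no cost).
    """

    cF: float = 0.0
    cM: float = 0.0
    chF: float = 1.0
    chM: float = 1.0
    crF: float = 0.0
    crM: float = 0.0
    dF: float = 0.0
    dhF: float = 0.0
    drF: float = 1.0
    fertility_mult: float = 1.0
    xiF: float = 1.0
    xiM: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cF", "cM", "chF", "chM", "crF", "crM", "dF", "dhF", "drF"):
            _check_prob(name, getattr(self, name))
        for pair, total in (
            (("chF", "crF"), self.chF + self.crF),
            (("chM", "crM"), self.chM + self.crM),
            (("dhF", "drF"), self.dhF + self.drF),
        ):
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"{pair[0]} + {pair[1]} = {total!r}; the resolution split must sum to 1"
                )
        for name in ("fertility_mult", "xiF", "xiM"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    # -- sex-indexed access -------------------------------------------------
    def cut_rates(self, sex: str) -> tuple[float, float, float]:
        """Return ``(c, ch, cr)`` for parent sex ``'F'`` or ``'M'``."""
        if sex == "F":
            return self.cF, self.chF, self.crF
        if sex == "M":
            return self.cM, self.chM, self.crM
        raise ParameterError(f"parent_sex must be 'F' or 'M', got {sex!r}")

    def fertility_multiplier(self, genotype: str) -> float:
        """Fecundity multiplier for a female of ``genotype``."""
        return self.fertility_mult if "H" in genotype else 1.0

    def pupation_multiplier(self, genotype: str, sex: str) -> float:
        """Larva-to-pupa success multiplier for ``genotype`` of ``sex``."""
        if "H" not in genotype:
            return 1.0
        if sex == "F":
            return self.xiF
        if sex == "M":
            return self.xiM
        raise ParameterError(f"sex must be 'F' or 'M', got {sex!r}")

    def evolve(self, **overrides) -> "DriveParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


def gamete_distribution(
    genotype: str, parent_sex: str, params: DriveParams
) -> dict[str, float]:
    """Allele distribution of gametes produced by a parent genotype.

    Germline cutting requires an ``H`` allele in the same genotype (Cas9 and
    the sgRNA are encoded on the construct) and acts only on ``W`` alleles,
    so the single non-Mendelian genotype is ``WH``: prior to meiosis the
    ``W`` allele is converted to ``H`` with probability ``c*ch`` (homing) or
    to ``R`` with ``c*cr`` (resistance), giving gamete probabilities

    ``P(H) = 1/2 + c*ch/2``,  ``P(W) = (1-c)/2``,  ``P(R) = c*cr/2``.

    All other genotypes segregate Mendelianly.
    """
    if genotype not in GENOTYPE_INDEX:
        raise ParameterError(f"unknown genotype {genotype!r}")
    c, ch, cr = params.cut_rates(parent_sex)
    if genotype == "WH":
        return {
            "W": 0.5 * (1.0 - c),
            "H": 0.5 + 0.5 * c * ch,
            "R": 0.5 * c * cr,
        }
    out = {a: 0.0 for a in ALLELES}
    for allele in genotype:
        out[allele] += 0.5
    return out


def _deposition_map(allele: str, params: DriveParams) -> dict[str, float]:
    """Fate of one zygotic allele under maternal Cas9-RNP deposition."""
    if allele != "W":
        return {allele: 1.0}
    d = params.dF
    return {
        "W": 1.0 - d,
        "H": d * params.dhF,
        "R": d * params.drF,
    }


def zygote_distribution(
    mother: str, father: str, params: DriveParams
) -> dict[str, float]:
    """Offspring genotype distribution for one parental pairing.

    The product of the maternal and paternal gamete distributions, followed
    by maternal deposition: if the mother carries ``H``, each ``W`` allele of
    the zygote is independently cut by deposited Cas9-RNP with probability
    ``dF`` and resolves to ``H`` (``dhF``) or ``R`` (``drF``).
    """
    gm = gamete_distribution(mother, "F", params)
    gp = gamete_distribution(father, "M", params)
    deposition = "H" in mother
    probs = {g: 0.0 for g in GENOTYPES}
    for am, pm in gm.items():
        if pm == 0.0:
            continue
        for ap, pp in gp.items():
            if pp == 0.0:
                continue
            base = pm * pp
            if deposition:
                fm = _deposition_map(am, params)
                fp = _deposition_map(ap, params)
                for a1, p1 in fm.items():
                    if p1 == 0.0:
                        continue
                    for a2, p2 in fp.items():
                        if p2 == 0.0:
                            continue
                        probs[canonical_genotype(a1, a2)] += base * p1 * p2
            else:
                probs[canonical_genotype(am, ap)] += base
    return probs


@dataclass(frozen=True)
class InheritanceCube:
    """Mother x father x offspring genotype probability tensor.

    ``probs[i, j, k]`` is the probability that a mating between a mother of
    genotype ``GENOTYPES[i]`` and a father of genotype ``GENOTYPES[j]``
    produces an offspring of genotype ``GENOTYPES[k]``.  Every parental row
    is a probability distribution (sums to 1 within 1e-12).
    """

    probs: np.ndarray
    genotypes: tuple[str, ...] = GENOTYPES

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        n = len(self.genotypes)
        if p.shape != (n, n, n):
            raise ParameterError(f"cube must be {n}x{n}x{n}, got {p.shape}")
        if (p < -1e-15).any():
            raise ParameterError("cube contains negative probabilities")
        rows = p.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-12, rtol=0.0):
            worst = float(np.abs(rows - 1.0).max())
            raise ParameterError(
                f"cube rows must sum to 1 within 1e-12 (worst deviation {worst:g})"
            )
        object.__setattr__(self, "probs", p)

    def row(self, mother: str, father: str) -> dict[str, float]:
        """Offspring distribution for one parental pairing, as a mapping."""
        i, j = GENOTYPE_INDEX[mother], GENOTYPE_INDEX[father]
        return dict(zip(self.genotypes, self.probs[i, j]))

    # -- CSV interchange ----------------------------------------------------
    def to_csv(self, path_or_buf: str | TextIO) -> None:
        """Write the cube as long-format CSV (mother,father,offspring,probability)."""
        records = [
            (m, f, o, self.probs[i, j, k])
            for i, m in enumerate(self.genotypes)
            for j, f in enumerate(self.genotypes)
            for k, o in enumerate(self.genotypes)
        ]
        df = pd.DataFrame(records, columns=["mother", "father", "offspring", "probability"])
        df.to_csv(path_or_buf, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path_or_buf: str | TextIO) -> "InheritanceCube":
        df = pd.read_csv(path_or_buf)
        required = {"mother", "father", "offspring", "probability"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"cube CSV missing columns: {sorted(missing)}")
        n = len(GENOTYPES)
        probs = np.zeros((n, n, n))
        for rec in df.itertuples(index=False):
            probs[
                GENOTYPE_INDEX[rec.mother],
                GENOTYPE_INDEX[rec.father],
                GENOTYPE_INDEX[rec.offspring],
            ] = rec.probability
        return cls(probs)


def build_cube(params: DriveParams) -> InheritanceCube:
    """Build the full homing inheritance cube for the given drive parameters."""
    n = len(GENOTYPES)
    probs = np.zeros((n, n, n))
    for i, mother in enumerate(GENOTYPES):
        for j, father in enumerate(GENOTYPES):
            dist = zygote_distribution(mother, father, params)
            for g, p in dist.items():
                probs[i, j, GENOTYPE_INDEX[g]] = p
    return InheritanceCube(probs)


def mendelian_cube() -> InheritanceCube:
    """Random-union-of-gametes cube over {W, H, R}: no cutting, no deposition."""
    return build_cube(DriveParams())
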