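"""Independent brute-force oracles used to cross-check the implementation.

The enumerator below walks the full event tree of one mating —
pre-meiotic conversion of each cleavable allele, Mendelian segregation,
and embryonic deposition on each zygotic wild-type allele — accumulating
exact probabilities.  It deliberately shares no code with the package's
cube construction.
"""

from collections import defaultdict


def enumerate_gametes(genotype: str, c: float, ch: float, cr: float) -> dict:
    """Gamete allele distribution by exhaustive event-tree enumeration."""
    has_cas9 = "H" in genotype

    def fates(allele):
        if allele == "W" and has_cas9:
            return [("W", 1.0 - c), ("H", c * ch), ("R", c * cr)]
        return [(allele, 1.0)]

    out: dict = defaultdict(float)
    a, b = genotype[0], genotype[1]
    for fa, pa in fates(a):
        for fb, pb in fates(b):
            out[fa] += 0.5 * pa * pb
            out[fb] += 0.5 * pa * pb
    return dict(out)


def enumerate_zygotes(
    mother: str,
    father: str,
    cF: float, chF: float, crF: float,
    cM: float, chM: float, crM: float,
    dF: float, dhF: float, drF: float,
) -> dict:
    """Offspring genotype distribution by exhaustive enumeration."""
    gm = enumerate_gametes(mother, cF, chF, crF)
    gp = enumerate_gametes(father, cM, chM, crM)
    deposit = "H" in mother

    def dep_fates(allele):
        if deposit and allele == "W":
            return [("W", 1.0 - dF), ("H", dF * dhF), ("R", dF * drF)]
        return [(allele, 1.0)]

    order = {"W": 0, "H": 1, "R": 2}
    out: dict = defaultdict(float)
    for am, pm in gm.items():
        for ap, pp in gp.items():
            for fm, qm in dep_fates(am):
                for fp, qp in dep_fates(ap):
                    pair = fm + fp if order[fm] <= order[fp] else fp + fm
                    out[pair] += pm * pp * qm * qp
    return dict(out)
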