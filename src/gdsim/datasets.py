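"""Bundled datasets: study count tables and documented default parameters.

The count tables are the published single-generation cross observations for
the *Aedes aegypti* homing gene-drive lines analysed by this package:

* ``load_ox1_pool_counts`` — first-outcross (OX-1) "low"/"high" drive pools
  per line and transgenic-parent sex: percent marker inheritance, number of
  offspring assessed, and the gene-drive-blocking-indel (GDBI) assay counts
  among marker-negative larvae.
* ``load_maternal_assay_counts`` — the trans-heterozygous maternal-deposition
  assay: embryos injected per replicate, surviving larvae, and the
  eCFP/mCherry genotype split.
* ``load_injection_survival`` — embryo-injection efforts used to establish
  the transgenic lines (survivor counts and percentages).

``load_fitness_defaults`` returns a *synthetic* but representative
life-parameter table (the measured values are not part of the bundled count
tables): wild-type (HWE) fecundity of 75 eggs/female/gonotrophic cycle,
larval viability 0.80, larva-to-pupa development 6 days; the Nos drive line
carries a significant 0.10 viability deficit while the Zpg line does not.
These are the documented defaults behind the simulated release scenarios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_ox1_pool_counts",
    "load_maternal_assay_counts",
    "load_injection_survival",
    "load_fitness_defaults",
    "CARB109_DEPOSITION_RATE",
    "TIMP4_DEPOSITION_RATE",
]

#: Observed maternal-deposition activity rate at the drive (Carb109) locus
#: among balancer (eCFP)-inheriting larvae, per drive line.  Used directly as
#: the deposition parameter dF when parameterizing the release simulations.
CARB109_DEPOSITION_RATE: dict[str, float] = {
    "AeaNosC109": 0.19,
    "AeaZpgC109": 0.14,
}

#: Observed activity rate at the secondary (TIMP-P4) locus targeted via
#: injected sgRNA in the same assay (context only; not a cube parameter).
TIMP4_DEPOSITION_RATE: dict[str, float] = {
    "AeaNosC109": 0.40,
    "AeaZpgC109": 0.16,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("gdsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_ox1_pool_counts() -> pd.DataFrame:
    """OX-1 pooled cross counts (one row per line / parent sex / drive pool)."""
    return _read("ox1_pool_counts.csv")


def load_maternal_assay_counts() -> pd.DataFrame:
    """Trans-heterozygous maternal-contribution assay counts (one row per replicate)."""
    return _read("maternal_assay_counts.csv")


def load_injection_survival() -> pd.DataFrame:
    """Embryo injection efforts and survivor counts per transgenic line."""
    return _read("injection_survival.csv")


def load_fitness_defaults() -> pd.DataFrame:
    """Synthetic representative life-parameter table (see module docstring)."""
    return _read("fitness_defaults_synthetic.csv")
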