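"""Experimental designs for legume genotype x rhizobium strain trials.

A trial crosses a panel of common-bean genotypes with a panel of rhizobium
strains in a randomized complete block design (RCBD), with replicate as the
blocking factor.  Each genotype additionally carries uninoculated controls:
*negative* (no N fertiliser, the N-difference baseline) and *positive*
(KNO3-fed, the yield ceiling used to normalise symbiotic performance).

Two reference layouts are provided: a wide screening in modified Leonard
jars (10 genotypes x 8 strains x 5 replicates plus 1+1 controls per
genotype, 500 units) and a confirmation experiment in sand pots on the
consistently nodulating subset (5 genotypes x 6 strains x 5 replicates plus
controls, 200 units) in which shoot %N is also measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

__all__ = [
    "TrialDesign",
    "GenotypeMeta",
    "design_unit_count",
    "kno3_nitrogen_conc",
    "KNO3_N_FRACTION",
    "POSITIVE_CONTROL",
    "NEGATIVE_CONTROL",
    "CONTROL_TREATMENTS",
    "BEAN_GENOTYPES",
    "JAR_STRAINS",
    "POT_STRAINS",
    "jar_design",
    "pot_design",
    "genotype_metadata_frame",
]

POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL = "negative_control"
CONTROL_TREATMENTS = (POSITIVE_CONTROL, NEGATIVE_CONTROL)

# standard atomic masses (IUPAC), g/mol
_MASS_N = 14.0067
_MASS_K = 39.0983
_MASS_O = 15.9994

#: Mass fraction of nitrogen in KNO3 (~0.13854).
KNO3_N_FRACTION = _MASS_N / (_MASS_K + _MASS_N + 3.0 * _MASS_O)


def kno3_nitrogen_conc(kno3_g_per_l: float) -> float:
    """Nitrogen concentration (g N / L) of a KNO3 solution.

    A 0.5 g/L KNO3 solution carries 0.06927 g N/L.

    Parameters
    ----------
    kno3_g_per_l : float
        KNO3 concentration in grams per litre; must be non-negative.
    """
    if kno3_g_per_l < 0:
        raise ValueError(f"KNO3 concentration must be >= 0, got {kno3_g_per_l}")
    return kno3_g_per_l * KNO3_N_FRACTION


@dataclass(frozen=True)
class TrialDesign:
    """Factor levels and control scheme of a factorial inoculation trial.

    ``controls_per_genotype`` is the (positive, negative) number of control
    treatments attached to every genotype; each control treatment is
    replicated like any strain treatment, so the total unit count is
    ``(n_genotypes * n_strains + n_genotypes * (pos + neg)) * replicates``.
    """

    experiment: str
    genotypes: tuple[str, ...]
    strains: tuple[str, ...]
    replicates: int
    controls_per_genotype: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "strains", tuple(self.strains))
        object.__setattr__(
            self, "controls_per_genotype", tuple(self.controls_per_genotype)
        )
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be unique")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain labels must be unique")
        if set(self.genotypes) & set(self.strains):
            raise ValueError("genotype and strain labels must not overlap")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        pos, neg = self.controls_per_genotype
        if pos < 0 or neg < 0:
            raise ValueError("control counts must be >= 0")
        if pos > 1 or neg > 1:
            # one treatment label per control type; more would collide
            raise ValueError("at most one positive and one negative control supported")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def treatments(self) -> tuple[str, ...]:
        """All treatment labels: strains then any controls."""
        pos, neg = self.controls_per_genotype
        extra: tuple[str, ...] = ()
        if pos:
            extra += (POSITIVE_CONTROL,)
        if neg:
            extra += (NEGATIVE_CONTROL,)
        return self.strains + extra

    @property
    def n_units(self) -> int:
        return design_unit_count(self)

    def iter_units(self) -> Iterator[tuple[str, str, int]]:
        """Yield (genotype, treatment, replicate) for every experimental unit."""
        for genotype in self.genotypes:
            for treatment in self.treatments:
                for rep in range(1, self.replicates + 1):
                    yield genotype, treatment, rep


def design_unit_count(design: TrialDesign) -> int:
    """Closed-form number of experimental units in a trial design.

    The jar layout (10 genotypes, 8 strains, 5 replicates, 1+1 controls per
    genotype) gives 500 units; the pot layout (5 genotypes, 6 strains, 5
    replicates, 1+1 controls) gives 200.
    """
    g = design.n_genotypes
    s = design.n_strains
    pos, neg = design.controls_per_genotype
    return (g * s + g * (pos + neg)) * design.replicates


GENEPOOLS = frozenset({"Andean", "Meso"})
GROWTH_HABITS = frozenset({"B", "IB", "IP", "C"})


@dataclass(frozen=True)
class GenotypeMeta:
    """Passport data for one bean genotype.

    growth_habit codes: B determinate bush, IB indeterminate bush,
    IP indeterminate prostrate, C indeterminate climbing.
    """

    genotype: str
    genepool: str
    growth_habit: str
    origin: str
    seed_weight_100: float

    def __post_init__(self) -> None:
        if self.genepool not in GENEPOOLS:
            raise ValueError(f"unknown genepool {self.genepool!r}")
        if self.growth_habit not in GROWTH_HABITS:
            raise ValueError(f"unknown growth habit {self.growth_habit!r}")
        if self.seed_weight_100 <= 0:
            raise ValueError("seed_weight_100 must be positive")


#: The ten-genotype bean panel: accession, genepool, habit, origin, 100-seed weight (g).
BEAN_GENOTYPES: tuple[GenotypeMeta, ...] = (
    GenotypeMeta("G764", "Andean", "C", "Ethiopia", 47.8),
    GenotypeMeta("G1372", "Andean", "B", "Kenya", 34.6),
    GenotypeMeta("G11481", "Andean", "B", "Ethiopia", 44.3),
    GenotypeMeta("G20528", "Andean", "B", "Kenya", 61.7),
    GenotypeMeta("G20544", "Andean", "B", "Kenya", 53.1),
    GenotypeMeta("G2889A", "Meso", "IB", "Kenya", 19.0),
    GenotypeMeta("G20141", "Meso", "IP", "Ethiopia", 21.6),
    GenotypeMeta("G20142", "Meso", "IP", "Ethiopia", 23.9),
    GenotypeMeta("G24484", "Meso", "C", "Kenya", 28.0),
    GenotypeMeta("G50545", "Meso", "IP", "Kenya", 26.3),
)

#: Eight-strain rhizobium panel used in the jar screening.
JAR_STRAINS: tuple[str, ...] = (
    "CFN42",
    "CIAT899",
    "ATCC14482",
    "NAE136",
    "NAE182",
    "LMG6133",
    "LMG23946",
    "NAK91",
)

#: Consistently nodulating subset carried forward to pots.
POT_STRAINS: tuple[str, ...] = (
    "CFN42",
    "CIAT899",
    "ATCC14482",
    "NAE136",
    "NAE182",
    "NAK91",
)

#: Genotype subset carried forward to pots.
POT_GENOTYPES: tuple[str, ...] = ("G1372", "G20544", "G20141", "G20142", "G24484")


def jar_design(replicates: int = 5) -> TrialDesign:
    """The Leonard-jar screening layout: 10 genotypes x 8 strains, 1+1 controls."""
    return TrialDesign(
        experiment="jar",
        genotypes=tuple(m.genotype for m in BEAN_GENOTYPES),
        strains=JAR_STRAINS,
        replicates=replicates,
        controls_per_genotype=(1, 1),
    )


def pot_design(replicates: int = 5) -> TrialDesign:
    """The pot confirmation layout: 5 genotypes x 6 strains, 1+1 controls."""
    return TrialDesign(
        experiment="pot",
        genotypes=POT_GENOTYPES,
        strains=POT_STRAINS,
        replicates=replicates,
        controls_per_genotype=(1, 1),
    )


def genotype_metadata_frame(meta: tuple[GenotypeMeta, ...] = BEAN_GENOTYPES) -> pd.DataFrame:
    """Genotype passport data as a DataFrame keyed by genotype."""
    return pd.DataFrame(
        [
            {
                "genotype": m.genotype,
                "genepool": m.genepool,
                "growth_habit": m.growth_habit,
                "origin": m.origin,
                "seed_weight_100": m.seed_weight_100,
            }
            for m in meta
        ]
    )
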