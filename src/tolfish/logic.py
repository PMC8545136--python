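"""Discrete regulatory logic of the TOL (pWW0) xyl operons.

The TOL plasmid of *Pseudomonas putida* mt-2 carries two catabolic operons:
the upper pathway (*xylUW*...) transcribed from the sigma-54 dependent *Pu*
promoter, and the lower pathway (*xylX*...) transcribed from *Pm*.  XylR,
activated by upper-pathway effectors (m-xylene, toluene, and the gratuitous
inducer o-xylene), turns on *Pu* and also overexpresses XylS, which then
activates *Pm* even without a lower-pathway effector.  Lower-pathway
substrates (benzoate, 3-methylbenzoate) activate XylS directly, inducing
*Pm* only.

Two engineered variants are modeled alongside the wild type:

* a strain with both operons and their regulators relocated to the
  chromosome (induction logic unchanged, higher transcriptional activity);
* a plasmid in which *Pu* is replaced by the T7 promoter, so *xylUW* is
  transcribed only by T7 RNA polymerase supplied from a chromosomal
  lacIq/Plac-T7pol cassette (IPTG-inducible, slightly leaky).

Rifampin blocks the host RNA polymerase but not T7 RNAP, and in addition
abolishes the focal (punctate) appearance of the mRNA signal: transcripts
disperse through the cytoplasm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Genotype(enum.Enum):
    """Host/replicon configuration of the xyl operons."""

    WT_PWW0 = "WT_pWW0"
    PAW140_CHROMOSOMAL = "PAW140_CHROMOSOMAL"
    PUXT7_IN_MT2 = "PUXT7_IN_MT2"
    PUXT7_IN_T7_HOST = "PUXT7_IN_T7_HOST"


class Inducer(enum.Enum):
    NONE = "NONE"
    M_XYLENE = "M_XYLENE"
    TOLUENE = "TOLUENE"
    O_XYLENE = "O_XYLENE"
    BENZOATE = "BENZOATE"
    MBZ3 = "MBZ3"  # 3-methylbenzoate


class Level(enum.Enum):
    OFF = 0
    LOW = 1
    HIGH = 2

    def __lt__(self, other: "Level") -> bool:
        return self.value < other.value

    def __le__(self, other: "Level") -> bool:
        return self.value <= other.value


#: Effectors of XylR (upper-pathway regulator).  o-Xylene is gratuitous: it
#: activates XylR (and hence XylS overexpression) without being metabolized.
UPPER_EFFECTORS = frozenset({Inducer.M_XYLENE, Inducer.TOLUENE, Inducer.O_XYLENE})
#: Effectors of XylS (lower-pathway regulator).
LOWER_EFFECTORS = frozenset({Inducer.BENZOATE, Inducer.MBZ3})

TRANSCRIPTS = ("xylUW", "xylX")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: strain genotype plus chemical treatment.

    ``iptg`` is only meaningful for :attr:`Genotype.PUXT7_IN_T7_HOST` (the
    only genotype expressing T7 RNAP); it is ignored otherwise.
    """

    genotype: Genotype = Genotype.WT_PWW0
    inducer: Inducer = Inducer.NONE
    iptg: bool = False
    rifampin: bool = False

    def label(self) -> str:
        parts = [self.genotype.value, self.inducer.value]
        if self.iptg:
            parts.append("IPTG")
        if self.rifampin:
            parts.append("RIF")
        return "+".join(parts)

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype.value,
            "inducer": self.inducer.value,
            "iptg": self.iptg,
            "rifampin": self.rifampin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        return cls(
            genotype=Genotype(d.get("genotype", "WT_pWW0")),
            inducer=Inducer(d.get("inducer", "NONE")),
            iptg=bool(d.get("iptg", False)),
            rifampin=bool(d.get("rifampin", False)),
        )


@dataclass(frozen=True)
class ExpressionState:
    """Qualitative expression level per transcript, plus signal morphology.

    ``focal=False`` (possible only under rifampin) means the red channel
    renders as a dispersed, non-punctate signal.
    """

    levels: dict = field(default_factory=dict)  # transcript -> Level
    focal: bool = True

    def __post_init__(self):
        for t in TRANSCRIPTS:
            if t not in self.levels:
                raise ValueError(f"missing level for transcript {t!r}")

    @property
    def xylUW(self) -> Level:
        return self.levels["xylUW"]

    @property
    def xylX(self) -> Level:
        return self.levels["xylX"]


def expressed_transcripts(cond: Condition) -> ExpressionState:
    """Resolve a condition to the expression state of xylUW and xylX.

    Total and deterministic over every combination of genotype, inducer,
    IPTG and rifampin.  Rifampin silences everything transcribed by the
    host RNA polymerase (always xylX; xylUW except when driven by the
    rifampin-insensitive T7 RNAP) and renders any remaining signal
    dispersed rather than focal.
    """
    upper = cond.inducer in UPPER_EFFECTORS
    lower = cond.inducer in LOWER_EFFECTORS

    xyluw = Level.OFF
    xylx = Level.OFF

    if cond.genotype in (Genotype.WT_PWW0, Genotype.PAW140_CHROMOSOMAL):
        if upper:
            # XylR cascade: Pu on, XylS overexpressed -> Pm on.
            xyluw = Level.HIGH
            xylx = Level.HIGH
        if lower:
            xylx = Level.HIGH
    elif cond.genotype == Genotype.PUXT7_IN_MT2:
        # Pu replaced by PT7 and no T7 RNAP in the host: xylUW never made.
        # XylR is still intact, so an upper effector overexpresses XylS,
        # which suffices to fire Pm without any lower effector.
        if upper or lower:
            xylx = Level.HIGH
    elif cond.genotype == Genotype.PUXT7_IN_T7_HOST:
        if cond.iptg:
            # Strong PT7 drive of the upper operon; the boosted XylS supply
            # propagates into full Pm activity with no aromatic effector.
            xyluw = Level.HIGH
            xylx = Level.HIGH
        else:
            # Leaky Plac-T7pol: faint xylUW signal without IPTG.
            xyluw = Level.LOW
        if upper or lower:
            xylx = Level.HIGH

    focal = True
    if cond.rifampin:
        xylx = Level.OFF  # host RNAP product, always silenced
        if cond.genotype != Genotype.PUXT7_IN_T7_HOST:
            xyluw = Level.OFF
        focal = False

    return ExpressionState(levels={"xylUW": xyluw, "xylX": xylx}, focal=focal)


def all_conditions():
    """Every combination of the condition space (4 x 6 x 2 x 2 = 96)."""
    for g in Genotype:
        for i in Inducer:
            for iptg in (False, True):
                for rif in (False, True):
                    yield Condition(g, i, iptg, rif)
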