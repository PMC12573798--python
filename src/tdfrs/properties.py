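"""Sequence- and buffer-level property calculations.

Covers the auxiliary quantities the thermodiffusion analysis consumes:
molecular weight and 280 nm extinction coefficients (molar and E_1%),
mass/molar concentration conversion, Henderson-Hasselbalch net charge and
isoelectric point with a configurable pKa table, acid/base speciation of
buffer components, and the mole-fraction-weighted immobilized-water
(hydration) index used to compare buffer hydrophilicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "ProteinSequence",
    "PkaSet",
    "DEFAULT_PKA_SET",
    "BufferComponent",
    "BufferSpec",
    "read_fasta",
    "apomyoglobin_sequence",
    "molecular_weight",
    "extinction_280",
    "mass_to_molar",
    "net_charge",
    "isoelectric_point",
    "speciation",
    "hydration_index",
    "nap_buffer",
    "naac_buffer",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Pace/ExPASy molar absorptivities at 280 nm, M^-1 cm^-1
_EPS_TRP = 5500.0
_EPS_TYR = 1490.0
_EPS_CYSTINE = 125.0

# Thermodynamic pKa values of the second phosphate and acetate dissociations
PHOSPHATE_PKA2 = 7.21
ACETATE_PKA = 4.76


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence restricted to the 20 standard one-letter codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if len(residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(residues) - set(STANDARD_AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def count(self, letter: str) -> int:
        return self.residues.count(letter)

    def __len__(self) -> int:
        return len(self.residues)


def _residues(seq: Union[ProteinSequence, str]) -> str:
    if isinstance(seq, ProteinSequence):
        return seq.residues
    return ProteinSequence(id="", residues=str(seq)).residues


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values (pH units, each in (0, 14)).

    Defaults are the Bjellqvist/ExPASy values, consistent with
    sequence-derived quantities computed by the ExPASy tools.  Any entry can
    be overridden; charge and isoelectric point depend materially on this
    choice.
    """

    asp: float = 4.05
    glu: float = 4.45
    his: float = 5.98
    cys: float = 9.0
    tyr: float = 10.0
    lys: float = 10.0
    arg: float = 12.0
    n_term: float = 7.5
    c_term: float = 3.55

    def __post_init__(self) -> None:
        for name in ("asp", "glu", "his", "cys", "tyr", "lys", "arg", "n_term", "c_term"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 < v < 14.0):
                raise ValueError(f"pKa {name}={v!r} must lie in (0, 14)")

    @property
    def acidic(self) -> dict:
        return {"D": self.asp, "E": self.glu, "C": self.cys, "Y": self.tyr}

    @property
    def basic(self) -> dict:
        return {"H": self.his, "K": self.lys, "R": self.arg}


DEFAULT_PKA_SET = PkaSet()


def read_fasta(path) -> List[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def apomyoglobin_sequence() -> ProteinSequence:
    """Mature horse apomyoglobin sequence (UniProt P68082, 153 residues)."""
    with resources.as_file(
        resources.files("tdfrs.data").joinpath("P68082_apomyoglobin.fasta")
    ) as p:
        return read_fasta(p)[0]


def molecular_weight(seq: Union[ProteinSequence, str]) -> float:
    """Average (not monoisotopic) molecular weight in Da.

    Sum of average residue masses minus one water per peptide bond; a single
    residue gives the free amino acid mass.
    """
    return float(ProteinAnalysis(_residues(seq)).molecular_weight())


def extinction_280(
    seq: Union[ProteinSequence, str], n_cystine: int = 0
) -> Tuple[float, float]:
    """Molar extinction coefficient at 280 nm and E_1%.

    ``epsilon = 5500 n_Trp + 1490 n_Tyr + 125 n_cystine`` (M^-1 cm^-1), all
    cysteines reduced by default; ``E_1% = 10 epsilon / MW`` is the
    absorbance of a 1 g/100 mL solution in a 1 cm cell.
    """
    r = _residues(seq)
    if n_cystine < 0 or 2 * n_cystine > r.count("C"):
        raise ValueError("n_cystine must be >= 0 and use at most all cysteines")
    eps = _EPS_TRP * r.count("W") + _EPS_TYR * r.count("Y") + _EPS_CYSTINE * n_cystine
    e1pct = 10.0 * eps / molecular_weight(r)
    return eps, e1pct


def mass_to_molar(conc_mg_per_ml: float, mw_da: float) -> float:
    """Convert mg/mL to mM given the molecular weight in Da."""
    if mw_da <= 0:
        raise ValueError("molecular weight must be > 0")
    if conc_mg_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return conc_mg_per_ml / mw_da * 1000.0


def net_charge(
    seq: Union[ProteinSequence, str],
    ph: float,
    pka_set: PkaSet = DEFAULT_PKA_SET,
) -> float:
    """Henderson-Hasselbalch net charge in elementary charges.

    Positive contributions from His/Lys/Arg and the N-terminus,
    ``1/(1 + 10^(pH - pKa))`` each; negative from Asp/Glu/Cys/Tyr and the
    C-terminus, ``-1/(1 + 10^(pKa - pH))`` each.
    """
    r = _residues(seq)
    if not math.isfinite(ph):
        raise ValueError("pH must be finite")
    pos = sum(r.count(aa) / (1.0 + 10.0 ** (ph - pka)) for aa, pka in pka_set.basic.items())
    pos += 1.0 / (1.0 + 10.0 ** (ph - pka_set.n_term))
    neg = sum(r.count(aa) / (1.0 + 10.0 ** (pka - ph)) for aa, pka in pka_set.acidic.items())
    neg += 1.0 / (1.0 + 10.0 ** (pka_set.c_term - ph))
    return pos - neg


def isoelectric_point(
    seq: Union[ProteinSequence, str], pka_set: PkaSet = DEFAULT_PKA_SET
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    r = _residues(seq)
    f = lambda ph: net_charge(r, ph, pka_set)
    if f(0.0) * f(14.0) > 0:
        raise ValueError("net charge does not change sign on [0, 14]: no pI")
    return float(brentq(f, 0.0, 14.0, xtol=1e-8))


def speciation(ph: float, pka: float) -> Tuple[float, float]:
    """Acid/base mole fractions of a monoprotic equilibrium at given pH.

    Returns ``(fraction_acid, fraction_base)``; the fractions sum to one
    exactly.
    """
    f_acid = 1.0 / (1.0 + 10.0 ** (ph - pka))
    return f_acid, 1.0 - f_acid


@dataclass(frozen=True)
class BufferComponent:
    """One buffer species with its immobilized-water count."""

    name: str
    mole_fraction: float
    n_immobilized: float
    pka: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mole_fraction <= 1.0:
            raise ValueError("mole_fraction must be in [0, 1]")
        if self.n_immobilized < 0:
            raise ValueError("n_immobilized must be >= 0")


@dataclass(frozen=True)
class BufferSpec:
    """A buffer as a set of components with mole fractions summing to one."""

    label: str
    components: Tuple[BufferComponent, ...]
    total_conc_mm: float
    ph: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        total = sum(c.mole_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component mole fractions sum to {total}, not 1")
        if self.total_conc_mm < 0:
            raise ValueError("total_conc_mm must be >= 0")


def hydration_index(spec: BufferSpec) -> float:
    """Mole-fraction-weighted mean immobilized-water count of a buffer.

    A larger index indicates a more strongly hydrated (kosmotropic, more
    hydrophilic) buffer.
    """
    return sum(c.mole_fraction * c.n_immobilized for c in spec.components)


def nap_buffer(total_conc_mm: float = 20.0, ph: float = 6.0) -> BufferSpec:
    """Sodium phosphate buffer with the conventional speciation at pH 6.

    Mole fractions 0.9 NaH2PO4 / 0.1 Na2HPO4 (the exact Henderson-Hasselbalch
    fraction at pH 6 with pKa2 = 7.21 is 0.94; see :func:`speciation`);
    immobilized-water counts 4 and 11 from dielectric spectroscopy.
    """
    return BufferSpec(
        label="NaP",
        components=(
            BufferComponent("NaH2PO4", 0.9, 4.0, pka=PHOSPHATE_PKA2),
            BufferComponent("Na2HPO4", 0.1, 11.0, pka=PHOSPHATE_PKA2),
        ),
        total_conc_mm=total_conc_mm,
        ph=ph,
    )


def naac_buffer(total_conc_mm: float = 20.0, ph: float = 4.0) -> BufferSpec:
    """Sodium acetate buffer at pH 4.

    Mole fractions 0.8 acetic acid / 0.2 sodium acetate with immobilized
    -water counts 1 and 5, giving a hydration index of 1.8.
    """
    return BufferSpec(
        label="NaAc",
        components=(
            BufferComponent("acetic acid", 0.8, 1.0, pka=ACETATE_PKA),
            BufferComponent("sodium acetate", 0.2, 5.0, pka=ACETATE_PKA),
        ),
        total_conc_mm=total_conc_mm,
        ph=ph,
    )
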