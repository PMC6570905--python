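"""Kinetic parameters of the inducer-coupled self-repressor network.

Reaction scheme (all rates per minute; counts are molecules in one cell):

operator binding/unbinding (TetR dimer, two operator sites, n = free TetR)::

    A11 + 2 TetR --(1/2 h n(n-1))--> A10        A10 + TetR --(f n)--> A11 + 3 TetR
    A11 + 2 TetR --(1/2 h n(n-1))--> A01        A01 + TetR --(f n)--> A11 + 3 TetR
    A10 + 2 TetR --(1/2 h n(n-1))--> A00        A00 + TetR --(f n)--> A10 + 3 TetR
    A01 + 2 TetR --(1/2 h n(n-1))--> A00        A00 + TetR --(f n)--> A01 + 3 TetR

A11 is the fully free ("on") operator pair, A00 fully occupied ("off").
Unbinding is competitor-assisted: a free TetR monomer catalyses release of the
bound dimer (net +2 free TetR), hence the linear dependence f·n.  The
``constant`` unbinding variant replaces f·n by the fixed value f·n_ref.

synthesis/degradation (transcription+translation lumped)::

    0 --(g_ij)--> TetR  for gene state A^ij,     TetR --(k1)--> 0

inducer (aTc) sequestration and membrane transport::

    TetR + I_aTc --(b n n_i)--> Ta    Ta --(a)--> TetR + I_aTc    Ta --(k2)--> 0
    0 --(c E_aTc)--> I_aTc            I_aTc --(c)--> 0

E_aTc is the constant external inducer reservoir.  Two derived dimensionless
groups: omega = f/k1, the adiabaticity parameter (operator unbinding speed
relative to protein turnover), and Xeq = f/h, the unbinding/binding equilibrium
ratio (inverse operator affinity).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

ATC_MOLAR_MASS_G_PER_MOL = 462.9
AVOGADRO = 6.02214076e23
DEFAULT_CELL_VOLUME_FL = 1.0


def atc_ng_per_ml_to_molecules(ng_per_ml: float, volume_fl: float = DEFAULT_CELL_VOLUME_FL) -> float:
    """Convert an aTc mass concentration to molecule numbers in a reaction volume.

    1 ng/mL = 1 ug/L; at 462.9 g/mol and a 1 fL (E. coli scale) volume this is
    ~1.30 molecules per ng/mL.
    """
    mol_per_l = ng_per_ml * 1e-6 / ATC_MOLAR_MASS_G_PER_MOL
    return mol_per_l * AVOGADRO * volume_fl * 1e-15


def atc_molecules_to_ng_per_ml(molecules: float, volume_fl: float = DEFAULT_CELL_VOLUME_FL) -> float:
    return molecules / (AVOGADRO * volume_fl * 1e-15) * ATC_MOLAR_MASS_G_PER_MOL * 1e6


@dataclass(frozen=True)
class RateParameters:
    """All kinetic constants of the reaction scheme.

    Defaults are calibration values (the source tables are not reproduced
    here): they put the circuit in the non-adiabatic regime at zero inducer
    (omega = f/k1 ~ 0.67), give an on-state mean expression of a few hundred
    molecules, and traverse unimodal-low -> unimodal-high -> bimodal as the
    external inducer rises over ~300-1500 ng/mL.
    """

    h: float = 3.0e-4      # operator binding, /molecule^2/min
    f: float = 1.0e-2      # operator unbinding, /molecule/min
    g11: float = 6.0       # synthesis when fully on, molecules/min
    g10: float = 0.03      # synthesis with one operator bound
    g01: float = 0.03
    g00: float = 0.03      # synthesis when fully off (leak)
    k1: float = 0.015      # TetR degradation + dilution, /min (46-min doubling)
    b: float = 1.2e-4      # TetR-aTc association, /molecule/min
    a: float = 0.01        # Ta complex dissociation, /min
    k2: float = 0.015      # Ta complex degradation, /min
    c: float = 0.1         # aTc membrane diffusion, /min
    E_aTc: float = 0.0     # external aTc reservoir, molecules (held constant)
    unbinding_mode: str = "concentration_dependent"  # or "constant"
    n_ref: float = 0.5     # reference free-TetR scale for the constant variant

    def __post_init__(self) -> None:
        for name in ("h", "f", "g11", "g10", "g01", "g00", "k1", "b", "a", "k2", "c", "E_aTc", "n_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be non-negative, got {getattr(self, name)}")
        if not (self.g11 >= self.g10 == self.g01 >= self.g00):
            raise ValueError(
                "synthesis rates must satisfy g11 >= g10 == g01 >= g00 "
                f"(got g11={self.g11}, g10={self.g10}, g01={self.g01}, g00={self.g00})"
            )
        if self.unbinding_mode not in ("concentration_dependent", "constant"):
            raise ValueError(f"unknown unbinding_mode {self.unbinding_mode!r}")

    @property
    def omega(self) -> float:
        """Adiabaticity parameter f/k1 (unbinding vs protein turnover)."""
        return self.f / self.k1

    @property
    def xeq(self) -> float:
        """Equilibrium constant f/h (inverse operator affinity), molecules."""
        return self.f / self.h

    def with_inducer(self, E_aTc: float) -> "RateParameters":
        return dataclasses.replace(self, E_aTc=E_aTc)

    def with_inducer_ng_per_ml(self, ng_per_ml: float, volume_fl: float = DEFAULT_CELL_VOLUME_FL) -> "RateParameters":
        return self.with_inducer(atc_ng_per_ml_to_molecules(ng_per_ml, volume_fl))

    def replace(self, **kwargs) -> "RateParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
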