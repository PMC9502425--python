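"""Material property container and published reference parameter sets.

The three bundled polymers are excipients commonly used for amorphous solid
dispersions: a polyvinylpyrrolidone-vinyl acetate copolymer (PVPVA, Plasdone
S-630), the polyvinyl caprolactam-polyvinyl acetate-PEG graft copolymer
Soluplus (SOL), and a basic butylated methacrylate copolymer (bBMA, Eudragit
EPO). Their Carreau-Arrhenius parameters are literature flow curves refitted
at a common reference temperature of 473 K; densities are pycnometer /
untapped bulk values.

The bundled geometry describes a Leistritz ZSE 27 MAXX corotating twin-screw
extruder with a cylindrical 3 mm x 11.7 mm die. Two of its numbers are not
published with the rest of the setup and are package assumptions documented
in docs/methods.md: the feeding-section pitch (0.06 m, a standard 60 mm
conveying element) and the nominal screw speed (1200 rpm).
"""

from __future__ import annotations

from dataclasses import dataclass

from .feeding import ExtruderGeometry, PowderState
from .rheology import CarreauArrheniusParams
from .units import rpm_to_per_s


@dataclass(frozen=True)
class MaterialProperties:
    """Densities plus melt rheology for one polymer."""

    name: str
    rho_bulk: float  # kg/m^3, untapped bulk density of the powder
    rho_true: float  # kg/m^3, helium-pycnometer true density
    rheology: CarreauArrheniusParams

    def powder(self, slip: float = 0.0) -> PowderState:
        """Powder state of this material at a given conveying slip."""
        return PowderState(rho_bulk=self.rho_bulk, rho_true=self.rho_true,
                           slip=slip)


PVPVA = MaterialProperties(
    name="PVPVA",
    rho_bulk=315.0,
    rho_true=1190.0,
    rheology=CarreauArrheniusParams(
        eta0=169.7, gammadot_c=133.1, c=0.387, Ea=198292.0, T_ref=473.0),
)

SOL = MaterialProperties(
    name="SOL",
    rho_bulk=597.0,
    rho_true=1080.0,
    rheology=CarreauArrheniusParams(
        eta0=147.3, gammadot_c=136.7, c=0.411, Ea=150773.0, T_ref=473.0),
)

BBMA = MaterialProperties(
    name="bBMA",
    rho_bulk=339.0,
    rho_true=1092.0,
    rheology=CarreauArrheniusParams(
        eta0=25.58, gammadot_c=1688.0, c=0.561, Ea=140336.0, T_ref=473.0),
)

REFERENCE_MATERIALS = {m.name: m for m in (PVPVA, SOL, BBMA)}

#: Conveying slips of the reference powders on the ZSE 27 setup, determined
#: from filled-barrel (SFL* = 1) operating points.
REFERENCE_SLIPS = {"PVPVA": 0.865, "SOL": 0.858, "bBMA": 0.850}


def zse27_geometry(l_pitch: float = 0.06,
                   n_max_rpm: float = 1200.0) -> ExtruderGeometry:
    """Leistritz ZSE 27 MAXX geometry with a 3 mm x 11.7 mm die.

    ``l_pitch`` and ``n_max_rpm`` default to the package's documented
    assumptions and can be overridden when the actual screw configuration is
    known.
    """
    return ExtruderGeometry(
        d=0.0283,
        A_free=4.91e-4,
        l_pitch=l_pitch,
        r_die=0.0015,
        l_die=0.0117,
        n_max=rpm_to_per_s(n_max_rpm),
    )
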