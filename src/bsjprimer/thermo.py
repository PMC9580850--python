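"""Primer thermodynamics: GC content and nearest-neighbor melting temperature.

Tm uses the SantaLucia unified nearest-neighbor parameter set
(dH kcal/mol, dS cal/mol/K per dinucleotide stack, terminal initiation
terms) with a divalent-to-monovalent equivalence salt correction:

    [Na+]eq (mM) = monovalent + 120 * sqrt(max(divalent - dNTP, 0))
    dS_salt      = dS + 0.368 * (N - 1) * ln([Na+]eq in M)
    Tm (K)       = 1000 * dH / (dS_salt + R * ln(CT / 4))

at a fixed total primer concentration CT = 250 nM (CT/4 for the
non-self-complementary excess-primer case; the self-complementary case
adds the symmetry entropy and uses CT/1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seq import revcomp, validate_bases

__all__ = ["ThermoSettings", "gc_content", "melting_temperature"]

R_GAS = 1.98722  # cal / (mol K)
PRIMER_CONC_NM = 250.0

# SantaLucia unified NN parameters: dH kcal/mol, dS cal/(mol K)
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal initiation terms per end
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
SYMMETRY_DS = -1.4


@dataclass(frozen=True)
class ThermoSettings:
    """Primer-design windows and ion conditions.

    Defaults are the optimized qPCR design set: primer length 16-20-30
    (min-opt-max), Tm 58-59-60 C with at most 2 C difference inside a
    pair, GC 30-50-80 %, 50 mM monovalent / 3 mM divalent cations,
    0.6 mM dNTP, amplicon 50-250 nt, 20 returned candidates, homopolymer
    runs capped at 4.
    """

    primer_len: tuple[int, int, int] = (16, 20, 30)
    primer_tm: tuple[float, float, float] = (58.0, 59.0, 60.0)
    max_tm_diff: float = 2.0
    primer_gc: tuple[float, float, float] = (30.0, 50.0, 80.0)
    monovalent: float = 50.0  # mM
    divalent: float = 3.0  # mM
    dntp: float = 0.6  # mM
    amplicon_len: tuple[int, int] = (50, 250)
    n_candidates: int = 20
    max_poly_x: int = 4
    junction_overlap: int = 0

    def __post_init__(self):
        for name in ("primer_len", "primer_tm", "primer_gc"):
            lo, opt, hi = getattr(self, name)
            if not lo <= opt <= hi:
                raise ValueError(f"{name}: need min <= opt <= max, got {lo}-{opt}-{hi}")
        if self.amplicon_len[0] > self.amplicon_len[1]:
            raise ValueError("amplicon_len: min > max")


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous DNA sequence."""
    if not seq:
        raise ValueError("empty sequence")
    validate_bases(seq, allow_n=False)
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def melting_temperature(
    seq: str,
    monovalent: float = 50.0,
    divalent: float = 3.0,
    dntp: float = 0.6,
    primer_conc_nm: float = PRIMER_CONC_NM,
) -> float:
    """Nearest-neighbor duplex melting temperature, in Celsius.

    Ion concentrations are in mM, primer concentration (total strand
    concentration CT) in nM.  Requires length >= 8 and bases in ACGT.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short for a nearest-neighbor Tm (< 8 nt)")
    validate_bases(seq, allow_n=False)
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += SYMMETRY_DS
    na_eq_mm = monovalent + 120.0 * math.sqrt(max(divalent - dntp, 0.0))
    if na_eq_mm <= 0:
        raise ValueError("non-positive effective monovalent concentration")
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na_eq_mm / 1000.0)
    ct = primer_conc_nm * 1e-9
    x = 1.0 if selfcomp else 4.0
    tm_k = 1000.0 * dh / (ds_salt + R_GAS * math.log(ct / x))
    return tm_k - 273.15
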