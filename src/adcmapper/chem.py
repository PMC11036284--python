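"""Monoisotopic mass arithmetic shared across the package.

All masses are monoisotopic daltons unless stated otherwise.  The DM1-MCC
payload of lysine-linked ADCs such as trastuzumab-emtansine is modelled as a
rigid +956.364 Da delta on a lysine side chain (or a chain N-terminus); its
elemental composition is kept alongside so isotope-aware helpers can account
for the chlorine and sulfur it carries.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565
HYDROGEN = 1.007825
# Mean spacing between adjacent isotopologue peaks of a peptide-like molecule.
NEUTRON_SPACING = 1.00286

#: Mass added to a lysine (or chain N-terminus) by the MCC-linked DM1 payload.
PAYLOAD_MASS = 956.364
#: Elemental composition of the DM1-MCC addition (monoisotopic 956.364 Da).
PAYLOAD_COMPOSITION = {"C": 47, "H": 61, "Cl": 1, "N": 4, "O": 13, "S": 1}

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses for the 20 canonical amino acids.
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_AA}


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a non-canonical residue."""


def residue_masses(sequence: str):
    """Return the per-residue monoisotopic masses of ``sequence`` as a list."""
    try:
        return [RESIDUE_MASS[aa] for aa in sequence]
    except KeyError as exc:
        raise UnknownResidueError(
            f"unknown amino-acid residue {exc.args[0]!r} in sequence"
        ) from None


def peptide_mass(sequence: str, payload_count: int = 0,
                 payload_mass: float = PAYLOAD_MASS) -> float:
    """Neutral monoisotopic mass of a peptide carrying ``payload_count`` payloads.

    The peptide is assumed to have free termini (one water over the residue
    sum); each payload adds a rigid ``payload_mass`` delta.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return sum(residue_masses(sequence)) + WATER + payload_count * payload_mass


def mz_from_neutral(neutral: float, charge: int) -> float:
    """m/z of a neutral mass observed at ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error of ``observed`` vs ``theoretical`` in ppm."""
    return (observed - theoretical) / theoretical * 1e6
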