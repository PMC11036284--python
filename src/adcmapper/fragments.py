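"""Theoretical fragment-ion generation for HCD, EThcD and UVPD.

Ion-type mass conventions (relative to the residue-mass sum of the fragment):

* N-terminal, sum ``S_n``: ``b = S_n``; ``a = S_n - CO``; ``a+1 = a + H``;
  ``c = S_n + NH3``.
* C-terminal, sum ``S_c``: ``y = S_c + H2O``; ``y-1 = y - H``;
  ``z = y - NH2`` (the z-radical ETD engines match by default; the
  even-electron convention ``z = y - NH3`` is available via ``z_radical=False``);
  ``x = y + (CO - H2)``; ``x+1 = x + H``.

UVPD searches use the nine-ion-type set (a, a+1, b, c, x, x+1, y, y-1, z);
EThcD uses b/y/c/z and HCD b/y.  Payloads are all-or-nothing: a fragment
carries the whole +956.364 Da payload for every conjugation site inside the
residue range it covers, and partial-payload masses are never generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import HYDROGEN, WATER, residue_masses
from .sequence import N_TERM, Proteoform

_CO = 27.994915
_NH3 = 17.026549
_NH2 = 16.018724


@dataclass(frozen=True)
class IonType:
    name: str
    terminus: str  # "N" | "C"
    neutral_offset: float  # relative to residue sum (C-terminal offsets include H2O)


def ion_types(z_radical: bool = True) -> dict[str, IonType]:
    """The nine supported ion types with their neutral offsets."""
    z_off = WATER - (_NH2 if z_radical else _NH3)
    x_off = WATER + 25.979265
    return {
        "b": IonType("b", "N", 0.0),
        "a": IonType("a", "N", -_CO),
        "a+1": IonType("a+1", "N", -_CO + HYDROGEN),
        "c": IonType("c", "N", _NH3),
        "y": IonType("y", "C", WATER),
        "y-1": IonType("y-1", "C", WATER - HYDROGEN),
        "z": IonType("z", "C", z_off),
        "x": IonType("x", "C", x_off),
        "x+1": IonType("x+1", "C", x_off + HYDROGEN),
    }


#: Ion-type sets per activation method.
SCHEME_IONS = {
    "HCD": ("b", "y"),
    "EThcD": ("b", "y", "c", "z"),
    "UVPD": ("a", "a+1", "b", "c", "x", "x+1", "y", "y-1", "z"),
}


@dataclass(frozen=True)
class ActivationScheme:
    name: str

    def __post_init__(self):
        if self.name not in SCHEME_IONS:
            raise ValueError(f"unknown activation scheme {self.name!r}")

    @property
    def ion_type_names(self) -> tuple[str, ...]:
        return SCHEME_IONS[self.name]


@dataclass(frozen=True)
class FragmentIon:
    """A typed terminal fragment of a proteoform.

    ``index`` is the cleavage ordinal counted from the fragment's own
    terminus (1..N-1); ``cleavage`` is the backbone bond ordinal counted from
    the N-terminus, so an N-terminal fragment has ``cleavage == index`` and a
    C-terminal fragment ``cleavage == N - index``.  ``covers`` is the 1-based
    peptide-local residue interval the fragment spans.
    """

    ion_type: str
    terminus: str
    index: int
    cleavage: int
    neutral_mass: float
    payload_count: int
    covers: tuple[int, int]


def fragment_arrays(proteoform: Proteoform, scheme: ActivationScheme | str,
                    z_radical: bool = True):
    """Vectorised fragment table for a proteoform.

    Returns ``(names, termini, index, cleavage, neutral, payload_count)`` as
    parallel numpy arrays over all ion types of the scheme and all N-1
    backbone cleavages.
    """
    if isinstance(scheme, str):
        scheme = ActivationScheme(scheme)
    types = ion_types(z_radical)
    seq = proteoform.peptide.sequence
    n = len(seq)
    if n < 2:
        empty = np.empty(0)
        return (np.empty(0, dtype=object), np.empty(0, dtype="U1"),
                empty.astype(int), empty.astype(int), empty, empty.astype(int))
    masses = np.asarray(residue_masses(seq))
    prefix = np.cumsum(masses)  # prefix[i-1] = sum of residues 1..i
    total = prefix[-1]
    local_sites = proteoform.local_payload_sites()
    # payloads on the N-terminal side of cleavage i: sites <= i (N_TERM always).
    sites_arr = np.asarray(local_sites, dtype=int)
    cleavages = np.arange(1, n)
    if sites_arr.size:
        n_count = (sites_arr[None, :] <= cleavages[:, None]).sum(axis=1)
    else:
        n_count = np.zeros(n - 1, dtype=int)
    total_pay = len(local_sites)
    c_count = total_pay - n_count

    names, termini, index, cleav, neutral, paycount = [], [], [], [], [], []
    pm = proteoform.payload_mass
    for tname in scheme.ion_type_names:
        it = types[tname]
        if it.terminus == "N":
            s = prefix[:-1]  # S_n for cleavage 1..n-1
            m = s + it.neutral_offset + n_count * pm
            idx = cleavages
            pc = n_count
        else:
            s = total - prefix[:-1]  # S_c for cleavage i covers i+1..n
            m = s + it.neutral_offset + c_count * pm
            idx = n - cleavages
            pc = c_count
        names.append(np.full(n - 1, tname, dtype=object))
        termini.append(np.full(n - 1, it.terminus, dtype="U1"))
        index.append(idx)
        cleav.append(cleavages)
        neutral.append(m)
        paycount.append(pc)
    return (np.concatenate(names), np.concatenate(termini),
            np.concatenate(index), np.concatenate(cleav),
            np.concatenate(neutral), np.concatenate(paycount))


def generate_fragments(proteoform: Proteoform, scheme: ActivationScheme | str,
                       z_radical: bool = True) -> list[FragmentIon]:
    """All theoretical fragments of ``proteoform`` for an activation scheme.

    Exactly ``|ion types| * (N-1)`` fragments; each carries the payloads whose
    sites fall inside the residue interval it covers (the chain N-terminal
    payload counts toward N-terminal fragments).
    """
    names, termini, index, cleav, neutral, paycount = fragment_arrays(
        proteoform, scheme, z_radical)
    n = len(proteoform.peptide)
    out = []
    for i in range(len(names)):
        if termini[i] == "N":
            covers = (1, int(cleav[i]))
        else:
            covers = (int(cleav[i]) + 1, n)
        out.append(FragmentIon(str(names[i]), str(termini[i]), int(index[i]),
                               int(cleav[i]), float(neutral[i]),
                               int(paycount[i]), covers))
    return out


def fragments_to_tsv(fragments, path):
    import pandas as pd

    pd.DataFrame([f.__dict__ for f in fragments]).to_csv(path, sep="\t", index=False)
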