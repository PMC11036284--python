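"""Antibody chain model, limited Lys-C digestion and payload placement.

Limited (partial) Lys-C proteolysis of an antibody produces middle-down
peptides whose boundaries obey Lys-C specificity (cleavage C-terminal to
lysine) but with any number of missed cleavages.  The candidate search space
for a lysine-conjugated ADC is therefore every substring that starts at the
chain N-terminus or immediately after a lysine and ends at a lysine or the
chain C-terminus, decorated with every combination of up to ``max_payloads``
payload placements over its lysines (and the chain N-terminus for the first
peptide).

Coordinates are 1-based and inclusive throughout; the chain N-terminus is the
sentinel position ``N_TERM`` (0), never residue 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .chem import CANONICAL_AA, PAYLOAD_MASS, peptide_mass

#: Sentinel for the chain N-terminal conjugation site (alpha-amine).
N_TERM = 0


@dataclass(frozen=True)
class ChainSequence:
    """One antibody chain (heavy or light) with its copy number per antibody."""

    chain_id: str
    role: str  # "heavy" | "light"
    residues: str
    copies_per_antibody: int = 2

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.residues) - set(CANONICAL_AA)
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.role not in ("heavy", "light"):
            raise ValueError(f"chain role must be 'heavy' or 'light', got {self.role!r}")
        if self.copies_per_antibody < 1:
            raise ValueError("copies_per_antibody must be >= 1")

    def __len__(self):
        return len(self.residues)

    @property
    def lysine_positions(self) -> tuple[int, ...]:
        """1-based positions of every lysine on the chain."""
        return tuple(i + 1 for i, aa in enumerate(self.residues) if aa == "K")


@dataclass(frozen=True)
class ConjugationSite:
    """A candidate payload attachment point: a lysine or a chain N-terminus."""

    chain_id: str
    position: int  # 1-based residue index, or N_TERM
    residue: str  # "K", or "N-term"
    copy: int = 1  # which chain copy of the antibody (1..copies_per_antibody)

    def __post_init__(self):
        if self.position == N_TERM:
            if self.residue != "N-term":
                raise ValueError("N-terminal site must have residue 'N-term'")
        elif self.residue != "K":
            raise ValueError("internal conjugation sites must be lysines")


@dataclass(frozen=True)
class Peptide:
    """A limited-digest peptide in chain coordinates (1-based, inclusive)."""

    chain_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")

    def __len__(self):
        return len(self.sequence)

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence)

    def internal_lysines(self) -> tuple[int, ...]:
        """Chain positions of lysines at ``start .. end-1`` (cleavage-eligible K excluded)."""
        return tuple(
            self.start + i
            for i, aa in enumerate(self.sequence[:-1])
            if aa == "K"
        )

    def candidate_sites(self, allow_cterm_K: bool = False) -> tuple[int, ...]:
        """Chain positions eligible for a payload on this peptide, sorted.

        ``N_TERM`` is eligible only for the chain's first peptide; the
        C-terminal (cleaved) lysine only when ``allow_cterm_K``.
        """
        sites = list(self.internal_lysines())
        if self.start == 1:
            sites.insert(0, N_TERM)
        if allow_cterm_K and self.sequence[-1] == "K":
            sites.append(self.end)
        return tuple(sites)

    def to_local(self, chain_pos: int) -> int:
        """Map a chain coordinate (or ``N_TERM``) to 1-based peptide-local coordinates."""
        if chain_pos == N_TERM:
            return N_TERM
        return chain_pos - self.start + 1


@dataclass(frozen=True)
class Proteoform:
    """A digest peptide plus a concrete set of payload placements.

    ``payload_sites`` are chain coordinates (``N_TERM`` for the alpha-amine).
    """

    peptide: Peptide
    payload_sites: frozenset[int] = frozenset()
    payload_mass: float = PAYLOAD_MASS
    neutral_mass: float = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        expected = self.peptide.mass + len(self.payload_sites) * self.payload_mass
        if self.neutral_mass is None:
            object.__setattr__(self, "neutral_mass", expected)
        elif abs(self.neutral_mass - expected) > 1e-6:
            raise ValueError("neutral_mass inconsistent with peptide + payloads")

    @property
    def n_payloads(self) -> int:
        return len(self.payload_sites)

    def local_payload_sites(self) -> tuple[int, ...]:
        """Payload sites in peptide-local coordinates, sorted (N_TERM first)."""
        return tuple(sorted(self.peptide.to_local(p) for p in self.payload_sites))

    def label(self) -> str:
        sites = ",".join(
            "Nterm" if p == N_TERM else f"K{p}" for p in sorted(self.payload_sites)
        )
        return f"{self.peptide.chain_id}:{self.peptide.start}-{self.peptide.end}[{sites}]"


def digest_limited(chain: ChainSequence, max_missed: int | None = None,
                   min_mass: float = 0.0, max_mass: float = math.inf) -> list[Peptide]:
    """Enumerate every Lys-C limited-digest peptide of ``chain``.

    ``max_missed=None`` means unlimited missed cleavages.  Peptides outside
    ``[min_mass, max_mass]`` (unmodified monoisotopic mass) are pruned.
    Output is ordered by (start, end).
    """
    if min_mass > max_mass:
        raise ValueError("min_mass exceeds max_mass")
    res = chain.residues
    n = len(res)
    k_positions = chain.lysine_positions
    starts = [1] + [k + 1 for k in k_positions if k < n]
    ends = [k for k in k_positions] + ([n] if (n not in k_positions) else [])
    ends.sort()
    out = []
    for s in starts:
        for e in ends:
            if e < s:
                continue
            seq = res[s - 1:e]
            missed = seq[:-1].count("K")
            if max_missed is not None and missed > max_missed:
                continue
            m = peptide_mass(seq)
            if not (min_mass <= m <= max_mass):
                continue
            out.append(Peptide(chain.chain_id, s, e, seq, missed))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def enumerate_sites(antibody: Sequence[ChainSequence]) -> list[ConjugationSite]:
    """All candidate conjugation sites over every chain copy of the antibody.

    One site per lysine per chain copy plus one N-terminal site per chain
    copy; for the 2 heavy + 2 light chains of an IgG with 31 + 13 lysines this
    is 2x(31+1) + 2x(13+1) = 92 sites.
    """
    if not antibody:
        raise ValueError("antibody must contain at least one chain")
    sites = []
    for chain in antibody:
        for copy in range(1, chain.copies_per_antibody + 1):
            sites.append(ConjugationSite(chain.chain_id, N_TERM, "N-term", copy))
            for pos in chain.lysine_positions:
                sites.append(ConjugationSite(chain.chain_id, pos, "K", copy))
    return sites


def place_payloads(peptide: Peptide, max_payloads: int = 2,
                   allow_cterm_K: bool = False,
                   payload_mass: float = PAYLOAD_MASS) -> list[Proteoform]:
    """All proteoforms of ``peptide`` with 0..``max_payloads`` payloads.

    Eligible positions are the internal lysines, the chain N-terminus for the
    first peptide, and (only when ``allow_cterm_K``) the C-terminal cleaved
    lysine — Lys-C cleavage after a conjugated lysine is assumed blocked.
    """
    if max_payloads < 0:
        raise ValueError("max_payloads must be >= 0")
    eligible = peptide.candidate_sites(allow_cterm_K)
    forms = []
    for k in range(0, max_payloads + 1):
        for combo in itertools.combinations(eligible, k):
            forms.append(Proteoform(peptide, frozenset(combo), payload_mass))
    return forms


def build_database(chains: Iterable[ChainSequence], max_missed: int | None = None,
                   min_mass: float = 0.0, max_mass: float = 20000.0,
                   max_payloads: int = 2, allow_cterm_K: bool = False,
                   payload_mass: float = PAYLOAD_MASS) -> list[Proteoform]:
    """Full candidate proteoform database for a set of chains."""
    forms: list[Proteoform] = []
    for chain in chains:
        for pep in digest_limited(chain, max_missed, min_mass, max_mass):
            forms.extend(place_payloads(pep, max_payloads, allow_cterm_K, payload_mass))
    return forms


def database_to_tsv(forms: Iterable[Proteoform], path: str | Path) -> None:
    rows = [
        {
            "chain_id": f.peptide.chain_id,
            "start": f.peptide.start,
            "end": f.peptide.end,
            "sequence": f.peptide.sequence,
            "missed_cleavages": f.peptide.missed_cleavages,
            "payload_positions": ";".join(str(p) for p in sorted(f.payload_sites)),
            "neutral_mass": round(f.neutral_mass, 6),
        }
        for f in forms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chain_fasta(path: str | Path, roles: dict[str, str] | None = None,
                     copies: dict[str, int] | None = None) -> list[ChainSequence]:
    """Read antibody chains from FASTA.

    Record ids become chain ids.  ``roles`` maps chain_id to heavy/light; when
    absent the role is guessed from length (>= 300 aa: heavy).  ``copies``
    overrides the default of two copies per antibody.
    """
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        role = (roles or {}).get(rec.id) or ("heavy" if len(seq) >= 300 else "light")
        chains.append(ChainSequence(rec.id, role, seq, (copies or {}).get(rec.id, 2)))
    if not chains:
        raise ValueError(f"no FASTA records in {path}")
    return chains


def load_trastuzumab() -> list[ChainSequence]:
    """The packaged trastuzumab heavy (des-Lys, 31 K) and light (13 K) chains."""
    from importlib.resources import files

    return read_chain_fasta(str(files("adcmapper") / "data" / "trastuzumab.fasta"))
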