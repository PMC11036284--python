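"""Limited Lys-C digestion, site enumeration and payload placement."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from adcmapper.chem import CANONICAL_AA, peptide_mass
from adcmapper.sequence import (ChainSequence, N_TERM, Peptide, Proteoform,
                                build_database, database_to_tsv,
                                digest_limited, enumerate_sites,
                                place_payloads, read_chain_fasta)


def brute_force_digest(residues, max_missed, min_mass, max_mass):
    """Independent oracle: enumerate every substring obeying the Lys-C
    boundary rule directly from its definition."""
    n = len(residues)
    out = []
    for start in range(1, n + 1):
        if not (start == 1 or residues[start - 2] == "K"):
            continue
        for end in range(start, n + 1):
            if not (end == n or residues[end - 1] == "K"):
                continue
            seq = residues[start - 1:end]
            missed = seq[:-1].count("K")
            if max_missed is not None and missed > max_missed:
                continue
            if not (min_mass <= peptide_mass(seq) <= max_mass):
                continue
            out.append((start, end, seq, missed))
    return out


def random_chain(rng, max_len=60):
    length = rng.randint(1, max_len)
    return "".join(rng.choice(CANONICAL_AA) for _ in range(length))


def test_digest_matches_brute_force_enumeration():
    rng = random.Random(42)
    for _ in range(200):
        residues = random_chain(rng)
        max_missed = rng.choice([None, 0, 1, 3])
        lo, hi = sorted(rng.uniform(0, 4000) for _ in range(2))
        chain = ChainSequence("c", "light", residues, 1)
        got = [(p.start, p.end, p.sequence, p.missed_cleavages)
               for p in digest_limited(chain, max_missed, lo, hi)]
        assert sorted(got) == sorted(brute_force_digest(residues, max_missed,
                                                        lo, hi))


def test_digest_examples(toy_chain):
    assert [p.sequence for p in digest_limited(toy_chain)] == [
        "AK", "AKRK", "AKRKG", "RK", "RKG", "G"]
    no_k = ChainSequence("x", "light", "AAA", 1)
    peps = digest_limited(no_k)
    assert [(p.sequence, p.missed_cleavages) for p in peps] == [("AAA", 0)]


def test_digest_zero_missed_tiles_the_chain(heavy_chain):
    peps = digest_limited(heavy_chain, max_missed=0)
    assert "".join(p.sequence for p in peps) == heavy_chain.residues


def test_digest_mass_window_covers_middle_down_range(trastuzumab):
    # the 1.8-16.9 kDa band of limited-proteolysis products is reachable
    peps = [p for c in trastuzumab for p in digest_limited(c, None, 1800, 16900)]
    masses = [p.mass for p in peps]
    assert peps and min(masses) >= 1800 and max(masses) <= 16900
    assert min(masses) < 3000 and max(masses) > 15000
    unrestricted = [p for c in trastuzumab for p in digest_limited(c)]
    assert len(unrestricted) > len(peps)  # the window actually prunes


def test_digest_invalid_inputs():
    with pytest.raises(ValueError):
        ChainSequence("c", "light", "", 1)
    with pytest.raises(ValueError):
        ChainSequence("c", "light", "ABZ", 1)
    chain = ChainSequence("c", "light", "AK", 1)
    with pytest.raises(ValueError):
        digest_limited(chain, None, 100.0, 10.0)


def test_enumerate_sites_counts(trastuzumab):
    sites = enumerate_sites(trastuzumab)
    assert len(sites) == 92  # 2 x (31 + 1) + 2 x (13 + 1)
    assert len(enumerate_sites([ChainSequence("a", "light", "AAA", 1)])) == 1
    assert len(enumerate_sites([ChainSequence("a", "light", "KK", 1)])) == 3
    with pytest.raises(ValueError):
        enumerate_sites([])


@given(st.text(alphabet=CANONICAL_AA, min_size=2, max_size=40),
       st.integers(min_value=0, max_value=3))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_proteoform_count_matches_binomial(seq, max_payloads):
    chain = ChainSequence("c", "light", seq, 1)
    for pep in digest_limited(chain):
        n_eligible = len(pep.candidate_sites())
        forms = place_payloads(pep, max_payloads)
        expected = sum(math.comb(n_eligible, k)
                       for k in range(0, max_payloads + 1))
        assert len(forms) == expected
        assert len({f.payload_sites for f in forms}) == len(forms)


def test_place_payloads_examples():
    # two internal K, not N-terminal, C-terminal K excluded by default
    pep = Peptide("c", 3, 9, "AKAAKAK", 2)
    forms = place_payloads(pep, 2)
    assert sorted(len(f.payload_sites) for f in forms) == [0, 1, 1, 2]
    assert place_payloads(pep, 2, allow_cterm_K=True)
    assert len(place_payloads(pep, 2, allow_cterm_K=True)) == 7
    # no lysines, not N-terminal: only the unmodified form
    bare = Peptide("c", 5, 7, "AAA", 0)
    assert len(place_payloads(bare, 2)) == 1
    # N-terminal peptide gains the alpha-amine site
    first = Peptide("c", 1, 3, "AAK", 0)
    forms = place_payloads(first, 1)
    assert {frozenset(f.payload_sites) for f in forms} == {
        frozenset(), frozenset({N_TERM})}


def test_proteoform_mass_invariant():
    pep = Peptide("c", 1, 4, "AKAK", 1)
    form = Proteoform(pep, frozenset({2}))
    assert form.neutral_mass == pytest.approx(pep.mass + 956.364, abs=1e-6)
    with pytest.raises(ValueError):
        Proteoform(pep, frozenset({2}), neutral_mass=pep.mass)


def test_fasta_reading_and_database_export(tmp_path, trastuzumab):
    path = tmp_path / "chains.fasta"
    path.write_text(">H my heavy\n" + trastuzumab[0].residues + "\n"
                    ">L my light\n" + trastuzumab[1].residues + "\n")
    chains = read_chain_fasta(path)
    assert [c.role for c in chains] == ["heavy", "light"]
    assert all(c.copies_per_antibody == 2 for c in chains)
    forms = build_database(chains[:1], None, 1800, 5000, max_payloads=1)
    out = tmp_path / "db.tsv"
    database_to_tsv(forms, out)
    header = out.read_text().splitlines()[0].split("\t")
    assert header == ["chain_id", "start", "end", "sequence",
                      "missed_cleavages", "payload_positions", "neutral_mass"]
    assert len(out.read_text().splitlines()) == len(forms) + 1
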