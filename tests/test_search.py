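"""Proteoform matching, replicate filtering and site-localization rules."""

import numpy as np
import pytest

from adcmapper.deconv import DeconvolutedMass
from adcmapper.fragments import generate_fragments
from adcmapper.search import (CandidateIndex, SiteEvidence,
                              aggregate_replicates, bracketing_fragments,
                              build_site_evidence, call_sites, census,
                              consistent_sites, make_decoy_database,
                              match_spectrum, proteoform_key, score_candidate)
from adcmapper.sequence import (ChainSequence, N_TERM, Peptide, Proteoform,
                                build_database, place_payloads)
from adcmapper.spectra import ScanPair, Spectrum


def make_form(seq, sites=(), start=1, chain="c"):
    pep = Peptide(chain, start, start + len(seq) - 1, seq, seq[:-1].count("K"))
    return Proteoform(pep, frozenset(sites))


def observed_from(form, scheme="UVPD", ppm_shift=0.0, subset=None):
    frags = generate_fragments(form, scheme)
    if subset is not None:
        frags = [f for f in frags if subset(f)]
    out = []
    for i, f in enumerate(frags):
        out.append(DeconvolutedMass(f.neutral_mass * (1 + ppm_shift * 1e-6),
                                    10.0, 1, f"obs{i}"))
    return out


def scan_pair_for(form, charge=5, activation="UVPD", rt=10.0):
    from adcmapper.chem import mz_from_neutral

    prec = mz_from_neutral(form.neutral_mass, charge)
    hcd = Spectrum("h", 2, [547.22], [100.0], rt - 0.001, "HCD",
                   precursor_mz=prec, precursor_charge=charge)
    trig = Spectrum("t", 2, [500.0], [1.0], rt, activation,
                    precursor_mz=prec, precursor_charge=charge)
    return ScanPair(hcd, trig, (547.22,))


def test_top_match_is_planted_proteoform():
    seq = "AESGKLMNPKRSTVWYK"
    peptide_forms = place_payloads(
        Peptide("c", 1, len(seq), seq, seq[:-1].count("K")), 2)
    planted = next(f for f in peptide_forms if f.payload_sites == {5})
    observed = observed_from(planted)
    matches = match_spectrum(scan_pair_for(planted), peptide_forms,
                             observed=observed)
    assert matches
    assert matches[0].proteoform.payload_sites == {5}
    assert not matches[0].co_top or matches[0].rank == 1
    assert matches[0].coverage_percent == 100.0
    assert abs(matches[0].precursor_error_da) < 1e-6


def test_vanishing_fragment_tolerance_matches_nothing():
    form = make_form("AESGKLMNPK", sites=(5,))
    observed = observed_from(form, ppm_shift=5.0)
    matches = match_spectrum(scan_pair_for(form), [form], observed=observed,
                             frag_tol_ppm=0.001)
    assert matches == []
    ok = match_spectrum(scan_pair_for(form), [form], observed=observed,
                        frag_tol_ppm=10.0)
    assert ok and ok[0].n_matched == len(observed)


def test_precursor_tolerance_window():
    form = make_form("AESGKLMNPK", sites=(5,))
    index = CandidateIndex([form])
    assert index.within(form.neutral_mass + 2.0, 2.2)
    assert not index.within(form.neutral_mass + 3.0, 2.2)


def test_aggregate_replicates_rule():
    form = make_form("AESGKLMNPK", sites=(5,))
    bare = make_form("AESGKLMNPK")

    def m(f, rep):
        ms = match_spectrum(scan_pair_for(f), [f], observed=observed_from(f),
                            replicate_id=rep)
        return ms[0]

    kept = aggregate_replicates([m(form, r) for r in ("r1", "r2", "r3")], 3)
    assert proteoform_key(form) in kept
    rejected = aggregate_replicates([m(form, r) for r in ("r1", "r5")], 3)
    assert proteoform_key(form) not in rejected
    # unmodified peptides are exempt from the replicate filter
    exempt = aggregate_replicates([m(bare, "r1")], 3)
    assert proteoform_key(bare) in exempt


def test_bracketing_fragment_definition():
    # ...K5 x x K8...: c-ions cleaving at 5..7 carry K5's payload and
    # bracket it against K8
    seq = "AAAAKXXKAAAK".replace("X", "G")
    form = make_form(seq, sites=(5,))
    match = match_spectrum(scan_pair_for(form), [form],
                           observed=observed_from(form))[0]
    brk = bracketing_fragments(match, 5)
    cleavages = {(f.ion_type, f.cleavage) for f in brk}
    assert ("c", 5) in cleavages and ("c", 6) in cleavages
    assert ("c", 4) in cleavages  # left flank: between N-term/K? and the site
    assert all(1 <= f.cleavage < 8 for f in brk)
    # the same fragment does NOT bracket a payload at K8
    form8 = make_form(seq, sites=(8,))
    match8 = match_spectrum(scan_pair_for(form8), [form8],
                            observed=observed_from(form8))[0]
    brk8 = bracketing_fragments(match8, 8)
    assert all(5 <= f.cleavage <= 11 for f in brk8)
    assert not any(f.cleavage < 5 for f in brk8)
    with pytest.raises(ValueError):
        bracketing_fragments(match, 8)


def test_consistent_sites_pins_and_ranges():
    seq = "AAAAKXXKAAAK".replace("X", "G")
    form = make_form(seq, sites=(5,))
    full = match_spectrum(scan_pair_for(form), [form],
                          observed=observed_from(form))[0]
    assert consistent_sites(full, 5) == (5,)
    # remove every fragment cleaving between K5 and K8: the payload can no
    # longer be told apart from a K8 placement
    blind = match_spectrum(
        scan_pair_for(form), [form],
        observed=observed_from(form, subset=lambda f: not 5 <= f.cleavage < 8)
    )[0]
    assert consistent_sites(blind, 5) == (5, 8)
    # a single discordant fragment must not pin the site on its own
    one = match_spectrum(
        scan_pair_for(form), [form],
        observed=observed_from(
            form, subset=lambda f: not 5 <= f.cleavage < 8 or
            (f.ion_type, f.cleavage) == ("c", 6))
    )[0]
    assert consistent_sites(one, 5) == (5, 8)
    assert consistent_sites(one, 5, min_inconsistent=1) == (5,)


def ev(site, rep, n_brackets, rng=None, chain="HC", key=None, unique=None):
    rng = rng if rng is not None else (site,)
    return SiteEvidence(chain, site, rep, "UVPD",
                        bracketing=tuple(("c", i, 0.0) for i in range(n_brackets)),
                        consistent_range=rng, peptide_key=key,
                        isomer_unique=unique or {})


def test_call_sites_unambiguous_rule():
    # >=2 bracketing fragments in >=2 replicates -> unambiguous
    calls = call_sites([ev(5, "r1", 3), ev(5, "r2", 3), ev(5, "r4", 3)])
    assert [(c.status, c.sites) for c in calls] == [("unambiguous", (5,))]
    # one replicate is not enough
    calls = call_sites([ev(5, "r1", 3)])
    assert calls[0].status == "ambiguous_range"
    # two fragments in only one replicate, one in the other -> ambiguous
    calls = call_sites([ev(5, "r1", 2), ev(5, "r2", 1)])
    assert calls[0].status == "ambiguous_range"


def test_call_sites_range_logic():
    rows = [ev(412, r, 4, rng=(412, 417)) for r in ("r1", "r2", "r3")]
    calls = call_sites(rows)
    assert [(c.status, c.sites) for c in calls] == \
        [("ambiguous_range", (412, 417))]
    # an independently pinned site absorbs its range
    rows += [ev(412, r, 4, key=("HC", 1, 5, (412,))) for r in ("r1", "r2")]
    rows += [ev(417, r, 4, key=("HC", 6, 9, (417,))) for r in ("r1", "r2")]
    calls = call_sites(rows)
    assert {(c.status, c.sites) for c in calls} == {
        ("unambiguous", (412,)), ("unambiguous", (417,))}


def test_call_sites_isomer_rule():
    key_a = ("HC", 1, 20, (5,))
    key_b = ("HC", 1, 20, (8,))
    # co-eluting isomers, each with >=4 unique fragments in >=3/5 replicates
    rows = []
    for r in ("r1", "r2", "r3"):
        rows.append(ev(5, r, 3, key=key_a, unique={(8,): 4}))
        rows.append(ev(8, r, 3, key=key_b, unique={(5,): 5}))
    calls = call_sites(rows)
    assert {(c.status, c.sites) for c in calls} == {
        ("unambiguous", (5,)), ("unambiguous", (8,))}
    # with only 3 unique fragments the pair stays unresolved
    rows = []
    for r in ("r1", "r2", "r3"):
        rows.append(ev(5, r, 3, key=key_a, unique={(8,): 3}))
        rows.append(ev(8, r, 3, key=key_b, unique={(5,): 3}))
    calls = call_sites(rows)
    assert all(c.status == "ambiguous_range" for c in calls)
    assert {c.sites for c in calls} == {(5, 8)}
    # 4 unique fragments but in only 2 replicates: still unresolved
    rows = [ev(5, r, 3, key=key_a, unique={(8,): 4}) for r in ("r1", "r2")]
    calls = call_sites(rows)
    assert calls[0].status == "ambiguous_range"


def test_census_arithmetic(trastuzumab):
    from adcmapper.search import SiteCall

    hc_positions = trastuzumab[0].lysine_positions[:19]
    lc_positions = trastuzumab[1].lysine_positions[:4]
    calls = [SiteCall("HC", (p,), "unambiguous") for p in hc_positions]
    calls += [SiteCall("LC", (p,), "unambiguous") for p in lc_positions]
    calls += [SiteCall("HC", (412, 417), "ambiguous_range")]
    out = census(calls, trastuzumab)
    assert out["unambiguous_heavy"] == 19
    assert out["unambiguous_light"] == 4
    assert out["ambiguous_heavy"] == 1
    assert out["per_antibody_unambiguous"] == 46
    empty = census([], trastuzumab)
    assert empty["per_antibody_unambiguous"] == 0


def test_coverage_definition_on_toy():
    form = make_form("AESGK")
    observed = observed_from(
        form, "HCD", subset=lambda f: (f.ion_type, f.index) in
        [("b", 1), ("y", 2)])
    matched, coverage = score_candidate(form, observed, "HCD")
    # bonds covered: b1 -> bond 1, y2 -> bond 3; 2 of 4 bonds
    assert coverage == pytest.approx(50.0)


def test_decoy_database_preserves_masses():
    chain = ChainSequence("c", "light", "AESGKLMNPKRSTVWYK", 1)
    forms = build_database([chain], None, 0, 1e6, 1)
    decoys = make_decoy_database(forms, seed=1)
    assert len(decoys) == len(forms)
    for t, d in zip(forms, decoys):
        assert d.peptide.chain_id.startswith("decoy_")
        assert d.n_payloads == t.n_payloads
        assert np.isclose(d.peptide.mass, t.peptide.mass, atol=1e-6)
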