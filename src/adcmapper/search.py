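"""Proteoform–spectrum matching and payload-site localization.

Matching works in neutral-mass space: the triggered scan is deconvoluted to
neutral monoisotopic fragment masses, candidate proteoforms within the
precursor tolerance (2.2 Da absolute, absorbing +/-1..2 Da monoisotopic-peak
misassignments) are scored by greedy minimal-ppm fragment matching at 10 ppm,
and ranked by matched-fragment count, then sequence coverage, then precursor
error.

Localization follows the bracketing-fragment logic: a payload site is pinned
by matched fragments from backbone cleavages between the site and its
neighbouring candidate sites, whose payload content proves which side of the
cleavage the payload sits on.  A site is unambiguous only with at least two
such bracketing fragments in at least two replicates; co-eluting positional
isomers are each called only with at least four isomer-unique fragments in at
least three of five replicates; otherwise the payload is reported on the
smallest lysine range consistent with the matched fragments.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .chem import neutral_from_mz
from .deconv import DeconvolutedMass, deconvolute
from .fragments import ActivationScheme, FragmentIon, fragment_arrays
from .sequence import N_TERM, ChainSequence, Peptide, Proteoform
from .spectra import ScanPair


def proteoform_key(form: Proteoform) -> tuple:
    pep = form.peptide
    return (pep.chain_id, pep.start, pep.end, tuple(sorted(form.payload_sites)))


@dataclass
class ProteoformSpectrumMatch:
    """One candidate proteoform scored against one triggered scan."""

    proteoform: Proteoform
    scan_id: str
    replicate_id: str
    activation: str
    matched_fragments: list[tuple[FragmentIon, DeconvolutedMass, float]]
    coverage_percent: float
    precursor_error_da: float
    retention_time: float = 0.0
    rank: int = 0
    co_top: bool = False

    @property
    def n_matched(self) -> int:
        return len(self.matched_fragments)

    def n_payload_fragments_by_count(self) -> dict[int, int]:
        out: dict[int, int] = defaultdict(int)
        for frag, _, _ in self.matched_fragments:
            out[frag.payload_count] += 1
        return dict(out)


class CandidateIndex:
    """Proteoform database indexed by neutral mass for precursor lookup."""

    def __init__(self, forms: list[Proteoform]):
        self.forms = sorted(forms, key=lambda f: f.neutral_mass)
        self.masses = np.array([f.neutral_mass for f in self.forms])

    def __len__(self):
        return len(self.forms)

    def within(self, neutral: float, tol_da: float) -> list[Proteoform]:
        lo = np.searchsorted(self.masses, neutral - tol_da)
        hi = np.searchsorted(self.masses, neutral + tol_da)
        return self.forms[lo:hi]


def _match_fragments(theo_neutral: np.ndarray, observed: list[DeconvolutedMass],
                     frag_tol_ppm: float):
    """Greedy minimal-ppm assignment; one observed mass per theoretical fragment."""
    if not observed or theo_neutral.size == 0:
        return []
    obs = np.array([m.neutral_mass for m in observed])
    order = np.argsort(obs, kind="stable")
    obs_sorted = obs[order]
    pairs = []  # (|ppm|, theo_idx, obs_idx, ppm)
    for ti, tm in enumerate(theo_neutral):
        tol = tm * frag_tol_ppm * 1e-6
        lo = np.searchsorted(obs_sorted, tm - tol)
        hi = np.searchsorted(obs_sorted, tm + tol)
        for oi in order[lo:hi]:
            ppm = (obs[oi] - tm) / tm * 1e6
            pairs.append((abs(ppm), ti, int(oi), ppm))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_t, used_o = set(), set()
    out = []
    for _, ti, oi, ppm in pairs:
        if ti in used_t or oi in used_o:
            continue
        used_t.add(ti)
        used_o.add(oi)
        out.append((ti, oi, ppm))
    return out


def score_candidate(form: Proteoform, observed: list[DeconvolutedMass],
                    scheme: ActivationScheme | str, frag_tol_ppm: float = 10.0,
                    z_radical: bool = True):
    """Match observed neutral masses against one proteoform's fragment set.

    Returns ``(matched, coverage_percent)`` where ``matched`` is a list of
    ``(FragmentIon, DeconvolutedMass, ppm_error)``.
    """
    names, termini, index, cleav, neutral, paycount = fragment_arrays(
        form, scheme, z_radical)
    assignments = _match_fragments(neutral, observed, frag_tol_ppm)
    n = len(form.peptide)
    matched = []
    bonds = set()
    for ti, oi, ppm in assignments:
        covers = (1, int(cleav[ti])) if termini[ti] == "N" else (int(cleav[ti]) + 1, n)
        frag = FragmentIon(str(names[ti]), str(termini[ti]), int(index[ti]),
                           int(cleav[ti]), float(neutral[ti]), int(paycount[ti]),
                           covers)
        matched.append((frag, observed[oi], ppm))
        bonds.add(frag.cleavage)
    coverage = 100.0 * len(bonds) / (n - 1) if n > 1 else 0.0
    return matched, coverage


def match_spectrum(pair: ScanPair, candidates: CandidateIndex | list[Proteoform],
                   prec_tol_da: float = 2.2, frag_tol_ppm: float = 10.0,
                   replicate_id: str = "r1", z_radical: bool = True,
                   observed: list[DeconvolutedMass] | None = None,
                   deconv_kwargs: dict | None = None
                   ) -> list[ProteoformSpectrumMatch]:
    """Score all candidates within precursor tolerance of a scan pair.

    ``observed`` may supply externally deconvoluted fragment masses; otherwise
    the triggered scan is deconvoluted here.  Matches are returned ranked by
    (matched-fragment count, coverage, |precursor error|); co-ranked top
    candidates are flagged ``co_top`` rather than arbitrarily broken.
    """
    trig = pair.triggered_scan
    if trig.precursor_charge is None:
        return []
    if not isinstance(candidates, CandidateIndex):
        candidates = CandidateIndex(list(candidates))
    prec_neutral = neutral_from_mz(trig.precursor_mz, trig.precursor_charge)
    forms = candidates.within(prec_neutral, prec_tol_da)
    if not forms:
        return []
    if observed is None:
        kw = dict(charge_range=(1, max(2, trig.precursor_charge)))
        kw.update(deconv_kwargs or {})
        observed = deconvolute(trig, **kw)
    scheme = ActivationScheme(trig.activation)
    matches = []
    for form in forms:
        matched, coverage = score_candidate(form, observed, scheme,
                                            frag_tol_ppm, z_radical)
        if not matched:
            continue
        matches.append(ProteoformSpectrumMatch(
            proteoform=form, scan_id=trig.scan_id, replicate_id=replicate_id,
            activation=trig.activation, matched_fragments=matched,
            coverage_percent=coverage,
            precursor_error_da=prec_neutral - form.neutral_mass,
            retention_time=trig.retention_time))
    matches.sort(key=lambda m: (-m.n_matched, -m.coverage_percent,
                                abs(m.precursor_error_da),
                                proteoform_key(m.proteoform)))
    if matches:
        top = matches[0]
        for i, m in enumerate(matches):
            m.rank = i + 1
            m.co_top = (m.n_matched == top.n_matched
                        and m.coverage_percent == top.coverage_percent)
    return matches


def aggregate_replicates(matches: list[ProteoformSpectrumMatch],
                         min_replicates: int = 3, top_only: bool = True
                         ) -> dict[tuple, list[ProteoformSpectrumMatch]]:
    """Replicate filter: keep payload-bearing proteoforms seen in enough runs.

    Payload-containing proteoforms are kept only when matched (as the top or
    co-top candidate of some scan) in at least ``min_replicates`` distinct
    replicates; unmodified peptides are exempt from the filter.
    """
    by_form: dict[tuple, list[ProteoformSpectrumMatch]] = defaultdict(list)
    for m in matches:
        if top_only and not (m.rank == 1 or m.co_top):
            continue
        by_form[proteoform_key(m.proteoform)].append(m)
    accepted = {}
    for key, ms in by_form.items():
        n_payloads = len(key[3])
        replicates = {m.replicate_id for m in ms}
        if n_payloads == 0 or len(replicates) >= min_replicates:
            accepted[key] = ms
    return accepted


# ---------------------------------------------------------------------------
# Localization

def _local_candidate_sites(form: Proteoform, allow_cterm_K: bool = False
                           ) -> list[int]:
    return [form.peptide.to_local(p)
            for p in form.peptide.candidate_sites(allow_cterm_K)]


def consistent_sites(match: ProteoformSpectrumMatch, site: int,
                     allow_cterm_K: bool = False,
                     min_inconsistent: int = 2) -> tuple[int, ...]:
    """Candidate sites the payload at ``site`` could occupy given the evidence.

    ``site`` is a chain coordinate (``N_TERM`` for the alpha-amine).  A
    candidate position is ruled out only when at least ``min_inconsistent``
    matched fragments contradict it — moving this payload there (keeping the
    other payloads fixed) would change their payload counts.  Requiring two
    discordant fragments keeps a single spurious (or conflicting) fragment
    from deciding a site on its own.  The matched proteoform's own site is
    always consistent; a single-element result pins the payload.
    """
    form = match.proteoform
    if site not in form.payload_sites:
        raise ValueError(f"{site} is not a payload site of the matched proteoform")
    pep = form.peptide
    s_local = pep.to_local(site)
    others_local = [pep.to_local(p) for p in form.payload_sites if p != site]
    cands = _local_candidate_sites(form, allow_cterm_K)
    result = []
    for alt in cands:
        if alt in others_local:
            continue
        n_inconsistent = 0
        for frag, _, _ in match.matched_fragments:
            # payloads on a fragment: sites within covered residues; the
            # N-terminal sentinel (0) belongs to the N-terminal side.
            if frag.terminus == "N":
                in_old = s_local <= frag.cleavage
                in_new = alt <= frag.cleavage
            else:
                in_old = s_local > frag.cleavage
                in_new = alt > frag.cleavage
            if in_old != in_new:
                n_inconsistent += 1
        if alt == s_local or n_inconsistent < min_inconsistent:
            chain_pos = alt if alt == N_TERM else pep.start + alt - 1
            result.append(chain_pos)
    return tuple(sorted(result))


def bracketing_fragments(match: ProteoformSpectrumMatch, site: int,
                         allow_cterm_K: bool = False) -> list[FragmentIon]:
    """Matched fragments that bracket the payload at ``site`` (chain coord).

    A bracketing fragment originates from a backbone cleavage between the
    site and its nearest neighbouring candidate site on either flank; its
    payload count then proves on which side of that cleavage the payload
    sits.  When no candidate site exists on a flank, the flank extends to the
    corresponding peptide terminus (a fragment cleaving there still pins the
    payload against the nearest alternative placement).
    """
    form = match.proteoform
    if site not in form.payload_sites:
        raise ValueError(f"{site} is not a payload site of the matched proteoform")
    pep = form.peptide
    s = pep.to_local(site)
    cands = _local_candidate_sites(form, allow_cterm_K)
    left = max((c for c in cands if c < s), default=None)
    right = min((c for c in cands if c > s), default=None)
    n = len(pep)
    r_bound = right if right is not None else n  # cleavages run 1..n-1
    l_bound = max(left, 1) if left is not None else 1
    out = []
    for frag, _, _ in match.matched_fragments:
        i = frag.cleavage  # bond between residues i and i+1 (local)
        # cleavages in [s, r_bound) separate the site from its right
        # neighbour; cleavages in [l_bound, s) from its left neighbour.
        right_side = max(s, 1) <= i < r_bound if s > N_TERM else i < r_bound
        left_side = l_bound <= i < s
        if right_side or left_side:
            out.append(frag)
    return out


@dataclass
class SiteEvidence:
    """Evidence for one payload placement from one replicate's matches."""

    chain_id: str
    site: int  # chain coordinate; N_TERM for the alpha-amine
    replicate_id: str
    method: str  # EThcD | UVPD
    bracketing: tuple = ()  # bracketing fragment descriptors
    consistent_range: tuple[int, ...] = ()  # chain coords incl. site
    peptide_key: tuple | None = None
    isomer_unique: dict = field(default_factory=dict)  # partner site -> n unique


@dataclass
class SiteCall:
    chain_id: str
    sites: tuple[int, ...]  # one element when unambiguous
    status: str  # unambiguous | ambiguous_range | unsupported
    replicates: tuple[str, ...] = ()
    methods: tuple[str, ...] = ()

    @property
    def site(self) -> int:
        return self.sites[0]


def _fragment_id(frag: FragmentIon) -> tuple:
    return (frag.ion_type, frag.index, round(frag.neutral_mass, 4))


def _n_isomer_unique(match: ProteoformSpectrumMatch, partner: Proteoform,
                     frag_tol_ppm: float, z_radical: bool) -> int:
    """Matched fragments whose mass does not occur in the positional isomer.

    Only fragments that theoretically discriminate the two payload placements
    count as isomer-unique; shared-mass fragments (detected or not in the
    partner's spectra) carry no positional information.
    """
    scheme = ActivationScheme(match.activation)
    theirs = np.sort(fragment_arrays(partner, scheme, z_radical)[4])
    n = 0
    for frag, _, _ in match.matched_fragments:
        tol = frag.neutral_mass * frag_tol_ppm * 1e-6
        lo = np.searchsorted(theirs, frag.neutral_mass - tol)
        hi = np.searchsorted(theirs, frag.neutral_mass + tol)
        if hi == lo:
            n += 1
    return n


def build_site_evidence(accepted: dict[tuple, list[ProteoformSpectrumMatch]],
                        allow_cterm_K: bool = False,
                        co_elution_minutes: float = 0.2,
                        frag_tol_ppm: float = 10.0,
                        z_radical: bool = True) -> list[SiteEvidence]:
    """Derive per-replicate site evidence from replicate-filtered matches.

    Positional isomers (same peptide and payload count, different sites) whose
    scans co-elute within ``co_elution_minutes`` additionally get counts of
    matched site-discriminating fragments unique to each isomer, feeding the
    isomer rule.
    """
    evidence: list[SiteEvidence] = []
    # group accepted proteoforms by (peptide, payload count) to find isomers
    groups: dict[tuple, list[tuple]] = defaultdict(list)
    for key in accepted:
        groups[(key[0], key[1], key[2], len(key[3]))].append(key)
    rts = {key: np.median([m.retention_time for m in ms])
           for key, ms in accepted.items()}
    forms = {key: ms[0].proteoform for key, ms in accepted.items()}
    for key, ms in accepted.items():
        chain_id = key[0]
        partners = [k for k in groups[(key[0], key[1], key[2], len(key[3]))]
                    if k != key and abs(rts[k] - rts[key]) <= co_elution_minutes]
        for m in ms:
            isomer_unique = {
                k[3]: _n_isomer_unique(m, forms[k], frag_tol_ppm, z_radical)
                for k in partners
            }
            for site in m.proteoform.payload_sites:
                brackets = bracketing_fragments(m, site, allow_cterm_K)
                rng = consistent_sites(m, site, allow_cterm_K)
                evidence.append(SiteEvidence(
                    chain_id=chain_id, site=site, replicate_id=m.replicate_id,
                    method=m.activation,
                    bracketing=tuple(_fragment_id(f) for f in brackets),
                    consistent_range=rng, peptide_key=key,
                    isomer_unique=isomer_unique))
    return evidence


DEFAULT_RULES = {
    "min_bracketing": 2,
    "min_replicates_unambiguous": 2,
    "isomer_min_unique": 4,
    "isomer_min_replicates": 3,
}


def call_sites(evidence: list[SiteEvidence], rules: dict | None = None
               ) -> list[SiteCall]:
    """Apply the localization rules to site evidence.

    A site is unambiguous when at least ``min_bracketing`` bracketing
    fragments pin it (consistent range collapses to the site itself) in at
    least ``min_replicates_unambiguous`` replicates; a site with co-eluting
    positional isomers additionally needs ``isomer_min_unique`` fragments
    unique against every partner in ``isomer_min_replicates`` replicates.
    Unpinned payloads are reported as the smallest consistent lysine range.
    """
    r = dict(DEFAULT_RULES)
    r.update(rules or {})
    # species-level isomer gate: a peptide species with co-eluting positional
    # isomers is usable for unambiguous calls only when, against every
    # partner, it shows >= isomer_min_unique discriminating fragments in
    # >= isomer_min_replicates replicates
    def species_key(ev: SiteEvidence) -> tuple:
        return ev.peptide_key or ("", ev.chain_id, ev.site)

    by_species: dict[tuple, list[SiteEvidence]] = defaultdict(list)
    for ev in evidence:
        by_species[species_key(ev)].append(ev)
    species_ok: dict[tuple, bool] = {}
    species_partners: dict[tuple, set] = {}
    for key, evs in by_species.items():
        partners = {p for ev in evs for p in ev.isomer_unique}
        species_partners[key] = partners
        ok = True
        for partner in partners:
            reps = {ev.replicate_id for ev in evs
                    if ev.isomer_unique.get(partner, 0) >= r["isomer_min_unique"]}
            if len(reps) < r["isomer_min_replicates"]:
                ok = False
        species_ok[key] = ok
    by_site: dict[tuple, list[SiteEvidence]] = defaultdict(list)
    for ev in evidence:
        by_site[(ev.chain_id, ev.site)].append(ev)
    calls: list[SiteCall] = []
    ambiguous: dict[tuple, list[SiteEvidence]] = defaultdict(list)
    for (chain_id, site), evs in sorted(by_site.items()):
        supporting = {
            ev.replicate_id for ev in evs
            if len(ev.bracketing) >= r["min_bracketing"]
            and ev.consistent_range == (site,)
            and species_ok[species_key(ev)]
        }
        if len(supporting) >= r["min_replicates_unambiguous"]:
            calls.append(SiteCall(
                chain_id, (site,), "unambiguous",
                tuple(sorted(supporting)),
                tuple(sorted({ev.method for ev in evs}))))
        else:
            for ev in evs:
                if len(ev.consistent_range) > 1:
                    rng = ev.consistent_range
                elif not species_ok[species_key(ev)]:
                    # unresolved co-eluting isomers: span of the isomer sites
                    span = {site}
                    for partner in species_partners[species_key(ev)]:
                        span.update(partner)
                    rng = tuple(sorted(span))
                else:
                    rng = (site,)
                ambiguous[(chain_id, rng)].append(ev)
    unambiguous_sites = {(c.chain_id, s) for c in calls for s in c.sites}
    for (chain_id, rng), evs in sorted(ambiguous.items()):
        if all((chain_id, s) in unambiguous_sites for s in rng):
            continue  # already resolved by better-supported evidence
        calls.append(SiteCall(
            chain_id, rng, "ambiguous_range",
            tuple(sorted({ev.replicate_id for ev in evs})),
            tuple(sorted({ev.method for ev in evs}))))
    return calls


def census(calls: list[SiteCall], antibody: list[ChainSequence],
           accepted: dict[tuple, list[ProteoformSpectrumMatch]] | None = None
           ) -> dict:
    """Summarise site calls per chain role and per antibody.

    Per-antibody totals multiply unique unambiguous positions by the chain
    copy number (two heavy + two light chains for an IgG).
    """
    roles = {c.chain_id: c.role for c in antibody}
    copies = {c.chain_id: c.copies_per_antibody for c in antibody}
    unamb: dict[str, set] = defaultdict(set)
    amb: dict[str, set] = defaultdict(set)
    for call in calls:
        role = roles.get(call.chain_id, "unknown")
        if call.status == "unambiguous":
            unamb[role].add((call.chain_id, call.site))
        elif call.status == "ambiguous_range":
            amb[role].add((call.chain_id, call.sites))
    per_antibody = sum(
        copies.get(chain_id, 1) for role in unamb for chain_id, _ in unamb[role])
    multi = []
    if accepted:
        for key in sorted(accepted):
            if len(key[3]) >= 2:
                multi.append({"chain_id": key[0], "start": key[1], "end": key[2],
                              "sites": key[3]})
    return {
        "unambiguous_heavy": len(unamb["heavy"]),
        "unambiguous_light": len(unamb["light"]),
        "ambiguous_heavy": len(amb["heavy"]),
        "ambiguous_light": len(amb["light"]),
        "per_antibody_unambiguous": per_antibody,
        "multi_payload_peptides": multi,
    }


# ---------------------------------------------------------------------------
# Decoy-based confidence (stand-in for an engine confidence score)

def make_decoy_database(forms: list[Proteoform], seed: int = 0
                        ) -> list[Proteoform]:
    """Shuffled-sequence decoy proteoforms for FDR estimation.

    Each peptide's internal residues are permuted (termini fixed so digest
    boundaries stay plausible); payload placements are re-derived on the
    shuffled lysine positions with the same payload count where possible.
    """
    rng = random.Random(seed)
    decoys = []
    cache: dict[tuple, Peptide] = {}
    for form in forms:
        pep = form.peptide
        pkey = (pep.chain_id, pep.start, pep.end)
        if pkey not in cache:
            inner = list(pep.sequence[1:-1])
            rng.shuffle(inner)
            seq = pep.sequence[0] + "".join(inner) + pep.sequence[-1]
            cache[pkey] = Peptide("decoy_" + pep.chain_id, pep.start, pep.end,
                                  seq, seq[:-1].count("K"))
        dpep = cache[pkey]
        eligible = list(dpep.candidate_sites())
        n = min(form.n_payloads, len(eligible))
        decoys.append(Proteoform(dpep, frozenset(eligible[:n]),
                                 form.payload_mass))
    return decoys
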