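"""Ground-truthed synthetic ADC runs.

The generator emulates the study conditions of a limited Lys-C digest of a
lysine-conjugated ADC analysed by reporter-triggered middle-down LC-MS/MS:

* a conjugated-antibody population with Poisson-distributed payload counts
  around a mean DAR of 3.5 spread over the 92 candidate sites;
* one limited digest of that population (partial cleavage at unconjugated
  lysines; cleavage after a conjugated lysine is blocked), shared by all
  technical replicates of the same sample;
* per replicate, a data-dependent acquisition loop: MS1 survey scans with
  averagine-shaped isotope envelopes, low-resolution HCD screening scans in
  which conjugated precursors yield the three DM1 reporter ions and
  payload-stripped backbone fragments, a reporter-triggered high-resolution
  EThcD/UVPD scan retaining payloads on fragments, and dynamic exclusion;
* payload-dependent retention shifts (more payloads elute later) and
  configurable positional-isomer offsets;
* a cleavage-suppression list emulating peptide regions where backbone
  fragments between adjacent lysines are not observed, producing genuinely
  ambiguous adjacent-lysine cases.

Every planted quantity is recorded in a :class:`GroundTruth` so each pipeline
stage can be scored without instrument data.  Fixed seeds give identical
outputs.
"""

from __future__ import annotations

import json
import zlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import NEUTRON_SPACING, PAYLOAD_MASS, PROTON, mz_from_neutral
from .deconv import averagine_envelope
from .fragments import fragment_arrays
from .sequence import (N_TERM, ChainSequence, Peptide, Proteoform,
                       load_trastuzumab)
from .spectra import ReporterConfig, Spectrum, detect_reporters, write_mzml


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic T-DM1-like experiment."""

    chains: list[ChainSequence] = field(default_factory=load_trastuzumab)
    mean_dar: float = 3.5
    n_molecules: int = 12
    n_replicates: int = 5
    triggered_activation: str = "UVPD"
    site_weights: dict | None = None  # (chain_id, position) -> weight
    payload_mass: float = PAYLOAD_MASS
    # limited digestion
    p_cleave: float = 0.5
    min_obs_mass: float = 600.0
    max_obs_mass: float = 20000.0
    # chromatography (minutes)
    gradient_minutes: float = 12.0
    elution_start: float = 1.0
    elution_span: float = 8.0
    rt_shift_per_payload: float = 0.8
    isomer_rt_spread: float = 0.4
    peak_sigma_minutes: float = 0.06
    replicate_rt_jitter: float = 0.02
    # acquisition
    top_n: int = 5
    ms1_duration: float = 0.010
    hcd_duration: float = 0.003
    triggered_duration: float = 0.012
    exclusion_repeats: int = 2
    exclusion_window_s: float = 7.0
    exclusion_duration_s: float = 30.0
    resolutions: dict = field(default_factory=lambda: {
        "MS1": 60000, "HCD": 30000, "triggered": 240000})
    # spectra
    reporters: ReporterConfig = field(default_factory=ReporterConfig)
    p_detect_fragment: float = 0.6
    max_fragments_per_scan: int = 250
    p_detect_hcd_fragment: float = 0.3
    p_hcd_payload_retention: float = 0.0
    p_precursor_mono_error: float = 0.1
    mz_jitter_ppm: float = 1.5
    intensity_cv: float = 0.05
    noise_peaks_per_scan: int = 30
    abundance_sigma: float = 0.4
    # regions where fragments between adjacent lysines are never observed
    # (chain_id, left site, right site), chain coordinates
    suppress_between: list = field(default_factory=lambda: [("HC", 412, 417)])
    rng_seed: int = 17


@dataclass
class SpeciesRecord:
    """One distinct digest proteoform in the simulated sample."""

    proteoform: Proteoform
    copies: int
    abundance: float
    charge: int
    rt_apex: float
    suppressed_bonds: tuple[int, ...] = ()

    @property
    def key(self) -> tuple:
        pep = self.proteoform.peptide
        return (pep.chain_id, pep.start, pep.end,
                tuple(sorted(self.proteoform.payload_sites)))


@dataclass
class GroundTruth:
    """Everything the generator planted, sufficient to score the pipeline."""

    molecules: list
    species: dict
    trigger_events: dict  # replicate -> list of {species, hcd, triggered}
    expected_unambiguous: list
    expected_ambiguous_ranges: list
    planted_sites: list

    def to_json(self, path: str | Path) -> None:
        payload = {
            "molecules": [sorted(map(list, m)) for m in self.molecules],
            "species": self.species,
            "trigger_events": self.trigger_events,
            "expected_unambiguous": [list(s) for s in self.expected_unambiguous],
            "expected_ambiguous_ranges":
                [[c, list(r)] for c, r in self.expected_ambiguous_ranges],
            "planted_sites": [list(s) for s in self.planted_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def _k(key: tuple) -> str:
        chain, start, end, sites = key
        return f"{chain}:{start}-{end}:" + ",".join(map(str, sites))


def _stable_rng(seed: int, *parts) -> np.random.Generator:
    tag = zlib.crc32("|".join(map(str, parts)).encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, tag])


def simulate_conjugation(cfg: SimulationConfig, rng=None) -> list[set]:
    """Sample conjugated antibody molecules.

    Each molecule's payload count is Poisson(``mean_dar``) truncated at the
    number of candidate sites; sites are drawn without replacement with
    probabilities proportional to ``site_weights`` (uniform by default) over
    every (chain, copy, site) of the antibody.  Returns one set of
    ``(chain_id, copy, position)`` per molecule.
    """
    rng = rng or _stable_rng(cfg.rng_seed, "conjugation")
    all_sites = []
    weights = []
    for chain in cfg.chains:
        positions = (N_TERM,) + chain.lysine_positions
        for copy in range(1, chain.copies_per_antibody + 1):
            for pos in positions:
                all_sites.append((chain.chain_id, copy, pos))
                w = 1.0
                if cfg.site_weights:
                    w = cfg.site_weights.get((chain.chain_id, pos), 0.0)
                weights.append(w)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("site_weights must have positive total mass")
    probs = weights / weights.sum()
    molecules = []
    for _ in range(cfg.n_molecules):
        n = min(int(rng.poisson(cfg.mean_dar)), int((probs > 0).sum()))
        chosen = rng.choice(len(all_sites), size=n, replace=False, p=probs)
        molecules.append({all_sites[i] for i in chosen})
    return molecules


def _digest_molecule(chain: ChainSequence, conjugated: set[int],
                     p_cleave: float, rng) -> list[tuple[int, int]]:
    """Partial Lys-C digest of one chain copy; conjugated K are never cut."""
    cuts = [k for k in chain.lysine_positions
            if k < len(chain) and k not in conjugated and rng.random() < p_cleave]
    bounds = [0] + cuts + [len(chain)]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


def _suppressed_bonds(pep: Peptide, payload_sites: frozenset[int],
                      suppress_between) -> tuple[int, ...]:
    bonds: list[int] = []
    for chain_id, a, b in suppress_between:
        if pep.chain_id != chain_id:
            continue
        if not (pep.start <= a <= pep.end and pep.start <= b <= pep.end):
            continue
        if a not in payload_sites and b not in payload_sites:
            continue
        la, lb = pep.to_local(a), pep.to_local(b)
        bonds.extend(range(la, lb))
    return tuple(sorted(set(bonds)))


def digest_population(cfg: SimulationConfig, molecules) -> list[SpeciesRecord]:
    """One limited digest of the molecule population, grouped into species.

    All replicates of a sample share this digest (one sample, several runs).
    """
    rng = _stable_rng(cfg.rng_seed, "digest")
    chains = {c.chain_id: c for c in cfg.chains}
    counts: dict[tuple, int] = defaultdict(int)
    for mol in molecules:
        per_copy: dict[tuple, set[int]] = defaultdict(set)
        for chain_id, copy, pos in mol:
            per_copy[(chain_id, copy)].add(pos)
        for chain in cfg.chains:
            for copy in range(1, chain.copies_per_antibody + 1):
                conj = per_copy.get((chain.chain_id, copy), set())
                for start, end in _digest_molecule(chain, conj, cfg.p_cleave, rng):
                    sites = frozenset(
                        p for p in conj
                        if (p == N_TERM and start == 1) or start <= p <= end)
                    counts[(chain.chain_id, start, end, tuple(sorted(sites)))] += 1
    species = []
    for (chain_id, start, end, sites), n in sorted(counts.items()):
        chain = chains[chain_id]
        seq = chain.residues[start - 1:end]
        pep = Peptide(chain_id, start, end, seq, seq[:-1].count("K"))
        form = Proteoform(pep, frozenset(sites), cfg.payload_mass)
        if not (cfg.min_obs_mass <= form.neutral_mass <= cfg.max_obs_mass):
            continue
        srng = _stable_rng(cfg.rng_seed, "species", chain_id, start, end)
        base_rt = cfg.elution_start + srng.uniform(0, cfg.elution_span)
        site_rng = _stable_rng(cfg.rng_seed, "sites", chain_id, start, end,
                               *sorted(sites))
        offset = (site_rng.uniform(-cfg.isomer_rt_spread, cfg.isomer_rt_spread)
                  if sites else 0.0)
        rt = base_rt + cfg.rt_shift_per_payload * len(sites) + offset
        abundance = n * float(site_rng.lognormal(0.0, cfg.abundance_sigma))
        charge = int(np.clip(round(form.neutral_mass / 1300) + 1, 1, 30))
        species.append(SpeciesRecord(
            form, n, abundance, charge, rt,
            _suppressed_bonds(pep, frozenset(sites), cfg.suppress_between)))
    return species


def _jitter(rng, mz, cfg):
    return mz * (1 + rng.normal(0, cfg.mz_jitter_ppm * 1e-6, np.shape(mz)))


def _noise_peaks(rng, cfg, scale, lo=300.0, hi=2000.0):
    n = cfg.noise_peaks_per_scan
    return rng.uniform(lo, hi, n), rng.uniform(0.002, 0.02, n) * scale


class _Acquisition:
    """DDA bookkeeping (dynamic exclusion) for one run."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.selections: dict[tuple, list[float]] = defaultdict(list)
        self.excluded_until: dict[tuple, float] = {}

    def selectable(self, key, t_minutes: float) -> bool:
        return t_minutes >= self.excluded_until.get(key, -1.0)

    def record(self, key, t_minutes: float) -> None:
        cfg = self.cfg
        window = cfg.exclusion_window_s / 60.0
        times = [x for x in self.selections[key] if t_minutes - x <= window]
        times.append(t_minutes)
        self.selections[key] = times
        if len(times) >= cfg.exclusion_repeats:
            self.excluded_until[key] = t_minutes + cfg.exclusion_duration_s / 60.0


def _fragment_envelope(rng, cfg, neutral, charge, scale):
    env = averagine_envelope(max(neutral, 60.0), 1e-3, grid=5.0)
    mono = mz_from_neutral(neutral, charge)
    grid = mono + np.arange(env.size) * NEUTRON_SPACING / charge
    inten = env * scale * (1 + rng.normal(0, cfg.intensity_cv, env.size))
    return _jitter(rng, grid, cfg), np.clip(inten, 0, None)


def simulate_run(cfg: SimulationConfig, species: list[SpeciesRecord],
                 replicate_id: str, rng=None):
    """One LC-MS/MS replicate over a digested population.

    Returns ``(spectra, trigger_events)`` where each trigger event records the
    species, the screening HCD scan and the triggered scan it fired.
    """
    rng = rng or _stable_rng(cfg.rng_seed, "run", replicate_id)
    acq = _Acquisition(cfg)
    spectra: list[Spectrum] = []
    events = []
    scan_no = 0
    rt_jit = {s.key: rng.normal(0, cfg.replicate_rt_jitter) for s in species}
    frag_cache: dict[tuple, tuple] = {}
    t = 0.0
    scheme = cfg.triggered_activation
    while t < cfg.gradient_minutes:
        # --- MS1 survey scan
        scan_no += 1
        mzs, ints = [], []
        eluting = []
        for s in species:
            apex = s.rt_apex + rt_jit[s.key]
            x = (t - apex) / cfg.peak_sigma_minutes
            if abs(x) > 4:
                continue
            inten = s.abundance * np.exp(-0.5 * x * x)
            eluting.append((inten, s))
            env = averagine_envelope(s.proteoform.neutral_mass, 1e-3, grid=5.0)
            mono = mz_from_neutral(s.proteoform.neutral_mass, s.charge)
            grid = mono + np.arange(env.size) * NEUTRON_SPACING / s.charge
            mzs.append(_jitter(rng, grid, cfg))
            ints.append(np.clip(
                env * inten * (1 + rng.normal(0, cfg.intensity_cv, env.size)),
                0, None))
        nm, ni = _noise_peaks(rng, cfg, max([e[0] for e in eluting], default=1.0))
        mzs.append(nm)
        ints.append(ni)
        spectra.append(Spectrum(
            f"{replicate_id}.scan={scan_no}", 1, np.concatenate(mzs),
            np.concatenate(ints), t, "NONE",
            resolution_setting=cfg.resolutions["MS1"]))
        t += cfg.ms1_duration
        # --- data-dependent MS2
        eluting.sort(key=lambda e: (-e[0], e[1].key))
        picked = [e for e in eluting
                  if e[0] >= 0.02 * e[1].abundance and acq.selectable(e[1].key, t)]
        for inten, s in picked[:cfg.top_n]:
            acq.record(s.key, t)
            form = s.proteoform
            prec_mono_mz = mz_from_neutral(form.neutral_mass, s.charge)
            prec_mz = prec_mono_mz
            if rng.random() < cfg.p_precursor_mono_error:
                prec_mz += rng.choice([-1, 1]) * NEUTRON_SPACING / s.charge
            conjugated = form.n_payloads > 0
            # HCD screening scan: reporters (conjugated only) + payload-
            # stripped b/y backbone fragments
            scan_no += 1
            hmz, hint = [], []
            if conjugated:
                rep_scale = inten * rng.uniform(0.5, 1.0)
                for r_mz, frac in zip(sorted(cfg.reporters.reporter_mzs),
                                      (0.4, 0.6, 1.0)):
                    hmz.append(_jitter(rng, np.array([r_mz]), cfg))
                    hint.append(np.array([rep_scale * frac]))
            stripped = Proteoform(form.peptide, frozenset(), cfg.payload_mass)
            skey = ("hcd", s.key, cfg.p_hcd_payload_retention)
            if skey not in frag_cache:
                src = form if rng.random() < cfg.p_hcd_payload_retention else stripped
                frag_cache[skey] = fragment_arrays(src, "HCD")
            _, _, _, _, fneutral, _ = frag_cache[skey]
            detected = rng.random(fneutral.size) < cfg.p_detect_hcd_fragment
            for fn in fneutral[detected]:
                zf = max(1, min(2, s.charge))
                hmz.append(_jitter(rng, np.array([mz_from_neutral(fn, zf)]), cfg))
                hint.append(np.array([inten * 0.3 * rng.lognormal(0, 0.6)]))
            nm, ni = _noise_peaks(rng, cfg, inten)
            hmz.append(nm)
            hint.append(ni * 0.05)
            hcd_scan = Spectrum(
                f"{replicate_id}.scan={scan_no}", 2, np.concatenate(hmz),
                np.concatenate(hint), t, "HCD", precursor_mz=prec_mz,
                precursor_charge=s.charge,
                resolution_setting=cfg.resolutions["HCD"])
            spectra.append(hcd_scan)
            t += cfg.hcd_duration
            # --- reporter-triggered high-resolution scan
            if cfg.reporters.trigger_mz not in detect_reporters(hcd_scan,
                                                                cfg.reporters):
                continue
            scan_no += 1
            fkey = ("trig", s.key)
            if fkey not in frag_cache:
                names, termini, index, cleav, neutral, paycount = \
                    fragment_arrays(form, scheme)
                keep = ~np.isin(cleav, np.asarray(s.suppressed_bonds, dtype=int))
                frag_cache[fkey] = (neutral[keep],)
            (tneutral,) = frag_cache[fkey]
            detected = np.nonzero(rng.random(tneutral.size)
                                  < cfg.p_detect_fragment)[0]
            scales = rng.lognormal(0, 0.6, detected.size)
            if detected.size > cfg.max_fragments_per_scan:
                top = np.argsort(-scales)[:cfg.max_fragments_per_scan]
                detected, scales = detected[top], scales[top]
            tmz, tint = [], []
            for fi, sc in zip(detected, scales):
                fn = tneutral[fi]
                zf = int(np.clip(round(fn / 1300) + 1, 1, s.charge))
                g, i2 = _fragment_envelope(rng, cfg, fn, zf, inten * sc)
                tmz.append(g)
                tint.append(i2)
            nm, ni = _noise_peaks(rng, cfg, inten * 0.5)
            tmz.append(nm)
            tint.append(ni)
            trig_scan = Spectrum(
                f"{replicate_id}.scan={scan_no}", 2, np.concatenate(tmz),
                np.concatenate(tint), t, scheme, precursor_mz=prec_mz,
                precursor_charge=s.charge,
                resolution_setting=cfg.resolutions["triggered"])
            spectra.append(trig_scan)
            events.append({"species": GroundTruth._k(s.key),
                           "hcd": hcd_scan.scan_id,
                           "triggered": trig_scan.scan_id})
            t += cfg.triggered_duration
    return spectra, events


def _expected_census(cfg: SimulationConfig, molecules, species,
                     trigger_events, min_replicates=3, max_payloads=2):
    """Derive the recoverable site census from the planted truth.

    A planted site is expected unambiguous when some species carrying it (with
    at most ``max_payloads`` payloads, and with discriminating cleavages not
    suppressed) was triggered in at least ``min_replicates`` replicates; sites
    whose every observation falls in a suppressed adjacent-lysine region are
    expected as ambiguous ranges instead.
    """
    planted = sorted({(chain_id, pos) for mol in molecules
                      for chain_id, _, pos in mol})
    by_species_reps: dict[str, set] = defaultdict(set)
    for rep, events in trigger_events.items():
        for ev in events:
            by_species_reps[ev["species"]].add(rep)
    recs = {GroundTruth._k(s.key): s for s in species}
    unamb, amb = set(), set()
    for skey, reps in by_species_reps.items():
        s = recs[skey]
        if len(reps) < min_replicates or s.proteoform.n_payloads > max_payloads:
            continue
        pep = s.proteoform.peptide
        cands = set(pep.candidate_sites())
        for site in s.proteoform.payload_sites:
            pinned = True
            for chain_id, a, b in cfg.suppress_between:
                if pep.chain_id == chain_id and site in (a, b):
                    other = b if site == a else a
                    if other in cands and other not in s.proteoform.payload_sites:
                        pinned = False
                        amb.add((pep.chain_id, (min(a, b), max(a, b))))
            if pinned:
                unamb.add((pep.chain_id, site))
    # a range is only expected when the ambiguity survives: ranges whose
    # member sites are all independently pinned elsewhere are resolved
    amb = {(chain, rng) for chain, rng in amb
           if not all((chain, s) in unamb for s in rng)}
    return planted, sorted(unamb), sorted(amb)


def simulate_experiment(cfg: SimulationConfig, out_dir: str | Path | None = None
                        ):
    """Full synthetic experiment: conjugation, digest, all replicate runs.

    Returns ``(runs, truth)`` where ``runs`` maps replicate id to the list of
    spectra; when ``out_dir`` is given each run is also written as mzML and
    the ground truth as JSON.
    """
    molecules = simulate_conjugation(cfg)
    species = digest_population(cfg, molecules)
    runs = {}
    trigger_events = {}
    for i in range(1, cfg.n_replicates + 1):
        rep = f"rep{i}"
        spectra, events = simulate_run(cfg, species, rep)
        runs[rep] = spectra
        trigger_events[rep] = events
    planted, unamb, amb = _expected_census(cfg, molecules, species,
                                           trigger_events)
    truth = GroundTruth(
        molecules=molecules,
        species={GroundTruth._k(s.key): {
            "sites": sorted(s.proteoform.payload_sites),
            "neutral_mass": s.proteoform.neutral_mass,
            "charge": s.charge, "rt_apex": s.rt_apex,
            "abundance": s.abundance, "copies": s.copies,
        } for s in species},
        trigger_events=trigger_events,
        expected_unambiguous=unamb,
        expected_ambiguous_ranges=amb,
        planted_sites=planted,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep, spectra in runs.items():
            write_mzml(spectra, out_dir / f"{rep}.mzML")
        truth.to_json(out_dir / "ground_truth.json")
    return runs, truth
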