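"""Charge-state deconvolution by averagine isotope-envelope fitting.

High-resolution MS2 (and MS1) spectra of middle-down peptides contain
isotopically resolved multi-charge envelopes.  This module converts them to
neutral monoisotopic masses by fitting theoretical averagine isotope
distributions: for each candidate (charge, monoisotopic alignment) the
observed peaks on the expected isotope grid are compared to the theoretical
distribution and the best-scoring assignment is accepted if it passes the
published-style thresholds (fit factor >= 0.80, remainder <= 0.25, S/N >= 3).

Definitions used here (a documented approximation of the vendor algorithm):

* *fit* — normalised dot product (cosine) between observed and theoretical
  envelope intensities on the isotope grid;
* *remainder* — the fraction of theoretical envelope intensity at grid slots
  with no observed peak;
* *S/N* — seed-peak intensity over 1.4826x the median absolute deviation of
  non-envelope peak intensities in the surrounding 100-Th window.

Extraction is greedy, seeded from the most intense unconsumed peak; peaks
consumed by an accepted envelope are removed before the next search, so the
result is deterministic for a given scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import NEUTRON_SPACING, PAYLOAD_COMPOSITION, PAYLOAD_MASS, PROTON

def _element_isotopes(element: str) -> tuple[float, ...]:
    """Isotope abundances of an element on a unit-spaced mass-number grid
    (lightest isotope first), from the NIST table shipped with pyteomics."""
    from pyteomics.mass import nist_mass

    entries = {a: ab for a, (_, ab) in nist_mass[element].items()
               if a != 0 and ab > 0}
    numbers = sorted(entries)
    lo, hi = numbers[0], numbers[-1]
    return tuple(entries.get(a, 0.0) for a in range(lo, hi + 1))


_ISOTOPES = {el: _element_isotopes(el)
             for el in ("C", "H", "N", "O", "S", "Cl")}

#: Averagine pseudo-residue: average elemental composition per 111.1254 Da.
AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

_MAXLEN = 256  # isotope grid length cap (covers > 60 kDa)


def _poly_pow(p: tuple[float, ...], n: int) -> np.ndarray:
    """(sum_k p_k x^k)^n by binary exponentiation, truncated to _MAXLEN."""
    result = np.array([1.0])
    base = np.asarray(p, dtype=float)
    while n:
        if n & 1:
            result = np.convolve(result, base)[:_MAXLEN]
        n >>= 1
        base = np.convolve(base, base)[:_MAXLEN]
    return result


def isotope_pattern(composition: dict[str, int]) -> np.ndarray:
    """Aggregated isotope distribution of an elemental composition.

    Returns relative abundances on a unit-spaced grid starting at the
    monoisotopic peak, normalised to sum 1.
    """
    dist = np.array([1.0])
    for element, count in composition.items():
        if count <= 0:
            continue
        dist = np.convolve(dist, _poly_pow(_ISOTOPES[element], int(count)))[:_MAXLEN]
    return dist / dist.sum()


def averagine_composition(neutral_mass: float) -> dict[str, int]:
    """Integer averagine composition scaled to ``neutral_mass``."""
    n = neutral_mass / AVERAGINE_MASS
    return {el: int(round(cnt * n)) for el, cnt in AVERAGINE.items()}


@lru_cache(maxsize=4096)
def _averagine_envelope_cached(mass_key: int, truncate: float) -> np.ndarray:
    dist = isotope_pattern(averagine_composition(float(mass_key)))
    keep = np.nonzero(dist >= truncate)[0]
    last = keep[-1] + 1 if keep.size else 1
    dist = dist[:last]
    return dist / dist.sum()


def averagine_envelope(neutral_mass: float, truncate: float = 1e-4,
                       grid: float = 1.0) -> np.ndarray:
    """Theoretical averagine isotope distribution for a neutral mass.

    Abundances start at the monoisotopic isotopologue, are truncated once they
    fall below ``truncate`` relative abundance, and sum to 1.  ``grid``
    coarsens the mass at which the pattern is computed (a cache key), which is
    irrelevant below ~25 Da and speeds up repeated calls.
    """
    if neutral_mass <= 0:
        raise ValueError("mass must be positive")
    key = int(round(neutral_mass / grid)) * int(grid) if grid > 1 else int(round(neutral_mass))
    return _averagine_envelope_cached(max(key, 1), truncate)


def apex_offset(neutral_mass: float, n_payloads: int = 0,
                payload_composition: dict[str, int] | None = None,
                payload_mass: float = PAYLOAD_MASS) -> int:
    """Isotopologue index of the most abundant peak of a species.

    The peptide part is modelled by averagine; when ``n_payloads`` > 0 and a
    payload elemental composition is known (default DM1-MCC, which carries Cl
    and S with strong M+2 isotopes) the payload part is convolved in exactly.
    """
    peptide_part = neutral_mass - n_payloads * payload_mass
    dist = isotope_pattern(averagine_composition(peptide_part))
    comp = PAYLOAD_COMPOSITION if payload_composition is None else payload_composition
    if n_payloads and comp:
        total = {el: cnt * n_payloads for el, cnt in comp.items()}
        dist = np.convolve(dist, isotope_pattern(total))[:_MAXLEN]
    return int(np.argmax(dist))


def apex_mz(neutral_mass: float, charge: int, n_payloads: int = 0,
            payload_composition: dict[str, int] | None = None,
            payload_mass: float = PAYLOAD_MASS) -> float:
    """m/z of the most abundant isotopologue — the value an EIC is drawn at."""
    k = apex_offset(neutral_mass, n_payloads, payload_composition, payload_mass)
    return (neutral_mass + k * NEUTRON_SPACING + charge * PROTON) / charge


@dataclass(frozen=True)
class IsotopeEnvelope:
    charge: int
    monoisotopic_mz: float
    peak_indices: tuple[int, ...]
    fit_score: float
    snr: float
    remainder: float


@dataclass(frozen=True)
class DeconvolutedMass:
    neutral_mass: float
    total_intensity: float
    charge: int
    scan_id: str | None = None
    envelope: IsotopeEnvelope | None = None


def _candidate_fit(mz, inten, alive, seed_idx, z, mono_mzs, theo, tol_mz,
                   min_peaks):
    """Score several monoisotopic alignments of one charge at once.

    Each isotope-grid slot takes its nearest peak within ``tol_mz`` (if
    alive).  Returns the best alignment as
    ``(fit, remainder, obs, matched, mono_mz)`` or ``None``.
    """
    k = np.arange(theo.size) * (NEUTRON_SPACING / z)
    grid = np.asarray(mono_mzs)[:, None] + k[None, :]  # (J, K)
    pos = np.searchsorted(mz, grid.ravel()).reshape(grid.shape)
    left = np.clip(pos - 1, 0, mz.size - 1)
    right = np.clip(pos, 0, mz.size - 1)
    use_right = np.abs(mz[right] - grid) < np.abs(mz[left] - grid)
    nearest = np.where(use_right, right, left)
    ok = (np.abs(mz[nearest] - grid) <= tol_mz) & alive[nearest]
    matched = np.where(ok, nearest, -1)
    n_matched = ok.sum(axis=1)
    viable = ((matched == seed_idx).any(axis=1)
              & (n_matched >= min(min_peaks, theo.size)))
    if not viable.any():
        return None
    obs = np.where(ok, inten[nearest], 0.0)
    norms = np.linalg.norm(obs, axis=1) * np.linalg.norm(theo)
    with np.errstate(invalid="ignore", divide="ignore"):
        fits = np.where(norms > 0, obs @ theo / norms, 0.0)
    remainders = ((~ok) * theo).sum(axis=1)
    fits = np.where(viable, fits, -1.0)
    j = int(np.argmax(fits))
    return (float(fits[j]), float(remainders[j]), obs[j], matched[j],
            float(np.asarray(mono_mzs)[j]))


def _neighbour_charges(mz, alive, seed, zmin, zmax, tol_mz, n_neighbours=4):
    """Charges implied by the spacing from the seed to nearby alive peaks."""
    seed_mz = mz[seed]
    cands: list[int] = []
    for lo, hi, take in (
            (np.searchsorted(mz, seed_mz - 1.1), seed, -1),
            (seed + 1, np.searchsorted(mz, seed_mz + 1.1), +1)):
        idx = np.arange(lo, hi)
        idx = idx[alive[idx]]
        if take < 0:
            idx = idx[::-1]
        for i in idx[:n_neighbours]:
            gap = abs(mz[i] - seed_mz)
            if gap <= 0:
                continue
            z = int(round(NEUTRON_SPACING / gap))
            if zmin <= z <= zmax and abs(NEUTRON_SPACING / z - gap) <= tol_mz:
                if z not in cands:
                    cands.append(z)
    return cands


def deconvolute(scan, charge_range: tuple[int, int] = (1, 20),
                tol_ppm: float = 10.0, fit_min: float = 0.80,
                remainder_max: float = 0.25, snr_min: float = 3.0,
                min_peaks: int = 2, envelope_truncate: float = 1e-3,
                max_envelopes: int | None = None) -> list[DeconvolutedMass]:
    """Extract neutral monoisotopic masses from a centroided scan.

    ``scan`` is anything with sorted ``mz``/``intensity`` arrays and a
    ``scan_id`` (see :class:`adcmapper.spectra.Spectrum`).  Returns accepted
    masses in extraction order (most intense envelope first).
    """
    mz = np.asarray(scan.mz, dtype=float)
    inten = np.asarray(scan.intensity, dtype=float)
    if mz.size == 0:
        return []
    alive = np.ones(mz.size, dtype=bool)
    results: list[DeconvolutedMass] = []
    zmin, zmax = charge_range
    while True:
        if max_envelopes is not None and len(results) >= max_envelopes:
            break
        live_idx = np.nonzero(alive)[0]
        if live_idx.size == 0:
            break
        seed = live_idx[np.argmax(inten[live_idx])]
        seed_mz = mz[seed]
        tol_mz = seed_mz * tol_ppm * 1e-6

        def try_charges(charges):
            best = None
            for z in charges:
                step = NEUTRON_SPACING / z
                approx_mass = max((seed_mz - PROTON) * z, 50.0)
                theo = averagine_envelope(approx_mass, envelope_truncate,
                                          grid=25.0)
                apex = int(np.argmax(theo))
                mono_mzs = [seed_mz - j * step
                            for j in range(max(0, apex - 2), apex + 3)
                            if seed_mz - j * step > 0]
                cand = _candidate_fit(mz, inten, alive, seed, z, mono_mzs,
                                      theo, tol_mz, min_peaks)
                if cand is None:
                    continue
                fit, remainder, obs, matched, mono_mz = cand
                key = (round(fit, 6), -round(remainder, 6), obs.sum(), -z)
                if best is None or key > best[0]:
                    best = (key, z, mono_mz, obs, matched, theo, fit, remainder)
            return best

        # charges implied by observed neighbour spacing first; full scan only
        # when none of them yields an acceptable envelope
        quick = _neighbour_charges(mz, alive, seed, zmin, zmax, tol_mz)
        best = try_charges(quick)
        if best is None or best[6] < fit_min or best[7] > remainder_max:
            full = try_charges([z for z in range(zmin, zmax + 1)
                                if z not in quick])
            if full is not None:
                if best is None or full[0] > best[0]:
                    best = full
        accepted = False
        if best is not None:
            _, z, mono_mz, obs, matched, theo, fit, remainder = best
            if fit >= fit_min and remainder <= remainder_max:
                # refine monoisotopic m/z from matched peaks
                ks = np.nonzero(matched >= 0)[0]
                peaks = matched[ks]
                w = inten[peaks]
                mono_ref = float(np.average(mz[peaks] - ks * NEUTRON_SPACING / z,
                                            weights=w))
                # local noise from non-envelope peaks within +/-50 Th
                lo = np.searchsorted(mz, seed_mz - 50.0)
                hi = np.searchsorted(mz, seed_mz + 50.0)
                window = np.arange(lo, hi)
                window = window[alive[window]]
                window = window[~np.isin(window, peaks)]
                if window.size >= 5:
                    # iterated-MAD noise floor: strip outlying (signal) peaks
                    x = inten[window]
                    for _ in range(3):
                        med = np.median(x)
                        mad = 1.4826 * np.median(np.abs(x - med))
                        kept = x[x <= med + 3 * mad]
                        if kept.size == x.size or kept.size < 5:
                            break
                        x = kept
                    med = np.median(x)
                    noise = 1.4826 * np.median(np.abs(x - med))
                    if noise == 0:
                        noise = med
                    snr = float(inten[seed] / noise) if noise > 0 else np.inf
                else:
                    snr = np.inf
                if snr >= snr_min:
                    env = IsotopeEnvelope(z, mono_ref, tuple(int(p) for p in peaks),
                                          fit, snr, remainder)
                    results.append(DeconvolutedMass(
                        neutral_mass=(mono_ref - PROTON) * z,
                        total_intensity=float(w.sum()), charge=z,
                        scan_id=getattr(scan, "scan_id", None), envelope=env))
                    alive[peaks] = False
                    accepted = True
        if not accepted:
            alive[seed] = False
    return results


def masses_to_tsv(masses, path: str | Path) -> None:
    rows = [
        {"scan_id": m.scan_id, "neutral_mass": float(m.neutral_mass),
         "charge": m.charge, "intensity": m.total_intensity}
        for m in masses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def masses_from_tsv(path: str | Path) -> list[DeconvolutedMass]:
    df = pd.read_csv(path, sep="\t")
    return [
        DeconvolutedMass(float(r.neutral_mass), float(r.intensity), int(r.charge),
                         str(r.scan_id))
        for r in df.itertuples()
    ]
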