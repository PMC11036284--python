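"""Centroided spectrum I/O, reporter-ion screening and scan pairing.

The acquisition scheme modelled here interleaves MS1 survey scans with fast
low-resolution HCD MS2 screening scans; when an HCD scan contains the DM1
payload reporter ion (m/z 547.22 by default) the instrument acquires a second,
high-resolution MS2 scan (EThcD or UVPD) on the same precursor.  This module
reads/writes such runs as centroided mzML, detects reporter ions, pairs each
triggered scan with the screening scan that fired it, and builds extracted
ion chromatograms.

mzML is read and written with a compact lxml layer (uncompressed or
zlib-compressed 32/64-bit float arrays, centroided, non-indexed) that
round-trips losslessly; MGF (via pyteomics) is supported for small
plain-text fixtures.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

ACTIVATIONS = ("NONE", "HCD", "EThcD", "UVPD", "UNKNOWN")


@dataclass
class Spectrum:
    """One centroided scan; peaks kept sorted by m/z."""

    scan_id: str
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float  # minutes
    activation: str = "NONE"
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    resolution_setting: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass(frozen=True)
class ReporterConfig:
    """Payload reporter ions screened for in HCD scans."""

    reporter_mzs: tuple[float, ...] = (547.22, 485.22, 453.19)
    trigger_mz: float = 547.22
    tolerance_ppm: float = 20.0
    min_relative_intensity: float = 0.01

    def __post_init__(self):
        if self.trigger_mz not in self.reporter_mzs:
            raise ValueError("trigger_mz must be one of reporter_mzs")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass
class ScanPair:
    """An HCD screening scan linked to the triggered scan on the same precursor."""

    hcd_scan: Spectrum
    triggered_scan: Spectrum
    reporter_hits: tuple[float, ...]

    def __post_init__(self):
        if self.triggered_scan.activation not in ("EThcD", "UVPD"):
            raise ValueError("triggered scan must be EThcD or UVPD")
        if not self.reporter_hits:
            raise ValueError("scan pair requires at least one reporter hit")


# ---------------------------------------------------------------------------
# mzML writing (minimal, centroided, uncompressed 64-bit, pyteomics-readable)

_NS = "http://psi.hupo.org/ms/mzml"

_ACTIVATION_CV = {
    "HCD": [("MS:1000422", "beam-type collision-induced dissociation")],
    "EThcD": [("MS:1000598", "electron transfer dissociation"),
              ("MS:1000422", "beam-type collision-induced dissociation")],
    "UVPD": [("MS:1000435", "photodissociation")],
}


def _cv(parent, accession, name, value="", unit=None):
    el = etree.SubElement(parent, "cvParam", cvRef="MS", accession=accession,
                          name=name, value=str(value))
    if unit:
        el.set("unitAccession", unit[0])
        el.set("unitName", unit[1])
        el.set("unitCvRef", "UO")
    return el


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def write_mzml(spectra: list[Spectrum], path) -> None:
    """Write scans to a minimal centroided mzML file."""
    root = etree.Element("mzML", nsmap={None: _NS}, version="1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cvlist, "cv", id="UO", fullName="UNIT-ONTOLOGY",
                     URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000580", "MSn spectrum")
    run = etree.SubElement(root, "run", id="run")
    speclist = etree.SubElement(run, "spectrumList", count=str(len(spectra)),
                                defaultDataProcessingRef="dp")
    for i, sp in enumerate(spectra):
        el = etree.SubElement(speclist, "spectrum", index=str(i), id=sp.scan_id,
                              defaultArrayLength=str(sp.mz.size))
        _cv(el, "MS:1000511", "ms level", sp.ms_level)
        _cv(el, "MS:1000579" if sp.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if sp.ms_level == 1 else "MSn spectrum")
        _cv(el, "MS:1000127", "centroid spectrum")
        if sp.resolution_setting is not None:
            etree.SubElement(el, "userParam", name="resolution_setting",
                             value=str(sp.resolution_setting))
        scanlist = etree.SubElement(el, "scanList", count="1")
        scan = etree.SubElement(scanlist, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(sp.retention_time)),
            unit=("UO:0000031", "minute"))
        if sp.ms_level == 2:
            plist = etree.SubElement(el, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            ilist = etree.SubElement(prec, "selectedIonList", count="1")
            ion = etree.SubElement(ilist, "selectedIon")
            _cv(ion, "MS:1000744", "selected ion m/z", repr(float(sp.precursor_mz)),
                unit=("MS:1000040", "m/z"))
            if sp.precursor_charge is not None:
                _cv(ion, "MS:1000041", "charge state", sp.precursor_charge)
            act = etree.SubElement(prec, "activation")
            for acc, name in _ACTIVATION_CV.get(sp.activation, []):
                _cv(act, acc, name)
            etree.SubElement(act, "userParam", name="activation_name",
                             value=sp.activation)
        balist = etree.SubElement(el, "binaryDataArrayList", count="2")
        for arr, acc, name in ((sp.mz, "MS:1000514", "m/z array"),
                               (sp.intensity, "MS:1000515", "intensity array")):
            encoded = _encode(arr)
            ba = etree.SubElement(balist, "binaryDataArray",
                                  encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, acc, name)
            etree.SubElement(ba, "binary").text = encoded
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def _activation_from_dict(activation: dict | None) -> str:
    if not activation:
        return "UNKNOWN"
    if "activation_name" in activation and activation["activation_name"] in ACTIVATIONS:
        return activation["activation_name"]
    names = set(activation)
    if "electron transfer dissociation" in names:
        return "EThcD"
    if "photodissociation" in names or "ultraviolet photodissociation" in names:
        return "UVPD"
    if ("beam-type collision-induced dissociation" in names
            or "collision-induced dissociation" in names):
        return "HCD"
    return "UNKNOWN"


def _qname(tag: str) -> str:
    return f"{{{_NS}}}{tag}"


def _params(element) -> dict[str, str]:
    """cvParam names / userParam names -> values for one element (non-recursive
    into child spectra structures it is called on directly)."""
    out = {}
    for child in element:
        tag = etree.QName(child).localname
        if tag in ("cvParam", "userParam"):
            out[child.get("name")] = child.get("value", "")
    return out


def _decode_binary_array(ba) -> np.ndarray:
    params = _params(ba)
    text = ""
    for child in ba:
        if etree.QName(child).localname == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def read_mzml(path) -> list[Spectrum]:
    """Read a centroided mzML run into acquisition-ordered Spectrum records.

    Profile-mode spectra raise an error advising centroiding; MS2 scans with
    no recognisable activation metadata are kept with activation UNKNOWN (a
    warning is emitted).
    """
    spectra = []
    for _, el in etree.iterparse(str(path), events=("end",),
                                 tag=_qname("spectrum")):
        top = _params(el)
        if "profile spectrum" in top:
            raise ValueError(
                f"{path}: profile-mode data; centroid the run before analysis")
        ms_level = int(top.get("ms level", 1))
        rt = 0.0
        res = top.get("resolution_setting")
        prec_mz = prec_z = None
        activation = "NONE" if ms_level == 1 else "UNKNOWN"
        mz = intensity = None
        for scan in el.iter(_qname("scan")):
            p = _params(scan)
            if "scan start time" in p:
                rt = float(p["scan start time"])
        for prec in el.iter(_qname("precursor")):
            for ion in prec.iter(_qname("selectedIon")):
                p = _params(ion)
                if "selected ion m/z" in p:
                    prec_mz = float(p["selected ion m/z"])
                if p.get("charge state"):
                    prec_z = int(p["charge state"])
            for act in prec.iter(_qname("activation")):
                activation = _activation_from_dict(_params(act))
        for ba in el.iter(_qname("binaryDataArray")):
            arr, params = _decode_binary_array(ba)
            if "m/z array" in params:
                mz = arr
            elif "intensity array" in params:
                intensity = arr
        if mz is None or intensity is None:
            raise ValueError(f"{path}: spectrum {el.get('id')} lacks peak arrays")
        if ms_level >= 2 and activation == "UNKNOWN":
            warnings.warn(f"scan {el.get('id')}: missing activation metadata")
        spectra.append(Spectrum(
            scan_id=el.get("id"), ms_level=ms_level, mz=mz,
            intensity=intensity, retention_time=rt, activation=activation,
            precursor_mz=prec_mz, precursor_charge=prec_z,
            resolution_setting=float(res) if res is not None else None))
        el.clear()
    if not spectra:
        raise ValueError(f"{path}: no spectra found")
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write MS2 scans to MGF (plain-text fixture format)."""
    entries = []
    for sp in spectra:
        if sp.ms_level != 2:
            continue
        params = {"title": sp.scan_id, "rtinseconds": sp.retention_time * 60.0,
                  "pepmass": sp.precursor_mz, "activation": sp.activation}
        if sp.precursor_charge:
            params["charge"] = sp.precursor_charge
        entries.append({"params": params, "m/z array": sp.mz,
                        "intensity array": sp.intensity})
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            p = entry["params"]
            charge = p.get("charge")
            spectra.append(Spectrum(
                scan_id=str(p.get("title", f"index={len(spectra)}")),
                ms_level=2, mz=entry["m/z array"],
                intensity=entry["intensity array"],
                retention_time=float(p.get("rtinseconds", 0.0)) / 60.0,
                activation=p.get("activation", "UNKNOWN"),
                precursor_mz=float(p["pepmass"][0]),
                precursor_charge=int(charge[0]) if charge else None))
    return spectra


# ---------------------------------------------------------------------------
# Reporter detection, scan pairing, XIC

def detect_reporters(scan: Spectrum, cfg: ReporterConfig = ReporterConfig()
                     ) -> tuple[float, ...]:
    """Reporter m/z values present in an MS2 scan.

    A reporter is a hit when its nearest peak lies within ``tolerance_ppm``
    and is at least ``min_relative_intensity`` of the base peak.
    """
    if scan.ms_level != 2:
        raise ValueError("reporter detection applies to MS2 scans")
    if scan.mz.size == 0:
        return ()
    base = scan.base_peak_intensity
    hits = []
    for target in cfg.reporter_mzs:
        tol = target * cfg.tolerance_ppm * 1e-6
        lo = np.searchsorted(scan.mz, target - tol)
        hi = np.searchsorted(scan.mz, target + tol)
        if hi > lo and scan.intensity[lo:hi].max() >= cfg.min_relative_intensity * base:
            hits.append(target)
    return tuple(hits)


def pair_scans(run: list[Spectrum], cfg: ReporterConfig = ReporterConfig(),
               pairing_ppm: float = 10.0, max_rt_gap_minutes: float = 5 / 60
               ) -> tuple[list[ScanPair], list[Spectrum]]:
    """Pair each triggered EThcD/UVPD scan with the HCD scan that fired it.

    A triggered scan pairs with the nearest preceding HCD scan whose precursor
    m/z matches within ``pairing_ppm`` (and charge, when both annotate one),
    whose trigger reporter fired, and which was acquired within
    ``max_rt_gap_minutes``.  Returns ``(pairs, orphans)``.
    """
    pairs: list[ScanPair] = []
    orphans: list[Spectrum] = []
    hcd_seen: list[tuple[Spectrum, tuple[float, ...]]] = []
    for sp in run:
        if sp.ms_level != 2:
            continue
        if sp.activation == "HCD":
            hcd_seen.append((sp, detect_reporters(sp, cfg)))
        elif sp.activation in ("EThcD", "UVPD"):
            match = None
            for hcd, hits in reversed(hcd_seen):
                if sp.retention_time - hcd.retention_time > max_rt_gap_minutes:
                    break
                if cfg.trigger_mz not in hits:
                    continue
                if abs(hcd.precursor_mz - sp.precursor_mz) > (
                        sp.precursor_mz * pairing_ppm * 1e-6):
                    continue
                if (hcd.precursor_charge and sp.precursor_charge
                        and hcd.precursor_charge != sp.precursor_charge):
                    continue
                match = (hcd, hits)
                break
            if match is None:
                orphans.append(sp)
            else:
                pairs.append(ScanPair(match[0], sp, match[1]))
    return pairs, orphans


def xic(run: list[Spectrum], target_mz: float, tol_ppm: float = 10.0
        ) -> list[tuple[float, float]]:
    """Extracted ion chromatogram: per-MS1-scan summed intensity at target m/z."""
    tol = target_mz * tol_ppm * 1e-6
    trace = []
    for sp in run:
        if sp.ms_level != 1:
            continue
        lo = np.searchsorted(sp.mz, target_mz - tol)
        hi = np.searchsorted(sp.mz, target_mz + tol)
        trace.append((sp.retention_time, float(sp.intensity[lo:hi].sum())))
    return trace
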