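"""mzML/MGF round trips, reporter detection, scan pairing and XICs."""

import numpy as np
import pytest

from adcmapper.spectra import (ReporterConfig, ScanPair, Spectrum,
                               detect_reporters, pair_scans, read_mgf,
                               read_mzml, write_mgf, write_mzml, xic)


def sample_run():
    return [
        Spectrum("scan=1", 1, [100.5, 200.25], [10.0, 20.0], 0.50, "NONE",
                 resolution_setting=60000),
        Spectrum("scan=2", 2, [120.1, 547.2199], [5.0, 50.0], 0.51, "HCD",
                 precursor_mz=1000.5, precursor_charge=7,
                 resolution_setting=30000),
        Spectrum("scan=3", 2, [333.3, 444.4], [1.0, 2.0], 0.52, "UVPD",
                 precursor_mz=1000.5, precursor_charge=7,
                 resolution_setting=240000),
        Spectrum("scan=4", 2, [333.3], [1.0], 0.53, "EThcD",
                 precursor_mz=900.1, precursor_charge=5),
    ]


def test_mzml_round_trip(tmp_path):
    path = tmp_path / "run.mzML"
    run = sample_run()
    write_mzml(run, path)
    back = read_mzml(path)
    assert len(back) == len(run)
    for a, b in zip(run, back):
        assert a.scan_id == b.scan_id
        assert a.ms_level == b.ms_level
        assert a.activation == b.activation
        np.testing.assert_allclose(a.mz, b.mz, atol=1e-6)
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-6)
        assert b.retention_time == pytest.approx(a.retention_time, abs=1e-9)
        assert a.resolution_setting == b.resolution_setting
        if a.ms_level == 2:
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-9)
            assert b.precursor_charge == a.precursor_charge


def test_mzml_errors(tmp_path):
    empty = tmp_path / "empty.mzML"
    empty.write_text('<?xml version="1.0"?>'
                     '<mzML xmlns="http://psi.hupo.org/ms/mzml"></mzML>')
    with pytest.raises(ValueError, match="no spectra"):
        read_mzml(empty)


def test_profile_mode_rejected(tmp_path):
    path = tmp_path / "profile.mzML"
    write_mzml([sample_run()[0]], path)
    text = path.read_text().replace("centroid spectrum", "profile spectrum")
    text = text.replace("MS:1000127", "MS:1000128")
    path.write_text(text)
    with pytest.raises(ValueError, match="centroid"):
        read_mzml(path)


def test_missing_activation_warns(tmp_path):
    path = tmp_path / "noact.mzML"
    write_mzml([sample_run()[0], sample_run()[2]], path)
    text = path.read_text().replace(
        '<cvParam cvRef="MS" accession="MS:1000435" name="photodissociation" '
        'value=""/>', "")
    text = text.replace('<userParam name="activation_name" value="UVPD"/>', "")
    path.write_text(text)
    with pytest.warns(UserWarning, match="activation"):
        back = read_mzml(path)
    assert back[1].activation == "UNKNOWN"


def test_mgf_round_trip(tmp_path):
    path = tmp_path / "run.mgf"
    run = sample_run()
    write_mgf(run, path)
    back = read_mgf(path)
    assert len(back) == 3  # MS2 only
    assert back[0].activation == "HCD"
    assert back[0].precursor_mz == pytest.approx(1000.5)
    np.testing.assert_allclose(back[0].mz, run[1].mz)


def test_detect_reporters():
    cfg = ReporterConfig()
    scan = sample_run()[1]  # 547.2199 at 100% base peak
    assert 547.22 in detect_reporters(scan, cfg)
    # out of tolerance
    far = Spectrum("x", 2, [547.30], [50.0], 0.5, "HCD", precursor_mz=900.0)
    assert detect_reporters(far, cfg) == ()
    # below the relative-intensity floor
    weak = Spectrum("w", 2, [547.22, 800.0], [0.1, 1000.0], 0.5, "HCD",
                    precursor_mz=900.0)
    assert detect_reporters(weak, cfg) == ()
    with pytest.raises(ValueError):
        detect_reporters(sample_run()[0], cfg)


def test_detect_reporters_permutation_invariant():
    rng = np.random.default_rng(1)
    mz = np.r_[rng.uniform(300, 1500, 50), [453.19, 485.22, 547.22]]
    inten = np.r_[rng.uniform(1, 5, 50), [50.0, 60.0, 70.0]]
    perm = rng.permutation(mz.size)
    a = Spectrum("a", 2, mz, inten, 0.5, "HCD", precursor_mz=900.0)
    b = Spectrum("b", 2, mz[perm], inten[perm], 0.5, "HCD", precursor_mz=900.0)
    assert detect_reporters(a) == detect_reporters(b) == (547.22, 485.22,
                                                          453.19)


def test_reporter_config_validation():
    with pytest.raises(ValueError):
        ReporterConfig(reporter_mzs=(453.19,), trigger_mz=547.22)
    with pytest.raises(ValueError):
        ReporterConfig(tolerance_ppm=0)


def test_pair_scans_basic():
    run = sample_run()
    pairs, orphans = pair_scans(run)
    assert len(pairs) == 1 and len(orphans) == 1
    assert pairs[0].hcd_scan.scan_id == "scan=2"
    assert pairs[0].triggered_scan.scan_id == "scan=3"
    assert pairs[0].reporter_hits == (547.22,)
    assert orphans[0].scan_id == "scan=4"  # no matching HCD precursor


def test_pair_scans_requires_matching_charge():
    hcd = Spectrum("h", 2, [547.22], [10.0], 0.5, "HCD", precursor_mz=1000.0,
                   precursor_charge=7)
    trig = Spectrum("t", 2, [500.0], [1.0], 0.51, "UVPD", precursor_mz=1000.0,
                    precursor_charge=6)
    pairs, orphans = pair_scans([hcd, trig])
    assert pairs == [] and len(orphans) == 1


def test_scan_pair_invariants():
    run = sample_run()
    with pytest.raises(ValueError):
        ScanPair(run[1], run[1], (547.22,))  # HCD cannot be the triggered scan
    with pytest.raises(ValueError):
        ScanPair(run[1], run[2], ())  # needs a reporter hit


def test_xic_traces():
    rts = np.linspace(0, 1, 11)
    apex = 0.5
    run = []
    for i, t in enumerate(rts):
        inten = np.exp(-0.5 * ((t - apex) / 0.1) ** 2) * 100
        run.append(Spectrum(f"s{i}", 1, [1000.0], [inten], t, "NONE"))
    trace = xic(run, 1000.0, 10)
    assert len(trace) == 11
    best_rt = max(trace, key=lambda p: p[1])[0]
    assert best_rt == pytest.approx(apex, abs=0.05)
    assert all(i == 0 for _, i in xic(run, 1500.0, 10))
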