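"""End-to-end orchestration: digest -> pair -> deconvolute -> search -> census.

The pipeline consumes a chain FASTA plus a set of replicate mzML runs and
produces proteoform-spectrum matches, payload site calls, a per-chain site
census, text sequence/coverage maps and a manifest with content hashes so a
run can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .search import (CandidateIndex, DEFAULT_RULES, ProteoformSpectrumMatch,
                     SiteCall, aggregate_replicates, build_site_evidence,
                     call_sites, census, match_spectrum, proteoform_key)
from .sequence import (N_TERM, ChainSequence, build_database, read_chain_fasta)
from .spectra import ReporterConfig, pair_scans, read_mzml

log = logging.getLogger("adcmapper")


@dataclass
class PipelineConfig:
    fasta: str | Path | None = None
    chains: list[ChainSequence] | None = None
    runs: list[tuple[str, str | Path]] = field(default_factory=list)
    output_dir: str | Path | None = None
    # database
    max_missed: int | None = None
    min_mass: float = 500.0
    max_mass: float = 20000.0
    max_payloads: int = 2
    allow_cterm_K: bool = False
    payload_mass: float = 956.364
    # matching
    prec_tol_da: float = 2.2
    frag_tol_ppm: float = 10.0
    pairing_ppm: float = 10.0
    reporters: ReporterConfig = field(default_factory=ReporterConfig)
    min_replicates: int = 3
    rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    snr_min: float = 3.0

    def resolve_chains(self) -> list[ChainSequence]:
        if self.chains:
            return self.chains
        if self.fasta:
            return read_chain_fasta(self.fasta)
        raise ValueError("PipelineConfig needs chains or a FASTA path")

    def validate(self):
        if not self.runs:
            raise ValueError("no mzML runs configured")
        reps = [r for r, _ in self.runs]
        if len(set(reps)) != len(reps):
            raise ValueError("replicate ids must be unique")
        for _, path in self.runs:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        self.resolve_chains()


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, plus stage counters."""

    matches: list[ProteoformSpectrumMatch]
    accepted: dict
    site_calls: list[SiteCall]
    census: dict
    stats: dict
    outputs: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the whole workflow; deterministic for identical inputs."""
    cfg.validate()
    chains = cfg.resolve_chains()
    stats: dict = {}
    t0 = time.time()
    db = build_database(chains, cfg.max_missed, cfg.min_mass, cfg.max_mass,
                        cfg.max_payloads, cfg.allow_cterm_K, cfg.payload_mass)
    index = CandidateIndex(db)
    stats["candidate_proteoforms"] = len(db)
    log.info("database: %d proteoforms (%.1fs)", len(db), time.time() - t0)
    all_matches: list[ProteoformSpectrumMatch] = []
    n_pairs = n_orphans = 0
    for replicate_id, path in cfg.runs:
        t1 = time.time()
        spectra = read_mzml(path)
        pairs, orphans = pair_scans(spectra, cfg.reporters, cfg.pairing_ppm)
        n_pairs += len(pairs)
        n_orphans += len(orphans)
        for pair in pairs:
            ms = match_spectrum(
                pair, index, cfg.prec_tol_da, cfg.frag_tol_ppm, replicate_id,
                deconv_kwargs={"snr_min": cfg.snr_min})
            all_matches.extend(m for m in ms if m.rank == 1 or m.co_top)
        log.info("%s: %d scans, %d pairs (%.1fs)", replicate_id, len(spectra),
                 len(pairs), time.time() - t1)
    stats["scan_pairs"] = n_pairs
    stats["orphan_triggered_scans"] = n_orphans
    stats["matches"] = len(all_matches)
    accepted = aggregate_replicates(all_matches, cfg.min_replicates)
    stats["accepted_proteoforms"] = len(accepted)
    stats["accepted_payload_proteoforms"] = sum(
        1 for key in accepted if key[3])
    evidence = build_site_evidence(accepted, cfg.allow_cterm_K)
    calls = call_sites(evidence, cfg.rules)
    summary = census(calls, chains, accepted)
    stats["runtime_s"] = round(time.time() - t0, 2)
    result = PipelineResult(all_matches, accepted, calls, summary, stats)
    if cfg.output_dir is not None:
        _write_outputs(cfg, chains, result)
    return result


# ---------------------------------------------------------------------------
# Reports

def matches_table(matches: list[ProteoformSpectrumMatch]) -> pd.DataFrame:
    rows = []
    for m in matches:
        key = proteoform_key(m.proteoform)
        rows.append({
            "replicate": m.replicate_id, "scan_id": m.scan_id,
            "activation": m.activation, "chain_id": key[0],
            "start": key[1], "end": key[2],
            "payload_sites": ";".join(map(str, key[3])),
            "n_payloads": len(key[3]), "n_matched": m.n_matched,
            "coverage_percent": round(m.coverage_percent, 2),
            "precursor_error_da": round(m.precursor_error_da, 4),
            "rank": m.rank, "co_top": m.co_top,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["replicate", "scan_id", "rank"],
                            kind="stable").reset_index(drop=True)
    return df


def site_calls_table(calls: list[SiteCall]) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda c: (c.chain_id, c.sites)):
        rows.append({
            "chain": c.chain_id, "start": min(c.sites), "end": max(c.sites),
            "sites": ";".join("Nterm" if s == N_TERM else f"K{s}"
                              for s in c.sites),
            "status": c.status,
            "replicates": ";".join(c.replicates),
            "methods": ";".join(c.methods),
        })
    return pd.DataFrame(rows)


def render_chain_map(calls: list[SiteCall], chain: ChainSequence,
                     width: int = 60) -> str:
    """Text map of a chain: every K and the N-terminus annotated.

    Unambiguous sites are marked ``*``, sites inside an ambiguous range
    ``?`` and unsupported candidate sites ``.`` under the sequence line;
    a legend of calls follows.
    """
    status: dict[int, str] = {p: "unsupported"
                              for p in (N_TERM,) + chain.lysine_positions}
    ranges = []
    for c in calls:
        if c.chain_id != chain.chain_id:
            continue
        if c.status == "unambiguous":
            status[c.site] = "unambiguous"
        elif c.status == "ambiguous_range":
            ranges.append(c.sites)
            for s in c.sites:
                if status.get(s) != "unambiguous":
                    status[s] = "ambiguous_range"
    mark = {"unambiguous": "*", "ambiguous_range": "?", "unsupported": "."}
    lines = [f"# {chain.chain_id} ({chain.role}, {len(chain)} aa, "
             f"{len(chain.lysine_positions)} K)"]
    nterm = status[N_TERM]
    lines.append(f"N-term: {nterm} {mark[nterm]}")
    seq = chain.residues
    for off in range(0, len(seq), width):
        row = seq[off:off + width]
        ann = "".join(mark[status[off + i + 1]] if aa == "K" else " "
                      for i, aa in enumerate(row))
        lines.append(f"{off + 1:>5} {row}")
        lines.append(f"      {ann}")
    for p in (N_TERM,) + chain.lysine_positions:
        if status[p] != "unsupported":
            name = "N-term" if p == N_TERM else f"K{p}"
            lines.append(f"{name}: {status[p]}")
    for rng in sorted(set(ranges)):
        lines.append("ambiguous range: " + "-".join(
            "Nterm" if s == N_TERM else f"K{s}" for s in rng))
    return "\n".join(lines) + "\n"


def render_coverage_map(match: ProteoformSpectrumMatch, width: int = 60) -> str:
    """Text coverage map of one match: ``|`` under each covered bond,
    ``*`` over payload positions."""
    pep = match.proteoform.peptide
    n = len(pep)
    bonds = {f.cleavage for f, _, _ in match.matched_fragments}
    pay = {pep.to_local(p) for p in match.proteoform.payload_sites}
    lines = [f"# {match.proteoform.label()} {match.activation} "
             f"coverage {match.coverage_percent:.0f}% "
             f"({match.n_matched} fragments)"]
    for off in range(0, n, width):
        row = pep.sequence[off:off + width]
        paymark = "".join("*" if (off + i + 1) in pay else " "
                          for i in range(len(row)))
        cov = "".join("|" if (off + i + 1) in bonds else " "
                      for i in range(len(row)))
        lines.append("      " + paymark)
        lines.append(f"{off + 1:>5} {row}")
        lines.append("      " + cov)
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(cfg: PipelineConfig, chains, result: PipelineResult):
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    matches_table(result.matches).to_csv(out / "matches.tsv", sep="\t",
                                         index=False)
    files["matches"] = out / "matches.tsv"
    site_calls_table(result.site_calls).to_csv(out / "site_calls.tsv",
                                               sep="\t", index=False)
    files["site_calls"] = out / "site_calls.tsv"
    (out / "census.json").write_text(json.dumps(result.census, indent=1,
                                                sort_keys=True))
    files["census"] = out / "census.json"
    maps = "\n".join(render_chain_map(result.site_calls, c) for c in chains)
    (out / "chain_maps.txt").write_text(maps)
    files["chain_maps"] = out / "chain_maps.txt"
    coverage = []
    for key in sorted(result.accepted):
        best = max(result.accepted[key], key=lambda m: m.n_matched)
        coverage.append(render_coverage_map(best))
    (out / "coverage_maps.txt").write_text("\n".join(coverage))
    files["coverage_maps"] = out / "coverage_maps.txt"
    manifest = {
        "adcmapper_version": __version__,
        "parameters": {
            "prec_tol_da": cfg.prec_tol_da, "frag_tol_ppm": cfg.frag_tol_ppm,
            "max_payloads": cfg.max_payloads, "min_mass": cfg.min_mass,
            "max_mass": cfg.max_mass, "min_replicates": cfg.min_replicates,
            "rules": cfg.rules, "payload_mass": cfg.payload_mass,
        },
        "inputs": {str(p): _sha256(Path(p)) for _, p in cfg.runs},
        "stats": result.stats,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    result.outputs = {name: str(p) for name, p in files.items()}
    result.outputs["manifest"] = str(out / "manifest.json")
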