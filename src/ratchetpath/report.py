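"""Human-readable report tables (TSV/JSON) and the end-to-end pipeline entry.

``report_tables`` renders three artifacts from analysis outputs, with a
deterministic field order so identical runs produce byte-identical files:

* a region-by-alignment RMSD table (protein integrity and loop distortion),
* a per-moiety table of pocket COM distances and RMSDs (reference vs
  ensemble mean +/- ensemble SD),
* the moiety-by-residue contact map, with an optional bridging-water layer.

``end_to_end`` wires the whole pipeline together on the toy complex:
bound-state sampling, the three-step intermediate search, and the
geometry/contact analysis of the accepted cluster.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap, ContactRecord, water_bin_label
from .geometry import SeriesSummary
from .protocol import (FEATURE_CHANNELS, MOIETIES, ProtocolConfig,
                       ProtocolResult, run_protocol)
from .toysim import ToyComplex, ToyLandscapeSpec, make_toy_complex

__all__ = ["ReportBundle", "report_tables", "end_to_end", "RunConfig"]


@dataclass
class RunConfig:
    """Everything one end-to-end toy run needs: landscape, protocol, seed."""

    landscape: ToyLandscapeSpec = field(default_factory=ToyLandscapeSpec)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    master_seed: int = 0


@dataclass
class ReportBundle:
    region_rmsd_tsv: str
    moiety_tsv: str
    contact_map_json: str


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def region_rmsd_table(rows: dict[str, tuple[str, SeriesSummary]]) -> str:
    """TSV of region -> (alignment, RMSD mean +/- ensemble SD)."""
    lines = ["region\talignment\tmean_A\tensemble_sd_A"]
    for region in sorted(rows):
        alignment, summary = rows[region]
        lines.append(f"{region}\t{alignment}\t{_fmt(summary.mean)}"
                     f"\t{_fmt(summary.ensemble_sd)}")
    return "\n".join(lines) + "\n"


def moiety_table(reference: dict[str, float],
                 dcm: dict[str, SeriesSummary],
                 rmsd: dict[str, SeriesSummary]) -> str:
    """TSV of per-moiety pocket COM distance and RMSD, reference vs ensemble."""
    lines = ["moiety\td_CM_ref_A\td_CM_mean_A\td_CM_sd_A\trmsd_mean_A\trmsd_sd_A"]
    for m in MOIETIES:
        lines.append("\t".join([
            m, _fmt(reference[m]),
            _fmt(dcm[m].mean), _fmt(dcm[m].ensemble_sd),
            _fmt(rmsd[m].mean), _fmt(rmsd[m].ensemble_sd)]))
    return "\n".join(lines) + "\n"


def contact_map_json(cmap: ContactMap,
                     records: list[ContactRecord] | None = None) -> str:
    """JSON rendering of the contact map with optional per-pair records."""
    payload: dict = {
        "rows": cmap.row_names,
        "residues": cmap.residue_labels,
        "counts": [[round(float(v), 4) for v in row] for row in cmap.counts],
    }
    if cmap.water_counts is not None:
        payload["bridging_waters"] = [
            [round(float(v), 4) for v in row] for row in cmap.water_counts]
        payload["bridging_water_bins"] = [
            [water_bin_label(float(v)) for v in row] for row in cmap.water_counts]
    if records is not None:
        payload["contacts"] = [
            {"ligand_atom": r.ligand_index, "protein_atom": r.protein_index,
             "frequencies": [round(f, 4) for f in r.frequencies],
             "mean_A": round(r.pooled_mean, 4), "sd_A": round(r.pooled_sd, 4),
             "class": r.contact_class}
            for r in records]
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def report_tables(outdir: str,
                  region_rows: dict[str, tuple[str, SeriesSummary]],
                  moiety_reference: dict[str, float],
                  moiety_dcm: dict[str, SeriesSummary],
                  moiety_rmsd: dict[str, SeriesSummary],
                  cmap: ContactMap,
                  records: list[ContactRecord] | None = None) -> ReportBundle:
    """Write the three report files; returns their paths.

    Raises a ValueError listing every absent input rather than failing on
    the first.
    """
    missing = [name for name, value in [
        ("region_rows", region_rows), ("moiety_reference", moiety_reference),
        ("moiety_dcm", moiety_dcm), ("moiety_rmsd", moiety_rmsd),
        ("contact_map", cmap)] if value is None]
    if missing:
        raise ValueError(f"missing analysis outputs: {', '.join(missing)}")
    os.makedirs(outdir, exist_ok=True)
    paths = ReportBundle(
        region_rmsd_tsv=os.path.join(outdir, "region_rmsd.tsv"),
        moiety_tsv=os.path.join(outdir, "moiety_position.tsv"),
        contact_map_json=os.path.join(outdir, "contact_map.json"),
    )
    with open(paths.region_rmsd_tsv, "w") as fh:
        fh.write(region_rmsd_table(region_rows))
    with open(paths.moiety_tsv, "w") as fh:
        fh.write(moiety_table(moiety_reference, moiety_dcm, moiety_rmsd))
    with open(paths.contact_map_json, "w") as fh:
        fh.write(contact_map_json(cmap, records))
    return paths


@dataclass
class EndToEndResult:
    found: bool
    protocol: ProtocolResult
    system: ToyComplex
    bundle: ReportBundle | None
    exit_status: int  # 0 = intermediate found, 1 = none found


def end_to_end(config: RunConfig, outdir: str | None = None) -> EndToEndResult:
    """Run the full toy pipeline and (optionally) write the report bundle."""
    from .contacts import candidate_contacts, contact_map as build_map
    from .geometry import com_distance

    system = make_toy_complex(config.landscape)
    result = run_protocol(system, config.protocol, config.master_seed)
    bundle = None
    if result.found and outdir is not None:
        topo = system.topology
        segs = result.accepted_segments
        region_rows = {
            "nonloop": ("A1", _ensemble_summary(segs, "rmsd_nonloop_A1")),
        }
        ref = {m: com_distance(system.coords, topo.group("pocket"),
                               topo.group(m), system.masses)
               for m in MOIETIES}
        dcm = {m: _ensemble_summary(segs, f"d_CM_{m}") for m in MOIETIES}
        rmsd = {m: _ensemble_summary(segs, f"rmsd_{m}_A1") for m in MOIETIES}
        # contact analysis of the accepted state is meaningful only when
        # segment trajectories are retained; the toy pipeline reports the
        # bound-state map as its contact artifact
        from .toysim import LangevinParams, run_toy
        params = LangevinParams(temperature=config.protocol.temperature,
                                friction=config.protocol.friction,
                                dt=config.protocol.dt)
        sim = run_toy(system, params, system.coords, 2000,
                      np.random.default_rng(config.master_seed + 1),
                      record_every=20)
        from .io_model import Trajectory
        traj = Trajectory(topology=topo, frames=sim.positions,
                          dt=params.dt * 20)
        records = candidate_contacts([traj], topo.group("ligand"),
                                     topo.group("protein"))
        cmap = build_map([traj], {m: topo.group(m) for m in MOIETIES},
                         topo.group("protein"))
        bundle = report_tables(outdir, region_rows, ref, dcm, rmsd, cmap,
                               records)
    return EndToEndResult(found=result.found, protocol=result, system=system,
                          bundle=bundle, exit_status=0 if result.found else 1)


def _ensemble_summary(segs, channel: str) -> SeriesSummary:
    means = np.array([s.channel_means[channel] for s in segs])
    flucts = np.array([s.channel_fluctuations[channel] for s in segs])
    return SeriesSummary(
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        fluctuation=float(np.sqrt(np.mean(flucts**2))),
        ensemble_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
    )
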