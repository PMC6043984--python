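"""The two assembled pipelines: reads -> cluster report, stacks -> position report.

Both run from a plain config dict (usually loaded from YAML), write only
TSV/JSON/FASTQ/TIFF artifacts, and embed a config hash and the package
version in every output so a report can be traced to the exact run that
produced it.  With a fixed config (including seeds) reruns are
byte-identical; anything time-dependent goes to the log, never to outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO

from . import __version__
from .mapper import (
    Reference,
    ReferenceSet,
    assign_weights,
    classify_uniqueness,
    map_library,
    mapping_summary,
)
from .nuclear_geometry import (
    NucleusMask,
    VolumeImage,
    colocalization_fraction,
    measure_cluster,
    segment_channel,
    segment_nucleus,
    two_sample_t,
)
from .pirna_stats import (
    coverage_profile,
    length_spectrum,
    partition_classes,
    pingpong_profile,
    rpm_normalize,
)
from .seq_io import InputError, Library, preprocess, read_sequences
from .synthetic_images import PhantomConfig, SpotSpec, render_phantom
from .synthetic_reads import SimConfig, simulate_library, truth_table, write_fastq

__all__ = [
    "config_hash",
    "load_references",
    "run_cluster_report",
    "run_position_report",
]

log = logging.getLogger("telopirna")


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable digest of a config mapping (order-independent)."""
    canonical = yaml.safe_dump(_plain(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _provenance(cfg_hash: str) -> dict:
    return {"tool": "telopirna", "version": __version__, "config_hash": cfg_hash}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, frame: pd.DataFrame, cfg_hash: str) -> None:
    with open(path, "wt") as out:
        out.write(f"# telopirna v{__version__} config_hash={cfg_hash}\n")
        frame.to_csv(out, sep="\t", index=False)


def load_references(path: str | Path, kind: str = "telomeric_element") -> ReferenceSet:
    """Read a reference FASTA into a ReferenceSet."""
    refs = [
        Reference(ref_id=rec.id, seq=str(rec.seq).upper(), kind=kind)  # type: ignore[arg-type]
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return ReferenceSet(refs)


def _library_from_config(config: Mapping[str, Any], outdir: Path, cfg_hash: str):
    """Obtain (Library, ReferenceSet) from either real files or a simulation block."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        ref_spec = sim.pop("reference")
        if isinstance(ref_spec, str):
            refs = load_references(ref_spec)
            reference = next(iter(refs))
        else:
            reference = Reference(
                ref_id=ref_spec.get("ref_id", "ref"), seq=ref_spec["seq"].upper()
            )
            refs = ReferenceSet([reference])
        sim_config = SimConfig(reference=reference, **sim)
        reads = simulate_library(sim_config)
        write_fastq(reads, outdir / "simulated.fastq", seed=sim_config.seed)
        _write_tsv(outdir / "simulated_truth.tsv", truth_table(reads), cfg_hash)
        library = preprocess(((r.read_id, r.seq) for r in reads), adapter=None)
    else:
        refs = load_references(config["references"])
        clip = config.get("clip", {})
        raw = ((r.read_id, r.seq) for r in read_sequences(config["reads"]))
        library = preprocess(
            raw,
            adapter=clip.get("adapter"),
            min_overlap=clip.get("min_overlap", 6),
            max_mismatch_rate=clip.get("max_mismatch_rate", 0.1),
            unclipped_policy=clip.get("unclipped_policy", "drop"),
        )
    return library, refs


def run_cluster_report(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Reads -> clip/filter/collapse -> map -> per-reference cluster report.

    Writes, per reference: strand-resolved windowed coverage TSV, length
    spectrum TSV, and a JSON summary (u1 per strand, piRNA/siRNA RPM,
    z(10), argmax overlap, uniqueness counts).  Returns the summary dict.
    An empty input library is a valid empty result (all statistics NA).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    log.info("cluster report: config %s -> %s", cfg_hash, outdir)

    k = int(config.get("mismatch_budget", 0))
    window = int(config.get("window_size", 30))
    max_overlap = int(config.get("max_overlap", 30))
    weight_mode = config.get("weight_mode", "fractional")

    library, refs = _library_from_config(config, outdir, cfg_hash)
    summaries: dict[str, Any] = {
        "provenance": _provenance(cfg_hash),
        "parameters": {
            "mismatch_budget": k,
            "window_size": window,
            "max_overlap": max_overlap,
            "weight_mode": weight_mode,
        },
        "total_reads": library.total_reads,
        "references": {},
    }
    if not library.reads:
        summaries["mapping"] = {"reads_total_unique_seqs": 0, "mapped": 0,
                                "unique": 0, "multi": 0}
        _write_json(outdir / "summary.json", summaries)
        return summaries

    hits_by_read = map_library(library, refs, k=k, mode="all_hits")
    summaries["mapping"] = mapping_summary(hits_by_read)
    weighted = assign_weights(hits_by_read, weight_mode=weight_mode)
    labels = classify_uniqueness(hits_by_read)

    for ref in refs:
        ref_hits = [h for h in weighted if h.ref_id == ref.ref_id]
        classes = partition_classes(ref_hits)
        pp = pingpong_profile(classes["piRNA"], max_overlap=max_overlap)
        cov_rows = []
        for strand in ("+", "-"):
            prof = coverage_profile(
                ref_hits, ref, strand, library.total_reads, window_size=window
            )
            for w, v in enumerate(prof.values):
                cov_rows.append(
                    {"window": w, "start": w * window,
                     "end": min((w + 1) * window, len(ref)),
                     "strand": strand, "rpm": v}
                )
        _write_tsv(outdir / f"{ref.ref_id}.coverage.tsv",
                   pd.DataFrame(cov_rows), cfg_hash)
        spec = length_spectrum(ref_hits, ref.ref_id, library.total_reads)
        _write_tsv(outdir / f"{ref.ref_id}.length_spectrum.tsv",
                   spec.rpm.reset_index(), cfg_hash)
        pp_frame = pd.DataFrame(
            {"overlap": pp.overlaps, "pair_count": pp.pair_counts, "z": pp.z}
        )
        _write_tsv(outdir / f"{ref.ref_id}.pingpong.tsv", pp_frame, cfg_hash)
        unique_on_ref = {
            h.read_id for h in ref_hits if labels[h.read_id] == "unique"
        }
        summaries["references"][ref.ref_id] = {
            "u1_plus": spec.u1_fraction["+"],
            "u1_minus": spec.u1_fraction["-"],
            "pirna_rpm": rpm_normalize(
                sum(h.weight for h in classes["piRNA"]), library.total_reads
            ),
            "sirna_rpm": rpm_normalize(
                sum(h.weight for h in classes["siRNA"]), library.total_reads
            ),
            "z10": None if pp.degenerate else pp.z_at(10),
            "argmax_o": None if pp.degenerate else pp.argmax_overlap,
            "pingpong_degenerate": pp.degenerate,
            "unique_mapped_seqs": len(unique_on_ref),
        }
    _write_json(outdir / "summary.json", summaries)
    return summaries


# --------------------------------------------------------------------------
# 3D position report


def _load_stack(entry: Mapping[str, Any], voxel_size) -> dict[str, VolumeImage]:
    """Load a CZYX TIFF into channel VolumeImages using the role mapping."""
    data = np.asarray(tifffile.imread(entry["path"]), dtype=float)
    if data.ndim == 3:
        data = data[None]
    channels: dict[str, VolumeImage] = {}
    for role, index in entry["channels"].items():
        channels[role] = VolumeImage(
            data=data[int(index)], voxel_size=tuple(voxel_size), channel=role
        )
    return channels


def _phantom_images(entry: Mapping[str, Any]) -> dict[str, VolumeImage]:
    spots = [SpotSpec(**{**s, "center_um": tuple(s["center_um"])})
             for s in entry.get("spots", [])]
    cfg = PhantomConfig(
        shape=tuple(entry["shape"]),
        voxel_size=tuple(entry.get("voxel_size", (1.05, 0.2, 0.2))),
        nucleus_center_um=(tuple(entry["nucleus_center_um"])
                           if entry.get("nucleus_center_um") else None),
        semi_axes_um=tuple(entry.get("semi_axes_um", (8.0, 10.0, 10.0))),
        spots=spots,
        noise_sd=float(entry.get("noise_sd", 0.0)),
        seed=int(entry.get("seed", 0)),
    )
    images, _ = render_phantom(cfg)
    return images


def run_position_report(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Stacks -> segmentation -> cluster measures -> colocalization -> t test.

    ``config["groups"]`` is a list of ``{"name", "nuclei": [...]}``; each
    nucleus entry is either a TIFF stack (``path`` + ``channels`` role map)
    or an inline phantom spec (``shape``/``semi_axes_um``/``spots``/...).
    Channel roles: "dapi" (nucleus), "fish" (measured cluster), optional
    "foci" (colocalization partner).  With two or more groups the first two
    are compared by the independent two-sample t test on cluster-to-surface
    distances.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    log.info("position report: config %s -> %s", cfg_hash, outdir)

    seg = config.get("segmentation", {})
    nucleus_method = seg.get("nucleus_method", "otsu")
    nucleus_threshold = seg.get("nucleus_threshold")
    spot_method = seg.get("spot_method", "otsu")
    spot_threshold = seg.get("spot_threshold")
    min_voxels = int(seg.get("min_voxels", 2))
    min_shared = int(seg.get("min_shared_voxels", 1))
    voxel_size = tuple(config.get("voxel_size", (1.05, 0.2, 0.2)))

    rows, coloc_rows = [], []
    distances: dict[str, list[float]] = {}
    for group in config["groups"]:
        gname = group["name"]
        distances[gname] = []
        for i, entry in enumerate(group["nuclei"]):
            nucleus_id = entry.get("id", f"{gname}_{i:03d}")
            channels = (
                _load_stack(entry, voxel_size)
                if "path" in entry
                else _phantom_images(entry)
            )
            if "dapi" not in channels or "fish" not in channels:
                raise InputError(f"nucleus {nucleus_id}: need dapi and fish channels")
            nucleus = segment_nucleus(
                channels["dapi"], nucleus_method, nucleus_threshold
            )
            fish_spots = segment_channel(
                channels["fish"], spot_method, spot_threshold, min_voxels
            )
            measure = measure_cluster(
                nucleus_id, channels["fish"], nucleus, spot_set=fish_spots
            )
            if measure is None:
                log.warning("nucleus %s: no FISH spots detected", nucleus_id)
                continue
            rows.append(
                {
                    "nucleus_id": nucleus_id,
                    "group": gname,
                    "center_z_um": measure.center_um[0],
                    "center_y_um": measure.center_um[1],
                    "center_x_um": measure.center_um[2],
                    "cluster_diameter_um": measure.cluster_diameter_um,
                    "distance_um": measure.distance_um,
                }
            )
            distances[gname].append(measure.distance_um)
            if "foci" in channels:
                foci = segment_channel(
                    channels["foci"], spot_method, spot_threshold, min_voxels
                )
                res = colocalization_fraction(fish_spots, foci, min_shared)
                coloc_rows.append({"nucleus_id": nucleus_id, "group": gname, **res})

    measures = pd.DataFrame(
        rows,
        columns=["nucleus_id", "group", "center_z_um", "center_y_um",
                 "center_x_um", "cluster_diameter_um", "distance_um"],
    )
    _write_tsv(outdir / "measures.tsv", measures, cfg_hash)
    if coloc_rows:
        _write_tsv(outdir / "colocalization.tsv", pd.DataFrame(coloc_rows), cfg_hash)

    summary: dict[str, Any] = {
        "provenance": _provenance(cfg_hash),
        "groups": {
            g: {
                "n": len(d),
                "mean_distance_um": float(np.mean(d)) if d else None,
                "sd_distance_um": float(np.std(d, ddof=1)) if len(d) > 1 else None,
            }
            for g, d in distances.items()
        },
    }
    names = [g["name"] for g in config["groups"]]
    if len(names) >= 2 and all(len(distances[n]) >= 2 for n in names[:2]):
        test = two_sample_t(distances[names[0]], distances[names[1]],
                            variant=config.get("t_test_variant", "welch"))
        summary["comparison"] = {"group1": names[0], "group2": names[1], **test}
    else:
        summary["comparison"] = None  # a single group is a valid result
    _write_json(outdir / "position_summary.json", summary)
    return summary
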