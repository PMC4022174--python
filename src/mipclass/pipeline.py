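"""End-to-end pipeline: simulate -> scan -> filter-extract -> tree -> classify.

A run is driven by a flat key-value config (YAML). Every stage writes its
outputs before the next starts, every random stage takes an explicit seed,
and a rerun with an identical config reproduces byte-identical artifacts.
A manifest (config echo, package version, data checksums, per-stage record
counts, warnings) is written whether the run succeeds or fails.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .arfilter import (
    choose_reference,
    extract_arr_filter,
    infer_specificity,
    load_reference_table,
    write_reference_table,
)
from .classify import (
    EvidenceBundle,
    assign_subfamily,
    summarize_calls,
    write_calls_tsv,
    write_summary_json,
)
from .motifs import classify_motif_pair, scan_npa_boxes
from .phylo import Msa, bootstrap_supports, jtt_distance_matrix, trim_msa
from .synthetic import (
    generate_heterokont_panel,
    packaged_references,
    read_fasta,
    write_fasta,
    write_truth_tables,
)

_CONFIG_DEFAULTS = {
    "mode": "panel",  # panel: generate the heterokont panel; fasta: user input
    "input_fasta": None,
    "panel_seed": None,
    "reference_table": "packaged",
    "msa": "true-alignment",  # alignment path, 'true-alignment' (panel) or 'none'
    "reference_labels": None,  # TSV leaf->subfamily for tree-based assignment
    "bootstrap_reps": 100,
    "bootstrap_seed": None,
    "gap_mode": "pairwise",  # pairwise | complete deletion for distances
    "min_separation": 40,
    "trim_threshold": 0.5,
    "support_threshold": 50.0,
    "output_dir": None,
}

_REQUIRED_SEEDS = {
    "panel": ("panel_seed",),
    "fasta": (),
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a run config; unknown keys are rejected."""
    cfg = dict(_CONFIG_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a mapping of keys to values")
        cfg.update(user)
        unknown = set(user) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if overrides:
        unknown = set(overrides) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for k, v in overrides.items():
            default = _CONFIG_DEFAULTS[k]
            if isinstance(default, (int, float)) and not isinstance(default, bool):
                v = type(default)(v)
            cfg[k] = v
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if cfg["mode"] not in ("panel", "fasta"):
        raise ConfigError(f"mode must be 'panel' or 'fasta', got {cfg['mode']!r}")
    if cfg["output_dir"] is None:
        raise ConfigError("missing required config field: output_dir")
    for key in _REQUIRED_SEEDS[cfg["mode"]]:
        if cfg[key] is None:
            raise ConfigError(f"missing required seed field: {key}")
    if cfg["msa"] not in (None, "none") and cfg["bootstrap_seed"] is None:
        raise ConfigError("missing required seed field: bootstrap_seed")
    if cfg["mode"] == "fasta":
        if cfg["input_fasta"] is None:
            raise ConfigError("mode 'fasta' requires input_fasta")
        if cfg["msa"] == "true-alignment":
            raise ConfigError("msa: true-alignment is only available in panel mode")


def validate_inputs(
    fasta=None, msa=None, reference_table=None, reference_labels=None
) -> dict:
    """Check input files for alphabet, length consistency and duplicate ids.

    Returns {'fatal': [...], 'warnings': [...], 'counts': {...}}; duplicate
    sequence ids and ragged alignments are fatal.
    """
    fatal, warnings, counts = [], [], {}
    if fasta is not None:
        try:
            seqs = read_fasta(fasta)
            ids = [s.seq_id for s in seqs]
            dup = {i for i in ids if ids.count(i) > 1}
            if dup:
                fatal.append(f"duplicate sequence id(s) in {fasta}: {sorted(dup)}")
            counts["fasta_records"] = len(seqs)
            for s in seqs:
                if len(s) < 100:
                    warnings.append(f"{s.seq_id}: shorter than 100 residues")
        except ValueError as exc:
            fatal.append(str(exc))
    if msa is not None and msa not in ("none", "true-alignment"):
        try:
            rows = read_fasta(msa)  # gapped FASTA; validate shape by hand
        except ValueError:
            rows = None
        try:
            aln = Msa.from_file(msa)
            counts["msa_rows"] = len(aln.ids)
            counts["msa_cols"] = aln.n_cols
        except Exception as exc:  # ragged rows, duplicates
            fatal.append(f"invalid alignment {msa}: {exc}")
    if reference_table is not None and reference_table != "packaged":
        try:
            refs = load_reference_table(reference_table)
            counts["references"] = len(refs)
        except Exception as exc:
            fatal.append(f"invalid reference table {reference_table}: {exc}")
    if reference_labels is not None:
        try:
            counts["reference_labels"] = len(_read_labels(reference_labels))
        except Exception as exc:
            fatal.append(f"invalid reference labels {reference_labels}: {exc}")
    return {"fatal": fatal, "warnings": warnings, "counts": counts}


def _read_labels(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            leaf, label = line.split("\t")[:2]
            out[leaf] = label
    return out


def _write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for leaf in sorted(labels):
            fh.write(f"{leaf}\t{labels[leaf]}\n")


def _data_checksums() -> dict[str, str]:
    out = {}
    data_dir = resources.files("mipclass.data")
    for item in sorted(data_dir.iterdir(), key=lambda p: p.name):
        if item.name.endswith((".dat", ".tsv")):
            out[item.name] = hashlib.sha256(item.read_bytes()).hexdigest()
    return out


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    data_checksums: dict = field(default_factory=_data_checksums)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    status: str = "running"
    failed_stage: str | None = None

    def write(self, path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "data_checksums": self.data_checksums,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
            "status": self.status,
            "failed_stage": self.failed_stage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(cfg: dict) -> RunManifest:
    """Execute all stages in fixed order under one config.

    Stage order: simulate/load -> scan -> filter-extract -> tree -> classify
    -> summary. Each stage's files land in ``output_dir`` before the next
    stage starts. A failing stage halts the run; the manifest records it.
    """
    validate_config(cfg)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(cfg))
    manifest_path = outdir / "manifest.json"
    stage = "setup"
    try:
        # ---- simulate / load ------------------------------------------
        stage = "simulate" if cfg["mode"] == "panel" else "load"
        tree_labels: dict[str, str] = {}
        panel = None
        if cfg["mode"] == "panel":
            panel = generate_heterokont_panel(seed=int(cfg["panel_seed"]))
            sequences = list(panel.sequences)
            write_truth_tables(
                sequences, panel.truth, outdir / "panel.fasta", outdir / "panel_truth.tsv"
            )
            tree_labels = dict(panel.reference_labels)
            _write_labels(tree_labels, outdir / "reference_labels.tsv")
        else:
            report = validate_inputs(
                fasta=cfg["input_fasta"],
                msa=cfg["msa"],
                reference_table=cfg["reference_table"],
                reference_labels=cfg["reference_labels"],
            )
            manifest.warnings.extend(report["warnings"])
            if report["fatal"]:
                raise ValueError("; ".join(report["fatal"]))
            sequences = read_fasta(cfg["input_fasta"])
            if cfg["reference_labels"]:
                tree_labels = _read_labels(cfg["reference_labels"])
        manifest.stage_counts[stage] = len(sequences)

        # ---- references -----------------------------------------------
        stage = "references"
        if cfg["reference_table"] == "packaged":
            refs = packaged_references()
        else:
            refs = load_reference_table(cfg["reference_table"])
        write_reference_table(refs, outdir / "references_used.tsv")
        manifest.stage_counts[stage] = len(refs)

        # ---- scan ------------------------------------------------------
        stage = "scan"
        box_pairs = {}
        with open(outdir / "scan.tsv", "w") as fh:
            fh.write("seq_id\tbox1\tpos1\tbox2\tpos2\tlabel\n")
            for s in sequences:
                pair = scan_npa_boxes(s, min_separation=int(cfg["min_separation"]))
                box_pairs[s.seq_id] = pair
                label = classify_motif_pair(pair)
                b1 = pair.first.motif if pair.first else "-"
                p1 = pair.first.start if pair.first else ""
                b2 = pair.second.motif if pair.second else "-"
                p2 = pair.second.start if pair.second else ""
                fh.write(f"{s.seq_id}\t{b1}\t{p1}\t{b2}\t{p2}\t{label}\n")
                manifest.warnings.extend(f"{s.seq_id}: {w}" for w in pair.warnings)
        manifest.stage_counts[stage] = len(box_pairs)

        # ---- filter extraction ----------------------------------------
        stage = "filter-extract"
        filters = {}
        with open(outdir / "filters.tsv", "w") as fh:
            fh.write("seq_id\tref_used\tH2\tH5\tLE1\tLE2\tfilter\tspecificity\trule_id\n")
            for s in sequences:
                ref = choose_reference(s, refs)
                filt = extract_arr_filter(s, ref)
                filters[s.seq_id] = filt
                spec = infer_specificity(filt)
                fh.write(
                    f"{s.seq_id}\t{ref.ref_id}\t{filt.h2}\t{filt.h5}\t{filt.le1}\t"
                    f"{filt.le2}\t{filt.filter_string}\t{spec.specificity}\t{spec.rule_id}\n"
                )
        manifest.stage_counts[stage] = len(filters)

        # ---- tree ------------------------------------------------------
        tree = None
        if cfg["msa"] not in (None, "none"):
            stage = "tree"
            if cfg["msa"] == "true-alignment":
                msa = panel.msa
            else:
                msa = Msa.from_file(cfg["msa"])
            msa = trim_msa(msa, terminal_gap_fraction=float(cfg["trim_threshold"]))
            dm = jtt_distance_matrix(msa, gap_mode=cfg["gap_mode"])
            dm.to_tsv(outdir / "distances.tsv")
            tree = bootstrap_supports(
                msa,
                n_reps=int(cfg["bootstrap_reps"]),
                seed=int(cfg["bootstrap_seed"]),
                gap_mode=cfg["gap_mode"],
            )
            tree.write(outdir / "tree.nwk")
            manifest.stage_counts[stage] = len(msa.ids)

        # ---- classify --------------------------------------------------
        stage = "classify"
        calls = []
        for s in sequences:
            bundle = EvidenceBundle(
                seq_id=s.seq_id,
                filt=filters[s.seq_id],
                boxes=box_pairs[s.seq_id],
                cterm=s.residues[-1],
            )
            calls.append(
                assign_subfamily(
                    bundle,
                    tree=tree,
                    reference_labels=tree_labels or None,
                    support_threshold=float(cfg["support_threshold"]),
                )
            )
        write_calls_tsv(calls, outdir / "calls.tsv")
        summary = summarize_calls(calls)
        write_summary_json(summary, outdir / "summary.json")
        manifest.stage_counts[stage] = len(calls)

        manifest.status = "ok"
        return manifest
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        raise
    finally:
        manifest.write(manifest_path)
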