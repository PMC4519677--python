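"""End-to-end orchestration: simulate/ingest -> qc -> align -> dist -> gap ->
tree -> design -> multiplex -> ipcr, with a manifest for reproducibility.

A run is described by a config mapping (usually loaded from YAML).  Each
stage logs its inputs, parameters and outputs; the manifest records the
config, the master seed and a SHA-256 checksum of every artifact, so a
rerun with the same config can verify determinism or resume after
completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

from . import barcode_gap, insilico_pcr, marker_design, nj_phylo, seqio
from .alignment import AlignParams, ingest_alignment, progressive_msa
from .distances import distance_matrix
from .errors import PipelineError
from .marker_design import DesignConstraints, ThermoParams
from .quality_control import QCParams, run_qc_batch
from .synthetic_data import SimParams, make_hybrid, simulate_species_set

log = logging.getLogger("barcodekit.pipeline")

STAGES = ["simulate", "qc", "align", "dist", "gap", "tree", "design",
          "multiplex", "ipcr"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config: Mapping[str, Any] | str | Path,
                 resume: bool = False) -> dict[str, Any]:
    """Execute the configured stages in order; returns the manifest.

    Config keys: ``outdir`` (required), ``seed``, ``stages`` (list; default
    all applicable), ``inputs`` (fasta / alignment / species_map paths when
    not simulating), and per-stage parameter blocks ``simulate``, ``qc``,
    ``align``, ``dist``, ``tree``, ``design``, ``multiplex``, ``ipcr``.

    With ``resume=True`` a stage whose outputs already exist under an
    unchanged config is skipped and its artifacts are reused.
    """
    cfg = _load_config(config)
    outdir = Path(cfg.get("outdir", "barcodekit_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    enabled = cfg.get("stages") or STAGES
    manifest: dict[str, Any] = {"config": cfg, "seed": seed, "stages": []}
    prev_path = outdir / "manifest.json"
    prev: dict[str, Any] | None = None
    if resume and prev_path.exists():
        prev = json.loads(prev_path.read_text())
        if prev.get("config") != cfg:
            prev = None

    state: dict[str, Any] = {}

    def record(stage: str, artifacts: dict[str, Path], params: Any) -> None:
        manifest["stages"].append({
            "stage": stage,
            "parameters": params,
            "artifacts": {k: {"path": str(p), "sha256": _sha256(p)}
                          for k, p in artifacts.items()},
        })

    def stage_done(stage: str) -> bool:
        if prev is None:
            return False
        for entry in prev["stages"]:
            if entry["stage"] == stage:
                ok = all(Path(a["path"]).exists() and _sha256(Path(a["path"])) == a["sha256"]
                         for a in entry["artifacts"].values())
                if ok:
                    manifest["stages"].append(entry)
                    return True
        return False

    try:
        _run_stages(cfg, outdir, seed, enabled, state, record, stage_done)
    except PipelineError:
        raise
    except Exception as exc:  # surface the failing stage
        raise PipelineError(f"stage {state.get('current', '?')!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stages(cfg, outdir: Path, seed, enabled, state, record, stage_done):
    inputs = cfg.get("inputs", {})

    # --- simulate ---------------------------------------------------------
    state["current"] = "simulate"
    if "simulate" in enabled and "fasta" not in inputs:
        fasta = outdir / "simulated.fasta"
        smap = outdir / "species_map.tsv"
        truth = outdir / "truth.json"
        if not stage_done("simulate"):
            params = SimParams(seed=seed, **cfg.get("simulate", {}))
            ds = simulate_species_set(params)
            seqio.write_fasta(ds.sequences, fasta)
            seqio.write_species_map(ds.records, smap)
            truth.write_text(json.dumps({
                "tree": ds.tree_newick,
                "planted_sites": [asdict(p) for p in ds.planted_sites],
            }, indent=2))
            record("simulate", {"fasta": fasta, "species_map": smap,
                                "truth": truth}, asdict(params))
        state["fasta"], state["species_map"] = fasta, smap
    else:
        state["fasta"] = Path(inputs["fasta"]) if "fasta" in inputs else None
        state["species_map"] = Path(inputs["species_map"])

    species = seqio.species_lookup(seqio.read_species_map(state["species_map"]))
    state["species_of"] = species

    # --- qc ---------------------------------------------------------------
    state["current"] = "qc"
    if "qc" in enabled and ("fastq" in inputs or "qual" in inputs):
        out_fasta = outdir / "qc_accepted.fasta"
        report = outdir / "qc_report.tsv"
        if not stage_done("qc"):
            if "fastq" in inputs:
                reads = seqio.read_quality(inputs["fastq"])
            else:
                reads = seqio.read_quality(inputs["fasta_raw"], inputs["qual"])
            params = QCParams(**cfg.get("qc", {}))
            results = run_qc_batch(reads, params)
            accepted = {sid: r.sequence.bases for sid, r in results.items()
                        if r.accepted}
            seqio.write_fasta(accepted, out_fasta)
            _write_qc_report(results, report)
            record("qc", {"fasta": out_fasta, "report": report}, asdict(params))
        state["fasta"] = out_fasta

    # --- align ------------------------------------------------------------
    state["current"] = "align"
    aligned = outdir / "aligned.fasta"
    if "alignment" in inputs:
        aln = ingest_alignment(inputs["alignment"], species)
    else:
        if not stage_done("align"):
            seqs = seqio.read_fasta(state["fasta"], allow_gaps=False)
            params = AlignParams(**cfg.get("align", {}))
            aln = progressive_msa(seqs, species, params)
            seqio.write_fasta(dict(zip(aln.ids, aln.rows)), aligned)
            record("align", {"aligned": aligned}, asdict(params))
        aln = ingest_alignment(aligned, species)
    state["aln"] = aln

    # --- dist -------------------------------------------------------------
    state["current"] = "dist"
    dist_path = outdir / "distances.tsv"
    model = cfg.get("dist", {}).get("model", "K2P")
    dmat = distance_matrix(aln, model=model)
    if "dist" in enabled and not stage_done("dist"):
        seqio.write_distance_tsv(dmat, dist_path)
        record("dist", {"distances": dist_path}, {"model": model})
    state["dmat"] = dmat

    # --- gap --------------------------------------------------------------
    state["current"] = "gap"
    if "gap" in enabled and not stage_done("gap"):
        gap_path = outdir / "gap_report.tsv"
        reports = barcode_gap.gap_analysis(dmat, species)
        barcode_gap.write_gap_report(reports, gap_path)
        record("gap", {"gap_report": gap_path},
               {"discriminated": barcode_gap.discrimination_count(reports)})
        state["gap_reports"] = reports

    # --- tree -------------------------------------------------------------
    state["current"] = "tree"
    if "tree" in enabled and not stage_done("tree"):
        tree_path = outdir / "nj_tree.nwk"
        tcfg = cfg.get("tree", {})
        replicates = int(tcfg.get("replicates", 1000))
        tree, dropped = nj_phylo.bootstrap_support(
            aln, replicates=replicates, seed=seed, model=model)
        seqio.write_newick(tree, tree_path)
        record("tree", {"tree": tree_path},
               {"replicates": replicates, "dropped": dropped, "seed": seed})
        state["tree"] = tree

    # --- design -----------------------------------------------------------
    state["current"] = "design"
    markers = []
    if "design" in enabled:
        marker_path = outdir / "markers.tsv"
        if stage_done("design"):
            markers = seqio.read_marker_report(marker_path)
        else:
            dcfg = dict(cfg.get("design", {}))
            thermo = ThermoParams(**dcfg.pop("thermo", {}))
            cons = DesignConstraints(thermo=thermo, **dcfg)
            per_species, tallies = marker_design.design_all_species(aln, cons)
            markers = [ms[0] for ms in per_species.values() if ms]
            seqio.write_marker_report(markers, marker_path)
            record("design", {"markers": marker_path},
                   {"species_with_marker": len(markers),
                    "tallies": {sp: dict(t) for sp, t in tallies.items()}})
        state["markers"] = markers

    # --- multiplex --------------------------------------------------------
    state["current"] = "multiplex"
    if "multiplex" in enabled and markers and not stage_done("multiplex"):
        mcfg = cfg.get("multiplex", {})
        groups, leftover = marker_design.build_multiplex_groups(
            markers, min_separation=int(mcfg.get("min_separation", 30)),
            temp_tolerance=float(mcfg.get("temp_tolerance", 3.0)))
        mpath = outdir / "multiplex_groups.json"
        mpath.write_text(json.dumps({
            "groups": [{"annealing_temp": g.annealing_temp,
                        "markers": [m.name for m in g.members],
                        "sizes": g.sizes()} for g in groups],
            "ungrouped": [{"marker": m.name, "reason": r} for m, r in leftover],
        }, indent=2))
        record("multiplex", {"groups": mpath}, dict(mcfg))

    # --- ipcr -------------------------------------------------------------
    state["current"] = "ipcr"
    if "ipcr" in enabled and markers and not stage_done("ipcr"):
        pcfg = cfg.get("ipcr", {})
        params = insilico_pcr.PCRParams(**pcfg)
        templates = {sid: aln.ungapped(sid) for sid in aln.ids}
        matrix = insilico_pcr.specificity_matrix(markers, templates, species,
                                                 params)
        spath = outdir / "specificity_matrix.tsv"
        matrix.to_dataframe().to_csv(spath, sep="\t")
        record("ipcr", {"specificity": spath},
               {"diagonal": matrix.is_diagonal(), **asdict(params)})
        state["specificity"] = matrix


def _write_qc_report(results, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", "status", "retained_start", "retained_end",
                    "masked", "n_fraction", "reason"])
        for sid, r in results.items():
            s, e = r.sequence.trimmed_range
            w.writerow([sid, r.status, s, e, r.masked_count,
                        f"{r.n_fraction:.4f}", r.reason or ""])


def run_hybrid_test(aln, markers, maternal_species: str,
                    candidate_species: list[str]):
    """Convenience: build a hybrid template from the first sequence of the
    maternal species and infer its seed parent from candidate markers."""
    maternal_sid = next(sid for sid in aln.ids
                        if aln.species_of[sid] == maternal_species)
    _, template = make_hybrid(aln.ungapped(maternal_sid))
    candidates = {m.target_species: m for m in markers
                  if m.target_species in candidate_species}
    return insilico_pcr.infer_maternal_parent(template, candidates)
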