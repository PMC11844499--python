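"""One-command orchestration: simulate -> register -> segment -> decode ->
genotype -> phenotype -> match -> stats.

A single config mapping (YAML on disk) drives every stage; all randomness
flows from one seed. Each run writes its tables plus a manifest (config hash,
package/library versions, per-stage counts) sufficient to reproduce it.
Deterministic stages are bit-identical under the same config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_table
from .segment import SegmentParams, measure_morphology, segment_cells, segment_nuclei
from .register import align_stack
from .decode import decode_stack
from .genotype import genotype_cells
from .match import global_cell_table, match_cells
from .phenotype import mean_if_intensity, quantify_nfish
from .simulate import SimConfig, simulate_screen
from .stats import compare_sgrnas

STAGES = ("simulate", "register", "segment", "decode", "genotype",
          "phenotype", "match", "stats")
_SECTIONS = set(STAGES) | {"seed", "out_dir", "stages"}
# stage -> stages it needs
_DEPS = {
    "register": ("simulate",),
    "segment": ("register",),
    "decode": ("segment",),
    "genotype": ("decode",),
    "phenotype": ("simulate",),
    "match": ("genotype", "phenotype"),
    "stats": ("match",),
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Normalize and validate a pipeline config; unknown keys are rejected."""
    cfg = dict(config or {})
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for sec in STAGES:
        val = cfg.setdefault(sec, {})
        if not isinstance(val, dict):
            raise ConfigError(f"section {sec!r} must be a mapping")
    toggles = cfg.setdefault("stages", {s: True for s in STAGES})
    unknown = set(toggles) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
    for s in STAGES:
        toggles.setdefault(s, True)
    for stage, needs in _DEPS.items():
        if toggles[stage] and not all(toggles[n] for n in needs):
            raise ConfigError(
                f"stage {stage!r} enabled but its dependency "
                f"{[n for n in needs if not toggles[n]]} is disabled"
            )
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "ops_run")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def run_screen(config: dict) -> dict:
    """Run the enabled stages; returns a manifest dict (also written to disk).

    A stage failure raises with the failing stage named; outputs written
    before the failure are retained in ``out_dir``.
    """
    cfg = validate_config(config)
    toggles = cfg["stages"]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "versions": {"opscreen": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "counts": {},
        "outputs": [],
    }

    def _write(name, df):
        write_table(df, out / name)
        manifest["outputs"].append(name)

    state = {}
    stage = "simulate"
    try:
        if toggles["simulate"]:
            sim_kw = dict(cfg["simulate"])
            sim_kw.setdefault("seed", cfg["seed"])
            codebook_csv = sim_kw.pop("codebook_csv", None)
            if codebook_csv:
                from .io import read_codebook

                sim_kw["codebook"] = read_codebook(codebook_csv)
            sim = simulate_screen(SimConfig(**sim_kw))
            state["sim"] = sim
            manifest["counts"]["simulate"] = {
                "n_cells": int(len(sim.truth.cells)),
                "n_spots": int(len(sim.truth.spots)),
                "n_iss_fovs": len(sim.iss_stacks),
                "n_pheno_fovs": len(sim.pheno_images),
            }
            _write("ground_truth_cells.csv", sim.truth.cells)
            _write("ground_truth_spots.csv", sim.truth.spots)
            _write("ground_truth_shifts.csv", sim.truth.shifts)

        if toggles["register"]:
            stage = "register"
            aligned, all_shifts = [], []
            for stack in state["sim"].iss_stacks:
                a, sh = align_stack(stack, **cfg["register"])
                sh["fov_id"] = stack.fov.fov_id
                aligned.append(a)
                all_shifts.append(sh)
            state["aligned"] = aligned
            shifts = pd.concat(all_shifts, ignore_index=True)
            state["shifts"] = shifts
            _write("shifts.csv", shifts)
            manifest["counts"]["register"] = {
                "n_failed_cycles": int(shifts["failed"].sum())
            }

        if toggles["segment"]:
            stage = "segment"
            params = SegmentParams(**cfg["segment"])
            nuclei_by_fov, cells_by_fov, morph = {}, {}, []
            for a in state["aligned"]:
                nuc = segment_nuclei(a.dapi(0), params)
                cells = segment_cells(nuc, a)
                nuclei_by_fov[a.fov.fov_id] = nuc
                cells_by_fov[a.fov.fov_id] = cells
                m = measure_morphology(nuc, a.fov)
                morph.append(global_cell_table(m, a.fov, dataset="iss"))
            state["nuclei"] = nuclei_by_fov
            state["cells"] = cells_by_fov
            iss_cells = pd.concat(morph, ignore_index=True)
            state["iss_cells"] = iss_cells
            _write("iss_cells.csv", iss_cells)
            manifest["counts"]["segment"] = {"n_iss_cells": int(len(iss_cells))}

        if toggles["decode"]:
            stage = "decode"
            reads = []
            for a in state["aligned"]:
                fid = a.fov.fov_id
                sh = state["shifts"][state["shifts"].fov_id == fid]
                reads.append(
                    decode_stack(a, cell_labels=state["cells"][fid],
                                 shifts=sh, **cfg["decode"])
                )
            reads = pd.concat(reads, ignore_index=True)
            state["reads"] = reads
            _write("reads.csv", reads)
            manifest["counts"]["decode"] = {
                "n_spots": int(len(reads)),
                "n_consistent": int(reads["consistent"].sum()),
            }

        if toggles["genotype"]:
            stage = "genotype"
            cb = state["sim"].config.codebook
            tables, summaries = [], []
            for a in state["aligned"]:
                fid = a.fov.fov_id
                labels = sorted(
                    int(x) for x in np.unique(state["cells"][fid]) if x > 0
                )
                sub = state["reads"][state["reads"].fov_id == fid]
                t, s = genotype_cells(sub, labels, cb, **cfg["genotype"])
                t["fov_id"] = fid
                tables.append(t)
                summaries.append(s)
            genotypes = pd.concat(tables, ignore_index=True)
            n_cells_total = sum(s["n_cells"] for s in summaries)
            total_reads = int(genotypes["n_reads"].sum())
            mapped_reads = sum(
                s["fraction_reads_mapped"]
                * t["n_reads"].sum()
                for s, t in zip(summaries, tables)
            )
            state["genotypes"] = genotypes
            _write("genotypes.csv", genotypes)
            manifest["counts"]["genotype"] = {
                "n_cells": int(len(genotypes)),
                "n_mapped": int((genotypes.mapped_sgrna_id != "unmapped").sum()),
                "fraction_cells_with_reads": (
                    float((genotypes["n_reads"] > 0).mean())
                    if n_cells_total else 0.0
                ),
                "reads_per_cell_mean": (
                    float(genotypes["n_reads"].mean()) if n_cells_total else 0.0
                ),
                "fraction_reads_mapped": (
                    float(mapped_reads / total_reads) if total_reads else 0.0
                ),
            }

        if toggles["phenotype"]:
            stage = "phenotype"
            mode = cfg["phenotype"].get("mode", "nfish")
            spot_kw = {k: v for k, v in cfg["phenotype"].items() if k != "mode"}
            phen, pheno_cells = [], []
            params = SegmentParams(**cfg["segment"]) if toggles["segment"] \
                else SegmentParams()
            for img in state["sim"].pheno_images:
                nuc = segment_nuclei(img.dapi, params)
                if mode == "nfish":
                    rec = quantify_nfish(img.signal, nuc,
                                         fov_id=img.fov.fov_id, **spot_kw)
                else:
                    rec = mean_if_intensity(nuc, img.signal,
                                            fov_id=img.fov.fov_id)
                phen.append(rec)
                # cells sliced by the tile border are fragments; the overlap
                # of the phenotype tiling guarantees each cell is whole in
                # at least one tile
                m = measure_morphology(nuc, img.fov)
                m = m[~m.touches_border]
                pheno_cells.append(
                    global_cell_table(m, img.fov, dataset="phenotype")
                )
            phenotypes = (pd.concat(phen, ignore_index=True) if phen
                          else pd.DataFrame())
            pheno_cells = (pd.concat(pheno_cells, ignore_index=True)
                           if pheno_cells else pd.DataFrame())
            state["phenotypes"] = phenotypes
            state["pheno_cells"] = pheno_cells
            _write("phenotypes.csv", phenotypes)
            _write("pheno_cells.csv", pheno_cells)
            manifest["counts"]["phenotype"] = {
                "n_pheno_cells": int(len(pheno_cells))
            }

        if toggles["match"]:
            stage = "match"
            matches = match_cells(state["iss_cells"], state["pheno_cells"],
                                  **cfg["match"])
            _write("matches.csv", matches)
            gt = state["genotypes"].set_index(["fov_id", "cell_label"])
            ph = state["phenotypes"].set_index(["fov_id", "cell_label"])
            rows = []
            for m in matches[matches.accepted].itertuples(index=False):
                gkey = (m.iss_fov, m.iss_label)
                pkey = (m.pheno_fov, m.pheno_label)
                if gkey not in gt.index or pkey not in ph.index:
                    continue
                g = gt.loc[gkey]
                p = ph.loc[pkey]
                val = (p["nfish_integrated_intensity"]
                       if "nfish_integrated_intensity" in p
                       else p["mean_intensity"])
                rows.append(dict(
                    iss_fov=m.iss_fov, iss_label=m.iss_label,
                    pheno_fov=m.pheno_fov, pheno_label=m.pheno_label,
                    sgrna_id=g["mapped_sgrna_id"], gene=g["gene"],
                    value=float(val),
                ))
            matched = pd.DataFrame(
                rows, columns=["iss_fov", "iss_label", "pheno_fov",
                               "pheno_label", "sgrna_id", "gene", "value"])
            state["matched"] = matched
            _write("matched_cells.csv", matched)
            manifest["counts"]["match"] = {
                "n_candidates": int(len(matches)),
                "n_accepted": int(matches.accepted.sum()),
                "n_genotyped_matches": int(len(matched)),
                "offset_um": list(matches.attrs.get("offset_um", (0, 0))),
            }

        if toggles["stats"]:
            stage = "stats"
            skw = dict(cfg["stats"])
            control_ids = skw.pop("control_ids", None)
            if control_ids is None:
                control_ids = sorted(
                    state["sim"].config.codebook.control_ids())
            usable = state["matched"][
                state["matched"].sgrna_id != "unmapped"]
            results = compare_sgrnas(usable, control_ids, **skw)
            state["results"] = results
            _write("results.csv", results)
            manifest["counts"]["stats"] = {
                "n_tests": int(results["n_tests"].iloc[0]) if len(results)
                else 0
            }
    except Exception as e:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    manifest["state"] = state
    return manifest
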