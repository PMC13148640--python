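"""End-to-end pipeline driver.

Runs the stages in dependency order on a config dict (or YAML file):
body-segment parameters -> joint-limit table -> moment-arm report ->
parsimony muscle map -> stance battery; writes CSV/JSON artifacts and a log
of each stage's inputs and outputs. Re-running with the same config and
seed reproduces the outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import epb, mesh_body, muscles as muscles_mod, stance, synthetic
from .config import gracilisuchus_rom_table
from .joints import rom_table


class StageError(RuntimeError):
    pass


def run_pipeline(config: dict = None, out_dir="pipeline_out", seed: int = 0) -> dict:
    """Run the full analysis on the synthetic taxon (default config) or on
    user-supplied inputs, writing a report bundle under ``out_dir``.

    Returns a dict of stage results. Stages: ``bsp`` (segment masses, whole-
    body COM, bipedality ratio), ``rom`` (joint-limit table), ``mma`` (mean
    dimensionless moment arms), ``epb`` (muscle map), ``stance`` (mass
    allometry, LDA battery, static criterion).
    """
    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []
    results = {}

    def stage(name, fn):
        try:
            results[name] = fn()
            log.append(f"stage {name}: ok")
        except Exception as e:
            log.append(f"stage {name}: FAILED ({e})")
            (out / "pipeline.log").write_text("\n".join(log) + "\n")
            raise StageError(f"stage {name!r} failed: {e}") from e

    spec = synthetic.ToyTaxonSpec(seed=seed, **config.get("toy_spec", {}))

    def bsp_stage():
        model, chain, oracle = synthetic.make_toy_skeleton(spec)
        summary = mesh_body.whole_body_summary(model)
        df = pd.DataFrame([
            {"segment": name, "mass_kg": p.mass, "volume_m3": p.volume,
             "net_density": p.net_density,
             "com_x": p.com[0], "com_y": p.com[1], "com_z": p.com[2],
             "mass_fraction": summary.mass_fractions[name]}
            for name, p in summary.segment_properties.items()])
        df.to_csv(out / "bsp.csv", index=False)
        return {"model": model, "chain": chain, "summary": summary,
                "oracle": oracle}

    stage("bsp", bsp_stage)

    def rom_stage():
        toy = rom_table(results["bsp"]["chain"])
        toy.to_csv(out / "rom_toy.csv", index=False)
        packaged = gracilisuchus_rom_table()
        packaged.to_csv(out / "rom_gracilisuchus.csv", index=False)
        return {"toy": toy, "packaged": packaged}

    stage("rom", rom_stage)

    def mma_stage():
        chain = results["bsp"]["chain"]
        mus, registry = synthetic.make_toy_muscles(spec)
        report = muscles_mod.mma_report(
            chain, mus, [("hip", "z"), ("knee", "z")],
            normalizing_lengths={"hip": spec.femur_length,
                                 "knee": abs(spec.limb_segments["crus"][1]
                                             - spec.limb_segments["crus"][0])})
        report.to_csv(out / "mma.csv", index=False)
        return {"report": report, "registry": registry}

    stage("mma", mma_stage)

    def epb_stage():
        tree, matrix, oracle = synthetic.make_toy_characters(seed=seed + 1)
        state_map = epb.fitch_optimize(tree, matrix)
        mismatches = sum(
            1 for ci, o in oracle.items()
            if state_map.change_counts[ci] != o["min_changes"])
        attachments = epb.load_attachment_dictionary()
        muscle_map = epb.build_muscle_map(attachments)
        muscle_map.to_csv(out / "muscle_map.csv", index=False)
        return {"state_map": state_map, "oracle_mismatches": mismatches,
                "muscle_map": muscle_map}

    stage("epb", epb_stage)

    def stance_stage():
        summary = results["bsp"]["summary"]
        dims = config.get("stylopodial_mm", (14.0, 13.0))
        mass_allom = stance.campione_evans_mass(*dims)
        dataset = synthetic.make_toy_morphometrics(seed=seed)
        verdict = stance.lda_stance_tests(dataset, "Focalus", seed=seed)
        static = stance.static_bipedalism_check(
            summary.com_cranial_offset, results["bsp"]["model"].femur_length)
        report = {
            "allometric_mass_kg": mass_allom,
            "model_mass_kg": summary.total_mass,
            "allometric_to_model_percent": 100 * mass_allom / summary.total_mass,
            "lda": verdict.summary(),
            "lda_quadrupedal": verdict.n_quadrupedal,
            "lda_tests": verdict.n_tests,
            "static_bipedalism": static.verdict,
            "com_offset_percent_femur": static.percent,
        }
        (out / "stance.json").write_text(json.dumps(report, indent=2))
        return {"report": report, "verdict": verdict, "static": static}

    stage("stance", stance_stage)

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return results
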