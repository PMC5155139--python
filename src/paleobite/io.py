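"""CSV/YAML I/O and end-to-end pipeline orchestration.

Two entry points mirror the study workflow: :func:`run_palaeoecology`
(body mass -> prey size -> bite force / BFQ -> relative premolar size ->
bending strengths -> microwear placement) and :func:`run_phylogeny`
(search -> length / CI / RI -> strict consensus -> Bremer -> optional
Templeton tests).  Stages whose inputs are absent from the config are
skipped and marked so in the report; every executed stage logs its
inputs and parameters.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, biomechanics, microwear
from .coefficients import SYNTHETIC_MASS_MODELS, SYNTHETIC_PREY_MODEL
from .parsimony import (bremer_support, ensemble_ci_ri, heuristic_search,
                        read_matrix, templeton_test, tree_length, Tree,
                        strict_consensus)

logger = logging.getLogger(__name__)

__all__ = [
    "load_config", "read_lever_csv", "read_sections_csv",
    "read_microwear_csv", "run_palaeoecology", "run_phylogeny",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# CSV readers

def read_lever_csv(path: str | Path) -> list[biomechanics.SkullLeverMeasurements]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(biomechanics.SkullLeverMeasurements(
            specimen_id=str(row["specimen_id"]),
            temporalis_area_mm2=float(row["temporalis_area_mm2"]),
            masseter_pterygoid_area_mm2=float(row["masseter_pterygoid_area_mm2"]),
            temporalis_arm_mm=float(row["temporalis_arm_mm"]),
            masseter_arm_mm=float(row["masseter_arm_mm"]),
            outlever_canine_mm=float(row["outlever_canine_mm"]),
            outlever_m1_mm=float(row["outlever_m1_mm"]),
            side=str(row.get("side", "left")),
        ))
    return out


def read_sections_csv(path: str | Path) -> list[biomechanics.BeamSection]:
    df = pd.read_csv(path)
    return [
        biomechanics.BeamSection(
            location=str(row["location"]),
            d_ap_mm=float(row["d_ap_mm"]),
            d_ml_mm=float(row["d_ml_mm"]),
            arm_mm=float(row["arm_mm"]),
        )
        for _, row in df.iterrows()
    ]


def read_microwear_csv(path: str | Path) -> list[microwear.MicrowearCounts]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        counts = np.array([float(row[f]) for f in microwear.FEATURE_NAMES])
        out.append(microwear.MicrowearCounts(
            specimen_id=str(row["specimen_id"]),
            counts=counts,
            taxon=str(row.get("taxon", "")),
            diet_category=str(row.get("diet_category", "unknown")),
            damaged=bool(row.get("damaged", False)),
        ))
    return out


def _model_from_block(block: dict, response_units: str = "kg"
                      ) -> allometry.AllometricModel:
    return allometry.AllometricModel(
        slope=float(block["slope"]),
        intercept=float(block["intercept"]),
        n=int(block.get("n", 3)),
        pe_fraction=block.get("pe_fraction"),
        re_factor=float(block.get("re_factor", 1.0)),
        response_units=response_units,
    )


# ---------------------------------------------------------------------------
# palaeoecology pipeline

def run_palaeoecology(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the craniodental palaeoecology stages named in config.

    Returns the report dict; with ``output_dir`` set, also writes
    ``palaeoecology_report.json`` and a human-readable summary.
    """
    report: dict = {"stages": {}}

    # --- body mass ----------------------------------------------------
    mass_cfg = config.get("body_mass")
    estimates: list[allometry.MassEstimate] = []
    if mass_cfg:
        models = {
            name: _model_from_block(blk)
            for name, blk in mass_cfg.get(
                "models", SYNTHETIC_MASS_MODELS).items()
        }
        if "models" not in mass_cfg:
            logger.warning("body_mass: using shipped SYNTHETIC placeholder "
                           "coefficients (non-canonical)")
        for m in mass_cfg.get("measurements", []):
            model = models[m["predictor_name"]]
            est = allometry.estimate_body_mass(
                float(m["value_mm"]), model,
                predictor_name=m["predictor_name"],
                specimen_id=str(m.get("specimen_id", "")),
            )
            estimates.append(est)
            logger.info("body_mass %s/%s: %.3f kg", est.specimen_id,
                        est.predictor_name, est.point_kg)
        report["stages"]["body_mass"] = [
            {"specimen_id": e.specimen_id, "predictor": e.predictor_name,
             "point_kg": round(e.point_kg, 1), "lo_kg": round(e.lo_kg, 1),
             "hi_kg": round(e.hi_kg, 1)}
            for e in (e.rounded() for e in estimates)
        ]
    else:
        report["stages"]["body_mass"] = "skipped"

    def preferred_mass() -> float | None:
        if not estimates:
            val = config.get("body_mass_kg")
            return float(val) if val is not None else None
        # the predictor with the lowest prediction-error fraction wins
        best_pe = min(estimates,
                      key=lambda e: (e.hi_kg - e.point_kg) / e.point_kg)
        return best_pe.point_kg

    def maximum_mass() -> float | None:
        if estimates:
            return max(e.point_kg for e in estimates)
        val = config.get("body_mass_kg")
        return float(val) if val is not None else None

    # --- prey size ----------------------------------------------------
    prey_cfg = config.get("prey_size")
    if prey_cfg is not None:
        mass = prey_cfg.get("predator_mass_kg") or maximum_mass()
        if mass is None:
            report["stages"]["prey_size"] = "skipped"
        else:
            if "training_csv" in prey_cfg:
                df = pd.read_csv(prey_cfg["training_csv"])
                model = allometry.fit_loglog(df["x"], df["y"])
            elif "model" in prey_cfg:
                model = _model_from_block(prey_cfg["model"])
            else:
                model = _model_from_block(SYNTHETIC_PREY_MODEL)
                logger.warning("prey_size: using shipped SYNTHETIC placeholder "
                               "coefficients (non-canonical)")
            est = allometry.estimate_max_prey_size(float(mass), model)
            report["stages"]["prey_size"] = {
                "predator_mass_kg": round(est.predator_mass_kg, 1),
                "point_kg": round(est.point_kg, 1),
                "ci95_lo_kg": round(est.ci95_lo_kg, 1),
                "ci95_hi_kg": round(est.ci95_hi_kg, 1),
            }
    else:
        report["stages"]["prey_size"] = "skipped"

    # --- bite force / BFQ --------------------------------------------
    bf_cfg = config.get("bite_force")
    if bf_cfg:
        stress = float(bf_cfg.get("muscle_stress_kPa", 300.0))
        levers = read_lever_csv(bf_cfg["levers_csv"]) \
            if "levers_csv" in bf_cfg else []
        rows = []
        for meas in levers:
            est = biomechanics.bite_force_estimate(meas, stress)
            row = {"specimen_id": meas.specimen_id,
                   "canine_force_N": round(est.canine_force_N),
                   "molar_force_N": round(est.molar_force_N)}
            if "comparative_csv" in bf_cfg:
                comp = pd.read_csv(bf_cfg["comparative_csv"])
                mass = bf_cfg.get("body_mass_kg") or maximum_mass()
                if mass is not None:
                    logger.info("bfq: using body mass %.3f kg (maximum of "
                                "supplied estimates unless overridden)", mass)
                    row["bfq"] = round(biomechanics.bite_force_quotient(
                        float(mass), est.canine_force_N,
                        comp[["mass_kg", "force_N"]].to_numpy()))
            rows.append(row)
            logger.info("bite_force %s: canine %.1f N at %s kPa",
                        meas.specimen_id, est.canine_force_N, stress)
        report["stages"]["bite_force"] = rows
    else:
        report["stages"]["bite_force"] = "skipped"

    # --- relative premolar size --------------------------------------
    rps_cfg = config.get("rps")
    if rps_cfg:
        mass = rps_cfg.get("body_mass_kg") or preferred_mass()
        if mass is None:
            report["stages"]["rps"] = "skipped"
        else:
            val = allometry.relative_premolar_size(
                float(rps_cfg["premolar_width_mm"]), float(mass))
            report["stages"]["rps"] = {
                "premolar_width_mm": val.premolar_width_mm,
                "body_mass_kg": val.body_mass_kg,
                "rps": round(val.rps, 2),
            }
    else:
        report["stages"]["rps"] = "skipped"

    # --- bending strengths -------------------------------------------
    bend_cfg = config.get("bending")
    if bend_cfg:
        sections = read_sections_csv(bend_cfg["sections_csv"])
        canines = [s for s in sections if s.location == "canine"]
        gaps = [s for s in sections if s.location != "canine"]
        rows = []
        for s in canines:
            bs = biomechanics.canine_bending_strength(s)
            rows.append({"location": "canine", "sx": bs.zx_over_arm,
                         "sy": bs.zy_over_arm, "zx_over_zy": bs.zx_over_zy})
        if gaps:
            for bs in biomechanics.mandible_force_profile(gaps):
                rows.append({"location": bs.location,
                             "zx_over_arm": bs.zx_over_arm,
                             "zy_over_arm": bs.zy_over_arm,
                             "zx_over_zy": bs.zx_over_zy})
        report["stages"]["bending"] = rows
    else:
        report["stages"]["bending"] = "skipped"

    # --- microwear placement -----------------------------------------
    mw_cfg = config.get("microwear")
    if mw_cfg:
        counts = read_microwear_csv(mw_cfg["counts_csv"])
        refs, queries, excluded = [], [], []
        for c in counts:
            try:
                prof = microwear.normalize_counts(c)
            except ValueError as exc:
                excluded.append({"specimen_id": c.specimen_id,
                                 "reason": str(exc)})
                continue
            (queries if c.diet_category == "unknown" else refs).append(prof)
        metric = mw_cfg.get("metric", "bray-curtis")
        k = int(mw_cfg.get("k", 5))
        logger.info("microwear: %s metric, k=%d", metric, k)
        placements = []
        if refs and queries:
            clf = microwear.MicrowearDietClassifier(k=k, metric=metric)
            clf.fit(refs)
            for q in queries:
                r = clf.rank(q)
                placements.append({
                    "specimen_id": q.specimen_id,
                    "predicted": r["predicted"],
                    "tie": r["tie"],
                    "neighbours": r["neighbours"],
                })
        report["stages"]["microwear"] = {
            "n_references": len(refs), "n_queries": len(queries),
            "excluded": excluded, "placements": placements,
        }
    else:
        report["stages"]["microwear"] = "skipped"

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "palaeoecology_report.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
        (outdir / "palaeoecology_summary.txt").write_text(_summarize(report))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _summarize(report: dict) -> str:
    lines = ["palaeoecology pipeline summary", "=" * 32]
    for stage, result in report["stages"].items():
        if result == "skipped":
            lines.append(f"{stage}: skipped (no input supplied)")
        else:
            lines.append(f"{stage}: {json.dumps(result, default=_json_default)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# phylogeny pipeline

def run_phylogeny(config: dict, output_dir: str | Path | None = None) -> dict:
    """Parsimony search, fit indices, consensus, Bremer and optional
    Templeton tests, per the config's ``phylogeny`` block."""
    cfg = config.get("phylogeny", config)
    matrix = read_matrix(cfg["matrix"], cfg.get("format"))
    seed = int(cfg.get("seed", 0))
    replicates = int(cfg.get("replicates", 10))
    logger.info("phylogeny: %d taxa x %d characters, %d replicates, seed %d",
                matrix.n_taxa, matrix.n_char, replicates, seed)
    result = heuristic_search(matrix, n_replicates=replicates, seed=seed)
    ci, ri = ensemble_ci_ri(result.trees[0], matrix)
    consensus = strict_consensus(result.trees)
    bremer = bremer_support(matrix, result.trees,
                            max_extra_steps=int(cfg.get("bremer_window", 3)),
                            seed=seed)
    report: dict = {
        "n_taxa": matrix.n_taxa,
        "n_char": matrix.n_char,
        "best_length": result.best_length,
        "n_mpts": len(result.trees),
        "ci": round(ci, 3),
        "ri": round(ri, 3),
        "consensus_newick": consensus.to_newick(),
        "bremer": [
            {"clade": sorted(clade),
             "decay": (d if math.isfinite(d) else None)}
            for clade, d in bremer.items()
        ],
    }
    alts = cfg.get("alternative_trees", [])
    if alts:
        tests = []
        for path in alts:
            alt = Tree.from_newick(Path(path).read_text())
            res = templeton_test(result.trees[0], alt, matrix)
            tests.append({
                "alternative": str(path),
                "length_difference": int(res.differences.sum()),
                "n_nonzero": res.n_nonzero,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            })
        report["templeton"] = tests
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "phylogeny_report.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
        (outdir / "mpts.nwk").write_text(
            "\n".join(t.to_newick() for t in result.trees) + "\n")
        (outdir / "consensus.nwk").write_text(consensus.to_newick() + "\n")
    return report
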