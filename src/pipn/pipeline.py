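"""End-to-end orchestration: synthesize (or load) inputs, run the selected
analysis arms, write CSV outputs plus a run manifest.

A run is configured by a single YAML document::

    seed: 17
    arms:
      pharmacovigilance:
        generate: {n_reports: 20000, exposure_odds_multiplier: 0.5}
        # or: inputs: {drugs: drug.txt, reacs: reac.txt, delim: "$"}
        target_drug: paclitaxel
      vonfrey:
        generate:
          n_sessions_per_group: 8
          groups: {vehicle: 12.0, paclitaxel: 2.0}
      morphometry:
        generate:
          groups:
            control: {degeneration_level: 0.0}
            degenerated: {degeneration_level: 0.6}

Exactly one of ``generate`` / ``inputs`` per arm; ``seed`` is mandatory
whenever any arm generates.  Identical config + seed produces byte-identical
outputs (the manifest records no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from pipn import __version__
from pipn.disproportionality import (
    ALPHA1_ANTAGONISTS,
    PIPN_CASE_DEFINITION,
    signal_table,
    select_target_reports,
)
from pipn.errors import ValidationError
from pipn.report_model import CaseDefinition, DrugGroup, ReportSet, normalize_name, read_reports
from pipn.synthetic_data import (
    NerveSynthParams,
    SyntheticReportParams,
    UpDownSimParams,
    generate_nerve_cross_section,
    generate_reports,
    generate_updown_session,
)
from pipn.vonfrey import estimate_threshold, summarize_groups, tukey_kramer
from pipn.morphometry import fibers_from_frame, measure_fiber, summarize_nerve

logger = logging.getLogger(__name__)

ARMS = ("pharmacovigilance", "vonfrey", "morphometry")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Any) -> None:
    if not isinstance(cfg, dict) or "arms" not in cfg or not isinstance(cfg["arms"], dict):
        raise ValidationError("config must be a mapping with an 'arms' section")
    unknown = set(cfg["arms"]) - set(ARMS)
    if unknown:
        raise ValidationError(f"unknown arms {sorted(unknown)}; valid: {ARMS}")
    needs_seed = False
    for arm, arm_cfg in cfg["arms"].items():
        if not isinstance(arm_cfg, dict):
            raise ValidationError(f"arm {arm!r} must be a mapping")
        has_gen, has_in = "generate" in arm_cfg, "inputs" in arm_cfg
        if has_gen == has_in:
            raise ValidationError(
                f"arm {arm!r}: exactly one of 'generate' or 'inputs' is required"
            )
        needs_seed |= has_gen
    if needs_seed and not isinstance(cfg.get("seed"), int):
        raise ValidationError("an integer 'seed' is mandatory when any arm generates data")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    return len(df)


def _signals_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group_name,
                "n11": r.table.n11,
                "n12": r.table.n12,
                "n21": r.table.n21,
                "n22": r.table.n22,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "yates_applied": r.yates_applied,
                "haldane_applied": r.haldane_applied,
                "rate_exposed_pct": 100 * r.reporting_rate_exposed,
                "rate_unexposed_pct": 100 * r.reporting_rate_unexposed,
            }
        )
    return pd.DataFrame(rows)


def _run_pharmacovigilance(arm_cfg: dict, seed: int | None, out: Path) -> dict:
    if "generate" in arm_cfg:
        params = SyntheticReportParams(**{"seed": seed, **arm_cfg["generate"]})
        rs, truth = generate_reports(params)
        truth_info = {"realized_table": truth.table.as_tuple(), "n_target": truth.n_target}
    else:
        inp = arm_cfg["inputs"]
        rs = read_reports(inp["drugs"], inp["reacs"], dialect=inp.get("delim", "$"))
        truth_info = {"input_digests": {k: _digest(Path(inp[k])) for k in ("drugs", "reacs")}}
    target = normalize_name(arm_cfg.get("target_drug", "paclitaxel"))
    cd = (
        CaseDefinition(arm_cfg["case_definition"]["name"], frozenset(map(normalize_name, arm_cfg["case_definition"]["terms"])))
        if "case_definition" in arm_cfg
        else PIPN_CASE_DEFINITION
    )
    if "groups" in arm_cfg:
        groups = [DrugGroup(n, frozenset(map(normalize_name, m))) for n, m in arm_cfg["groups"].items()]
    else:
        groups = [DrugGroup("tamsulosin", frozenset({"tamsulosin"})), ALPHA1_ANTAGONISTS]
    stratum = select_target_reports(rs, target)
    results = signal_table(
        stratum,
        groups,
        cd,
        z=float(arm_cfg.get("z", 1.96)),
        yates_policy=arm_cfg.get("yates_policy", "observed"),
        haldane=bool(arm_cfg.get("haldane", False)),
    )
    n = _write_csv(_signals_frame(results), out / "signals.csv")
    return {"outputs": {"signals.csv": n}, "n_reports": len(rs), "n_target": len(stratum), **truth_info}


def _run_vonfrey(arm_cfg: dict, seed: int | None, out: Path) -> dict:
    rows = []
    if "generate" in arm_cfg:
        gen = arm_cfg["generate"]
        n_per = int(gen.get("n_sessions_per_group", 8))
        shared = {
            k: gen[k]
            for k in ("slope", "filament_forces_g", "max_trials", "n_after_reversal")
            if k in gen
        }
        if "filament_forces_g" in shared:
            shared["filament_forces_g"] = tuple(shared["filament_forces_g"])
        for gi, (group, thr) in enumerate(sorted(gen["groups"].items())):
            for j in range(n_per):
                params = UpDownSimParams(
                    true_threshold_g=float(thr), seed=seed + 1000 * gi + j, **shared
                )
                s = generate_updown_session(params, session_id=f"{group}_{j:02d}")
                est = estimate_threshold(
                    s, params.n_after_reversal, params.max_trials
                )
                rows.append(
                    {
                        "session_id": s.session_id,
                        "group": group,
                        "threshold_g": est.threshold_g,
                        "censored": est.censored,
                        "n_trials": est.n_trials,
                    }
                )
        thresholds = pd.DataFrame(rows)
    else:
        sessions = pd.read_csv(arm_cfg["inputs"]["sessions"])
        from pipn.vonfrey import session_from_forces

        for sid, sub in sessions.groupby("session_id", sort=True):
            sub = sub.sort_values("trial_index")
            s = session_from_forces(str(sid), sub["force_g"], sub["response"].astype(bool))
            est = estimate_threshold(s)
            rows.append(
                {
                    "session_id": sid,
                    "group": sub["group"].iloc[0] if "group" in sub else "all",
                    "threshold_g": est.threshold_g,
                    "censored": est.censored,
                    "n_trials": est.n_trials,
                }
            )
        thresholds = pd.DataFrame(rows)
    n1 = _write_csv(thresholds, out / "thresholds.csv")
    summary = summarize_groups(thresholds)
    n2 = _write_csv(summary, out / "vonfrey_summary.csv")
    info = {"outputs": {"thresholds.csv": n1, "vonfrey_summary.csv": n2}}
    by_group = {g: sub["threshold_g"].tolist() for g, sub in thresholds.groupby("group")}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        tk = tukey_kramer(by_group)
        n3 = _write_csv(tk.comparisons, out / "vonfrey_comparisons.csv")
        info["outputs"]["vonfrey_comparisons.csv"] = n3
        info["anova_f"] = tk.anova_f
    return info


def _run_morphometry(arm_cfg: dict, seed: int | None, out: Path) -> dict:
    per_group_fibers: dict[str, list] = {}
    if "generate" in arm_cfg:
        for gi, (group, gspec) in enumerate(sorted(arm_cfg["generate"]["groups"].items())):
            params = NerveSynthParams(**{"seed": seed + 7000 + gi, **gspec})
            per_group_fibers[group] = generate_nerve_cross_section(params)
    else:
        df = pd.read_csv(arm_cfg["inputs"]["fibers"])
        per_group_fibers["all"] = fibers_from_frame(df)
    contour = arm_cfg.get("circularity_contour", "axon")
    rows, summaries = [], []
    for group, fibers in per_group_fibers.items():
        morphs = [measure_fiber(f, contour) for f in fibers]
        for m in morphs:
            rows.append({"group": group, **dataclasses.asdict(m)})
        s = summarize_nerve(morphs)
        s.insert(0, "group", group)
        summaries.append(s)
    n1 = _write_csv(pd.DataFrame(rows), out / "morphometry.csv")
    n2 = _write_csv(pd.concat(summaries, ignore_index=True), out / "nerve_summary.csv")
    return {"outputs": {"morphometry.csv": n1, "nerve_summary.csv": n2}}


_RUNNERS = {
    "pharmacovigilance": _run_pharmacovigilance,
    "vonfrey": _run_vonfrey,
    "morphometry": _run_morphometry,
}


def run(cfg: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured arms; returns (and writes) the run manifest.

    A failing arm is recorded in the manifest with its error and does not
    abort the other arms; at least one failure makes the caller exit
    non-zero.
    """
    validate_config(cfg)
    if seed is None:
        seed = cfg.get("seed")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "arms": {},
        "errors": {},
    }
    for arm, arm_cfg in sorted(cfg["arms"].items()):
        try:
            manifest["arms"][arm] = _RUNNERS[arm](arm_cfg, seed, out)
            logger.info("arm %s completed: %s", arm, manifest["arms"][arm].get("outputs"))
        except Exception as exc:  # keep other arms running
            logger.error("arm %s failed: %s", arm, exc)
            manifest["errors"][arm] = f"{type(exc).__name__}: {exc}"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
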