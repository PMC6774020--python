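"""Directory-level orchestration of the full analysis.

`run_discovery` loads (or simulates) a cohort, fits :class:`TMIModel`, and
writes every artifact plus a machine-readable manifest recording thresholds,
seed and decision flags. `run_validation` reloads the frozen discovery
artifacts — asserting by hash that nothing was re-estimated — and writes the
validation stratification report. `report` renders composition tables and an
oncoprint-style acquired-mutation matrix.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import pandas as pd

from .model import AnalysisConfig, PREDICTORS, TMIModel, TMIResults
from .resistance import acquired_gene_frequencies, acquired_mutation_set
from .scoring import NB
from .survival import SUBGROUP_PREDICATES, km_estimate
from .simulate import SimulationConfig, read_fixture, simulate_cohort, write_fixture

MANIFEST_FILE = "manifest.json"


def simulate_fixture(
    sim_config: SimulationConfig, fixture_dir: str | Path
) -> dict[str, Path]:
    """Generate a synthetic cohort and write it as a fixture directory."""
    return write_fixture(simulate_cohort(sim_config), fixture_dir)


def run_discovery(
    fixture_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    discovery_ids: list[str] | None = None,
) -> TMIResults:
    """Fit the model on a fixture directory and write all artifacts."""
    fixture_dir = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = TMIModel.from_fixture(fixture_dir, config=config)
    results = model.fit(discovery_ids=discovery_ids)

    results.burdens.to_csv(out / "burdens.tsv", sep="\t")
    results.nb_screen.assign(benefit=results.benefit).to_csv(
        out / "nb_screen.tsv", sep="\t"
    )
    results.unfavorable.to_tsv(out / "unfavorable_mutations.tsv")
    pd.DataFrame(
        {
            "patient_id": results.analysis_ids,
            "ums": results.predictor_values.loc[results.analysis_ids, "UMS"].astype(int),
        }
    ).assign(group=lambda d: d["ums"].map(
        lambda s: "positive" if s >= results.config.positive_min else "negative"
    )).to_csv(out / "ums_scores.tsv", sep="\t", index=False)
    results.scorecards_frame().to_csv(out / "tmi_scorecards.tsv", sep="\t",
                                      index=False)

    evaluations = {
        name: _evaluation_to_dict(ev) for name, ev in results.evaluations.items()
    }
    (out / "predictor_evaluations.json").write_text(
        json.dumps(evaluations, indent=1, sort_keys=True, default=float) + "\n"
    )

    manifest = {
        "fixture_dir": str(fixture_dir),
        "frozen": results.frozen_artifacts(),
        "frozen_hash": results.frozen_hash(),
        "tmi_cutoff_source": results.tmi_cutoff_source,
        "counts": {
            "patients": int(len(model.clinical)),
            "nb_excluded": int((results.benefit == NB).sum()),
            "analysis": len(results.analysis_ids),
            "discovery": len(results.discovery_ids),
            "validation": len(results.validation_ids),
            "unfavorable": len(results.unfavorable),
            "tested_mutations": results.unfavorable.n_tested,
        },
    }
    (out / MANIFEST_FILE).write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float) + "\n"
    )
    return results


def _refit_from_manifest(out_dir: Path) -> TMIResults:
    from .model import hash_frozen

    manifest = json.loads((out_dir / MANIFEST_FILE).read_text())
    frozen = manifest["frozen"]
    if hash_frozen(frozen) != manifest["frozen_hash"]:
        raise RuntimeError("frozen discovery artifacts do not match their hash")
    cfg_dict = dict(frozen["config"])
    if cfg_dict.get("panel") is not None:
        cfg_dict["panel"] = tuple(cfg_dict["panel"])
    config = AnalysisConfig(**cfg_dict)
    model = TMIModel.from_fixture(manifest["fixture_dir"], config=config)
    results = model.fit(discovery_ids=frozen["discovery_ids"])
    if results.frozen_hash() != manifest["frozen_hash"]:
        raise RuntimeError(
            "frozen discovery artifacts changed between discovery and validation"
        )
    return results


def run_validation(out_dir: str | Path) -> dict:
    """Validate with discovery-frozen parameters; writes validation.json."""
    out = Path(out_dir)
    results = _refit_from_manifest(out)
    report = results.validate()
    payload = {
        "tmi_cutoff": report.tmi_cutoff,
        "test": report.test,
        "frozen_hash": report.frozen_hash,
        "arms": {
            name: {
                "status": arm.status,
                "n_low": arm.n_low,
                "n_high": arm.n_high,
                "pfs_p": arm.pfs.p_value if arm.pfs else None,
                "os_p": arm.os.p_value if arm.os else None,
                "pfs_medians": list(arm.pfs.group_medians) if arm.pfs else None,
                "os_medians": list(arm.os.group_medians) if arm.os else None,
            }
            for name, arm in report.arms.items()
        },
    }
    (out / "validation.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_json_num) + "\n"
    )
    _write_km_curves(results, out)
    return payload


def _write_km_curves(results: TMIResults, out: Path) -> None:
    clinical = results.model.clinical
    frames = []
    for cls in ("low", "high"):
        ids = [p for p in results.analysis_ids if results.tmi_class[p] == cls]
        if not ids:
            continue
        sub = clinical.loc[ids]
        for endpoint in ("pfs", "os"):
            curve = km_estimate(sub[f"{endpoint}_days"], sub[f"{endpoint}_event"])
            frame = curve.to_frame()
            frame.insert(0, "endpoint", endpoint)
            frame.insert(0, "tmi_class", cls)
            frames.append(frame)
    if frames:
        pd.concat(frames).to_csv(out / "km_curves.tsv", sep="\t", index=False)


def report(fixture_dir: str | Path, out_dir: str | Path) -> dict:
    """Composition tables per predictor class and the acquired-mutation
    gene-by-patient matrix; writes TSVs plus summary.txt."""
    out = Path(out_dir)
    results = _refit_from_manifest(out)
    cohort = read_fixture(fixture_dir)

    comp_rows = []
    clinical = results.model.clinical.loc[results.analysis_ids]
    classes = {
        **{
            f"{name}_responder": results.predictor_values.loc[
                results.analysis_ids, name
            ] < results.evaluations[name].cutoff
            for name in PREDICTORS
        },
        "TMI_low": results.tmi_class.loc[results.analysis_ids] == "low",
    }
    for cls_name, member in classes.items():
        for sg_name, pred in SUBGROUP_PREDICATES.items():
            in_sg = pred(clinical).astype(bool)
            n_cls = int(member.sum())
            n_both = int((member & in_sg).sum())
            comp_rows.append(
                {
                    "predictor_class": cls_name,
                    "subgroup": sg_name,
                    "n_class": n_cls,
                    "n_subgroup_in_class": n_both,
                    "fraction": (n_both / n_cls) if n_cls else math.nan,
                    "status": "ok" if n_cls else "empty_class",
                }
            )
    comp = pd.DataFrame(comp_rows)
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)

    # oncoprint-style acquired-mutation matrix over patients with PD samples
    reports = []
    for pid in results.model.clinical.index:
        bl_id, pd_id = f"{pid}_BL", f"{pid}_PD"
        if pd_id not in results.filtered:
            continue
        reports.append(
            acquired_mutation_set(results.filtered[bl_id], results.filtered[pd_id])
        )
    genes = sorted({g for r in reports for g in r.genes()})
    matrix = pd.DataFrame(
        {r.patient_id: [r.per_gene_counts.get(g, 0) for g in genes] for r in reports},
        index=pd.Index(genes, name="gene"),
    )
    matrix.to_csv(out / "acquired_oncoprint.tsv", sep="\t")
    freqs = (
        acquired_gene_frequencies(reports, [r.patient_id for r in reports])
        if reports
        else {}
    )
    (out / "acquired_gene_frequencies.json").write_text(
        json.dumps(freqs, indent=1, sort_keys=True) + "\n"
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
    return {"composition_rows": len(comp_rows), "acquired_genes": len(genes)}


def _evaluation_to_dict(ev) -> dict:
    def _maybe(obj):
        return None if obj is None else dataclasses.asdict(obj)

    d = {
        "name": ev.name,
        "cutoff": ev.cutoff,
        "km_pfs": _maybe(ev.km_pfs),
        "km_os": _maybe(ev.km_os),
        "roc_pfs": _maybe(ev.roc_pfs),
        "roc_os": _maybe(ev.roc_os),
        "subgroups": {k: dataclasses.asdict(v) for k, v in ev.subgroups.items()},
    }
    if ev.cutoff_scan is not None:
        d["cutoff_scan"] = {
            "cutoff": ev.cutoff_scan.cutoff,
            "chosen_p": ev.cutoff_scan.chosen_p,
            "n_candidates": len(ev.cutoff_scan.p_profile),
        }
    return d


def _json_num(value):
    if isinstance(value, float) and math.isinf(value):
        return "not_reached"
    return float(value)
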