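"""The TMI analysis model: discovery fitting, scoring, and validation.

:class:`TMIModel` is built from a cohort of mutation profiles plus a
clinical table and, on :meth:`TMIModel.fit`, runs the full discovery
analysis: the plasma SNV filter chain, burden predictors, the no-benefit
exclusion, the unfavorable-mutation screen, minimum-p cutoff scans, the
per-subgroup predictor evaluations, and the TMI score cards with the
combined TMI + IDH1 exon-4 classifier. The returned :class:`TMIResults`
carries every artifact, renders a ``summary()`` table, and evaluates the
frozen discovery parameters on the held-out validation split via
:meth:`TMIResults.validate`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import (
    FilterResult,
    SampleProfile,
    apply_call_filters,
    compute_burdens,
)
from .resistance import DEFAULT_RESISTANCE_PANEL, ResistancePanel, nb_exclusion_flag
from .scoring import (
    DCB,
    INDETERMINATE,
    NB,
    NDB,
    TMIScoreCard,
    classify_benefit,
    combined_tmi_idh1,
    predictor_baseline_points,
    subgroup_points,
    tmi_classify,
)
from .survival import (
    CutoffError,
    CutoffResult,
    ROCResult,
    SubgroupResult,
    TwoSampleTestResult,
    km_estimate,
    median_survival,
    roc_auc,
    subgroup_evaluation,
    two_sample_test,
    ward_cutoff_scan,
)
from .ums import UnfavorableMutationSet, screen_unfavorable_mutations, ums_score

PREDICTORS = ("GS_MB", "NS_MB", "UMS")


def hash_frozen(frozen: dict) -> str:
    """Canonical hash of discovery-frozen artifacts (leak guard)."""
    blob = json.dumps(frozen, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class AnalysisConfig:
    """All thresholds and choices of one analysis run."""

    min_depth: int = 100
    germline_vaf_threshold: float = 0.20
    panel: tuple[str, ...] | None = None  # None = default 168-gene panel
    alpha: float = 0.01
    p_mode: str = "raw"
    ums_key_set: str = "gs"
    min_carriers: int = 3
    positive_min: int = 1
    discovery_fraction: float = 62.0 / 85.0
    min_group: int = 3
    discovery_test: str = "gehan"
    validation_test: str = "logrank"
    nb_max_days: float = 45.0
    dcb_min_days: float = 130.0
    subgroup_cap: int = 50
    exclude_by: str = "benefit"  # or "panel"
    tmi_cutoff_fallback: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.discovery_fraction < 1.0:
            raise ValueError("discovery_fraction must be in (0, 1)")
        if self.exclude_by not in ("benefit", "panel"):
            raise ValueError("exclude_by must be 'benefit' or 'panel'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.panel is not None:
            d["panel"] = list(self.panel)
        return d


@dataclass(frozen=True)
class PredictorEvaluation:
    """One dichotomised predictor with its discovery-cohort performance."""

    name: str
    cutoff: float
    cutoff_scan: CutoffResult | None
    km_pfs: TwoSampleTestResult | None
    km_os: TwoSampleTestResult | None
    roc_pfs: ROCResult | None
    roc_os: ROCResult | None
    subgroups: dict[str, SubgroupResult] = field(default_factory=dict)

    def is_responder(self, value: float) -> bool:
        """Responder side: predictor value strictly below the cutoff
        (burden below threshold; UMS-negative)."""
        return value < self.cutoff


@dataclass
class ValidationArm:
    cohort: str
    status: str
    n_low: int = 0
    n_high: int = 0
    pfs: TwoSampleTestResult | None = None
    os: TwoSampleTestResult | None = None


@dataclass
class ValidationReport:
    tmi_cutoff: float
    test: str
    arms: dict[str, ValidationArm] = field(default_factory=dict)
    frozen_hash: str = ""


class TMIModel:
    """Circulating-DNA stratification model for one NSCLC cohort.

    Parameters
    ----------
    profiles : mapping of sample id (``<patient>_<BL|PD>``) to SampleProfile
    clinical : per-patient table (see :mod:`ctdna_tmi.profiles`)
    config : analysis thresholds; defaults follow the published workflow
    resistance_panel : panel for the no-benefit exclusion screen
    """

    def __init__(
        self,
        profiles: Mapping[str, SampleProfile],
        clinical: pd.DataFrame,
        config: AnalysisConfig | None = None,
        resistance_panel: ResistancePanel = DEFAULT_RESISTANCE_PANEL,
    ):
        self.config = config or AnalysisConfig()
        self.config.validate()
        self.profiles = dict(profiles)
        self.clinical = clinical
        self.resistance_panel = resistance_panel
        for pid in clinical.index:
            if f"{pid}_BL" not in self.profiles:
                raise ValueError(f"missing BL sample for patient {pid}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort, config: AnalysisConfig | None = None) -> "TMIModel":
        return cls(cohort.profiles, cohort.clinical, config=config)

    @classmethod
    def from_fixture(
        cls, directory: str | Path, config: AnalysisConfig | None = None
    ) -> "TMIModel":
        from .simulate import read_fixture

        return cls.from_cohort(read_fixture(directory), config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self, discovery_ids: list[str] | None = None) -> "TMIResults":
        """Run the discovery analysis and return the fitted results.

        ``discovery_ids`` pins the discovery split; by default the analysis
        patients (non-NB) are split at ``discovery_fraction`` with the
        config seed.
        """
        cfg = self.config
        clinical = self.clinical

        filtered: dict[str, FilterResult] = {
            sid: apply_call_filters(
                prof,
                min_depth=cfg.min_depth,
                germline_vaf_threshold=cfg.germline_vaf_threshold,
                panel=cfg.panel,
            )
            for sid, prof in self.profiles.items()
        }

        burdens = pd.DataFrame(
            {
                pid: dataclasses.asdict(compute_burdens(filtered[f"{pid}_BL"]))
                for pid in clinical.index
            }
        ).T.rename_axis("patient_id")

        benefit = pd.Series(
            {
                pid: classify_benefit(
                    clinical.loc[pid, "pfs_days"],
                    bool(clinical.loc[pid, "pfs_event"]),
                    bool(clinical.loc[pid, "intolerance"]),
                    nb_max_days=cfg.nb_max_days,
                    dcb_min_days=cfg.dcb_min_days,
                )
                for pid in clinical.index
            },
            name="benefit",
        )

        nb_rows = {}
        for pid in clinical.index:
            flag, matched = nb_exclusion_flag(
                filtered[f"{pid}_BL"], self.resistance_panel
            )
            nb_rows[pid] = {
                "panel_flag": flag,
                "matched_keys": ";".join(str(k) for k in matched),
            }
        nb_screen = pd.DataFrame(nb_rows).T.rename_axis("patient_id")

        if cfg.exclude_by == "benefit":
            excluded = benefit == NB
        else:
            excluded = nb_screen["panel_flag"].astype(bool)
        analysis_ids = [pid for pid in clinical.index if not excluded[pid]]
        if len(analysis_ids) < 4 * cfg.min_group:
            raise ValueError(
                f"cohort too small after exclusion: {len(analysis_ids)} analysis "
                f"patients for min_group={cfg.min_group}"
            )

        if discovery_ids is None:
            rng = np.random.default_rng(cfg.seed)
            order = list(analysis_ids)
            rng.shuffle(order)
            n_disc = int(round(cfg.discovery_fraction * len(order)))
            n_disc = min(max(n_disc, 2 * cfg.min_group), len(order) - 1)
            discovery_ids = sorted(order[:n_disc])
        else:
            unknown = set(discovery_ids) - set(analysis_ids)
            if unknown:
                raise ValueError(f"discovery ids not in analysis set: {sorted(unknown)}")
            discovery_ids = sorted(discovery_ids)
        validation_ids = sorted(set(analysis_ids) - set(discovery_ids))

        disc = clinical.loc[discovery_ids]
        unfavorable = screen_unfavorable_mutations(
            {pid: filtered[f"{pid}_BL"] for pid in discovery_ids},
            disc,
            alpha=cfg.alpha,
            p_mode=cfg.p_mode,
            test=cfg.discovery_test,
            key_set=cfg.ums_key_set,
            min_carriers=cfg.min_carriers,
        )

        ums_scores = pd.Series(
            {
                pid: ums_score(
                    filtered[f"{pid}_BL"], unfavorable,
                    key_set=cfg.ums_key_set, positive_min=cfg.positive_min
                ).score
                for pid in analysis_ids
            },
            name="UMS",
        )

        values = pd.DataFrame(
            {
                "GS_MB": burdens.loc[analysis_ids, "gs_mb"].astype(float),
                "NS_MB": burdens.loc[analysis_ids, "ns_mb"].astype(float),
                "UMS": ums_scores.astype(float),
            }
        )

        pfs_benefit = benefit.loc[discovery_ids].map(
            {DCB: True, NDB: False, INDETERMINATE: None, NB: None}
        )
        os_curve = km_estimate(disc["os_days"], disc["os_event"])
        os_median = median_survival(os_curve)
        os_benefit = pd.Series(
            [
                True if t > os_median
                else (False if e else None)
                for t, e in zip(disc["os_days"], disc["os_event"])
            ],
            index=discovery_ids,
            dtype=object,
        )

        evaluations: dict[str, PredictorEvaluation] = {}
        for name in PREDICTORS:
            vals = values.loc[discovery_ids, name]
            scan = None
            if name == "UMS":
                cutoff = float(cfg.positive_min) - 0.5
            else:
                scan = ward_cutoff_scan(
                    vals.to_numpy(), disc["pfs_days"], disc["pfs_event"],
                    min_group=cfg.min_group, test=cfg.discovery_test,
                )
                cutoff = scan.cutoff
            responder = vals < cutoff
            evaluations[name] = self._evaluate_predictor(
                name, cutoff, scan, disc, responder, vals, pfs_benefit, os_benefit
            )

        scorecards = {}
        for pid in analysis_ids:
            card = _score_patient(
                pid, values.loc[pid], clinical.loc[pid], evaluations,
                cap=cfg.subgroup_cap,
            )
            scorecards[pid] = card

        tmi_values = pd.Series(
            {pid: scorecards[pid].tmi for pid in analysis_ids}, name="TMI"
        )
        tmi_cutoff_source = "ward_scan"
        try:
            tmi_scan: CutoffResult | None = ward_cutoff_scan(
                tmi_values.loc[discovery_ids].to_numpy(),
                disc["pfs_days"], disc["pfs_event"],
                min_group=cfg.min_group, test=cfg.discovery_test,
            )
            tmi_cutoff = tmi_scan.cutoff
        except CutoffError:
            tmi_scan = None
            tmi_cutoff = cfg.tmi_cutoff_fallback
            tmi_cutoff_source = "fallback_default"

        tmi_class = tmi_values.map(lambda v: tmi_classify(v, tmi_cutoff))
        combined = pd.Series(
            {
                pid: combined_tmi_idh1(
                    tmi_class[pid], bool(clinical.loc[pid, "idh1_exon4_mutant"])
                )
                for pid in analysis_ids
            },
            name="combined_class",
        )

        return TMIResults(
            model=self,
            config=cfg,
            filtered=filtered,
            burdens=burdens,
            benefit=benefit,
            nb_screen=nb_screen,
            analysis_ids=analysis_ids,
            discovery_ids=discovery_ids,
            validation_ids=validation_ids,
            unfavorable=unfavorable,
            predictor_values=values,
            evaluations=evaluations,
            scorecards=scorecards,
            tmi_values=tmi_values,
            tmi_cutoff=tmi_cutoff,
            tmi_cutoff_source=tmi_cutoff_source,
            tmi_scan=tmi_scan,
            tmi_class=tmi_class,
            combined_class=combined,
        )

    def _evaluate_predictor(
        self, name, cutoff, scan, disc, responder, vals, pfs_benefit, os_benefit
    ) -> PredictorEvaluation:
        cfg = self.config
        km_pfs = km_os = None
        if responder.sum() > 0 and (~responder).sum() > 0:
            km_pfs = two_sample_test(
                disc.loc[responder, "pfs_days"], disc.loc[responder, "pfs_event"],
                disc.loc[~responder, "pfs_days"], disc.loc[~responder, "pfs_event"],
                cfg.discovery_test,
            )
            km_os = two_sample_test(
                disc.loc[responder, "os_days"], disc.loc[responder, "os_event"],
                disc.loc[~responder, "os_days"], disc.loc[~responder, "os_event"],
                cfg.discovery_test,
            )
        roc_pfs = _safe_roc(vals, pfs_benefit)
        roc_os = _safe_roc(vals, os_benefit)
        subgroups = subgroup_evaluation(
            disc, responder, vals,
            pfs_benefit, os_benefit,
            min_group=cfg.min_group, test=cfg.discovery_test,
        )
        return PredictorEvaluation(
            name, float(cutoff), scan, km_pfs, km_os, roc_pfs, roc_os, subgroups
        )


def _safe_roc(vals: pd.Series, labels: pd.Series) -> ROCResult | None:
    usable = labels.notna()
    if usable.sum() == 0:
        return None
    lab = labels[usable].astype(bool)
    if lab.nunique() < 2:
        return None
    return roc_auc(vals[usable].to_numpy(), lab.to_numpy())


def _score_patient(
    pid: str,
    patient_values: pd.Series,
    clinical_row: pd.Series,
    evaluations: Mapping[str, PredictorEvaluation],
    cap: int,
) -> TMIScoreCard:
    bl_points: dict[str, int] = {}
    sg_points: dict[str, int] = {}
    for name, ev in evaluations.items():
        responder = ev.is_responder(float(patient_values[name]))
        bl_points[name] = predictor_baseline_points(responder)
        sg_points[name] = subgroup_points(clinical_row, ev.subgroups, responder, cap=cap)
    return TMIScoreCard(pid, bl_points, sg_points)


@dataclass
class TMIResults:
    """Everything the discovery fit produced; see :meth:`summary`."""

    model: TMIModel
    config: AnalysisConfig
    filtered: dict[str, FilterResult]
    burdens: pd.DataFrame
    benefit: pd.Series
    nb_screen: pd.DataFrame
    analysis_ids: list[str]
    discovery_ids: list[str]
    validation_ids: list[str]
    unfavorable: UnfavorableMutationSet
    predictor_values: pd.DataFrame
    evaluations: dict[str, PredictorEvaluation]
    scorecards: dict[str, TMIScoreCard]
    tmi_values: pd.Series
    tmi_cutoff: float
    tmi_cutoff_source: str
    tmi_scan: CutoffResult | None
    tmi_class: pd.Series
    combined_class: pd.Series

    # -- derived tables -----------------------------------------------------

    def scorecards_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.analysis_ids:
            card = self.scorecards[pid]
            row = {"patient_id": pid}
            for name in PREDICTORS:
                row[f"bl_{name}"] = card.bl_points[name]
                row[f"sub_{name}"] = card.subgroup_points[name]
            row["total"] = card.total
            row["tmi"] = round(card.tmi, 1)
            row["tmi_class"] = self.tmi_class[pid]
            row["combined_class"] = self.combined_class[pid]
            rows.append(row)
        return pd.DataFrame(rows).set_index("patient_id", drop=False)

    def frozen_artifacts(self) -> dict:
        """The discovery-frozen parameters validation is allowed to use."""
        return {
            "config": self.config.to_dict(),
            "discovery_ids": self.discovery_ids,
            "validation_ids": self.validation_ids,
            "unfavorable_keys": sorted(str(k) for k in self.unfavorable.keys()),
            "cutoffs": {
                name: ev.cutoff for name, ev in self.evaluations.items()
            },
            "tmi_cutoff": self.tmi_cutoff,
            "subgroup_results": {
                name: {
                    sg: dataclasses.asdict(res)
                    for sg, res in ev.subgroups.items()
                }
                for name, ev in self.evaluations.items()
            },
        }

    def frozen_hash(self) -> str:
        return hash_frozen(self.frozen_artifacts())

    # -- validation ---------------------------------------------------------

    def validate(self) -> ValidationReport:
        """Stratify the held-out validation cohort (and the pooled cohort)
        by the frozen TMI cutoff; no parameter is re-estimated."""
        if set(self.discovery_ids) & set(self.validation_ids):
            raise ValueError("discovery and validation cohorts overlap")
        report = ValidationReport(
            tmi_cutoff=self.tmi_cutoff,
            test=self.config.validation_test,
            frozen_hash=self.frozen_hash(),
        )
        for cohort, ids in (
            ("validation", self.validation_ids),
            ("pooled", self.analysis_ids),
        ):
            report.arms[cohort] = self._stratify(cohort, ids)
        return report

    def _stratify(self, cohort: str, ids: list[str]) -> ValidationArm:
        clinical = self.model.clinical
        low_ids = [p for p in ids if self.tmi_class[p] == "low"]
        high_ids = [p for p in ids if self.tmi_class[p] == "high"]
        arm = ValidationArm(cohort, "ok", n_low=len(low_ids), n_high=len(high_ids))
        if not low_ids or not high_ids:
            arm.status = "not_evaluable"
            return arm
        low = clinical.loc[low_ids]
        high = clinical.loc[high_ids]
        arm.pfs = two_sample_test(
            low["pfs_days"], low["pfs_event"], high["pfs_days"], high["pfs_event"],
            self.config.validation_test,
        )
        arm.os = two_sample_test(
            low["os_days"], low["os_event"], high["os_days"], high["os_event"],
            self.config.validation_test,
        )
        return arm

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = []
        n_all = len(self.model.clinical)
        n_nb = int((self.benefit == NB).sum())
        lines.append("TMI analysis summary")
        lines.append("=" * 64)
        lines.append(
            f"Patients: {n_all} total, {n_nb} no-benefit excluded, "
            f"{len(self.analysis_ids)} analysed "
            f"({len(self.discovery_ids)} discovery / "
            f"{len(self.validation_ids)} validation)"
        )
        flag = self.nb_screen["panel_flag"].astype(bool)
        nb_ids = self.benefit[self.benefit == NB].index
        if len(nb_ids) > 0:
            frac = flag.loc[nb_ids].mean()
            lines.append(
                f"Resistance panel at BL: {int(flag.loc[nb_ids].sum())}/{len(nb_ids)}"
                f" NB patients flagged ({100 * frac:.0f}%)"
            )
        lines.append(
            f"Unfavorable mutations: {len(self.unfavorable)} retained of "
            f"{self.unfavorable.n_tested} tested "
            f"({self.unfavorable.p_mode} p < {self.unfavorable.alpha:g})"
        )
        lines.append("-" * 64)
        header = f"{'predictor':<9}{'cutoff':>9}{'KM PFS p':>12}{'KM OS p':>11}" \
                 f"{'AUC PFS':>9}{'AUC OS':>8}"
        lines.append(header)
        for name in PREDICTORS:
            ev = self.evaluations[name]
            lines.append(
                f"{name:<9}{ev.cutoff:>9.1f}"
                f"{_fmt_p(ev.km_pfs):>12}{_fmt_p(ev.km_os):>11}"
                f"{_fmt_auc(ev.roc_pfs):>9}{_fmt_auc(ev.roc_os):>8}"
            )
        lines.append("-" * 64)
        n_low = int((self.tmi_class == "low").sum())
        n_high = int((self.tmi_class == "high").sum())
        lines.append(
            f"TMI cutoff: {self.tmi_cutoff:.1f} ({self.tmi_cutoff_source}); "
            f"low {n_low} / high {n_high}"
        )
        for cls in ("low", "high"):
            ids = [p for p in self.analysis_ids if self.tmi_class[p] == cls]
            if not ids:
                continue
            sub = self.model.clinical.loc[ids]
            med = median_survival(km_estimate(sub["pfs_days"], sub["pfs_event"]))
            lines.append(
                f"  TMI {cls:<4} (n={len(ids):>3}): median PFS "
                f"{_fmt_days(med)}"
            )
        n_unfav = int((self.combined_class == "unfavorable").sum())
        lines.append(
            f"Combined TMI + IDH1 exon-4: {n_unfav} unfavorable / "
            f"{len(self.analysis_ids) - n_unfav} favorable"
        )
        return "\n".join(lines)


def _fmt_p(res: TwoSampleTestResult | None) -> str:
    return "n/a" if res is None else f"{res.p_value:.4f}"


def _fmt_auc(res: ROCResult | None) -> str:
    return "n/a" if res is None else f"{res.auc:.2f}"


def _fmt_days(days: float) -> str:
    return "not reached" if math.isinf(days) else f"{days:.0f} d"
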