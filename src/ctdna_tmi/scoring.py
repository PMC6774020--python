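"""Benefit classification and the Tumor Mutation Index scoring rules.

The TMI condenses three dichotomised predictors (G+S MB, N+S MB, UMS) into
one number per patient. Per predictor a patient earns a 50-point baseline
when classified on the responder side, plus subgroup points derived from how
well that predictor stratifies the patient's own demographic subgroups
(significance of the Kaplan–Meier comparisons and of the ROC analysis),
capped at 50 so the grand total stays within 300. The total is homogenised:

    TMI = 100 x (300 - total) / 300

so TMI runs from 0 (maximal score, least likely responder) to 100; low TMI
marks the likely-responder side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .survival import SubgroupResult, patient_subgroups

NB = "NB"
NDB = "NDB"
DCB = "DCB"
INDETERMINATE = "indeterminate"
BENEFIT_CLASSES = (NB, NDB, DCB)

TMI_TOTAL_MAX = 300
BASELINE_POINTS = 50
SUBGROUP_CAP = 50


def classify_benefit(
    pfs_days: float,
    pfs_event: bool,
    intolerance: bool = False,
    nb_max_days: float = 45.0,
    dcb_min_days: float = 130.0,
) -> str:
    """Clinical benefit class from progression-free survival.

    NB (no benefit): progression within ``nb_max_days`` or drug intolerance.
    NDB (no durable benefit): progression after NB window but within
    ``dcb_min_days``. DCB (durable clinical benefit): disease control past
    ``dcb_min_days`` — a patient still progression-free (censored) beyond
    that bound also qualifies. A patient censored at or before
    ``dcb_min_days`` carries too little follow-up to classify and is
    returned as ``indeterminate``.
    """
    if pfs_days <= 0:
        raise ValueError("pfs_days must be > 0")
    if intolerance:
        return NB
    if pfs_days > dcb_min_days:
        return DCB
    if not pfs_event:
        return INDETERMINATE
    return NB if pfs_days <= nb_max_days else NDB


def significance_points(p: float) -> int:
    """Points for a Kaplan–Meier comparison p-value: 3 below 0.001, 2 below
    0.01, 1 below 0.05, else 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return 3
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


def auc_points(auc: float, null_p: float) -> int:
    """Points for an ROC analysis: 1 for AUC above 0.7, plus the
    significance-style points of the null-hypothesis test p-value."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    return (1 if auc > 0.7 else 0) + significance_points(null_p)


def predictor_baseline_points(responder: bool) -> int:
    """50 baseline points for a patient on the responder side of a
    predictor (burden below its cutoff; UMS negative), else 0."""
    return BASELINE_POINTS if responder else 0


def subgroup_result_points(res: SubgroupResult) -> int:
    """Points one evaluable subgroup contributes: KM significance for PFS
    and OS plus AUC points for both ROC analyses. Not-evaluable: 0."""
    if res.status != "ok":
        return 0
    return (
        significance_points(res.km_pfs_p)
        + significance_points(res.km_os_p)
        + auc_points(res.auc_pfs, res.null_p_pfs)
        + auc_points(res.auc_os, res.null_p_os)
    )


def subgroup_points(
    patient_row,
    subgroup_results: dict[str, SubgroupResult],
    responder: bool,
    cap: int = SUBGROUP_CAP,
) -> int:
    """Subgroup points of one patient under one predictor.

    Summed over the five subgroups the patient belongs to, awarded only to
    predictor-responders, and capped so the per-predictor maximum (baseline
    + subgroup) is 100.
    """
    if not responder:
        return 0
    total = 0
    for name in patient_subgroups(patient_row):
        res = subgroup_results.get(name)
        if res is not None:
            total += subgroup_result_points(res)
    return min(total, cap)


@dataclass(frozen=True)
class TMIScoreCard:
    """The six score components and the homogenised TMI of one patient."""

    patient_id: str
    bl_points: dict[str, int]        # predictor -> 0 or 50
    subgroup_points: dict[str, int]  # predictor -> 0..cap

    @property
    def total(self) -> int:
        return sum(self.bl_points.values()) + sum(self.subgroup_points.values())

    @property
    def tmi(self) -> float:
        return tmi_from_total(self.total)


def tmi_from_total(total: float) -> float:
    """Homogenisation: TMI = 100 x (300 - total) / 300."""
    if not 0 <= total <= TMI_TOTAL_MAX:
        raise ValueError(f"total score must be in [0, {TMI_TOTAL_MAX}], got {total}")
    return 100.0 * (TMI_TOTAL_MAX - total) / TMI_TOTAL_MAX


def tmi_classify(tmi: float, cutoff: float) -> str:
    """"low" (responder side) iff tmi < cutoff, else "high"; the boundary
    value classifies high (strict-less convention)."""
    return "low" if tmi < cutoff else "high"


def combined_tmi_idh1(tmi_class: str, idh1_exon4_mutant: bool) -> str:
    """Combined classifier: unfavorable only for high TMI together with an
    IDH1 exon-4 mutation; every other combination is favorable."""
    if tmi_class not in ("low", "high"):
        raise ValueError(f"tmi_class must be 'low' or 'high', got {tmi_class!r}")
    return "unfavorable" if (tmi_class == "high" and idh1_exon4_mutant) else "favorable"
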