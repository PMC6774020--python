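"""Synthetic plasma-sequencing cohorts with known planted structure.

The generator emulates the statistical shape the downstream analyses assume:
a 168-gene capture panel; per-sample calls carrying depth and VAF with
germline-like (VAF near 0.5) and somatic-like (low VAF) components that the
VAF>20% proxy separates imperfectly; a low- and a high-burden patient
stratum; a set of planted "unfavorable" mutations that multiply the
progression hazard of their carriers; ARID1A/BRCA2 resistance point
mutations carried by most no-benefit patients at baseline; IDH1 exon-4
status; exponential (optionally Weibull) progression-free survival with
independent censoring; and progression-timepoint profiles with acquired
mutations for durable responders. Every planted effect is recorded in a
truth block so tests can score recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL_GENES
from .profiles import (
    MutationKey,
    MutationRecord,
    SampleProfile,
    read_clinical_table,
    read_mutation_table,
    write_clinical_table,
    write_mutation_table,
)
from .resistance import DEFAULT_RESISTANCE_PANEL
from .scoring import DCB, classify_benefit

_BASES = "ACGT"
_REQUIRED_GENES = ("ARID1A", "BRCA2", "TGFBR2", "IDH1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort; the seed fully determines output.

    Hazard ratios multiply the baseline progression hazard (exponential with
    median ``baseline_median_pfs_days``): per high-burden membership, per
    carried unfavorable mutation, and per IDH1 exon-4 mutation. Burden means
    are counts of panel calls per baseline sample.
    """

    n_patients: int = 111
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    mean_gs_burden_low: float = 60.0
    mean_gs_burden_high: float = 200.0
    frac_high_burden: float = 0.30
    n_unfavorable: int = 12
    prevalence_unfavorable: float = 0.15
    unfavorable_clustering: float = 4.0
    hr_unfavorable: float = 2.0
    hr_high_burden: float = 1.65
    hr_idh1: float = 1.8
    frac_idh1: float = 0.20
    frac_nb: float = 26.0 / 111.0
    prob_nb_resistance_panel: float = 0.92
    background_panel_rate: float = 0.03
    baseline_median_pfs_days: float = 210.0
    os_factor_median: float = 2.4
    os_factor_sigma: float = 0.30
    censor_rate: float = 0.20
    acquired_rate: float = 4.0
    prob_resistant_acquirer: float = 0.60
    n_shared_background: int = 150
    weibull_shape: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        missing = [g for g in _REQUIRED_GENES if g not in self.panel_genes]
        if missing:
            raise ValueError(f"panel_genes must include {missing}")
        for name in (
            "frac_high_burden", "prevalence_unfavorable", "frac_idh1",
            "frac_nb", "prob_nb_resistance_panel", "background_panel_rate",
            "censor_rate", "prob_resistant_acquirer",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("hr_unfavorable", "hr_high_burden", "hr_idh1",
                     "baseline_median_pfs_days", "weibull_shape",
                     "os_factor_median", "unfavorable_clustering"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name in ("mean_gs_burden_low", "mean_gs_burden_high",
                     "acquired_rate", "os_factor_sigma"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in ("n_unfavorable", "n_shared_background"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel_genes"] = list(self.panel_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "panel_genes" in d:
            d["panel_genes"] = tuple(d["panel_genes"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Simulated samples, clinical table, and the planted truth."""

    profiles: dict[str, SampleProfile]
    clinical: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def bl_profile(self, patient_id: str) -> SampleProfile:
        return self.profiles[f"{patient_id}_BL"]


@dataclass
class _MutationDef:
    key: MutationKey
    gene: str
    effect_class: str
    synonymous: bool
    germline: bool


class _Universe:
    """Allocates globally unique mutation identities."""

    def __init__(self, rng: np.random.Generator, genes: tuple[str, ...]):
        self.rng = rng
        self.genes = genes
        self.used: set[tuple[str, int]] = {
            (e.key.chrom, e.key.pos) for e in DEFAULT_RESISTANCE_PANEL.entries
        }

    def new_key(self, gene: str | None = None) -> tuple[MutationKey, str]:
        rng = self.rng
        if gene is None:
            gene = self.genes[int(rng.integers(len(self.genes)))]
        while True:
            chrom = f"chr{int(rng.integers(1, 23))}"
            pos = int(rng.integers(1, 250_000_000))
            if (chrom, pos) not in self.used:
                break
        self.used.add((chrom, pos))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        return MutationKey(chrom, pos, str(ref), str(alt)), gene

    def new_def(
        self,
        gene: str | None = None,
        germline: bool | None = None,
        effect_class: str | None = None,
        synonymous: bool | None = None,
    ) -> _MutationDef:
        rng = self.rng
        key, gene = self.new_key(gene)
        if germline is None:
            germline = bool(rng.random() < 0.40)
        if effect_class is None:
            effect_class = str(
                rng.choice(
                    ["MODIFIER", "LOW", "MODERATE", "HIGH"],
                    p=[0.15, 0.15, 0.40, 0.30],
                )
            )
        if synonymous is None:
            synonymous = bool(
                effect_class in ("MODERATE", "HIGH") and rng.random() < 0.25
            )
        return _MutationDef(key, gene, effect_class, synonymous, germline)


def _draw_record(
    rng: np.random.Generator, mdef: _MutationDef, assured_depth: bool = False
) -> MutationRecord:
    # ~3% of calls fall below the 100x depth filter, as in shallow corners
    # of real capture data; clinically validated hotspot loci (the
    # resistance panel) are backfilled to assured coverage.
    if not assured_depth and rng.random() < 0.03:
        depth = int(rng.integers(20, 100))
    else:
        depth = int(max(100, rng.poisson(500)))
    if mdef.germline:
        vaf = float(rng.beta(30.0, 30.0))
    else:
        vaf = float(rng.beta(2.0, 18.0))
    vaf = round(min(max(vaf, 0.0005), 0.9995), 6)
    return MutationRecord(
        mdef.key, mdef.gene, mdef.effect_class, mdef.synonymous, depth, vaf
    )


def _pfs_sample(rng: np.random.Generator, hazard: float, shape: float) -> float:
    median = math.log(2.0) / hazard
    if shape == 1.0:
        return float(rng.exponential(1.0 / hazard))
    scale = median / math.log(2.0) ** (1.0 / shape)
    return float(scale * rng.weibull(shape))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort; same config (incl. seed) => same cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = _Universe(rng, tuple(config.panel_genes))
    n = config.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]

    # --- patient-level covariates and strata -------------------------------
    gender = np.where(rng.random(n) < 0.60, "M", "F")
    smoking = rng.random(n) < 0.55
    pathology = np.where(rng.random(n) < 0.75, "LUAD", "LUSC")
    driver_positive = rng.random(n) < 0.45
    metastases = rng.poisson(2.5, size=n)
    idh1 = rng.random(n) < config.frac_idh1
    high_burden = rng.random(n) < config.frac_high_burden
    nb_flag = rng.random(n) < config.frac_nb
    resistant = rng.random(n) < config.prob_resistant_acquirer

    # --- shared mutation universe ------------------------------------------
    shared_defs: list[_MutationDef] = []
    shared_prev: list[float] = []
    for _ in range(config.n_shared_background):
        shared_defs.append(universe.new_def())
        shared_prev.append(float(rng.uniform(0.05, 0.40)))
    unfavorable_defs: list[_MutationDef] = []
    for _ in range(config.n_unfavorable):
        effect = "HIGH" if rng.random() < 0.5 else "MODERATE"
        unfavorable_defs.append(
            universe.new_def(germline=False, effect_class=effect, synonymous=False)
        )
    panel_defs = {
        e.key: _MutationDef(e.key, e.gene, "HIGH", False, False)
        for e in DEFAULT_RESISTANCE_PANEL.entries
    }
    panel_keys = list(panel_defs)

    shared_carrier = rng.random((len(shared_defs), n)) < np.array(shared_prev)[:, None]
    # Unfavorable carriage is clustered across patients (beta-binomial):
    # a patient-level propensity with mean `prevalence_unfavorable` and
    # concentration `unfavorable_clustering` reproduces the long-tailed,
    # strongly co-occurring unfavorable loads seen in real cohorts.
    prev = config.prevalence_unfavorable
    kappa = config.unfavorable_clustering
    if config.n_unfavorable > 0 and 0.0 < prev < 1.0 and math.isfinite(kappa):
        propensity = rng.beta(prev * kappa, (1.0 - prev) * kappa, size=n)
    else:
        propensity = np.full(n, prev)
    unfav_carrier = (
        rng.random((len(unfavorable_defs), n)) < propensity[None, :]
    )

    expected_shared = float(np.sum(shared_prev)) + (
        config.n_unfavorable * config.prevalence_unfavorable
    )

    # --- survival ------------------------------------------------------------
    base_hazard = math.log(2.0) / config.baseline_median_pfs_days
    n_unfav_carried = unfav_carrier.sum(axis=0)
    hazards = (
        base_hazard
        * np.power(config.hr_high_burden, high_burden.astype(float))
        * np.power(config.hr_unfavorable, n_unfav_carried.astype(float))
        * np.power(config.hr_idh1, idh1.astype(float))
    )

    pfs_days = np.zeros(n)
    pfs_event = np.zeros(n, dtype=bool)
    for i in range(n):
        if nb_flag[i]:
            pfs_days[i] = float(rng.integers(7, 46))
            pfs_event[i] = True
            continue
        t = _pfs_sample(rng, hazards[i], config.weibull_shape)
        if config.censor_rate > 0:
            c_rate = hazards[i] * config.censor_rate / (1.0 - config.censor_rate)
            c = float(rng.exponential(1.0 / c_rate))
        else:
            c = math.inf
        pfs_event[i] = t <= c
        pfs_days[i] = max(1.0, math.ceil(min(t, c)))

    os_factor = np.maximum(
        1.05,
        np.exp(rng.normal(math.log(config.os_factor_median),
                          config.os_factor_sigma, size=n)),
    )
    os_days = np.maximum(pfs_days + 1.0, np.ceil(pfs_days * os_factor))
    os_event = rng.random(n) < (1.0 - config.censor_rate)
    shrink = rng.uniform(0.5, 1.0, size=n)
    os_days = np.where(os_event, os_days,
                       np.maximum(pfs_days + 1.0, np.ceil(os_days * shrink)))

    # --- baseline profiles -----------------------------------------------------
    profiles: dict[str, SampleProfile] = {}
    nb_panel_carriers: list[str] = []
    truth_acquired: dict[str, list[str]] = {}
    for i, pid in enumerate(ids):
        prof = SampleProfile(pid, "BL")
        for j, mdef in enumerate(shared_defs):
            if shared_carrier[j, i]:
                prof.add(_draw_record(rng, mdef))
        for j, mdef in enumerate(unfavorable_defs):
            if unfav_carrier[j, i]:
                prof.add(_draw_record(rng, mdef))
        carries_panel = (
            rng.random() < config.prob_nb_resistance_panel
            if nb_flag[i]
            else rng.random() < config.background_panel_rate
        )
        if carries_panel and panel_keys:
            n_keys = int(rng.integers(1, min(2, len(panel_keys)) + 1))
            chosen = rng.choice(len(panel_keys), size=n_keys, replace=False)
            for idx in np.sort(chosen):
                prof.add(
                    _draw_record(rng, panel_defs[panel_keys[idx]],
                                 assured_depth=True)
                )
            if nb_flag[i]:
                nb_panel_carriers.append(pid)
        mean_target = (
            config.mean_gs_burden_high if high_burden[i]
            else config.mean_gs_burden_low
        )
        n_private = int(rng.poisson(max(0.0, mean_target - expected_shared)))
        for _ in range(n_private):
            prof.add(_draw_record(rng, universe.new_def()))
        profiles[prof.sample_id] = prof

    # --- PD profiles with acquired mutations for durable responders ----------
    for i, pid in enumerate(ids):
        benefit = classify_benefit(pfs_days[i], bool(pfs_event[i]))
        if benefit != DCB:
            continue
        bl = profiles[f"{pid}_BL"]
        pd_prof = SampleProfile(pid, "PD")
        for rec in bl:
            pd_prof.add(rec)
        n_acq = int(rng.poisson(config.acquired_rate))
        acquired_keys: list[str] = []
        for _ in range(n_acq):
            if resistant[i] and rng.random() < 0.70:
                gene = "ARID1A" if rng.random() < 0.5 else "BRCA2"
                # prefer the published panel keys when not already present
                open_keys = [k for k in panel_keys
                             if k not in pd_prof.records
                             and panel_defs[k].gene == gene]
                if open_keys and rng.random() < 0.5:
                    mdef = panel_defs[open_keys[0]]
                else:
                    mdef = universe.new_def(gene=gene, germline=False,
                                            effect_class="HIGH", synonymous=False)
            else:
                mdef = universe.new_def(germline=False, effect_class="HIGH",
                                        synonymous=False)
            rec = _draw_record(rng, mdef)
            pd_prof.add(rec)
            acquired_keys.append(str(mdef.key))
        profiles[pd_prof.sample_id] = pd_prof
        truth_acquired[pid] = sorted(acquired_keys)

    clinical = pd.DataFrame(
        {
            "patient_id": ids,
            "gender": gender,
            "smoking": smoking,
            "pathology": pathology,
            "driver_positive": driver_positive,
            "metastases": metastases,
            "pfs_days": pfs_days,
            "pfs_event": pfs_event,
            "os_days": os_days,
            "os_event": os_event,
            "intolerance": False,
            "idh1_exon4_mutant": idh1,
        }
    ).set_index("patient_id", drop=False)

    truth = {
        "config": config.to_dict(),
        "unfavorable_keys": sorted(str(m.key) for m in unfavorable_defs),
        "unfavorable_carriers": {
            str(unfavorable_defs[j].key): sorted(
                ids[i] for i in range(n) if unfav_carrier[j, i]
            )
            for j in range(len(unfavorable_defs))
        },
        "high_burden_ids": sorted(ids[i] for i in range(n) if high_burden[i]),
        "idh1_ids": sorted(ids[i] for i in range(n) if idh1[i]),
        "nb_ids": sorted(ids[i] for i in range(n) if nb_flag[i]),
        "nb_panel_carriers": sorted(nb_panel_carriers),
        "resistant_ids": sorted(
            ids[i] for i in range(n) if resistant[i] and f"{ids[i]}_PD" in profiles
        ),
        "acquired": truth_acquired,
        "hazards": {pid: float(hazards[i]) for i, pid in enumerate(ids)},
        "burden_means": {
            "low": config.mean_gs_burden_low,
            "high": config.mean_gs_burden_high,
        },
    }
    return SyntheticCohort(profiles, clinical, truth)


# ---------------------------------------------------------------------------
# Fixture IO
# ---------------------------------------------------------------------------

MUTATIONS_FILE = "mutations.tsv"
CLINICAL_FILE = "clinical.tsv"
TRUTH_FILE = "truth.json"


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write ``mutations.tsv``, ``clinical.tsv`` and ``truth.json``.

    The files round-trip losslessly through :func:`read_fixture`, and the
    truth block records the full generating configuration (including the
    seed), so the fixture can be regenerated byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": directory / MUTATIONS_FILE,
        "clinical": directory / CLINICAL_FILE,
        "truth": directory / TRUTH_FILE,
    }
    write_mutation_table(cohort.profiles, paths["mutations"])
    write_clinical_table(cohort.clinical, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Read a fixture directory back into a :class:`SyntheticCohort`."""
    directory = Path(directory)
    profiles = read_mutation_table(directory / MUTATIONS_FILE)
    clinical = read_clinical_table(directory / CLINICAL_FILE)
    truth_path = directory / TRUTH_FILE
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return SyntheticCohort(profiles, clinical, truth)
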