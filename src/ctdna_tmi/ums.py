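"""Per-mutation survival screening and the Unfavorable Mutation Score.

Every mutation observed at baseline that splits the cohort (carried by some
but not all patients) is tested: carriers vs non-carriers compared on PFS
with a two-sample survival test, p-values adjusted across all tested
mutations by Benjamini–Hochberg. Mutations passing the threshold whose
carriers fare *worse* form the unfavorable set; a patient's UMS is simply
how many of those mutations they carry (each weighted 1), and patients
partition into UMS-negative (score 0) and UMS-positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import FilterResult, MutationKey
from .survival import batch_two_sample_test, bh_adjust, km_estimate, median_survival


@dataclass(frozen=True)
class UnfavorableEntry:
    key: MutationKey
    gene: str
    raw_p: float
    adjusted_p: float
    carrier_count: int


@dataclass(frozen=True)
class UnfavorableMutationSet:
    """Screened unfavorable mutations, sorted by adjusted p-value."""

    entries: tuple[UnfavorableEntry, ...]
    alpha: float
    p_mode: str
    n_tested: int
    status: str = "ok"  # "ok" or "no_splittable_mutations"

    def keys(self) -> set[MutationKey]:
        return {e.key for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"mutation": str(e.key), "gene": e.gene, "raw_p": e.raw_p,
                 "adjusted_p": e.adjusted_p, "carriers": e.carrier_count}
                for e in self.entries
            ],
            columns=["mutation", "gene", "raw_p", "adjusted_p", "carriers"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class UMSResult:
    patient_id: str
    score: int
    group: str  # "negative" or "positive"


def screen_unfavorable_mutations(
    bl_profiles: Mapping[str, FilterResult],
    outcomes: pd.DataFrame,
    alpha: float = 0.01,
    p_mode: str = "adjusted",
    test: str = "gehan",
    key_set: str = "gs",
    direction_filter: bool = True,
    min_carriers: int = 3,
) -> UnfavorableMutationSet:
    """Screen baseline mutations for association with shorter PFS.

    ``bl_profiles`` maps patient id to that patient's filtered baseline
    profile; ``outcomes`` must carry ``pfs_days`` and ``pfs_event`` indexed
    by patient id. Mutations carried by zero or by all patients cannot split
    the cohort and are skipped. ``key_set`` chooses which retained call set
    defines carriage ("gs" or "somatic"). ``p_mode`` selects whether the
    retention threshold ``alpha`` applies to the BH-adjusted p-values
    (default) or to the raw ones ("raw"); adjusted p-values are reported
    either way. With ``direction_filter`` only mutations whose carriers have
    the shorter median PFS are retained — without it, protective mutations
    would also enter the score. ``min_carriers`` keeps private (near-singleton)
    mutations, which carry no usable survival contrast, out of the tested set
    so they do not dilute the multiple-testing adjustment; set it to 1 to
    test every splittable mutation.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if p_mode not in ("adjusted", "raw"):
        raise ValueError(f"p_mode must be 'adjusted' or 'raw', got {p_mode!r}")
    if key_set not in ("gs", "somatic"):
        raise ValueError(f"key_set must be 'gs' or 'somatic', got {key_set!r}")
    patients = sorted(bl_profiles)
    if len(patients) < 2:
        raise ValueError("screening needs at least 2 patients")
    missing = [p for p in patients if p not in outcomes.index]
    if missing:
        raise ValueError(f"outcomes missing for patients {missing}")

    carried: dict[MutationKey, tuple[str, set[str]]] = {}
    for pid in patients:
        prof = bl_profiles[pid]
        keys = prof.gs_keys if key_set == "gs" else prof.somatic_keys
        for key in keys:
            gene = prof.profile.records[key].gene
            entry = carried.setdefault(key, (gene, set()))
            entry[1].add(pid)

    if min_carriers < 1:
        raise ValueError(f"min_carriers must be >= 1, got {min_carriers}")
    n = len(patients)
    testable = sorted(
        k for k, (_, pids) in carried.items()
        if min_carriers <= len(pids) < n
    )
    if not testable:
        warnings.warn("no splittable mutations at baseline; empty screen")
        return UnfavorableMutationSet((), alpha, p_mode, 0,
                                      status="no_splittable_mutations")

    time = outcomes.loc[patients, "pfs_days"].to_numpy(dtype=float)
    event = outcomes.loc[patients, "pfs_event"].to_numpy(dtype=bool)
    index = {pid: i for i, pid in enumerate(patients)}
    masks = np.zeros((len(testable), n), dtype=bool)
    for row, key in enumerate(testable):
        for pid in carried[key][1]:
            masks[row, index[pid]] = True

    _, raw_p = batch_two_sample_test(time, event, masks, weighting=_weighting(test))
    adj_p = bh_adjust(raw_p)
    threshold_p = adj_p if p_mode == "adjusted" else raw_p

    entries = []
    for row, key in enumerate(testable):
        if threshold_p[row] >= alpha:
            continue
        mask = masks[row]
        if direction_filter:
            med_carrier = median_survival(km_estimate(time[mask], event[mask]))
            med_other = median_survival(km_estimate(time[~mask], event[~mask]))
            if not med_carrier < med_other:
                continue
        gene, pids = carried[key]
        entries.append(
            UnfavorableEntry(key, gene, float(raw_p[row]), float(adj_p[row]),
                             len(pids))
        )
    entries.sort(key=lambda e: (e.adjusted_p, e.raw_p, str(e.key)))
    return UnfavorableMutationSet(tuple(entries), alpha, p_mode, len(testable))


def _weighting(test: str) -> str:
    if test in ("gehan", "gehan_wilcoxon", "wilcoxon"):
        return "gehan_wilcoxon"
    if test == "logrank":
        return "logrank"
    raise ValueError(f"unknown test {test!r}")


def ums_score(
    profile: FilterResult,
    unfavorable: UnfavorableMutationSet,
    key_set: str = "gs",
    positive_min: int = 1,
) -> UMSResult:
    """Count the unfavorable mutations a baseline profile carries.

    Each carried unfavorable mutation scores 1; ``positive_min`` sets the
    score at which a patient is called UMS-positive (default 1, so negative
    means score 0 and the two groups partition the cohort; pass 2 for the
    stricter high-risk reading).
    """
    keys = profile.gs_keys if key_set == "gs" else profile.somatic_keys
    score = len(keys & unfavorable.keys())
    group = "positive" if score >= positive_min else "negative"
    return UMSResult(profile.patient_id, score, group)
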