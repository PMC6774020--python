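"""Acquired-mutation analysis and the ARID1A/BRCA2 no-benefit exclusion.

Comparing each patient's progression (PD) profile against baseline (BL)
yields the acquired-mutation set — nonsynonymous HIGH-effect calls present
at PD but not at BL. Aggregated per gene over a patient subgroup these give
the acquired-mutation frequencies. Separately, a small panel of ARID1A and
BRCA2 frameshift mutations checked at baseline flags patients likely to
derive no benefit from therapy (primary resistance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .profiles import FilterResult, MutationKey


@dataclass(frozen=True)
class PanelEntry:
    key: MutationKey
    gene: str
    label: str


@dataclass(frozen=True)
class ResistancePanel:
    """Point mutations whose baseline presence flags primary resistance."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("resistance panel must be non-empty")

    def keys(self) -> set[MutationKey]:
        return {e.key for e in self.entries}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResistancePanel":
        df = pd.read_csv(path, sep="\t", dtype={"pos": int})
        entries = tuple(
            PanelEntry(MutationKey(r.chrom, int(r.pos), r.ref, r.alt), r.gene,
                       getattr(r, "label", ""))
            for r in df.itertuples(index=False)
        )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": e.gene, "chrom": e.key.chrom, "pos": e.key.pos,
             "ref": e.key.ref, "alt": e.key.alt, "label": e.label}
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: The four published resistance point mutations (frameshifts in ARID1A and
#: BRCA2); user panels may extend this set.
DEFAULT_RESISTANCE_PANEL = ResistancePanel(
    (
        PanelEntry(MutationKey("chr1", 26779439, "TG", "T"), "ARID1A", "A1850fs"),
        PanelEntry(MutationKey("chr1", 26762190, "TC", "T"), "ARID1A", "G766fs"),
        PanelEntry(MutationKey("chr13", 32379885, "CA", "C"), "BRCA2", "T3033fs"),
        PanelEntry(MutationKey("chr13", 32379885, "C", "CA"), "BRCA2", ""),
    )
)


@dataclass(frozen=True)
class AcquiredMutationReport:
    """Mutations acquired between BL and PD for one patient."""

    patient_id: str
    acquired: frozenset[MutationKey]
    per_gene_counts: dict[str, int] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return {g for g, c in self.per_gene_counts.items() if c > 0}


def acquired_mutation_set(
    bl: FilterResult, pd_result: FilterResult
) -> AcquiredMutationReport:
    """Set difference PD \\ BL over nonsynonymous HIGH-effect calls.

    Presence is defined post-filter: a mutation below the filters at BL but
    above them at PD counts as acquired. Profiles must belong to the same
    patient and carry BL/PD timepoints.
    """
    if bl.patient_id != pd_result.patient_id:
        raise ValueError(
            f"patient mismatch: {bl.patient_id!r} vs {pd_result.patient_id!r}"
        )
    if bl.timepoint != "BL" or pd_result.timepoint != "PD":
        raise ValueError("expected a BL profile and a PD profile")
    acquired = frozenset(pd_result.nonsyn_high_keys - bl.nonsyn_high_keys)
    counts: dict[str, int] = {}
    for key in acquired:
        gene = pd_result.profile.records[key].gene
        counts[gene] = counts.get(gene, 0) + 1
    return AcquiredMutationReport(bl.patient_id, acquired, counts)


def acquired_gene_frequencies(
    reports: Iterable[AcquiredMutationReport],
    subgroup_ids: Iterable[str],
) -> dict[str, float]:
    """Fraction of subgroup patients with >= 1 acquired mutation per gene.

    The denominator is the subgroup size; patients without a report count
    as having no acquisitions.
    """
    ids = list(dict.fromkeys(subgroup_ids))
    if not ids:
        raise ValueError("subgroup must be non-empty")
    by_patient: Mapping[str, AcquiredMutationReport] = {
        r.patient_id: r for r in reports
    }
    gene_hits: dict[str, int] = {}
    for pid in ids:
        rep = by_patient.get(pid)
        if rep is None:
            continue
        for gene in rep.genes():
            gene_hits[gene] = gene_hits.get(gene, 0) + 1
    return {gene: hits / len(ids) for gene, hits in sorted(gene_hits.items())}


def nb_exclusion_flag(
    bl: FilterResult, panel: ResistancePanel = DEFAULT_RESISTANCE_PANEL
) -> tuple[bool, list[MutationKey]]:
    """True iff the baseline profile carries at least one resistance-panel
    mutation (exact key match against the retained call set)."""
    matched = sorted(bl.gs_keys & panel.keys())
    return bool(matched), matched
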