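"""Mutation-call tables, the plasma SNV filter chain, and burden predictors.

The central container is the mutation table: one row per called variant, one
column per plasma sample, each cell holding ``depth:vaf``. Samples are
identified as ``<patient>_<BL|PD>`` (baseline / progression of disease).
From a per-sample profile the filter chain derives two burden predictors:

* **G+S MB** — germline + somatic mutation burden: every depth-passing call
  in a panel gene.
* **N+S MB** — nonsynonymous + synonymous somatic burden: the subset that
  looks somatic (VAF at or below the germline threshold) and carries a
  MODERATE or HIGH predicted effect.

Effect classes follow the SnpEff/VEP convention (MODIFIER, LOW, MODERATE,
HIGH) and are trusted input; no annotation is performed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

EFFECT_CLASSES = ("MODIFIER", "LOW", "MODERATE", "HIGH")
LOW_EFFECT = frozenset({"MODIFIER", "LOW"})
HIGH_EFFECT = frozenset({"MODERATE", "HIGH"})
TIMEPOINTS = ("BL", "PD")

ORIGIN_GERMLINE = "germline"
ORIGIN_SOMATIC = "somatic"
ORIGIN_UNASSIGNED = "unassigned"


class ParseError(ValueError):
    """Malformed mutation-table content, with row/column context."""


@dataclass(frozen=True, order=True)
class MutationKey:
    """Identity of a variant: chromosome, 1-based position, ref/alt alleles.

    This key is the identity used everywhere downstream (set differences,
    screening, scoring); no left-normalisation is applied, so keys must match
    the input dialect exactly. Indels use the ref/alt slash style, e.g.
    ``TG/T`` for a 1-bp deletion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}/{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "MutationKey":
        """Parse ``chr1:26779439:TG/T``; grouping spaces as printed in
        clinical reports (``chr 1: 26 779 439:TG/T``) are stripped."""
        compact = re.sub(r"\s+", "", text)
        m = re.fullmatch(r"([^:]+):(\d+):([A-Za-z*-]+)/([A-Za-z*-]+)", compact)
        if m is None:
            raise ParseError(f"cannot parse mutation key {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3), m.group(4))


@dataclass(frozen=True)
class MutationRecord:
    """One called variant in one sample."""

    key: MutationKey
    gene: str
    effect_class: str
    synonymous: bool
    depth: int
    vaf: float
    origin: str = ORIGIN_UNASSIGNED

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect_class {self.effect_class!r}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.origin not in (ORIGIN_GERMLINE, ORIGIN_SOMATIC, ORIGIN_UNASSIGNED):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class SampleProfile:
    """All mutation records of one sample (one patient at one timepoint)."""

    patient_id: str
    timepoint: str
    records: dict[MutationKey, MutationRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be BL or PD, got {self.timepoint!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{self.timepoint}"

    def add(self, record: MutationRecord) -> None:
        if record.key in self.records:
            raise ValueError(f"duplicate mutation {record.key} in {self.sample_id}")
        self.records[record.key] = record

    def keys(self) -> set[MutationKey]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


@dataclass(frozen=True)
class BurdenSummary:
    """The two burden predictors of one sample."""

    gs_mb: int
    ns_mb: int

    def __post_init__(self) -> None:
        if not 0 <= self.ns_mb <= self.gs_mb:
            raise ValueError(f"need 0 <= ns_mb <= gs_mb, got {self}")


@dataclass
class FilterResult:
    """Outcome of the call-filter chain on one sample.

    Nothing is destroyed: ``profile`` keeps every input record; the sets
    label which records survive each stage. ``somatic_keys`` is the
    synonymous+nonsynonymous somatic set counted by N+S MB;
    ``nonsyn_high_keys`` is the nonsynonymous HIGH-effect subset used by the
    acquired-mutation comparison.
    """

    profile: SampleProfile
    gs_keys: set[MutationKey]
    somatic_keys: set[MutationKey]
    nonsyn_keys: set[MutationKey]
    nonsyn_high_keys: set[MutationKey]
    origins: dict[MutationKey, str]
    meta: dict = field(default_factory=dict)

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id

    @property
    def timepoint(self) -> str:
        return self.profile.timepoint

    @property
    def filtered(self) -> SampleProfile:
        """The retained (depth- and panel-passing) records with origins set."""
        out = SampleProfile(self.profile.patient_id, self.profile.timepoint)
        for key in sorted(self.gs_keys):
            rec = self.profile.records[key]
            out.add(replace(rec, origin=self.origins[key]))
        return out


def apply_call_filters(
    profile: SampleProfile,
    min_depth: int = 100,
    germline_vaf_threshold: float = 0.20,
    panel: Iterable[str] | None = None,
    wbc: SampleProfile | None = None,
) -> FilterResult:
    """Run the plasma SNV filter chain on one sample.

    Records below ``min_depth`` or in genes outside ``panel`` are dropped
    from every retained set. Among the survivors (the G+S set), a record is
    called germline when it appears in the matched white-blood-cell sample
    if one is given, otherwise when its VAF exceeds ``germline_vaf_threshold``
    (the proxy used when no WBC control is sequenced). The somatic set
    additionally requires a MODERATE or HIGH predicted effect; its
    nonsynonymous subset feeds the acquired-mutation analysis.

    An empty profile yields an empty (but valid) result.
    """
    if panel is None:
        from .panel import DEFAULT_PANEL_GENES

        panel = DEFAULT_PANEL_GENES
    panel_set = set(panel)
    if not panel_set:
        raise ValueError("panel must be non-empty")

    gs: set[MutationKey] = set()
    somatic: set[MutationKey] = set()
    nonsyn: set[MutationKey] = set()
    nonsyn_high: set[MutationKey] = set()
    origins: dict[MutationKey, str] = {}
    n_depth_fail = 0
    n_off_panel = 0

    wbc_keys = wbc.keys() if wbc is not None else None
    for rec in profile:
        if rec.depth < min_depth:
            n_depth_fail += 1
            continue
        if rec.gene not in panel_set:
            n_off_panel += 1
            continue
        gs.add(rec.key)
        if wbc_keys is not None:
            is_germline = rec.key in wbc_keys
        else:
            is_germline = rec.vaf > germline_vaf_threshold
        origins[rec.key] = ORIGIN_GERMLINE if is_germline else ORIGIN_SOMATIC
        if is_germline or rec.effect_class in LOW_EFFECT:
            continue
        somatic.add(rec.key)
        if not rec.synonymous:
            nonsyn.add(rec.key)
            if rec.effect_class == "HIGH":
                nonsyn_high.add(rec.key)

    meta = {
        "min_depth": min_depth,
        "germline_vaf_threshold": germline_vaf_threshold,
        "germline_mode": "wbc" if wbc is not None else "vaf_threshold",
        "n_input": len(profile),
        "n_depth_fail": n_depth_fail,
        "n_off_panel": n_off_panel,
        "n_retained": len(gs),
    }
    return FilterResult(profile, gs, somatic, nonsyn, nonsyn_high, origins, meta)


def compute_burdens(filtered: FilterResult) -> BurdenSummary:
    """G+S MB = all retained records; N+S MB = the somatic subset."""
    return BurdenSummary(gs_mb=len(filtered.gs_keys), ns_mb=len(filtered.somatic_keys))


# ---------------------------------------------------------------------------
# Mutation-table and clinical-table IO
# ---------------------------------------------------------------------------

_META_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect_class", "synonymous"]

ABSENT_CELL = "0:0.0"

#: Clinical-table columns; booleans serialised as 0/1.
CLINICAL_COLUMNS = [
    "patient_id",
    "gender",
    "smoking",
    "pathology",
    "driver_positive",
    "metastases",
    "pfs_days",
    "pfs_event",
    "os_days",
    "os_event",
    "intolerance",
    "idh1_exon4_mutant",
]
_CLINICAL_BOOL = ["smoking", "driver_positive", "pfs_event", "os_event",
                  "intolerance", "idh1_exon4_mutant"]


def _parse_cell(cell: str, row: int, column: str) -> tuple[int, float] | None:
    """A cell is ``depth:vaf``; zero depth encodes absence."""
    text = str(cell).strip()
    if text in ("", ".", "nan"):
        return None
    parts = text.split(":")
    if len(parts) != 2:
        raise ParseError(f"malformed cell {cell!r} at row {row}, column {column!r}")
    try:
        depth = int(parts[0])
        vaf = float(parts[1])
    except ValueError as exc:
        raise ParseError(
            f"malformed cell {cell!r} at row {row}, column {column!r}"
        ) from exc
    if depth == 0:
        return None
    return depth, vaf


def read_mutation_table(path: str | Path) -> dict[str, SampleProfile]:
    """Read a mutation table TSV into one :class:`SampleProfile` per sample.

    Returns a mapping keyed by sample id (``<patient>_<BL|PD>``). Cells with
    zero depth produce no record. Malformed cells, duplicate mutation rows
    and unknown effect classes raise :class:`ParseError` naming the row and
    column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"mutation table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _META_COLUMNS]
    profiles: dict[str, SampleProfile] = {}
    for col in sample_cols:
        patient_id, sep, timepoint = col.rpartition("_")
        if not sep or timepoint not in TIMEPOINTS:
            raise ParseError(f"sample column {col!r} is not <patient>_<BL|PD>")
        profiles[col] = SampleProfile(patient_id, timepoint)

    seen: set[MutationKey] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rowd = dict(zip(df.columns, row))
        try:
            pos = int(re.sub(r"\s+", "", rowd["pos"]))
            key = MutationKey(rowd["chrom"].strip(), pos, rowd["ref"], rowd["alt"])
        except (ValueError, ParseError) as exc:
            raise ParseError(f"bad mutation identity at row {i}: {exc}") from exc
        if key in seen:
            raise ParseError(f"duplicate mutation row {key} at row {i}")
        seen.add(key)
        effect = rowd["effect_class"]
        if effect not in EFFECT_CLASSES:
            raise ParseError(f"unknown effect_class {effect!r} at row {i}")
        synonymous = rowd["synonymous"] in ("1", "True", "true")
        for col in sample_cols:
            parsed = _parse_cell(rowd[col], i, col)
            if parsed is None:
                continue
            depth, vaf = parsed
            try:
                rec = MutationRecord(key, rowd["gene"], effect, synonymous, depth, vaf)
            except ValueError as exc:
                raise ParseError(f"row {i}, column {col!r}: {exc}") from exc
            profiles[col].add(rec)
    return profiles


def write_mutation_table(profiles: Mapping[str, SampleProfile], path: str | Path) -> None:
    """Serialize profiles back to the TSV dialect read by
    :func:`read_mutation_table`. Row metadata (gene, effect, synonymous) must
    agree across samples for a given key."""
    meta: dict[MutationKey, tuple[str, str, bool]] = {}
    for prof in profiles.values():
        for rec in prof:
            info = (rec.gene, rec.effect_class, rec.synonymous)
            if meta.setdefault(rec.key, info) != info:
                raise ValueError(f"inconsistent annotation for {rec.key}")
    keys = sorted(meta)
    cols = sorted(profiles)
    rows = []
    for key in keys:
        gene, effect, syn = meta[key]
        row = [key.chrom, str(key.pos), key.ref, key.alt, gene, effect,
               "1" if syn else "0"]
        for col in cols:
            rec = profiles[col].records.get(key)
            row.append(ABSENT_CELL if rec is None else f"{rec.depth}:{rec.vaf:.6f}")
        rows.append(row)
    out = pd.DataFrame(rows, columns=_META_COLUMNS + cols)
    out.to_csv(path, sep="\t", index=False)


def read_vcf(
    path: str | Path,
    gene_tag: str = "GENE",
    effect_tag: str = "EFFECT",
    synonymous_tag: str = "SYN",
) -> dict[str, SampleProfile]:
    """Import a minimal multi-sample VCF onto the same profile records.

    Expects per-record INFO tags for gene symbol and effect class, an
    optional synonymous flag, and per-sample ``DP``/``AF`` FORMAT fields;
    sample names follow the ``<patient>_<BL|PD>`` convention. Samples with
    missing or zero depth at a site produce no record.
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    profiles: dict[str, SampleProfile] = {}
    for sample in reader.samples:
        patient_id, sep, timepoint = sample.rpartition("_")
        if not sep or timepoint not in TIMEPOINTS:
            raise ParseError(f"VCF sample {sample!r} is not <patient>_<BL|PD>")
        profiles[sample] = SampleProfile(patient_id, timepoint)
    for var in reader:
        if not var.ALT:
            continue
        key = MutationKey(var.CHROM, var.POS, var.REF, var.ALT[0])
        gene = var.INFO.get(gene_tag)
        effect = var.INFO.get(effect_tag)
        if gene is None or effect is None:
            raise ParseError(f"{key}: missing {gene_tag}/{effect_tag} INFO tag")
        if effect not in EFFECT_CLASSES:
            raise ParseError(f"{key}: unknown effect_class {effect!r}")
        synonymous = bool(var.INFO.get(synonymous_tag))
        depths = var.format("DP")
        afs = var.format("AF")
        if depths is None or afs is None:
            raise ParseError(f"{key}: missing DP/AF FORMAT fields")
        for i, sample in enumerate(reader.samples):
            depth = int(depths[i][0])
            vaf = float(afs[i][0])
            if depth <= 0 or not 0.0 <= vaf <= 1.0:  # missing sentinel / nan
                continue
            profiles[sample].add(
                MutationRecord(key, gene, effect, synonymous, depth, vaf)
            )
    return profiles


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical table, indexed by patient id."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing columns {missing}")
    for col in _CLINICAL_BOOL:
        df[col] = df[col].astype(int).astype(bool)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.set_index("patient_id", drop=False)


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    df = clinical.reset_index(drop=True).copy()
    for col in _CLINICAL_BOOL:
        df[col] = df[col].astype(int)
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)
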