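"""Post-denoising quality filters for eDNA metabarcoding ASV tables.

The stage consumes a denoised samples x ASVs read-count table plus per-ASV
sequences and taxonomic assignments, and applies, in order:

1. taxonomic retention (keep the target class, e.g. ray-finned fishes);
2. negative-control contamination subtraction (per-ASV, clipped at zero);
3. occurrence (>= 2 samples) and total-read (>= 10) thresholds;
4. NUMT screen — flag sequences that translate with an in-frame stop codon
   under the vertebrate mitochondrial code;
5. marine-family exclusion;
6. pooling of sites to basin-level presence/absence.

Read abundances are deliberately dropped at pooling: all downstream analyses
are occurrence-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align

from .synthetic_data import MARINE_FAMILIES, MITO_STOP_CODONS

logger = logging.getLogger(__name__)

RANKS = ("class", "order", "family", "genus", "species")
FAMILY_RANK = RANKS.index("family")


@dataclass
class ReadMatrix:
    """Samples x ASVs integer read counts with per-sample control flags."""

    counts: pd.DataFrame
    is_control: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and ASV ids must be unique")
        self.is_control = self.is_control.reindex(self.counts.index).fillna(False).astype(bool)
        if self.is_control.all():
            raise ValueError("need at least one non-control sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ASVRecord:
    """One amplicon sequence variant: id, sequence, taxonomy and screen flags."""

    asv_id: str
    sequence: str
    taxon_path: tuple[str, ...] = ("", "", "", "", "")
    confidence: float = float("nan")
    flags: set = field(default_factory=set)

    def rank(self, name: str) -> str:
        return self.taxon_path[RANKS.index(name)] if len(self.taxon_path) > RANKS.index(name) else ""

    @property
    def has_family_or_deeper(self) -> bool:
        return any(r.strip() for r in self.taxon_path[FAMILY_RANK:])


@dataclass
class CommunityMatrix:
    """Basins x ASVs presence/absence with side-of-divide labels."""

    presence: pd.DataFrame
    side_of_divide: pd.Series

    @property
    def basin_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.presence.columns)


def records_from_tables(sequences: dict[str, str], taxonomy: pd.DataFrame) -> list[ASVRecord]:
    """Join a FASTA dict and a taxonomy table (asv_id, 'Class;...;Species',
    confidence) into ASVRecords; ASVs without a taxonomy row get empty ranks."""
    tax = taxonomy.set_index("asv_id") if "asv_id" in taxonomy.columns else taxonomy
    records = []
    for aid, seq in sequences.items():
        path: tuple[str, ...] = ("", "", "", "", "")
        conf = float("nan")
        if aid in tax.index:
            row = tax.loc[aid]
            parts = str(row["taxon_path"]).split(";")
            path = tuple((parts + [""] * 5)[:5])
            conf = float(row.get("confidence", float("nan")))
        records.append(ASVRecord(asv_id=aid, sequence=seq, taxon_path=path, confidence=conf))
    return records


# ---------------------------------------------------------------------------
# contamination subtraction and thresholds
# ---------------------------------------------------------------------------

def subtract_control_reads(matrix: ReadMatrix, combine: str = "sum") -> ReadMatrix:
    """Per-ASV negative-control subtraction.

    For each ASV the reads observed in negative controls (summed, or the
    maximum with ``combine='max'``) are subtracted from every field sample,
    clipping at zero; control rows are dropped from the result.
    """
    ctrl = matrix.counts.loc[matrix.is_control]
    if ctrl.empty:
        logger.warning("no control samples: contamination subtraction is a no-op")
        c = pd.Series(0, index=matrix.counts.columns)
    elif combine == "sum":
        c = ctrl.sum(axis=0)
    elif combine == "max":
        c = ctrl.max(axis=0)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    out = matrix.counts.loc[~matrix.is_control].sub(c, axis=1).clip(lower=0)
    return ReadMatrix(counts=out.astype(int), is_control=pd.Series(False, index=out.index))


def filter_occurrence_and_reads(
    matrix: ReadMatrix, min_samples: int = 2, min_total_reads: int = 10
) -> ReadMatrix:
    """Drop ASVs detected in fewer than ``min_samples`` field samples or with
    fewer than ``min_total_reads`` reads overall (controls excluded from both)."""
    f = matrix.counts.loc[~matrix.is_control]
    keep = ((f > 0).sum(axis=0) >= min_samples) & (f.sum(axis=0) >= min_total_reads)
    if not keep.any():
        logger.warning("occurrence/read filter removed every ASV")
    return ReadMatrix(counts=matrix.counts.loc[:, keep[keep].index],
                      is_control=matrix.is_control)


# ---------------------------------------------------------------------------
# NUMT screen
# ---------------------------------------------------------------------------

def _has_inframe_stop(trimmed: str) -> bool:
    """True iff any complete codon is a vertebrate-mitochondrial stop; codons
    containing ambiguity codes are left untranslated and never count as stops."""
    s = trimmed.upper()
    for i in range(0, len(s) - 2, 3):
        codon = s[i:i + 3]
        if set(codon) <= set("ACGT") and codon in MITO_STOP_CODONS:
            return True
    return False


def _frame_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # amplicon may sit inside a longer CDS: end gaps are free
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def screen_numts(
    record: ASVRecord, reference_cds: str, mode: str = "alignment-frame"
) -> ASVRecord:
    """Set or clear the ``numt`` flag on a record by stop-codon screening.

    ``fixed-trim-15`` removes the first 15 bases (five codons, assuming a fixed
    amplicon start in frame 0 of the reference) and translates the rest with the
    vertebrate mitochondrial code. ``alignment-frame`` instead derives the codon
    phase from a global alignment to an in-frame reference CDS and translates
    from the first complete codon. Either way the record is flagged ``numt`` iff
    at least one stop codon appears. Sequences shorter than 18 bases are flagged
    ``unscreenable`` (treated as removed downstream).
    """
    seq = record.sequence.upper()
    flags = set(record.flags) - {"numt", "unscreenable"}
    if len(seq) < 18:
        logger.warning("%s: too short to screen (%d bp)", record.asv_id, len(seq))
        return replace(record, flags=flags | {"unscreenable"})
    if mode == "fixed-trim-15":
        trimmed = seq[15:]
    elif mode == "alignment-frame":
        aln = _frame_aligner().align(reference_cds.upper(), seq)[0]
        tgt_blocks, qry_blocks = aln.aligned
        if len(qry_blocks) == 0:
            return replace(record, flags=flags | {"unscreenable"})
        t0, q0 = int(tgt_blocks[0][0]), int(qry_blocks[0][0])
        # first query position >= q0 whose reference coordinate t0+(q-q0) is a codon start
        shift = (-t0) % 3
        trimmed = seq[q0 + shift:]
    else:
        raise ValueError(f"unknown NUMT screen mode {mode!r}")
    if _has_inframe_stop(trimmed):
        flags |= {"numt"}
    return replace(record, flags=flags)


# ---------------------------------------------------------------------------
# taxonomy filters
# ---------------------------------------------------------------------------

def filter_taxa(
    records: list[ASVRecord],
    keep_class: str | None = "Actinopterygii",
    excluded_families: tuple[str, ...] = MARINE_FAMILIES,
    require_at_least: str | None = None,
) -> tuple[list[ASVRecord], list[tuple[str, str]]]:
    """Taxonomic retention rules; returns (kept records, removal log).

    Drops records outside ``keep_class`` (when set), flags and drops the
    excluded marine families (case-insensitive exact match on the family rank),
    and — when ``require_at_least='family'`` — drops records with no assignment
    at family rank or deeper.
    """
    excluded = {f.lower() for f in excluded_families}
    kept, removed = [], []
    for rec in records:
        if keep_class is not None and rec.rank("class") != keep_class:
            removed.append((rec.asv_id, f"class != {keep_class}"))
            continue
        if rec.rank("family").lower() in excluded:
            rec = replace(rec, flags=set(rec.flags) | {"marine"})
            removed.append((rec.asv_id, f"marine family {rec.rank('family')}"))
            continue
        if require_at_least == "family" and not rec.has_family_or_deeper:
            rec = replace(rec, flags=set(rec.flags) | {"below_family"})
            removed.append((rec.asv_id, "no assignment at family level or deeper"))
            continue
        if require_at_least not in (None, "family"):
            logger.warning("unknown rank requirement %r: ignored", require_at_least)
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_to_basins(matrix: ReadMatrix, metadata: pd.DataFrame) -> CommunityMatrix:
    """Merge samples into basin-level presence/absence.

    ``presence[b, a]`` is True iff any sample of basin ``b`` has a positive count
    for ASV ``a``; all-zero ASV columns are dropped. Read counts do not propagate.
    """
    meta = metadata.set_index("sample_id")
    f = matrix.counts.loc[~matrix.is_control]
    unknown = [s for s in f.index if s not in meta.index or not str(meta.loc[s, "basin"]).strip()]
    if unknown:
        raise ValueError(f"samples with unknown basin: {unknown}")
    basin_of = meta.loc[f.index, "basin"]
    presence = (f > 0).groupby(basin_of).any()
    presence = presence.loc[:, presence.any(axis=0)]
    presence.index.name = "basin_id"
    side = meta.loc[f.index].groupby(basin_of)["side"].first()
    return CommunityMatrix(presence=presence, side_of_divide=side.loc[presence.index])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    community: CommunityMatrix
    matrix: ReadMatrix                 # field samples x surviving ASVs
    records: list[ASVRecord]           # surviving records
    report: pd.DataFrame               # asv_id, step_removed, reason


def run_filter_pipeline(
    matrix: ReadMatrix,
    records: list[ASVRecord],
    metadata: pd.DataFrame,
    reference_cds: str,
    *,
    min_samples: int = 2,
    min_total_reads: int = 10,
    numt_mode: str = "alignment-frame",
    keep_class: str = "Actinopterygii",
    excluded_families: tuple[str, ...] = MARINE_FAMILIES,
    control_combine: str = "sum",
) -> FilterResult:
    """Run every quality filter in order and pool survivors to basins.

    Order: class retention -> control subtraction -> occurrence/reads -> NUMT
    screen -> marine exclusion -> basin pooling. Idempotent: re-running on its
    own output changes nothing.
    """
    report_rows: list[dict] = []

    def log_removed(ids, step, reason_map=None):
        for aid in ids:
            report_rows.append({
                "asv_id": aid, "step_removed": step,
                "reason": (reason_map or {}).get(aid, step),
            })

    # 1. class retention
    kept, removed = filter_taxa(records, keep_class=keep_class, excluded_families=())
    log_removed([a for a, _ in removed], "taxon_class", dict(removed))
    by_id = {r.asv_id: r for r in kept}
    mat = ReadMatrix(
        counts=matrix.counts.loc[:, [a for a in matrix.asv_ids if a in by_id]],
        is_control=matrix.is_control,
    )

    # 2. contamination subtraction
    mat = subtract_control_reads(mat, combine=control_combine)

    # 3. occurrence / total reads
    before = set(mat.asv_ids)
    mat = filter_occurrence_and_reads(mat, min_samples=min_samples,
                                      min_total_reads=min_total_reads)
    log_removed(sorted(before - set(mat.asv_ids)), "occurrence_reads")

    # 4. NUMT screen
    screened = {
        aid: screen_numts(by_id[aid], reference_cds, mode=numt_mode)
        for aid in mat.asv_ids
    }
    numts = sorted(a for a, r in screened.items() if r.flags & {"numt", "unscreenable"})
    log_removed(numts, "numt_screen")
    mat = ReadMatrix(counts=mat.counts.drop(columns=numts), is_control=mat.is_control)

    # 5. marine families
    kept2, removed2 = filter_taxa(
        [screened[a] for a in mat.asv_ids], keep_class=None,
        excluded_families=excluded_families,
    )
    log_removed([a for a, _ in removed2], "marine_family", dict(removed2))
    mat = ReadMatrix(counts=mat.counts.loc[:, [r.asv_id for r in kept2]],
                     is_control=mat.is_control)

    # 6. pool to basins
    community = pool_to_basins(mat, metadata)

    report = pd.DataFrame(report_rows, columns=["asv_id", "step_removed", "reason"])
    survivors = [r for r in kept2 if r.asv_id in set(community.asv_ids)]
    # ASVs zeroed everywhere (fully subtracted) never reach pooling
    mat = ReadMatrix(counts=mat.counts.loc[:, community.asv_ids], is_control=mat.is_control)
    return FilterResult(community=community, matrix=mat, records=survivors, report=report)
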