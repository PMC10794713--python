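"""Quantification of encapsidated RNA from read-alignment tables.

Nanopore direct-RNA reads aligned against a coding-sequence (CDS)
reference set are reduced to per-CDS abundances.  The workflow:

1. retain alignments at the aligner's maximal mapping quality (MAPQ 60);
2. keep only reads whose alignment ends within a fixed window (50 nt) of
   the reference 3' end — direct RNA sequencing proceeds 3'->5', so a
   3'-anchored alignment is the signature of a (near-)full-length
   transcript;
3. count reads per CDS and convert to transcripts per million (TPM);
4. form *adjusted* TPM over the transcripts detected in both biological
   replicates (others discarded, survivors renormalized per replicate to
   a proper per-million composition, then averaged);
5. per-base coverage, globally normalized to one million bases and
   smoothed with a 40-base moving mean, plus base-pair percentages per
   RNA class (CP, p97, rRNA, other).

Coordinates are 0-based half-open internally; SAM input (1-based) is
converted at ingestion via pysam.  Each read id must appear exactly once
(primary alignments only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSet",
    "QuantResult",
    "RNA_CLASSES",
    "filter_mapq",
    "filter_three_prime",
    "count_per_cds",
    "tpm",
    "adjusted_tpm",
    "per_base_coverage",
    "normalize_coverage",
    "smooth_coverage",
    "bp_percent_by_class",
    "quantify_replicates",
    "read_alignments_tsv",
    "read_alignments_sam",
    "read_reference_classes_tsv",
    "write_bedgraph",
]

RNA_CLASSES = ("CP", "p97", "rRNA", "other")

ALN_COLUMNS = ["read_id", "ref_id", "start", "end", "mapq"]


@dataclass(frozen=True)
class ReferenceSet:
    """CDS reference universe: per-ref length (nt), RNA class, display name."""

    lengths: dict[str, int]
    classes: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ref_id, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"reference {ref_id!r} has non-positive length {length}")
        for ref_id, cls in self.classes.items():
            if cls not in RNA_CLASSES:
                raise ValueError(f"unknown RNA class {cls!r} for {ref_id!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.lengths)

    def class_of(self, ref_id: str) -> str:
        return self.classes.get(ref_id, "other")


def _validate_alignments(alns: pd.DataFrame, refs: ReferenceSet | None = None) -> None:
    if len(alns) == 0:
        return
    if alns["read_id"].duplicated().any():
        dup = alns.loc[alns["read_id"].duplicated(), "read_id"].iloc[0]
        raise ValueError(f"duplicate read_id {dup!r}: one primary alignment per read expected")
    if (alns["start"] >= alns["end"]).any():
        raise ValueError("alignment with start >= end (coordinates are 0-based half-open)")
    if ((alns["mapq"] < 0) | (alns["mapq"] > 60)).any():
        raise ValueError("MAPQ outside 0..60")
    if refs is not None:
        for ref_id, sub in alns.groupby("ref_id"):
            if ref_id not in refs.lengths:
                raise KeyError(f"reference {ref_id!r} absent from ReferenceSet")
            if int(sub["end"].max()) > refs.lengths[ref_id]:
                raise ValueError(f"alignment beyond reference {ref_id!r} end")


def filter_mapq(alns: pd.DataFrame, keep: int = 60) -> pd.DataFrame:
    """Retain alignments whose MAPQ equals ``keep`` (order preserved)."""
    if not (0 <= keep <= 60):
        raise ValueError("keep must lie in 0..60")
    return alns[alns["mapq"] == keep].reset_index(drop=True)


def filter_three_prime(
    alns: pd.DataFrame, refs: ReferenceSet, window: int = 50
) -> pd.DataFrame:
    """Retain alignments ending within ``window`` nt of the reference 3' end.

    Criterion on the alignment end coordinate: ref_length - end <= window.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(alns) == 0:
        return alns.copy()
    missing = set(alns["ref_id"]) - set(refs.lengths)
    if missing:
        raise KeyError(f"reference {sorted(missing)[0]!r} absent from ReferenceSet")
    ref_len = alns["ref_id"].map(refs.lengths)
    return alns[(ref_len - alns["end"]) <= window].reset_index(drop=True)


def count_per_cds(alns: pd.DataFrame, refs: ReferenceSet | None = None) -> pd.Series:
    """Read count per reference (each read counted once).

    When ``refs`` is given, zero-count references are included so downstream
    tables cover the whole universe.
    """
    counts = alns.groupby("ref_id").size() if len(alns) else pd.Series(dtype=int)
    if refs is not None:
        counts = counts.reindex(refs.ids, fill_value=0)
    counts.name = "count"
    return counts.astype(int)


def tpm(counts: pd.Series, refs: ReferenceSet) -> pd.Series:
    """Transcripts per million from counts and reference lengths.

    rate_i = count_i / length_i; TPM_i = rate_i / sum(rates) * 1e6.  An
    all-zero count vector yields all-zero TPM with ``attrs['all_zero']``
    set on the result.
    """
    counts = counts.reindex(refs.ids, fill_value=0)
    lengths = pd.Series(refs.lengths, dtype=float)
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        out = pd.Series(0.0, index=counts.index, name="tpm")
        out.attrs["all_zero"] = True
        return out
    out = rates / total * 1e6
    out.name = "tpm"
    out.attrs["all_zero"] = False
    return out


def adjusted_tpm(
    tpm_rep1: pd.Series, tpm_rep2: pd.Series, renormalize: bool = True
) -> pd.DataFrame:
    """Replicate-consistent adjusted TPM.

    Transcripts with TPM > 0 in *both* biological replicates are retained;
    the rest are discarded.  With ``renormalize=True`` (default) each
    replicate's surviving TPMs are rescaled to sum to 1e6 before averaging,
    so every column remains a proper per-million composition; with
    ``renormalize=False`` surviving raw TPMs are averaged as-is (their sum
    is then generally below 1e6).

    Returns a DataFrame indexed by retained ref_id with columns rep1, rep2,
    mean.
    """
    if set(tpm_rep1.index) != set(tpm_rep2.index):
        raise ValueError("replicates must share the same reference universe")
    r2 = tpm_rep2.reindex(tpm_rep1.index)
    shared = (tpm_rep1 > 0) & (r2 > 0)
    if not shared.any():
        raise ValueError("no transcripts present in both replicates")
    a, b = tpm_rep1[shared].astype(float), r2[shared].astype(float)
    if renormalize:
        a = a / a.sum() * 1e6
        b = b / b.sum() * 1e6
    out = pd.DataFrame({"rep1": a, "rep2": b})
    out["mean"] = out.mean(axis=1)
    return out


def per_base_coverage(alns: pd.DataFrame, refs: ReferenceSet) -> dict[str, np.ndarray]:
    """Raw per-base coverage track for every reference.

    coverage[b] = number of alignments overlapping base b (0-based).
    """
    _validate_alignments(alns, refs)
    tracks = {ref_id: np.zeros(length, dtype=float) for ref_id, length in refs.lengths.items()}
    for row in alns.itertuples():
        track = tracks[row.ref_id]
        track[int(row.start)] += 1
        if int(row.end) < len(track):
            track[int(row.end)] -= 1
    return {ref_id: np.cumsum(t) for ref_id, t in tracks.items()}


def normalize_coverage(tracks: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Normalize coverage to one million bases across the whole reference set.

    Every base is divided by the grand total of coverage over all references
    and multiplied by 1e6, so the output's grand total is exactly 1e6.
    """
    grand_total = float(sum(t.sum() for t in tracks.values()))
    if grand_total == 0:
        raise ValueError("all-zero coverage: nothing to normalize")
    return {ref_id: t / grand_total * 1e6 for ref_id, t in tracks.items()}


def smooth_coverage(track: np.ndarray, window: int = 40) -> np.ndarray:
    """Centered moving mean over ``window`` consecutive bases.

    The window is truncated at the track edges (mean over the bases actually
    inside), so output length equals input length and constant tracks pass
    through unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(track, dtype=float))
    return s.rolling(window=window, center=True, min_periods=1).mean().to_numpy()


def bp_percent_by_class(alns: pd.DataFrame, refs: ReferenceSet) -> dict[str, float]:
    """Percentage of aligned base pairs per RNA class.

    Class bp = sum of (end - start) over alignments to references of that
    class; percentages over all classes sum to 100.
    """
    if len(alns) == 0:
        raise ValueError("zero total aligned bp")
    spans = (alns["end"] - alns["start"]).astype(float)
    cls = alns["ref_id"].map(refs.class_of)
    by_class = spans.groupby(cls).sum()
    total = by_class.sum()
    if total == 0:
        raise ValueError("zero total aligned bp")
    return {c: float(by_class.get(c, 0.0) / total * 100.0) for c in RNA_CLASSES}


@dataclass(frozen=True)
class QuantResult:
    """Full quantification of a two-replicate alignment experiment."""

    counts: list[pd.Series]  # retained read counts per replicate
    tpm: list[pd.Series]  # raw TPM per replicate
    adjusted: pd.DataFrame  # replicate-consistent adjusted TPM
    coverage_raw: dict[str, np.ndarray]  # pooled over replicates
    coverage_norm: dict[str, np.ndarray]
    coverage_smooth: dict[str, np.ndarray]
    bp_percent: dict[str, float]


def quantify_replicates(
    replicates: Sequence[pd.DataFrame],
    refs: ReferenceSet,
    mapq: int = 60,
    three_prime_window: int = 50,
    smooth_window: int = 40,
    renormalize: bool = True,
) -> QuantResult:
    """Run the full quantification pipeline on two replicate alignment tables."""
    if len(replicates) != 2:
        raise ValueError("adjusted TPM is defined over exactly two biological replicates")
    mapq_kept, filtered = [], []
    for alns in replicates:
        _validate_alignments(alns, refs)
        kept = filter_mapq(alns, keep=mapq)
        mapq_kept.append(kept)
        filtered.append(filter_three_prime(kept, refs, window=three_prime_window))
    counts = [count_per_cds(f, refs) for f in filtered]
    tpms = [tpm(c, refs) for c in counts]
    adjusted = adjusted_tpm(tpms[0], tpms[1], renormalize=renormalize)
    # coverage and bp% use the MAPQ-retained alignments (the 3' window is a
    # counting sensor, not a coverage mask), pooled across replicates;
    # read ids are per-replicate unique, so suffix them before validation
    pooled = pd.concat(mapq_kept, ignore_index=True)
    pooled = pooled.assign(
        read_id=[f"{r}|{i}" for i, r in enumerate(pooled["read_id"])]
    )
    cov_raw = per_base_coverage(pooled, refs)
    cov_norm = normalize_coverage(cov_raw)
    cov_smooth = {ref_id: smooth_coverage(t, smooth_window) for ref_id, t in cov_norm.items()}
    bp_pct = bp_percent_by_class(pooled, refs)
    return QuantResult(
        counts=counts,
        tpm=tpms,
        adjusted=adjusted,
        coverage_raw=cov_raw,
        coverage_norm=cov_norm,
        coverage_smooth=cov_smooth,
        bp_percent=bp_pct,
    )


# ---------------------------------------------------------------------------
# I/O


def read_alignments_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read the TSV alignment dialect (read_id, ref_id, start, end, mapq)."""
    alns = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_id": str})
    missing = set(ALN_COLUMNS) - set(alns.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    _validate_alignments(alns)
    return alns[ALN_COLUMNS]


def read_alignments_sam(path: Union[str, Path]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read minimal single-end SAM via pysam.

    Returns the alignment table (0-based half-open coordinates) and the
    reference lengths taken from the @SQ header lines.  Unmapped, secondary
    and supplementary records are rejected: the data model holds exactly one
    primary alignment per read.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped:
                raise ValueError(f"unmapped record {rec.query_name!r} in alignment input")
            if rec.is_secondary or rec.is_supplementary:
                raise ValueError(
                    f"secondary/supplementary record {rec.query_name!r}: primary only"
                )
            rows.append(
                {
                    "read_id": rec.query_name,
                    "ref_id": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_end,
                    "mapq": rec.mapping_quality,
                }
            )
    alns = pd.DataFrame(rows, columns=ALN_COLUMNS)
    _validate_alignments(alns)
    return alns, ref_lengths


def read_reference_classes_tsv(path: Union[str, Path], lengths: Mapping[str, int]) -> ReferenceSet:
    """Build a ReferenceSet from a two-column TSV (ref_id, class) plus lengths."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    classes = dict(zip(table["ref_id"], table["class"]))
    return ReferenceSet(lengths=dict(lengths), classes=classes)


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: Union[str, Path]) -> None:
    """Write coverage tracks as bedGraph (runs of equal value collapsed)."""
    with open(path, "w") as fh:
        for ref_id, track in tracks.items():
            track = np.asarray(track)
            if len(track) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(track)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(track)]])
            for s, e in zip(starts, ends):
                fh.write(f"{ref_id}\t{s}\t{e}\t{track[s]:g}\n")
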