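"""Barcode demultiplexing of paired-end reads.

Read 1 carries the spatial barcode as concatenated fixed-width letters after
a constant 5' handle.  Because each new letter is ligated 5' of the previous
one, the *last*-ligated letter sits nearest the handle: Read 1 presents the
letters in reverse ligation-round order, and the parser flips them back.
Letters are decoded window-by-window by minimum Hamming distance against
the alphabet; indels are not handled (the windows are fixed-width), which is
adequate for substitution-dominated short-read errors over 20-nt letters.

Decoded codewords are assigned to regions under one of three policies:
``exact`` (error detection only), ``nearest-unique`` (accept a codeword with
exactly one codebook entry at Hamming distance <= 1), or ``repeat-collapse``
(decode an r-repeat codeword by requiring at least one surviving repeat per
digit).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from .codebook import Codebook, Codeword, Letter

__all__ = [
    "DemuxError",
    "ReadLayout",
    "Rejection",
    "DemuxResult",
    "validate_alphabet_separation",
    "parse_barcode",
    "assign_region",
    "demux_pairs",
    "demux_fastq",
    "tabulate",
]

REJECT_NO_HANDLE = "no-handle"
REJECT_LETTER_MISMATCH = "letter-mismatch"
REJECT_AMBIGUOUS = "ambiguous"
REJECT_LENGTH = "length-anomaly"
REJECT_NO_MATCH = "no-match"


class DemuxError(ValueError):
    """Invalid layout, alphabet, or demultiplexing configuration."""


@dataclass(frozen=True)
class ReadLayout:
    """Structure of Read 1: handle, barcode slot, optional 3' anchor."""

    handle: str
    n_letters: int
    letter_bp: int = 20
    anchor: str = ""

    def __post_init__(self) -> None:
        if not self.handle:
            raise DemuxError("handle must be non-empty")
        if self.n_letters < 1 or self.letter_bp < 1:
            raise DemuxError("n_letters and letter_bp must be >= 1")

    @property
    def slot_width(self) -> int:
        return self.n_letters * self.letter_bp


@dataclass(frozen=True)
class Rejection:
    """A read that could not be decoded, with the reason why."""

    reason: str
    detail: str = ""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_alphabet_separation(
    letters: Sequence[Letter], max_mm_per_letter: int
) -> None:
    """Require pairwise letter distance > 2*max_mm so decoding is unambiguous."""
    threshold = 2 * max_mm_per_letter
    for i, a in enumerate(letters):
        for b in letters[i + 1:]:
            if _hamming(a.sequence, b.sequence) <= threshold:
                raise DemuxError(
                    f"letters L{a.id} and L{b.id} are separated by "
                    f"<= {threshold} mismatches; decoding at "
                    f"max_mm={max_mm_per_letter} would be unsafe"
                )


def _find_handle(read: str, handle: str) -> int:
    """Offset of the handle (exact preferred, else <= 1 mismatch), or -1."""
    pos = read.find(handle)
    if pos >= 0:
        return pos
    for off in range(len(read) - len(handle) + 1):
        if _hamming(read[off:off + len(handle)], handle) <= 1:
            return off
    return -1


def parse_barcode(
    read1: str,
    layout: ReadLayout,
    letters: Sequence[Letter],
    max_mm_per_letter: int = 2,
) -> Codeword | Rejection:
    """Decode the spatial barcode from a Read 1 sequence.

    Locates the handle, then matches each fixed-width window against the
    alphabet by minimum Hamming distance; a letter is accepted iff its best
    match is unique and within ``max_mm_per_letter``.  The decoded letters
    are reversed into ligation-round order before being returned.
    """
    read1 = read1.upper()
    off = _find_handle(read1, layout.handle)
    if off < 0:
        return Rejection(REJECT_NO_HANDLE)
    start = off + len(layout.handle)
    if len(read1) - start < layout.slot_width:
        return Rejection(REJECT_LENGTH, "read shorter than barcode slot")
    decoded: list[int] = []
    for i in range(layout.n_letters):
        window = read1[start + i * layout.letter_bp:
                       start + (i + 1) * layout.letter_bp]
        dists = sorted(
            (_hamming(window, let.sequence), let.id) for let in letters
        )
        best_d, best_id = dists[0]
        if best_d > max_mm_per_letter:
            return Rejection(REJECT_LETTER_MISMATCH, f"window {i}")
        if len(dists) > 1 and dists[1][0] == best_d:
            return Rejection(REJECT_AMBIGUOUS, f"window {i}")
        decoded.append(best_id)
    return Codeword(tuple(reversed(decoded)))  # back to round order


def assign_region(
    codeword: Codeword,
    codebook: Codebook,
    policy: str = "exact",
    repeats: int = 1,
) -> str | Rejection:
    """Map a decoded codeword to a region id under the chosen policy.

    ``exact``
        The codeword must equal an assigned codeword (any error → reject).
    ``nearest-unique``
        Accept iff exactly one assigned codeword lies within Hamming
        distance 1.
    ``repeat-collapse``
        The codebook holds unexpanded codewords ligated as ``repeats``-fold
        repeat codes; each digit matches iff at least one of its repeats
        survived, then the collapsed word must match exactly one region.
    """
    if policy == "exact":
        for rid, cw in codebook.assignment.items():
            if cw.digits == codeword.digits:
                return rid
        return Rejection(REJECT_NO_MATCH)
    if policy == "nearest-unique":
        hits = [
            rid for rid, cw in codebook.assignment.items()
            if len(cw) == len(codeword) and cw.hamming(codeword) <= 1
        ]
        if not hits:
            return Rejection(REJECT_NO_MATCH)
        if len(hits) > 1:
            return Rejection(REJECT_AMBIGUOUS, "equidistant codewords")
        return hits[0]
    if policy == "repeat-collapse":
        if repeats < 1:
            raise DemuxError("repeats must be >= 1")
        if len(codeword) != codebook.n * repeats:
            return Rejection(REJECT_LENGTH, "repeat-expanded length mismatch")
        hits = []
        for rid, cw in codebook.assignment.items():
            ok = all(
                cw.digits[j] in codeword.digits[j * repeats:(j + 1) * repeats]
                for j in range(codebook.n)
            )
            if ok:
                hits.append(rid)
        if not hits:
            return Rejection(REJECT_NO_MATCH)
        if len(hits) > 1:
            return Rejection(REJECT_AMBIGUOUS, "multiple collapsed matches")
        return hits[0]
    raise DemuxError(f"unknown assignment policy {policy!r}")


def _open_maybe_gzip(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def demux_pairs(
    pairs: Iterable[tuple[str, str, str]],
    layout: ReadLayout,
    codebook: Codebook,
    policy: str = "exact",
    max_mm_per_letter: int = 2,
    repeats: int = 1,
    species_index: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Demultiplex an iterable of (read_id, read1_seq, read2_seq) triples.

    Returns one row per read: ``read_id, codeword, region, reason, species``
    (codeword/region empty when rejected; species looked up from the exact
    Read 2 tag when an index is provided).
    """
    validate_alphabet_separation(codebook.letters, max_mm_per_letter)
    rows = []
    for read_id, r1, r2 in pairs:
        parsed = parse_barcode(r1, layout, codebook.letters, max_mm_per_letter)
        if isinstance(parsed, Rejection):
            rows.append((read_id, "", "", parsed.reason, ""))
            continue
        assigned = assign_region(parsed, codebook, policy, repeats)
        if isinstance(assigned, Rejection):
            rows.append((read_id, str(parsed), "", assigned.reason, ""))
            continue
        species = ""
        if species_index is not None:
            species = species_index.get(r2.upper(), "")
        rows.append((read_id, str(parsed), assigned, "", species))
    return pd.DataFrame(
        rows, columns=["read_id", "codeword", "region", "reason", "species"]
    )


def demux_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    layout: ReadLayout,
    codebook: Codebook,
    policy: str = "exact",
    max_mm_per_letter: int = 2,
    repeats: int = 1,
    species_index: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Demultiplex paired FASTQ files (gzip-transparent)."""

    def _pairs() -> Iterator[tuple[str, str, str]]:
        with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
            for rec1, rec2 in zip(
                SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")
            ):
                yield rec1.id, str(rec1.seq), str(rec2.seq)

    return demux_pairs(
        _pairs(), layout, codebook, policy, max_mm_per_letter, repeats,
        species_index,
    )


@dataclass
class DemuxResult:
    """Aggregated demultiplexing tables."""

    region_counts: pd.Series
    reject_counts: pd.Series
    composition: pd.DataFrame
    misassignment_rate: Optional[float]
    n_total: int
    n_assigned: int


def tabulate(
    per_read: pd.DataFrame,
    truth: Optional[pd.DataFrame] = None,
) -> DemuxResult:
    """Summarize per-read calls into per-region tallies.

    ``truth``, when given, must carry ``read_id`` and ``region`` (the
    generating region) and may carry ``species``; it enables per-region
    species composition and the overall misassignment rate.  With zero
    assigned reads all tables are empty and no rate is reported.
    """
    assigned = per_read[per_read["region"] != ""]
    region_counts = assigned["region"].value_counts().sort_index()
    reject_counts = (
        per_read.loc[per_read["reason"] != "", "reason"]
        .value_counts()
        .sort_index()
    )
    misassignment: Optional[float] = None
    merged = assigned
    if truth is not None and len(truth):
        t = truth.rename(
            columns={"region": "true_region", "species": "true_species"}
        )
        merged = assigned.merge(t, on="read_id", how="left")
        if len(merged):
            misassignment = float(
                (merged["region"] != merged["true_region"]).mean()
            )
    species_col = None
    if "true_species" in merged.columns and merged["true_species"].notna().any():
        species_col = "true_species"
    elif (merged.get("species", pd.Series(dtype=str)) != "").any():
        species_col = "species"
    if species_col and len(merged):
        sub = merged[merged[species_col].astype(str) != ""]
        composition = (
            pd.crosstab(sub["region"], sub[species_col], normalize="index")
            if len(sub)
            else pd.DataFrame()
        )
    else:
        composition = pd.DataFrame()
    return DemuxResult(
        region_counts=region_counts,
        reject_counts=reject_counts,
        composition=composition,
        misassignment_rate=misassignment,
        n_total=len(per_read),
        n_assigned=len(assigned),
    )
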