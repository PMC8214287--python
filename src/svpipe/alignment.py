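"""Per-read feature extraction from long-read alignments.

A read that spans a structural-variant breakpoint aligns "noisily": large
soft-clips, long insertion/deletion runs, clustered mismatches. This module
parses SAM alignment records and reduces each read to a fixed-width,
location-independent feature vector that a downstream classifier uses to
flag such reads for re-alignment with a more SV-sensitive aligner.

All features are computed from the read's primary alignment record only;
secondary/supplementary records contribute solely to split-read detection
(:func:`is_split`). Mismatch positions are taken from ``=``/``X`` CIGAR
operations when present, otherwise from the MD tag; with neither, positional
mismatch features degrade to zero and only the total mismatch count is
recovered from NM.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import CigarError, MDFormatError, SchemaError

log = logging.getLogger(__name__)

SCHEMA_VERSION = "svfeat-1"

#: Ordered names of the 21 per-read features, frozen under SCHEMA_VERSION.
FEATURE_NAMES: tuple[str, ...] = (
    "s1",
    "s2",
    "cm",
    "NM",
    "AS",
    "ins_bases",
    "del_bases",
    "mismatch_bases",
    "longest_del_run",
    "longest_ins_run",
    "longest_mismatch_run",
    "longest_del_run_gap1",
    "longest_ins_run_gap1",
    "longest_mismatch_run_gap1",
    "softclip_left",
    "softclip_right",
    "bin_top1",
    "bin_top2",
    "bin_top3",
    "bin_top4",
    "read_length",
)

N_FEATURES = len(FEATURE_NAMES)

_CIGAR_OPS = "MIDNSHP=X"
_READ_CONSUMING = frozenset("MIS=X")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def parse_cigar(cigar_text: str) -> list[tuple[str, int]]:
    """Tokenize a SAM CIGAR string into an ordered ``(op, length)`` list.

    The unmapped sentinel ``"*"`` yields an empty list. Malformed input
    raises :class:`CigarError` naming the first offending character position.
    """
    if cigar_text == "*" or cigar_text == "":
        return []
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar_text):
        if m.start() != pos:
            raise CigarError(
                f"malformed CIGAR {cigar_text!r}: unexpected character at position {pos}"
            )
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar_text):
        raise CigarError(
            f"malformed CIGAR {cigar_text!r}: unexpected character at position {pos}"
        )
    return ops


def cigar_read_length(ops: Sequence[tuple[str, int]]) -> int:
    """Read length implied by the CIGAR (sum over M, I, S, =, X)."""
    return sum(n for op, n in ops if op in _READ_CONSUMING)


@dataclass
class AlignmentRecord:
    """One SAM alignment line, reduced to the fields this pipeline uses.

    ``pos`` is the 1-based leftmost reference coordinate (SAM convention);
    ``cigar`` is an ordered list of ``(op, length)`` pairs; ``tags`` maps
    two-character SAM tag names to values. ``seq_len`` is the read length in
    bases — inferred from the CIGAR when no sequence is stored.
    """

    read_name: str
    flags: int = 0
    ref_name: str = "*"
    pos: int = 0
    mapq: int = 0
    cigar: list[tuple[str, int]] = field(default_factory=list)
    tags: dict[str, object] = field(default_factory=dict)
    seq_len: int = 0
    seq: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cigar, str):
            self.cigar = parse_cigar(self.cigar)
        if self.seq is not None:
            self.seq_len = len(self.seq)
        elif self.seq_len == 0:
            self.seq_len = cigar_read_length(self.cigar)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FLAG_SUPPLEMENTARY)

    @property
    def is_primary(self) -> bool:
        return not (self.flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @classmethod
    def from_pysam(cls, aln: "pysam.AlignedSegment") -> "AlignmentRecord":
        cigar = [(_CIGAR_OPS[op], n) for op, n in (aln.cigartuples or [])]
        seq = aln.query_sequence
        if seq is not None:
            seq_len = len(seq)
        else:
            seq_len = aln.infer_read_length() or cigar_read_length(cigar)
        return cls(
            read_name=aln.query_name or "",
            flags=aln.flag,
            ref_name=aln.reference_name or "*",
            pos=(aln.reference_start + 1) if aln.reference_start >= 0 else 0,
            mapq=aln.mapping_quality,
            cigar=cigar,
            tags=dict(aln.get_tags()),
            seq_len=seq_len,
            seq=seq,
        )


# ---------------------------------------------------------------------------
# Alignment event stream
# ---------------------------------------------------------------------------

#: Event kinds, in alignment order: ('clip'|'match'|'mismatch'|'ins'|'del'|'skip',
#: read_offset, length). read_offset indexes the full read including soft clips;
#: for 'del' it is the offset of the next read base (deletions consume no read).
Event = tuple[str, int, int]


def _md_tokens(md: str) -> list[object]:
    toks: list[object] = []
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MDFormatError(f"invalid MD string {md!r} at position {pos}")
        if m.group(1) is not None:
            toks.append(int(m.group(1)))
        elif m.group(2) is not None:
            toks.append(("del", m.group(2)[1:]))
        else:
            toks.append(("mm", m.group(3)))
        pos = m.end()
    if pos != len(md):
        raise MDFormatError(f"invalid MD string {md!r} at position {pos}")
    return toks


def alignment_events(
    cigar: Sequence[tuple[str, int]], md: str | None = None
) -> list[Event]:
    """Expand a CIGAR (plus optional MD tag) into a run-length event stream.

    When the CIGAR carries ``=``/``X`` operations the MD tag is ignored;
    otherwise mismatch positions inside M runs are recovered by walking MD
    in lockstep with the CIGAR. An MD tag inconsistent with the CIGAR raises
    :class:`MDFormatError`.
    """
    has_eq_x = any(op in "=X" for op, _ in cigar)
    toks: list[object] | None = None
    if md is not None and not has_eq_x:
        toks = _md_tokens(md)
    ti = 0  # token index
    carry = 0  # unconsumed match bases from the current numeric MD token
    events: list[Event] = []
    read_off = 0

    def md_error(msg: str) -> MDFormatError:
        return MDFormatError(f"MD tag inconsistent with CIGAR: {msg}")

    for op, length in cigar:
        if op == "S":
            events.append(("clip", read_off, length))
            read_off += length
        elif op in ("H", "P"):
            continue
        elif op == "=":
            events.append(("match", read_off, length))
            read_off += length
        elif op == "X":
            events.append(("mismatch", read_off, length))
            read_off += length
        elif op == "I":
            events.append(("ins", read_off, length))
            read_off += length
        elif op in ("D", "N"):
            if op == "D":
                events.append(("del", read_off, length))
            else:
                events.append(("skip", read_off, length))
            if toks is not None and op == "D":
                if carry != 0:
                    raise md_error("match run crosses a deletion")
                while ti < len(toks) and toks[ti] == 0:
                    ti += 1  # zero-length match runs flank deletions in MD
                if ti >= len(toks) or not (
                    isinstance(toks[ti], tuple) and toks[ti][0] == "del"
                ):
                    raise md_error(f"expected ^-deletion of {length} bases")
                if len(toks[ti][1]) != length:
                    raise md_error(
                        f"deletion length {len(toks[ti][1])} != CIGAR D{length}"
                    )
                ti += 1
        elif op == "M":
            if toks is None:
                events.append(("match", read_off, length))
                read_off += length
                continue
            remaining = length
            while remaining > 0:
                if carry > 0:
                    take = min(carry, remaining)
                    events.append(("match", read_off, take))
                    carry -= take
                    remaining -= take
                    read_off += take
                    continue
                if ti >= len(toks):
                    raise md_error("MD exhausted before CIGAR aligned bases")
                tok = toks[ti]
                ti += 1
                if isinstance(tok, int):
                    carry = tok
                elif tok[0] == "mm":
                    events.append(("mismatch", read_off, 1))
                    remaining -= 1
                    read_off += 1
                else:
                    raise md_error("^-deletion inside an M run")
        else:
            raise CigarError(f"unsupported CIGAR op {op!r}")

    if toks is not None:
        # trailing zero-length match tokens are tolerated
        while ti < len(toks) and toks[ti] == 0:
            ti += 1
        if carry != 0 or ti < len(toks):
            raise md_error("MD longer than CIGAR aligned bases")
    return events


def _events_for(rec: AlignmentRecord) -> tuple[list[Event], bool]:
    """Event stream for a record plus whether mismatch positions are known."""
    if rec.is_unmapped or not rec.cigar:
        return [], False
    md = rec.tags.get("MD")
    has_eq_x = any(op in "=X" for op, _ in rec.cigar)
    positional = has_eq_x or md is not None
    return alignment_events(rec.cigar, None if has_eq_x else md), positional


def count_edit_ops(rec: AlignmentRecord) -> tuple[int, int, int]:
    """Total inserted, deleted, and mismatched bases of one alignment.

    Unmapped records yield ``(0, 0, 0)`` with a warning. Without positional
    mismatch information (no MD, no ``=``/``X``), the mismatch count falls
    back to ``max(0, NM - ins - del)``.
    """
    if rec.is_unmapped or not rec.cigar:
        log.warning("count_edit_ops on unmapped record %s: zeros", rec.read_name)
        return (0, 0, 0)
    events, positional = _events_for(rec)
    ins = sum(n for k, _, n in events if k == "ins")
    dele = sum(n for k, _, n in events if k == "del")
    if positional:
        mism = sum(n for k, _, n in events if k == "mismatch")
    else:
        nm = int(rec.tags.get("NM", 0))
        mism = max(0, nm - ins - dele)
    return (ins, dele, mism)


def _longest_run(events: Iterable[Event], kind: str, allow_one_match: bool) -> int:
    best = 0
    cur = 0
    evs = list(events)
    for i, (k, _, n) in enumerate(evs):
        if k == kind:
            cur += n
            best = max(best, cur)
        elif (
            allow_one_match
            and k == "match"
            and n == 1
            and cur > 0
            and i + 1 < len(evs)
            and evs[i + 1][0] == kind
        ):
            continue  # single matched base bridging two runs: contributes 0
        else:
            cur = 0
    return best


def longest_run(rec: AlignmentRecord, kind: str, allow_one_match: bool = False) -> int:
    """Longest run of inserted/deleted/mismatched bases in one alignment.

    With ``allow_one_match``, runs separated by exactly one matched base are
    joined; the bridging match contributes nothing to the run length.
    """
    if kind not in ("ins", "del", "mismatch"):
        raise ValueError(f"kind must be ins/del/mismatch, got {kind!r}")
    events, _ = _events_for(rec)
    return _longest_run(events, kind, allow_one_match)


def softclip_ends(rec: AlignmentRecord) -> tuple[int, int]:
    """Lengths of the leading and trailing soft clips (H ops ignored)."""
    ops = [(op, n) for op, n in rec.cigar if op not in ("H", "P")]
    left = ops[0][1] if ops and ops[0][0] == "S" else 0
    right = ops[-1][1] if len(ops) > 1 and ops[-1][0] == "S" else 0
    if len(ops) == 1 and ops[0][0] == "S":
        right = 0
    return (left, right)


def bin_counts(rec: AlignmentRecord, bin_size: int = 100) -> np.ndarray:
    """Per-bin edit totals (insertions + deletions + mismatches) over read coords.

    The read is split into ``ceil(seq_len / bin_size)`` consecutive bins.
    Inserted and mismatched bases are charged to the bin of their read
    offset; a deletion run (which consumes no read bases) is charged in full
    to the bin containing the read offset at which it occurs.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = max(1, math.ceil(rec.seq_len / bin_size)) if rec.seq_len else 1
    totals = np.zeros(n_bins, dtype=np.int64)
    events, _ = _events_for(rec)
    for k, off, n in events:
        if k in ("ins", "mismatch"):
            # bases occupy read offsets off..off+n-1, possibly spanning bins
            start = off
            remaining = n
            while remaining > 0:
                b = min(start // bin_size, n_bins - 1)
                in_bin = min(remaining, (b + 1) * bin_size - start)
                totals[b] += in_bin
                start += in_bin
                remaining -= in_bin
        elif k == "del":
            b = min(off // bin_size, n_bins - 1)
            totals[b] += n
    return totals


def bin_top_counts(rec: AlignmentRecord, bin_size: int = 100, k: int = 4) -> list[int]:
    """The ``k`` largest bin edit totals, descending, zero-padded."""
    if k <= 0:
        raise ValueError("k must be positive")
    totals = sorted(bin_counts(rec, bin_size=bin_size).tolist(), reverse=True)
    totals = totals[:k]
    return totals + [0] * (k - len(totals))


@dataclass
class FeatureVector:
    """The ordered 21-feature description of one read (see FEATURE_NAMES)."""

    values: np.ndarray
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise SchemaError(
                f"feature vector has {self.values.shape} values, expected {N_FEATURES}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def _primary_record(records: Sequence[AlignmentRecord]) -> AlignmentRecord:
    if not records:
        raise ValueError("extract_features requires at least one alignment record")
    for rec in records:
        if rec.is_primary:
            return rec
    log.warning(
        "no primary record for read %s; using first record", records[0].read_name
    )
    return records[0]


def extract_features(records: Sequence[AlignmentRecord]) -> FeatureVector:
    """Compute the feature vector for one read from its alignment records.

    Features come from the primary record only. Aligner-specific tags
    (s1/s2/cm/AS) default to 0 when absent; NM falls back to the sum of
    observed edits. The result is location-independent: it depends only on
    the CIGAR, MD, tags, and read length — never on position or contig.
    """
    rec = _primary_record(records)
    ins, dele, mism = count_edit_ops(rec)
    events, _ = _events_for(rec)
    nm = rec.tags.get("NM")
    if nm is None:
        nm = ins + dele + mism
    left, right = softclip_ends(rec)
    tops = bin_top_counts(rec)
    values = [
        float(rec.tags.get("s1", 0)),
        float(rec.tags.get("s2", 0)),
        float(rec.tags.get("cm", 0)),
        float(nm),
        float(rec.tags.get("AS", 0)),
        float(ins),
        float(dele),
        float(mism),
        float(_longest_run(events, "del", False)),
        float(_longest_run(events, "ins", False)),
        float(_longest_run(events, "mismatch", False)),
        float(_longest_run(events, "del", True)),
        float(_longest_run(events, "ins", True)),
        float(_longest_run(events, "mismatch", True)),
        float(left),
        float(right),
        float(tops[0]),
        float(tops[1]),
        float(tops[2]),
        float(tops[3]),
        float(rec.seq_len),
    ]
    return FeatureVector(values=np.array(values))


def is_split(records: Sequence[AlignmentRecord]) -> bool:
    """True iff the read has a supplementary alignment or carries an SA tag."""
    return any(r.is_supplementary or "SA" in r.tags for r in records)


# ---------------------------------------------------------------------------
# SAM and feature-table I/O
# ---------------------------------------------------------------------------


def read_alignments(path: str) -> dict[str, list[AlignmentRecord]]:
    """Read a SAM/BAM file into records grouped by read name (input order)."""
    groups: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            rec = AlignmentRecord.from_pysam(aln)
            groups.setdefault(rec.read_name, []).append(rec)
    return groups


def features_from_sam(
    path: str,
) -> tuple[list[str], np.ndarray, dict[str, bool]]:
    """Extract per-read features and split status from an alignment file.

    Returns read names, the feature matrix (one row per read, in file
    order), and a read-name → is-split map. Reads with no mapped record are
    skipped.
    """
    groups = read_alignments(path)
    names: list[str] = []
    rows: list[np.ndarray] = []
    split: dict[str, bool] = {}
    for name, records in groups.items():
        if all(r.is_unmapped for r in records):
            continue
        names.append(name)
        rows.append(extract_features(records).values)
        split[name] = is_split(records)
    X = np.vstack(rows) if rows else np.empty((0, N_FEATURES))
    return names, X, split


def write_feature_table(
    path: str,
    names: Sequence[str],
    X: np.ndarray,
    labels: Sequence[int] | None = None,
) -> None:
    """Write a tab-separated feature table: read_name, 21 features[, label]."""
    df = pd.DataFrame(np.asarray(X), columns=list(FEATURE_NAMES))
    df.insert(0, "read_name", list(names))
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path: str,
) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    names = df["read_name"].astype(str).tolist()
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
    return names, X, labels
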