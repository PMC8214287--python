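"""Read selection for re-alignment and unification of two aligners' SAM output.

The pipeline re-aligns only a small subset of reads with the slow,
SV-sensitive aligner: the classifier's positives plus every read the fast
aligner itself split (fast aligners split some reads wrongly, notably reads
spanning translocations, so those go to the accurate aligner regardless).
The two aligners' outputs are then merged into one stream; because they
emit different optional-tag vocabularies — which breaks SAM→BAM conversion
— records are first harmonized to a shared tag allow-list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .alignment import AlignmentRecord
from .errors import FastqFormatError, ReferenceMismatchError

log = logging.getLogger(__name__)

#: Optional tags retained when merging the two aligners' records.
TAG_ALLOWLIST = ("NM", "AS", "SA", "MD")

#: Lower-case (locally defined) tag recording which aligner produced a record.
SOURCE_TAG = "so"

CLASSIFIER_POSITIVE = "classifier_positive"
SPLIT_BY_FAST_ALIGNER = "split_by_fast_aligner"


@dataclass
class ReadSelection:
    """The set of read names to re-align, with a per-name reason."""

    names: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.names)


def select_for_realignment(
    classifier_labels: Mapping[str, int], fast_split: Iterable[str]
) -> ReadSelection:
    """Union of classifier positives and fast-aligner split reads.

    A read in both groups is recorded as split_by_fast_aligner (it would be
    re-aligned even without the classifier).
    """
    sel = ReadSelection()
    for name, lab in classifier_labels.items():
        if lab == 1:
            sel.names.add(name)
            sel.provenance[name] = CLASSIFIER_POSITIVE
    for name in fast_split:
        sel.names.add(name)
        sel.provenance[name] = SPLIT_BY_FAST_ALIGNER
    return sel


def normalize_read_name(name: str) -> str:
    """FASTQ/SAM read-name normalization: token before the first whitespace."""
    return name.split()[0] if name else name


def extract_reads_by_name(fastq_in: str, names: Iterable[str], fastq_out: str) -> int:
    """Stream a FASTQ file, keeping records whose name is in ``names``.

    Names are compared after whitespace normalization (aligners strip
    comments). Records keep their input order; returns the count written.
    """
    wanted = {normalize_read_name(n) for n in names}
    count = 0
    seen = 0
    with open(fastq_in) as src, open(fastq_out, "w") as dst:
        try:
            for title, seq, qual in FastqGeneralIterator(src):
                seen += 1
                if normalize_read_name(title) in wanted:
                    dst.write(f"@{title}\n{seq}\n+\n{qual}\n")
                    count += 1
        except ValueError as exc:
            raise FastqFormatError(
                f"malformed FASTQ in {fastq_in} near record {seen}: {exc}"
            ) from exc
    return count


def harmonize_tags(
    rec: AlignmentRecord,
    source: str,
    allowlist: tuple[str, ...] = TAG_ALLOWLIST,
) -> AlignmentRecord:
    """Restrict a record's optional tags to the shared allow-list.

    Aligner-specific tags are dropped; a provenance tag naming the source
    aligner is added. Mandatory SAM fields are untouched.
    """
    tags = {k: v for k, v in rec.tags.items() if k in allowlist}
    tags[SOURCE_TAG] = source
    return AlignmentRecord(
        read_name=rec.read_name,
        flags=rec.flags,
        ref_name=rec.ref_name,
        pos=rec.pos,
        mapq=rec.mapq,
        cigar=list(rec.cigar),
        tags=tags,
        seq_len=rec.seq_len,
        seq=rec.seq,
    )


def _sq_pairs(header: pysam.AlignmentHeader) -> list[tuple[str, int]]:
    return [(sq["SN"], sq["LN"]) for sq in header.to_dict().get("SQ", [])]


def _harmonize_pysam(
    aln: pysam.AlignedSegment, source: str, allowlist: tuple[str, ...]
) -> None:
    tags = [(k, v, t) for k, v, t in aln.get_tags(with_value_type=True) if k in allowlist]
    tags.append((SOURCE_TAG, source, "Z"))
    aln.set_tags(tags)


def merge_alignments(
    sam_a: str,
    sam_b: str,
    out_sam: str,
    source_a: str = "fast_aligner",
    source_b: str = "accurate_aligner",
    allowlist: tuple[str, ...] = TAG_ALLOWLIST,
) -> tuple[int, int]:
    """Merge two SAM/BAM files aligned to the same reference into one SAM.

    Both streams must carry identical @SQ (name, length) pairs; @PG lines
    are concatenated and an entry for this tool appended. Every record is
    tag-harmonized and written; nothing is dropped or deduplicated (a read
    aligned by both aligners stays duplicated — downstream SV filtering
    counts unique supporting names). Returns per-stream record counts.
    """
    with pysam.AlignmentFile(sam_a, check_sq=False) as fa, pysam.AlignmentFile(
        sam_b, check_sq=False
    ) as fb:
        sq_a, sq_b = _sq_pairs(fa.header), _sq_pairs(fb.header)
        if sorted(sq_a) != sorted(sq_b):
            raise ReferenceMismatchError(
                f"@SQ mismatch between {sam_a} and {sam_b}: {sq_a} vs {sq_b}"
            )
        hdr = fa.header.to_dict()
        hdr_b = fb.header.to_dict()
        pg = hdr.get("PG", []) + hdr_b.get("PG", [])
        pg.append({"ID": "svpipe-merge", "PN": "svpipe"})
        hdr["PG"] = pg
        counts = [0, 0]
        with pysam.AlignmentFile(out_sam, "w", header=pysam.AlignmentHeader.from_dict(hdr)) as out:
            for idx, (fh, source) in enumerate(((fa, source_a), (fb, source_b))):
                for aln in fh.fetch(until_eof=True):
                    _harmonize_pysam(aln, source, allowlist)
                    out.write(aln)
                    counts[idx] += 1
    return counts[0], counts[1]
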