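"""Post-processing of structural-variant call sets from two callers.

Running two aligners and two SV callers buys sensitivity at the price of
redundancy: a read split by both aligners is counted twice as support for
the same variant, and a variant found by both callers appears twice in the
combined call set. This module removes both kinds of double counting:

* support is recounted as the number of *unique* supporting read names, and
  calls below a minimum support (by default half the sequencing coverage,
  rounded up) are dropped;
* calls of the same type whose breakpoints differ by less than a window
  (default 50 bp) are unified across callers, keeping the better-supported
  call.

Calls can also be scored against a truth set of injected variants: a call
is correct when its type matches and its breakpoint lies within a tolerance
(default 10 bp) of the true breakpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA")

DEFAULT_MERGE_WINDOW = 50
DEFAULT_MATCH_TOL = 10


@dataclass
class SVCall:
    """One structural-variant call.

    ``pos`` is the 1-based breakpoint (VCF anchor convention: the last
    unaffected base before the event); ``end`` is the second coordinate
    (for a translocation, the breakpoint on ``chrom2``). ``length`` is
    stored absolute. ``support_reads`` may be empty when the caller reports
    only a count, in which case ``support_count`` stands alone.
    """

    sv_type: str
    chrom: str
    pos: int
    end: int
    length: int = 0
    support_reads: frozenset[str] = frozenset()
    support_count: int = 0
    caller: str = ""
    chrom2: str | None = None
    info: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support_reads = frozenset(self.support_reads)
        self.length = abs(int(self.length))
        if self.support_reads:
            self.support_count = len(self.support_reads)

    @property
    def key(self) -> tuple:
        return (self.sv_type, self.chrom, self.pos)


def unique_support(call: SVCall) -> int:
    """Distinct supporting read names; falls back to the reported count.

    A read aligned (and split) by both aligners appears twice in the merged
    BAM and is listed twice by the caller — counting distinct names undoes
    that double counting.
    """
    if call.support_reads:
        return len(call.support_reads)
    return call.support_count


def min_support_threshold(coverage: float) -> int:
    """Minimum supporting reads for a given coverage: ⌈coverage / 2⌉.

    At least half of the average depth must support a variant; 10× coverage
    requires 5 reads. Odd coverages round up (conservative against false
    positives).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    return math.ceil(coverage / 2.0)


def filter_min_support(calls: Iterable[SVCall], min_support: int) -> list[SVCall]:
    """Keep calls whose unique support reaches ``min_support``."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return [c for c in calls if unique_support(c) >= min_support]


def _merge_priority(call: SVCall) -> tuple:
    # greedy order: more support first; prefer named support over count-only;
    # then lexicographic caller id, then position — fully deterministic
    return (
        -unique_support(call),
        0 if call.support_reads else 1,
        call.caller,
        call.chrom,
        call.pos,
    )


def _within_window(a: SVCall, b: SVCall, window: int) -> bool:
    if a.sv_type != b.sv_type or a.chrom != b.chrom:
        return False
    if a.sv_type == "TRA":
        if (a.chrom2 or a.chrom) != (b.chrom2 or b.chrom):
            return False
        return abs(a.pos - b.pos) < window and abs(a.end - b.end) < window
    return abs(a.pos - b.pos) < window and abs(a.end - b.end) < window


def merge_calls(
    calls_a: Sequence[SVCall],
    calls_b: Sequence[SVCall],
    window: int = DEFAULT_MERGE_WINDOW,
) -> list[SVCall]:
    """Unify redundant calls across two callers.

    Two calls merge when they have the same type and chromosome(s) and both
    breakpoint coordinates differ by strictly less than ``window``; the
    member with more unique supporting reads survives (ties broken by named
    support, caller id, then position). Each call participates in at most
    one unification, chosen greedily in descending support order; unmatched
    calls pass through. The surviving call records both callers and the
    union of supporting read names.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    pool = sorted(list(calls_a) + list(calls_b), key=_merge_priority)
    consumed = [False] * len(pool)
    out: list[SVCall] = []
    for i, call in enumerate(pool):
        if consumed[i]:
            continue
        consumed[i] = True
        partner_idx = None
        best_dist = None
        for j in range(i + 1, len(pool)):
            if consumed[j]:
                continue
            other = pool[j]
            if other.caller == call.caller:
                continue
            if _within_window(call, other, window):
                dist = abs(call.pos - other.pos) + abs(call.end - other.end)
                if best_dist is None or dist < best_dist:
                    best_dist = dist
                    partner_idx = j
        if partner_idx is None:
            out.append(call)
            continue
        consumed[partner_idx] = True
        other = pool[partner_idx]
        merged_info = dict(call.info)
        callers = sorted({call.caller, other.caller})
        merged_info["CALLERS"] = ",".join(callers)
        out.append(
            replace(
                call,
                support_reads=call.support_reads | other.support_reads,
                support_count=max(unique_support(call), unique_support(other)),
                info=merged_info,
            )
        )
    out.sort(key=lambda c: (c.chrom, c.pos, c.sv_type))
    return out


@dataclass
class MatchResult:
    """Outcome of scoring a call set against a truth set."""

    recall: float
    fdr: float
    per_type_recall: dict[str, float]
    tp: list[tuple[SVCall, SVCall]]
    fp: list[SVCall]
    fn: list[SVCall]


def match_to_truth(
    calls: Sequence[SVCall],
    truth: Sequence[SVCall],
    tol: int = DEFAULT_MATCH_TOL,
) -> MatchResult:
    """Greedy one-to-one matching of calls to injected truth variants.

    A call matches a truth record when the types are identical, the
    chromosomes agree, and the breakpoint distance is strictly less than
    ``tol``. Recall = TP / |truth|; FDR = FP / |calls| (0 for an empty call
    set). Matching is greedy in descending support order, nearest truth
    first.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    matched_truth = [False] * len(truth)
    tp: list[tuple[SVCall, SVCall]] = []
    fp: list[SVCall] = []
    for call in sorted(calls, key=_merge_priority):
        best = None
        best_dist = None
        for ti, t in enumerate(truth):
            if matched_truth[ti]:
                continue
            if t.sv_type != call.sv_type or t.chrom != call.chrom:
                continue
            if t.sv_type == "TRA" and (t.chrom2 or t.chrom) != (call.chrom2 or call.chrom):
                continue
            dist = abs(t.pos - call.pos)
            if dist < tol and (best_dist is None or dist < best_dist):
                best, best_dist = ti, dist
        if best is None:
            fp.append(call)
        else:
            matched_truth[best] = True
            tp.append((call, truth[best]))
    fn = [t for ti, t in enumerate(truth) if not matched_truth[ti]]
    recall = len(tp) / len(truth) if truth else 0.0
    fdr = len(fp) / len(calls) if calls else 0.0
    per_type: dict[str, float] = {}
    for svt in SV_TYPES:
        n_truth = sum(1 for t in truth if t.sv_type == svt)
        if n_truth:
            n_tp = sum(1 for _, t in tp if t.sv_type == svt)
            per_type[svt] = n_tp / n_truth
    return MatchResult(recall=recall, fdr=fdr, per_type_recall=per_type, tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_SUPPORT_NAME_KEYS = ("RNAMES", "READS")
_SUPPORT_COUNT_KEYS = ("SUPPORT", "RE", "DV")


def _info_get(rec: "pysam.VariantRecord", key: str):
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def parse_sv_vcf(
    vcf_path: str,
    caller_id: str,
    rnames_key: str = "RNAMES",
) -> list[SVCall]:
    """Read one caller's VCF into SVCall objects.

    Supporting read names are taken from ``rnames_key`` (falling back to
    common long-read caller dialects), or a numeric support count from
    SUPPORT/RE/DV. Breakend (BND) mates describing one translocation are
    collapsed to a single TRA call; records without SVTYPE are skipped with
    a warning.
    """
    calls: list[SVCall] = []
    seen_bnd: set[tuple] = set()
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            svtype = _info_get(rec, "SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype is None:
                log.warning("record %s:%s lacks SVTYPE; skipped", rec.chrom, rec.pos)
                continue
            svtype = str(svtype)
            names: tuple = ()
            for key in (rnames_key, *_SUPPORT_NAME_KEYS):
                val = _info_get(rec, key)
                if val:
                    names = val if isinstance(val, tuple) else (val,)
                    break
            count = 0
            if not names:
                for key in _SUPPORT_COUNT_KEYS:
                    val = _info_get(rec, key)
                    if val is not None:
                        count = int(val[0] if isinstance(val, tuple) else val)
                        break
            chrom2 = _info_get(rec, "CHR2")
            info: dict[str, object] = {}
            seq = _info_get(rec, "SEQ")
            if seq:
                info["SEQ"] = str(seq[0] if isinstance(seq, tuple) else seq)
            svlen = _info_get(rec, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            end = _info_get(rec, "END2") or rec.stop
            if svtype == "BND":
                alt = rec.alts[0] if rec.alts else ""
                mate = _parse_bnd_alt(str(alt))
                if mate is None:
                    log.warning("unparseable BND ALT %r; skipped", alt)
                    continue
                chrom2, pos2 = mate
                bkey = tuple(sorted([(rec.chrom, rec.pos), (chrom2, pos2)]))
                if bkey in seen_bnd:
                    continue
                seen_bnd.add(bkey)
                svtype, end = "TRA", pos2
            calls.append(
                SVCall(
                    sv_type=svtype,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    end=int(end),
                    length=int(svlen or 0),
                    support_reads=frozenset(str(n) for n in names),
                    support_count=count,
                    caller=caller_id,
                    chrom2=str(chrom2) if chrom2 else None,
                    info=info,
                )
            )
    return calls


def _parse_bnd_alt(alt: str) -> tuple[str, int] | None:
    for br in ("[", "]"):
        if br in alt:
            try:
                inner = alt.split(br)[1]
                chrom, pos = inner.split(":")
                return chrom, int(pos)
            except (IndexError, ValueError):
                return None
    return None


def _vcf_header(contigs: dict[str, int] | None) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    hdr.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    hdr.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate">')
    hdr.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    hdr.add_line('##INFO=<ID=CHR2,Number=1,Type=String,Description="Second contig (TRA)">')
    hdr.add_line('##INFO=<ID=END2,Number=1,Type=Integer,Description="Breakpoint on CHR2">')
    hdr.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Unique supporting reads">')
    hdr.add_line('##INFO=<ID=CALLERS,Number=1,Type=String,Description="Callers reporting this SV">')
    hdr.add_line('##INFO=<ID=RNAMES,Number=.,Type=String,Description="Supporting read names">')
    hdr.add_line('##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">')
    for name, length in (contigs or {}).items():
        hdr.contigs.add(name, length=length)
    return hdr


def write_sv_vcf(
    calls: Sequence[SVCall],
    path: str,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write calls as a VCF 4.x file with SVTYPE/END/SVLEN/SUPPORT INFO keys."""
    hdr = _vcf_header(contigs)
    if contigs is None:
        for c in sorted({c.chrom for c in calls} | {c.chrom2 for c in calls if c.chrom2}):
            hdr.contigs.add(c)
    with pysam.VariantFile(path, "w", header=hdr) as out:
        for i, call in enumerate(
            sorted(calls, key=lambda c: (c.chrom, c.pos, c.sv_type))
        ):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=max(call.end, call.pos) if call.sv_type != "TRA" else call.pos,
                alleles=("N", f"<{call.sv_type}>"),
                id=f"svpipe_{i}",
            )
            rec.info["SVTYPE"] = call.sv_type
            if call.sv_type == "TRA":
                rec.info["CHR2"] = call.chrom2 or call.chrom
                rec.info["END2"] = call.end
            if call.length:
                rec.info["SVLEN"] = call.length
            rec.info["SUPPORT"] = unique_support(call)
            if call.support_reads:
                rec.info["RNAMES"] = tuple(sorted(call.support_reads))
            for key in ("CALLERS", "SEQ"):
                if key in call.info:
                    rec.info[key] = str(call.info[key])
            if not call.info.get("CALLERS") and call.caller:
                rec.info["CALLERS"] = call.caller
            out.write(rec)
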