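"""Synthetic inputs for every pipeline stage.

Real training data for this pipeline comes from injecting structural
variants into a reference, simulating error-prone PacBio-like reads, and
running two long-read aligners and two SV callers. This module emulates
each of those products at desk scale — toy references with injected
DEL/INS/INV/DUP/TRA and exact truth breakpoints, error-prone reads at a
stated coverage, alignment records with controlled CIGAR/MD/tag content and
known informative labels, and paired caller VCFs with analytically known
merge outcomes — so the bespoke stages are fully testable with no external
binaries or downloads.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .alignment import AlignmentRecord, FeatureVector, extract_features
from .errors import CapacityError
from .svmerge import SVCall, _merge_priority, unique_support

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

Reference = dict[str, str]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


def make_toy_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Seeded i.i.d. random sequence with the requested GC fraction."""
    if length < 1000:
        raise ValueError("reference length must be at least 1000")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def toy_genome(
    lengths: dict[str, int], gc: float = 0.5, seed: int = 0
) -> Reference:
    """Several independent toy contigs keyed by name."""
    return {
        name: make_toy_reference(length, gc=gc, seed=seed + k)
        for k, (name, length) in enumerate(lengths.items())
    }


def write_fasta(reference: Reference, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Reference:
    ref: Reference = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    ref[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        ref[name] = "".join(chunks)
    return ref


# ---------------------------------------------------------------------------
# SV injection
# ---------------------------------------------------------------------------


@dataclass
class SVSpec:
    """How many variants of each type to inject, and how large.

    Lengths are drawn uniformly per type; all SVs are at least 50 bp (the
    conventional size floor for a structural variant). ``min_gap`` keeps
    injected variants (and translocation breakpoints) well separated.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 3, "INS": 3, "INV": 2, "DUP": 2, "TRA": 0}
    )
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    default_length_range: tuple[int, int] = (60, 2000)
    min_gap: int = 500
    margin: int = 2000
    seed: int = 0

    def length_range(self, sv_type: str) -> tuple[int, int]:
        lo, hi = self.length_ranges.get(sv_type, self.default_length_range)
        if lo < 50:
            raise ValueError("SV lengths must be >= 50 bp")
        return lo, hi


def _apply_contig_edits(seq: str, edits: Sequence[SVCall]) -> str:
    """Apply non-TRA edits (original coordinates) right-to-left."""
    for t in sorted(edits, key=lambda t: -t.pos):
        if t.sv_type == "DEL":
            seq = seq[: t.pos] + seq[t.end :]
        elif t.sv_type == "INS":
            seq = seq[: t.pos] + str(t.info["SEQ"]) + seq[t.pos :]
        elif t.sv_type == "INV":
            seq = seq[: t.pos] + revcomp(seq[t.pos : t.end]) + seq[t.end :]
        elif t.sv_type == "DUP":
            seq = seq[: t.end] + seq[t.pos : t.end] + seq[t.end :]
        else:
            raise ValueError(f"unexpected edit type {t.sv_type}")
    return seq


def apply_truth(reference: Reference, truth: Sequence[SVCall]) -> Reference:
    """Reconstruct the altered genome from original sequences plus truth calls.

    Truth coordinates are 1-based on the ORIGINAL reference and follow the
    VCF anchor convention: ``pos`` is the last unaffected base before the
    event and ``end`` the last affected base, so DEL removes
    ``pos+1..end``, INS inserts after ``pos`` (sequence in ``info['SEQ']``),
    INV reverse-complements ``pos+1..end`` and DUP tandem-duplicates it.
    TRA is a reciprocal tail swap at ``pos`` on ``chrom`` and ``end`` on
    ``chrom2``. Indel-type edits defined in a swapped tail travel with that
    tail.
    """
    per_contig: dict[str, list[SVCall]] = {c: [] for c in reference}
    swaps: dict[str, tuple[int, str, int]] = {}
    for t in truth:
        if t.sv_type == "TRA":
            if t.chrom2 is None:
                raise ValueError("TRA truth record requires chrom2")
            if t.chrom in swaps or t.chrom2 in swaps:
                raise ValueError("at most one translocation per contig")
            swaps[t.chrom] = (t.pos, t.chrom2, t.end)
            swaps[t.chrom2] = (t.end, t.chrom, t.pos)
        else:
            per_contig.setdefault(t.chrom, []).append(t)

    def shifted(e: SVCall, delta: int) -> SVCall:
        return replace(e, pos=e.pos + delta, end=e.end + delta)

    out: Reference = {}
    for contig, seq in reference.items():
        if contig not in swaps:
            out[contig] = _apply_contig_edits(seq, per_contig[contig])
            continue
        own_pos, partner, partner_pos = swaps[contig]
        prefix_edits = [e for e in per_contig[contig] if e.end <= own_pos]
        if len(prefix_edits) != len(per_contig[contig]):
            raise ValueError("edit straddles a translocation breakpoint")
        prefix = _apply_contig_edits(seq[:own_pos], prefix_edits)
        tail_src = reference[partner][partner_pos:]
        tail_edits = [
            shifted(e, -partner_pos)
            for e in per_contig[partner]
            if e.pos >= partner_pos
        ]
        out[contig] = prefix + _apply_contig_edits(tail_src, tail_edits)
    return out


def inject_svs(
    reference: Reference, spec: SVSpec
) -> tuple[Reference, list[SVCall]]:
    """Place non-overlapping SVs on a reference and return truth records.

    Placements keep ``min_gap`` bases between variants and stay ``margin``
    bases away from contig ends. Translocations need at least two contigs
    and use each contig at most once (a reciprocal tail swap). Raises
    :class:`CapacityError` when the reference cannot host the request.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(reference)
    lengths = {c: len(reference[c]) for c in names}
    n_tra = spec.counts.get("TRA", 0)
    if n_tra and len(names) < 2:
        raise CapacityError("translocations require at least two contigs")
    if n_tra > len(names) // 2:
        raise CapacityError(
            f"{n_tra} translocations need {2 * n_tra} contigs, have {len(names)}"
        )

    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    tail_limit: dict[str, int] = {c: lengths[c] for c in names}
    truth: list[SVCall] = []

    def conflicts(contig: str, lo: int, hi: int) -> bool:
        return any(not (hi < a or lo > b) for a, b in reserved[contig])

    # translocations first: they constrain where indel-type SVs may go
    tra_contigs = list(names)
    for _ in range(n_tra):
        i = int(rng.integers(0, len(tra_contigs)))
        c1 = tra_contigs.pop(i)
        j = int(rng.integers(0, len(tra_contigs)))
        c2 = tra_contigs.pop(j)
        p1 = int(rng.integers(spec.margin, lengths[c1] - spec.margin))
        p2 = int(rng.integers(spec.margin, lengths[c2] - spec.margin))
        truth.append(
            SVCall(sv_type="TRA", chrom=c1, pos=p1, end=p2, chrom2=c2, caller="truth")
        )
        reserved[c1].append((p1 - spec.min_gap, lengths[c1]))
        reserved[c2].append((p2 - spec.min_gap, lengths[c2]))
        tail_limit[c1] = p1 - spec.min_gap
        tail_limit[c2] = p2 - spec.min_gap

    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    for sv_type in ("DEL", "INS", "INV", "DUP"):
        lo_len, hi_len = spec.length_range(sv_type)
        for _ in range(spec.counts.get(sv_type, 0)):
            placed = False
            for _attempt in range(500):
                contig = names[int(rng.choice(len(names), p=weights))]
                length = int(rng.integers(lo_len, hi_len + 1))
                upper = min(lengths[contig], tail_limit[contig]) - spec.margin - length
                if upper <= spec.margin:
                    continue
                pos = int(rng.integers(spec.margin, upper))
                end = pos + length
                if conflicts(contig, pos - spec.min_gap, end + spec.min_gap):
                    continue
                reserved[contig].append((pos - spec.min_gap, end + spec.min_gap))
                info = {}
                if sv_type == "INS":
                    ins_seq = "".join(
                        _BASES[i] for i in rng.integers(0, 4, size=length)
                    )
                    info["SEQ"] = ins_seq
                    end = pos
                truth.append(
                    SVCall(
                        sv_type=sv_type,
                        chrom=contig,
                        pos=pos,
                        end=end,
                        length=length,
                        caller="truth",
                        info=info,
                    )
                )
                placed = True
                break
            if not placed:
                raise CapacityError(
                    f"could not place a {sv_type} of {lo_len}-{hi_len} bp after retries"
                )
    truth.sort(key=lambda t: (t.chrom, t.pos))
    return apply_truth(reference, truth), truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSimParams:
    """PacBio-like read simulation settings (error rates are per base)."""

    coverage: float = 10.0
    mean_length: int = 8000
    sd_length: int = 2500
    min_length: int = 300
    sub_rate: float = 0.04
    ins_rate: float = 0.05
    del_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) > 0.3:
            raise ValueError("error rates must be >= 0 and total <= 0.3")


def _mutate(seq: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    total = params.sub_rate + params.ins_rate + params.del_rate
    if total == 0:
        return seq
    draws = rng.random(len(seq))
    out: list[str] = []
    for base, r in zip(seq, draws):
        if r < params.sub_rate:
            out.append(_BASES[(int(_BASES.index(base)) + int(rng.integers(1, 4))) % 4])
        elif r < params.sub_rate + params.ins_rate:
            out.append(base)
            out.append(_BASES[int(rng.integers(0, 4))])
        elif r < total:
            continue
        else:
            out.append(base)
    return "".join(out)


def simulate_reads(
    reference: Reference, params: ReadSimParams
) -> list[tuple[str, str, str]]:
    """Draw error-prone reads to the requested coverage.

    Start positions are uniform over each contig, lengths follow a truncated
    normal, and strands are random. Read names encode the true origin as
    ``read<i> <contig>:<start>-<end>:<strand>`` (1-based, inclusive, on the
    sequence the reads were drawn from) so downstream checks can recover it.
    Returns ``(name, sequence, quality)`` triples.
    """
    rng = np.random.default_rng(params.seed)
    names = list(reference)
    lengths = np.array([len(reference[c]) for c in names], dtype=float)
    if params.mean_length >= lengths.sum():
        raise ValueError("mean read length must be below the reference length")
    weights = lengths / lengths.sum()
    target = params.coverage * lengths.sum()
    reads: list[tuple[str, str, str]] = []
    emitted = 0
    i = 0
    while emitted < target:
        contig = names[int(rng.choice(len(names), p=weights))]
        clen = len(reference[contig])
        length = int(
            np.clip(
                rng.normal(params.mean_length, params.sd_length),
                params.min_length,
                clen,
            )
        )
        start = int(rng.integers(0, clen - length + 1))
        frag = reference[contig][start : start + length]
        strand = "+"
        if rng.random() < 0.5:
            frag = revcomp(frag)
            strand = "-"
        read = _mutate(frag, params, rng)
        name = f"read{i:06d} {contig}:{start + 1}-{start + length}:{strand}"
        reads.append((name, read, "I" * len(read)))
        emitted += len(read)
        i += 1
    return reads


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Controlled alignment records
# ---------------------------------------------------------------------------


def default_informative_rule(fv: FeatureVector) -> bool:
    """The generative rule behind synthetic informative reads.

    A read is informative when its soft-clipped ends total more than 200
    bases or it contains a deletion run longer than 40 bases — the two
    alignment signatures of an unsplit read spanning an SV breakpoint.
    """
    return fv["softclip_left"] + fv["softclip_right"] > 200 or fv["longest_del_run"] > 40


@dataclass
class _Body:
    events: list[tuple[str, int]]  # (kind, length) kind in match/ins/del/mm
    read_bases: int
    ins: int
    dele: int
    mism: int


def _random_body(
    aligned_target: int, rng: np.random.Generator, long_del: int = 0
) -> _Body:
    """Alternating match/edit segments totalling roughly aligned_target."""
    events: list[tuple[str, int]] = []
    read_bases = ins = dele = mism = 0
    consumed = 0
    long_del_at = int(rng.integers(1, 6)) if long_del else -1
    k = 0
    while consumed < aligned_target:
        run = int(rng.integers(30, 400))
        run = min(run, aligned_target - consumed)
        events.append(("match", run))
        read_bases += run
        consumed += run
        if consumed >= aligned_target:
            break
        k += 1
        if k == long_del_at:
            events.append(("del", long_del))
            dele += long_del
            continue
        kind = rng.random()
        if kind < 0.35:
            n = int(rng.integers(1, 9))
            events.append(("ins", n))
            read_bases += n
            ins += n
        elif kind < 0.7:
            n = int(rng.integers(1, 11))
            events.append(("del", n))
            dele += n
        else:
            events.append(("mm", 1))
            read_bases += 1
            mism += 1
            consumed += 1
    if long_del and long_del_at > k:
        events.append(("del", long_del))
        events.append(("match", 50))
        read_bases += 50
        dele += long_del
    return _Body(events, read_bases, ins, dele, mism)


def _body_to_cigar_md(
    body: _Body, clip_left: int, clip_right: int, rng: np.random.Generator
) -> tuple[str, str]:
    cigar_parts: list[str] = []
    if clip_left:
        cigar_parts.append(f"{clip_left}S")
    md_parts: list[str] = []
    md_match = 0
    # merge adjacent CIGAR ops of the same type as a SAM writer would
    ops: list[tuple[str, int]] = []
    for kind, n in body.events:
        op = {"match": "M", "mm": "M", "ins": "I", "del": "D"}[kind]
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))
    for op, n in ops:
        cigar_parts.append(f"{n}{op}")
    if clip_right:
        cigar_parts.append(f"{clip_right}S")
    for kind, n in body.events:
        if kind == "match":
            md_match += n
        elif kind == "mm":
            md_parts.append(str(md_match))
            md_parts.append(_BASES[int(rng.integers(0, 4))])
            md_match = 0
        elif kind == "del":
            md_parts.append(str(md_match))
            md_parts.append(
                "^" + "".join(_BASES[i] for i in rng.integers(0, 4, size=n))
            )
            md_match = 0
        # insertions are invisible to MD
    md_parts.append(str(md_match))
    return "".join(cigar_parts), "".join(md_parts)


def synth_alignments(
    n: int,
    informative_rule: Callable[[FeatureVector], bool] | None = None,
    seed: int = 0,
    informative_fraction: float = 0.01,
    split_fraction: float = 0.0,
    contig: str = "contig1",
    contig_len: int = 1_000_000,
) -> tuple[dict[str, list[AlignmentRecord]], dict[str, int]]:
    """Alignment records with known informative labels, no aligner needed.

    Background reads carry small scattered edits and modest soft clips;
    informative reads (a seeded Bernoulli fraction, default 1%) get either
    a large one-sided soft clip, a long deletion run, or both, so that
    ``default_informative_rule`` holds exactly. A ``split_fraction`` of
    reads additionally get an SA tag plus a supplementary record, emulating
    reads the fast aligner split. Returns records grouped by read name and
    the ground-truth informative labels.
    """
    rule = informative_rule or default_informative_rule
    rng = np.random.default_rng(seed)
    groups: dict[str, list[AlignmentRecord]] = {}
    labels: dict[str, int] = {}
    for i in range(n):
        name = f"synread{i:06d}"
        informative = rng.random() < informative_fraction
        read_len = int(np.clip(rng.normal(8000, 2500), 1500, 20000))
        if informative:
            mode = rng.random()
            big_clip = mode < 0.45 or mode >= 0.9
            long_del = int(rng.integers(50, 400)) if (mode >= 0.45) else 0
        else:
            big_clip = False
            long_del = 0
        if big_clip:
            big = int(rng.integers(220, 1500))
            small = int(rng.integers(0, 60))
            clip_left, clip_right = (big, small) if rng.random() < 0.5 else (small, big)
        else:
            clip_left = int(rng.integers(0, 60))
            clip_right = int(rng.integers(0, 59))
        aligned_target = max(500, read_len - clip_left - clip_right)
        body = _random_body(aligned_target, rng, long_del=long_del)
        cigar, md = _body_to_cigar_md(body, clip_left, clip_right, rng)
        seq_len = clip_left + clip_right + body.read_bases
        nm = body.ins + body.dele + body.mism
        aligned = body.read_bases
        tags: dict[str, object] = {
            "s1": int(0.9 * aligned + rng.integers(0, 200)),
            "s2": int(rng.integers(0, max(2, aligned // 4))),
            "cm": aligned // 18,
            "NM": nm,
            "AS": aligned - 5 * nm,
            "MD": md,
        }
        flags = 16 if rng.random() < 0.5 else 0
        pos = int(rng.integers(1, max(2, contig_len - seq_len)))
        rec = AlignmentRecord(
            read_name=name,
            flags=flags,
            ref_name=contig,
            pos=pos,
            mapq=60,
            cigar=cigar,
            tags=tags,
        )
        records = [rec]
        if rng.random() < split_fraction:
            supp_len = 120
            supp_pos = int(rng.integers(1, contig_len - supp_len))
            rec.tags["SA"] = f"{contig},{supp_pos},+,{supp_len}M,60,0;"
            records.append(
                AlignmentRecord(
                    read_name=name,
                    flags=flags | 2048,
                    ref_name=contig,
                    pos=supp_pos,
                    mapq=60,
                    cigar=[("H", max(0, seq_len - supp_len)), ("M", supp_len)],
                    tags={"NM": 0},
                )
            )
        groups[name] = records
        labels[name] = int(rule(extract_features(records)))
    return groups, labels


def write_sam(
    groups: dict[str, list[AlignmentRecord]],
    contigs: dict[str, int],
    path: str,
) -> None:
    """Write grouped alignment records as a SAM file with an @SQ header."""
    import pysam

    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        refs = {name: i for i, name in enumerate(contigs)}
        for records in groups.values():
            for rec in records:
                aln = pysam.AlignedSegment(out.header)
                aln.query_name = rec.read_name
                aln.flag = rec.flags
                aln.reference_id = refs.get(rec.ref_name, -1)
                aln.reference_start = rec.pos - 1
                aln.mapping_quality = rec.mapq
                aln.cigarstring = (
                    "".join(f"{n}{op}" for op, n in rec.cigar) if rec.cigar else None
                )
                if rec.seq is not None:
                    aln.query_sequence = rec.seq
                tags = []
                for k, v in rec.tags.items():
                    if isinstance(v, (int, np.integer)):
                        tags.append((k, int(v), "i"))
                    elif isinstance(v, float):
                        tags.append((k, v, "f"))
                    else:
                        tags.append((k, str(v), "Z"))
                aln.set_tags(tags)
                out.write(aln)


# ---------------------------------------------------------------------------
# Paired caller VCFs
# ---------------------------------------------------------------------------


def synth_vcf_pair(
    truth: Sequence[SVCall],
    jitter_a: int = 5,
    jitter_b: int = 8,
    dropout_a: float = 0.0,
    dropout_b: float = 0.0,
    support_range: tuple[int, int] = (4, 12),
    seed: int = 0,
    window: int = 50,
) -> tuple[list[SVCall], list[SVCall], list[SVCall]]:
    """Two noisy caller views of one truth set, plus the expected merge.

    Each caller reports each truth variant with a seeded breakpoint jitter
    (pos and end shifted together) and per-call dropout; supporting read
    names are drawn from a shared per-variant pool so the two callers'
    name lists overlap. ``jitter_a + jitter_b`` must stay below ``window``
    so that intended merges fall inside the merge window. The expected
    post-merge call set is derived analytically from the construction:
    per truth variant, the surviving caller's call, or — when both survive —
    the one with more unique support (documented tie-break), carrying the
    union of both callers' read names.
    """
    if jitter_a + jitter_b >= window:
        raise ValueError("jitter_a + jitter_b must be below the merge window")
    rng = np.random.default_rng(seed)
    calls_a: list[SVCall] = []
    calls_b: list[SVCall] = []
    expected: list[SVCall] = []
    for i, t in enumerate(truth):
        pool = [f"sv{i}_r{j}" for j in range(max(support_range) + 4)]
        per_caller: dict[str, SVCall] = {}
        for caller, jitter, dropout, sink in (
            ("callerA", jitter_a, dropout_a, calls_a),
            ("callerB", jitter_b, dropout_b, calls_b),
        ):
            if rng.random() < dropout:
                continue
            delta = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            k = int(rng.integers(support_range[0], support_range[1] + 1))
            offset = int(rng.integers(0, 3))
            names = frozenset(pool[offset : offset + k])
            call = replace(
                t,
                pos=t.pos + delta,
                end=t.end + delta,
                support_reads=names,
                support_count=len(names),
                caller=caller,
                info={},
            )
            per_caller[caller] = call
            sink.append(call)
        if not per_caller:
            continue
        if len(per_caller) == 1:
            expected.append(next(iter(per_caller.values())))
        else:
            a, b = per_caller["callerA"], per_caller["callerB"]
            winner, loser = sorted((a, b), key=_merge_priority)
            expected.append(
                replace(
                    winner,
                    support_reads=winner.support_reads | loser.support_reads,
                    support_count=max(unique_support(winner), unique_support(loser)),
                    info={"CALLERS": "callerA,callerB"},
                )
            )
    expected.sort(key=lambda c: (c.chrom, c.pos, c.sv_type))
    return calls_a, calls_b, expected


def coverage_of(
    reads: Sequence[tuple[str, str, str]], reference: Reference
) -> float:
    """Realized fold coverage of a simulated read set."""
    total = sum(len(seq) for _, seq, _ in reads)
    return total / sum(len(s) for s in reference.values())


def estimate_gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else math.nan
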