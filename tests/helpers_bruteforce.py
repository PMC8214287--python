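"""Independent per-base oracle for alignment feature extraction.

Everything here works at single-base granularity with explicit loops and a
hand-written tokenizer, deliberately sharing no code with the package's
run-length implementation. Restricted to CIGARs using M/I/D/S with an MD
tag, which is what the random generator below produces.
"""

from __future__ import annotations

import numpy as np

#: a column is (kind, read_offset) with kind in clip/match/mismatch/ins/del;
#: deletion columns do not advance the read offset.
Column = tuple[str, int]


def _parse_cigar_simple(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    assert num == ""
    return ops


def _md_symbols(md: str) -> list[str]:
    """One symbol per aligned reference base: 'm', 'x', or 'd'."""
    out: list[str] = []
    i = 0
    while i < len(md):
        ch = md[i]
        if ch.isdigit():
            j = i
            while j < len(md) and md[j].isdigit():
                j += 1
            out.extend("m" * int(md[i:j]))
            i = j
        elif ch == "^":
            i += 1
            while i < len(md) and md[i].isalpha():
                out.append("d")
                i += 1
        else:
            out.append("x")
            i += 1
    return out


def expand_columns(cigar: str, md: str) -> list[Column]:
    cols: list[Column] = []
    aligned = iter(_md_symbols(md))
    read_off = 0
    for op, n in _parse_cigar_simple(cigar):
        if op == "S":
            for _ in range(n):
                cols.append(("clip", read_off))
                read_off += 1
        elif op == "M":
            for _ in range(n):
                sym = next(aligned)
                assert sym in ("m", "x"), "MD deletion inside M run"
                cols.append(("match" if sym == "m" else "mismatch", read_off))
                read_off += 1
        elif op == "I":
            for _ in range(n):
                cols.append(("ins", read_off))
                read_off += 1
        elif op == "D":
            for _ in range(n):
                sym = next(aligned)
                assert sym == "d", "CIGAR deletion without MD ^"
                cols.append(("del", read_off))
        else:
            raise AssertionError(f"oracle does not handle op {op}")
    assert next(aligned, None) is None, "MD longer than CIGAR"
    return cols


def bf_counts(cols: list[Column]) -> tuple[int, int, int]:
    kinds = [k for k, _ in cols]
    return kinds.count("ins"), kinds.count("del"), kinds.count("mismatch")


def bf_softclips(cols: list[Column]) -> tuple[int, int]:
    left = 0
    for k, _ in cols:
        if k == "clip":
            left += 1
        else:
            break
    right = 0
    for k, _ in reversed(cols):
        if k == "clip":
            right += 1
        else:
            break
    if left == len(cols):
        right = 0
    return left, right


def bf_longest_run(cols: list[Column], kind: str, allow_one_match: bool) -> int:
    kinds = [k for k, _ in cols]
    best = cur = 0
    for i, k in enumerate(kinds):
        if k == kind:
            cur += 1
            best = max(best, cur)
        elif (
            allow_one_match
            and k == "match"
            and cur > 0
            and i + 1 < len(kinds)
            and kinds[i + 1] == kind
            and kinds[i - 1] == kind
        ):
            continue
        else:
            cur = 0
    return best


def bf_bin_tops(
    cols: list[Column], seq_len: int, bin_size: int = 100, k: int = 4
) -> list[int]:
    n_bins = max(1, -(-seq_len // bin_size))
    bins = [0] * n_bins
    for kind, off in cols:
        if kind in ("ins", "mismatch", "del"):
            bins[min(off // bin_size, n_bins - 1)] += 1
    tops = sorted(bins, reverse=True)[:k]
    return tops + [0] * (k - len(tops))


_BASES = "ACGT"


def random_cigar_md(rng: np.random.Generator, min_len: int = 100, max_len: int = 1200):
    """A random valid (cigar, md, seq_len) triple built base by base."""
    n = int(rng.integers(min_len, max_len))
    plan: list[str] = []
    clip_l = int(rng.integers(0, 100)) if rng.random() < 0.5 else 0
    clip_r = int(rng.integers(0, 100)) if rng.random() < 0.5 else 0
    plan.extend("s" * clip_l)
    body = 0
    plan.append("m")  # alignments must start with an aligned base after clips
    body += 1
    while body < n:
        r = rng.random()
        if r < 0.04:
            run = int(rng.integers(1, 8))
            plan.extend("i" * run)
            body += run
        elif r < 0.08:
            run = int(rng.integers(1, 10))
            plan.extend("d" * run)
        elif r < 0.10:
            # deliberately exercise the one-match-gap join
            run = int(rng.integers(1, 5))
            plan.extend("d" * run + "m" + "d" * run)
            body += 1
        elif r < 0.14:
            plan.append("x")
            body += 1
        else:
            run = int(rng.integers(1, 60))
            plan.extend("m" * run)
            body += run
    if plan[-1] in ("i", "d"):
        plan.append("m")
    plan.extend("s" * clip_r)

    cigar_parts: list[str] = []
    md_parts: list[str] = []
    match_count = 0
    op_map = {"m": "M", "x": "M", "i": "I", "d": "D", "s": "S"}
    prev_op = None
    run = 0
    for sym in plan + ["$"]:
        op = op_map.get(sym)
        if op == prev_op:
            run += 1
        else:
            if prev_op is not None:
                cigar_parts.append(f"{run}{prev_op}")
            prev_op, run = op, 1
    i = 0
    while i < len(plan):
        sym = plan[i]
        if sym == "m":
            match_count += 1
        elif sym == "x":
            md_parts.append(str(match_count))
            md_parts.append(_BASES[int(rng.integers(0, 4))])
            match_count = 0
        elif sym == "d":
            md_parts.append(str(match_count))
            match_count = 0
            dseq = ""
            while i < len(plan) and plan[i] == "d":
                dseq += _BASES[int(rng.integers(0, 4))]
                i += 1
            md_parts.append("^" + dseq)
            continue
        i += 1
    md_parts.append(str(match_count))
    seq_len = sum(1 for s in plan if s in "mxis")
    return "".join(cigar_parts), "".join(md_parts), seq_len
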