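"""Extract the 21 alignment features that flag SV-informative reads.

Builds two alignment records by hand — one clean, one with the noisy
signature of a read spanning a deletion breakpoint — and prints their
feature vectors.
"""

from svpipe import AlignmentRecord, FEATURE_NAMES, extract_features

clean = AlignmentRecord(
    "clean_read",
    cigar="8000M",
    tags={"MD": "8000", "s1": 7600, "s2": 120, "cm": 440, "NM": 0, "AS": 7900},
)

# 900 bp soft-clip on the left plus a 180 bp deletion run: the classic look
# of an unsplit read crossing a deletion
noisy = AlignmentRecord(
    "breakpoint_read",
    cigar="900S3000M180D4100M",
    tags={"MD": "3000^" + "A" * 180 + "4100", "s1": 6400, "s2": 800, "cm": 380,
          "NM": 180, "AS": 6100},
)

for rec in (clean, noisy):
    fv = extract_features([rec])
    print(f"\n{rec.read_name}:")
    for name in ("softclip_left", "longest_del_run", "del_bases", "bin_top1",
                 "read_length"):
        print(f"  {name:18s} {fv[name]:10.0f}")

print(
    "\nThe noisy read's large soft clip and long deletion run are exactly the "
    "signals the informative-read classifier keys on; the clean read shows "
    "zeros everywhere except its length."
)
print(f"(each vector has {len(FEATURE_NAMES)} ordered features)")
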