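"""Lysine-centered windows and 40%-identity redundancy filtering.

Extracts 41-residue peptide windows around lysines (dummy code X pads the
termini), then shows the greedy de-redundancy pass dropping a window that
is more than 40% identical to one already kept.
"""

from topoptm import (
    PeptideWindow,
    SampleSet,
    extract_window,
    pairwise_identity,
    redundancy_filter,
)

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
positions = [i + 1 for i, ch in enumerate(seq) if ch == "K"]
print(f"lysines at positions {positions}\n")

windows = [extract_window(seq, p, "demo") for p in positions]
for w in windows:
    print(f"K{w.center:<3} {w.peptide}")

print("\npairwise identities over the 41 aligned positions:")
for i, a in enumerate(windows):
    for b in windows[i + 1:]:
        print(f"  K{a.center} vs K{b.center}: {pairwise_identity(a, b):.3f}")

# two nearly identical windows: the second is dropped at the 40% threshold
near_dup = PeptideWindow(
    "demo2", windows[0].center, windows[0].peptide[:41], "unlabeled"
)
pool = SampleSet(tuple(windows) + (near_dup,))
kept = redundancy_filter(pool, threshold=0.40)
print(f"\n{len(pool)} windows before filtering, {len(kept)} after:")
for w in kept.windows:
    print(f"  kept {w.protein_id} K{w.center}")
print("the duplicate of the first window was removed (identity 1.0 > 0.40)")
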