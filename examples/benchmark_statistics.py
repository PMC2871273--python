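"""Recompute the headline directionality statistics from the packaged tables.

Loads the two benchmark sets (34 proteins with positive previous-contact
ALR, 34 with negative), counts per-protein wins of the forward sequential
algorithm over its reverse, runs the exact sign test, and prints the
summary statistics the tables support.
"""

from cotransfold.tables import (
    directionality_headline,
    extreme_differences,
    load_pooled,
    load_results,
    pairwise_counts,
    summary_stats,
)

for label in ("positive", "negative"):
    table = load_results(label)
    s = pairwise_counts(table, "mean", "saint", "reverse")
    print(f"{label} set, mean GDT_TS: forward wins {s.wins_a}, "
          f"reverse wins {s.wins_b}, ties {s.ties} "
          f"(sign test p = {s.p_value:.2e} {s.stars})")

print(f"\ndirectionality headline: forward beats reverse for "
      f"{directionality_headline()}% of all 68 proteins")

pos, neg = summary_stats(load_results("positive")), summary_stats(load_results("negative"))
print(f"mean-of-means GDT_TS, positive set: sequential {pos['saint']['mean_of_means']}, "
      f"non-sequential {pos['rosetta']['mean_of_means']}")
print(f"mean-of-means GDT_TS, negative set: sequential {neg['saint']['mean_of_means']}, "
      f"non-sequential {neg['rosetta']['mean_of_means']}")
print(f"satisfactory best models (max GDT_TS >= 30), positive set: "
      f"sequential {pos['saint']['satisfactory']}, "
      f"non-sequential {pos['rosetta']['satisfactory']}")

code, diff = extreme_differences(load_pooled(), "saint", "reverse", "mean")
print(f"largest forward-vs-reverse mean gap: {diff:+.2f} GDT_TS points ({code})")
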