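"""Method-agreement statistics on the bundled reference cohorts.

Loads the 30-subject chest-belt vs accelerometer respiration counts shipped
with the package and reports the statistics conventionally used for method
agreement: Pearson r, the Wilcoxon rank-sum test (midranks, tie-corrected,
continuity-corrected), and Bland-Altman bias with 95% limits of agreement.
"""

from accelresp import bland_altman, pearson_r, rank_sum
from accelresp.datasets import load_belt_accel, load_phone, load_placement

for name, cmp_ in (
    ("chest belt vs accelerometer (n=30)", load_belt_accel()),
    ("shoulder vs foot placement (n=10)", load_placement()),
    ("phone model 1 vs model 2 (n=10)", load_phone()),
):
    r = pearson_r(cmp_.rr_a, cmp_.rr_b)
    rs = rank_sum(cmp_.rr_a, cmp_.rr_b)
    ba = bland_altman(cmp_)
    print(name)
    print(f"  Pearson r = {r:.2f}")
    print(f"  rank-sum  W = {rs.W:g}, z = {rs.z:.2f}, p = {rs.p:.2f}")
    print(
        f"  Bland-Altman bias = {ba.mean_diff:.2f} breaths/min, "
        f"95% LoA [{ba.loa_lo:.2f}, {ba.loa_hi:.2f}]"
    )
# p > 0.05 means no detectable systematic difference between the two
# measurements; the LoA give the expected per-subject disagreement range.
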