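"""Scale encodings and one subject's pre/post difference scores.

Builds the examination battery of a strongly improving subject (logMAR
1.00 -> 0.10, interocular rivalry gap 4 -> 1 levels, horizontal PEP
1.2 -> 0.64 degrees, stereo 400" -> 200") and prints the four difference
scores that enter the composite index.
"""

from visioncouple import (
    ExamRecord,
    brbp_level_to_proportions,
    compute_difference_vector,
    decimal_to_logmar,
    encode_stereoacuity,
)

print("decimal 0.1 acuity ->", decimal_to_logmar(0.1), "logMAR")
print("BRBP level 8 -> signal/noise", brbp_level_to_proportions(8))
print("stereo 200 arcsec -> level", encode_stereoacuity(200).level)

pre = ExamRecord.from_raw(
    "S1", "pre", va_logmar=1.00, brbp_right=8, brbp_left=4, pep_h=1.2, stereo_level=1
)
post = ExamRecord.from_raw(
    "S1", "post", va_logmar=0.10, brbp_right=8, brbp_left=7, pep_h=0.64, stereo_level=3
)
d = compute_difference_vector(pre, post)
print(f"\ndifference scores (post - pre) for {d.subject_id}:")
print(f"  visual acuity   {d.d_va:+.2f} logMAR   (negative = clearer vision)")
print(f"  BRBP gap        {d.d_brbp:+d} levels    (negative = more balanced eyes)")
print(f"  horizontal PEP  {d.d_hpep:+.2f} deg      (negative = better eye-position control)")
print(f"  stereoacuity    {d.d_sa:+d} levels    (positive = finer depth discrimination)")
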