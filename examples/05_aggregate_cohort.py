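"""Aggregating profiles across a cohort aligned at an anchor position.

A synthetic cohort of 20 two-kilobase "genes" aligned at a nominal
transcription start site: half carry a (CG)12 insert 100 bp upstream.  At
transcription-scale stress the positional mean profile shows the upstream
peak, and the per-sequence Z-region caller (p > 80%) counts exactly the
carriers in the upstream window.
"""

from sibz import aggregate_profiles, make_context, profile_sequence
from sibz.fixtures import tss_cohort

cohort, anchor = tss_cohort(n_sequences=20, length=2000, anchor=1000,
                            insert="CG" * 12, offset=-100, seed=3)
profiles = []
for fx in cohort:
    ctx = make_context(fx.sequence, circular=False)
    prof, _ = profile_sequence(ctx, sigma=-0.07)
    profiles.append(prof)

res = aggregate_profiles(profiles, anchor, level=0.8,
                         windows=[(-1000, -1), (1, 1000)])
peak = res.mean_p.argmax()
print(f"cohort of {len(profiles)} sequences, anchor at position {anchor + 1}")
print(f"mean-profile peak at position {peak + 1} "
      f"(mean p = {res.mean_p[peak]:.3f})")
for (lo, hi), n in res.window_counts.items():
    side = "upstream" if hi < 0 else "downstream"
    print(f"window {lo}..{hi} ({side}): {n}/{len(profiles)} sequences with "
          "a Z-forming region call")
print("only the 10 insert carriers are called, all upstream of the anchor")
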