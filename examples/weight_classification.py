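"""Weight analysis of the packaged path-level counts: which predictors are
consistently significant?"""

from metaweight import group_paths, records_from_counts, weight_table

corpus = records_from_counts()
table = weight_table(group_paths(corpus, min_examinations=3))

print(f"{len(table)} paths examined 3+ times\n")
print("Predictors of behavioral intention (top weights):")
bi = [w for w in table if w.outcome == "behavioral intention"]
for w in sorted(bi, key=lambda w: -w.W)[:8]:
    print(
        f"  {w.predictor:24s} S/E={w.S:2d}/{w.E:2d}  "
        f"W={w.W:.3f}  {w.classification}"
    )

print(
    "\nW = S/E is the fraction of examinations finding significance."
    "\n'best' needs W >= 0.800 over >= 5 examinations; a perfect W on"
    "\nfewer than 5 examinations is only 'promising'."
)
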