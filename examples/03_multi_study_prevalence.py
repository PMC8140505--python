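"""Equally-weighted prevalence across simulated amplicon studies.

Simulates three surveys of different sizes with known per-study presence
probabilities, then computes per-study FO/RA, equally-weighted averages,
dominant/common classification and a study accumulation curve. Because
each study gets equal weight, the 600-sample study does not swamp the
60-sample one.
"""

import polytax as pt

design = pt.CommunityDesign(
    n_studies=3,
    samples_per_study=(600, 200, 60),
    taxon_pool=("Faecalibacterium", "Bacteroides", "Akkermansia", "RareTaxon"),
    presence_prob=(
        (0.95, 0.90, 0.40, 0.02),
        (0.90, 0.85, 0.20, 0.00),
        (0.99, 0.80, 0.35, 0.05),
    ),
    seed=11,
)
tables = pt.make_otu_tables(design)
summaries = [pt.study_summary(t) for t in tables]
prevalences = pt.equally_weighted(summaries)
classes = pt.classify_taxa(prevalences)

print(f"{'taxon':<18}{'ew RA':>10}{'ew FO':>9}  class")
for p in prevalences:
    tags = [c for c in ("dominant", "common") if p.taxon in classes[c]]
    print(f"{p.taxon:<18}{p.ew_ra:>10.4f}{p.ew_fo:>8.1f}%  {'+'.join(tags) or '-'}")

curve = pt.accumulation_curve(summaries, n_perm=100, seed=1)
print("\naccumulation curve (mean distinct taxa after k studies):")
for _, row in curve.iterrows():
    print(f"  k={int(row['k'])}: {row['mean']:.2f} +/- {row['sd']:.2f}")
print("\new FO tracks the mean presence probability of the design; the")
print("curve flattening means additional studies add few new taxa.")
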