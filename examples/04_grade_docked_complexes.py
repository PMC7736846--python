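"""Score and grade the packaged docked-complex table.

Applies the seven-parameter weight map to the 68 packaged mutant
complexes, computes each docking category's mean total score, grades
every complex against its category mean, and counts the distinct
more-disrupting variants per (mutated gene, wild-type partner) pair.
"""

from slitrobo import disruptor_count_matrix, grade_all, load_docking_fixture

complexes = load_docking_fixture()
summaries = grade_all(complexes)
for summary in summaries.values():
    print(f"{summary.category}: n={summary.n_complexes} "
          f"mean TS={summary.mean_total_score:.3f} "
          f"-> {summary.n_more} more / {summary.n_less} less disrupting")

print("high-disruptor counts (distinct variants, aliases merged):")
for (gene, partner), n in disruptor_count_matrix(complexes).items():
    print(f"  {gene} mutants vs {partner}(WT): {n}")
# A complex whose total score (0-14) exceeds its category mean is graded
# more disrupting than the average mutation of that docking pairing; the
# wild-type:wild-type reference sits at 0.
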