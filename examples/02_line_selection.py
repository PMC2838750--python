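"""Select hyper-dispersed lines for expression profiling.

Ranks lines by male and female relative fitness and picks five
high-male/low-female, five low-male/high-female and five average lines,
after excluding the noisiest quartile of lines (replicate SE).
"""

from antagene import FitnessSimConfig, simulate_fitness_study
from antagene.fitness import relative_fitness_from_values, select_lines

assays, _ = simulate_fitness_study(FitnessSimConfig(seed=0))
relfit = relative_fitness_from_values(assays)
sel = select_lines(relfit)

print("high-male / low-female:", ", ".join(sel.high_m_low_f))
print("low-male / high-female:", ", ".join(sel.low_m_high_f))
print("average:               ", ", ".join(sel.average))

ranks = sel.ranks.set_index("line")
for group, lines in [("high_m_low_f", sel.high_m_low_f),
                     ("low_m_high_f", sel.low_m_high_f)]:
    sub = ranks.loc[lines]
    print(f"{group}: mean rank_m {sub['rank_m'].mean():.1f}, "
          f"mean rank_f {sub['rank_f'].mean():.1f}")

# The two extreme groups sit at opposite corners of the male/female rank
# plane; the antagonism score is rank_m - rank_f.
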