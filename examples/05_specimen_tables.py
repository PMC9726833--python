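"""Specimen-level trait handling and the simple frequentist comparisons.

Builds specimen records, aggregates them to species (presence is the union
over specimens, length the mean of specimen means, shape the modal
category), combines diet guilds, and runs the Mann-Whitney and chi-square
tests used for sex and regional comparisons.
"""

from bristlephylo import traitdata as td

# two specimens of one species: one bristled female, one unbristled male
recs = [
    td.SpecimenRecord("Podargus strigoides", sex="female", upper_rictal=True,
                      lorial=True, interramal=True,
                      lengths_left=(21.0, 23.5), lengths_right=(22.0,),
                      shape="Branched"),
    td.SpecimenRecord("Podargus strigoides", sex="male"),
]
sp = td.species_aggregate(recs)
print(f"{sp.species}: rictal={sp.rictal} length={sp.mean_length:.2f} mm "
      f"shape={sp.shape}")

# combined foraging guilds use an en dash, at most two components
print("guild:", td.combine_guilds("Invertivore", "Vertivore"))

# sex comparison of bristle lengths (Mann-Whitney, asymptotic)
females = [21.5, 19.0, 24.2, 22.8, 20.1]
males = [20.9, 18.5, 23.0, 21.2, 19.8]
r = td.mann_whitney(females, males)
print(f"Mann-Whitney W = {r.statistic:.1f}, p = {r.p_value:.3f}")

# regional presence/absence contingency (chi-square without correction)
r = td.chi_square([[14, 6], [11, 9]])
print(f"chi-square = {r.statistic:.3f}, df = {r.df}, p = {r.p_value:.3f}")
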