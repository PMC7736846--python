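"""Detect a planted structural perturbation in a toy mutant model.

Builds a wild-type/mutant pair of helical peptide dimers in which the only
difference is a broken backbone hydrogen bond at residue A:6, then runs
the geometric comparison the structure stage uses.
"""

from slitrobo import SimulationConfig, compare_wt_mut, generate_toy_complex

config = SimulationConfig(seed=1)
for planted in ("none", "remove_hbond", "add_clash", "bury_site"):
    wt, mut, truth = generate_toy_complex(config, planted)
    outcome = compare_wt_mut(wt, mut, truth["site"], n_points=320)
    print(f"planted={planted:12s} -> hbond_changed={outcome.hbond_changed} "
          f"clash_changed={outcome.clash_changed} "
          f"asa_shift={outcome.asa_shift.value}")
# Each flag feeds one point of the structure-stage score: a changed
# hydrogen-bond pattern, a changed steric-clash set, or a shift of the
# residue's solvent-accessibility orbit.
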