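"""Compute the extraction-target m/z values used throughout the workflow.

Budesonide (BUD) and the internal standard triamcinolone acetonide (TA)
are detected as Girard-P hydrazone cations: the reagent's hydrazide
condenses with the steroid's ketone, losing one water, and the product
keeps the pyridinium charge.  Heme B marks tissue, tiotropium marks the
deposited calibration spots, and protonated ferulic acid (the matrix) is
the lock mass.
"""

from msiquant import (
    DerivativeSpec,
    GirardReagent,
    IonSpec,
    IonType,
    builtin_targets,
    derivative_mz,
    girard_mass_shift,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)

bud = parse_formula("C25H34O6")
print(f"budesonide neutral monoisotopic mass : {monoisotopic_mass(bud):10.5f} Da")
print(f"Girard-P hydrazone mass shift        : {girard_mass_shift(GirardReagent.GirP):10.5f} Da")
print(f"BUD-GirP cation m/z                  : {derivative_mz(DerivativeSpec(bud)):10.4f}")

ta = parse_formula("C24H31FO6")
print(f"TA-GirP cation m/z (internal std)    : {derivative_mz(DerivativeSpec(ta)):10.4f}")

tio = ion_mz(IonSpec(parse_formula("C19H22NO4S2"), 1, IonType.PRECHARGED))
heme = ion_mz(IonSpec(parse_formula("C34H32FeN4O4"), 1, IonType.RADICAL))
fa = ion_mz(IonSpec(parse_formula("C10H10O4"), 1, IonType.PROTONATED))
print(f"tiotropium cation m/z (spot marker)  : {tio:10.4f}")
print(f"heme B radical cation m/z (tissue)   : {heme:10.4f}")
print(f"ferulic acid [M+H]+ m/z (lock mass)  : {fa:10.4f}")

print("\nbuilt-in target table:")
for t in builtin_targets().values():
    print(f"  {t.name:11s} {t.mz:9.4f}  {t.role}")
print(
    "\nEach value is computed from elemental composition with electron-mass"
    "\ncorrection; ion images are extracted in a +/-0.005 Da window around them."
)
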