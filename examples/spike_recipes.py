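"""Spiking arithmetic for the control homogenates and calibration spots.

A surfactant-budesonide formulation is prepared by mixing a budesonide
solution into poractant alfa; homogenized lung tissue is then spiked
with the formulation at a known w/w fraction (unit density assumed).
"""

from msiquant import spike_arithmetic

high = spike_arithmetic(
    volume_a_ul=285, conc_a_mg_per_ml=0.25, volume_b_ul=714, spike_fraction_ww=0.20
)
low = spike_arithmetic(285, 0.25, 714, 0.10)
print(f"20% w/w surfBUD spike -> {high:.2f} ug/g budesonide in tissue")
print(f"10% w/w surfBUD spike -> {low:.2f} ug/g budesonide in tissue")

amount = 5.0 * 0.5  # 5 ng/uL standard, 500 nL drop
print(f"control spot: 5 ng/uL x 0.5 uL = {amount:.1f} ng deposited")
print(
    "\nThese are the reference concentrations against which the imaging"
    "\nworkflow's back-calculated values are judged."
)
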