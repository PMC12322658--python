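"""Plate-reader corrections and light-unit conversion.

Shows the two autofluorescence corrections applied to raw plate-reader
wells (per-OD expression and total signal) and converts the blue-light
photon doses used in this system to irradiance.
"""

from optoferm import (
    PlateReading,
    normalized_fluorescence_per_od,
    photon_flux_to_irradiance,
    total_fluorescence,
)

strain = PlateReading(fluorescence=1000.0, od=2.0, role="strain")
media = PlateReading(fluorescence=100.0, od=0.1, role="media_blank")
control = PlateReading(fluorescence=300.0, od=2.0, role="no_fluor_control")

per_od = normalized_fluorescence_per_od(strain, media, control)
total = total_fluorescence(strain.fluorescence, control.fluorescence)
print(f"fluorescence/OD (media- and autofluorescence-corrected): {per_od:.2f} a.u./OD")
print(f"total fluorescence (wild-type control subtracted):       {total:.0f} a.u.")

print("\nPhoton flux -> irradiance at the 462 nm panel wavelength:")
for flux in (5.0, 10.0, 30.0, 50.0, 70.0):
    w = photon_flux_to_irradiance(flux, 462.0)
    print(f"  {flux:5.0f} umol m-2 s-1  =  {w:5.1f} W/m2")
print("The 5-70 umol m-2 s-1 design spans roughly 1.3-18 W/m2.")
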