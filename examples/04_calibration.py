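"""AD-scale conventions: 12-bit quantization and Newton calibration.

The acquisition chain digitizes 0–3.3 V at 12 bits onto [0, 1]; force
AD values convert to Newtons by F = 1985.6·ad − 75.066. The conversion
is unclamped, so an idle force channel reads slightly negative.
"""

from earforce import calibrate_force, quantize_ad

print("voltage -> AD value:")
for v in (0.0, 1.65, 3.3):
    print(f"  {v:4.2f} V -> {quantize_ad(v):.4f}")

print("\nforce AD value -> Newtons:")
for ad in (0.0448, 0.0614, 0.4411, 0.6004):
    print(f"  {ad:.4f} -> {calibrate_force(ad):8.2f} N (~{round(calibrate_force(ad))} N)")

print(
    "\n0.6004 AD is a hard (>1000 N) bite on the second molar; 0.0448 AD "
    "is barely above the light-contact baseline. The zero crossing sits "
    f"at ad = {75.066 / 1985.6:.4f}."
)
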